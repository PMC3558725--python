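"""Matched synthetic pathways and empirical enrichment p-values."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemegxe import (
    MatchingInfeasibleError,
    build_matched_pathway,
    build_synthetic_pathway_set,
    count_below_threshold,
    empirical_enrichment_p,
    load_pathway,
    pathway_enrichment_analysis,
    snp_count_window,
)
from hemegxe.pathway import PathwayDefinition
from hemegxe.simulate import GeneAnnotation


class TestLoadPathway:
    def test_bundled_iron_pathway_shape(self, heme_template):
        assert heme_template.n_genes == 29
        assert len(heme_template.all_snps) == 316
        counts = heme_template.snp_counts
        assert min(counts) == 1 and max(counts) == 37

    def test_duplicate_rows_collapsed_with_warning(self, caplog, tmp_path):
        f = tmp_path / "pw.tsv"
        f.write_text("gene_id\tsnp_id\nG1\trs1\nG1\trs1\nG1\trs2\n")
        with caplog.at_level("WARNING"):
            pw = load_pathway(f)
        assert pw.gene_to_snps == {"G1": ["rs1", "rs2"]}
        assert any("duplicate" in r.message for r in caplog.records)

    def test_single_row_file(self, tmp_path):
        f = tmp_path / "pw.tsv"
        f.write_text("gene_id\tsnp_id\nG1\trs1\n")
        pw = load_pathway(f)
        assert pw.n_genes == 1 and pw.all_snps == {"rs1"}

    def test_empty_and_malformed_rejected(self, tmp_path):
        empty = tmp_path / "e.tsv"
        empty.write_text("gene_id\tsnp_id\n")
        with pytest.raises(ValueError):
            load_pathway(empty)
        bad = tmp_path / "b.tsv"
        bad.write_text("foo\tbar\nG1\trs1\n")
        with pytest.raises(ValueError, match="columns"):
            load_pathway(bad)


class TestCountWindow:
    def test_ten_percent_window_around_ten(self):
        assert snp_count_window(10, 0.10) == (9, 11)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_small_genes_require_exact_match(self, k):
        assert snp_count_window(k, 0.10) == (k, k)

    @given(st.integers(1, 500), st.floats(0.0, 0.5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_window_always_contains_template_count(self, k, tol):
        lo, hi = snp_count_window(k, tol)
        assert lo <= k <= hi


class TestMatching:
    def test_synthetic_set_satisfies_all_constraints(self, heme_template, platform):
        annotation, _ = platform
        syn = build_synthetic_pathway_set(
            annotation, heme_template, n=50, tolerance=0.10, seed=1
        )
        template_counts = heme_template.snp_counts
        template_snps = heme_template.all_snps
        for pw in syn.pathways:
            assert pw.n_genes == heme_template.n_genes
            counts = pw.snp_counts
            for got, k in zip(counts, template_counts):
                lo, hi = snp_count_window(k, 0.10)
                assert lo <= got <= hi
            assert not pw.all_snps & template_snps
            assert len(pw.gene_to_snps) == len(set(pw.gene_to_snps))

    def test_fixed_seed_reproduces_pathway_set(self, heme_template, platform):
        annotation, _ = platform
        a = build_synthetic_pathway_set(annotation, heme_template, n=10, seed=7)
        b = build_synthetic_pathway_set(annotation, heme_template, n=10, seed=7)
        assert [p.gene_to_snps for p in a.pathways] == [
            p.gene_to_snps for p in b.pathways
        ]

    def test_matching_infeasible_when_only_template_genes_exist(self, rng):
        template = PathwayDefinition("t", {"G1": ["rs1", "rs2"], "G2": ["rs3"]})
        ann = GeneAnnotation(
            gene_ids=["G1", "G2"],
            gene_to_snps={"G1": ["rs1", "rs2"], "G2": ["rs3"]},
        )
        with pytest.raises(MatchingInfeasibleError, match="G1|G2"):
            build_matched_pathway(ann, template, {"rs1", "rs2", "rs3"}, 0.10, rng)

    def test_excluded_snps_never_drawn(self, rng):
        template = PathwayDefinition("t", {"T1": ["rsA", "rsB"]})
        ann = GeneAnnotation(
            gene_ids=["T1", "X1", "X2"],
            gene_to_snps={
                "T1": ["rsA", "rsB"],
                "X1": ["rsA", "rs9"],  # overlaps excluded -> ineligible
                "X2": ["rs10", "rs11"],
            },
        )
        for _ in range(10):
            pw = build_matched_pathway(ann, template, {"rsA", "rsB"}, 0.10, rng)
            assert pw.gene_to_snps == {"X2": ["rs10", "rs11"]}


class TestCounting:
    def test_strict_threshold_counting(self):
        pvals = {"a": 0.04, "b": 0.06}
        assert count_below_threshold(pvals, {"a", "b"}, 0.05) == 1
        assert count_below_threshold(pvals, {"a", "b"}, 1.0) == 2
        assert count_below_threshold(pvals, set(), 0.05) == 0

    def test_missing_pvalues_dropped(self):
        pvals = {"a": 0.01, "b": math.nan}
        assert count_below_threshold(pvals, {"a", "b", "c"}, 0.05) == 1


class TestEmpiricalP:
    def test_boundary_values(self):
        c_syn = np.zeros(1000, dtype=int)
        p_strict, p_conv = empirical_enrichment_p(5, c_syn)
        assert p_strict == 1.0
        p_strict, p_conv = empirical_enrichment_p(0, c_syn)
        assert p_strict == 0.0 and p_conv == 1.0

    @given(
        st.integers(0, 20),
        st.lists(st.integers(0, 20), min_size=1, max_size=200),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strict_complement_partition(self, c_obs, c_syn):
        c_syn = np.array(c_syn)
        p_strict, _ = empirical_enrichment_p(c_obs, c_syn)
        frac_ge = (c_syn >= c_obs).sum() / c_syn.size
        assert p_strict + frac_ge == pytest.approx(1.0)

    def test_null_self_consistency(self, rng):
        """When the observed count is just another draw from the synthetic
        distribution, both estimators average to ~1/2 over repetitions."""
        means_paper, means_conv = [], []
        for _ in range(500):
            c_syn = rng.binomial(300, 0.3, size=1000)
            c_obs = int(rng.binomial(300, 0.3))
            pp, pc = empirical_enrichment_p(c_obs, c_syn)
            means_paper.append(pp)
            means_conv.append(pc)
        assert abs(np.mean(means_paper) - 0.5) < 0.05
        assert abs(np.mean(means_conv) - 0.5) < 0.05


def _results_frame(snps, p):
    return pd.DataFrame({"SNP": snps, "P_MARG": p, "P_1DF": p})


class TestEnrichmentAnalysis:
    def test_all_p_one_gives_zero_counts(self, heme_template, platform):
        annotation, _ = platform
        snps = sorted(annotation.all_snps | heme_template.all_snps)
        res = pathway_enrichment_analysis(
            _results_frame(snps, 1.0), heme_template, annotation,
            thresholds=(0.05,), n_syn=20, seed=0,
        )
        for e in res:
            assert e.c_obs == 0 and (e.c_syn == 0).all()
            assert e.empirical_p_strict == 0.0

    def test_constructed_enrichment_beats_every_synthetic(
        self, heme_template, platform, rng
    ):
        annotation, _ = platform
        bg = sorted(annotation.all_snps)
        obs = sorted(heme_template.all_snps)
        df = pd.concat(
            [
                _results_frame(obs, 1e-6),
                _results_frame(bg, rng.uniform(0.2, 1.0, len(bg))),
            ]
        )
        res = pathway_enrichment_analysis(
            df, heme_template, annotation, thresholds=(0.05,), n_syn=50, seed=2
        )
        for e in res:
            assert e.empirical_p_strict == 1.0
            assert e.empirical_p_conventional == pytest.approx(1 / 51)

    def test_enriching_template_never_decreases_strict_p(
        self, heme_template, platform, rng
    ):
        annotation, _ = platform
        snps = sorted(annotation.all_snps | heme_template.all_snps)
        p = rng.uniform(0, 1, len(snps))
        base = _results_frame(snps, p)
        better = base.copy()
        in_t = better["SNP"].isin(heme_template.all_snps)
        better.loc[in_t, ["P_MARG", "P_1DF"]] = (
            better.loc[in_t, ["P_MARG", "P_1DF"]] / 10
        )
        kw = dict(thresholds=(0.05, 0.01), n_syn=40, seed=4)
        r0 = pathway_enrichment_analysis(base, heme_template, annotation, **kw)
        r1 = pathway_enrichment_analysis(better, heme_template, annotation, **kw)
        for a, b in zip(r0, r1):
            assert b.empirical_p_strict >= a.empirical_p_strict
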