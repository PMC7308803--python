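"""Scoring: APOE diplotype table, weighted-sum correctness and invariances,
covariate adjustment, and gene-set interval mapping."""

import numpy as np
import pandas as pd
import pytest

from agestrat_prs.datatypes import SUMSTATS_COLUMNS
from agestrat_prs.score import (
    APOE_REGION,
    GeneSet,
    RegionSpec,
    ScoreConfig,
    adjust_and_standardize,
    call_apoe,
    call_apoe_panel,
    compute_prs,
    pathway_variants,
    resolve_gene_set,
)
from tests.conftest import make_panel


def sumstats_rows(rows):
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


class TestCallApoe:
    # all nine unphased rs429358 x rs7412 genotype combinations
    @pytest.mark.parametrize(
        "g1,g2,diplotype,e2,e4,amb",
        [
            ("TT", "CC", "e3/e3", 0, 0, False),
            ("TT", "CT", "e2/e3", 1, 0, False),
            ("TT", "TT", "e2/e2", 2, 0, False),
            ("CT", "CC", "e3/e4", 0, 1, False),
            ("CT", "CT", "e2/e4", 1, 1, True),
            ("CC", "CC", "e4/e4", 0, 2, False),
            # the remaining three imply the vanishingly rare ε1 haplotype
            ("CT", "TT", "ambiguous", 2, 1, True),
            ("CC", "CT", "ambiguous", 1, 2, True),
            ("CC", "TT", "ambiguous", 2, 2, True),
        ],
    )
    def test_mapping_table(self, g1, g2, diplotype, e2, e4, amb):
        call = call_apoe(g1, g2)
        assert call.diplotype == diplotype
        assert call.e2_dose == e2
        assert call.e4_dose == e4
        assert call.ambiguous is amb

    def test_dose_input_equivalent_to_strings(self):
        assert call_apoe(1, 0) == call_apoe("CT", "CC")
        assert call_apoe(2, 0) == call_apoe("CC", "CC")

    def test_missing_genotype_gives_missing_call(self):
        call = call_apoe(None, "CC")
        assert call.diplotype is None and call.e2_dose is None

    def test_unexpected_alleles_rejected_naming_variant(self):
        with pytest.raises(ValueError, match="rs429358"):
            call_apoe("AG", "CC")
        with pytest.raises(ValueError, match="rs7412"):
            call_apoe("TT", "AG")

    def test_panel_calls_match_haplotype_truth(self, apoe_panel):
        calls = call_apoe_panel(apoe_panel)
        cols = apoe_panel.sim_info["apoe_cols"]
        assert (calls["e4_dose"] == apoe_panel.dosages[:, cols[0]]).all()
        assert (calls["e2_dose"] == apoe_panel.dosages[:, cols[1]]).all()
        assert calls["diplotype"].notna().all()
        assert (calls["e2_dose"] + calls["e4_dose"] <= 2).all()


class TestComputePrs:
    def fixture_panel(self):
        # one sample with doses (2, 1, 0); betas (0.1, -0.2, 0.3) -> score 0
        return make_panel(np.array([[2.0, 1.0, 0.0]]), effect=["A", "A", "A"],
                          other=["G", "G", "G"])

    def fixture_ss(self, betas=(0.1, -0.2, 0.3), flip_second=False):
        rows = []
        for j, b in enumerate(betas):
            ea, oa = ("G", "A") if (flip_second and j == 1) else ("A", "G")
            rows.append([f"v{j + 1}", "1", 1 + j * 1000, ea, oa, b, 0.05, 0.01])
        return sumstats_rows(rows)

    def test_hand_computed_weighted_sum(self):
        result = compute_prs(self.fixture_panel(), self.fixture_ss(),
                             ["v1", "v2", "v3"], ScoreConfig(exclude_regions=()))
        assert result["raw_score"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert result["n_variants_used"].iloc[0] == 3

    def test_orientation_reconciliation(self):
        # sumstats count the other allele for v2: dose 1 -> 2 - 1 = 1, but the
        # beta now applies to the opposite allele so the score shifts by -2b
        res_flip = compute_prs(self.fixture_panel(), self.fixture_ss(flip_second=True),
                               ["v1", "v2", "v3"], ScoreConfig(exclude_regions=()))
        # manual: 0.1*2 + (-0.2)*(2-1) + 0.3*0 = 0.0
        assert res_flip["raw_score"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_allele_flip_invariance_of_scores(self, apoe_panel, cohort):
        *_, ss = cohort
        ids = apoe_panel.variants["id"].tolist()[:20]
        base = compute_prs(apoe_panel, ss, ids, ScoreConfig(exclude_regions=()))
        flipped = apoe_panel.subset_variants(np.arange(apoe_panel.n_variants) < 20)
        v = flipped.variants.copy()
        v.loc[3, ["effect_allele", "other_allele"]] = (
            v.loc[3, ["other_allele", "effect_allele"]].to_numpy())
        flipped.variants = v
        flipped.dosages[:, 3] = 2 - flipped.dosages[:, 3]
        alt = compute_prs(flipped, ss, ids, ScoreConfig(exclude_regions=()))
        np.testing.assert_allclose(base["raw_score"], alt["raw_score"], atol=1e-12)

    def test_p_threshold_filters_variants(self):
        ss = self.fixture_ss()
        ss.loc[2, "p"] = 0.9
        res = compute_prs(self.fixture_panel(), ss, ["v1", "v2", "v3"],
                          ScoreConfig(p_threshold=0.5, exclude_regions=()))
        assert res["n_variants_used"].iloc[0] == 2

    def test_exclude_whole_genome_gives_zero(self):
        res = compute_prs(self.fixture_panel(), self.fixture_ss(), ["v1", "v2", "v3"],
                          ScoreConfig(exclude_regions=(RegionSpec("1", 1, 10**9),)))
        assert (res["raw_score"] == 0).all()
        assert (res["n_variants_used"] == 0).all()

    def test_apoe_exclusion_noop_without_apoe_variants(self):
        with_excl = compute_prs(self.fixture_panel(), self.fixture_ss(),
                                ["v1", "v2", "v3"], ScoreConfig())
        without = compute_prs(self.fixture_panel(), self.fixture_ss(),
                              ["v1", "v2", "v3"], ScoreConfig(exclude_regions=()))
        np.testing.assert_array_equal(with_excl["raw_score"], without["raw_score"])

    def test_linearity_over_disjoint_sets(self, apoe_panel, cohort):
        *_, ss = cohort
        ids = apoe_panel.variants["id"].tolist()
        a, b = ids[:15], ids[15:40]
        cfg = ScoreConfig(p_threshold=1.0, exclude_regions=())
        s_all = compute_prs(apoe_panel, ss, a + b, cfg)["raw_score"]
        s_a = compute_prs(apoe_panel, ss, a, cfg)["raw_score"]
        s_b = compute_prs(apoe_panel, ss, b, cfg)["raw_score"]
        np.testing.assert_allclose(s_all, s_a + s_b, atol=1e-10)

    def test_mean_substitution_for_missing_dose(self):
        d = np.array([[0.0], [2.0], [1.0]])
        missing = np.array([[False], [False], [True]])
        panel = make_panel(d, missing=missing)
        ss = sumstats_rows([["v1", "1", 1, "A", "G", 0.5, 0.05, 0.01]])
        res = compute_prs(panel, ss, ["v1"], ScoreConfig(exclude_regions=()))
        assert res["raw_score"].iloc[2] == pytest.approx(0.5 * 1.0)  # mean of (0, 2)

    def test_mismatched_alleles_dropped_with_warning(self):
        ss = self.fixture_ss()
        ss.loc[1, ["effect_allele", "other_allele"]] = ["C", "T"]
        with pytest.warns(UserWarning, match="mismatch"):
            res = compute_prs(self.fixture_panel(), ss, ["v1", "v2", "v3"],
                              ScoreConfig(exclude_regions=()))
        assert res["n_variants_used"].iloc[0] == 2
        assert res.attrs["n_dropped_mismatch"] == 1

    def test_unknown_retained_variant_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            compute_prs(self.fixture_panel(), self.fixture_ss(), ["nope"], ScoreConfig())


class TestAdjustStandardize:
    def _raw(self, values):
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(values))],
                             "raw_score": values, "n_variants_used": 5})

    def test_intercept_only_reduces_to_zscore(self):
        rng = np.random.default_rng(1)
        y = rng.normal(3, 2, 200)
        out = adjust_and_standardize(self._raw(y), self._raw(y)[["sample_id"]], [])
        np.testing.assert_allclose(out["standardized_score"], (y - y.mean()) / y.std(),
                                   rtol=1e-6)

    def test_standardized_moments(self, apoe_panel, cohort, case_control_table):
        *_, ss = cohort
        raw = compute_prs(apoe_panel, ss, apoe_panel.variants["id"].tolist()[:30])
        out = adjust_and_standardize(raw, case_control_table, ["age", "sex", "pc1", "pc2"])
        assert abs(out["standardized_score"].mean()) < 1e-10
        assert abs(out["standardized_score"].std(ddof=0) - 1) < 1e-10

    def test_adjustment_removes_covariate_signal(self):
        rng = np.random.default_rng(2)
        covars = pd.DataFrame({"sample_id": [f"s{i}" for i in range(500)],
                               "age": rng.normal(70, 8, 500)})
        y = 0.3 * covars["age"].to_numpy() + rng.normal(size=500)
        out = adjust_and_standardize(self._raw(y), covars, ["age"])
        assert abs(np.corrcoef(out["adjusted_score"], covars["age"])[0, 1]) < 1e-10

    def test_exact_linear_function_flagged_degenerate(self):
        covars = pd.DataFrame({"sample_id": [f"s{i}" for i in range(50)],
                               "age": np.arange(50.0)})
        y = 2.0 * covars["age"].to_numpy() + 1.0
        with pytest.warns(UserWarning, match="SD below tolerance"):
            out = adjust_and_standardize(self._raw(y), covars, ["age"])
        assert out.attrs["degenerate_sd"]
        np.testing.assert_allclose(out["adjusted_score"], 0, atol=1e-8)

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(3)
        covars = pd.DataFrame({"sample_id": [f"s{i}" for i in range(100)],
                               "age": rng.normal(70, 5, 100)})
        covars["age_twice"] = 2 * covars["age"]
        with pytest.raises(ValueError, match="age_twice"):
            adjust_and_standardize(self._raw(rng.normal(size=100)), covars,
                                   ["age", "age_twice"])


class TestGeneSets:
    def _bed(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "19", "1"],
                "start": [100, 5_001, 44_900_000, 300],
                "end": [200, 10_000, 44_950_000, 400],
                "gene": ["G1", "G2", "RELB_LIKE", "G1"],
            }
        )

    def test_lookup_and_duplicate_union(self):
        gs = resolve_gene_set("demo", ["G1"], self._bed())
        assert len(gs.intervals) == 2  # both G1 rows retained
        assert gs.unresolved == []

    def test_absent_gene_reported_not_dropped(self):
        gs = resolve_gene_set("demo", ["G1", "MISSING"], self._bed())
        assert gs.unresolved == ["MISSING"]

    def test_empty_resolution_rejected(self):
        with pytest.raises(ValueError, match="no genes resolved"):
            resolve_gene_set("demo", ["NOPE"], self._bed())

    def test_interval_boundaries_inclusive(self):
        panel = make_panel(np.zeros((2, 3)) + 1, pos=[99, 100, 201],
                           ids=["below", "at_start", "past_end"])
        gs = GeneSet("demo", ["G1"], [("1", 100, 200)])
        assert pathway_variants(gs, panel) == ["at_start"]

    def test_pathway_score_with_whole_genome_equals_global(self, apoe_panel, cohort):
        *_, ss = cohort
        ids = apoe_panel.variants["id"].tolist()
        cfg_global = ScoreConfig(p_threshold=1.0, exclude_regions=())
        everything = GeneSet("all", ["g"], [("1", 1, 10**9), ("19", 1, 10**9)])
        cfg_path = ScoreConfig(p_threshold=1.0, exclude_regions=(),
                               include_regions=everything.include_regions())
        np.testing.assert_allclose(
            compute_prs(apoe_panel, ss, ids, cfg_global)["raw_score"],
            compute_prs(apoe_panel, ss, ids, cfg_path)["raw_score"],
        )

    def test_apoe_region_pathway_scored_when_exclusion_off(self, apoe_panel, cohort):
        # a pathway overlapping the APOE region: with region-exclusion off,
        # its variants (here the APOE SNPs themselves) contribute
        *_, ss = cohort
        gs = GeneSet("apoe_region", ["g"],
                     [(APOE_REGION.chrom, APOE_REGION.start_bp, APOE_REGION.end_bp)])
        ids = pathway_variants(gs, apoe_panel)
        assert set(ids) == {"rs429358", "rs7412"}
        res = compute_prs(apoe_panel, ss, ids,
                          ScoreConfig(p_threshold=1.0, exclude_regions=(),
                                      include_regions=gs.include_regions()))
        assert (res["n_variants_used"] == 2).all()
        res_excl = compute_prs(apoe_panel, ss, ids,
                               ScoreConfig(p_threshold=1.0,
                                           include_regions=gs.include_regions()))
        assert (res_excl["n_variants_used"] == 0).all()


class TestRegionSpec:
    def test_parse_and_contains(self):
        r = RegionSpec.parse("19:44400000-46500000")
        assert r == APOE_REGION
        assert r.contains(["19", "19", "1"], [44_400_000, 46_500_001, 45_000_000]).tolist() \
            == [True, False, False]

    def test_invalid_region_rejected(self):
        with pytest.raises(ValueError, match="start"):
            RegionSpec("1", 100, 50)
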