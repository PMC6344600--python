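import pytest

from eetscan.abundance import (
    compute_abundances, housekeeping_denominator, mag_fraction_with_eet,
    summarize_mags, summarize_metagenome, tidy_gene_table,
)
from eetscan.io_model import (
    CoverageTable, MAGAssignment, ValidationError, assign_ranks,
)


def features(*rows):
    return assign_ranks([(gid, contig, i * 1000, i * 1000 + 900, "+")
                         for i, (gid, contig) in enumerate(rows)])


class TestNormalization:
    def test_hand_computed_quotient(self, params):
        feats = features(("g", "cg"), ("h1", "ch1"), ("h2", "ch2"))
        cov = CoverageTable({"cg": 12.0, "ch1": 6.0, "ch2": 6.0})
        ab = compute_abundances(feats, cov, {"h1", "h2"}, params)
        assert ab["g"].value == 2.0
        assert ab["g"].denominator == 6.0

    def test_gene_matching_housekeeping_coverage_is_exactly_one(self, params):
        for c in (0.3, 7.0, 1234.5):
            feats = features(("g", "cg"), ("h1", "ch1"))
            cov = CoverageTable({"cg": c, "ch1": c})
            assert compute_abundances(feats, cov, {"h1"}, params)["g"].value == 1.0

    def test_global_rescaling_leaves_values_unchanged(self, params):
        feats = features(("g", "cg"), ("h1", "ch1"), ("h2", "ch2"))
        base = {"cg": 9.0, "ch1": 2.0, "ch2": 10.0}
        expected = compute_abundances(feats, CoverageTable(base), {"h1", "h2"}, params)
        for scale in (3.0, 0.1):
            scaled = CoverageTable({k: v * scale for k, v in base.items()})
            got = compute_abundances(feats, scaled, {"h1", "h2"}, params)
            assert got["g"].value == pytest.approx(expected["g"].value)

    def test_empty_housekeeping_set_rejected(self, params):
        feats = features(("g", "cg"))
        with pytest.raises(ValidationError, match="housekeeping"):
            compute_abundances(feats, CoverageTable({"cg": 1.0}), set(), params)

    def test_zero_denominator_rejected(self, params):
        feats = features(("g", "cg"), ("h1", "ch1"))
        cov = CoverageTable({"cg": 1.0, "ch1": 0.0})
        with pytest.raises(ValidationError, match="zero"):
            housekeeping_denominator({f.gene_id: f for f in feats}, cov, {"h1"}, params)

    def test_median_option(self, params):
        import copy

        p = copy.deepcopy(params)
        p["abundance"]["hk_stat"] = "median"
        feats = features(("g", "cg"), ("h1", "c1"), ("h2", "c2"), ("h3", "c3"))
        cov = CoverageTable({"cg": 4.0, "c1": 1.0, "c2": 2.0, "c3": 100.0})
        assert compute_abundances(feats, cov, {"h1", "h2", "h3"}, p)["g"].value == 2.0


class TestSummaries:
    def test_bin_sums_hand_case(self, params, refs):
        # two MHCs: 6 hemes at normalized 1.5, 12 hemes at normalized 0.5
        from eetscan.motif_scan import HemeScan, classify_mhc

        feats = features(("a", "ca"), ("b", "cb"), ("h", "ch"))
        cov = CoverageTable({"ca": 3.0, "cb": 1.0, "ch": 2.0})
        ab = compute_abundances(feats, cov, {"h"}, params)
        mhc_calls = {
            "a": classify_mhc(HemeScan("a", tuple(range(0, 36, 6))), params),
            "b": classify_mhc(HemeScan("b", tuple(range(0, 72, 6))), params),
        }
        tidy = tidy_gene_table(
            mhc_calls, [], ab, {f.gene_id: f for f in feats}, MAGAssignment()
        )
        summary = summarize_metagenome("m", tidy, mhc_calls, [], [])
        assert summary.mhc_all_5_10 == pytest.approx(1.5)
        assert summary.mhc_all_gt10 == pytest.approx(0.5)
        assert summary.mhc_eet_5_10 == 0.0 and summary.cyc2 == 0.0

    def test_empty_input_gives_all_zero_summary(self, params):
        import pandas as pd

        summary = summarize_metagenome("m", pd.DataFrame(), {}, [], [])
        assert all(
            v == 0 for k, v in summary.to_row().items() if k != "metagenome_id"
        )

    def test_mag_mean_and_membership(self, default_result, default_metagenome):
        result, truth = default_result
        data, _ = default_metagenome
        ms = result.mag_summary
        # every row with calls: mean equals direct average of member genes
        feats = data.feature_by_id()
        for _, row in ms.iterrows():
            members = [
                c for c in result.calls
                if data.mags.mag_of(feats[c.gene_id].contig_id) == row["mag_id"]
            ]
            if members:
                direct = sum(result.abundances[c.gene_id].value for c in members) / len(members)
                assert row["mean_normalized_abundance"] == pytest.approx(direct)
                assert row["n_eet_genes"] == len(members)
        # MAGs without EET calls are absent (except the reserved unbinned row)
        assert set(ms.loc[ms["n_eet_genes"] == 0, "mag_id"]) <= {"unbinned"}

    def test_unbinned_eet_genes_are_accounted(self, default_result):
        result, truth = default_result
        unbinned_truth = truth.genes[
            (truth.genes["mag_id"] == "unbinned")
            & truth.genes["kind"].isin(("pcc_known", "pcc_novel", "outer_surface", "cyc2"))
        ]
        row = result.mag_summary.set_index("mag_id").loc["unbinned"]
        called_unbinned = set(result.calls_df.loc[
            result.calls_df["mag_id"] == "unbinned", "gene_id"
        ])
        assert row["n_eet_genes"] == len(called_unbinned)
        assert set(unbinned_truth["gene_id"]) <= called_unbinned | {""}

    def test_metagenome_totals_are_additive_over_mags(self, default_result):
        result, _ = default_result
        per_mag = result.tidy.groupby(["series", "mag_id"])["value"].sum()
        totals = result.tidy.groupby("series")["value"].sum()
        for series, total in totals.items():
            assert per_mag.loc[series].sum() == pytest.approx(total)

    def test_fraction_of_mags_with_eet_matches_truth(self, default_result, default_metagenome):
        result, truth = default_result
        data, _ = default_metagenome
        eet_kinds = ("pcc_known", "pcc_novel", "outer_surface", "cell_wall", "cyc2")
        truth_mags = {
            m for m in truth.genes.loc[truth.genes["kind"].isin(eet_kinds), "mag_id"]
            if m != "unbinned"
        }
        expected = len(truth_mags) / len(data.mags.mags())
        assert mag_fraction_with_eet(result.mag_summary, data.mags) == pytest.approx(expected)
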