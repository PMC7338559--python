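import numpy as np
import pandas as pd
import pytest

from assemblyscape import (CommunityTable, apply_scenario, build_pair_table,
                           classify_pair, mean_fractions_over_groups,
                           pair_covariates, split_dataset, summarize_fractions)
from assemblyscape.classify import PROCESS_LABELS, ScenarioFilter
from tests.conftest import neutral_table


class TestClassifyPair:
    @pytest.mark.parametrize("bnti, rc, label", [
        (2.5, -0.99, "variable_selection"),     # selection branch wins first
        (-3.0, 0.99, "homogeneous_selection"),
        (-1.0, 0.99, "dispersal_limitation_drift"),
        (0.5, -0.99, "homogenizing_dispersal"),
        (1.0, 0.3, "undominated"),
        (2.0, 0.99, "dispersal_limitation_drift"),  # threshold tie -> stochastic
        (-2.0, -0.99, "homogenizing_dispersal"),
        (0.0, 0.95, "undominated"),                  # RC tie -> undominated
        (float("nan"), 0.5, "unclassified"),
    ])
    def test_decision_tree(self, bnti, rc, label):
        assert classify_pair(bnti, rc) == label

    def test_partition_of_the_plane(self):
        """Every finite (betaNTI, RC) point receives exactly one of the five labels."""
        rng = np.random.default_rng(0)
        bnti = rng.uniform(-6, 6, 10_000)
        rc = rng.uniform(-1, 1, 10_000)
        labels = {classify_pair(b, r) for b, r in zip(bnti, rc)}
        assert labels <= set(PROCESS_LABELS)
        for b, r in zip(bnti[:100], rc[:100]):
            assert classify_pair(b, r) in PROCESS_LABELS


class TestPairCovariates:
    def test_three_four_five(self, toy_frame):
        cov = pair_covariates(toy_frame)
        row = cov[(cov.sample_i == "s1") & (cov.sample_j == "s2")].iloc[0]
        assert row.spatial_dist == pytest.approx(5.0)
        assert row.temporal_dist == 0.0
        assert row.same_occasion

    def test_temporal_days(self, toy_frame):
        cov = pair_covariates(toy_frame)
        row = cov[(cov.sample_i == "s1") & (cov.sample_j == "s3")].iloc[0]
        assert row.temporal_dist == 180.0
        assert not row.same_occasion

    def test_env_differences(self, toy_frame):
        cov = pair_covariates(toy_frame)
        row = cov[(cov.sample_i == "s1") & (cov.sample_j == "s2")].iloc[0]
        assert row.env_diff_moisture == pytest.approx(0.3)


def _pairs_with_covariates(n=40, seed=5):
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append({"sample_i": ids[i], "sample_j": ids[j],
                         "bnti": rng.normal(), "rc_bray": rng.uniform(-1, 1),
                         "process": "undominated",
                         "spatial_dist": rng.uniform(0, 14),
                         "temporal_dist": rng.choice([0, 60, 120, 200]),
                         "same_occasion": False,
                         "env_diff_moisture": rng.uniform(0, 1)})
    pairs = pd.DataFrame(rows)
    pairs.loc[pairs.temporal_dist == 0, "same_occasion"] = True
    return pairs


class TestScenarios:
    def test_within_months_keeps_same_occasion_only(self):
        pairs = _pairs_with_covariates()
        out = apply_scenario(pairs, "within_months")
        assert (out.temporal_dist == 0).all()

    def test_near_late_excludes_far_pairs(self):
        pairs = _pairs_with_covariates()
        out = apply_scenario(pairs, "near_late")
        assert (out.spatial_dist < 2).all() and (out.temporal_dist > 150).all()
        # a 5 m pair can never appear
        assert not ((out.spatial_dist > 4.9) & (out.spatial_dist < 5.1)).any()

    def test_upper_quartile_filter_size(self):
        pairs = _pairs_with_covariates()
        filt = ScenarioFilter("uq_sm", env_quartile=("moisture", "UQ"))
        out = apply_scenario(pairs, filt)
        n = len(pairs)
        assert abs(len(out) - n / 4) <= max(2, 0.02 * n)  # boundary-inclusive

    def test_empty_scenario_warns(self):
        pairs = _pairs_with_covariates()
        with pytest.warns(UserWarning, match="matched no pairs"):
            out = apply_scenario(pairs, ScenarioFilter("none", min_spatial=99))
        assert out.empty


class TestSummaries:
    def test_all_undominated(self):
        pairs = pd.DataFrame({"sample_i": ["a", "a"], "sample_j": ["b", "c"],
                              "process": ["undominated"] * 2})
        frac = summarize_fractions(pairs)
        assert frac["undominated"].iloc[0] == 1.0
        total = sum(frac[lab].iloc[0] for lab in PROCESS_LABELS)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self):
        pairs = _pairs_with_covariates(n=12)
        rng = np.random.default_rng(1)
        pairs["process"] = rng.choice(PROCESS_LABELS, len(pairs))
        frac = summarize_fractions(pairs)
        assert sum(frac[lab].iloc[0] for lab in PROCESS_LABELS) == pytest.approx(1.0)

    def test_duplicate_pairs_rejected(self):
        pairs = pd.DataFrame({"sample_i": ["a", "b"], "sample_j": ["b", "a"],
                              "process": ["undominated"] * 2})
        with pytest.raises(ValueError, match="duplicate"):
            summarize_fractions(pairs)

    def test_group_mean_ci_hand_example(self):
        """Two groups at 0.4/0.6 -> mean 0.5, CI half-width 1.96*SE."""
        frac = pd.DataFrame({
            "group": ["g1", "g2"],
            **{lab: [0.0, 0.0] for lab in PROCESS_LABELS}})
        frac["undominated"] = [0.4, 0.6]
        out = mean_fractions_over_groups(frac)
        row = out[out.process == "undominated"].iloc[0]
        se = np.std([0.4, 0.6], ddof=1) / np.sqrt(2)
        assert row["mean"] == pytest.approx(0.5)
        assert row.ci_high - row["mean"] == pytest.approx(1.96 * se)


class TestSplitDataset:
    def test_by_occasion_partitions_samples(self, toy_table, toy_frame):
        parts = split_dataset(toy_table, "by_occasion", frame=toy_frame)
        ids = sorted(s for t in parts.values() for s in t.sample_ids)
        assert ids == sorted(toy_table.sample_ids)
        assert set(parts) == {"occasion_1", "occasion_2"}

    def test_by_taxon_group_threshold(self):
        table, _ = neutral_table(n_samples=4, n_otus=30, depth=200, seed=2)
        groups = pd.Series(["Acidobacteria"] * 20 + ["Firmicutes"] * 10,
                           index=table.otu_ids)
        parts = split_dataset(table, "by_taxon_group", otu_groups=groups,
                              min_otus=15)
        assert list(parts) == ["Acidobacteria"]
        assert parts["Acidobacteria"].n_otus == 20

    def test_rare_subsets_too_few_eligible(self):
        table, _ = neutral_table(n_samples=10, n_otus=50, depth=300, seed=3)
        with pytest.raises(ValueError, match="cannot draw"):
            split_dataset(table, "rare_subsets", subset_size=500,
                          occ_range=(1, 10))

    def test_rare_subsets_deterministic(self):
        table, _ = neutral_table(n_samples=20, n_otus=120, depth=500, seed=4)
        kw = dict(n_subsets=3, subset_size=10, occ_range=(1, 19), seed=9)
        a = split_dataset(table, "rare_subsets", **kw)
        b = split_dataset(table, "rare_subsets", **kw)
        for k in a:
            assert a[k].otu_ids == b[k].otu_ids

    def test_rare_subsets_respect_occupancy_window(self):
        table, _ = neutral_table(n_samples=20, n_otus=120, depth=500, seed=4)
        parts = split_dataset(table, "rare_subsets", n_subsets=2,
                              subset_size=10, occ_range=(2, 10), seed=1)
        occ = pd.Series((table.counts > 0).sum(axis=0), index=table.otu_ids)
        for t in parts.values():
            assert occ[t.otu_ids].between(2, 10).all()
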