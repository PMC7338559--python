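"""Five-way assembly-process classification and scenario-conditioned summaries.

Each unordered sample pair is assigned one process from its (betaNTI,
RC_Bray) coordinates:

* betaNTI > +2            -> variable (heterogeneous) selection
* betaNTI < -2            -> homogeneous (homogenizing) selection
* |betaNTI| <= 2 and RC_Bray >  0.95 -> dispersal limitation (with drift)
* |betaNTI| <= 2 and RC_Bray < -0.95 -> homogenizing dispersal
* otherwise                           -> undominated

Inequalities are strict on both thresholds, so boundary values fall through
to the stochastic/undominated side (conservative). A pair whose betaNTI is
undefined (degenerate null) is labelled ``unclassified``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_formats import CommunityTable, SampleFrame

__all__ = [
    "PROCESS_LABELS",
    "ScenarioFilter",
    "SCENARIO_PRESETS",
    "classify_pair",
    "build_pair_table",
    "pair_covariates",
    "apply_scenario",
    "summarize_fractions",
    "mean_fractions_over_groups",
    "split_dataset",
]

PROCESS_LABELS = ("variable_selection", "homogeneous_selection",
                  "homogenizing_dispersal", "dispersal_limitation_drift",
                  "undominated")

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def classify_pair(bnti: float, rc: float, bnti_threshold: float = BNTI_THRESHOLD,
                  rc_threshold: float = RC_THRESHOLD) -> str:
    """Map one (betaNTI, RC_Bray) pair to a process label (total function)."""
    if not np.isfinite(bnti):
        return "unclassified"
    if bnti > bnti_threshold:
        return "variable_selection"
    if bnti < -bnti_threshold:
        return "homogeneous_selection"
    if rc > rc_threshold:
        return "dispersal_limitation_drift"
    if rc < -rc_threshold:
        return "homogenizing_dispersal"
    return "undominated"


# ---------------------------------------------------------------------------
# pair covariates and the long-format pair table
# ---------------------------------------------------------------------------

def pair_covariates(frame: SampleFrame) -> pd.DataFrame:
    """Spatial (m), temporal (days) and absolute environmental distances per pair."""
    data = frame.data
    ids = frame.sample_ids
    rows = []
    xy = data[["x", "y"]].to_numpy(dtype=float)
    dates = data["date"].to_numpy(dtype=float)
    occ = data["occasion"].to_numpy()
    env = {v: data[v].to_numpy(dtype=float) for v in frame.env_vars}
    for i, j in combinations(range(len(ids)), 2):
        row = {
            "sample_i": ids[i], "sample_j": ids[j],
            "spatial_dist": float(np.hypot(*(xy[i] - xy[j]))),
            "temporal_dist": abs(float(dates[i] - dates[j])),
            "same_occasion": bool(occ[i] == occ[j]),
        }
        for v, vals in env.items():
            row[f"env_diff_{v}"] = abs(float(vals[i] - vals[j]))
        rows.append(row)
    return pd.DataFrame(rows)


def build_pair_table(sample_ids: list[str], bnti: np.ndarray, rc: np.ndarray,
                     frame: SampleFrame | None = None,
                     bnti_threshold: float = BNTI_THRESHOLD,
                     rc_threshold: float = RC_THRESHOLD) -> pd.DataFrame:
    """Assemble the long-format pair table from the two pairwise matrices."""
    n = len(sample_ids)
    if bnti.shape != (n, n) or rc.shape != (n, n):
        raise ValueError("matrix shapes do not match sample_ids")
    rows = []
    for i, j in combinations(range(n), 2):
        rows.append({
            "sample_i": sample_ids[i], "sample_j": sample_ids[j],
            "bnti": bnti[i, j], "rc_bray": rc[i, j],
            "process": classify_pair(bnti[i, j], rc[i, j],
                                     bnti_threshold, rc_threshold),
        })
    pairs = pd.DataFrame(rows)
    if frame is not None:
        cov = pair_covariates(frame.select_samples(list(sample_ids)))
        pairs = pairs.merge(cov, on=["sample_i", "sample_j"], how="left")
    return pairs


# ---------------------------------------------------------------------------
# scenario filters
# ---------------------------------------------------------------------------

@dataclass
class ScenarioFilter:
    """Pure predicate over pair covariates.

    Spatial thresholds are meters, temporal thresholds days. ``same_occasion``
    True/False encodes the "within months" / "between months" scenarios
    (temporal distance 0 means the same sampling campaign). ``env_quartile``
    keeps pairs whose absolute difference in one environmental variable lies
    in the upper ('UQ') or lower ('LQ') quartile of the analysed pair table,
    quartiles computed with the median-unbiased quantile estimator and
    boundary-inclusive membership.
    """

    name: str
    max_spatial: float | None = None
    min_spatial: float | None = None
    max_temporal: float | None = None
    min_temporal: float | None = None
    same_occasion: bool | None = None
    env_quartile: tuple[str, str] | None = None  # (variable, 'UQ' | 'LQ')

    def mask(self, pairs: pd.DataFrame) -> np.ndarray:
        keep = np.ones(len(pairs), dtype=bool)
        if self.max_spatial is not None:
            keep &= pairs["spatial_dist"].to_numpy() < self.max_spatial
        if self.min_spatial is not None:
            keep &= pairs["spatial_dist"].to_numpy() > self.min_spatial
        if self.max_temporal is not None:
            keep &= pairs["temporal_dist"].to_numpy() < self.max_temporal
        if self.min_temporal is not None:
            keep &= pairs["temporal_dist"].to_numpy() > self.min_temporal
        if self.same_occasion is not None:
            keep &= pairs["same_occasion"].to_numpy() == self.same_occasion
        if self.env_quartile is not None:
            var, which = self.env_quartile
            col = f"env_diff_{var}"
            if col not in pairs.columns:
                raise KeyError(f"pair table has no column {col}")
            vals = pairs[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if which == "UQ":
                q = np.nanquantile(vals, 0.75, method="median_unbiased")
                keep &= ok & (vals >= q)
            elif which == "LQ":
                q = np.nanquantile(vals, 0.25, method="median_unbiased")
                keep &= ok & (vals <= q)
            else:
                raise ValueError("env_quartile must be 'UQ' or 'LQ'")
        return keep


SCENARIO_PRESETS = {
    "within_months": ScenarioFilter("within_months", same_occasion=True),
    "between_months": ScenarioFilter("between_months", same_occasion=False),
    "near_late": ScenarioFilter("near_late", max_spatial=2.0, min_temporal=150.0),
    "far_early": ScenarioFilter("far_early", min_spatial=8.0, max_temporal=60.0),
}


def apply_scenario(pairs: pd.DataFrame, scenario: ScenarioFilter | str) -> pd.DataFrame:
    """Subset a pair table to the rows matching a scenario predicate.

    Quartile-based filters are computed on the distribution of pairwise
    differences within the input table.
    """
    if isinstance(scenario, str):
        scenario = SCENARIO_PRESETS[scenario]
    out = pairs.loc[scenario.mask(pairs)].reset_index(drop=True)
    if out.empty:
        import warnings
        warnings.warn(f"scenario {scenario.name!r} matched no pairs", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# fraction summaries
# ---------------------------------------------------------------------------

def _fraction_row(processes: pd.Series) -> dict:
    n = len(processes)
    classified = processes[processes != "unclassified"]
    row: dict = {"n_pairs": n, "n_classified": len(classified)}
    for label in PROCESS_LABELS:
        row[label] = (classified == label).mean() if len(classified) else np.nan
    return row


def summarize_fractions(pairs: pd.DataFrame, group_by: str | None = None) -> pd.DataFrame:
    """Per-group process-label fractions (over classified pairs) and pair counts.

    Duplicate pair rows are rejected: fractions must count each unordered
    pair exactly once.
    """
    key = pairs[["sample_i", "sample_j"]].apply(frozenset, axis=1) if len(pairs) else pd.Series([], dtype=object)
    dup_cols = [key] + ([pairs[group_by]] if group_by else [])
    if len(pairs) and pd.concat(dup_cols, axis=1).duplicated().any():
        raise ValueError("duplicate pair rows in pair table")
    if group_by is None:
        return pd.DataFrame([{"group": "all", **_fraction_row(pairs["process"])}])
    rows = [{"group": g, **_fraction_row(sub["process"])}
            for g, sub in pairs.groupby(group_by, sort=True)]
    return pd.DataFrame(rows)


def mean_fractions_over_groups(fractions: pd.DataFrame) -> pd.DataFrame:
    """Mean fraction per label across groups with a 1.96*SE normal CI."""
    rows = []
    for label in PROCESS_LABELS:
        vals = fractions[label].dropna().to_numpy(dtype=float)
        k = len(vals)
        mean = vals.mean() if k else np.nan
        se = vals.std(ddof=1) / np.sqrt(k) if k > 1 else np.nan
        rows.append({"process": label, "mean": mean, "n_groups": k,
                     "ci_low": mean - 1.96 * se if k > 1 else np.nan,
                     "ci_high": mean + 1.96 * se if k > 1 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(table: CommunityTable, mode: str, *,
                  frame: SampleFrame | None = None,
                  otu_groups: pd.Series | dict | None = None,
                  min_otus: int = 600,
                  n_subsets: int = 10, subset_size: int = 500,
                  occ_range: tuple[int, int] = (120, 240),
                  seed: int = 0) -> dict[str, CommunityTable]:
    """Split the table for per-occasion, per-taxon or rare-biosphere analyses.

    ``by_occasion``: one table per sampling campaign (all OTUs; sample sets
    partition the input). ``by_taxon_group``: one table per OTU group label
    with more than ``min_otus`` member OTUs. ``rare_subsets``: ``n_subsets``
    random draws of ``subset_size`` OTUs whose number of non-zero
    observations lies within ``occ_range`` (the rare-to-intermediate
    biosphere).
    """
    if mode == "by_occasion":
        if frame is None:
            raise ValueError("by_occasion split needs a SampleFrame")
        out = {}
        occ = frame.data["occasion"]
        for value in sorted(occ.unique()):
            ids = [s for s in table.sample_ids if occ.get(s) == value]
            out[f"occasion_{int(value)}"] = table.select_samples(ids)
        return out
    if mode == "by_taxon_group":
        if otu_groups is None:
            raise ValueError("by_taxon_group split needs per-OTU group labels")
        groups = pd.Series(otu_groups)
        out = {}
        for label in sorted(groups.dropna().unique()):
            members = [o for o in table.otu_ids if groups.get(o) == label]
            if len(members) > min_otus:
                out[str(label)] = table.select_otus(members)
        if not out:
            raise ValueError(f"no taxon group exceeds {min_otus} OTUs")
        return out
    if mode == "rare_subsets":
        nonzero = (table.counts > 0).sum(axis=0)
        lo, hi = occ_range
        eligible = [o for o, nz in zip(table.otu_ids, nonzero) if lo <= nz <= hi]
        if len(eligible) < subset_size:
            raise ValueError(
                f"only {len(eligible)} OTUs have {lo}-{hi} non-zero observations; "
                f"cannot draw subsets of {subset_size}")
        rng = np.random.default_rng(seed)
        out = {}
        for k in range(n_subsets):
            chosen = rng.choice(len(eligible), size=subset_size, replace=False)
            out[f"rare_subset_{k + 1}"] = table.select_otus(
                [eligible[i] for i in sorted(chosen)])
        return out
    raise ValueError(f"unknown split mode {mode!r}")
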