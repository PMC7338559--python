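"""Readers, writers and validation for community tables, trees and sample metadata.

All tabular formats are tab-separated UTF-8 with '.' decimal separators; trees
are Newick. The three input objects (:class:`CommunityTable`, a scikit-bio
``TreeNode`` phylogeny, :class:`SampleFrame`) are validated on construction and
cross-validated by :func:`align_inputs`, which makes sample and OTU orderings
consistent before any pairwise analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityTable",
    "SampleFrame",
    "read_community_table",
    "write_community_table",
    "read_newick",
    "write_newick",
    "read_sample_frame",
    "write_sample_frame",
    "align_inputs",
    "write_pair_table",
    "read_pair_table",
    "write_summary",
    "read_summary",
]

#: columns every long-format pair table carries (env differences are appended
#: as ``env_diff_<variable>`` columns)
PAIR_COLUMNS = ("sample_i", "sample_j", "bmntd", "bnti", "rc_bray", "process",
                "spatial_dist", "temporal_dist")


@dataclass
class CommunityTable:
    """Samples x OTUs matrix of non-negative integer read counts.

    Rows are samples, columns are OTUs (community-ecology convention). The
    counts array is always ``int64``; ids are case-sensitive exact strings.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x OTUs)")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = ~np.isclose(counts, rounded)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"OTU {self.otu_ids[j]!r}: {counts[i, j]!r}")
            counts = rounded
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}: {counts[i, j]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")
        self.counts = counts

    # -- convenience accessors -------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts (each sample sums to 1)."""
        totals = self.sample_totals.astype(float)
        if (totals == 0).any():
            empty = [self.sample_ids[i] for i in np.flatnonzero(totals == 0)]
            raise ValueError(f"samples with zero total count: {empty}")
        return self.counts / totals[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.otu_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CommunityTable":
        return cls(list(frame.index.astype(str)), list(frame.columns.astype(str)),
                   frame.to_numpy())

    def select_samples(self, sample_ids: list[str]) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(sample_ids, list(self.otu_ids), self.counts[idx])

    def select_otus(self, otu_ids: list[str]) -> "CommunityTable":
        pos = {o: k for k, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return CommunityTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx])

    def drop_empty_otus(self) -> "CommunityTable":
        keep = self.counts.sum(axis=0) > 0
        return CommunityTable(list(self.sample_ids),
                              [o for o, k in zip(self.otu_ids, keep) if k],
                              self.counts[:, keep])


@dataclass
class SampleFrame:
    """Per-sample coordinates (m), sampling occasion, date (days) and environment.

    ``data`` is indexed by sample id and must carry columns ``x``, ``y``,
    ``occasion`` and ``date``; every other numeric column is treated as an
    environmental variable (missing values allowed — pairs touching a missing
    value are excluded only from analyses that use that variable).
    """

    data: pd.DataFrame
    RESERVED: tuple = field(default=("x", "y", "occasion", "date"), repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("x", "y", "occasion", "date") if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample frame missing required columns: {missing}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in sample frame")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite x/y coordinate in sample frame")
        occ = self.data["occasion"]
        if (occ <= 0).any() or (occ.astype(int) != occ).any():
            raise ValueError("occasion must be a positive integer")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def env_vars(self) -> list[str]:
        return [c for c in self.data.columns
                if c not in self.RESERVED and pd.api.types.is_numeric_dtype(self.data[c])]

    def select_samples(self, sample_ids: list[str]) -> "SampleFrame":
        return SampleFrame(self.data.loc[sample_ids])


# ---------------------------------------------------------------------------
# community table I/O
# ---------------------------------------------------------------------------

def read_community_table(path, transpose: bool = False) -> CommunityTable:
    """Read a TSV count table (first column sample ids, header row OTU ids).

    Set ``transpose=True`` only for files stored OTUs x samples; orientation
    is never guessed silently.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing cells")
    try:
        values = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if transpose:
        values = values.T
    return CommunityTable.from_frame(values)


def write_community_table(table: CommunityTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = list(tree.tips())
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    names = [t.name for t in tips]
    if any(n is None for n in names):
        raise ValueError("tree has unnamed tips")
    if len(set(names)) != len(names):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            who = node.name or "internal node"
            raise ValueError(
                f"branch leading to {who} has no length; "
                "betaMNTD requires branch lengths on every edge")
        if node.length < 0:
            raise ValueError(f"negative branch length on {node.name or 'internal node'}")
    return tree


def read_newick(path) -> TreeNode:
    """Read a single rooted Newick tree; every edge must carry a length."""
    tree = TreeNode.read(str(path), format="newick")
    return _validate_tree(tree)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# sample metadata I/O
# ---------------------------------------------------------------------------

def read_sample_frame(path) -> SampleFrame:
    data = pd.read_csv(path, sep="\t", index_col=0)
    return SampleFrame(data)


def write_sample_frame(frame: SampleFrame, path) -> None:
    frame.data.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# cross-file alignment
# ---------------------------------------------------------------------------

def align_inputs(table: CommunityTable, tree: TreeNode | None = None,
                 frame: SampleFrame | None = None):
    """Make table / tree / frame mutually consistent.

    OTUs absent from the tree are dropped (with a warning counting removed
    reads); samples absent from the metadata are dropped; the tree is pruned
    to the retained OTUs. Returns ``(table, tree, frame)`` with ``None``
    passed through for absent inputs. Idempotent.
    """
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        keep = [o for o in table.otu_ids if o in tip_names]
        if not keep:
            raise ValueError("no overlap between table OTUs and tree tips")
        dropped = [o for o in table.otu_ids if o not in tip_names]
        if dropped:
            lost = int(table.select_otus(dropped).counts.sum())
            msg = (f"dropping {len(dropped)} OTU(s) absent from the tree "
                   f"({lost} reads): {dropped[:10]}{'...' if len(dropped) > 10 else ''}")
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)
            table = table.select_otus(keep)
        if {t.name for t in tree.tips()} != set(keep):
            tree = tree.shear(keep)
            _validate_tree(tree)
    if frame is not None:
        known = set(frame.sample_ids)
        keep_s = [s for s in table.sample_ids if s in known]
        if not keep_s:
            raise ValueError("no overlap between table samples and metadata")
        dropped_s = [s for s in table.sample_ids if s not in known]
        if dropped_s:
            msg = f"dropping {len(dropped_s)} sample(s) absent from metadata: {dropped_s[:10]}"
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)
            table = table.select_samples(keep_s)
        frame = frame.select_samples(table.sample_ids)
    return table, tree, frame


# ---------------------------------------------------------------------------
# pair table and summary I/O
# ---------------------------------------------------------------------------

def write_pair_table(pairs: pd.DataFrame, path) -> None:
    """Write a long-format per-pair table (one row per unordered sample pair)."""
    pairs.to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary(summary: dict, path) -> None:
    """Write a flat or nested dict as machine-parseable ``key<TAB>value`` lines.

    Nested keys are joined with '.'.
    """
    def _flatten(d, prefix=""):
        for k, v in d.items():
            key = f"{prefix}{k}"
            if isinstance(v, dict):
                yield from _flatten(v, prefix=key + ".")
            else:
                yield key, v

    with open(path, "w", encoding="utf-8") as fh:
        for key, value in _flatten(summary):
            fh.write(f"{key}\t{value!r}\n" if isinstance(value, str) else f"{key}\t{value}\n")


def read_summary(path) -> dict:
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, raw = line.rstrip("\n").partition("\t")
            try:
                value = eval(raw, {"__builtins__": {}}, {"nan": float("nan"), "inf": float("inf")})
            except Exception:
                value = raw
            out[key] = value
    return out
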