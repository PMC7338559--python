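"""Non-phylogenetic beta-diversity: local contributions to beta-diversity
(LCBD), multiple-site Sorensen turnover/nestedness partitioning, and Mantel
tests.

LCBD partitions the total community variance among sites: from the
Bray-Curtis dissimilarity matrix D, Gower-center G = -1/2 H (D o D) H with
H = I - 11'/n; LCBD_i = G_ii / trace(G), summing to 1 over sites. A large
LCBD flags a site with unusual composition. Significance is assessed by
permuting each OTU column independently across samples and recomputing.

The multiple-site Sorensen dissimilarity beta_SOR decomposes additively into
a turnover (species replacement, beta_SIM) and a nestedness-resultant
(richness difference, beta_SNE) component; rare-biosphere turnover is probed
by computing the partition within occupancy bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io_formats import CommunityTable

__all__ = [
    "LcbdResult",
    "BetaPartition",
    "lcbd",
    "sorensen_partition_multisite",
    "frequency_partitioned_betapart",
    "mantel",
]


@dataclass
class LcbdResult:
    sample_ids: list[str]
    lcbd: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    total_beta: float       # SS_total / (n - 1)
    adjust_method: str


@dataclass
class BetaPartition:
    beta_sor: float
    beta_sim: float
    beta_sne: float


# ---------------------------------------------------------------------------
# LCBD
# ---------------------------------------------------------------------------

def _lcbd_from_counts(counts: np.ndarray, use_sqrt: bool = True
                      ) -> tuple[np.ndarray, float]:
    d = squareform(pdist(counts.astype(float), metric="braycurtis"))
    if use_sqrt:
        # Bray-Curtis is not Euclidean-embeddable; sqrt(BC) (nearly) is, which
        # keeps the Gower-centred diagonal, hence every LCBD, non-negative
        d = np.sqrt(d)
    a = -0.5 * d * d
    n = a.shape[0]
    h = np.eye(n) - np.full((n, n), 1.0 / n)
    g = h @ a @ h
    trace = float(np.trace(g))
    if trace <= 0:
        raise ValueError("all samples identical: total beta-diversity is zero, "
                         "LCBD undefined")
    return np.diag(g) / trace, trace


def lcbd(table: CommunityTable, n_perm: int = 999, seed: int = 0,
         adjust: str = "holm", use_sqrt: bool = True) -> LcbdResult:
    """LCBD per sample with one-sided permutation p-values.

    p_i = (#{permuted LCBD_i >= observed} + 1) / (n_perm + 1), adjusted with
    Holm by default ('fdr_bh' available). ``use_sqrt`` (default) centres
    sqrt(Bray-Curtis) instead of raw Bray-Curtis so contributions stay
    non-negative.
    """
    if table.n_samples < 3:
        raise ValueError("LCBD needs at least 3 samples")
    counts = table.counts
    obs, trace = _lcbd_from_counts(counts, use_sqrt)
    rng = np.random.default_rng(seed)
    n, s = counts.shape
    exceed = np.zeros(n)
    for _ in range(n_perm):
        perm = counts.copy()
        for j in range(s):
            perm[:, j] = perm[rng.permutation(n), j]
        try:
            perm_lcbd, _ = _lcbd_from_counts(perm, use_sqrt)
        except ValueError:
            perm_lcbd = np.full(n, 1.0 / n)
        exceed += perm_lcbd >= obs
    p = (exceed + 1.0) / (n_perm + 1.0)
    method = {"holm": "holm", "fdr_bh": "fdr_bh"}[adjust]
    p_adj = multipletests(p, method=method)[1]
    return LcbdResult(list(table.sample_ids), obs, p, p_adj,
                      trace / (n - 1), adjust)


# ---------------------------------------------------------------------------
# Baselga multiple-site partition
# ---------------------------------------------------------------------------

def sorensen_partition_multisite(incidence: np.ndarray) -> BetaPartition:
    """Multiple-site Sorensen dissimilarity and its turnover/nestedness parts.

    With per-site richness S_i, pooled richness S_T and, for every site pair,
    the numbers of species unique to each side b_ij / b_ji::

        beta_SIM = Sum min / (Sum_i S_i - S_T + Sum min)
        beta_SOR = (Sum min + Sum max) / (2 (Sum_i S_i - S_T) + Sum min + Sum max)
        beta_SNE = beta_SOR - beta_SIM

    where Sum min / Sum max run over unordered pairs.
    """
    inc = np.asarray(incidence) > 0
    if inc.ndim != 2 or inc.shape[0] < 2:
        raise ValueError("need an incidence matrix with >= 2 sites")
    richness = inc.sum(axis=1)
    if (richness == 0).any():
        raise ValueError("a site with zero species makes the partition undefined")
    shared = (inc.astype(np.int64) @ inc.astype(np.int64).T)
    unique = richness[:, None] - shared  # unique[i, j] = species in i not in j
    iu = np.triu_indices(inc.shape[0], k=1)
    b_ij, b_ji = unique[iu], unique.T[iu]
    sum_min = float(np.minimum(b_ij, b_ji).sum())
    sum_max = float(np.maximum(b_ij, b_ji).sum())
    pooled = int(inc.any(axis=0).sum())
    core = float(richness.sum() - pooled)  # Sum_i S_i - S_T
    if sum_min + sum_max == 0:
        return BetaPartition(0.0, 0.0, 0.0)
    beta_sim = sum_min / (core + sum_min)
    beta_sor = (sum_min + sum_max) / (2.0 * core + sum_min + sum_max)
    return BetaPartition(beta_sor, beta_sim, beta_sor - beta_sim)


def frequency_partitioned_betapart(table: CommunityTable,
                                   bins: np.ndarray | None = None) -> pd.DataFrame:
    """Sorensen partition within occupancy-fraction bins of the OTU pool.

    ``bins`` are right-inclusive upper edges over (0, 1] (default deciles).
    Sites empty within a bin are dropped for that bin; bins left with < 2
    sites or no OTUs are flagged and skipped.
    """
    if bins is None:
        bins = np.linspace(0.1, 1.0, 10)
    bins = np.asarray(bins, dtype=float)
    if bins[-1] < 1.0:
        raise ValueError("bins must cover occupancy fractions up to 1.0")
    occ_frac = (table.counts > 0).sum(axis=0) / table.n_samples
    edges = np.concatenate([[0.0], bins])
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (occ_frac > lo) & (occ_frac <= hi)
        row = {"bin_low": lo, "bin_high": hi, "n_otus": int(in_bin.sum())}
        if not in_bin.any():
            row.update(beta_sor=np.nan, beta_sim=np.nan, beta_sne=np.nan,
                       status="empty_bin")
            rows.append(row)
            continue
        inc = table.counts[:, in_bin] > 0
        nonempty = inc.any(axis=1)
        if nonempty.sum() < 2:
            row.update(beta_sor=np.nan, beta_sim=np.nan, beta_sne=np.nan,
                       status="too_few_sites")
            rows.append(row)
            continue
        part = sorensen_partition_multisite(inc[nonempty])
        row.update(beta_sor=part.beta_sor, beta_sim=part.beta_sim,
                   beta_sne=part.beta_sne, status="ok",
                   n_sites=int(nonempty.sum()))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(dist_a: np.ndarray, dist_b: np.ndarray, n_perm: int = 999,
           seed: int = 0) -> tuple[float, float]:
    """Spearman Mantel test between two same-ordered distance matrices.

    The correlation is computed on the upper triangles; the null permutes the
    second matrix's rows and columns jointly. Two-sided p-value
    ``(#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1)``.

    Because a joint row/column permutation of a symmetric matrix only permutes
    the multiset of off-diagonal entries, ranks can be computed once on the
    full matrix and permuted, reducing each permutation to a dot product.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or b.shape != (n, n):
        raise ValueError("distance matrices must be square and same-shaped")
    if n < 4:
        raise ValueError("Mantel test needs at least 4 objects")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("distance matrices must be symmetric")
    iu = np.triu_indices(n, k=1)
    ra = rankdata(a[iu])
    rb_flat = rankdata(b[iu])
    if ra.std() == 0 or rb_flat.std() == 0:
        raise ValueError("constant distance matrix: rank correlation undefined")
    # square matrix of ranks of b's upper-triangle entries (symmetric)
    rb_sq = np.zeros((n, n))
    rb_sq[iu] = rb_flat
    rb_sq = rb_sq + rb_sq.T

    za = (ra - ra.mean()) / ra.std()
    sb = rb_flat.std()
    mb = rb_flat.mean()

    def _corr(rb_vec):
        return float(za @ ((rb_vec - mb) / sb)) / ra.size

    r_obs = _corr(rb_flat)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rb_perm = rb_sq[np.ix_(perm, perm)][iu]
        if abs(_corr(rb_perm)) >= abs(r_obs):
            exceed += 1
    p = (exceed + 1.0) / (n_perm + 1.0)
    return r_obs, p
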