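"""Rank genes by up-regulation significance from replicate log2 ratios.

Treated and control expression matrices (genes x replicas) are reduced to a
matrix of per-replica log2 fold changes, which is treated as a sample from an
n-dimensional (one dimension per replica) distribution. A gene's empirical
p-value is the fraction of genes whose log2 ratios dominate it in *every*
replica — the upper-orthant survival function of the multivariate empirical
distribution (with no censoring the Kaplan–Meier estimator of that survival
function reduces to the plain ECDF). The statistic is rank-based, so it is
invariant under any strictly increasing per-replica transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RatioMatrix",
    "GeneRanking",
    "compute_log2_ratios",
    "ecdf_pvalues",
    "select_upregulated",
]


@dataclass(frozen=True)
class RatioMatrix:
    """Genes x replicas matrix of log2(treated/control) values."""

    gene_ids: list[str]
    values: np.ndarray  # (m, n)
    replica_ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        m, n = v.shape
        if m != len(self.gene_ids):
            raise ValueError("values rows must match gene_ids")
        if n != len(self.replica_ids):
            raise ValueError("values columns must match replica_ids")
        if m < 2:
            raise ValueError("need at least 2 genes")
        if n < 1:
            raise ValueError("need at least 1 replica")
        if not np.all(np.isfinite(v)):
            raise ValueError("RatioMatrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.replica_ids)


@dataclass(frozen=True)
class GeneRanking:
    """Per-gene empirical p-values and mean log2 fold changes, 1-based ranks."""

    gene_ids: list[str]
    p_value: np.ndarray
    mean_log2: np.ndarray
    rank: np.ndarray  # permutation of 1..m, ascending (p, then -mean_log2)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": self.gene_ids,
                "mean_log2": self.mean_log2,
                "fold": np.exp2(self.mean_log2),
                "p_value": self.p_value,
                "rank": self.rank,
            }
        )
        return df.sort_values("rank", ignore_index=True)


def compute_log2_ratios(
    treated: pd.DataFrame, control: pd.DataFrame
) -> RatioMatrix:
    """Element-wise log2(treated/control) of matching expression matrices.

    Both frames must share shape, gene index order and column order, and be
    strictly positive.
    """
    if treated.shape != control.shape:
        raise ValueError(
            f"shape mismatch: treated {treated.shape} vs control {control.shape}"
        )
    if list(treated.index) != list(control.index):
        raise ValueError("gene order differs between treated and control")
    t = treated.to_numpy(dtype=float)
    c = control.to_numpy(dtype=float)
    for name, arr in (("treated", t), ("control", c)):
        bad = np.argwhere(~(arr > 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-positive {name} expression for gene "
                f"{treated.index[i]!r}, replica {treated.columns[j]!r}"
            )
    return RatioMatrix(
        list(map(str, treated.index)),
        np.log2(t / c),
        list(map(str, treated.columns)),
    )


def ecdf_pvalues(
    ratios: RatioMatrix, direction: str = "up", mode: str = "all"
) -> GeneRanking:
    """Multivariate empirical-CDF p-values of replicate log2 ratios.

    For ``direction="up"`` the p-value of gene g is the fraction of genes
    (self included) whose values are >= g's in every replica (``mode="all"``,
    the upper-orthant survival fraction) or in at least one replica
    (``mode="any"``, the complementary orthant bound). ``direction="down"``
    mirrors with <=. Minimum attainable p is 1/m; p is never 0.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    v = ratios.values if direction == "up" else -ratios.values
    m = v.shape[0]
    # pairwise componentwise domination; m is desk-scale so O(m^2 n) is fine,
    # chunked to bound memory
    counts = np.empty(m, dtype=np.int64)
    chunk = max(1, int(4e7) // (m * v.shape[1]) or 1)
    for lo in range(0, m, chunk):
        hi = min(m, lo + chunk)
        ge = v[None, :, :] >= v[lo:hi, None, :]  # (b, m, n)
        dom = ge.all(axis=2) if mode == "all" else ge.any(axis=2)
        counts[lo:hi] = dom.sum(axis=1)
    p = counts / m
    mean_log2 = ratios.values.mean(axis=1)
    order = np.lexsort((-mean_log2, p))
    rank = np.empty(m, dtype=np.int64)
    rank[order] = np.arange(1, m + 1)
    return GeneRanking(list(ratios.gene_ids), p, mean_log2, rank)


def select_upregulated(
    ranking: GeneRanking,
    min_mean_ratio: float | None = 2.0,
    max_p: float | None = 0.005,
) -> list[str]:
    """Genes passing the fold-change and p-value cuts, in rank order.

    The fold criterion is the geometric-mean linear fold change across
    replicas, 2**mean_log2, and is *strict* ("higher than" the threshold).
    Either criterion may be disabled by passing None.
    """
    keep = np.ones(len(ranking.gene_ids), dtype=bool)
    if min_mean_ratio is not None:
        if min_mean_ratio <= 0:
            raise ValueError("min_mean_ratio must be > 0")
        keep &= np.exp2(ranking.mean_log2) > min_mean_ratio
    if max_p is not None:
        if max_p <= 0:
            raise ValueError("max_p must be > 0")
        keep &= ranking.p_value <= max_p
    idx = [i for i in np.argsort(ranking.rank) if keep[i]]
    return [ranking.gene_ids[i] for i in idx]
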