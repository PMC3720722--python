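"""Hypergeometric over/under-representation of signed annotation terms in clusters.

A hand-curated vocabulary assigns each gene a set of *signed* function terms
("CATEGORY:sign", e.g. ``GROWTH:-`` for an anti-growth role, ``GROWTH:+`` for
pro-growth, ``SRF_REGULATED:.`` for an unsigned regulatory tag); a pro and an
anti variant of the same category are distinct terms. For a universe of N
clustered genes, k of which carry a term, the probability that a cluster of
size n contains exactly x carriers is the hypergeometric pmf

    P(X = x) = C(k, x) * C(N - k, n - x) / C(N, n)

and enrichment/depletion are the one-sided tails P(X >= x) / P(X <= x)
(equal to one-sided Fisher's exact tests on the 2x2 table). Probabilities
are computed with exact integer arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import pandas as pd

__all__ = [
    "Vocabulary",
    "EnrichmentQuery",
    "EnrichmentResult",
    "hypergeom_pmf",
    "hypergeom_tail_ge",
    "hypergeom_tail_le",
    "enrich_clusters",
]

TERM_RE = re.compile(r"^[A-Za-z0-9_.\-]+:[+\-.]$")


@dataclass(frozen=True)
class Vocabulary:
    """Gene -> set of signed terms, with a closed term list."""

    entries: dict[str, frozenset[str]]
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        for term in self.terms:
            if not TERM_RE.match(term):
                raise ValueError(
                    f"malformed term {term!r} (expected CATEGORY:sign with sign in +-.)"
                )
        known = set(self.terms)
        for gene, terms in self.entries.items():
            stray = set(terms) - known
            if stray:
                raise ValueError(
                    f"gene {gene!r} carries terms absent from the header: {sorted(stray)}"
                )

    def genes_with(self, term: str) -> set[str]:
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in the vocabulary header")
        return {g for g, t in self.entries.items() if term in t}


@dataclass(frozen=True)
class EnrichmentQuery:
    """One hypergeometric query: N genes, k term carriers, cluster of n, x observed."""

    N_total: int
    k_marked: int
    n_cluster: int
    x_observed: int

    def __post_init__(self) -> None:
        N, k, n, x = self.N_total, self.k_marked, self.n_cluster, self.x_observed
        if not (0 <= k <= N and 0 < n <= N):
            raise ValueError(f"invalid query sizes N={N}, k={k}, n={n}")
        if not 0 <= x <= min(k, n):
            raise ValueError(f"x={x} outside [0, min(k, n)={min(k, n)}]")


@dataclass(frozen=True)
class EnrichmentResult:
    cluster: object
    term: str
    query: EnrichmentQuery
    p_over: float
    p_under: float


def _pmf_fraction(N: int, k: int, n: int, x: int) -> Fraction:
    if n - x > N - k:  # infeasible: not enough unmarked genes
        return Fraction(0)
    return Fraction(comb(k, x) * comb(N - k, n - x), comb(N, n))


def hypergeom_pmf(q: EnrichmentQuery) -> float:
    """Exact probability of observing exactly x term carriers in the cluster."""
    return float(_pmf_fraction(q.N_total, q.k_marked, q.n_cluster, q.x_observed))


def hypergeom_tail_ge(q: EnrichmentQuery) -> float:
    """Enrichment tail P(X >= x_observed)."""
    N, k, n, x = q.N_total, q.k_marked, q.n_cluster, q.x_observed
    total = sum(
        (_pmf_fraction(N, k, n, xp) for xp in range(x, min(n, k) + 1)),
        Fraction(0),
    )
    return float(total)


def hypergeom_tail_le(q: EnrichmentQuery) -> float:
    """Depletion tail P(X <= x_observed)."""
    N, k, n, x = q.N_total, q.k_marked, q.n_cluster, q.x_observed
    total = sum((_pmf_fraction(N, k, n, xp) for xp in range(0, x + 1)), Fraction(0))
    return float(total)


def enrich_clusters(
    vocab: Vocabulary,
    assignments: dict[str, object],
    terms: list[str] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One over/under-representation test per (cluster, term).

    The universe is the set of clustered genes (N); every annotated gene must
    belong to it. No multiple-testing correction by default; with
    ``bh_correct`` Benjamini–Hochberg adjusted columns are appended.
    """
    universe = set(assignments)
    stray = set(vocab.entries) - universe
    if stray:
        raise ValueError(
            f"annotated genes missing from the clustered universe: {sorted(stray)[:5]}"
        )
    if terms is None:
        terms = list(vocab.terms)
    else:
        for t in terms:
            if t not in vocab.terms:
                raise ValueError(f"term {t!r} not in the vocabulary header")

    N = len(universe)
    clusters = sorted(set(assignments.values()), key=str)
    rows = []
    for term in terms:
        carriers = vocab.genes_with(term) & universe
        k = len(carriers)
        for cl in clusters:
            members = {g for g, c in assignments.items() if c == cl}
            n = len(members)
            x = len(members & carriers)
            q = EnrichmentQuery(N, k, n, x)
            rows.append(
                {
                    "cluster": cl,
                    "term": term,
                    "N": N,
                    "k": k,
                    "n": n,
                    "x": x,
                    "p_over": hypergeom_tail_ge(q),
                    "p_under": hypergeom_tail_le(q),
                }
            )
    df = pd.DataFrame(rows)
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        for col in ("p_over", "p_under"):
            df[f"{col}_bh"] = multipletests(df[col], method="fdr_bh")[1]
    return df
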