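"""CArG-box detection in promoter sequences by consensus and PWM scanning.

The CArG box, CC[A/T]6GG, is the serum-response-factor (SRF) binding motif.
Two detectors are provided: an exact consensus matcher (the pattern class is
closed under reverse complement, so a plus-strand scan covers both strands),
and a position-weight-matrix scanner reporting the min-max scaled log-odds
("relative") score in [0, 1], the convention under which a 0.8 cutoff is the
standard scanning threshold. Cross-species conservation is flagged by a
simplified intersection rule: a hit is conserved when every species carries
the identical matched 10-mer at a start offset within a tolerance — a
stand-in for alignment-based conservation calls, not a reconstruction of
them.

Coordinates are 0-based half-open on the 5'->3' promoter sequence, position
0 being the most upstream base; ``upstream_span - start`` converts to
"distance upstream of the TSS".
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PromoterRecord",
    "PWM",
    "MotifHit",
    "CARG_RE",
    "carg_pwm",
    "scan_consensus",
    "relative_score",
    "scan_pwm",
    "conserved_hits",
]

CARG_RE = re.compile(r"CC[AT]{6}GG")
_ALPHABET = set("ACGTN")
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRecord:
    """An upstream regulatory sequence of one gene in one species."""

    species: str
    gene_id: str
    sequence: str
    upstream_span: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
        if self.upstream_span is None:
            object.__setattr__(self, "upstream_span", len(seq))


@dataclass(frozen=True)
class MotifHit:
    gene: str
    species: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # "+" or "-"
    matched: str  # window on the + strand
    consensus_match: bool
    relative_score: float
    conserved: bool = False

    def upstream_distance(self, upstream_span: int) -> int:
        """Distance of the hit start upstream of the TSS."""
        return upstream_span - self.start


class PWM:
    """Position count/weight matrix with log-odds scoring against a background.

    ``counts`` is 4 x L, rows in A, C, G, T order. A pseudocount (default
    0.8) is added to every cell before converting to log-odds.
    """

    def __init__(self, counts, background=None, pseudocount: float = 0.8):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (rows A, C, G, T)")
        if counts.shape[1] < 1:
            raise ValueError("PWM length must be >= 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or np.any(bg <= 0) or not math.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 positive frequencies summing to 1")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.counts = counts
        self.background = bg
        self.pseudocount = pseudocount
        adj = counts + pseudocount
        freq = adj / adj.sum(axis=0, keepdims=True)
        self.log_odds = np.log2(freq / bg[:, None])  # (4, L)
        self._smax = float(self.log_odds.max(axis=0).sum())
        self._smin = float(self.log_odds.min(axis=0).sum())
        self._degenerate = math.isclose(self._smax, self._smin)
        if self._degenerate:
            warnings.warn("degenerate PWM: max and min scores coincide", stacklevel=2)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_jaspar(cls, path_or_handle, **kwargs) -> "PWM":
        """Read a JASPAR-format count matrix (e.g. the SRF matrix MA0083.1)."""
        from Bio import motifs as bio_motifs

        if hasattr(path_or_handle, "read"):
            m = bio_motifs.read(path_or_handle, "jaspar")
        else:
            with open(path_or_handle) as fh:
                m = bio_motifs.read(fh, "jaspar")
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        return cls(counts, **kwargs)


def carg_pwm(core_weight: float = 20.0, off_weight: float = 1.0) -> PWM:
    """Synthetic CArG-consensus count matrix (for tests and demos).

    Built from the CC[A/T]6GG consensus itself: the consensus base(s) at
    each position get ``core_weight`` counts, other bases ``off_weight``.
    This is a stand-in constructed from the published consensus, not the
    JASPAR MA0083.1 count data.
    """
    cols = ["C", "C"] + ["AT"] * 6 + ["G", "G"]
    counts = np.full((4, 10), off_weight)
    for j, allowed in enumerate(cols):
        for b in allowed:
            counts[_BASE_IDX[b], j] = core_weight
    return PWM(counts)


def scan_consensus(record: PromoterRecord) -> list[MotifHit]:
    """All loci matching CC[A/T]6GG (strand-symmetric pattern class).

    The reverse complement of any CC[A/T]6GG 10-mer again matches the
    pattern, so each locus is reported once, on the plus strand. Windows
    containing N never match.
    """
    hits = []
    seq = record.sequence
    for pos in range(len(seq) - 9):
        window = seq[pos : pos + 10]
        if CARG_RE.fullmatch(window):
            hits.append(
                MotifHit(
                    gene=record.gene_id,
                    species=record.species,
                    start=pos,
                    end=pos + 10,
                    strand="+",
                    matched=window,
                    consensus_match=True,
                    relative_score=float("nan"),
                )
            )
    return hits


def relative_score(window: str, pwm: PWM) -> float:
    """Min-max scaled log-odds score of a window, in [0, 1].

    1.0 for the per-position-best word, 0.0 for the per-position-worst;
    a degenerate matrix (all words equal) scores 0.5 by convention.
    """
    window = window.upper()
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    if "N" in window:
        raise ValueError("window contains N")
    if pwm._degenerate:
        return 0.5
    s = sum(pwm.log_odds[_BASE_IDX[b], j] for j, b in enumerate(window))
    return float((s - pwm._smin) / (pwm._smax - pwm._smin))


def scan_pwm(
    record: PromoterRecord, pwm: PWM, threshold: float = 0.8
) -> list[MotifHit]:
    """Hits on both strands with relative score >= threshold.

    Windows containing N are skipped. Minus-strand hits report the
    plus-strand window as ``matched`` with strand "-". Consensus match is
    annotated independently of the score.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    seq = record.sequence
    L = pwm.length
    hits = []
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        if "N" in window:
            continue
        is_consensus = bool(CARG_RE.fullmatch(window)) if L == 10 else False
        for strand, word in (("+", window), ("-", reverse_complement(window))):
            score = relative_score(word, pwm)
            if score >= threshold:
                hits.append(
                    MotifHit(
                        gene=record.gene_id,
                        species=record.species,
                        start=pos,
                        end=pos + L,
                        strand=strand,
                        matched=window,
                        consensus_match=is_consensus,
                        relative_score=score,
                    )
                )
    return hits


def conserved_hits(
    hits_by_species: dict[str, list[MotifHit]], offset_tolerance: int = 50
) -> list[MotifHit]:
    """Hits shared by all species: identical matched 10-mer, nearby offset.

    A hit is conserved when every other species has a hit with the same
    matched word whose start offset differs by at most ``offset_tolerance``
    bases. Returns copies of all such hits with ``conserved=True``.
    """
    if len(hits_by_species) < 2:
        raise ValueError("conservation needs hits from at least 2 species")
    out = []
    for species, hits in hits_by_species.items():
        for hit in hits:
            shared = all(
                any(
                    other.matched == hit.matched
                    and abs(other.start - hit.start) <= offset_tolerance
                    for other in other_hits
                )
                for other_sp, other_hits in hits_by_species.items()
                if other_sp != species
            )
            if shared:
                out.append(replace(hit, conserved=True))
    return out
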