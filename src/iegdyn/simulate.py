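"""Synthetic inputs with the statistical structure of an immediate-early-gene study.

The generators emulate a hippocampal disinhibition experiment: a minority of
genes strongly induced within 90 minutes of treatment, measured as
treated/control fold changes in three biological replicas, sampled at a dozen
time points; plus replicate log2-ratio matrices for ranking, and promoter
sequences from several species carrying shared CArG boxes (CC[A/T]6GG).

Three trajectory templates stand in for the dynamical patterns this kind of
data exhibits:

* ``plateau`` — fast saturating rise, levelling off around 50 minutes
  (Hill curve ``1 + A*t^h/(t^h + tau^h)``),
* ``ramp`` — near-linear increase through the whole window (``1 + r*t``),
* ``pulse`` — transient peak near 50 minutes followed by decline
  (gamma-like ``1 + A*(t/tau)*exp(1 - t/tau)``).

Replica noise is log-normal (Gaussian in log2 space), parameterised by the
coefficient of variation on the linear scale, because fold changes are
ratio-scaled quantities.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .ranking import RatioMatrix
from .timecourse import TimeCourseSet
from .motifs import PromoterRecord, CARG_RE

__all__ = [
    "SimulationConfig",
    "PatternParams",
    "generate_timecourses",
    "generate_ratio_matrix",
    "generate_promoters",
    "generate_vocabulary",
    "pattern_template",
]

#: default sampling grid: 12 time points spanning 10..95 minutes
DEFAULT_TIME_POINTS = tuple(float(t) for t in np.linspace(10.0, 95.0, 12))


@dataclass(frozen=True)
class PatternParams:
    """Shape parameters of one planted trajectory template."""

    kind: str  # "plateau" | "ramp" | "pulse"
    amplitude: float = 5.0
    tau_min: float = 40.0  # characteristic time, minutes
    hill: float = 6.0  # plateau steepness
    rate: float = 0.05  # ramp slope, fold / minute
    shape: float = 3.0  # pulse sharpness; larger = more pronounced decline


DEFAULT_PATTERNS = (
    PatternParams("plateau", amplitude=6.0, tau_min=40.0, hill=6.0),
    PatternParams("ramp", rate=0.05),
    PatternParams("pulse", amplitude=5.0, tau_min=50.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters shared by all generators.

    ``noise_cv`` is the coefficient of variation of the multiplicative
    replica noise on the linear fold-change scale; ``effect_log2`` the mean
    log2 up-regulation of induced genes in ratio matrices.
    """

    n_genes: int = 33
    n_replicas: int = 3
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    cluster_profile_params: tuple[PatternParams, ...] = DEFAULT_PATTERNS
    noise_cv: float = 0.15
    n_up: int = 50
    n_flat: int = 950
    effect_log2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points, dtype=float)
        if tp.ndim != 1 or tp.size < 2:
            raise ValueError("time_points must be a 1-D sequence of >= 2 values")
        if not np.all(np.diff(tp) > 0):
            raise ValueError("time_points must be strictly increasing")
        if tp[0] <= 0:
            raise ValueError("time_points must all be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for name in ("n_genes", "n_replicas", "n_up", "n_flat"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def log2_noise_sd(noise_cv: float) -> float:
    """Gaussian sd in log2 space matching a linear-scale lognormal CV."""
    if noise_cv == 0:
        return 0.0
    return math.sqrt(math.log1p(noise_cv**2)) / math.log(2.0)


def pattern_template(params: PatternParams, times: np.ndarray) -> np.ndarray:
    """Noiseless fold-change template of one pattern at the given minutes."""
    t = np.asarray(times, dtype=float)
    if params.kind == "plateau":
        th = t**params.hill
        return 1.0 + params.amplitude * th / (th + params.tau_min**params.hill)
    if params.kind == "ramp":
        return 1.0 + params.rate * t
    if params.kind == "pulse":
        # gamma-like transient peaking at tau; the shape exponent sharpens
        # the peak and deepens the post-peak decline (>50% of the induction
        # lost by ~95 min at the default), while leaving the peak time fixed
        x = t / params.tau_min
        return 1.0 + params.amplitude * (x * np.exp(1.0 - x)) ** params.shape
    raise ValueError(f"unknown pattern kind: {params.kind!r}")


def generate_timecourses(
    config: SimulationConfig, cluster_sizes: list[int] | tuple[int, ...]
) -> tuple[TimeCourseSet, np.ndarray]:
    """Planted-pattern fold-change trajectories for every gene and replica.

    Each gene follows the noiseless template of its planted pattern;
    replicas differ by independent multiplicative (lognormal) noise.

    Returns the sampled :class:`TimeCourseSet` and the integer array of true
    pattern labels (one per gene).
    """
    sizes = [int(s) for s in cluster_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster_sizes must all be >= 1")
    if sum(sizes) != config.n_genes:
        raise ValueError(
            f"cluster_sizes sum to {sum(sizes)}, expected n_genes = {config.n_genes}"
        )
    if len(sizes) != len(config.cluster_profile_params):
        raise ValueError(
            "need one cluster size per planted pattern "
            f"({len(config.cluster_profile_params)} patterns, {len(sizes)} sizes)"
        )

    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.time_points, dtype=float)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    templates = np.stack(
        [pattern_template(p, times) for p in config.cluster_profile_params]
    )
    sd = log2_noise_sd(config.noise_cv)
    noise = rng.normal(0.0, 1.0, size=(config.n_genes, config.n_replicas, times.size))
    values = templates[labels][:, None, :] * np.exp2(sd * noise)

    gene_ids = [f"g{i + 1:03d}" for i in range(config.n_genes)]
    replica_ids = [f"r{j + 1}" for j in range(config.n_replicas)]
    return TimeCourseSet(gene_ids, replica_ids, times, values), labels


def generate_ratio_matrix(
    config: SimulationConfig, log2_sd: float | None = None
) -> tuple[RatioMatrix, np.ndarray]:
    """Replicate log2-ratio matrix with a planted minority of induced genes.

    The first ``n_up`` genes have mean log2 ratio ``effect_log2`` across
    replicas, the remaining ``n_flat`` have mean 0; per-replica Gaussian
    noise with sd ``log2_sd`` (default: the log2-domain sd implied by
    ``noise_cv``). Returns the matrix and the boolean true-up-regulated flags.
    """
    if config.n_up + config.n_flat != config.n_genes:
        raise ValueError(
            f"n_up + n_flat = {config.n_up + config.n_flat} != n_genes = {config.n_genes}"
        )
    sd = log2_noise_sd(config.noise_cv) if log2_sd is None else float(log2_sd)
    rng = np.random.default_rng(config.seed)
    up = np.zeros(config.n_genes, dtype=bool)
    up[: config.n_up] = True
    means = np.where(up, config.effect_log2, 0.0)
    values = means[:, None] + sd * rng.normal(
        size=(config.n_genes, config.n_replicas)
    )
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    replica_ids = [f"r{j + 1}" for j in range(config.n_replicas)]
    return RatioMatrix(gene_ids, values, replica_ids), up


_BASES = np.array(list("ACGT"))


def generate_promoters(
    n_species: int,
    length: int,
    planted_boxes: list[tuple[int, str]],
    divergence: float,
    seed: int,
    gene_id: str = "synthetic_gene",
    species: list[str] | None = None,
) -> list[PromoterRecord]:
    """Per-species promoter sequences sharing planted CArG boxes.

    One ancestral uniform-random sequence is drawn; planted boxes (each a
    10-mer matching CC[A/T]6GG) are written at their offsets; every species
    copy then accumulates i.i.d. substitutions at rate ``divergence`` outside
    the box positions (boxes are exempt, so they stay identical across
    species).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    for offset, box in planted_boxes:
        if not re.fullmatch(CARG_RE, box):
            raise ValueError(f"planted 10-mer {box!r} does not match CC[A/T]6GG")
        if offset < 0 or offset + len(box) > length:
            raise ValueError(f"planted box at {offset} does not fit in length {length}")
    if species is None:
        species = [f"sp{i + 1}" for i in range(n_species)]
    elif len(species) != n_species:
        raise ValueError("species labels must match n_species")

    rng = np.random.default_rng(seed)
    ancestral = rng.integers(0, 4, size=length)
    protected = np.zeros(length, dtype=bool)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for offset, box in planted_boxes:
        ancestral[offset : offset + len(box)] = [base_index[b] for b in box]
        protected[offset : offset + len(box)] = True

    records = []
    for label in species:
        seq = ancestral.copy()
        if divergence > 0:
            hit = (rng.random(length) < divergence) & ~protected
            # substitute to a uniformly chosen *different* base
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        records.append(
            PromoterRecord(
                species=label,
                gene_id=gene_id,
                sequence="".join(_BASES[seq]),
                upstream_span=length,
            )
        )
    return records


def generate_vocabulary(
    gene_ids: list[str],
    term_assignments: dict[str, list[str]],
    all_terms: list[str] | None = None,
) -> "dict[str, object]":
    """Convenience builder for a signed-term vocabulary over a gene universe.

    ``term_assignments`` maps a term (e.g. ``"GROWTH:-"``) to the genes that
    carry it. Returns the mapping consumed by :class:`iegdyn.enrichment.Vocabulary`.
    """
    from .enrichment import Vocabulary

    entries: dict[str, set[str]] = {g: set() for g in gene_ids}
    for term, genes in term_assignments.items():
        for g in genes:
            if g not in entries:
                raise ValueError(f"annotated gene {g!r} not in the gene universe")
            entries[g].add(term)
    terms = list(term_assignments) if all_terms is None else list(all_terms)
    return Vocabulary({g: frozenset(t) for g, t in entries.items()}, tuple(terms))
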