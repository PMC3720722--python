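"""End-to-end orchestration: simulate -> rank -> cluster -> enrich -> scan.

``run_pipeline`` drives the stages in the order the analysis is meant to be
read: replicate ranking of up-regulation, time-course clustering with
unsupervised k selection, cluster enrichment against a signed vocabulary,
and CArG-box scanning of promoters. Every stochastic stage is seeded from
the single config seed; a JSON manifest records parameters, seeds, library
versions and input checksums, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, enrichment, io, motifs, ranking, simulate, timecourse

logger = logging.getLogger("iegdyn")


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one pipeline run."""

    out_dir: str = "iegdyn_run"
    seed: int = 0
    # inputs; any left None is either simulated (simulate=True) or skipped
    treated: str | None = None
    control: str | None = None
    timecourses: str | None = None
    vocabulary: str | None = None
    promoters: list[str] = field(default_factory=list)
    pwm: str | None = None
    simulate: bool = False
    # stage parameters
    direction: str = "up"
    min_fold: float | None = 2.0
    max_p: float | None = 0.005
    smoothing: float | None = timecourse.DEFAULT_SMOOTHING
    grid_step: float = 1.0
    k_range: tuple[int, int] = (1, 8)
    alpha: float = timecourse.DEFAULT_ALPHA
    n_restarts: int = 100
    n_permutations: int = 1000
    pwm_threshold: float = 0.8
    offset_tolerance: int = 50
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config keys: {sorted(stray)}")
        cfg = cls(**raw)
        if isinstance(cfg.k_range, list):
            cfg.k_range = tuple(cfg.k_range)
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    pass


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all configured stages; returns the run directory.

    Stages with missing optional inputs are skipped with a warning. Partial
    outputs of a failed stage keep a ``.partial`` suffix.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, config.verbosity)

    inputs = {}
    for name in ("treated", "control", "timecourses", "vocabulary", "pwm"):
        p = getattr(config, name)
        if p is not None:
            if not Path(p).exists():
                raise FileNotFoundError(f"input {name!r} not found: {p}")
            inputs[name] = p
    for p in config.promoters:
        if not Path(p).exists():
            raise FileNotFoundError(f"promoter FASTA not found: {p}")
        inputs[f"promoters:{p}"] = p

    manifest = {
        "iegdyn_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"
        },
        "inputs": {k: _sha256(v) for k, v in inputs.items()},
        "versions": _library_versions(),
        "outputs": [],
    }

    if config.simulate:
        _simulate_stage(config, out, manifest)

    if config.treated and config.control:
        _rank_stage(config, out, manifest)
    else:
        logger.warning("ranking skipped: treated/control matrices not provided")

    assignments = None
    if config.timecourses:
        assignments = _cluster_stage(config, out, manifest)
    else:
        logger.warning("clustering skipped: no time-course table provided")

    if assignments is not None and config.vocabulary:
        _enrich_stage(config, out, manifest, assignments)
    elif config.vocabulary is None:
        logger.warning("enrichment skipped: no vocabulary provided")

    if config.promoters:
        _scan_stage(config, out, manifest)
    else:
        logger.warning("motif scan skipped: no promoter FASTA provided")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out)
    return out


def _setup_logging(out: Path, verbosity: str) -> None:
    logger.setLevel(getattr(logging, verbosity.upper(), logging.INFO))
    if not logger.handlers:
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)


def _library_versions() -> dict[str, str]:
    import Bio
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "biopython": Bio.__version__,
    }


def _emit(out: Path, name: str, writer, manifest) -> Path:
    """Write through a .partial temp name; rename only on success."""
    final = out / name
    partial = out / (name + ".partial")
    writer(partial)
    partial.replace(final)
    manifest["outputs"].append(name)
    return final


@_stage("simulate")
def _simulate_stage(config: PipelineConfig, out: Path, manifest) -> None:
    sim = simulate.SimulationConfig(seed=config.seed)
    tcs, labels = simulate.generate_timecourses(sim, [13, 14, 6])
    _emit(out, "sim_timecourses.tsv", lambda p: io.write_timecourses(tcs, p), manifest)
    rm_cfg = simulate.SimulationConfig(
        n_genes=1000, n_up=50, n_flat=950, seed=config.seed, noise_cv=0.15
    )
    rm, _ = simulate.generate_ratio_matrix(rm_cfg, log2_sd=0.3)
    _emit(out, "sim_ratios.tsv", lambda p: io.write_ratio_matrix(rm, p), manifest)
    promoters = simulate.generate_promoters(
        3, 2000, [(600, "CCTTATTAGG")], divergence=0.1, seed=config.seed
    )
    _emit(
        out,
        "sim_promoters.fa",
        lambda p: io.write_promoters_fasta(promoters, p),
        manifest,
    )
    # tag the first planted group with an anti-growth term, as a worked example
    vocab = simulate.generate_vocabulary(
        tcs.gene_ids,
        {
            "GROWTH:-": [g for g, l in zip(tcs.gene_ids, labels) if l == 0][:4],
            "GROWTH:+": [g for g, l in zip(tcs.gene_ids, labels) if l == 1][:6],
        },
    )
    _emit(out, "sim_vocabulary.tsv", lambda p: io.write_vocabulary(vocab, p), manifest)
    config.timecourses = str(out / "sim_timecourses.tsv")
    config.treated = config.control = None  # ratios already computed
    config.vocabulary = str(out / "sim_vocabulary.tsv")
    config.promoters = [str(out / "sim_promoters.fa")]
    ranking_obj = ranking.ecdf_pvalues(rm, direction=config.direction)
    _emit(out, "ranking.tsv", lambda p: io.write_ranking(ranking_obj, p), manifest)


@_stage("rank")
def _rank_stage(config: PipelineConfig, out: Path, manifest) -> None:
    treated = io.read_expression_matrix(config.treated)
    control = io.read_expression_matrix(config.control)
    ratios = ranking.compute_log2_ratios(treated, control)
    rank = ranking.ecdf_pvalues(ratios, direction=config.direction)
    selected = ranking.select_upregulated(rank, config.min_fold, config.max_p)
    _emit(out, "ratios.tsv", lambda p: io.write_ratio_matrix(ratios, p), manifest)
    _emit(out, "ranking.tsv", lambda p: io.write_ranking(rank, p), manifest)
    _emit(
        out,
        "selected_genes.txt",
        lambda p: Path(p).write_text("".join(g + "\n" for g in selected)),
        manifest,
    )
    logger.info("ranking: %d genes selected", len(selected))


@_stage("cluster")
def _cluster_stage(config: PipelineConfig, out: Path, manifest) -> dict[str, int]:
    tcs = io.read_timecourses(config.timecourses)
    bundle = timecourse.build_trajectories(
        tcs, smoothing=config.smoothing, grid_step=config.grid_step
    )
    k_lo, k_hi = config.k_range
    theta, k_opt, fits = timecourse.theta_criterion(
        bundle,
        range(k_lo, k_hi + 1),
        alpha=config.alpha,
        seed=config.seed,
        n_restarts=config.n_restarts,
    )
    best = fits[k_opt]
    z = timecourse.clustering_zscore(
        bundle, best.assignments, config.n_permutations, config.seed
    )
    best.z_score = z
    assignments = best.labels_dict()
    _emit(out, "clusters.tsv", lambda p: io.write_clusters(assignments, p), manifest)
    import pandas as pd

    _emit(
        out,
        "theta.tsv",
        lambda p: io.write_tsv(
            pd.DataFrame({"k": list(theta), "theta": list(theta.values())}), p
        ),
        manifest,
    )
    curves = pd.DataFrame(bundle.averages.T, index=bundle.grid, columns=bundle.gene_ids)
    _emit(
        out,
        "curves.tsv",
        lambda p: io.write_tsv(curves.rename_axis("time_min"), p, index=True),
        manifest,
    )
    summary = {
        "k_opt": int(k_opt),
        "z_score": z,
        "inertia": best.inertia,
        "seed": config.seed,
        "n_restarts": config.n_restarts,
        "theta_by_k": {str(k): v for k, v in theta.items()},
    }
    _emit(
        out,
        "cluster_summary.json",
        lambda p: Path(p).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n"),
        manifest,
    )
    logger.info("clustering: k_opt = %d, Z = %.2f", k_opt, z)
    return assignments


@_stage("enrich")
def _enrich_stage(config, out: Path, manifest, assignments) -> None:
    vocab = io.read_vocabulary(config.vocabulary)
    # restrict the vocabulary to the clustered universe
    entries = {g: t for g, t in vocab.entries.items() if g in assignments}
    vocab = enrichment.Vocabulary(entries, vocab.terms)
    table = enrichment.enrich_clusters(vocab, assignments)
    _emit(out, "enrichment.tsv", lambda p: io.write_tsv(table, p), manifest)


@_stage("scan")
def _scan_stage(config, out: Path, manifest) -> None:
    records = []
    for path in config.promoters:
        records.extend(io.read_promoters_fasta(path))
    pwm = (
        motifs.PWM.from_jaspar(config.pwm) if config.pwm else motifs.carg_pwm()
    )
    by_species: dict[str, list] = {}
    all_hits = []
    for rec in records:
        hits = motifs.scan_pwm(rec, pwm, config.pwm_threshold)
        by_species.setdefault(rec.species, []).extend(hits)
        all_hits.extend(hits)
    conserved = (
        motifs.conserved_hits(by_species, config.offset_tolerance)
        if len(by_species) >= 2
        else []
    )
    conserved_keys = {(h.species, h.start, h.strand, h.matched) for h in conserved}
    flagged = [
        dataclasses.replace(
            h, conserved=(h.species, h.start, h.strand, h.matched) in conserved_keys
        )
        for h in all_hits
    ]
    _emit(
        out,
        "carg_hits.tsv",
        lambda p: io.write_tsv(io.hits_to_frame(flagged), p),
        manifest,
    )
    _emit(out, "carg_hits.bed", lambda p: io.write_hits_bed(flagged, p), manifest)
    logger.info("motif scan: %d hits, %d conserved", len(flagged), len(conserved_keys))
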