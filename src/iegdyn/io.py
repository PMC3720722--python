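"""Readers and writers for the pipeline's tabular and sequence formats.

TSV is the canonical tabular format: UTF-8, "." decimal, mandatory header
row, floats written with 12 significant digits (lossless round trip at that
precision). Gene identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import Vocabulary
from .motifs import MotifHit, PromoterRecord
from .ranking import GeneRanking, RatioMatrix
from .timecourse import TimeCourseSet

FLOAT_FMT = "%.12g"


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes-in-rows expression TSV/CSV: first column gene id, header row."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no replica columns found")
    df.index = df.index.astype(str)
    return df


def write_ratio_matrix(ratios: RatioMatrix, path) -> None:
    write_tsv(ratios.to_frame().rename_axis("gene"), path, index=True)


def read_ratio_matrix(path) -> RatioMatrix:
    df = read_expression_matrix(path)
    return RatioMatrix(list(df.index), df.to_numpy(float), list(map(str, df.columns)))


def write_ranking(ranking: GeneRanking, path) -> None:
    write_tsv(ranking.to_frame(), path)


def write_timecourses(tcs: TimeCourseSet, path) -> None:
    write_tsv(tcs.to_frame(), path)


def read_timecourses(path) -> TimeCourseSet:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if {"ct_target_treated", "ct_ref_treated"}.issubset(df.columns):
        return timecourses_from_ct(df)
    return TimeCourseSet.from_frame(df)


def timecourses_from_ct(df: pd.DataFrame) -> TimeCourseSet:
    """Raw-Ct table -> fold changes via the ddCt method, then TimeCourseSet."""
    from .timecourse import ddct_fold_change

    need = {
        "gene",
        "replica",
        "time_min",
        "ct_target_treated",
        "ct_ref_treated",
        "ct_target_control",
        "ct_ref_control",
    }
    if not need.issubset(df.columns):
        raise ValueError(f"raw-Ct table must have columns {sorted(need)}")
    fold = [
        ddct_fold_change(r.ct_target_treated, r.ct_ref_treated,
                         r.ct_target_control, r.ct_ref_control)
        for r in df.itertuples()
    ]
    tidy = df[["gene", "replica", "time_min"]].copy()
    tidy["fold_change"] = fold
    return TimeCourseSet.from_frame(tidy)


def write_vocabulary(vocab: Vocabulary, path) -> None:
    with open(path, "w") as fh:
        fh.write("# terms: " + ";".join(vocab.terms) + "\n")
        fh.write("gene\tterms\n")
        for gene in vocab.entries:
            fh.write(f"{gene}\t{';'.join(sorted(vocab.entries[gene]))}\n")


def read_vocabulary(path) -> Vocabulary:
    """Vocabulary TSV: optional '# terms:' header line, then gene<TAB>terms
    with semicolon-separated signed terms. Without the header line the term
    set is the union of observed terms."""
    header_terms: list[str] | None = None
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            body_start += 1
            if "terms:" in line:
                header_terms = [
                    t.strip()
                    for t in line.split("terms:", 1)[1].split(";")
                    if t.strip()
                ]
        else:
            break
    df = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), sep="\t").fillna("")
    if not {"gene", "terms"}.issubset(df.columns):
        raise ValueError("vocabulary must have columns gene, terms")
    entries = {}
    for row in df.itertuples():
        terms = frozenset(t for t in str(row.terms).split(";") if t)
        entries[str(row.gene)] = terms
    if header_terms is None:
        header_terms = sorted(set().union(*entries.values()) if entries else set())
    return Vocabulary(entries, tuple(header_terms))


def write_clusters(assignments: dict[str, int], path) -> None:
    write_tsv(pd.DataFrame({"gene": list(assignments), "cluster": list(assignments.values())}), path)


def read_clusters(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene"].astype(str), df["cluster"].astype(int)))


def write_promoters_fasta(records: list[PromoterRecord], path) -> None:
    """Multi-FASTA with 'species|gene' headers."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=f"{r.species}|{r.gene_id}", description="")
        for r in records
    ]
    SeqIO.write(seqs, path, "fasta")


def read_promoters_fasta(path, species: str | None = None) -> list[PromoterRecord]:
    """Read promoters; headers 'species|gene', or pass ``species`` for plain ids."""
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        if "|" in rec.id:
            sp, gene = rec.id.split("|", 1)
        elif species is not None:
            sp, gene = species, rec.id
        else:
            raise ValueError(
                f"{path}: header {rec.id!r} lacks 'species|gene' form and no "
                "species label was given"
            )
        records.append(PromoterRecord(sp, gene, str(rec.seq)))
    return records


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [h.gene for h in hits],
            "species": [h.species for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "matched": [h.matched for h in hits],
            "consensus_match": [h.consensus_match for h in hits],
            "relative_score": [h.relative_score for h in hits],
            "conserved": [h.conserved for h in hits],
        }
    )


def write_hits_bed(hits: list[MotifHit], path) -> None:
    """BED6-style: chrom = gene id surrogate, score = 1000 * relative score."""
    with open(path, "w") as fh:
        for h in hits:
            score = 0 if np.isnan(h.relative_score) else int(round(1000 * h.relative_score))
            fh.write(
                f"{h.gene}\t{h.start}\t{h.end}\t{h.matched}\t{score}\t{h.strand}\n"
            )
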