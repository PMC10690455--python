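"""Readers and writers for the on-disk formats the pipeline touches.

All genomic intervals are converted to 0-based half-open on read (GTF starts
are shifted by -1). Tables are plain TSV with ``#`` comment lines.
"""

from __future__ import annotations

import random
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from .types import (
    SPIKEIN_PREFIX,
    CountMatrix,
    GeneModel,
    OutcomeTable,
    PWM,
    ReadIntervalSet,
    SampleTable,
)

_TSV_KW = dict(sep="\t", comment="#")


def read_counts(path: str | Path, library_sizes: str | Path | None = None) -> CountMatrix:
    """Read a gene x sample integer count TSV.

    First column holds gene ids, header row sample ids. Spike-in rows
    (``ERCC-`` prefix) are split off and excluded from library sizes.
    ``library_sizes`` optionally points at a two-column TSV
    (sample_id, total) overriding the default column sums.
    """
    df = pd.read_csv(path, index_col=0, **_TSV_KW)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no genes")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValueError(f"{path}: non-numeric count at gene {row!r}, sample {col!r}")
        if not np.allclose(vals, np.round(vals)):
            row = df.index[(vals != np.round(vals)).values][0]
            raise ValueError(f"{path}: non-integer count at gene {row!r}, sample {col!r}")
    mat = df.astype(np.int64)
    is_spike = mat.index.str.startswith(SPIKEIN_PREFIX)
    spikes = mat[is_spike] if is_spike.any() else None
    mat = mat[~is_spike]
    if mat.shape[0] == 0:
        raise ValueError(f"{path}: no genes (only spike-ins)")
    if library_sizes is not None:
        ls = pd.read_csv(library_sizes, index_col=0, **_TSV_KW).iloc[:, 0]
        lib = ls.reindex(mat.columns)
        if lib.isna().any():
            raise ValueError(f"{library_sizes}: missing totals for {list(lib.index[lib.isna()])}")
        lib = lib.to_numpy(float)
    else:
        lib = mat.sum(axis=0).to_numpy(float)
    return CountMatrix(list(mat.index), list(mat.columns), mat.to_numpy(), lib, spikes)


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, **_TSV_KW)
    if "stage" not in df.columns and "cohort" in df.columns:
        from .types import COHORT_STAGE

        df["stage"] = df["cohort"].map(COHORT_STAGE)
    return SampleTable(df)


# ---------------------------------------------------------------------------
# gene models

def _models_from_bed12(path: Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 needs 12 fields, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{ln}: blockSizes/blockStarts inconsistent with blockCount")
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            if exons[-1][1] != end:
                raise ValueError(f"{path}:{ln}: blocks do not end at chromEnd")
            tss = start if strand == "+" else end - 1
            out.append(GeneModel(name, chrom, strand, tss, exons))
    return out


def _models_from_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]) - 1, int(f[4]), f[6], f[8]
            tid = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("transcript_id"):
                    tid = part.split(None, 1)[1].strip().strip('"')
            if tid is None:
                raise ValueError(f"{path}: exon without transcript_id")
            rec = exons.setdefault(tid, {"chrom": chrom, "strand": strand, "exons": []})
            rec["exons"].append((start, end))
    out = []
    for tid, rec in exons.items():
        span = (min(a for a, _ in rec["exons"]), max(b for _, b in rec["exons"]))
        tss = span[0] if rec["strand"] == "+" else span[1] - 1
        out.append(GeneModel(tid, rec["chrom"], rec["strand"], tss, rec["exons"]))
    return out


def read_gene_models(path: str | Path, seed: int = 0) -> list[GeneModel]:
    """Read transcript models from BED12 or GTF.

    Transcript names of the form ``gene|isoform`` (or repeated gene_ids in
    GTF) are collapsed to one model per gene by choosing an isoform uniformly
    at random under ``seed``, mirroring random-isoform selection from an
    annotation database.
    """
    path = Path(path)
    if path.suffix.lower() in {".gtf", ".gff"}:
        models = _models_from_gtf(path)
    else:
        models = _models_from_bed12(path)
    by_gene: dict[str, list[GeneModel]] = {}
    for m in models:
        gene = m.gene_id.split("|")[0]
        by_gene.setdefault(gene, []).append(m)
    rng = random.Random(seed)
    chosen = []
    for gene in sorted(by_gene):
        isoforms = by_gene[gene]
        pick = isoforms[0] if len(isoforms) == 1 else rng.choice(isoforms)
        chosen.append(GeneModel(gene, pick.chrom, pick.strand, pick.tss, pick.exons))
    return chosen


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pwms(path: str | Path) -> list[PWM]:
    """Parse JASPAR-format PFM text (``>id name`` headers, 4 A/C/G/T rows)."""
    with open(path) as fh:
        try:
            parsed = motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise ValueError(f"{path}: malformed JASPAR file ({exc})") from exc
        out = []
        for m in parsed:
            lengths = {len(m.counts[b]) for b in "ACGT"}
            if len(lengths) != 1:
                raise ValueError(f"{path}: ragged rows in motif {m.matrix_id or m.name}")
            mat = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            # PWM validation covers negativity / zero columns
            out.append(PWM(m.matrix_id or m.name, mat))
    if not out:
        raise ValueError(f"{path}: no motifs parsed")
    return out


def read_read_intervals(
    path: str | Path, mark_name: str, stage_label: str, total_mapped: int | None = None
) -> ReadIntervalSet:
    """Read aligned-read intervals from BED (first three columns used)."""
    df = pd.read_csv(path, header=None, **_TSV_KW)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    chroms = df[0].astype(str).tolist()
    ivals = df[[1, 2]].to_numpy(np.int64)
    total = int(total_mapped) if total_mapped is not None else len(df)
    return ReadIntervalSet(mark_name, stage_label, ivals, chroms, total)


def write_read_intervals(rs: ReadIntervalSet, path: str | Path) -> None:
    pd.DataFrame(
        {"chrom": rs.chroms, "start": rs.intervals[:, 0], "end": rs.intervals[:, 1]}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_go_annotation(path: str | Path) -> dict[str, set[str]]:
    """TSV gene_id -> comma-separated GO terms (or one term per row)."""
    df = pd.read_csv(path, **_TSV_KW)
    gene_col, term_col = df.columns[:2]
    ann: dict[str, set[str]] = {}
    for gene, terms in zip(df[gene_col], df[term_col]):
        if pd.isna(terms):
            continue
        ann.setdefault(str(gene), set()).update(
            t for t in str(terms).split(",") if t
        )
    return ann


def read_outcome_table(path: str | Path) -> OutcomeTable:
    return OutcomeTable(pd.read_csv(path, **_TSV_KW))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = cm.to_frame()
    if cm.spikeins is not None:
        df = pd.concat([df, cm.spikeins])
    df.index.name = "gene_id"
    write_tsv(df, path, index=True)


def write_gene_models_bed12(models: list[GeneModel], path: str | Path) -> None:
    rows = []
    for m in models:
        start, end = m.span
        sizes = ",".join(str(b - a) for a, b in m.exons)
        starts = ",".join(str(a - start) for a, b in m.exons)
        rows.append(
            [m.chrom, start, end, m.gene_id, 0, m.strand, start, end, "0",
             len(m.exons), sizes, starts]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
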