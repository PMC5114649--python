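"""Readers and writers for the plain-text formats the pipeline exchanges.

BED (3+ columns, half-open), FASTA (via Biopython), tab-delimited tables
for expression, methylation, het sites and allelic counts, and fixed-step
wiggle text for depth tracks. Every reader validates the invariants of the
container it builds; writers emit exactly what the readers accept, so
round-trips are identity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DepthTrack,
    ExpressionMatrix,
    GenomicInterval,
    HetSite,
    MethylationDataset,
    ParseError,
    PeakSet,
    SampleRecord,
    SchemaError,
    TSSRecord,
)

logger = logging.getLogger("xescape")

_TSS_META_COLS = ["tss_id", "chrom", "start", "end", "strand",
                  "nearest_gene", "par_flag", "repeat_overlap"]


# ---------------------------------------------------------------- BED

def read_bed(path, **peak_attrs) -> PeakSet:
    """Read a BED3+ file into a :class:`PeakSet`.

    ``track``/``browser``/``#`` header lines are skipped. Malformed lines
    (fewer than 3 columns, non-integer coordinates, end <= start) raise
    :class:`ParseError` naming the offending line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals=intervals, **peak_attrs)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for iv in peaks.intervals:
            name = peaks.dataset_id or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------- expression

def read_expression(path):
    """Read an expression TSV into (ExpressionMatrix, [TSSRecord]).

    Layout: annotation columns ``tss_id chrom start end strand nearest_gene
    par_flag repeat_overlap`` followed by one numeric column per sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _TSS_META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing annotation columns {missing}")
    if df["tss_id"].duplicated().any():
        dup = df.loc[df["tss_id"].duplicated(), "tss_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate tss_id {dup!r}")
    sample_cols = [c for c in df.columns if c not in _TSS_META_COLS]
    values = df[sample_cols].to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative expression value")
    records = [
        TSSRecord(
            tss_id=row.tss_id,
            location=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            nearest_gene=row.nearest_gene,
            par_flag=bool(row.par_flag),
            repeat_overlap=bool(row.repeat_overlap),
        )
        for row in df.itertuples(index=False)
    ]
    matrix = ExpressionMatrix(df["tss_id"].tolist(), sample_cols, values)
    return matrix, records


def write_expression(matrix: ExpressionMatrix, records, path) -> None:
    by_id = {r.tss_id: r for r in records}
    meta = {
        "tss_id": matrix.tss_ids,
        "chrom": [by_id[t].location.chrom for t in matrix.tss_ids],
        "start": [by_id[t].location.start for t in matrix.tss_ids],
        "end": [by_id[t].location.end for t in matrix.tss_ids],
        "strand": [by_id[t].location.strand for t in matrix.tss_ids],
        "nearest_gene": [by_id[t].nearest_gene for t in matrix.tss_ids],
        "par_flag": [by_id[t].par_flag for t in matrix.tss_ids],
        "repeat_overlap": [by_id[t].repeat_overlap for t in matrix.tss_ids],
    }
    out = pd.concat([pd.DataFrame(meta), matrix.to_frame().reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- samples

def read_samples(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex_label"}
    if not required.issubset(df.columns):
        raise SchemaError(f"{path}: need columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        cats = getattr(row, "categories", "")
        cats = frozenset(str(cats).split(",")) - {"", "nan"} if pd.notna(cats) else frozenset()
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                sex_label=row.sex_label,
                categories=cats,
                donor_id=str(getattr(row, "donor_id", row.sample_id)),
                replicate_index=int(getattr(row, "replicate_index", 1)),
                treated=bool(getattr(row, "treated", False)),
            )
        )
    if len({r.sample_id for r in records}) != len(records):
        raise SchemaError(f"{path}: duplicate sample_id")
    return records


def write_samples(samples, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "sex_label": [s.sex_label for s in samples],
            "donor_id": [s.donor_id for s in samples],
            "replicate_index": [s.replicate_index for s in samples],
            "treated": [s.treated for s in samples],
            "categories": [",".join(sorted(s.categories)) for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def filter_samples(samples) -> list:
    """Drop treated samples and all but the first donation per donor."""
    kept = [
        s for s in samples
        if not s.treated and s.replicate_index == 1
    ]
    n_dropped = len(samples) - len(kept)
    if n_dropped:
        logger.info("filter_samples: dropped %d of %d samples", n_dropped, len(samples))
    return kept


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict:
    """Read FASTA into {name: upper-case sequence string}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------- methylation

def read_methylation(betas_path, covariates_path) -> MethylationDataset:
    """Read probe betas (``probe_id chrom pos`` + sample columns; ``pos``
    1-based in the file) and per-sample covariates (``sample_id sex [age stage]``)."""
    df = pd.read_csv(betas_path, sep="\t", dtype={"chrom": str})
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise SchemaError(f"{betas_path}: missing column {col!r}")
    if df["probe_id"].duplicated().any():
        raise SchemaError(f"{betas_path}: duplicate probe_id")
    sample_cols = [c for c in df.columns if c not in ("probe_id", "chrom", "pos")]
    betas = df.set_index("probe_id")[sample_cols]
    positions = {
        row.probe_id: GenomicInterval(row.chrom, int(row.pos) - 1, int(row.pos))
        for row in df.itertuples(index=False)
    }
    covars = pd.read_csv(covariates_path, sep="\t").set_index("sample_id")
    return MethylationDataset(betas=betas, probe_positions=positions, covariates=covars)


def write_methylation(dataset: MethylationDataset, betas_path, covariates_path) -> None:
    meta = pd.DataFrame(
        {
            "probe_id": dataset.betas.index,
            "chrom": [dataset.probe_positions[p].chrom for p in dataset.betas.index],
            "pos": [dataset.probe_positions[p].start + 1 for p in dataset.betas.index],
        }
    )
    pd.concat([meta, dataset.betas.reset_index(drop=True)], axis=1).to_csv(
        betas_path, sep="\t", index=False
    )
    dataset.covariates.to_csv(covariates_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------- het sites

def read_het_sites(path) -> list:
    """Read het sites (``site_id chrom pos allele_a allele_b maternal paternal``;
    ``pos`` 1-based in the file, stored 0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        HetSite(
            site_id=row.site_id,
            chrom=row.chrom,
            pos=int(row.pos) - 1,
            allele_a=row.allele_a,
            allele_b=row.allele_b,
            maternal=row.maternal,
            paternal=row.paternal,
        )
        for row in df.itertuples(index=False)
    ]


def write_het_sites(hets, path) -> None:
    pd.DataFrame(
        {
            "site_id": [h.site_id for h in hets],
            "chrom": [h.chrom for h in hets],
            "pos": [h.pos + 1 for h in hets],
            "allele_a": [h.allele_a for h in hets],
            "allele_b": [h.allele_b for h in hets],
            "maternal": [h.maternal for h in hets],
            "paternal": [h.paternal for h in hets],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- allelic counts

ALLELIC_COUNT_COLS = ["site_id", "dataset_id", "factor", "lab",
                      "count_allele_a", "count_allele_b"]


def read_allelic_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELIC_COUNT_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if (df[["count_allele_a", "count_allele_b"]] < 0).any().any():
        raise ValueError(f"{path}: negative read count")
    return df


def write_allelic_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- depth tracks

def read_wiggle(path) -> DepthTrack:
    """Read a fixedStep step=1 wiggle file (1-based starts)."""
    chunks: dict = {}
    chrom, pos = None, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1
                if int(kv.get("step", 1)) != 1:
                    raise ParseError(f"{path}:{lineno}: only step=1 supported")
                chunks.setdefault(chrom, [])
            else:
                if chrom is None:
                    raise ParseError(f"{path}:{lineno}: value before fixedStep header")
                try:
                    val = float(line)
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric value") from exc
                chunks[chrom].append((pos, val))
                pos += 1
    coverage = {}
    for c, pairs in chunks.items():
        size = max(p for p, _ in pairs) + 1
        arr = np.zeros(size)
        for p, v in pairs:
            arr[p] = v
        coverage[c] = arr
    return DepthTrack(coverage=coverage)


def write_wiggle(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, vals in track.coverage.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(f"{v:g}" for v in vals))
            fh.write("\n")
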