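"""Shared domain types and coordinate conventions.

All coordinates are internally 0-based, half-open ``[start, end)`` (BED
convention). Inputs that arrive 1-based (e.g. methylation probe positions
given as single bases) are converted on read. Strand-aware logic is limited
to locating the 5' end of a TSS; every window in the pipeline (±50 bp,
±500 bp, ±5 kb) is applied symmetrically around that point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")

#: IUPAC degenerate codes for unordered heterozygous base pairs.
IUPAC_PAIRS = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

#: Bases represented by each (possibly degenerate) genome symbol.
IUPAC_BASES = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "N": frozenset("ACGT"),
}


class SchemaError(ValueError):
    """An input table violates the expected schema (columns, uniqueness)."""


class ParseError(ValueError):
    """A text input could not be parsed; the message names the line."""


class ConfigError(ValueError):
    """An infeasible or inconsistent configuration."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval; ``strand`` is '+', '-' or '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Point overlap under half-open semantics: [100,200) covers 199, not 200."""
        return self.start <= pos < self.end

    def distance_to_point(self, pos: int) -> int:
        """0 if ``pos`` falls inside the interval, else the gap in bp."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' position (start for '+'/'.', end-1 for '-')."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass
class SampleRecord:
    """One cohort sample with the attributes driving sample exclusion."""

    sample_id: str
    sex_label: str = "unknown"  # male / female / unknown
    categories: frozenset = frozenset()
    donor_id: str = ""
    replicate_index: int = 1
    treated: bool = False

    def __post_init__(self) -> None:
        if self.sex_label not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex_label {self.sex_label!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        self.categories = frozenset(self.categories)


@dataclass
class TSSRecord:
    """A CAGE-style TSS with its nearest-gene label and filter flags.

    ``par_flag`` marks pseudoautosomal TSSs (excluded from X-specific
    analyses); ``repeat_overlap`` marks TSSs overlapping repetitive
    elements (excluded before differential testing).
    """

    tss_id: str
    location: GenomicInterval
    nearest_gene: str = ""
    par_flag: bool = False
    repeat_overlap: bool = False

    @property
    def five_prime(self) -> int:
        return self.location.five_prime

    @property
    def chrom(self) -> str:
        return self.location.chrom

    def is_x_nonpar(self, x_chrom: str = "chrX") -> bool:
        return self.location.chrom == x_chrom and not self.par_flag


class ExpressionMatrix:
    """TSS x sample matrix of tags-per-million values (non-negative)."""

    def __init__(self, tss_ids, sample_ids, values) -> None:
        values = np.asarray(values, dtype=float)
        tss_ids = list(tss_ids)
        sample_ids = list(sample_ids)
        if values.shape != (len(tss_ids), len(sample_ids)):
            raise SchemaError(
                f"matrix shape {values.shape} does not match "
                f"{len(tss_ids)} TSSs x {len(sample_ids)} samples"
            )
        if len(set(tss_ids)) != len(tss_ids):
            raise SchemaError("duplicate tss_id in expression matrix")
        if len(set(sample_ids)) != len(sample_ids):
            raise SchemaError("duplicate sample_id in expression matrix")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite and >= 0")
        self.tss_ids = tss_ids
        self.sample_ids = sample_ids
        self.values = values

    @property
    def shape(self):
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tss_ids, columns=self.sample_ids)

    def subset_tss(self, ids) -> "ExpressionMatrix":
        idx = {t: i for i, t in enumerate(self.tss_ids)}
        rows = [idx[t] for t in ids]
        return ExpressionMatrix(list(ids), self.sample_ids, self.values[rows])

    def subset_samples(self, ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in ids]
        return ExpressionMatrix(self.tss_ids, list(ids), self.values[:, cols])


@dataclass
class PeakSet:
    """A named set of peak intervals from one ChIP-seq/DNase dataset."""

    intervals: list
    dataset_id: str = ""
    factor: str = ""
    cell: str = ""
    cell_sex: str = ""
    lab: str = ""


@dataclass
class DepthTrack:
    """Per-base coverage, one non-negative float array per chromosome."""

    coverage: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coverage = {c: np.asarray(v, dtype=float) for c, v in self.coverage.items()}
        for chrom, vals in self.coverage.items():
            if np.any(vals < 0):
                raise ValueError(f"negative coverage on {chrom}")


@dataclass
class MethylationDataset:
    """450k-style beta values with probe coordinates and sample covariates.

    ``betas``: probe x sample DataFrame in [0, 1].
    ``probe_positions``: probe -> 1-bp GenomicInterval.
    ``covariates``: per-sample DataFrame with at least a ``sex`` column;
    ``age``/``stage`` are required only for the autosomal nested-model test.
    """

    betas: pd.DataFrame
    probe_positions: dict
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.betas.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if "sex" not in self.covariates.columns:
            raise SchemaError("covariates require a 'sex' column")
        missing = set(self.betas.columns) - set(self.covariates.index)
        if missing:
            raise SchemaError(f"samples without covariates: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class HetSite:
    """A phased heterozygous site; alleles are single upper-case bases."""

    site_id: str
    chrom: str
    pos: int  # 0-based
    allele_a: str
    allele_b: str
    maternal: str
    paternal: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.site_id}: homozygous allele pair")
        if {self.maternal, self.paternal} != {self.allele_a, self.allele_b}:
            raise ValueError(f"{self.site_id}: phase does not match the allele pair")

    @property
    def iupac(self) -> str:
        return IUPAC_PAIRS[frozenset((self.allele_a, self.allele_b))]

    def xi_allele(self, xi_parent: str = "paternal") -> str:
        if xi_parent not in ("maternal", "paternal"):
            raise ValueError("xi_parent must be 'maternal' or 'paternal'")
        return self.paternal if xi_parent == "paternal" else self.maternal


def merge_intervals(intervals) -> list:
    """Merge overlapping/adjacent intervals per chromosome (strand dropped)."""
    by_chrom: dict = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged
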