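"""PFM motif scanning and over-representation around TSS flanks.

Motifs are position-frequency matrices (JASPAR text format); only motifs
with at least 8 bits of total information content are informative enough
to scan. TSS flanks (±500 bp, merged) are scanned on both strands at a
relative log-odds score threshold (default 85% of the motif's score
range), and per-motif over-representation is a one-tailed Fisher exact
test of regions-with-hit counts against either a GC/length-matched or a
non-differentially-transcribed background region set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from .core import GenomicInterval, merge_intervals

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifModel:
    """A PFM with pseudocount regularization over a background."""

    motif_id: str
    counts: np.ndarray  # 4 x L, rows A, C, G, T
    pseudocount: float = 0.8
    background: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be a 4 x L matrix with L >= 1")
        if np.any(self.counts < 0) or np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError("counts must be non-negative with positive column sums")
        bg = np.asarray(self.background, dtype=float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        """Column probabilities with the pseudocount spread by background."""
        bg = np.asarray(self.background)[:, None]
        return (self.counts + self.pseudocount * bg) / (
            self.counts.sum(axis=0) + self.pseudocount
        )

    def pssm(self) -> np.ndarray:
        """log2 odds versus the background frequencies."""
        bg = np.asarray(self.background)[:, None]
        return np.log2(self.probabilities() / bg)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmax(self.probabilities(), axis=0))

    def anti_consensus(self) -> str:
        return "".join("ACGT"[i] for i in np.argmin(self.pssm(), axis=0))


def information_content(motif: MotifModel) -> float:
    """Total specificity in bits: sum over columns of 2 + sum_b p log2 p."""
    p = motif.probabilities()
    return float(np.sum(2.0 + np.sum(p * np.log2(p), axis=0)))


def filter_by_information(models, min_bits: float = 8.0) -> list:
    return [m for m in models if information_content(m) >= min_bits]


def read_jaspar(path, pseudocount: float = 0.8) -> list:
    """Read JASPAR-format PFMs into MotifModels."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float)
        mid = m.matrix_id or m.name
        out.append(MotifModel(motif_id=mid, counts=counts, pseudocount=pseudocount))
    return out


@dataclass
class RegionSet:
    """Merged intervals with their extracted sequences."""

    intervals: list
    sequences: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequences and len(self.sequences) != len(self.intervals):
            raise ValueError("one sequence per interval required")
        for iv, seq in zip(self.intervals, self.sequences):
            if len(seq) != len(iv):
                raise ValueError(f"sequence length mismatch at {iv.chrom}:{iv.start}")

    def gc_fractions(self) -> np.ndarray:
        out = []
        for seq in self.sequences:
            acgt = sum(seq.count(b) for b in "ACGT")
            gc = seq.count("G") + seq.count("C")
            out.append(gc / acgt if acgt else 0.0)
        return np.array(out)


def build_regions(tsss, genome: dict, flank: int = 500) -> RegionSet:
    """±flank windows around strand-aware 5' TSS positions, merged, with
    sequences extracted; windows running off a contig are clipped."""
    windows = []
    for tss in tsss:
        contig = genome[tss.chrom]
        p5 = tss.five_prime
        start = max(0, p5 - flank)
        end = min(len(contig), p5 + flank + 1)
        windows.append(GenomicInterval(tss.chrom, start, end))
    merged = merge_intervals(windows)
    seqs = [genome[iv.chrom][iv.start:iv.end].upper() for iv in merged]
    return RegionSet(intervals=merged, sequences=seqs)


def _encode(seq: str) -> np.ndarray:
    idx = np.full(len(seq), 4, dtype=np.int8)  # 4 = N / anything else
    for b, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return idx


def scan_region(seq: str, motif: MotifModel, rel_threshold: float = 0.85) -> list:
    """Scan both strands; return hits as (offset, strand, rel_score).

    The relative score normalizes the window log-odds into the motif's
    attainable range: (score - min) / (max - min). N positions contribute
    zero log-odds. Offsets index the forward sequence for both strands.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must lie in (0, 1]")
    L = motif.length
    n = len(seq)
    if L > n:
        return []
    pssm = motif.pssm()
    smin, smax = pssm.min(axis=0).sum(), pssm.max(axis=0).sum()
    span = smax - smin if smax > smin else 1.0
    idx = _encode(seq.upper())
    ext = np.vstack([pssm, np.zeros(L)])  # row 4: N scores 0
    rc = np.vstack([pssm[::-1, ::-1], np.zeros(L)])  # minus strand on fwd offsets
    hits = []
    for mat, strand in ((ext, "+"), (rc, "-")):
        scores = np.zeros(n - L + 1)
        for j in range(L):
            scores += mat[idx[j:j + n - L + 1], j]
        rel = (scores - smin) / span
        for off in np.nonzero(rel >= rel_threshold - 1e-12)[0]:
            hits.append((int(off), strand, float(rel[off])))
    return sorted(hits)


def count_regions_with_hit(regions: RegionSet, motif: MotifModel,
                           rel_threshold: float = 0.85) -> int:
    return sum(bool(scan_region(seq, motif, rel_threshold)) for seq in regions.sequences)


def gc_length_matched_background(targets: RegionSet, pool: RegionSet,
                                 gc_tol: float = 0.05, len_tol: float = 0.10,
                                 n_per_target: int = 10, seed=None) -> RegionSet:
    """Sample, per target region, ``n_per_target`` pool regions with GC
    within ±gc_tol and length within ±len_tol (relative), without
    replacement across the whole draw. Raises if a target cannot be
    matched, naming it."""
    rng = np.random.default_rng(seed)
    pool_gc = pool.gc_fractions()
    pool_len = np.array([len(iv) for iv in pool.intervals], dtype=float)
    target_gc = targets.gc_fractions()
    available = np.ones(len(pool.intervals), dtype=bool)
    chosen = []
    for i, (iv, gc) in enumerate(zip(targets.intervals, target_gc)):
        ok = (
            available
            & (np.abs(pool_gc - gc) <= gc_tol + 1e-12)
            & (np.abs(pool_len - len(iv)) <= len_tol * len(iv) + 1e-9)
        )
        cand = np.nonzero(ok)[0]
        if cand.size < n_per_target:
            raise ValueError(
                f"cannot match target {iv.chrom}:{iv.start}-{iv.end} "
                f"(GC {gc:.3f}, len {len(iv)}): {cand.size} of "
                f"{n_per_target} candidates"
            )
        pick = rng.choice(cand, size=n_per_target, replace=False)
        available[pick] = False
        chosen.extend(pick.tolist())
    return RegionSet(
        intervals=[pool.intervals[i] for i in chosen],
        sequences=[pool.sequences[i] for i in chosen],
    )


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    target_hit_regions: int
    target_regions: int
    background_hit_regions: int
    background_regions: int
    fisher_score: float  # -ln of the one-tailed enrichment p
    fold: float
    p_value: float


def fisher_motif_test(motif_id: str, target_hits: int, target_regions: int,
                      background_hits: int, background_regions: int) -> MotifEnrichmentResult:
    """One-tailed (enrichment) Fisher exact on regions-with-hit counts."""
    from scipy.stats import fisher_exact

    if background_regions == 0:
        raise ValueError("background region set is empty")
    if target_hits > target_regions or background_hits > background_regions:
        raise ValueError("hit counts exceed region counts")
    table = [[target_hits, target_regions - target_hits],
             [background_hits, background_regions - background_hits]]
    _, p = fisher_exact(table, alternative="greater")
    target_rate = target_hits / target_regions
    bg_rate = background_hits / background_regions
    fold = target_rate / bg_rate if bg_rate > 0 else (np.inf if target_rate > 0 else 0.0)
    return MotifEnrichmentResult(
        motif_id=motif_id,
        target_hit_regions=target_hits,
        target_regions=target_regions,
        background_hit_regions=background_hits,
        background_regions=background_regions,
        fisher_score=float(-np.log(max(p, np.finfo(float).tiny))),
        fold=float(fold),
        p_value=float(p),
    )


def rank_motifs(results_by_background: dict, percentile: float = 95.0):
    """Motifs with Fisher score strictly above the per-background
    percentile; returns ({background: set of motif ids}, intersection).
    Percentile 0 returns every motif."""
    top_by_bg = {}
    for bg, results in results_by_background.items():
        scores = np.array([r.fisher_score for r in results])
        if percentile <= 0:
            top = {r.motif_id for r in results}
        else:
            cut = np.percentile(scores, percentile)
            top = {r.motif_id for r in results if r.fisher_score > cut}
        top_by_bg[bg] = top
    inter = set.intersection(*top_by_bg.values()) if top_by_bg else set()
    return top_by_bg, inter
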