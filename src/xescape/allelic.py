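"""Phased allelic ChIP-seq imbalance between the active and inactive X.

The pipeline builds a personalized genome with heterozygous positions as
IUPAC degenerate codes (so neither allele's reads pay a mismatch),
exhaustively simulates every read window over each het site to filter out
positions with allele-biased mapability, assigns phased counts to Xa/Xi
(paternal X = Xi in GM12878), and tests each (site, dataset) pair for
imbalance against the dataset's overall Xa:Xi read totals with a Fisher
exact test and Benjamini-Hochberg FDR control. The imbalance score
log2((Ra+1)/(Ri+1)) is the visualization-scale statistic: positive means
Xa-biased binding.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import IUPAC_BASES, IUPAC_PAIRS, GenomicInterval, merge_intervals

logger = logging.getLogger("xescape")

_COMPLEMENT = str.maketrans("ACGTRYSWKMN", "TGCAYRSWMKN")
#: bitmask per genome symbol: A=1, C=2, G=4, T=8, degenerate = union
_BITS = {sym: sum(1 << "ACGT".index(b) for b in bases)
         for sym, bases in IUPAC_BASES.items()}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_personalized_genome(sequences: dict, hets) -> dict:
    """Replace each het position with its IUPAC degenerate code.

    The reference base must be one of the site's two alleles; a mismatch
    raises a consistency error naming the site.
    """
    out = {}
    mutable = {c: list(s.upper()) for c, s in sequences.items()}
    for h in hets:
        if h.chrom not in mutable:
            raise ValueError(f"{h.site_id}: unknown chromosome {h.chrom}")
        ref = mutable[h.chrom][h.pos]
        if ref not in (h.allele_a, h.allele_b):
            raise ValueError(
                f"{h.site_id}: reference base {ref} at {h.chrom}:{h.pos} "
                f"matches neither allele {h.allele_a}/{h.allele_b}"
            )
        mutable[h.chrom][h.pos] = IUPAC_PAIRS[frozenset((h.allele_a, h.allele_b))]
    for c, chars in mutable.items():
        out[c] = "".join(chars)
    return out


def enumerate_simulated_reads(sequences: dict, hets, regions,
                              read_len: int = 36, region_flank: int = 100) -> list:
    """Every possible read window over each in-region het, per allele and
    strand.

    ``regions`` are peak intervals; each is widened by ``region_flank`` bp
    and the set merged before the in-region test. An interior het yields
    read_len offsets x 2 alleles x 2 strands reads; windows truncated by
    contig ends are dropped. Returns (site_id, allele, strand, offset, seq)
    tuples, reads instantiated from the reference with the focal allele
    substituted.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    widened = [
        GenomicInterval(iv.chrom, max(0, iv.start - region_flank), iv.end + region_flank)
        for iv in regions
    ]
    merged = merge_intervals(widened)
    by_chrom: dict = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    reads = []
    for h in hets:
        if not any(iv.contains(h.pos) for iv in by_chrom.get(h.chrom, [])):
            continue
        contig = sequences[h.chrom]
        for off in range(read_len):
            start = h.pos - off
            if start < 0 or start + read_len > len(contig):
                continue
            window = list(contig[start:start + read_len].upper())
            for allele in (h.allele_a, h.allele_b):
                window[off] = allele
                fwd = "".join(window)
                reads.append((h.site_id, allele, "+", off, fwd))
                reads.append((h.site_id, allele, "-", off, _revcomp(fwd)))
    return reads


def _match_positions(read: str, genome_bits: np.ndarray) -> int:
    """Number of positions where the read matches the (IUPAC) genome."""
    L = len(read)
    n = genome_bits.size
    if L > n:
        return 0
    rb = np.array([_BITS.get(b, 0) for b in read], dtype=np.int8)
    ok = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        ok &= (genome_bits[j:j + n - L + 1] & rb[j]) != 0
        if not ok.any():
            return 0
    return int(ok.sum())


def toy_unique_mapper(reads, sequences: dict, max_n_bases: int = 0) -> list:
    """Map each read exactly against the IUPAC genome, both strands.

    A read base matches a genome symbol if it is contained in the symbol's
    degenerate base set. Status is ``unique`` (exactly one match over both
    strands and all contigs), ``multi`` (more), or ``unmapped`` (none, or
    more than ``max_n_bases`` ambiguous bases in the read itself).
    Returns (site_id, allele, strand, offset, status) tuples.
    """
    bits = {c: np.array([_BITS.get(b, 0) for b in s.upper()], dtype=np.int8)
            for c, s in sequences.items()}
    out = []
    cache: dict = {}
    for site_id, allele, strand, off, seq in reads:
        if seq in cache:
            status = cache[seq]
        else:
            if sum(seq.count(b) for b in "ACGT") < len(seq) - max_n_bases:
                status = "unmapped"
            else:
                total = 0
                rc = _revcomp(seq)
                for gb in bits.values():
                    total += _match_positions(seq, gb)
                    total += _match_positions(rc, gb)
                    if total > 1:
                        break
                status = "unique" if total == 1 else ("multi" if total > 1 else "unmapped")
            cache[seq] = status
        out.append((site_id, allele, strand, off, status))
    return out


def unique_read_counts(mapped) -> pd.DataFrame:
    """Per (site, allele) counts of uniquely mapped simulated reads."""
    df = pd.DataFrame(mapped, columns=["site_id", "allele", "strand", "offset", "status"])
    uniq = df[df["status"] == "unique"]
    counts = uniq.groupby(["site_id", "allele"]).size().rename("n_unique").reset_index()
    # sites with zero unique reads for an allele still need a row
    all_pairs = df[["site_id", "allele"]].drop_duplicates()
    counts = all_pairs.merge(counts, on=["site_id", "allele"], how="left").fillna(0)
    counts["n_unique"] = counts["n_unique"].astype(int)
    return counts


def mapability_filter(allele_counts: pd.DataFrame, lo: float = 0.4,
                      hi: float = 0.6) -> list:
    """Sites whose unique simulated-read counts are allele-balanced.

    A site is kept iff either allele's unique-read fraction lies in
    [lo, hi] (the two readings coincide by complementarity when
    lo = 1 - hi); zero-total sites are dropped.
    """
    kept = []
    for site_id, grp in allele_counts.groupby("site_id", sort=True):
        total = grp["n_unique"].sum()
        if total == 0:
            continue
        frac = grp["n_unique"].iloc[0] / total
        if lo <= frac <= hi or lo <= 1 - frac <= hi:
            kept.append(site_id)
    return kept


def assign_alleles(raw_counts: pd.DataFrame, hets,
                   xi_parent: str = "paternal") -> pd.DataFrame:
    """Turn per-allele counts into Xa/Xi counts using the phase.

    ``raw_counts`` columns: site_id, dataset_id, factor, lab,
    count_allele_a, count_allele_b. The count of the ``xi_parent`` allele
    becomes Ri, the other Ra. Sites without a het record are excluded
    (logged).
    """
    by_id = {h.site_id: h for h in hets}
    rows, skipped = [], 0
    for rec in raw_counts.itertuples(index=False):
        h = by_id.get(rec.site_id)
        if h is None:
            skipped += 1
            continue
        xi = h.xi_allele(xi_parent)
        if xi == h.allele_a:
            ri, ra = rec.count_allele_a, rec.count_allele_b
        else:
            ri, ra = rec.count_allele_b, rec.count_allele_a
        rows.append((rec.site_id, rec.dataset_id, rec.factor, rec.lab,
                     int(ra), int(ri)))
    if skipped:
        logger.info("assign_alleles: %d count rows without phased sites excluded", skipped)
    return pd.DataFrame(rows, columns=["site_id", "dataset_id", "factor", "lab",
                                       "ra", "ri"])


def merge_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum Ra/Ri within (site, factor, lab) groups; the merged dataset id
    is ``factor.lab``."""
    merged = (counts.groupby(["site_id", "factor", "lab"], as_index=False)
              [["ra", "ri"]].sum())
    merged["dataset_id"] = merged["factor"] + "." + merged["lab"]
    return merged[["site_id", "dataset_id", "factor", "lab", "ra", "ri"]]


def imbalance_score(ra, ri):
    """log2((Ra + 1) / (Ri + 1)); positive = Xa-biased."""
    ra = np.asarray(ra, dtype=float)
    ri = np.asarray(ri, dtype=float)
    if np.any(ra < 0) or np.any(ri < 0):
        raise ValueError("read counts must be non-negative")
    out = np.log2((ra + 1.0) / (ri + 1.0))
    return float(out) if out.ndim == 0 else out


def batch_imbalance_test(counts: pd.DataFrame, fdr_alpha: float = 0.05,
                         alternative: str = "two-sided") -> pd.DataFrame:
    """Per-(site, dataset) Fisher exact test against the dataset totals.

    Only pairs with Ra > 0 and Ri > 0 are tested; the 2x2 table is
    [Ra_h, Ri_h; ΣRa - Ra_h, ΣRi - Ri_h]. BH-FDR across all tested pairs.
    The log2 odds ratio uses a Haldane +0.5 correction on all four cells
    (never the p-value); positive = Xa-biased relative to the dataset.
    Datasets with a zero total on either allele are skipped (logged).
    """
    rows = []
    for dataset_id, grp in counts.groupby("dataset_id", sort=True):
        tot_ra = int(grp["ra"].sum())
        tot_ri = int(grp["ri"].sum())
        if tot_ra == 0 or tot_ri == 0:
            logger.info("batch_imbalance_test: dataset %s has a zero allele total; skipped",
                        dataset_id)
            continue
        for rec in grp.itertuples(index=False):
            ra, ri = int(rec.ra), int(rec.ri)
            if ra == 0 or ri == 0:
                continue
            rest_a, rest_i = tot_ra - ra, tot_ri - ri
            _, p = stats.fisher_exact([[ra, ri], [rest_a, rest_i]],
                                      alternative=alternative)
            log2_odds = float(np.log2(((ra + 0.5) * (rest_i + 0.5))
                                      / ((ri + 0.5) * (rest_a + 0.5))))
            rows.append((rec.site_id, dataset_id, ra, ri, float(p), log2_odds,
                         imbalance_score(ra, ri)))
    out = pd.DataFrame(rows, columns=["site_id", "dataset_id", "ra", "ri",
                                      "raw_p", "log2_odds", "score"])
    if len(out):
        reject, fdr_p, _, _ = multipletests(out["raw_p"], alpha=fdr_alpha,
                                            method="fdr_bh")
        out["fdr_p"] = fdr_p
        out["significant"] = reject
    else:
        out["fdr_p"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def summarize_sites(pairs: pd.DataFrame, fdr_alpha: float = 0.05):
    """Multi-dataset consistency of significant imbalance calls.

    Returns (summary dict, per-site DataFrame). Direction uses the sign of
    the log2 odds among a site's significant pairs: all negative = "Xi",
    all positive = "Xa", else "mixed". The per-site table doubles as the
    heatmap-ready long summary input.
    """
    sig = pairs[pairs["fdr_p"] <= fdr_alpha] if len(pairs) else pairs
    if len(sig) == 0:
        empty = pd.DataFrame(columns=["site_id", "n_significant_datasets", "direction"]
                             ).set_index("site_id")
        return {"n_significant_pairs": 0, "n_significant_sites": 0,
                "n_multi_dataset_sites": 0, "n_consistent_xi": 0,
                "n_consistent_xa": 0, "n_mixed": 0}, empty
    rows = []
    for site_id, grp in sig.groupby("site_id", sort=True):
        signs = np.sign(grp["log2_odds"].to_numpy())
        if np.all(signs < 0):
            direction = "Xi"
        elif np.all(signs > 0):
            direction = "Xa"
        else:
            direction = "mixed"
        rows.append((site_id, len(grp), direction))
    per_site = pd.DataFrame(rows, columns=["site_id", "n_significant_datasets",
                                           "direction"]).set_index("site_id")
    multi = per_site[per_site["n_significant_datasets"] > 1]
    summary = {
        "n_significant_pairs": int(len(sig)),
        "n_significant_sites": int(len(per_site)),
        "n_multi_dataset_sites": int(len(multi)),
        "n_consistent_xi": int((multi["direction"] == "Xi").sum()),
        "n_consistent_xa": int((multi["direction"] == "Xa").sum()),
        "n_mixed": int((multi["direction"] == "mixed").sum()),
    }
    return summary, per_site


def replicate_concordance(scores_rep1: pd.Series, scores_rep2: pd.Series):
    """Pearson correlation of per-site imbalance scores across replicates
    (shared sites only; needs >= 3 and non-constant vectors)."""
    shared = scores_rep1.index.intersection(scores_rep2.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared sites")
    a = scores_rep1.loc[shared].to_numpy(dtype=float)
    b = scores_rep2.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant score vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
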