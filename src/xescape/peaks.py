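"""ChIP-seq peak over-representation around escapee TSSs.

One TSS per escapee gene (the most significant) is tested against
expression-matched background TSS sets — 5 expression-percentile bins,
background drawn to the targets' bin distribution — from chrX (which
additionally requires a Bonferroni p of exactly 1, i.e. solidly
non-differential) and from the autosomes. Per peak dataset, a one-sided
Fisher exact test compares how many target vs background TSSs carry a
peak within ±500 bp; read-depth profile ratios around the TSSs provide
the corresponding signal-level view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DepthTrack, PeakSet


def select_unique_esc(results: pd.DataFrame, tss_records) -> list:
    """One escTSS per gene: smallest raw p, ties by larger |coefficient|,
    then lexicographic tss_id."""
    by_id = {r.tss_id: r for r in tss_records}
    esc = results[results["tss_class"] == "escTSS"]
    best = {}
    for tss_id, row in esc.iterrows():
        gene = by_id[tss_id].nearest_gene
        key = (row["raw_p"], -abs(row["sex_coefficient"]), tss_id)
        if gene not in best or key < best[gene][0]:
            best[gene] = (key, tss_id)
    return [by_id[t] for _, t in sorted(v for v in best.values())]


def assign_expression_bins(mean_expr: pd.Series, n_bins: int = 5) -> pd.Series:
    """Equal-sized bins of average-expression percentile ranks (0-based)."""
    ranks = mean_expr.rank(method="first")
    return pd.qcut(ranks, n_bins, labels=False).astype(int)


def _largest_remainder_quotas(proportions: np.ndarray, n: int) -> np.ndarray:
    raw = proportions * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def expression_matched_background(tss_records, mean_expr: pd.Series, targets,
                                  n: int, domain: str = "chrX",
                                  results: pd.DataFrame = None,
                                  nondt_required: bool = False,
                                  n_bins: int = 5, seed=None,
                                  x_chrom: str = "chrX") -> list:
    """Sample ``n`` background TSSs matching the targets' expression-bin
    distribution (largest-remainder quotas summing exactly to n).

    ``domain`` is "chrX" (X-non-PAR; with ``nondt_required`` the pool is
    limited to TSSs with Bonferroni p exactly 1) or "autosomes". Targets
    are always excluded from the pool. Raises if a bin's pool cannot fill
    its quota, naming the bin.
    """
    rng = np.random.default_rng(seed)
    bins = assign_expression_bins(mean_expr, n_bins)
    target_ids = {t.tss_id for t in targets}
    target_bins = bins.loc[[t for t in target_ids if t in bins.index]]
    if target_bins.empty:
        raise ValueError("no target TSS has an expression rank")
    props = np.array([(target_bins == b).mean() for b in range(n_bins)])
    quotas = _largest_remainder_quotas(props, n)

    by_id = {r.tss_id: r for r in tss_records}
    pool = []
    for tss_id in mean_expr.index:
        rec = by_id.get(tss_id)
        if rec is None or tss_id in target_ids:
            continue
        if domain == "chrX":
            if not rec.is_x_nonpar(x_chrom):
                continue
            if nondt_required:
                if results is None or tss_id not in results.index:
                    continue
                if not bool(results.loc[tss_id, "nondt_background"]):
                    continue
        elif domain == "autosomes":
            if rec.location.chrom == x_chrom:
                continue
        else:
            raise ValueError(f"unknown domain {domain!r}")
        pool.append(tss_id)

    pool_bins = bins.loc[pool]
    selected = []
    for b in range(n_bins):
        cand = pool_bins.index[pool_bins == b].to_numpy()
        if quotas[b] > cand.size:
            raise ValueError(
                f"bin {b}: quota {quotas[b]} exceeds pool of {cand.size} TSSs"
            )
        if quotas[b]:
            selected.extend(rng.choice(cand, size=quotas[b], replace=False).tolist())
    return [by_id[t] for t in selected]


@dataclass
class PeakEnrichmentResult:
    dataset_id: str
    target_with_peak: int
    target_total: int
    bg_with_peak: int
    bg_total: int
    raw_p: float
    bonferroni_p: float
    log2_ratio: float


def _has_peak_near(tsss, peaks: PeakSet, window: int) -> np.ndarray:
    starts_by_chrom: dict = {}
    for iv in peaks.intervals:
        starts_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    arr = {c: (np.array([s for s, _ in sorted(v)]),
               np.array([e for _, e in sorted(v)]))
           for c, v in starts_by_chrom.items()}
    out = np.zeros(len(tsss), dtype=bool)
    for i, tss in enumerate(tsss):
        if tss.chrom not in arr:
            continue
        starts, ends = arr[tss.chrom]
        p5 = tss.five_prime
        # interval within ±window of the TSS point, boundaries inclusive
        out[i] = bool(np.any((starts <= p5 + window) & (ends - 1 >= p5 - window)))
    return out


def peak_overlap_test(targets, background, peaks: PeakSet, window: int = 500,
                      n_datasets_tested: int = 1) -> PeakEnrichmentResult:
    """One-sided Fisher exact on targets vs background TSSs carrying at
    least one peak within ±window bp of the 5' position (inclusive);
    Bonferroni over ``n_datasets_tested``."""
    if not targets or not background:
        raise ValueError("target and background sets must be non-empty")
    tw = int(_has_peak_near(targets, peaks, window).sum())
    bw = int(_has_peak_near(background, peaks, window).sum())
    tt, bt = len(targets), len(background)
    if not peaks.intervals:
        raw_p = 1.0
    else:
        _, raw_p = stats.fisher_exact([[tw, tt - tw], [bw, bt - bw]],
                                      alternative="greater")
    t_rate, b_rate = tw / tt, bw / bt
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = float(np.log2(t_rate / b_rate)) if b_rate > 0 else (
            np.inf if t_rate > 0 else np.nan)
    return PeakEnrichmentResult(
        dataset_id=peaks.dataset_id,
        target_with_peak=tw, target_total=tt,
        bg_with_peak=bw, bg_total=bt,
        raw_p=float(raw_p),
        bonferroni_p=min(1.0, float(raw_p) * n_datasets_tested),
        log2_ratio=log2_ratio,
    )


def run_peak_enrichment(targets, background, peaksets, window: int = 500) -> pd.DataFrame:
    """Test every peak dataset; Bonferroni across the datasets in the run."""
    m = len(peaksets)
    rows = []
    for ps in peaksets:
        r = peak_overlap_test(targets, background, ps, window, n_datasets_tested=m)
        rows.append({
            "dataset_id": ps.dataset_id, "factor": ps.factor, "cell": ps.cell,
            "cell_sex": ps.cell_sex, "lab": ps.lab,
            "target_with_peak": r.target_with_peak, "target_total": r.target_total,
            "bg_with_peak": r.bg_with_peak, "bg_total": r.bg_total,
            "raw_p": r.raw_p, "bonferroni_p": r.bonferroni_p,
            "log2_ratio": r.log2_ratio,
        })
    return pd.DataFrame(rows).set_index("dataset_id")


def ratio_distribution_tests(female_ratios, male_ratios):
    """Distribution tests of the per-dataset log2 percent-overlap ratios.

    Non-finite ratios are excluded (their count is reported). Returns a
    dict with one-sample Wilcoxon signed-rank tests against 0 per sex
    (alternative: greater) and a one-sided two-sample rank-sum test
    (female > male), each as (statistic, p).
    """
    def finite(x):
        x = np.asarray(x, dtype=float)
        return x[np.isfinite(x)]

    f, m = finite(female_ratios), finite(male_ratios)
    n_dropped = (len(np.atleast_1d(female_ratios)) - f.size
                 + len(np.atleast_1d(male_ratios)) - m.size)
    if f.size == 0 or m.size == 0:
        raise ValueError("a ratio list is empty after removing non-finite values")
    out = {"n_nonfinite_dropped": n_dropped}
    for name, vals in (("female_vs_zero", f), ("male_vs_zero", m)):
        if np.all(vals == 0):
            raise ValueError(f"{name}: all ratios are zero; test degenerate")
        res = stats.wilcoxon(vals, alternative="greater")
        out[name] = (float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(f, m, alternative="greater")
    out["female_vs_male"] = (float(res.statistic), float(res.pvalue))
    return out


def depth_profile_ratio(track: DepthTrack, set_a, set_b, flank: int = 5000,
                        core: int = 50):
    """Mean depth profiles over ±flank around two TSS sets and their
    core-ratio: mean depth of set_a within ±core over set_b's.

    Positions off a contig are excluded from the means.
    """
    def profile(tsss):
        width = 2 * flank + 1
        acc = np.zeros(width)
        cnt = np.zeros(width)
        core_vals = []
        for tss in tsss:
            cov = track.coverage.get(tss.chrom)
            if cov is None:
                continue
            p5 = tss.five_prime
            lo, hi = p5 - flank, p5 + flank + 1
            c_lo, c_hi = max(0, lo), min(len(cov), hi)
            if c_lo >= c_hi:
                continue
            sl = cov[c_lo:c_hi]
            off = c_lo - lo
            acc[off:off + sl.size] += sl
            cnt[off:off + sl.size] += 1
            k_lo, k_hi = max(0, p5 - core), min(len(cov), p5 + core + 1)
            if k_lo < k_hi:
                core_vals.append(cov[k_lo:k_hi])
        with np.errstate(invalid="ignore"):
            prof = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        core_mean = float(np.mean(np.concatenate(core_vals))) if core_vals else np.nan
        return prof, core_mean

    prof_a, core_a = profile(set_a)
    prof_b, core_b = profile(set_b)
    ratio = core_a / core_b if core_b and np.isfinite(core_b) and core_b > 0 else np.nan
    return prof_a, prof_b, float(ratio)
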