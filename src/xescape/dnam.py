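"""Sex-similarity analysis of promoter DNA methylation.

On chrX, subject-gene promoters are methylated on the Xi, so the male/
female beta-value ratio (M) tracks the average level (A) and the two are
strongly correlated; escapee promoters stay unmethylated on both X copies
and fall off that trend. The similarity score of a probe is therefore its
residual from a Tukey-bisquare robust regression of M on A: higher
residual = more sex-similar methylation than the chrX norm, the signature
of escape. Autosomal probes are instead tested for differential
methylation with a nested-model F test adjusting for age and stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

BISQUARE_C = 4.685  # 95% Gaussian efficiency tuning constant
MAD_SCALE = 0.6745  # normal-consistency factor for the MAD


def compute_beta(meth, unmeth, offset: float = 100.0):
    """Array beta value Meth / (Meth + Unmeth + offset), in [0, 1)."""
    meth = np.asarray(meth, dtype=float)
    unmeth = np.asarray(unmeth, dtype=float)
    if np.any(meth < 0) or np.any(unmeth < 0):
        raise ValueError("intensities must be non-negative")
    out = meth / (meth + unmeth + offset)
    return float(out) if out.ndim == 0 else out


def ma_transform(beta_male_mean, beta_female_mean):
    """M = log2(male/female), A = log2(mean of the two).

    Probes with a non-positive mean in either sex are not representable on
    the log scale and come back as (nan, nan) for upstream exclusion.
    """
    bm = np.asarray(beta_male_mean, dtype=float)
    bf = np.asarray(beta_female_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where((bm > 0) & (bf > 0), np.log2(bm / bf), np.nan)
        A = np.where((bm > 0) & (bf > 0), np.log2((bm + bf) / 2.0), np.nan)
    if M.ndim == 0:
        return float(M), float(A)
    return M, A


def ma_table(betas: pd.DataFrame, sex) -> pd.DataFrame:
    """Per-probe M/A from a probe x sample beta table and per-sample sex.

    Sex means use all non-missing samples per probe; probes with a zero
    mean in either sex are dropped.
    """
    sex = np.asarray(sex)
    bm = betas.loc[:, sex == "male"].mean(axis=1, skipna=True)
    bf = betas.loc[:, sex == "female"].mean(axis=1, skipna=True)
    M, A = ma_transform(bm.to_numpy(), bf.to_numpy())
    out = pd.DataFrame({"M": M, "A": A}, index=betas.index)
    return out.dropna()


class TukeyBisquareRegressor(BaseEstimator, RegressorMixin):
    """Straight-line robust regression by bisquare IRLS.

    Iteratively reweighted least squares with Tukey's bisquare weights
    w(u) = (1 - u^2)^2 for |u| < 1 and 0 beyond — gross outliers get
    weight exactly zero. The residual scale is re-estimated each iteration
    as MAD/0.6745; initialization is ordinary least squares.

    Attributes: ``intercept_`` (d0), ``slope_`` (d1), ``weights_``,
    ``residuals_`` (the similarity scores), ``rho_`` (Pearson r of y on x),
    ``converged_``, ``n_iter_``.
    """

    def __init__(self, tuning_c: float = BISQUARE_C, max_iter: int = 50,
                 tol: float = 1e-8):
        self.tuning_c = tuning_c
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size or x.size < 3:
            raise ValueError("need >= 3 paired observations")
        X = np.column_stack([np.ones_like(x), x])
        params = np.linalg.lstsq(X, y, rcond=None)[0]
        converged = False
        it = 0
        w = np.ones_like(y)
        for it in range(1, self.max_iter + 1):
            resid = y - X @ params
            scale = np.median(np.abs(resid)) / MAD_SCALE
            if scale <= np.finfo(float).eps:
                w = np.ones_like(y)
                converged = True
                break
            u = resid / (self.tuning_c * scale)
            w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
            if w.sum() < 2 or np.linalg.matrix_rank(X * np.sqrt(w)[:, None]) < 2:
                break  # weights degenerate; keep last iterate
            new_params = np.linalg.lstsq(X * np.sqrt(w)[:, None],
                                         y * np.sqrt(w), rcond=None)[0]
            if np.max(np.abs(new_params - params)) < self.tol:
                params = new_params
                converged = True
                break
            params = new_params
        self.intercept_, self.slope_ = float(params[0]), float(params[1])
        self.coef_ = np.array([self.slope_])
        self.residuals_ = y - (self.intercept_ + self.slope_ * x)
        self.weights_ = w
        self.converged_ = converged
        self.n_iter_ = it
        self.rho_ = float(np.corrcoef(x, y)[0, 1]) if np.std(x) > 0 and np.std(y) > 0 else np.nan
        return self

    def predict(self, x):
        x = np.asarray(x, dtype=float).ravel()
        return self.intercept_ + self.slope_ * x


@dataclass
class MAFit:
    """Robust M-on-A fit; ``residuals`` are the similarity scores."""

    d0: float
    d1: float
    weights: np.ndarray
    residuals: np.ndarray
    rho: float
    converged: bool


def robust_fit(M, A, tuning_c: float = BISQUARE_C, max_iter: int = 50,
               tol: float = 1e-8) -> MAFit:
    """Fit M = d0 + d1*A by bisquare IRLS; residuals are similarity scores."""
    reg = TukeyBisquareRegressor(tuning_c=tuning_c, max_iter=max_iter, tol=tol)
    reg.fit(A, M)
    return MAFit(d0=reg.intercept_, d1=reg.slope_, weights=reg.weights_,
                 residuals=reg.residuals_, rho=reg.rho_, converged=reg.converged_)


def probe_tss_similarity(scores: pd.Series, probe_positions: dict, tsss,
                         window: int = 50) -> pd.Series:
    """Mean similarity score of the probes within ±window bp of each TSS.

    Distance is measured from the probe base to the strand-aware 5' TSS
    position, boundary inclusive; TSSs with no probe in range are omitted.
    """
    by_chrom: dict = {}
    for pid in scores.index:
        iv = probe_positions[pid]
        by_chrom.setdefault(iv.chrom, []).append((iv.start, scores[pid]))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    out = {}
    for tss in tsss:
        probes = by_chrom.get(tss.chrom)
        if not probes:
            continue
        p5 = tss.five_prime
        vals = [v for pos, v in probes if abs(pos - p5) <= window]
        if vals:
            out[tss.tss_id] = float(np.mean(vals))
    return pd.Series(out, name="similarity", dtype=float)


def compare_similarity(esc_scores, nondt_scores):
    """One-sided Wilcoxon rank-sum: escapee scores > nonDT scores.

    Uses the exact null when there are no ties, the tie-corrected normal
    approximation otherwise. Returns (U statistic, p).
    """
    esc = np.asarray(esc_scores, dtype=float)
    non = np.asarray(nondt_scores, dtype=float)
    if esc.size == 0 or non.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([esc, non])
    method = "exact" if len(np.unique(combined)) == combined.size else "asymptotic"
    res = stats.mannwhitneyu(esc, non, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def autosomal_dm_test(betas, sex, age, stage, n_probes_tested: int = 1):
    """Nested-model F test for sex-differential methylation of one probe.

    Reduced model: beta ~ 1 + age + stage; full model adds sex.
    F = ((RSS_r - RSS_f)/1) / (RSS_f/(n - p_f)); Bonferroni over
    ``n_probes_tested``. Returns (F, raw_p, bonferroni_p).
    """
    y = np.asarray(betas, dtype=float)
    sex = np.asarray(sex)
    sex_num = (sex == "male").astype(float) if sex.dtype.kind in "UO" else sex.astype(float)
    age = np.asarray(age, dtype=float)
    stage = np.asarray(stage, dtype=float)
    n = y.size
    if n <= 4:
        raise ValueError("need more than 4 samples")
    Xr = np.column_stack([np.ones(n), age, stage])
    Xf = np.column_stack([Xr, sex_num])
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("rank-deficient design (sex/age/stage collinear)")

    def rss(X):
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ beta
        return float(r @ r)

    rss_r, rss_f = rss(Xr), rss(Xf)
    dof = n - Xf.shape[1]
    if rss_f <= np.finfo(float).eps * max(1.0, rss_r):
        return float("inf"), 0.0, 0.0
    F = (rss_r - rss_f) / (rss_f / dof)
    raw_p = float(stats.f.sf(F, 1, dof))
    return float(F), raw_p, min(1.0, raw_p * n_probes_tested)


def autosomal_dm_table(dataset, probe_ids=None) -> pd.DataFrame:
    """Run the nested F test over autosomal probes of a MethylationDataset."""
    covars = dataset.covariates.loc[dataset.betas.columns]
    if not {"age", "stage"}.issubset(covars.columns):
        raise ValueError("autosomal test requires age and stage covariates")
    if probe_ids is None:
        probe_ids = [p for p in dataset.betas.index
                     if dataset.probe_positions[p].chrom != "chrX"]
    m = len(probe_ids)
    rows = []
    for pid in probe_ids:
        F, raw_p, bonf = autosomal_dm_test(
            dataset.betas.loc[pid].to_numpy(),
            covars["sex"].to_numpy(), covars["age"].to_numpy(),
            covars["stage"].to_numpy(), n_probes_tested=m,
        )
        rows.append((pid, F, raw_p, bonf))
    return pd.DataFrame(rows, columns=["probe_id", "F", "raw_p", "bonferroni_p"]
                        ).set_index("probe_id")
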