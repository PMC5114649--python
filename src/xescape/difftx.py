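"""Covariate-adjusted differential transcription and escapee-TSS calling.

Per TSS k the model is

    y_k = a_k0 + sum_t a_kt C_t + a_sex S + e,

where y_k = log10(TPM_k + 5), C_t are the leading principal components of
the sample x cell-category membership matrix (enough components to explain
the variance threshold, default 90%), and S codes sex as male = 1,
female = 0 — so a negative sex coefficient means higher female expression.
TSSs overlapping repeats are excluded before Bonferroni correction;
escTSSs are the retained TSSs with corrected p <= alpha and a negative sex
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .core import ExpressionMatrix, SchemaError

PSEUDO_TPM = 5.0


def transform_expression(tpm):
    """log10(TPM + 5); rejects negative input."""
    arr = np.asarray(tpm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("expression must be non-negative")
    out = np.log10(arr + PSEUDO_TPM)
    return float(out) if np.isscalar(tpm) else out


@dataclass
class CategoryPCs:
    """Retained principal components of the category-membership matrix."""

    n_components: int
    variance_explained: np.ndarray  # ratio per retained component
    scores: pd.DataFrame  # sample x component


def category_pcs(membership: pd.DataFrame, variance_threshold: float = 0.90,
                 scale: bool = False) -> CategoryPCs:
    """PCA of the binary sample x category matrix (centered, unscaled by
    default); keeps the smallest k whose cumulative explained variance
    strictly exceeds ``variance_threshold`` (all of it when none does,
    e.g. threshold 1.0)."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    X = membership.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 1e-12:
        raise ValueError("degenerate membership matrix: no variance")
    ratios = var / total
    rank = int(np.sum(s > s[0] * 1e-10))
    cum = np.cumsum(ratios)
    above = np.nonzero(cum > variance_threshold)[0]
    k = int(above[0]) + 1 if above.size else rank
    k = min(k, rank)
    scores = (X @ vt[:k].T)
    return CategoryPCs(
        n_components=k,
        variance_explained=ratios[:k],
        scores=pd.DataFrame(scores, index=membership.index,
                            columns=[f"PC{i+1}" for i in range(k)]),
    )


def _ols_sex(Y: np.ndarray, design: np.ndarray):
    """OLS of each row of Y on ``design`` (sex in the last column);
    returns (coef, two-sided p) arrays for the sex term."""
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        corr = np.corrcoef(design[:, 1:].T)
        raise ValueError(
            "rank-deficient design: collinear columns "
            f"(column correlation matrix:\n{np.round(corr, 3)})"
        )
    if n <= p:
        raise ValueError("more parameters than samples")
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = Y @ (design @ xtx_inv)  # rows: per-TSS coefficients
    resid = Y - beta @ design.T
    dof = n - p
    sigma2 = np.sum(resid ** 2, axis=1) / dof
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, -1] / se, np.inf * np.sign(beta[:, -1]))
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    pvals = np.where(se > 0, pvals, 0.0)
    pvals = np.where(beta[:, -1] == 0, np.where(se > 0, pvals, 1.0), pvals)
    return beta[:, -1], pvals


def fit_tss_model(y, pcs: CategoryPCs, sex):
    """OLS of one TSS's transformed expression on [1, PCs, sex];
    returns (sex_coefficient, two-sided p of its t test)."""
    y = np.asarray(y, dtype=float)
    sex = np.asarray(sex, dtype=float)
    design = np.column_stack([np.ones(len(y)), pcs.scores.to_numpy(), sex])
    if len(y) <= design.shape[1] + 1:
        raise ValueError("too few samples for the design")
    coef, p = _ols_sex(y[None, :], design)
    return float(coef[0]), float(p[0])


def classify_tss(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni-correct over the tested universe and assign classes.

    ``results`` must carry ``sex_coefficient`` and ``raw_p`` for every
    retained TSS (repeat-excluded TSSs are not in it). Adds
    ``bonferroni_p``, ``tss_class`` (escTSS / male_biased / nonDT) and
    ``nondt_background`` (corrected p exactly 1, the background subset).
    """
    if len(results) == 0:
        raise ValueError("empty TSS universe")
    m = len(results)
    out = results.copy()
    out["bonferroni_p"] = np.minimum(1.0, out["raw_p"] * m)
    cls = np.where(
        (out["bonferroni_p"] <= alpha) & (out["sex_coefficient"] < 0), "escTSS",
        np.where((out["bonferroni_p"] <= alpha) & (out["sex_coefficient"] > 0),
                 "male_biased", "nonDT"),
    )
    out["tss_class"] = cls
    out["nondt_background"] = out["bonferroni_p"] == 1.0
    return out


class EscapeeCaller(BaseEstimator):
    """Escapee-TSS caller: per-TSS OLS with category-PC covariates.

    fit() consumes an :class:`ExpressionMatrix`, its TSS records, and
    sex-labelled samples; fitted attributes:

    results_ : DataFrame indexed by tss_id with sex_coefficient, raw_p,
        bonferroni_p, tss_class (escTSS/male_biased/nonDT/excluded_repeat)
        and nondt_background.
    pcs_ : the retained :class:`CategoryPCs` (None if no categories).
    n_tested_ : Bonferroni universe size (retained non-repeat X-non-PAR TSSs).
    """

    def __init__(self, alpha: float = 0.05, variance_threshold: float = 0.90,
                 scale_pcs: bool = False, use_categories: bool = True,
                 x_chrom: str = "chrX"):
        self.alpha = alpha
        self.variance_threshold = variance_threshold
        self.scale_pcs = scale_pcs
        self.use_categories = use_categories
        self.x_chrom = x_chrom

    def fit(self, expr: ExpressionMatrix, tss_records, samples):
        from .simulate import category_membership

        by_id = {r.tss_id: r for r in tss_records}
        labelled = [s for s in samples if s.sex_label in ("male", "female")]
        if not labelled:
            raise ValueError("no sex-labelled samples")
        expr = expr.subset_samples([s.sample_id for s in labelled])
        sex = np.array([1.0 if s.sex_label == "male" else 0.0 for s in labelled])

        universe = [t for t in expr.tss_ids
                    if t in by_id and by_id[t].is_x_nonpar(self.x_chrom)]
        if not universe:
            raise ValueError("empty X-non-PAR TSS universe")
        retained = [t for t in universe if not by_id[t].repeat_overlap]
        excluded = [t for t in universe if by_id[t].repeat_overlap]
        if not retained:
            raise ValueError("all TSSs repeat-excluded")

        pcs = None
        if self.use_categories and any(s.categories for s in labelled):
            membership = category_membership(labelled)
            pcs = category_pcs(membership, self.variance_threshold, self.scale_pcs)
            design = np.column_stack(
                [np.ones(len(labelled)), pcs.scores.to_numpy(), sex])
        else:
            design = np.column_stack([np.ones(len(labelled)), sex])
        self.pcs_ = pcs

        Y = transform_expression(expr.subset_tss(retained).values)
        coef, raw_p = _ols_sex(Y, design)
        tested = pd.DataFrame(
            {"sex_coefficient": coef, "raw_p": raw_p},
            index=pd.Index(retained, name="tss_id"),
        )
        tested = classify_tss(tested, alpha=self.alpha)
        if excluded:
            excl = pd.DataFrame(
                {"sex_coefficient": np.nan, "raw_p": np.nan,
                 "bonferroni_p": np.nan, "tss_class": "excluded_repeat",
                 "nondt_background": False},
                index=pd.Index(excluded, name="tss_id"),
            )
            tested = pd.concat([tested, excl])
        self.results_ = tested.loc[[t for t in universe if t in tested.index]]
        self.n_tested_ = len(retained)
        return self

    @property
    def escapee_tss_ids_(self):
        return self.results_.index[self.results_["tss_class"] == "escTSS"].tolist()


def gene_rollup(esc_tss_ids, tss_records) -> set:
    """Unique nearest-gene symbols of the escapee TSSs."""
    by_id = {r.tss_id: r for r in tss_records}
    try:
        return {by_id[t].nearest_gene for t in esc_tss_ids}
    except KeyError as exc:
        raise SchemaError(f"escTSS without a TSS record: {exc}") from exc


def _round_half_up(x: float, places: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places, ROUND_HALF_UP))


@dataclass
class BenchmarkResult:
    predicted_genes: set
    true_escapees: set
    per_list_overlap: dict
    precision: float
    recall: float
    precision_rounded: float
    recall_rounded: float


def benchmark_escapees(predicted: set, published: list) -> BenchmarkResult:
    """Precision/recall against published escapee lists.

    True escapees are genes reported by >= 2 of the four approaches (the
    predicted list counts as one approach). Precision = |predicted ∩ true|
    / |predicted|; recall = |predicted ∩ true| / |true|. Rounded values use
    half-up rounding to 2 decimals for reporting.
    """
    predicted = set(predicted)
    published = [set(lst) for lst in published]
    if not predicted:
        raise ValueError("precision undefined for an empty predicted set")
    all_genes = predicted.union(*published) if published else set(predicted)
    votes = {
        g: int(g in predicted) + sum(g in lst for lst in published)
        for g in all_genes
    }
    true = {g for g, v in votes.items() if v >= 2}
    tp = len(predicted & true)
    precision = tp / len(predicted)
    recall = tp / len(true) if true else float("nan")
    overlap = {f"list_{i}": len(predicted & lst) for i, lst in enumerate(published)}
    return BenchmarkResult(
        predicted_genes=predicted,
        true_escapees=true,
        per_list_overlap=overlap,
        precision=precision,
        recall=recall,
        precision_rounded=_round_half_up(precision),
        recall_rounded=_round_half_up(recall) if true else float("nan"),
    )


def expression_log2_ratio(mean_male: float, mean_female: float, c: float) -> float:
    """log2((mean_male + c) / (mean_female + c)); c is typically the 5th
    percentile of expression, guarding zero denominators."""
    if c <= 0:
        raise ValueError("constant c must be > 0")
    if mean_male < 0 or mean_female < 0:
        raise ValueError("means must be non-negative")
    return float(np.log2((mean_male + c) / (mean_female + c)))
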