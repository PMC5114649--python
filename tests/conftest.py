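"""Shared fixtures and independent oracles.

The oracles (exact hypergeometric enumeration, normal-equation OLS,
exhaustive motif scoring) are deliberately naive re-derivations used only
to check the package's fast paths; they never share code with them.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from xescape.simulate import (
    AllelicSimConfig,
    CohortConfig,
    MethylationConfig,
    generate_cohort,
    generate_methylation,
    generate_toy_genome,
    simulate_allelic_counts,
)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic expression cohort (seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def methylation():
    """Default synthetic methylation panel (seed 0)."""
    return generate_methylation(MethylationConfig(seed=0))


@pytest.fixture(scope="session")
def toy_genome():
    return generate_toy_genome(seed=0)


@pytest.fixture(scope="session")
def allelic_default():
    return simulate_allelic_counts(AllelicSimConfig(seed=0))


# ------------------------------------------------------------------ oracles

def hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> Fraction:
    """P(top-left cell = a) for fixed margins, as an exact rational."""
    n = row1 + row2
    return Fraction(comb(row1, a) * comb(row2, col1 - a), comb(n, col1))


def fisher_exact_enum(table, alternative: str = "two-sided") -> float:
    """Fisher exact p by exhaustive enumeration over the support."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(row1, col1)
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf(k, row1, row2, col1)
        if alternative == "greater":
            if k >= a:
                total += pk
        elif alternative == "less":
            if k <= a:
                total += pk
        else:  # two-sided: all outcomes no more probable than observed
            if pk <= p_obs * (1 + Fraction(1, 10 ** 12)):
                total += pk
    return float(total)


def ols_normal_equations(X, y):
    """OLS by explicit normal equations; returns (beta, se, t, two-sided p)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p


def exhaustive_motif_hits(seq: str, motif, rel_threshold: float):
    """Per-offset, per-strand scoring by direct summation (no vectorization)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    pssm = motif.pssm()
    L = motif.length
    smin = sum(min(pssm[b, j] for b in range(4)) for j in range(L))
    smax = sum(max(pssm[b, j] for b in range(4)) for j in range(L))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    seq = seq.upper()
    for strand in "+-":
        for off in range(len(seq) - L + 1):
            window = seq[off:off + L]
            if strand == "-":
                window = "".join(comp.get(ch, "N") for ch in reversed(window))
            score = 0.0
            for j, ch in enumerate(window):
                if ch in base_idx:
                    score += pssm[base_idx[ch], j]
            rel = (score - smin) / (smax - smin) if smax > smin else 0.0
            if rel >= rel_threshold - 1e-12:
                hits.append((off, strand, round(rel, 10)))
    return sorted(hits)
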