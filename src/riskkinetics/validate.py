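"""Histology cross-validation: FA vs axon-density agreement.

Two checks tie the imaging biomarker to tissue ground truth: a Pearson
correlation between per-nerve FA and neurofilament-positive axon density
(one-tailed t-based p, since degeneration predicts a positive association),
and a Spearman rank correlation between per-animal FA ratios and axon-count
ratios with an *exact* permutation p for small n (all n! rank orders are
enumerated for n <= 8; the large-sample approximation is used beyond that).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationSummary", "pearson_one_tailed", "spearman_exact", "validate_histology"]

_EXACT_N_MAX = 8


@dataclass
class CorrelationSummary:
    pearson_r: float
    pearson_df: int
    pearson_p_one_tailed: float
    spearman_r: float
    spearman_n: int
    spearman_p_one_sided: float
    spearman_p_two_sided: float
    spearman_exact: bool


def pearson_one_tailed(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pearson r with one-tailed p from t = r sqrt(df / (1 - r^2)), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    if abs(r) >= 1.0:
        return r, df, 0.0 if r > 0 else 1.0
    t = r * math.sqrt(df / (1.0 - r * r))
    return r, df, float(stats.t.sf(t, df))


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Spearman rank correlation with exact permutation p for small n.

    Returns (rho, one-sided p for positive association, two-sided p,
    exact flag).  The exact p enumerates all n! orderings of one rank
    vector; perfect agreement over n pairs therefore gives p = 1/n!.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples with n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = x.size
    if n > _EXACT_N_MAX:
        res = stats.spearmanr(x, y)
        two = float(res.pvalue)
        one = two / 2.0 if rho >= 0 else 1.0 - two / 2.0
        return rho, one, two, False
    total = math.factorial(n)
    ge = 0
    ge_abs = 0
    tol = 1e-12
    for perm in permutations(ry):
        r = _spearman_rho(rx, np.asarray(perm))
        if r >= rho - tol:
            ge += 1
        if abs(r) >= abs(rho) - tol:
            ge_abs += 1
    return rho, ge / total, ge_abs / total, True


def validate_histology(
    degen_terminal: pd.DataFrame, histology: pd.DataFrame
) -> CorrelationSummary:
    """Cross-validate terminal FA against histology.

    ``degen_terminal`` needs columns subject_id, eye, fa; ``histology``
    needs subject_id, eye, nf_density and (on affected rows) an
    axon_count_ratio.  Pearson runs across all matched nerves; Spearman
    runs across animals on (FA ratio, axon-count ratio) pairs.
    """
    merged = degen_terminal.merge(histology, on=["subject_id", "eye"], how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 matched nerves")
    r, df, p1 = pearson_one_tailed(merged["fa"].to_numpy(), merged["nf_density"].to_numpy())

    fa = merged.pivot_table(index="subject_id", columns="eye", values="fa")
    ratios = histology.dropna(subset=["axon_count_ratio"]).set_index("subject_id")
    subjects = [s for s in ratios.index if s in fa.index and {"affected", "fellow"} <= set(fa.columns)]
    fa_ratio = np.array([fa.loc[s, "affected"] / fa.loc[s, "fellow"] for s in subjects])
    axon_ratio = ratios.loc[subjects, "axon_count_ratio"].to_numpy(dtype=float)
    if fa_ratio.size < 3:
        raise ValueError("need at least 3 paired-eye animals for the rank check")
    rho, p_one, p_two, exact = spearman_exact(fa_ratio, axon_ratio)
    return CorrelationSummary(
        pearson_r=r,
        pearson_df=df,
        pearson_p_one_tailed=p1,
        spearman_r=rho,
        spearman_n=fa_ratio.size,
        spearman_p_one_sided=p_one,
        spearman_p_two_sided=p_two,
        spearman_exact=exact,
    )
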