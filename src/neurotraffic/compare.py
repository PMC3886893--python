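"""Ensemble statistical comparison machinery.

Node-level metrics from replicate simulations on an empirical network are
compared against replicate simulations on degree-matched surrogate networks:
for each surrogate realization, Welch's unequal-variance t-test (Satterthwaite
degrees of freedom) is applied per node, the t- and p-values are averaged
across realizations, and the averaged p-values are corrected across nodes by
Benjamini–Hochberg FDR.  Fisher's r-to-z transform compares correlation
coefficients between scenario-similarity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "welch_t",
    "bh_fdr",
    "fisher_r_to_z_diff",
    "compare_ensembles",
]


def welch_t(sample_a, sample_b):
    """Welch's two-sample t-test with Satterthwaite degrees of freedom.

    Returns a dict with ``t``, ``df`` and two-sided ``p``.  With zero
    variance on both sides and equal means, the statistic is undefined and
    all three are NaN.

    t  = (x̄_a − x̄_b) / sqrt(v_a/n_a + v_b/n_b)
    df = (v_a/n_a + v_b/n_b)² / [ (v_a/n_a)²/(n_a−1) + (v_b/n_b)²/(n_b−1) ]
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    t, df, p = _welch_cols(a[:, None], b[:, None])
    return {"t": float(t[0]), "df": float(df[0]), "p": float(p[0])}


def _welch_cols(a, b):
    """Vectorized Welch test down axis 0 of two 2-D arrays."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    denom = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom)
        df = denom ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    undef = denom == 0
    t = np.where(undef, np.nan, t)
    df = np.where(undef, np.nan, df)
    p = np.where(np.isfinite(t), 2 * sps.t.sf(np.abs(t), df), np.nan)
    return t, df, p


def bh_fdr(p_values, q=0.05):
    """Benjamini–Hochberg step-up rejection flags at FDR level q.

    NaN entries are excluded from the family size m and never rejected.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return flags
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    thresh = (np.arange(1, m + 1) / m) * q
    below = pv[order] <= thresh
    if below.any():
        cut = np.max(np.nonzero(below)[0])
        rej = np.zeros(m, dtype=bool)
        rej[order[: cut + 1]] = True
        flags[valid] = rej
    return flags


def fisher_r_to_z_diff(r1, n1, r2, n2):
    """Fisher r-to-z contrast of two independent correlation coefficients:
    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))."""
    for r in (r1, r2):
        if abs(r) >= 1:
            return float("nan")  # infinite transform, flagged
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 on both sides")
    return (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1 / (n1 - 3) + 1 / (n2 - 3))


@dataclass
class ComparisonResult:
    """Per-item (node or edge) ensemble comparison.

    ``table`` columns: mean_diff, avg_t, avg_df, avg_p, q_flag, direction,
    n_sig_realizations.  ``q`` is the FDR level used.
    """

    table: pd.DataFrame
    q: float
    n_realizations: int


def compare_ensembles(empirical_runs, surrogate_runs, q=0.05, items=None,
                      alpha_per_realization=0.05):
    """Empirical-vs-surrogate comparison protocol.

    Parameters
    ----------
    empirical_runs : array (n_runs, n_items)
        One metric value per run and item (e.g. per-node mean contents).
    surrogate_runs : array (n_realizations, n_runs, n_items)
        The same metric from runs on each surrogate realization.
    q : float
        FDR level applied across items to the realization-averaged p-values.

    For each realization a Welch test compares the empirical runs with that
    realization's runs per item; t, df and p are averaged across
    realizations, BH-FDR is applied to the averaged p-values, and the count
    of individually significant realizations (raw p < ``alpha_per_realization``)
    is reported.
    """
    emp = np.asarray(empirical_runs, dtype=float)
    sur = np.asarray(surrogate_runs, dtype=float)
    if emp.ndim != 2:
        raise ValueError("empirical_runs must be (n_runs, n_items)")
    if sur.ndim == 2:
        sur = sur[None, :, :]
    if sur.ndim != 3:
        raise ValueError("surrogate_runs must be (n_realizations, n_runs, n_items)")
    if emp.shape[0] < 2 or sur.shape[1] < 2:
        raise ValueError("need at least 2 runs per side")
    if emp.shape[1] != sur.shape[2]:
        raise ValueError("empirical and surrogate item sets differ")
    n_real = sur.shape[0]
    ts = np.empty((n_real, emp.shape[1]))
    dfs = np.empty_like(ts)
    ps = np.empty_like(ts)
    for r in range(n_real):
        ts[r], dfs[r], ps[r] = _welch_cols(emp, sur[r])
    avg_t = np.nanmean(ts, axis=0)
    avg_df = np.nanmean(dfs, axis=0)
    avg_p = np.nanmean(ps, axis=0)
    mean_diff = emp.mean(axis=0) - sur.mean(axis=(0, 1))
    flags = bh_fdr(avg_p, q)
    n_sig = (ps < alpha_per_realization).sum(axis=0)
    if items is None:
        items = pd.RangeIndex(emp.shape[1], name="item")
    table = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "avg_t": avg_t,
            "avg_df": avg_df,
            "avg_p": avg_p,
            "q_flag": flags,
            "direction": np.sign(mean_diff),
            "n_sig_realizations": n_sig,
        },
        index=pd.Index(items, name=getattr(items, "name", "item")),
    )
    return ComparisonResult(table, q, n_real)
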