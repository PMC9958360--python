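"""Repeated-measures ANOVA of intra-personal velocity ranges.

The unit of analysis is the dyad (participants and trials are averaged
upstream); the design is fully within-subject: proximity (Far/Near) x
visual contact (NoVision/Vision) x body part (10 levels).  Degrees of
freedom of every effect involving the 10-level factor are Greenhouse–Geisser
corrected, unconditionally, and reported alongside the uncorrected ones.
Effect sizes are generalized eta squared (all error SS plus the
between-subject SS in the denominator).  Post-hoc pairwise body-part
comparisons use paired t tests with Holm–Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import PART_NAMES, PROXIMITY_LEVELS, VISION_LEVELS
from .permstats import holm_bonferroni


def gg_epsilon(contrast_cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the covariance of orthonormal
    within-subject contrast scores.

    With eigenvalues ``lam`` of the ``d x d`` covariance,
    ``eps = (sum lam)^2 / (d * sum lam^2)``, clipped to ``[1/d, 1]``.
    A 2-level factor (``d = 1``) always gives 1.
    """
    s = np.asarray(contrast_cov, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("contrast covariance must be square")
    d = s.shape[0]
    tr = np.trace(s)
    tr2 = np.trace(s @ s)
    if tr2 <= 0 or tr <= 0:
        warnings.warn("degenerate contrast covariance; epsilon set to lower bound")
        return 1.0 / d
    return float(np.clip(tr ** 2 / (d * tr2), 1.0 / d, 1.0))


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels orthonormal contrast matrix (rows orthonormal,
    orthogonal to the unit vector)."""
    h = np.eye(levels) - 1.0 / levels
    q, _ = np.linalg.qr(h.T)
    return q[:, : levels - 1].T


def rm_anova_within(data: np.ndarray, factor_names: tuple[str, ...]) -> pd.DataFrame:
    """Fully within-subject factorial ANOVA.

    ``data`` has shape ``(n_subjects, l1, ..., lk)`` with one axis per
    factor.  Returns one row per effect (all main effects and interactions)
    with uncorrected and GG-corrected df, F, p values and generalized eta
    squared.
    """
    x = np.asarray(data, dtype=float)
    k = x.ndim - 1
    if k != len(factor_names):
        raise ValueError("factor_names must match the number of factor axes")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    levels = x.shape[1:]
    all_axes = tuple(range(x.ndim))

    # mean of x over every axis not in `keep`, broadcast back to full shape
    means: dict[frozenset, np.ndarray] = {}

    def mean_over(keep: frozenset) -> np.ndarray:
        if keep not in means:
            drop = tuple(ax for ax in all_axes if ax not in keep)
            means[keep] = x.mean(axis=drop, keepdims=True) if drop else x
        return means[keep]

    def effect_ss(subset: frozenset) -> float:
        e = np.zeros((1,) * x.ndim)
        for r in range(len(subset) + 1):
            for u in itertools.combinations(sorted(subset), r):
                sign = (-1) ** (len(subset) - r)
                e = e + sign * mean_over(frozenset(u))
        scale = np.prod([x.shape[ax] for ax in all_axes if ax not in subset])
        return float((e ** 2).sum() * scale)

    factor_axes = tuple(range(1, k + 1))
    effects = []
    for r in range(1, k + 1):
        effects.extend(itertools.combinations(factor_axes, r))

    # flush round-off residue (scale on the uncentered magnitude, since for a
    # constant table the centered SS is itself residue)
    tol = 1e-12 * max(float((x ** 2).sum()), 1e-300)

    def flush(v: float) -> float:
        return 0.0 if v <= tol else v

    ss_subj = flush(effect_ss(frozenset({0})))
    ss_eff = {s: flush(effect_ss(frozenset(s))) for s in effects}
    ss_err = {s: flush(effect_ss(frozenset(s) | {0})) for s in effects}
    eta_den_common = ss_subj + sum(ss_err.values())

    contrasts = {ax: _orthonormal_contrasts(x.shape[ax]) for ax in factor_axes}
    flat = x.reshape(n, -1)

    rows = []
    for s in effects:
        df_num = int(np.prod([x.shape[ax] - 1 for ax in s]))
        df_den = df_num * (n - 1)
        ms_num = ss_eff[s] / df_num
        ms_den = ss_err[s] / df_den
        f = np.inf if ms_den == 0 and ms_num > 0 else (
            0.0 if ms_den == 0 else ms_num / ms_den)

        # orthonormal contrast scores for the GG correction
        mats = [contrasts[ax] if ax in s else np.full((1, x.shape[ax]), 1.0 / x.shape[ax])
                for ax in factor_axes]
        m = mats[0]
        for mm in mats[1:]:
            m = np.kron(m, mm)
        z = flat @ m.T
        if df_num == 1:
            eps = 1.0
        else:
            cov = np.cov(z, rowvar=False, ddof=1)
            eps = gg_epsilon(np.atleast_2d(cov))

        p_unc = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
        p_gg = float(stats.f.sf(f, eps * df_num, eps * df_den)) if np.isfinite(f) else 0.0
        if f == 0.0:
            p_unc = p_gg = 1.0

        eta = ss_eff[s] / (ss_eff[s] + eta_den_common) if (ss_eff[s] + eta_den_common) > 0 else 0.0
        rows.append({
            "effect": " x ".join(factor_names[ax - 1] for ax in s),
            "df_num": df_num,
            "df_den": df_den,
            "F": f,
            "epsilon_gg": eps,
            "df_num_gg": eps * df_num,
            "df_den_gg": eps * df_den,
            "p_gg": p_gg,
            "p_uncorrected": p_unc,
            "eta_g": eta,
        })
    return pd.DataFrame(rows)


def range_table_to_array(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Pivot a tidy range table (columns dyad, proximity, vision, part,
    range) into a ``(n_dyads, 2, 2, 10)`` array; dyads with missing cells
    are dropped with a warning."""
    required = {"dyad", "proximity", "vision", "part", "range"}
    if not required.issubset(table.columns):
        raise ValueError(f"range table must have columns {sorted(required)}")
    pivot = table.pivot_table(index="dyad", columns=["proximity", "vision", "part"],
                              values="range")
    full_cols = pd.MultiIndex.from_product(
        [PROXIMITY_LEVELS, VISION_LEVELS, PART_NAMES])
    pivot = pivot.reindex(columns=full_cols)
    complete = pivot.notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} dyads with incomplete cells")
        pivot = pivot[complete]
    arr = pivot.to_numpy().reshape(len(pivot), 2, 2, len(PART_NAMES))
    return arr, list(pivot.index)


def rm_anova_2x2x10(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """The 2x2x10 velocity-range ANOVA (proximity x vision x body part).

    ``table`` is either the tidy range table or a ready
    ``(n_dyads, 2, 2, 10)`` array.
    """
    if isinstance(table, pd.DataFrame):
        arr, _ = range_table_to_array(table)
    else:
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 4 or arr.shape[1:] != (2, 2, len(PART_NAMES)):
            raise ValueError(f"expected (n_dyads, 2, 2, 10), got {arr.shape}")
    return rm_anova_within(arr, ("proximity", "vision", "body_part"))


def posthoc_pairwise(marginals: np.ndarray,
                     part_names: tuple[str, ...] = PART_NAMES) -> pd.DataFrame:
    """Holm–Bonferroni adjusted paired t tests between body-part marginal
    means (``marginals``: ``(n_dyads, 10)``), all 45 pairs, two-sided."""
    m = np.asarray(marginals, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(part_names):
        raise ValueError(f"expected (n_dyads, {len(part_names)}), got {m.shape}")
    pairs = list(itertools.combinations(range(len(part_names)), 2))
    rows = []
    for i, j in pairs:
        d = m[:, i] - m[:, j]
        if d.std(ddof=1) == 0:  # degenerate pair: no spread in differences
            t, p = (0.0, 1.0) if d.mean() == 0 else (np.inf * np.sign(d.mean()), 0.0)
        else:
            res = stats.ttest_rel(m[:, i], m[:, j])
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "part_a": part_names[i], "part_b": part_names[j],
            "mean_diff": float(d.mean()), "t": t, "p_raw": p,
        })
    df = pd.DataFrame(rows)
    df["p_holm"] = holm_bonferroni(df["p_raw"].to_numpy())
    return df
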