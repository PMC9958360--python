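"""Permutation inference for interpersonal synchrony coefficients.

Two analyses share the same null-building move — shuffling one participant's
velocity time series within a trial, which destroys the temporal relation
between partners while preserving each series' marginal distribution:

* the *consistency test*: per condition and body-part combination, a
  one-sample t statistic of the dyad-level coefficients against zero is
  compared with the t distribution obtained from shuffled series
  (one-sided, strict inequality, ``p = #(t_pseudo > t_genuine) / n_perm``);
* the *permutation ANOVA*: per combination, pseudo F values of the 2x2
  within-dyad ANOVA (proximity x vision) on shuffled condition-level
  coefficients form the null for the genuine F of each main effect and the
  interaction.

P values are corrected across the 55 combinations with Benjamini–Hochberg
FDR, separately per condition (consistency) or per effect (ANOVA).
Effect sizes are one-sample Cohen's d (consistency) and generalized eta
squared (ANOVA).  All randomness flows from one caller-supplied generator,
and which partner is shuffled is drawn uniformly per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .landmarks import CONDITIONS
from .synchrony import COMBO_LABELS, TRIL_INDICES

EFFECTS_2X2 = ("proximity", "vision", "interaction")


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def shuffle_series(x: np.ndarray, rng: np.random.Generator,
                   scheme: str = "full_permutation") -> np.ndarray:
    """Return a surrogate of ``x`` along its first axis.

    ``full_permutation`` (default) reorders samples uniformly at random;
    ``circular_shift`` applies a random rotation, preserving autocorrelation.
    """
    x = np.asarray(x)
    if scheme == "full_permutation":
        return x[rng.permutation(x.shape[0])]
    if scheme == "circular_shift":
        return np.roll(x, int(rng.integers(x.shape[0])), axis=0)
    raise ValueError(f"unknown shuffle scheme {scheme!r}")


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must be finite and within [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def holm_bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must be finite and within [0, 1]")
    return multipletests(p.ravel(), method="holm")[1].reshape(p.shape)


def cohens_d(values: np.ndarray) -> float:
    """One-sample Cohen's d against zero: mean / SD (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("Cohen's d undefined: zero standard deviation")
    return float(v.mean() / sd)


def one_sample_t(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """One-sample t against zero along ``axis`` (SD with ddof=1).

    Degenerate inputs: all-zero samples give t = 0; nonzero constant samples
    give signed infinity.
    """
    v = np.asarray(values, dtype=float)
    n = v.shape[axis]
    mean = v.mean(axis=axis)
    sd = v.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def permutation_p(genuine: np.ndarray, null: np.ndarray,
                  smoothing: bool = False) -> np.ndarray:
    """One-sided permutation p: fraction of null draws strictly exceeding the
    genuine statistic.  ``smoothing`` switches to the guaranteed-positive
    ``(count + 1) / (n + 1)`` variant."""
    count = (null > genuine).sum(axis=0)
    n = null.shape[0]
    if smoothing:
        return (count + 1) / (n + 1)
    return count / n


# ---------------------------------------------------------------------------
# 2x2 repeated-measures ANOVA (closed form, broadcastable)
# ---------------------------------------------------------------------------

def rm_anova_2x2(y: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
    """Within-subject 2x2 ANOVA from the standard decomposition.

    ``y`` has shape ``(..., n_subjects, 2, 2)`` (factor A slow, factor B
    fast; leading axes broadcast).  Returns, per effect in
    :data:`EFFECTS_2X2`, the F value with df ``(1, n-1)`` and generalized
    eta squared (all error SS plus between-subject SS in the denominator).

    Degenerate tables: zero effect and zero error give F = 0; positive
    effect with zero error gives F = +inf.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 3 or y.shape[-1] != 2 or y.shape[-2] != 2:
        raise ValueError(f"expected shape (..., n, 2, 2), got {y.shape}")
    n = y.shape[-3]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = y.mean(axis=(-3, -2, -1), keepdims=True)
    m_subj = y.mean(axis=(-2, -1), keepdims=True)
    m_a = y.mean(axis=(-3, -1), keepdims=True)
    m_b = y.mean(axis=(-3, -2), keepdims=True)
    m_sa = y.mean(axis=-1, keepdims=True)
    m_sb = y.mean(axis=-2, keepdims=True)
    m_ab = y.mean(axis=-3, keepdims=True)

    def ssq(arr):
        return np.broadcast_to(arr, y.shape).reshape(y.shape[:-3] + (-1,)).sum(axis=-1)

    ss_subj = ssq((m_subj - grand) ** 2)
    ss_a = ssq((m_a - grand) ** 2)
    ss_b = ssq((m_b - grand) ** 2)
    ss_ab = ssq((m_ab - m_a - m_b + grand) ** 2)
    ss_as = ssq((m_sa - m_subj - m_a + grand) ** 2)
    ss_bs = ssq((m_sb - m_subj - m_b + grand) ** 2)
    ss_abs = ssq((y - m_sa - m_sb - m_ab + m_a + m_b + m_subj - grand) ** 2)

    # flush round-off residue so constant tables yield exact zero SS
    # (scale on the uncentered magnitude: centered SS is itself residue here)
    tol = 1e-12 * np.maximum(ssq(y ** 2), 1e-300)
    ss_subj, ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs = (
        np.where(s <= tol, 0.0, s)
        for s in (ss_subj, ss_a, ss_b, ss_ab, ss_as, ss_bs, ss_abs))

    err_total = ss_as + ss_bs + ss_abs

    def f_ratio(ss_eff, ss_err):
        num = ss_eff  # df 1
        den = ss_err / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = num / den
        return np.where(den == 0, np.where(num == 0, 0.0, np.inf), f)

    out = {}
    for name, ss_eff, ss_err in (
        ("proximity", ss_a, ss_as),
        ("vision", ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        with np.errstate(invalid="ignore", divide="ignore"):
            eta = ss_eff / (ss_eff + ss_subj + err_total)
        out[name] = {
            "F": f_ratio(ss_eff, ss_err),
            "eta_g": np.where(ss_eff + ss_subj + err_total == 0, 0.0, eta),
            "df": (1, n - 1),
        }
    return out


# ---------------------------------------------------------------------------
# study container and the shared permutation engine
# ---------------------------------------------------------------------------

@dataclass
class StudyVelocities:
    """Z-scored part-velocity panels of a whole study, organised for the
    permutation analyses.

    ``trials[d][c]`` is the list of ``(A, B)`` arrays (samples x 10) for dyad
    index ``d`` in condition index ``c`` (condition order
    :data:`imsync.landmarks.CONDITIONS`).
    """

    dyad_ids: list[str]
    trials: list[list[list[tuple[np.ndarray, np.ndarray]]]]
    raw_ranges: dict | None = None  # optional: (dyad, cond) -> (participant, 10) ranges
    truth: dict = field(default_factory=dict)

    @property
    def n_dyads(self) -> int:
        return len(self.dyad_ids)

    def validate(self) -> None:
        for d in range(self.n_dyads):
            if len(self.trials[d]) != len(CONDITIONS):
                raise ValueError(f"dyad {self.dyad_ids[d]}: expected "
                                 f"{len(CONDITIONS)} condition cells")
            for c, cell in enumerate(self.trials[d]):
                if len(cell) == 0:
                    raise ValueError(
                        f"dyad {self.dyad_ids[d]}, condition {CONDITIONS[c]}: no trials")


def _colzscore(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    return (x - mean) / sd


def _combo_from_matrices(c: np.ndarray) -> np.ndarray:
    """Symmetrise stacked 10x10 matrices (..., 10, 10) -> (..., 55)."""
    sym = (c + np.swapaxes(c, -1, -2)) / 2.0
    return sym[..., TRIL_INDICES[0], TRIL_INDICES[1]]


def condition_coefficients(study: StudyVelocities) -> np.ndarray:
    """Genuine symmetrised condition-level coefficients,
    shape ``(n_dyads, 4, 55)`` (trial matrices averaged within condition)."""
    out = np.zeros((study.n_dyads, len(CONDITIONS), len(COMBO_LABELS)))
    for d in range(study.n_dyads):
        for c in range(len(CONDITIONS)):
            mats = []
            for a, b in study.trials[d][c]:
                az, bz = _colzscore(a), _colzscore(b)
                mats.append(az.T @ bz / a.shape[0])
            out[d, c] = _combo_from_matrices(np.mean(np.stack(mats), axis=0))
    return out


def pseudo_condition_coefficients(study: StudyVelocities, n_perm: int,
                                  rng: np.random.Generator,
                                  scheme: str = "full_permutation",
                                  chunk: int = 100) -> np.ndarray:
    """Pseudo condition-level coefficients, shape ``(n_perm, n_dyads, 4, 55)``.

    For every permutation replicate, every trial independently has one
    partner's series (chosen at random) shuffled before the 10x10 matrix is
    recomputed; trial matrices are then averaged within condition and
    symmetrised, mirroring the genuine statistic path.  The shuffled-series
    correlations are accumulated in single precision (the null draws feed
    rank comparisons only).
    """
    n_combo = len(COMBO_LABELS)
    out = np.zeros((n_perm, study.n_dyads, len(CONDITIONS), n_combo))
    for d in range(study.n_dyads):
        for c in range(len(CONDITIONS)):
            cell = study.trials[d][c]
            acc = np.zeros((n_perm, 10, 10), dtype=np.float32)
            for a, b in cell:
                n = a.shape[0]
                az = _colzscore(a).astype(np.float32)
                bz = _colzscore(b).astype(np.float32)
                swap = rng.random(n_perm) < 0.5  # which partner is shuffled
                for start in range(0, n_perm, chunk):
                    stop = min(start + chunk, n_perm)
                    m = stop - start
                    if scheme == "full_permutation":
                        idx = rng.permuted(
                            np.broadcast_to(np.arange(n), (m, n)), axis=1)
                    elif scheme == "circular_shift":
                        shifts = rng.integers(n, size=m)
                        idx = (np.arange(n)[None, :] + shifts[:, None]) % n
                    else:
                        raise ValueError(f"unknown shuffle scheme {scheme!r}")
                    sw = swap[start:stop]
                    cmats = np.empty((m, 10, 10), dtype=np.float32)
                    if sw.any():
                        ap = az[idx[sw]]                       # (k, n, 10)
                        cmats[sw] = np.matmul(ap.transpose(0, 2, 1), bz) / n
                    if (~sw).any():
                        bp = bz[idx[~sw]]
                        cmats[~sw] = np.matmul(az.T[None], bp) / n
                    acc[start:stop] += cmats
            out[:, d, c] = _combo_from_matrices(acc.astype(float) / len(cell))
    return out


# ---------------------------------------------------------------------------
# the two analyses
# ---------------------------------------------------------------------------

def consistency_test(genuine: np.ndarray, pseudo: np.ndarray,
                     condition: tuple[str, str] | None = None,
                     smoothing: bool = False) -> pd.DataFrame:
    """Permutation consistency test of IMS against zero, one condition.

    ``genuine``: dyad-level coefficients, ``(n_dyads, 55)``;
    ``pseudo``: ``(n_perm, n_dyads, 55)``.  Returns one row per combination
    with the genuine t, raw one-sided p, BH-FDR q across the 55 combos and
    Cohen's d.
    """
    genuine = np.asarray(genuine, dtype=float)
    if genuine.shape[0] < 3:
        raise ValueError("need at least 3 dyads for a meaningful t statistic")
    t_gen = one_sample_t(genuine, axis=0)
    t_null = one_sample_t(pseudo, axis=1)
    p_raw = permutation_p(t_gen, t_null, smoothing=smoothing)
    q = fdr_bh(p_raw)
    sd = genuine.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(sd > 0, genuine.mean(axis=0) / sd, np.nan)
    df = pd.DataFrame({
        "combo": COMBO_LABELS,
        "t": t_gen,
        "p_raw": p_raw,
        "q_fdr": q,
        "cohens_d": d,
        "n_perm": t_null.shape[0],
    })
    if condition is not None:
        df.insert(0, "proximity", condition[0])
        df.insert(1, "vision", condition[1])
    return df


def run_consistency(study: StudyVelocities, n_perm: int = 1000,
                    rng: np.random.Generator | None = None,
                    scheme: str = "full_permutation",
                    pseudo: np.ndarray | None = None,
                    genuine: np.ndarray | None = None,
                    smoothing: bool = False) -> pd.DataFrame:
    """Consistency tests for all four conditions of a study (FDR within
    condition).  Precomputed genuine/pseudo coefficient arrays may be passed
    to share the permutation draws with :func:`run_permutation_anova`."""
    rng = rng if rng is not None else np.random.default_rng()
    if genuine is None:
        genuine = condition_coefficients(study)
    if pseudo is None:
        pseudo = pseudo_condition_coefficients(study, n_perm, rng, scheme)
    frames = []
    for c, cond in enumerate(CONDITIONS):
        frames.append(consistency_test(genuine[:, c, :], pseudo[:, :, c, :],
                                       cond, smoothing=smoothing))
    return pd.concat(frames, ignore_index=True)


def _anova_f_per_combo(coeffs: np.ndarray) -> np.ndarray:
    """F values of the 2x2 ANOVA per combo.

    ``coeffs``: ``(..., n_dyads, 4, 55)`` -> F ``(..., 3, 55)`` in
    :data:`EFFECTS_2X2` order."""
    y = np.moveaxis(coeffs, -1, -3)                 # (..., 55, n, 4)
    y = y.reshape(y.shape[:-1] + (2, 2))            # (prox, vis)
    res = rm_anova_2x2(y)
    return np.stack([res[e]["F"] for e in EFFECTS_2X2], axis=-2)


def run_permutation_anova(study: StudyVelocities, n_perm: int = 1000,
                          rng: np.random.Generator | None = None,
                          scheme: str = "full_permutation",
                          pseudo: np.ndarray | None = None,
                          genuine: np.ndarray | None = None,
                          smoothing: bool = False) -> pd.DataFrame:
    """Permutation 2x2 ANOVA (proximity x vision) per body-part combination.

    Returns one row per combination and effect with the genuine F,
    generalized eta squared, raw permutation p and BH-FDR q across the 55
    combos within effect.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if genuine is None:
        genuine = condition_coefficients(study)
    if pseudo is None:
        pseudo = pseudo_condition_coefficients(study, n_perm, rng, scheme)
    f_gen = _anova_f_per_combo(genuine)             # (3, 55)
    f_null = _anova_f_per_combo(pseudo)             # (n_perm, 3, 55)
    p_raw = permutation_p(f_gen, f_null, smoothing=smoothing)

    y = np.moveaxis(genuine, -1, 0).reshape(55, genuine.shape[0], 2, 2)
    res = rm_anova_2x2(y)
    eta = np.stack([res[e]["eta_g"] for e in EFFECTS_2X2], axis=0)

    frames = []
    for e, effect in enumerate(EFFECTS_2X2):
        frames.append(pd.DataFrame({
            "effect": effect,
            "combo": COMBO_LABELS,
            "F": f_gen[e],
            "eta_g": eta[e],
            "p_raw": p_raw[e],
            "q_fdr": fdr_bh(p_raw[e]),
            "n_perm": n_perm,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# single-combination consistency test (vectorised, for calibration studies)
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Outcome of one permutation test for a single combination."""

    label: str
    genuine_stat: float
    null_stats: np.ndarray
    p_raw: float
    effect_size: float
    n_perm: int

    @property
    def q_fdr(self) -> float:  # single test: q equals p
        return self.p_raw


def single_combo_consistency(a: np.ndarray, b: np.ndarray, n_perm: int,
                             rng: np.random.Generator,
                             label: str = "combo") -> PermutationResult:
    """Consistency test for one body-part combination.

    ``a`` and ``b`` are ``(n_dyads, n_samples)`` velocity series of the two
    partners.  Per replicate, partner B's series is shuffled within each dyad
    (with symmetrised coefficients the partner choice is immaterial, so a
    fixed partner keeps the fast path simple).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_dyads, n = a.shape
    if n_dyads < 3:
        raise ValueError("need at least 3 dyads")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    r_gen = (az * bz).mean(axis=1)                  # per-dyad r
    r_null = np.empty((n_perm, n_dyads))
    base = np.broadcast_to(np.arange(n), (n_perm, n))
    for d in range(n_dyads):
        idx = rng.permuted(base, axis=1)
        r_null[:, d] = (bz[d][idx] @ az[d]) / n
    t_gen = float(one_sample_t(r_gen))
    t_null = one_sample_t(r_null, axis=1)
    p = float((t_null > t_gen).mean())
    sd = r_gen.std(ddof=1)
    return PermutationResult(
        label=label,
        genuine_stat=t_gen,
        null_stats=t_null,
        p_raw=p,
        effect_size=float(r_gen.mean() / sd) if sd > 0 else np.nan,
        n_perm=n_perm,
    )
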