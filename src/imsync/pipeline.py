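"""End-to-end orchestration: synthetic study -> all analyses -> result files.

:func:`run` executes the full chain — generation (or ingestion), velocity
preprocessing, synchrony matrices, permutation tests, the velocity-range
ANOVA, cross-correlation lag analysis and circular-phase statistics — and
writes tidy CSV tables, a JSON summary (which conditions show significant
synchrony, peak-lag summaries, phase locking by vision) and a run log to an
output directory.  Every output records the configuration hash and seed, and
reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular as circ
from .anova import posthoc_pairwise, range_table_to_array, rm_anova_2x2x10
from .crosscorr import lag_grid, peak_lag_summary, regularize, wilcoxon_signed_rank, xcorr_columns
from .landmarks import CONDITIONS, PART_NAMES
from .permstats import (
    StudyVelocities, condition_coefficients, pseudo_condition_coefficients,
    run_consistency, run_permutation_anova,
)
from .synchrony import COMBO_LABELS, TRIL_INDICES, tidy_table
from .synthetic import SyntheticConfig, generate_study, range_table_from_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one end-to-end run."""

    out_dir: str = "results/run"
    seed: int = 0
    n_perm: int = 1000
    alpha: float = 0.05
    shuffle_scheme: str = "full_permutation"
    xcorr_max_lag: float = 10.0
    xcorr_step: float = 0.1
    run_xcorr: bool = True
    run_circular: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.shuffle_scheme not in ("full_permutation", "circular_shift"):
            raise ValueError("unknown shuffle scheme")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
        syn_unknown = set(syn) - syn_known
        if syn_unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(syn_unknown)}")
        return cls(synthetic=SyntheticConfig(**syn), **d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # scientific identity, not output location
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _xcorr_stage(study: StudyVelocities, cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Vision vs No-Vision cross-correlation peak lags per combination."""
    syn = cfg.synthetic
    grid = lag_grid(cfg.xcorr_max_lag, cfg.xcorr_step)
    group_conds = {"Vision": [i for i, c in enumerate(CONDITIONS) if c[1] == "Vision"],
                   "NoVision": [i for i, c in enumerate(CONDITIONS) if c[1] == "NoVision"]}
    ii, jj = TRIL_INDICES
    mean_fns, peaks = {}, {}
    for group, conds in group_conds.items():
        acc = np.zeros((grid.size, len(COMBO_LABELS)))
        n_fn = 0
        for d in range(study.n_dyads):
            for c in conds:
                for a, b in study.trials[d][c]:
                    t1 = (a.shape[0] - 1) / syn.frame_rate
                    ra = regularize(a, syn.frame_rate, t1=t1, step=cfg.xcorr_step)
                    rb = regularize(b, syn.frame_rate, t1=t1, step=cfg.xcorr_step)
                    # all ordered part pairs, then symmetrised to 55 combos
                    xa = ra[:, np.repeat(np.arange(10), 10)]
                    xb = rb[:, np.tile(np.arange(10), 10)]
                    cmat = xcorr_columns(xa, xb, cfg.xcorr_max_lag,
                                         cfg.xcorr_step).reshape(grid.size, 10, 10)
                    sym = (cmat + np.swapaxes(cmat, 1, 2)) / 2.0
                    acc += sym[:, ii, jj]
                    n_fn += 1
        mean_fn = acc / n_fn
        mean_fns[group] = {COMBO_LABELS[k]: mean_fn[:, k]
                           for k in range(len(COMBO_LABELS))}
        peaks[group] = peak_lag_summary(mean_fns[group], grid)
    rows = []
    for group in ("Vision", "NoVision"):
        for combo, lag in peaks[group]["per_combo"].items():
            rows.append({"vision_group": group, "combo": combo, "peak_lag_s": lag})
    lag_table = pd.DataFrame(rows)
    v = np.array([peaks["Vision"]["per_combo"][c] for c in COMBO_LABELS])
    nv = np.array([peaks["NoVision"]["per_combo"][c] for c in COMBO_LABELS])
    try:
        wil = wilcoxon_signed_rank(nv, v)
    except ValueError:
        wil = {"W": np.nan, "Z": np.nan, "p": np.nan, "n_nonzero": 0,
               "method": "undefined"}
    summary = {"vision": {k: peaks["Vision"][k] for k in
                          ("mean", "q1", "median", "q3", "fraction_fast")},
               "novision": {k: peaks["NoVision"][k] for k in
                            ("mean", "q1", "median", "q3", "fraction_fast")},
               "wilcoxon_novision_minus_vision": wil}
    return lag_table, summary


def _circular_stage(study: StudyVelocities, cfg: RunConfig) -> pd.DataFrame:
    """Homologous-part circular correlation and relative-phase variance,
    averaged across trials within dyad and condition."""
    rows = []
    for d in range(study.n_dyads):
        for c, (prox, vis) in enumerate(CONDITIONS):
            rho_acc = np.zeros(len(PART_NAMES))
            var_acc = np.zeros(len(PART_NAMES))
            n_tr = 0
            for a, b in study.trials[d][c]:
                for p in range(len(PART_NAMES)):
                    pa = circ.instantaneous_phase(a[:, p])
                    pb = circ.instantaneous_phase(b[:, p])
                    rho_acc[p] += circ.circular_correlation(pa, pb)
                    var_acc[p] += circ.circular_variance_of_relative_phase(pa, pb)
                n_tr += 1
            for p, part in enumerate(PART_NAMES):
                rows.append({"dyad": study.dyad_ids[d], "proximity": prox,
                             "vision": vis, "combo": f"{part}-{part}",
                             "rho_c": rho_acc[p] / n_tr, "V": var_acc[p] / n_tr})
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs under
    ``config.out_dir``.  Returns the result tables and summary in memory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("imsync")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    results: dict = {"config_hash": config.config_hash, "seed": config.seed}
    try:
        stage = "simulate"
        logger.info("generating synthetic study (hash %s)", config.config_hash)
        rng = np.random.default_rng(config.seed)
        study = generate_study(config.synthetic, level="velocity", rng=rng)

        stage = "synchrony"
        genuine = condition_coefficients(study)
        coeff_map = {}
        for d, dyad in enumerate(study.dyad_ids):
            for c, cond in enumerate(CONDITIONS):
                coeff_map[(dyad, cond)] = genuine[d, c]
        synchrony_table = tidy_table(coeff_map)
        results["synchrony"] = synchrony_table

        stage = "permtest"
        pseudo = pseudo_condition_coefficients(study, config.n_perm, rng,
                                               config.shuffle_scheme)
        consistency = run_consistency(study, pseudo=pseudo, genuine=genuine)
        perm_anova = run_permutation_anova(study, pseudo=pseudo, genuine=genuine)
        results["consistency"] = consistency
        results["perm_anova"] = perm_anova

        stage = "anova"
        range_table = range_table_from_study(study)
        anova_table = rm_anova_2x2x10(range_table)
        arr, _ = range_table_to_array(range_table)
        posthoc = posthoc_pairwise(arr.mean(axis=(1, 2)))
        results["range_table"] = range_table
        results["range_anova"] = anova_table
        results["posthoc"] = posthoc

        if config.run_xcorr:
            stage = "xcorr"
            lag_table, lag_summary = _xcorr_stage(study, config)
            results["peak_lags"] = lag_table
        else:
            lag_summary = None
        if config.run_circular:
            stage = "circular"
            results["circular"] = _circular_stage(study, config)

        stage = "report"
        sig = {}
        for (prox, vis), g in consistency.groupby(["proximity", "vision"]):
            sig[f"{prox}-{vis}"] = int((g["q_fdr"] < config.alpha).sum())
        summary = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "significant_combos_per_condition": sig,
            "conditions_with_significant_ims": [
                k for k, v in sig.items() if v > 0],
            "range_anova": {
                r["effect"]: {"F": r["F"], "p_gg": r["p_gg"], "eta_g": r["eta_g"]}
                for r in anova_table.to_dict("records")},
        }
        if lag_summary is not None:
            summary["peak_lags"] = lag_summary
        if config.run_circular:
            circ_df = results["circular"]
            summary["circular_V_by_vision"] = {
                vis: float(g["V"].mean()) for vis, g in circ_df.groupby("vision")}
        results["summary"] = summary

        meta = {"config_hash": config.config_hash, "seed": config.seed}
        for name in ("synchrony", "consistency", "perm_anova", "range_table",
                     "range_anova", "posthoc", "peak_lags", "circular"):
            if name in results:
                df = results[name].copy()
                for k, v in meta.items():
                    df[k] = v
                df.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, default=str))
        logger.info("run complete; outputs in %s", out)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return results
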