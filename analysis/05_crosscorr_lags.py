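"""How fast does synchrony emerge? Cross-correlation peak-lag analysis.

Regenerates the default study, resamples part-velocity series to a regular
0.1-s grid, computes +/-10-s cross-correlation functions per body-part
combination, averages them across trials (separately for Vision and
No Vision) and dyads, and takes the absolute lag of each combination's
peak.  The Vision and No Vision lag distributions are compared with a
Wilcoxon signed-rank test.  Writes ``peak_lags.csv`` and
``peak_lag_summary.json``.

To keep this driver's runtime moderate the study here is 12 dyads x 60-s
trials; the statistical pattern (Vision peaks near zero lag, No Vision
peaks scattered over the window) does not depend on the full size.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from imsync import RunConfig, SyntheticConfig
from imsync.pipeline import _xcorr_stage
from imsync.synthetic import generate_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-dyads", type=int, default=12)
    ap.add_argument("--duration", type=float, default=60.0)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    syn = SyntheticConfig(seed=args.seed, n_dyads=args.n_dyads,
                          duration=args.duration, missing_frac=0.0,
                          outlier_frac=0.0)
    cfg = RunConfig(out_dir=str(out), seed=args.seed, synthetic=syn)
    rng = np.random.default_rng(args.seed)
    study = generate_study(syn, level="velocity", rng=rng)
    lag_table, summary = _xcorr_stage(study, cfg)
    lag_table.to_csv(out / "peak_lags.csv", index=False)
    (out / "peak_lag_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))

    for group in ("vision", "novision"):
        s = summary[group]
        print(f"{group:>9}: mean |peak lag| = {s['mean']:.2f}s, "
              f"Q1 = {s['q1']:.2f}s, Q3 = {s['q3']:.2f}s, "
              f"{100 * s['fraction_fast']:.1f}% of peaks < 0.5s")
    w = summary["wilcoxon_novision_minus_vision"]
    print(f"Wilcoxon (NoVision vs Vision peak lags, 55 combos): "
          f"Z = {w['Z']:.2f}, p = {w['p']:.2e}")


if __name__ == "__main__":
    main()
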