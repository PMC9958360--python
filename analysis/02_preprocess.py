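"""Preprocess the demonstration landmark data into velocity panels.

Reads ``results/data_demo/`` (written by 01_simulate.py), runs the cleaning
chain (outlier removal, interpolation, smoothing, velocity, z-scoring,
body-part grouping), flags artifact trials, and writes the z-scored
part-velocity panels (long CSV) and a QC report (JSON) under ``results/``.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from imsync import preprocess_trial, read_manifest, read_tabular
from imsync.preprocess import flag_artifact_trials


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data_demo")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    data = Path(args.data)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(data / "manifest.csv")

    panels, rows = [], []
    for m in manifest:
        trial = f"{m.dyad_id}_t{m.trial_index:02d}"
        for who in ("a", "b"):
            series = read_tabular(data / f"{trial}_{who}.csv", frame_rate=30.0,
                                  participant_id=f"{m.dyad_id}{who}",
                                  trial_id=trial)
            panel = preprocess_trial(series)
            panels.append(panel)
            n = panel.n_samples
            rows.append(pd.DataFrame({
                "trial": trial, "participant": panel.participant_id,
                "proximity": m.proximity, "vision": m.vision,
                "sample": np.tile(np.arange(n), len(panel.part_names)),
                "part": np.repeat(panel.part_names, n),
                "velocity_z": panel.velocity.T.ravel(),
                "velocity_raw": panel.raw_velocity.T.ravel(),
            }))
    qc = flag_artifact_trials(panels)
    long = pd.concat(rows, ignore_index=True)
    long.to_csv(out / "velocity_panels.csv", index=False)

    report = {
        "n_panels": len(panels),
        "artifact_flags": qc,
        "provenance": {p.participant_id + "/" + p.trial_id: p.provenance
                       for p in panels},
    }
    (out / "qc_report.json").write_text(json.dumps(report, indent=2, default=float))

    miss = np.mean([p.provenance["missing_frac"] for p in panels])
    outl = np.mean([p.provenance["outlier_frac"] for p in panels])
    print(f"preprocessed {len(panels)} participant-trials -> "
          f"{out / 'velocity_panels.csv'}")
    print(f"mean missing fraction {miss:.3f}, mean outlier fraction {outl:.4f}, "
          f"{qc['n_flagged']} trials QC-flagged")


if __name__ == "__main__":
    main()
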