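"""Generate a small landmark-level demonstration dataset.

Writes, under ``results/data_demo/``: per-trial long-format keypoint CSVs
for both participants of two dyads (20-s trials, one per condition), a
sample per-frame keypoint JSON file, the trial manifest, and the planted
ground truth (burst events and coupling) as JSON.  The full-size study used
by the statistical drivers (23 dyads x 12 x 120-s trials) is regenerated
from its seed in each driver rather than stored.
"""

import argparse
import json
from pathlib import Path

from imsync import (
    CONDITIONS, SyntheticConfig, generate_dyad_trial, write_keypoint_json,
    write_manifest, write_tabular,
)
from imsync.landmarks import TrialManifest
import numpy as np


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/data_demo")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)
    cfg = SyntheticConfig(n_dyads=2, trials_per_condition=1, duration=20.0,
                          seed=args.seed)

    manifest, truths = [], {}
    for d in range(cfg.n_dyads):
        dyad = f"dyad{d + 1:02d}"
        for idx, cond in enumerate(CONDITIONS, start=1):
            trial = f"{dyad}_t{idx:02d}"
            a, b, truth = generate_dyad_trial(cfg, cond, rng, dyad_id=dyad,
                                              trial_id=trial)
            write_tabular(a, out / f"{trial}_a.csv")
            write_tabular(b, out / f"{trial}_b.csv")
            manifest.append(TrialManifest(
                dyad_id=dyad, participant_a=f"{dyad}a", participant_b=f"{dyad}b",
                proximity=cond[0], vision=cond[1], block=1, trial_index=idx,
                duration=cfg.duration))
            truths[trial] = {
                "condition": list(cond), "coupled": truth.coupled,
                "n_events_a": len(truth.events[0]),
                "n_events_b": len(truth.events[1]),
                "n_responses": len(truth.responses),
                "responses": truth.responses,
            }
            if d == 0 and idx == 1:
                write_keypoint_json(a, out / f"{trial}_a.keypoints.json")
    write_manifest(manifest, out / "manifest.csv")
    (out / "truth.json").write_text(json.dumps(truths, indent=2))

    n_resp = sum(t["n_responses"] for t in truths.values())
    coupled = [k for k, t in truths.items() if t["coupled"]]
    print(f"wrote {len(manifest)} trials for {cfg.n_dyads} dyads to {out}")
    print(f"coupled (Vision) trials: {coupled}")
    print(f"total planted response events: {n_resp} "
          f"(only in Vision trials, lag {cfg.coupling_lag}s)")


if __name__ == "__main__":
    main()
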