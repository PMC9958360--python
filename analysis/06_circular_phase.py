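"""Circular statistics of dyadic movement phase.

Extracts the instantaneous phase (analytic signal) of each partner's
homologous part-velocity series, computes the Fisher–Lee circular
correlation between partners and the circular variance of their continuous
relative phase, per dyad x condition (averaged across trials).  Phase
locking (lower circular variance, higher circular correlation) should
appear only under Vision, mirroring the linear-correlation results.
Writes ``circular_phase.csv``.

Uses a reduced study (12 dyads x 60-s trials) for runtime.
"""

import argparse
from pathlib import Path

import numpy as np

from imsync import RunConfig, SyntheticConfig
from imsync.pipeline import _circular_stage
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
    table = _circular_stage(study, cfg)
    table.to_csv(out / "circular_phase.csv", index=False)

    print("circular statistics by condition (homologous parts, "
          "mean over dyads):")
    for (p, v), g in table.groupby(["proximity", "vision"]):
        print(f"  {p:>4}-{v:<9} rho_c = {g['rho_c'].mean():+.4f}   "
              f"V(rel phase) = {g['V'].mean():.4f}")
    by_vis = table.groupby("vision")["V"].mean()
    print(f"phase locking contrast: V_Vision = {by_vis['Vision']:.4f} "
          f"< V_NoVision = {by_vis['NoVision']:.4f} -> "
          f"{'yes' if by_vis['Vision'] < by_vis['NoVision'] else 'no'}")


if __name__ == "__main__":
    main()
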