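"""Calibration harness for the shipped dynamics/plasticity defaults.

The model's cellular constants are not uniquely determined by its
structural description; they must place a trained network in the bistable
regime where cell assemblies (CAs) are ignitable by intrinsic noise yet
self-terminating.  This script runs the full reduced-scale pipeline for a
parameter override set and prints the diagnostics used to choose the
defaults:

* mean CA size per area (want primary < secondary < central, primary
  close to the pattern size);
* probe reactivation per area (want middle areas well above noise,
  approaching the driven areas);
* spontaneous ignition events in the noise-driven recording (want tens of
  episodes with durations of a few tens of steps, not 0 and not a
  recording-long plateau);
* first-significant-activation step per centrality level.

Usage::

    python scripts/calibrate.py --seed 1 --set dynamics.kS=0.22 \
        --set plasticity.w_max=0.5
"""

import argparse
import time

import numpy as np

from hebbca import reduced_preset
from hebbca.experiments import run_experiment


def apply_override(cfg, spec: str) -> None:
    key, raw = spec.split("=", 1)
    section, field = key.split(".")
    target = getattr(cfg, section)
    current = getattr(target, field)
    value = type(current)(raw) if not isinstance(current, bool) else raw == "true"
    setattr(target, field, value)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--variant", default="full",
                    choices=["full", "no_jumping", "no_noise"])
    ap.add_argument("--set", dest="overrides", action="append", default=[],
                    metavar="SECTION.FIELD=VALUE")
    args = ap.parse_args()

    cfg = reduced_preset(args.variant, args.seed)
    for spec in args.overrides:
        apply_override(cfg, spec)
    cfg.validate()

    t0 = time.time()
    rec = run_experiment(cfg, keep_recording=True)
    probe_max = rec.profile.reshape(
        cfg.patterns.n_patterns, 6, -1).max(axis=2).mean(axis=0)

    print(f"runtime: {time.time() - t0:.0f} s")
    print("mean CA size per area:")
    print(rec.mean_ca_size_per_area().round(1).to_string())
    print("probe reactivation (mean over patterns of per-area max):",
          np.round(probe_max, 2).tolist())
    print(f"ignition events: {rec.n_events} across "
          f"{rec.n_igniting_cas}/{rec.membership.n_patterns} CAs")
    if rec.events:
        durs = [e.duration for e in rec.events]
        print(f"event duration median {int(np.median(durs))}, "
              f"max {max(durs)} steps")
    print("first significant above-baseline step:", rec.onsets)


if __name__ == "__main__":
    main()
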