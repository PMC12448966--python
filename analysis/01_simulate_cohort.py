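#!/usr/bin/env python
"""Simulate the study cohort: 33 adaptive learning sessions + resting-state
time series with a planted connectivity–forgetting relation.

Uses the low-noise variant of the cohort spec (study-sized sessions and
volume counts, stronger planted slopes, halved latency noise) so the
downstream prediction stages have a cleanly recoverable signal; see
docs/methods.md for the rationale.  Writes trial logs, ROI time series,
ground truth, and raw session statistics under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from sofnet import io as sio
from sofnet.cohort import CohortSpec, simulate_cohort_behavior, simulate_cohort_timeseries

OUT = Path("results/cohort")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    spec = CohortSpec.low_noise(seed=SEED)
    print(f"simulating {spec.n_participants} participants (seed {SEED}) ...")
    logs, phis, truth = simulate_cohort_behavior(spec)

    (OUT / "trials").mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in sorted(logs):
        log = logs[pid]
        sio.write_trial_log(log, OUT / "trials" / f"{pid}.csv")
        tests = [t for t in log if t.kind == "test"]
        rows.append({
            "participant": pid,
            "sof_true": truth.sof_true[pid],
            "n_trials": len(log),
            "n_items": len({t.item for t in log}),
            "accuracy": np.mean([t.correct for t in tests]) if tests else np.nan,
        })
    stats = pd.DataFrame(rows)
    stats.to_csv(OUT / "session_stats.csv", index=False)

    ts = simulate_cohort_timeseries(spec, truth)
    (OUT / "timeseries").mkdir(exist_ok=True)
    for pid, frame in ts.items():
        frame.to_csv(OUT / "timeseries" / f"{pid}.csv", index=False)
    pd.DataFrame(
        {"participant": truth.participants,
         "sof_true": [truth.sof_true[p] for p in truth.participants]}
    ).to_csv(OUT / "ground_truth.csv", index=False)

    print(f"trials per session: mean {stats.n_trials.mean():.1f} "
          f"(range {stats.n_trials.min()}–{stats.n_trials.max()})")
    print(f"items seen: mean {stats.n_items.mean():.1f}; "
          f"test accuracy: mean {stats.accuracy.mean():.2f}")
    print(f"true SoF: mean {stats.sof_true.mean():.3f}, sd {stats.sof_true.std():.3f}")
    print(f"wrote cohort artifacts to {OUT}/")


if __name__ == "__main__":
    main()
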