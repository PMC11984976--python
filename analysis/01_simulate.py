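#!/usr/bin/env python
"""Simulate a synthetic participant cohort and store the raw sessions.

Each participant performs the full randomized protocol: 4 hand gestures
x 5 added loads x 8 reaching positions x 3 repetitions = 480 grasp
trials (3 s hold + 3 s rest), recorded as 8-channel EMG + 8-channel FMG
at 2000 Hz.  Sessions are written as HDF5 plus a JSON event table under
``results/sessions/`` (roughly 370 MB per participant at the full rate —
pass ``--rate 500`` for a lightweight look).

Run from the repository root:  python analysis/01_simulate.py
"""

import argparse
import dataclasses
from pathlib import Path

from myofuse.io_cli import PipelineConfig, simulate_participant, write_session
from myofuse.synthetic_data import SimulationConfig

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--participants", type=int, default=3)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--rate", type=float, default=2000.0)
parser.add_argument("--out", type=Path, default=Path("results/sessions"))
args = parser.parse_args()

cfg = PipelineConfig(
    simulation=SimulationConfig(sample_rate_hz=args.rate),
    n_participants=args.participants,
    schedule_seed=args.seed,
    signal_seed=args.seed + 1000,
)
args.out.mkdir(parents=True, exist_ok=True)
for i in range(args.participants):
    rec = simulate_participant(cfg, i)
    path = args.out / f"{rec.participant_id}.h5"
    write_session(rec, path)
    print(
        f"{rec.participant_id}: {len(rec.events)} trials, "
        f"{rec.n_samples} samples/channel at {rec.sample_rate_hz:g} Hz -> {path}"
    )
print(f"done: {args.participants} sessions under {args.out}")
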