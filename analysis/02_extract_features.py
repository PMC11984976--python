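#!/usr/bin/env python
"""Segment stored sessions and extract window-level feature tables.

Every trial's central 70 % of the 3 s hold (2.1 s) is cut into 200 ms
windows advanced by 50 ms (39 windows per repetition).  Each window
yields the Hudgins time-domain set per EMG channel (40 features), the
per-channel mean absolute value for FMG (8), and their stacked
concatenation (48).  One CSV per participant lands in
``results/features/``.

Run after 01_simulate.py:  python analysis/02_extract_features.py
"""

import argparse
from pathlib import Path

from myofuse.io_cli import PipelineConfig, participant_features, read_session, config_hash

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--sessions", type=Path, default=Path("results/sessions"))
parser.add_argument("--out", type=Path, default=Path("results/features"))
args = parser.parse_args()

cfg = PipelineConfig()
args.out.mkdir(parents=True, exist_ok=True)
paths = sorted(args.sessions.glob("*.h5"))
if not paths:
    raise SystemExit(f"no sessions under {args.sessions}; run 01_simulate.py first")
for path in paths:
    rec = read_session(path)
    feats = participant_features(cfg, rec)
    out_path = args.out / f"{rec.participant_id}.csv"
    with open(out_path, "w") as fh:
        fh.write(f"# config_hash={config_hash(cfg)}\n")
        feats.to_csv(fh, index=False)
    n_reps = feats.groupby(["gesture", "load_g", "position", "repetition"]).ngroups
    print(
        f"{rec.participant_id}: {len(feats)} windows over {n_reps} repetitions "
        f"({len(feats) // n_reps} windows each) -> {out_path}"
    )
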