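#!/usr/bin/env python
"""Run the three cross-condition classification designs per participant.

Test 1: 160-class (gesture, load, position) cross-validation, plus the
4-gesture neutral-vs-varying comparison.  Test 2: train in a single
(load, position) cell and transfer to the varied factor.  Test 3: train
neutral, test at the four extreme cells.  All designs run for EMG, FMG
and the stacked EMG+FMG fusion.  Outputs: a tidy accuracy-record table,
per-scheme descriptive summaries, and the across-participant averaged
160-class confusion matrix per modality, under ``results/``.

Run after 02_extract_features.py:  python analysis/03_classification_tests.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from myofuse import evaluation as ev
from myofuse.io_cli import PipelineConfig, config_hash

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--features", type=Path, default=Path("results/features"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

tag = config_hash(PipelineConfig())
paths = sorted(args.features.glob("*.csv"))
if not paths:
    raise SystemExit(f"no feature tables under {args.features}; run 02 first")

frames, confusions = [], {m: [] for m in ("emg", "fmg", "emg_fmg")}
for path in paths:
    feats = pd.read_csv(path, comment="#")
    records, cms = ev.evaluate_participant(feats)
    frames.append(records)
    for m, cm in cms.items():
        confusions[m].append(cm)
    pid = records["participant_id"].iloc[0]
    t1 = records[records.scheme == "test1_combined"]
    print(pid + ": test-1 accuracy " + ", ".join(
        f"{r.modality}={r.accuracy_pct:.1f}%" for r in t1.itertuples()
    ))

records = pd.concat(frames, ignore_index=True)
summary = ev.summarize(records)
args.out.mkdir(parents=True, exist_ok=True)
for name, df in (("records.csv", records), ("summary.csv", summary)):
    with open(args.out / name, "w") as fh:
        fh.write(f"# config_hash={tag}\n")
        df.to_csv(fh, index=False)

for m, cms in confusions.items():
    avg = ev.average_confusion(cms)
    labels = ["|".join(map(str, lab)) for lab in cms[0].labels]
    extremes = ev.diag_extremes(avg, labels)
    print(
        f"{m}: best condition {extremes['max_condition']} "
        f"({extremes['max_accuracy_pct']:.1f}%), worst "
        f"{extremes['min_condition']} ({extremes['min_accuracy_pct']:.1f}%)"
    )
    out = pd.DataFrame(np.round(avg, 2), index=labels, columns=labels)
    out.reset_index(names="true_condition").to_csv(
        args.out / f"confusion_test1_{m}.csv", index=False
    )

print("\nper-scheme summary (mean % across participants):")
print(
    summary.pivot(index="scheme", columns="modality", values="mean_pct")
    .round(2)
    .to_string()
)
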