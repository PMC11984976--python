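#!/usr/bin/env python
"""Mixed-model comparison of sensing modalities per evaluation scheme.

For each scheme, per-participant mean accuracies feed a random-intercept
linear mixed model (participant as the random effect, modality as the
fixed effect, fit by REML).  Estimated marginal means and
Benjamini-Hochberg-adjusted pairwise contrasts quantify which modality
differences survive multiple-comparison control at alpha = 0.05.
Writes ``results/contrasts.csv``.

Run after 03_classification_tests.py:  python analysis/04_stats.py
"""

import argparse
from pathlib import Path

import pandas as pd

from myofuse.stats import fit_random_intercept_lme, pairwise_emm_contrasts

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--records", type=Path, default=Path("results/records.csv"))
parser.add_argument("--out", type=Path, default=Path("results/contrasts.csv"))
args = parser.parse_args()

records = pd.read_csv(args.records, comment="#")
frames = []
for scheme, grp in records.groupby("scheme"):
    per_part = (
        grp.groupby(["participant_id", "modality"])["accuracy_pct"]
        .mean()
        .reset_index()
    )
    if per_part["participant_id"].nunique() < 3:
        print(f"{scheme}: fewer than 3 participants, skipping model")
        continue
    fit = fit_random_intercept_lme(per_part)
    contrasts = pairwise_emm_contrasts(fit)
    contrasts.insert(0, "scheme", scheme)
    frames.append(contrasts)
    emms = ", ".join(
        f"{lev}={emm:.2f}±{se:.2f}" for lev, emm, se in
        zip(fit.levels, fit.emm, fit.emm_se)
    )
    print(f"{scheme}: EMM {emms}; sigma_u={fit.sigma_u:.2f}, "
          f"sigma_e={fit.sigma_e:.2f}")
    for row in contrasts.itertuples():
        flag = "*" if row.significant else " "
        print(f"  {row.level_a} vs {row.level_b}: "
              f"diff={row.estimate:+.2f}, p_adj={row.p_adj:.4f} {flag}")

if frames:
    pd.concat(frames, ignore_index=True).to_csv(args.out, index=False)
    print(f"wrote {args.out}")
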