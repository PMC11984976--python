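"""The three cross-condition evaluation designs and their aggregation.

Test 1 asks how well each sensing modality separates full
(gesture, load, position) combinations — a 160-class problem — and, in a
second analysis, compares 4-gesture classification at the neutral
unloaded posture against classification pooled over all load/position
combinations.  Test 2 trains a 4-gesture classifier in a single cell
(one load and one position) and measures transfer to the remaining
positions (constant load) or remaining loads (constant position).
Test 3 trains at the neutral unloaded cell and tests at the four extreme
conditions: neutral, heavily loaded, outstretched, and outstretched +
loaded.

Every design uses window-level LDA with leave-one-repetition-out
cross-validation where train and test data would otherwise overlap, and
the diagonal-mean (macro-recall) accuracy of the resulting confusion
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classification import (
    ConfusionMatrix,
    DEFAULT_SHRINKAGE,
    accuracy,
    fit_lda,
    leave_one_repetition_out_cv,
    predict,
)
from .features import MODALITIES, modality_columns
from .synthetic_data import (
    GESTURES,
    LOADS_G,
    NEUTRAL_LOAD_G,
    NEUTRAL_POSITION,
    POSITIONS,
    all_conditions,
)

__all__ = [
    "SCHEMES",
    "TEST3_CONDITIONS",
    "EvaluationReport",
    "test1_combined",
    "test1_neutral_vs_varying",
    "test2_transfer",
    "test3_extremes",
    "evaluate_participant",
    "average_confusion",
    "summarize",
    "diag_extremes",
]

SCHEMES = (
    "test1_combined",
    "test1_neutral",
    "test1_varying",
    "test2_const_load",
    "test2_const_pos",
    "test3",
)

#: Test-3 evaluation cells: name -> (position, load_g).
TEST3_CONDITIONS = {
    "neutral": (NEUTRAL_POSITION, NEUTRAL_LOAD_G),
    "loaded": (NEUTRAL_POSITION, 1000),
    "outstretched": (5, NEUTRAL_LOAD_G),
    "outstretched_loaded": (5, 1000),
}

_CANONICAL_160 = [c.as_tuple() for c in all_conditions()]


def _xy(df: pd.DataFrame, modality: str) -> np.ndarray:
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    return df[modality_columns(modality)].to_numpy(dtype=float)


def _condition_tuples(df: pd.DataFrame) -> np.ndarray:
    return np.array(
        list(zip(df["gesture"], df["load_g"], df["position"])), dtype=object
    )


def test1_combined(
    df: pd.DataFrame, modality: str, shrinkage: float = DEFAULT_SHRINKAGE
) -> tuple[ConfusionMatrix, float]:
    """160-class cross-validated confusion matrix and its accuracy.

    The class label is the full (gesture, load, position) combination in
    canonical order; the matrix is 160 x 160.
    """
    cells = df.groupby(["gesture", "load_g", "position"]).size()
    if len(cells) != len(_CANONICAL_160):
        missing = set(_CANONICAL_160) - set(cells.index)
        raise ValueError(f"missing conditions: {sorted(missing)[:5]} ...")
    X = _xy(df, modality)
    y = [tuple(t) for t in _condition_tuples(df)]
    cm = leave_one_repetition_out_cv(
        X, y, df["repetition"].to_numpy(), class_order=_CANONICAL_160,
        shrinkage=shrinkage,
    )
    return cm, accuracy(cm)


def diag_extremes(cm_pct: np.ndarray, labels: Sequence) -> dict:
    """Best and worst diagonal entries of a row-normalised matrix."""
    diag = np.diag(cm_pct)
    return {
        "max_condition": labels[int(np.argmax(diag))],
        "max_accuracy_pct": float(np.max(diag)),
        "min_condition": labels[int(np.argmin(diag))],
        "min_accuracy_pct": float(np.min(diag)),
    }


def _gesture_cv(
    df: pd.DataFrame, modality: str, shrinkage: float
) -> tuple[ConfusionMatrix, float]:
    cm = leave_one_repetition_out_cv(
        _xy(df, modality),
        df["gesture"].to_numpy(object),
        df["repetition"].to_numpy(),
        class_order=list(GESTURES),
        shrinkage=shrinkage,
    )
    return cm, accuracy(cm)


def test1_neutral_vs_varying(
    df: pd.DataFrame, modality: str, shrinkage: float = DEFAULT_SHRINKAGE
) -> dict:
    """4-gesture accuracy at the neutral unloaded cell vs pooled over all cells."""
    neutral = df[
        (df["position"] == NEUTRAL_POSITION) & (df["load_g"] == NEUTRAL_LOAD_G)
    ]
    cm_n, acc_n = _gesture_cv(neutral, modality, shrinkage)
    cm_v, acc_v = _gesture_cv(df, modality, shrinkage)
    return {
        "neutral": {"confusion": cm_n, "accuracy_pct": acc_n},
        "varying": {"confusion": cm_v, "accuracy_pct": acc_v},
    }


def test2_transfer(
    df: pd.DataFrame,
    modality: str,
    mode: str,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> pd.DataFrame:
    """Single-cell training with transfer to the varied factor.

    ``constant_load``: for each load, train a 4-gesture classifier on all
    three repetitions at one position and test on each other position
    (8 x 7 = 56 cells per load).  ``constant_position`` swaps the factor
    roles (5 x 4 = 20 cells per position).  Returns one row per
    (held-constant level, train level, test level) with the accuracy.
    """
    if mode == "constant_load":
        held_vals, vary_vals = list(LOADS_G), list(POSITIONS)
        held_col, vary_col = "load_g", "position"
    elif mode == "constant_position":
        held_vals, vary_vals = list(POSITIONS), list(LOADS_G)
        held_col, vary_col = "position", "load_g"
    else:
        raise ValueError(
            "mode must be 'constant_load' or 'constant_position', got " f"{mode!r}"
        )

    rows = []
    for held in held_vals:
        at_held = df[df[held_col] == held]
        for train_level in vary_vals:
            train_df = at_held[at_held[vary_col] == train_level]
            model = fit_lda(
                _xy(train_df, modality),
                train_df["gesture"].to_numpy(object),
                class_order=list(GESTURES),
                shrinkage=shrinkage,
            )
            for test_level in vary_vals:
                if test_level == train_level:
                    continue
                test_df = at_held[at_held[vary_col] == test_level]
                cm = _confusion_from_model(model, test_df, modality)
                rows.append(
                    {
                        held_col: held,
                        f"train_{vary_col}": train_level,
                        f"test_{vary_col}": test_level,
                        "accuracy_pct": accuracy(cm),
                    }
                )
    return pd.DataFrame(rows)


def _confusion_from_model(model, test_df: pd.DataFrame, modality: str) -> ConfusionMatrix:
    pred = predict(model, _xy(test_df, modality))
    labels = model.class_labels
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(test_df["gesture"], pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def test3_extremes(
    df: pd.DataFrame, modality: str, shrinkage: float = DEFAULT_SHRINKAGE
) -> dict:
    """Neutral-trained 4-gesture accuracy at the four extreme cells.

    The neutral baseline is leave-one-repetition-out CV within the
    neutral cell (no train-on-test); the other three cells are disjoint
    from the training data, so the model trains on all three neutral
    repetitions.
    """
    neutral = df[
        (df["position"] == NEUTRAL_POSITION) & (df["load_g"] == NEUTRAL_LOAD_G)
    ]
    out = {}
    _, out_neutral = _gesture_cv(neutral, modality, shrinkage)
    out["neutral"] = out_neutral
    model = fit_lda(
        _xy(neutral, modality),
        neutral["gesture"].to_numpy(object),
        class_order=list(GESTURES),
        shrinkage=shrinkage,
    )
    for name, (pos, load) in TEST3_CONDITIONS.items():
        if name == "neutral":
            continue
        cell = df[(df["position"] == pos) & (df["load_g"] == load)]
        cm = _confusion_from_model(model, cell, modality)
        out[name] = accuracy(cm)
    return out


def evaluate_participant(
    df: pd.DataFrame,
    modalities: Iterable[str] = MODALITIES,
    tests: Iterable[int] = (1, 2, 3),
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> tuple[pd.DataFrame, dict]:
    """All requested designs for one participant's feature table.

    Returns a tidy accuracy-record frame (participant, modality, scheme,
    train/test condition, accuracy) plus a dict of per-modality Test-1
    confusion matrices for across-participant averaging.
    """
    tests = set(tests)
    participant = str(df["participant_id"].iloc[0])
    records = []
    confusions: dict = {}

    def rec(modality, scheme, train, test, acc):
        records.append(
            {
                "participant_id": participant,
                "modality": modality,
                "scheme": scheme,
                "train_condition": train,
                "test_condition": test,
                "accuracy_pct": acc,
            }
        )

    for modality in modalities:
        if 1 in tests:
            cm, acc = test1_combined(df, modality, shrinkage)
            confusions[modality] = cm
            rec(modality, "test1_combined", "all_conditions_cv", "all_conditions_cv", acc)
            nv = test1_neutral_vs_varying(df, modality, shrinkage)
            rec(modality, "test1_neutral", "neutral_cv", "neutral_cv",
                nv["neutral"]["accuracy_pct"])
            rec(modality, "test1_varying", "varying_cv", "varying_cv",
                nv["varying"]["accuracy_pct"])
        if 2 in tests:
            for mode, scheme in (
                ("constant_load", "test2_const_load"),
                ("constant_position", "test2_const_pos"),
            ):
                t2 = test2_transfer(df, modality, mode, shrinkage)
                held_col = "load_g" if mode == "constant_load" else "position"
                vary = "position" if mode == "constant_load" else "load_g"
                for _, row in t2.iterrows():
                    rec(
                        modality,
                        scheme,
                        f"{held_col}={row[held_col]},{vary}={row[f'train_{vary}']}",
                        f"{held_col}={row[held_col]},{vary}={row[f'test_{vary}']}",
                        row["accuracy_pct"],
                    )
        if 3 in tests:
            t3 = test3_extremes(df, modality, shrinkage)
            for name, acc in t3.items():
                rec(modality, "test3", "neutral", name, acc)

    return pd.DataFrame(records), confusions


def average_confusion(matrices: Sequence[ConfusionMatrix]) -> np.ndarray:
    """Elementwise mean of row-normalised matrices across participants (%)."""
    if len(matrices) == 0:
        raise ValueError("no confusion matrices to average")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("confusion matrices have mismatched labels")
    return np.mean([m.row_normalized_pct() for m in matrices], axis=0)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summaries per scheme x modality.

    Mean, sample SD, standard error SD/sqrt(n_participants), median and
    IQR (linear-interpolation quartiles) of the per-participant mean
    accuracies.  With a single participant SD/SE/IQR are reported as NaN.
    """
    if records.empty:
        raise ValueError("no accuracy records to summarise")
    per_participant = (
        records.groupby(["scheme", "modality", "participant_id"])["accuracy_pct"]
        .mean()
        .reset_index()
    )
    out = []
    for (scheme, modality), grp in per_participant.groupby(["scheme", "modality"]):
        vals = grp["accuracy_pct"].to_numpy()
        n = vals.size
        sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
        q1, q3 = np.percentile(vals, [25, 75])
        out.append(
            {
                "scheme": scheme,
                "modality": modality,
                "n_participants": n,
                "mean_pct": float(np.mean(vals)),
                "sd_pct": sd,
                "se_pct": sd / np.sqrt(n) if n > 1 else np.nan,
                "median_pct": float(np.median(vals)),
                "iqr_pct": float(q3 - q1) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(out)
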