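"""Train/validation/test splits and cross-validation folds.

Two splitting levels are supported:

* **subject level** — every window of a subject lands in one partition, so the
  model never sees test subjects during training (no identity leakage);
* **sample level** — windows are assigned independently of their subject, so
  the same person's gait typically appears on both sides of the split.

Both levels stratify on the faller label so the faller/non-faller ratio is
approximately preserved in each partition.  The test fraction defaults to 10%
of the data, with the remaining 90% split 80/20 into train and validation for
early stopping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import SubjectRecord
from .preprocess import Window

PARTITIONS = ("train", "val", "test")


class InfeasibleStratificationError(ValueError):
    """Raised when the faller ratio cannot be preserved across partitions."""


@dataclass
class SplitPlan:
    """Assignment of every retained window to train/val/test."""

    level: str  # "subject" or "sample"
    assignment: dict[str, str]  # window_id -> partition
    seed: int
    ratios: tuple[float, float]  # (train+val fraction, test fraction)
    fold_id: int = 0

    def window_ids(self, partition: str) -> list[str]:
        return [w for w, p in self.assignment.items() if p == partition]

    def subjects_in(self, partition: str, subject_of: dict[str, str]) -> set[str]:
        return {subject_of[w] for w in self.window_ids(partition)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_id": list(self.assignment), "partition": list(self.assignment.values()), "fold_id": self.fold_id}
        )

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump({"level": self.level, "seed": self.seed, "ratios": list(self.ratios)}, fh)


def _check_level(level: str) -> None:
    if level not in ("subject", "sample"):
        raise ValueError(f"level must be 'subject' or 'sample', got {level!r}")


def _ratio_tolerance_ok(labels: np.ndarray, overall: float, tolerance: float) -> bool:
    # rounding granularity 1/n is unavoidable at small partition sizes
    if len(labels) == 0:
        return True
    dev = abs(float(np.mean(labels)) - overall)
    return dev <= max(tolerance, 1.0 / len(labels))


def _split_units(
    units: list[str], labels: np.ndarray, test_fraction: float, val_fraction: float, stratify, seed: int
) -> dict[str, str]:
    """Stratified train/val/test assignment of atomic units (subjects or windows)."""
    units = np.asarray(units)
    strat = labels if stratify else None
    try:
        trainval, test = train_test_split(
            np.arange(len(units)), test_size=test_fraction, stratify=strat, random_state=seed
        )
        strat_tv = labels[trainval] if stratify else None
        train, val = train_test_split(trainval, test_size=val_fraction, stratify=strat_tv, random_state=seed + 1)
    except ValueError as exc:
        raise InfeasibleStratificationError(
            f"cannot stratify faller ratio across partitions: {exc}"
        ) from exc
    out: dict[str, str] = {}
    for idx, part in ((train, "train"), (val, "val"), (test, "test")):
        for i in idx:
            out[str(units[i])] = part
    return out


def split(
    windows: list[Window],
    subjects: list[SubjectRecord],
    level: str = "subject",
    ratios: tuple[float, float] = (0.9, 0.1),
    val_fraction: float = 0.2,
    stratify_on_fall: bool = True,
    tolerance: float = 0.05,
    seed: int = 0,
) -> SplitPlan:
    """Build a stratified train/val/test split at the requested level.

    ``ratios`` is (train+val, test); ``val_fraction`` carves the validation
    set out of the train+val block.  When stratified, each partition's faller
    ratio must match the overall ratio within ``tolerance`` (or within the
    granularity that integer counts allow); otherwise the split is rejected.
    """
    _check_level(level)
    if not windows:
        raise ValueError("no windows to split")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    label_of = {s.subject_id: s.fall_status for s in subjects}
    if level == "subject":
        sids = sorted({w.subject_id for w in windows})
        labels = np.array([label_of[s] for s in sids])
        part_of_subject = _split_units(sids, labels, ratios[1], val_fraction, stratify_on_fall, seed)
        assignment = {w.window_id: part_of_subject[w.subject_id] for w in windows}
        unit_labels = {p: labels[[part_of_subject[s] == p for s in sids]] for p in PARTITIONS}
    else:
        wids = [w.window_id for w in windows]
        labels = np.array([label_of[w.subject_id] for w in windows])
        assignment = _split_units(wids, labels, ratios[1], val_fraction, stratify_on_fall, seed)
        unit_labels = {p: labels[[assignment[w] == p for w in wids]] for p in PARTITIONS}
    if stratify_on_fall:
        overall = float(np.mean(labels))
        for p in PARTITIONS:
            if not _ratio_tolerance_ok(unit_labels[p], overall, tolerance):
                raise InfeasibleStratificationError(
                    f"faller ratio in {p} deviates from overall {overall:.3f} beyond ±{tolerance}"
                )
    return SplitPlan(level=level, assignment=assignment, seed=seed, ratios=ratios)


def kfold(
    windows: list[Window],
    subjects: list[SubjectRecord],
    level: str = "subject",
    k: int = 10,
    val_fraction: float = 0.2,
    stratify_on_fall: bool = True,
    seed: int = 0,
) -> list[SplitPlan]:
    """Stratified k-fold plans whose test parts are disjoint and exhaustive.

    Within each fold the non-test block is further split 80/20 into train and
    validation (stratified), mirroring the hold-out convention.
    """
    _check_level(level)
    if k < 2:
        raise ValueError("k must be >= 2")
    label_of = {s.subject_id: s.fall_status for s in subjects}
    if level == "subject":
        units = sorted({w.subject_id for w in windows})
    else:
        units = [w.window_id for w in windows]
    if k > len(units):
        raise ValueError(f"k={k} exceeds the {len(units)} available {level}-level units")
    if level == "subject":
        labels = np.array([label_of[u] for u in units])
    else:
        subj_of_w = {w.window_id: w.subject_id for w in windows}
        labels = np.array([label_of[subj_of_w[u]] for u in units])
    units_arr = np.asarray(units)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    try:
        folds = list(splitter.split(units_arr, labels if stratify_on_fall else np.zeros(len(units_arr), int)))
    except ValueError as exc:
        raise InfeasibleStratificationError(f"cannot build {k} stratified folds: {exc}") from exc
    plans = []
    for fold_id, (trainval, test) in enumerate(folds):
        strat_tv = labels[trainval] if stratify_on_fall else None
        try:
            train, val = train_test_split(
                trainval, test_size=val_fraction, stratify=strat_tv, random_state=seed + 100 + fold_id
            )
        except ValueError as exc:
            raise InfeasibleStratificationError(f"fold {fold_id}: {exc}") from exc
        part_of_unit: dict[str, str] = {}
        for idx, part in ((train, "train"), (val, "val"), (test, "test")):
            for i in idx:
                part_of_unit[str(units_arr[i])] = part
        if level == "subject":
            assignment = {w.window_id: part_of_unit[w.subject_id] for w in windows}
        else:
            assignment = {w.window_id: part_of_unit[w.window_id] for w in windows}
        plans.append(SplitPlan(level=level, assignment=assignment, seed=seed, ratios=(0.9, 0.1), fold_id=fold_id))
    return plans
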