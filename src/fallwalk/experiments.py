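"""End-to-end experiment arms over synthetic cohorts.

Five arms mirror the study design this package operationalises:

* **E1** — single-task fall-status classification, subject-level split
  (no identity leakage; the honest prognostic setting);
* **E2** — the same pipeline split at the sample level, where windows of one
  person can appear in both train and test (identity leakage inflates AUC);
* **E3** — sample-level multi-task learning with subject identity as the
  auxiliary head, probing whether the E2 inflation is identity memorisation;
  loss-weight ratios of interest are 1:1 and 10⁴:1 (main:auxiliary);
* **E4** — subject-level multi-task learning with an anthropometric auxiliary
  head (gender, age, weight or height);
* **E5** — E4 plus the spectral gait filter that drops windows whose dominant
  vertical frequency is ≤0.2 Hz.

``run_experiment`` generates the cohort, windows and (optionally filtered)
dataset, builds stratified splits or folds, trains the configured network per
fold, aggregates window predictions to subject medians, and reports fold-wise
AUCs plus a leakage audit (train/test subject overlap).  ``report`` tabulates
arms side by side with z- and t-test comparisons.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SubjectRecord, generate_cohort, generate_recordings
from .evaluate import (
    EvalReport,
    compare_auc_ttest,
    compare_auc_ztest,
    identity_ova_auc,
    roc_auc,
    subject_scores,
)
from .nets import ModelSpec, TaskHead, build_model, default_head, train
from .partition import SplitPlan, kfold, split
from .preprocess import (
    dominant_frequency_vt,
    filter_gait_windows,
    segment_windows,
    standardize_windows,
    windows_to_array,
)

EXPERIMENTS = ("E1", "E2", "E3", "E4", "E5")
_LEVEL_OF = {"E1": "subject", "E2": "sample", "E3": "sample", "E4": "subject", "E5": "subject"}


@dataclass
class ExperimentConfig:
    """One experiment arm: cohort, preprocessing, split, model and training.

    Defaults are a small-compute profile (tens of subjects, 25 Hz sampling,
    N=8 filters, pooling on) chosen so a full arm trains in seconds on one
    CPU; the cohort emulated by the generator scales to 296 subjects at
    100 Hz via these same fields.
    """

    experiment_id: str = "E1"
    # cohort
    n_subjects: int = 30
    faller_fraction: float = 0.341
    faller_delta: float = 1.5
    faller_freq_shift: float = 0.2
    contamination_rate: float = 0.0
    bouts_per_subject: int = 6
    bout_duration_s: float = 60.0
    sampling_rate: float = 25.0
    noise_sd: float = 0.05
    variability_range: tuple[float, float] = (0.02, 0.08)
    # preprocessing
    window_s: float = 10.0
    filter_on: bool = False
    filter_threshold: float = 0.2
    normalize: str = "none"  # none | window | global
    # split
    folds: int = 2
    val_fraction: float = 0.2
    # model
    family: str = "ConvLSTM"
    n_filters: int = 8
    kernel_size: int = 9
    pool: int = 2
    pool_layers: int = 2  # decimate 25 Hz -> 6.25 Hz; keeps the gait band below Nyquist
    dropout_rate: float = 0.1
    aux_task: str | None = None
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (main, auxiliary)
    learning_rate: float = 3e-3
    epochs: int = 20
    batch_size: int = 32
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.experiment_id not in EXPERIMENTS:
            raise ValueError(f"experiment_id must be one of {EXPERIMENTS}")
        if self.experiment_id == "E3" and self.aux_task != "identity":
            raise ValueError("E3 requires auxiliary task 'identity'")
        if self.experiment_id in ("E4", "E5") and self.aux_task not in (None, "gender", "age", "weight", "height"):
            raise ValueError("E4/E5 auxiliary task must be an anthropometric attribute or none")
        if self.experiment_id in ("E1", "E2") and self.aux_task is not None:
            raise ValueError(f"{self.experiment_id} is single-task")
        if self.experiment_id == "E5" and not self.filter_on:
            raise ValueError("E5 requires the spectral gait filter to be on")

    @property
    def level(self) -> str:
        return _LEVEL_OF[self.experiment_id]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["level"] = self.level
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _model_spec(cfg: ExperimentConfig, fold: int, n_train_subjects: int) -> ModelSpec:
    heads = [default_head("fall_status", loss_weight=cfg.loss_weights[0])]
    if cfg.aux_task is not None:
        heads.append(default_head(cfg.aux_task, n_subjects=n_train_subjects, loss_weight=cfg.loss_weights[1]))
    return ModelSpec(
        family=cfg.family,
        n_filters=cfg.n_filters,
        kernel_size=cfg.kernel_size,
        pool=cfg.pool,
        pool_layers=cfg.pool_layers,
        dropout_rate=cfg.dropout_rate,
        heads=heads,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        patience=cfg.patience,
        seed=cfg.seed * 1009 + fold,
    )


def build_dataset(cfg: ExperimentConfig):
    """Generate the cohort and its (optionally filtered) window set."""
    cohort_cfg = CohortConfig(
        faller_delta=cfg.faller_delta,
        faller_freq_shift=cfg.faller_freq_shift,
        noise_sd=cfg.noise_sd,
        variability_range=tuple(cfg.variability_range),
    )
    subjects, signatures = generate_cohort(
        cfg.n_subjects, cfg.faller_fraction, attribute_model=cohort_cfg, seed=cfg.seed
    )
    bouts = generate_recordings(
        subjects,
        signatures,
        bouts_per_subject=cfg.bouts_per_subject,
        bout_duration_s=cfg.bout_duration_s,
        sampling_rate=cfg.sampling_rate,
        contamination_rate=cfg.contamination_rate,
        seed=cfg.seed + 1,
        config=cohort_cfg,
    )
    windows = [w for b in bouts for w in segment_windows(b, cfg.window_s)]
    for w in windows:
        dominant_frequency_vt(w)
    n_total = len(windows)
    if cfg.filter_on:
        windows, excluded = filter_gait_windows(windows, cfg.filter_threshold)
    else:
        excluded = []
    return subjects, windows, {"n_windows_total": n_total, "n_windows_excluded": len(excluded)}


def _targets_for(windows_subjects: list[str], subjects: list[SubjectRecord], tasks, id_index: dict[str, int]):
    rec = {s.subject_id: s for s in subjects}
    out: dict[str, np.ndarray] = {}
    for task in tasks:
        if task == "fall_status":
            out[task] = np.array([rec[s].fall_status for s in windows_subjects], int)
        elif task == "identity":
            out[task] = np.array([id_index[s] for s in windows_subjects], int)
        else:
            out[task] = np.array([getattr(rec[s], task) for s in windows_subjects], float)
    return out


def run_experiment(cfg: ExperimentConfig) -> tuple[EvalReport, dict]:
    """Run one arm end to end; returns the main-task report and a manifest."""
    subjects, windows, data_info = build_dataset(cfg)
    label_of = {s.subject_id: s.fall_status for s in subjects}
    X_all, w_subjects = windows_to_array(windows)
    if cfg.normalize == "window":
        X_all, _ = standardize_windows(X_all, "window")
    wid_index = {w.window_id: i for i, w in enumerate(windows)}
    id_index = {s.subject_id: i for i, s in enumerate(subjects)}

    if cfg.folds >= 2:
        plans = kfold(windows, subjects, level=cfg.level, k=cfg.folds, val_fraction=cfg.val_fraction, seed=cfg.seed)
    else:
        plans = [
            split(windows, subjects, level=cfg.level, val_fraction=cfg.val_fraction, seed=cfg.seed)
        ]

    tasks = ["fall_status"] + ([cfg.aux_task] if cfg.aux_task else [])
    fold_aucs: list[float] = []
    fold_identity: list[float] = []
    fold_subject_scores: list[list[tuple[str, float, int]]] = []
    overlaps: list[int] = []
    histories = []
    for plan in plans:
        part_idx = {
            p: np.array([wid_index[w] for w in plan.window_ids(p)], int) for p in ("train", "val", "test")
        }
        subj_arr = np.array(w_subjects)
        train_subjects = sorted(set(subj_arr[part_idx["train"]]))
        test_subjects = set(subj_arr[part_idx["test"]])
        overlaps.append(len(set(train_subjects) & test_subjects))
        targets = _targets_for(w_subjects, subjects, tasks, id_index)
        if cfg.aux_task == "identity":
            # vocabulary = whole cohort so indices stay valid across partitions
            n_vocab = len(subjects)
        else:
            n_vocab = len(train_subjects)
        spec = _model_spec(cfg, plan.fold_id, n_vocab)
        net = build_model(spec, input_shape=X_all.shape[1:])
        X_parts = {p: X_all[part_idx[p]] for p in ("train", "val", "test")}
        if cfg.normalize == "global":
            X_parts["train"], stats = standardize_windows(X_parts["train"], "global")
            X_parts["val"], _ = standardize_windows(X_parts["val"], "global", stats)
            X_parts["test"], _ = standardize_windows(X_parts["test"], "global", stats)
        y_tr = {t: targets[t][part_idx["train"]] for t in tasks}
        y_va = {t: targets[t][part_idx["val"]] for t in tasks}
        model = train(net, X_parts["train"], y_tr, X_parts["val"], y_va)
        histories.append({"stopped_epoch": model.stopped_epoch, "final_loss": model.history["loss"][-1]})
        preds = model.predict(X_parts["test"])
        subs = subject_scores(
            preds["fall_status"], list(subj_arr[part_idx["test"]]), label_of
        )
        rep = roc_auc([s.aggregate for s in subs], [s.label for s in subs])
        if not rep.undefined:
            fold_aucs.append(rep.auc)
        fold_subject_scores.append([(s.subject_id, s.aggregate, s.label) for s in subs])
        if cfg.aux_task == "identity":
            ova = identity_ova_auc(
                preds["identity"], list(subj_arr[part_idx["test"]]), [s.subject_id for s in subjects]
            )
            fold_identity.append(ova["mean_auc"])

    report = EvalReport(per_fold_aucs=fold_aucs)
    if fold_aucs:
        report.mean_auc = float(np.mean(fold_aucs))
        report.sd_auc = float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
    manifest = {
        "experiment_id": cfg.experiment_id,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "level": cfg.level,
        "n_subjects": len(subjects),
        **data_info,
        "n_windows_used": len(windows),
        "folds": len(plans),
        "per_fold_aucs": fold_aucs,
        "mean_auc": report.mean_auc,
        "sd_auc": report.sd_auc,
        "identity_mean_ova_aucs": fold_identity,
        "subject_scores": fold_subject_scores,
        "train_test_subject_overlap": overlaps,
        "histories": histories,
    }
    if fold_identity:
        manifest["identity_mean_ova_auc"] = float(np.mean(fold_identity))
    return report, manifest


_COHORT_KEYS = (
    "n_subjects",
    "faller_fraction",
    "faller_delta",
    "faller_freq_shift",
    "contamination_rate",
    "bouts_per_subject",
    "bout_duration_s",
    "sampling_rate",
    "window_s",
)


def report(manifests: list[dict]) -> pd.DataFrame:
    """Tabulate arms (mean AUC, sd) with pairwise z- and t-test p-values.

    Arms generated from incompatible cohort settings are rejected; arms with
    the same configuration but different seeds are flagged non-comparable.
    """
    if not manifests:
        raise ValueError("need at least one manifest")
    ref = {k: manifests[0]["config"][k] for k in _COHORT_KEYS if k != "contamination_rate"}
    for m in manifests[1:]:
        other = {k: m["config"][k] for k in _COHORT_KEYS if k != "contamination_rate"}
        if other != ref:
            raise ValueError("manifests come from incompatible cohort configurations")
    rows = []
    for m in manifests:
        rows.append(
            {
                "experiment_id": m["experiment_id"],
                "level": m["level"],
                "mean_auc": m["mean_auc"],
                "sd_auc": m["sd_auc"],
                "folds": m["folds"],
                "seed": m["seed"],
                "non_comparable_seed": False,
            }
        )
    df = pd.DataFrame(rows)
    seen: dict[str, int] = {}
    for i, m in enumerate(manifests):
        h = m["config_hash"]
        if h in seen and m["seed"] != manifests[seen[h]]["seed"]:
            df.loc[i, "non_comparable_seed"] = True
        seen.setdefault(h, i)
    tests = []
    for i in range(len(manifests)):
        for j in range(i + 1, len(manifests)):
            a, b = manifests[i], manifests[j]
            if a["mean_auc"] is None or b["mean_auc"] is None:
                continue
            zres = compare_auc_ztest(
                a["mean_auc"], a["sd_auc"] or 0.0, a["folds"], b["mean_auc"], b["sd_auc"] or 0.0, b["folds"]
            )
            row = {
                "pair": f"{a['experiment_id']}-vs-{b['experiment_id']}",
                "z": zres.statistic,
                "p_z": zres.p_value,
            }
            if len(a["per_fold_aucs"]) >= 2 and len(b["per_fold_aucs"]) >= 2:
                tres = compare_auc_ttest(a["per_fold_aucs"], b["per_fold_aucs"])
                row.update(t=tres.statistic, p_t=tres.p_value)
            tests.append(row)
    df.attrs["comparisons"] = pd.DataFrame(tests)
    return df
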