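"""Desk-scale reproductions of the two study protocols.

* the **seven-group ablation**: train one LSTM-CNN per sensor-site
  combination on a common synthetic cohort, evaluate all of them on the
  same held-out test cycles, and tabulate per-phase precision/recall/F1
  plus the macro aggregates and confusion matrices;
* the **DPF comparison**: run the phase-routed specialist engine and the
  always-on full-site model over identical held-out validation streams,
  per subject, and compare accuracy and macro-F1 (paired design).

Splitting is by whole gait cycle, never by window: stride-overlapping
windows from the same cycle would otherwise leak across a window-level
split.  Each subject×speed trial of ten cycles contributes its first six
cycles to training, the next two to the ablation test set, and the final
two — kept contiguous so the engine sees an uninterrupted walking stream —
to the DPF validation set.  Disjointness is asserted programmatically.

The default cohort (six subjects, three speeds, ten cycles each) and the
training budget (30-epoch cap with early stopping) keep a full ablation in
the minutes range on one CPU while preserving the protocol's structure.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dpf import DPFConfig, DPFResult, run_stream
from .labeling import label_windows, phases_from_grf
from .metrics import MetricsReport, evaluate
from .nets import ModelSpec, TrainConfig, TrainedModel, build_model, train
from .phases import PHASE_NAMES, SITES
from .preprocess import (
    WINDOW_LEN,
    NormalizerParams,
    SensorGroup,
    apply_normalizer,
    fit_normalizer,
    interpolate_recording,
    select_channels,
    window_stack,
)
from .synthgait import GaitRecording, SynthConfig, simulate_recording

logger = logging.getLogger(__name__)

#: specialist model id -> ablation group id used by the DPF engine
SPECIALIST_GROUP_IDS = {"LSTM-CNN-1": 7, "LSTM-CNN-2": 6, "LSTM-CNN-3": 4}


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ExperimentPlan:
    """Everything needed to rerun both protocols from a single master seed."""

    synth: SynthConfig = field(default_factory=lambda: SynthConfig(n_subjects=6))
    spec: ModelSpec = field(default_factory=ModelSpec)
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            batch_size=128,
            max_epochs=30,
            early_stop_patience=3,
            early_stop_min_delta=1e-3,
        )
    )
    dpf: DPFConfig = field(default_factory=DPFConfig)
    groups: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    train_cycles: int = 6
    test_cycles: int = 2
    val_cycles: int = 2
    train_stride: int = 5
    test_stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_cycles + self.test_cycles + self.val_cycles
        if total != self.synth.cycles_per_speed:
            raise ValueError(
                f"train+test+val cycles ({total}) must equal cycles_per_speed "
                f"({self.synth.cycles_per_speed})"
            )
        if min(self.train_cycles, self.test_cycles, self.val_cycles) < 1:
            raise ValueError("each split needs at least one cycle")

    def seeded(self) -> "ExperimentPlan":
        """A copy whose cohort seed is derived from the master seed."""
        return dataclasses.replace(
            self,
            synth=dataclasses.replace(self.synth, seed=_derive_seed(self.seed, 1)),
        )


@dataclass
class Dataset:
    """Cycle-split windows and streams for one synthetic cohort."""

    train_windows: np.ndarray  # (N, 20, 6) raw degrees
    train_labels: np.ndarray
    test_windows: np.ndarray
    test_labels: np.ndarray
    normalizer: NormalizerParams  # fitted on the training cycles only
    val_streams: list[GaitRecording]  # contiguous validation cycles
    subjects: list[str]


def _split_ranges(plan: ExperimentPlan, npc: int) -> dict[str, tuple[int, int]]:
    a = plan.train_cycles * npc
    b = a + plan.test_cycles * npc
    c = b + plan.val_cycles * npc
    return {"train": (0, a), "test": (a, b), "val": (b, c)}


def build_dataset(plan: ExperimentPlan) -> Dataset:
    """Simulate the cohort, label it from GRF, and split by whole cycles."""
    plan = plan.seeded()
    cfg = plan.synth
    subjects = cfg.subject_ids()

    train_slices: list[GaitRecording] = []
    val_streams: list[GaitRecording] = []
    tr_w, tr_y, te_w, te_y = [], [], [], []
    for sid in subjects:
        for speed in cfg.speeds:
            rec = interpolate_recording(simulate_recording(cfg, sid, speed))
            npc = rec.samples_per_cycle
            assert npc is not None
            ranges = _split_ranges(plan, npc)
            # the leakage guard: split sample ranges must be disjoint
            assert ranges["train"][1] <= ranges["test"][0] <= ranges["test"][1] <= ranges["val"][0]
            track = phases_from_grf(rec.grf_left, rec.grf_right)
            for split, stride, ws, ys in (
                ("train", plan.train_stride, tr_w, tr_y),
                ("test", plan.test_stride, te_w, te_y),
            ):
                lo, hi = ranges[split]
                stack, starts = window_stack(
                    rec.angle_matrix()[lo:hi], WINDOW_LEN, stride
                )
                ws.append(stack)
                ys.append(label_windows(starts, track[lo:hi], WINDOW_LEN))
            train_slices.append(rec.slice(*ranges["train"]))
            val_streams.append(rec.slice(*ranges["val"]))

    normalizer = fit_normalizer(train_slices, SITES)
    return Dataset(
        train_windows=np.concatenate(tr_w),
        train_labels=np.concatenate(tr_y),
        test_windows=np.concatenate(te_w),
        test_labels=np.concatenate(te_y),
        normalizer=normalizer,
        val_streams=val_streams,
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# protocol 1: the seven-group ablation

@dataclass
class AblationResult:
    reports: dict[int, MetricsReport]
    models: dict[int, TrainedModel]

    def table(self) -> pd.DataFrame:
        """Per-group per-phase rows plus one aggregate row per group."""
        rows = []
        for gid, rep in self.reports.items():
            for i, phase in enumerate(PHASE_NAMES):
                rows.append(
                    {
                        "group": gid,
                        "row": phase,
                        "precision": rep.precision[i],
                        "recall": rep.recall[i],
                        "f1": rep.f1[i],
                    }
                )
            rows.append(
                {
                    "group": gid,
                    "row": "macro",
                    "precision": rep.macro_precision,
                    "recall": rep.macro_recall,
                    "f1": rep.macro_f1,
                    "accuracy": rep.accuracy,
                }
            )
        return pd.DataFrame(rows)


def run_ablation(plan: ExperimentPlan, dataset: Dataset | None = None) -> AblationResult:
    """Train and evaluate one model per sensor group on a common cohort."""
    if dataset is None:
        dataset = build_dataset(plan)
    reports: dict[int, MetricsReport] = {}
    models: dict[int, TrainedModel] = {}
    for gid in plan.groups:
        t0 = time.perf_counter()
        group = SensorGroup(gid)
        norm = dataset.normalizer.subset(group.sites)
        x_tr = apply_normalizer(norm, select_channels(dataset.train_windows, group))
        x_te = apply_normalizer(norm, select_channels(dataset.test_windows, group))
        seed = _derive_seed(plan.seed, 2, gid)
        net = build_model(plan.spec, group.n_channels, seed=seed)
        model = train(
            net,
            x_tr,
            dataset.train_labels,
            dataclasses.replace(plan.train, seed=seed),
            sensor_group=group,
            normalizer=norm,
            name=f"group-{gid}",
        )
        pred = model.predict(x_te)
        reports[gid] = evaluate(dataset.test_labels, pred)
        models[gid] = model
        logger.info(
            "group %d: %d epochs, test accuracy %.4f (%.1f s)",
            gid,
            len(model.history),
            reports[gid].accuracy,
            time.perf_counter() - t0,
        )
    return AblationResult(reports=reports, models=models)


# ---------------------------------------------------------------------------
# protocol 2: DPF vs the always-on full-site model

@dataclass
class ComparisonResult:
    per_subject: pd.DataFrame  # one row per subject plus an Average row
    dpf_reports: dict[str, MetricsReport]
    baseline_reports: dict[str, MetricsReport]
    dpf_results: dict[str, list[DPFResult]]


def specialists_from_ablation(ablation: AblationResult) -> dict[str, TrainedModel]:
    """Bind the DPF model ids to the ablation's group-7/6/4 models."""
    missing = [
        gid for gid in SPECIALIST_GROUP_IDS.values() if gid not in ablation.models
    ]
    if missing:
        raise ValueError(f"ablation lacks required specialist group(s) {missing}")
    out = {}
    for name, gid in SPECIALIST_GROUP_IDS.items():
        model = ablation.models[gid]
        out[name] = dataclasses.replace(model, name=name)
    return out


def run_dpf_comparison(
    plan: ExperimentPlan,
    dataset: Dataset,
    specialists: dict[str, TrainedModel],
) -> ComparisonResult:
    """Paired evaluation on the held-out validation streams, per subject.

    Both methods see the identical stride-1 window streams; the baseline is
    the full six-site model applied to every window, the DPF engine routes
    windows to specialists and debounces commits.
    """
    baseline = specialists[plan.dpf.initial_model]
    by_subject: dict[str, dict[str, list[np.ndarray]]] = {
        sid: {"truth": [], "dpf": [], "base": []} for sid in dataset.subjects
    }
    dpf_results: dict[str, list[DPFResult]] = {sid: [] for sid in dataset.subjects}

    for stream in dataset.val_streams:
        sid = stream.subject_id
        res = run_stream(stream, specialists, plan.dpf, stride=1)
        assert res.truth is not None
        stack, _ = window_stack(
            interpolate_recording(stream).angle_matrix(), WINDOW_LEN, 1
        )
        base_pred = baseline.predict_on_raw(stack).argmax(axis=1).astype(np.int8)
        by_subject[sid]["truth"].append(res.truth)
        by_subject[sid]["dpf"].append(res.prediction_track)
        by_subject[sid]["base"].append(base_pred)
        dpf_results[sid].append(res)

    rows = []
    dpf_reports: dict[str, MetricsReport] = {}
    base_reports: dict[str, MetricsReport] = {}
    for sid in dataset.subjects:
        truth = np.concatenate(by_subject[sid]["truth"])
        rep_d = evaluate(truth, np.concatenate(by_subject[sid]["dpf"]))
        rep_b = evaluate(truth, np.concatenate(by_subject[sid]["base"]))
        dpf_reports[sid], base_reports[sid] = rep_d, rep_b
        rows.append(
            {
                "subject": sid,
                "lstm_cnn_1_accuracy": rep_b.accuracy,
                "lstm_cnn_1_macro_f1": rep_b.macro_f1,
                "dpf_accuracy": rep_d.accuracy,
                "dpf_macro_f1": rep_d.macro_f1,
            }
        )
    df = pd.DataFrame(rows)
    avg = df.drop(columns="subject").mean()
    df = pd.concat(
        [df, pd.DataFrame([{"subject": "Average", **avg.to_dict()}])],
        ignore_index=True,
    )
    return ComparisonResult(
        per_subject=df,
        dpf_reports=dpf_reports,
        baseline_reports=base_reports,
        dpf_results=dpf_results,
    )


# ---------------------------------------------------------------------------
# one-call driver

@dataclass
class ExperimentResult:
    plan: ExperimentPlan
    dataset: Dataset
    ablation: AblationResult
    comparison: ComparisonResult


def run_full(plan: ExperimentPlan) -> ExperimentResult:
    """Build the cohort, run the ablation, then the DPF comparison,
    reusing the ablation's group-7/6/4 models as the specialists."""
    t0 = time.perf_counter()
    dataset = build_dataset(plan)
    logger.info(
        "dataset: %d train / %d test windows (%.1f s)",
        len(dataset.train_labels),
        len(dataset.test_labels),
        time.perf_counter() - t0,
    )
    ablation = run_ablation(plan, dataset)
    specialists = specialists_from_ablation(ablation)
    comparison = run_dpf_comparison(plan, dataset, specialists)
    logger.info("experiment complete in %.1f s", time.perf_counter() - t0)
    return ExperimentResult(
        plan=plan, dataset=dataset, ablation=ablation, comparison=comparison
    )
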