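"""Offline accuracy reporting, method comparison and online MCR/MST simulation.

The online simulation emulates the real-time use of the sequence
classifier: trials are presented in random task order, and at each new
muscular activation event (once at least three activations are available
under some task's threshold vector, or at the end of the transient window)
the partial 12-element feature is re-encoded and classified.  A trial is
completed when the target class is output before the trial ends; the
motion selection time (MST) is measured from movement onset to the first
correct classification, and the motion completion rate (MCR) is the
percentage of completed trials per task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import TrainedModel
from .io_formats import FeatureTable
from .onset import RestModel, detect_soa
from .sequences import PREFIX_LEN, TASKS, encode_sequence
from .synthetic import EnvelopeRecording
from .thresholds import ThresholdVector


@dataclass
class AccuracyReport:
    """Per-(subject, configuration, model) accuracies with aggregation."""

    rows: pd.DataFrame  # columns: subject, config, model, accuracy (%)
    confusions: dict = field(default_factory=dict)  # (config, model) -> DataFrame

    def mean_sd(self) -> pd.DataFrame:
        g = self.rows.groupby(["config", "model"])["accuracy"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"std": "sd", "count": "n_subjects"})

    def summary(self) -> str:
        table = self.mean_sd()
        lines = ["Offline classification accuracy (%, mean +/- sd over datasets)"]
        for _, r in table.iterrows():
            sd = 0.0 if np.isnan(r["sd"]) else r["sd"]
            lines.append(f"  {r['config']:>8s}  {r['model']:>4s}  "
                         f"{r['mean']:5.1f} +/- {sd:4.1f}  (n={int(r['n_subjects'])})")
        return "\n".join(lines)


def accuracy_and_confusion(y_true: Sequence[str], y_pred: Sequence[str],
                           classes: Sequence[str] | None = None):
    """Accuracy (%), per-class accuracy (%) and a confusion DataFrame."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    acc = 100.0 * float(np.mean(y_true == y_pred)) if y_true.size else float("nan")
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    per_class = {
        c: (100.0 * conf.loc[c, c] / conf.loc[c].sum()) if conf.loc[c].sum() else float("nan")
        for c in classes}
    return acc, per_class, conf


def offline_evaluate(runs) -> AccuracyReport:
    """Aggregate held-out evaluations.

    ``runs`` yields ``(subject_id, config, model, test_table)`` tuples; the
    model's feature kind must match the table's.
    """
    rows = []
    confusions: dict = {}
    for subject, config, model, table in runs:
        if model.feature_kind != table.kind:
            raise ValueError(f"feature-kind mismatch: model expects "
                             f"{model.feature_kind!r}, table is {table.kind!r}")
        pred = model.predict(table.X)
        acc, _, conf = accuracy_and_confusion(table.labels, pred, model.classes)
        rows.append({"subject": subject, "config": config,
                     "model": model.kind, "accuracy": acc})
        key = (config, model.kind)
        confusions[key] = conf if key not in confusions else confusions[key] + conf
    return AccuracyReport(rows=pd.DataFrame(rows), confusions=confusions)


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    significant: bool
    normal_differences: bool


def compare_methods(accuracies_a: Sequence[float], accuracies_b: Sequence[float],
                    alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated inter-method test.

    Shapiro-Wilk on the paired differences routes to a paired t-test when
    normality is not rejected (p > alpha) and to a two-sided Mann-Whitney
    U-test otherwise.  The U-test is applied unpaired, matching its
    conventional form, even though the inputs are paired per dataset.
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired equal-length vectors required")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    diffs = a - b
    if np.ptp(diffs) == 0.0:
        # Zero-variance differences: Shapiro and the t denominator degenerate.
        if diffs[0] == 0.0:
            return ComparisonResult("paired t-test", 0.0, 1.0, False, True)
        return ComparisonResult("paired t-test", float(np.inf), 0.0, True, True)
    normal = stats.shapiro(diffs).pvalue > alpha
    if normal:
        res = stats.ttest_rel(a, b)
        name = "paired t-test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
    return ComparisonResult(name, float(res.statistic), float(res.pvalue),
                            bool(res.pvalue < alpha), normal)


@dataclass
class TaskOnline:
    attempts: int = 0
    completed: int = 0
    mst_values_ms: list = field(default_factory=list)

    @property
    def mcr(self) -> float:
        return 100.0 * self.completed / self.attempts if self.attempts else float("nan")

    @property
    def mst_mean_ms(self) -> float | None:
        return float(np.mean(self.mst_values_ms)) if self.mst_values_ms else None

    @property
    def mst_sd_ms(self) -> float | None:
        if len(self.mst_values_ms) < 2:
            return 0.0 if self.mst_values_ms else None
        return float(np.std(self.mst_values_ms, ddof=1))


@dataclass
class OnlineResult:
    per_task: dict

    @property
    def overall_mcr(self) -> float:
        att = sum(t.attempts for t in self.per_task.values())
        comp = sum(t.completed for t in self.per_task.values())
        return 100.0 * comp / att if att else float("nan")


def make_trial_stream(profiles, noise, attempts_per_task: int = 5, seed=0,
                      subject_id: str = "online", **kwargs):
    """Generate trials for each gesture profile and shuffle their order."""
    from .synthetic import generate_dataset

    trials = generate_dataset(profiles, noise, attempts_per_task, seed,
                              subject_id=subject_id, **kwargs)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def online_simulate(model: TrainedModel,
                    representative_vectors: Mapping[str, ThresholdVector],
                    rest: RestModel,
                    trial_stream: Sequence[EnvelopeRecording],
                    sustain_ms: float = 50.0, window_ms: float = 300.0,
                    min_activations: int = PREFIX_LEN,
                    tasks: Sequence[str] = TASKS) -> OnlineResult:
    """Sample-by-sample emulation of online sequence classification.

    Each trial is scanned for its SoA; every TH_High crossing under any
    task vector is an activation event.  At each event where some task
    vector has accumulated ``min_activations`` crossings — and once more at
    the end of the transient window — the partial feature is encoded from
    the crossings observed so far and classified.  The first correct output
    completes the trial; MST is that decision time minus the ground-truth
    movement onset.
    """
    result = {task: TaskOnline() for task in tasks}
    for rec in trial_stream:
        if rec.truth is None or rec.truth.get("onset_ms") is None:
            raise ValueError("online trials require a ground-truth onset")
        task = rec.label
        if task not in result:
            result[task] = TaskOnline()
        tracker = result[task]
        tracker.attempts += 1
        ann = detect_soa(rec, rest, sustain_ms)
        if ann.soa_ms is None:
            continue  # no decision before trial end -> failed
        # Crossing latencies (from SoA) per task vector.
        per_task = {
            t: encode_sequence(rec, ann.soa_ms, representative_vectors[t],
                               window_ms).latencies_ms
            for t in tasks}
        events = sorted({lat for lats in per_task.values()
                         for lat in lats.values()})
        decision_times = [t for t in events
                          if max(sum(1 for lat in lats.values() if lat <= t)
                                 for lats in per_task.values()) >= min_activations]
        decision_times.append(window_ms)  # final decision at window end
        onset = rec.truth["onset_ms"]
        for t_dec in decision_times:
            feature = []
            for tk in tasks:
                seen = sorted((lat, ch) for ch, lat in per_task[tk].items()
                              if lat <= t_dec)
                block = [ch for _, ch in seen][:PREFIX_LEN]
                feature.extend(block + [0] * (PREFIX_LEN - len(block)))
            pred = model.predict(np.asarray(feature, dtype=float))[0]
            if pred == task:
                tracker.completed += 1
                tracker.mst_values_ms.append(ann.soa_ms + t_dec - onset)
                break
    return OnlineResult(per_task=result)
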