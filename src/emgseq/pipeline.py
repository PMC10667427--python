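"""End-to-end model: recordings in, fitted sequence classifier out.

``SequenceClassifier`` bundles the full training procedure — rest-statistic
estimation, double-threshold onset detection, per-task TH_High search,
sequence (or baseline) feature encoding and classifier training — behind a
statsmodels-style Model/Results pair: construct the model from a list of
labeled envelope recordings, call :meth:`SequenceClassifier.fit`, and read
estimates, held-out accuracy and diagnostics off the returned
:class:`SequenceClassifierResults` (or print :meth:`~SequenceClassifierResults.summary`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import baselines, classify, evaluate, io_formats, onset, sequences, thresholds
from .io_formats import FeatureTable
from .sequences import TASKS
from .synthetic import EnvelopeRecording


class SequenceClassifier:
    """Transient-state gesture classifier trained on envelope recordings.

    Parameters
    ----------
    recordings : list of EnvelopeRecording
        Labeled acquisitions of one dataset (typically one subject,
        50 repetitions of each of the four gestures, optionally Rest).
    n_steps : int
        Ladder depth of the TH_High search, 2..5.
    x : float
        Low-threshold multiplier (TH_Low = mu + x sigma).
    classifier : str
        One of ``nlr``, ``svm``, ``ann``, ``lda``.
    feature_kind : str
        ``sequence12`` (activation-sequence features), ``ets`` (binned
        transient envelope) or ``ess`` (steady-state MAV).
    """

    def __init__(self, recordings: Sequence[EnvelopeRecording], *,
                 n_steps: int = 4, x: float = 15.0, sustain_ms: float = 50.0,
                 window_ms: float = 300.0, classifier: str = "nlr",
                 feature_kind: str = "sequence12",
                 hyperparams: dict | None = None,
                 train_fraction: float = 0.8, tasks: Sequence[str] = TASKS):
        if not recordings:
            raise ValueError("no recordings")
        self.recordings = list(recordings)
        self.n_steps = n_steps
        self.x = x
        self.sustain_ms = sustain_ms
        self.window_ms = window_ms
        self.classifier = classifier
        self.feature_kind = feature_kind
        self.hyperparams = hyperparams or {}
        self.train_fraction = train_fraction
        self.tasks = tuple(tasks)

    @classmethod
    def from_directory(cls, directory, **kwargs) -> "SequenceClassifier":
        return cls(io_formats.load_dataset(directory), **kwargs)

    def fit(self, seed: int = 0) -> "SequenceClassifierResults":
        rest = onset.estimate_rest_model(self.recordings, x=self.x)
        annotations = [onset.detect_soa(r, rest, self.sustain_ms)
                       for r in self.recordings]

        # Gesture-task acquisitions with a detected SoA feed the classifier;
        # acquisitions without one are treated as Rest upstream.
        usable, usable_anns = [], []
        dropped_no_soa = 0
        for rec, ann in zip(self.recordings, annotations):
            if rec.label not in self.tasks:
                continue
            if ann.soa_ms is None:
                dropped_no_soa += 1
                continue
            usable.append(rec)
            usable_anns.append(ann)
        if not usable:
            raise ValueError("no gesture acquisition with a detected SoA")

        labels = [r.label for r in usable]
        tr_idx, te_idx = classify.stratified_split_indices(
            labels, self.train_fraction, seed)
        train_recs = [usable[i] for i in tr_idx]
        train_anns = [usable_anns[i] for i in tr_idx]

        vectors, modal = thresholds.fit_threshold_matrix(
            train_recs, train_anns, rest.th_low, self.n_steps, self.tasks,
            self.window_ms)

        train_table = self._encode_table(train_recs, train_anns, vectors)
        test_table = self._encode_table([usable[i] for i in te_idx],
                                        [usable_anns[i] for i in te_idx],
                                        vectors)

        spec = classify.ModelSpec(self.classifier, self.hyperparams, seed)
        model = classify.train(train_table, spec)
        return SequenceClassifierResults(
            model=self, seed=seed, rest_model=rest, annotations=annotations,
            threshold_vectors=vectors, modal_sequences=modal,
            train_table=train_table, test_table=test_table,
            classifier_model=model, dropped_no_soa=dropped_no_soa,
            usable=usable, usable_annotations=usable_anns,
            train_index=tr_idx, test_index=te_idx)

    def _encode_table(self, recs, anns, vectors) -> FeatureTable:
        rows, ids, labels = [], [], []
        for rec, ann in zip(recs, anns):
            if self.feature_kind == "sequence12":
                row = sequences.encode_features(rec, ann.soa_ms, vectors,
                                                self.window_ms, self.tasks)
            elif self.feature_kind == "ets":
                row = baselines.ets_features(rec, ann.soa_ms, self.window_ms)
            elif self.feature_kind == "ess":
                row, _ = baselines.ess_features(rec)
            else:
                raise ValueError(f"unknown feature kind {self.feature_kind!r}")
            rows.append(row)
            ids.append(rec.recording_id or rec.label)
            labels.append(rec.label)
        X = np.asarray(rows, dtype=float)
        return FeatureTable(ids=ids, labels=labels, X=X, kind=self.feature_kind)


@dataclass
class SequenceClassifierResults:
    """Fitted thresholds, classifier and held-out diagnostics."""

    model: SequenceClassifier
    seed: int
    rest_model: onset.RestModel
    annotations: list
    threshold_vectors: dict
    modal_sequences: dict
    train_table: FeatureTable
    test_table: FeatureTable
    classifier_model: classify.TrainedModel
    dropped_no_soa: int
    usable: list = field(repr=False, default_factory=list)
    usable_annotations: list = field(repr=False, default_factory=list)
    train_index: np.ndarray | None = None
    test_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        pred_tr = self.classifier_model.predict(self.train_table.X)
        pred_te = self.classifier_model.predict(self.test_table.X)
        self.train_accuracy, _, _ = evaluate.accuracy_and_confusion(
            self.train_table.labels, pred_tr, self.classifier_model.classes)
        (self.test_accuracy, self.per_class_accuracy,
         self.confusion) = evaluate.accuracy_and_confusion(
            self.test_table.labels, pred_te, self.classifier_model.classes)

    # -- estimates -----------------------------------------------------

    def threshold_frame(self) -> pd.DataFrame:
        """The 4x6 representative TH_High matrix ('NA' for Not Active)."""
        data = {}
        for task in self.model.tasks:
            vals = self.threshold_vectors[task].values
            data[task] = ["NA" if thresholds.is_na(v) else round(v, 4)
                          for v in vals]
        return pd.DataFrame.from_dict(
            data, orient="index",
            columns=[f"emg{i}" for i in range(1, 7)])

    def timing_summary(self) -> sequences.TimingSummary:
        """Activation timing/entity over all usable acquisitions."""
        seqs = [sequences.encode_sequence(rec, ann.soa_ms,
                                          self.threshold_vectors[rec.label],
                                          self.model.window_ms)
                for rec, ann in zip(self.usable, self.usable_annotations)]
        counts = [sum(ann.active_flags) for ann in self.usable_annotations]
        return sequences.activation_timing_summary(seqs, active_counts=counts)

    def timing_comparisons(self) -> pd.DataFrame:
        """Per-acquisition sequence vs steady-state class-selection timing."""
        rows = []
        for rec, ann in zip(self.usable, self.usable_annotations):
            seq = sequences.encode_sequence(rec, ann.soa_ms,
                                            self.threshold_vectors[rec.label],
                                            self.model.window_ms)
            if not seq.latencies_ms:
                continue
            _, anchor = baselines.ess_features(rec)
            tc = baselines.timing_comparison(ann.soa_ms,
                                             list(seq.latencies_ms.values()),
                                             anchor)
            rows.append({"recording_id": rec.recording_id, "label": rec.label,
                         "t_seq_ms": tc.t_seq_ms, "t_ess_ms": tc.t_ess_ms,
                         "gap_ms": tc.gap_ms})
        return pd.DataFrame(rows)

    # -- application ---------------------------------------------------

    def predict(self, recordings: Sequence[EnvelopeRecording]) -> list[str]:
        """Classify new acquisitions with the fitted thresholds and model."""
        out = []
        for rec in recordings:
            ann = onset.detect_soa(rec, self.rest_model, self.model.sustain_ms)
            if ann.soa_ms is None:
                out.append("Rest")
                continue
            if self.model.feature_kind == "sequence12":
                row = sequences.encode_features(rec, ann.soa_ms,
                                                self.threshold_vectors,
                                                self.model.window_ms,
                                                self.model.tasks)
            elif self.model.feature_kind == "ets":
                row = baselines.ets_features(rec, ann.soa_ms, self.model.window_ms)
            else:
                row, _ = baselines.ess_features(rec)
            out.append(str(self.classifier_model.predict(row)[0]))
        return out

    def simulate_online(self, trial_stream, **kwargs) -> evaluate.OnlineResult:
        return evaluate.online_simulate(self.classifier_model,
                                        self.threshold_vectors,
                                        self.rest_model, trial_stream,
                                        sustain_ms=self.model.sustain_ms,
                                        window_ms=self.model.window_ms,
                                        tasks=self.model.tasks, **kwargs)

    def refit(self, classifier: str, hyperparams: dict | None = None,
              seed: int | None = None) -> "SequenceClassifierResults":
        """Retrain a different classifier on the already-encoded features."""
        spec = classify.ModelSpec(classifier, hyperparams or {},
                                  self.seed if seed is None else seed)
        model = classify.train(self.train_table, spec)
        return SequenceClassifierResults(
            model=self.model, seed=spec.seed, rest_model=self.rest_model,
            annotations=self.annotations,
            threshold_vectors=self.threshold_vectors,
            modal_sequences=self.modal_sequences,
            train_table=self.train_table, test_table=self.test_table,
            classifier_model=model, dropped_no_soa=self.dropped_no_soa,
            usable=self.usable, usable_annotations=self.usable_annotations,
            train_index=self.train_index, test_index=self.test_index)

    # -- reporting -----------------------------------------------------

    def summary(self) -> str:
        m = self.model
        lines = [
            "Muscular activation sequence classifier",
            "=" * 55,
            f"recordings: {len(m.recordings)}   usable gesture acquisitions: "
            f"{len(self.usable)}   dropped (no SoA): {self.dropped_no_soa}",
            f"rest: mu = {self.rest_model.mu:.4f} V, sigma = "
            f"{self.rest_model.sigma:.5f} V, x = {self.rest_model.x:g} "
            f"-> TH_Low = {self.rest_model.th_low:.4f} V",
            f"features: {m.feature_kind}   #step = {m.n_steps}   "
            f"classifier: {m.classifier.upper()}   seed = {self.seed}",
            f"split: {len(self.train_table)} train / {len(self.test_table)} test "
            f"(fraction {m.train_fraction:g}, stratified by task)",
            "",
            "Representative TH_High matrix (V):",
            self.threshold_frame().to_string(),
            "",
            "Modal sequences (train):",
        ]
        for task in m.tasks:
            seq, count = self.modal_sequences[task]
            lines.append(f"  {task:>10s}: {seq}  (count {count})")
        lines += [
            "",
            f"train accuracy: {self.train_accuracy:.1f}%   "
            f"held-out accuracy: {self.test_accuracy:.1f}%",
            "per-class held-out accuracy: " + ", ".join(
                f"{c}: {a:.0f}%" for c, a in self.per_class_accuracy.items()),
        ]
        return "\n".join(lines)

    def plot_confusion(self, ax=None):
        """Heatmap of the held-out confusion matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        conf = self.confusion
        ax.imshow(conf.to_numpy(), cmap="Blues")
        ax.set_xticks(range(len(conf.columns)), conf.columns, rotation=45)
        ax.set_yticks(range(len(conf.index)), conf.index)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(len(conf.index)):
            for j in range(len(conf.columns)):
                ax.text(j, i, str(conf.iat[i, j]), ha="center", va="center")
        return ax
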