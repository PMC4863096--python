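"""Sorting-quality metrics and the all-combinations comparison grid.

With ground truth (simulated signals):

* **CV** (cluster validity): minimum squared between-class centre distance
  divided by the mean squared within-class distance, computed from the
  *true* labels — measures how separable a feature space renders the
  units, independently of any clusterer.
* **CA** (classification accuracy, %): detected events carry a true label
  (their source unit, or NOISE for false-positive detections); predicted
  clusters are matched one-to-one to true units by an
  accuracy-maximising bipartite assignment.  A true spike is correct when
  its matched cluster agrees; a noise event is correct only when left
  unclassified, so CA reaches 100 only for a perfect sorting.

Without ground truth (real recordings):

* **ICV** (intracluster variance): per cluster, the mean squared deviation
  of member waveforms from the cluster mean, averaged across clusters.
* the unclassified-spike percentage and the good-cluster count ratio, two
  quantitative proxies for an expert's visual inspection.

:func:`run_grid` evaluates every feature-extraction × clustering
combination plus O-sort on one signal: models are trained on the first
~1/3 of detected spikes and the remaining spikes are classified on the
fly, mirroring on-line use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import cluster as cl
from . import detect as det
from .core import (
    InputError,
    NOISE_LABEL,
    Trace,
    TrainingError,
    UNCLASSIFIED,
)
from .features import FE_METHODS, FeatureExtractor
from .simulate import GroundTruth

__all__ = [
    "cluster_validity",
    "classification_accuracy",
    "intracluster_variance",
    "unclassified_fraction",
    "cluster_count_ratio",
    "good_cluster_count",
    "match_events_to_truth",
    "run_grid",
    "ALL_COMBOS",
]


def cluster_validity(features: np.ndarray, truth_labels: np.ndarray) -> float:
    """Between-over-within squared-distance ratio under the true labels."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(truth_labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise InputError("cluster validity needs at least 2 true classes")
    centers = []
    within = 0.0
    for c in classes:
        members = X[y == c]
        if members.shape[0] == 0:
            raise InputError(f"true class {c} has no members")
        mu = members.mean(axis=0)
        centers.append(mu)
        within += float(((members - mu) ** 2).sum())
    within /= X.shape[0]
    between = min(
        float(((centers[i] - centers[j]) ** 2).sum())
        for i in range(len(classes))
        for j in range(i + 1, len(classes))
    )
    if within == 0:
        return np.inf
    return between / within


def classification_accuracy(pred_labels: np.ndarray,
                            truth_labels: np.ndarray) -> float:
    """CA (%) with optimal one-to-one cluster-to-unit matching.

    ``truth_labels`` uses NOISE_LABEL for false-positive detections;
    ``pred_labels`` uses UNCLASSIFIED for abstentions.  Correct events are
    matched-label agreements plus noise events left unclassified.
    """
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if pred.shape != truth.shape:
        raise InputError("prediction/truth length mismatch")
    if pred.size == 0:
        raise InputError("empty event list")
    pred_ids = np.unique(pred[pred != UNCLASSIFIED])
    true_ids = np.unique(truth[truth != NOISE_LABEL])
    correct = int(np.sum((truth == NOISE_LABEL) & (pred == UNCLASSIFIED)))
    if len(pred_ids) and len(true_ids):
        agree = np.zeros((len(pred_ids), len(true_ids)), dtype=np.int64)
        for i, p in enumerate(pred_ids):
            for j, t in enumerate(true_ids):
                agree[i, j] = np.sum((pred == p) & (truth == t))
        rows, cols = linear_sum_assignment(-agree)
        correct += int(agree[rows, cols].sum())
    return 100.0 * correct / pred.size


def intracluster_variance(waveforms: np.ndarray,
                          pred_labels: np.ndarray) -> float:
    """Mean over clusters of the mean squared deviation from the template."""
    W = np.asarray(waveforms, dtype=np.float64)
    y = np.asarray(pred_labels)
    clusters = [c for c in np.unique(y) if c != UNCLASSIFIED]
    if not clusters:
        raise InputError("no classified spikes")
    vals = []
    for c in clusters:
        members = W[y == c]
        mu = members.mean(axis=0)
        vals.append(float(((members - mu) ** 2).sum(axis=1).mean()))
    return float(np.mean(vals))


def unclassified_fraction(pred_labels: np.ndarray) -> float:
    """Percentage of events the sorter abstained on."""
    pred = np.asarray(pred_labels)
    if pred.size == 0:
        return 0.0
    return 100.0 * float(np.mean(pred == UNCLASSIFIED))


def cluster_count_ratio(n_found_good: int, n_true: int) -> float:
    """Good-cluster count over true unit count, clipped to [0, 1]."""
    if n_true <= 0:
        raise InputError("n_true must be positive")
    return float(np.clip(n_found_good / n_true, 0.0, 1.0))


def good_cluster_count(pred_labels: np.ndarray, truth_labels: np.ndarray,
                       purity: float = 0.8) -> int:
    """Clusters whose members are ≥ 80% one true unit (inspection proxy)."""
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    n_good = 0
    for c in np.unique(pred[pred != UNCLASSIFIED]):
        member_truth = truth[pred == c]
        units, counts = np.unique(
            member_truth[member_truth != NOISE_LABEL], return_counts=True
        )
        if len(counts) and counts.max() >= purity * len(member_truth):
            n_good += 1
    return n_good


def match_events_to_truth(event_peaks: np.ndarray, truth: GroundTruth,
                          fs_hz: float,
                          tol_s: float = 0.001) -> np.ndarray:
    """True label per detected event (NOISE_LABEL for false positives).

    Each detected peak claims the nearest unclaimed true spike within the
    tolerance; closer pairs are resolved first.
    """
    peaks = np.asarray(event_peaks, dtype=np.int64)
    tol = int(round(tol_s * fs_hz))
    labels = np.full(len(peaks), NOISE_LABEL, dtype=np.int64)
    if truth.n_spikes == 0 or len(peaks) == 0:
        return labels
    pairs = []
    for i, p in enumerate(peaks):
        j = int(np.searchsorted(truth.spike_times, p))
        for jj in (j - 1, j, j + 1):
            if 0 <= jj < truth.n_spikes:
                d = abs(int(truth.spike_times[jj]) - int(p))
                if d <= tol:
                    pairs.append((d, i, jj))
    used_true = np.zeros(truth.n_spikes, dtype=bool)
    used_event = np.zeros(len(peaks), dtype=bool)
    for d, i, jj in sorted(pairs):
        if used_true[jj] or used_event[i]:
            continue
        used_true[jj] = True
        used_event[i] = True
        labels[i] = truth.unit_labels[jj]
    return labels


#: All implemented (feature method, clusterer) combinations, plus O-sort.
ALL_COMBOS: tuple[tuple[str | None, str], ...] = tuple(
    [(fe, clu) for fe in FE_METHODS for clu in ("kmeans", "fcm", "dbc")]
    + [(None, "osort")]
)


@dataclass
class GridOptions:
    """Tunables of the combination grid (defaults match routine use)."""

    train_fraction: float = 1.0 / 3.0
    fcm_m: float = 3.0
    dbc_levels: int = 32
    osort_correction: float = 2.0
    detect_k: float = 4.0


def _classify_stream(clusterer: str, model, feats: np.ndarray) -> np.ndarray:
    fn = {"kmeans": cl.kmeans_classify, "fcm": cl.fcm_classify,
          "dbc": cl.dbc_classify}[clusterer]
    return np.array([fn(model, f) for f in feats], dtype=np.int64)


def run_grid(trace: Trace, truth: GroundTruth | None = None,
             combos: tuple[tuple[str | None, str], ...] = ALL_COMBOS,
             options: GridOptions | None = None,
             seed: int = 0) -> pd.DataFrame:
    """Evaluate every combination on one signal; one report row per combo.

    The signal is filtered and scanned for spikes once; each trained
    combination fits on the first ``train_fraction`` of the detected
    spikes and classifies the rest on the fly.  With ground truth the
    report carries CV and CA; without it, ICV and the inspection proxies.
    """
    opt = options or GridOptions()
    filt = det.bandpass(trace)
    waves = det.detect_and_extract(filt, k=opt.detect_k)
    if len(waves) < 10:
        raise InputError("too few detected spikes to evaluate")
    W = np.array([w.samples for w in waves])
    peaks = np.array([w.t_peak for w in waves])
    n_train = int(round(len(waves) * opt.train_fraction))
    n_train = max(2, min(n_train, len(waves) - 2))
    W_train, W_eval = W[:n_train], W[n_train:]

    truth_eval = None
    if truth is not None:
        event_truth = match_events_to_truth(peaks, truth, trace.fs_hz)
        truth_eval = event_truth[n_train:]
        n_true_units = len(np.unique(truth.unit_labels))

    rows = []
    for fe_method, clusterer in combos:
        row: dict = {"fe_method": fe_method or "", "clusterer": clusterer,
                     "n_spikes": len(W_eval), "seed": seed, "failed": False}
        try:
            if clusterer == "osort":
                pred = _run_osort(filt, waves, n_train, opt)
            else:
                fe = FeatureExtractor(fe_method).train(W_train)
                F_train = fe.transform_many(W_train)
                F_eval = fe.transform_many(W_eval)
                if clusterer == "kmeans":
                    model = cl.kmeans_fit(F_train, seed=seed)
                elif clusterer == "fcm":
                    model = cl.fcm_fit(F_train, m=opt.fcm_m, seed=seed)
                else:
                    model = cl.dbc_train(F_train, n_levels=opt.dbc_levels)
                pred = _classify_stream(clusterer, model, F_eval)
                if truth is not None:
                    row["CV"] = cluster_validity(
                        F_eval[truth_eval != NOISE_LABEL],
                        truth_eval[truth_eval != NOISE_LABEL],
                    )
            if truth is not None:
                row["CA_percent"] = classification_accuracy(pred, truth_eval)
                n_good = good_cluster_count(pred, truth_eval)
                row["cluster_count_ratio"] = cluster_count_ratio(
                    n_good, n_true_units
                )
            classified_any = np.any(pred != UNCLASSIFIED)
            row["ICV"] = (
                intracluster_variance(W_eval, pred) if classified_any
                else np.nan
            )
            row["unclassified_percent"] = unclassified_fraction(pred)
        except (TrainingError, InputError) as exc:
            row["failed"] = True
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _run_osort(filt: Trace, waves, n_train: int,
               opt: GridOptions) -> np.ndarray:
    """O-sort over all spikes in order; report labels of the eval part."""
    n = len(waves[0].samples)
    tracker = cl.VarianceTracker(filt.fs_hz)
    tracker.update(filt.samples)
    model = cl.OSortModel(n_samples=n, correction=opt.osort_correction)
    raw = [
        model.process(w.samples, sigma2=tracker.sigma2_at(w.t_cross))
        for w in waves
    ]
    resolved = model.resolve_labels(raw)
    pruned = cl.osort_prune(resolved, duration_s=filt.duration_s)
    return pruned[n_train:]
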