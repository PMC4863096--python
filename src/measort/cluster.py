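"""Spike classifiers: K-means+PBM, fuzzy-C-means, density-based LUT, O-sort.

Four ways to turn per-spike features (or raw waveforms, for O-sort) into
unit labels:

* **K-means** with the cluster count chosen by maximising the PBM index
  ``PBM(K) = ((1/K) · (E_1/E_K) · S_K)²`` where ``E_1`` is the summed
  distance of all points to the global centre, ``E_K`` the summed distance
  of points to their own centroid, and ``S_K`` the maximum centroid
  separation.  Never abstains.
* **Fuzzy-C-means** with the cluster count chosen by minimising the
  validity ``S = Σ_i Σ_j μ_ij^m ||c_i − x_j||² / (N · min_{i≠k} ||c_i −
  c_k||²)``; defuzzification assigns the maximum-membership label only when
  it reaches ``1/C + 0.1``, otherwise the spike stays unclassified.
* **Density-based clustering (DBC)** quantises the 3-D feature space into
  ``N³`` cells, accumulates a kernel-smoothed density of the training
  spikes, labels density basins from their local maxima, optionally merges
  weak nearby peaks, and classifies on-line by an O(1) look-up table.
* **O-sort** template matching on raw waveforms: an incoming spike joins
  the nearest running mean waveform when the squared Euclidean distance is
  below ``T_M = c·n·⟨σ⟩²`` (``⟨σ⟩²`` = signal variance over a sliding
  ~1-minute window), otherwise it founds a new cluster; template pairs
  closer than ``T_S = T_M`` are merged.  No training phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .core import InputError, TrainingError, UNCLASSIFIED

__all__ = [
    "pbm_index",
    "KMeansModel",
    "kmeans_fit",
    "kmeans_classify",
    "FCMModel",
    "fcm_memberships",
    "fcm_fit",
    "fcm_classify",
    "DensityModel",
    "dbc_train",
    "dbc_merge",
    "dbc_classify",
    "OSortModel",
    "VarianceTracker",
    "osort_process",
    "osort_prune",
]


# ----------------------------------------------------------------------
# K-means with PBM model selection
# ----------------------------------------------------------------------

def pbm_index(features: np.ndarray, labels: np.ndarray,
              centroids: np.ndarray) -> float:
    """PBM cluster-structure index (higher is better)."""
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    C = np.asarray(centroids, dtype=np.float64)
    K = C.shape[0]
    if K < 2:
        raise InputError("PBM requires at least 2 clusters")
    center = X.mean(axis=0)
    e1 = float(np.sum(np.linalg.norm(X - center, axis=1)))
    ek = float(
        np.sum(np.linalg.norm(X - C[labels], axis=1))
    )
    sk = float(
        max(
            np.linalg.norm(C[i] - C[j])
            for i in range(K)
            for j in range(i + 1, K)
        )
    )
    if ek == 0:
        return np.inf
    return ((1.0 / K) * (e1 / ek) * sk) ** 2


@dataclass
class KMeansModel:
    """Trained K-means state with the PBM curve used to pick K."""

    centroids: np.ndarray
    k: int
    pbm_curve: dict[int, float] = field(default_factory=dict)


def kmeans_fit(features: np.ndarray, k_range: Sequence[int] = range(2, 7),
               restarts: int = 10, seed: int = 0) -> KMeansModel:
    """Best-of-restarts Lloyd fits per K; the final K maximises PBM."""
    X = np.asarray(features, dtype=np.float64)
    k_range = list(k_range)
    if X.shape[0] < max(k_range) + 1:
        raise TrainingError(
            f"K-means needs at least {max(k_range) + 1} points"
        )
    if np.allclose(X, X[0]):
        raise TrainingError("degenerate data: all feature points identical")
    best: KMeansModel | None = None
    curve: dict[int, float] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < k:
            continue  # collapsed fit cannot enter the PBM comparison
        curve[k] = pbm_index(X, lab, km.cluster_centers_)
        if best is None or curve[k] > curve[best.k]:
            best = KMeansModel(centroids=km.cluster_centers_.copy(), k=k)
    if best is None:
        raise TrainingError("no K produced a valid clustering")
    best.pbm_curve = curve
    return best


def kmeans_classify(model: KMeansModel, feature: np.ndarray) -> int:
    """Nearest-centroid label (ties to the lowest label); never abstains."""
    d = np.linalg.norm(model.centroids - np.asarray(feature), axis=1)
    return int(np.argmin(d))


# ----------------------------------------------------------------------
# Fuzzy-C-means with validity-S model selection
# ----------------------------------------------------------------------

def fcm_memberships(centers: np.ndarray, X: np.ndarray,
                    m: float) -> np.ndarray:
    """Membership matrix μ (C × N) from centre distances; columns sum to 1.

    A point coincident with a centre gets membership 1 for that centre.
    """
    C = centers.shape[0]
    d2 = np.maximum(
        ((X[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2), 0.0
    )
    u = np.zeros((C, X.shape[0]))
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=0)
    if any_zero.any():
        cols = np.flatnonzero(any_zero)
        for j in cols:
            hits = np.flatnonzero(zero[:, j])
            u[hits[0], j] = 1.0  # lowest-index centre on exact ties
    rest = ~any_zero
    if rest.any():
        p = 1.0 / (m - 1.0)
        inv = d2[:, rest] ** -p
        u[:, rest] = inv / inv.sum(axis=0, keepdims=True)
    return u


def _fcm_single(X: np.ndarray, c: int, m: float, rng: np.random.Generator,
                tol: float = 1e-6, max_iter: int = 300) -> np.ndarray:
    """One FCM run: alternate membership/centre updates until convergence."""
    idx = rng.choice(X.shape[0], size=c, replace=False)
    centers = X[idx].astype(np.float64).copy()
    centers += 1e-9 * rng.standard_normal(centers.shape)  # break exact ties
    for _ in range(max_iter):
        u = fcm_memberships(centers, X, m)
        um = u ** m
        new = (um @ X) / np.maximum(um.sum(axis=1, keepdims=True), 1e-300)
        shift = np.max(np.linalg.norm(new - centers, axis=1))
        centers = new
        if shift < tol:
            break
    return centers


def fcm_validity(centers: np.ndarray, X: np.ndarray, m: float) -> float:
    """Compactness/separation validity S (lower is better)."""
    u = fcm_memberships(centers, X, m)
    d2 = ((X[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
    num = float(np.sum((u ** m) * d2))
    C = centers.shape[0]
    sep = min(
        float(((centers[i] - centers[k]) ** 2).sum())
        for i in range(C)
        for k in range(i + 1, C)
    )
    if sep == 0:
        return np.inf
    return num / (X.shape[0] * sep)


@dataclass
class FCMModel:
    """Trained fuzzy-C-means state."""

    centers: np.ndarray
    m: float
    c: int
    s_curve: dict[int, float] = field(default_factory=dict)

    @property
    def membership_threshold(self) -> float:
        """Defuzzification cutoff ``1/C + 0.1``."""
        return 1.0 / self.c + 0.1


def fcm_fit(features: np.ndarray, m: float = 3.0,
            c_range: Sequence[int] = range(2, 7), seed: int = 0,
            restarts: int = 5) -> FCMModel:
    """Fit FCM for each candidate C and keep the C minimising validity S."""
    if m <= 1:
        raise InputError("fuzziness m must exceed 1")
    X = np.asarray(features, dtype=np.float64)
    c_range = list(c_range)
    if X.shape[0] < max(c_range) + 1:
        raise TrainingError(
            f"FCM needs at least {max(c_range) + 1} points"
        )
    rng = np.random.default_rng(seed)
    best: FCMModel | None = None
    curve: dict[int, float] = {}
    for c in c_range:
        best_s, best_centers = np.inf, None
        for _ in range(restarts):
            centers = _fcm_single(X, c, m, rng)
            s = fcm_validity(centers, X, m)
            if s < best_s:
                best_s, best_centers = s, centers
        curve[c] = best_s
        if best is None or best_s < curve[best.c]:
            best = FCMModel(centers=best_centers, m=m, c=c)
    best.s_curve = curve
    return best


def fcm_classify(model: FCMModel, feature: np.ndarray) -> int:
    """Maximum-membership label, or UNCLASSIFIED below ``1/C + 0.1``."""
    u = fcm_memberships(model.centers,
                        np.asarray(feature, dtype=np.float64)[None, :],
                        model.m)[:, 0]
    best = int(np.argmax(u))
    if u[best] < model.membership_threshold:
        return UNCLASSIFIED
    return best


# ----------------------------------------------------------------------
# Density-based clustering with a label look-up table
# ----------------------------------------------------------------------

def _default_kernel() -> np.ndarray:
    """3×3×3 accumulation stencil: centre weight 2, neighbours 1."""
    k = np.ones((3, 3, 3))
    k[1, 1, 1] = 2.0
    return k


@dataclass
class DensityModel:
    """Trained density map and label LUT over the quantised feature space."""

    lo: np.ndarray  # per-dimension lower bound (with margin)
    hi: np.ndarray  # per-dimension upper bound (with margin)
    n_levels: int
    density: np.ndarray  # (N, N, N)
    label_lut: np.ndarray  # (N, N, N) int; UNCLASSIFIED = unlabeled
    peaks: dict[int, tuple[tuple[int, int, int], float]] = field(
        default_factory=dict
    )  # label -> (peak cell, peak density)
    d_merge: float = 3.0
    f_merge: float = 0.9

    @property
    def n_clusters(self) -> int:
        return len(self.peaks)

    def quantize(self, feature: np.ndarray) -> tuple[int, int, int] | None:
        f = np.asarray(feature, dtype=np.float64)
        if np.any(f < self.lo) or np.any(f > self.hi):
            return None
        cell = ((f - self.lo) / (self.hi - self.lo) * self.n_levels).astype(int)
        return tuple(np.minimum(cell, self.n_levels - 1))


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def dbc_train(features: np.ndarray, n_levels: int = 32,
              kernel: np.ndarray | None = None, margin: float = 0.05,
              d_merge: float = 3.0, f_merge: float = 0.9,
              peak_floor: float = 0.1,
              merge: bool = True) -> DensityModel:
    """Build the density map and label its basins.

    Grid bounds are the training min/max per dimension widened by
    ``margin``; the density is the cell histogram convolved with the
    kernel; every positive-density cell is assigned to the basin of the
    local density maximum reached by steepest ascent.  Basins whose peak
    density falls below ``peak_floor`` of the highest peak are left
    unlabeled — they are stray cells of the distribution tails, not
    units.  With ``merge=True`` the weak-nearby-peak merging step runs
    to fixpoint.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != 3:
        raise InputError("DBC expects N×3 features")
    if X.shape[0] < 2:
        raise TrainingError("DBC needs at least 2 spikes")
    span = X.max(axis=0) - X.min(axis=0)
    if np.any(span == 0):
        raise TrainingError("degenerate features: a dimension is constant")
    lo = X.min(axis=0) - margin * span
    hi = X.max(axis=0) + margin * span
    if kernel is None:
        kernel = _default_kernel()

    cells = ((X - lo) / (hi - lo) * n_levels).astype(int)
    cells = np.minimum(cells, n_levels - 1)
    hist = np.zeros((n_levels,) * 3)
    np.add.at(hist, (cells[:, 0], cells[:, 1], cells[:, 2]), 1.0)
    density = ndimage.convolve(hist, kernel, mode="constant", cval=0.0)

    # Basin labelling by descending-density flooding: the highest cell of a
    # basin founds it, every other cell joins its densest labelled
    # neighbour.  Ties are broken by flat cell index, making the result
    # deterministic on plateaus.
    lut = np.full(density.shape, UNCLASSIFIED, dtype=np.int64)
    occupied = np.argwhere(density > 0)
    dens_vals = density[occupied[:, 0], occupied[:, 1], occupied[:, 2]]
    flat = occupied[:, 0] * n_levels * n_levels + occupied[:, 1] * n_levels \
        + occupied[:, 2]
    order = np.lexsort((flat, -dens_vals))
    peaks: dict[int, tuple[tuple[int, int, int], float]] = {}
    next_label = 0
    for oi in order:
        x, y, z = occupied[oi]
        best_lab, best_key = None, None
        for dx, dy, dz in _NEIGHBOR_OFFSETS:
            nx, ny, nz = x + dx, y + dy, z + dz
            if not (0 <= nx < n_levels and 0 <= ny < n_levels
                    and 0 <= nz < n_levels):
                continue
            lab = lut[nx, ny, nz]
            if lab == UNCLASSIFIED:
                continue
            key = (density[nx, ny, nz],
                   -(nx * n_levels * n_levels + ny * n_levels + nz))
            if best_key is None or key > best_key:
                best_key, best_lab = key, lab
        if best_lab is None:
            lut[x, y, z] = next_label
            peaks[next_label] = ((int(x), int(y), int(z)),
                                 float(density[x, y, z]))
            next_label += 1
        else:
            lut[x, y, z] = best_lab

    if peaks and peak_floor > 0:
        top = max(p for _, p in peaks.values())
        weak = [lab for lab, (_, p) in peaks.items() if p < peak_floor * top]
        for lab in weak:
            lut[lut == lab] = UNCLASSIFIED
            del peaks[lab]
        remap = {old: new for new, old in enumerate(sorted(peaks))}
        new_lut = np.full_like(lut, UNCLASSIFIED)
        for old, new in remap.items():
            new_lut[lut == old] = new
        lut = new_lut
        peaks = {remap[old]: val for old, val in peaks.items()}

    model = DensityModel(lo=lo, hi=hi, n_levels=n_levels, density=density,
                         label_lut=lut, peaks=peaks, d_merge=d_merge,
                         f_merge=f_merge)
    if merge:
        model = dbc_merge(model)
    return model


def dbc_merge(model: DensityModel) -> DensityModel:
    """Merge weak nearby peaks to fixpoint.

    Two clusters merge when their peak cells are within ``d_merge`` cells
    of each other and the smaller peak density is at most ``f_merge`` times
    the larger one; the spikes of the weaker peak join the stronger one.
    The fixpoint is order-independent: the highest-density mergeable pair
    is always merged first.
    """
    peaks = dict(model.peaks)
    lut = model.label_lut.copy()
    while True:
        labels = sorted(peaks)
        candidate = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                (ca, pa), (cb, pb) = peaks[a], peaks[b]
                dist = float(np.linalg.norm(np.array(ca) - np.array(cb)))
                if dist > model.d_merge:
                    continue
                small, big = (a, b) if pa <= pb else (b, a)
                if peaks[small][1] <= model.f_merge * peaks[big][1]:
                    key = (peaks[big][1], -big, -small)
                    if candidate is None or key > candidate[0]:
                        candidate = (key, small, big)
        if candidate is None:
            break
        _, small, big = candidate
        lut[lut == small] = big
        del peaks[small]
    # compact labels to 0..k-1 preserving order
    remap = {old: new for new, old in enumerate(sorted(peaks))}
    new_lut = np.full_like(lut, UNCLASSIFIED)
    for old, new in remap.items():
        new_lut[lut == old] = new
    new_peaks = {remap[old]: val for old, val in peaks.items()}
    return DensityModel(lo=model.lo, hi=model.hi, n_levels=model.n_levels,
                        density=model.density, label_lut=new_lut,
                        peaks=new_peaks, d_merge=model.d_merge,
                        f_merge=model.f_merge)


def dbc_classify(model: DensityModel, feature: np.ndarray) -> int:
    """O(1) LUT lookup; outside the mapped volume → UNCLASSIFIED."""
    cell = model.quantize(feature)
    if cell is None:
        return UNCLASSIFIED
    return int(model.label_lut[cell])


# ----------------------------------------------------------------------
# O-sort template matching
# ----------------------------------------------------------------------

class VarianceTracker:
    """Signal variance ⟨σ⟩² over a sliding window of 1-second chunks.

    Samples are appended in arbitrary chunk sizes and consolidated into
    exact 1-second windows, so the variance seen by a spike depends only on
    the spike's position in the stream — never on how the stream was cut
    into blocks.
    """

    def __init__(self, fs_hz: float, window_s: float = 60.0):
        self.win = int(round(fs_hz))
        self.n_chunks = max(1, int(round(window_s)))
        self._stats: list[tuple[int, float, float]] = []  # (n, Σx, Σx²)
        self._partial = np.empty(0, dtype=np.float64)

    def update(self, samples: np.ndarray) -> None:
        x = np.concatenate([self._partial, np.asarray(samples, float)])
        while len(x) >= self.win:
            chunk, x = x[: self.win], x[self.win:]
            self._stats.append(
                (self.win, float(chunk.sum()), float((chunk ** 2).sum()))
            )
        self._partial = x

    def n_complete(self) -> int:
        return len(self._stats)

    def sigma2_at(self, t_sample: int) -> float:
        """Pooled variance of the ≤ 60 completed chunks up to ``t_sample``."""
        last = min(t_sample // self.win, len(self._stats) - 1)
        if last < 0:
            if len(self._partial) > 1:
                return float(np.var(self._partial))
            raise InputError("no samples available for the variance window")
        first = max(0, last - self.n_chunks + 1)
        n = s = ss = 0.0
        for cn, cs, css in self._stats[first:last + 1]:
            n += cn
            s += cs
            ss += css
        return max(ss / n - (s / n) ** 2, 0.0)


@dataclass
class _Template:
    mean: np.ndarray
    count: int


class OSortModel:
    """Incremental template-matching sorter (no training phase).

    Labels returned by :meth:`process` are provisional cluster ids; merges
    are tracked by union-find, so :meth:`resolve_labels` maps a recorded
    label sequence onto the surviving clusters at any point.
    """

    def __init__(self, n_samples: int, correction: float = 2.0):
        self.n_samples = n_samples
        self.correction = correction
        self.templates: dict[int, _Template] = {}
        self._parent: dict[int, int] = {}
        self._next = 0
        self.sigma2: float | None = None

    # -- union-find over merged cluster ids ---------------------------
    def _find(self, label: int) -> int:
        root = label
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[label] != root:
            self._parent[label], label = root, self._parent[label]
        return root

    def resolve_labels(self, labels: Sequence[int]) -> np.ndarray:
        return np.array([
            self._find(int(l)) if int(l) != UNCLASSIFIED else UNCLASSIFIED
            for l in labels
        ], dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def threshold(self) -> float:
        """``T_M = T_S = c · n · ⟨σ⟩²`` under the current variance."""
        if self.sigma2 is None:
            raise InputError("O-sort variance ⟨σ⟩² has not been set")
        return self.correction * self.n_samples * self.sigma2

    def process(self, waveform: np.ndarray,
                sigma2: float | None = None) -> int:
        """Assign a spike to the nearest template or found a new cluster."""
        w = np.asarray(waveform, dtype=np.float64)
        if sigma2 is not None:
            self.sigma2 = float(sigma2)
        t = self.threshold
        label = None
        if self.templates:
            ids = sorted(self.templates)
            dists = [float(((self.templates[i].mean - w) ** 2).sum())
                     for i in ids]
            j = int(np.argmin(dists))
            if dists[j] < t:
                label = ids[j]
        if label is None:
            label = self._next
            self._next += 1
            self.templates[label] = _Template(mean=w.copy(), count=1)
            self._parent[label] = label
        else:
            tpl = self.templates[label]
            tpl.mean = (tpl.mean * tpl.count + w) / (tpl.count + 1)
            tpl.count += 1
        self._merge_step(t)
        return label

    def _merge_step(self, t: float) -> None:
        """Merge template pairs closer than T_S (weighted-mean merge)."""
        merged = True
        while merged and len(self.templates) > 1:
            merged = False
            ids = sorted(self.templates)
            best = None
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    d = float(
                        ((self.templates[a].mean - self.templates[b].mean) ** 2
                         ).sum()
                    )
                    if d < t and (best is None or d < best[0]):
                        best = (d, a, b)
            if best is not None:
                _, a, b = best
                ta, tb = self.templates[a], self.templates[b]
                # survivor: larger count, ties to the lower id
                keep, drop = (a, b) if ta.count >= tb.count else (b, a)
                tk, td = self.templates[keep], self.templates[drop]
                tk.mean = (tk.mean * tk.count + td.mean * td.count) / (
                    tk.count + td.count
                )
                tk.count += td.count
                del self.templates[drop]
                self._parent[drop] = keep
                merged = True

    def cluster_counts(self) -> dict[int, int]:
        return {lab: tpl.count for lab, tpl in self.templates.items()}


def osort_process(model: OSortModel, waveform: np.ndarray,
                  sigma2: float | None = None) -> tuple[int, OSortModel]:
    """Process one spike; returns ``(provisional label, model)``."""
    return model.process(waveform, sigma2=sigma2), model


def osort_prune(labels: Sequence[int], duration_s: float,
                min_rate_per_min: float = 5.0) -> np.ndarray:
    """Drop sparse clusters: fewer than 5 spikes per 60 s → UNCLASSIFIED."""
    labels = np.asarray(labels, dtype=np.int64)
    threshold = min_rate_per_min * duration_s / 60.0
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == UNCLASSIFIED:
            continue
        if np.sum(labels == lab) < threshold:
            out[labels == lab] = UNCLASSIFIED
    return out
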