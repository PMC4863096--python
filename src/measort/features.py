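"""Per-spike feature extraction and reduction to a 3-D feature space.

Four extractors are provided, all mapping a fixed-length spike waveform
``s(n)`` to a feature vector:

* **PCA** — project the mean-centred waveform onto the first three
  principal components of the training covariance matrix.
* **FSDE** — first/second discrete derivative extrema: with
  ``FD(n) = s(n) − s(n−1)`` and ``SD(n) = FD(n) − FD(n−1)``, the features
  are ``(FD_max, SD_min, SD_max)``.  Training-free.
* **GEO** — seven geometric descriptors: positive amplitude, negative
  amplitude, peak-to-peak amplitude, positive area, negative area,
  positive/negative area ratio, and maximum slope.
* **DWT** — three-level Haar wavelet decomposition; the coefficient vector
  is ``(a_−3, d_−3, d_−2, d_−1)``.

GEO and DWT produce more than three coefficients, so a *maximum
difference* selection is trained: for each consecutive pair of training
spikes the three coordinates with the largest absolute difference are
tallied, and the three most-often-tallied coordinates are kept.  PCA keeps
its first three components; FSDE is already 3-D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import InputError, StateError, TrainingError

__all__ = [
    "PCBasis",
    "ReductionState",
    "FeatureExtractor",
    "pca_train",
    "pca_project",
    "fsde",
    "geo",
    "dwt_haar",
    "max_diff_select",
    "reduce_features",
    "FE_METHODS",
]

#: Guard for the GEO positive/negative area ratio on monophasic waveforms.
GEO_RATIO_EPS = 1e-12
GEO_RATIO_CAP = 1e6


@dataclass
class PCBasis:
    """Trained PCA state: orthonormal components of the spike covariance."""

    components: np.ndarray  # (n_components, n)
    mean_waveform: np.ndarray  # (n,)
    eigenvalues: np.ndarray  # (n_components,) descending

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


@dataclass
class ReductionState:
    """Trained coefficient selection for GEO/DWT (3 distinct indices)."""

    method: str
    selected_indices: tuple[int, int, int]
    n_train: int = 0

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.selected_indices)
        if len(set(idx)) != 3:
            raise InputError("selection must contain 3 distinct indices")
        self.selected_indices = idx  # type: ignore[assignment]


def pca_train(waveforms: np.ndarray, n_components: int = 3) -> PCBasis:
    """Eigendecomposition of the mean-centred spike covariance matrix.

    Sign convention: each component's largest-magnitude entry is positive,
    so retraining on the same data reproduces the identical basis.
    """
    W = np.asarray(waveforms, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] < n_components + 1:
        raise TrainingError(
            f"PCA needs at least {n_components + 1} spikes, got {W.shape[0]}"
        )
    mean = W.mean(axis=0)
    X = W - mean
    cov = X.T @ X / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    comps = evecs[:, order].T
    evals = np.clip(evals[order], 0.0, None)
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCBasis(components=comps, mean_waveform=mean, eigenvalues=evals)


def pca_project(basis: PCBasis, waveform: np.ndarray) -> np.ndarray:
    """PC coefficients ``c_i = Σ_n PC_i(n) · (s(n) − mean(n))``."""
    s = np.asarray(waveform, dtype=np.float64)
    if s.shape[-1] != basis.components.shape[1]:
        raise InputError("waveform length does not match the PC basis")
    return (s - basis.mean_waveform) @ basis.components.T


def fsde(waveform: np.ndarray) -> np.ndarray:
    """First/second derivative extrema ``(FD_max, SD_min, SD_max)``."""
    s = np.asarray(waveform, dtype=np.float64)
    if s.size < 3:
        raise InputError("FSDE needs at least 3 samples")
    fd = np.diff(s)
    sd = np.diff(fd)
    return np.array([fd.max(), sd.min(), sd.max()])


def geo(waveform: np.ndarray) -> np.ndarray:
    """Seven geometric features of a spike waveform.

    ``(pos amp, neg amp, peak-to-peak, pos area, neg area,
    pos/neg area ratio, max |slope|)``; the area ratio is capped to stay
    finite on monophasic waveforms.
    """
    s = np.asarray(waveform, dtype=np.float64)
    if s.size < 2:
        raise InputError("GEO needs at least 2 samples")
    pos_amp = float(max(s.max(), 0.0))
    neg_amp = float(abs(min(s.min(), 0.0)))
    p2p = float(s.max() - s.min())
    pos_area = float(np.sum(s[s > 0]))
    neg_area = float(np.abs(np.sum(s[s < 0])))
    ratio = min(pos_area / (neg_area + GEO_RATIO_EPS), GEO_RATIO_CAP)
    max_slope = float(np.max(np.abs(np.diff(s))))
    return np.array([pos_amp, neg_amp, p2p, pos_area, neg_area, ratio,
                     max_slope])


def dwt_haar(waveform: np.ndarray, levels: int = 3,
             wavelet: str = "haar") -> np.ndarray:
    """Multi-level orthonormal Haar decomposition of a spike waveform.

    The input is zero-padded to the next multiple of ``2**levels`` (75 → 80
    samples at 25 kHz) so every level halves exactly; the returned vector
    concatenates ``(a_−levels, d_−levels, ..., d_−1)`` and preserves the
    energy of the padded input.
    """
    s = np.asarray(waveform, dtype=np.float64)
    block = 2 ** levels
    if s.size < block:
        raise InputError(f"DWT with {levels} levels needs >= {block} samples")
    pad = (-s.size) % block
    if pad:
        s = np.concatenate([s, np.zeros(pad)])
    coeffs = pywt.wavedec(s, wavelet, mode="periodization", level=levels)
    return np.concatenate(coeffs)


def max_diff_select(feature_matrix: np.ndarray,
                    method: str = "") -> ReductionState:
    """Pick the 3 coordinates with the highest spike-to-spike variability.

    For every consecutive pair of training feature vectors, the indices of
    the three largest absolute element-wise differences are tallied; the
    final selection is the three indices with the highest tallies (ties
    broken toward the lowest index).
    """
    F = np.asarray(feature_matrix, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 2:
        raise InputError("selection needs at least 2 training spikes")
    d = F.shape[1]
    if d < 3:
        raise InputError("feature dimension must be at least 3")
    tally = np.zeros(d, dtype=np.int64)
    diffs = np.abs(np.diff(F, axis=0))
    for row in diffs:
        # top-3 |difference| indices of this pair, ties to the lowest index
        top = np.lexsort((np.arange(d), -row))[:3]
        tally[top] += 1
    selected = tuple(np.lexsort((np.arange(d), -tally))[:3])
    return ReductionState(method=method, selected_indices=selected,
                          n_train=F.shape[0])


def reduce_features(
    state: PCBasis | ReductionState | None,
    raw: np.ndarray,
    method: str,
) -> np.ndarray:
    """Map raw features (or a waveform, for PCA) to the 3-D feature space."""
    if method == "pca":
        if not isinstance(state, PCBasis):
            raise StateError("PCA reduction requires a trained PCBasis")
        return pca_project(state, raw)[:3]
    if method == "fsde":
        v = np.asarray(raw, dtype=np.float64)
        if v.shape[-1] != 3:
            raise InputError("FSDE features must already be 3-D")
        return v
    if method in ("geo", "dwt"):
        if not isinstance(state, ReductionState):
            raise StateError(f"{method} reduction requires a trained selection")
        v = np.asarray(raw, dtype=np.float64)
        return v[list(state.selected_indices)]
    raise InputError(f"unknown feature method {method!r}")


#: The implemented feature-extraction methods.
FE_METHODS = ("pca", "fsde", "geo", "dwt")


@dataclass
class FeatureExtractor:
    """A trained (or training-free) FE pipeline: waveform → 3-D features.

    ``train`` fits whatever state the method needs (PC basis or coefficient
    selection); ``transform`` maps waveforms to 3-D feature vectors and is
    identical between training-time and on-line use.
    """

    method: str
    basis: PCBasis | None = None
    reduction: ReductionState | None = None

    def __post_init__(self) -> None:
        if self.method not in FE_METHODS:
            raise InputError(f"unknown feature method {self.method!r}")

    @property
    def needs_training(self) -> bool:
        return self.method != "fsde"

    @property
    def is_trained(self) -> bool:
        if self.method == "fsde":
            return True
        if self.method == "pca":
            return self.basis is not None
        return self.reduction is not None

    def raw_features(self, waveform: np.ndarray) -> np.ndarray:
        if self.method == "pca":
            if self.basis is None:
                raise StateError("PCA extractor is untrained")
            return pca_project(self.basis, waveform)
        if self.method == "fsde":
            return fsde(waveform)
        if self.method == "geo":
            return geo(waveform)
        return dwt_haar(waveform)

    def train(self, waveforms: np.ndarray) -> "FeatureExtractor":
        W = np.asarray(waveforms, dtype=np.float64)
        if self.method == "pca":
            self.basis = pca_train(W, n_components=3)
        elif self.method in ("geo", "dwt"):
            raw = np.array([self.raw_features(w) for w in W])
            self.reduction = max_diff_select(raw, method=self.method)
        return self

    def transform(self, waveform: np.ndarray) -> np.ndarray:
        if not self.is_trained:
            raise StateError(f"{self.method} extractor is untrained")
        if self.method == "pca":
            return reduce_features(self.basis, waveform, "pca")
        raw = self.raw_features(waveform)
        if self.method == "fsde":
            return raw
        return reduce_features(self.reduction, raw, self.method)

    def transform_many(self, waveforms: np.ndarray) -> np.ndarray:
        return np.array([self.transform(w) for w in np.asarray(waveforms)])
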