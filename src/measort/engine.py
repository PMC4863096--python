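"""Off-line and block-streaming orchestration of the sorting pipeline.

On-line acquisition hardware delivers fixed-length data blocks per
channel.  :func:`stream_process` mirrors that mode: for every block and
channel it applies the causal band-pass filter (filter state carried
across blocks), feeds the samples to the incremental spike detector
(noise-level state and pending events carried too), and classifies each
completed spike with the channel's trained sorter.  Because the filter
and the detector are strictly incremental, the concatenated streaming
output is identical to running the same pipeline on the whole trace at
once — block length changes latency, never labels.

A :class:`SorterModel` bundles one feature-extraction method with one
classifier.  PCA/GEO/DWT front-ends and K-means/FCM/DBC classifiers need
a training pass over the first spikes; FSDE is training-free, and O-sort
needs no training at all.  Models serialise to a single JSON document so
a streaming run can reload exactly the state that was trained off-line.

The benchmark harness reports wall-clock per pipeline stage as a
percentage of the block length — the budget available before the next
buffer arrives — plus the static per-spike operation counts of each
method.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from . import cluster as cl
from .core import (
    ConfigError,
    InputError,
    SpikeWaveform,
    StateError,
    Trace,
    TrainingError,
)
from .detect import SpikeDetector, bandpass_sos
from .features import FeatureExtractor, PCBasis, ReductionState

__all__ = [
    "Combo",
    "SorterModel",
    "train_sorter",
    "save_model",
    "load_model",
    "StreamConfig",
    "BlockResult",
    "ArrayBlockSource",
    "stream_process",
    "worst_case_source",
    "operation_counts",
    "benchmark",
]


@dataclass(frozen=True)
class Combo:
    """One spike-sorting pipeline choice: feature method + classifier.

    ``fe_method`` is one of ``pca/fsde/geo/dwt`` (or None for O-sort,
    which consumes raw waveforms); ``clusterer`` is one of
    ``kmeans/fcm/dbc/osort``.
    """

    fe_method: str | None
    clusterer: str

    def __post_init__(self) -> None:
        if self.clusterer == "osort":
            if self.fe_method is not None:
                raise ConfigError("O-sort consumes raw waveforms, no FE")
        elif self.fe_method not in ("pca", "fsde", "geo", "dwt"):
            raise ConfigError(f"unknown feature method {self.fe_method!r}")
        if self.clusterer not in ("kmeans", "fcm", "dbc", "osort"):
            raise ConfigError(f"unknown clusterer {self.clusterer!r}")

    @property
    def needs_training(self) -> bool:
        return self.clusterer != "osort"

    def __str__(self) -> str:
        return self.clusterer if self.fe_method is None \
            else f"{self.fe_method}+{self.clusterer}"


@dataclass
class SorterModel:
    """Trained state of one combo, ready for per-spike classification."""

    combo: Combo
    extractor: FeatureExtractor | None = None
    kmeans: cl.KMeansModel | None = None
    fcm: cl.FCMModel | None = None
    dbc: cl.DensityModel | None = None
    osort: cl.OSortModel | None = None
    seed: int = 0

    def classify(self, waveform: SpikeWaveform | np.ndarray,
                 sigma2: float | None = None) -> int:
        """Label one spike (UNCLASSIFIED when the sorter abstains)."""
        w = waveform.samples if isinstance(waveform, SpikeWaveform) \
            else np.asarray(waveform)
        if self.combo.clusterer == "osort":
            if self.osort is None:
                raise StateError("O-sort state missing")
            return self.osort.process(w, sigma2=sigma2)
        if self.extractor is None:
            raise StateError("feature extractor missing")
        f = self.extractor.transform(w)
        if self.combo.clusterer == "kmeans":
            return cl.kmeans_classify(self.kmeans, f)
        if self.combo.clusterer == "fcm":
            return cl.fcm_classify(self.fcm, f)
        return cl.dbc_classify(self.dbc, f)


def train_sorter(waveforms: Sequence[np.ndarray] | np.ndarray, combo: Combo,
                 seed: int = 0, fcm_m: float = 3.0,
                 dbc_levels: int = 32,
                 osort_correction: float = 2.0,
                 n_samples: int | None = None) -> SorterModel:
    """Fit the FE front-end and the classifier of one combo.

    O-sort needs no training and returns an immediately ready model (pass
    ``n_samples`` when no waveforms are supplied).  FSDE needs no FE
    training but its clusterer still does.
    """
    if combo.clusterer == "osort":
        if n_samples is None:
            if len(waveforms) == 0:
                raise TrainingError("n_samples required for an empty O-sort "
                                    "initialisation")
            n_samples = len(np.asarray(waveforms[0]))
        return SorterModel(combo=combo,
                           osort=cl.OSortModel(n_samples,
                                               correction=osort_correction),
                           seed=seed)
    W = np.asarray(waveforms, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] < 8:
        raise TrainingError(
            f"combo {combo}: needs at least 8 training spikes, got "
            f"{0 if W.ndim != 2 else W.shape[0]} (feature-extraction stage)"
        )
    extractor = FeatureExtractor(combo.fe_method).train(W)
    F = extractor.transform_many(W)
    model = SorterModel(combo=combo, extractor=extractor, seed=seed)
    try:
        if combo.clusterer == "kmeans":
            model.kmeans = cl.kmeans_fit(F, seed=seed)
        elif combo.clusterer == "fcm":
            model.fcm = cl.fcm_fit(F, m=fcm_m, seed=seed)
        else:
            model.dbc = cl.dbc_train(F, n_levels=dbc_levels)
    except TrainingError as exc:
        raise TrainingError(f"combo {combo}: {exc} (clustering stage)") \
            from exc
    return model


# ----------------------------------------------------------------------
# Model serialisation (single JSON document; exact float round-trip)
# ----------------------------------------------------------------------

def _arr(x: np.ndarray) -> list:
    return np.asarray(x).tolist()


def save_model(model: SorterModel, path: str) -> None:
    """Serialise a trained sorter to a JSON file."""
    doc: dict = {"fe_method": model.combo.fe_method,
                 "clusterer": model.combo.clusterer, "seed": model.seed}
    ex = model.extractor
    if ex is not None:
        if ex.basis is not None:
            doc["pca"] = {"components": _arr(ex.basis.components),
                          "mean": _arr(ex.basis.mean_waveform),
                          "eigenvalues": _arr(ex.basis.eigenvalues)}
        if ex.reduction is not None:
            doc["reduction"] = {"indices": list(ex.reduction.selected_indices),
                                "n_train": ex.reduction.n_train}
    if model.kmeans is not None:
        doc["kmeans"] = {"centroids": _arr(model.kmeans.centroids),
                         "k": model.kmeans.k}
    if model.fcm is not None:
        doc["fcm"] = {"centers": _arr(model.fcm.centers), "m": model.fcm.m,
                      "c": model.fcm.c}
    if model.dbc is not None:
        d = model.dbc
        doc["dbc"] = {"lo": _arr(d.lo), "hi": _arr(d.hi),
                      "n_levels": d.n_levels,
                      "density": _arr(d.density.ravel()),
                      "label_lut": _arr(d.label_lut.ravel()),
                      "peaks": {str(k): [list(v[0]), v[1]]
                                for k, v in d.peaks.items()},
                      "d_merge": d.d_merge, "f_merge": d.f_merge}
    if model.osort is not None:
        o = model.osort
        doc["osort"] = {"n_samples": o.n_samples, "correction": o.correction,
                        "templates": {str(k): [_arr(t.mean), t.count]
                                      for k, t in o.templates.items()},
                        "parent": {str(k): v for k, v in o._parent.items()},
                        "next": o._next, "sigma2": o.sigma2}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str) -> SorterModel:
    """Reload a sorter saved by :func:`save_model`."""
    with open(path) as fh:
        doc = json.load(fh)
    combo = Combo(doc["fe_method"], doc["clusterer"])
    model = SorterModel(combo=combo, seed=doc.get("seed", 0))
    if combo.clusterer != "osort":
        ex = FeatureExtractor(combo.fe_method)
        if "pca" in doc:
            p = doc["pca"]
            ex.basis = PCBasis(components=np.asarray(p["components"]),
                               mean_waveform=np.asarray(p["mean"]),
                               eigenvalues=np.asarray(p["eigenvalues"]))
        if "reduction" in doc:
            r = doc["reduction"]
            ex.reduction = ReductionState(method=combo.fe_method,
                                          selected_indices=tuple(r["indices"]),
                                          n_train=r["n_train"])
        model.extractor = ex
    if "kmeans" in doc:
        k = doc["kmeans"]
        model.kmeans = cl.KMeansModel(centroids=np.asarray(k["centroids"]),
                                      k=k["k"])
    if "fcm" in doc:
        f = doc["fcm"]
        model.fcm = cl.FCMModel(centers=np.asarray(f["centers"]), m=f["m"],
                                c=f["c"])
    if "dbc" in doc:
        d = doc["dbc"]
        n = d["n_levels"]
        model.dbc = cl.DensityModel(
            lo=np.asarray(d["lo"]), hi=np.asarray(d["hi"]), n_levels=n,
            density=np.asarray(d["density"]).reshape(n, n, n),
            label_lut=np.asarray(d["label_lut"], dtype=np.int64
                                 ).reshape(n, n, n),
            peaks={int(k): (tuple(v[0]), v[1])
                   for k, v in d["peaks"].items()},
            d_merge=d["d_merge"], f_merge=d["f_merge"])
    if "osort" in doc:
        o = doc["osort"]
        os_model = cl.OSortModel(o["n_samples"], correction=o["correction"])
        for k, (mean, count) in o["templates"].items():
            os_model.templates[int(k)] = cl._Template(mean=np.asarray(mean),
                                                      count=count)
        os_model._parent = {int(k): v for k, v in o["parent"].items()}
        os_model._next = o["next"]
        os_model.sigma2 = o["sigma2"]
        model.osort = os_model
    return model


# ----------------------------------------------------------------------
# Block streaming
# ----------------------------------------------------------------------

@dataclass
class StreamConfig:
    """Configuration of a streaming run."""

    fs_hz: float
    block_ms: float = 500.0
    detect_k: float = 4.0
    low_hz: float = 200.0
    high_hz: float = 3000.0
    min_block_ms: float | None = None
    max_block_ms: float = 3000.0

    def __post_init__(self) -> None:
        window_ms = 3.0  # one spike cutout
        min_ms = self.min_block_ms if self.min_block_ms is not None \
            else window_ms
        if self.block_ms < min_ms or self.block_ms < window_ms:
            raise ConfigError(
                f"block length {self.block_ms} ms is below the minimum "
                f"({max(min_ms, window_ms)} ms: one spike window)"
            )
        if self.block_ms > self.max_block_ms:
            raise ConfigError("block length above the configured maximum")

    @property
    def block_samples(self) -> int:
        return int(round(self.block_ms / 1000.0 * self.fs_hz))


@dataclass
class SpikeEvent:
    """One classified spike emitted by the streaming engine."""

    channel_id: int
    t_cross: int
    t_peak: int
    label: int


@dataclass
class BlockResult:
    """Everything emitted while processing one input block."""

    block_index: int
    events: list[SpikeEvent]
    timing: dict[str, float] = field(default_factory=dict)


class ArrayBlockSource:
    """Replays in-memory multichannel data as fixed-length blocks."""

    def __init__(self, data: np.ndarray, fs_hz: float):
        data = np.atleast_2d(np.asarray(data, dtype=np.float64))
        self.data = data  # (n_channels, n_samples)
        self.fs_hz = fs_hz

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def iter_blocks(self, block_samples: int) -> Iterator[np.ndarray]:
        n = self.data.shape[1]
        for start in range(0, n, block_samples):
            yield self.data[:, start: start + block_samples]


class _ChannelState:
    """Per-channel streaming state: filter, detector, variance, sorter."""

    def __init__(self, channel_id: int, config: StreamConfig,
                 model: SorterModel):
        self.sos = bandpass_sos(config.fs_hz, config.low_hz, config.high_hz)
        self.zi = np.zeros((self.sos.shape[0], 2))
        self.detector = SpikeDetector(config.fs_hz, k=config.detect_k,
                                      channel_id=channel_id)
        self.tracker = cl.VarianceTracker(config.fs_hz)
        self.model = model
        self.channel_id = channel_id

    def process(self, samples: np.ndarray, final: bool = False
                ) -> list[SpikeEvent]:
        filt, self.zi = sps.sosfilt(self.sos, samples, zi=self.zi)
        self.tracker.update(filt)
        waves = self.detector.process(filt)
        if final:
            waves.extend(self.detector.flush())
        out = []
        for w in waves:
            sigma2 = None
            if self.model.combo.clusterer == "osort":
                sigma2 = self.tracker.sigma2_at(w.t_cross)
            label = self.model.classify(w, sigma2=sigma2)
            out.append(SpikeEvent(self.channel_id, w.t_cross, w.t_peak,
                                  int(label)))
        return out


def stream_process(source: ArrayBlockSource, config: StreamConfig,
                   models: Sequence[SorterModel],
                   collect_timing: bool = False) -> list[BlockResult]:
    """Run the full pipeline block by block over a multichannel source.

    One trained (or training-free) model per channel.  Channels are
    processed sequentially within each block.  Events are emitted exactly
    once: a spike whose cutout crosses a block boundary is carried over
    and appears in the block where its window completes.
    """
    if len(models) != source.n_channels:
        raise ConfigError(
            f"{source.n_channels} channels but {len(models)} models"
        )
    states = [_ChannelState(ch, config, models[ch])
              for ch in range(source.n_channels)]
    blocks = list(source.iter_blocks(config.block_samples))
    results = []
    for bi, block in enumerate(blocks):
        final = bi == len(blocks) - 1
        events: list[SpikeEvent] = []
        timing: dict[str, float] = {}
        t0 = time.perf_counter()
        for ch, state in enumerate(states):
            events.extend(state.process(block[ch], final=final))
        timing["total_s"] = time.perf_counter() - t0
        if collect_timing:
            timing["block_s"] = block.shape[1] / config.fs_hz
            timing["runtime_percent"] = (
                100.0 * timing["total_s"] / timing["block_s"]
            )
        events.sort(key=lambda e: (e.t_cross, e.channel_id))
        results.append(BlockResult(block_index=bi, events=events,
                                   timing=timing))
    return results


def offline_sort(trace: Trace, model: SorterModel,
                 config: StreamConfig | None = None) -> list[SpikeEvent]:
    """Off-line pipeline: the whole trace as one block (same code path)."""
    cfg = config or StreamConfig(fs_hz=trace.fs_hz,
                                 block_ms=1000.0 * trace.duration_s,
                                 max_block_ms=np.inf)
    source = ArrayBlockSource(trace.samples[None, :], trace.fs_hz)
    results = stream_process(source, cfg, [model])
    return [e for r in results for e in r.events]


def worst_case_source(n_channels: int = 60, rate_hz: float = 250.0,
                      duration_s: float = 1.0, seed: int = 0,
                      fs_hz: float = 25000.0) -> ArrayBlockSource:
    """Worst-case load: every channel firing at ~250 Hz simultaneously.

    At 250 Hz the 4 ms refractory period saturates, so each channel
    carries one unit firing on a regular 4 ms grid (phase-shifted per
    channel) over independently seeded background noise at SNR 4 —
    "one spike every 4 ms at every channel".  The returned source
    exposes the per-channel truth as ``ground_truths``.
    """
    refractory_s = 0.004
    if rate_hz * refractory_s > 1.0 + 1e-9:
        raise InputError("rate incompatible with the 4 ms refractory period")
    from .simulate import GroundTruth, make_noise, make_template_bank, \
        render_signal

    n_total = int(round(duration_s * fs_hz))
    period = int(round(fs_hz / rate_hz))
    base = np.random.SeedSequence(entropy=seed)
    bank_seed = int(base.generate_state(1)[0] % (2 ** 31 - 1))
    tpl = make_template_bank(2, n_samples=round(0.003 * fs_hz),
                             seed=bank_seed)[0]
    margin = round(0.004 * fs_hz)
    data = np.empty((n_channels, n_total))
    truths = []
    for ch in range(n_channels):
        child = np.random.SeedSequence(entropy=seed, spawn_key=(ch,))
        rng = np.random.default_rng(child)
        phase = int(rng.integers(0, period))
        times = np.arange(margin + phase, n_total - margin, period)
        truth = GroundTruth(times, np.zeros(len(times), dtype=np.int64),
                            [tpl], provenance={"channel": ch})
        noise = make_noise(duration_s, fs_hz, rng=rng)
        trace, truth = render_signal([tpl], truth, noise, snr_target=4.0)
        data[ch] = trace.samples
        truths.append(truth)
    source = ArrayBlockSource(data, fs_hz)
    source.ground_truths = truths
    return source


# ----------------------------------------------------------------------
# Benchmark harness
# ----------------------------------------------------------------------

def operation_counts(method: str, n: int = 75, n_clusters: int = 4,
                     n_levels: int = 32) -> dict[str, int]:
    """Static per-spike operation counts of each processing method.

    ``n`` is the number of samples per spike, ``n_clusters`` the number of
    clusters or templates, ``n_levels`` the density-LUT resolution.
    """
    c, N = n_clusters, n_levels
    table = {
        "pca": (3 * n, 3 * n, 0),
        "dwt": (4 * n, 6 * n, 0),
        "fsde": (2 * n - 3, 0, 2 * (n - 1)),
        "geo": (2 * n, 1, 6 * n - 2),
        "fcm": (5 * c, 6 * c, c),
        "dbc": (0, 0, 6 * N),
        "osort": (6 * c * n + 2 * n, 6 * c * n + 2 * n + 1, 8),
    }
    if method not in table:
        raise InputError(f"unknown method {method!r}")
    adds, mults, ifs = table[method]
    return {"additions": adds, "multiplications": mults,
            "comparisons": ifs}


def benchmark(source: ArrayBlockSource, config: StreamConfig,
              models: Sequence[SorterModel]) -> dict:
    """Time a streaming run and report runtime as % of block length.

    Timing figures are hardware-dependent and informational only; the
    static operation counts per method are included for reference.
    """
    results = stream_process(source, config, models, collect_timing=True)
    percents = [r.timing["runtime_percent"] for r in results]
    combos = {str(m.combo) for m in models}
    report = {
        "block_ms": config.block_ms,
        "n_channels": source.n_channels,
        "n_blocks": len(results),
        "n_events": sum(len(r.events) for r in results),
        "runtime_percent_mean": float(np.mean(percents)),
        "runtime_percent_max": float(np.max(percents)),
        "per_block_percent": percents,
        "operation_counts": {},
    }
    for combo in combos:
        for stage in combo.split("+"):
            report["operation_counts"][stage] = operation_counts(stage)
    return report
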