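# Methods

This note records the scientific and numerical choices behind
`measort`: what each processing block assumes, which parameters matter,
what the ground-truth simulator does and does not emulate, and where
the design was genuinely open.

## Detection and alignment

The raw trace is band-pass filtered at 200–3000 Hz with a 2nd-order
Butterworth filter.  The filter is *causal* by default so the off-line
and streaming paths share one code path (a zero-phase variant is
available off-line).  The noise level is re-estimated once per second
as `median(|x|)/0.6745` — the median absolute deviation is exact for
Gaussian noise and barely inflated by spike transients, unlike the
plain standard deviation.  An event starts when the filtered signal
reaches `+kσ` or `−kσ` (`k = 4`); all crossings within one 3 ms window
collapse into a single event, so a biphasic spike crossing both
polarities is counted once, and consecutive cutouts can never overlap.
Each event is cut as 1 ms before the crossing and 2 ms after it
(75 samples at 25 kHz) and re-cut so the sample of maximum absolute
amplitude sits exactly 1 ms into the window; ties go to the earliest
sample.  Alignment on the absolute amplitude handles both
negative-going (dominant in extracellular data) and positive-going
spikes.

The detector is implemented as an incremental consumer of samples:
noise-window state, dead-time state, and events awaiting their 2 ms
look-ahead survive across arbitrary chunk boundaries.  The first
1-second window is thresholded with its own noise estimate (one second
of start-up latency); every later window uses the estimate from the
window before it, which keeps the streaming path strictly causal.
Spikes closer than one window length to the very end of a stream are
dropped rather than emitted unaligned.

## Feature extraction and reduction

All four extractors map the 75-sample cutout to a 3-D feature vector:

* **PCA** — eigendecomposition of the mean-centred spike covariance;
  the first three components are kept.  Centring is not strictly
  required by the projection formula but stabilises the cluster
  geometry; each component's largest-magnitude entry is made positive
  so retraining is bit-reproducible.
* **FSDE** — `(max FD, min SD, max SD)` of the first and second
  discrete derivatives.  Training-free.
* **GEO** — positive/negative amplitude, peak-to-peak, positive and
  negative area, their ratio (guarded by `ε = 1e-12` and capped at
  `1e6` for monophasic events), and the maximum absolute slope.
* **DWT** — three-level orthonormal Haar decomposition.  75 samples is
  not a multiple of 8, so the input is zero-padded to 80; the padding is
  part of the trained contract, making training-time and on-line
  coefficients identical.  The `periodization` boundary mode keeps the
  transform exactly energy-preserving.

GEO and DWT are reduced to three coordinates by maximum-difference
selection: for every consecutive pair of training spikes the indices of
the three largest absolute element-wise differences are tallied, and
the three most-tallied indices are kept (ties to the lowest index).
This rewards coefficients with high spike-to-spike variability at
negligible cost.

## Clustering

* **K-means** candidates `K = 2…6` are each fitted by best-of-10
  restarts (scikit-learn's seeded k-means++/Lloyd); the final `K`
  maximises the PBM index.  `K = 1` is excluded: the PBM separation
  term is undefined for one cluster, and multi-unit channels are the
  use case.  K-means never abstains.
* **Fuzzy-C-means** alternates membership and centre updates to a
  `1e-6` centre-shift tolerance (max 300 iterations, 5 restarts per
  candidate `C`); `C = 2…6` is chosen by minimising the validity `S`.
  The denominator of `S` uses the minimum over *distinct* centre pairs.
  Defuzzification assigns the maximum-membership label only when it
  reaches `1/C + 0.1` (0.6 for `C = 2`); a spike coincident with a
  centre has membership 1 by the continuous limit.  The default
  fuzziness is `m = 3`; `m → 1` recovers hard, K-means-like labels.
* **Density-based clustering** quantises each feature dimension into
  `N = 32` (or 16) levels over the training min/max ±5%.  The cell
  histogram is smoothed with a 3×3×3 kernel (centre weight 2,
  neighbours 1 — the smallest stencil consistent with spreading mass to
  surrounding cells).  Basins are labelled by descending-density
  flooding: the densest unlabelled cell founds a cluster, every other
  occupied cell joins its densest labelled neighbour; plateau ties are
  broken by cell index, making the labelling deterministic.  Basins
  whose peak density is below 10% of the strongest peak are left
  unlabelled — they are stray tail cells, not units.  Two clusters
  merge when their peaks lie within 3 cells *and* the smaller peak is
  at most 0.9× the larger, repeated to a fixpoint (highest-density
  mergeable pair first, so the fixpoint is order-independent).  The
  0.9 height ratio was calibrated on simulated signals: a blob
  fragmented by sampling noise produces near-equal sub-peaks that a
  0.5 ratio would never merge, while genuinely distinct units at
  useful SNR sit farther than 3 cells apart.  On-line classification is
  a pure LUT lookup; features outside the mapped volume stay
  unclassified, and the density map is frozen after training.
* **O-sort** keeps running mean waveforms.  An incoming spike joins the
  nearest template when the squared Euclidean distance is below
  `T_M = c·n·⟨σ⟩²`, else founds a new cluster; template pairs closer
  than `T_S = T_M` merge (weighted mean, survivor = larger count).
  `⟨σ⟩²` is the signal variance over a sliding ~60 s window of exact
  1-second chunks, anchored to each spike's crossing time so the value
  a spike sees never depends on how the stream was cut into blocks.
  The correction factor must exceed 2 for same-unit matching to be
  possible at all — the expected squared distance between two noisy
  realisations of one template is `2nσ²`, above the uncorrected
  threshold `nσ²` — and must stay below the nearest inter-unit
  distance; a sweep over the simulator's study conditions (20 seeds ×
  SNR {2, 3, 4}) put the best median accuracy and a monotone SNR trend
  at `c = 2.0`, the default.  After a run, clusters with fewer than 5
  spikes per 60 s are discarded and their spikes marked unclassified.
  Merges are tracked by union-find so recorded labels can be resolved
  to the surviving clusters at any point.  Templates are compared on
  the aligned 75-sample waveforms directly, without per-comparison
  shift compensation.

`UNCLASSIFIED = −1` is a reserved sentinel distinct from every cluster
id and preserved through all I/O; `NOISE_LABEL = −2` marks, on the
ground-truth side only, detected events that match no true spike.

## Evaluation

CV is the minimum squared between-class centre distance over the mean
squared within-class distance, computed from *true* labels — a
clusterer-independent separability measure.  CA matches predicted
clusters one-to-one to true units by an accuracy-maximising bipartite
assignment (Hungarian algorithm); unmatched clusters contribute only
errors, a true spike left unclassified is an error, and a noise event
is correct only when left unclassified — so 100% requires both perfect
clustering and perfect abstention on false positives.  Detected events
inherit truth labels by nearest-spike matching within ±1 ms, closest
pairs first, one-to-one.  ICV is aggregated across clusters by
unweighted mean (configurable input; the per-cluster definition leaves
the aggregation open).  The expert-inspection judgment of real-data
studies is replaced by a deterministic proxy: a found cluster counts as
good when ≥80% of its members share one true unit.

`run_grid` trains every combination on the first ~1/3 of the detected
spikes and classifies the remainder on the fly, mirroring on-line use;
metrics are computed on the on-line-classified remainder.  4 feature
methods × 3 clusterers + O-sort = 13 report rows.

## Ground-truth simulator

The generator builds signals whose answer is known exactly:

* **Templates** stand in for a lab's bank of aligned average waveforms.
  Every unit is a biphasic shape — dominant trough, delayed positive
  after-lobe, small positive pre-lobe — with the trough at the same
  window position for all units, because an aligned waveform bank
  carries no position information.  Realism constraints that turned out
  to be load-bearing: templates are themselves band-limited to
  200–3000 Hz (recorded averages have passed the acquisition filter)
  and cosine-tapered to zero at the window edges, otherwise the
  truncation step and residual low-frequency content ring through the
  causal detection filter and re-trigger the detector 2–3 ms after
  every loud spike; trough widths are 0.10–0.18 ms, sharp enough for
  unambiguous peak alignment yet in-band; and each template receives a
  band-limited sub-sample shift so its causally-filtered peak lands
  exactly on the sampling grid — without this, a unit whose filtered
  peak falls mid-sample is aligned to either neighbouring sample at
  random and splits into two shifted clusters.  A screening step
  rejects shapes whose filtered secondary extremum exceeds 0.85 of the
  primary or whose filtered tail beyond the dead time exceeds 8% of
  the peak.
* **Similarity control.**  The shape parameters start maximally diverse
  and are morphed toward their common mean by a mixing factor found by
  grid search until the mean pairwise Bray-Curtis similarity of the
  bank lands within ±0.05 of the requested target.  Amplitudes spread
  over a ~2.7× range (units at different distances from the electrode)
  and converge with the morph.  The attainable range is bimodal and
  realistic for aligned banks: mixed-polarity banks reach ≈0–0.15
  (2 units), same-polarity banks ≳0.55, and 3-unit banks fill 0.2–0.35
  through one opposite-polarity unit.  The search redraws its
  parameters (deterministically, from the seed) up to 8 times before
  declaring a target unreachable.
* **Spike trains** are uniform with a hard 2 ms refractory period.
  Per-unit rates are drawn from 3–8 Hz conditioned on a 10–16 Hz total,
  which yields the ~600–1000 spikes per 60 s that multi-unit MEA
  channels show; overlapping spikes from different units are allowed
  and each counted once in the truth.
* **Noise** is white Gaussian filtered by the same 2nd-order 200–3000 Hz
  Butterworth band-pass and normalised to unit standard deviation.
* **SNR** is the mean absolute peak of the 3 ms cutouts around the true
  spike times divided by the mean peak-to-peak amplitude of the noise
  over non-overlapping 1-s windows (read as absolute peak, not
  peak-to-peak, of the spike; configurable).  The noise gain is solved
  by bisection to 1% relative tolerance, so `measure_snr` of a rendered
  signal returns the request within a few percent.
* **Catalog.**  12 template groups — (2 units, BCS target) ∈
  {0.05, 0.10, 0.60, 0.65, 0.75, 0.85} and (3 units, target) ∈
  {0.20, 0.25, 0.30, 0.65, 0.70, 0.80} — × SNR {2, 3, 4} = 36 signals,
  all seeds derived deterministically from one master seed.

What the simulator does **not** emulate: electrode drift and
spike-shape non-stationarity, bursting statistics, non-Gaussian or
correlated real MEA noise, and sub-sample spike timing (spikes are
placed on the sampling grid, matching the aligned-bank construction).
Passing tests therefore demonstrate correct mechanics and achievable
accuracy under stationary, Gaussian-noise conditions — not performance
on drifting or bursty cultures.

## Streaming engine

Per channel and block: causal filter with carried state → incremental
detector → per-spike feature extraction and classification.  Because
every stage is partition-invariant, streaming output is label-for-label
identical to the off-line pipeline for any block length of at least one
spike window (the configured operating range is 100 ms–3 s); a spike
straddling a block boundary is emitted exactly once, in the block where
its look-ahead completes.  Channels are processed sequentially.  The
worst-case load source drives every channel at 250 Hz (one spike every
4 ms — the refractory-saturated grid) at SNR 4.  The benchmark reports
wall-clock per stage as a percentage of the block length plus static
per-spike operation counts (e.g. FSDE: `2n−3` additions and `2(n−1)`
comparisons at `n = 75`); timing numbers are hardware-dependent and
never asserted against.

## Problem sizes used in the checks

The accuracy and equivalence checks run on 60-s single-channel signals
at 25 kHz (10 seeds × 3 SNR levels for the recovery study); unit tests
use 12-s signals; model-selection recovery uses 50 trials of 3-D
Gaussian blobs; oracle agreement uses ≥100 random instances per
formula at `1e-9` relative tolerance.
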