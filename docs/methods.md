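# Methods

This note documents the models, conventions and numerical choices
behind `rookvoc`, in the order the pipeline applies them, together with
what the synthetic-data generator does and does not emulate.

## Vocal units and the song rule

The atomic observation is the *vocal unit*: one vocalization forming a
continuous spectrogram trace, annotated with its time interval
(half-open `[start_s, end_s)`, seconds) and emitter. Units are *song
units* when they belong to a song — a maximal same-individual run with
successive gaps strictly below 10 s that contains at least 5 units of
at least 2 perceptually different types — and *call units* otherwise.
Type tags come from annotation (or synthetic ground truth); the
classifier never infers types acoustically, because perceptual typing
is an annotation-level judgement. Classification is idempotent,
order-invariant and total (every unit ends up call or song). Only units
from identified emitters that do not overlap other sounds enter the
analysis.

Label tracks use the convention `Individual[;type][;context]`
(semicolon-separated, regex-configurable), since annotation dialects
vary; the unit-table CSV is the canonical interchange format.

## Spectrogram representation

Per unit: (1) the channel with the highest SNR is selected, where
SNR = 10·log₁₀(RMS²_unit / RMS²_flank) against flanking context
(0.5 s per side by default; without flanks, highest in-unit RMS; ties
to the lowest channel index). (2) Spectral-gating denoising: a
per-frequency gate at mean + 1.5 SD of STFT magnitude, estimated from
the flanking context when available, else from the quietest 10 % of the
unit's own frames; sub-gate magnitude is attenuated by the configured
strength (default: fully) after smoothing the gate mask. The gate
scales with the signal, so denoising commutes with amplitude scaling.
(3) Pre-emphasis y[t] = x[t] − 0.97·x[t−1] (the conventional speech /
bioacoustics coefficient; the low-frequency roll-off is additionally
enforced by an optional 4th-order 100 Hz high-pass, on by default).
(4) Power spectrogram with a 480-sample (10 ms at 48 kHz) Hamming
window and 96-sample hop (80 % overlap); n_frames = 1 + ⌊(N−480)/96⌋;
units shorter than one window are zero-padded with a warning.
(5) 80 triangular mel filters (HTK mel scale) spanning 100 Hz–Nyquist;
the 100 Hz cut doubles as noise removal. (6) Frames whose total energy
falls more than 60 dB (configurable; the threshold is a package
convention) below the peak frame are trimmed from the edges only;
all-zero input raises "empty after trim". (7) dB conversion
(10·log₁₀ of power, machine-epsilon guarded), floor at 20 dB below the
maximum, linear map of [max−20 dB, max] onto [0, 1]. A constant matrix
maps to all ones by convention. The result is invariant to scaling the
input waveform by any positive constant — the point of the
normalization — and deterministic given the configuration.

## DFTW distance

Two unit spectrograms are compared by a two-level dynamic program. The
outer level aligns time frames; its local cost for frame pair (i, j)
is the inner level: a monotone alignment of the two 80-bin frame
spectra over mel bins. Both levels use the symmetric step pattern
(match / insert / delete, weight 1, endpoint-anchored) and banded
search — the outer a Sakoe–Chiba band of half-width
max(1, round(0.1 × longer length)), widened to |n_A − n_B| when that is
larger (otherwise the corners are unreachable); the inner a maximum bin
displacement of 8. Elementwise cost is |a − b| by default (squared
optional). Each level divides its optimal total by the warping-path
length, making distances comparable across unit durations; ties
between equal-cost alignments resolve to the shortest path, which
makes the normalized value well defined (the optimization is
lexicographic in (total, length), which is Bellman-decomposable).

The exact banding and normalization of the distance are package
conventions, config-exposed (`time_band_frac`, `freq_band_bins`,
`local_cost`, `normalize_by`); the defaults above are used throughout.
The distance is nonnegative, symmetric, zero on identical inputs, and
never increases when a band is widened; like all DTW-family measures
it violates the triangle inequality, so downstream methods treat it as
a dissimilarity, not a metric. Kernels are numba-compiled; the full
matrix is computed in restartable row chunks, stored float32, and the
result is independent of chunking.

## Embedding, validation, soft clusters

The distance matrix is projected to 2-D by UMAP (precomputed metric,
`n_neighbors=30`, `min_dist=0`, fixed seed; `n_neighbors` is reduced
with a warning when the dataset is smaller). Projection quality is
checked with the rank-based trustworthiness and continuity measures:
trustworthiness penalizes points that enter an embedded k-neighborhood
without being original-space neighbors, by their original rank excess;
continuity is the symmetric counterpart. Both equal 1 exactly when the
embedding preserves all neighborhoods; k defaults to 30, matching
`n_neighbors`, capped at ⌊(n−1)/2⌋. Neighbor ties resolve by point
index, making both measures deterministic.

Clusters come from HDBSCAN on the 2-D coordinates
(`min_samples=30`, `min_cluster_size=30`); clustering operates on the
embedding, not the raw matrix. Each unit then receives a soft
membership vector over the K clusters from a heavy-tailed (Cauchy)
kernel, r_c² / (r_c² + d_c(x)²), renormalized to the simplex. When the
distance matrix is available (the pipeline default), d_c(x) is the
DFTW distance to the nearest member of cluster c and r_c the median
within-cluster nearest-neighbor distance — memberships then measure
acoustic intermediacy and do not depend on the arbitrary absolute
scale of the UMAP layout. Two deliberate consequences: memberships are
never exactly one-hot (a Gaussian kernel underflows to one-hots on
tight clusters and freezes the gradation index at 0), and
density-unassignable (noise) points still get meaningful vectors. A
point with vanishing affinity to every cluster receives the uniform
vector 1/K — maximal gradation, consistent with such points being
intermediate by construction. Hard labels (HDBSCAN's, noise = −1) are
kept alongside; the assignment summary reports K and the
assigned/noise fractions, which sum to 1 exactly.

## Complexity indices

Effective cluster numbers of a simplex vector p:
D₁ = exp(−Σ_{pᵢ>0} pᵢ ln pᵢ) (Shannon; all clusters weighted equally)
and D₂ = 1/Σ pᵢ² (Simpson; dominated by large clusters). Both lie in
[1, K], D₁ ≥ D₂, and both are normalized as (D − 1)/(K − 1) so 0 means
one cluster and 1 means all clusters equally; K = 1 is degenerate and
defined as 0 with a warning. *Gradation* is the normalized effective
number per unit; *diversity* the same applied to an individual's
repertoire profile — the arithmetic mean of its units' membership
vectors (closed on the simplex), built per unit type (call, song) and
pooled. Noise-labelled units participate in profiles through their
soft vectors by default (dropping them would discard precisely the
intermediate units; a switch restricts to hard-assigned units for
sensitivity analyses). Both index variants are always computed.

*Overlap* between two profiles is Morisita–Horn,
MH = 2Σxᵢyᵢ/(Σxᵢ² + Σyᵢ²): symmetric, relabeling-invariant, 1 iff the
distributions coincide, 0 iff supports are disjoint. Matrices are
produced per unit type and for call-vs-song, whose diagonal holds
self-similarity cells (an individual's call profile against its own
song profile); missing profile combinations are NaN, never 0. Heatmap
row order for reproduction of clustered displays uses average-linkage
hierarchical clustering on 1 − MH (linkage is a package choice).
Profiles use mean soft-membership vectors, not hard-count abundances —
the convention that keeps unassigned units in the analysis. Exported
tidy tables code pairs by sex (FF/FM/MM, sorted) and colony
(within/between).

## Synthetic colonies

The generator exists to make every stage testable against known ground
truth. Archetype unit types are harmonic stacks with sinusoidal FM
(fundamentals log-spaced 400–5000 Hz, 2–4 harmonics, flat or
attack-decay envelopes, 60 ms by default); they are deliberately *not*
corvid-realistic — the downstream stages only consume spectrogram
shape, so what matters is cluster geometry: separation between
archetypes, continuous within-type spread (per-unit duration jitter
±5 % and pitch jitter ±2 %, mimicking production variability), a
morphing parameter λ that interpolates every unit's parameters toward
a random other archetype by a per-unit level drawn from
U(0, λ), additive white noise at a configured SNR (30 dB default), and
per-individual repertoire distributions over archetype pools (a shared
female pool vs private male pools reproduces the observed sex
contrast). Call units are laid out with > 10 s gaps and song bouts as
runs of 5–8 units of ≥ 2 types with sub-second gaps, so the song rule
recovers the ground-truth types exactly. All randomness derives from
one colony seed through named substreams.

Closed-form oracles accompany the generator: `expected_overlap` (MH on
the *configured* distributions) and `empirical_overlap` (MH on the
*realized* archetype counts). The two differ by multinomial sampling
noise, which at desk-scale unit counts can exceed the pipeline's own
error; recovery tests therefore compare against the realized counts —
the value perfect clustering would produce for the sample actually
emitted.

What the generator does not emulate: reverberation and room acoustics,
multi-microphone geometry (channel selection is tested with synthetic
per-channel gain/noise differences), overlapping vocalizations,
non-stationary noise, and realistic corvid spectral envelopes. Passing
recovery tests therefore demonstrates the pipeline's correctness on
separable, moderately noisy corpora — not its robustness to field
recording conditions, where denoising quality and annotation accuracy
dominate.

## Test problem sizes

Stochastic end-to-end checks run on deliberately small colonies so the
suite stays desk-sized, with clustering parameters scaled to the
cluster sizes those colonies produce: archetype recovery uses 6
archetypes × 4 individuals × 50 units (≈ 25–45 units per archetype;
`min_samples = min_cluster_size = 15`, `n_neighbors = 25`) over 10
seeded replicates; the sex-contrast and gradation checks use 120-unit
colonies. At a few dozen points per cluster, a paper-scale
`n_neighbors` relative to the dataset would be far too local and
fragments clusters along their within-type spread; `n_neighbors`
comparable to the cluster size keeps each archetype's units connected
in the UMAP graph. The acceptance script uses the same sizes and
finishes in a few minutes on one CPU.

## Known limitations

* The banded DFTW variant here is a standard decomposition with
  documented defaults; distances are not numerically interchangeable
  with other DFTW parameterizations, so cross-study comparisons should
  recompute matrices with one configuration.
* UMAP coordinates depend on the seed; all reported quantities are
  computed at a fixed recorded seed, and memberships anchored in DFTW
  space reduce (but cannot remove) the embedding's influence via the
  cluster partition itself.
* Soft memberships are a package construction (HDBSCAN exposes only a
  per-point cluster-confidence score through scikit-learn); the kernel
  and its anchoring are documented above and config-visible in the run
  manifest.
* Statistical modelling of the exported tables (GLMMs, model
  selection, post-hoc tests) is intentionally out of scope; the
  package exports tidy CSVs for external tools.
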