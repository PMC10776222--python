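# rookvoc

Quantifying vocal repertoire complexity from annotated recordings —
built around the rook (*Corvus frugilegus*), a corvid whose colonies mix
graded calls with soft, individually variable song, but applicable to
any corpus of annotated vocal units.

The package answers three questions about a repertoire without ever
hand-picking acoustic parameters or call types:

* **How graded is it?** Per vocal unit: does the unit sit inside one
  acoustic cluster, or between several?
* **How diverse is each individual?** Effective number of clusters an
  individual actually uses.
* **How much do individuals share?** Pairwise repertoire overlap — e.g.
  do females share a common call repertoire while each male sounds like
  no one else?

## Method

Each annotated vocal unit (start/end time, emitter, optional type and
context tags, from Audacity label tracks or a unit-table CSV) is turned
into a normalized mel spectrogram: best-SNR channel, spectral-gating
denoising, pre-emphasis, 10 ms Hamming window with 80 % overlap, 80 mel
bands above 100 Hz, edge trimming, log scaling, 20 dB dynamic-range
threshold, linear mapping onto [0, 1]. The representation is invariant
to recording amplitude.

Units are compared by a **dynamic frequency–time warping (DFTW)**
distance: a two-level dynamic program that warps spectrograms in time
(outer alignment over frames) and frequency (inner alignment over mel
bins per frame pair), both Sakoe–Chiba banded, with the optimal
alignment cost — normalized by warping-path length — as the acoustic
distance. The pairwise matrix is embedded in 2-D with UMAP
(`n_neighbors=30`, `min_dist=0`, precomputed metric), validated by the
rank-based trustworthiness and continuity measures, and clustered with
HDBSCAN (`min_samples=30`, `min_cluster_size=30`). Every unit gets a
*soft membership* vector p over the K clusters (simplex), so sparse and
intermediate units stay in the analysis instead of being dropped.

From soft memberships the complexity indices are, with D an effective
cluster number:

    D₁ = exp(−Σᵢ pᵢ ln pᵢ)   (Shannon)      D₂ = 1 / Σᵢ pᵢ²   (Simpson)

normalized onto [0, 1] as (D − 1)/(K − 1). **Gradation** applies this
per unit; **diversity** per individual, on the mean membership vector
x̄ of the individual's units (its *repertoire profile*); **overlap**
between two profiles x, y is the Morisita–Horn index

    MH(x, y) = 2 Σᵢ xᵢ yᵢ / (Σᵢ xᵢ² + Σᵢ yᵢ²)  ∈ [0, 1],

computed per unit type (call, song) and across (call vs song, including
an individual's call-vs-own-song self cell). Tidy CSVs with sex /
colony / unit-type factor columns are exported for external statistics.

A synthetic colony generator renders archetype unit types as harmonic
FM tones, samples per-individual repertoires (shared vs private
archetype pools), morphs units between archetypes to set a known
gradation level, and lays units out so the song rule (≥ 5 units of ≥ 2
types with < 10 s gaps) holds by construction — so the full pipeline is
testable against ground truth without any recordings.

## Worked example

A colony of 3 females drawing calls from one shared archetype pool and
3 males with private pools, 20 units each:

```python
from rookvoc import pipeline, synthetic

config = synthetic.sex_structured_colony(
    n_females=3, n_males=3, units_per_individual=20, seed=42
)
colony = synthetic.generate_colony(config)
results = pipeline.run_arrays(
    colony.records,
    colony.unit_waves,
    pipeline.PipelineConfig(n_neighbors=10, min_samples=8,
                            min_cluster_size=8, quality_k=10, seed=42),
)

print(f"units: {len(results['records'])}, clusters: {results['K']}, "
      f"assigned: {results['fraction_assigned']:.1%}")
print(f"trustworthiness: {results['quality']['trustworthiness']:.3f}, "
      f"continuity: {results['quality']['continuity']:.3f}")
call = results["overlap"][results["overlap"].block == "call"]
for pair in ("FF", "MM", "FM"):
    print(f"mean call overlap {pair}: {call[call.sex_pair == pair]['value'].mean():.3f}")
```

prints

```
units: 120, clusters: 9, assigned: 100.0%
trustworthiness: 0.988, continuity: 0.980
mean call overlap FF: 0.973
mean call overlap MM: 0.028
mean call overlap FM: 0.090
```

The 9 clusters are the 3 shared + 3 × 2 private archetypes; the
embedding preserves the distance structure (both quality scores near
1); and the configured social structure is read straight off the
overlap: females share nearly identical call repertoires (MH ≈ 0.97)
while each male's repertoire is almost disjoint from every other
bird's (MH ≈ 0.03).

The same analysis runs from the shell on a corpus directory (WAV +
label tracks):

```sh
rookvoc synth colony/ --archetypes 6 --individuals 4 --seed 1
rookvoc run colony/ out/ --seed 1
```

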