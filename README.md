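# crinosize

Body-size macroevolution of Palaeozoic crinoids, as a tested, reusable
pipeline. Crinoid genera are represented by a single calyx biovolume
estimate (the cup housing the viscera, approximated by a geometric solid
and analysed as log₁₀ mm³) carried across the genus's whole
stratigraphic range. From a genus range/size table the package builds
stage-binned trait time series, compares likelihood models of trait
evolution, partitions mean-size changes at extinction boundaries into
extinction- and origination-driven components, and tests for a
temperature–size relationship with GLS regression under autocorrelated
errors. A synthetic-data generator emulates the structure of a compiled
genus database (clade mix, log-size distributions, extinction pulses
with tunable size selectivity), so the whole pipeline runs
self-contained.

## The statistics at the core

**Evolutionary-mode model selection.** A trait series of bin means
y = (y₁, …, yₙ) at elapsed times t₁ < … < tₙ is treated as one draw from
a multivariate normal (joint parametrization); every model adds the
sampling-error variance εᵢ = varᵢ/nᵢ to the covariance diagonal. The
candidate set is

| model | mean | covariance | K |
|---|---|---|---|
| StrictStasis | θ | δᵢⱼ εᵢ | 1 |
| Stasis | θ | δᵢⱼ (ω + εᵢ) | 2 |
| URW | a | σ²ₛ min(tᵢ,tⱼ) + δᵢⱼ εᵢ | 2 |
| GRW | a + μₛ tᵢ | σ²ₛ min(tᵢ,tⱼ) + δᵢⱼ εᵢ | 3 |
| Punc-1, Stasis-URW, Stasis-GRW, URW-Stasis, GRW-Stasis | two regimes split at a profiled shift point | blockwise | K₁+K₂+1 |

Models are ranked by AICc = −2 logL + 2K + 2K(K+1)/(n−K−1) and Akaike
weights wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2).

**Size-biased extinction decomposition.** At a stage boundary the change
in mean log size splits exactly into

```
extinction component  = mean(survivors) − mean(extant, previous stage)
origination component = mean(next stage) − mean(survivors)
total change          = extinction + origination components
```

because each surviving genus carries its single size into both stages.
A negative extinction component means larger genera preferentially died
— the signature behind post-extinction "Lilliput" faunas. K-S tests
compare size distributions across intervals.

**Climate regression.** yₜ = β₀ + β₁xₜ + eₜ with eₜ = φeₜ₋₁ + ηₜ, fitted
by exact ML (AR0 fixes φ = 0) and compared by AICc against an
intercept-only null, optionally after first-differencing both series.

## Worked example

The late-Givetian extinction, rebuilt from its cohort summary (75 genera
extant with mean size 0.254 log mm³, 55 of them victims with mean 0.4,
46 Frasnian originators with mean −0.213):

```python
from crinosize import default_timescale, decompose
from crinosize.synth import make_cohort_table

ts = default_timescale()
records = make_cohort_table(ts, "Givetian", 75, 0.254, 55, 0.4, 46, -0.213,
                            spread=0.3, seed=0)
d = decompose(records, "Givetian", ts)
print(f"survivors {d.n_survivors} mean {d.mean_survivors:.4f}")
print(f"extinction {d.extinction_component:.4f} "
      f"origination {d.origination_component:.4f} total {d.total_change:.4f}")
```

prints

```
survivors 20 mean -0.1475
extinction -0.4015 origination -0.0457 total -0.4472
```

i.e. the boundary's −0.447 log mm³ drop in mean calyx size was almost
entirely extinction-driven (survivors averaged 0.55 log units smaller
than the victims), with the small-bodied originators nudging the mean
down a further −0.046.

The full pipeline, end to end on synthetic data:

```
crinosize run-all --seed 1 --out-dir runs/demo
```

writes the genus table, per-clade/per-interval trait series, the
nine-model AICc comparison for each, the boundary-by-boundary
decomposition, K-S letter groups, GLS summaries, and a manifest with the
seed and library versions. Individual steps are also exposed
(`crinosize simulate / build-series / fit-models / decompose / climate`).

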