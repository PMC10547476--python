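# isletwave

Analysis of pancreatic-islet Ca²⁺ oscillations across genetically diverse
mouse strains: waveform decomposition, spectral summaries, correlation of
waveform parameters with islet protein abundances, and nomination of
candidate genes by overlap with human glycemic-trait GWAS signals.

Pancreatic β-cells secrete insulin in pulses driven by oscillatory Ca²⁺
influx, and the *shape* of the Ca²⁺ wave — not just its average level —
carries mechanistic information. For an oscillating islet the package
estimates, per perifusion condition (8 mM glucose, 8G + amino acids,
+ GIP, 2 mM basal):

* **peak** — mean oscillation maximum;
* **period** *T* — time between pulses;
* **active duration** *A*_D — per-pulse time above 50% of peak amplitude
  (the secretory phase);
* **pulse duration** *P*_D — *A*_D plus the Ca²⁺-extrusion tail;
* **silent duration** *S*_D = *T* − *A*_D (the triggering phase that ends
  in K_ATP closure);
* **plateau fraction** *P*_F = *A*_D / *T*.

Islets that plateau are coded *P*_F = 1, *T* = 0; islets that fall silent
are coded *P*_F = 0, *T* = 40 min (the measurement time). Oscillations
with *T* < 2 min are *fast* (wild-derived-strain-like), 2–10 min *slow*
(classical-strain-like). A periodogram per segment adds the top two
component frequencies and their powers.

Animal-averaged parameters are Z-scored ((x − μ)/σ, sample SD) and
correlated (pairwise-complete Pearson) against a protein-abundance
matrix; proteins with |r| ≥ 0.5 on ≥ 3 of six focus parameters are
flagged as candidate regulators. Flagged candidates' human orthologues
are then screened for glycemic-trait GWAS SNPs with −log10(p) > 8 lying
within ±100 kbp of the gene or in regions looping to its promoter
(promoter-capture HiC), yielding a nominated-gene table.

A synthetic-data generator (`isletwave.synthgen`) reproduces the
statistical structure of all three inputs — burst-shaped traces in
strain-by-sex cohorts at 6-s sampling over four 40-min conditions,
protein matrices with planted correlations, and toy gene/SNP/loop
fixtures — so the full pipeline runs and is tested without any external
data. See `docs/methods.md` for the estimator details and their limits.

## Worked example

Simulate a two-strain cohort — one slow-oscillating like the classical
B6 background, one fast like wild-derived CAST — and extract waveform
parameters:

```python
from isletwave import synthgen as sg, pipeline as pl

spec = sg.CohortSpec(
    strains=("B6like", "CASTlike"),
    sexes=("M", "F"),
    animals_per_group=2,
    islets_per_animal=3,
    archetype_map={
        "B6like": [sg.WaveSpec("slow", period=4.0, duty=0.5, noise_sd=0.05)] * 3
        + [sg.WaveSpec("silent", noise_sd=0.05)],
        "CASTlike": [sg.WaveSpec("fast", period=1.0, duty=0.4, noise_sd=0.05)] * 3
        + [sg.WaveSpec("silent", noise_sd=0.05)],
    },
    seed=1,
)
traces, schedule = sg.make_cohort(spec)
params, spectra = pl.extract_parameters(traces, schedule)
print(params[params.segment == "8G"]
      .groupby("strain")[["period_min", "active_min", "silent_min", "plateau_fraction"]]
      .mean().round(3))
print(spectra[spectra.segment == "8G"].groupby("strain")["freq1_per_min"].mean().round(3))
```

prints

```
          period_min  active_min  silent_min  plateau_fraction
strain
B6like           4.0       1.968       2.033             0.492
CASTlike         1.0       0.378       0.622             0.378

strain
B6like      0.25
CASTlike    1.00
Name: freq1_per_min, dtype: float64
```

The slow strain's 4-min period and 0.5 duty cycle are recovered (period
4.0 min, plateau fraction 0.49) and the fast strain's 1-min period gives
a leading spectral component at 1 cycle/min — despite 10% measurement
noise on every trace.

The same stages are available from the shell:

```sh
isletwave simulate  --config cohort.toml --out sim/
isletwave extract   --traces sim/traces.csv --schedule sim/schedule.csv --out params.csv
isletwave spectra   --traces sim/traces.csv --schedule sim/schedule.csv --out spectra.csv
isletwave correlate --params params.csv --proteins proteins.csv --focus default6
isletwave nominate  --genes genes.bed --snps snps.tsv --loops loops.bedpe
```

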