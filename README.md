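# filotip

Quantification toolkit for integrin biology at filopodia tips. It packages,
as one tested Python library, the measurement procedures used to
characterize how adhesion receptors distribute and activate along
filopodia — thin actin-rich protrusions with a tip (where myosin-X and
active β1-integrin concentrate) and a shaft ending at the lamellipodium:

* **Filopodia maps** — tip→base line-intensity profiles are reduced to 40
  median bins and averaged per channel into heatmap-ready maps. Per
  filopodium the toolkit scores the **enrichment ratio**
  `mean(bins 1–6) / mean(bins 7–40)` and **tip positivity** (tip-bin
  average ≥ 5000 on the normalized 0–65535 scale).
* **Spot counting and dynamics** — ImageJ-style find-maxima counting of
  extracellular MYO10 puncta (prominence semantics, F-actin cell masking),
  plus LoG spot detection (0.8 µm diameter) and gap-free LAP linking
  (1 µm gate) to measure puncta lifetimes from 5-s-interval movies.
* **Immunogold distributions** — probability-density curves of
  gold-particle distances to the filopodium tip and a bootstrap two-sample
  Kolmogorov–Smirnov test (pooled resampling, +1-corrected p).
* **Binding affinities** — microscale-thermophoresis titrations fitted with
  the single-site ligand-depletion quadratic
  `[AL] = ½((A₀+L₀+K_d) − √((A₀+L₀+K_d)² − 4A₀L₀))`,
  `signal = F_free + (F_bound − F_free)·[AL]/A₀`, yielding K_d with free
  amplitudes; ΔFnorm = F₁/F₀ is supported as input.
* **Flow-cytometric activity indices** — `AI = (F − F_EDTA)/F_PB1` and
  `IA = (F_9EG7 − F_2ndAb)/(F_P5D2 − F_2ndAb)` — and qPCR fold changes by
  2^−ΔΔCt.
* **Resampling statistics** — label-randomization tests (exact enumeration
  or Monte Carlo), bootstrap effect sizes with percentile CIs, Tukey
  boxplot summaries.
* **Synthetic data with ground truth** — every stage has a generator
  (scenes with channel-specific intensity laws and Poisson+read noise,
  gold-particle sets, titrations, flow populations, time lapses) so the
  whole pipeline is testable without any external data.

The intended users are cell-biology labs quantifying receptor distribution
along linear protrusions from annotated fluorescence images, and anyone who
needs the accompanying binding/statistics machinery in scripted form.

## Worked example

`examples/simulate_and_map.py` renders a 30-filopodium scene (MYO10 and
active integrin tip-enriched, F-actin and inactive integrin uniform;
active-integrin tip signal present on 75% of filopodia by construction),
extracts and bins all profiles, and prints:

```
channel               median enrichment  % tip-positive
MYO10                             10.13           100.0
F-actin                            0.98           100.0
active-integrin                    6.40            90.0
inactive-integrin                  0.98           100.0
```

Tip-concentrated channels show enrichment ≫ 1 while uniform channels sit at
≈ 1, and the classified active-integrin positivity (90.0% for this seed)
equals the scene's ground-truth positive fraction. The other scripts in
`examples/` walk through binding fits, gold-particle statistics, lifetime
tracking, screen spot counts and the flow/qPCR indices, each printing the
numbers it computes and what they mean.

A thin CLI mirrors the workflows (`filotip simulate|map|screen|track|sem|
mst|flow|stats|run`); see `filotip --help`.

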