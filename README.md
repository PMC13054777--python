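# stancekin

Stance-phase limb kinematics of terrestrial mammals: angular excursion
metrics, factor-wise comparative statistics, the fore/hind-limb angular
utilization quadrant framework, and phylogenetic robustness checks.

## The problem

Comparative studies of mammalian walking digitize joint poses at three
stance events — touchdown (TD), midstance (MS) and toe-off (TO) — for the
shoulder, elbow and wrist (forelimb) and hip, knee and ankle (hindlimb),
across species spanning several decades of body mass and diverse limb
postures and locomotor habits. From those poses, three metrics summarize
how a limb uses its joints during stance:

* **JAE**, joint angular excursion: `max − min` angle of one joint across
  the stance events;
* **TAE**, total angular excursion: the net sweep of the functional limb
  segment (ground-contact point to shoulder or hip) from TD to TO;
* **AUI%**, angular utilization index: `100 · TAE / ∑JAE`, the share of
  summed joint excursion realized as net limb excursion.

The scientific questions this package serves: how do JAE and TAE scale with
body mass and vary across posture, speed and habit categories, and is AUI%
conserved despite that variation? Because species are phylogenetically
related, scaling is checked with PGLS under a Brownian-motion correlation
structure (Pagel's λ = 1), `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` with
`C[i,j]` the shared root-to-MRCA path length, and factor effects are
re-tested with a simulation-based phylogenetic ANOVA. A quadrant framework
classifies species by whether forelimb and hindlimb AUI% exceed 50% and
tests factor–quadrant association with χ² and per-cell Fisher exact tests.

A synthetic-data generator produces species tables and trees with the
statistical structure the analysis assumes (TAE declining ≈ 10° per decade
of body mass around phylogenetically structured residuals; mass-independent
AUI% near the mid-50s), so the full pipeline is testable end to end without
access-restricted empirical data. See `docs/methods.md` for the model and
all conventions.

## Worked example

Generate a 60-species dataset and run the full analysis:

```sh
stancekin simulate --n-species 60 --seed 42 --out demo
stancekin run-all --table demo/species.csv --tree demo/tree.nwk \
    --seed 42 --n-sim 500 --out demo/out
```

`demo/out/` then contains `metrics.csv` (per species × limb: JAE per joint,
∑JAE, TAE, AUI%, relative JAE), descriptive tables by joint and by
factor × category, `group_tests.csv`, `correlations.csv`, `quadrants.csv`
and `quadrant_tests.csv`, the phylogenetic results, an exclusion log and a
manifest. The PGLS table from this exact run:

```
    response  n      slope  se_slope         t  df            p       r2
    tae_fore 60 -12.399709  2.685829 -4.616715  58 2.208274e-05 0.268730
aui_pct_fore 60   3.098626  8.962048  0.345750  58 7.307818e-01 0.002057
    tae_hind 60  -9.133079  1.563038 -5.843160  58 2.468618e-07 0.370540
aui_pct_hind 60  20.101457 14.187309  1.416862  58 1.618725e-01 0.033454
```

Read: in this replicate, hindlimb TAE falls by 9.1° (±1.6 SE) per tenfold
increase in body mass (p ≈ 2 × 10⁻⁷) and forelimb TAE by 12.4°, while
neither limb's AUI% shows significant mass dependence (p = 0.73, 0.16) —
the generated pattern of shrinking excursions with conserved utilization.
The quadrant split of the same run is I: 30, II: 14, IV: 10, III: 6, and
mean hindlimb AUI% is 59.5 (SD 14.2).

The same stages are available programmatically:

```python
from stancekin import GeneratorConfig, generate_species_dataset
from stancekin.io import records_from_dataframe
from stancekin.pipeline import compute_metrics, run_pgls

species, truth, tree = generate_species_dataset(GeneratorConfig(n_species=60, seed=42))
records, _ = records_from_dataframe(species)
metrics = compute_metrics(records)
fits, _ = run_pgls(metrics, tree)
```

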