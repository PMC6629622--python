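# capnoseq

State-sequence analysis of capnography monitoring during procedural
sedation.

Sedative and analgesic drugs depress breathing. On the capnography channel
this shows up as waveform abnormalities — reduced depth (hypopnea), slowed
rate (bradypnea) and apneic pauses — whose patterning over a procedure
differs widely between patients. `capnoseq` is a pipeline for researchers
studying sedation-induced respiratory depression: it turns per-second
monitoring records into categorical **respiratory state sequences**,
quantifies between-patient differences with a **chi-squared dissimilarity**
on state-occupancy distributions, derives a **typology** of common patterns
by Ward hierarchical clustering, and measures how much of the
inter-individual variation patient characteristics explain via
**multivariable distance matrix regression** with permutation inference.
A synthetic cohort generator with known ground truth makes every stage
testable end-to-end.

## The method in brief

Each monitored second is classified as

- APNEA — no capnography waveform, or etCO₂ = 0 mmHg,
- BRADYPNEA — respiratory rate < 8 breaths/min,
- HYPOPNEA — waveform amplitude deviating > 10% from the pre-sedation
  baseline,
- NORMAL otherwise (artifact seconds are excluded as MISSING),

with precedence in that order. Sequences x, y are compared through their
state-occupancy distributions p, q:

```
d_chi2(x, y) = sqrt( Σ_s (p_s − q_s)² / m_s )
```

where m_s is the pooled cohort proportion of time in state s, so rare
states weigh more. The n×n matrix D is clustered (Ward.D2, k chosen from a
silhouette/point-biserial report over k = 2..6), and regressed on
covariates through the Gower-centered matrix G = −½J(D∘D)J:

```
pseudo-R²(total) = tr(HGH)/tr(G),   per-term shares by drop-one ΔSS,
p-values by permuting patient identities (default 1000 permutations).
```

See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
102-patient cohort, writing artifacts to `results/`:

```
python analysis/01_simulate_cohort.py
python analysis/02_classify_states.py
python analysis/03_sequence_distances.py
python analysis/04_cluster_typology.py
python analysis/05_distance_regression.py
```

Selected output from a run (seed 1):

```
archetype counts: {'NORMAL': 40, 'HYPOPNEA': 40, 'APNEA': 14, 'BRADYPNEA': 8}
...
cluster-quality report (average silhouette width / point-biserial):
  k=2: ASW 0.576  PB 0.501
  k=3: ASW 0.808  PB 0.861
  k=4: ASW 0.931  PB 0.946 <-
  k=5: ASW 0.701  PB 0.790
  k=6: ASW 0.470  PB 0.674
final typology at k=4:
  type 1 (apnea     ) n= 14 (14%)
  type 2 (normal    ) n= 40 (39%)
  type 3 (hypopnea  ) n= 40 (39%)
  type 4 (bradypnea ) n=  8 (8%)
adjusted Rand index vs hidden archetypes: 1.000
...
                 term  pseudo_F  pseudo_R2  proportion_explained  p_value
           tcco2_peak     6.441      0.057                 0.230    0.002
             ...
                Total     1.747      0.248                 1.000    0.006
```

Reading this: the silhouette report singles out four clusters; the k = 4
Ward cut recovers the four hidden sequence archetypes perfectly (adjusted
Rand index 1.0) with cluster shares near the configured 41/37/15/7%
prevalences; and the distance regression attributes about a quarter of the
total sequence discrepancy to the covariate set, with peak transcutaneous
CO₂ the strongest single term (pseudo-R² 0.057, permutation p = 0.002) —
the weak-association regime the generator is built to produce.

The same stages are available as a command-line tool
(`capnoseq simulate|classify|dist|cluster|mdmra|run-all`) and as library
functions (`capnoseq.simulate_cohort`, `capnoseq.pairwise_dissimilarity`,
`capnoseq.ward_cluster`, `capnoseq.mdmra_fit`, ...).

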