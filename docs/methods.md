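# Methods

## Problem and model

During nurse-administered procedural sedation (typically midazolam +
fentanyl), respiratory depression manifests on the capnography channel as
waveform abnormalities: reduced breathing depth, slowed respiratory rate,
and apneic pauses. `capnoseq` treats each patient's procedure as a
*categorical state sequence*: every monitored second is assigned one of
four respiratory states,

| state | criterion (per second) |
|---|---|
| APNEA | no capnography waveform, or etCO₂ = 0 mmHg |
| BRADYPNEA | capnography-derived respiratory rate < 8 breaths/min |
| HYPOPNEA | waveform amplitude deviating > 10% from the pre-sedation baseline |
| NORMAL | none of the above |

with artifact-flagged seconds (talking, dislodged sampling cannula) coded
MISSING and excluded from all denominators. When criteria co-occur the
severity order APNEA > BRADYPNEA > HYPOPNEA applies; the amplitude
criterion is symmetric (increase or decrease) and strict, as is the rate
cut-off. Apnea is flagged from the first second; monitor alert delays are
display behaviour, not part of the state definition. Sequences may also be
supplied as observer-marked onset/offset intervals, expanded with the
half-open `[start, end)` convention in 0-based integer seconds.

## Sequence dissimilarity

Patients are compared through **state-occupancy distributions**: the
fraction of non-missing time spent in each state, optionally over K
equal-width spans of the sequence (default K = 1, the whole sequence).
Two metrics are available, both plain Euclidean norms in a weighted
coordinate system and therefore true metrics:

- Euclidean: `d(x, y) = sqrt(Σ_k Σ_s (p_ks − q_ks)²) / sqrt(K)`
- chi-squared (primary): `d(x, y) = sqrt(Σ_k Σ_s (p_ks − q_ks)² / m_s) / sqrt(K)`

where `m_s` is the *pooled* proportion of time the analyzed cohort spends
in state s (computed from pooled second counts, not averaged per-patient
proportions; states with zero pooled time are dropped from the support).
The inverse-prevalence weights give rare states — bradypnea in this
setting — more influence. Normalization for unequal procedure lengths is
by construction: occupancy proportions are length-invariant (repeating a
sequence k times leaves all its distances unchanged), and the `sqrt(K)`
divisor keeps values comparable across interval settings. This
normalization convention is stated as ours; software packages implementing
chi-squared sequence distances differ in unstated default normalizations,
so numerical identity with any particular one is not claimed. MISSING
seconds are excluded from numerators and denominators; redistribution
options are deliberately not offered.

## Typology

Ward minimum-variance hierarchical clustering is applied to the
dissimilarity matrix in the **Ward.D2** convention (the Lance–Williams
recurrence on squared dissimilarities; `scipy.cluster.hierarchy.linkage`
with `method="ward"` on the condensed matrix). D2 is the
variance-minimizing form appropriate for non-Euclidean dissimilarity
inputs. Candidate solutions k = 2..6 are scored with the average
silhouette width (computed directly from the precomputed dissimilarities;
degenerate partitions score 0 by convention) and the point-biserial
correlation between dissimilarity and the different-cluster indicator.
The final k is a judgment informed by that report; the pipeline default is
k = 4. Clusters are labelled 1..k by order of first appearance (a
deterministic tie-break) and auto-named by the modal state over member
seconds. Sequence index plots draw one horizontal bar per patient with a
fixed state→color map, one panel per cluster, sorted within panel by
decreasing sequence length (the sort order is our convention).

Note that agglomerative Ward is greedy: it does not guarantee the globally
minimal within-cluster sum of squares, and the test suite checks optimality
against an exhaustive oracle only on clearly two-cluster 1-D toy data where
the greedy path attains it.

## Distance matrix regression

Associations between the dissimilarity matrix D and patient covariates are
quantified without embedding: with `G = −½ J (D∘D) J` (Gower centering,
`trace(G) = SS_T = (1/n) Σ_{i<j} d²_ij`) and hat matrix `H` of the
intercept-augmented design,

- total pseudo-R² = `tr(H G H) / tr(G)`;
- total pseudo-F = `(SS_expl/m) / (SS_res/(n−m−1))`, m = model df excluding
  the intercept;
- per-term statistics are **marginal (drop-one)**: the loss in explained
  discrepancy when the term's column block leaves the full design. This
  partitioning is order-invariant; with correlated covariates the term
  shares need not sum to the total, and suppression can make a drop-one
  share exceed a bivariate one.
- proportion explained = term pseudo-R² / total pseudo-R² (the Total row
  is 1 by construction).

Numeric covariates are standardized; categorical ones are reference-coded
against the first sorted level; patients with any missing model covariate
are dropped listwise with a logged count; rank-deficient designs are
rejected by name. Inference permutes patient identities of D (n_perm
default 1000) with the add-one correction `p = (1 + #{F* ≥ F})/(n_perm+1)`,
applied to the F statistic of each term recomputed per permutation. When D
derives from Euclidean points and the design is one binary covariate, the
total pseudo-F equals the classical one-way ANOVA F exactly (this
equivalence, and agreement with an independent PERMANOVA implementation,
are tested). Covariates too degenerate for the joint model — here,
hypoxemia duration, since desaturation is rare — are tested separately as
bivariate models.

## Synthetic cohort generator

The generator emulates the cohort the analysis is designed for, so every
stage is testable with known ground truth:

- **Archetypes.** Each patient belongs to one of four hidden archetypes,
  named after their dominant state, at default prevalences
  (0.41, 0.37, 0.15, 0.07). Membership follows a multinomial logit on
  standardized covariates with small coefficients (defaults of 0.1–0.8 on
  the logit scale for OSA, smoking, Charlson and age); the intercepts are
  calibrated by fixed-point iteration so cohort-average membership
  probabilities equal the configured prevalences despite the nonlinear
  link.
- **State stream.** A semi-Markov chain with geometric dwell times: the
  dominant state dwells 90 s on average, other states 10 s, and excursions
  return to the dominant state with weight 0.75. This yields roughly 90%
  dominant-state occupancy — long homogeneous spells, well-separated
  occupancy distributions, and a simple oracle (run lengths are geometric).
- **Emissions.** Per-second rate/etCO₂/amplitude are drawn strictly on the
  correct side of the classifier cut-offs (a 10⁻³ margin keeps boundary
  draws away from the thresholds), so with no artifacts the classifier
  reproduces the hidden state; APNEA emits no waveform and etCO₂ = 0.
  Artifacts are i.i.d. per second at rate 0.01.
- **Durations.** Lognormal, median 1800 s (30 min), σ = 0.4, clipped at
  60 s. No duration statistics are available for this setting; the median
  is a convention chosen as typical of cardiac-catheterization procedures,
  and the analysis is length-invariant anyway.
- **Side channels.** SpO₂ sits at a hyperoxic baseline (≈98.5%) with a
  3%-per-patient chance of one 30–80 s desaturation episode below 90%, and
  occasional pulse-undetected seconds whose SpO₂ values must be (and are)
  ignored downstream. TcCO₂ = baseline + patient-specific procedure drift +
  patient-specific gain × cumulative hypoventilation/apnea burden + smoothed
  noise; the per-patient slope and gain heterogeneity (σ = 2.5 and 2.0
  mmHg) deliberately keeps peak TcCO₂ a *weak* correlate of the sequence
  typology, in the few-percent pseudo-R² regime the analysis expects, while
  remaining positively associated with burden. Interventions to support
  breathing occur with probability `logistic(−3.3 + 3.5 × apnea fraction)`,
  i.e. preferentially in apnea-heavy patients (≈10–15% of a cohort).
- **Determinism.** One `numpy` Generator seeded from the config; identical
  config ⇒ byte-identical cohort.

What the generator does **not** emulate: capnogram waveform morphology,
pharmacokinetics of dose–response, autocorrelated artifact bursts,
measurement error in the observer's state marking, or any real-data
relationship between covariates beyond the configured links. Passing
recovery tests therefore shows the pipeline is correct and well calibrated
under its own assumptions, not that four archetypes exist in any real
cohort.

## Derived covariates

- **Dose PCA.** Midazolam and fentanyl totals are standardized and the 2×2
  correlation matrix eigen-decomposed (eigenvalues 1 ± r); both component
  scores enter the model as separate 1-df terms. Sign convention: the
  largest-magnitude loading of each component is positive.
- **Oxygenation.** Seconds with undetectable pulse are filtered out first;
  hyperoxia = #{SpO₂ > 97}, hypoxemia = #{SpO₂ < 90}, both strict.
- **TcCO₂ summary.** Baseline = mean of a pre-sedation window (default the
  first 60 s — the window length is a convention, as only "a stabilized
  pre-sedation reading" is specified); peak = maximum over the procedure,
  artifact seconds included by default.

## Numerical and design choices

- Distances are computed by embedding each sequence's (interval-wise,
  weight-scaled) distribution and calling a standard pairwise-Euclidean
  routine, so symmetry and the triangle inequality hold to machine
  precision.
- An interval consisting entirely of missing seconds contributes a zero
  occupancy row; an entirely missing sequence is an error naming the
  patient.
- `tr(HGH) = tr(HG)` (H idempotent) is evaluated as an elementwise product
  sum; permutations act on G's rows and columns jointly, reusing the
  pre-computed full and reduced hat matrices.
- Permutation p-values use the add-one correction, so p ∈ (0, 1] and a
  199-permutation test at α = 0.05 rejects exactly when the observed
  statistic ranks in the top 10 — giving exact 5% size under
  exchangeability.
- Problem sizes in tests (procedure-duration medians of 120–300 s instead
  of the 1800 s pipeline default, cohorts of 20–500) were chosen so the
  statistical property under test is unaffected — occupancy distributions
  are length-invariant — while simulation stays cheap; the dwell-time
  check uses 2500 s medians because interior-run means are censoring-biased
  when dwells are not small relative to the procedure.
- The power experiment couples effect levels by common random numbers:
  inverse-transform geometric dwells from a per-patient reproducible
  uniform stream keep the visited-state path identical across effect
  levels, so only target-state run lengths grow. Effect levels are dwell
  multipliers (1.5, 3, 6) on the apnea state for half the patients.

## Limitations

- The chi-squared normalization convention may differ numerically from
  other software's unstated defaults; comparisons across implementations
  should use the recorded marginal weights in the distance sidecar.
- Drop-one term shares are one of several defensible partitionings
  (sequential/Type-I shares would differ with correlated covariates).
- Greedy Ward agglomeration is not globally optimal; the quality report,
  not the dendrogram alone, should inform the final k.
- The generator's archetypes are far better separated than clinical data
  are likely to be; recovery metrics on synthetic cohorts are upper bounds.
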