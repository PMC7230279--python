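# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Calorimetry reduction

Measured REE comes from the modified Weir formula without the
urinary-nitrogen term, `REE = (3.941·V̇O₂ + 1.106·V̇CO₂)·1440` kcal/day
with gas volumes in L/min. Steady state is the **earliest sliding window**
of at least 5 minutes (on the trace's native timestamps, not point counts)
in which RQ varies by less than 5 % and V̇O₂ and minute ventilation by
less than 10 %. "Variation" is not a standardised term; we use the
coefficient of variation (SD/mean), the common calorimetry convention,
with a range-based alternative ((max−min)/mean) behind
`variation="range"`. Records are excluded when no window qualifies or the
steady-state RQ falls strictly outside [0.67, 1.3] — boundary values are
kept.

## Anthropometry

Upper-arm composition uses the classical circumference/skinfold areas
(Frisancho): TUA = C²/4π, UME = (C − πT)²/4π with the triceps skinfold
converted mm → cm, UFE = TUA − UME, arm fat % = 100·UFE/TUA. These are
taken as the *definition* of the derived variables. Growth z-scores use
the LMS method with linear interpolation of L, M, S between reference
rows; references are pluggable CSVs (`sex,age_months,L,M,S`; for
weight-for-length the key column holds length in cm). WHO status: obese at
z ≥ +2 SDS, wasted at z < −2 SDS (the strict inequality follows the WHO
convention); BMI-for-age classifies from age 5 years (a 5.0-year-old uses
BMI), weight-for-length below it.

## Prediction equations

Coefficients are data, not code: one CSV row per (equation, sex, age
band), transcribed from the published tables with MJ/day forms converted
at 239.006 kcal/MJ. Age bands are half-open [lo, hi), so a 10.0-year-old
falls in the 10–18 band. The Harris–Benedict adult equations are applied
to children unchanged (no pediatric bands exist for it); the WHO and
Oxford equations are used in their weight-only pediatric forms, Schofield
in both its weight-only and weight+height forms — together the five
formulae in common pediatric use. Each band declares its height unit so
the published form survives transcription exactly (Harris–Benedict per cm,
Schofield weight+height per metre).

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. It emulates a mixed healthy pediatric population: n = 561,
ages 2–17 y with mean 13.0 and SD 3.5 (a Beta-shaped density leaning
toward adolescence — no truncated normal admits that spread at that mean
on [2, 17]), 67.5 % boys, 20 % obese and 3 % wasted assigned as exact
counts then shuffled. A BMI z-score is drawn per nutritional category
(obese: 2 + |N(0, 0.35)| capped at 3.6; wasted: −2.01 − |N(0, 0.3)|;
normal: N(1.05, 0.9) truncated to (−2, 2)) and mapped through the
package's **synthetic LMS references** to BMI (age ≥ 5) or
weight-for-length (age < 5), so the WHO classifier recovers the injected
categories by construction. Height follows piecewise-linear sex-specific
growth curves plus N(0, 6) noise; weight = BMI·height²; skinfolds are
log-normal in the z-score; arm circumference is linear in age and z.

Latent REE is a smooth allometric law in a fat-free-mass proxy,

    REE* = 65.5 · (W·(1 − 0.5·fat%/100))^0.75 · (1 + 0.06·male) + 12·age,

deliberately nonlinear in the quantities the equations use linearly, so a
flexible model has genuine headroom. Measured REE adds N(0, 90) kcal/day
of biological noise (which bounds any model's achievable MAE at
≈ 90·√(2/π) ≈ 72 kcal/day), and VO₂/VCO₂ are back-solved through the Weir
relation at an RQ drawn uniformly from [0.71, 0.95] (mean 0.83, SD 0.07) —
Weir applied to a record's gas values returns its measured REE exactly.
All constants were calibrated once at n = 20 000 against the target
marginal profile (age 13.0, weight 62.8 kg, height 156.5 cm, REE
1417.6 kcal/day) and then frozen.

What the generator does **not** emulate: the true multivariate covariance
of a real pediatric population (its correlations are conventions), pubertal
stage, secular trends, or measurement error in anthropometry. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that the qualitative method ranking holds under a plausible nonlinear
generating law — not that the same margins would be observed in a clinical
cohort. A known limitation of the marginal calibration: arm fat % averages
≈ 42 % rather than the 47.8 % a real population table reports, because the
generator's arm-circumference and triceps marginals jointly determine it;
the derived-area identities (TUA = UME + UFE) hold exactly.

The selection benchmark (`generate_selection_benchmark`) is distinct from
the cohort: 13 *independent* columns named like the modelling variables,
of which exactly 7 (age, female, weight, BMI, TUA, UME, arm fat %) drive a
target with linear terms plus a weight×TUA interaction and N(0, 50) noise.
Independence is deliberate — in real anthropometry TUA = UME + UFE makes
"the true subset" ill-defined, whereas here recovery is measurable by
Jaccard overlap.

## Auto Contractive Map

A three-layer contractive network of width N with mono-weights v
(input→hidden) and a full matrix w (hidden→output), all bounded by a
contraction parameter C (default N). Forward pass for a [0,1]-scaled
record m:

    h_s  = m_s (1 − v_s/C)
    Net_j = (1/N) Σ_s h_s (1 − w_sj/C)
    o_j  = h_j (1 − Net_j/C)

with updates Δv_s = α·m_s(1 − v_s/C) and Δw_sj = α·h_s·o_j·(1 − w_sj/C),
α = 0.1, weights initialised to exactly zero, records presented in fixed
order — training is fully deterministic. The mono-weights are the
contraction clock: they absorb the input and squeeze the output to zero,
while w accrues Hebbian co-activation mass before the input is gone, so
co-varying variables end with the largest weights. Normalising Net by the
fan-in makes the output track the contracting hidden layer, which is what
guarantees the mean output activation (the convergence criterion,
tolerance 1e-4) decays monotonically. Published descriptions of this
architecture differ in detail and the original reference is not fully
specified; the rules above are this package's definition, chosen to
satisfy a documented contract — determinism, weights within [0, C],
monotone output decay, correlated pairs bonding more strongly than
independent ones, block-correlated data yielding block-coherent spanning
trees that agree with a correlation-distance oracle — and they are
isolated in one function so a variant transcription can be swapped in.

Variable distances are d_ij = 1 − ((w_ij + w_ji)/2)/C ∈ [0, 1]; the map is
the Kruskal minimum spanning tree with edges inserted in lexicographic
(i, j) order so ties resolve identically on every platform. The central
node is found by recursively deleting degree-1 nodes; if two survive, the
larger summed incident strength wins, then lexicographic order. Note the
min-max scaling keeps each variable's mean offset, so association
strengths compress into a narrow band; the MST uses only their ordering,
which is the robust part.

## TWIST

Each genome is a variable mask plus an A/B label per record. Fitness
trains the MLP on A (masked columns), scores B, repeats in reverse with a
fresh network, and returns −(mean of the two testing MAEs) −
0.5 kcal/day per active variable. The parsimony weight is small enough
never to outweigh a real predictive difference but breaks ties toward
smaller subsets. Degenerate genomes (< 2 variables, a subset below 2
records, or |#A−#B| above 5 % of n) score −∞. The engine is a standard
generational GA: tournament selection k = 2, uniform crossover on both
chromosome parts, bit-flip mutation at 1/L per mask gene, one
count-preserving A↔B label swap per child, elitism 2, population 16,
20 generations by default; fitness values are cached by genome. The
original system's proprietary evolutionary operators are unpublished;
this is a documented approximation. Inside the GA the MLP trains for 200
epochs (the final reported fit uses the full budget); fitness is
deterministic given the run seed, so the whole selection is reproducible.

## MLP and the two-run protocol

One sigmoid hidden layer, default 4 units, sigmoid output; inputs and
target affinely mapped to [0.1, 0.9] with parameters fitted on the
training subset (so predictions are invariant to affine rescaling of raw
units); weights initialised uniformly in ±0.3 from the seed; online
backpropagation with learning rate 0.05 and momentum 0.9, fixed record
order, at most 2000 epochs with early stop when training MSE improves by
less than 1e-7 over 50 epochs. The inner loop is numba-compiled. The
evaluation protocol is strict: the network trained on A is frozen and its
weights handed to a virgin twin that scores B without learning (tested
bit-for-bit); a fresh network (seed+1) trains on B and scores A; metrics
are computed per testing run and averaged field-wise, and the per-record
out-of-sample predictions are kept for curve plots.

## Metrics and reports

MAE, SD of absolute errors, RMSE, NMSE (= MSE / variance of the measured
series; "normalised" admits several conventions and this one is our
documented choice), signed mean error (our interpretation of the loosely
used term "real error"), imprecision % = 100·MAE / mean measured REE **of
the evaluated group** (each subgroup uses its own mean), Pearson r and r²,
Kendall tau-b (tie-corrected), and the two-sided paired t-test. Raw
p-values are always emitted; p < 0.001 is the conventional threshold given
multiple testing. Subgroup panels (overall / obese / wasted / normal)
require n ≥ 3, otherwise they are flagged unavailable rather than
fabricated. The tendency line is a degree-5 least-squares polynomial of a
prediction series against its rank index when ordered by measured REE.

## Pipeline determinism and problem sizes

One global seed drives everything; each stage derives its own seed as
CRC32("seed:stage") (< 2³¹). Reruns with the same configuration are
byte-identical at the artifact level, and chaining the stage functions by
hand reproduces the orchestrator's outputs exactly (tested). Default
problem sizes: the study replica runs at the full n = 561 with a
16×20-genome GA and 2000-epoch final fits (seconds to a few minutes on one
core); unit tests use 80–300-record cohorts and reduced GA budgets, chosen
to exercise every code path at comfortable interactive speed.

## Known limitations

* The synthetic latent law guarantees the ANN-vs-equations ordering only
  under its own nonlinearity; it is a demonstration harness, not evidence
  about any real cohort.
* The Auto-CM transcription is a contract-faithful reconstruction, not a
  replication of the original implementation; absolute edge strengths are
  not comparable to published figures, only their ordering.
* The GA approximates the original evolutionary engine; selected subsets
  on the 13 collinear anthropometric variables are one of several
  near-equivalent optima, since TUA, UME, UFE and arm fat % are
  algebraically redundant with circumference and triceps skinfold.
* Harris–Benedict is extrapolated to children deliberately — that is how
  it is used in pediatric practice, no pediatric bands having been
  published.
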