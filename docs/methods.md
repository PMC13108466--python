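# Methods

## The evaluation design

Each quiz item pairs one embryo with a positive outcome (biochemical
pregnancy or live birth, depending on the clinic's endpoint) with one
negative-outcome embryo from the same clinic, so that clinic-level
differences in imaging and protocol cancel within a pair. Every
selector — each rater, the score-based model, and the majority-vote
committee — answers the same items by picking one embryo per pair; the
positive embryo is, by construction, the correct answer. This turns an
embryo-ranking problem into a sequence of binary decisions whose
per-selector success rate has a direct probabilistic reading.

Assumptions inherited from the design:

- outcomes are unambiguous (single-embryo transfers only), so each
  pair has exactly one correct answer;
- pairs are statistically exchangeable within a clinic; the pairing
  bijection is uniform random with no covariate matching;
- raters answer independently of one another and see only the two
  images, the same information the model receives.

## Accuracy ≡ pairwise AUC

For score-based selection, "pick the higher score, credit ties ½"
applied to every positive × negative combination reproduces the
Mann–Whitney U estimator of P(score⁺ > score⁻), term by term — so quiz
accuracy on the exhaustive pairing *equals* the ROC AUC (asserted to
1e−12 in tests), and on a random one-to-one pairing it is an unbiased
estimate of it. Two numerical consequences are enforced throughout:

- tie credit is always ½, for model score ties and committee vote ties
  alike, because any other convention breaks the identity;
- every score-based statistic is invariant under strictly increasing
  transforms of the score scale (tested); the 0–10 range of exported
  scores is purely cosmetic.

The ROC curve sweeps thresholds over the distinct score values in
descending order; its trapezoidal area equals the Mann–Whitney value
exactly, including tie-induced diagonal segments.

## McNemar comparisons

All selector-vs-selector tests condition on the discordant pairs
(b, c). Three variants are always computed:

- exact conditional binomial: p = min(1, 2·P(Bin(b+c, ½) ≤ min(b, c)))
  — the reported default, safest at small discordance;
- χ²: (b−c)²/(b+c) on 1 df;
- continuity-corrected χ²: (|b−c|−1)²/(b+c), the standard Edwards
  form without clamping (so b = c gives statistic 1/(b+c), not 0,
  matching common library behaviour).

b + c = 0 is degenerate: statistic 0, all p-values 1, flagged.

**Committee ties in testing.** The exact test needs integer counts, but
committee ties carry half-credit. Two policies are implemented, neither
privileged as historically authoritative:

- *randomized* (default): each tie is broken by an independent fair
  coin; the test is recomputed over n seeded replicates (default 999)
  and the median p with an interquartile band is reported. Note that
  coin-broken ties make b and c independent binomials, slightly
  under-dispersing b − c relative to the conditional null, so under a
  true null the exact p concentrates near ~0.67 rather than being
  uniform — conservative, never anti-conservative (verified by
  simulation in the tests).
- *fractional*: each tie contributes 0.5 to both correctness cells via
  product allocation (b = Σ r(1−m), c = Σ (1−r)m with r, m ∈
  {0, ½, 1}); only the χ² variants apply and the exact test is flagged
  unavailable.

**Mean-of-raters comparison.** The per-rater discordant counts vs the
model are averaged (b̄, c̄) and the test applied to the means — the χ²
variants on the raw means, the exact variant on the means rounded to
the nearest integer, flagged as rounded. Per-rater p-values are
reported unadjusted, with a Holm step-down adjustment available.

## Committee and agreement

The committee selector takes the per-pair majority over the raters who
answered that pair; equal votes are recorded as ties (credited ½), and
pairs with zero responses are excluded and listed. Fleiss κ is computed
from its definition, (P̄ − P̄ₑ)/(1 − P̄ₑ) over the two choice
categories, with per-item rater counts so incomplete matrices degrade
gracefully (items with fewer than two responses are dropped). In this
design "which embryo was chosen" and "was the choice correct" induce
the same binary partition — the positive embryo is always the correct
answer — so the two category schemes yield identical κ; both labels are
accepted for interface completeness. If every response falls in one
category, κ is 1 when agreement is perfect and flagged undefined
otherwise.

Pairwise agreement between two selectors is the expected fraction of
commonly answered pairs on which they choose the same embryo, with tie
mass handled as v₁v₂ + (1−v₁)(1−v₂) (the expectation under independent
fair-coin tie breaks). The "agrees-or-better" summary reduces to
1 − P(committee correct ∧ model wrong), which with committee tie value
v and model correctness m is the mean of 1 − v(1−m).

The experience–accuracy association uses Pearson's r on (years,
accuracy), Spearman's ρ on midranks, and R² = r²; zero variance in
either variable is flagged undefined rather than silently reported as
zero correlation.

## The synthetic cohort generator

The generator's role is to produce complete studies with known ground
truth so every stage is testable end to end. Its generative model is
the simplest one producing the observed structure:

- latent quality: q⁺ ~ N(d, 1), q⁻ ~ N(0, 1) per pair;
- model score: q + σₘ·ε, affinely mapped to [0, 10] for file export
  (rank-preserving, hence statistically irrelevant — tested);
- rater r's choice: argmax of q + σᵣ·ε, noise independent per rater
  per embryo; σᵣ is a fixed per-rater trait, so accuracy is stable;
- experience values are assigned independently of σᵣ (mirroring a null
  experience–accuracy association); correlating them is possible by
  constructing the config explicitly.

Closed form: a selector with noise σ is correct with probability
Φ(d / √(2(1+σ²))), inverted by `calibrate_sigma` as
σ = √(d²/(2 Φ⁻¹(target)²) − 1) (round-trip verified to 1e−9; targets at
or above the ceiling Φ(d/√2) are rejected with the ceiling stated).

**Defaults of the study-shaped preset** (`preset: paper`): 1681 pairs —
1237 from the biochemical-endpoint clinics (C: 500, D: 400, F: 337) and
444 from the live-birth clinics (A: 150, B: 150, E: 144); the group
totals are the study dimensions and the within-group split is a fixed
package choice, since only totals are published. d = 1.0 (a realistic
morphology signal leaving all selectors well below ceiling
Φ(1/√2) ≈ 0.76); 20 raters with σᵣ calibrated to accuracies evenly
spread over 0.60–0.69; σₘ calibrated to model accuracy 0.70; experience
evenly spread over 2–37 years and shuffled against skill.

**What the generator does and does not emulate.** It reproduces the
design's dimensions, sub-ceiling heterogeneous accuracies, positive
inter-rater agreement, committee gains over the mean individual, and a
null experience correlation. It does *not* emulate shared perceptual
structure between raters beyond the outcome-linked latent (real raters
also agree on outcome-irrelevant features, e.g. morphological
conventions), so its Fleiss κ at realistic accuracy levels is ~0.15–0.2
rather than the ~0.5–0.6 seen in real reader panels, and its committee
gains are somewhat larger than real panels show. Passing tests
therefore demonstrate correctness of the statistical machinery under a
known generative process, not calibration of agreement levels to any
particular rater population. It also makes no attempt at image-level
effects; clinics exist only as strata.

## Randomness and determinism

Every entry point takes one integer seed. The simulator spawns five
named `numpy` `SeedSequence` children (latents, model noise, rater
noise, display order, experience shuffle); the pair builder derives
pairing and display seeds the same way. Reports serialize with fixed
key order and full float precision, so identical inputs, configuration
and seed give byte-identical files (asserted in tests). Randomized
tie-breaking is itself seeded, so even the resampled committee test is
reproducible.

## Numerical and degenerate-input choices

- Exact binomial p-values are clamped to [0, 1]; b = c yields 1.
- Display-order assignment never enters any statistic (tested by
  flipping it).
- Missing responses are never imputed: each rater is scored on the
  pairs they answered, with per-rater denominators reported; the
  committee and κ use per-item counts.
- Subgroup tables satisfy the pooling identity exactly: the
  pair-count-weighted mean of per-clinic accuracies equals the pooled
  accuracy (asserted to 1e−12).
- Validation errors name the offending identifier or line; the CLI
  maps validation failures to exit code 2 and I/O failures to 3.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to keep Monte Carlo bands
tight at three standard errors while the whole suite stays fast:
parameter recovery at 20,000 pairs per (d, σ) point; type-I control
with 2,000 replicates of 400 pairs; the null-κ band with 20 raters on
5,000 items; committee dominance with 200 replicates of 1,000 pairs and
11 raters; coin-flip calibration bands at 10⁵ draws.

## Known limitations

- The exact McNemar test is conservative at small b + c; no
  mid-p variant is implemented.
- The committee significance test under the randomized policy reports
  a median over tie-break replicates, not a single test; the
  under-dispersion noted above makes it conservative.
- No covariate-matched pairing (age, device, cycle type) and no
  multi-level modelling of clinic effects; clinics are strata only.
- The generator's agreement structure is a single shared latent; it
  cannot reproduce arbitrary κ and accuracy combinations jointly.
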