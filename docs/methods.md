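# Methods

## Study design being modelled

The package reimplements a retrospective cohort analysis of post-operative
complications after clean, minimally invasive surgeries (peripheral lymph
node biopsies and laparoscopic biopsies) in macaques, with two exposures of
interest: perioperative antibiotic prophylaxis and SIV/SHIV infection
status at the time of surgery.  The unit of analysis is the **procedure**:
animals undergo repeated surgeries and each procedure contributes one
Bernoulli outcome (complication / no complication) to its stratum.  No
within-animal clustering correction is applied; repeated procedures are
treated as independent trials, matching the published group sizes, which
count procedures rather than animals.

## Complication identification

Identification is two-stage:

* **Flagging** (screening, high sensitivity).  A procedure flags when any
  of the following hold: a prescription with drug class ANTIBIOTIC, NSAID
  or OPIOID attached to the procedure at a post-operative day offset in the
  closed window [1, 8] (day 0 = surgery day), or an observation period of
  ≥ 9 days.  Day conventions: offsets are calendar-day differences; day 0
  is deliberately excluded so that surgery-day perioperative dosing does
  not flag.  Care events link to procedures only by animal identity and the
  day window, so an event can attach to two procedures of one animal if
  their windows overlap — attachment to both is the conservative choice.
* **Adjudication** (specificity).  An override table, when provided, is
  authoritative; it stands in for the manual records review used on real
  data (e.g. antibiotics prescribed for dermatitis unrelated to the
  surgery are cleared).  Without an override, a flag is confirmed when a
  treatment-class trigger is present, an in-window note matches the
  adverse lexicon, or the flag arose from extended observation.  The
  default lexicon (inappetence, inflammation, swelling, bruising, pain,
  discharge, abscess, suture removal, ulceration, dehiscence) is matched
  as case-insensitive substrings; severity grading ("moderate to severe")
  is not machine-recoverable from notes and is not attempted — any match
  counts, and the lexicon is configurable.

Complication rates are complications ÷ total procedures per stratum,
printed to two decimals.

## Randomization test

The test statistic is the signed difference in proportions
D = x₁/n₁ − x₂/n₂ with group 1 fixed per comparison as the prophylaxis
(resp. infected) stratum.  The null is label exchangeability: the x₁+x₂
complications are re-assigned among the n₁+n₂ procedures preserving group
sizes, B = 50,000 times by default, and

    p = #{ b : D_b ≥ D } / B            (upper tail, ties included).

The one-sided, ties-included convention is forced by the behaviour of the
published values themselves: the infected-vs-uninfected laparoscopy
comparison has a *negative* observed difference and p = 0.995, which is
impossible under a two-sided or absolute-value convention.  The raw
proportion b/B is reported; the (b+1)/(B+1) variant is available via
`add_one=True` for methodological comparison (it cannot return 0).

Because D is strictly increasing in the group-1 count k under fixed
margins, D_b ≥ D reduces to k ≥ x₁ in integer arithmetic; both the sampler
and the oracle use this, so tie handling involves no floating-point
comparison.  Two sampling mechanics are implemented: per-replicate
hypergeometric draws of k (default; vectorized) and a literal shuffle of
the 0/1 outcome vector (audit mode).  They are exactly equivalent in
distribution.  The analytic oracle is the hypergeometric upper tail
P(X ≥ x₁), X ~ HG(n₁+n₂, x₁+x₂, n₁), summed over the support via
`scipy.stats.hypergeom`; the test suite independently verifies it by full
enumeration of label assignments (Fraction arithmetic) on tables with
total ≤ 12.  Monte-Carlo standard error is √(p(1−p)/B) and the suite
checks |p_mc − p_exact| ≤ 4·SE across ≥ 120 seeded runs.

Degenerate tables (x₁+x₂ = 0 or = n₁+n₂) give p = 1: every permuted
difference ties the observed one.  Self-comparisons give D = 0 and, by the
symmetry of the null around zero with ties included, p ≥ ½ (p = 1 only
when the stratum has no complications).

## Count reconstruction

Published tables print (rate %, n) per cell.  `reconstruct_counts` returns
round(rate/100 × n) (half away from zero) and warns when rate × n is more
than 0.1 from an integer.  All 18 printed cells reconstruct unambiguously
and every margin is consistent: 24+25 = 49 PLN complications of 2,230,
3+10 = 13 laparoscopic of 1,399, 12+19 = 31, 12+6 = 18, 2+2 = 4, 1+8 = 9,
and the prophylaxis margins cross-check (12+12 = 24, 19+6 = 25, 2+1 = 3,
2+8 = 10).

## Which published p-values the procedure-level test reproduces

With the reconstructed counts, the exact permutation tail gives (published
value in parentheses): 0.353 (0.341), 0.037 (0.038), 0.381 (0.375), 0.348
(0.249), 0.458 (0.250), 0.995 (0.995), 0.011 (0.011), 0.539 (0.382).  The
three laparoscopy-signal values and the two near-0.38 PLN values agree to
within Monte-Carlo/rounding error; the three mid-range values 0.249, 0.250
and 0.382 do **not**, and no exchangeable permutation of procedure-level
outcomes can produce them (upper/lower/two-sided tails, strict or
tie-included, mid-p, bootstrap nulls and whole-population-margin
permutations were all checked).  The most plausible explanation is that
the original analysis permuted at the animal level — its description says
"proportion of animals" — whose per-group animal counts were not
published.  The package deliberately reports what the procedure-level
tables imply rather than tuning toward the printed values; the
corresponding reproduction tests are left failing with this explanation.
The qualitative conclusion (exactly the two laparoscopy prophylaxis
comparisons significant at α = 0.05) is reproduced either way.

## Synthetic cohort generator

The generator emulates the cohort's statistical structure, not its
clinical content:

* **Strata** — default eight strata at the published sizes (455, 885, 556,
  334 PLN; 39, 822, 44, 494 laparoscopic; total 3,629) and published rates
  (2.64%, 2.15%, 2.16%, 1.80%, 5.13%, 0.24%, 2.27%, 1.62%).  Complications
  are independent Bernoulli(true_rate) per procedure, so stratum totals
  are Binomial.
* **Evidence** — every planted complication materializes through one
  branch chosen uniformly: antibiotic prescription (cefazolin/cephalexin),
  NSAID prescription (meloxicam), each at a uniform day 1–8, or an
  observation period extended to 9–14 days; with probability 0.5 an
  adverse note is added as corroborating (non-essential) evidence.
* **Animals** — 1,056 animals; procedures are assigned uniformly at random
  to animals with free capacity, giving a mean of 3.44 procedures per
  animal (= 3,629/1,056); the true per-animal distribution is unpublished,
  so only the mean is matched.  Demographics reproduce the published
  marginals exactly (1,006 rhesus / 50 cynomolgus; 616 M / 440 F) with
  ages uniform on [0.04, 25.56] years and BCS uniform on [1.5, 5.0].
* **Dates** — surgeries fall on a per-animal 17-day grid inside the study
  window (2018-05-01 to 2021-01-19).  The 17-day spacing (> 2 × the 8-day
  screening window) guarantees that care events never straddle two
  procedures of one animal, so planted evidence attaches only to its own
  procedure and noise-free recovery is exact by construction.  Real data
  do not have this property (same-day paired biopsies and back-to-back
  surgeries occur); passing recovery tests therefore demonstrates the
  pipeline's correctness, not its false-positive rate on overlapping
  real-world schedules.
* **Noise** — procedures without a complication receive an unrelated
  antibiotic prescription with probability 0.02 (paired with an override
  entry that clears it, mirroring manual review) and a benign note with
  probability 0.10.  These rates are the package's own choice of a
  plausible confounder load; the source records' true rates are unknown.

Everything is deterministic given the spec's seed; identical spec+seed
yields byte-identical CSV bundles.

## Calibration

Under equal true rates in both strata (2.1%, n = 200 per stratum, 500
replicate cohorts, B = 2,000) the full pipeline's empirical type-I error
at α = 0.05 is 0.018 — below nominal, as expected for a one-sided test on
a discrete null at small expected counts (≈ 4 per stratum).  Problem sizes
for simulations (replicates, B, per-stratum n) were chosen to make the
Monte-Carlo error small relative to the quantities asserted while keeping
desk-scale runtimes.

## Known limitations

* Procedure-level permutation ignores within-animal correlation; an
  animal-level frailty term is not modelled (generated procedures are
  independent given stratum).
* Adjudication without overrides is purely lexical; no NLP beyond
  substring matching, no severity grading, no wound classification (all
  modelled procedures are clean by design).
* Whether one adverse event spanning two same-animal procedures should
  count once or twice is unspecified in the workflow being modelled; the
  package counts per procedure.
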