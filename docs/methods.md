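# Methods

## The inference chain

The package treats a multigenerational pedigree as a dispersal instrument.
For a hermaphroditic, self-incompatible perennial, each recruit has a seed
(ovule) parent and a pollen donor. Seeds fall by gravity within a few
meters, so the parent nearest to the offspring is interpreted as the seed
parent and the farthest as the pollen donor; an offspring whose pollen donor
sits on a different habitat patch is a between-patch (pollen-mediated)
effective dispersal event. Functional connectivity is the percentage of
such events among all events; effective connectivity asks whether the
migrant-derived recruits themselves reproduce.

## Simulator (`simdata`)

The generator emulates a six-patch coastal system surveyed for ten annual
cohorts.

* **Landscape.** Six disjoint disks placed so barycenter separations span
  ~160–1,650 m and within-patch mean pairwise distances span ~20–95 m
  (for a uniform disk the mean pairwise distance is 128R/45π ≈ 0.905R).
* **Demography.** Founders recruit in year 0; adults survive each year with
  probability 0.5 and reproduce from age 1 to at most 20. Each mother
  recruits Poisson(1.6) offspring per year, so λ = s(1+f) ≈ 1.3 — a tenfold
  rise over ten years, matching the surveyed expansion. An optional
  per-patch carrying capacity subsamples recruits uniformly (used to bound
  replicate experiments; uniform, hence unbiased for dispersal estimates).
  25 founders per patch reproduce the surveyed within-patch gene diversity
  (Hs ≈ 0.67–0.69).
* **Dispersal.** Offspring position = mother position + an isotropic
  exponential displacement (mean 4 m), resampled/clipped into the mother's
  patch — recruits never change patch by seed. The pollen donor is local
  with probability 1 − m (chosen ∝ exp(−d/20 m) among patch-mates,
  excluding the mother) and from another patch with probability m
  (donor patch ∝ 1/barycenter distance, reproducing a distance decay in
  pairwise connectivity). Self-incompatibility is enforced only as
  mother ≠ father; no S-locus is modelled.
* **Markers.** 18 microsatellite loci with allelic richness 3–29; founder
  frequencies are fixed Dirichlet(1) draws (internal seed), giving
  per-locus expected heterozygosity ≈ 1 − 2/(k+1) (0.5–0.93), a panel with
  cumulative parent-pair exclusion > 0.999. Per-allele miscalls (rate
  0.01, replacement drawn by frequency) and per-cell missingness (0.005)
  are applied after transmission.
* **Fitness effect.** `migrant_fecundity_multiplier` scales a
  migrant-derived plant's fecundity as mother *and* its sampling weight as
  pollen donor, so its total offspring rate scales by the multiplier. The
  default is 1 (no effect); the study-like analysis runs use 2.

What the generator does **not** emulate: the real system's much larger
census (~12,500 plants) and shallower sampling of parents, seed dormancy,
pollinator behaviour, spatially heterogeneous survey effort, or allele
mutation. Consequences observed in the output: simulated patches are
*more* differentiated (θST ≈ 0.08–0.11 vs ~0.04 in a large system) because
colonization bottlenecks weigh more at this scale; the assignment rate is
higher (~80% vs ~23%) because nearly every parent is sampled; and the
pedigree collapses into one giant family rather than hundreds of small
ones. Passing tests therefore validate the estimators and their
calibration, not the field system's absolute parameter values.

## QC (`genotype_io`)

Thresholds are strict "less than": loci are kept when their missing
fraction is < 0.05, then individuals are re-evaluated against the surviving
loci and kept when < 0.10. Filtering is idempotent. Duplicate search
compares unordered allele pairs over loci typed in both individuals
(default: zero mismatching loci allowed; a tolerance flag exists) and
reports connected components.

## Population statistics (`popgen`)

* Hexp uses Nei's small-sample factor n/(n−1) with n counted in genes;
  PIC = 1 − Σp² − [(Σp²)² − Σp⁴]; allelic richness is the raw allele count
  (a rarefaction option is deliberately out of scope).
* The parent-pair exclusion probability is derived in closed form: a
  genotype contains allele x with probability u_x = p_x(2 − p_x); a random
  HWE pair can produce offspring {x,y} iff one member carries x and the
  other y, giving
  PPexp = Σ_x p_x²(1 − u_x²) + Σ_{x<y} 2p_xp_y[1 − (2u_xu_y − 4p_x²p_y²)].
  The formula is verified against exhaustive enumeration in the tests.
  Cumulative exclusion over a panel is 1 − Π(1 − P_l).
* HWE: exact conditional test (Levene/Haldane distribution of the
  heterozygote count) for biallelic loci; otherwise a chi-square on
  genotype classes with expected-<5 classes pooled; df = classes − alleles.
* θST follows Weir & Cockerham's per-locus, per-allele variance components
  a (among populations), b (among individuals within populations) and
  c (within individuals), with multilocus θ = Σa/Σ(a+b+c). Per-locus sample
  sizes adapt to missingness. Permutation p-values shuffle whole
  individuals among populations: p = (1 + #{θ* ≥ θ}) / (1 + n_perm),
  n_perm defaulting to 999 (199 in the pipeline for speed). Negative
  estimates are reported as computed. When the pooled HWE pre-filter would
  discard the whole panel (which happens whenever strong structure induces
  a Wahlund heterozygote deficit at large n), θ falls back to the full
  panel with a logged warning rather than failing.
* Per-cohort θST uses individuals whose first sampling year equals the
  cohort year.

## Parentage (`parentage`)

A per-offspring posterior replaces a full MCMC over pedigrees. For each
offspring, candidates are plants first observed strictly before the
offspring's year and no more than 20 years before. Hypotheses are all
unordered candidate pairs plus {candidate, unsampled} and
{unsampled, unsampled}, under a flat prior with the unsampled parent
treated as one pseudo-candidate. Likelihood per locus: each parent
contributes a gamete (½/½ on its alleles; population frequencies when the
parent hypothesis is "unsampled" or the candidate's locus is missing), and
each observed offspring allele equals the transmitted one with probability
1 − e (default e = 0.01), otherwise a random allele by frequency. Loci
missing in the offspring are skipped. Triads are retained when the top
*pair* hypothesis exceeds posterior 0.95.

A bitmask exclusion prefilter removes candidates Mendelian-incompatible at
more than 4 loci before enumeration; over a ≥16-locus informative panel the
pruned hypotheses are many orders of magnitude below the retained ones, so
the normalized posterior is unaffected at the reported precision.

Measured properties (tests): with full parental sampling, ~1.4% of retained
triads are not the true pair (relatives substituting for a parent), safely
under the 2% control. Two systematic behaviours worth knowing:

1. **Relative substitution under incomplete sampling.** When a true parent
   is unsampled, a close relative of it can occasionally clear the 0.95
   bar; the naive expectation "offspring of deleted parents are never
   assigned" holds only when candidates are unrelated.
2. **Retention selection.** Within-patch offspring face more competing
   relative pairs than between-patch offspring, so conservative
   thresholding retains between-patch events slightly preferentially —
   inflating the connectivity estimate by roughly 1.1–1.3× at the
   simulated population scale. The recovery experiments quantify this: the
   exact binomial CI of the estimate still covers the generating m in
   ≥90% of replicates at m ∈ {0.01, 0.03, 0.10}.

## Pedigree summaries (`pedigree`)

Only triads enter the pedigree, so every non-founder has exactly two
parents. Relationship categories are counted once per unordered pair under
the genealogically closest applicable category, in the order
parent–offspring (counted as directed links, two per triad), full sib,
half sib, grandparent–offspring, full avuncular, half avuncular, full
first cousin. Half-sib counting ignores parental role (hermaphrodites).
Families are weakly connected components of the link graph; generation
depth is the longest ancestor chain + 1.

## Connectivity (`connectivity`)

Events require coordinates for all three triad members (excluded triads
are counted). Equidistant parents are tie-broken lexicographically and
logged (probability zero with continuous coordinates). A validation
counter reports events whose *closest* parent is on a different patch,
where the seed-parent-is-local reading would be wrong; these are ≲0.1% in
simulation. Per-patch rates use the patch's offspring-event count as
denominator: inbound = between-patch events recruiting on the patch,
outbound = between-patch events whose pollen donor is on the patch,
total = inbound + outbound, self-recruitment = 100 − inbound. The pairwise
rate for patches (i, j) divides the events linking i and j by the events
*involving* either patch (offspring or pollen donor there); a "located"
reading (offspring-side only) is switchable, since the verbal definition
admits both. Distance decay is a two-sided Spearman test over the 15
unordered patch pairs, ties mid-ranked. Percentages are reported at one
decimal place.

## Demography and fitness (`demofit`)

λ(patch, T) = N_T / N_{T−1} on the census of first-year plants; cells with
N_{T−1} ∈ {0, 1} are undefined, and per-patch medians are taken over
defined cells only. (The growth-rate definition follows "λ > 1 means
expansion"; the reciprocal form sometimes seen in print contradicts that
reading and is not used.)

The fitness comparison takes every triad offspring with cohort year at
most (last survey year − 2) — later recruits' offspring would be censored —
labels it migrant-derived or resident by its own event's between-patch
flag, and counts the retained triads in which it appears as a parent (over
the whole survey). The effect is estimated by NB2 negative-binomial
regression of the count on status with patch fixed effects and
cluster-robust standard errors grouped on the seed parent; the
back-transformed status coefficient is the migrant/resident rate ratio. A
negative-binomial *mixed* model with random intercepts for patch and both
parents would be the fuller specification, but no random-effects NB
implementation exists in the Python scientific stack, and the fixed-effect
model with clustered errors recovers a generating rate ratio of 2 within
[1.5, 2.7] in ≈94% of replicate simulations. At a realistic 3% migration
the migrant group is small (tens of plants), so single-dataset estimates
are noisy even when the replicated calibration is tight. A Poisson
overdispersion statistic (Pearson χ²/df) is always reported alongside the
NB dispersion α.

## Problem sizes and numerical choices

Replicate experiments (recovery, error control) use reduced populations —
10 founders per patch with a 40-plant capacity, ~1,000 plants and ~500
triads per replicate, 50 replicates per condition — chosen to keep a full
replicate near one second while leaving enough events for exact binomial
CIs to be informative. The false-triad control runs at the full default
scale (25 founders, no capacity, ~3,000 plants) because error control
depends on relatedness, which the reduced populations overstate. All
experiment and pipeline randomness descends from a single master seed via
`numpy` `SeedSequence` splitting; equal configs and seeds reproduce results
bit-for-bit, including file outputs. Likelihoods are accumulated in log
space; Mendelian-impossible hypotheses at e = 0 get −∞ and drop out of the
normalization.

## Known limitations

* Dyads (single-parent links) are excluded from the pedigree by design;
  assignment-rate tables still report the one-identified-parent fraction.
* The per-offspring posterior ignores pedigree-level consistency (one
  plant's parentage does not constrain another's); this is exactly the
  approximation that makes the method deterministic and desk-scale, and
  its conservatism is validated on simulated truth rather than proved.
* Connectivity estimates inherit the retention-selection bias described
  above; at very low m this can reach ~1.3× and should be read with the
  replicate calibration, not as an unbiased point estimate.
* The exact HWE test covers biallelic loci only; multiallelic loci use the
  pooled chi-square, which is conservative after heavy pooling.
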