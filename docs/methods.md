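# Methods

This document describes the statistical model behind `hrdscar`, every default
parameter with its rationale, the scope of the synthetic-data generators, and
known limitations.

## 1. Genome model

The built-in genome is a 22-autosome build (hg19 lengths and centromere
intervals); sex chromosomes are excluded because allele-specific copy number
on X/Y is not comparable across sexes. Chromosome arms are the intervals
outside the centromere. Segments are half-open `[start, end)` intervals
carrying an integer allele state `(major_cn, minor_cn)` with
`minor_cn <= major_cn`; profiles may leave parts of the genome uncovered
(panel data) but segments never overlap.

## 2. Scar rules

All three counts operate on a merged profile: same-state neighbours separated
by at most `merge_max_gap = 3 Mb` of uncovered sequence are fused first, so
that panel gaps do not split one biological event into two. Candidate regions
are maximal runs of segments satisfying the state predicate, allowing
internal coverage gaps up to the same 3 Mb.

- **LOH** (`loh_min_len = 15 Mb`, strict inequality): regions with
  `minor_cn = 0` and `major_cn >= 1` longer than 15 Mb, excluding any region
  spanning the chromosome's whole covered extent (whole-chromosome LOH
  reflects aneuploidy, not recombination-deficient repair). Homozygous
  deletions (`0,0`) are not LOH — there is no retained allele.
- **TAI** (`tai_min_len = 11 Mb`): allele-imbalanced regions
  (`major_cn != minor_cn`) of at least 11 Mb that reach exactly one telomere
  and do not overlap the centromere. "Reaching a telomere" means starting
  within `telomere_tolerance = 1 Mb` of the chromosome end, or at the first
  or last covered base when coverage does not extend to the physical end.
  Regions touching both telomeres are whole-chromosome events and excluded.
- **LST** (`lst_min_seg = 10 Mb`, `lst_smooth_len = 3 Mb`): per chromosome
  arm, segments are clipped to the arm, fragments shorter than 3 Mb are
  removed and same-state neighbours re-fused until a fixed point, and every
  state change between two flanking segments of at least 10 Mb with at most
  3 Mb between them counts as one transition. Transitions are never counted
  across the centromere.

`HRD score = LOH + TAI + LST`. Classification cutoffs: 21 (primary) and 30
(stricter). These values are the published clinical choices, not fitted
quantities; they are configuration, never adjusted by the pipeline.

The test suite contains independent brute-force implementations of all three
rules (explicit enumeration of every segment span with maximality checks) and
verifies exact agreement on hundreds of random profiles.

## 3. Tumor/normal mixture model

A specimen of purity `rho` mixes tumor cells at state `(major, minor)` with
diploid normal cells. At a heterozygous SNP:

```
D      = 2 (1 - rho) + rho * (major + minor)
D_psi  = 2 (1 - rho) + rho * psi            # psi = tumor mean ploidy
BAF    = (1 - rho + rho * minor) / D
logR   = gamma * log2(D / D_psi)
```

`gamma` (default 1.0) is the platform logR-compression factor. Because SNP
phase is unknown, BAF is folded about 0.5 everywhere downstream. A `(0,0)`
state at purity 1 has no reads: BAF is NaN and logR `-inf`, and such states
are flagged missing rather than inverted.

## 4. Segmentation

Per chromosome, SNPs are first split into coverage blocks wherever
consecutive positions are more than 3 Mb apart (uncovered panel gaps must
survive as gaps, since the scar rules treat them specially). Each block is
segmented by recursive binary splitting on the joint cost of the
noise-normalized channels `(|BAF - 0.5|, logR)`: a split is accepted only
when it reduces the summed squared error by more than a penalty of
`6 log n` per chromosome (a BIC-style penalty; two channels and one
breakpoint parameter). Minimum segment size is 3 SNPs. Noise scales are
estimated robustly from the median absolute successive difference, which is
insensitive to level shifts.

Per-segment `baf_dev` is bias-corrected as
`sqrt(max(mean((BAF-0.5)^2) - sigma^2, 0))`: the naive mean of folded noise
is inflated on balanced segments, and without the correction balanced
segments at low purity masquerade as imbalanced.

## 5. Purity/ploidy grid fit

The fit inverts the mixture model on a grid (`rho` 0.05–1.00 step 0.01,
`psi` 1.0–5.5 step 0.05) by demanding that the implied real-valued allele
copies per segment fall near nonnegative integers. The raw
distance-to-integer objective is degenerate in four empirically observed
ways, and the selection rule addresses each:

1. **Copy doubling.** Doubling all copies at `psi' = 2 psi` fits exactly at a
   predictable purity (`rho' = rho / (2 - rho)` or `rho' = 2 rho / (1 + rho)`).
   Resolved by ploidy parsimony: candidates within 0.1 of the smallest
   candidate ploidy are preferred.
2. **Ladder shift.** Subtracting one copy from every allele at `psi' = psi - 2`
   also fits exactly, but sends the diploid bulk of the genome to total copy
   zero. Grid cells implying more than 5% of the genome at total copy zero
   are rejected as non-viable tumors.
3. **Near-flat high-purity fit.** At `rho ~ 1` with fractional copies the
   residual is small but the propagated noise floor is tiny; judging the
   residual *relative* to the noise floor (delta-method propagation of the
   SNP-level noise through the inversion, plus a `3e-4` grid-discretization
   slack) removes it.
4. **Trivial low-purity fit.** At very low `rho` noise amplification makes
   every integer reachable; cells whose noise floor exceeds 0.05 (approaching
   the `1/12`-per-allele variance of a uniformly random distance-to-integer)
   are excluded as uninformative.

Among the surviving cells, candidates scoring within `max(2.0, 1.5 x best)`
of the best noise-consistency ratio enter the parsimony step; remaining ties
break by ratio, then toward higher purity, so the result is deterministic.
All thresholds were set from analysis of the degeneracies on held-out
simulations, not tuned against any downstream check.

A profile in which no segment carries signal beyond `z = 4.5` standard errors
of its own noise (minimum 10 SNPs per segment) is *flat*: compatible with
purity 0, reported as `identifiable=False`, and never given copy-number
calls. This is the pipeline's refusal behaviour at 0% tumor content.

Integer states are then called per segment by nearest expected
`(|BAF - 0.5|, logR)` over all states with `minor <= major <= 12`, ties going
to lower total copy then lower major. The mixture model round-trips exactly:
`expected_baf_logr` followed by `call_integer_cn` recovers every state with
total copy at most 8 at purities 0.3, 0.6, and 1.0.

## 6. Synthetic data generators

These stand in for patient data that are not publicly deposited. They are
generators with *known ground truth*, not attempts to model full biological
complexity.

- **Planted profiles** (`simulate_profile`): each requested LOH/TAI/LST event
  is placed on a chromosome arm with a 4 Mb uncovered gap isolating it
  (wider than the 3 Mb continuity limit), so each event contributes exactly
  one scar count and the planted totals are the exact expected scores.
  Infeasible requests (more events than arm space) raise an error before any
  output is produced.
- **SNP emission** (`emit_snps`): uniform positions over the covered genome;
  observed values are the mixture expectations plus independent Gaussian
  noise (`sd_BAF = 0.03`, `sd_logR = 0.10`, a signal-level stand-in for
  ~500x panel sequencing), BAF clipped to [0, 1].
- **Dilution series** (`dilution_series`): 7 purities
  (50/40/30/20/10/5/0%) x 3 replicates by default, the signal-level analogue
  of a DNA dilution experiment. The full pipeline keeps all replicates
  HRD-positive down to 20% purity and refuses to fit at 0%.
- **Cohorts** (`simulate_cohort`): HRD scores are negative-binomial
  (dispersion 1.6 — overdispersed, zeros possible, as observed in real score
  distributions), with the *marginal* median of each clinical group
  calibrated by bisection against the mutation-shift mixture CDF (mutated
  genes add mean shifts; calibrating only the unshifted component would bias
  group medians low). Survival times are exponential with log-hazard
  `log(HR) x 1[score >= cutoff]`; censoring replaces events with uniform
  earlier times.

## 7. Statistical conventions

- Descriptives: medians and quartiles by linear interpolation, sample SD
  (n-1), percentages recomputed from raw counts and displayed to one decimal.
- Group score comparisons: Kruskal-Wallis rank-sum (tie-corrected, chi-square
  approximation); identical samples give (0, 1) by convention.
- Contingency tables: Pearson chi-square **without** continuity correction by
  default — this is the convention that reproduces the published p = 0.019 on
  the 2x2 IDC-P by high-score table; the Yates-corrected variant (~0.030) is
  available by flag.
- Multiple testing: unadjusted p values by default; a Benjamini-Hochberg
  column is an explicitly opt-in extension.
- Survival: Kaplan-Meier product-limit curves (median = smallest time with
  S(t) <= 0.5, "not reached" when never crossed), unweighted log-rank tests,
  Cox proportional-hazards with Efron tie handling (months-resolution times
  tie heavily) and Wald 95% CIs. Separation/monotone-likelihood surfaces as
  an explicit convergence error, never silent output. Endpoints per stratum:
  total and M1 use CRPC-free and overall survival; M0 uses CRPC-free and
  metastasis-free survival (too few deaths among localized patients).

All hypothesis tests are calibration-checked in the test suite: type-I error
within [0.035, 0.065] under null simulation, and Cox CI coverage of a true
hazard ratio of 2 at n = 500.

## 8. Limitations

- The segmentation is a hand-rolled binary-splitting implementation (no
  change-point library is available in the supported environment); it is
  validated on step-recovery and full-pipeline tests but is not tuned for
  exotic noise (waviness, GC bias).
- The grid fit assumes one dominant clone; subclonal copy-number states
  violate the integer assumption and will inflate `fit_error` rather than be
  modelled.
- SNP emission is a signal-level noise model, not a read-level simulator: no
  coverage waviness, allele-specific bias, or mapping artifacts.
- Simulated cohorts reproduce the marginal structure used by the analyses
  (group medians, proportions, hazard ratios) but not correlations beyond
  those explicitly modelled (e.g. mutation co-occurrence).
- The genome model covers autosomes only.
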