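# Methods

## Scope and model

`ctg18` computes everything downstream of a sized electropherogram for
molecular diagnosis of the *TCF4* CTG18.1 trinucleotide repeat expansion
(the dominant genetic risk factor for late-onset Fuchs endothelial corneal
dystrophy), and the case-control statistics used to quantify the
association.  Raw trace processing (size-standard fitting, baseline
subtraction) is the instrument software's job; the package starts from
(size bp, height) peak tables and approximate gel band sizes.

### Fragment-size arithmetic

Both assays are linear in the repeat count *n*:

* STR-PCR product: `L_STR(n) = 114 + 3n` bp.  The offset is the flanking
  sequence amplified together with the repeat tract; it is configurable
  and was fixed from the printed anchor pairs (147 bp ↔ 11 repeats, and
  the 235 bp normal/pathological threshold ↔ 40 repeats under nearest-
  integer rounding).  An offset of 115 satisfies the same two anchors
  under rounding; 114 satisfies 147 ↔ 11 exactly and was preferred.
* TP-PCR ladder rung for an annealing position at triplet *k*:
  `L_TP(k) = 54 + 3k`, `k = 5..n`, because the triplet-primed reverse
  primer anchors five consecutive CTG triplets.  An allele of *n* repeats
  thus yields `n − 4` rungs, from 69 bp up to `54 + 3n` bp.  The offset
  satisfies 69 ↔ 5, 84 ↔ 10, 87 ↔ 11, 99 ↔ 15 exactly and 452 ↔ 133 under
  rounding.

Inversion uses nearest-integer rounding and reports the signed rounding
residual; residuals above 1.5 bp (possible only when a size clamps to the
1-repeat minimum, or when comparing against an externally asserted repeat
count) set a sizing-warning flag.  Published capillary sizes for the same
sample are mutually inconsistent at the 1-2 repeat level across assays
(e.g. one sample printed as 14/17 by STR-PCR and 12/17 by TP-PCR); such
sizes are treated as noisy measurements, never as calibration anchors,
which is why cross-assay adjudication tolerates a 3-repeat gap before
declaring discordance.

An allele is pathological (X) iff it carries **more than 40** triplets
(strict inequality); the equivalent product-size threshold 235 bp is
applied inclusively to gel bands, matching the 40-repeat nominal product
(234 bp) within rounding.

### Peak calling

STR peaks below 5% of the tallest peak are discarded (stutter/noise);
peaks within 1.5 bp merge height-weighted (co-migrating products); more
than two surviving products is a contamination error; zero products is a
*signal* (biallelic dropout), not an error.  TP peaks above the detection
floor are chained into a ladder while successive spacing stays within
3 ± 0.8 bp; one missing rung may be bridged (an analyst reads across an
isolated dropped rung), two consecutive missing rungs end the ladder.
Allele boundaries are detected as intensity step-downs: a rung below 65%
of the median of the trailing five rungs opens a new cluster.  The
trailing-window reference matters: against a whole-cluster median, plain
geometric decay would eventually trip the detector on any long ladder.
Each cluster's repeat count comes from its terminal rung size; the
rung-count estimate is kept as a cross-check and any disagreement is
flagged (the two can differ by one under sizing noise; the last-peak size
wins because counting by eye has no published tie rule).  None of these
thresholds are published; all are config-exposed, and the defaults were
chosen to pass the noise-free and default-noise simulations.

### Genotype adjudication

Two normal STR products → N/N.  One STR product plus a TP ladder past the
cutoff → N/X with the expanded allele right-censored (ladder extent is a
lower bound).  No STR product plus an expanded ladder → X/X, both calls
censored; the lower allele is taken from the last cluster break beyond the
cutoff, since breaks in the normal range of an X/X ladder can only be
intensity noise.  One STR product matched within ±1 repeat by a single TP
cluster → homozygous N/N *candidate*, a distinct class because the lab can
only prove homozygosity by sequencing; downstream statistics count it as
N/N.  Contradictory evidence (a ladder far beyond two normal STR calls; a
normal-only ladder with no STR product at all) raises a discordance error
for manual review instead of guessing.

### Diagnostic workflows

The established protocol runs gel + STR fragment analysis + TP fragment
analysis on every sample.  The proposed protocol runs the gel first and
stops — calling N/N — only when it sees two clearly separated bands, both
within the normal size range; everything else (one band, no band, a band
past 235 bp, bands closer than the trust margin) escalates directly to
TP-PCR fragment analysis, never re-running STR on the capillary.  Gel
resolution is modelled as a configurable merge distance (default 6 bp,
a plausible figure for 4% high-resolution agarose; no value is published,
only that three study samples showed bands in "close proximity").  Because
ambiguity always escalates, the proposed path can only ever add cost on
awkward samples, not change a genotype class; costs are abstract units per
assay.  Sequencing is modelled as a zero-information confirmation step
with a cost.

### Synthetic cohorts

Subjects are drawn per status (case-control sampling, not a liability
model): two haplotypes per subject from the four-haplotype distribution
implied by the per-status risk-allele frequencies and a target D′ (scaling
by the frequency-bound maximum makes any |D′| ≤ 1 feasible).  Defaults are
the study conditions: 36 cases / 58 controls, expanded-allele frequency
0.32 vs 0.03, risk-G frequency 0.40 vs 0.17, D′ 0.76.  Normal alleles are
uniform on 10–35 repeats and expanded alleles uniform on 41–150; the true
distribution of Greek normal alleles is unpublished, so these ranges are
illustrative, not population estimates.

Instrument model: capillary sizing error is dominated by run-to-run
calibration, so each injection gets one shared Gaussian shift (σ = 0.7 bp,
the scale of the reported sizing reproducibility) plus a small independent
per-peak jitter (σ = 0.12 bp) — fully independent 0.7 bp noise per peak
would destroy the 3 bp rung spacing that real instruments preserve.
Expanded alleles (> 40 repeats) drop out of STR-PCR deterministically by
default (in the study no expanded allele ever produced an STR product); a
logistic dropout curve is available.  TP rung *k* has intensity
(alleles spanning *k*) × 1000 × 0.97^(k−5), log-normal height noise
(σ = 0.25), and rungs below the detection floor (20 units) are absent.
The decay/floor/amplitude triple puts the deterministic fade-out at 133
repeats — the deepest ladder reported (452 bp) — and the height-noise σ
was calibrated so the replicate CV of the censored estimate falls in the
reported 3–5% counting-reproducibility band (measured 3.3%).

What the generator does **not** emulate: PCR stutter shoulders, dye-
dependent mobility shifts, baseline drift, off-ladder artifacts, somatic
repeat mosaicism.  Passing tests therefore demonstrate the logic of the
calling and decision rules under a faithful intensity/censoring model, not
robustness to every artifact a real capillary run can produce.

### Association statistics

Loci are analysed as biallelic markers (expansion collapsed to N/X).
The HWE test is the standard exact conditional test (enumerate all
heterozygote counts compatible with the allele counts; sum probabilities
at or below the observed configuration), computed in log-space with
gamma-function factorials.  Inheritance models are logistic regressions of
status on codominant / dominant / recessive / allele-dose codings, with
Wald 95% CIs, likelihood-ratio p-values against the (covariate-only) null
— matching SNPStats behaviour — and AIC = 2k − 2 log L for selection, ties
broken toward fewer parameters.  Without covariates the dominant and
recessive ORs equal the 2×2 cross-product ratios (verified to 1e-6).  The
published ORs are sex/age-adjusted, but per-subject covariates were never
published, so printed-table fits are unadjusted; covariate adjustment is
supported for per-subject (e.g. simulated) data.  Contrasts with a zero
cell report NA with a one-sided CI flag rather than a Haldane-corrected
estimate, mirroring the published tables.

Haplotype frequencies come from the standard two-locus EM (only double
heterozygotes are phase-ambiguous; convergence at 1e-10 frequency change
or 10^4 iterations), with D′ normalised by the sign-dependent maximum and
r = D/√(p_A p_a p_B p_b).  The haplotype case-control OR contrasts the
double-risk haplotype frequency between statuses and is flagged unstable
whenever any haplotype frequency falls below one chromosome's worth.
Chi-square power uses the noncentral χ²(df, λ = N·w²) distribution; note
that at N ≈ 94 the exact multinomial rejection rate can differ from this
asymptotic value by a few percent depending on the alternative's
direction, so the formula is validated against simulation in the
local-alternative regime.

## Problem sizes in the test suite

The suite exercises law-of-large-number checks at n = 5×10^4–10^5
subjects (genotype level only — assay simulation is not needed for allele
frequencies), full-pipeline parameter recovery at 40 replicates of
250/250 subjects, censoring calibration at 150 replicate traces, and the
EM grid oracle on a 0.01-step simplex (≈ 1.8×10^5 grid points,
vectorised).  These sizes keep the whole suite around half a minute while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Allele-level repeat counts for merged gel bands are approximate (the
  class is still exact); only fragment analysis resolves 1-repeat
  differences.
* The censored X/X lower-allele estimate inherits cluster-boundary noise
  and can be attributed a rung count beyond the true lower allele; only
  the terminal (largest) censored estimate carries the truncation
  guarantee.
* Dominant-truth model selection by AIC concedes to the codominant coding
  at the asymptotic P(χ²₁ > 2) ≈ 16% rate; that is a property of AIC, not
  a defect of the fit.
* The power figure printed for the study (59%) is not reproducible from
  the standard noncentral-χ² formula with any obvious (df, N) choice; the
  power routine is generic and makes no attempt to match it.
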