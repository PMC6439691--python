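# Methods

`chipcall` is a desk-scale reimplementation of a clinical sequencing
analysis: detecting clonal hematopoiesis of indeterminate potential (CHIP)
from UMI-tagged, dual-set amplicon sequencing of blood/bone-marrow DNA, and
associating driver-gene clones with survival in a chronic-heart-failure
cohort.  Because no patient-level data are public, every stage is paired
with a calibrated simulator so the whole pipeline is testable end to end
against known truth.

## The assay model

Each targeted region is covered by two independent primer sets (`CAT_A`,
`CAT_B`).  Every original DNA molecule carries a 6-bp unique molecular
identifier (UMI); PCR then produces a random number of duplicate reads per
molecule.  The simulator draws:

- **molecules per amplicon** — `depth_per_set` (default 630, the observed
  UMI-collapsed median depth);
- **duplicates per molecule** — geometric with mean `duplicate_mean`
  (default 6.8, the observed raw/consensus depth ratio 4282/630);
- **UMIs** — uniform over a pool of `umi_pool_size` tags (default the full
  4^6 = 4096 six-mer space), with per-read single-base corruption at rate
  0.01 to exercise UMI error handling;
- **alternate molecules** — Binomial(molecules, true VAF) per spiked
  variant; somatic clones have true VAF in (0, 0.45), germline
  heterozygotes are drawn essentially balanced (uniform on
  [0.497, 0.503]);
- **sequencing errors** — independent substitutions per read base at
  `error_rate` (default 1e-3), base quality constant Q30, mapping quality
  60.

### What the simulator does not model

Indels, strand bias, primer-specific artifacts, alignment ambiguity (reads
are emitted pre-assigned to their amplicon on 400-bp synthetic contigs),
GC-dependent depth variation, and germline allelic imbalance beyond ±0.003.
Passing tests therefore demonstrate that the *pipeline logic* recovers
truth under its stated error model, not that the thresholds are optimal for
any particular instrument.

## UMI grouping and consensus

Reads sharing (amplicon, contig, start) are grouped by UMI.  Two policies
are implemented:

- **exact** (`max_edit=0`, the pipeline default): families are exact
  (UMI, coordinate) groups;
- **directional** (`max_edit=1`): within a coordinate bucket, a UMI is
  absorbed into a higher-count UMI at Hamming distance ≤ 1 when
  `count_child ≤ count_parent/2 + 1`, seeds visited by (count descending,
  lexicographic) so the partition is order-independent.

The default is exact because a 6-bp UMI space **saturates** at this assay's
depth: with ~630 molecules per amplicon drawn from 4096 tags, each true UMI
has ~2.8 one-substitution neighbours that are themselves true molecules,
and any count-ratio rule then absorbs roughly half of the real families
(measured: 630 molecules → ~274 directional families vs ~587 exact).
Under exact grouping, birthday collisions (−7%) and corruption-induced
singletons (+7%) nearly cancel, and the simulated raw→consensus contraction
reproduces the observed 4282×→630× ratio within a few percent.  Directional
clustering remains available (and tested) for low-density data, which is
the regime it was designed for.

Consensus is per-position majority base with per-position maximum quality.
A position with no unique majority (e.g. a 1-1 split in a two-read family)
is ambiguous and becomes `N` at quality 0, so it can never vote in the
pileup; without this, raw errors passing through small families measurably
inflate the cross-patient recurrence of error alleles.  Families smaller
than `min_family_size` (default 1, i.e. no size filter) are dropped.

## Calling and filtering

Pileups count consensus reads per allele, separately per amplicon set,
excluding bases below Q20 and reads below mapping quality 20 (threshold
comparisons are "≥ keep").  Calling is permissive: every non-reference
allele with ≥ 2 supporting consensus reads becomes a candidate, with
VAF = alt / (ref + alt) and no frequency floor.

The cascade then applies, in fixed order, stamping the first failing rule:

1. `POP_MAF` — population MAF ≥ 5% in any of 1000 Genomes/EVS/ExAC
   (packaged synthetic stand-in tables; absent ⇒ MAF 0);
2. `MQ20` — mean mapping quality < 20;
3. `RECUR8` — the same variant in ≥ 8% of the cohort's patients
   (distinct patients, counted on pre-VAF-window candidates; ties at
   exactly 8% fail);
4. `DUALSET`/`SETGAP` — either set's depth < 100 consensus reads, or
   alternate support below the calling minimum (2) in either set;
   `SETGAP` marks sites the panel covers with only one set;
5. `DBSNP` — flagged common (≥1%) in dbSNP;
6. `EFFECT` — predicted effect LOW or MODIFIER;
7. `VAFWIN` — VAF below the floor (0.02 by default; 0.005 for the
   clone-size analysis) or inside the closed germline band [0.45, 0.55].

Removal counts plus survivors always equal the input count, the cascade is
idempotent on its own survivors, and lowering the floor never removes a
survivor.  The rule order is a package choice (the audit trail makes it
reproducible); the result set is order-independent, the audit counts are
not.

## Patient classification

A patient is a CHIP carrier when ≥ 1 call survives at the active floor.
Clone size is the maximum VAF over DNMT3A/TET2 calls, banded as
(0.005, 0.01), [0.01, 0.02), [0.02, ∞) — boundary values 0.01 and 0.02
belong to the upper band ("at least").  Under the all-heterozygous
assumption a clone at VAF v occupies 2v of nucleated cells (defined for
v ≤ 0.5).  Printed percentages use exact rational arithmetic with half-up
rounding.

## Survival statistics

- **Kaplan-Meier** product-limit estimator with Greenwood variance; events
  precede censorings at tied times.
- **Log-rank** k-sample test: observed minus expected over hypergeometric
  variance at each distinct event time.
- **Cox proportional hazards** by Newton-Raphson on the partial
  likelihood, Efron tie correction by default and Breslow behind a flag
  (they coincide without ties, which is tested).  Convergence is gradient
  max-norm < 1e-9 or a vanishing Newton step — the gradient is a sum over
  events, so its attainable precision scales with |log-likelihood| and the
  absolute gradient criterion alone is unreachable for large cohorts.
  Step-halving keeps the likelihood non-decreasing; a coefficient passing
  |β| > 20 (HR ~ 5×10^8) is diagnosed as monotone likelihood / complete
  separation.  Confidence intervals are Wald, exp(β ± 1.96 SE).
- **Stepwise Cox**: forward selection, entry at Wald p < 0.05, no removal,
  with a likelihood-ratio entry log.  NT-proBNP enters per 1000 pg/mL;
  prognostic scores enter as tertile indicators (lowest tertile
  reference).
- **Group comparisons**: one-way ANOVA for continuous variables; Pearson
  chi-square (no continuity correction) for categorical, with Fisher's
  exact test for 2×2 tables under Cochran's conditions (any expected cell
  < 5 or n < 40).  Pearson correlation via the t transform.

The composite endpoint is death or heart-failure rehospitalization,
whichever occurs first.

## Cohort simulator

Ages are truncated normal (mean 64, SD 10.7, clipped to [40, 90]).  CHIP
carriage is Bernoulli per age decade (defaults 5%/10%/20.9%/26.6%/30% for
the 40s through 80s; the three middle values are the observed prevalences,
the ends are extrapolations).  Death times are exponential with hazard
0.06/yr × HR^carrier (default carrier HR 2.1); rehospitalization is an
independent exponential at 0.03/yr scaled by the same ratio; censoring is
exponential at 0.10/yr truncated at 6 years, which gives ~27% observed
mortality and a median follow-up near 4.4 years.  Carrier clone sizes are
log-uniform on [0.02, 0.23]; in dose-response mode carriers are assigned a
clone-size band with band-specific hazard ratios instead.

## Reproduction studies and problem sizes

`chipcall.experiments` holds the calibrated studies that
`scripts/acceptance.py` and the acceptance tests run:

- **Cox recovery** — 200 cohorts of 200 patients at true HR 2.1; reports
  mean recovered HR, 95% CI coverage, and the fraction of estimates within
  3 SE of truth.
- **Log-rank type-I error** — 200 cohorts at HR 1; rejection rate at
  α = 0.05.
- **Dose-response** — 30 cohorts of 2000 patients with band HRs
  (1, 1.5, 2, 3); success means monotone 5-year KM ordering across the
  four bands plus a significant Cox trend on the band score.  The cohort
  size is chosen so each band holds ~200 patients, enough that the
  pairwise KM gaps (~0.10 in 5-year survival) are resolved.
- **Filter truth recovery** — 50 patients on a 16-gene dual-set panel
  (a desk-scale stand-in for the real 56-gene/594-amplicon design; a
  4-gene panel has so few targetable sites that spiked clones from
  different patients collide and trip the recurrence rule, an artifact of
  panel narrowness rather than of the method), 3 clones/patient at true
  VAF uniform [0.02, 0.25], one private balanced germline het per patient
  at 800 molecules/set, plus a fixed-site artifact in 20% of patients.
  Reports cascade sensitivity for qualifying clones, germline survivors
  (expected 0), and whether the artifact is removed exactly by the
  recurrence rule.
- **UMI collapse calibration** — 100 amplicons at 630 molecules and
  duplicate mean 6.8; reports median raw and consensus depth and their
  ratio.
- **Marrow/blood correlation** — 23 paired clone VAFs with Gaussian
  measurement noise (SD 0.042, calibrated so Pearson r ≈ 0.8), averaged
  over 100 replicates.

## Known limitations

Substitutions only (no indels, though real CHIP drivers include
frameshifts); no realignment or base-quality recalibration; annotation
tables are packaged synthetic stand-ins, not live database queries; the
COSMIC/ClinVar literature-curation step of variant validation is manual
and out of scope; hazard ratios from any single simulated cohort carry the
usual sampling noise and the package makes no claim to reproduce
patient-level estimates that depend on unavailable data.
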