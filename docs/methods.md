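# Methods

This note documents the models and procedures implemented in `poipanel`,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate about real data.

## Ovarian age and eligibility

OvAge is a fixed linear model of AMH (ng/ml), FSH (mU/L), antral follicle
count, flow index and vascular index, with AMH×AFC and FSH×AFC interaction
terms, returning an "ovarian age" in years. The coefficients (intercept
48.05; −3.14 AMH; +0.07 FSH; −0.77 AFC; −0.11 FI; +0.25 VI; +0.10 AMH·AFC;
+0.02 FSH·AFC) were fitted upstream by a generalized linear model on a
large reference database and are treated as constants; refitting is out of
scope. VFI is carried in the patient profile but does not enter the
equation. Units are trusted as given; no conversion is attempted.

Eligibility follows the comparison symbols of the recruitment rules
literally: case thresholds are strict (FSH > 40, E2 < 20, AMH < 1,
OvAge − age > 10), the control band is inclusive (|OvAge − age| ≤ 2), so
the two arms are provably disjoint. Any exclusion condition (pregnancy,
endometriosis, chemotherapy, ...) makes a profile ineligible for either
arm. Disease onset before age 40 is a recruitment-time criterion applied
upstream of this computation, so it is surfaced as an informational flag
rather than a hard gate.

## Variant filter cascade

Stages run in a pinned order — per-call QC, control subtraction,
population-frequency filter — because the per-stage counts (though not the
final retained set) depend on the order, and reports should be
reproducible. Thresholds: coverage ≥ 200 and quality ≥ 30 per call
(inclusive); run-level QC fails below 200,000 reads, 200× mean depth or 90%
uniformity (strict <, so boundary runs pass).

Population allele frequencies are stored as **percentages** throughout.
This is the only reading consistent with the packaged tables: retained
rare variants carry values such as 0.07048, which would violate the 1%
filter if read as fractions (7%) but are consistent with retention — and
with their assigned PM2 codes — when read as 0.07048%. A variant is
excluded when either frequency source exceeds 1% (configurable to require
both); a variant reported in neither source is retained, absence from the
population databases being itself evidence of rarity.

Control subtraction uses exact (gene, aa_change) key identity; no fuzzy
matching is attempted because the matching granularity of the original
pipeline is unspecified and protein-level keys are what the tables print.
A variant table carrying no coverage/quality columns at all is treated as
upstream-QC'd (the published tables are post-QC); missing values in present
columns still fail per variant.

## ACMG evidence combination

The engine implements the standard combining table over unmodulated codes
(PVS1; PS1–PS4; PM1–PM6; PP1–PP5; BA1; BS1–BS4; BP1–BP7):

- Pathogenic: PVS1 with (≥1 PS | ≥2 PM | 1 PM + 1 PP | ≥2 PP); or ≥2 PS;
  or 1 PS with (≥3 PM | 2 PM + ≥2 PP | 1 PM + ≥4 PP).
- Likely pathogenic: PVS1 + 1 PM; 1 PS + 1–2 PM; 1 PS + ≥2 PP; ≥3 PM;
  2 PM + ≥2 PP; 1 PM + ≥4 PP.
- Benign: BA1 or ≥2 BS. Likely benign: 1 BS + 1 BP, or ≥2 BP.
- Otherwise VUS.

Parsing is forgiving by design: duplicate codes are collapsed to one with a
warning (treating a duplicated PM2 as two independent moderate criteria
would flip a curated VUS to LP, so collapse is the only defensible
reading), and tokens outside the closed vocabulary (e.g. a bare "PM") are
dropped with a warning rather than repaired — repair would be inventive and
the downstream class is unchanged either way for the cases observed.

Conflict policies:

- `strict` (default for new data): contradictory evidence yields VUS. The
  contradiction test is side-aware — a benign-side rule firing while any
  pathogenic-side code is present (or vice versa) is a conflict. Under this
  mode the classification is monotone: adding a pathogenic-side code never
  moves the output toward benign, and symmetrically (property-tested).
- `paper_concordant`: benign-side rules are evaluated first and dominate
  co-occurring pathogenic codes. Curated call sets sometimes let strong
  benign population evidence (BS1 plus supporting BP codes) overrule
  residual pathogenic-side annotations; this mode reproduces that
  behaviour. Per-variant overrides are applied last and always logged; the
  shipped list has exactly one entry (CDKN1B P117S → VUS, a variant whose
  PS3+PM2 codes combine to LP but whose curated call was VUS — an explicit
  override records that outcome instead of inventing a PS3-discount rule).

Heuristic evidence assignment from predictor scores (PP3/BP4 by strict
majority of SIFT ≤ 0.05, PolyPhen ≥ 0.85, CADD ≥ 20, MutationTaster = D;
PM2 from rarity; PM4/PVS1 from variant anatomy) exists for synthetic
cohorts only and never overwrites curated criteria strings. Clinical-grade
assignment of segregation/functional/de-novo criteria is a non-goal.

## CNV calling

The coverage model: each sample is scaled to unit total; the baseline is
the per-amplicon median over ≥2 controls; per-amplicon ratios are divided
by the median ratio of their GC bin (bin width 0.05 in GC fraction; bins
with fewer than 5 amplicons are merged into the nearest populated bin) and
log2-transformed. Bin-median scaling was chosen over curve fitting because
it is deterministic, robust and directly testable; an imposed linear GC
bias is removed to within |median| < 0.02 per bin in simulation.

MAPD — the median absolute difference of genome-adjacent amplicon log2
ratios, computed within chromosomes only — gates calling at < 0.4. For
i.i.d. Gaussian ratios with scale s, MAPD = s·√2·Φ⁻¹(0.75) ≈ 0.954·s; the
per-sample emission scale is estimated by the conventional inversion
σ = MAPD/1.349 (floored at 1e-3 for degenerate noiseless input).

Ploidy is decoded by Viterbi over integer states {0,1,2,3,4} with Gaussian
emissions centred on log2(k/2) (k = 0 floored at a pseudo-copy of 0.05 to
keep the mean finite), stay probability 1 − 1e-4, off-diagonal mass
uniform, uniform start. This is the simplest model consistent with
predicting integer ploidy from normalized amplicon coverage; the original
instrument pipeline's HMM is proprietary and its forms unpublished.
Same-state runs merge into segments spanning first-amplicon start to
last-amplicon end, so segments partition the amplicon sequence; neutral
segments are emitted but marked.

Confidence is the summed log10 likelihood ratio of the called state
against diploid. The published significance threshold (> 10) is therefore
read as "ten orders of magnitude"; the exact formula behind the original
score is unpublished, so this is the package's own convention, documented
here. Focal means length < 3 Mb (strict).

Structural-variant pathogenicity banding uses the X-CNV MVP score — the
only predictor with published numeric band boundaries: [0.46, 0.76] likely
pathogenic, [0.16, 0.46) uncertain, [0.14, 0.16) likely benign. Lower
bounds are inclusive, upper bounds exclusive, except the pathogenic band is
closed at 0.76. Scores outside all bands are reported as `out_of_band`
rather than extrapolated. StrVCTVRE and CADD-SV are carried and reported
but never override the band; none of the three predictors is recomputed.

qPCR validation support is the comparative-Ct method: relative quantity
2^(−ΔΔCt) normalized to a reference gene (typically GAPDH) and a
calibrator sample, with a two-sample t-test on per-replicate ΔCt values
for group comparisons.

## Synthetic-data generator

The generator emulates the study conditions: 100 cases and 200 controls by
default, a 72-gene panel (the 41 genes of the packaged variant tables, the
CNV-only gene INHBB, and 30 further recurrently implicated genes with
deterministic pseudo-loci, since the source tables print protein-level
changes only), and 21 amplicons per gene (~1500 amplicons total).

Hormone marginals are not published, so truncated lognormal/uniform shapes
are used and eligibility is enforced by rejection sampling against the
OvAge equation (error after 10⁴ draws per patient). Nothing downstream
depends on the marginals beyond the eligibility predicates.

Variant plant rates derive from the published cohort marginals via the
Poisson identity: P(≥1 variant) = 0.60 gives a total rate
λ = −ln(0.4) ≈ 0.916, split as λ_pathogenic ≈ 0.261 (so P(≥1 LP/P) = 0.23)
and λ_VUS ≈ 0.655; the same Poisson predicts a monogenic share of 0.611
among mutated patients versus the published 37/60 = 0.617, with no
additional tuning. Planted classes: rare case-only (frequency absent with
probability 0.7, matching the missingness pattern of the source tables,
else lognormal below 1%), shared-with-controls (added to the control key
set), and common (frequency 1.5–15%). Criteria strings are drawn per class
so that the planted class determines the combined classification.

Coverage noise is multiplicative lognormal with natural-log sdlog σ
(default 0.1) on a per-amplicon efficiency (lognormal, sdlog 0.3, shared
across samples) times a linear GC factor 1 + c·(gc − 0.5) (default
c = 0.5). Under this model the log2-ratio scale is σ/ln 2 ≈ 1.443σ, so the
expected MAPD of a diploid sample is 0.954 × 1.443σ ≈ 1.376σ (slightly
higher once baseline sampling noise from 20 controls is included);
simulations at σ = 0.1 land within a few percent of 1.349σ. CNV plants are
specified in bp coordinates with a ploidy and a carrier fraction, and every
plant is recorded in a truth sidecar.

What the synthetic tests show: that the cascade, classifier and CNV caller
recover known truth under the stated noise model (e.g. a planted
20-amplicon single-copy loss in a 200-amplicon panel at σ = 0.1 is
recovered with breakpoints within ±1 amplicon in ≥ 90% of seeds). What
they do not show: robustness to real amplicon dropout, pool imbalance,
mappability artifacts, batch effects, or linkage structure — none of which
the generator models. Read-level simulation (FASTQ/BAM) is a non-goal.

## Numerical and interface conventions

- Coordinates are 0-based half-open internally (BED-style); VCF positions
  are shifted by −1 on ingestion; human-readable reports are 1-based
  inclusive.
- Missing values are explicit (`None`/NaN; "NA", "na" or "." on disk) and
  never silently zero.
- Variant identity is (gene, aa_change); genomic coordinates are optional.
- The test and acceptance simulations use scaled-down problem sizes
  (4 genes × 50 amplicons, 20 coverage controls, cohorts of 6–100) chosen
  to exercise every code path with comfortable statistical margins.

## Known limitations

- The full-cohort diagnostic yield (60% mutated / 23% LP-P / 37% VUS-only)
  is validated on synthetic cohorts matching the published marginals within
  binomial sampling error: the patient-to-variant map of the source study
  is published only for its 37 monogenic patients, whose roll-up is
  validated exactly.
- Gene functional-class summaries require a user-supplied gene→class
  mapping and are not computed by default.
- The VCF subset supported is SNV+indel (no breakends or symbolic ALTs);
  liftover and live annotation retrieval are out of scope.
- The abstract-level count of "42 genes affected" versus 41 genes in the
  variant tables is reported as two separate numbers (41 SNV genes; INHBB
  adds a CNV-only gene); the package does not guess a reconciliation.
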