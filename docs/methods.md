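# Methods

## Problem setting

The pipeline emulates a germline predisposition screen of an unselected
plasma cell dyscrasia cohort (multiple myeloma, smouldering myeloma,
MGUS, plasma cell leukaemia): exome-derived germline variant calls from
~128 patients are reduced to rare, candidate-gene, protein-impacting
variants; classified on the five-tier ACMG/AMP scale; and the fraction of
carrier patients is compared against large population reference subsets
(a global non-cancer exome collection, n = 118 477, and its Finnish
stratum, n = 10 816, which controls for founder-population clustering of
rare alleles).

## Filtering cascade

Steps run in fixed order — genotype quality, panel membership, rarity,
coding impact — each logging input/surviving counts and removed variant
ids, so the report telescopes exactly. Panel, rarity and impact are pure
per-record predicates and therefore commute (property-tested); quality
runs first because it edits carrier sets rather than records.

Defaults, all config-overridable:

| parameter | default | rationale |
|---|---|---|
| max MAF, global subset | 1e-3 | conventional "rare" cutoff for dominant predisposition alleles |
| max MAF, subpopulation | 1e-3 | applied per subset independently; a variant must be rare everywhere |
| allowed impacts | missense, nonsense, frameshift, splice site, start lost, in-frame indel | canonical protein-impacting classes; synonymous/other excluded |
| min depth (DP) | 10 | usual short-read germline QC floor |
| min genotype quality (GQ) | 20 | ditto |
| het allele balance | [0.25, 0.75] | flags likely artefacts / mosaic or somatic contamination |

The concrete QC thresholds of the original screen are not public; these
stand-ins were chosen once such that every variant of the curated fixture
survives the cascade, and are documented as defaults rather than facts.
Rarity is allele frequency AC/AN (reference MAF semantics), not carrier
frequency; a variant absent from a subset counts as frequency 0 and is
flagged "unobserved" (the convention that reference browsers print as
N/A). AN = 0 for a listed variant is treated as unobserved with a
warning. Quality filtering is a warning no-op when the source carries no
genotype metrics (the TSV dialect), by design: curated fixtures are
already quality-controlled.

## ACMG/AMP combination engine

Evidence codes arrive as inputs (criteria assignment — e.g. deriving
PM2 from frequencies — is deliberately out of scope; curated tables
supply codes directly). Codes map to (direction, default strength);
strength overrides are supported but unused by default. The combining
rules are held as an ordered clause table (pathogenic clauses before
likely-pathogenic, benign before likely-benign, stronger evidence first);
`classify` reports the first satisfied clause as `matched_rule` and
`explain` returns the full trace. If both a pathogenic-side and a
benign-side clause are satisfied the result is VUS with a conflict flag.

PP5/BP6 (reputable-source assertions) are accepted by default because
published variant tables use them heavily; `allow_reputable_source=False`
drops them before combining, reflecting later guidance deprecating them.

The engine is verified two ways: exhaustively against an independently
written brute-force evaluation of the published rule table on **all**
criteria subsets of size ≤ 4 (24 158 sets), and against the 13 curated
fixture rows. Eleven rows reproduce the printed tier exactly. Two rows'
printed criteria do not satisfy any standard clause for their printed
tier (one splice-acceptor variant printed P with PM1+PM2+PP3+PP5, which
combines to LP; one missense variant printed LP with PM2+PP3+PP5, which
combines to VUS). The source's exact combining procedure for these rows
is unknown; the fixture ships them verbatim with a `known_discrepancy`
flag and the engine is **not** bent to match them. The same fixture also
preserves a printed impact-label inconsistency (a splice-acceptor HGVS
labelled "Missense") verbatim.

Because of those two rows the fixture offers two classified views:
`fixture_table1_classified` attaches the curated tiers verbatim (used for
carrier summaries of the published table), while `classify_table` applies
the engine (used everywhere else, including the end-to-end screen).

## Carrier-burden statistics

The counting unit is the carrier individual, matching how screens report
("12/128 patients"), not the allele. Reference carriers are approximated
as AC − nHom, exact for ultra-rare variants where almost all carriers are
heterozygous; for gene/panel scopes member-variant carriers are summed
(an upper bound — genotype-level co-carriage in the reference is
unobservable). Cohort-side gene/panel scopes count a patient once.

* Odds ratio: cross-product ad/bc; 95% CI by Woolf's log-OR normal
  approximation with z = 1.96. Any zero cell → OR and CI reported as
  N/A (published-table convention); an opt-in Haldane–Anscombe +0.5
  correction exists for exploratory use. Exact conditional
  maximum-likelihood intervals are out of scope in this version.
* Significance: two-sided Fisher exact test by minimum-likelihood
  summation (all margin-fixed tables with point probability ≤ observed),
  delegated to `scipy.stats.fisher_exact` and verified against a direct
  hypergeometric enumeration oracle in the tests.
* Multiple testing: raw p by default (as screens of this size report);
  Benjamini–Hochberg q-values optional, computed within scope via
  statsmodels.

Calibration (recomputed by `scripts/acceptance.py` and the test suite):
Woolf 95% CI empirical coverage at true OR ∈ {1, 2, 5} with expected
cell counts ≥ 5 lies in [0.92, 0.97] over 2000 replicates per OR;
type-I error at α = 0.05 under the null replicate stream is within
[0.03, 0.07] over 1000 replicates; the median OR estimate over 200
replicates at generative OR 3 (cohort 200, reference 20 000) falls in
[2, 4.5]. These replicate sizes keep the full calibration under a few
seconds on one CPU while leaving the binomial noise on each rate well
inside its acceptance band.

## Cohort summaries

Percentages are rounded half-up to one decimal (so 12/128 → 9.4,
27/128 → 21.1), matching how such tables are printed, rather than
banker's rounding. The dominant stratum counts unique patients with ≥1
P/LP variant in a dominant panel gene; the inclusive stratum adds
heterozygous carriers of recessive panel genes (homozygotes are not
"heterozygous carriers" and are excluded from that extension). Onset
medians use age at diagnosis of the plasma-cell dyscrasia; carriers
lacking an age are excluded with a warning, and callers can merge onset
ages of carriers outside the phenotype table (the fixture's fourth
telomere-gene carrier comes from an auxiliary case series; the onset age
is not printed in the source and is taken as the maximum of the printed
range 50–77, labelled inferred in the manifest). Co-segregation
summaries partition a family's affected members by tested genotype for
one variant; untyped pedigrees count everyone untested, with a warning.

## Synthetic cohorts

`simulate_cohort` defaults encode the study conditions: 128 patients,
two reference subsets sized 118 477 and 10 816, planted P/LP variants
giving exactly 12 dominant-gene carriers and 15 further recessive-gene
heterozygotes (so the two strata are 12/128 = 9.4% and 27/128 = 21.1%),
and 100 background variants with MAF drawn log-uniformly from
[1e-4, 0.2]. Planted carriers are assigned to globally distinct random
patients, heterozygous, as in a screen of unrelated adults. Background
carriage is Hardy–Weinberg (carrier probability 2p(1−p)+p², homozygous
with conditional probability p²); reference AC is Binomial(AN, MAF) per
subset, with an optional Finnish-enrichment multiplier to emulate
founder clustering. Background variants sit in non-panel filler genes by
default (they exercise the panel filter); a switch places them in panel
genes to exercise the rarity filter instead. Everything is reproducible
from the seed, and the manifest records every planted fact, so any count
the pipeline reports on a bundle is derivable from the manifest alone.

What the generator does **not** emulate: linkage disequilibrium,
relatedness within the cohort, sequencing error, genotype-likelihood
uncertainty, or realistic site spectra. Passing tests on synthetic
bundles therefore demonstrate the pipeline's bookkeeping and statistics,
not robustness to real-data artefacts.

Genomic coordinates in the curated fixture are synthetic placeholders
(the source prints HGVS only); the chromosome is the gene's true
chromosome and positions are stable, so variant ids are deterministic
join keys but not real genome coordinates.

## Known limitations

* Published reference odds ratios cannot be reproduced: they depend on
  unprinted, version-dependent reference genotype counts. The package
  demonstrates the machinery on synthetic references with known
  generative OR instead.
* X-linked dosage, phasing, structural variants and genotype likelihoods
  are out of scope; ploidy is fixed diploid autosomal.
* Variant normalisation trims shared prefix/suffix bases only; full
  left-alignment against a reference genome is not performed.
* HGVS strings are carried as opaque annotations, never parsed.
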