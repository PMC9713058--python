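# germscreen

A pipeline for germline cancer-predisposition screening in patient
cohorts, built around the analysis of rare pathogenic variants in plasma
cell dyscrasia (multiple myeloma and related conditions). It is aimed at
analysts who have cohort-level germline variant calls and want to answer
three questions:

1. **Which variants qualify?** A multistep filtering cascade reduces all
   cohort variants to rare (reference MAF ≤ 10⁻³ in every configured
   population subset), candidate-panel, protein-impacting calls, with a
   per-step audit trail.
2. **Are they pathogenic?** An ACMG/AMP 2015 evidence-combination engine
   turns per-variant criteria sets (PVS1, PS1–4, PM1–6, PP1–5, BA1,
   BS1–4, BP1–7) into the five-tier classification with a full rule
   trace. Contradictory evidence resolves to VUS with a conflict flag.
3. **Are carriers enriched?** Carrier-based 2×2 association against
   population reference allele-count tables (AC/AN/nHom per subset, as
   published by gnomAD-style resources): odds ratio OR = ad/bc with a
   Woolf confidence interval exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), and a
   two-sided Fisher exact p-value, at variant, gene and panel scope.
   Reference carriers are approximated as AC − nHom; a zero cell reports
   the OR as N/A (with an optional Haldane–Anscombe +0.5 mode).

Cohort reporting follows screening conventions: unique-patient carrier
counts by inheritance mode (dominant genes; optionally including
heterozygous carriers of recessive genes), per-gene recurrence (≥2
patients hit), onset-age medians, and pedigree co-segregation summaries.

The package also ships a synthetic-cohort generator (`synthetic_data`)
that emits fully self-contained bundles — VCF + TSV variant calls,
phenotypes, pedigrees, reference count tables, criteria, and a
ground-truth manifest — plus a curated 13-row fixture transcribed from a
published table of dominant-gene P/LP findings in a 128-patient cohort.

## Worked example

```python
from germscreen import fixture_table1, fixture_table1_classified, build_report

bundle = fixture_table1()                       # curated 13-row fixture, n=128
classified = fixture_table1_classified(bundle)  # rows with their curated tiers
report = build_report(
    classified, bundle.panel, bundle.phenotypes, cohort_n=bundle.cohort_n,
    pedigrees=bundle.pedigrees,
    extra_onset_ages={"POT1": [bundle.manifest["pot1_external_carrier"]["age"]]},
)
print(report.to_text())
```

prints

```
cohort n = 128
dominant-gene P/LP carriers: 12 (9.4%)
incl. recessive-gene heterozygotes: 12 (9.4%)
recurrently hit genes (>=2 patients): CHEK2 (5), POT1 (3), BRCA2 (2)
...
POT1 onset: median 60.5 (range 50.0-77.0, n=4)
family 2 / 7:124508000:G:A: 2 affected carriers, 0 affected non-carriers, 1 affected untested
family 3 / 7:124510000:T:A: 1 affected carriers, 1 affected non-carriers, 0 affected untested
```

12 of 128 patients (9.4%) carry a pathogenic or likely pathogenic
variant in a dominant panel gene; the recurrent CHEK2 frameshift
accounts for 5 carriers (3.9%) and POT1 for 3 (2.3%). The POT1 carriers'
median onset is 60.5 years (range 50–77, including one carrier from an
auxiliary case series). In family 3 the affected father does not carry
the index's POT1 variant (he shares only the CHEK2 variant) — the
co-segregation line makes that visible.

The same analysis runs from the shell:

```
germscreen simulate --table1 --out bundle/
germscreen summarize --variants bundle/variants.tsv --criteria bundle/criteria.tsv \
    --panel bundle/panel.tsv --phenotypes bundle/phenotypes.tsv \
    --ref-counts bundle/ref_counts.tsv --ped bundle/pedigrees.ped --out out/
```

`germscreen simulate` (without `--table1`) draws a synthetic cohort
instead; `filter`, `classify` and `burden` expose the individual stages.

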