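"""Cohort-level reporting and the end-to-end screen orchestrator.

Summaries follow the reporting conventions of germline predisposition
screens: carrier *individuals* are the unit (a patient with several
qualifying variants counts once per stratum, but contributes to each
gene's count), percentages are rounded half-up to one decimal, and the
recurrence screen lists genes hit in at least ``min_patients`` distinct
patients — the usual criterion for nominating a novel predisposition
gene.
"""

from __future__ import annotations

import json
import statistics
import warnings
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .acmg import ClassifiedVariant, classify_table
from .burden_stats import AssociationResult, Scope, associate, results_to_tsv
from .filtering import FilterConfig, FilterReport, run_cascade
from .io_formats import (
    Inheritance,
    PanelGene,
    PatientPhenotype,
    PedigreeGraph,
    ValidationError,
    Zygosity,
    read_panel,
    read_phenotypes,
    read_pedigree,
    read_reference_counts,
    read_variant_table,
)

__all__ = [
    "CohortReport",
    "InheritanceSummary",
    "CosegregationSummary",
    "ScreenConfig",
    "ScreenResult",
    "carrier_frequency",
    "summarize_by_inheritance",
    "recurrent_gene_screen",
    "median_onset",
    "cosegregation_summary",
    "build_report",
    "run_screen",
]


def carrier_frequency(carrier_count: int, cohort_n: int) -> float:
    """Carrier percentage, rounded half-up to one decimal (e.g. 12/128 -> 9.4)."""
    if cohort_n <= 0:
        raise ValidationError("cohort_n must be positive")
    if not 0 <= carrier_count <= cohort_n:
        raise ValidationError(
            f"carrier_count {carrier_count} outside [0, {cohort_n}]"
        )
    percent = Decimal(100 * carrier_count) / Decimal(cohort_n)
    return float(percent.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class InheritanceSummary:
    cohort_n: int
    carriers_ad: int
    percent_ad: float
    carriers_ad_plus_ar_het: int
    percent_ad_plus_ar_het: float


def summarize_by_inheritance(
    classified_records: Sequence[ClassifiedVariant],
    panel: Iterable[PanelGene],
    cohort_n: int,
) -> InheritanceSummary:
    """Unique-patient carrier counts for the dominant-gene stratum and for
    the dominant-plus-recessive-heterozygous stratum."""
    inheritance = {entry.gene: entry.inheritance for entry in panel}
    ad_carriers: set[str] = set()
    ar_het_carriers: set[str] = set()
    for cv in classified_records:
        if not cv.classification.is_plp:
            continue
        gene = cv.record.gene
        if gene not in inheritance:
            raise ValidationError(f"gene {gene} missing from panel")
        if inheritance[gene] is Inheritance.AD:
            ad_carriers |= cv.record.carrier_ids
        elif inheritance[gene] is Inheritance.AR:
            ar_het_carriers |= {
                pid
                for pid, zyg in cv.record.carriers.items()
                if zyg is Zygosity.HET
            }
    combined = ad_carriers | ar_het_carriers
    return InheritanceSummary(
        cohort_n=cohort_n,
        carriers_ad=len(ad_carriers),
        percent_ad=carrier_frequency(len(ad_carriers), cohort_n),
        carriers_ad_plus_ar_het=len(combined),
        percent_ad_plus_ar_het=carrier_frequency(len(combined), cohort_n),
    )


def recurrent_gene_screen(
    classified_records: Sequence[ClassifiedVariant], min_patients: int = 2
) -> list[tuple[str, int]]:
    """Genes carrying P/LP variants in >= min_patients distinct patients,
    descending by patient count (alphabetical tie-break)."""
    carriers_by_gene: dict[str, set[str]] = {}
    for cv in classified_records:
        if cv.classification.is_plp:
            carriers_by_gene.setdefault(cv.record.gene, set()).update(
                cv.record.carrier_ids
            )
    hits = [
        (gene, len(patients))
        for gene, patients in carriers_by_gene.items()
        if len(patients) >= min_patients
    ]
    return sorted(hits, key=lambda item: (-item[1], item[0]))


def median_onset(ages: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Median onset age with (min, max) range; mean of middle two for even n."""
    if not ages:
        raise ValidationError("no onset ages supplied")
    return float(statistics.median(ages)), (float(min(ages)), float(max(ages)))


@dataclass
class CosegregationSummary:
    family_id: str
    variant_id: str
    tested_affected: int
    affected_carriers: int
    affected_noncarriers: int
    untested_affected: int


def cosegregation_summary(
    pedigree: PedigreeGraph, variant_id: str
) -> CosegregationSummary:
    """Partition a family's affected members by tested genotype for one
    variant.  A pedigree with no genotype data for the variant counts all
    affected members as untested (with a warning)."""
    affected = pedigree.affected_members()
    if not affected:
        raise ValidationError(f"family {pedigree.family_id} has no affected member")
    if not any(variant_id in m.genotypes for m in pedigree.members.values()):
        warnings.warn(
            f"family {pedigree.family_id}: no tested genotypes for {variant_id}",
            stacklevel=2,
        )
    carriers = noncarriers = untested = 0
    for member in affected:
        status = member.genotypes.get(variant_id)
        if status == "carrier":
            carriers += 1
        elif status == "noncarrier":
            noncarriers += 1
        else:
            untested += 1
    return CosegregationSummary(
        family_id=pedigree.family_id,
        variant_id=variant_id,
        tested_affected=carriers + noncarriers,
        affected_carriers=carriers,
        affected_noncarriers=noncarriers,
        untested_affected=untested,
    )


@dataclass
class CohortReport:
    cohort_n: int
    inheritance: InheritanceSummary
    per_gene_carriers: dict[str, int]
    recurrent_genes: list[tuple[str, int]]
    onset_by_gene: dict[str, dict]
    cosegregation: list[CosegregationSummary] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cohort_n": self.cohort_n,
            "inheritance": asdict(self.inheritance),
            "per_gene_carriers": dict(sorted(self.per_gene_carriers.items())),
            "recurrent_genes": [list(item) for item in self.recurrent_genes],
            "onset_by_gene": self.onset_by_gene,
            "cosegregation": [asdict(c) for c in self.cosegregation],
        }

    def to_text(self) -> str:
        inh = self.inheritance
        lines = [
            f"cohort n = {self.cohort_n}",
            f"dominant-gene P/LP carriers: {inh.carriers_ad} ({inh.percent_ad}%)",
            "incl. recessive-gene heterozygotes: "
            f"{inh.carriers_ad_plus_ar_het} ({inh.percent_ad_plus_ar_het}%)",
            "recurrently hit genes (>=2 patients): "
            + (
                ", ".join(f"{g} ({n})" for g, n in self.recurrent_genes)
                or "none"
            ),
        ]
        for gene in sorted(self.onset_by_gene):
            onset = self.onset_by_gene[gene]
            lines.append(
                f"{gene} onset: median {onset['median']} "
                f"(range {onset['min']}-{onset['max']}, n={onset['n']})"
            )
        for c in self.cosegregation:
            lines.append(
                f"family {c.family_id} / {c.variant_id}: "
                f"{c.affected_carriers} affected carriers, "
                f"{c.affected_noncarriers} affected non-carriers, "
                f"{c.untested_affected} affected untested"
            )
        return "\n".join(lines) + "\n"


def build_report(
    classified_records: Sequence[ClassifiedVariant],
    panel: Iterable[PanelGene],
    phenotypes: Sequence[PatientPhenotype],
    cohort_n: int | None = None,
    pedigrees: Sequence[PedigreeGraph] = (),
    min_patients: int = 2,
    extra_onset_ages: Mapping[str, Sequence[float]] | None = None,
) -> CohortReport:
    """Assemble the cohort report from classified records.

    ``extra_onset_ages`` lets callers merge onset ages of carriers outside
    the phenotype table (e.g. carriers found in an auxiliary case series).
    Carriers lacking an onset age are excluded from medians with a warning.
    """
    panel = list(panel)
    cohort_n = cohort_n if cohort_n is not None else len(phenotypes)
    age_by_patient = {p.patient_id: p.age_at_diagnosis for p in phenotypes}

    plp = [cv for cv in classified_records if cv.classification.is_plp]
    per_gene: dict[str, set[str]] = {}
    for cv in plp:
        per_gene.setdefault(cv.record.gene, set()).update(cv.record.carrier_ids)

    onset_by_gene: dict[str, dict] = {}
    for gene, patients in sorted(per_gene.items()):
        ages = []
        for pid in sorted(patients):
            age = age_by_patient.get(pid)
            if age is None:
                warnings.warn(
                    f"carrier {pid} lacks age_at_diagnosis; excluded from "
                    f"{gene} onset summary",
                    stacklevel=2,
                )
            else:
                ages.append(age)
        if extra_onset_ages and gene in extra_onset_ages:
            ages.extend(extra_onset_ages[gene])
        if ages:
            med, (lo, hi) = median_onset(ages)
            onset_by_gene[gene] = {"median": med, "min": lo, "max": hi, "n": len(ages)}

    coseg = []
    plp_ids = {cv.record.variant_id for cv in plp}
    for pedigree in pedigrees:
        tested_ids = set()
        for member in pedigree.members.values():
            tested_ids.update(member.genotypes)
        for vid in sorted(tested_ids & plp_ids):
            coseg.append(cosegregation_summary(pedigree, vid))

    return CohortReport(
        cohort_n=cohort_n,
        inheritance=summarize_by_inheritance(plp, panel, cohort_n),
        per_gene_carriers={g: len(p) for g, p in per_gene.items()},
        recurrent_genes=recurrent_gene_screen(plp, min_patients),
        onset_by_gene=onset_by_gene,
        cosegregation=coseg,
    )


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class ScreenConfig:
    variants_path: str
    variants_format: str  # "vcf" | "tsv"
    panel_path: str
    phenotypes_path: str
    ref_counts_path: str
    criteria_path: str
    ped_path: str | None = None
    out_dir: str | None = None
    cohort_n: int | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    screen_mode: bool = True
    scopes: tuple[str, ...] = ("variant", "gene", "panel")
    min_patients: int = 2


@dataclass
class ScreenResult:
    report: CohortReport
    filter_report: FilterReport
    classified: list[ClassifiedVariant]
    associations: list[AssociationResult]


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"screen stage {name!r} failed: {exc}") from exc

    return _StageContext()


def run_screen(config: ScreenConfig) -> ScreenResult:
    """Run the whole screen: read inputs, filter, classify, associate,
    summarize; optionally write every stage output under ``out_dir``.

    Deterministic given the same inputs: outputs are stably sorted and
    carry no timestamps, so re-runs are byte-identical.
    """
    from .synthetic_data import read_criteria

    with _stage("read_inputs"):
        records = read_variant_table(config.variants_path, config.variants_format)
        panel = read_panel(config.panel_path)
        phenotypes = read_phenotypes(config.phenotypes_path)
        reference_tables = read_reference_counts(config.ref_counts_path)
        criteria = read_criteria(config.criteria_path)
        pedigrees = read_pedigree(config.ped_path) if config.ped_path else []
    cohort_n = config.cohort_n if config.cohort_n is not None else len(phenotypes)

    with _stage("filter"):
        survivors, filter_report = run_cascade(
            records, panel, reference_tables, config.filter_config
        )

    with _stage("classify"):
        missing = [r.variant_id for r in survivors if r.variant_id not in criteria]
        if missing:
            raise ValidationError(f"no criteria for variants: {missing}")
        classified = classify_table(
            [(rec, criteria[rec.variant_id]) for rec in survivors],
            screen_mode=config.screen_mode,
        )

    with _stage("associate"):
        associations = associate(
            classified,
            panel,
            reference_tables,
            scopes=[Scope(s) for s in config.scopes],
            cohort_n=cohort_n,
        )

    with _stage("summarize"):
        report = build_report(
            classified,
            panel,
            phenotypes,
            cohort_n=cohort_n,
            pedigrees=pedigrees,
            min_patients=config.min_patients,
        )

    if config.out_dir is not None:
        with _stage("write_outputs"):
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / "filter_report.tsv").write_text(
                filter_report.to_tsv(), encoding="utf-8"
            )
            (out / "classified.tsv").write_text(
                _classified_to_tsv(classified), encoding="utf-8"
            )
            (out / "associations.tsv").write_text(
                results_to_tsv(associations), encoding="utf-8"
            )
            (out / "cohort_report.json").write_text(
                json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            (out / "cohort_report.txt").write_text(
                report.to_text(), encoding="utf-8"
            )

    return ScreenResult(report, filter_report, classified, associations)


def _classified_to_tsv(classified: Sequence[ClassifiedVariant]) -> str:
    lines = ["variant_id\tgene\timpact\tcriteria\ttier\tmatched_rule\tcarriers"]
    for cv in sorted(classified, key=lambda cv: cv.record.variant_id):
        lines.append(
            "\t".join(
                [
                    cv.record.variant_id,
                    cv.record.gene,
                    cv.record.coding_impact.value,
                    ",".join(sorted(cv.criteria.codes())),
                    cv.classification.tier.value,
                    cv.classification.matched_rule,
                    ",".join(sorted(cv.record.carrier_ids)),
                ]
            )
        )
    return "\n".join(lines) + "\n"
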