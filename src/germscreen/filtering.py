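"""Multistep candidate-variant filtering with a per-step audit trail.

The cascade reduces all cohort variants to rare, panel-gene,
protein-impacting candidates in a fixed order:

1. genotype quality (per-carrier depth / genotype quality / allele balance,
   available only when the source is a VCF with those FORMAT fields);
2. panel membership (annotates surviving records with inheritance mode);
3. rarity against every configured reference subset (allele frequency
   AC/AN; a variant absent from a subset counts as frequency zero);
4. coding impact (protein-impacting classes only).

Every step logs input count, surviving count and the removed variant ids,
so the report telescopes exactly.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import (
    CodingImpact,
    GenotypeMetrics,
    PanelGene,
    ReferenceCountTable,
    VariantRecord,
    Zygosity,
)

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterReport",
    "apply_quality_filter",
    "apply_panel_filter",
    "apply_rarity_filter",
    "apply_impact_filter",
    "run_cascade",
]

DEFAULT_IMPACTS = frozenset(
    {
        CodingImpact.MISSENSE,
        CodingImpact.NONSENSE,
        CodingImpact.FRAMESHIFT,
        CodingImpact.SPLICE_SITE,
        CodingImpact.START_LOST,
        CodingImpact.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the cascade; all overridable, defaults documented
    in the methods note as stand-ins chosen so curated pathogenic variants
    at reference frequency <= 1e-3 survive."""

    max_global_maf: float = 0.001
    max_subpop_maf: float = 0.001
    allowed_impacts: frozenset[CodingImpact] = DEFAULT_IMPACTS
    min_depth: int = 10
    min_gq: int = 20
    het_ab_range: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        for name in ("max_global_maf", "max_subpop_maf"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        low, high = self.het_ab_range
        if not (0 <= low < high <= 1):
            raise ValueError(f"het_ab_range must satisfy 0 <= low < high <= 1")


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_out: int
    removed: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, before: list[VariantRecord], after: list[VariantRecord]):
        surviving = {r.variant_id for r in after}
        removed = sorted(r.variant_id for r in before if r.variant_id not in surviving)
        self.steps.append(FilterStep(name, len(before), len(after), removed))

    def to_tsv(self) -> str:
        lines = ["step\tn_in\tn_out\tremoved_variant_ids"]
        for s in self.steps:
            lines.append(f"{s.name}\t{s.n_in}\t{s.n_out}\t{','.join(s.removed)}")
        return "\n".join(lines) + "\n"


MetricsMap = Mapping[tuple[str, str], GenotypeMetrics]


def apply_quality_filter(
    records: Iterable[VariantRecord],
    genotype_metrics: MetricsMap | None,
    config: FilterConfig,
) -> list[VariantRecord]:
    """Drop carriers whose genotype fails DP/GQ/allele-balance thresholds;
    drop records left with no carriers.

    Permissive by design: with no metrics available (e.g. a TSV source
    without FORMAT fields) the step is a warning no-op, and a carrier with
    a missing metric passes that check.
    """
    records = [copy.deepcopy(r) for r in records]
    if genotype_metrics is None:
        if records:
            warnings.warn(
                "no genotype metrics available; quality filter is a no-op",
                stacklevel=2,
            )
        return records
    out: list[VariantRecord] = []
    ab_low, ab_high = config.het_ab_range
    for rec in records:
        keep: dict[str, Zygosity] = {}
        for patient_id, zyg in rec.carriers.items():
            m = genotype_metrics.get((rec.variant_id, patient_id))
            if m is None:
                keep[patient_id] = zyg
                continue
            if m.dp is not None and m.dp < config.min_depth:
                continue
            if m.gq is not None and m.gq < config.min_gq:
                continue
            if zyg is Zygosity.HET and m.ab is not None and not (
                ab_low <= m.ab <= ab_high
            ):
                continue
            keep[patient_id] = zyg
        rec.carriers = keep
        if keep:
            out.append(rec)
    return out


def apply_panel_filter(
    records: Iterable[VariantRecord], panel: Iterable[PanelGene]
) -> list[VariantRecord]:
    """Keep records in panel genes, annotating each with inheritance mode."""
    by_gene = {entry.gene: entry for entry in panel}
    if not by_gene:
        raise ValueError("panel is empty")
    out = []
    for rec in records:
        entry = by_gene.get(rec.gene)
        if entry is None:
            continue
        rec = copy.deepcopy(rec)
        rec.inheritance = entry.inheritance
        out.append(rec)
    return out


def apply_rarity_filter(
    records: Iterable[VariantRecord],
    reference_tables: Mapping[str, ReferenceCountTable],
    config: FilterConfig,
) -> list[VariantRecord]:
    """Keep records rare in EVERY configured reference subset.

    Rarity is allele frequency AC/AN (reference MAF semantics), not cohort
    carrier frequency.  An unobserved variant has frequency zero and always
    survives; so does a listed variant with AN=0 (warned, treated as
    unobserved).
    """
    thresholds = {
        name: (
            config.max_subpop_maf
            if name.lower() not in ("global", "noncancer_global")
            else config.max_global_maf
        )
        for name in reference_tables
    }
    out = []
    for rec in records:
        if all(
            reference_tables[name].maf(rec.variant_id) <= thresholds[name]
            for name in reference_tables
        ):
            out.append(rec)
    return out


def apply_impact_filter(
    records: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    return [r for r in records if r.coding_impact in config.allowed_impacts]


def run_cascade(
    records: Iterable[VariantRecord],
    panel: Iterable[PanelGene],
    reference_tables: Mapping[str, ReferenceCountTable],
    config: FilterConfig | None = None,
    genotype_metrics: MetricsMap | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run quality -> panel -> rarity -> impact; return survivors + report."""
    config = config or FilterConfig()
    report = FilterReport()
    current = list(records)

    with warnings.catch_warnings():
        if genotype_metrics is None:
            warnings.simplefilter("ignore")  # no-op warning already documented
        after = apply_quality_filter(current, genotype_metrics, config)
    report.add("quality", current, after)
    current = after

    after = apply_panel_filter(current, panel)
    report.add("panel", current, after)
    current = after

    after = apply_rarity_filter(current, reference_tables, config)
    report.add("rarity", current, after)
    current = after

    after = apply_impact_filter(current, config)
    report.add("impact", current, after)

    return after, report
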