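"""Carrier-burden association of a cohort against reference populations.

Each comparison is a 2x2 carrier table

    =============  ========  ============
                   carriers  non-carriers
    cohort         a         b
    reference      c         d
    =============  ========  ============

where the counting unit is the individual, not the allele: reference
carriers are approximated as AC - nHom (allele count minus homozygotes),
which is exact for ultra-rare variants where AC is essentially the number
of heterozygous carriers.  The odds ratio is the cross-product ad/bc with
a Woolf (log-OR normal approximation) 95% interval; significance is the
two-sided Fisher exact test.  When any cell is zero the OR and CI are
reported as not available, matching the reporting convention of published
variant tables, unless the Haldane-Anscombe +0.5 continuity correction is
switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .acmg import ClassifiedVariant
from .io_formats import PanelGene, ReferenceCountTable, ValidationError

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "Scope",
    "build_table",
    "odds_ratio_woolf",
    "fisher_exact_p",
    "associate",
    "bh_adjust",
]


class Scope(str, Enum):
    VARIANT = "variant"
    GENE = "gene"
    PANEL = "panel"


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # cohort carriers
    b: int  # cohort non-carriers
    c: int  # reference carriers
    d: int  # reference non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative cell in {self}")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationResult:
    scope: Scope
    unit: str  # variant_id, gene symbol, or "panel"
    subset_name: str
    table: ContingencyTable
    or_estimate: float | None
    ci95: tuple[float, float] | None
    p_value: float
    q_value: float | None = None
    method: str = "woolf_ci+fisher_exact"
    flags: list[str] = field(default_factory=list)


def build_table(
    carrier_count: int,
    cohort_n: int,
    reference: ReferenceCountTable,
    variant_ids: Sequence[str],
) -> ContingencyTable:
    """2x2 carrier table for a set of variants against one reference subset.

    Reference carriers for each variant are AC - nHom; for multi-variant
    scopes (gene, panel) they are summed over member variants, an upper
    bound that is tight for ultra-rare variants (reference genotype-level
    carrier lists are not published, so co-carriage cannot be resolved).
    """
    if cohort_n <= 0:
        raise ValidationError("cohort_n must be positive")
    if not 0 <= carrier_count <= cohort_n:
        raise ValidationError(
            f"carrier_count {carrier_count} outside [0, {cohort_n}]"
        )
    c = sum(reference.lookup(vid).n_carriers for vid in variant_ids)
    if c > reference.n_individuals:
        raise ValidationError(
            f"reference carriers {c} exceed subset size {reference.n_individuals}"
        )
    return ContingencyTable(
        a=carrier_count,
        b=cohort_n - carrier_count,
        c=c,
        d=reference.n_individuals - c,
    )


def odds_ratio_woolf(
    table: ContingencyTable, continuity_correction: bool = False
) -> tuple[float | None, tuple[float, float] | None]:
    """Cross-product odds ratio with Woolf 95% CI.

    OR = ad/(bc); CI = exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
    Any zero cell makes both undefined (returned as None) unless the
    Haldane-Anscombe correction (+0.5 to every cell) is enabled.
    """
    a, b, c, d = (float(x) for x in table.cells)
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            return None, None
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_estimate)
    ci = (math.exp(log_or - 1.96 * se), math.exp(log_or + 1.96 * se))
    return or_estimate, ci


def fisher_exact_p(table: ContingencyTable, sidedness: str = "two_sided") -> float:
    """Exact hypergeometric p for a 2x2 table.

    Two-sided by minimum-likelihood summation: all tables with the same
    margins whose point probability does not exceed the observed one.
    """
    alternative = {
        "two_sided": "two-sided",
        "greater": "greater",
        "less": "less",
    }[sidedness]
    arr = [[table.a, table.b], [table.c, table.d]]
    return float(stats.fisher_exact(arr, alternative=alternative)[1])


def _unique_carriers(variants: Iterable[ClassifiedVariant]) -> set[str]:
    carriers: set[str] = set()
    for cv in variants:
        carriers |= cv.record.carrier_ids
    return carriers


def associate(
    classified_records: Sequence[ClassifiedVariant],
    panel: Iterable[PanelGene],
    reference_tables: Mapping[str, ReferenceCountTable],
    scopes: Sequence[Scope | str] = (Scope.VARIANT, Scope.GENE, Scope.PANEL),
    cohort_n: int | None = None,
    plp_only: bool = True,
    continuity_correction: bool = False,
) -> list[AssociationResult]:
    """One association per (scope unit x reference subset).

    Gene and panel scope count each patient once ("carrier of >=1
    qualifying variant in scope").  ``cohort_n`` defaults to the number of
    distinct patients seen across records, but should normally be the full
    cohort size since non-carriers carry no variant rows.
    """
    scopes = [Scope(s) for s in scopes]
    records = [
        cv for cv in classified_records if cv.classification.is_plp or not plp_only
    ]
    if cohort_n is None:
        cohort_n = len(_unique_carriers(classified_records)) or 1
    panel_genes = {entry.gene for entry in panel}

    units: list[tuple[Scope, str, list[ClassifiedVariant]]] = []
    if Scope.VARIANT in scopes:
        for cv in records:
            units.append((Scope.VARIANT, cv.record.variant_id, [cv]))
    if Scope.GENE in scopes:
        by_gene: dict[str, list[ClassifiedVariant]] = {}
        for cv in records:
            by_gene.setdefault(cv.record.gene, []).append(cv)
        for gene in sorted(by_gene):
            units.append((Scope.GENE, gene, by_gene[gene]))
    if Scope.PANEL in scopes:
        in_panel = [cv for cv in records if cv.record.gene in panel_genes]
        units.append((Scope.PANEL, "panel", in_panel))

    results = []
    for scope, unit, members in units:
        variant_ids = [cv.record.variant_id for cv in members]
        carrier_count = len(_unique_carriers(members))
        for subset_name in sorted(reference_tables):
            reference = reference_tables[subset_name]
            table = build_table(carrier_count, cohort_n, reference, variant_ids)
            flags = []
            if any(
                not reference.lookup(vid).observed for vid in variant_ids
            ):
                flags.append("reference_unobserved")
            or_est, ci = odds_ratio_woolf(table, continuity_correction)
            if or_est is None:
                flags.append("zero_cell")
            p = fisher_exact_p(table)
            results.append(
                AssociationResult(
                    scope=scope,
                    unit=unit,
                    subset_name=subset_name,
                    table=table,
                    or_estimate=or_est,
                    ci95=ci,
                    p_value=p,
                    flags=flags,
                )
            )
    return results


def bh_adjust(results: Sequence[AssociationResult]) -> list[AssociationResult]:
    """Benjamini-Hochberg step-up q-values, computed within each scope."""
    from statsmodels.stats.multitest import multipletests

    results = list(results)
    for scope in {r.scope for r in results}:
        group = [r for r in results if r.scope is scope]
        pvals = [r.p_value for r in group]
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(group, qvals):
            r.q_value = float(q)
    return results


def results_to_tsv(results: Sequence[AssociationResult]) -> str:
    header = "scope\tunit\tsubset\ta\tb\tc\td\tOR\tci_low\tci_high\tp\tq\tflags"
    lines = [header]
    for r in results:
        or_s = "NA" if r.or_estimate is None else f"{r.or_estimate:.6g}"
        lo = "NA" if r.ci95 is None else f"{r.ci95[0]:.6g}"
        hi = "NA" if r.ci95 is None else f"{r.ci95[1]:.6g}"
        q = "NA" if r.q_value is None else f"{r.q_value:.6g}"
        lines.append(
            f"{r.scope.value}\t{r.unit}\t{r.subset_name}\t"
            f"{r.table.a}\t{r.table.b}\t{r.table.c}\t{r.table.d}\t"
            f"{or_s}\t{lo}\t{hi}\t{r.p_value:.6g}\t{q}\t{';'.join(r.flags)}"
        )
    return "\n".join(lines) + "\n"
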