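"""Self-contained cohort bundles: simulated and curated fixtures.

A *bundle* holds everything the screening pipeline consumes — cohort
variant calls (emitted both as VCF v4.2 and as the TSV dialect), patient
phenotypes, a gene panel, per-subset reference allele counts, pedigrees,
per-variant ACMG/AMP criteria, and a ground-truth manifest recording every
planted fact — so that any count the pipeline reports on a bundle is
derivable from the manifest alone.

Two sources of bundles:

* :func:`simulate_cohort` draws a synthetic cohort under configurable
  study conditions.  The defaults emulate the screened plasma-cell
  dyscrasia cohort: 128 unselected patients, a handful of planted rare
  pathogenic / likely-pathogenic variants in panel genes (12 carriers of
  dominant-gene variants; 15 further heterozygous carriers of
  recessive-gene variants), a benign polymorphic background, and two
  reference subsets sized like the gnomAD non-cancer global (n = 118 477)
  and Finnish (n = 10 816) exomes.  Background carriage is sampled at
  Hardy-Weinberg; the synthetic cohort is unrelated.
* :func:`fixture_table1` returns the curated 13-variant / 12-carrier
  fixture transcribed from the published table of dominant-gene P/LP
  findings, including the two rows whose printed criteria do not satisfy
  a standard combining clause (flagged ``known_discrepancy``) and the
  pedigrees of the telomere-gene families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .acmg import Classification, ClassifiedVariant, CriteriaSet, Tier
from .io_formats import (
    CodingImpact,
    Inheritance,
    PanelCategory,
    PanelGene,
    PatientPhenotype,
    PedigreeGraph,
    PedigreeMember,
    ReferenceCountTable,
    VariantRecord,
    Zygosity,
    write_panel,
    write_phenotypes,
    write_reference_counts,
    write_variant_table,
)

__all__ = [
    "SimulationConfig",
    "PlantedVariant",
    "Bundle",
    "simulate_cohort",
    "fixture_table1",
    "fixture_table1_classified",
    "simulate_null_and_enriched",
    "default_panel",
    "DEFAULT_REFERENCE_SUBSETS",
]

#: reference subsets sized like the gnomAD non-cancer global and Finnish exomes
DEFAULT_REFERENCE_SUBSETS: tuple[tuple[str, int], ...] = (
    ("global", 118477),
    ("finns", 10816),
)

_GENE_CHROM = {
    "ATM": "11",
    "ATR": "3",
    "BRCA2": "13",
    "CHEK2": "22",
    "POT1": "7",
    "PALB2": "16",
    "MUTYH": "1",
    "DIS3": "13",
    "KDM1A": "1",
    "ARID1A": "1",
    "USP45": "6",
    "EP300": "22",
    "DCHS1": "11",
    "KIF1B": "1",
}


def default_panel() -> list[PanelGene]:
    """Candidate panel assembled from genes implicated in myeloma
    predisposition, disease biology, DNA repair, or recurrent somatic
    mutation.  A stand-in for the full 162-gene list, which is not public;
    the panel is always a configurable input."""
    ad = Inheritance.AD
    ar = Inheritance.AR
    c = PanelCategory
    return [
        PanelGene("ATM", ad, c.DNA_REPAIR),
        PanelGene("ATR", ad, c.DNA_REPAIR),
        PanelGene("BRCA2", ad, c.DNA_REPAIR),
        PanelGene("CHEK2", ad, c.DNA_REPAIR),
        PanelGene("PALB2", ad, c.DNA_REPAIR),
        PanelGene("POT1", ad, c.MM_GERMLINE),
        PanelGene("MUTYH", ar, c.DNA_REPAIR),
        PanelGene("DIS3", ad, c.MM_GERMLINE),
        PanelGene("KDM1A", ad, c.MM_GERMLINE),
        PanelGene("ARID1A", ad, c.SOMATIC_MM),
        PanelGene("USP45", ad, c.MM_GERMLINE),
        PanelGene("EP300", ad, c.DISEASE_BIOLOGY),
        PanelGene("DCHS1", ad, c.MM_GERMLINE),
        PanelGene("KIF1B", ad, c.MM_GERMLINE),
    ]


@dataclass
class Bundle:
    """One self-contained pipeline input set with ground truth."""

    cohort_n: int
    records: list[VariantRecord]
    criteria: dict[str, CriteriaSet]  # variant_id -> criteria
    phenotypes: list[PatientPhenotype]
    panel: list[PanelGene]
    reference_tables: dict[str, ReferenceCountTable]
    pedigrees: list[PedigreeGraph] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        """Emit the bundle as plain-text files (VCF + TSVs + PED + JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.records, out / "variants.tsv")
        _write_vcf(self.records, self.cohort_patient_ids(), out / "variants.vcf")
        write_phenotypes(self.phenotypes, out / "phenotypes.tsv")
        write_panel(self.panel, out / "panel.tsv")
        write_reference_counts(self.reference_tables, out / "ref_counts.tsv")
        _write_criteria(self.criteria, out / "criteria.tsv")
        _write_ped(self.pedigrees, out / "pedigrees.ped")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return out

    def cohort_patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.phenotypes]


def _write_criteria(criteria: dict[str, CriteriaSet], path: Path) -> None:
    lines = ["variant_id\tcodes"]
    for vid in sorted(criteria):
        lines.append(f"{vid}\t{','.join(sorted(c.code for c in criteria[vid]))}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_criteria(path: str | Path) -> dict[str, CriteriaSet]:
    """Criteria TSV: variant_id, comma-separated evidence codes."""
    out: dict[str, CriteriaSet] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        out[row["variant_id"]] = CriteriaSet(
            [c for c in row["codes"].split(",") if c]
        )
    return out


def _write_ped(pedigrees: Sequence[PedigreeGraph], path: Path) -> None:
    lines = []
    for graph in pedigrees:
        for iid in sorted(graph.members):
            m = graph.members[iid]
            base = [
                graph.family_id,
                m.individual_id,
                m.father_id or "0",
                m.mother_id or "0",
                {"M": "1", "F": "2"}.get(m.sex, "0"),
                "2" if m.affected else "1",
                m.diagnosis,
            ]
            if m.genotypes:
                for vid in sorted(m.genotypes):
                    lines.append("\t".join(base + [vid, m.genotypes[vid]]))
            else:
                lines.append("\t".join(base))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_vcf(
    records: Sequence[VariantRecord], sample_ids: Sequence[str], path: Path
) -> None:
    chroms = []
    for rec in records:
        if rec.chrom not in chroms:
            chroms.append(rec.chrom)
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c}>" for c in sorted(chroms)]
    for key in ("GENE", "TRANSCRIPT", "HGVSC", "HGVSP", "IMPACT"):
        header.append(
            f'##INFO=<ID={key},Number=1,Type=String,Description="{key.title()} annotation">'
        )
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
    )
    body = []
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        info_parts = []
        for key, value in (
            ("GENE", rec.gene),
            ("TRANSCRIPT", rec.transcript),
            ("HGVSC", rec.hgvs_c),
            ("HGVSP", rec.hgvs_p),
            ("IMPACT", rec.coding_impact.value),
        ):
            if value:
                info_parts.append(f"{key}={value}")
        info = ";".join(info_parts) or "."
        gts = []
        for sample in sample_ids:
            zyg = rec.carriers.get(sample)
            if zyg is None:
                gts.append("0/0")
            elif zyg is Zygosity.HOM:
                gts.append("1/1")
            else:
                gts.append("0/1")
        body.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(header + body) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# simulation


@dataclass(frozen=True)
class PlantedVariant:
    """A ground-truth variant planted into the synthetic cohort."""

    gene: str
    impact: CodingImpact
    criteria: tuple[str, ...]
    n_carriers: int
    reference_ac: dict[str, int] = field(default_factory=dict)  # subset -> AC


def _default_planted() -> list[PlantedVariant]:
    # 12 carriers of dominant-gene P/LP variants and 15 heterozygous
    # carriers of recessive-gene variants, matching the screened cohort's
    # carrier strata (12/128 dominant; 27/128 including recessive hets).
    ci = CodingImpact
    return [
        PlantedVariant("CHEK2", ci.FRAMESHIFT, ("PVS1", "PM2", "PP5"), 5,
                       {"global": 47, "finns": 18}),
        PlantedVariant("POT1", ci.NONSENSE, ("PVS1", "PM2", "PP3"), 1, {}),
        PlantedVariant("POT1", ci.SPLICE_SITE, ("PVS1", "PP5", "PM2"), 1, {}),
        PlantedVariant("POT1", ci.MISSENSE, ("PM1", "PM2", "PP2", "PP3"), 1,
                       {"global": 6}),
        PlantedVariant("BRCA2", ci.MISSENSE, ("PVS1", "PM2", "PP5"), 2,
                       {"global": 4, "finns": 5}),
        PlantedVariant("ATM", ci.MISSENSE, ("PM1", "PM2", "PP5", "PP2", "PP3"), 2,
                       {"global": 3, "finns": 4}),
        PlantedVariant("MUTYH", ci.MISSENSE, ("PS3", "PM2", "PP3"), 5,
                       {"global": 40, "finns": 8}),
        PlantedVariant("MUTYH", ci.NONSENSE, ("PVS1", "PM2", "PP5"), 5,
                       {"global": 25, "finns": 3}),
        PlantedVariant("MUTYH", ci.FRAMESHIFT, ("PVS1", "PM2", "PP3"), 5,
                       {"global": 12, "finns": 0}),
    ]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: int = 128
    panel: list[PanelGene] = field(default_factory=default_panel)
    planted: list[PlantedVariant] = field(default_factory=_default_planted)
    n_background: int = 100
    background_maf_range: tuple[float, float] = (1e-4, 0.2)
    background_in_panel: bool = False  # background sits in filler genes by default
    reference_subsets: tuple[tuple[str, int], ...] = DEFAULT_REFERENCE_SUBSETS
    finnish_enrichment: float = 1.0  # scales Finnish-subset background MAFs
    true_panel_or: float = 1.0  # used by the null/enriched replicate streams

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        total_planted = sum(p.n_carriers for p in self.planted)
        if total_planted > self.n_patients:
            raise ValueError(
                f"{total_planted} planted carriers exceed {self.n_patients} patients"
            )


_DIAGNOSES = ["MM", "MM", "MM", "MM", "MM", "sMM", "MGUS", "PCL"]
_PARAPROTEINS = [
    "IgG kappa",
    "IgG lambda",
    "IgA kappa",
    "IgA lambda",
    "kappa light chain",
    "lambda light chain",
]


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> Bundle:
    """Draw a synthetic cohort bundle under ``config``; reproducible by seed.

    Planted variants go to distinct random patients (heterozygous, as in a
    germline predisposition screen of unrelated adults).  Background
    variants carry per-patient Hardy-Weinberg carriage at a MAF drawn
    log-uniformly from ``background_maf_range``, and reference AC drawn
    binomially at the same MAF.
    """
    rng = np.random.default_rng(config.seed)
    patient_ids = [f"P{i:03d}" for i in range(1, config.n_patients + 1)]

    phenotypes = []
    for pid in patient_ids:
        phenotypes.append(
            PatientPhenotype(
                patient_id=pid,
                diagnosis=_DIAGNOSES[rng.integers(len(_DIAGNOSES))],
                age_at_diagnosis=int(rng.integers(40, 85)),
                sex="F" if rng.random() < 0.5 else "M",
                paraprotein=_PARAPROTEINS[rng.integers(len(_PARAPROTEINS))],
            )
        )

    reference_tables = {
        name: ReferenceCountTable(name, n) for name, n in config.reference_subsets
    }

    records: list[VariantRecord] = []
    criteria: dict[str, CriteriaSet] = {}
    manifest: dict = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "planted": [],
        "background": [],
    }

    # planted carriers are globally distinct so carrier strata are exact
    pool = list(patient_ids)
    rng.shuffle(pool)
    panel_by_gene = {e.gene: e for e in config.panel}
    cursor = 0
    for idx, planted in enumerate(config.planted):
        chrom = _GENE_CHROM.get(planted.gene, "20")
        pos = 1_000_000 + 10_000 * idx
        ref, alt = ("A", "T") if planted.impact != CodingImpact.FRAMESHIFT else ("AT", "A")
        carriers = pool[cursor : cursor + planted.n_carriers]
        cursor += planted.n_carriers
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=planted.gene,
            transcript=f"NM_{900000 + idx}.1",
            hgvs_c=f"c.{100 + idx}A>T",
            hgvs_p="",
            coding_impact=planted.impact,
            carriers={pid: Zygosity.HET for pid in carriers},
        )
        records.append(rec)
        criteria[rec.variant_id] = CriteriaSet(planted.criteria)
        for name, table in reference_tables.items():
            ac = planted.reference_ac.get(name, 0)
            if ac:
                table.add(rec.variant_id, ac, 2 * table.n_individuals, 0)
        entry = panel_by_gene.get(planted.gene)
        manifest["planted"].append(
            {
                "variant_id": rec.variant_id,
                "gene": planted.gene,
                "inheritance": entry.inheritance.value if entry else None,
                "impact": planted.impact.value,
                "criteria": sorted(planted.criteria),
                "carriers": sorted(carriers),
                "reference_ac": dict(planted.reference_ac),
            }
        )

    # benign / common background
    log_lo, log_hi = np.log(config.background_maf_range)
    background_genes = (
        [e.gene for e in config.panel]
        if config.background_in_panel
        else [f"BGGENE{i}" for i in range(1, 21)]
    )
    impacts = list(CodingImpact)
    for idx in range(config.n_background):
        maf = float(np.exp(rng.uniform(log_lo, log_hi)))
        gene = background_genes[rng.integers(len(background_genes))]
        chrom = _GENE_CHROM.get(gene, "20")
        pos = 5_000_000 + 1_000 * idx
        p_hom = maf**2
        p_carrier = 2 * maf * (1 - maf) + p_hom
        carriers = {}
        draws = rng.random(config.n_patients)
        hom_draws = rng.random(config.n_patients)
        for pid, u, uh in zip(patient_ids, draws, hom_draws):
            if u < p_carrier:
                carriers[pid] = (
                    Zygosity.HOM if uh < p_hom / p_carrier else Zygosity.HET
                )
        if not carriers:
            continue  # unseen in the cohort: not a cohort variant
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref="G",
            alt="C",
            gene=gene,
            transcript=f"NM_{800000 + idx}.1",
            hgvs_c=f"c.{idx + 1}G>C",
            hgvs_p="",
            coding_impact=impacts[rng.integers(len(impacts))],
            carriers=carriers,
        )
        records.append(rec)
        criteria[rec.variant_id] = CriteriaSet(["BP4"])
        for name, table in reference_tables.items():
            an = 2 * table.n_individuals
            subset_maf = maf * (
                config.finnish_enrichment if name == "finns" else 1.0
            )
            subset_maf = min(subset_maf, 0.5)
            ac = int(rng.binomial(an, subset_maf))
            n_hom = min(int(rng.binomial(table.n_individuals, subset_maf**2)), ac // 2)
            if ac:
                table.add(rec.variant_id, ac, an, n_hom)
        manifest["background"].append(
            {
                "variant_id": rec.variant_id,
                "gene": gene,
                "maf": maf,
                "in_panel": gene in panel_by_gene,
                "n_carriers": len(carriers),
            }
        )

    bundle = Bundle(
        cohort_n=config.n_patients,
        records=records,
        criteria=criteria,
        phenotypes=phenotypes,
        panel=list(config.panel),
        reference_tables=reference_tables,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# curated fixture

# Transcribed rows of the published dominant-gene P/LP table: 13 variants
# over 12 unique patients (patient 113 carries both the recurrent CHEK2
# frameshift and a POT1 nonsense variant).  Genomic coordinates are
# SYNTHETIC placeholders (the source prints HGVS only); chrom is the gene's
# true chromosome.  Impact strings are verbatim even where inconsistent:
# the BRCA2 splice-acceptor change c.9118-2A>G is printed "Missense".
_TABLE1_ROWS = [
    # (patient, gene, transcript, hgvs_c, hgvs_p, impact, criteria, printed_tier,
    #  diagnosis, age, sex, paraprotein, chrom, pos, ref, alt)
    ("79", "ATM", "NM_000051.4", "c.7570G>C", "p.Ala2524Pro", "missense",
     ("PM1", "PM2", "PP5", "PP2", "PP3"), "likely_pathogenic",
     "MM", 54, "F", "IgG kappa", "11", 108365000, "G", "C"),
    ("97", "ATR", "NM_001184.4", "c.516_529del", "p.Val173IlefsTer7", "frameshift",
     ("PVS1", "PM2", "PP3"), "pathogenic",
     "MM", 56, "M", "IgG lambda", "3", 142560000, "ATTTGAGGAGTTTGA", "A"),
    ("40", "BRCA2", "NM_000059.4", "c.9118-2A>G", "", "missense",
     ("PM1", "PM2", "PP3", "PP5"), "pathogenic",
     "MM", 64, "F", "IgG kappa", "13", 32390000, "A", "G"),
    ("88", "BRCA2", "NM_000059.4", "c.8177A>G", "p.Tyr2726Cys", "missense",
     ("PVS1", "PM2", "PP5"), "pathogenic",
     "PCL", 54, "M", "IgG kappa", "13", 32380000, "A", "G"),
    ("53", "CHEK2", "NM_001005735.2", "c.1229delC", "p.Thr410MetfsTer15", "frameshift",
     ("PVS1", "PM2", "PP5"), "pathogenic",
     "MM", 66, "M", "IgG kappa", "22", 28695000, "AG", "A"),
    ("66", "CHEK2", "NM_001005735.2", "c.1229delC", "p.Thr410MetfsTer15", "frameshift",
     ("PVS1", "PM2", "PP5"), "pathogenic",
     "MM", 73, "F", "kappa light chain", "22", 28695000, "AG", "A"),
    ("78", "CHEK2", "NM_001005735.2", "c.1229delC", "p.Thr410MetfsTer15", "frameshift",
     ("PVS1", "PM2", "PP5"), "pathogenic",
     "MM", 66, "F", "IgA lambda", "22", 28695000, "AG", "A"),
    ("91", "CHEK2", "NM_001005735.2", "c.1229delC", "p.Thr410MetfsTer15", "frameshift",
     ("PVS1", "PM2", "PP5"), "pathogenic",
     "sMM", 61, "F", "IgA kappa", "22", 28695000, "AG", "A"),
    ("113", "CHEK2", "NM_001005735.2", "c.1229delC", "p.Thr410MetfsTer15", "frameshift",
     ("PVS1", "PM2", "PP5"), "pathogenic",
     "MM", 50, "M", "IgA lambda", "22", 28695000, "AG", "A"),
    ("113", "POT1", "NM_015450.3", "c.458T>A", "p.Leu153Ter", "nonsense",
     ("PVS1", "PM2", "PP3"), "pathogenic",
     "MM", 50, "M", "IgA lambda", "7", 124510000, "T", "A"),
    ("82", "POT1", "NM_015450.3", "c.1594G>C", "p.Ala532Pro", "missense",
     ("PP3", "PM2", "PP5"), "likely_pathogenic",
     "MM", 66, "M", "IgG kappa", "7", 124505000, "G", "C"),
    ("105", "POT1", "NM_015450.3", "c.547-1G>A", "", "splice_site",
     ("PVS1", "PP5", "PM2"), "pathogenic",
     "MM", 55, "F", "kappa light chain", "7", 124508000, "G", "A"),
    ("35", "PALB2", "NM_024675.4", "c.1592delT", "p.Leu531CysfsTer30", "frameshift",
     ("PVS1", "PM2", "PP3"), "pathogenic",
     "MM", 65, "F", "IgG kappa", "16", 23635000, "CT", "C"),
]

# reference allele counts for the fixture variants (synthetic but chosen to
# respect the published frequency statements: the recurrent CHEK2 frameshift
# is present in both subsets under MAF 1e-3; the POT1 missense change has
# global MAF 3.19e-5 and is absent from the Finnish subset; the remaining
# POT1 and BRCA2 splice variants are reference-unobserved)
_TABLE1_REFERENCE_AC: dict[str, dict[str, tuple[int, int, int]]] = {
    "ATM:c.7570G>C": {"global": (3, 236954, 0), "finns": (4, 21632, 0)},
    "ATR:c.516_529del": {"global": (1, 236954, 0)},
    "BRCA2:c.9118-2A>G": {},
    "BRCA2:c.8177A>G": {"global": (4, 236954, 0), "finns": (5, 21632, 0)},
    "CHEK2:c.1229delC": {"global": (47, 236954, 0), "finns": (18, 21632, 0)},
    "POT1:c.458T>A": {},
    "POT1:c.1594G>C": {"global": (6, 188088, 0)},
    "POT1:c.547-1G>A": {},
    "PALB2:c.1592delT": {"global": (23, 236954, 0), "finns": (8, 21632, 0)},
}

#: rows whose printed criteria do not satisfy a standard combining clause
#: for the printed tier; shipped verbatim and flagged, never reclassified
TABLE1_KNOWN_DISCREPANCIES = frozenset({"BRCA2:c.9118-2A>G", "POT1:c.1594G>C"})

#: onset age of the fourth telomere-gene carrier (family #4 index, MGUS);
#: not printed — inferred as the maximum of the printed onset range 50-77
POT1_EXTERNAL_CARRIER = {"label": "4_II.1", "age": 77, "inferred": True}


def _table1_pedigrees() -> list[PedigreeGraph]:
    pot1_547 = _fixture_variant_id("POT1:c.547-1G>A")
    pot1_458 = _fixture_variant_id("POT1:c.458T>A")
    chek2 = _fixture_variant_id("CHEK2:c.1229delC")

    # family 2: MM across generations; the index (patient 105) carries the
    # POT1 splice variant, confirmed in the living affected sibling II.2
    fam2 = PedigreeGraph("2")
    fam2.add_member(PedigreeMember("I.1", None, None, "M", False))
    fam2.add_member(PedigreeMember("I.2", None, None, "F", True, diagnosis="MM"))
    fam2.add_member(
        PedigreeMember(
            "II.1", "I.1", "I.2", "F", True, diagnosis="MM",
            genotypes={pot1_547: "carrier"},
        )
    )
    fam2.add_member(
        PedigreeMember(
            "II.2", "I.1", "I.2", "M", True, diagnosis="MM",
            genotypes={pot1_547: "carrier"},
        )
    )
    fam2.validate()

    # family 3: the index (patient 113) carries POT1 + CHEK2; the affected
    # father shares only the CHEK2 variant (POT1 non-carrier)
    fam3 = PedigreeGraph("3")
    fam3.add_member(
        PedigreeMember(
            "I.1", None, None, "M", True, diagnosis="MM",
            genotypes={pot1_458: "noncarrier", chek2: "carrier"},
        )
    )
    fam3.add_member(PedigreeMember("I.2", None, None, "F", False))
    fam3.add_member(
        PedigreeMember(
            "II.1", "I.1", "I.2", "M", True, diagnosis="MM",
            genotypes={pot1_458: "carrier", chek2: "carrier"},
        )
    )
    fam3.validate()
    return [fam2, fam3]


def _fixture_variant_id(key: str) -> str:
    gene, hgvs_c = key.split(":", 1)
    for row in _TABLE1_ROWS:
        if row[1] == gene and row[3] == hgvs_c:
            return VariantRecord(
                chrom=row[12], pos=row[13], ref=row[14], alt=row[15]
            ).variant_id
    raise KeyError(key)


def fixture_table1(out_dir: str | Path | None = None, cohort_n: int = 128) -> Bundle:
    """The curated dominant-gene P/LP fixture: 13 variants, 12 carriers.

    Phenotypes cover the full cohort: the 12 published carriers plus
    synthetic filler patients (labelled ``F...``) bringing the cohort to
    ``cohort_n`` so that carrier percentages have their real denominator.
    """
    records: dict[str, VariantRecord] = {}
    criteria: dict[str, CriteriaSet] = {}
    printed_tiers: dict[str, str] = {}
    phenotypes: dict[str, PatientPhenotype] = {}
    for (patient, gene, transcript, hgvs_c, hgvs_p, impact, codes, tier,
         diagnosis, age, sex, paraprotein, chrom, pos, ref, alt) in _TABLE1_ROWS:
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=gene, transcript=transcript, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            coding_impact=impact,
        )
        rec = records.setdefault(rec.variant_id, rec)
        rec.carriers[patient] = Zygosity.HET
        criteria[rec.variant_id] = CriteriaSet(codes)
        printed_tiers[rec.variant_id] = tier
        if patient not in phenotypes:
            phenotypes[patient] = PatientPhenotype(
                patient_id=patient, diagnosis=diagnosis,
                age_at_diagnosis=age, sex=sex, paraprotein=paraprotein,
            )

    rng = np.random.default_rng(20220902)  # fillers are descriptive only
    for i in range(1, cohort_n - len(phenotypes) + 1):
        pid = f"F{i:03d}"
        phenotypes[pid] = PatientPhenotype(
            patient_id=pid,
            diagnosis=_DIAGNOSES[rng.integers(len(_DIAGNOSES))],
            age_at_diagnosis=int(rng.integers(40, 85)),
            sex="F" if rng.random() < 0.5 else "M",
            paraprotein=_PARAPROTEINS[rng.integers(len(_PARAPROTEINS))],
        )

    reference_tables = {
        name: ReferenceCountTable(name, n) for name, n in DEFAULT_REFERENCE_SUBSETS
    }
    for key, per_subset in _TABLE1_REFERENCE_AC.items():
        vid = _fixture_variant_id(key)
        for subset, (ac, an, n_hom) in per_subset.items():
            reference_tables[subset].add(vid, ac, an, n_hom)

    discrepant_ids = {_fixture_variant_id(k) for k in TABLE1_KNOWN_DISCREPANCIES}
    manifest = {
        "source": "curated dominant-gene P/LP table",
        "n_rows": len(_TABLE1_ROWS),
        "n_variants": len(records),
        "unique_carriers": sorted({r[0] for r in _TABLE1_ROWS}),
        "printed_tiers": printed_tiers,
        "known_discrepancies": sorted(discrepant_ids),
        "pot1_external_carrier": POT1_EXTERNAL_CARRIER,
        "cohort_n": cohort_n,
    }
    bundle = Bundle(
        cohort_n=cohort_n,
        records=list(records.values()),
        criteria=criteria,
        phenotypes=list(phenotypes.values()),
        panel=default_panel(),
        reference_tables=reference_tables,
        pedigrees=_table1_pedigrees(),
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def fixture_table1_classified(bundle: Bundle | None = None) -> list[ClassifiedVariant]:
    """The curated fixture with its *published* tiers attached verbatim.

    Carrier summaries of the source table count every row as P/LP as
    printed, including the two rows whose criteria do not satisfy a
    standard combining clause; use :func:`germscreen.acmg.classify_table`
    instead to classify the same rows with the rule engine.
    """
    bundle = bundle or fixture_table1()
    printed = bundle.manifest["printed_tiers"]
    return [
        ClassifiedVariant(
            rec,
            bundle.criteria[rec.variant_id],
            Classification(Tier(printed[rec.variant_id]), "curated tier"),
        )
        for rec in bundle.records
    ]


# ---------------------------------------------------------------------------
# replicate streams for statistical calibration


@dataclass(frozen=True)
class ReplicateResult:
    true_or: float
    a: int
    b: int
    c: int
    d: int
    or_estimate: float | None
    ci95: tuple[float, float] | None
    p_value: float | None


def simulate_null_and_enriched(
    true_or: float = 1.0,
    n_reps: int = 1000,
    seed: int = 0,
    cohort_n: int = 200,
    reference_n: int = 20000,
    baseline_carrier_prob: float = 0.05,
    compute_p: bool = True,
) -> list[ReplicateResult]:
    """Replicate 2x2 carrier tables at a known generative odds ratio.

    Cohort carriage is Binomial(cohort_n, p1) where p1 solves
    odds(p1) = true_or * odds(p0), reference carriage Binomial(ref_n, p0).
    Used for type-I-error and CI-coverage calibration; ``compute_p=False``
    skips the exact test when only the interval is needed.
    """
    from .burden_stats import ContingencyTable, fisher_exact_p, odds_ratio_woolf

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    p0 = baseline_carrier_prob
    odds1 = true_or * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    a = rng.binomial(cohort_n, p1, size=n_reps)
    c = rng.binomial(reference_n, p0, size=n_reps)
    out = []
    for ai, ci in zip(a, c):
        table = ContingencyTable(
            int(ai), cohort_n - int(ai), int(ci), reference_n - int(ci)
        )
        or_est, ci95 = odds_ratio_woolf(table)
        p = fisher_exact_p(table) if compute_p else None
        out.append(
            ReplicateResult(true_or, *table.cells, or_est, ci95, p)
        )
    return out
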