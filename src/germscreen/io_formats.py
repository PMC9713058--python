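"""Readers, writers and the canonical in-memory cohort model.

The pipeline exchanges five kinds of external tables:

* cohort variant calls — VCF v4.2 (GT in FORMAT, per-gene annotation in
  INFO) or an equivalent tab-separated dialect with one row per
  (patient, variant) pair;
* a patient phenotype table;
* a candidate gene panel with inheritance modes;
* per-subset population reference allele counts (AC/AN/nHom), emulating
  the gnomAD non-cancer global and Finnish exome subsets;
* pedigrees in six-column PED with optional extension columns for
  diagnosis and tested genotypes.

All coordinates are 1-based VCF convention.  The canonical variant key is
``chrom:pos:ref:alt`` after minimal (prefix/suffix-trimmed) normalisation,
so cohort and reference tables join on a single string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "CodingImpact",
    "Zygosity",
    "VariantRecord",
    "PatientPhenotype",
    "PanelGene",
    "Inheritance",
    "ReferenceCounts",
    "ReferenceCountTable",
    "PedigreeMember",
    "PedigreeGraph",
    "GenotypeMetrics",
    "FormatError",
    "ValidationError",
    "normalize_variant",
    "make_variant_id",
    "read_variant_table",
    "write_variant_table",
    "read_reference_counts",
    "read_panel",
    "read_phenotypes",
    "read_pedigree",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a model invariant."""


class CodingImpact(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    START_LOST = "start_lost"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"


class Inheritance(str, Enum):
    AD = "AD"
    AR = "AR"
    XL = "XL"


class PanelCategory(str, Enum):
    MM_GERMLINE = "MM_germline"
    DISEASE_BIOLOGY = "disease_biology"
    DNA_REPAIR = "DNA_repair"
    SOMATIC_MM = "somatic_MM"


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim shared suffix then shared prefix.

    Left-alignment against a reference genome is out of scope; trimming
    alone makes equivalent biallelic encodings collide on one key.
    """
    if pos < 1:
        raise ValidationError(f"pos must be >= 1, got {pos}")
    if ref == alt:
        raise ValidationError(f"ref equals alt ({ref!r})")
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def make_variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    pos, ref, alt = normalize_variant(pos, ref, alt)
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class VariantRecord:
    """One biallelic variant plus its carriers in the cohort."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    coding_impact: CodingImpact = CodingImpact.OTHER
    carriers: dict[str, Zygosity] = field(default_factory=dict)
    inheritance: Inheritance | None = None  # annotated by the panel filter

    def __post_init__(self) -> None:
        self.pos, self.ref, self.alt = normalize_variant(self.pos, self.ref, self.alt)
        if isinstance(self.coding_impact, str) and not isinstance(
            self.coding_impact, CodingImpact
        ):
            try:
                self.coding_impact = CodingImpact(self.coding_impact)
            except ValueError as exc:
                raise ValidationError(
                    f"unknown coding impact {self.coding_impact!r}"
                ) from exc

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def carrier_ids(self) -> set[str]:
        return set(self.carriers)

    @property
    def allele_count(self) -> int:
        """Alt alleles carried in the cohort (het + 2*hom)."""
        return sum(2 if z is Zygosity.HOM else 1 for z in self.carriers.values())


@dataclass
class PatientPhenotype:
    patient_id: str
    diagnosis: str = "other"  # MM, sMM, MGUS, PCL, other
    age_at_diagnosis: int | None = None
    sex: str = ""
    paraprotein: str = ""
    other_malignancies: list[str] = field(default_factory=list)
    family_history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age_at_diagnosis is not None and self.age_at_diagnosis <= 0:
            raise ValidationError(
                f"age_at_diagnosis must be positive for {self.patient_id}"
            )


@dataclass(frozen=True)
class PanelGene:
    gene: str
    inheritance: Inheritance
    category: PanelCategory = PanelCategory.MM_GERMLINE


@dataclass(frozen=True)
class ReferenceCounts:
    ac: int
    an: int
    n_hom: int
    observed: bool = True  # False when filled in by the absent-as-zero policy

    @property
    def maf(self) -> float:
        return self.ac / self.an if self.an else 0.0

    @property
    def n_carriers(self) -> int:
        """Carrier individuals approximated as AC - nHom."""
        return self.ac - self.n_hom


class ReferenceCountTable:
    """Allele counts for one reference subset, keyed by variant_id."""

    def __init__(self, subset_name: str, n_individuals: int):
        if n_individuals <= 0:
            raise ValidationError("n_individuals must be positive")
        self.subset_name = subset_name
        self.n_individuals = n_individuals
        self._counts: dict[str, ReferenceCounts] = {}

    def add(self, variant_id: str, ac: int, an: int, n_hom: int) -> None:
        if not (0 <= ac <= an):
            raise ValidationError(
                f"{self.subset_name}/{variant_id}: need 0 <= AC <= AN, got AC={ac} AN={an}"
            )
        if n_hom > ac / 2:
            raise ValidationError(
                f"{self.subset_name}/{variant_id}: nHom={n_hom} exceeds AC/2={ac / 2}"
            )
        if an > 2 * self.n_individuals:
            raise ValidationError(
                f"{self.subset_name}/{variant_id}: AN={an} exceeds "
                f"2*n_individuals={2 * self.n_individuals}"
            )
        self._counts[variant_id] = ReferenceCounts(ac, an, n_hom)

    def lookup(self, variant_id: str, absent_as_zero: bool = True) -> ReferenceCounts:
        """Counts for a variant; unlisted variants come back flagged unobserved.

        Absent-as-zero mirrors reference browsers reporting "N/A" frequencies
        for variants never seen in the subset.
        """
        try:
            return self._counts[variant_id]
        except KeyError:
            if absent_as_zero:
                return ReferenceCounts(0, 0, 0, observed=False)
            raise KeyError(variant_id) from None

    def maf(self, variant_id: str) -> float:
        counts = self.lookup(variant_id)
        if counts.observed and counts.an == 0:
            warnings.warn(
                f"{self.subset_name}/{variant_id}: AN=0, treated as unobserved",
                stacklevel=2,
            )
            return 0.0
        return counts.maf

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._counts

    def __len__(self) -> int:
        return len(self._counts)

    def variant_ids(self) -> set[str]:
        return set(self._counts)


@dataclass
class PedigreeMember:
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str
    affected: bool
    diagnosis: str = ""
    # tested genotype per variant_id: "carrier" | "noncarrier"; absent = untested
    genotypes: dict[str, str] = field(default_factory=dict)


class PedigreeGraph:
    def __init__(self, family_id: str):
        self.family_id = family_id
        self.members: dict[str, PedigreeMember] = {}

    def add_member(self, member: PedigreeMember) -> None:
        if member.individual_id in self.members:
            raise ValidationError(
                f"duplicate individual {member.individual_id} in family {self.family_id}"
            )
        self.members[member.individual_id] = member

    @property
    def founders(self) -> set[str]:
        return {
            m.individual_id
            for m in self.members.values()
            if m.father_id is None and m.mother_id is None
        }

    def affected_members(self) -> list[PedigreeMember]:
        return [m for m in self.members.values() if m.affected]

    def validate(self) -> None:
        for m in self.members.values():
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in self.members:
                    raise ValidationError(
                        f"family {self.family_id}: unresolved parent id {parent!r}"
                    )
        # no individual may be its own ancestor
        for start in self.members:
            seen: set[str] = set()
            stack = [start]
            while stack:
                current = self.members[stack.pop()]
                for parent in (current.father_id, current.mother_id):
                    if parent is None:
                        continue
                    if parent == start:
                        raise ValidationError(
                            f"family {self.family_id}: {start} is its own ancestor"
                        )
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)


@dataclass(frozen=True)
class GenotypeMetrics:
    """Per-carrier genotype quality pulled from VCF FORMAT fields."""

    dp: int | None = None
    gq: int | None = None
    ab: float | None = None  # alt-allele balance, defined for hets


# ---------------------------------------------------------------------------
# readers / writers

VARIANT_TSV_COLUMNS = [
    "patient_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "coding_impact",
    "zygosity",
]


def _read_tsv_rows(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file, header row required (line 1)")
    header = lines[0].rstrip("\n").split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: header missing column(s) {missing} (line 1)")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {len(header)}"
            )
        rows.append(dict(zip(header, fields)))
    return rows


def _variant_records_from_tsv(path: str | Path) -> list[VariantRecord]:
    records: dict[str, VariantRecord] = {}
    for row in _read_tsv_rows(path, VARIANT_TSV_COLUMNS):
        rec = VariantRecord(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            transcript=row["transcript"],
            hgvs_c=row["hgvs_c"],
            hgvs_p=row["hgvs_p"],
            coding_impact=row["coding_impact"],
        )
        existing = records.setdefault(rec.variant_id, rec)
        existing.carriers[row["patient_id"]] = Zygosity(row["zygosity"])
    return list(records.values())


def _variant_records_from_vcf(path: str | Path) -> list[VariantRecord]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise FormatError(f"{path}: not a readable VCF ({exc})") from exc
    samples = list(vcf.samples)
    records: dict[str, VariantRecord] = {}
    for site in vcf:
        alts = site.ALT or []
        info = dict(site.INFO)
        for alt_index, alt in enumerate(alts, start=1):
            impact = str(info.get("IMPACT", "other"))
            rec = VariantRecord(
                chrom=site.CHROM,
                pos=site.POS,
                ref=site.REF,
                alt=alt,
                gene=str(info.get("GENE", "")),
                transcript=str(info.get("TRANSCRIPT", "")),
                hgvs_c=str(info.get("HGVSC", "")),
                hgvs_p=str(info.get("HGVSP", "")),
                coding_impact=impact,
            )
            rec = records.setdefault(rec.variant_id, rec)
            for sample, gt in zip(samples, site.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                dose = sum(1 for a in alleles if a == alt_index)
                if dose == 0:
                    continue
                zyg = Zygosity.HOM if dose >= 2 else Zygosity.HET
                rec.carriers[sample] = zyg
    return list(records.values())


def read_variant_table(path: str | Path, format: str = "tsv") -> list[VariantRecord]:
    """Load cohort variants from a VCF (v4.2, GT required) or the TSV dialect.

    Multi-allelic VCF sites are decomposed into biallelic records; a sample
    is a carrier of a record when it bears >= 1 copy of that record's alt.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _variant_records_from_tsv(path)
    if format == "vcf":
        return _variant_records_from_vcf(path)
    raise ValueError(f"unknown variant table format {format!r}")


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Emit the TSV dialect, one row per (patient, variant), stable order."""
    lines = ["\t".join(VARIANT_TSV_COLUMNS)]
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        for patient_id in sorted(rec.carriers):
            lines.append(
                "\t".join(
                    [
                        patient_id,
                        rec.chrom,
                        str(rec.pos),
                        rec.ref,
                        rec.alt,
                        rec.gene,
                        rec.transcript,
                        rec.hgvs_c,
                        rec.hgvs_p,
                        rec.coding_impact.value,
                        rec.carriers[patient_id].value,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_reference_counts(path: str | Path) -> dict[str, ReferenceCountTable]:
    """Load per-subset AC/AN/nHom tables; returns {subset_name: table}."""
    tables: dict[str, ReferenceCountTable] = {}
    for row in _read_tsv_rows(
        path, ["subset", "n_individuals", "variant_id", "AC", "AN", "nHom"]
    ):
        subset = row["subset"]
        table = tables.get(subset)
        if table is None:
            table = ReferenceCountTable(subset, int(row["n_individuals"]))
            tables[subset] = table
        table.add(row["variant_id"], int(row["AC"]), int(row["AN"]), int(row["nHom"]))
    return tables


def write_reference_counts(
    tables: Mapping[str, ReferenceCountTable], path: str | Path
) -> None:
    lines = ["\t".join(["subset", "n_individuals", "variant_id", "AC", "AN", "nHom"])]
    for subset in sorted(tables):
        table = tables[subset]
        for vid in sorted(table.variant_ids()):
            counts = table.lookup(vid)
            lines.append(
                "\t".join(
                    [
                        subset,
                        str(table.n_individuals),
                        vid,
                        str(counts.ac),
                        str(counts.an),
                        str(counts.n_hom),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_panel(path: str | Path) -> list[PanelGene]:
    panel: list[PanelGene] = []
    seen: set[str] = set()
    for row in _read_tsv_rows(path, ["gene", "inheritance", "category"]):
        if row["gene"] in seen:
            raise ValidationError(f"duplicate panel gene {row['gene']}")
        seen.add(row["gene"])
        panel.append(
            PanelGene(
                gene=row["gene"],
                inheritance=Inheritance(row["inheritance"]),
                category=PanelCategory(row["category"]),
            )
        )
    return panel


def write_panel(panel: Iterable[PanelGene], path: str | Path) -> None:
    lines = ["gene\tinheritance\tcategory"]
    for entry in panel:
        lines.append(f"{entry.gene}\t{entry.inheritance.value}\t{entry.category.value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_phenotypes(path: str | Path) -> list[PatientPhenotype]:
    phenotypes = []
    seen: set[str] = set()
    for row in _read_tsv_rows(
        path, ["patient_id", "diagnosis", "age_at_diagnosis", "sex", "paraprotein"]
    ):
        if row["patient_id"] in seen:
            raise ValidationError(f"duplicate patient_id {row['patient_id']}")
        seen.add(row["patient_id"])
        age = row["age_at_diagnosis"]
        phenotypes.append(
            PatientPhenotype(
                patient_id=row["patient_id"],
                diagnosis=row["diagnosis"],
                age_at_diagnosis=int(age) if age not in ("", "NA") else None,
                sex=row["sex"],
                paraprotein=row["paraprotein"],
                other_malignancies=[
                    s for s in row.get("other_malignancies", "").split(";") if s
                ],
                family_history=[
                    s for s in row.get("family_history", "").split(";") if s
                ],
            )
        )
    return phenotypes


def write_phenotypes(phenotypes: Iterable[PatientPhenotype], path: str | Path) -> None:
    lines = [
        "\t".join(
            [
                "patient_id",
                "diagnosis",
                "age_at_diagnosis",
                "sex",
                "paraprotein",
                "other_malignancies",
                "family_history",
            ]
        )
    ]
    for p in phenotypes:
        lines.append(
            "\t".join(
                [
                    p.patient_id,
                    p.diagnosis,
                    "" if p.age_at_diagnosis is None else str(p.age_at_diagnosis),
                    p.sex,
                    p.paraprotein,
                    ";".join(p.other_malignancies),
                    ";".join(p.family_history),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pedigree(path: str | Path) -> list[PedigreeGraph]:
    """Parse six-column PED plus optional diagnosis / tested-genotype columns.

    Extension columns: 7 = diagnosis label, 8 = tested variant_id,
    9 = tested result ("carrier"/"noncarrier").  "0" means missing parent.
    """
    families: dict[str, PedigreeGraph] = {}
    rows: dict[tuple[str, str], PedigreeMember] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(f"{path}: line {lineno} has fewer than 6 PED columns")
        fam, iid, father, mother, sex, phen = fields[:6]
        if iid in (father, mother):
            raise ValidationError(
                f"{path}: line {lineno}: individual {iid} is its own parent"
            )
        key = (fam, iid)
        member = rows.get(key)
        if member is None:
            member = PedigreeMember(
                individual_id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex={"1": "M", "2": "F"}.get(sex, ""),
                affected=phen == "2",
                diagnosis=fields[6] if len(fields) > 6 else "",
            )
            rows[key] = member
            families.setdefault(fam, PedigreeGraph(fam)).add_member(member)
        if len(fields) > 8 and fields[7]:
            member.genotypes[fields[7]] = fields[8]
    result = list(families.values())
    for graph in result:
        graph.validate()
    return result
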