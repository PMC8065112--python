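"""Cohort data model, table I/O, germline filtering and pathogenicity rules.

The native interchange format is a trio of tab-separated tables:

* **variants**: ``patient_id, gene, chrom, pos, ref, alt, protein_change,
  variant_class, vaf_pct, pop_af_pct, context3`` — one row per variant call.
  ``vaf_pct`` and ``pop_af_pct`` are percentages in [0, 100]; coordinates are
  1-based, fully closed, GRCh37 (MAF conventions).
* **clinical**: ``patient_id, subtype, lines_of_treatment, disease_sites,
  tissue_her2_status`` — one row per patient; ``disease_sites`` is a
  ``;``-separated list.
* **copy number**: ``patient_id, gene, observed_pcn``.

Lines starting with ``#`` are metadata headers and are ignored on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "in-frame indel", "splice", "synonymous", "other"}
)
INDEL_CLASSES = frozenset({"frameshift", "in-frame indel"})
SUBTYPES = frozenset({"HR+HER2-", "HR+HER2+", "HR-HER2+", "TNBC", "unknown"})
PATHOGENIC_STATES = frozenset({"pathogenic", "non-pathogenic", "unclassified"})

#: Genes whose pathogenic point mutations count as MAPK-pathway alterations.
MAPK_MUTATION_GENES = frozenset(
    {
        "EGFR", "HRAS", "KRAS", "NRAS", "ARAF", "BRAF", "RAF1",
        "MAP2K1", "MAP2K2", "MAPK1", "MAPK3", "FGFR1", "FGFR2", "FGFR3",
    }
)
#: Genes whose fusions count as MAPK-pathway alterations.
MAPK_FUSION_GENES = frozenset({"FGFR2", "FGFR3"})
#: Genes whose plasma copy number > 3 counts as a MAPK-pathway alteration.
MAPK_CN_GENES = frozenset({"BRAF", "EGFR", "FGFR1", "FGFR2", "KRAS"})

#: Key breast-cancer genes for the recurrence branch of the pathogenicity rule.
DEFAULT_KEY_BREAST_GENES = frozenset({"ESR1", "HER2", "PIK3CA", "EGFR", "RB1", "FGFR2"})

_DNA = frozenset("ACGT")


@dataclass
class VariantCall:
    """One mutation call in one patient.

    VAF and population allele frequency are both stored in **percent**;
    fraction-scaled inputs must be converted explicitly on read
    (``vaf_scale="fraction"``), never by guessing.
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    protein_change: str = ""
    variant_class: str = "other"
    vaf: float = 0.0
    population_af: float | None = None
    context3: str | None = None
    pathogenic: str = "unclassified"
    pathogenic_reason: str | None = None

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if self.context3 is not None:
            self.context3 = self.context3.upper() or None
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"unknown variant_class {self.variant_class!r} for {self.gene} in {self.patient_id}"
            )
        if not 0.0 <= self.vaf <= 100.0:
            raise ValueError(f"vaf must be in [0, 100] percent, got {self.vaf}")
        if self.population_af is not None and not 0.0 <= self.population_af <= 100.0:
            raise ValueError(f"population_af must be in [0, 100] percent, got {self.population_af}")
        if self.pathogenic not in PATHOGENIC_STATES:
            raise ValueError(f"invalid pathogenic state {self.pathogenic!r}")
        if self.is_snv and self.context3 is not None:
            if len(self.context3) != 3 or set(self.context3) - _DNA:
                raise ValueError(f"context3 must be a 3-mer over ACGT, got {self.context3!r}")
            if self.context3[1] != self.ref_allele:
                raise ValueError(
                    f"context3 middle base {self.context3[1]!r} does not match "
                    f"ref allele {self.ref_allele!r}"
                )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in _DNA
            and self.alt_allele in _DNA
        )

    @property
    def is_indel(self) -> bool:
        return self.variant_class in INDEL_CLASSES or len(self.ref_allele) != len(self.alt_allele)

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        """Genomic identity used to deduplicate recurrent sites across patients."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class CopyNumberCall:
    """Observed (and, once computed, purity-adjusted) plasma copy number of a gene."""

    patient_id: str
    gene: str
    observed_pcn: float
    adjusted_pcn: float | None = None

    def __post_init__(self) -> None:
        if self.observed_pcn < 0:
            raise ValueError(f"observed_pcn must be >= 0, got {self.observed_pcn}")


@dataclass
class FusionCall:
    """A gene fusion call (only the partner identities matter here)."""

    patient_id: str
    gene5: str
    gene3: str = ""


@dataclass
class PatientProfile:
    """A patient's clinical covariates plus their variant and copy-number calls."""

    patient_id: str
    subtype: str = "unknown"
    lines_of_treatment: int | None = None
    disease_sites: set[str] = field(default_factory=set)
    tissue_her2_status: str = "unknown"
    variants: list[VariantCall] = field(default_factory=list)
    cn_calls: list[CopyNumberCall] = field(default_factory=list)
    fusions: list[FusionCall] = field(default_factory=list)
    mvaf: float | None = None

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r} for patient {self.patient_id}")


class Cohort:
    """An ordered collection of :class:`PatientProfile`, keyed by patient_id."""

    def __init__(self, profiles: Iterable[PatientProfile] = ()) -> None:
        self._profiles: dict[str, PatientProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: PatientProfile) -> None:
        if profile.patient_id in self._profiles:
            raise ValueError(f"duplicate patient_id {profile.patient_id!r}")
        self._profiles[profile.patient_id] = profile

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[PatientProfile]:
        return iter(self._profiles.values())

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self._profiles

    def __getitem__(self, patient_id: str) -> PatientProfile:
        return self._profiles[patient_id]

    @property
    def patient_ids(self) -> list[str]:
        return list(self._profiles)

    def all_variants(self) -> Iterator[VariantCall]:
        for profile in self:
            yield from profile.variants

    def variants_frame(self) -> pd.DataFrame:
        """All variant calls as a tidy DataFrame (one row per call)."""
        rows = [
            {
                "patient_id": v.patient_id,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "protein_change": v.protein_change,
                "variant_class": v.variant_class,
                "vaf_pct": v.vaf,
                "pop_af_pct": v.population_af,
                "context3": v.context3,
                "pathogenic": v.pathogenic,
            }
            for v in self.all_variants()
        ]
        columns = [
            "patient_id", "gene", "chrom", "pos", "ref", "alt", "protein_change",
            "variant_class", "vaf_pct", "pop_af_pct", "context3", "pathogenic",
        ]
        return pd.DataFrame(rows, columns=columns)


@dataclass
class AnnotationResources:
    """Plain-table annotation inputs used by the pathogenicity classifier.

    Keys are case-normalised ``(GENE, protein_change)`` pairs with any
    leading ``p.`` stripped from the protein change.
    """

    hotspot_set: set[tuple[str, str]] = field(default_factory=set)
    oncogenic_set: set[tuple[str, str]] = field(default_factory=set)
    recurrence_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    key_breast_genes: frozenset[str] = DEFAULT_KEY_BREAST_GENES

    def __post_init__(self) -> None:
        if not self.key_breast_genes:
            raise ValueError("key_breast_genes must be non-empty")
        self.hotspot_set = {_norm_key(g, p) for g, p in self.hotspot_set}
        self.oncogenic_set = {_norm_key(g, p) for g, p in self.oncogenic_set}
        self.recurrence_counts = {
            _norm_key(g, p): int(n) for (g, p), n in self.recurrence_counts.items()
        }
        self.key_breast_genes = frozenset(g.upper() for g in self.key_breast_genes)


def _norm_key(gene: str, protein_change: str) -> tuple[str, str]:
    pc = protein_change.strip()
    if pc.lower().startswith("p."):
        pc = pc[2:]
    return gene.strip().upper(), pc.upper()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "protein_change",
    "variant_class", "vaf_pct", "pop_af_pct", "context3",
]
CLINICAL_COLUMNS = [
    "patient_id", "subtype", "lines_of_treatment", "disease_sites", "tissue_her2_status",
]
CN_COLUMNS = ["patient_id", "gene", "observed_pcn"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _parse_pct(raw: str, *, scale: str, path: str | Path, line: int, col: str) -> float | None:
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError:
        raise ValueError(f"{path}, line {line}: malformed {col} value {raw!r}") from None
    if scale == "fraction":
        value *= 100.0
    return value


def read_cohort(
    variant_path: str | Path,
    clinical_path: str | Path,
    cn_path: str | Path | None = None,
    *,
    vaf_scale: str = "percent",
) -> Cohort:
    """Read the native three-table cohort format.

    ``vaf_scale`` is ``"percent"`` (default) or ``"fraction"``; in the latter
    case VAF and population AF columns are multiplied by 100 on read.
    Patients present in the clinical table with no variant rows are retained
    with empty variant lists (they are the "no ctDNA alteration" denominator).
    """
    if vaf_scale not in ("percent", "fraction"):
        raise ValueError(f"vaf_scale must be 'percent' or 'fraction', got {vaf_scale!r}")

    clinical = _read_tsv(clinical_path, CLINICAL_COLUMNS)
    cohort = Cohort()
    for _, row in clinical.iterrows():
        sites = {s for s in row["disease_sites"].split(";") if s}
        lines = int(row["lines_of_treatment"]) if row["lines_of_treatment"] != "" else None
        cohort.add(
            PatientProfile(
                patient_id=row["patient_id"],
                subtype=row["subtype"] or "unknown",
                lines_of_treatment=lines,
                disease_sites=sites,
                tissue_her2_status=row["tissue_her2_status"] or "unknown",
            )
        )

    variants = _read_tsv(variant_path, VARIANT_COLUMNS)
    unknown = sorted(set(variants["patient_id"]) - set(cohort.patient_ids))
    if unknown:
        raise ValueError(
            f"{variant_path}: variant rows reference patients absent from the "
            f"clinical table: {', '.join(unknown)}"
        )
    for idx, row in variants.iterrows():
        line = idx + 2  # 1-based, after the header line
        vaf = _parse_pct(row["vaf_pct"], scale=vaf_scale, path=variant_path, line=line, col="vaf_pct")
        if vaf is None:
            raise ValueError(f"{variant_path}, line {line}: missing vaf_pct")
        pop_af = _parse_pct(
            row["pop_af_pct"], scale=vaf_scale, path=variant_path, line=line, col="pop_af_pct"
        )
        cohort[row["patient_id"]].variants.append(
            VariantCall(
                patient_id=row["patient_id"],
                gene=row["gene"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref_allele=row["ref"],
                alt_allele=row["alt"],
                protein_change=row["protein_change"],
                variant_class=row["variant_class"] or "other",
                vaf=vaf,
                population_af=pop_af,
                context3=row["context3"] or None,
            )
        )

    if cn_path is not None:
        cn = _read_tsv(cn_path, CN_COLUMNS)
        unknown = sorted(set(cn["patient_id"]) - set(cohort.patient_ids))
        if unknown:
            raise ValueError(
                f"{cn_path}: copy-number rows reference patients absent from the "
                f"clinical table: {', '.join(unknown)}"
            )
        for _, row in cn.iterrows():
            cohort[row["patient_id"]].cn_calls.append(
                CopyNumberCall(row["patient_id"], row["gene"], float(row["observed_pcn"]))
            )
    return cohort


def _meta_lines(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {key}={value}\n" for key, value in meta.items())


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write a DataFrame as TSV with optional ``# key=value`` metadata headers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def write_cohort(
    cohort: Cohort,
    variant_path: str | Path,
    clinical_path: str | Path,
    cn_path: str | Path | None = None,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a cohort back to the native three-table format."""
    vdf = cohort.variants_frame().drop(columns=["pathogenic"])
    write_table(vdf, variant_path, meta)

    crows = [
        {
            "patient_id": p.patient_id,
            "subtype": p.subtype,
            "lines_of_treatment": "" if p.lines_of_treatment is None else p.lines_of_treatment,
            "disease_sites": ";".join(sorted(p.disease_sites)),
            "tissue_her2_status": p.tissue_her2_status,
        }
        for p in cohort
    ]
    write_table(pd.DataFrame(crows, columns=CLINICAL_COLUMNS), clinical_path, meta)

    if cn_path is not None:
        cnrows = [
            {"patient_id": c.patient_id, "gene": c.gene, "observed_pcn": c.observed_pcn}
            for p in cohort
            for c in p.cn_calls
        ]
        write_table(pd.DataFrame(cnrows, columns=CN_COLUMNS), cn_path, meta)


def read_vcf_variants(
    path: str | Path,
    *,
    vaf_field: str = "AF",
    vaf_scale: str = "fraction",
    gene_info_field: str = "GENE",
) -> list[VariantCall]:
    """Read variant calls from a VCF, one call per sample with a non-missing VAF.

    The VAF is taken from the named per-sample FORMAT field (``AF`` by
    default, fraction-scaled as VCF convention dictates); the gene symbol
    from an INFO field.  VCF positions are already 1-based, matching the
    native convention.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    if vaf_scale not in ("percent", "fraction"):
        raise ValueError(f"vaf_scale must be 'percent' or 'fraction', got {vaf_scale!r}")
    factor = 100.0 if vaf_scale == "fraction" else 1.0

    vcf = VCF(str(path))
    samples = vcf.samples
    calls: list[VariantCall] = []
    for record in vcf:
        try:
            per_sample = record.format(vaf_field)
        except KeyError:
            raise ValueError(f"{path}: FORMAT field {vaf_field!r} absent") from None
        gene = record.INFO.get(gene_info_field, "") or ""
        for sample_idx, sample in enumerate(samples):
            vaf = float(per_sample[sample_idx][0])
            if vaf < 0:  # cyvcf2 encodes missing values as negative sentinels
                continue
            calls.append(
                VariantCall(
                    patient_id=sample,
                    gene=gene,
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref_allele=record.REF,
                    alt_allele=record.ALT[0],
                    vaf=vaf * factor,
                )
            )
    return calls


def add_contexts_from_fasta(cohort: Cohort, fasta_path: str | Path) -> int:
    """Fill missing SNV trinucleotide contexts from an indexed FASTA.

    Positions are 1-based; the reference base at each SNV must match the
    call's ref allele, otherwise the variant is reported in the error.
    Returns the number of contexts filled.
    """
    from pyfaidx import Fasta  # optional: only needed when contexts are absent

    genome = Fasta(str(fasta_path))
    filled = 0
    for v in cohort.all_variants():
        if not v.is_snv or v.context3 is not None:
            continue
        seq = str(genome[v.chrom][v.pos - 2 : v.pos + 1]).upper()
        if len(seq) != 3:
            raise ValueError(f"{v.chrom}:{v.pos} too close to a contig edge for a 3-mer")
        if seq[1] != v.ref_allele:
            raise ValueError(
                f"{v.chrom}:{v.pos} reference base {seq[1]!r} does not match "
                f"ref allele {v.ref_allele!r} for {v.gene} in {v.patient_id}"
            )
        v.context3 = seq
        filled += 1
    return filled


def read_annotation_resources(
    hotspots_path: str | Path,
    oncogenic_path: str | Path,
    recurrence_path: str | Path,
    key_breast_genes: Iterable[str] = DEFAULT_KEY_BREAST_GENES,
) -> AnnotationResources:
    """Load the three annotation tables (gene, protein_change[, count])."""
    hs = _read_tsv(hotspots_path, ["gene", "protein_change"])
    onc = _read_tsv(oncogenic_path, ["gene", "protein_change"])
    rec = _read_tsv(recurrence_path, ["gene", "protein_change", "count"])
    return AnnotationResources(
        hotspot_set={(r["gene"], r["protein_change"]) for _, r in hs.iterrows()},
        oncogenic_set={(r["gene"], r["protein_change"]) for _, r in onc.iterrows()},
        recurrence_counts={
            (r["gene"], r["protein_change"]): int(r["count"]) for _, r in rec.iterrows()
        },
        key_breast_genes=frozenset(g.upper() for g in key_breast_genes),
    )


# ---------------------------------------------------------------------------
# Germline filtering and pathogenicity
# ---------------------------------------------------------------------------

def filter_germline(
    cohort: Cohort,
    vaf_center: float = 50.0,
    vaf_halfwidth: float = 2.0,
    pop_af_threshold: float = 0.001,
) -> tuple[Cohort, list[VariantCall]]:
    """Remove likely-germline calls from a cohort.

    A call is removed iff its VAF lies within ``vaf_center +- vaf_halfwidth``
    percent AND its population allele frequency exceeds ``pop_af_threshold``
    percent.  An absent population AF is treated as 0, so it never triggers
    removal.  Returns a new cohort plus the removed calls (full records).
    """
    filtered = Cohort()
    removed: list[VariantCall] = []
    for profile in cohort:
        kept: list[VariantCall] = []
        for v in profile.variants:
            in_window = abs(v.vaf - vaf_center) <= vaf_halfwidth
            common = (v.population_af or 0.0) > pop_af_threshold
            (removed if in_window and common else kept).append(v)
        filtered.add(replace(profile, variants=kept, mvaf=None))
    return filtered, removed


def classify_pathogenic(
    variant: VariantCall,
    resources: AnnotationResources,
    recurrence_min: int = 3,
) -> tuple[str, str]:
    """Classify a variant as pathogenic or non-pathogenic, with a reason code.

    Branches, in order: annotated hotspot; annotated oncogenic; recurrent
    mutation (>= ``recurrence_min`` reports) in a key breast-cancer gene;
    splice-site mutation.  Anything else is non-pathogenic.
    """
    key = _norm_key(variant.gene, variant.protein_change)
    if key in resources.hotspot_set:
        return "pathogenic", "hotspot"
    if key in resources.oncogenic_set:
        return "pathogenic", "oncogenic"
    if key[0] in resources.key_breast_genes and resources.recurrence_counts.get(key, 0) >= recurrence_min:
        return "pathogenic", "recurrent-key-gene"
    if variant.variant_class == "splice":
        return "pathogenic", "splice"
    return "non-pathogenic", "no-evidence"


def classify_cohort(
    cohort: Cohort, resources: AnnotationResources, recurrence_min: int = 3
) -> Cohort:
    """Annotate every variant in place with its pathogenicity call."""
    for v in cohort.all_variants():
        v.pathogenic, v.pathogenic_reason = classify_pathogenic(v, resources, recurrence_min)
    return cohort


def is_mapk_alteration(alteration: VariantCall | CopyNumberCall | FusionCall) -> bool:
    """True if the alteration activates the MAPK/FGFR axis.

    Pathogenic point mutations in the MAPK gene set, FGFR2/FGFR3 fusions, or
    plasma copy number strictly greater than 3 in the MAPK copy-number gene
    set all qualify.
    """
    if isinstance(alteration, VariantCall):
        return (
            alteration.pathogenic == "pathogenic"
            and alteration.gene.upper() in MAPK_MUTATION_GENES
        )
    if isinstance(alteration, CopyNumberCall):
        return alteration.gene.upper() in MAPK_CN_GENES and alteration.observed_pcn > 3.0
    if isinstance(alteration, FusionCall):
        genes = {alteration.gene5.upper(), alteration.gene3.upper()}
        return bool(genes & MAPK_FUSION_GENES)
    raise TypeError(f"unsupported alteration type {type(alteration).__name__}")


def alteration_rate(cohort: Cohort) -> float:
    """Fraction of patients with at least one reported ctDNA alteration.

    Counts variants, fusions and copy-number calls alike; apply it before
    and after :func:`filter_germline` to get both headline denominators.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    hits = sum(1 for p in cohort if p.variants or p.fusions or p.cn_calls)
    return hits / len(cohort)
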