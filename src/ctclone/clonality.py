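"""Cancer fractions, clonal dominance, polyclonality and hotspot variation.

The cancer fraction (CF) of a mutation is its VAF divided by the sample's
maximum somatic VAF (mVAF), under the assumption that the mutation with the
highest allele frequency is truncal.  Mutations with CF >= 0.5 are called
clonally dominant, those below subclonal; samples with a single retained
alteration are not assessable (there is nothing to normalise against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import Cohort, PatientProfile, VariantCall
from .stats import bh_adjust, fisher_exact_2x2

DOMINANCE_THRESHOLD = 0.5


@dataclass
class ClonalityAnnotation:
    """Cancer fraction and dominance label for one variant."""

    cancer_fraction: float | None
    dominance: str  # "dominant" | "subclonal" | "not_assessable"


@dataclass
class GeneClonalitySummary:
    """Per-gene clonal-dominance summary against the rest of the cohort."""

    gene: str
    cancer_fractions: list[float]
    mean_cf: float
    n_dominant: int
    n_subclonal: int
    p_value: float
    q_value: float
    direction: str  # "more dominant" | "more subclonal" | "none"
    n_single: int = 0
    n_multiple: int = 0


def compute_mvaf(profile: PatientProfile, *, pathogenic_only: bool = False) -> float | None:
    """Maximum VAF over a patient's retained somatic variants (percent).

    Returns ``None`` for patients with no variants.  Germline filtering is
    assumed to have been applied already.  By default all retained somatic
    calls enter the maximum; set ``pathogenic_only`` to restrict to
    pathogenic-classified calls.
    """
    variants = profile.variants
    if pathogenic_only:
        variants = [v for v in variants if v.pathogenic == "pathogenic"]
    if not variants:
        return None
    return max(v.vaf for v in variants)


def annotate_clonality(
    profile: PatientProfile, *, pathogenic_only_mvaf: bool = False
) -> list[ClonalityAnnotation]:
    """Cancer fraction and dominance for each variant of one patient.

    Profiles with fewer than two variants are not assessable.  The returned
    list is aligned with ``profile.variants``; ``profile.mvaf`` is set as a
    side effect.
    """
    mvaf = compute_mvaf(profile, pathogenic_only=pathogenic_only_mvaf)
    profile.mvaf = mvaf
    if len(profile.variants) < 2:
        return [ClonalityAnnotation(None, "not_assessable") for _ in profile.variants]
    if mvaf == 0:
        raise ValueError(
            f"patient {profile.patient_id}: mVAF is 0 with variants present (inconsistent input)"
        )
    annotations = []
    for v in profile.variants:
        cf = v.vaf / mvaf
        label = "dominant" if cf >= DOMINANCE_THRESHOLD else "subclonal"
        annotations.append(ClonalityAnnotation(cf, label))
    return annotations


def clonality_table(cohort: Cohort, *, pathogenic_only_mvaf: bool = False) -> pd.DataFrame:
    """Per-variant clonality annotations for a whole cohort, as a DataFrame.

    Columns: patient_id, gene, chrom, pos, ref, alt, protein_change,
    variant_class, pathogenic, subtype, vaf_pct, mvaf_pct, cancer_fraction,
    dominance, context3.
    """
    rows = []
    for profile in cohort:
        annotations = annotate_clonality(profile, pathogenic_only_mvaf=pathogenic_only_mvaf)
        for v, ann in zip(profile.variants, annotations):
            rows.append(
                {
                    "patient_id": v.patient_id,
                    "gene": v.gene,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                    "protein_change": v.protein_change,
                    "variant_class": v.variant_class,
                    "pathogenic": v.pathogenic,
                    "subtype": profile.subtype,
                    "vaf_pct": v.vaf,
                    "mvaf_pct": profile.mvaf,
                    "cancer_fraction": ann.cancer_fraction,
                    "dominance": ann.dominance,
                    "context3": v.context3,
                }
            )
    columns = [
        "patient_id", "gene", "chrom", "pos", "ref", "alt", "protein_change",
        "variant_class", "pathogenic", "subtype", "vaf_pct", "mvaf_pct",
        "cancer_fraction", "dominance", "context3",
    ]
    return pd.DataFrame(rows, columns=columns)


def _rank_test(x: np.ndarray, y: np.ndarray, *, statistic: str = "mannwhitney") -> float:
    """Two-sided rank comparison of two independent CF samples."""
    if len(np.unique(np.concatenate([x, y]))) == 1:
        return 1.0  # all observations tied: no evidence either way
    if statistic == "mannwhitney":
        # asymptotic, no continuity correction: symmetric samples give p = 1 exactly
        return float(
            sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
        )
    if statistic == "ranksums":
        return float(sps.ranksums(x, y).pvalue)
    raise ValueError(f"unknown rank statistic {statistic!r}")


def gene_dominance_table(
    cohort: Cohort,
    *,
    pathogenic_only: bool = False,
    statistic: str = "mannwhitney",
    min_mutations: int = 1,
) -> pd.DataFrame:
    """Clonal-dominance comparison of every gene against the rest of the cohort.

    Each gene's assessable cancer fractions are compared with the pooled
    cancer fractions of all other genes by a two-sided rank-sum test, with
    Benjamini-Hochberg correction across the tested genes.  Each mutation
    contributes its own CF (no per-patient consensus).
    """
    table = clonality_table(cohort)
    table = table[table["cancer_fraction"].notna()]
    if pathogenic_only:
        table = table[table["pathogenic"] == "pathogenic"]
    if table.empty:
        raise ValueError("no assessable cancer fractions in cohort")

    genes = [g for g, sub in table.groupby("gene") if len(sub) >= min_mutations]
    rows = []
    for gene in genes:
        cfs = table.loc[table["gene"] == gene, "cancer_fraction"].to_numpy()
        rest = table.loc[table["gene"] != gene, "cancer_fraction"].to_numpy()
        p = _rank_test(cfs, rest, statistic=statistic) if len(rest) else 1.0
        direction = "none"
        if len(rest):
            if cfs.mean() > rest.mean():
                direction = "more dominant"
            elif cfs.mean() < rest.mean():
                direction = "more subclonal"
        rows.append(
            {
                "gene": gene,
                "n": len(cfs),
                "mean_cf": cfs.mean(),
                "n_dominant": int((cfs >= DOMINANCE_THRESHOLD).sum()),
                "n_subclonal": int((cfs < DOMINANCE_THRESHOLD).sum()),
                "p": p,
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows).sort_values("mean_cf", ascending=False).reset_index(drop=True)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def gene_dominance_test(
    cohort: Cohort, gene: str, *, pathogenic_only: bool = False, statistic: str = "mannwhitney"
) -> GeneClonalitySummary:
    """Dominance summary for one gene (BH-corrected across all tested genes)."""
    table = gene_dominance_table(cohort, pathogenic_only=pathogenic_only, statistic=statistic)
    match = table[table["gene"] == gene]
    if match.empty:
        raise ValueError(f"gene {gene!r} has no assessable cancer fractions in this cohort")
    row = match.iloc[0]
    ct = clonality_table(cohort)
    ct = ct[(ct["gene"] == gene) & ct["cancer_fraction"].notna()]
    if pathogenic_only:
        ct = ct[ct["pathogenic"] == "pathogenic"]
    poly = ct.groupby("patient_id").size()
    return GeneClonalitySummary(
        gene=gene,
        cancer_fractions=ct["cancer_fraction"].tolist(),
        mean_cf=float(row["mean_cf"]),
        n_dominant=int(row["n_dominant"]),
        n_subclonal=int(row["n_subclonal"]),
        p_value=float(row["p"]),
        q_value=float(row["q"]),
        direction=str(row["direction"]),
        n_single=int((poly == 1).sum()),
        n_multiple=int((poly >= 2).sum()),
    )


def polyclonality_table(cohort: Cohort, *, pathogenic_only: bool = True) -> pd.DataFrame:
    """Single- versus multiple-mutation carrier counts per gene, with Fisher tests.

    For each gene, carriers with exactly one pathogenic mutation are compared
    against carriers with two or more, versus the aggregate of all remaining
    genes, by a two-sided Fisher's exact test with BH correction across genes.
    """
    counts: dict[str, dict[str, int]] = {}
    for profile in cohort:
        per_gene: dict[str, int] = {}
        for v in profile.variants:
            if pathogenic_only and v.pathogenic != "pathogenic":
                continue
            per_gene[v.gene] = per_gene.get(v.gene, 0) + 1
        for gene, n in per_gene.items():
            slot = counts.setdefault(gene, {"single": 0, "multiple": 0})
            slot["single" if n == 1 else "multiple"] += 1
    if not counts:
        raise ValueError(
            "no qualifying variants; if the cohort is unclassified, run "
            "classify_cohort first or pass pathogenic_only=False"
        )

    total_single = sum(c["single"] for c in counts.values())
    total_multiple = sum(c["multiple"] for c in counts.values())
    rows = []
    for gene, c in sorted(counts.items()):
        table = [
            [c["multiple"], c["single"]],
            [total_multiple - c["multiple"], total_single - c["single"]],
        ]
        p = fisher_exact_2x2(table)
        n_carriers = c["single"] + c["multiple"]
        rows.append(
            {
                "gene": gene,
                "n_single": c["single"],
                "n_multiple": c["multiple"],
                "fraction_multiple": c["multiple"] / n_carriers,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def polyclonality_summary(
    cohort: Cohort, gene: str, *, pathogenic_only: bool = True
) -> pd.Series:
    """Polyclonality counts and Fisher test for one gene (see :func:`polyclonality_table`)."""
    table = polyclonality_table(cohort, pathogenic_only=pathogenic_only)
    match = table[table["gene"] == gene]
    if match.empty:
        raise ValueError(f"gene {gene!r} has no qualifying carriers in this cohort")
    return match.iloc[0]


@dataclass
class HotspotVariationResult:
    """Cancer-fraction distributions per hotspot and the across-hotspot test."""

    gene: str
    cf_by_hotspot: dict[str, list[float]]
    statistic: float
    p_value: float


def hotspot_cf_variation(
    cohort: Cohort,
    gene: str,
    min_count: int = 3,
    *,
    pathogenic_only: bool = True,
) -> HotspotVariationResult:
    """Variation in clonal dominance across a gene's hotspot mutations.

    Hotspots are keyed by protein change; an SNV hotspot is included when it
    recurs at least ``min_count`` times in the data set, while indels are
    always included.  A Kruskal-Wallis test assesses variation in cancer
    fraction across the included hotspots.
    """
    table = clonality_table(cohort)
    table = table[
        (table["gene"] == gene)
        & table["cancer_fraction"].notna()
        & (table["protein_change"] != "")
    ]
    if pathogenic_only:
        table = table[table["pathogenic"] == "pathogenic"]

    cf_by_hotspot: dict[str, list[float]] = {}
    for change, sub in table.groupby("protein_change"):
        is_indel = sub["variant_class"].isin(("frameshift", "in-frame indel")).any()
        if len(sub) >= min_count or is_indel:
            cf_by_hotspot[str(change)] = sub["cancer_fraction"].tolist()
    if len(cf_by_hotspot) < 2:
        raise ValueError(
            f"fewer than 2 qualifying hotspots for {gene}: across-hotspot test undefined"
        )
    groups = list(cf_by_hotspot.values())
    if len({cf for g in groups for cf in g}) == 1:
        statistic, p = 0.0, 1.0  # all values tied
    else:
        statistic, p = sps.kruskal(*groups)
    return HotspotVariationResult(gene, cf_by_hotspot, float(statistic), float(p))


@dataclass
class DualMutationLinkage:
    """Anchor-versus-partner cancer fractions in double-mutant patients."""

    gene: str
    anchor_change: str
    pairs: pd.DataFrame  # patient_id, anchor_cf, partner_change, partner_cf
    p_value: float | None


def dual_mutation_linkage(
    cohort: Cohort,
    gene: str,
    anchor_change: str,
    *,
    pathogenic_only: bool = True,
) -> DualMutationLinkage:
    """Pair the anchor hotspot's CF with co-occurring same-gene mutation CFs.

    Restricted to patients carrying the anchor plus at least one other
    pathogenic mutation in the gene; the two CF samples are compared with a
    two-sided rank-sum test.  With no qualifying patients the result is
    empty and no test is run.
    """
    table = clonality_table(cohort)
    table = table[(table["gene"] == gene) & table["cancer_fraction"].notna()]
    if pathogenic_only:
        table = table[table["pathogenic"] == "pathogenic"]

    rows = []
    for patient_id, sub in table.groupby("patient_id"):
        anchors = sub[sub["protein_change"] == anchor_change]
        partners = sub[sub["protein_change"] != anchor_change]
        if anchors.empty or partners.empty:
            continue
        anchor_cf = float(anchors["cancer_fraction"].max())
        for _, partner in partners.iterrows():
            rows.append(
                {
                    "patient_id": patient_id,
                    "anchor_cf": anchor_cf,
                    "partner_change": partner["protein_change"],
                    "partner_cf": float(partner["cancer_fraction"]),
                }
            )
    pairs = pd.DataFrame(rows, columns=["patient_id", "anchor_cf", "partner_change", "partner_cf"])
    p = None
    if len(pairs):
        p = _rank_test(pairs["anchor_cf"].to_numpy(), pairs["partner_cf"].to_numpy())
    return DualMutationLinkage(gene, anchor_change, pairs, p)
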