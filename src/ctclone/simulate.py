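"""Seeded synthetic ctDNA cohorts with ground truth, for end-to-end checks.

The generator emulates the statistical structure the analyses assume: each
patient carries one truncal mutation whose VAF sets the true mVAF, plus
subclonal mutations at Beta-distributed cancer fractions whose VAFs are
``CF x mVAF``; near-50%-VAF germline contaminants with non-trivial
population allele frequencies; multi-hit hotspot genes (ESR1, PIK3CA);
APOBEC-channel-enriched subclonal mutations in hormone-receptor-positive
patients; and observed HER2 plasma copy numbers produced by the purity
model ``observed = 2 (1 - t) + t x CN_true + noise``.

Coordinates live on a toy contig (``chrS``) with self-consistent
trinucleotide contexts, so no reference genome is needed.  All outputs are
deterministic for a fixed config seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .channels import APOBEC_CHANNELS, CHANNELS
from .io import (
    AnnotationResources,
    Cohort,
    CopyNumberCall,
    PatientProfile,
    VariantCall,
    write_cohort,
    write_table,
)
from .signatures import MutationCatalogue, SignatureMatrix, synthetic_signatures

# Cohort composition of a large metastatic breast-cancer ctDNA screening
# population: subtype mix and relative gene alteration frequencies.
DEFAULT_SUBTYPE_PROPORTIONS = {
    "HR+HER2-": 0.644,
    "HR+HER2+": 0.050,
    "HR-HER2+": 0.041,
    "TNBC": 0.173,
    "unknown": 0.092,
}

DEFAULT_GENE_PREVALENCE = {
    "TP53": 0.441,
    "PIK3CA": 0.349,
    "ESR1": 0.331,
    "GATA3": 0.110,
    "ARID1A": 0.078,
    "PTEN": 0.069,
    "AKT1": 0.040,
    "HER2": 0.035,
    "KRAS": 0.030,
    "NF1": 0.030,
    "SMAD4": 0.020,
}

# Hotspot spectra: protein change -> relative weight among the gene's
# mutations; the remaining mass produces private "novel" changes.
DEFAULT_HOTSPOT_SPECTRA = {
    "PIK3CA": {
        "H1047R": 0.30, "E545K": 0.20, "E542K": 0.12, "N345K": 0.08,
        "E726K": 0.08, "G1049R": 0.05, "C420R": 0.05,
    },
    "ESR1": {"D538G": 0.35, "Y537S": 0.20, "Y537N": 0.10, "E380Q": 0.12, "L536R": 0.08},
    "AKT1": {"E17K": 0.90},
    "TP53": {"R175H": 0.20, "R248Q": 0.20, "R273H": 0.20},
    "GATA3": {"D336fs": 0.50, "M294K": 0.20},
    "KRAS": {"G12D": 0.50, "G12V": 0.30, "G13D": 0.20},
    "HER2": {"L755S": 0.40, "V777L": 0.30, "S310F": 0.30},
}

DEFAULT_APOBEC_ENRICHMENT = {
    "HR+": {"dominant": 0.05, "subclonal": 0.40},
    "other": {"dominant": 0.10, "subclonal": 0.10},
}

_EXTRA_PANEL_GENES = ("ATM", "BRCA1", "BRCA2", "CDH1", "RB1", "EGFR")


@dataclass
class CohortConfig:
    """Tunable parameters of the synthetic-cohort generator.

    Distribution defaults: truncal mVAF ~ LogNormal(median 10%, sigma_log 1)
    truncated to (0.1, 80)%; subclonal cancer fraction ~ Beta(1.2, 2.5);
    VAF measurement noise sigma 0.25 percentage points (approximating
    binomial counting error at duplex-panel unique-molecule depths);
    germline contaminant VAF ~ Normal(50, 1) with population AF
    10^U(-2.5, 0) percent.
    """

    n_patients: int = 500
    subtype_proportions: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPORTIONS))
    gene_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_GENE_PREVALENCE))
    hotspot_spectra: dict = field(
        default_factory=lambda: {g: dict(s) for g, s in DEFAULT_HOTSPOT_SPECTRA.items()}
    )
    multi_hit_prob: dict = field(default_factory=lambda: {"ESR1": 0.50, "PIK3CA": 0.23})
    n_subclonal_mean: float = 2.0
    truncal_mvaf_median: float = 10.0
    truncal_mvaf_sigma_log: float = 1.0
    truncal_mvaf_bounds: tuple = (0.1, 80.0)
    subclonal_cf_alpha: float = 1.2
    subclonal_cf_beta: float = 2.5
    vaf_noise_sd: float = 0.25
    germline_rate: float = 0.2
    germline_vaf_sd: float = 1.0
    germline_pop_af_log10_range: tuple = (-2.5, 0.0)
    apobec_enrichment: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_APOBEC_ENRICHMENT.items()}
    )
    her2_amplification_rate: float = 0.09
    her2_true_cn: float = 10.0
    cn_noise_sd: float = 0.5
    organotropism: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        total = sum(self.subtype_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"subtype proportions must sum to 1 (got {total})")
        for name in ("vaf_noise_sd", "germline_rate", "cn_noise_sd", "n_subclonal_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for group in self.apobec_enrichment.values():
            for rate in group.values():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError("APOBEC enrichment rates must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("truncal_mvaf_bounds", "germline_pop_af_log10_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["truncal_mvaf_bounds"] = list(self.truncal_mvaf_bounds)
        data["germline_pop_af_log10_range"] = list(self.germline_pop_af_log10_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """True per-variant and per-patient quantities behind a synthetic cohort."""

    variants: pd.DataFrame
    patients: pd.DataFrame

    def write(self, variants_path, patients_path) -> None:
        write_table(self.variants, variants_path)
        write_table(self.patients, patients_path)


def _crc(text: str) -> int:
    return zlib.crc32(text.encode())


def _hotspot_registry(spectra: dict) -> dict[tuple[str, str], dict]:
    """Deterministic genomic identity (position, channel, class) per hotspot."""
    registry: dict[tuple[str, str], dict] = {}
    used_positions: set[int] = set()
    for gene in sorted(spectra):
        for change in sorted(spectra[gene]):
            crc = _crc(f"{gene}:{change}")
            pos = 1_000_000 + (crc % 100_000_000)
            while pos in used_positions:
                pos += 1
            used_positions.add(pos)
            if change.endswith("fs"):
                entry = {
                    "pos": pos, "ref": "A", "alt": "AT", "context3": None,
                    "variant_class": "frameshift",
                }
            else:
                label = CHANNELS[crc % 96]
                entry = {
                    "pos": pos,
                    "ref": label[2],
                    "alt": label[4],
                    "context3": label[0] + label[2] + label[6],
                    "variant_class": "missense",
                }
            registry[(gene, change)] = entry
    return registry


def resources_for(config: CohortConfig) -> AnnotationResources:
    """Annotation resources matching the generator's hotspot spectra."""
    hotspots = {
        (gene, change) for gene, spectrum in config.hotspot_spectra.items() for change in spectrum
    }
    return AnnotationResources(hotspot_set=hotspots)


def _channel_mixtures(config: CohortConfig, signatures: SignatureMatrix) -> dict:
    """Channel distributions per (HR class, dominance) from the APOBEC enrichment."""
    frame = signatures.to_frame()
    apobec = frame["Signature 13"].to_numpy()
    background = 0.6 * frame["Signature 1"].to_numpy() + 0.4 * frame["Signature 5"].to_numpy()
    mixtures = {}
    for hr_class, rates in config.apobec_enrichment.items():
        for dominance, frac in rates.items():
            p = frac * apobec + (1.0 - frac) * background
            mixtures[(hr_class, dominance)] = p / p.sum()
    return mixtures


def _truncated_lognormal(rng, median: float, sigma_log: float, bounds: tuple) -> float:
    lo, hi = bounds
    mu = np.log(median)
    for _ in range(1000):
        value = float(np.exp(rng.normal(mu, sigma_log)))
        if lo < value < hi:
            return value
    raise RuntimeError("truncated log-normal rejection sampling failed")


def generate_cohort(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a seeded synthetic cohort plus its ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    signatures = synthetic_signatures()
    mixtures = _channel_mixtures(config, signatures)
    registry = _hotspot_registry(config.hotspot_spectra)

    subtype_names = list(config.subtype_proportions)
    subtype_probs = np.array([config.subtype_proportions[s] for s in subtype_names])
    gene_names = list(config.gene_prevalence)
    gene_weights = np.array([config.gene_prevalence[g] for g in gene_names], dtype=float)
    gene_probs = gene_weights / gene_weights.sum()
    germline_genes = gene_names + list(_EXTRA_PANEL_GENES)
    sites = ("bone", "liver", "lymph node", "soft tissue", "visceral")
    site_probs = {"bone": 0.5, "liver": 0.35, "lymph node": 0.4, "soft tissue": 0.3, "visceral": 0.45}

    novel_pos = 500_000_000  # above the hotspot range; incremented per novel site
    novel_count = 0
    cohort = Cohort()
    truth_variants: list[dict] = []
    truth_patients: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        subtype = str(rng.choice(subtype_names, p=subtype_probs))
        hr_class = "HR+" if subtype.startswith("HR+") else "other"
        lines = int(rng.poisson(2.0))
        disease_sites = {s for s in sites if rng.random() < site_probs[s]}
        profile = PatientProfile(
            patient_id=pid,
            subtype=subtype,
            lines_of_treatment=lines,
            disease_sites=disease_sites,
        )

        mvaf_true = _truncated_lognormal(
            rng, config.truncal_mvaf_median, config.truncal_mvaf_sigma_log,
            config.truncal_mvaf_bounds,
        )

        # (gene, cf) plan: one truncal mutation plus Poisson subclonal ones
        plan: list[tuple[str, float]] = [(str(rng.choice(gene_names, p=gene_probs)), 1.0)]
        for _ in range(rng.poisson(config.n_subclonal_mean)):
            cf = float(rng.beta(config.subclonal_cf_alpha, config.subclonal_cf_beta))
            plan.append((str(rng.choice(gene_names, p=gene_probs)), cf))
        for gene, prob in config.multi_hit_prob.items():
            if any(g == gene for g, _ in plan) and rng.random() < prob:
                cf = float(rng.beta(config.subclonal_cf_alpha, config.subclonal_cf_beta))
                plan.append((gene, cf))
        for gene, (site, rate_in, rate_out) in config.organotropism.items():
            rate = rate_in if site in disease_sites else rate_out
            if rng.random() < rate:
                cf = float(rng.beta(config.subclonal_cf_alpha, config.subclonal_cf_beta))
                plan.append((gene, cf))

        seen_changes: set[tuple[str, str]] = set()
        for gene, cf in plan:
            dominance = "dominant" if cf >= 0.5 else "subclonal"
            spectrum = config.hotspot_spectra.get(gene, {})
            change = ""
            if spectrum:
                names = sorted(spectrum)
                probs = np.array([spectrum[n] for n in names])
                novel_mass = max(0.0, 1.0 - probs.sum())
                choice = rng.choice(len(names) + 1, p=np.append(probs, novel_mass) / (probs.sum() + novel_mass))
                if choice < len(names):
                    change = names[choice]
                    if (gene, change) in seen_changes:  # multi-hit picks a distinct change
                        alternatives = [n for n in names if (gene, n) not in seen_changes]
                        change = alternatives[0] if alternatives else ""
            if change:
                entry = registry[(gene, change)]
                seen_changes.add((gene, change))
                pos, ref, alt = entry["pos"], entry["ref"], entry["alt"]
                context3, vclass = entry["context3"], entry["variant_class"]
            else:
                channel = int(rng.choice(96, p=mixtures[(hr_class, dominance)]))
                label = CHANNELS[channel]
                novel_count += 1
                novel_pos += 1
                pos, ref, alt = novel_pos, label[2], label[4]
                context3 = label[0] + label[2] + label[6]
                vclass = "missense"
                change = f"X{novel_count}Y"

            vaf_true = cf * mvaf_true
            vaf = vaf_true
            if config.vaf_noise_sd > 0:
                vaf = float(np.clip(vaf_true + rng.normal(0.0, config.vaf_noise_sd), 0.01, 100.0))
            profile.variants.append(
                VariantCall(
                    patient_id=pid, gene=gene, chrom="chrS", pos=pos,
                    ref_allele=ref, alt_allele=alt, protein_change=change,
                    variant_class=vclass, vaf=vaf, context3=context3,
                )
            )
            is_apobec = context3 is not None and (
                CHANNELS.index(f"{context3[0]}[{ref}>{alt}]{context3[2]}") in APOBEC_CHANNELS
                if ref in "CT"
                else False
            )
            truth_variants.append(
                {
                    "patient_id": pid, "chrom": "chrS", "pos": pos, "ref": ref, "alt": alt,
                    "gene": gene, "protein_change": change, "true_cf": cf,
                    "true_dominance": dominance, "true_apobec": is_apobec, "germline": False,
                }
            )

        # germline contaminants: near-50% VAF, common in the population
        for _ in range(rng.poisson(config.germline_rate)):
            gene = str(rng.choice(germline_genes))
            channel = int(rng.choice(96, p=mixtures[("other", "dominant")]))
            label = CHANNELS[channel]
            novel_count += 1
            novel_pos += 1
            vaf = float(np.clip(rng.normal(50.0, config.germline_vaf_sd), 0.01, 100.0))
            pop_af = float(10.0 ** rng.uniform(*config.germline_pop_af_log10_range))
            profile.variants.append(
                VariantCall(
                    patient_id=pid, gene=gene, chrom="chrS", pos=novel_pos,
                    ref_allele=label[2], alt_allele=label[4],
                    protein_change=f"G{novel_count}L", variant_class="missense",
                    vaf=vaf, population_af=pop_af,
                    context3=label[0] + label[2] + label[6],
                )
            )
            truth_variants.append(
                {
                    "patient_id": pid, "chrom": "chrS", "pos": novel_pos,
                    "ref": label[2], "alt": label[4], "gene": gene,
                    "protein_change": f"G{novel_count}L", "true_cf": np.nan,
                    "true_dominance": "germline", "true_apobec": channel in APOBEC_CHANNELS,
                    "germline": True,
                }
            )

        # HER2 plasma copy number via the purity model
        amplified = bool(rng.random() < config.her2_amplification_rate)
        cn_true = config.her2_true_cn if amplified else 2.0
        t_true = min(1.0, 2.0 * mvaf_true / 100.0)
        observed = 2.0 * (1.0 - t_true) + t_true * cn_true
        if config.cn_noise_sd > 0:
            observed += float(rng.normal(0.0, config.cn_noise_sd))
        observed = max(observed, 0.0)
        profile.cn_calls.append(CopyNumberCall(pid, "HER2", observed))
        profile.tissue_her2_status = "positive" if amplified else "negative"

        cohort.add(profile)
        truth_patients.append(
            {
                "patient_id": pid, "subtype": subtype, "mvaf_true": mvaf_true,
                "t_true": t_true, "her2_cn_true": cn_true, "her2_amplified": amplified,
            }
        )

    truth = GroundTruth(
        variants=pd.DataFrame(truth_variants),
        patients=pd.DataFrame(truth_patients),
    )
    return cohort, truth


def generate_signature_mixture(
    signatures: SignatureMatrix,
    exposures,
    n_mutations: int,
    seed: int | None = None,
) -> tuple[list[VariantCall], MutationCatalogue]:
    """Sample a mutation list from a known signature mixture.

    Channels are drawn i.i.d. from ``signatures @ exposures`` with any
    unassigned residual spread uniformly; the emitted variant list carries
    synthetic coordinates and self-consistent contexts, so it can be fed
    back through the catalogue builder and the exposure fitter as an
    end-to-end oracle.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be at least 1")
    e = np.asarray(exposures, dtype=float)
    if e.shape != (signatures.k,):
        raise ValueError(f"exposures must have length {signatures.k}")
    if np.any(e < 0) or e.sum() > 1.0 + 1e-9:
        raise ValueError("exposures must be non-negative with sum <= 1")
    p = signatures.probs @ e + (1.0 - e.sum()) / 96.0
    p = p / p.sum()

    rng = np.random.default_rng(seed)
    channels = rng.choice(96, size=n_mutations, p=p)
    variants = []
    for i, channel in enumerate(channels):
        label = CHANNELS[channel]
        variants.append(
            VariantCall(
                patient_id="SIM", gene="SYN", chrom="chrS", pos=i + 1,
                ref_allele=label[2], alt_allele=label[4], protein_change="",
                variant_class="missense", vaf=10.0,
                context3=label[0] + label[2] + label[6],
            )
        )
    return variants, MutationCatalogue.from_channels(channels)


def write_synthetic_cohort(
    config: CohortConfig, out_dir, meta: dict | None = None
) -> dict[str, Path]:
    """Generate a cohort and write the native tables plus the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(config)
    paths = {
        "variants": out / "variants.tsv",
        "clinical": out / "clinical.tsv",
        "cn": out / "cn.tsv",
        "truth_variants": out / "truth_variants.tsv",
        "truth_patients": out / "truth_patients.tsv",
    }
    write_cohort(cohort, paths["variants"], paths["clinical"], paths["cn"], meta)
    truth.write(paths["truth_variants"], paths["truth_patients"])
    return paths
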