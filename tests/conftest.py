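"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from ctclone import (
    AnnotationResources,
    Cohort,
    PatientProfile,
    VariantCall,
    synthetic_signatures,
)
from ctclone.simulate import CohortConfig, generate_cohort

_POS = itertools.count(1)


def make_variant(
    patient_id: str = "P1",
    gene: str = "TP53",
    vaf: float = 10.0,
    *,
    protein_change: str = "",
    variant_class: str = "missense",
    population_af: float | None = None,
    ref: str = "C",
    alt: str = "T",
    context3: str | None = "ACA",
    pos: int | None = None,
    pathogenic: str = "unclassified",
) -> VariantCall:
    """A valid variant call with auto-incrementing position."""
    return VariantCall(
        patient_id=patient_id,
        gene=gene,
        chrom="chrT",
        pos=pos if pos is not None else next(_POS),
        ref_allele=ref,
        alt_allele=alt,
        protein_change=protein_change,
        variant_class=variant_class,
        vaf=vaf,
        population_af=population_af,
        context3=context3,
        pathogenic=pathogenic,
    )


def make_cohort(variants_by_patient: dict[str, list[VariantCall]], **profile_kwargs) -> Cohort:
    """Build a cohort from a {patient_id: [variants]} mapping."""
    cohort = Cohort()
    for pid, variants in variants_by_patient.items():
        cohort.add(PatientProfile(patient_id=pid, variants=list(variants), **profile_kwargs))
    return cohort


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Independent of scipy: exact integer arithmetic over all tables with the
    observed margins, summing the probabilities of tables no more probable
    than the observed one.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    denom = comb(r1 + r2, c1)
    return sum(nx for nx in nums.values() if nx <= nums[a]) / denom


@pytest.fixture(scope="session")
def signatures():
    return synthetic_signatures()


@pytest.fixture(scope="session")
def resources():
    return AnnotationResources(
        hotspot_set={("PIK3CA", "H1047R"), ("ESR1", "D538G"), ("AKT1", "E17K")},
        oncogenic_set={("KRAS", "G12D")},
        recurrence_counts={("ESR1", "A283V"): 5, ("TP53", "P72R"): 8},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A default synthetic cohort (seed 1) with its ground truth."""
    return generate_cohort(CohortConfig(seed=1))
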