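"""Contingency statistics: Fisher/chi-squared tests, BH FDR, co-occurrence.

All p-values are two-sided.  The two-sided Fisher test uses the
probability-mass definition (sum of hypergeometric probabilities no larger
than the observed table's), and the chi-squared test applies no continuity
correction by default.  FDR families follow the analysis groupings: one
Benjamini-Hochberg family per analysis, not one global family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import Cohort


@dataclass
class ContingencyResult:
    """A single 2x2 (or stratified) test with its FDR-corrected q-value."""

    family: str
    unit_a: str
    unit_b: str
    table: np.ndarray
    test: str
    statistic: float | None
    p_value: float
    q_value: float | None = None
    direction: str = "none"


def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table.

    A table with a zero margin carries no information about association;
    it returns p = 1 with a warning.
    """
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("2x2 table has a zero margin; returning p = 1", stacklevel=2)
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def chi2_2x2(table, continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test (1 df) for a 2x2 table.

    No Yates continuity correction by default.  Returns ``(statistic, p)``.
    """
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin; chi-squared undefined")
    res = sps.chi2_contingency(t, correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def proportion_pct(k: int, n: int) -> float:
    """Incidence as a percentage (e.g. 3 of 41 -> 7.32)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * k / n


def _direction_from_or(table: np.ndarray) -> str:
    a, b = table[0]
    c, d = table[1]
    ad, bc = a * d, b * c
    if ad > bc:
        return "co-occurrent"
    if ad < bc:
        return "mutually exclusive"
    return "none"


def gene_presence(cohort: Cohort, *, pathogenic_only: bool = True) -> pd.DataFrame:
    """Patients x genes boolean presence matrix of (pathogenic) mutations."""
    patients = cohort.patient_ids
    presence: dict[str, set[str]] = {}
    for v in cohort.all_variants():
        if pathogenic_only and v.pathogenic != "pathogenic":
            continue
        presence.setdefault(v.gene, set()).add(v.patient_id)
    data = {
        gene: [pid in carriers for pid in patients]
        for gene, carriers in sorted(presence.items())
    }
    return pd.DataFrame(data, index=patients, dtype=bool)


def cooccurrence_matrix(
    cohort: Cohort,
    min_incidence: float = 0.05,
    *,
    pathogenic_only: bool = True,
    family: str = "cooccurrence",
) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual-exclusivity tests over qualifying genes.

    Genes altered in at least ``min_incidence`` of the cohort are tested in
    all unordered pairs with a two-sided Fisher's exact test, BH-corrected
    across pairs; the direction comes from the odds ratio relative to 1.

    Returns a long-format DataFrame: family, unit_a, unit_b, a, b, c, d,
    test, statistic, p, q, direction.
    """
    presence = gene_presence(cohort, pathogenic_only=pathogenic_only)
    n = len(cohort)
    qualifying = [g for g in presence.columns if presence[g].sum() / n >= min_incidence]
    if len(qualifying) < 2:
        raise ValueError(
            f"fewer than 2 genes reach {min_incidence:.0%} incidence; no pairs to test"
        )
    rows = []
    for gene_a, gene_b in combinations(qualifying, 2):
        in_a = presence[gene_a].to_numpy()
        in_b = presence[gene_b].to_numpy()
        a = int((in_a & in_b).sum())
        b = int((in_a & ~in_b).sum())
        c = int((~in_a & in_b).sum())
        d = int((~in_a & ~in_b).sum())
        table = np.array([[a, b], [c, d]])
        rows.append(
            {
                "family": family,
                "unit_a": gene_a,
                "unit_b": gene_b,
                "a": a, "b": b, "c": c, "d": d,
                "test": "fisher",
                "statistic": np.nan,
                "p": fisher_exact_2x2(table),
                "direction": _direction_from_or(table),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out[["family", "unit_a", "unit_b", "a", "b", "c", "d",
                "test", "statistic", "p", "q", "direction"]]


@dataclass
class GroupAssociationResult:
    """Per-level 2x2 Fisher tests plus, for >2 exclusive levels, a group-wise chi-squared."""

    gene: str
    grouping: str
    levels: pd.DataFrame  # family, unit_a, unit_b, a, b, c, d, test, statistic, p, q, direction
    overall_statistic: float | None
    overall_p: float | None


def _patient_levels(cohort: Cohort, grouping) -> tuple[str, dict[str, set[str]], bool]:
    """Resolve a grouping spec into level -> patient-id sets.

    Returns ``(name, levels, exclusive)`` where ``exclusive`` is True when
    each patient belongs to exactly one level (categorical covariate) and
    False for set-valued covariates such as disease sites.
    """
    if callable(grouping):
        name = getattr(grouping, "__name__", "custom")
        levels: dict[str, set[str]] = {}
        for p in cohort:
            level = grouping(p)
            if level is None:
                continue
            levels.setdefault(str(level), set()).add(p.patient_id)
        return name, levels, True
    if grouping == "disease_sites":
        levels = {}
        for p in cohort:
            for site in p.disease_sites:
                levels.setdefault(site, set()).add(p.patient_id)
        return grouping, levels, False
    if grouping in ("subtype", "tissue_her2_status", "lines_of_treatment"):
        levels = {}
        for p in cohort:
            value = getattr(p, grouping)
            if value is None or value == "unknown":
                continue
            levels.setdefault(str(value), set()).add(p.patient_id)
        return grouping, levels, True
    raise ValueError(f"unknown grouping {grouping!r}")


def group_association(
    cohort: Cohort,
    gene: str,
    grouping,
    *,
    pathogenic_only: bool = True,
) -> GroupAssociationResult:
    """Association of a gene's alterations with a clinical covariate.

    ``grouping`` is a covariate name (``subtype``, ``disease_sites``,
    ``tissue_her2_status``, ``lines_of_treatment``) or a callable mapping a
    :class:`PatientProfile` to a level (return ``None`` to drop a patient).
    Each level gets a 2x2 Fisher test of mutated x in-level; levels with no
    patients are dropped with a warning; BH correction is applied across the
    levels of this one analysis.  For exclusive groupings with more than two
    levels a group-wise chi-squared over the full contingency table is also
    reported.
    """
    name, levels, exclusive = _patient_levels(cohort, grouping)
    levels = {lvl: pids for lvl, pids in levels.items() if pids or _warn_empty(lvl)}
    if not levels:
        raise ValueError(f"grouping {name!r} produced no populated levels")

    carriers = {
        v.patient_id
        for v in cohort.all_variants()
        if v.gene == gene and (not pathogenic_only or v.pathogenic == "pathogenic")
    }
    universe = set(cohort.patient_ids)

    rows = []
    for level, pids in sorted(levels.items()):
        a = len(carriers & pids)
        b = len(pids - carriers)
        c = len(carriers - pids)
        d = len(universe - pids - carriers)
        table = np.array([[a, b], [c, d]])
        direction = "none"
        if a * d != b * c:
            direction = "enriched-in-A" if a * d > b * c else "enriched-in-B"
        rows.append(
            {
                "family": f"{gene}~{name}",
                "unit_a": gene,
                "unit_b": level,
                "a": a, "b": b, "c": c, "d": d,
                "test": "fisher",
                "statistic": np.nan,
                "p": fisher_exact_2x2(table),
                "direction": direction,
            }
        )
    per_level = pd.DataFrame(rows)
    per_level["q"] = bh_adjust(per_level["p"].to_numpy())
    per_level = per_level[["family", "unit_a", "unit_b", "a", "b", "c", "d",
                           "test", "statistic", "p", "q", "direction"]]

    overall_stat = overall_p = None
    if exclusive and len(levels) >= 2:
        counts = np.array(
            [
                [len(carriers & pids), len(pids - carriers)]
                for _, pids in sorted(levels.items())
            ]
        ).T  # 2 x L: mutated / wild-type per level
        if np.all(counts.sum(axis=0) > 0) and np.all(counts.sum(axis=1) > 0):
            res = sps.chi2_contingency(counts, correction=False)
            overall_stat, overall_p = float(res.statistic), float(res.pvalue)
    return GroupAssociationResult(gene, name, per_level, overall_stat, overall_p)


def _warn_empty(level: str) -> bool:
    warnings.warn(f"dropping level {level!r} with zero patients", stacklevel=3)
    return False
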