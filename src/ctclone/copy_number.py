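"""Purity adjustment of plasma copy number and amplification calling.

Plasma copy number is diluted by normal cell-free DNA.  With tumour
fraction ``t`` estimated from the maximum somatic VAF under a
heterozygous-truncal assumption (``t = 2 x mVAF / 100``), the tumour-level
copy number is recovered as ``adjusted = (observed - 2 (1 - t)) / t``:
a copy-neutral gene (observed 2) maps to 2 for every tumour fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from statsmodels.stats.proportion import proportion_confint

from .clonality import compute_mvaf
from .io import Cohort


@dataclass
class TumourFraction:
    """Estimated tumour-derived fraction of plasma DNA."""

    t: float
    clamped: bool = False


def tumour_fraction(mvaf_pct: float) -> TumourFraction:
    """Tumour fraction from the maximum somatic VAF (percent).

    ``t = 2 x mVAF / 100``, clamped to 1 with a warning when mVAF exceeds
    50% (VAF above 50% implies LOH or copy-number effects this linear model
    ignores).  An mVAF of zero or below leaves the adjustment undefined.
    """
    if mvaf_pct <= 0:
        raise ValueError(f"mVAF must be positive to estimate tumour fraction, got {mvaf_pct}")
    t = 2.0 * mvaf_pct / 100.0
    if t > 1.0:
        warnings.warn(
            f"mVAF {mvaf_pct}% implies tumour fraction {t:.2f} > 1; clamping to 1",
            stacklevel=2,
        )
        return TumourFraction(1.0, clamped=True)
    return TumourFraction(t)


def adjust_pcn(observed_pcn: float, t: float, *, floor: bool = True) -> float:
    """Purity-adjusted plasma copy number ``(observed - 2 (1 - t)) / t``.

    Negative adjusted values (purity overestimation artefacts) are floored
    at 0 with a warning unless ``floor=False``.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"tumour fraction must be in (0, 1], got {t}")
    adjusted = (observed_pcn - 2.0 * (1.0 - t)) / t
    if adjusted < 0 and floor:
        warnings.warn(
            f"adjusted pCN {adjusted:.3f} < 0 (observed {observed_pcn}, t {t}); flooring at 0",
            stacklevel=2,
        )
        return 0.0
    return adjusted


def adjust_cohort(
    cohort: Cohort, gene: str = "HER2", operating_threshold: float = 2.0
) -> pd.DataFrame:
    """Purity-adjust one gene's plasma copy number across a cohort.

    Patients without a copy-number call for the gene, or without a positive
    mVAF, are skipped (adjustment undefined).  Returns a DataFrame with both
    the raw and the floored adjusted values and the call at the operating
    threshold (strictly greater than).
    """
    rows = []
    for profile in cohort:
        mvaf = profile.mvaf if profile.mvaf is not None else compute_mvaf(profile)
        for call in profile.cn_calls:
            if call.gene != gene:
                continue
            if mvaf is None or mvaf <= 0:
                continue
            # clamping (mVAF > 50%) and negative adjusted values are routine
            # at cohort scale; the table records the raw values instead of
            # warning per patient
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tf = tumour_fraction(mvaf)
                raw = adjust_pcn(call.observed_pcn, tf.t, floor=False)
            adjusted = max(raw, 0.0)
            call.adjusted_pcn = adjusted
            rows.append(
                {
                    "patient_id": profile.patient_id,
                    "gene": gene,
                    "observed_pcn": call.observed_pcn,
                    "mvaf_pct": mvaf,
                    "t": tf.t,
                    "adjusted_pcn_raw": raw,
                    "adjusted_pcn": adjusted,
                    "call_at_threshold": adjusted > operating_threshold,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "gene", "observed_pcn", "mvaf_pct", "t",
            "adjusted_pcn_raw", "adjusted_pcn", "call_at_threshold",
        ],
    )


@dataclass
class RocResult:
    """ROC of adjusted copy number against tissue amplification labels."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    operating_threshold: float
    sens_at_threshold: float
    sens_ci: tuple[float, float]
    spec_at_threshold: float
    spec_ci: tuple[float, float]
    ci_method: str = "clopper-pearson"


def amplification_roc(
    adjusted_pcn,
    tissue_labels,
    operating_threshold: float = 2.0,
) -> RocResult:
    """Evaluate amplification calling against binary tissue labels.

    The classification rule is ``adjusted_pcn > threshold`` (strict).  The
    full ROC is traced over the sorted unique adjusted values with
    trapezoidal AUC; sensitivity and specificity at the operating threshold
    get exact Clopper-Pearson 95% confidence intervals.
    """
    scores = np.asarray(adjusted_pcn, dtype=float)
    labels = np.asarray(tissue_labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("adjusted_pcn and tissue_labels must have the same length")
    if labels.all() or not labels.any():
        raise ValueError("tissue labels contain a single class; ROC undefined")

    fpr, tpr, thresholds = roc_curve(labels, scores)
    roc_auc = float(auc(fpr, tpr))

    pred = scores > operating_threshold
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    sens_ci = proportion_confint(tp, n_pos, alpha=0.05, method="beta")
    spec_ci = proportion_confint(tn, n_neg, alpha=0.05, method="beta")
    return RocResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=roc_auc,
        operating_threshold=operating_threshold,
        sens_at_threshold=sens,
        sens_ci=(float(sens_ci[0]), float(sens_ci[1])),
        spec_at_threshold=spec,
        spec_ci=(float(spec_ci[0]), float(spec_ci[1])),
    )
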