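"""Age-bias correction and the brain-age gap (BAG).

Brain-age models systematically over-predict young and under-predict
old subjects (regression to the mean).  The correction fits the line

    Y = alpha * Omega + beta

of predicted age Y on chronological age Omega in the training sample,
then adjusts predictions elsewhere as

    corrected = Y + Omega - (alpha * Omega + beta)

so that a prediction lying exactly on the fitted line maps to the
subject's own chronological age.  The brain-age gap is

    BAG = corrected - Omega        (years)

On the fitting sample itself the corrected predictions regress on Omega
with slope 1 and intercept 0, BAG equals the OLS residuals (mean 0,
uncorrelated with age) — properties the test-suite asserts to 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BiasCorrection", "fit_bias", "apply_bias", "compute_bag", "bag_table"]


@dataclass(frozen=True)
class BiasCorrection:
    """The (alpha, beta) line of predicted on chronological age.

    ``source`` records which predictions were used to fit it
    ("out-of-fold" or "in-sample")."""

    alpha: float
    beta: float
    source: str = "out-of-fold"


def fit_bias(predicted: np.ndarray, ages: np.ndarray, source: str = "out-of-fold") -> BiasCorrection:
    """OLS fit of predicted age on chronological age."""
    y = np.asarray(predicted, dtype=float)
    omega = np.asarray(ages, dtype=float)
    if len(y) != len(omega) or len(y) < 3:
        raise ValueError("need >= 3 aligned (prediction, age) pairs")
    if np.ptp(omega) == 0:
        raise ValueError("bias fit undefined: chronological ages are constant")
    res = stats.linregress(omega, y)
    return BiasCorrection(alpha=float(res.slope), beta=float(res.intercept), source=source)


def apply_bias(predicted: np.ndarray, ages: np.ndarray, bc: BiasCorrection) -> np.ndarray:
    """corrected = Y + Omega - (alpha*Omega + beta), elementwise."""
    y = np.asarray(predicted, dtype=float)
    omega = np.asarray(ages, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(omega))):
        raise ValueError("non-finite predictions or ages")
    return y + omega - (bc.alpha * omega + bc.beta)


def compute_bag(corrected: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """BAG = corrected predicted age - chronological age (years)."""
    corrected = np.asarray(corrected, dtype=float)
    omega = np.asarray(ages, dtype=float)
    if corrected.shape != omega.shape:
        raise ValueError("corrected and age vectors must have equal length")
    return corrected - omega


def bag_table(
    subject_ids: list[str],
    ages: np.ndarray,
    predicted: np.ndarray,
    bc: BiasCorrection,
    modality: str,
) -> pd.DataFrame:
    """Per-subject BAG report (one modality)."""
    corrected = apply_bias(predicted, ages, bc)
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": np.asarray(ages, dtype=float),
            "predicted_age": np.asarray(predicted, dtype=float),
            "corrected_predicted_age": corrected,
            "bag": compute_bag(corrected, ages),
            "modality": modality,
        }
    )
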