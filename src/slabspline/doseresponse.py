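"""Dose-response curves with delta-method pointwise uncertainty.

The estimand is the dose-response difference

    Delta(x) = E[Y | X = x] - E[Y | X = x_ref]

with x_ref = 0 for all strategies except the zero-dose-excluding one, whose
reference is the minimum observed positive dose (a different estimand).
Because every model here is linear in its coefficients, Delta-hat(x) is a
linear contrast c'beta-hat with c = (design row at x) - (design row at
x_ref); covariate entries cancel. The pointwise standard error is the
delta-method quadratic form sqrt(c' V c) with V the robust covariance, and
bands use normal quantiles (1.96 at the 95% level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import InvalidInputError, InvalidReferenceError
from .modelzoo import FitResult, ModelSpec, exposure_row

__all__ = ["DoseResponseEstimate", "contrast", "delta_curve"]


@dataclass
class DoseResponseEstimate:
    """Delta-hat(x) over a dose grid with pointwise SEs and confidence bounds.

    Grid points where the estimand is undefined for the strategy (doses below
    the minimum observed positive dose when zero doses are excluded, or doses
    falling in a category that was empty in the fitted data) carry NaN.
    """

    grid: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference_dose: float
    level: float
    model_label: str = ""

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "dose": self.grid,
                "estimate": self.estimate,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "reference_dose": self.reference_dose,
                "model_label": self.model_label,
            }
        )


def contrast(spec: ModelSpec, x: float, reference: float, design_labels: list[str]) -> np.ndarray:
    """Coefficient weights c with Delta-hat(x) = c' beta-hat.

    Built as the difference of exposure design rows at ``x`` and at
    ``reference``, aligned to the fitted labels; covariate weights are zero.
    Raises if the reference is excluded by the spec (zero dose for the
    zero-excluding strategy) or if the contrast needs a design column that
    was dropped from the fit (an empty category level).
    """
    if x < 0 or reference < 0:
        raise InvalidInputError("doses must be nonnegative")
    if spec.exclude_zero_dose and reference == 0:
        raise InvalidReferenceError(
            "zero dose is excluded by this strategy; reference must be a positive dose"
        )
    rows, labels = exposure_row(spec, [x, reference])
    diff = rows[0] - rows[1]
    c = np.zeros(len(design_labels))
    for lab, w in zip(labels, diff):
        if lab in design_labels:
            c[design_labels.index(lab)] = w
        elif w != 0:
            raise InvalidReferenceError(
                f"contrast at dose {x} needs column {lab!r} absent from the fit"
            )
    return c


def delta_curve(
    fit: FitResult,
    spec: ModelSpec,
    grid,
    reference_rule: str | None = None,
    level: float = 0.95,
) -> DoseResponseEstimate:
    """Evaluate Delta-hat with delta-method pointwise confidence bands.

    ``reference_rule`` defaults to the spec's own rule. Grid points where the
    estimand is undefined are flagged as NaN rather than aborting.
    """
    grid = np.asarray(grid, dtype=float).ravel()
    if np.any(grid < 0):
        raise InvalidInputError("grid doses must be nonnegative")
    rule = reference_rule or spec.reference_rule
    if rule == "minimum_observed_positive":
        if fit.min_positive_dose is None:
            raise InvalidReferenceError("no positive doses observed; reference undefined")
        reference = fit.min_positive_dose
    else:
        reference = 0.0
    z = norm.ppf(0.5 + level / 2.0)
    V = fit.robust_covariance
    est = np.full(len(grid), np.nan)
    se = np.full(len(grid), np.nan)
    for i, gx in enumerate(grid):
        if spec.exclude_zero_dose and gx < reference:
            continue  # below the minimum observed dose: estimand undefined
        try:
            c = contrast(spec, float(gx), reference, fit.design_labels)
        except InvalidReferenceError:
            continue
        est[i] = c @ fit.coefficients
        se[i] = np.sqrt(max(c @ V @ c, 0.0))
    return DoseResponseEstimate(
        grid=grid,
        estimate=est,
        se=se,
        ci_lower=est - z * se,
        ci_upper=est + z * se,
        reference_dose=reference,
        level=level,
        model_label=spec.label,
    )
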