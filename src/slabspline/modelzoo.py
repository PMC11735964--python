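"""The nine dose-response modeling strategies and their estimation machinery.

Strategies compared by the Monte-Carlo study (dose fractions are literal
dose values):

1. linear dose, no spike (embeds the safe-dose assumption);
2. linear dose + spike at zero;
3. quadratic dose + spike at zero (correctly specified under the study's
   generating mechanism);
4. categorical dose: 0, (0, 1/3], (1/3, 2/3], > 2/3;
5. natural cubic spline, knots {1/8, 1/2, 7/8}, no spike;
6. natural cubic spline, knots {1/8, 1/2, 7/8}, + spike;
7. natural cubic spline, knots {1/3, 1/2, 2/3}, + spike;
8. slab-and-spline, knots {7/16, 5/8, 13/16}: spike indicator plus the
   zero-slope-constrained spline basis, so the exposed-group curve is a
   constant "slab" over (0, 7/16) joining the spline smoothly at 7/16 while
   the zero-dose group keeps its own intercept (one fewer degree of freedom
   than spike + spline);
9. natural cubic spline among positive doses only (zero-dose rows excluded),
   estimand referenced to the minimum observed positive dose.

Estimation is ordinary least squares with Huber-White (sandwich)
heteroskedasticity-consistent standard errors, optionally cluster-robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import KnotSet, dose_categories, ncs_basis, slab_spline_basis, spike_indicator
from .exceptions import (
    CollinearityError,
    InsufficientDataError,
    InvalidInputError,
    InvalidSpecError,
)

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "catalog_models",
    "build_design",
    "exposure_row",
    "fit_ols",
    "robust_covariance",
    "fit_model",
]

_EXPOSURE_FORMS = {"linear", "quadratic", "categorical", "ncs", "slab_spline"}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one modeling strategy."""

    strategy_id: int
    label: str
    exposure_form: str
    include_spike: bool = False
    knots: KnotSet | None = None
    breaks: tuple[float, ...] | None = None
    exclude_zero_dose: bool = False
    reference_rule: str = "zero_dose"

    def __post_init__(self) -> None:
        if self.exposure_form not in _EXPOSURE_FORMS:
            raise InvalidSpecError(f"unknown exposure_form {self.exposure_form!r}")
        if self.exposure_form in ("ncs", "slab_spline") and self.knots is None:
            raise InvalidSpecError(f"{self.exposure_form} requires knots")
        if self.exposure_form == "categorical":
            if self.breaks is None:
                raise InvalidSpecError("categorical exposure requires breaks")
            if self.include_spike:
                raise InvalidSpecError(
                    "categorical models take zero dose as its own category; "
                    "a spike term would be collinear"
                )
        if self.reference_rule not in ("zero_dose", "minimum_observed_positive"):
            raise InvalidSpecError(f"unknown reference_rule {self.reference_rule!r}")
        if self.exclude_zero_dose and self.reference_rule != "minimum_observed_positive":
            raise InvalidSpecError(
                "excluding zero doses leaves no zero-dose reference; use "
                "reference_rule='minimum_observed_positive'"
            )


def catalog_models(knot_scale: float = 1.0) -> list[ModelSpec]:
    """The nine strategies of the simulation study.

    ``knot_scale`` multiplies all knot and break values (default 1: knots are
    the literal printed dose fractions; pass the dose-scale parameter to
    express them as fractions of the maximum dose instead).
    """
    s = float(knot_scale)
    if s <= 0:
        raise InvalidSpecError("knot_scale must be positive")
    k_wide = KnotSet((s / 8, s / 2, 7 * s / 8))
    k_mid = KnotSet((s / 3, s / 2, 2 * s / 3))
    k_slab = KnotSet((7 * s / 16, 5 * s / 8, 13 * s / 16))
    return [
        ModelSpec(1, "linear, no spike", "linear"),
        ModelSpec(2, "linear + spike", "linear", include_spike=True),
        ModelSpec(3, "quadratic + spike", "quadratic", include_spike=True),
        ModelSpec(4, "categorical", "categorical", breaks=(s / 3, 2 * s / 3)),
        ModelSpec(5, "NCS {1/8,1/2,7/8}, no spike", "ncs", knots=k_wide),
        ModelSpec(6, "NCS {1/8,1/2,7/8} + spike", "ncs", include_spike=True, knots=k_wide),
        ModelSpec(7, "NCS {1/3,1/2,2/3} + spike", "ncs", include_spike=True, knots=k_mid),
        # the slab model keeps the zero-dose group distinct (spike) and holds
        # the exposed curve constant over (0, 7/16): one fewer df than
        # spike + spline, without reimposing a through-the-origin low-dose fit
        ModelSpec(8, "slab-and-spline {7/16,5/8,13/16}", "slab_spline", include_spike=True, knots=k_slab),
        ModelSpec(
            9,
            "NCS, zero doses excluded",
            "ncs",
            knots=k_wide,
            exclude_zero_dose=True,
            reference_rule="minimum_observed_positive",
        ),
    ]


@dataclass
class Design:
    """Assembled design matrix with labels and row bookkeeping."""

    matrix: np.ndarray
    labels: list[str]
    row_mask: np.ndarray  # True for rows kept (False only when zero doses excluded)
    dropped_levels: list[str] = field(default_factory=list)
    category_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]


def _exposure_columns(spec: ModelSpec, x: np.ndarray):
    """Exposure-part columns (beyond intercept and spike) and their labels."""
    anchored = True  # affine reparametrization; fits and contrasts unchanged
    if spec.exposure_form == "linear":
        return x[:, None], ["dose"]
    if spec.exposure_form == "quadratic":
        return np.column_stack([x, x**2]), ["dose", "dose^2"]
    if spec.exposure_form == "ncs":
        b = ncs_basis(x, spec.knots, anchor_at_zero=anchored)
        return b.values, b.column_labels
    if spec.exposure_form == "slab_spline":
        b = slab_spline_basis(x, spec.knots, anchor_at_zero=anchored)
        return b.values, b.column_labels
    if spec.exposure_form == "categorical":
        cats = dose_categories(x, spec.breaks)
        n_levels = len(spec.breaks) + 2  # zero + bins + top-open
        cols = np.zeros((len(x), n_levels - 1))
        for j in range(1, n_levels):
            cols[:, j - 1] = cats == j
        labels = [f"cat{j}" for j in range(1, n_levels)]
        return cols, labels
    raise InvalidSpecError(spec.exposure_form)


def exposure_row(spec: ModelSpec, x) -> tuple[np.ndarray, list[str]]:
    """Design rows (intercept, spike, exposure columns) at arbitrary doses.

    Used both to build fitting designs and to form dose-response contrasts.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    parts = [np.ones((len(x), 1))]
    labels = ["intercept"]
    if spec.include_spike:
        parts.append(spike_indicator(x)[:, None])
        labels.append("spike")
    cols, exp_labels = _exposure_columns(spec, x)
    parts.append(cols)
    labels.extend(exp_labels)
    return np.hstack(parts), labels


def _rank_check(X: np.ndarray, labels: list[str]) -> None:
    # QR with pivoting localizes near-zero diagonal entries to named columns
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise CollinearityError(bad)


def build_design(spec: ModelSpec, x, covariates=None, drop_empty_categories: bool = True) -> Design:
    """Assemble the design matrix for a strategy.

    Column order: intercept, spike (if any), exposure columns, covariates.
    For a strategy that excludes zero doses the full data are passed in and
    the zero-dose rows are dropped; ``row_mask`` records which rows survive.
    Empty dose categories (possible in sparse samples) are dropped from the
    design and recorded in ``dropped_levels`` rather than aborting the fit.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.any(x < 0):
        raise InvalidInputError("doses must be nonnegative")
    row_mask = np.ones(len(x), dtype=bool)
    if spec.exclude_zero_dose:
        row_mask = x > 0
        if not row_mask.any():
            raise InvalidInputError("all doses are zero; nothing left after exclusion")
    xk = x[row_mask]
    X, labels = exposure_row(spec, xk)

    dropped: list[str] = []
    counts: dict[str, int] = {}
    if spec.exposure_form == "categorical":
        keep = []
        for j, lab in enumerate(labels):
            if lab.startswith("cat"):
                n_in = int(X[:, j].sum())
                counts[lab] = n_in
                if n_in == 0 and drop_empty_categories:
                    dropped.append(lab)
                    continue
            keep.append(j)
        X = X[:, keep]
        labels = [labels[j] for j in keep]

    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != len(x):
            raise InvalidInputError("covariates must have one row per observation")
        if hasattr(covariates, "columns"):
            zlabels = [str(c) for c in covariates.columns]
        else:
            zlabels = [f"z{j}" for j in range(Z.shape[1])]
        X = np.hstack([X, Z[row_mask]])
        labels = labels + zlabels

    # rank is only checkable with at least as many rows as columns; a short
    # design is legal to build (e.g. single-row contrast evaluation) and the
    # fit itself rejects n <= p
    if X.shape[0] >= X.shape[1]:
        _rank_check(X, labels)
    return Design(X, labels, row_mask, dropped, counts)


@dataclass
class FitResult:
    """OLS fit with robust covariance.

    ``sigma_hat`` is the residual standard deviation with the usual
    degrees-of-freedom correction, sqrt(RSS / (n - p)).
    """

    coefficients: np.ndarray
    robust_covariance: np.ndarray
    residuals: np.ndarray
    n_obs: int
    sigma_hat: float
    design_labels: list[str]
    cluster_count: int | None = None
    dropped_levels: list[str] = field(default_factory=list)
    row_mask: np.ndarray | None = None
    min_positive_dose: float | None = None

    def coef(self, label: str) -> float:
        return float(self.coefficients[self.design_labels.index(label)])

    def se(self, label: str) -> float:
        j = self.design_labels.index(label)
        return float(np.sqrt(self.robust_covariance[j, j]))


def fit_ols(design: Design, y) -> FitResult:
    """Ordinary least squares via QR; robust covariance is filled in separately."""
    y = np.asarray(y, dtype=float).ravel()
    if design.row_mask is not None and len(y) == len(design.row_mask):
        y = y[design.row_mask]
    if len(y) != design.n_obs:
        raise InvalidInputError("outcome length does not match design rows")
    if design.n_obs <= design.n_params:
        raise InsufficientDataError(
            f"need more than {design.n_params} observations, got {design.n_obs}"
        )
    X = design.matrix
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < design.n_params:
        _rank_check(X, design.labels)  # raises naming the columns
        raise CollinearityError(design.labels)
    resid = y - X @ beta
    dof = design.n_obs - design.n_params
    sigma = float(np.sqrt(resid @ resid / dof))
    return FitResult(
        coefficients=beta,
        robust_covariance=np.full((design.n_params, design.n_params), np.nan),
        residuals=resid,
        n_obs=design.n_obs,
        sigma_hat=sigma,
        design_labels=list(design.labels),
        dropped_levels=list(design.dropped_levels),
        row_mask=design.row_mask,
    )


def robust_covariance(fit: FitResult, design: Design, cluster_ids=None, kind: str = "HC1") -> np.ndarray:
    """Huber-White sandwich covariance (XtX)^-1 M (XtX)^-1.

    The meat M is X' diag(e^2) X for independent observations, or the sum of
    outer products of within-cluster score sums when ``cluster_ids`` are
    given. ``kind``:

    * ``"HC0"`` -- no small-sample factor;
    * ``"HC1"`` -- n/(n-p) factor, or for clusters G/(G-1) * (n-1)/(n-p).

    With every observation its own cluster the HC0 cluster meat reduces
    exactly to the per-observation meat.
    """
    if kind not in ("HC0", "HC1"):
        raise InvalidInputError(f"kind must be HC0 or HC1, got {kind!r}")
    X = design.matrix
    e = fit.residuals
    n, p = X.shape
    bread = np.linalg.inv(X.T @ X)
    if cluster_ids is None:
        Xe = X * e[:, None]
        meat = Xe.T @ Xe
        factor = n / (n - p) if kind == "HC1" else 1.0
        n_clusters = None
    else:
        cluster_ids = np.asarray(cluster_ids).ravel()
        if design.row_mask is not None and len(cluster_ids) == len(design.row_mask):
            cluster_ids = cluster_ids[design.row_mask]
        if len(cluster_ids) != n:
            raise InvalidInputError("cluster_ids must have one id per design row")
        Xe = X * e[:, None]
        _, inverse = np.unique(cluster_ids, return_inverse=True)
        G = int(inverse.max()) + 1
        sums = np.zeros((G, p))
        np.add.at(sums, inverse, Xe)
        meat = sums.T @ sums
        factor = (G / (G - 1)) * ((n - 1) / (n - p)) if kind == "HC1" else 1.0
        n_clusters = G
    V = (bread @ meat @ bread) * factor
    V = (V + V.T) / 2.0
    fit.robust_covariance = V
    fit.cluster_count = n_clusters
    return V


def fit_model(spec: ModelSpec, x, y, covariates=None, cluster_ids=None, kind: str = "HC1") -> FitResult:
    """Build the design for a strategy, fit OLS, attach the sandwich covariance."""
    design = build_design(spec, x, covariates=covariates)
    fit = fit_ols(design, y)
    robust_covariance(fit, design, cluster_ids=cluster_ids, kind=kind)
    x = np.asarray(x, dtype=float).ravel()
    pos = x[x > 0]
    fit.min_positive_dose = float(pos.min()) if pos.size else None
    return fit
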