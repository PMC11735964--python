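"""Design-matrix building blocks for semicontinuous dose-response models.

A semicontinuous dose has positive probability mass at exactly zero and a
continuous distribution over positive values. The exposure representations
here cover the strategies compared in the Monte-Carlo study:

* ``spike_indicator`` -- the binary 1(dose > 0) "spike-at-zero" column, which
  gives exposed observations their own intercept and frees the fitted
  dose-response difference from being forced through the origin;
* ``ncs_basis`` -- a natural cubic spline basis (piecewise cubic, linear
  beyond the boundary knots, C2 at interior knots);
* ``slab_spline_basis`` -- the natural-spline subspace whose members have
  zero slope at and left of the lower boundary knot, so every fitted curve
  is a constant "slab" on [0, first knot) that joins the spline C1-smoothly;
* ``dose_categories`` -- discretization with dose 0 as its own category.

The natural spline basis is built from interpolating cardinal splines
(each column is the natural cubic spline interpolant of a unit vector at
the knots, continued linearly beyond the boundaries). Any basis spanning
the same function space gives identical fits, so span -- not a particular
formula -- is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import null_space

from .exceptions import InvalidInputError, InvalidSpecError

__all__ = [
    "KnotSet",
    "BasisMatrix",
    "ncs_basis",
    "spike_indicator",
    "slab_spline_basis",
    "dose_categories",
]


@dataclass(frozen=True)
class KnotSet:
    """Ordered spline knots in dose units.

    The first and last knots are the boundary knots: the fitted spline is
    linear outside [lower_boundary, upper_boundary]. Knots must be strictly
    increasing and strictly positive (doses), with at least 3 for spline use.
    """

    knots: tuple[float, ...]

    def __init__(self, knots) -> None:
        knots = tuple(float(k) for k in knots)
        if len(knots) < 3:
            raise InvalidSpecError(
                f"spline bases need at least 3 knots, got {len(knots)}"
            )
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise InvalidSpecError(f"knots must be strictly increasing: {knots}")
        if knots[0] <= 0:
            raise InvalidSpecError(f"knots must be strictly positive doses: {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def lower_boundary(self) -> float:
        return self.knots[0]

    @property
    def upper_boundary(self) -> float:
        return self.knots[-1]

    def __len__(self) -> int:
        return len(self.knots)

    def scaled(self, factor: float) -> "KnotSet":
        """Knots multiplied by ``factor`` (e.g. a dose-scale parameter)."""
        return KnotSet(tuple(k * factor for k in self.knots))


@dataclass
class BasisMatrix:
    """Evaluated basis columns with labels and knot metadata.

    ``values`` has one row per input dose and one column per basis function
    (no intercept). When ``anchored_at_zero`` is true every column is exactly
    0 at dose 0, so zero-dose rows contribute only to the intercept.
    """

    values: np.ndarray
    column_labels: list[str]
    anchored_at_zero: bool
    knots: KnotSet | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("basis evaluation produced non-finite values")
        if self.values.shape[1] != len(self.column_labels):
            raise InvalidSpecError("column label count does not match basis columns")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _check_doses(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise InvalidInputError("doses must be finite and nonnegative")
    return x


def _cardinal_spline(knots: KnotSet) -> CubicSpline:
    """Vector-valued natural spline interpolating the identity at the knots.

    Component j is the cardinal basis function N_j with N_j(t_i) = 1(i == j).
    The N_j span the whole natural-spline space and sum to the constant 1.
    """
    t = np.asarray(knots.knots)
    return CubicSpline(t, np.eye(len(t)), bc_type="natural", axis=0)


def _eval_natural(cs: CubicSpline, knots: KnotSet, x: np.ndarray, nu: int = 0):
    """Evaluate the cardinal splines (or a derivative) with linear tails.

    scipy's CubicSpline extrapolates with the boundary cubic; a natural
    spline is linear outside the boundary knots, so tails are continued
    from the boundary value and first derivative. This keeps the function
    C2 at the boundaries because the natural condition zeroes f'' there.
    """
    lo, hi = knots.lower_boundary, knots.upper_boundary
    inside = cs(np.clip(x, lo, hi), nu=nu)
    left = x < lo
    right = x > hi
    if nu == 0:
        if np.any(left):
            inside[left] = cs(lo) + np.outer(x[left] - lo, cs(lo, 1))
        if np.any(right):
            inside[right] = cs(hi) + np.outer(x[right] - hi, cs(hi, 1))
    elif nu == 1:
        if np.any(left):
            inside[left] = cs(lo, 1)
        if np.any(right):
            inside[right] = cs(hi, 1)
    else:
        if np.any(left | right):
            inside[left | right] = 0.0
    return inside


def ncs_basis(x, knots: KnotSet, anchor_at_zero: bool = True) -> BasisMatrix:
    """Natural cubic spline basis, K-1 columns for K knots (intercept aside).

    Parameters
    ----------
    x : array-like of nonnegative doses.
    knots : KnotSet with at least 3 strictly increasing positive knots.
    anchor_at_zero : subtract each column's value at dose 0 so all columns
        vanish there. This is an affine reparametrization: fitted curves and
        dose-response contrasts are unchanged, but alongside a spike column
        the spike coefficient becomes directly interpretable as the limiting
        effect of an infinitesimally small dose.
    """
    x = _check_doses(x)
    if not isinstance(knots, KnotSet):
        knots = KnotSet(knots)
    cs = _cardinal_spline(knots)
    vals = _eval_natural(cs, knots, x)
    # drop the first cardinal function: {1, N_2, ..., N_K} spans the space
    # because sum_j N_j == 1
    vals = vals[:, 1:]
    if anchor_at_zero:
        at0 = _eval_natural(cs, knots, np.zeros(1))[:, 1:]
        vals = vals - at0
    labels = [f"ncs{j}" for j in range(1, len(knots))]
    return BasisMatrix(vals, labels, anchored_at_zero=anchor_at_zero, knots=knots)


def spike_indicator(x) -> np.ndarray:
    """Binary exposure indicator 1(dose > 0), the spike-at-zero column."""
    x = _check_doses(x)
    return (x > 0).astype(float)


def _slab_nullspace(knots: KnotSet) -> np.ndarray:
    """Transformation from NCS columns to the zero-slope-at-first-knot subspace.

    The derivative of each NCS column at the lower boundary knot forms a row
    vector d; columns of the returned matrix are an orthonormal basis of its
    null space, so (ncs values) @ T spans {f in NCS span : f'(t_1) = 0}.
    Because a natural spline is linear left of t_1, members are constant on
    (-inf, t_1] and join the interior curve with a continuous derivative.
    """
    cs = _cardinal_spline(knots)
    d = cs(knots.lower_boundary, 1)[1:]
    T = null_space(d[None, :])
    if T.shape[1] != len(knots) - 2:
        raise InvalidSpecError("degenerate derivative constraint at lower boundary")
    return T


def slab_spline_basis(x, knots: KnotSet, anchor_at_zero: bool = True) -> BasisMatrix:
    """Slab-and-spline basis: natural spline constrained to zero slope at t_1.

    The span is exactly the subspace of the natural-spline span whose members
    have first derivative 0 at (and, by linearity of the left tail, everywhere
    left of) the lower boundary knot, so fitted curves are constant on
    [0, t_1) -- the "slab" -- and C1 at t_1. One fewer column than
    ``ncs_basis`` on the same knots; with 3 knots, a single column.
    """
    x = _check_doses(x)
    if not isinstance(knots, KnotSet):
        knots = KnotSet(knots)
    raw = ncs_basis(x, knots, anchor_at_zero=False)
    T = _slab_nullspace(knots)
    vals = raw.values @ T
    if anchor_at_zero:
        at0 = ncs_basis(np.zeros(1), knots, anchor_at_zero=False).values @ T
        vals = vals - at0
    labels = [f"slab{j}" for j in range(1, T.shape[1] + 1)]
    return BasisMatrix(vals, labels, anchored_at_zero=anchor_at_zero, knots=knots)


def dose_categories(x, breaks) -> np.ndarray:
    """Discretize doses: 0 -> category 0; positive doses into (b_{j-1}, b_j].

    ``breaks`` are strictly increasing positive cut points. Category 0 is
    reserved for dose exactly 0; category j (1-based) is the left-open,
    right-closed interval ending at breaks[j-1]; the last category is open
    above the top break. Returns an integer category index per dose.
    """
    x = _check_doses(x)
    breaks = np.asarray(breaks, dtype=float)
    if breaks.ndim != 1 or len(breaks) < 1:
        raise InvalidSpecError("breaks must be a non-empty 1-d sequence")
    if np.any(np.diff(breaks) <= 0) or breaks[0] <= 0:
        raise InvalidSpecError("breaks must be strictly increasing and positive")
    cats = np.searchsorted(breaks, x, side="left") + 1
    cats[x == 0] = 0
    return cats.astype(int)
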