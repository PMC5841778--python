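"""Natural cubic regression spline basis on the transformed-age scale.

This is the mean-curve workhorse of the shape-invariant growth model: a
B-spline-backed natural cubic basis (zero second derivative at and beyond
the boundary knots, hence linear extrapolation) with analytic first
derivatives.  The basis deliberately excludes the constant function, so
that the overall level of a fitted curve is carried by an explicit
intercept / size parameter and is never confounded with the spline
coefficients.

Conventions
-----------
* ``df`` is the number of basis columns.  Together with an intercept the
  columns span the full space of natural cubic splines on the given knot
  sequence (``df + 1`` dimensions for ``df - 1`` interior knots plus two
  boundary knots).
* Interior knots default to equally spaced quantiles of the design ages;
  boundary knots to their min and max.
* Evaluation outside the boundary knots is the first-order Taylor
  extension from the nearest boundary knot — never an error, because the
  tempo/velocity transformations routinely push scaled ages outside the
  design range during optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "make_spline_spec", "basis", "basis_derivative"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic regression spline.

    Knot positions are on the *transformed* age scale (log-years by
    default elsewhere in the package).  ``df`` equals the number of basis
    columns, which is ``len(interior_knots) + 1``.
    """

    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...]
    df: int
    # lazily built evaluation cache; excluded from equality/repr
    _cache: dict = field(default_factory=dict, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must be increasing")
        ik = np.asarray(self.interior_knots, dtype=float)
        if ik.size and (ik.min() <= lo or ik.max() >= hi):
            raise ValueError("interior knots must lie strictly inside the boundary knots")
        if np.any(np.diff(ik) <= 0):
            raise ValueError("interior knots must be strictly increasing")
        if self.df != ik.size + 1:
            raise ValueError(
                f"df={self.df} inconsistent with {ik.size} interior knots "
                f"(expected df = interior + 1)"
            )

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "boundary_knots": [float(b) for b in self.boundary_knots],
            "interior_knots": [float(k) for k in self.interior_knots],
            "df": int(self.df),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            boundary_knots=tuple(float(b) for b in d["boundary_knots"]),
            interior_knots=tuple(float(k) for k in d["interior_knots"]),
            df=int(d["df"]),
        )

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.concatenate(([lo], self.interior_knots, [hi]))


def make_spline_spec(transformed_ages: np.ndarray, df: int) -> SplineSpec:
    """Place knots for a ``df``-column natural spline basis.

    Interior knots go at the ``df - 1`` equally spaced interior quantiles
    of the supplied transformed ages; boundary knots at the min and max.
    Requires at least ``df + 2`` distinct ages so every knot interval is
    populated.
    """
    x = np.asarray(transformed_ages, dtype=float)
    if df < 3:
        raise ValueError(f"df must be >= 3, got {df}")
    distinct = np.unique(x)
    if distinct.size < df + 2:
        raise ValueError(
            f"need at least {df + 2} distinct transformed ages for df={df}, "
            f"got {distinct.size}"
        )
    probs = np.linspace(0.0, 1.0, df + 1)[1:-1]
    interior = np.asarray(np.quantile(x, probs), dtype=float)
    lo, hi = float(distinct[0]), float(distinct[-1])
    # quantile ties (heavily repeated design ages) would collapse knots;
    # nudge ties apart deterministically
    for j in range(1, interior.size):
        if interior[j] <= interior[j - 1]:
            interior[j] = interior[j - 1] + 1e-8 * (hi - lo)
    if interior.size and (interior[0] <= lo or interior[-1] >= hi):
        raise ValueError("degenerate age distribution: quantile knots hit the boundary")
    return SplineSpec(boundary_knots=(lo, hi), interior_knots=tuple(interior), df=df)


# ---------------------------------------------------------------------------
# basis construction
# ---------------------------------------------------------------------------

def _bspline_knots(spec: SplineSpec) -> np.ndarray:
    lo, hi = spec.boundary_knots
    return np.concatenate(([lo] * 4, spec.interior_knots, [hi] * 4))


def _transform_matrix(spec: SplineSpec) -> np.ndarray:
    """Map raw cubic B-spline coefficients to the final df basis columns.

    Two steps: (1) restrict to the null space of the natural constraints
    (zero second derivative at both boundary knots), leaving df + 1
    directions; (2) drop the direction representing the constant
    function, so the remaining df columns plus an intercept span the
    full natural-spline space.
    """
    t = _bspline_knots(spec)
    ncol = len(t) - 4
    lo, hi = spec.boundary_knots
    d2 = BSpline(t, np.eye(ncol), 3)(np.array([lo, hi]), nu=2)  # (2, ncol)
    _, _, vt = np.linalg.svd(d2)
    null = vt[2:].T  # (ncol, df + 1)
    # coefficients (constrained space) reproducing the constant function 1
    pts = np.linspace(lo, hi, null.shape[1] + 2)[1:-1]
    design = BSpline(t, np.eye(ncol), 3)(pts) @ null
    c0, *_ = np.linalg.lstsq(design, np.ones(pts.size), rcond=None)
    c0 /= np.linalg.norm(c0)
    u_, _, _ = np.linalg.svd(np.eye(c0.size) - np.outer(c0, c0))
    comp = u_[:, : c0.size - 1]  # orthonormal complement of the constant
    return null @ comp  # (ncol, df)


def _splines(spec: SplineSpec) -> tuple[BSpline, BSpline]:
    """Cached vector-valued BSpline objects (value, derivative)."""
    cached = spec._cache.get("splines")
    if cached is None:
        t = _bspline_knots(spec)
        tf = _transform_matrix(spec)
        b = BSpline(t, tf, 3)  # maps u -> (df,) row
        cached = (b, b.derivative())
        spec._cache["splines"] = cached
    return cached


def basis(spec: SplineSpec, u: np.ndarray) -> np.ndarray:
    """Evaluate the df basis columns at scaled transformed ages ``u``.

    Points beyond the boundary knots are linearly extrapolated (the
    natural condition), so the result is finite for any real ``u``.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    b, db = _splines(spec)
    lo, hi = spec.boundary_knots
    inside = np.clip(u, lo, hi)
    out = b(inside)
    below = u < lo
    above = u > hi
    if below.any():
        out[below] = b(lo) + np.outer(u[below] - lo, db(lo))
    if above.any():
        out[above] = b(hi) + np.outer(u[above] - hi, db(hi))
    return out


def basis_derivative(spec: SplineSpec, u: np.ndarray) -> np.ndarray:
    """First derivative of each basis column with respect to ``u``.

    Constant beyond the boundary knots (linear extrapolation regime).
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    _, db = _splines(spec)
    lo, hi = spec.boundary_knots
    out = db(np.clip(u, lo, hi))
    below = u < lo
    above = u > hi
    if below.any():
        out[below] = db(lo)
    if above.any():
        out[above] = db(hi)
    return out
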