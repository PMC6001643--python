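"""Restricted (natural) cubic splines on the log-time scale.

The basis is the non-orthogonalised Royston–Parmar form used by flexible
parametric survival models fitted on the log cumulative hazard scale: a
linear column in ``u`` plus, for each interior knot ``k_j``, the truncated
cubic

    v_j(u) = (u - k_j)_+^3 - lam_j (u - k_min)_+^3 - (1 - lam_j) (u - k_max)_+^3

with ``lam_j = (k_max - k_j) / (k_max - k_min)``, which is linear beyond the
boundary knots.  ``u`` is usually ln(t).  The intercept is *not* part of the
basis; model code adds it separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["SplineSpec", "rcs_basis", "knots_for"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a restricted cubic spline.

    Parameters
    ----------
    boundary_knots
        Two values bracketing the interior knots (on the ``u`` scale,
        typically ln-time).
    interior_knots
        Strictly increasing values strictly inside the boundary knots.
        With no interior knots the basis degenerates to ``{u}``.
    """

    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ValueError(f"boundary knots must be finite and increasing, got {self.boundary_knots}")
        ks = np.asarray(self.interior_knots, dtype=float)
        if ks.size:
            if np.any(np.diff(ks) <= 0):
                raise ValueError(f"interior knots must be strictly increasing, got {self.interior_knots}")
            if ks[0] <= lo or ks[-1] >= hi:
                raise ValueError("interior knots must lie strictly inside the boundary knots")

    @property
    def df(self) -> int:
        """Number of basis columns (excluding the intercept)."""
        return 1 + len(self.interior_knots)

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray([self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]])


def rcs_basis(u, spec: SplineSpec):
    """Evaluate the restricted cubic spline basis and its derivative.

    Parameters
    ----------
    u
        Scalar or array of evaluation points.
    spec
        Knot layout.

    Returns
    -------
    basis, deriv
        Arrays of shape ``u.shape + (spec.df,)`` holding the basis values
        and their first derivatives with respect to ``u``.
    """
    u = np.asarray(u, dtype=float)
    kmin, kmax = spec.boundary_knots
    cols = [u]
    dcols = [np.ones_like(u)]
    pmin = np.maximum(u - kmin, 0.0)
    pmax = np.maximum(u - kmax, 0.0)
    for kj in spec.interior_knots:
        lam = (kmax - kj) / (kmax - kmin)
        pj = np.maximum(u - kj, 0.0)
        cols.append(pj**3 - lam * pmin**3 - (1.0 - lam) * pmax**3)
        dcols.append(3.0 * (pj**2 - lam * pmin**2 - (1.0 - lam) * pmax**2))
    return np.stack(cols, axis=-1), np.stack(dcols, axis=-1)


def knots_for(values, df: int) -> SplineSpec:
    """Default knot placement: boundary at min/max, interior at quantiles.

    With ``df = 3`` the interior knots sit at the tertiles of ``values``
    (the conventional placement for baseline log-time splines).  Tied
    quantiles are collapsed with a warning, reducing the effective df.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to place knots")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("cannot place knots: all values identical")
    if df == 1:
        return SplineSpec((lo, hi))
    qs = np.arange(1, df) / df
    interior = np.quantile(v, qs)
    interior = interior[(interior > lo) & (interior < hi)]
    uniq = np.unique(interior)
    if uniq.size < df - 1:
        warnings.warn(
            f"knot placement collapsed ties: requested {df - 1} interior knots, kept {uniq.size}",
            stacklevel=2,
        )
    return SplineSpec((lo, hi), tuple(uniq))
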