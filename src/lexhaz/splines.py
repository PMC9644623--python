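"""Restricted cubic spline bases for time-scales and covariates.

A restricted cubic spline (RCS) with knots ``k_1 < ... < k_K`` is a
piecewise cubic polynomial that is continuous up to its second derivative
at every knot and constrained to be *linear* beyond the boundary knots.
The basis used here is the restricted truncated-power basis without an
intercept column::

    v_1(u) = u
    v_j(u) = (u - k_j)_+^3 - lam_j (u - k_1)_+^3 - (1 - lam_j) (u - k_K)_+^3

for ``j = 2..K-1`` with ``lam_j = (k_K - k_j) / (k_K - k_1)``, giving
``K - 1`` columns.  Columns are deliberately *not* rescaled or
orthogonalised, so coefficients are directly comparable between the
quadrature-based and Poisson time-split fits.

When a basis is declared on the log scale, ``u = log(x)`` and the knots
are stored on the log scale as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineBasis", "place_knots", "rcs_design"]


@dataclass(frozen=True)
class SplineBasis:
    """Restricted cubic spline basis on one axis.

    Parameters
    ----------
    knots : ndarray
        Strictly increasing knot locations (on the log scale when
        ``log_transform`` is true).
    log_transform : bool
        Evaluate the basis at ``log(x)`` instead of ``x``.
    name : str
        Axis label, used in error messages and coefficient names.
    """

    knots: np.ndarray
    log_transform: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        if knots.ndim != 1 or knots.size < 2:
            raise ValueError(f"spline '{self.name}': need at least 2 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError(f"spline '{self.name}': knots must be strictly increasing")
        object.__setattr__(self, "knots", knots)

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def n_basis(self) -> int:
        """Number of columns: linear term plus K-2 restricted cubic terms."""
        return self.knots.size - 1

    @property
    def lambdas(self) -> np.ndarray:
        k = self.knots
        return (k[-1] - k[1:-1]) / (k[-1] - k[0])

    def design(self, x) -> np.ndarray:
        return rcs_design(x, self)

    def column_names(self, prefix: str) -> list[str]:
        return [f"{prefix} spline {j + 1}" for j in range(self.n_basis)]


def place_knots(
    event_times,
    n_knots: int,
    boundary_rule: str = "event_range",
    transform: bool = False,
    name: str = "",
) -> SplineBasis:
    """Place RCS knots over the distribution of event times.

    Boundary knots go at the first and last event times; interior knots at
    equally spaced centiles of the event-time distribution (e.g. the 33.3rd
    and 66.7th centiles for four knots), computed by linear interpolation of
    the empirical CDF (type-7 quantiles).  With ``transform`` the centiles
    are taken on the log event times.
    """
    if boundary_rule != "event_range":
        raise ValueError(f"unknown boundary rule {boundary_rule!r}")
    t = np.asarray(event_times, dtype=float)
    if t.size == 0:
        raise ValueError(f"spline '{name}': no event times to place knots on")
    if n_knots < 2:
        raise ValueError(f"spline '{name}': n_knots must be >= 2")
    if transform and np.any(t <= 0):
        raise ValueError(f"spline '{name}': non-positive event times with log transform")
    u = np.log(t) if transform else t
    if np.unique(u).size < n_knots:
        raise ValueError(
            f"spline '{name}': only {np.unique(u).size} distinct event times "
            f"for {n_knots} knots"
        )
    centiles = np.linspace(0.0, 1.0, n_knots)
    knots = np.quantile(u, centiles)  # type-7: linear interpolation
    # boundary rule: force exact min/max regardless of quantile rounding
    knots[0], knots[-1] = u.min(), u.max()
    return SplineBasis(knots=knots, log_transform=transform, name=name)


def rcs_design(x, basis: SplineBasis) -> np.ndarray:
    """Evaluate the restricted cubic spline design matrix.

    Returns an ``(len(x), K - 1)`` matrix: column 1 the (log-) linear term,
    columns 2..K-1 the restricted cubic terms, which vanish identically for
    arguments at or below the first knot.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError(f"spline '{basis.name}': non-finite argument")
    if basis.log_transform:
        if np.any(x <= 0):
            raise ValueError(f"spline '{basis.name}': log basis evaluated at x <= 0")
        u = np.log(x)
    else:
        u = x
    k = basis.knots
    lam = basis.lambdas
    out = np.empty((u.size, basis.n_basis))
    out[:, 0] = u
    cube = lambda v: np.clip(v, 0.0, None) ** 3
    first, last = cube(u - k[0]), cube(u - k[-1])
    for j in range(1, basis.n_basis):
        out[:, j] = cube(u - k[j]) - lam[j - 1] * first - (1.0 - lam[j - 1]) * last
    return out
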