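"""Natural cubic spline bases for smooth weather adjustment.

The regression models adjust for temperature and relative humidity through
natural cubic splines with 3 degrees of freedom each. A natural cubic
spline is a piecewise cubic that is constrained to be linear beyond its
boundary knots; with boundary knots at the covariate min/max and df - 1
interior knots at equally spaced quantiles (33.3rd and 66.7th percentiles
for df = 3), the basis has exactly ``df`` columns (no intercept column —
the conditional model has no global intercept to absorb it, but any
cluster-constant shift is eliminated by the conditioning anyway).

The basis used is the truncated-power natural basis: with knots
``k_1 < ... < k_K`` (boundary knots included) define

    d_j(x) = [ (x - k_j)_+^3 - (x - k_K)_+^3 ] / (k_K - k_j)

and take columns ``x`` and ``d_j(x) - d_{K-1}(x)`` for j = 1..K-2. Each
column is exactly linear outside [k_1, k_K], and together with a constant
they span the natural cubic splines on those knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SplineBasis:
    """A fitted natural cubic spline basis (knots frozen at construction)."""

    knots: np.ndarray  # all knots, boundary included, sorted
    df: int
    matrix: np.ndarray = field(repr=False)  # n x df basis evaluated at the data

    def transform(self, x) -> np.ndarray:
        """Evaluate the basis (same knots) at new points."""
        return _natural_basis(np.asarray(x, dtype=float), self.knots)


def _natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k_last = knots[-1]
    k_penult = knots[-2]

    def d(k):
        num = np.clip(x - k, 0, None) ** 3 - np.clip(x - k_last, 0, None) ** 3
        return num / (k_last - k)

    d_penult = d(k_penult)
    cols = [x] + [d(k) - d_penult for k in knots[:-2]]
    return np.column_stack(cols)


def natural_spline_basis(values, df: int = 3, knots=None) -> SplineBasis:
    """Natural cubic basis with ``df`` columns for one covariate series.

    Interior knots sit at the df-1 equally spaced interior quantiles of the
    data (for df = 3: the 33.3rd and 66.7th percentiles); boundary knots at
    the min and max. This is the conventional quantile knot rule; it is a
    documented implementation convention, configurable only by refitting on
    a different subset. Passing ``knots`` (boundary included, df + 1 sorted
    values) overrides the quantile rule.

    Raises
    ------
    ValueError
        If the covariate is constant or has fewer than df + 2 distinct
        values (knots would coincide).
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("covariate contains missing values")
    if knots is None:
        distinct = np.unique(x)
        if distinct.size < df + 2:
            raise ValueError(
                f"need >= {df + 2} distinct covariate values for df={df}, got {distinct.size}"
            )
        probs = np.linspace(0, 100, df + 1)
        knots = np.percentile(x, probs, method="linear")
    knots = np.unique(np.asarray(knots, dtype=float))
    if knots.size < df + 1:
        raise ValueError("knots coincide; covariate too concentrated for requested df")
    return SplineBasis(knots=knots, df=df, matrix=_natural_basis(x, knots))
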