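"""Restricted (natural) cubic splines for nonlinear exposure-response curves.

The basis is the standard truncated-power natural spline: for knots
t_1 < ... < t_k the design contains the linear term plus k-2 nonlinear columns

    s_j(x) = [ (x - t_j)_+^3
               - (x - t_{k-1})_+^3 (t_k - t_j)/(t_k - t_{k-1})
               + (x - t_k)_+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2,

which is exactly zero below the first knot and linear beyond both boundary
knots.  Default knots sit at the 5/35/65/95 weighted percentiles (4 knots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .phasor import weighted_quantile

__all__ = ["rcs_basis", "RCSBasis", "spline_curve", "nonlinearity_test"]

KNOT_PERCENTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


class KnotPlacementError(ValueError):
    """Knots are not distinct (degenerate exposure distribution)."""


@dataclass
class RCSBasis:
    """A restricted cubic spline basis: knots plus the evaluated design columns."""

    knots: np.ndarray
    columns: list

    def evaluate(self, x) -> pd.DataFrame:
        """Basis columns at new points ``x`` (linear term first)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        t = self.knots
        k = len(t)
        scale = (t[-1] - t[0]) ** 2

        def pos3(v):
            return np.clip(v, 0.0, None) ** 3

        cols = {self.columns[0]: x}
        for j in range(k - 2):
            num = (
                pos3(x - t[j])
                - pos3(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
                + pos3(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
            )
            cols[self.columns[j + 1]] = num / scale
        return pd.DataFrame(cols)


def rcs_basis(
    x,
    n_knots: int = 4,
    weights=None,
    knots=None,
    name: str = "x",
) -> tuple[pd.DataFrame, RCSBasis]:
    """Restricted cubic spline design for ``x``.

    Returns ``(design, basis)`` where design has the linear column plus
    ``n_knots - 2`` nonlinear columns and basis carries the knot locations for
    later evaluation on a prediction grid.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if n_knots not in KNOT_PERCENTILES:
            raise ValueError("n_knots must be one of 3, 4, 5")
        qs = KNOT_PERCENTILES[n_knots]
        knots = np.asarray(
            weighted_quantile(x, list(qs), weights, interpolate=True), dtype=float
        )
    else:
        knots = np.sort(np.asarray(knots, dtype=float))
    if len(np.unique(knots)) != len(knots):
        raise KnotPlacementError(f"duplicate knots {knots}; exposure variance too low")
    columns = [name] + [f"{name}_rcs{j+1}" for j in range(len(knots) - 2)]
    basis = RCSBasis(knots=knots, columns=columns)
    return basis.evaluate(x), basis


def spline_curve(
    params: pd.Series,
    cov_params: pd.DataFrame,
    basis: RCSBasis,
    grid,
    reference: float,
    df_design: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exposure-response ratio curve normalized to 1.0 at ``reference``.

    Given a fitted model whose design contained the spline columns, the
    log-ratio at x is ``(B(x) - B(ref)) . beta_spline`` with delta-method
    pointwise CIs from the design-based covariance.  Works identically for
    odds ratios (logistic) and hazard ratios (Cox).
    """
    grid = np.asarray(grid, dtype=float)
    if not (grid.min() <= reference <= grid.max()):
        raise ValueError("reference value lies outside the evaluated exposure range")
    cols = basis.columns
    Bg = basis.evaluate(grid)[cols].to_numpy()
    Br = basis.evaluate([reference])[cols].to_numpy()
    diff = Bg - Br
    beta = params.loc[cols].to_numpy()
    V = cov_params.loc[cols, cols].to_numpy()
    log_ratio = diff @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", diff, V, diff))
    crit = (
        scipy.stats.norm.ppf(1 - alpha / 2)
        if df_design is None
        else scipy.stats.t.ppf(1 - alpha / 2, df_design)
    )
    return pd.DataFrame({
        "x": grid,
        "ratio": np.exp(log_ratio),
        "ci_lower": np.exp(log_ratio - crit * se),
        "ci_upper": np.exp(log_ratio + crit * se),
    })


def nonlinearity_test(params: pd.Series, cov_params: pd.DataFrame, basis: RCSBasis) -> dict:
    """Wald test that all nonlinear spline coefficients are zero."""
    nl = basis.columns[1:]
    b = params.loc[nl].to_numpy()
    V = cov_params.loc[nl, nl].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    dof = len(nl)
    return {"statistic": stat, "df": dof, "p_value": float(scipy.stats.chi2.sf(stat, dof))}
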