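"""Sweep over (d+, d-, alpha_r) producing paired sign maps of the bulk
mean difference and bulk variance difference.

The sweep evaluates, at every grid point, the closed-form group difference in
bulk mean and in bulk variance between a shifted group and the baseline.  The
two sign maps differ: with a decreased subset-+ proportion (alpha_r < 1) a
positive expression shift in both subsets can still produce a *negative* mean
difference, and cells where the mean difference and the variance difference
disagree in sign are exactly the genes that differential-expression and
differential-variability analyses classify differently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    DomainError,
    GroupParams,
    MeasurementNoise,
    ShiftParams,
    apply_shift,
    mean_difference,
    variance_bulk,
)

__all__ = ["GridResult", "sweep_grid", "default_baseline", "DEFAULT_D_VALUES", "DEFAULT_ALPHA_VALUES"]

DEFAULT_D_VALUES = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))
DEFAULT_ALPHA_VALUES = (0.2, 0.5, 0.8)

#: zero-classification tolerance for the sign labels
_SIGN_TOL = 1e-12


def default_baseline() -> GroupParams:
    """Baseline group for the canonical sweep: E+=2, E-=1, Er=0.5, V+=0.3, V-=0.1, Vr=0.05."""
    return GroupParams(e_plus=2.0, e_minus=1.0, e_r=0.5, v_plus=0.3, v_minus=0.1, v_r=0.05)


@dataclass
class GridResult:
    """Result of a (d+, d-, alpha_r) sweep.

    ``delta_mean`` and ``delta_var`` have shape
    (len(d_plus_values), len(d_minus_values), len(alpha_values)); sign labels
    are "positive" / "negative" / "boundary" (|x| <= 1e-12) / "invalid".
    """

    d_plus_values: np.ndarray
    d_minus_values: np.ndarray
    alpha_values: np.ndarray
    delta_mean: np.ndarray
    delta_var: np.ndarray
    sign_mean: np.ndarray
    sign_var: np.ndarray
    invalid_cells: list[tuple[float, float, float, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per grid cell."""
        rows = []
        for i, dp in enumerate(self.d_plus_values):
            for j, dm in enumerate(self.d_minus_values):
                for k, a in enumerate(self.alpha_values):
                    rows.append(
                        {
                            "d_plus": dp,
                            "d_minus": dm,
                            "alpha_r": a,
                            "delta_mean": self.delta_mean[i, j, k],
                            "delta_var": self.delta_var[i, j, k],
                            "sign_mean": self.sign_mean[i, j, k],
                            "sign_var": self.sign_var[i, j, k],
                        }
                    )
        return pd.DataFrame(rows)


def _sign_label(x: float) -> str:
    if np.isnan(x):
        return "invalid"
    if abs(x) <= _SIGN_TOL:
        return "boundary"
    return "positive" if x > 0 else "negative"


def sweep_grid(
    gp: GroupParams | None = None,
    noise: MeasurementNoise | None = None,
    d_values: "np.typing.ArrayLike | None" = None,
    alpha_values: "np.typing.ArrayLike | None" = None,
) -> GridResult:
    """Evaluate the mean and variance group differences over the grid.

    Defaults reproduce the canonical 11 x 11 x 3 sweep: d+ and d- on
    0, 0.1, ..., 1 and alpha_r in {0.2, 0.5, 0.8} on the
    :func:`default_baseline` group with no measurement noise (an additive,
    group-invariant noise term cancels in the variance difference anyway).

    Grid points where the shifted proportion leaves [0, 1] are recorded as
    invalid cells (NaN deltas) and the sweep continues.
    """
    if gp is None:
        gp = default_baseline()
    if noise is None:
        noise = MeasurementNoise(0.0)
    d_plus_values = np.asarray(DEFAULT_D_VALUES if d_values is None else d_values, dtype=float)
    d_minus_values = d_plus_values.copy()
    alphas = np.asarray(
        DEFAULT_ALPHA_VALUES if alpha_values is None else alpha_values, dtype=float
    )

    shape = (d_plus_values.size, d_minus_values.size, alphas.size)
    delta_mean = np.full(shape, np.nan)
    delta_var = np.full(shape, np.nan)
    baseline_var = variance_bulk(gp, noise)
    invalid: list[tuple[float, float, float, str]] = []

    for i, dp in enumerate(d_plus_values):
        for j, dm in enumerate(d_minus_values):
            for k, a in enumerate(alphas):
                try:
                    shift = ShiftParams(d_plus=dp, d_minus=dm, alpha_r=a)
                    delta_mean[i, j, k] = mean_difference(gp, shift)
                    delta_var[i, j, k] = variance_bulk(apply_shift(gp, shift), noise) - baseline_var
                except DomainError as exc:
                    invalid.append((float(dp), float(dm), float(a), str(exc)))

    label = np.vectorize(_sign_label)
    return GridResult(
        d_plus_values=d_plus_values,
        d_minus_values=d_minus_values,
        alpha_values=alphas,
        delta_mean=delta_mean,
        delta_var=delta_var,
        sign_mean=label(delta_mean),
        sign_var=label(delta_var),
        invalid_cells=invalid,
    )
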