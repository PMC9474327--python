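"""Generative simulator for two-group bulk expression under the mixture model.

For each of N donors per group the donor-level parameters are drawn as

    mu_plus  ~ Normal(E+ [+ d+*(E+-E-)], V+)
    mu_minus ~ Normal(E- [+ d-*(E+-E-)], V-)
    r        ~ Uniform with mean Er [* alpha_r] and variance Vr

(the second argument of every distribution is a *variance*; the uniform is
the unique uniform with the requested mean and variance).  Each donor then
contributes n single cells

    y ~ r * Normal(mu_plus, Vy+) + (1 - r) * Normal(mu_minus, Vy-)

with the component chosen Bernoulli(r) per cell, and the bulk value is

    Y = k * mean(y_1 .. y_n) + e,      e ~ Normal(0, Verr).

Two presets reproduce the canonical differential-variability-without-
differential-expression constructions: preset 1 changes the subset
proportion (variance decreases in the shifted group), preset 2 widens the
component-mean gap (variance increases), and in both alpha_r is computed so
the two group means are exactly equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DomainError,
    GroupParams,
    InvalidParameterError,
    MeasurementNoise,
    ShiftParams,
    cancellation_alpha_bound,
    expected_bulk,
    variance_bulk,
)

__all__ = [
    "SimulationConfig",
    "DonorParams",
    "BulkDataset",
    "uniform_from_mean_var",
    "sample_donor_params",
    "simulate_cells",
    "simulate_bulk",
    "preset_example",
    "expected_within_cell_variance",
    "expected_bulk_moments",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulator-only parameters.

    Parameters
    ----------
    n_samples
        Number of donors N per group (>= 2 so group variances exist).
    n_cells
        Number of cells n per donor (>= 1).
    v_err
        Variance of the additive measurement error on the bulk value.
    v_y_plus, v_y_minus
        Within-subset cell-to-cell variances Vy+ and Vy-.
    k
        Proportionality constant between the cell-mean and the bulk value.
    seed
        Seed for the single generator driving the whole simulation.
    """

    n_samples: int
    n_cells: int
    v_err: float = 0.0
    v_y_plus: float = 0.0
    v_y_minus: float = 0.0
    k: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_samples) != self.n_samples or self.n_samples < 2:
            raise InvalidParameterError(f"n_samples must be an integer >= 2, got {self.n_samples}")
        if int(self.n_cells) != self.n_cells or self.n_cells < 1:
            raise InvalidParameterError(f"n_cells must be an integer >= 1, got {self.n_cells}")
        for name in ("v_err", "v_y_plus", "v_y_minus"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.k > 0.0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class DonorParams:
    """Realised donor-level mixture parameters for one sample."""

    mu_plus: float
    mu_minus: float
    r: float
    group: str = "C"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise InvalidParameterError(f"r must lie in [0, 1], got {self.r}")


@dataclass(frozen=True)
class BulkDataset:
    """Simulated bulk values with the ground-truth donor parameters retained.

    ``table`` has one row per donor with columns
    ``sample_id, group, Y, mu_plus, mu_minus, r``.
    """

    table: pd.DataFrame
    group_params: GroupParams
    shift: ShiftParams
    config: SimulationConfig

    def values(self, group: str) -> np.ndarray:
        return self.table.loc[self.table["group"] == group, "Y"].to_numpy()


def uniform_from_mean_var(mean: float, variance: float) -> tuple[float, float]:
    """Bounds (lower, upper) of the unique uniform with the given mean and variance.

    A Uniform(a, b) has mean (a+b)/2 and variance (b-a)^2/12, so
    a, b = mean -/+ sqrt(3 * variance).
    """
    if variance < 0.0:
        raise DomainError(f"variance must be >= 0, got {variance}")
    half_width = math.sqrt(3.0 * variance)
    return mean - half_width, mean + half_width


def _r_support(gp: GroupParams, alpha_r: float) -> tuple[float, float]:
    lo, hi = uniform_from_mean_var(alpha_r * gp.e_r, gp.v_r)
    if lo < -1e-12 or hi > 1.0 + 1e-12:
        raise DomainError(
            f"uniform support for r is [{lo:.6g}, {hi:.6g}], outside [0, 1] "
            f"(mean {alpha_r * gp.e_r:.6g}, variance {gp.v_r:.6g})"
        )
    return max(lo, 0.0), min(hi, 1.0)


def sample_donor_params(
    gp: GroupParams,
    shift: ShiftParams | None,
    n_samples: int,
    rng: np.random.Generator,
) -> list[DonorParams]:
    """Draw N independent donors; ``shift=None`` means the control group.

    mu_plus and mu_minus are Normal with the configured *variances*; r is the
    uniform matching (Er, Vr) exactly.  Configurations whose uniform support
    for r leaves [0, 1] are rejected up front rather than clamped, so the
    sampled moments always match the closed-form model.
    """
    if shift is None:
        e_plus, e_minus, alpha_r, group = gp.e_plus, gp.e_minus, 1.0, "C"
    else:
        d_abs_plus, d_abs_minus = shift.absolute_shifts(gp)
        e_plus = gp.e_plus + d_abs_plus
        e_minus = gp.e_minus + d_abs_minus
        alpha_r, group = shift.alpha_r, "D"
    lo, hi = _r_support(gp, alpha_r)
    mu_plus = rng.normal(e_plus, math.sqrt(gp.v_plus), n_samples)
    mu_minus = rng.normal(e_minus, math.sqrt(gp.v_minus), n_samples)
    r = rng.uniform(lo, hi, n_samples) if hi > lo else np.full(n_samples, lo)
    return [
        DonorParams(float(mp), float(mm), float(rr), group)
        for mp, mm, rr in zip(mu_plus, mu_minus, r)
    ]


def simulate_cells(
    dp: DonorParams, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """n i.i.d. single-cell values from the donor's two-component normal mixture.

    Each cell belongs to subset + with probability r (Bernoulli per cell, not
    a fixed r*n split), so the finite-cell noise carries the binomial term.
    """
    n = cfg.n_cells
    in_plus = rng.random(n) < dp.r
    y = np.empty(n)
    n_plus = int(in_plus.sum())
    y[in_plus] = rng.normal(dp.mu_plus, math.sqrt(cfg.v_y_plus), n_plus)
    y[~in_plus] = rng.normal(dp.mu_minus, math.sqrt(cfg.v_y_minus), n - n_plus)
    return y


def simulate_bulk(
    gp: GroupParams, shift: ShiftParams, cfg: SimulationConfig
) -> BulkDataset:
    """Simulate N bulk values per group, with ground truth attached.

    Reproducible from ``cfg.seed``; each donor's cells come from a
    deterministically derived sub-stream, so changing ``n_cells`` does not
    reshuffle the donor-level parameters.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_params_c, ss_params_d, ss_cells, ss_err = root.spawn(4)
    donors = sample_donor_params(gp, None, cfg.n_samples, np.random.default_rng(ss_params_c))
    donors += sample_donor_params(gp, shift, cfg.n_samples, np.random.default_rng(ss_params_d))
    cell_streams = ss_cells.spawn(len(donors))
    errors = np.random.default_rng(ss_err).normal(0.0, math.sqrt(cfg.v_err), len(donors))

    rows = []
    for i, (dp, stream) in enumerate(zip(donors, cell_streams)):
        cells = simulate_cells(dp, cfg, np.random.default_rng(stream))
        y = cfg.k * float(cells.mean()) + errors[i]
        rows.append(
            {
                "sample_id": f"{dp.group}{(i % cfg.n_samples) + 1:04d}",
                "group": dp.group,
                "Y": y,
                "mu_plus": dp.mu_plus,
                "mu_minus": dp.mu_minus,
                "r": dp.r,
            }
        )
    return BulkDataset(pd.DataFrame(rows), gp, shift, cfg)


def expected_within_cell_variance(
    gp: GroupParams, cfg: SimulationConfig, shift: ShiftParams | None = None
) -> float:
    """E over donors of the within-donor cell variance V[y | mu+, mu-, r].

    V[y | donor] = r*Vy+ + (1-r)*Vy- + r(1-r)(mu+ - mu-)^2; taking the
    expectation under donor-parameter independence gives

        Er*Vy+ + (1-Er)*Vy- + (Er - Er^2 - Vr) * ((E+-E-)^2 + V+ + V-).

    Divided by n (and scaled by k^2) this is the finite-cell correction to
    the across-donor bulk variance; it vanishes as n grows, which is why
    cell-to-cell variability does not appear in the closed-form bulk
    variance.
    """
    g = gp if shift is None else _shifted(gp, shift)
    er, gap2 = g.e_r, (g.e_plus - g.e_minus) ** 2
    e_r_one_minus_r = er - er * er - g.v_r
    return (
        er * cfg.v_y_plus
        + (1.0 - er) * cfg.v_y_minus
        + e_r_one_minus_r * (gap2 + g.v_plus + g.v_minus)
    )


def _shifted(gp: GroupParams, shift: ShiftParams) -> GroupParams:
    from .model import apply_shift

    return apply_shift(gp, shift)


def expected_bulk_moments(
    gp: GroupParams, cfg: SimulationConfig, shift: ShiftParams | None = None
) -> tuple[float, float]:
    """Exact (mean, variance) of the simulated bulk value Y at finite n.

    mean = k * E[Y_model];  variance = k^2 * (V_model - v_err') + v_err +
    k^2 * E[V[y|donor]]/n, where the measurement error enters unscaled
    because it is added after the proportionality constant.
    """
    g = gp if shift is None else _shifted(gp, shift)
    mean = cfg.k * expected_bulk(g)
    model_var = variance_bulk(g, MeasurementNoise(0.0))
    var = (
        cfg.k**2 * model_var
        + cfg.v_err
        + cfg.k**2 * expected_within_cell_variance(gp, cfg, shift) / cfg.n_cells
    )
    return mean, var


def preset_example(
    which: int,
    *,
    seed: int = 0,
    n_samples: int | None = None,
    n_cells: int | None = None,
) -> tuple[GroupParams, ShiftParams, SimulationConfig]:
    """The two canonical DV-without-DE presets.

    Preset 1: E+=2, E-=1, Er=0.9, V+=1, V-=0.1, Vr=0.001, d+=d-=0.5 —
    the proportion of the high-variance subset drops (alpha_r = 4/9) and the
    bulk variance *decreases* while the group means stay equal.

    Preset 2: same baseline but V+=V-=0.01 and d+=10, d-=0.1 — the
    component-mean gap widens and the bulk variance *increases*, again at
    equal means.

    In both, alpha_r is computed from the cancellation bound (never
    hard-coded) so E[Y_C] = E[Y_D] holds to machine precision.  ``n_samples``
    and ``n_cells`` default to N=1000 donors per group and n=10000 cells but
    may be overridden for cheaper runs; the model parameters are fixed.
    """
    if which == 1:
        gp = GroupParams(e_plus=2.0, e_minus=1.0, e_r=0.9, v_plus=1.0, v_minus=0.1, v_r=0.001)
        d_plus, d_minus = 0.5, 0.5
    elif which == 2:
        gp = GroupParams(e_plus=2.0, e_minus=1.0, e_r=0.9, v_plus=0.01, v_minus=0.01, v_r=0.001)
        d_plus, d_minus = 10.0, 0.1
    else:
        raise ValueError(f"preset must be 1 or 2, got {which!r}")
    alpha_r = cancellation_alpha_bound(gp, d_plus, d_minus)
    shift = ShiftParams(d_plus=d_plus, d_minus=d_minus, alpha_r=alpha_r)
    cfg = SimulationConfig(
        n_samples=1000 if n_samples is None else n_samples,
        n_cells=10000 if n_cells is None else n_cells,
        v_err=0.1,
        v_y_plus=1.0,
        v_y_minus=1.0,
        k=1.0,
        seed=seed,
    )
    return gp, shift, cfg
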