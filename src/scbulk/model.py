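"""Closed-form model of bulk expression under a two-subset cell mixture.

A bulk expression value for one gene in one sample is modelled as

    Y = k * E[y] + e = k * (r*mu_plus + (1-r)*mu_minus) + e

where the single-cell expression ``y`` follows a two-component mixture with
component means ``mu_plus >= mu_minus`` (cellular subsets "+" and "-"), ``r``
is the subset-+ proportion, ``k`` a proportionality constant (fixed to 1 in
all closed forms here) and ``e`` an additive measurement error.  Across
donors, (mu_plus, mu_minus, r) are independent random variables with
population means (E+, E-, Er) and variances (V+, V-, Vr).

This module provides the population-level consequences of that model:

* :func:`expected_bulk` — the bulk mean  E[Y] = Er*E+ + (1-Er)*E-.
* :func:`variance_bulk` — the bulk variance decomposition

      V[Y] = (E+-E-)^2*Vr + Er^2*V+ + (1-Er)^2*V- + (V+ + V-)*Vr + V[e]

  whose five additive terms are the levers of differential variability.
* :func:`apply_shift` / :func:`mean_difference` — a disease group D obtained
  from a control group C by shifting the component means by d± (normalised
  by E+ - E-) and scaling the expected proportion by alpha_r, and the
  closed-form group mean difference E[Y_D] - E[Y_C].
* :func:`cancellation_alpha_bound` — the alpha_r at which a positive
  expression shift is exactly cancelled by the proportion decrease, so the
  gene is invisible to differential-expression analysis.

Note that cell-to-cell variability within a subset does not appear in
``variance_bulk``: with many cells per sample it only enters the finite-cell
correction handled by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = [
    "DomainError",
    "InvalidParameterError",
    "GroupParams",
    "ShiftParams",
    "MeasurementNoise",
    "VarianceTerms",
    "expected_bulk",
    "variance_bulk",
    "variance_bulk_terms",
    "apply_shift",
    "mean_difference",
    "cancellation_alpha_bound",
]


class InvalidParameterError(ValueError):
    """A parameter set violates its structural invariants (e.g. Er outside [0, 1])."""


class DomainError(ValueError):
    """Inputs are structurally valid but outside the domain of the requested operation."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if value != value or value in (float("inf"), float("-inf")):
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class GroupParams:
    """Population moments of the donor-level mixture parameters for one group.

    Parameters
    ----------
    e_plus, e_minus
        Expected component means E[mu+] and E[mu-] (expression units).
    e_r
        Expected subset-+ proportion E[r]; must lie in [0, 1].
    v_plus, v_minus, v_r
        Across-donor variances V[mu+], V[mu-], V[r]; must be nonnegative.
    """

    e_plus: float
    e_minus: float
    e_r: float
    v_plus: float = 0.0
    v_minus: float = 0.0
    v_r: float = 0.0

    def __post_init__(self) -> None:
        for name in ("e_plus", "e_minus", "e_r", "v_plus", "v_minus", "v_r"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if not 0.0 <= self.e_r <= 1.0:
            raise InvalidParameterError(f"e_r must lie in [0, 1], got {self.e_r}")
        for name in ("v_plus", "v_minus", "v_r"):
            if getattr(self, name) < 0.0:
                raise InvalidParameterError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ShiftParams:
    """Group-difference parameters (d+, d-, alpha_r).

    ``d_plus`` and ``d_minus`` are expression shifts *normalised* by the
    control-group component-mean gap (E+ - E-); the absolute shifts applied
    to the component means are ``delta_mu_plus = d_plus * (E+ - E-)`` and
    likewise for the minus subset.  ``alpha_r`` multiplies the expected
    subset-+ proportion.  Use :meth:`from_absolute` when the shifts are
    known on the expression scale instead.
    """

    d_plus: float
    d_minus: float
    alpha_r: float

    def __post_init__(self) -> None:
        for name in ("d_plus", "d_minus", "alpha_r"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.alpha_r < 0.0:
            raise InvalidParameterError(f"alpha_r must be >= 0, got {self.alpha_r}")

    @classmethod
    def from_absolute(
        cls,
        delta_mu_plus: float,
        delta_mu_minus: float,
        alpha_r: float,
        gp: "GroupParams",
    ) -> "ShiftParams":
        """Build from absolute expression shifts, normalising by (E+ - E-) of ``gp``.

        The two conventions coincide whenever E+ - E- = 1.
        """
        gap = gp.e_plus - gp.e_minus
        if gap == 0.0:
            raise DomainError("cannot normalise shifts: e_plus - e_minus is 0")
        return cls(delta_mu_plus / gap, delta_mu_minus / gap, alpha_r)

    def absolute_shifts(self, gp: "GroupParams") -> tuple[float, float]:
        """Absolute component-mean shifts (delta_mu+, delta_mu-) for baseline ``gp``."""
        gap = gp.e_plus - gp.e_minus
        return self.d_plus * gap, self.d_minus * gap


@dataclass(frozen=True)
class MeasurementNoise:
    """Additive measurement error on the bulk value: e ~ (0, v_err)."""

    v_err: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "v_err", _require_finite("v_err", self.v_err))
        if self.v_err < 0.0:
            raise InvalidParameterError(f"v_err must be >= 0, got {self.v_err}")


class VarianceTerms(NamedTuple):
    """The five additive components of the bulk variance."""

    gap_proportion: float  # (E+ - E-)^2 * Vr
    plus: float            # Er^2 * V+
    minus: float           # (1 - Er)^2 * V-
    interaction: float     # (V+ + V-) * Vr
    noise: float           # V[e]

    @property
    def total(self) -> float:
        return float(sum(self))


def expected_bulk(gp: GroupParams) -> float:
    """Population mean of the bulk value: E[Y] = Er*E+ + (1 - Er)*E-."""
    return gp.e_r * gp.e_plus + (1.0 - gp.e_r) * gp.e_minus


def variance_bulk_terms(
    gp: GroupParams, noise: MeasurementNoise | None = None
) -> VarianceTerms:
    """The five additive terms of the bulk variance, itemised for reporting.

    The decomposition separates the three biological levers of differential
    variability — the component-mean gap acting through Vr, the proportion
    acting through Er^2*V+ + (1-Er)^2*V-, and the donor-level variances
    themselves — from the proportion-mean interaction and measurement noise.
    """
    if noise is None:
        noise = MeasurementNoise(0.0)
    gap = gp.e_plus - gp.e_minus
    return VarianceTerms(
        gap_proportion=gap * gap * gp.v_r,
        plus=gp.e_r * gp.e_r * gp.v_plus,
        minus=(1.0 - gp.e_r) ** 2 * gp.v_minus,
        interaction=(gp.v_plus + gp.v_minus) * gp.v_r,
        noise=noise.v_err,
    )


def variance_bulk(gp: GroupParams, noise: MeasurementNoise | None = None) -> float:
    """Population variance of the bulk value across donors.

    V[Y] = (E+-E-)^2*Vr + Er^2*V+ + (1-Er)^2*V- + (V+ + V-)*Vr + v_err.
    """
    return variance_bulk_terms(gp, noise).total


def apply_shift(gp: GroupParams, shift: ShiftParams) -> GroupParams:
    """Population parameters of the shifted (disease) group.

    E+ and E- move by the absolute shifts d± * (E+ - E-); the expected
    proportion becomes alpha_r * Er.  Donor-level variances are unchanged.

    Raises
    ------
    DomainError
        If alpha_r * e_r falls outside [0, 1] (no valid proportion exists).
    """
    new_e_r = shift.alpha_r * gp.e_r
    if not 0.0 <= new_e_r <= 1.0:
        raise DomainError(
            f"alpha_r * e_r = {new_e_r} is outside [0, 1] "
            f"(alpha_r={shift.alpha_r}, e_r={gp.e_r})"
        )
    d_abs_plus, d_abs_minus = shift.absolute_shifts(gp)
    return replace(
        gp,
        e_plus=gp.e_plus + d_abs_plus,
        e_minus=gp.e_minus + d_abs_minus,
        e_r=new_e_r,
    )


def mean_difference(gp_c: GroupParams, shift: ShiftParams) -> float:
    """Closed-form group difference in bulk means, E[Y_D] - E[Y_C].

    Equals ``expected_bulk(apply_shift(gp_c, shift)) - expected_bulk(gp_c)``
    but written in the factored form

        (E+ - E-) * (Er*(alpha_r - 1) + alpha_r*Er*d+ + (1 - alpha_r*Er)*d-)

    which makes the cancellation between a positive expression shift
    (d± > 0) and a proportion decrease (alpha_r < 1) explicit.
    """
    new_e_r = shift.alpha_r * gp_c.e_r
    if not 0.0 <= new_e_r <= 1.0:
        raise DomainError(
            f"alpha_r * e_r = {new_e_r} is outside [0, 1] "
            f"(alpha_r={shift.alpha_r}, e_r={gp_c.e_r})"
        )
    gap = gp_c.e_plus - gp_c.e_minus
    er = gp_c.e_r
    a = shift.alpha_r
    return gap * (er * (a - 1.0) + a * er * shift.d_plus + (1.0 - a * er) * shift.d_minus)


def cancellation_alpha_bound(gp_c: GroupParams, d_plus: float, d_minus: float) -> float:
    """The alpha_r at which the bulk mean difference is exactly zero.

    Solving ``mean_difference == 0`` for alpha_r gives

        alpha_r* = (1 - d-/Er) / (1 + d+ - d-)

    Under the assumptions E+ > E-, Er > 0 and 1 + d+ - d- > 0, any
    alpha_r <= alpha_r* gives E[Y_D] - E[Y_C] <= 0 when d+ > 0 and
    d- >= 0: the gene's single-cell activation is invisible (or inverted)
    at the bulk level.

    Raises
    ------
    DomainError
        Naming whichever assumption (E+ > E-, Er > 0, 1 + d+ - d- > 0)
        is violated.
    """
    if not gp_c.e_plus > gp_c.e_minus:
        raise DomainError(
            f"requires e_plus > e_minus, got e_plus={gp_c.e_plus}, e_minus={gp_c.e_minus}"
        )
    if not gp_c.e_r > 0.0:
        raise DomainError(f"requires e_r > 0, got e_r={gp_c.e_r}")
    denom = 1.0 + d_plus - d_minus
    if not denom > 0.0:
        raise DomainError(f"requires 1 + d_plus - d_minus > 0, got {denom}")
    return (1.0 - d_minus / gp_c.e_r) / denom
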