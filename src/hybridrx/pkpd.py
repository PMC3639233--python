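"""Pharmacokinetics (dose -> concentration) and pharmacodynamics (concentration -> effect).

The PK layer models periodic drug intake.  Two effect-site concentration
profiles are supported, both restarting at every dose time ``k*tau`` (no
inter-dose accumulation):

``three_stage``
    Exponential absorption up to the peak, an equilibrium plateau, then
    first-order elimination.  Within a period, with ``s = t mod tau``::

        u(s) = exp(lambda_a * s) - 1          0    <= s < p1   (rise)
        u(s) = zeta                           p1   <= s < p2   (plateau)
        u(s) = zeta * exp(-lambda_d*(s - p2)) p2   <= s < tau  (decay)

    ``p1`` and ``p2`` are the stage-boundary *times since dosing* (the plateau
    lasts ``p2 - p1``).  Continuity at ``p1`` fixes the absorption quotient,
    ``lambda_a = ln(1 + zeta)/p1``; a user-supplied conflicting value is
    overridden with a warning.  The peak ``zeta`` is identified with the unit
    dose (proportionality constant 1) so stated dose values are usable
    directly.

``decay_only``
    Pure first-order elimination from the peak, ``u(s) = zeta*exp(-lambda_d*s)``
    (absorption and equilibrium treated as instantaneous).

The PD layer is a piecewise-linear approximation of the sigmoidal Emax
(Hill) concentration-response curve: no effect below the minimum effective
dose ``theta_lower`` (MinED), a linear ramp of slope ``q`` between the
thresholds, and saturation above the maximum effective dose ``theta_upper``
(MaxED).  :func:`emax_to_pd` builds the approximation from Emax/EC50/m by
matching the Hill curve's slope at EC50 (``q = m*Emax/(4*EC50)``) and its
total swing (``q*(MaxED - MinED) = Emax``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "DoseRegimen",
    "PDCurve",
    "StageTimes",
    "concentration",
    "drug_effect_factor",
    "emax_to_pd",
    "stage_times",
    "period_breakpoints",
    "dosing_density",
]


@dataclass(frozen=True)
class DoseRegimen:
    """Periodic dosing schedule and effect-site concentration profile.

    Parameters
    ----------
    tau
        Dosing period (time units, > 0).
    dose
        Unit dose; equals the peak concentration ``zeta``.
    lambda_d
        First-order elimination quotient (1/time, > 0).
    p1, p2
        Rise-end and plateau-end times measured from each dose instant
        (``0 <= p1 <= p2 <= tau``); both 0 for ``decay_only``.
    profile
        ``"three_stage"`` or ``"decay_only"``.
    lambda_a
        Absorption quotient.  Derived as ``ln(1+zeta)/p1`` for three-stage
        profiles so the concentration is continuous at ``p1``; a conflicting
        explicit value triggers a warning and the derived value wins.
    """

    tau: float
    dose: float
    lambda_d: float
    p1: float = 0.0
    p2: float = 0.0
    profile: str = "three_stage"
    lambda_a: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")
        if not self.lambda_d > 0:
            raise ValueError(f"lambda_d must be > 0, got {self.lambda_d}")
        if self.profile not in ("three_stage", "decay_only"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.profile == "decay_only":
            if self.p1 != 0 or self.p2 != 0:
                raise ValueError("decay_only profiles have p1 = p2 = 0")
            object.__setattr__(self, "lambda_a", math.inf)
            return
        if not 0 < self.p1 <= self.p2 <= self.tau:
            raise ValueError(
                f"need 0 < p1 <= p2 <= tau, got p1={self.p1}, p2={self.p2}, tau={self.tau}"
            )
        derived = math.log1p(self.dose) / self.p1
        if self.lambda_a is not None and not math.isclose(
            self.lambda_a, derived, rel_tol=1e-9, abs_tol=1e-12
        ):
            warnings.warn(
                f"lambda_a={self.lambda_a} conflicts with the continuity constraint "
                f"ln(1+dose)/p1={derived:.6g}; using the derived value",
                stacklevel=2,
            )
        object.__setattr__(self, "lambda_a", derived)

    @property
    def zeta(self) -> float:
        """Peak concentration reached after each dose."""
        return self.dose

    @property
    def alpha(self) -> float:
        """Intake density dose/tau (total-exposure / toxicity proxy)."""
        return self.dose / self.tau

    def concentration(self, t) -> np.ndarray | float:
        """Effect-site concentration at time(s) ``t >= 0``."""
        scalar = np.isscalar(t)
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be >= 0")
        s = np.mod(t, self.tau)
        if self.profile == "decay_only":
            u = self.zeta * np.exp(-self.lambda_d * s)
        else:
            u = np.where(
                s < self.p1,
                np.expm1(self.lambda_a * np.minimum(s, self.p1)),
                np.where(
                    s < self.p2,
                    self.zeta,
                    self.zeta * np.exp(-self.lambda_d * np.maximum(s - self.p2, 0.0)),
                ),
            )
        return float(u) if scalar else u


def concentration(reg: DoseRegimen, t) -> np.ndarray | float:
    """Functional alias for :meth:`DoseRegimen.concentration`."""
    return reg.concentration(t)


@dataclass(frozen=True)
class PDCurve:
    """Piecewise-linear concentration-to-effect map.

    ``effect(u) = q * clip(u - theta_lower, 0, theta_upper - theta_lower)``.
    The unsaturated linear special case (``theta_lower=0``,
    ``theta_upper=inf``) gives ``effect(u) = q*u`` and is used for experiments
    whose parameterization gives a slope but no effective-dose thresholds.
    """

    q: float
    theta_lower: float = 0.0
    theta_upper: float = math.inf

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError(f"PD slope q must be >= 0, got {self.q}")
        if not 0 <= self.theta_lower < self.theta_upper:
            raise ValueError(
                f"need 0 <= theta_lower < theta_upper, got "
                f"[{self.theta_lower}, {self.theta_upper}]"
            )

    @property
    def saturated_effect(self) -> float:
        """Maximal effect ``q*(theta_upper - theta_lower)`` (inf if unsaturated)."""
        return self.q * (self.theta_upper - self.theta_lower)

    @property
    def unsaturated(self) -> bool:
        return math.isinf(self.theta_upper)

    def effect(self, u) -> np.ndarray | float:
        scalar = np.isscalar(u)
        u = np.asarray(u, dtype=float)
        if np.any(u < 0):
            raise ValueError("concentration must be >= 0")
        width = self.theta_upper - self.theta_lower
        e = self.q * np.clip(u - self.theta_lower, 0.0, width)
        return float(e) if scalar else e


def drug_effect_factor(pd: PDCurve, u) -> np.ndarray | float:
    """Drug-effect factor gamma^u at concentration ``u`` (alias for ``pd.effect``)."""
    return pd.effect(u)


def emax_to_pd(emax: float, ec50: float, m: float) -> PDCurve:
    """Piecewise-linear approximation of the sigmoidal Emax model.

    The Hill curve ``E(C) = Emax*C^m/(EC50^m + C^m)`` has slope
    ``m*Emax/(4*EC50)`` at ``C = EC50``; the approximation uses that slope for
    the linear range and centers the range on EC50, which together with the
    swing constraint ``q*(MaxED - MinED) = Emax`` fixes both thresholds.  If
    the lower threshold would be negative (shallow curves, ``m < 2``) it is
    clipped at 0 with the width preserved, shifting the center (a warning is
    issued).
    """
    if not (emax > 0 and ec50 > 0 and m > 0):
        raise ValueError("emax, ec50 and m must all be > 0")
    q = m * emax / (4.0 * ec50)
    half_width = emax / (2.0 * q)  # = 2*ec50/m
    lo, hi = ec50 - half_width, ec50 + half_width
    if lo < 0:
        warnings.warn(
            f"MinED would be negative ({lo:.4g}); clipping at 0 and preserving the "
            "linear-range width",
            stacklevel=2,
        )
        hi -= lo
        lo = 0.0
    return PDCurve(q=q, theta_lower=lo, theta_upper=hi)


@dataclass(frozen=True)
class StageTimes:
    """Threshold-crossing schedule of the concentration within one period.

    Scenario A (peak above MaxED) visits all five effect domains; scenario B
    (peak between MinED and MaxED) never saturates, so the MaxED crossings
    ``t2``/``t5`` are absent; scenario C (peak below MinED) has no effective
    stages at all.  Times that a crossing would reach only after the period
    ends are reported as ``None``.

    Attributes
    ----------
    scenario : str
        ``"A"``, ``"B"`` or ``"C"``.
    t1, t2 : float or None
        Up-crossings of MinED and MaxED during absorption.
    t3, t4 : float
        Rise end ``k*tau + p1`` and plateau end ``k*tau + p2``.
    t5, t6 : float or None
        Down-crossings of MaxED and MinED during elimination.
    """

    scenario: str
    t1: float | None = None
    t2: float | None = None
    t3: float | None = None
    t4: float | None = None
    t5: float | None = None
    t6: float | None = None
    period_start: float = 0.0
    period_end: float = 0.0

    def times(self) -> Iterator[tuple[str, float]]:
        for name in ("t1", "t2", "t3", "t4", "t5", "t6"):
            v = getattr(self, name)
            if v is not None:
                yield name, v


def stage_times(reg: DoseRegimen, pd: PDCurve, k: int = 0) -> StageTimes:
    """Locate the PD-threshold crossings of the concentration in period ``k``.

    For three-stage profiles the rise crossings come from inverting the
    absorption law (``u = exp(lambda_a*s) - 1``) and the decay crossings from
    the elimination law; for decay-only profiles only the down-crossings
    exist.  All returned times satisfy ``concentration(t) == threshold`` up to
    roundoff, which the test suite cross-validates.
    """
    t0 = k * reg.tau
    t_end = t0 + reg.tau
    zeta = reg.zeta
    lo, hi = pd.theta_lower, pd.theta_upper

    if zeta <= lo:
        return StageTimes("C", period_start=t0, period_end=t_end)
    scenario = "A" if zeta > hi else "B"

    def clip(t: float | None) -> float | None:
        return None if (t is None or t > t_end) else t

    if reg.profile == "decay_only":
        t5 = t0 + math.log(zeta / hi) / reg.lambda_d if scenario == "A" else None
        if lo > 0:
            start = t5 if t5 is not None else t0
            level = min(zeta, hi)
            t6 = start + math.log(level / lo) / reg.lambda_d
        else:
            t6 = None
        return StageTimes(
            scenario, t5=clip(t5), t6=clip(t6), period_start=t0, period_end=t_end
        )

    # three-stage: rise crossings (t1, t2), stage boundaries (t3, t4), decay
    # crossings (t5, t6)
    t1 = t0 + (math.log1p(lo) / reg.lambda_a if lo > 0 else 0.0)
    t2 = t0 + math.log1p(hi) / reg.lambda_a if scenario == "A" else None
    t3, t4 = t0 + reg.p1, t0 + reg.p2
    t5 = t4 + math.log(zeta / hi) / reg.lambda_d if scenario == "A" else None
    if lo > 0:
        start = t5 if t5 is not None else t4
        level = min(zeta, hi)
        t6 = start + math.log(level / lo) / reg.lambda_d
    else:
        t6 = None
    return StageTimes(
        scenario,
        t1=clip(t1),
        t2=clip(t2),
        t3=t3,
        t4=t4,
        t5=clip(t5),
        t6=clip(t6),
        period_start=t0,
        period_end=t_end,
    )


def period_breakpoints(reg: DoseRegimen, pd: PDCurve, k: int = 0) -> list[float]:
    """Sorted segment boundaries within period ``k``: the dose time, the PK
    stage boundaries, the PD threshold crossings, and the period end.

    Between consecutive breakpoints the coupled dynamics are smooth (the
    concentration law and the PD regime are both fixed), which is what the
    simulator and the stage-wise analytic solver rely on.
    """
    st = stage_times(reg, pd, k)
    t0, t_end = st.period_start, st.period_end
    pts = {t0, t_end}
    for _, t in st.times():
        if t0 < t < t_end:
            pts.add(t)
    if reg.profile == "three_stage":
        pts.update((t0 + reg.p1, t0 + reg.p2))
    return sorted(pts)


def dosing_density(dose: float, tau: float) -> float:
    """Intake density ``alpha = dose/tau``, the exposure/toxicity proxy."""
    if not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return dose / tau
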