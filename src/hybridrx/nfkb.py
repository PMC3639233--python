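"""NF-kB / IkBa signaling module with drug perturbations.

A nine-species mass-action model of the core NF-kB negative feedback loop:
cytoplasmic NF-kB (x1), IkBa (x2) and their complex (x3); the nuclear
counterparts (x4, x5, x6); and the kinase branch IKK (x7), IKK:IkBa (x8) and
IKK:IkBa:NF-kB (x9).  A stimulus ``k(t)`` produces active IKK, IKK-bound IkBa
is degraded catalytically (releasing NF-kB), free NF-kB shuttles into the
nucleus, and nuclear NF-kB drives IkBa resynthesis with a transcriptional /
translational delay ``tau_delay`` — the delayed negative feedback that makes
nuclear NF-kB (x4) oscillate under sustained stimulation.

Drug perturbations:

* **Drug X** — a kinase inhibitor that competitively sequesters free IKK with
  the same binding kinetics as the natural IKK + NF-kB:IkBa reaction
  (association ``a7``, dissociation ``d1``).  It adds a tenth species
  ``x10 = IKK:X``; the free drug is held at its nominal concentration
  (excess-drug assumption) and binds free IKK only.
* **Bortezomib** — a proteasome inhibitor modeled by scaling every
  proteasome-mediated degradation rate (``r1``, the catalytic part of the
  lumped ``r4+d4`` release rate, ``deg1``, ``deg4``) by ``1 - f`` where ``f``
  is the inhibition fraction.

The delay system is integrated by the method of steps: the horizon is split
into intervals of one delay length, each integrated with dense output so the
lagged ``x4(t - tau_delay)`` term interpolates the previously accepted
solution.  ``tau_delay = 0`` falls back to a plain ODE integration.

The published equations are implemented verbatim, which leaves total
NF-kB slightly non-conserved (the x1 + x8 binding term has no matching
production, and the x9 release/loss coefficients differ by ``d4 - d1``); a
``strict_balance`` flag restores exact mass balance for comparison and is OFF
by default.  The IKK branch *is* exactly balanced either way:
``d/dt (x7+x8+x9+x10) = k(t) - k02*x7``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

__all__ = [
    "NFkBParams",
    "DrugScenario",
    "OscillationMetrics",
    "NFkBTrajectory",
    "nfkb_rhs",
    "apply_bortezomib",
    "default_initial_state",
    "simulate_nfkb",
]

#: Default stimulus (uM/min).  The smallest order of magnitude at which the
#: delayed feedback sustains nuclear NF-kB oscillation with the default total
#: NF-kB of 0.1 uM; see docs/methods.md for the selection procedure.
DEFAULT_STIMULUS = 1e-4

#: Default total NF-kB (uM), placed entirely in the cytoplasmic complex x3.
DEFAULT_NFKB_TOTAL = 0.1

SPECIES = (
    "NFkB", "IkBa", "IkBa:NFkB", "NFkB_n", "IkBa_n", "IkBa_n:NFkB_n",
    "IKK", "IKK:IkBa", "IKK:IkBa:NFkB", "IKK:X",
)


@dataclass(frozen=True)
class NFkBParams:
    """Mass-action rate constants (uM and minutes).

    ``r4`` stores only the catalytic part of the lumped release rate reported
    as ``r4 + d4 = 11.1``/min (i.e. 11.1 - d4 = 11.07), so that proteasome
    inhibition can scale the catalytic part while leaving the dissociation
    part ``d4`` untouched.
    """

    a4: float = 30.0      # NF-kB + IkBa association (1/(uM min))
    a7: float = 11.1      # NF-kB:IkBa + IKK association (1/(uM min))
    a1: float = 1.38      # IkBa + IKK association (1/(uM min))
    d4: float = 0.03      # NF-kB:IkBa dissociation (1/min)
    d1: float = 0.075     # IKK-complex dissociation (1/min)
    deg1: float = 0.006   # free IkBa degradation (1/min)
    deg4: float = 0.0013  # complex degradation releasing NF-kB (1/min)
    k01: float = 0.0048   # nuclear NF-kB export (1/min)
    tp2: float = 0.025    # nuclear IkBa export (1/min)
    k2: float = 0.84      # nuclear complex export (1/min)
    k1: float = 5.4       # NF-kB nuclear import (1/min)
    tp1: float = 0.05     # IkBa nuclear import (1/min)
    k02: float = 0.002    # IKK inactivation (1/min)
    r4: float = 11.1 - 0.03  # catalyzed degradation of IKK:IkBa:NFkB (1/min)
    r1: float = 2.22      # catalyzed degradation of IKK:IkBa (1/min)
    s_synthesis: float = 0.24  # delayed IkBa synthesis per nuclear NF-kB (1/min)
    tau_delay: float = 40.0   # transcriptional delay (min)

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")


@dataclass(frozen=True)
class DrugScenario:
    """Drug settings and stimulus for one run."""

    drug_x_conc: float = 0.0       # uM; 0 = off
    bortezomib_inhibition: float = 0.0  # fraction in [0, 1); 0 = off
    stimulus: float | Callable[[float], float] = DEFAULT_STIMULUS  # k(t), uM/min
    strict_balance: bool = False

    def __post_init__(self) -> None:
        if self.drug_x_conc < 0:
            raise ValueError("drug X concentration must be >= 0")
        if not 0 <= self.bortezomib_inhibition < 1:
            raise ValueError("bortezomib inhibition fraction must be in [0, 1)")

    def k(self, t: float) -> float:
        if callable(self.stimulus):
            return self.stimulus(t)
        return float(self.stimulus)


def apply_bortezomib(params: NFkBParams, f: float) -> NFkBParams:
    """Scale proteasome-mediated degradation rates by ``1 - f``.

    Affects ``r1``, the catalytic ``r4``, ``deg1`` and ``deg4``; binding,
    transport and the dissociation part ``d4`` are untouched.
    """
    if not 0 <= f < 1:
        raise ValueError("inhibition fraction must be in [0, 1)")
    s = 1.0 - f
    return replace(
        params, r1=params.r1 * s, r4=params.r4 * s,
        deg1=params.deg1 * s, deg4=params.deg4 * s,
    )


def nfkb_rhs(
    state: Sequence[float],
    x4_delayed: float,
    t: float,
    params: NFkBParams,
    scenario: DrugScenario,
) -> np.ndarray:
    """Derivative of the (10-species) state; ``x10`` is inert without drug X."""
    x = np.asarray(state, dtype=float)
    if x.shape != (10,):
        raise ValueError(f"state must have 10 components, got shape {x.shape}")
    p = apply_bortezomib(params, scenario.bortezomib_inhibition)
    x1, x2, x3, x4, x5, x6, x7, x8, x9, x10 = x
    X = scenario.drug_x_conc
    k_t = scenario.k(t)
    release = (p.r4 + p.d4) * x9 if not scenario.strict_balance else p.r4 * x9

    dx = np.empty(10)
    dx[0] = (
        -p.a4 * x1 * x2 + p.d4 * x3 - p.a4 * x1 * x8 + release
        + p.deg4 * x3 - p.k1 * x1 + p.k01 * x4
    )
    dx[1] = (
        -p.a1 * x2 * x7 + p.d1 * x8 - p.a4 * x1 * x2 + p.d4 * x3
        - p.deg1 * x2 - p.tp1 * x2 + p.tp2 * x5 + p.s_synthesis * x4_delayed
    )
    dx[2] = (
        p.a4 * x1 * x2 - p.d4 * x3 - p.a7 * x3 * x7 + p.d1 * x9
        + p.k2 * x6 - p.deg4 * x3
    )
    dx[3] = p.k1 * x1 - p.a4 * x4 * x5 + p.d4 * x6 - p.k01 * x4
    dx[4] = p.tp1 * x2 - p.tp2 * x5 - p.a4 * x4 * x5 + p.d4 * x6
    dx[5] = p.a4 * x4 * x5 - p.d4 * x6 - p.k2 * x6
    dx[6] = (
        k_t - p.k02 * x7 - p.a1 * x2 * x7 + (p.d1 + p.r1) * x8
        - p.a7 * x3 * x7 + (p.d1 + p.r4) * x9
        - (p.a7 * X * x7 - p.d1 * x10)
    )
    dx[7] = p.a1 * x2 * x7 - (p.d1 + p.r1) * x8
    dx[8] = p.a7 * x3 * x7 - (p.d1 + p.r4) * x9
    dx[9] = p.a7 * X * x7 - p.d1 * x10
    if scenario.strict_balance:
        dx[7] -= p.a4 * x1 * x8
        dx[8] += p.a4 * x1 * x8
    return dx


def default_initial_state(nfkb_total: float = DEFAULT_NFKB_TOTAL) -> np.ndarray:
    """All NF-kB starts sequestered in the cytoplasmic complex x3 (resting cell)."""
    x0 = np.zeros(10)
    x0[2] = nfkb_total
    return x0


@dataclass(frozen=True)
class OscillationMetrics:
    """Summary of the nuclear NF-kB (x4) time course."""

    n_peaks: int
    amplitude: float  # max - min of x4 over the run
    period: float | None  # mean inter-peak spacing (min), None if < 2 peaks
    mean_x4: float  # time average of x4
    max_x4: float
    sustained: bool  # >= 3 peaks with prominence above 10% of the maximum


@dataclass
class NFkBTrajectory:
    times: np.ndarray
    states: np.ndarray  # (n, 10)
    species: tuple[str, ...] = SPECIES

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times}
        for j, s in enumerate(self.species):
            data[f"x{j+1}"] = self.states[:, j]
        return pd.DataFrame(data)


def oscillation_metrics(times: np.ndarray, x4: np.ndarray) -> OscillationMetrics:
    prom = 0.1 * max(float(x4.max()), 1e-15)
    peaks, _ = find_peaks(x4, prominence=prom)
    period = float(np.mean(np.diff(times[peaks]))) if len(peaks) >= 2 else None
    mean = float(np.trapezoid(x4, times) / (times[-1] - times[0]))
    return OscillationMetrics(
        n_peaks=int(len(peaks)),
        amplitude=float(x4.max() - x4.min()),
        period=period,
        mean_x4=mean,
        max_x4=float(x4.max()),
        sustained=len(peaks) >= 3,
    )


def simulate_nfkb(
    params: NFkBParams | None = None,
    scenario: DrugScenario | None = None,
    x_init: Sequence[float] | None = None,
    t_end: float = 600.0,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    samples: int = 2001,
    history: Callable[[float], float] | None = None,
) -> tuple[NFkBTrajectory, OscillationMetrics]:
    """Integrate the delay system and summarize the x4 oscillation.

    ``history`` supplies ``x4`` on ``[-tau_delay, 0]``; the default is the
    constant initial value (resting history).  Integration proceeds by the
    method of steps with dense interpolation of the lagged term.
    """
    params = params or NFkBParams()
    scenario = scenario or DrugScenario()
    x0 = (
        np.asarray(x_init, dtype=float).copy()
        if x_init is not None
        else default_initial_state()
    )
    if x0.shape == (9,):  # convenience: accept the drug-free 9-species state
        x0 = np.append(x0, 0.0)
    if x0.shape != (10,):
        raise ValueError("initial state must have 9 or 10 components")
    hist = history if history is not None else (lambda t: float(x0[3]))
    lag = params.tau_delay

    sols = []

    def x4_at(tq: float) -> float:
        if tq <= 0:
            return hist(tq)
        for s in sols:
            if s.t[0] - 1e-9 <= tq <= s.t[-1] + 1e-9:
                return float(s.sol(tq)[3])
        raise RuntimeError(f"no history available at t={tq}")  # pragma: no cover

    t, x = 0.0, x0
    if lag == 0.0:

        def rhs0(tt, xx):
            return nfkb_rhs(xx, xx[3], tt, params, scenario)

        sol = solve_ivp(
            rhs0, (0.0, t_end), x, rtol=rel_tol, atol=abs_tol,
            dense_output=True, max_step=5.0,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        sols.append(sol)
    else:
        while t < t_end - 1e-9:
            t_next = min(t + lag, t_end)

            def rhs_seg(tt, xx):
                return nfkb_rhs(xx, x4_at(tt - lag), tt, params, scenario)

            sol = solve_ivp(
                rhs_seg, (t, t_next), x, rtol=rel_tol, atol=abs_tol,
                dense_output=True, max_step=min(5.0, max(lag, 1e-6)),
            )
            if not sol.success:
                raise RuntimeError(
                    f"integration failed on [{t:.4g}, {t_next:.4g}]: {sol.message}"
                )
            sols.append(sol)
            x = sol.y[:, -1]
            t = t_next

    if np.any(x < -abs_tol):
        warnings.warn(
            f"species went negative (min {x.min():.3g}); clipping to 0", stacklevel=2
        )
    tg = np.linspace(0.0, t_end, samples)
    out = np.empty((samples, 10))
    si = 0
    for i, tt in enumerate(tg):
        while tt > sols[si].t[-1] + 1e-9:
            si += 1
        out[i] = sols[si].sol(min(tt, sols[si].t[-1]))
    out = np.maximum(out, 0.0)
    traj = NFkBTrajectory(times=tg, states=out)
    return traj, oscillation_metrics(tg, out[:, 3])
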