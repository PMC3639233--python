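"""Semi-analytic stage-wise solutions, the per-period cycle map, and the
two-gene eigen-analysis.

One-gene system
---------------
A disease gene with impaired self-regulation obeys the scalar linear ODE

    dx/dt = beta1 - [gamma1 + gamma_u(t)] * x,

where ``gamma_u(t)`` is the drug-effect factor driven by the periodic
concentration.  Within each segment between PK/PD breakpoints the total
degradation rate ``g(t) = gamma1 + gamma_u(t)`` has a closed-form
antiderivative ``G``, so the exact solution is obtained from the integrating
factor:

    x(t) = x(t_a) * exp(-(G(t)-G(t_a)))
         + beta1 * \\int_{t_a}^{t} exp(G(s) - G(t)) ds.

Segments with constant ``g`` use the elementary relaxation formula; rise and
decay segments inside the linear PD range evaluate the convolution integral by
adaptive quadrature.  The exponent ``G(s) - G(t)`` is always <= 0, so the
integrand never overflows.  Chaining segments over one dosing period yields the
cycle map ``x(k*tau) -> x((k+1)*tau)``; the drug is *effective* when the map
decreases, and iterating it to its fixed point gives the settled limit cycle.

Two-gene system
---------------
A positive-feedback pair with a drug on gene 1,

    dx1/dt = beta1 + eta1*x2 - (gamma1 + gamma_u)*x1
    dx2/dt = beta2 + eta2*x1 - gamma2*x2,

reduces (for constant ``gamma_u``) to a damped second-order ODE
``x1'' + a x1' + b x1 = d`` with ``a = gamma1+gamma_u+gamma2``,
``b = (gamma1+gamma_u)*gamma2 - eta1*eta2`` and ``d = beta1*gamma2 +
beta2*eta1``.  Its discriminant ``a^2-4b = (gamma1+gamma_u-gamma2)^2 +
4*eta1*eta2`` is positive, so both eigenvalues are real and the slower one
changes sign exactly where drug-boosted degradation balances the loop gain,
``(gamma1+gamma_u)*gamma2 = eta1*eta2``.  Stages where the concentration sits
outside the linear PD range therefore admit the closed-form solution
``x1 = d/b + k1*exp(lam1 t) + k2*exp(lam2 t)``; the linear-PD stages are
integrated numerically and the pieces are stitched continuously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .pkpd import DoseRegimen, PDCurve, StageTimes, period_breakpoints, stage_times
from .simulate import Trajectory, classify_domain

__all__ = [
    "OneGeneParams",
    "CycleMapResult",
    "FixedPointResult",
    "one_gene_stage_solution",
    "one_gene_cycle_map",
    "one_gene_fixed_point",
    "TwoGeneParams",
    "TwoGeneEigen",
    "two_gene_eigen",
    "two_gene_solution",
    "two_gene_stage_trajectory",
]

_QUAD_TOL = 1e-10


@dataclass(frozen=True)
class OneGeneParams:
    """Disease-gene parameters plus the dosing/PD context."""

    beta1: float
    gamma1: float
    pd: PDCurve
    reg: DoseRegimen

    def __post_init__(self) -> None:
        if not self.beta1 > 0:
            raise ValueError("beta1 must be > 0")
        if self.gamma1 < 0:
            raise ValueError("gamma1 must be >= 0")


@dataclass(frozen=True)
class _Segment:
    """One smooth piece of the one-gene dynamics.

    ``ulaw`` is "rise" | "plateau" | "decay"; ``regime`` is "off" | "linear" |
    "sat".  ``t_ref`` anchors the concentration law (period start for rise,
    decay start for decay) and ``u_ref`` is the concentration at ``t_ref`` for
    decay laws.
    """

    ta: float
    tb: float
    ulaw: str
    regime: str
    t_ref: float = 0.0
    u_ref: float = 0.0


def _gamma_const(p: OneGeneParams, seg: _Segment) -> float | None:
    """Total degradation rate if constant on the segment, else None."""
    pd = p.pd
    if seg.regime == "off":
        return p.gamma1
    if seg.regime == "sat":
        return p.gamma1 + pd.saturated_effect
    if seg.ulaw == "plateau":
        return p.gamma1 + pd.effect(p.reg.zeta)
    return None


def _G(p: OneGeneParams, seg: _Segment) -> Callable[[float], float]:
    """Antiderivative of the total degradation rate with ``G(seg.ta) = 0``."""
    g0 = _gamma_const(p, seg)
    if g0 is not None:
        return lambda t: g0 * (t - seg.ta)
    q, lo = p.pd.q, p.pd.theta_lower
    g1 = p.gamma1
    if seg.ulaw == "rise":
        la, tr = p.reg.lambda_a, seg.t_ref

        def G(t: float) -> float:
            expo = (math.exp(la * (t - tr)) - math.exp(la * (seg.ta - tr))) / la
            return g1 * (t - seg.ta) + q * (expo - (1.0 + lo) * (t - seg.ta))

        return G
    if seg.ulaw == "decay":
        ld, tr, u0 = p.reg.lambda_d, seg.t_ref, seg.u_ref

        def G(t: float) -> float:
            expo = (
                u0
                * (math.exp(-ld * (seg.ta - tr)) - math.exp(-ld * (t - tr)))
                / ld
            )
            return g1 * (t - seg.ta) + q * (expo - lo * (t - seg.ta))

        return G
    raise ValueError(f"unhandled segment {seg}")


def _advance(p: OneGeneParams, seg: _Segment, x_a: float, t: float) -> float:
    """Exact solution value at ``t`` in ``[seg.ta, seg.tb]`` from ``x(seg.ta)=x_a``."""
    if not seg.ta - 1e-12 <= t <= seg.tb + 1e-12:
        raise ValueError(f"t={t} outside segment [{seg.ta}, {seg.tb}]")
    g0 = _gamma_const(p, seg)
    dt = t - seg.ta
    if g0 is not None:
        if g0 == 0.0:
            return x_a + p.beta1 * dt
        x_ss = p.beta1 / g0
        return x_ss + (x_a - x_ss) * math.exp(-g0 * dt)
    G = _G(p, seg)
    Gt = G(t)
    integral, _ = quad(
        lambda s: math.exp(G(s) - Gt), seg.ta, t, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL
    )
    return x_a * math.exp(-Gt) + p.beta1 * integral


def _gamma_total(p: OneGeneParams, t: float) -> float:
    return p.gamma1 + p.pd.effect(p.reg.concentration(t))


_STAGE_SPECS = {
    # stage -> (u-law, PD regime); letters follow the within-period itinerary
    # D1-rise, D3-rise, D5-rise, D5-plateau, D5-decay, D3-decay, D1-decay.
    "a": ("rise", "off"),
    "b": ("rise", "linear"),
    "c": ("rise", "sat"),
    "d": ("plateau", "sat"),
    "e": ("decay", "sat"),
    "f": ("decay", "linear"),
    "g": ("decay", "off"),
}


def one_gene_stage_solution(
    stage: str,
    params: OneGeneParams,
    x_start: float,
    t_start: float,
    t: float,
) -> float:
    """Closed-form / quadrature value of ``x1(t)`` within a named stage.

    Stages ``a`` and ``g`` are drug-free relaxations toward ``beta1/gamma1``;
    ``c``, ``d``, ``e`` relax toward the saturated steady state
    ``beta1/(gamma1 + q*(MaxED-MinED))``; ``b`` and ``f`` carry a
    concentration-dependent degradation rate and are evaluated through the
    integrating factor with adaptive quadrature.
    """
    if stage not in _STAGE_SPECS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(_STAGE_SPECS)}")
    ulaw, regime = _STAGE_SPECS[stage]
    if t < t_start:
        raise ValueError("t must be >= t_start")
    reg = params.reg
    k = math.floor((t_start + 1e-12) / reg.tau)
    t_ref, u_ref = k * reg.tau, 0.0
    if ulaw == "decay":
        t_ref = t_start
        u_ref = reg.concentration(t_start)
    seg = _Segment(t_start, t, ulaw, regime, t_ref=t_ref, u_ref=u_ref)
    return _advance(params, seg, x_start, t)


def _segments(params: OneGeneParams, k: int) -> list[_Segment]:
    reg, pd = params.reg, params.pd
    bps = period_breakpoints(reg, pd, k)
    t0 = k * reg.tau
    segs = []
    for ta, tb in zip(bps[:-1], bps[1:]):
        mid = 0.5 * (ta + tb)
        u_mid = reg.concentration(mid)
        regime = {"D1": "off", "D3": "linear", "D5": "sat"}[classify_domain(u_mid, pd)]
        s_mid = mid - t0
        if reg.profile == "decay_only":
            ulaw, t_ref, u_ref = "decay", t0, reg.zeta
        elif s_mid < reg.p1:
            ulaw, t_ref, u_ref = "rise", t0, 0.0
        elif s_mid < reg.p2:
            ulaw, t_ref, u_ref = "plateau", t0, reg.zeta
        else:
            ulaw, t_ref, u_ref = "decay", t0 + reg.p2, reg.zeta
        segs.append(_Segment(ta, tb, ulaw, regime, t_ref=t_ref, u_ref=u_ref))
    return segs


@dataclass(frozen=True)
class CycleMapResult:
    """One application of the per-period map ``x(k*tau) -> x((k+1)*tau)``."""

    x_start: float
    x_next: float
    stage_values: tuple[tuple[float, float], ...]  # (time, x) at segment boundaries
    stage_times: StageTimes
    peak: float
    effective: bool


def one_gene_cycle_map(
    params: OneGeneParams, x_k: float, k: int = 0
) -> CycleMapResult:
    """Chain the stage solutions through one dosing period.

    Besides the end-of-period value the result carries the within-period peak
    (located by root-finding on ``dx/dt = beta1 - g(t)*x(t)`` inside segments
    whose derivative changes sign), which is the settled-level measurement the
    efficacy analysis reports, and the effectiveness flag
    ``x((k+1)tau) < x(k*tau)``.
    """
    if x_k < 0:
        raise ValueError("x_k must be >= 0")
    segs = _segments(params, k)
    vals = [(segs[0].ta, x_k)]
    x = x_k
    peak = x
    for seg in segs:
        x_b = _advance(params, seg, x, seg.tb)

        def xdot(t: float, _seg=seg, _xa=x) -> float:
            return params.beta1 - _gamma_total(params, min(t, _seg.tb - 1e-13)) * _advance(
                params, _seg, _xa, t
            )

        da, db = xdot(seg.ta), xdot(seg.tb)
        if da > 0 and db < 0:  # interior maximum
            t_star = brentq(xdot, seg.ta, seg.tb, xtol=1e-12)
            peak = max(peak, _advance(params, seg, x, t_star))
        peak = max(peak, x_b)
        x = x_b
        vals.append((seg.tb, x))
    return CycleMapResult(
        x_start=x_k,
        x_next=x,
        stage_values=tuple(vals),
        stage_times=stage_times(params.reg, params.pd, k),
        peak=peak,
        effective=x < x_k,
    )


@dataclass(frozen=True)
class FixedPointResult:
    """Settled state of the iterated cycle map."""

    x_star: float  # pre-dose fixed point
    peak: float  # settled-cycle peak (the reported "settles at" level)
    n_iter: int
    converged: bool
    diverged: bool
    cycle: CycleMapResult | None


def one_gene_fixed_point(
    params: OneGeneParams,
    x0: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    diverge_bound: float = 1e9,
) -> FixedPointResult:
    """Iterate the cycle map to its fixed point ("settles" semantics).

    The map is affine in ``x`` with contraction factor ``exp(-int g dt) < 1``
    whenever any degradation acts, so plain iteration converges geometrically;
    iteration is used instead of root-finding to mirror the settling process
    itself.
    """
    x = x0 if x0 is not None else (params.beta1 / params.gamma1 if params.gamma1 > 0 else 1.0)
    res = None
    for i in range(1, max_iter + 1):
        res = one_gene_cycle_map(params, x)
        if abs(res.x_next - x) < tol:
            final = one_gene_cycle_map(params, res.x_next)
            return FixedPointResult(
                x_star=final.x_next,
                peak=final.peak,
                n_iter=i,
                converged=True,
                diverged=False,
                cycle=final,
            )
        x = res.x_next
        if not math.isfinite(x) or x > diverge_bound:
            return FixedPointResult(
                x_star=math.inf, peak=math.inf, n_iter=i, converged=False,
                diverged=True, cycle=res,
            )
    return FixedPointResult(
        x_star=x, peak=res.peak if res else x, n_iter=max_iter,
        converged=False, diverged=False, cycle=res,
    )


# ---------------------------------------------------------------------------
# two-gene positive-feedback analysis


@dataclass(frozen=True)
class TwoGeneParams:
    """Positive-feedback pair: synthesis, loop gains, degradations."""

    beta1: float
    beta2: float
    eta1: float
    eta2: float
    gamma1: float
    gamma2: float

    def __post_init__(self) -> None:
        if self.eta1 * self.eta2 <= 0:
            raise ValueError("a positive feedback loop requires eta1*eta2 > 0")
        if min(self.gamma1, self.gamma2) < 0:
            raise ValueError("degradation rates must be >= 0")


@dataclass(frozen=True)
class TwoGeneEigen:
    """Second-order reduction coefficients, eigenvalues and stability class."""

    a: float
    b: float
    d: float
    lam1: float
    lam2: float
    stability: str  # "stable" | "marginal" | "unstable"


def two_gene_eigen(
    gamma1: float,
    gamma2: float,
    gamma1u: float,
    eta1: float,
    eta2: float,
    beta1: float,
    beta2: float,
) -> TwoGeneEigen:
    """Eigen-structure of the positive-feedback pair at constant drug effect.

    ``lam2`` is always negative; ``lam1`` has the opposite sign of
    ``b = (gamma1+gamma1u)*gamma2 - eta1*eta2``: the system is stable exactly
    when drug-boosted degradation outweighs the feedback-loop gain.
    """
    if eta1 * eta2 <= 0:
        raise ValueError("eta1*eta2 must be > 0")
    a = gamma1 + gamma1u + gamma2
    b = (gamma1 + gamma1u) * gamma2 - eta1 * eta2
    d = beta1 * gamma2 + beta2 * eta1
    disc = a * a - 4.0 * b  # = (gamma1+gamma1u-gamma2)^2 + 4*eta1*eta2 > 0
    root = math.sqrt(disc)
    lam1, lam2 = (-a + root) / 2.0, (-a - root) / 2.0
    stability = "stable" if b > 0 else ("marginal" if b == 0 else "unstable")
    return TwoGeneEigen(a=a, b=b, d=d, lam1=lam1, lam2=lam2, stability=stability)


def two_gene_solution(
    eig: TwoGeneEigen,
    x1_0: float,
    x1dot_0: float,
    t0: float,
    t,
    return_derivative: bool = False,
):
    """Closed-form ``x1(t)`` of ``x1'' + a x1' + b x1 = d`` from initial data.

    The general solution is the constant particular term plus two real
    exponentials, ``x1 = d/b + k1 exp(lam1 (t-t0)) + k2 exp(lam2 (t-t0))``;
    the marginal case ``b = 0`` (``lam1 = 0``) switches to the resonant form
    with a linearly growing particular term ``(d/a) * (t - t0)``.
    """
    t = np.asarray(t, dtype=float)
    dt = t - t0
    if eig.b != 0.0:
        xp = eig.d / eig.b
        k1 = (x1dot_0 - eig.lam2 * (x1_0 - xp)) / (eig.lam1 - eig.lam2)
        k2 = (x1_0 - xp) - k1
        x = xp + k1 * np.exp(eig.lam1 * dt) + k2 * np.exp(eig.lam2 * dt)
        dx = eig.lam1 * k1 * np.exp(eig.lam1 * dt) + eig.lam2 * k2 * np.exp(eig.lam2 * dt)
    else:
        a = eig.a
        slope = eig.d / a
        c2 = (slope - x1dot_0) / a
        c0 = x1_0 - c2
        x = c0 + c2 * np.exp(-a * dt) + slope * dt
        dx = -a * c2 * np.exp(-a * dt) + slope
    if return_derivative:
        return x, dx
    return x


def two_gene_stage_trajectory(
    params: TwoGeneParams,
    reg: DoseRegimen,
    pd: PDCurve,
    x0: Sequence[float],
    n_periods: int,
    samples_per_period: int = 200,
) -> Trajectory:
    """Stage-wise semi-analytic trajectory of the positive-feedback pair.

    Segments where the drug effect is constant (below MinED or saturated) use
    the closed-form eigen-solution for ``x1`` — with ``x2`` recovered from
    ``x2 = (x1' - beta1 + (gamma1+gamma_u) x1)/eta1`` — while segments inside
    the linear PD range are integrated numerically; the pieces are stitched
    continuously at every breakpoint.
    """
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != (2,):
        raise ValueError("x0 must have two components")
    times = [0.0]
    states = [x.copy()]
    period_ends = []
    events: list[tuple[float, str]] = []
    for k in range(n_periods):
        bps = period_breakpoints(reg, pd, k)
        events.append((bps[0], "dose"))
        events.extend((t, "pk-stage") for t in bps[1:-1])
        grid = np.linspace(bps[0], bps[-1], samples_per_period + 1)[1:]
        for ta, tb in zip(bps[:-1], bps[1:]):
            mid = 0.5 * (ta + tb)
            dom = classify_domain(float(reg.concentration(mid)), pd)
            tseg = grid[(grid > ta) & (grid <= tb)]
            tseg = np.unique(np.append(tseg, tb))
            if dom in ("D1", "D5"):
                gu = 0.0 if dom == "D1" else pd.saturated_effect
                eig = two_gene_eigen(
                    params.gamma1, params.gamma2, gu,
                    params.eta1, params.eta2, params.beta1, params.beta2,
                )
                x1dot = (
                    params.beta1 + params.eta1 * x[1] - (params.gamma1 + gu) * x[0]
                )
                x1s, dx1s = two_gene_solution(
                    eig, x[0], x1dot, ta, tseg, return_derivative=True
                )
                x2s = (dx1s - params.beta1 + (params.gamma1 + gu) * x1s) / params.eta1
                for tt, v1, v2 in zip(tseg, x1s, x2s):
                    times.append(float(tt))
                    states.append(np.array([v1, v2]))
                x = np.array([x1s[-1], x2s[-1]])
            else:

                def rhs(t, y):
                    gu = pd.effect(float(reg.concentration(t)))
                    return [
                        params.beta1 + params.eta1 * y[1] - (params.gamma1 + gu) * y[0],
                        params.beta2 + params.eta2 * y[0] - params.gamma2 * y[1],
                    ]

                sol = solve_ivp(
                    rhs, (ta, tb), x, rtol=1e-10, atol=1e-12, dense_output=True,
                    max_step=(tb - ta) / 4.0,
                )
                if not sol.success:
                    raise RuntimeError(
                        f"two-gene stage integration failed on [{ta}, {tb}]: {sol.message}"
                    )
                for tt in tseg:
                    times.append(float(tt))
                    states.append(sol.sol(tt))
                x = sol.y[:, -1].copy()
        period_ends.append(x.copy())
    t_arr = np.asarray(times)
    x_arr = np.vstack(states)
    u_arr = np.asarray(reg.concentration(t_arr))
    return Trajectory(
        times=t_arr,
        states=x_arr,
        u=u_arr,
        gamma_u=np.asarray(pd.effect(u_arr)),
        domain=[classify_domain(float(u), pd) for u in u_arr],
        events=events,
        genes=("x1", "x2"),
        period_ends=np.vstack(period_ends),
    )
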