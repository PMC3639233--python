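"""Threshold-switched gene regulatory networks under drug perturbation.

A network couples continuous protein/gene-expression dynamics with discrete
regulatory logic: each synthesis term is a maximal rate multiplied by unit-step
functions of the regulators' expression levels, so the state space is carved
into regions with affine dynamics.  Per gene ``i`` the rate of change is

    dx_i/dt =  sum_k  beta_ik * prod(Omega) * (1 - prod(Xi))      (synthesis)
             - gamma_i * x_i                                      (degradation)
             - sum_s  rate_s * omega_gate(x) * x_i                (gated degradation)
             + sum_f  eta_f * x_source                            (linear feedback)
             + drug terms: +effect (activating) or -effect * x_i  (repressing)

where each ``Omega``/``Xi`` factor is ``s+(x_j, theta+) * s-(x_j, theta-)``,
``s+`` the right-closed unit step and ``s- = 1 - s+``.  The drug ``effect`` is
the concentration-dependent extra degradation rate supplied by the PK/PD layer
(:mod:`hybridrx.pkpd`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "step_plus",
    "step_minus",
    "RegulatorFactor",
    "SynthesisTerm",
    "DrugCoupling",
    "SwitchedDegradation",
    "LinearFeedback",
    "HybridNetwork",
    "eval_rhs",
    "freeze_regime",
]


def step_plus(x: float, theta: float) -> float:
    """Right-closed unit step: 1.0 iff ``x >= theta``, else 0.0.

    The boundary is included (``step_plus(theta, theta) == 1``) so that event
    handling at switching surfaces is deterministic.  ``theta = -inf`` acts as
    the "always on" sentinel and ``theta = +inf`` as "always off".
    """
    return 1.0 if x >= theta else 0.0


def step_minus(x: float, theta: float) -> float:
    """Complementary step, ``1 - step_plus(x, theta)``."""
    return 0.0 if x >= theta else 1.0


@dataclass(frozen=True)
class RegulatorFactor:
    """One ``s+(x_j, theta+) * s-(x_j, theta-)`` factor of a synthesis term.

    ``theta_plus is None`` means the lower threshold is absent (the ``s+``
    factor is identically 1); ``theta_minus is None`` means the upper threshold
    is absent (the ``s-`` factor is identically 1).  With both present the
    factor is an expression-window indicator, requiring
    ``theta_plus < theta_minus``.
    """

    regulator: int
    theta_plus: float | None = None
    theta_minus: float | None = None

    def __post_init__(self) -> None:
        for name in ("theta_plus", "theta_minus"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be a finite nonnegative number or None, got {v}")
        if (
            self.theta_plus is not None
            and self.theta_minus is not None
            and not self.theta_plus < self.theta_minus
        ):
            raise ValueError(
                f"theta_plus ({self.theta_plus}) must be < theta_minus ({self.theta_minus})"
            )

    def omega(self, x: Sequence[float]) -> float:
        """Evaluate the factor at state ``x``."""
        v = x[self.regulator]
        out = 1.0
        if self.theta_plus is not None:
            out *= step_plus(v, self.theta_plus)
        if self.theta_minus is not None and out:
            out *= step_minus(v, self.theta_minus)
        return out

    def thresholds(self) -> Iterator[tuple[int, float]]:
        if self.theta_plus is not None:
            yield (self.regulator, self.theta_plus)
        if self.theta_minus is not None:
            yield (self.regulator, self.theta_minus)


@dataclass(frozen=True)
class SynthesisTerm:
    """``beta * prod(activator factors) * (1 - prod(inhibitor factors))``.

    An empty activator list makes the activator product 1; an empty inhibitor
    list makes the whole ``(1 - prod)`` factor 1 (constitutive synthesis).
    """

    beta: float
    activators: tuple[RegulatorFactor, ...] = ()
    inhibitors: tuple[RegulatorFactor, ...] = ()

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"synthesis rate beta must be > 0, got {self.beta}")
        object.__setattr__(self, "activators", tuple(self.activators))
        object.__setattr__(self, "inhibitors", tuple(self.inhibitors))

    def rate(self, x: Sequence[float]) -> float:
        out = self.beta
        for f in self.activators:
            out *= f.omega(x)
            if out == 0.0:
                return 0.0
        if self.inhibitors:
            inhib = 1.0
            for f in self.inhibitors:
                inhib *= f.omega(x)
                if inhib == 0.0:
                    break
            out *= 1.0 - inhib
        return out


@dataclass(frozen=True)
class DrugCoupling:
    """How a drug input acts on one gene.

    ``repressing`` contributes ``-effect * x_target`` (extra degradation),
    ``activating`` contributes ``+effect`` (extra synthesis), where ``effect``
    is the drug-effect factor computed from the concentration through a PD
    curve.  ``pd`` may pin a specific curve to this coupling; when ``None`` the
    curve passed to the simulator applies.
    """

    target: int
    mode: str = "repressing"
    pd: object | None = None  # PDCurve; kept loose to avoid a circular import

    def __post_init__(self) -> None:
        if self.mode not in ("repressing", "activating"):
            raise ValueError(f"mode must be 'repressing' or 'activating', got {self.mode!r}")


@dataclass(frozen=True)
class SwitchedDegradation:
    """A degradation term ``-rate * omega_gate(x) * x_gene`` gated by another gene."""

    gene: int
    rate: float
    gate: RegulatorFactor

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"switched degradation rate must be >= 0, got {self.rate}")


@dataclass(frozen=True)
class LinearFeedback:
    """An unswitched linear cross term ``+eta * x_source`` on ``target``."""

    source: int
    target: int
    eta: float


@dataclass
class HybridNetwork:
    """A threshold-switched gene regulatory network with drug couplings.

    Parameters
    ----------
    genes
        Ordered gene names; the state dimension equals ``len(genes)``.
    synthesis
        Per-gene tuple of :class:`SynthesisTerm`.
    gamma
        Per-gene constitutive self-degradation rates (1/time, >= 0).
    switched_degradation, feedback, drug_couplings
        Optional structure; see the class docstrings above.
    """

    genes: tuple[str, ...]
    synthesis: tuple[tuple[SynthesisTerm, ...], ...]
    gamma: np.ndarray
    switched_degradation: tuple[SwitchedDegradation, ...] = ()
    feedback: tuple[LinearFeedback, ...] = ()
    drug_couplings: tuple[DrugCoupling, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.synthesis = tuple(tuple(terms) for terms in self.synthesis)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.switched_degradation = tuple(self.switched_degradation)
        self.feedback = tuple(self.feedback)
        self.drug_couplings = tuple(self.drug_couplings)
        n = len(self.genes)
        if len(self.synthesis) != n:
            raise ValueError(f"synthesis has {len(self.synthesis)} entries for {n} genes")
        if self.gamma.shape != (n,):
            raise ValueError(f"gamma must have shape ({n},), got {self.gamma.shape}")
        if np.any(self.gamma < 0):
            raise ValueError("degradation rates gamma must be >= 0")
        for j, theta in self.thresholds():
            if not 0 <= j < n:
                raise ValueError(f"regulator index {j} out of range for {n} genes")
        for c in self.drug_couplings:
            if not 0 <= c.target < n:
                raise ValueError(f"drug coupling target {c.target} out of range")
        for f in self.feedback:
            if not (0 <= f.source < n and 0 <= f.target < n):
                raise ValueError("feedback indices out of range")
        for s in self.switched_degradation:
            if not 0 <= s.gene < n:
                raise ValueError("switched degradation gene index out of range")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self, name: str) -> int:
        try:
            return self.genes.index(name)
        except ValueError:
            raise KeyError(f"unknown gene {name!r}; genes are {self.genes}") from None

    def thresholds(self) -> Iterator[tuple[int, float]]:
        """All (regulator index, threshold) pairs appearing in the network."""
        for terms in self.synthesis:
            for term in terms:
                for f in (*term.activators, *term.inhibitors):
                    yield from f.thresholds()
        for s in self.switched_degradation:
            yield from s.gate.thresholds()

    def eval_rhs(self, x: Sequence[float], drug_effects: Sequence[float] = ()) -> np.ndarray:
        """Instantaneous state derivative at ``x``.

        ``drug_effects`` holds one nonnegative effect factor per entry of
        ``drug_couplings`` (the gamma^u / beta^u value already mapped through
        the PD curve); pass an empty sequence for the drug-free vector field.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_genes,):
            raise ValueError(f"state must have shape ({self.n_genes},), got {x.shape}")
        drug_effects = tuple(drug_effects)
        if drug_effects and len(drug_effects) != len(self.drug_couplings):
            raise ValueError(
                f"got {len(drug_effects)} drug effects for "
                f"{len(self.drug_couplings)} couplings"
            )
        dx = np.empty(self.n_genes)
        for i, terms in enumerate(self.synthesis):
            dx[i] = sum(t.rate(x) for t in terms) - self.gamma[i] * x[i]
        for s in self.switched_degradation:
            dx[s.gene] -= s.rate * s.gate.omega(x) * x[s.gene]
        for f in self.feedback:
            dx[f.target] += f.eta * x[f.source]
        for c, eff in zip(self.drug_couplings, drug_effects):
            if c.mode == "repressing":
                dx[c.target] -= eff * x[c.target]
            else:
                dx[c.target] += eff
        return dx


def eval_rhs(
    net: HybridNetwork, x: Sequence[float], drug_effects: Sequence[float] = ()
) -> np.ndarray:
    """Functional alias for :meth:`HybridNetwork.eval_rhs`."""
    return net.eval_rhs(x, drug_effects)


def freeze_regime(net: HybridNetwork, x0: Sequence[float]) -> HybridNetwork:
    """Pin every state-threshold step factor to its value at ``x0``.

    Returns a copy of the network in which each regulator factor is replaced by
    the constant it evaluates to at ``x0`` (thresholds swapped for sentinels),
    i.e. the piecewise-affine system restricted to the regulatory regime of the
    initial state.  This is an analysis device, not a simulation mode: the true
    hybrid dynamics switch regimes whenever a threshold is crossed, while the
    frozen system keeps the initial regulatory logic forever.  It is useful for
    reasoning about regime-local stability (e.g. which feedback loops are
    active at a given disease stage) and reproduces qualitative claims that
    hold only while no switching surface is crossed.
    """
    x0 = np.asarray(x0, dtype=float)

    def freeze_factor(f: RegulatorFactor) -> RegulatorFactor:
        on = f.omega(x0) == 1.0
        # omega == 1 -> factor identically 1 (no thresholds); omega == 0 ->
        # an unsatisfiable window (s+ with +inf threshold via theta at inf is
        # rejected by validation, so encode "always 0" with theta_plus just
        # above any reachable level: use the regulator's own huge bound).
        if on:
            return RegulatorFactor(f.regulator, None, None)
        return _AlwaysOffFactor(f.regulator)

    def freeze_term(t: SynthesisTerm) -> SynthesisTerm:
        return SynthesisTerm(
            t.beta,
            tuple(freeze_factor(f) for f in t.activators),
            tuple(freeze_factor(f) for f in t.inhibitors),
        )

    return replace(
        net,
        synthesis=tuple(tuple(freeze_term(t) for t in terms) for terms in net.synthesis),
        switched_degradation=tuple(
            SwitchedDegradation(s.gene, s.rate, freeze_factor(s.gate))
            for s in net.switched_degradation
        ),
        name=(net.name + ":frozen") if net.name else "frozen",
    )


@dataclass(frozen=True)
class _AlwaysOffFactor(RegulatorFactor):
    """A regulator factor pinned to 0 (used by :func:`freeze_regime`)."""

    def __post_init__(self) -> None:  # skip threshold validation
        pass

    def omega(self, x: Sequence[float]) -> float:
        return 0.0

    def thresholds(self) -> Iterator[tuple[int, float]]:
        return iter(())
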