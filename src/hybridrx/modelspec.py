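"""Structured-text model specifications and the packaged benchmark fixtures.

A model spec is a YAML (or JSON — YAML is a superset) mapping with keys
``genes``, ``synthesis``, ``gamma``, and optionally ``switched_degradation``,
``feedback``, ``drug_couplings``, ``regimen``, ``pd`` and ``x0``.  Regulator
references use gene *names*; thresholds may be given as ``theta_plus`` /
``theta_minus`` (absent thresholds collapse the corresponding step factor to
1, never encoded as floating-point infinities).  The PD block accepts either
the piecewise-linear parameters (``q`` with optional ``theta_lower`` /
``theta_upper``) or a Hill parameterization (``Emax``, ``EC50``, ``m``) that
is converted through :func:`hybridrx.pkpd.emax_to_pd`.

The packaged fixtures are the fully parameterized benchmark systems used
throughout the documentation and tests; load them by name with
:func:`benchmark_fixture` or list them with :func:`available_fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .network import (
    DrugCoupling,
    HybridNetwork,
    LinearFeedback,
    RegulatorFactor,
    SwitchedDegradation,
    SynthesisTerm,
)
from .pkpd import DoseRegimen, PDCurve, emax_to_pd

__all__ = [
    "ModelBundle",
    "load_model",
    "parse_model",
    "benchmark_fixture",
    "available_fixtures",
]

_FIXTURE_NAMES = (
    "one_gene",
    "two_gene_repression",
    "two_gene_positive_feedback",
    "three_gene",
)


@dataclass
class ModelBundle:
    """A network together with its default regimen, PD curve and initial state."""

    name: str
    description: str
    network: HybridNetwork
    regimen: DoseRegimen | None
    pd: PDCurve | None
    x0: np.ndarray


def _factor(spec: dict, gene_index: dict[str, int]) -> RegulatorFactor:
    gene = spec.get("gene")
    if gene not in gene_index:
        raise ValueError(f"regulator references unknown gene {gene!r}")
    return RegulatorFactor(
        regulator=gene_index[gene],
        theta_plus=spec.get("theta_plus"),
        theta_minus=spec.get("theta_minus"),
    )


def parse_pd(spec: dict) -> PDCurve:
    if {"Emax", "EC50", "m"} <= set(spec):
        return emax_to_pd(spec["Emax"], spec["EC50"], spec["m"])
    if "q" not in spec:
        raise ValueError("pd block needs either q (+ optional thresholds) or Emax/EC50/m")
    return PDCurve(
        q=spec["q"],
        theta_lower=spec.get("theta_lower", 0.0),
        theta_upper=spec.get("theta_upper", float("inf")),
    )


def parse_regimen(spec: dict) -> DoseRegimen:
    return DoseRegimen(
        tau=spec["tau"],
        dose=spec["dose"],
        lambda_d=spec["lambda_d"],
        p1=spec.get("p1", 0.0),
        p2=spec.get("p2", 0.0),
        profile=spec.get("profile", "three_stage"),
        lambda_a=spec.get("lambda_a"),
    )


def parse_model(doc: dict, name: str = "") -> ModelBundle:
    """Build a :class:`ModelBundle` from a parsed spec mapping."""
    genes = tuple(doc["genes"])
    gi = {g: j for j, g in enumerate(genes)}

    synthesis = []
    for g in genes:
        terms = []
        for t in doc.get("synthesis", {}).get(g, []):
            terms.append(
                SynthesisTerm(
                    beta=t["beta"],
                    activators=tuple(_factor(f, gi) for f in t.get("activators", [])),
                    inhibitors=tuple(_factor(f, gi) for f in t.get("inhibitors", [])),
                )
            )
        synthesis.append(tuple(terms))

    gamma = np.array([doc.get("gamma", {}).get(g, 0.0) for g in genes], dtype=float)
    switched = tuple(
        SwitchedDegradation(
            gene=gi[s["gene"]], rate=s["rate"], gate=_factor(s["gate"], gi)
        )
        for s in doc.get("switched_degradation", [])
    )
    feedback = tuple(
        LinearFeedback(source=gi[f["from"]], target=gi[f["to"]], eta=f["eta"])
        for f in doc.get("feedback", [])
    )
    couplings = tuple(
        DrugCoupling(target=gi[c["target"]], mode=c.get("mode", "repressing"))
        for c in doc.get("drug_couplings", [])
    )
    net = HybridNetwork(
        genes=genes,
        synthesis=tuple(synthesis),
        gamma=gamma,
        switched_degradation=switched,
        feedback=feedback,
        drug_couplings=couplings,
        name=doc.get("name", name),
    )
    regimen = parse_regimen(doc["regimen"]) if "regimen" in doc else None
    pd = parse_pd(doc["pd"]) if "pd" in doc else None
    x0 = np.array([doc.get("x0", {}).get(g, 0.0) for g in genes], dtype=float)
    return ModelBundle(
        name=doc.get("name", name),
        description=doc.get("description", "").strip(),
        network=net,
        regimen=regimen,
        pd=pd,
        x0=x0,
    )


def load_model(path: str | Path) -> ModelBundle:
    """Load a model spec file (YAML or JSON)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"model spec {path} did not parse to a mapping")
    return parse_model(doc, name=Path(path).stem)


def available_fixtures() -> tuple[str, ...]:
    """Names of the packaged benchmark fixtures."""
    return _FIXTURE_NAMES


def benchmark_fixture(name: str) -> ModelBundle:
    """Load a packaged benchmark fixture by name.

    Each fixture ships the exact reference parameterization of the corresponding
    benchmark system (network rates and thresholds, dosing regimen, PD curve
    and initial state).
    """
    if name not in _FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(_FIXTURE_NAMES)}"
        )
    text = resources.files("hybridrx.fixtures").joinpath(f"{name}.yaml").read_text()
    return parse_model(yaml.safe_load(text), name=name)
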