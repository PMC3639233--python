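"""Run configuration, trajectory serialization, provenance.

Plumbing shared by the CLI and scripted workflows.  Values are written at 12
significant digits so round-trips are exact at printed precision and
regression comparisons are stable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .modelspec import ModelBundle, load_model, benchmark_fixture, parse_pd, parse_regimen
from .pkpd import DoseRegimen, PDCurve
from .simulate import SimOptions, Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "provenance",
]

_FMT = "%.12g"


@dataclass
class RunConfig:
    """A fully resolved simulation run: model + regimen/PD overrides + options."""

    model: str  # fixture name or spec-file path
    tau: float | None = None
    dose: float | None = None
    n_periods: int = 50
    samples_per_period: int = 200
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    settle_eps: float = 0.01
    regimen: dict = field(default_factory=dict)  # full regimen block (optional)
    pd: dict = field(default_factory=dict)  # full PD block (optional)
    out: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {', '.join(sorted(unknown))}")
        if "model" not in doc:
            raise ValueError("config missing required field 'model'")
        return cls(**doc)

    def resolve(self) -> tuple[ModelBundle, DoseRegimen, PDCurve, SimOptions]:
        """Load the model and apply overrides, validating feasibility."""
        from .modelspec import _FIXTURE_NAMES

        bundle = (
            benchmark_fixture(self.model)
            if self.model in _FIXTURE_NAMES
            else load_model(self.model)
        )
        reg = parse_regimen(self.regimen) if self.regimen else bundle.regimen
        pdc = parse_pd(self.pd) if self.pd else bundle.pd
        if reg is None:
            raise ValueError("config field 'regimen' (or a model default) is required")
        if pdc is None:
            raise ValueError("config field 'pd' (or a model default) is required")
        new_tau = self.tau if self.tau is not None else reg.tau
        if reg.profile == "three_stage" and new_tau < reg.p2:
            raise ValueError(
                f"infeasible regimen: tau={new_tau} is shorter than the plateau "
                f"end p2={reg.p2}"
            )
        overrides = {}
        if self.tau is not None:
            overrides["tau"] = self.tau
        if self.dose is not None:
            overrides["dose"] = self.dose
        if overrides:
            from dataclasses import replace

            reg = replace(reg, lambda_a=None, **overrides)
        opts = SimOptions(
            rel_tol=self.rel_tol,
            abs_tol=self.abs_tol,
            n_periods=self.n_periods,
            samples_per_period=self.samples_per_period,
            settle_eps=self.settle_eps,
        )
        return bundle, reg, pdc, opts


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return RunConfig.from_dict(doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def provenance(bundle: ModelBundle, reg: DoseRegimen, pdc: PDCurve, opts: SimOptions) -> dict:
    """All resolved parameters of a run (emitted alongside every output)."""
    return {
        "model": bundle.name,
        "genes": list(bundle.network.genes),
        "regimen": {
            "profile": reg.profile,
            "tau": reg.tau,
            "dose": reg.dose,
            "lambda_a": None if np.isinf(reg.lambda_a) else reg.lambda_a,
            "lambda_d": reg.lambda_d,
            "p1": reg.p1,
            "p2": reg.p2,
            "alpha": reg.alpha,
        },
        "pd": {
            "q": pdc.q,
            "theta_lower": pdc.theta_lower,
            "theta_upper": None if np.isinf(pdc.theta_upper) else pdc.theta_upper,
        },
        "x0": list(map(float, bundle.x0)),
        "options": asdict(opts),
    }


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=_FMT)


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV back; raises with the line number on bad rows."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed trajectory file {path}: {e}") from e
    required = {"time", "u", "gamma_u", "domain"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"trajectory file {path} missing column(s): {', '.join(sorted(missing))}"
        )
    genes = tuple(c for c in df.columns if c not in required)
    non_numeric = df["time"].apply(lambda v: not np.isreal(v))
    if non_numeric.any():
        line = int(non_numeric.idxmax()) + 2  # header + 1-based
        raise ValueError(f"non-numeric time value at line {line} of {path}")
    return Trajectory(
        times=df["time"].to_numpy(float),
        states=df[list(genes)].to_numpy(float),
        u=df["u"].to_numpy(float),
        gamma_u=df["gamma_u"].to_numpy(float),
        domain=[str(d) for d in df["domain"]],
        events=[],
        genes=genes,
    )
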