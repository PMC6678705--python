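"""Pipeline configuration: one YAML file with per-stage blocks.

The method has ~15 interacting parameters (baseline λ/p/windows, panel
wavenumbers, solver box, polynomial orders, simulation truth, seed); a
single structured config keeps runs reproducible. Command-line flags
override individual values; every run echoes its effective config into the
output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from .baseline import BaselineConfig
from .errors import ConfigurationError
from .features import WavenumberPanel
from .inversion import SolverConfig


@dataclass(frozen=True)
class SimulationBlock:
    """Simulator settings exposed through the config (truth stays default
    unless overridden programmatically)."""

    replicates_per_set: int = 30
    noise_sigma: float = 0.002


@dataclass(frozen=True)
class PipelineConfig:
    baseline: BaselineConfig = BaselineConfig()
    panel: WavenumberPanel = WavenumberPanel()
    solver: SolverConfig = SolverConfig()
    simulation: SimulationBlock = SimulationBlock()
    orders: tuple[int, int] = (2, 2)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "baseline": {
                "lambda": self.baseline.lam,
                "p": self.baseline.p,
                "exclusion_windows": [list(w) for w in self.baseline.exclusion_windows],
                "max_iter": self.baseline.max_iter,
                "tol": self.baseline.tol,
            },
            "panel": {
                "wavenumbers_cm-1": list(self.panel.nus),
                "search_halfwidth_cm-1": self.panel.search_halfwidth,
            },
            "solver": asdict(self.solver),
            "simulation": asdict(self.simulation),
            "orders": list(self.orders),
            "seed": self.seed,
        }

    def save(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            b = d.get("baseline", {})
            baseline = BaselineConfig(
                lam=b.get("lambda", 500.0),
                p=b.get("p", 0.99),
                exclusion_windows=tuple(tuple(w) for w in b.get(
                    "exclusion_windows", [[1000.0, 1100.0]])),
                max_iter=b.get("max_iter", 50),
                tol=b.get("tol", 1e-8),
            )
            pa = d.get("panel", {})
            panel = WavenumberPanel(
                nus=tuple(pa.get("wavenumbers_cm-1", (1034.0, 1063.0, 1078.0))),
                search_halfwidth=pa.get("search_halfwidth_cm-1", 2.0),
            )
            solver = SolverConfig(**d.get("solver", {}))
            sim = SimulationBlock(**d.get("simulation", {}))
            orders = tuple(d.get("orders", (2, 2)))
            if len(orders) != 2:
                raise ConfigurationError(f"orders must be a pair, got {orders}")
            return cls(baseline=baseline, panel=panel, solver=solver,
                       simulation=sim, orders=orders, seed=int(d.get("seed", 0)))
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid pipeline config: {exc}")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
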