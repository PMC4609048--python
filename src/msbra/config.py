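"""Configuration parsing, run manifests and result serialisation.

Scenario and grid settings are written as YAML with a small fixed key set;
unknown keys are rejected so typos cannot silently fall back to defaults.
A run manifest captures the configuration echo, every named stage seed, the
package version and the fixture checksums, which is sufficient to reproduce
any published output bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from .evaluation import GridResult, GridSpec, ScenarioConfig, ScenarioResult
from .serious_risks import RiskDistributionSpec, RiskFamily
from .tree_model import ALTERNATIVES

__all__ = ["parse_config", "serialise_config", "RunManifest", "write_results"]

_SCENARIO_KEYS = {
    "risk_family",
    "k",
    "background_proportion",
    "min_utility_difference",
    "edss",
    "iterations",
    "seed",
}
_GRID_KEYS = {
    "risk_families",
    "ks",
    "background_proportions",
    "min_utility_differences",
    "edss_levels",
    "iterations",
    "seed",
}


def _risk_spec(family: str, k: float) -> RiskDistributionSpec:
    fam = RiskFamily(str(family).upper())
    return RiskDistributionSpec(fam, float(k))


def parse_config(text: str) -> ScenarioConfig | tuple[GridSpec, int]:
    """Parse YAML configuration text.

    A mapping with scalar keys yields a :class:`ScenarioConfig`; a mapping
    under a top-level ``grid:`` key yields ``(GridSpec, seed)``.  Unknown
    keys and out-of-range values are rejected.
    """
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")

    if "grid" in data:
        extra = set(data) - {"grid"}
        if extra:
            raise ValueError(f"unknown top-level keys: {sorted(extra)}")
        g = data["grid"] or {}
        unknown = set(g) - _GRID_KEYS
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        families = g.get("risk_families")
        if families is None:
            from .evaluation import DEFAULT_RISK_FAMILIES

            specs = DEFAULT_RISK_FAMILIES
        else:
            ks = g.get("ks", [5.0] * len(families))
            specs = tuple(_risk_spec(f, k) for f, k in zip(families, ks))
        spec = GridSpec(
            risk_specs=specs,
            background_proportions=tuple(g.get("background_proportions", (0.0, 0.10, 0.25, 0.50))),
            min_utility_differences=tuple(
                g.get("min_utility_differences", GridSpec.min_utility_differences)
            ),
            edss_levels=tuple(g.get("edss_levels", (4, 5))),
            n_iterations=int(g.get("iterations", 10_000)),
        )
        for pi in spec.background_proportions:
            if not 0.0 <= pi <= 0.5:
                raise ValueError("background proportions must lie in [0, 0.5]")
        for d in spec.min_utility_differences:
            if not 0.0 <= d <= 0.99:
                raise ValueError("minimum utility differences must lie in [0, 0.99]")
        return spec, int(g.get("seed", 0))

    unknown = set(data) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return ScenarioConfig(
        risk_spec=_risk_spec(data.get("risk_family", "UNIFORM"), data.get("k", 5.0)),
        background_proportion=float(data.get("background_proportion", 0.0)),
        min_utility_difference=float(data.get("min_utility_difference", 0.0)),
        edss_level=int(data.get("edss", 4)),
        n_iterations=int(data.get("iterations", 10_000)),
        seed=int(data.get("seed", 0)),
    )


def serialise_config(config: ScenarioConfig) -> str:
    """YAML text whose re-parse reproduces ``config`` exactly."""
    payload = {
        "risk_family": config.risk_spec.family.value,
        "k": float(config.risk_spec.rate_multiplier),
        "background_proportion": float(config.background_proportion),
        "min_utility_difference": float(config.min_utility_difference),
        "edss": int(config.edss_level),
        "iterations": int(config.n_iterations),
        "seed": int(config.seed),
    }
    return yaml.safe_dump(payload, sort_keys=True)


@dataclass
class RunManifest:
    """Everything needed to regenerate a run's outputs bit-identically."""

    config: dict
    master_seed: int
    stage_seeds: dict[str, int]
    fixture_checksums: dict[str, str]
    version: str = __version__
    timestamp: str = field(default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _stage_seeds(master: int) -> dict[str, int]:
    stages = (
        "fit-effectiveness",
        "fit-nonserious",
        "risks",
        "utilities",
        "lowdose-interpolation",
    )
    return {stage: derive_seed(master, stage) for stage in stages}


def write_results(
    result: ScenarioResult | GridResult,
    path: str | Path,
    fixture_checksums: dict[str, str] | None = None,
) -> list[Path]:
    """Write a result as delimited text plus a run manifest.

    Scenario results produce expected-utility draws and a preference-rate
    summary; grid results produce the one-row-per-cell table.  Returns the
    written paths.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(result, ScenarioResult):
        eu = pd.DataFrame(
            result.expected_utilities, columns=[f"eu_{a.value}" for a in ALTERNATIVES]
        )
        p = out / "expected_utilities.tsv"
        eu.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)

        p = out / "summary.tsv"
        result.summary().to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)

        manifest = RunManifest(
            config=yaml.safe_load(serialise_config(result.config)),
            master_seed=result.config.seed,
            stage_seeds=_stage_seeds(result.config.seed),
            fixture_checksums=fixture_checksums or {},
        )
    else:
        p = out / "grid.tsv"
        result.table.to_csv(p, sep="\t", index=False, float_format="%.17g")
        written.append(p)
        manifest = RunManifest(
            config={
                "grid": {
                    "risk_families": [s.name() for s in result.spec.risk_specs],
                    "background_proportions": list(result.spec.background_proportions),
                    "min_utility_differences": list(result.spec.min_utility_differences),
                    "edss_levels": list(result.spec.edss_levels),
                    "iterations": result.spec.n_iterations,
                    "seed": result.seed,
                }
            },
            master_seed=result.seed,
            stage_seeds=_stage_seeds(result.seed),
            fixture_checksums=fixture_checksums or {},
        )

    p = out / "manifest.json"
    p.write_text(manifest.to_json() + "\n", encoding="utf-8")
    written.append(p)
    return written
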