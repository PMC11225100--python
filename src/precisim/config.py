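"""Study configuration: YAML schema, parsing, and round-trip emission.

Schema::

    seed: 20230629
    variance_convention: unit_residual   # or "standardized"
    alpha: 0.05
    ref_method: unadjusted
    scenarios:
      - {label: IL6_N100, a: 0.274, b: 0.125, c_prime: 0.0, n: 100, nsim: 1000}
      ...

Per-scenario seeds and variance conventions are resolved from the
top-level values when the study runs, so a config round-trips
(parse -> emit -> parse) identically.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import IO, Mapping

import yaml

from .simstudy import ConfigError, Scenario

__all__ = [
    "StudyConfig",
    "load_study_config",
    "paper_config_path",
    "study_config_to_yaml",
]


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """A full simulation study: scenarios plus study-wide settings."""

    scenarios: tuple[Scenario, ...]
    seed: int = 0
    variance_convention: str = "unit_residual"
    alpha: float = 0.05
    ref_method: str = "unadjusted"

    def __post_init__(self) -> None:
        # scenarios inherit the study-wide seed and variance convention, so a
        # config round-trips and a Scenario can always be run standalone
        resolved = tuple(
            dataclasses.replace(
                s, seed=self.seed, variance_convention=self.variance_convention
            )
            for s in self.scenarios
        )
        object.__setattr__(self, "scenarios", resolved)
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")

    def true_values(self) -> dict[str, float]:
        """Generating focal coefficient (b) per scenario label."""
        return {s.label: s.b for s in self.scenarios}


def load_study_config(source: str | Path | IO[str]) -> StudyConfig:
    """Parse a study configuration from a YAML path or open stream."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, Mapping):
        raise ConfigError("study config must be a YAML mapping")
    seed = int(doc.get("seed", 0))
    convention = str(doc.get("variance_convention", "unit_residual"))
    alpha = float(doc.get("alpha", 0.05))
    ref_method = str(doc.get("ref_method", "unadjusted"))
    scenarios = []
    for entry in doc.get("scenarios", []) or []:
        try:
            scenarios.append(
                Scenario(
                    label=str(entry["label"]),
                    a=float(entry["a"]),
                    b=float(entry["b"]),
                    c_prime=float(entry.get("c_prime", 0.0)),
                    n=int(entry["n"]),
                    nsim=int(entry["nsim"]),
                    seed=seed,
                    variance_convention=convention,
                )
            )
        except KeyError as exc:
            raise ConfigError(f"scenario entry missing required key: {exc}") from None
    return StudyConfig(
        scenarios=tuple(scenarios),
        seed=seed,
        variance_convention=convention,
        alpha=alpha,
        ref_method=ref_method,
    )


def study_config_to_yaml(config: StudyConfig, path: str | Path | None = None) -> str:
    """Emit the YAML form of a config; optionally write it to ``path``."""
    doc = {
        "seed": config.seed,
        "variance_convention": config.variance_convention,
        "alpha": config.alpha,
        "ref_method": config.ref_method,
        "scenarios": [
            {
                "label": s.label,
                "a": s.a,
                "b": s.b,
                "c_prime": s.c_prime,
                "n": s.n,
                "nsim": s.nsim,
            }
            for s in config.scenarios
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def paper_config_path() -> Path:
    """Path to the bundled canonical study configuration (2 proteins x 3 Ns)."""
    return Path(resources.files("precisim").joinpath("data/paper_config.yaml"))
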