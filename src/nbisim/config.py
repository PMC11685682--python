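"""Pipeline configuration: a validated YAML schema shared by all commands.

Unknown keys are rejected so typos fail loudly before any stage runs. All
randomness in the pipeline flows from the seeds declared here; no stage
draws from global entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import DEFAULT_EXPANSION, VariableExpansion
from .colorimetry import WavelengthGrid
from .errors import ConfigError
from .fixtures import FixtureConfig
from .nbi import (
    DEFAULT_BAND_CENTERS,
    BandModel,
    LorentzianBand,
    OptimizationConfig,
    default_band_model,
)
from .reconstruction import DEFAULT_N_PC

__all__ = ["PipelineConfig", "load_config"]


def _take(doc: dict, allowed: set[str], context: str) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")


@dataclass(frozen=True)
class PipelineConfig:
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    expansion: VariableExpansion = DEFAULT_EXPANSION
    n_pc: int = DEFAULT_N_PC
    bands: BandModel = field(default_factory=default_band_model)
    annealing: OptimizationConfig = field(default_factory=OptimizationConfig)
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        if not isinstance(doc, dict):
            raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
        _take(doc, {"grid", "expansion", "n_pc", "bands", "annealing", "fixtures"}, "config")
        try:
            grid_doc = doc.get("grid", {})
            _take(grid_doc, {"start_nm", "stop_nm", "step_nm"}, "grid")
            grid = WavelengthGrid(**grid_doc)

            if "expansion" in doc:
                expansion = VariableExpansion(terms=tuple(tuple(t) for t in doc["expansion"]))
            else:
                expansion = DEFAULT_EXPANSION

            n_pc = int(doc.get("n_pc", DEFAULT_N_PC))

            if "bands" in doc:
                bands_doc = doc["bands"]
                _take(bands_doc, {"centers", "gammas", "amplitudes"}, "bands")
                centers = bands_doc.get("centers", list(DEFAULT_BAND_CENTERS))
                default = default_band_model()
                gammas = bands_doc.get(
                    "gammas", [b.gamma_nm for b in default.bands][: len(centers)]
                )
                amplitudes = bands_doc.get(
                    "amplitudes", [b.amplitude for b in default.bands][: len(centers)]
                )
                if not (len(centers) == len(gammas) == len(amplitudes)):
                    raise ConfigError(
                        "bands: centers, gammas and amplitudes must have equal length"
                    )
                bands = BandModel(
                    bands=tuple(
                        LorentzianBand(center_nm=float(c), gamma_nm=float(g), amplitude=float(a))
                        for c, g, a in zip(centers, gammas, amplitudes)
                    )
                )
            else:
                bands = default_band_model()

            ann_doc = dict(doc.get("annealing", {}))
            _take(
                ann_doc,
                {
                    "max_iterations",
                    "seed",
                    "initial_temperature",
                    "visiting_param",
                    "acceptance_param",
                    "local_polish",
                    "n_restarts",
                    "optimize_centers",
                    "center_window_nm",
                    "gamma_bounds",
                    "amplitude_bounds",
                    "pin_first_amplitude",
                },
                "annealing",
            )
            for key in ("gamma_bounds", "amplitude_bounds"):
                if key in ann_doc:
                    ann_doc[key] = tuple(float(v) for v in ann_doc[key])
            annealing = OptimizationConfig(**ann_doc)

            fix_doc = dict(doc.get("fixtures", {}))
            _take(fix_doc, {"seed", "n_gaussians", "noise_sd", "patch_pixels"}, "fixtures")
            fixtures = FixtureConfig(grid=grid, **fix_doc)
        except ConfigError:
            raise
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid config value: {exc}") from exc
        return cls(
            grid=grid,
            expansion=expansion,
            n_pc=n_pc,
            bands=bands,
            annealing=annealing,
            fixtures=fixtures,
        )


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config file; a missing path gives the defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    return PipelineConfig.from_dict(doc or {})
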