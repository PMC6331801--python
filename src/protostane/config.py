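"""Run configuration: one serializable record of every tunable parameter.

Defaults reproduce the packaged study conditions (tolerances, retention-time
window, preparation constants, Student's t at α = 0.05).  Config files are
TOML; CLI flags override file values, and every run echoes its effective
configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .chem import HYDROGEN_ATOM, PROTON, AdductConvention
from .quant import PrepConstants

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Effective parameters of a pipeline run."""

    ms1_tol_ppm: float = 5.0
    fragment_tol_ppm: float = 15.0
    fragment_floor_da: float = 0.003
    adduct: str = "hydrogen-atom"
    rt_window_min: float = 0.5
    min_fragment_hits: int = 2
    max_loss_depth: int = 4
    sample_mass_g: float = 0.20
    extraction_volume_ml: float = 25.0
    is_mix_dilution: float = 2.0
    t_test: str = "student"  # or "welch"
    alpha: float = 0.05
    seed: int = 0

    @property
    def adduct_convention(self) -> AdductConvention:
        return {"hydrogen-atom": HYDROGEN_ATOM, "proton": PROTON}[self.adduct]

    @property
    def prep_constants(self) -> PrepConstants:
        return PrepConstants(self.sample_mass_g, self.extraction_volume_ml, self.is_mix_dilution)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            elif isinstance(v, bool):
                lines.append(f"{f.name} = {str(v).lower()}")
            else:
                lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def echo(self, out_dir) -> Path:
        """Write the effective configuration into a run's output directory."""
        out = Path(out_dir) / "effective_config.toml"
        out.write_text(self.to_toml())
        return out
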