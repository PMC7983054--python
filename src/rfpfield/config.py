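"""Pipeline configuration: one validated block of all free parameters."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .fieldsolver import VacuumChromophore
from .fixtures import MARCUS_FIT_INCLUDE
from .marcus import DEFAULT_ETA_GRID

__all__ = ["PipelineConfig", "load_config"]


class VacuumBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dmu0_x_D: float = 5.53
    dmu0_y_D: float = -3.17
    dalpha_xx_A3: float = -61.3
    dalpha_yy_A3: float = 6.9
    nu0_cm: float = 16260.0

    def to_chromophore(self) -> VacuumChromophore:
        return VacuumChromophore(
            dmu0_x=self.dmu0_x_D,
            dmu0_y=self.dmu0_y_D,
            dalpha_xx=self.dalpha_xx_A3,
            dalpha_yy=self.dalpha_yy_A3,
            nu0=self.nu0_cm,
        )


class MarcusBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    q_esu: float = 1.54e-10
    dG_vac_kcal_mol: float = -7.9
    temperature_K: float = 298.15


class PipelineConfig(BaseModel):
    """All tunables of the end-to-end analysis.

    ``refractive_index_2pa`` defaults to the aqueous-buffer 1.33; the
    protein-interior alternative 1.4 may be set explicitly but the two are
    never mixed silently.
    """

    model_config = ConfigDict(extra="forbid")

    refractive_index_emission: float = 1.33
    refractive_index_2pa: float = 1.33
    temperature_K: float = 298.15
    vacuum: VacuumBlock = Field(default_factory=VacuumBlock)
    marcus_constants: MarcusBlock = Field(default_factory=MarcusBlock)
    fit_include: tuple[str, ...] = MARCUS_FIT_INCLUDE
    eta_grid: tuple[float, ...] = DEFAULT_ETA_GRID
    beta_prior_deg: float = -10.0

    @field_validator("refractive_index_emission", "refractive_index_2pa")
    @classmethod
    def _n_gt_1(cls, v: float) -> float:
        if not v > 1:
            raise ValueError("refractive index must exceed 1")
        return v


def load_config(path: Optional[str] = None) -> PipelineConfig:
    """Load a YAML or JSON config file; defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig.model_validate(data or {})
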