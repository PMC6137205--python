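"""Run configuration and the anticipatory-threshold derivation.

The anticipatory/confirmatory boundary is a physical distance derived from
the apparatus: the diameter of a chopstick tip (4 mm) plus the radius of
the marble (8 mm), multiplied by three to allow for the spatial dispersion
the fixation detector tolerates (a fixation's reported point can sit
anywhere inside its dispersion window).  With the defaults this gives
(4 + 8) * 3 = 36 mm.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Tuple

from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError

TIP_DIAMETER_MM = 4.0
MARBLE_RADIUS_MM = 8.0
DISPERSION_FACTOR = 3.0


def anticipatory_threshold_mm(
    tip_diameter_mm: float = TIP_DIAMETER_MM,
    marble_radius_mm: float = MARBLE_RADIUS_MM,
    dispersion_factor: float = DISPERSION_FACTOR,
) -> float:
    """Derive the anticipatory lead threshold (mm) from apparatus geometry."""
    if tip_diameter_mm <= 0 or marble_radius_mm <= 0 or dispersion_factor <= 0:
        raise ConfigurationError("threshold components must be positive")
    return (tip_diameter_mm + marble_radius_mm) * dispersion_factor


class RunConfig(BaseModel):
    """Pipeline configuration.

    ``cylinder_physical_length_mm`` is required and has no default: the
    pixel-to-millimetre scale comes entirely from the known physical length
    of the reference cylinder seen in each frame.
    """

    dispersion_px: float = Field(default=100.0, gt=0)
    min_fix_duration_ms: float = Field(default=80.0, gt=0)
    lead_threshold_mm: float = Field(default=36.0, gt=0)
    cylinder_physical_length_mm: float = Field(gt=0)
    setup_roi: Tuple[float, float, float, float] = (0.0, 0.0, 1280.0, 960.0)
    dialect: Literal["csv", "smi-like"] = "csv"
    max_gap_samples: int = Field(default=2, ge=0)

    @field_validator("setup_roi")
    @classmethod
    def _roi_ordered(cls, v):
        x0, y0, x1, y1 = v
        if not (x1 > x0 and y1 > y0):
            raise ValueError("setup_roi must be (x0, y0, x1, y1) with x1>x0, y1>y0")
        return v

    @property
    def delimiter(self) -> str:
        return "\t" if self.dialect == "smi-like" else ","

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"config {path} is not valid JSON: {exc}") from exc
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))
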