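"""Model configuration.

All tunable numerical choices of the pipeline live here so that every
module reads them from one validated object.  The defaults are the
documented model conventions; see docs/methods.md for rationale.
"""

from __future__ import annotations

from typing import Literal, Sequence

from pydantic import BaseModel, Field


class InterpolationConfig(BaseModel):
    """Weighting scheme for the baseline-year production extrapolation.

    ``linear``  — weights rise linearly from 1 (oldest year) to 2 (newest).
    ``uniform`` — ordinary least squares.
    ``custom``  — explicit per-year weights (oldest first) via ``custom_weights``.
    """

    weights: Literal["linear", "uniform", "custom"] = "linear"
    custom_weights: Sequence[float] | None = None


class MassflowConfig(BaseModel):
    days_per_year: float = Field(default=365.0, gt=0)
    #: how regional in-home waste fractions collapse to one global fraction
    waste_collapse: Literal["population", "supply"] = "population"


class ModelConfig(BaseModel):
    interpolation: InterpolationConfig = InterpolationConfig()
    massflow: MassflowConfig = MassflowConfig()
    #: an animal group below this fraction of its baseline production counts
    #: as absent when classifying a scenario's diet mode
    diet_mode_threshold: float = Field(default=0.01, ge=0, le=1)
    #: nutrient gaps at or below this percentage of target are immaterial
    material_threshold_pct: float = Field(default=5.0, ge=0)


DEFAULT_CONFIG = ModelConfig()
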