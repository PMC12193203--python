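"""Pipeline configuration.

All tunable parameters of the discovery pipeline live in one validated
object. The defaults are the published operating point of the workflow the
package implements: SNR 2 peak detection, DBSCAN with eps 0.02 Da and a
minimum density of 100 peaks, a 10,000-peak group-size filter, and ±0.25 Da
identity-transfer tolerance. Those density/size filters presume full-tissue
acquisitions (tens of thousands of pixels); :meth:`PipelineConfig.desk_profile`
rescales them proportionally to the pixel count of a small synthetic dataset
while leaving every per-spectrum parameter untouched.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = ["PipelineConfig"]


class PipelineConfig(BaseModel):
    """Validated parameter set for the full discovery pipeline.

    Units: all m/z quantities in Da; intensities in arbitrary abundance
    units; counts are peak or pixel counts.
    """

    snr_threshold: float = Field(2.0, gt=0, description="peak retention SNR")
    smooth_sigma: float = Field(0.005, gt=0, description="Gauss smoothing sd (Da)")
    tophat_width: float = Field(1.5, gt=0, description="TopHat structuring element width (Da)")
    noise_window: float = Field(50.0, gt=0, description="sliding MAD noise window (Da)")
    min_peak_points: int = Field(7, ge=1, description="min samples above half-apex")
    dbscan_eps: float = Field(0.02, gt=0, description="DBSCAN neighborhood radius (Da)")
    dbscan_min_density: int = Field(100, ge=1, description="DBSCAN minPts (incl. self)")
    min_group_size: int = Field(10000, ge=1, description="min peaks per retained group")
    match_tolerance: float = Field(0.25, gt=0, description="identity-transfer tolerance (Da)")
    mass_range: Tuple[float, float] = (800.0, 4000.0)
    normalization: Literal["tic", "calibrant", "none"] = "calibrant"
    log_offset: float = Field(1.0, ge=0, description="offset inside ln() for zero entries")
    calibrant_window: float = Field(0.5, gt=0, description="calibrant search window (Da)")
    auc_min: float = Field(0.6, ge=0.5, le=1.0, description="min oriented AUC for a call")
    q_max: float = Field(0.05, gt=0, le=1.0, description="max BH q-value for a call")
    min_patients: int = Field(3, ge=1, description="min patients supporting a protein call")
    hotspot_quantile: Optional[float] = Field(
        None, gt=0, lt=1,
        description="optional per-group intensity cap quantile (hotspot removal)",
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check_mass_range(self) -> "PipelineConfig":
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError(f"mass_range must be increasing, got {self.mass_range}")
        if self.smooth_sigma > (hi - lo) / 2:
            raise ValueError("smooth_sigma larger than half the mass range")
        return self

    def desk_profile(self, n_pixels: int) -> "PipelineConfig":
        """Rescale the pooled-peak density/size filters to a small dataset.

        ``min_group_size`` becomes half the pixel count (a feature must be
        present in at least half the pixels) and ``dbscan_min_density``
        0.5% of the pixel count, floors applied — the same proportions the
        published thresholds represent on a full-tissue acquisition.
        """
        return self.model_copy(
            update={
                "min_group_size": max(2, n_pixels // 2),
                "dbscan_min_density": max(3, round(0.005 * n_pixels)),
            }
        )

    # -- serialization -------------------------------------------------

    def config_hash(self) -> str:
        """Stable short hash of the full parameter set (logged per run)."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump()
        data["mass_range"] = list(data["mass_range"])
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls(**data)
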