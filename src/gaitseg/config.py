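"""Run configuration: every algorithm constant, serializable and hashable.

Nothing is hard-coded in the pipeline; the defaults here are the published
operating point (14 Hz order-8 filter, 0.4-4.0 s stride band, lambda = 0.4,
mu = 0.1, Itakura slope 2, 20%-of-stride matching tolerance).
"""

from __future__ import annotations

import hashlib
import json
import tomllib

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ArgumentError


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    filter_cutoff_hz: float = 14.0
    filter_order: int = 8
    max_gap_s: float = 0.5
    acf_band_s: tuple[float, float] = (0.4, 4.0)
    acf_prominence_frac: float = 0.1
    acf_height_frac: float = 0.5
    lambda_thr: float = 0.4
    mu: float = 0.1
    itakura_slope: float = 2.0
    tol_frac: float = 0.2
    gyration_only: bool = False
    model_stride: str | None = None
    analysis_interval: tuple[float, float] | None = None
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        try:
            return cls(**data)
        except ValidationError as exc:
            raise ArgumentError(f"invalid config {path}: {exc}") from exc

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def provenance(self) -> dict:
        from . import __version__
        return {"package": "gaitseg", "version": __version__,
                "config_sha256": self.config_hash()}
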