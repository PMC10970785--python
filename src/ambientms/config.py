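"""Run configuration: one structured document capturing every parameter.

Every artifact the pipeline writes embeds the hash of the configuration it
was produced under, so any numeric result is traceable to its exact
parameters and seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


def _default_validation() -> dict:
    return {"p": 0.2, "repeats": 25,
            "usage_fractions": [round(0.1 * i, 1) for i in range(1, 11)]}


@dataclass
class RunConfig:
    """Serializable bundle of all pipeline parameters."""

    binning: dict = field(default_factory=lambda: {
        "mz_min": 100.0, "mz_max": 1000.0, "bin_width": 0.1})
    qc: dict = field(default_factory=lambda: {
        "min_scans": 3, "min_total_intensity": 1e3})
    normalization: str = "tic"
    model: dict = field(default_factory=lambda: {
        "n_pc": "fifth", "ridge": 1e-6, "cov_ridge": 1e-6})
    classification: dict = field(default_factory=lambda: {
        "threshold": 0.95, "outlier_quantile": 0.999})
    validation: dict = field(default_factory=_default_validation)
    seeds: dict = field(default_factory=lambda: {"default": 0})
    simulate: dict = field(default_factory=dict)
    io: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        base = cls()
        for key, value in (doc or {}).items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config section: {key!r}")
            current = getattr(base, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(base, key, value)
        return base

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        """Stable short hash of the canonical JSON form."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
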