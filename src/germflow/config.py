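"""Scan configuration: defaults, file round-trip, and overrides."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class ScanConfig:
    """Tunable parameters of the scan pipeline.

    Defaults follow the study design: 20 kb windows stepped by 10 kb, an
    8,000-bp effective-site floor, f_d windows needing >= 30 SNPs, top-5%
    candidate calling, 5 Mb jackknife blocks, 1 kb LD thinning, and a 0.9
    outgroup fixation threshold. ``seed`` has no default: randomized stages
    must be given one explicitly.
    """

    window_size: int = 20_000
    step: int = 10_000
    min_effective_sites: int = 8_000
    min_snps_fd: int = 30
    top_quantile: float = 0.05
    block_size: int = 5_000_000
    thin_gap: int = 1_000
    outgroup_fix_threshold: float = 0.9
    min_call_rate: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "window_size", "step", "min_effective_sites", "min_snps_fd",
            "block_size", "thin_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.top_quantile < 1:
            raise ValueError("top_quantile must be in (0, 1)")
        if not 0 < self.outgroup_fix_threshold <= 1:
            raise ValueError("outgroup_fix_threshold must be in (0, 1]")

    # -- file round-trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScanConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_overrides(self, overrides: dict) -> "ScanConfig":
        data = self.to_dict()
        for key, value in overrides.items():
            if key not in data:
                raise ValueError(f"unknown config key {key!r}")
            current = data[key]
            if current is not None and value is not None:
                value = type(current)(value)
            data[key] = value
        return ScanConfig.from_dict(data)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def parse_set_overrides(pairs: list[str]) -> dict:
    """Parse ``--set key=value`` strings into a typed override mapping."""
    out: dict = {}
    for pair in pairs:
        if "=" not in pair:
            raise ValueError(f"override {pair!r} is not key=value")
        key, value = pair.split("=", 1)
        out[key.strip()] = yaml.safe_load(value)
    return out
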