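"""Run configuration: every threshold and mode flag in one validated place.

The approval and QC thresholds are operational choices, not published
constants, so they must be visible and overridable: a YAML file may set
any of them, CLI flags override the file, and unknown keys are rejected
rather than ignored.

Example YAML::

    approval:
      min_depth: 20
      min_genotype_quality: 20
      min_strand_alt_depth: 1
    qc_thresholds:
      min_uniformity_pct: 90
      max_duplicate_pct: 10
    coverage_floor: 20
    star_mode: strict
    interval_rule: mean
    resolution: low
    alpha: 0.05
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .qc import QcThresholds
from .variants import ApprovalThresholds

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    approval: ApprovalThresholds = field(default_factory=ApprovalThresholds)
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    coverage_floor: int = 20
    star_mode: str = "strict"  # strict | wildcard
    interval_rule: str = "mean"  # mean | min
    on_target_of: str = "aligned"  # aligned | total
    resolution: str = "low"  # low | high
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.star_mode not in ("strict", "wildcard"):
            raise ValueError(f"star_mode must be strict|wildcard, got {self.star_mode!r}")
        if self.interval_rule not in ("mean", "min"):
            raise ValueError(f"interval_rule must be mean|min, got {self.interval_rule!r}")
        if self.on_target_of not in ("aligned", "total"):
            raise ValueError(f"on_target_of must be aligned|total, got {self.on_target_of!r}")
        if self.resolution not in ("low", "high"):
            raise ValueError(f"resolution must be low|high, got {self.resolution!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.coverage_floor < 0:
            raise ValueError("coverage_floor must be non-negative")


_SCALAR_KEYS = {
    "coverage_floor",
    "star_mode",
    "interval_rule",
    "on_target_of",
    "resolution",
    "alpha",
    "seed",
}


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus keyword
    overrides (overrides win). Unknown keys anywhere are an error."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - _SCALAR_KEYS - {"approval", "qc_thresholds"}
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    approval_cfg = data.pop("approval", {})
    if isinstance(approval_cfg, ApprovalThresholds):
        approval = approval_cfg
    else:
        known = {f.name for f in dataclasses.fields(ApprovalThresholds)}
        bad = set(approval_cfg) - known
        if bad:
            raise ValueError(f"unknown approval threshold(s): {sorted(bad)}")
        approval = ApprovalThresholds(**approval_cfg)

    qc_cfg = data.pop("qc_thresholds", {})
    qc = qc_cfg if isinstance(qc_cfg, QcThresholds) else QcThresholds.from_dict(qc_cfg)

    return RunConfig(approval=approval, qc_thresholds=qc, **data)
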