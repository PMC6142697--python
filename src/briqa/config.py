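"""Configuration for the quality-scoring pipeline.

All knobs that affect a quality score live here so that a report can be
reproduced from its configuration alone.  The defaults are the recommended
operating point: perceptual weights (0.1, 0.1, 0.7, 0.1), moments computed
over the foreground, 4-connected edge extraction, and volume-level cut-offs
of 0.40 (T1) and 0.45 (T2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["Weights", "Config"]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class Weights:
    """Perceptual weights for the four quality attributes.

    ``q1`` luminance contrast, ``q2`` texture, ``q3`` texture contrast,
    ``q4`` lightness.  Texture contrast dominates the total score because it
    is by far the strongest driver of perceived quality in complex scenes.
    The weights must be non-negative and sum to one.
    """

    w_q1: float = 0.1
    w_q2: float = 0.1
    w_q3: float = 0.7
    w_q4: float = 0.1

    def __post_init__(self) -> None:
        ws = (self.w_q1, self.w_q2, self.w_q3, self.w_q4)
        if any(w < 0 for w in ws):
            raise ValueError(f"weights must be non-negative, got {ws}")
        if abs(sum(ws) - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1, got {sum(ws)!r}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.w_q1, self.w_q2, self.w_q3, self.w_q4)


@dataclass(frozen=True)
class Config:
    """Pipeline configuration.

    Parameters
    ----------
    window:
        Explicit odd range-filter width.  ``None`` selects 3/5/7 from the
        slice dimensions; an explicit value always wins over the rule.
    weights:
        Attribute weights for the total score.
    moments_over:
        ``"foreground"`` (default) computes both feature-image first moments
        over foreground pixels only; ``"full"`` uses every pixel.
    edge_connectivity:
        4 (default) or 8; neighbourhood used to define the inner boundary
        ("edge pixels") of a bright region.
    edge_denominator:
        If True, the luminance-contrast and texture scores divide by the
        larger *edge-pixel* count instead of the larger bright-pixel count,
        so that identical binary pairs score exactly 1.  Off by default: the
        printed definition divides by bright-pixel counts.
    cutoff_t1, cutoff_t2:
        Volume-level pass/fail cut-offs on the mean total score, per
        sequence.  Unknown sequences fall back to the T1 cut-off.
    axis:
        Slicing axis for 3-D volumes (default: last axis).
    seed:
        Seed recorded with reports for provenance of any stochastic step.
    """

    window: Optional[int] = None
    weights: Weights = field(default_factory=Weights)
    moments_over: str = "foreground"
    edge_connectivity: int = 4
    edge_denominator: bool = False
    cutoff_t1: float = 0.40
    cutoff_t2: float = 0.45
    axis: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window is not None and (self.window < 3 or self.window % 2 == 0):
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if self.moments_over not in ("foreground", "full"):
            raise ValueError(f"moments_over must be 'foreground' or 'full', got {self.moments_over!r}")
        if self.edge_connectivity not in (4, 8):
            raise ValueError(f"edge_connectivity must be 4 or 8, got {self.edge_connectivity}")
        for name in ("cutoff_t1", "cutoff_t2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def cutoff_for(self, sequence_tag: str) -> float:
        """Default cut-off for a sequence tag (T2 gets its own, else T1)."""
        return self.cutoff_t2 if sequence_tag == "T2" else self.cutoff_t1

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load a configuration from a YAML or JSON mapping."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        if "weights" in data and not isinstance(data["weights"], Weights):
            w = data["weights"]
            data["weights"] = Weights(*w) if isinstance(w, (list, tuple)) else Weights(**w)
        return cls(**data)

    def with_(self, **kwargs) -> "Config":
        return replace(self, **kwargs)
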