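"""Rank-correlation validation against observer scores.

Objective slice scores are validated against mean opinion scores (MOS,
0-100) from human observers with Spearman's rank correlation

    rho = 1 - 6 * sum(d^2) / (n^3 - n),

where ``d`` is the per-observation difference between the two rank lists.
This is the no-ties form; tied observations receive average ranks and the
same formula is applied, the standard approximation for lightly tied data
such as integer MOS values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scores import VolumeReport

__all__ = ["ScorePairing", "spearman_rho", "summary_table"]


@dataclass(frozen=True)
class ScorePairing:
    """Paired objective (per-slice Q) and subjective (MOS) score lists."""

    objective: tuple[float, ...]
    subjective: tuple[float, ...]
    n: int = field(init=False)

    def __post_init__(self) -> None:
        obj = tuple(float(x) for x in self.objective)
        sub = tuple(float(x) for x in self.subjective)
        object.__setattr__(self, "objective", obj)
        object.__setattr__(self, "subjective", sub)
        object.__setattr__(self, "n", len(obj))
        if len(obj) != len(sub):
            raise ValueError(
                f"objective and subjective lengths differ: {len(obj)} vs {len(sub)}"
            )
        if self.n < 3:
            raise ValueError(f"need at least 3 paired observations, got {self.n}")


def spearman_rho(pairing: ScorePairing) -> float:
    """Spearman rank correlation of a score pairing.

    Raises on a constant list: with all ranks tied the printed formula has
    no meaningful value.
    """
    obj = np.asarray(pairing.objective)
    sub = np.asarray(pairing.subjective)
    if np.ptp(obj) == 0 or np.ptp(sub) == 0:
        raise ValueError("rank correlation is undefined for a constant score list")
    d = rankdata(obj) - rankdata(sub)
    n = pairing.n
    return float(1.0 - 6.0 * np.sum(d * d) / (n**3 - n))


def summary_table(
    volumes: Sequence[VolumeReport],
    pairings: Optional[Sequence[Optional[ScorePairing]]] = None,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One summary row per condition/volume.

    Columns: label, number of slices, mean objective score, and — where a
    pairing is supplied — mean subjective score and the objective-subjective
    rank correlation.
    """
    volumes = list(volumes)
    if not volumes:
        raise ValueError("summary_table needs at least one volume")
    if pairings is None:
        pairings = [None] * len(volumes)
    if len(pairings) != len(volumes):
        raise ValueError("pairings must match volumes in length")
    if labels is None:
        labels = [f"volume_{i}" for i in range(len(volumes))]

    rows = []
    for label, vol, pairing in zip(labels, volumes, pairings):
        row: dict = {
            "label": label,
            "n_slices": len(vol.per_slice),
            "mean_objective": vol.mean_Q,
            "mean_subjective": np.nan,
            "rho_objective_subjective": np.nan,
        }
        if pairing is not None:
            row["mean_subjective"] = float(np.mean(pairing.subjective))
            row["rho_objective_subjective"] = spearman_rho(pairing)
        rows.append(row)
    return pd.DataFrame(rows)
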