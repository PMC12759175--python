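"""Species-level habitat suitability into group-level per-reach layers.

Upstream ensemble distribution models supply, per species, one continuous
suitability prediction per algorithm plus an AUC score and evaluation points.
This module implements the consensus rules that turn those into the layers
weighting the connectivity indices: discard algorithms with AUC <= 0.8,
binarize each retained prediction at the threshold maximizing sensitivity +
specificity, call a cell present where strictly more than half of the retained
models agree, and average suitability across the species of a group
(migratory, sedentary, or combined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .river_graph import RiverNetwork

__all__ = [
    "SpeciesModelOutput",
    "SuitabilitySet",
    "RasterGrid",
    "max_sss_threshold",
    "consensus_presence",
    "consensus_model",
    "group_mean",
    "cells_to_reaches",
]

logger = logging.getLogger(__name__)

AUC_MIN = 0.8
EPOCHS = ("current", "2030", "2050", "2070", "2090")
CLIMATES = ("current", "moderate", "pessimistic")
GROUPS = ("combined", "migratory", "sedentary")


@dataclass
class SpeciesModelOutput:
    """Per-algorithm predictions and evaluation data for one species.

    ``predictions``: suitability in [0, 1] indexed by reach (or cell), one
    column per algorithm. ``auc``: algorithm -> AUC. ``eval_scores``: the
    algorithms' suitabilities at the evaluation points; ``eval_labels``: the
    matching presence (1) / background (0) labels.
    """

    species_id: str
    group: str
    predictions: pd.DataFrame
    auc: Mapping[str, float]
    eval_scores: Optional[pd.DataFrame] = None
    eval_labels: Optional[pd.Series] = None

    def retained_algorithms(self, auc_min: float = AUC_MIN) -> list[str]:
        """Algorithms passing the AUC filter (strictly greater than)."""
        return [a for a in self.predictions.columns if self.auc[a] > auc_min]


class SuitabilitySet:
    """Per-reach suitability layers keyed by (group, climate, epoch)."""

    def __init__(self, layers: Optional[dict[tuple[str, str, str], pd.Series]] = None):
        self._layers: dict[tuple[str, str, str], pd.Series] = {}
        if layers:
            for key, s in layers.items():
                self.add(*key, s)

    @staticmethod
    def _key(group: str, climate: str, epoch) -> tuple[str, str, str]:
        return (str(group), str(climate), str(epoch))

    def add(self, group: str, climate: str, epoch, values: pd.Series) -> None:
        v = values.astype(float)
        if ((v < 0) | (v > 1)).any():
            raise ValueError(
                f"suitability layer {(group, climate, epoch)} outside [0, 1]"
            )
        self._layers[self._key(group, climate, epoch)] = v

    def get(self, group: str, climate: str, epoch) -> pd.Series:
        key = self._key(group, climate, epoch)
        if key not in self._layers:
            raise KeyError(f"no suitability layer for {key}")
        return self._layers[key]

    def __contains__(self, key) -> bool:
        return self._key(*key) in self._layers

    def keys(self) -> list[tuple[str, str, str]]:
        return sorted(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (group, climate, epoch), s in sorted(self._layers.items()):
            df = s.rename("suitability").rename_axis("reach_id").reset_index()
            df.insert(1, "group", group)
            df.insert(2, "climate", climate)
            df.insert(3, "epoch", epoch)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "SuitabilitySet":
        out = cls()
        key_col = "group" if "group" in df.columns else "species_id"
        for (group, climate, epoch), sub in df.groupby(
            [key_col, "climate", "epoch"], sort=True
        ):
            s = pd.Series(
                sub["suitability"].to_numpy(float),
                index=sub["reach_id"].astype(str).to_numpy(),
            )
            out.add(str(group), str(climate), str(epoch), s)
        return out


def max_sss_threshold(suitabilities, labels) -> float:
    """Binarization threshold maximizing sensitivity + specificity.

    Candidates are the observed suitability values; the prediction rule is
    "present if suitability >= threshold". Ties return the smallest
    maximizing threshold.
    """
    scores = np.asarray(suitabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("suitabilities and labels must be equal-length 1-D")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one presence and one absence")
    best_t, best_sss = None, -np.inf
    for t in np.unique(scores):  # ascending, so ties keep the smallest t
        pred = scores >= t
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        if sens + spec > best_sss + 1e-12:
            best_t, best_sss = float(t), sens + spec
    return best_t


def consensus_presence(binary_maps: Iterable[pd.Series]) -> pd.Series:
    """Majority-rule presence: present where > m/2 of m model maps agree."""
    maps = list(binary_maps)
    if not maps:
        raise ValueError("need at least one model map")
    idx = maps[0].index
    for m in maps[1:]:
        if not m.index.equals(idx):
            raise ValueError("model maps have mismatched supports")
    votes = sum(m.astype(int) for m in maps)
    return (votes > len(maps) / 2).rename("present")


def consensus_model(
    output: SpeciesModelOutput, auc_min: float = AUC_MIN
) -> Optional[tuple[pd.Series, pd.Series]]:
    """AUC-filtered (continuous, binary) consensus prediction for one species.

    Continuous consensus is the mean suitability of the retained algorithms;
    binary consensus binarizes each retained algorithm at its max-sens+spec
    threshold and applies the majority rule. Returns ``None`` (with a logged
    warning) when no algorithm survives the AUC filter.
    """
    algos = output.retained_algorithms(auc_min)
    if not algos:
        logger.warning(
            "species %s: no algorithm with AUC > %.2f, excluded",
            output.species_id,
            auc_min,
        )
        return None
    cont = output.predictions[algos].mean(axis=1).rename("suitability")
    binary_maps = []
    for a in algos:
        if output.eval_scores is None or output.eval_labels is None:
            raise ValueError("binary consensus needs eval_scores and eval_labels")
        t = max_sss_threshold(output.eval_scores[a], output.eval_labels)
        binary_maps.append(output.predictions[a] >= t)
    return cont, consensus_presence(binary_maps)


def group_mean(
    layers: Mapping[str, pd.Series], group: Iterable[str]
) -> pd.Series:
    """Arithmetic mean suitability over the species of a group, per reach."""
    ids = list(group)
    if not ids:
        raise ValueError("empty species group")
    idx = layers[ids[0]].index
    for s in ids[1:]:
        if not layers[s].index.equals(idx):
            raise ValueError("species layers cover different reach sets")
    stacked = pd.concat([layers[s] for s in ids], axis=1)
    return stacked.mean(axis=1).rename("suitability")


@dataclass
class RasterGrid:
    """Regular raster of suitability values, row 0 at ``y0`` (south-west origin).

    ``values[iy, ix]`` covers the square cell with lower-left corner
    ``(x0 + ix*cell_size, y0 + iy*cell_size)``.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1)))

    def cell_box(self, ix: int, iy: int):
        from shapely.geometry import box

        cs = self.cell_size
        return box(
            self.x0 + ix * cs, self.y0 + iy * cs,
            self.x0 + (ix + 1) * cs, self.y0 + (iy + 1) * cs,
        )


def cells_to_reaches(grid: RasterGrid, network: RiverNetwork) -> pd.Series:
    """Project a raster layer onto reaches: length-weighted mean of the cells
    a reach's polyline crosses.

    Every reach must carry a geometry and intersect at least one cell.
    """
    ny, nx = grid.values.shape
    cs = grid.cell_size
    out = {}
    for r in network.reaches:
        if r.geometry is None:
            raise ValueError(f"reach {r.reach_id!r} has no geometry")
        line = r.geometry
        minx, miny, maxx, maxy = line.bounds
        ix0 = max(int(np.floor((minx - grid.x0) / cs)), 0)
        ix1 = min(int(np.floor((maxx - grid.x0) / cs)), nx - 1)
        iy0 = max(int(np.floor((miny - grid.y0) / cs)), 0)
        iy1 = min(int(np.floor((maxy - grid.y0) / cs)), ny - 1)
        wsum = vsum = 0.0
        for iy in range(iy0, iy1 + 1):
            for ix in range(ix0, ix1 + 1):
                seg = line.intersection(grid.cell_box(ix, iy))
                if not seg.is_empty and seg.length > 0:
                    wsum += seg.length
                    vsum += seg.length * float(grid.values[iy, ix])
        if wsum == 0.0:
            raise ValueError(f"reach {r.reach_id!r} intersects no raster cell")
        out[r.reach_id] = vsum / wsum
    return pd.Series(out, name="suitability").reindex(network.reach_ids)
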