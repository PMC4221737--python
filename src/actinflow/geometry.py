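"""Nucleus-centered velocity decomposition and spatio-temporal pooling.

Two readouts are produced from the PIV fields:

* around the nucleus, each vector's component along the line from its node
  toward the nuclear center — **positive = inward** (toward the nucleus),
  negative = outward — pooled over space and time and split by sign;
* over the whole cell, the pooled Euclidean speeds of all valid vectors.

Both per-class sample sets store magnitudes (nonnegative, so each is
gamma-fittable on x >= 0); the signed components are retained in the long
table.  Exactly tangential vectors (signed component 0) belong to neither
class and are excluded, as are nodes coinciding with the center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import CellMask, ConfigurationError, NucleusSpec, VelocityField

logger = logging.getLogger("actinflow.geometry")

__all__ = [
    "VelocitySampleSet",
    "radial_component",
    "sample_table",
    "classify_and_pool",
    "pool_speeds",
]


@dataclass
class VelocitySampleSet:
    """Pooled scalar velocity samples (speeds or one directional class)."""

    values: np.ndarray
    direction_class: str  # inward | outward | all
    region: str  # around_nucleus | whole_cell
    n_frames_pooled: int
    n_nodes_pooled: int
    units: str = "px/frame"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and self.values.min() < 0:
            raise ConfigurationError("sample values must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.size

    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else np.nan


def radial_component(
    vector: tuple[float, float],
    node: tuple[float, float],
    center: tuple[float, float],
) -> float:
    """Signed component of ``vector`` toward ``center``: v . r_hat, with
    r_hat the unit vector from the node toward the center.  Positive means
    inward (toward the nucleus)."""
    rx, ry = center[0] - node[0], center[1] - node[1]
    norm = float(np.hypot(rx, ry))
    if norm == 0:
        raise ConfigurationError("node coincides with the center: direction undefined")
    return float((vector[0] * rx + vector[1] * ry) / norm)


def _in_mask(mask: CellMask, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    H, W = mask.shape
    ix = np.clip(np.round(x).astype(int), 0, W - 1)
    iy = np.clip(np.round(y).astype(int), 0, H - 1)
    return mask.raster[iy, ix]


def sample_table(
    fields: Sequence[VelocityField],
    mask: CellMask,
    nucleus: NucleusSpec | None = None,
    include_interpolated: bool = False,
) -> pd.DataFrame:
    """Long table of all usable vectors: one row per valid in-mask node per
    frame pair, with speed and (if a nucleus is given) the signed radial
    component and inward/outward class."""
    rows = []
    for f in fields:
        X, Y = f.grid
        use = f.valid & np.isfinite(f.u) & np.isfinite(f.v)
        if not include_interpolated:
            use &= ~f.interpolated
        use &= _in_mask(mask, X, Y)
        x, y = X[use], Y[use]
        u, v = f.u[use], f.v[use]
        df = pd.DataFrame(
            {
                "frame_pair": f.frame_pair[0],
                "x": x, "y": y, "u": u, "v": v,
                "speed": np.hypot(u, v),
            }
        )
        if nucleus is not None:
            cx, cy = nucleus.center
            rx, ry = cx - x, cy - y
            rn = np.hypot(rx, ry)
            at_center = rn == 0
            with np.errstate(invalid="ignore", divide="ignore"):
                signed = np.where(at_center, np.nan, (u * rx + v * ry) / np.where(rn == 0, 1, rn))
            df["signed_radial"] = signed
            df["in_nucleus_region"] = nucleus.contains(x, y) & ~at_center
            if at_center.any():
                logger.info("excluded %d node(s) at the nucleus center", int(at_center.sum()))
        rows.append(df)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)


def classify_and_pool(
    fields: Sequence[VelocityField],
    nucleus: NucleusSpec,
    mask: CellMask,
    include_interpolated: bool = False,
) -> tuple[VelocitySampleSet, VelocitySampleSet]:
    """Inward/outward magnitude sample sets around the nucleus, pooled over
    all frame pairs.  Positive signed components populate the inward set,
    negative the outward set (as magnitudes); exact zeros are excluded."""
    table = sample_table(fields, mask, nucleus, include_interpolated)
    if table.empty or not table["in_nucleus_region"].any():
        raise ConfigurationError("no valid vectors in the around-nucleus region")
    sub = table[table["in_nucleus_region"] & np.isfinite(table["signed_radial"])]
    signed = sub["signed_radial"].to_numpy()
    n_zero = int((signed == 0).sum())
    if n_zero:
        logger.info("excluded %d exactly-tangential vector(s)", n_zero)
    n_pairs = int(sub["frame_pair"].nunique())
    n_nodes = int(len(sub.drop_duplicates(["x", "y"])))
    units = fields[0].units
    inward = VelocitySampleSet(
        values=signed[signed > 0],
        direction_class="inward", region="around_nucleus",
        n_frames_pooled=n_pairs, n_nodes_pooled=n_nodes, units=units,
    )
    outward = VelocitySampleSet(
        values=-signed[signed < 0],
        direction_class="outward", region="around_nucleus",
        n_frames_pooled=n_pairs, n_nodes_pooled=n_nodes, units=units,
    )
    logger.info(
        "around-nucleus pooling: %d inward, %d outward samples "
        "(%d frame pairs, %d nodes)",
        inward.n, outward.n, n_pairs, n_nodes,
    )
    return inward, outward


def pool_speeds(
    fields: Sequence[VelocityField],
    mask: CellMask,
    region: str = "whole_cell",
    include_interpolated: bool = False,
) -> VelocitySampleSet:
    """Euclidean speeds of all valid in-mask vectors pooled over space and
    time (the whole-cell velocity distribution)."""
    table = sample_table(fields, mask, None, include_interpolated)
    if table.empty:
        raise ConfigurationError("no valid vectors to pool")
    return VelocitySampleSet(
        values=table["speed"].to_numpy(),
        direction_class="all", region=region,
        n_frames_pooled=int(table["frame_pair"].nunique()),
        n_nodes_pooled=int(len(table.drop_duplicates(["x", "y"]))),
        units=fields[0].units,
    )
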