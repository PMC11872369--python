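"""Projection onto a target region, ensemble averaging, district aggregation.

Fitted models are projected cellwise onto a target environmental grid and
averaged into a single habitat-suitability (HS) surface; HS is then reduced
to one mean per district polygon (cell-centre membership, no area
weighting) and classified into unsuitable / marginal / optimal using the
0.3 and 0.6 thresholds. Boundary values go to the upper class. Predictions
are produced natively in [0, 1]; no 0-1000 rescaling step is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import shapely

from .geo import EnvGridStack, RegionPolygons
from .sdm import FittedSDM

log = logging.getLogger(__name__)

HS_CLASSES = ("unsuitable", "marginal", "optimal")
CLASS_ORDER = {c: i for i, c in enumerate(HS_CLASSES)}


@dataclass
class SuitabilityMap:
    """Ensemble-mean habitat suitability on a target grid."""

    hs: np.ndarray
    n_models: int
    species: str = ""


@dataclass
class DistrictHS:
    """Mean HS over one district's cells and its suitability class."""

    district: str
    mean_hs: float
    n_cells: int
    hs_class: str | None


def ensemble_project(models: list[FittedSDM], target_env: EnvGridStack,
                     species: str = "") -> SuitabilityMap:
    """Cellwise arithmetic mean of each model's prediction on the target
    grid; cells lacking data in any required layer propagate as NaN."""
    if not models:
        raise ValueError("no models to project")
    acc = None
    for m in models:
        pred = m.predict_grid(target_env)
        acc = pred if acc is None else acc + pred
    return SuitabilityMap(hs=acc / len(models), n_models=len(models),
                          species=species)


def zonal_mean(smap: SuitabilityMap, districts: RegionPolygons,
               env: EnvGridStack,
               t_low: float = 0.3, t_high: float = 0.6) -> list[DistrictHS]:
    """Per-district mean HS over cells whose centres fall inside the polygon.

    Districts with no overlapping data cells are flagged with an undefined
    mean (NaN) and no class.
    """
    gx, gy = env.center_grids()
    pts = shapely.points(gx.ravel(), gy.ravel())
    hs = smap.hs.ravel()
    out = []
    for name, poly in districts.polygons.items():
        inside = shapely.covers(poly, pts)
        vals = hs[inside]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            log.warning("district %r overlaps no data cells", name)
            out.append(DistrictHS(name, float("nan"), 0, None))
            continue
        mean = float(vals.mean())
        out.append(DistrictHS(name, mean, int(vals.size),
                              classify_hs(mean, t_low, t_high)))
    return out


def classify_hs(hs: float, t_low: float = 0.3, t_high: float = 0.6) -> str:
    """Map an HS value to unsuitable (< t_low), marginal ([t_low, t_high))
    or optimal (>= t_high); boundary values go to the upper class."""
    if not 0.0 <= hs <= 1.0:
        raise ValueError(f"HS must be in [0, 1], got {hs}")
    if hs < t_low:
        return "unsuitable"
    if hs < t_high:
        return "marginal"
    return "optimal"
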