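"""Occurrence cleaning, spatial thinning and environmental-variable selection.

The pre-modelling pipeline: drop records with impossible or duplicated
coordinates, restrict to the species' native range, rarefy points so no two
retained occurrences are closer than the raster resolution (1 km by
default), and reduce the environmental layers to a subset with all pairwise
|Pearson r| below a cutoff (0.70 by default).

Thinning follows the spThin heuristic: repeatedly remove the record with the
most neighbours within the thinning distance (ties broken uniformly at
random), run several replicates and keep the one retaining the most records.
It is greedy, not optimal, but in practice lands within one record of the
brute-force optimum on small instances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geo import EnvGridStack, RegionPolygons, pairwise_distance_km

log = logging.getLogger(__name__)


@dataclass
class ThinningResult:
    """Outcome of minimum-distance thinning (best of ``reps`` replicates)."""

    retained: pd.DataFrame
    n_input: int
    n_retained: int
    replicate_id: int
    dist_km: float


@dataclass
class VariableSelection:
    """Correlation-filter outcome: kept layers plus, for each dropped layer,
    the partner whose correlation triggered the drop."""

    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (name, partner, |r|)
    cutoff: float
    correlations: pd.DataFrame = field(repr=False, default=None)


def clean_coordinates(occ: pd.DataFrame,
                      land_mask: np.ndarray | None = None,
                      env: EnvGridStack | None = None,
                      geographic: bool = True) -> tuple[pd.DataFrame, dict]:
    """Drop invalid occurrence rows; returns (cleaned table, drop report).

    Rules, applied in order: non-finite coordinates; out-of-bounds lon/lat
    (only meaningful for geographic coordinates); the exact (0, 0) artefact;
    exact duplicates within species; and, when a land mask plus its grid are
    given, points whose cell is flagged non-terrestrial.
    """
    df = occ.copy()
    report = {}

    finite = np.isfinite(df["lon"]) & np.isfinite(df["lat"])
    report["non_finite"] = int((~finite).sum())
    df = df[finite]

    if geographic:
        inb = (df["lon"].abs() <= 180) & (df["lat"].abs() <= 90)
    else:
        inb = pd.Series(True, index=df.index)
    report["out_of_bounds"] = int((~inb).sum())
    df = df[inb]

    zero = (df["lon"] == 0) & (df["lat"] == 0)
    report["zero_zero"] = int(zero.sum())
    df = df[~zero]

    dup = df.duplicated(subset=["species", "lon", "lat"])
    report["duplicate"] = int(dup.sum())
    df = df[~dup]

    if land_mask is not None:
        if env is None:
            raise ValueError("land_mask requires the grid (env) it refers to")
        row, col = env.cell_of(df["lon"].to_numpy(), df["lat"].to_numpy())
        inside = env.contains(row, col)
        terrestrial = np.zeros(len(df), bool)
        terrestrial[inside] = np.asarray(land_mask, bool)[row[inside], col[inside]]
        report["non_terrestrial"] = int((~terrestrial).sum())
        df = df[terrestrial]

    report["retained"] = len(df)
    if sum(v for k, v in report.items() if k != "retained"):
        log.info("clean_coordinates dropped rows: %s", report)
    return df.reset_index(drop=True), report


def filter_native_range(occ: pd.DataFrame, polygons: RegionPolygons) -> pd.DataFrame:
    """Retain rows whose point lies inside the union of the given polygons
    (boundary points count as inside)."""
    union = polygons.union()
    pts = shapely.points(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    keep = shapely.covers(union, pts)
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_native_range dropped %d of %d rows", dropped, len(occ))
    return occ[keep].reset_index(drop=True)


def _thin_once(dist: np.ndarray, dist_km: float,
               rng: np.random.Generator) -> np.ndarray:
    """One greedy thinning pass; returns indices retained."""
    n = dist.shape[0]
    close = (dist < dist_km) & ~np.eye(n, dtype=bool)
    alive = np.ones(n, bool)
    counts = close.sum(axis=1).astype(float)
    while True:
        active = np.flatnonzero(alive)
        if counts[active].max(initial=0) == 0:
            break
        worst = counts[active].max()
        ties = active[counts[active] == worst]
        victim = rng.choice(ties)
        alive[victim] = False
        counts[close[victim]] -= 1
        counts[victim] = 0
    return np.flatnonzero(alive)


def thin_min_distance(occ: pd.DataFrame, dist_km: float, reps: int = 10,
                      seed: int = 0, geographic: bool = True) -> ThinningResult:
    """Rarefy occurrences so every retained pair is >= ``dist_km`` apart.

    Runs ``reps`` replicates of the greedy max-neighbour removal heuristic
    with random tie-breaking and returns the replicate retaining the most
    records (first replicate wins ties).
    """
    if dist_km <= 0:
        raise ValueError("dist_km must be > 0")
    n = len(occ)
    if n <= 1:
        return ThinningResult(occ.reset_index(drop=True), n, n, 0, dist_km)
    dist = pairwise_distance_km(occ["lon"].to_numpy(), occ["lat"].to_numpy(),
                                geographic)
    rng = np.random.default_rng(seed)
    best_idx, best_rep = None, -1
    for rep in range(reps):
        idx = _thin_once(dist, dist_km, rng)
        if best_idx is None or idx.size > best_idx.size:
            best_idx, best_rep = idx, rep
    retained = occ.iloc[np.sort(best_idx)].reset_index(drop=True)
    return ThinningResult(retained, n, len(retained), best_rep, dist_km)


def filter_correlated(env: EnvGridStack,
                      region_mask: np.ndarray | None = None,
                      cutoff: float = 0.70,
                      n_sample_cells: int = 10_000,
                      seed: int = 0) -> VariableSelection:
    """Greedy correlation-based variable elimination (caret-style).

    Pearson correlations are computed on up to ``n_sample_cells`` random
    cells inside ``region_mask`` (excluding nodata). While any pair has
    |r| >= cutoff, the member of the worst pair with the larger mean absolute
    correlation to all remaining variables is dropped.
    """
    if env.n_layers < 2:
        raise ValueError("need at least 2 layers")
    mask = env.valid_mask()
    if region_mask is not None:
        mask = mask & np.asarray(region_mask, bool)
    cells = np.flatnonzero(mask.ravel())
    if cells.size == 0:
        raise ValueError("no valid cells to sample")
    rng = np.random.default_rng(seed)
    if cells.size > n_sample_cells:
        cells = rng.choice(cells, n_sample_cells, replace=False)
    arr = env.as_array().reshape(env.n_layers, -1)[:, cells]
    names = env.layer_names
    corr = pd.DataFrame(np.corrcoef(arr), index=names, columns=names)

    kept = list(names)
    dropped: list[tuple[str, str, float]] = []
    while True:
        sub = corr.loc[kept, kept].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] < cutoff:
            break
        # mean |r| of each candidate with the other remaining variables
        mean_i = sub[i].sum() / (len(kept) - 1)
        mean_j = sub[j].sum() / (len(kept) - 1)
        loser, partner = (i, j) if mean_i >= mean_j else (j, i)
        dropped.append((kept[loser], kept[partner], float(sub[i, j])))
        del kept[loser]
        if len(kept) == 1:
            break
    log.info("filter_correlated kept %d/%d layers (cutoff %.2f)",
             len(kept), len(names), cutoff)
    return VariableSelection(kept, dropped, cutoff, corr)
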