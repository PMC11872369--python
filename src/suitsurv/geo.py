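"""Spatial containers and file IO.

Everything downstream operates on :class:`EnvGridStack` (an aligned multi-layer
raster with an affine georeference) plus plain tables. Grids are row-major with
the origin at the top-left corner; a point belongs to the cell whose half-open
extent ``[x0, x0 + w) x (y0 - h, y0]`` contains it.

Two coordinate conventions are supported and made explicit per dataset:
a planar CRS in kilometres (the synthetic pipeline) and geographic lon/lat
degrees, for which great-circle (haversine) distances are used wherever a
metric distance is needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from shapely import geometry as sgeom
from shapely.validation import make_valid

EARTH_RADIUS_KM = 6371.0088

OCCURRENCE_COLUMNS = ("species", "lon", "lat", "source")
INVENTORY_COLUMNS = ("individual_id", "species", "garden", "status",
                     "death_cause", "year")

# GeoTIFF / GDAL tag codes used by the stack writer
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GeoIOError(ValueError):
    """Malformed spatial/tabular input."""


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference: top-left corner origin and positive cell sizes."""

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self):
        if self.dx <= 0 or self.dy <= 0:
            raise GeoIOError("cell sizes must be positive")

    def cell_of(self, x, y):
        """Row/col of the cell containing (x, y).

        Left/top edges belong to the cell, right/bottom edges to the next one,
        implementing the half-open extent [x0, x0+w) x (y0-h, y0].
        """
        col = np.floor((np.asarray(x, float) - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - np.asarray(y, float)) / self.dy).astype(int)
        return row, col

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.dx
        y = self.y0 - (row + 0.5) * self.dy
        return x, y


@dataclass
class EnvGridStack:
    """Aligned multi-layer environmental raster.

    Parameters
    ----------
    layers
        Mapping of layer name to 2-D float array; all arrays share one shape.
    transform
        Affine georeference of the shared grid.
    crs
        Coordinate-reference tag; ``"planar_km"`` for the synthetic pipeline
        or an ``"EPSG:4326"``-style geographic tag.
    nodata
        Sentinel marking missing cells (NaN also always counts as missing).
    """

    layers: dict[str, np.ndarray]
    transform: GridTransform
    crs: str = "planar_km"
    nodata: float = float("nan")

    def __post_init__(self):
        if not self.layers:
            raise GeoIOError("stack needs at least one layer")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise GeoIOError(f"layers have mismatched shapes: {sorted(shapes)}")
        if len(set(self.layers)) != len(self.layers):
            raise GeoIOError("layer names must be unique")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}

    # -- basic geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def is_geographic(self) -> bool:
        return self.crs.lower() not in ("planar_km", "planar")

    def as_array(self) -> np.ndarray:
        """(n_layers, rows, cols) view of the stack."""
        return np.stack([self.layers[k] for k in self.layers])

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer has data."""
        arr = self.as_array()
        ok = np.isfinite(arr)
        if np.isfinite(self.nodata):
            ok &= arr != self.nodata
        return ok.all(axis=0)

    def cell_centers(self):
        """x (cols) and y (rows) coordinate vectors of cell centres."""
        rows, cols = self.shape
        x = self.transform.x0 + (np.arange(cols) + 0.5) * self.transform.dx
        y = self.transform.y0 - (np.arange(rows) + 0.5) * self.transform.dy
        return x, y

    def center_grids(self):
        x, y = self.cell_centers()
        return np.meshgrid(x, y)

    def cell_of(self, x, y):
        return self.transform.cell_of(x, y)

    def contains(self, row, col) -> np.ndarray:
        r, c = self.shape
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < r) & (col >= 0) & (col < c)

    def sample(self, x, y, layer_names=None) -> np.ndarray:
        """Layer values at points, (n_points, n_layers); NaN outside grid."""
        names = layer_names if layer_names is not None else self.layer_names
        row, col = self.cell_of(np.atleast_1d(x), np.atleast_1d(y))
        inside = self.contains(row, col)
        out = np.full((row.size, len(names)), np.nan)
        for j, name in enumerate(names):
            out[inside, j] = self.layers[name][row[inside], col[inside]]
        if np.isfinite(self.nodata):
            out[out == self.nodata] = np.nan
        return out

    def subset(self, layer_names) -> "EnvGridStack":
        missing = [n for n in layer_names if n not in self.layers]
        if missing:
            raise GeoIOError(f"unknown layers: {missing}")
        return EnvGridStack({n: self.layers[n] for n in layer_names},
                            self.transform, self.crs, self.nodata)


@dataclass
class RegionPolygons:
    """Named polygons (districts or native ranges) in one CRS."""

    polygons: dict[str, sgeom.base.BaseGeometry]
    crs: str = "planar_km"

    def __post_init__(self):
        if not self.polygons:
            raise GeoIOError("empty polygon set")
        self.polygons = {
            name: geom if geom.is_valid else make_valid(geom)
            for name, geom in self.polygons.items()
        }

    def __len__(self):
        return len(self.polygons)

    def union(self) -> sgeom.base.BaseGeometry:
        import shapely
        return shapely.union_all(list(self.polygons.values()))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def pairwise_distance_km(x, y, geographic: bool) -> np.ndarray:
    """Symmetric pairwise distance matrix in km (planar coords already in km)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if geographic:
        return haversine_km(x[:, None], y[:, None], x[None, :], y[None, :])
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return np.hypot(dx, dy)


def cross_distance_km(x1, y1, x2, y2, geographic: bool) -> np.ndarray:
    x1, y1, x2, y2 = (np.asarray(a, float) for a in (x1, y1, x2, y2))
    if geographic:
        return haversine_km(x1[:, None], y1[:, None], x2[None, :], y2[None, :])
    return np.hypot(x1[:, None] - x2[None, :], y1[:, None] - y2[None, :])


# ---------------------------------------------------------------------------
# raster IO (multi-band GeoTIFF via tifffile)
# ---------------------------------------------------------------------------

def write_env_stack(stack: EnvGridStack, path) -> None:
    """Write a stack as a multi-band GeoTIFF.

    Band order follows layer order; layer names, crs and the transform are
    stored in a JSON image description alongside standard GeoTIFF
    pixel-scale/tiepoint tags and a GDAL nodata tag, so the files open in
    GIS tools as well as round-tripping exactly through
    :func:`read_env_stack`.
    """
    tr = stack.transform
    meta = {
        "layers": stack.layer_names,
        "crs": stack.crs,
        "nodata": None if math.isnan(stack.nodata) else stack.nodata,
        "transform": [tr.x0, tr.y0, tr.dx, tr.dy],
    }
    nodata_str = "nan" if math.isnan(stack.nodata) else repr(stack.nodata)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (tr.dx, tr.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, tr.x0, tr.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    arr = stack.as_array()
    with tifffile.TiffWriter(path) as tw:
        for i in range(arr.shape[0]):
            tw.write(
                arr[i],
                description=json.dumps(meta) if i == 0 else None,
                extratags=extratags if i == 0 else [],
                contiguous=False,
            )


def read_env_stack(path) -> EnvGridStack:
    """Read a (multi-band) GeoTIFF written by :func:`write_env_stack`.

    Foreign single/multi-band TIFFs lacking the JSON description are accepted
    with layers named ``band_1..n`` and georeference taken from GeoTIFF tags
    when present.
    """
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise GeoIOError(f"bands have mismatched shapes: {sorted(shapes)}")
        arrays = [p.asarray().astype(float) for p in pages]
        first = pages[0]
        desc = first.tags.get("ImageDescription")
        meta = None
        if desc is not None:
            try:
                parsed = json.loads(desc.value)
                if isinstance(parsed, dict) and "layers" in parsed:
                    meta = parsed
            except (json.JSONDecodeError, TypeError):
                meta = None
        if meta is not None:
            names = list(meta["layers"])
            if len(names) != len(arrays):
                raise GeoIOError("layer-name count does not match band count")
            x0, y0, dx, dy = meta["transform"]
            nodata = meta["nodata"]
            nodata = float("nan") if nodata is None else float(nodata)
            crs = meta["crs"]
        else:
            names = [f"band_{i + 1}" for i in range(len(arrays))]
            scale = first.tags.get(_TAG_PIXEL_SCALE)
            tie = first.tags.get(_TAG_TIEPOINT)
            if scale is not None and tie is not None:
                dx, dy = scale.value[0], scale.value[1]
                x0, y0 = tie.value[3], tie.value[4]
            else:
                x0, y0, dx, dy = 0.0, float(arrays[0].shape[0]), 1.0, 1.0
            nd = first.tags.get(_TAG_GDAL_NODATA)
            nodata = float(nd.value) if nd is not None and nd.value != "nan" \
                else float("nan")
            crs = "unknown"
    return EnvGridStack(dict(zip(names, arrays)),
                        GridTransform(x0, y0, dx, dy), crs, nodata)


@dataclass
class AlignmentReport:
    """Outcome of a grid-alignment check between two stacks."""

    ok: bool
    messages: list[str] = field(default_factory=list)

    def __bool__(self):
        return self.ok


def check_alignment(a: EnvGridStack, b: EnvGridStack,
                    origin_tol: float = 1e-9) -> AlignmentReport:
    """Pass iff shapes, transforms and crs agree (origins to ``origin_tol``)."""
    msgs = []
    if a.shape != b.shape:
        msgs.append(f"shape mismatch: {a.shape} vs {b.shape}")
    ta, tb = a.transform, b.transform
    if abs(ta.dx - tb.dx) > 0 or abs(ta.dy - tb.dy) > 0:
        msgs.append(f"cell size mismatch: ({ta.dx},{ta.dy}) vs ({tb.dx},{tb.dy})")
    off = (ta.x0 - tb.x0, ta.y0 - tb.y0)
    if abs(off[0]) > origin_tol or abs(off[1]) > origin_tol:
        msgs.append(f"origin offset: dx0={off[0]!r}, dy0={off[1]!r}")
    if a.crs != b.crs:
        msgs.append(f"crs mismatch: {a.crs} vs {b.crs}")
    return AlignmentReport(ok=not msgs, messages=msgs)


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GeoIOError(f"{what} is missing required columns: {missing}")


def read_occurrences(path) -> pd.DataFrame:
    """Occurrence table (species, lon, lat, source); row order preserved.

    Coordinates must parse as numbers and species must be nonempty; sanity of
    the coordinate *values* (bounds, duplicates, (0,0)) is deferred to
    ``occurrence_prep.clean_coordinates``.
    """
    df = pd.read_csv(path)
    _require_columns(df, OCCURRENCE_COLUMNS, "occurrence table")
    df = df.loc[:, list(OCCURRENCE_COLUMNS)].copy()
    bad = (~np.isfinite(pd.to_numeric(df["lon"], errors="coerce"))
           | ~np.isfinite(pd.to_numeric(df["lat"], errors="coerce"))
           | df["species"].isna() | (df["species"].astype(str).str.len() == 0))
    n_bad = int(bad.sum())
    if n_bad:
        df = df.loc[~bad]
    df.attrs["n_dropped_unparseable"] = n_bad
    df["lon"] = df["lon"].astype(float)
    df["lat"] = df["lat"].astype(float)
    return df.reset_index(drop=True)


def write_occurrences(df: pd.DataFrame, path) -> None:
    _require_columns(df, OCCURRENCE_COLUMNS, "occurrence table")
    df.loc[:, list(OCCURRENCE_COLUMNS)].to_csv(path, index=False)


def read_inventory(path) -> pd.DataFrame:
    """Garden inventory table; dead rows must carry a cause, ids unique."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _require_columns(df, INVENTORY_COLUMNS, "inventory table")
    df = df.loc[:, list(INVENTORY_COLUMNS)].copy()
    statuses = set(df["status"].unique())
    if not statuses <= {"alive", "dead"}:
        raise GeoIOError(f"invalid status values: {sorted(statuses - {'alive', 'dead'})}")
    dead_no_cause = (df["status"] == "dead") & df["death_cause"].isna()
    if dead_no_cause.any():
        raise GeoIOError(f"{int(dead_no_cause.sum())} dead rows lack a death cause")
    if df["individual_id"].duplicated().any():
        raise GeoIOError("duplicate individual ids")
    return df.reset_index(drop=True)


def write_inventory(df: pd.DataFrame, path) -> None:
    _require_columns(df, INVENTORY_COLUMNS, "inventory table")
    df.loc[:, list(INVENTORY_COLUMNS)].to_csv(path, index=False)


def read_regions(path, crs: str = "planar_km") -> RegionPolygons:
    """GeoJSON FeatureCollection with a ``name`` property per feature."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GeoIOError("expected a GeoJSON FeatureCollection")
    polys = {}
    for i, feat in enumerate(gj.get("features", [])):
        name = (feat.get("properties") or {}).get("name", f"region_{i}")
        polys[str(name)] = sgeom.shape(feat["geometry"])
    return RegionPolygons(polys, crs=crs)


def write_regions(regions: RegionPolygons, path) -> None:
    feats = [
        {"type": "Feature", "properties": {"name": name},
         "geometry": sgeom.mapping(geom)}
        for name, geom in regions.polygons.items()
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
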