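"""Core domain types, file I/O, compositional transforms and geodesy.

The canonical in-memory objects are :class:`CalibrationSet` (the modern
training data: a site x taxon percentage matrix plus site geography and
per-site climate values) and :class:`FossilSequence` (a dated fossil
site x taxon matrix for one site).  Abundances are stored as percentages
(rows summing to 100); proportions are derived where a formula needs them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088

#: Default environmental lapse rate for temperature, degC per km of elevation.
DEFAULT_LAPSE_RATE = 6.4

#: Sentinel for a prediction/extraction that could not be made.
MISSING = float("nan")


class DataError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TaxonTable:
    """A site x taxon abundance matrix.

    Parameters
    ----------
    site_ids : list of str
        Unique row identifiers.
    taxon_names : list of str
        Unique column identifiers.
    values : ndarray of shape (n_sites, n_taxa)
        Non-negative abundances.
    unit : {'counts', 'percent'}
        If ``'percent'`` every row sums to 100 (relative tolerance 1e-6).
    """

    site_ids: list[str]
    taxon_names: list[str]
    values: np.ndarray
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.unit not in ("counts", "percent"):
            raise DataError(f"unknown unit {self.unit!r}")
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.site_ids) or m != len(self.taxon_names):
            raise DataError(
                f"shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.taxon_names)} taxa"
            )
        for label, items in (("site_id", self.site_ids), ("taxon", self.taxon_names)):
            dupes = pd.Index(items)[pd.Index(items).duplicated()]
            if len(dupes):
                raise DataError(f"duplicate {label}: {sorted(set(dupes))}")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            i, j = np.argwhere((self.values < 0) | ~np.isfinite(self.values))[0]
            raise DataError(
                f"negative or non-finite abundance at site "
                f"{self.site_ids[i]!r}, taxon {self.taxon_names[j]!r}"
            )
        if self.unit == "percent":
            sums = self.values.sum(axis=1)
            bad = np.where(np.abs(sums - 100.0) > 1e-6 * 100.0)[0]
            if len(bad):
                raise DataError(
                    f"percent rows must sum to 100; site "
                    f"{self.site_ids[bad[0]]!r} sums to {sums[bad[0]]:g}"
                )

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.site_ids, name="site_id"),
                            columns=self.taxon_names)


@dataclass
class SiteMeta:
    """Geographic metadata for one site (WGS84 decimal degrees, metres)."""

    site_id: str
    lon: float
    lat: float
    elevation: float = 0.0

    def __post_init__(self) -> None:
        # normalize longitudes to [-180, 180]
        if 180.0 < self.lon <= 360.0:
            self.lon -= 360.0
        if not (-180.0 <= self.lon <= 180.0):
            raise DataError(f"site {self.site_id!r}: longitude {self.lon} out of range")
        if not (-90.0 <= self.lat <= 90.0):
            raise DataError(f"site {self.site_id!r}: latitude {self.lat} out of range")


@dataclass
class ClimateVector:
    """Per-site climate values, variable name -> numeric value."""

    site_id: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise DataError(f"site {self.site_id!r}: variable {k!r} is not finite")


@dataclass
class CalibrationSet:
    """Modern calibration data: taxa (percent), geography and climate, aligned."""

    taxa: TaxonTable
    meta: list[SiteMeta]
    climate: list[ClimateVector]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.taxa.unit != "percent":
            raise DataError("CalibrationSet taxa must be in percent")
        ids = self.taxa.site_ids
        if [m.site_id for m in self.meta] != ids or [c.site_id for c in self.climate] != ids:
            raise DataError("site_id sets/order differ between taxa, meta and climate")
        if self.taxa.n_sites < 2 or self.taxa.n_taxa < 2:
            raise DataError("calibration set needs at least 2 sites and 2 taxa")
        names = set(self.climate[0].values)
        for c in self.climate:
            if set(c.values) != names:
                raise DataError(f"site {c.site_id!r} is missing climate variables")

    @property
    def n_sites(self) -> int:
        return self.taxa.n_sites

    @property
    def variables(self) -> list[str]:
        return sorted(self.climate[0].values)

    def coords(self) -> np.ndarray:
        """(n_sites, 2) array of lon, lat."""
        return np.array([[m.lon, m.lat] for m in self.meta])

    def response(self, variable: str) -> np.ndarray:
        if variable not in self.climate[0].values:
            raise DataError(f"climate variable {variable!r} not present "
                            f"(have {self.variables})")
        return np.array([c.values[variable] for c in self.climate])

    def climate_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.values for c in self.climate],
                            index=pd.Index(self.taxa.site_ids, name="site_id"))


@dataclass
class FossilSequence:
    """Dated fossil samples from a single site; ages in cal ka."""

    taxa: TaxonTable
    ages: np.ndarray
    site: SiteMeta

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if len(self.ages) != self.taxa.n_sites:
            raise DataError("ages and taxa rows differ in length")
        d = np.diff(self.ages)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise DataError("ages must be strictly monotone")
        if self.taxa.unit != "percent":
            raise DataError("FossilSequence taxa must be in percent")

    @property
    def n_samples(self) -> int:
        return self.taxa.n_sites


@dataclass
class ClimateGrid:
    """A gridded climate field with a companion elevation field.

    ``value`` and ``elev`` are (n_lat, n_lon) arrays on cell-centre
    coordinates; ``nodata`` cells are missing.
    """

    lon_coords: np.ndarray
    lat_coords: np.ndarray
    value: np.ndarray
    elev: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.lon_coords = np.asarray(self.lon_coords, dtype=float)
        self.lat_coords = np.asarray(self.lat_coords, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.elev = np.asarray(self.elev, dtype=float)
        for c in (self.lon_coords, self.lat_coords):
            d = np.diff(c)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise DataError("grid coordinates must be strictly monotone")
        shape = (len(self.lat_coords), len(self.lon_coords))
        if self.value.shape != shape or self.elev.shape != shape:
            raise DataError(f"grid fields must have shape {shape}")


# ---------------------------------------------------------------------------
# compositional transforms
# ---------------------------------------------------------------------------


def percent_normalize(table: TaxonTable) -> TaxonTable:
    """Rescale every row to sum to 100 and mark the table as percentages.

    Idempotent: an already-percent table is returned with the same values.
    A row summing to zero is an error (a sample with no pollen at all
    carries no compositional information).
    """
    sums = table.values.sum(axis=1)
    zero = np.where(sums <= 0)[0]
    if len(zero):
        raise DataError(f"site {table.site_ids[zero[0]]!r} has zero total abundance")
    values = 100.0 * table.values / sums[:, None]
    return TaxonTable(list(table.site_ids), list(table.taxon_names), values, "percent")


def sqrt_transform(table: TaxonTable) -> np.ndarray:
    """Element-wise square root of a percentage matrix.

    This is the variance-stabilizing transform applied to the species data
    for the weighted-averaging family (WA, WAPLS) only; the tree-ensemble
    and network methods take raw percentages.
    """
    if table.unit != "percent":
        raise DataError("sqrt_transform expects a percent table")
    return np.sqrt(table.values)


# ---------------------------------------------------------------------------
# geodesy
# ---------------------------------------------------------------------------


def great_circle_km(a: Sequence[float], b: Sequence[float]) -> float:
    """Haversine distance in km between two (lon, lat) points.

    Uses a sphere of radius 6371.0088 km; symmetric, zero iff the points
    coincide.
    """
    lon1, lat1 = float(a[0]), float(a[1])
    lon2, lat2 = float(b[0]), float(b[1])
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            raise DataError(f"coordinate ({lon}, {lat}) out of range")
    return float(pairwise_great_circle_km(np.array([[lon1, lat1]]),
                                          np.array([[lon2, lat2]]))[0, 0])


def pairwise_great_circle_km(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise haversine distances (km) between (lon, lat) coordinate arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = a if b is None else np.atleast_2d(np.asarray(b, dtype=float))
    lon1, lat1 = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon2, lat2 = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    s = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# gridded-climate extraction
# ---------------------------------------------------------------------------


def _bracket(coords: np.ndarray, x: float) -> tuple[int, int, float]:
    """Indices of the two cell centres bracketing x and the interpolation weight."""
    asc = coords if coords[1] > coords[0] else coords[::-1]
    if not (asc[0] <= x <= asc[-1]):
        raise DataError(f"coordinate {x} outside grid extent [{asc[0]}, {asc[-1]}]")
    j = int(np.clip(np.searchsorted(asc, x) - 1, 0, len(asc) - 2))
    t = (x - asc[j]) / (asc[j + 1] - asc[j])
    if coords[1] > coords[0]:
        return j, j + 1, t
    n = len(coords)
    return n - 1 - j, n - 2 - j, t


def extract_climate(grid: ClimateGrid, site: SiteMeta,
                    lapse_rate: float = DEFAULT_LAPSE_RATE,
                    apply_lapse: bool = True) -> float:
    """Bilinear interpolation of a gridded climate value at a site.

    The value and the grid elevation are both interpolated from the four
    surrounding cell centres; nodata cells are dropped with weight
    renormalization.  With ``apply_lapse`` the value is lapse-rate corrected
    for the difference between the site elevation and the interpolated grid
    elevation (default 6.4 degC per km, the standard environmental lapse
    rate for near-surface air temperature)::

        corrected = value - lapse_rate * (site_elev - grid_elev) / 1000

    Returns NaN when all four surrounding cells are nodata.
    """
    j0, j1, tx = _bracket(grid.lon_coords, site.lon)
    i0, i1, ty = _bracket(grid.lat_coords, site.lat)
    cells = [(i0, j0, (1 - ty) * (1 - tx)), (i0, j1, (1 - ty) * tx),
             (i1, j0, ty * (1 - tx)), (i1, j1, ty * tx)]
    wsum = vsum = esum = 0.0
    for i, j, w in cells:
        v, e = grid.value[i, j], grid.elev[i, j]
        if v == grid.nodata or e == grid.nodata or not np.isfinite(v):
            continue
        wsum += w
        vsum += w * v
        esum += w * e
    if wsum == 0.0:
        return MISSING
    value = vsum / wsum
    if apply_lapse:
        value -= lapse_rate * (site.elevation - esum / wsum) / 1000.0
    return float(value)


def read_esri_ascii(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (lon_centres, lat_centres, data, nodata).

    ``data`` is oriented with rows following ``lat_centres`` (descending,
    as stored: first row = northernmost).
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    data = np.array([v for r in rows for v in r]).reshape(nrows, ncols)
    lon = header["xllcorner"] + cell * (np.arange(ncols) + 0.5)
    lat = header["yllcorner"] + cell * (np.arange(nrows) + 0.5)
    return lon, lat[::-1], data, header.get("nodata_value", -9999.0)


def write_esri_ascii(path: str | Path, lon: np.ndarray, lat: np.ndarray,
                     data: np.ndarray, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (rows northernmost-first, matching ``lat``)."""
    cell = float(abs(lon[1] - lon[0]))
    with open(path, "w") as fh:
        fh.write(f"ncols {len(lon)}\nnrows {len(lat)}\n")
        fh.write(f"xllcorner {min(lon) - cell / 2:.10g}\n")
        fh.write(f"yllcorner {min(lat) - cell / 2:.10g}\n")
        fh.write(f"cellsize {cell:.10g}\nNODATA_value {nodata:.10g}\n")
        for row in data:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def load_climate_grid(value_path: str | Path, elev_path: str | Path) -> ClimateGrid:
    """Load a climate variable grid and its companion elevation grid."""
    lon, lat, value, nodata = read_esri_ascii(value_path)
    lon2, lat2, elev, _ = read_esri_ascii(elev_path)
    if not (np.allclose(lon, lon2) and np.allclose(lat, lat2)):
        raise DataError("value and elevation grids are not co-registered")
    return ClimateGrid(lon, lat, value, elev, nodata)


# ---------------------------------------------------------------------------
# taxon alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignmentReport:
    """Book-keeping from aligning two taxon tables on their shared taxa."""

    shared_taxa: list[str]
    dropped_from_first: list[str]
    dropped_from_second: list[str]
    mass_lost_first: np.ndarray    # per-sample % mass in dropped taxa
    mass_lost_second: np.ndarray


def align_taxa(cal: CalibrationSet, fossil: FossilSequence
               ) -> tuple[np.ndarray, np.ndarray, AlignmentReport]:
    """Restrict calibration and fossil matrices to their shared taxa.

    Both matrices are returned with columns in the same (calibration) order
    and rows re-normalized to sum to 100.  The report records the taxa
    dropped from each side and the percentage mass each sample lost.
    """
    cal_names, fos_names = cal.taxa.taxon_names, fossil.taxa.taxon_names
    shared = [t for t in cal_names if t in set(fos_names)]
    if not shared:
        raise DataError("no shared taxa between calibration and fossil data")
    cal_idx = [cal_names.index(t) for t in shared]
    fos_idx = [fos_names.index(t) for t in shared]
    cal_m = cal.taxa.values[:, cal_idx]
    fos_m = fossil.taxa.values[:, fos_idx]
    lost_cal = 100.0 - cal_m.sum(axis=1)
    lost_fos = 100.0 - fos_m.sum(axis=1)
    for m, which in ((cal_m, "calibration"), (fos_m, "fossil")):
        if np.any(m.sum(axis=1) <= 0):
            raise DataError(f"a {which} sample retains zero abundance after alignment")
    cal_m = 100.0 * cal_m / cal_m.sum(axis=1, keepdims=True)
    fos_m = 100.0 * fos_m / fos_m.sum(axis=1, keepdims=True)
    report = AlignmentReport(
        shared_taxa=shared,
        dropped_from_first=[t for t in cal_names if t not in set(shared)],
        dropped_from_second=[t for t in fos_names if t not in set(shared)],
        mass_lost_first=lost_cal,
        mass_lost_second=lost_fos,
    )
    return cal_m, fos_m, report


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_calibration(taxa_path: str | Path, meta_path: str | Path,
                     climate_path: str | Path) -> CalibrationSet:
    """Load a calibration set from the three-file CSV layout.

    Files are inner-joined on ``site_id`` in taxa-file order; counts are
    percent-normalized; unmatched sites are dropped with a warning.
    """
    taxa_df = pd.read_csv(taxa_path)
    meta_df = pd.read_csv(meta_path)
    clim_df = pd.read_csv(climate_path)
    for name, df in (("taxa", taxa_df), ("meta", meta_df), ("climate", clim_df)):
        if "site_id" not in df.columns:
            raise DataError(f"{name} file lacks a site_id column")
        dupes = df.site_id[df.site_id.duplicated()]
        if len(dupes):
            raise DataError(f"duplicate site_id {dupes.iloc[0]!r} in {name} file")
        df.set_index("site_id", inplace=True)

    keep = [s for s in taxa_df.index if s in meta_df.index and s in clim_df.index]
    dropped = [s for s in taxa_df.index if s not in keep]
    if dropped:
        logger.warning("dropping %d site(s) absent from meta/climate: %s",
                       len(dropped), dropped)
    if not keep:
        raise DataError("no site_id is shared by all three files")

    taxa_df = taxa_df.loc[keep]
    table = percent_normalize(TaxonTable([str(s) for s in keep],
                                         list(taxa_df.columns),
                                         taxa_df.to_numpy(float), "counts"))
    meta = [SiteMeta(str(s), float(meta_df.at[s, "lon"]), float(meta_df.at[s, "lat"]),
                     float(meta_df.at[s, "elevation"]) if "elevation" in meta_df else 0.0)
            for s in keep]
    climate = [ClimateVector(str(s), {v: float(clim_df.at[s, v]) for v in clim_df.columns})
               for s in keep]
    return CalibrationSet(table, meta, climate)


def save_calibration(cal: CalibrationSet, out_dir: str | Path) -> dict[str, Path]:
    """Write the three-file CSV layout; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"taxa": out / "taxa.csv", "meta": out / "meta.csv",
             "climate": out / "climate.csv"}
    cal.taxa.to_frame().to_csv(paths["taxa"], float_format="%.12g")
    pd.DataFrame([{"site_id": m.site_id, "lon": m.lon, "lat": m.lat,
                   "elevation": m.elevation} for m in cal.meta]
                 ).to_csv(paths["meta"], index=False, float_format="%.12g")
    cal.climate_frame().to_csv(paths["climate"], float_format="%.12g")
    return paths


def load_fossil(path: str | Path, lon: float = 0.0, lat: float = 0.0,
                elevation: float = 0.0, site_id: str = "fossil") -> FossilSequence:
    """Load a fossil sequence CSV (sample_id, age_ka, then taxon columns)."""
    df = pd.read_csv(path)
    for col in ("sample_id", "age_ka"):
        if col not in df.columns:
            raise DataError(f"fossil file lacks a {col} column")
    taxa_cols = [c for c in df.columns if c not in ("sample_id", "age_ka")]
    table = percent_normalize(TaxonTable([str(s) for s in df.sample_id],
                                         taxa_cols, df[taxa_cols].to_numpy(float),
                                         "counts"))
    return FossilSequence(table, df.age_ka.to_numpy(float),
                          SiteMeta(site_id, lon, lat, elevation))


def save_fossil(fossil: FossilSequence, path: str | Path) -> None:
    df = fossil.taxa.to_frame().reset_index().rename(columns={"site_id": "sample_id"})
    df.insert(1, "age_ka", fossil.ages)
    df.to_csv(path, index=False, float_format="%.12g")
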