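"""Synthetic calibration and fossil data with realistic spatial structure.

The generator plants the three statistical features the calibration and
cross-validation machinery is built to handle, so every stage of the
toolkit is testable without external pollen databases:

* **spatially autocorrelated climate surfaces** -- each climate variable is
  a Gaussian random field with a circular covariance of configurable range,
  sampled at sites scattered uniformly over a km-scale box and mapped to
  realistic units;
* **unimodal taxon responses** -- expected abundances follow Gaussian
  response surfaces in a primary and a secondary climate variable, with
  configurable subsets of primary-only and secondary-indicator taxa;
* **compositional count noise** -- observed assemblages are multinomial
  draws of a fixed pollen sum per site, converted to percentages.

All outputs are deterministic functions of (config, seed), and the planted
parameters (field ranges, inter-variable correlation, taxon optima, true
site climates) are returned alongside the data for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .data import (CalibrationSet, ClimateVector, DataError, FossilSequence,
                   SiteMeta, TaxonTable, pairwise_great_circle_km,
                   percent_normalize)
from .hblock import circular_semivariance

KM_PER_DEG_LAT = 111.19492664455873  # mean-Earth-radius degree of latitude


@dataclass
class TaxonResponse:
    """Gaussian response surface of one taxon in the two climate variables.

    ``tol2 = inf`` makes the taxon a primary-only indicator (flat in the
    secondary variable), and vice versa.
    """

    name: str
    opt1: float
    tol1: float
    opt2: float
    tol2: float
    max_abundance: float

    def expected(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        e = np.full_like(np.asarray(x1, float), self.max_abundance)
        if np.isfinite(self.tol1):
            e = e * np.exp(-((x1 - self.opt1) ** 2) / (2.0 * self.tol1**2))
        if np.isfinite(self.tol2):
            e = e * np.exp(-((x2 - self.opt2) ** 2) / (2.0 * self.tol2**2))
        return e


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults are the desk-scale preset: 300 sites in a
    3000-km box, two climate variables with 400-km autocorrelation range
    and near-zero cross-correlation (rho = 0.05), 30 taxa, pollen sums of
    300 grains.
    """

    n_sites: int = 300
    extent_km: float = 3000.0
    ref_lon: float = 10.0
    ref_lat: float = 50.0
    variables: tuple[str, str] = ("T_jul", "water_balance")
    var_bounds: tuple[tuple[float, float], ...] = ((8.0, 22.0), (-300.0, 300.0))
    range_km: tuple[float, float] = (400.0, 400.0)
    rho: float = 0.05
    n_taxa: int = 30
    frac_primary_only: float = 0.5
    frac_secondary: float = 0.15
    count_depth: int | None = 300
    taxa: list[TaxonResponse] | None = None
    # spatially autocorrelated observation error added to the *recorded*
    # primary climate values (taxa still respond to the true values); this
    # plants a known autocorrelation range in transfer-function residuals
    residual_range_km: float | None = None
    residual_sd: float = 0.0
    residual_nugget_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_sites < 2 or self.n_taxa < 2:
            raise DataError("need at least 2 sites and 2 taxa")
        if any(r <= 0 for r in self.range_km):
            raise DataError("range_km must be positive")
        if abs(self.rho) > 1:
            raise DataError("|rho| must be <= 1")
        if self.count_depth is not None and self.count_depth < 50:
            raise DataError("count_depth must be >= 50 (or None for noiseless)")


def default_preset(**overrides) -> SyntheticConfig:
    """The default desk-scale preset; keyword overrides are applied on top."""
    return SyntheticConfig(**overrides)


# ---------------------------------------------------------------------------
# Gaussian random fields
# ---------------------------------------------------------------------------


def gaussian_field(coords_lonlat: np.ndarray, range_km: float, rng,
                   n_fields: int = 1, dist: np.ndarray | None = None
                   ) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian fields with circular covariance.

    The covariance at separation d is ``1 - gamma_circ(d; range)``: positive
    within the range, exactly zero beyond it.
    """
    if dist is None:
        dist = pairwise_great_circle_km(coords_lonlat)
    cov = 1.0 - circular_semivariance(dist, 0.0, 1.0, range_km)
    cov[dist >= range_km] = 0.0
    np.fill_diagonal(cov, cov.diagonal() + 1e-8)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((dist.shape[0], n_fields))
    return L @ z


def _affine_to_bounds(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    zmin, zmax = float(np.min(z)), float(np.max(z))
    if zmax <= zmin:
        return np.full_like(z, 0.5 * (lo + hi))
    return lo + (hi - lo) * (z - zmin) / (zmax - zmin)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _streams(seed: int):
    taxa_ss, space_ss, count_ss, fossil_ss = SeedSequence(seed).spawn(4)
    return (default_rng(taxa_ss), default_rng(space_ss),
            default_rng(count_ss), default_rng(fossil_ss))


def default_taxa(config: SyntheticConfig, rng) -> list[TaxonResponse]:
    """Draw a taxon roster: primary-only, secondary-indicator and generalist.

    Optima are spread over (a 10%-expanded version of) each variable's
    bounds; tolerances are 10-25% of the gradient span, so responses are
    genuinely unimodal within the sampled domain.
    """
    (lo1, hi1), (lo2, hi2) = config.var_bounds
    span1, span2 = hi1 - lo1, hi2 - lo2
    n = config.n_taxa
    n_primary = int(round(config.frac_primary_only * n))
    n_secondary = int(round(config.frac_secondary * n))
    roles = (["primary"] * n_primary + ["secondary"] * n_secondary
             + ["both"] * (n - n_primary - n_secondary))
    taxa = []
    for k, role in enumerate(roles):
        opt1 = rng.uniform(lo1 - 0.1 * span1, hi1 + 0.1 * span1)
        opt2 = rng.uniform(lo2 - 0.1 * span2, hi2 + 0.1 * span2)
        tol1 = rng.uniform(0.10, 0.25) * span1
        tol2 = rng.uniform(0.10, 0.25) * span2
        if role == "primary":
            tol2 = np.inf
        elif role == "secondary":
            tol1 = np.inf
        taxa.append(TaxonResponse(f"taxon_{k:02d}", opt1, tol1, opt2, tol2,
                                  max_abundance=rng.uniform(5.0, 100.0)))
    return taxa


def gen_climate_surface(config: SyntheticConfig, seed: int = 0) -> pd.DataFrame:
    """Site coordinates plus two correlated, autocorrelated climate variables.

    Sites are uniform over the km box (mapped to lon/lat around the
    reference point); each variable is a circular-covariance Gaussian field
    affinely mapped to its configured units; the cross-variable correlation
    is induced by shared-component mixing to the target rho.
    """
    _, space_rng, _, _ = _streams(seed)
    xy = space_rng.uniform(0.0, config.extent_km, size=(config.n_sites, 2))
    lat = config.ref_lat + (xy[:, 1] - config.extent_km / 2) / KM_PER_DEG_LAT
    lon = config.ref_lon + (xy[:, 0] - config.extent_km / 2) / (
        KM_PER_DEG_LAT * np.cos(np.radians(config.ref_lat)))
    coords = np.column_stack([lon, lat])
    dist = pairwise_great_circle_km(coords)

    z1 = gaussian_field(coords, config.range_km[0], space_rng, dist=dist)[:, 0]
    z2i = gaussian_field(coords, config.range_km[1], space_rng, dist=dist)[:, 0]
    rho = config.rho
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * z2i
    elev = np.maximum(200.0 + 150.0 * gaussian_field(
        coords, config.range_km[0], space_rng, dist=dist)[:, 0], 0.0)

    v1, v2 = config.variables
    df = pd.DataFrame({
        "site_id": [f"site_{i:04d}" for i in range(config.n_sites)],
        "lon": lon, "lat": lat, "elevation": elev,
        v1: _affine_to_bounds(z1, *config.var_bounds[0]),
        v2: _affine_to_bounds(z2, *config.var_bounds[1]),
    })
    return df


def gen_taxa(x1: np.ndarray, x2: np.ndarray, config: SyntheticConfig,
             seed: int = 0, sample_ids: Sequence[str] | None = None,
             count_rng=None) -> tuple[TaxonTable, list[TaxonResponse]]:
    """Assemblages for given climate values under the Gaussian response model.

    With a finite ``count_depth``, counts are multinomial with that pollen
    sum per sample; with ``count_depth=None`` the noiseless expected
    percentages are returned.
    """
    taxa_rng, _, default_count_rng, _ = _streams(seed)
    if count_rng is None:
        count_rng = default_count_rng
    taxa = config.taxa if config.taxa is not None else default_taxa(config, taxa_rng)
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    E = np.column_stack([t.expected(x1, x2) for t in taxa])
    zero = E.sum(axis=1) <= 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} site(s) with zero expected abundance; "
                      "using a uniform composition there")
        E[zero] = 1.0
    P = E / E.sum(axis=1, keepdims=True)
    ids = (list(sample_ids) if sample_ids is not None
           else [f"site_{i:04d}" for i in range(len(x1))])
    names = [t.name for t in taxa]
    if config.count_depth is None:
        table = TaxonTable(ids, names, 100.0 * P, "percent")
    else:
        counts = np.array([count_rng.multinomial(config.count_depth, p)
                           for p in P], dtype=float)
        table = percent_normalize(TaxonTable(ids, names, counts, "counts"))
    return table, taxa


def gen_calibration(config: SyntheticConfig, seed: int = 0
                    ) -> tuple[CalibrationSet, dict]:
    """A full synthetic CalibrationSet plus the planted ground truth.

    The returned truth dict holds the true (noise-free) site climates, the
    taxon response parameters and the generator settings; when a residual
    observation error is configured, the *recorded* primary-variable values
    are true + spatially autocorrelated error, while taxa respond to truth.
    """
    taxa_rng, space_rng, count_rng, _ = _streams(seed)
    surf = gen_climate_surface(config, seed)
    v1, v2 = config.variables
    x1_true = surf[v1].to_numpy()
    x2_true = surf[v2].to_numpy()
    table, taxa = gen_taxa(x1_true, x2_true, config, seed,
                           sample_ids=surf.site_id, count_rng=count_rng)

    x1_obs = x1_true.copy()
    if config.residual_range_km is not None and config.residual_sd > 0:
        coords = surf[["lon", "lat"]].to_numpy()
        err_rng = default_rng(SeedSequence(seed).spawn(5)[4])
        err = config.residual_sd * gaussian_field(
            coords, config.residual_range_km, err_rng)[:, 0]
        if config.residual_nugget_sd > 0:
            err = err + err_rng.normal(0.0, config.residual_nugget_sd,
                                       size=len(err))
        x1_obs = x1_true + err

    meta = [SiteMeta(r.site_id, r.lon, r.lat, r.elevation)
            for r in surf.itertuples()]
    climate = [ClimateVector(sid, {v1: float(a), v2: float(b)})
               for sid, a, b in zip(surf.site_id, x1_obs, x2_true)]
    cal = CalibrationSet(table, meta, climate)
    truth = {
        "x1_true": x1_true, "x2_true": x2_true, "x1_observed": x1_obs,
        "taxa": taxa, "range_km": config.range_km, "rho": config.rho,
        "variables": config.variables,
        "residual_range_km": config.residual_range_km,
    }
    return cal, truth


def gen_fossil(trajectory: np.ndarray, config: SyntheticConfig, seed: int = 0,
               site: SiteMeta | None = None) -> tuple[FossilSequence, dict]:
    """A fossil sequence generated from a known climate trajectory.

    ``trajectory`` is an (n_samples, 3) array of (age_ka, x1, x2); taxon
    responses and count noise follow the same model (and the same seeded
    taxon roster) as :func:`gen_calibration`, so fossil assemblages are
    directly comparable with the matching calibration set.
    """
    trajectory = np.asarray(trajectory, float)
    if trajectory.ndim != 2 or trajectory.shape[1] != 3:
        raise DataError("trajectory must be (n, 3): age_ka, x1, x2")
    ages = trajectory[:, 0]
    _, _, _, fossil_rng = _streams(seed)
    table, taxa = gen_taxa(trajectory[:, 1], trajectory[:, 2], config, seed,
                           sample_ids=[f"samp_{i:04d}" for i in
                                       range(len(ages))],
                           count_rng=fossil_rng)
    if site is None:
        site = SiteMeta("synthetic_core", config.ref_lon, config.ref_lat, 150.0)
    fossil = FossilSequence(table, ages, site)
    truth = {"ages": ages, "x1_true": trajectory[:, 1],
             "x2_true": trajectory[:, 2], "taxa": taxa}
    return fossil, truth
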