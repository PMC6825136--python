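"""Variable-radius h-block spatial cross-validation.

For each held-out site the training set omits not only the test sample but
every calibration sample within a radius *h* (km) of it, neutralizing the
skill inflation that spatial autocorrelation produces in ordinary
leave-one-out CV.  Running the CV over a grid of *h* (default 0-1500 km in
100 km steps) traces how performance degrades as pseudo-replicates, and then
genuine analogues, are removed.  An optimal *h* is estimated independently
as the range of a circular variogram fitted to the residuals of a
weighted-averaging model under leave-one-out CV.

Boundary convention: a neighbour at distance exactly *h* is excluded (the
exclusion zone is a closed ball), so *h* = 0 removes only the test sample
and is literally leave-one-out CV.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence
from scipy.optimize import least_squares

from .data import CalibrationSet, DataError, MISSING, pairwise_great_circle_km
from .methods import METHOD_CODES, MethodSpec, fit_model, sq_chord_matrix

DEFAULT_H_GRID = tuple(range(0, 1501, 100))


@dataclass
class CVSpec:
    """A cross-validation campaign: radii, methods, response variable, seed."""

    methods: list[MethodSpec]
    response: str
    h_grid: tuple[float, ...] = DEFAULT_H_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        h = np.asarray(self.h_grid, float)
        if len(h) == 0 or np.any(h < 0) or np.any(np.diff(h) <= 0):
            raise DataError("h_grid must be non-negative and strictly increasing")


@dataclass
class CVResult:
    """One (h, method) cross-validation: per-site records plus summary metrics."""

    h: float
    method: str
    sites: pd.DataFrame  # site_id, observed, predicted, residual, n_train, best_analog
    summary: dict[str, float] = field(default_factory=dict)

    def recompute_summary(self, n_segments: int = 10) -> dict[str, float]:
        s = self.sites
        ok = np.isfinite(s.residual.to_numpy())
        n_total = len(s)
        summary = {
            "rmsep": rmsep(s.residual.to_numpy()),
            "max_bias": max_bias(s.residual.to_numpy(), s.observed.to_numpy(),
                                 n_segments=n_segments),
            "r2": r_squared(s.observed.to_numpy()[ok], s.predicted.to_numpy()[ok]),
            "median_data_loss_fraction": float(
                np.median(1.0 - s.n_train.to_numpy() / (n_total - 1))),
            "median_best_analog": float(np.nanmedian(s.best_analog.to_numpy())),
            "n_missing": int(np.sum(~ok)),
        }
        return summary


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------


def rmsep(residuals: np.ndarray) -> float:
    """Root-mean-square error of prediction; missing residuals are excluded."""
    r = np.asarray(residuals, float)
    r = r[np.isfinite(r)]
    if len(r) == 0:
        raise DataError("all residuals are missing")
    return float(np.sqrt(np.mean(r**2)))


def max_bias(residuals: np.ndarray, observed: np.ndarray,
             n_segments: int = 10) -> float:
    """Maximum absolute mean residual over equal-length gradient segments.

    The observed-value range is split into ``n_segments`` equal intervals;
    the statistic is the largest absolute per-interval mean residual over
    non-empty intervals -- a worst-segment error for the climate gradient.
    """
    r = np.asarray(residuals, float)
    obs = np.asarray(observed, float)
    if len(r) != len(obs):
        raise DataError("residuals and observed differ in length")
    ok = np.isfinite(r) & np.isfinite(obs)
    r, obs = r[ok], obs[ok]
    lo, hi = float(np.min(obs)), float(np.max(obs))
    if hi <= lo:
        raise DataError("degenerate climate gradient (max == min)")
    seg = np.clip(((obs - lo) / (hi - lo) * n_segments).astype(int), 0,
                  n_segments - 1)
    worst = 0.0
    for s in range(n_segments):
        mask = seg == s
        if np.any(mask):
            worst = max(worst, abs(float(np.mean(r[mask]))))
    return worst


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if len(obs) != len(pred) or len(obs) < 2:
        raise DataError("need >= 2 paired points")
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise DataError("zero variance in observed or predicted values")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# the h-block engine
# ---------------------------------------------------------------------------


def hblock_training_indices(meta, test_index: int, h: float) -> np.ndarray:
    """Training indices for one fold: all sites strictly farther than h km.

    ``meta`` is a list of SiteMeta (or an (n, 2) lon/lat array).  Sites at
    distance exactly h are excluded; at h = 0 this is leave-one-out.
    """
    if h < 0:
        raise DataError("h must be non-negative")
    coords = (np.array([[m.lon, m.lat] for m in meta])
              if not isinstance(meta, np.ndarray) else meta)
    d = pairwise_great_circle_km(coords[test_index][None, :], coords)[0]
    idx = np.where(d > h)[0]
    idx = idx[idx != test_index]
    if len(idx) == 0:
        sid = getattr(meta[test_index], "site_id", test_index)
        raise DataError(f"no training sites remain for site {sid!r} at h={h} km")
    return idx


def _fold_seed(master: int, method_code: str, h: float, fold: int) -> int:
    ss = SeedSequence([int(master), METHOD_CODES.index(method_code),
                       int(round(h)), int(fold)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_hblock_cv(cal: CalibrationSet, spec: MethodSpec, response: str,
                  h: float, seed: int = 0,
                  dist: np.ndarray | None = None) -> CVResult:
    """One full h-block CV cycle for one method at one radius.

    Per site: build the h-block training set, fit the method, predict the
    held-out site, and record the residual, the surviving training-set size,
    and the squared-chord distance to the best remaining analogue.  Folds
    whose training set falls below the method's minimum viable size yield a
    missing prediction rather than an abort.  Stochastic methods are
    re-seeded deterministically per (method, h, fold).
    """
    y = cal.response(response)
    X = cal.taxa.values
    P = X / 100.0
    names = cal.taxa.taxon_names
    ids = cal.taxa.site_ids
    n = cal.n_sites
    if dist is None:
        dist = pairwise_great_circle_km(cal.coords())
    min_train = spec.min_train_size()

    rows = []
    n_short = 0
    for i in range(n):
        train = np.where(dist[i] > h)[0]
        train = train[train != i]
        n_train = len(train)
        best = MISSING
        pred = MISSING
        if n_train:
            best = float(np.min(sq_chord_matrix(P[i][None, :], P[train])[0]))
        if n_train >= min_train:
            fold_spec = spec.with_seed(_fold_seed(seed, spec.code, h, i))
            model = fit_model(fold_spec, X[train], y[train], taxon_names=names)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred = float(model.predict(X[i][None, :])[0])
        else:
            n_short += 1
        rows.append({"site_id": ids[i], "observed": float(y[i]), "predicted": pred,
                     "residual": pred - float(y[i]), "n_train": n_train,
                     "best_analog": best})
    if n_short:
        warnings.warn(f"{spec.code} h={h:g}: {n_short} site(s) below the minimum "
                      f"training size ({min_train}); predictions set to missing")
    result = CVResult(h=float(h), method=spec.code, sites=pd.DataFrame(rows))
    try:
        result.summary = result.recompute_summary()
    except DataError:
        result.summary = {"rmsep": MISSING, "max_bias": MISSING, "r2": MISSING,
                          "median_data_loss_fraction": float(np.median(
                              1.0 - result.sites.n_train.to_numpy() / (n - 1))),
                          "median_best_analog": float(
                              np.nanmedian(result.sites.best_analog.to_numpy())),
                          "n_missing": int(np.sum(~np.isfinite(
                              result.sites.residual.to_numpy())))}
    return result


def run_cv_series(cal: CalibrationSet, cvspec: CVSpec) -> list[CVResult]:
    """One CVResult per (h, method); deterministic under ``cvspec.seed``."""
    dist = pairwise_great_circle_km(cal.coords())
    results = []
    for spec in cvspec.methods:
        for h in cvspec.h_grid:
            results.append(run_hblock_cv(cal, spec, cvspec.response, h,
                                         seed=cvspec.seed, dist=dist))
    return results


def series_frame(results: list[CVResult]) -> pd.DataFrame:
    """Tidy long-format per-site table across a CV series."""
    frames = []
    for r in results:
        df = r.sites.copy()
        df.insert(0, "method", r.method)
        df.insert(0, "h", r.h)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summary_frame(results: list[CVResult]) -> pd.DataFrame:
    """One row of summary metrics per (h, method)."""
    return pd.DataFrame([{"h": r.h, "method": r.method, **r.summary}
                         for r in results])


# ---------------------------------------------------------------------------
# variograms
# ---------------------------------------------------------------------------


def empirical_variogram(coords: np.ndarray, residuals: np.ndarray,
                        n_bins: int = 15,
                        max_lag_km: float | None = None) -> pd.DataFrame:
    """Binned semivariance of residuals: gamma(lag) = mean of 0.5*(r_i - r_j)^2.

    Bins are equal-width up to ``max_lag_km`` (default: half the maximum
    pairwise distance, standard geostatistical practice).  Returns a table
    with bin-centre lag, semivariance and pair count.
    """
    coords = np.asarray(coords, float)
    r = np.asarray(residuals, float)
    ok = np.isfinite(r)
    coords, r = coords[ok], r[ok]
    if len(r) < 2:
        raise DataError("need >= 2 sites with finite residuals")
    if len(r) < 30:
        warnings.warn("fewer than 30 sites: the empirical variogram is noisy")
    d = pairwise_great_circle_km(coords)
    iu = np.triu_indices(len(r), k=1)
    lags = d[iu]
    gamma_pairs = 0.5 * (r[iu[0]] - r[iu[1]]) ** 2
    if max_lag_km is None:
        max_lag_km = float(np.max(lags)) / 2.0
    edges = np.linspace(0.0, max_lag_km, n_bins + 1)
    rows = []
    for b in range(n_bins):
        mask = (lags >= edges[b]) & (lags < edges[b + 1])
        if b == n_bins - 1:
            mask |= lags == edges[b + 1]
        rows.append({"lag": 0.5 * (edges[b] + edges[b + 1]),
                     "semivariance": float(np.mean(gamma_pairs[mask]))
                     if np.any(mask) else MISSING,
                     "n_pairs": int(np.sum(mask))})
    return pd.DataFrame(rows)


def circular_semivariance(d, nugget: float, partial_sill: float,
                          range_km: float) -> np.ndarray:
    """Circular variogram model, reaching the sill exactly at the range."""
    d = np.asarray(d, float)
    x = np.clip(d / range_km, 0.0, 1.0)
    g = 1.0 - (2.0 / np.pi) * np.arccos(x) + (2.0 * x / np.pi) * np.sqrt(
        np.maximum(1.0 - x**2, 0.0))
    return nugget + partial_sill * g


@dataclass
class VariogramFit:
    """A fitted circular variogram: nugget, partial sill and range (km)."""

    nugget: float
    partial_sill: float
    range_km: float
    bins: pd.DataFrame
    sse: float
    no_structure: bool = False

    def predict(self, d) -> np.ndarray:
        return circular_semivariance(d, self.nugget, self.partial_sill,
                                     self.range_km)


def fit_circular_variogram(bins: pd.DataFrame,
                           structure_tol: float = 0.05) -> VariogramFit:
    """Weighted least-squares fit of the circular model to a binned variogram.

    Weights are pair counts; multiple starting ranges are tried and the best
    SSE kept.  A fit whose partial sill is below ``structure_tol`` of the
    total sill is flagged as having no spatial structure, with the range
    collapsed to the smallest bin lag.
    """
    ok = bins.dropna(subset=["semivariance"])
    ok = ok[ok.n_pairs > 0]
    if len(ok) < 4:
        raise DataError(f"need >= 4 non-empty bins, have {len(ok)}")
    lag = ok.lag.to_numpy(float)
    gamma = ok.semivariance.to_numpy(float)
    w = np.sqrt(ok.n_pairs.to_numpy(float))

    sill0 = max(float(np.mean(gamma[-3:])), 1e-12)
    nugget0 = max(float(gamma[0]), 0.0)
    best = None
    for a0 in np.linspace(lag[0], lag[-1], 8):
        x0 = [min(nugget0, sill0), max(sill0 - nugget0, 0.1 * sill0), max(a0, 1.0)]
        try:
            res = least_squares(
                lambda p: w * (circular_semivariance(lag, *np.abs(p)) - gamma),
                # ranges beyond the observed lags are not identifiable
                x0, bounds=([0, 0, 1e-6], [np.inf, np.inf, 1.25 * lag[-1]]),
                x_scale=[max(sill0, 1e-6), max(sill0, 1e-6), lag[-1]])
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        raise DataError("circular variogram fit failed from every start")
    sse, (c0, c, a) = best
    # no resolvable structure: negligible partial sill, or a range inside
    # the first lag bin (pure nugget at every observable distance)
    no_structure = (c < structure_tol * max(c0 + c, 1e-12)) or (a <= lag[0])
    if no_structure:
        a = float(lag[0])
    return VariogramFit(float(c0), float(c), float(a), bins, sse, no_structure)


# ---------------------------------------------------------------------------
# optimal-h estimation
# ---------------------------------------------------------------------------


@dataclass
class BestHEstimate:
    """The variogram-range estimate of the optimal exclusion radius."""

    h_km: float
    fitted_range_km: float
    variogram: VariogramFit
    no_spatial_structure: bool


def estimate_best_h(cal: CalibrationSet, response: str, h_step: float = 100.0,
                    h_max: float = 1500.0, n_bins: int = 15,
                    max_lag_km: float | None = None,
                    seed: int = 0) -> BestHEstimate:
    """Estimate the optimal h as the variogram range of WA leave-one-out residuals.

    A weighted-averaging model (monotonic deshrinking, tolerance
    down-weighting, square-root transform) is cross-validated leave-one-out;
    a circular variogram is fitted to the spatial structure of its residuals
    and the fitted range is rounded up to the h-grid granularity.  Pure
    nugget residuals (no spatial structure) collapse the estimate to the
    smallest grid value.
    """
    wa = MethodSpec("WA")
    loo = run_hblock_cv(cal, wa, response, h=0.0, seed=seed)
    resid = loo.sites.residual.to_numpy(float)
    fit = fit_circular_variogram(
        empirical_variogram(cal.coords(), resid, n_bins=n_bins,
                            max_lag_km=max_lag_km))
    if fit.no_structure:
        return BestHEstimate(0.0, fit.range_km, fit, True)
    h = min(math.ceil(fit.range_km / h_step) * h_step, h_max)
    return BestHEstimate(float(h), fit.range_km, fit, False)
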