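"""The eight pollen-climate calibration methods behind one fit/predict contract.

Three classical transfer-function methods are implemented in full:

* **MAT** -- modern analogue technique: k-nearest-neighbour prediction in
  assemblage space under the squared-chord dissimilarity, inverse-distance
  weighted mean of the k closest analogues.
* **WA** -- weighted averaging with tolerance down-weighting and a choice of
  inverse, classical or monotonic (isotonic) deshrinking, on square-root
  transformed percentages.
* **WAPLS** -- weighted averaging partial least squares: the iterative
  weighted component extraction with orthogonalization, followed by an
  ordinary least-squares regression of the response on the component scores.

Five machine-learning methods (RF, ETREES, BRT, NNET, ELM) are thin adapters
over standard regression backends, parameterized as in the source
methodology: RF = 100-tree random forest; ETREES = extremely randomized
trees; BRT = squared-error gradient boosting (learning rate 0.025, depth-4
trees, bag fraction 0.5, tree count <= 3000 chosen by internal 5-fold CV);
NNET = single sigmoid hidden layer with linear output; ELM = extreme
learning machine, mean of 5 networks with rectified-linear hidden units and
least-squares output weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.random import SeedSequence

from .data import DataError, MISSING, TaxonTable, sqrt_transform

METHOD_CODES = ("MAT", "WA", "WAPLS", "RF", "ETREES", "BRT", "NNET", "ELM")

#: Default hyperparameters per method (the standard parameterization).
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "MAT": {"k": 5},
    "WA": {"deshrinking": "monotonic", "tolerance_dw": True},
    "WAPLS": {"n_components": 3},
    "RF": {"n_trees": 100},
    "ETREES": {"n_trees": 100, "n_random_cuts": 5},
    "BRT": {"max_trees": 3000, "learning_rate": 0.025, "tree_depth": 4,
            "bag_fraction": 0.5, "cv_folds": 5},
    # hidden-layer sizes are dataset-specific and must be configured
    "NNET": {"n_hidden": None},
    "ELM": {"n_hidden": None, "n_networks": 5},
}


@dataclass
class MethodSpec:
    """A calibration method choice: code, hyperparameters, seed."""

    code: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.code not in METHOD_CODES:
            raise DataError(f"unknown method code {self.code!r}; "
                            f"choose from {METHOD_CODES}")
        merged = dict(DEFAULT_PARAMS[self.code])
        unknown = set(self.params) - set(merged)
        if unknown:
            raise DataError(f"{self.code}: unknown parameter(s) {sorted(unknown)}")
        merged.update(self.params)
        self.params = merged
        self._validate()

    def _validate(self) -> None:
        p = self.params
        if self.code == "MAT" and (not isinstance(p["k"], int) or p["k"] < 1):
            raise DataError("MAT requires integer k >= 1")
        if self.code == "WA":
            if p["deshrinking"] not in ("inverse", "classical", "monotonic"):
                raise DataError(f"unknown deshrinking {p['deshrinking']!r}")
        if self.code == "WAPLS" and (not isinstance(p["n_components"], int)
                                     or p["n_components"] < 1):
            raise DataError("WAPLS requires integer n_components >= 1")
        if self.code == "ELM" and p["n_networks"] < 1:
            raise DataError("ELM requires n_networks >= 1")

    def with_seed(self, seed: int | None) -> "MethodSpec":
        return MethodSpec(self.code, dict(self.params), seed)

    def min_train_size(self) -> int:
        """Smallest admissible training partition for this method."""
        floor = 10
        if self.code == "MAT":
            return max(self.params["k"], floor)
        if self.code == "WAPLS":
            return max(self.params["n_components"] + 1, floor)
        return floor


def table2_defaults(nnet_hidden: int | None = None,
                    elm_hidden: int | None = None,
                    seed: int | None = None) -> list[MethodSpec]:
    """The full eight-method roster with default parameterization.

    Hidden-layer sizes for NNET/ELM are dataset-specific and must be given
    explicitly before those two methods can be fitted.
    """
    specs = []
    for code in METHOD_CODES:
        params: dict[str, Any] = {}
        if code == "NNET" and nnet_hidden is not None:
            params["n_hidden"] = nnet_hidden
        if code == "ELM" and elm_hidden is not None:
            params["n_hidden"] = elm_hidden
        specs.append(MethodSpec(code, params, seed))
    return specs


# ---------------------------------------------------------------------------
# squared-chord dissimilarity
# ---------------------------------------------------------------------------


def sq_chord(p: np.ndarray, q: np.ndarray) -> float:
    """Squared chord distance sum_k (sqrt(p_k) - sqrt(q_k))^2 in [0, 2].

    ``p`` and ``q`` are proportion vectors (non-negative, summing to 1).
    """
    p, q = np.asarray(p, float), np.asarray(q, float)
    if p.shape != q.shape:
        raise DataError(f"length mismatch: {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise DataError("proportions must be non-negative")
    return float(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def sq_chord_matrix(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Pairwise squared-chord distances between rows of two proportion matrices."""
    sp, sq = np.sqrt(np.asarray(P, float)), np.sqrt(np.asarray(Q, float))
    # ||a-b||^2 = ||a||^2 + ||b||^2 - 2 a.b  on the sqrt-scale
    d = (np.sum(sp**2, axis=1)[:, None] + np.sum(sq**2, axis=1)[None, :]
         - 2.0 * sp @ sq.T)
    return np.maximum(d, 0.0)


def _as_proportions(X: np.ndarray) -> np.ndarray:
    """Percent rows -> proportion rows; zero-sum rows propagate as NaN."""
    X = np.asarray(X, float)
    s = X.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(s > 0, X / s, np.nan)
    return P


# ---------------------------------------------------------------------------
# fitted-model contract
# ---------------------------------------------------------------------------


class FittedModel:
    """Base class: a fitted calibration method bound to an ordered taxon list."""

    def __init__(self, spec: MethodSpec, taxon_names: list[str],
                 train_range: tuple[float, float]):
        self.spec = spec
        self.taxon_names = list(taxon_names)
        self.train_range = train_range

    def _check(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = np.atleast_2d(np.asarray(Xnew, float))
        if Xnew.shape[1] != len(self.taxon_names):
            raise DataError(f"{self.spec.code}: expected {len(self.taxon_names)} "
                            f"taxon columns, got {Xnew.shape[1]}")
        return Xnew

    def predict(self, Xnew: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _names(taxon_names, X) -> list[str]:
    return list(taxon_names) if taxon_names is not None else [
        f"taxon_{j}" for j in range(np.asarray(X).shape[1])]


# ---------------------------------------------------------------------------
# MAT
# ---------------------------------------------------------------------------


class MATModel(FittedModel):
    """Modern analogue technique: stored training assemblages and responses."""

    def __init__(self, spec, taxon_names, P_train, y):
        super().__init__(spec, taxon_names, (float(np.min(y)), float(np.max(y))))
        self.P_train = P_train
        self.y = y

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        return self.predict_with_analog(Xnew)[0]

    def predict_with_analog(self, Xnew: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictions and the per-sample minimum squared-chord distance."""
        Xnew = self._check(Xnew)
        Pnew = _as_proportions(Xnew)
        k = self.spec.params["k"]
        n = len(self.y)
        if k > n:
            raise DataError(f"MAT: k={k} exceeds {n} training samples")
        pred = np.full(len(Pnew), MISSING)
        mind = np.full(len(Pnew), MISSING)
        for i, p in enumerate(Pnew):
            if not np.all(np.isfinite(p)):
                continue
            d = sq_chord_matrix(p[None, :], self.P_train)[0]
            order = np.argsort(d, kind="stable")[:k]  # ties: training-row order
            dk, yk = d[order], self.y[order]
            zero = dk < 1e-12
            if np.any(zero):
                pred[i] = float(np.mean(yk[zero]))
            else:
                w = 1.0 / dk
                pred[i] = float(np.sum(w * yk) / np.sum(w))
            mind[i] = float(dk[0])
        return pred, mind


def fit_mat(X: np.ndarray, y: np.ndarray, k: int = 5,
            taxon_names: list[str] | None = None) -> MATModel:
    """Fit MAT: store training proportions and responses (no free parameters)."""
    X, y = np.asarray(X, float), np.asarray(y, float)
    spec = MethodSpec("MAT", {"k": int(k)})
    if X.shape[0] != len(y):
        raise DataError("X rows and y length differ")
    if k > X.shape[0]:
        raise DataError(f"MAT: k={k} exceeds {X.shape[0]} training samples")
    P = _as_proportions(X)
    if np.any(~np.isfinite(P)):
        raise DataError("a training sample has zero total abundance")
    return MATModel(spec, _names(taxon_names, X), P, y.copy())


def predict_mat(model: MATModel, Xnew: np.ndarray) -> np.ndarray:
    return model.predict(Xnew)


# ---------------------------------------------------------------------------
# WA
# ---------------------------------------------------------------------------


class _MonotonicMap:
    """Isotonic (PAV) regression map with linear interpolation between knots
    and end-segment-slope linear extrapolation beyond the fitted range."""

    def __init__(self, r: np.ndarray, y: np.ndarray):
        from sklearn.isotonic import IsotonicRegression
        ir = IsotonicRegression(increasing=True, out_of_bounds="clip")
        ir.fit(r, y)
        self.xk = np.asarray(ir.X_thresholds_, float)
        self.yk = np.asarray(ir.y_thresholds_, float)

    def _end_slope(self, lo: bool) -> float:
        xs, ys = self.xk, self.yk
        if len(xs) < 2:
            return 0.0
        if lo:
            return (ys[1] - ys[0]) / (xs[1] - xs[0])
        return (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, float)
        out = np.interp(r, self.xk, self.yk)
        below, above = r < self.xk[0], r > self.xk[-1]
        out[below] = self.yk[0] + self._end_slope(True) * (r[below] - self.xk[0])
        out[above] = self.yk[-1] + self._end_slope(False) * (r[above] - self.xk[-1])
        return out


class WAModel(FittedModel):
    """Weighted averaging with taxon optima, tolerances and a deshrinking map."""

    def __init__(self, spec, taxon_names, optima, tolerances, deshrink, keep_idx,
                 train_range):
        super().__init__(spec, taxon_names, train_range)
        self.optima = optima            # over kept taxa
        self.tolerances = tolerances
        self._deshrink = deshrink       # callable raw -> response
        self._keep = keep_idx           # indices of kept taxa in taxon_names

    def raw_scores(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = self._check(Xnew)
        Y = np.sqrt(np.maximum(Xnew[:, self._keep], 0.0))
        if np.any(Xnew < 0):
            raise DataError("negative abundances")
        if self.spec.params["tolerance_dw"]:
            w = 1.0 / self.tolerances**2
            num = Y @ (self.optima * w)
            den = Y @ w
        else:
            num = Y @ self.optima
            den = Y.sum(axis=1)
        out = np.full(len(Y), MISSING)
        ok = den > 0
        if not np.all(ok):
            warnings.warn("sample(s) share no taxa with the model; returning NaN")
        out[ok] = num[ok] / den[ok]
        return out

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        r = self.raw_scores(Xnew)
        out = np.full_like(r, MISSING)
        ok = np.isfinite(r)
        out[ok] = self._deshrink(r[ok])
        return out


def fit_wa(X: np.ndarray, y: np.ndarray, deshrinking: str = "monotonic",
           tolerance_dw: bool = True, taxon_names: list[str] | None = None,
           site_ids: list[str] | None = None) -> WAModel:
    """Fit weighted averaging on square-root transformed percentages.

    Taxon optimum: abundance-weighted mean of the response,
    ``u_k = sum_i Y_ik y_i / sum_i Y_ik``; tolerance: the matching weighted
    standard deviation, floored at max(1% of the response range, the
    smallest positive tolerance) so single-occurrence taxa cannot blow up
    the tolerance down-weighting.  Raw scores are deshrunk by the chosen
    rule (inverse/classical OLS, or monotonic: isotonic regression with
    end-slope extrapolation).
    """
    spec = MethodSpec("WA", {"deshrinking": deshrinking, "tolerance_dw": tolerance_dw})
    X, y = np.asarray(X, float), np.asarray(y, float)
    names = _names(taxon_names, X)
    table = TaxonTable(site_ids or [f"s{i}" for i in range(len(X))], names, X,
                       "percent")
    Yfull = sqrt_transform(table)
    rowsum = Yfull.sum(axis=1)
    if np.any(rowsum <= 0):
        bad = table.site_ids[int(np.argmax(rowsum <= 0))]
        raise DataError(f"site {bad!r} has all-zero taxa")
    keep = np.where(Yfull.sum(axis=0) > 0)[0]
    if len(keep) < Yfull.shape[1]:
        warnings.warn(f"dropping {Yfull.shape[1] - len(keep)} zero-sum taxon column(s)")
    Y = Yfull[:, keep]
    K = Y.sum(axis=0)
    u = (Y.T @ y) / K
    t = np.sqrt(np.maximum((Y * (y[:, None] - u[None, :]) ** 2).sum(axis=0) / K, 0.0))
    positive = t[t > 0]
    floor = 0.01 * (np.max(y) - np.min(y))
    if len(positive):
        floor = max(floor, float(np.min(positive)))
    if floor <= 0:
        floor = 1.0  # degenerate constant response
    t = np.maximum(t, floor)

    model = WAModel(spec, names, u, t, lambda r: r, keep,
                    (float(np.min(y)), float(np.max(y))))
    r = model.raw_scores(X)
    if deshrinking == "inverse":
        b, a = np.polyfit(r, y, 1)
        model._deshrink = lambda s, a=a, b=b: a + b * s
    elif deshrinking == "classical":
        b, a = np.polyfit(y, r, 1)
        model._deshrink = lambda s, a=a, b=b: (s - a) / b
    else:
        model._deshrink = _MonotonicMap(r, y)
    return model


def predict_wa(model: WAModel, Xnew: np.ndarray) -> np.ndarray:
    return model.predict(Xnew)


# ---------------------------------------------------------------------------
# WAPLS
# ---------------------------------------------------------------------------


class WAPLSModel(FittedModel):
    """WA-PLS: stored component weights plus an OLS on component scores."""

    def __init__(self, spec, taxon_names, keep_idx, components, beta, train_range):
        super().__init__(spec, taxon_names, train_range)
        self._keep = keep_idx
        # components: list of (u_vector, orth_coefs, norm)
        self.components = components
        self.beta = beta  # (intercept, b_1..b_A)

    def scores(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = self._check(Xnew)
        Y = np.sqrt(np.maximum(Xnew[:, self._keep], 0.0))
        R = Y.sum(axis=1)
        ok = R > 0
        T = np.full((len(Y), len(self.components)), np.nan)
        for a, (u, orth, norm) in enumerate(self.components):
            r = np.full(len(Y), np.nan)
            r[ok] = (Y[ok] @ u) / R[ok]
            for p, c in enumerate(orth):
                r = r - c * T[:, p]
            T[:, a] = r / norm
        return T

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        T = self.scores(Xnew)
        out = self.beta[0] + T @ self.beta[1:]
        return np.asarray(out, float)


def fit_wapls(X: np.ndarray, y: np.ndarray, n_components: int = 3,
              taxon_names: list[str] | None = None) -> WAPLSModel:
    """Fit WA-PLS on square-root transformed percentages.

    Components are extracted by the standard update cycle -- weighted
    averaging of the current residual into taxon scores, projection back to
    site scores, orthogonalization against earlier components under the
    site-total weights -- and the response is regressed on all component
    scores by ordinary least squares; its residual seeds the next component.
    With one component this reproduces WA with inverse deshrinking (no
    tolerance down-weighting) exactly.
    """
    spec = MethodSpec("WAPLS", {"n_components": int(n_components)})
    X, y = np.asarray(X, float), np.asarray(y, float)
    n, m = X.shape
    if not (1 <= n_components < min(n, m) + 1):
        raise DataError(f"need 1 <= n_components < min(n_sites, n_taxa); "
                        f"got {n_components} with {n} sites, {m} taxa")
    names = _names(taxon_names, X)
    Yfull = np.sqrt(np.maximum(X, 0.0))
    keep = np.where(Yfull.sum(axis=0) > 0)[0]
    Y = Yfull[:, keep]
    R = Y.sum(axis=1)
    if np.any(R <= 0):
        raise DataError("a site has all-zero taxa")
    K = Y.sum(axis=0)
    W = R / R.sum()
    ybar_w = float(W @ y)

    components: list[tuple[np.ndarray, list[float], float]] = []
    T = np.empty((n, 0))
    resid = y - ybar_w
    beta = np.array([ybar_w])
    for a in range(n_components):
        u = (Y.T @ resid) / K
        r = (Y @ u) / R
        orth: list[float] = []
        for p in range(T.shape[1]):
            c = float(np.sum(W * r * T[:, p]))  # T columns are W-orthonormal
            orth.append(c)
            r = r - c * T[:, p]
        norm = float(np.sqrt(np.sum(W * r**2)))
        if norm < 1e-10 * max(1.0, abs(ybar_w)):
            warnings.warn(f"WAPLS rank deficient: stopping at {a} component(s)")
            break
        r = r / norm
        components.append((u, orth, norm))
        T = np.column_stack([T, r])
        A = np.column_stack([np.ones(n), T])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
    if not components:
        raise DataError("WAPLS could not extract any component")
    return WAPLSModel(spec, names, keep, components, beta,
                      (float(np.min(y)), float(np.max(y))))


def predict_wapls(model: WAPLSModel, Xnew: np.ndarray) -> np.ndarray:
    return model.predict(Xnew)


# ---------------------------------------------------------------------------
# machine-learning adapters
# ---------------------------------------------------------------------------


def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = SeedSequence(seed if seed is not None else 0)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


class SklearnModel(FittedModel):
    """Adapter over a fitted scikit-learn regressor (RF/ETREES/BRT/NNET)."""

    def __init__(self, spec, taxon_names, backend, train_range,
                 x_scale: float = 1.0, y_loc: float = 0.0, y_scale: float = 1.0):
        super().__init__(spec, taxon_names, train_range)
        self.backend = backend
        self._x_scale, self._y_loc, self._y_scale = x_scale, y_loc, y_scale

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = self._check(Xnew) / self._x_scale
        return self._y_loc + self._y_scale * np.asarray(
            self.backend.predict(Xnew), float)


class ELMModel(FittedModel):
    """Extreme learning machine: mean of several random-hidden-layer networks.

    Each network draws hidden weights from Uniform(-1, 1), applies a
    rectified ('positive') linear activation and solves the output weights
    by least squares; the prediction is the mean over the networks.
    """

    def __init__(self, spec, taxon_names, networks, train_range, y_loc, y_scale):
        super().__init__(spec, taxon_names, train_range)
        self.networks = networks  # list of (W_hidden incl. bias row, beta_out)
        self._y_loc, self._y_scale = y_loc, y_scale

    @staticmethod
    def _hidden(Xp: np.ndarray, W: np.ndarray) -> np.ndarray:
        H = np.column_stack([np.ones(len(Xp)), Xp]) @ W
        return np.maximum(H, 0.0)

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xp = self._check(Xnew) / 100.0
        preds = []
        for W, beta in self.networks:
            H = self._hidden(Xp, W)
            preds.append(np.column_stack([np.ones(len(H)), H]) @ beta)
        return self._y_loc + self._y_scale * np.mean(preds, axis=0)


def _fit_brt(params: dict, X: np.ndarray, y: np.ndarray, seed: int | None):
    from sklearn.ensemble import GradientBoostingRegressor
    from sklearn.model_selection import KFold
    seeds = _child_seeds(seed, 2)
    kwargs = dict(loss="squared_error", learning_rate=params["learning_rate"],
                  max_depth=params["tree_depth"], subsample=params["bag_fraction"],
                  random_state=seeds[0])
    max_trees, folds = params["max_trees"], params["cv_folds"]
    n_best = max_trees
    if folds and folds > 1 and len(y) >= 2 * folds:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seeds[1])
        sse = np.zeros(max_trees)
        for tr, va in kf.split(X):
            gbm = GradientBoostingRegressor(n_estimators=max_trees, **kwargs)
            gbm.fit(X[tr], y[tr])
            for stage, pred in enumerate(gbm.staged_predict(X[va])):
                sse[stage] += float(np.sum((pred - y[va]) ** 2))
        n_best = int(np.argmin(sse)) + 1
    final = GradientBoostingRegressor(n_estimators=n_best, **kwargs)
    final.fit(X, y)
    return final


def fit_ml(spec: MethodSpec, X: np.ndarray, y: np.ndarray,
           taxon_names: list[str] | None = None) -> FittedModel:
    """Fit one of the machine-learning methods (RF, ETREES, BRT, NNET, ELM).

    Inputs are raw percentages (the square-root transform belongs to the
    weighted-averaging family only); NNET/ELM predictors are divided by 100
    and their response is standardized internally for optimizer stability.
    All stochastic methods are fully determined by ``spec.seed``.
    """
    if spec.code not in ("RF", "ETREES", "BRT", "NNET", "ELM"):
        raise DataError(f"fit_ml does not handle {spec.code!r}")
    X, y = np.asarray(X, float), np.asarray(y, float)
    names = _names(taxon_names, X)
    rng_seed = _child_seeds(spec.seed, 1)[0]
    tr = (float(np.min(y)), float(np.max(y)))

    if spec.code == "RF":
        from sklearn.ensemble import RandomForestRegressor
        backend = RandomForestRegressor(n_estimators=spec.params["n_trees"],
                                        random_state=rng_seed)
        backend.fit(X, y)
        return SklearnModel(spec, names, backend, tr)

    if spec.code == "ETREES":
        from sklearn.ensemble import ExtraTreesRegressor
        backend = ExtraTreesRegressor(n_estimators=spec.params["n_trees"],
                                      random_state=rng_seed)
        backend.fit(X, y)
        return SklearnModel(spec, names, backend, tr)

    if spec.code == "BRT":
        backend = _fit_brt(spec.params, X, y, spec.seed)
        return SklearnModel(spec, names, backend, tr)

    n_hidden = spec.params["n_hidden"]
    if n_hidden is None:
        raise DataError(f"{spec.code}: the hidden-layer size is dataset-specific "
                        "and must be configured (params['n_hidden'])")

    y_loc, y_scale = float(np.mean(y)), float(np.std(y))
    if y_scale == 0.0:
        # degenerate constant response: nothing to learn
        from sklearn.dummy import DummyRegressor
        backend = DummyRegressor(strategy="constant", constant=y_loc)
        backend.fit(X, y)
        return SklearnModel(spec, names, backend, tr)
    ys = (y - y_loc) / y_scale

    if spec.code == "NNET":
        from sklearn.neural_network import MLPRegressor
        backend = MLPRegressor(hidden_layer_sizes=(n_hidden,),
                               activation="logistic", solver="lbfgs",
                               alpha=0.0, max_iter=500, tol=1e-8,
                               random_state=rng_seed)
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning
            warnings.simplefilter("ignore", ConvergenceWarning)
            backend.fit(X / 100.0, ys)
        return SklearnModel(spec, names, backend, tr,
                            x_scale=100.0, y_loc=y_loc, y_scale=y_scale)

    # ELM
    rng = np.random.default_rng(rng_seed)
    Xp = X / 100.0
    networks = []
    for _ in range(spec.params["n_networks"]):
        W = rng.uniform(-1.0, 1.0, size=(Xp.shape[1] + 1, n_hidden))
        H = ELMModel._hidden(Xp, W)
        A = np.column_stack([np.ones(len(H)), H])
        beta, *_ = np.linalg.lstsq(A, ys, rcond=None)
        networks.append((W, beta))
    return ELMModel(spec, names, networks, tr, y_loc, y_scale)


def fit_model(spec: MethodSpec, X: np.ndarray, y: np.ndarray,
              taxon_names: list[str] | None = None,
              site_ids: list[str] | None = None) -> FittedModel:
    """Dispatch on ``spec.code`` to the appropriate fit routine."""
    if spec.code == "MAT":
        return fit_mat(X, y, k=spec.params["k"], taxon_names=taxon_names)
    if spec.code == "WA":
        return fit_wa(X, y, deshrinking=spec.params["deshrinking"],
                      tolerance_dw=spec.params["tolerance_dw"],
                      taxon_names=taxon_names, site_ids=site_ids)
    if spec.code == "WAPLS":
        n_comp = min(spec.params["n_components"],
                     min(np.asarray(X).shape) - 1)
        if n_comp < spec.params["n_components"]:
            warnings.warn(f"WAPLS: reducing to {n_comp} feasible component(s)")
        return fit_wapls(X, y, n_components=max(n_comp, 1), taxon_names=taxon_names)
    return fit_ml(spec, X, y, taxon_names=taxon_names)


def relative_influence(model: FittedModel) -> "pd.Series":
    """Per-taxon contribution (%) of a fitted BRT model, sorted descending.

    Contributions are the reduction-in-squared-error attributable to splits
    on each taxon, normalized to sum to 100.
    """
    import pandas as pd
    if model.spec.code != "BRT":
        raise DataError(f"relative influence is defined for BRT, not "
                        f"{model.spec.code}")
    imp = np.asarray(model.backend.feature_importances_, float)
    total = imp.sum()
    pct = 100.0 * imp / total if total > 0 else np.full_like(imp, 100.0 / len(imp))
    return pd.Series(pct, index=model.taxon_names).sort_values(ascending=False)
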