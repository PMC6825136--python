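"""Reconstruction-variable selection: correlation screening and R2 ranking.

The workflow screens a candidate pool of climate variables down to a subset
whose pairwise absolute Spearman correlations stay below a threshold
(default 0.7), then ranks the survivors by how well an ensemble of
calibration methods explains each of them from the species data
(cross-validated mean R2).  The final primary/secondary designation remains
an ecological judgment and is deliberately not automated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import CalibrationSet, DataError
from .hblock import r_squared, run_hblock_cv
from .methods import MethodSpec, fit_model, table2_defaults


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman correlations among climate variables."""

    variables: list[str]
    rho: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.variables, columns=self.variables)


def spearman_matrix(climate: pd.DataFrame) -> CorrelationMatrix:
    """Spearman correlation matrix of a site x variable climate table.

    Ties receive average ranks.  A constant variable has no rank ordering
    and is rejected by name.
    """
    if climate.shape[0] < 3 or climate.shape[1] < 2:
        raise DataError("need >= 3 sites and >= 2 variables")
    for v in climate.columns:
        if climate[v].nunique() <= 1:
            raise DataError(f"variable {v!r} is constant")
    rho = spearmanr(climate.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    return CorrelationMatrix(list(climate.columns), rho, len(climate))


def max_uncorrelated_subset(cm: CorrelationMatrix, threshold: float = 0.7,
                            keep: list[str] | None = None,
                            exact_limit: int = 25) -> list[str]:
    """A maximum-cardinality subset with all pairwise |rho| < threshold.

    Exact search (branch and bound over the conflict graph) up to
    ``exact_limit`` variables, greedy max-degree removal beyond that.  Ties
    are broken deterministically by variable-name order; ``keep`` forces
    named variables into the subset (an error if they conflict mutually).
    """
    names = cm.variables
    conflict = np.abs(cm.rho) >= threshold
    np.fill_diagonal(conflict, False)
    keep = list(keep or [])
    for v in keep:
        if v not in names:
            raise DataError(f"forced variable {v!r} not in the matrix")
    kidx = [names.index(v) for v in keep]
    for a, b in itertools.combinations(kidx, 2):
        if conflict[a, b]:
            raise DataError(f"forced variables {names[a]!r} and {names[b]!r} "
                            f"are correlated at |rho| >= {threshold}")
    # candidates compatible with every forced variable
    cand = [j for j in range(len(names))
            if j not in kidx and not any(conflict[j, k] for k in kidx)]

    if len(names) <= exact_limit:
        best: list[int] = []

        def bnb(chosen: list[int], remaining: list[int]) -> None:
            nonlocal best
            if len(chosen) + len(remaining) <= len(best):
                return  # bound: cannot beat the incumbent
            if not remaining:
                if len(chosen) > len(best):
                    best = list(chosen)
                return
            j, rest = remaining[0], remaining[1:]
            bnb(chosen + [j], [r for r in rest if not conflict[j, r]])
            bnb(chosen, rest)

        bnb(sorted(kidx), sorted(cand))
        chosen = best
    else:
        chosen = sorted(kidx) + sorted(cand)
        while True:
            sub = np.ix_(chosen, chosen)
            deg = conflict[sub].sum(axis=1)
            if deg.max(initial=0) == 0:
                break
            # drop the most-conflicted non-forced variable (last by name on ties)
            order = sorted(range(len(chosen)),
                           key=lambda i: (deg[i], names[chosen[i]]))
            drop = next(i for i in reversed(order) if chosen[i] not in kidx)
            chosen.pop(drop)
    subset = sorted(names[j] for j in chosen)
    sub_idx = [names.index(v) for v in subset]
    assert not conflict[np.ix_(sub_idx, sub_idx)].any()
    return subset


@dataclass
class VariableRanking:
    """Per-variable cross-validated R2, per model and as the ensemble mean."""

    table: pd.DataFrame  # index: variable; columns: per-model R2 + mean_r2

    @property
    def ranked_variables(self) -> list[str]:
        return list(self.table.index)


def _cv_r2(cal: CalibrationSet, spec: MethodSpec, variable: str,
           cv: str | int, seed: int) -> float:
    if cv == "loo":
        res = run_hblock_cv(cal, spec, variable, h=0.0, seed=seed)
        return res.summary["r2"]
    from sklearn.model_selection import KFold
    y = cal.response(variable)
    X = cal.taxa.values
    pred = np.full(len(y), np.nan)
    kf = KFold(n_splits=int(cv), shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(kf.split(X)):
        model = fit_model(spec.with_seed(seed + f), X[tr], y[tr],
                          taxon_names=cal.taxa.taxon_names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred[te] = model.predict(X[te])
    ok = np.isfinite(pred)
    return r_squared(y[ok], pred[ok])


def ensemble_r2_ranking(cal: CalibrationSet, variables: list[str],
                        model_set: list[MethodSpec] | None = None,
                        cv: str | int = "loo", seed: int = 0
                        ) -> VariableRanking:
    """Rank climate variables by mean cross-validated R2 across an ensemble.

    The default model set is the full eight-method roster, which requires
    dataset-specific hidden-layer sizes for the two network methods; pass an
    explicit ``model_set`` to use a smaller ensemble.  Ties in mean R2 are
    broken by variable name.
    """
    if model_set is None:
        model_set = table2_defaults()
        for spec in model_set:
            if spec.code in ("NNET", "ELM") and spec.params["n_hidden"] is None:
                raise DataError(
                    "the default ensemble includes NNET/ELM, whose hidden-layer "
                    "sizes are dataset-specific; configure them or pass model_set")
    rows = {}
    for v in variables:
        rows[v] = {spec.code: _cv_r2(cal, spec, v, cv, seed)
                   for spec in model_set}
    table = pd.DataFrame(rows).T
    table["mean_r2"] = table.mean(axis=1)
    table = table.sort_values(["mean_r2"], ascending=False)
    table = table.iloc[np.lexsort((table.index, -table.mean_r2.to_numpy()))]
    return VariableRanking(table)
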