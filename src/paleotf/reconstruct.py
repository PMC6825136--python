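"""Fossil palaeoclimate reconstruction with multiple calibration methods."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (AlignmentReport, CalibrationSet, DataError, FossilSequence,
                   MISSING, align_taxa)
from .methods import MethodSpec, fit_model, sq_chord_matrix


@dataclass
class ReconstructionTable:
    """Per-sample reconstructions: ages, one column per method, diagnostics."""

    table: pd.DataFrame           # age_ka, <method columns>, best_analog
    methods: list[str]
    alignment: AlignmentReport

    def values(self, method: str) -> np.ndarray:
        return self.table[method].to_numpy(float)


def reconstruct(fossil: FossilSequence, cal: CalibrationSet,
                specs: list[MethodSpec], response: str) -> ReconstructionTable:
    """Apply calibration models to a fossil sequence.

    Taxa are intersected (both sides re-normalized to 100), each model is
    fitted on the full aligned calibration set and applied to every fossil
    sample.  The per-sample minimum squared-chord distance to the
    calibration assemblages is recorded as an analogue-quality diagnostic,
    and a multi-method median and range are appended when two or more
    methods are requested.
    """
    cal_m, fos_m, report = align_taxa(cal, fossil)
    y = cal.response(response)
    analog = sq_chord_matrix(fos_m / 100.0, cal_m / 100.0).min(axis=1)

    data: dict[str, np.ndarray] = {"age_ka": fossil.ages}
    codes = []
    for spec in specs:
        if spec.code in codes:
            raise DataError(f"duplicate method {spec.code} in reconstruction")
        codes.append(spec.code)
        model = fit_model(spec, cal_m, y, taxon_names=report.shared_taxa)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            data[spec.code] = model.predict(fos_m)
    df = pd.DataFrame(data)
    df["best_analog"] = analog
    rt = ReconstructionTable(df, codes, report)
    if len(codes) >= 2:
        summary = multi_method_summary(rt)
        for col in summary.columns:
            df[col] = summary[col].to_numpy()
    return rt


def multi_method_summary(rt: ReconstructionTable) -> pd.DataFrame:
    """Row-wise median, min, max and inter-method range, ignoring missing."""
    if len(rt.methods) < 2:
        raise DataError("need >= 2 method columns to summarize")
    vals = rt.table[rt.methods].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(vals, axis=1)
        lo = np.nanmin(vals, axis=1)
        hi = np.nanmax(vals, axis=1)
    return pd.DataFrame({"median": med, "min": lo, "max": hi,
                         "range": hi - lo})
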