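"""Covariate design-matrix construction shared by all model-fitting modules.

Continuous covariates are z-scored; binary (0/1) covariates are left as is.
Missing values are mean-imputed and accompanied by a 0/1 missingness-indicator
column, mirroring the convention of trial analyses that keep incomplete
patients in the model rather than dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignInfo", "build_design", "apply_design"]


@dataclass
class DesignInfo:
    input_names: list[str]
    names: list[str]              # output column names, incl. missingness indicators
    center: np.ndarray            # per output column
    scale: np.ndarray             # per output column (1.0 for binary / indicators)
    indicator_for: dict = field(default_factory=dict)  # output name -> source covariate


def _is_binary(values: np.ndarray) -> bool:
    vals = np.unique(values[~np.isnan(values)])
    return vals.size <= 2 and np.isin(vals, [0.0, 1.0]).all()


def build_design(df: pd.DataFrame, names: list[str]) -> tuple[np.ndarray, DesignInfo]:
    """Fit standardization/imputation on ``df[names]`` and return the design matrix."""
    cols, out_names, centers, scales = [], [], [], []
    indicator_for = {}
    for name in names:
        x = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        miss = np.isnan(x)
        if miss.all():
            raise ValueError(f"covariate '{name}' has no observed values")
        mean = float(np.nanmean(x))
        filled = np.where(miss, mean, x)
        if _is_binary(x):
            center, scale = 0.0, 1.0
        else:
            center = mean
            sd = float(np.nanstd(x, ddof=1)) if np.sum(~miss) > 1 else 1.0
            scale = sd if sd > 0 else 1.0
        cols.append((filled - center) / scale)
        out_names.append(name)
        centers.append(center)
        scales.append(scale)
        if miss.any():
            ind = name + "_missing"
            cols.append(miss.astype(float))
            out_names.append(ind)
            centers.append(0.0)
            scales.append(1.0)
            indicator_for[ind] = name
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    info = DesignInfo(list(names), out_names, np.asarray(centers), np.asarray(scales),
                      indicator_for)
    # impute value memo (training mean) stored via center/scale on the source column
    info._impute = {n: float(np.nanmean(pd.to_numeric(df[n], errors="coerce")))
                    for n in names}
    return X, info


def apply_design(df: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    """Apply frozen standardization/imputation parameters to a new cohort table."""
    missing = [n for n in info.input_names if n not in df.columns]
    if missing:
        raise ValueError(f"cohort is missing covariate columns: {missing}")
    cols = {}
    for name in info.input_names:
        x = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        miss = np.isnan(x)
        cols[name] = np.where(miss, info._impute[name], x)
        cols[name + "_missing"] = miss.astype(float)
    out = []
    for j, name in enumerate(info.names):
        src = cols.get(name)
        if src is None:  # indicator for a column with no missing data at training time
            src = np.zeros(len(df))
        out.append((src - info.center[j]) / info.scale[j])
    return np.column_stack(out) if out else np.empty((len(df), 0))
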