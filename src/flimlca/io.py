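"""File formats: cohort TSV round-trip, lifetime-image TIFFs, JSON reports.

Cohorts are tab-separated with the header
``patient_id  time  event  [true_class]  <covariate...>``; missing covariate
values are empty fields and stay missing on read.  Lifetime images are
single-channel 32-bit float TIFFs in nanoseconds; masks are 8-bit 0/255.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortValidationError

__all__ = ["read_cohort", "write_cohort", "read_lifetime_pair",
           "write_lifetime_pair", "write_report", "package_version"]


def package_version() -> str:
    from . import __version__
    return __version__


def read_cohort(path) -> Cohort:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str},
                     float_precision="round_trip")
    for col in ("patient_id", "time", "event"):
        if col not in df.columns:
            raise CohortValidationError(
                f"{path.name}: missing mandatory column '{col}'")
    t = pd.to_numeric(df["time"], errors="coerce")
    if t.isna().any():
        row = int(df.index[t.isna()][0])
        raise CohortValidationError(
            f"{path.name}: non-numeric 'time' at line {row + 2}")
    return Cohort(df, name=path.stem)


def write_cohort(cohort: Cohort, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(path, sep="\t", index=False, na_rep="")


def write_lifetime_pair(pair, directory, stem: str) -> dict:
    """Write D/DA/intensity as float32 TIFF and mask/regions as uint TIFF."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for suffix, data in (
        ("tau_d", np.asarray(pair.tau_d_map, dtype=np.float32)),
        ("tau_da", np.asarray(pair.tau_da_map, dtype=np.float32)),
        ("intensity", np.asarray(pair.donor_intensity_map, dtype=np.float32)),
        ("mask", (np.asarray(pair.mask, dtype=np.uint8) * 255)),
        ("regions", np.asarray(pair.region_labels, dtype=np.uint16)),
    ):
        p = directory / f"{stem}_{suffix}.tif"
        tifffile.imwrite(p, data)
        paths[suffix] = str(p)
    return paths


def read_lifetime_pair(directory, stem: str):
    import tifffile

    from .flim import LifetimeImagePair

    directory = Path(directory)
    load = lambda sfx: tifffile.imread(directory / f"{stem}_{sfx}.tif")
    return LifetimeImagePair(
        tau_d_map=load("tau_d"), tau_da_map=load("tau_da"),
        donor_intensity_map=load("intensity"),
        mask=load("mask") > 0,
        region_labels=load("regions").astype(int))


def config_hash(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_report(payload: dict, path, seed: int | None = None,
                 config: dict | None = None) -> None:
    """Write a JSON artifact embedding provenance (config hash, seed, version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = dict(payload)
    out["_provenance"] = {
        "package_version": package_version(),
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    path.write_text(json.dumps(out, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
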