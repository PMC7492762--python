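"""FRET-efficiency quantification from matched donor / donor+acceptor
fluorescence-lifetime images.

The donor fluorophore's lifetime shortens when energy transfers to a nearby
acceptor, so for a tissue region the FRET efficiency is

    E = 1 - tau_DA / tau_D

where ``tau_D`` and ``tau_DA`` are the average donor lifetimes over the
region in the donor-only and donor-with-acceptor images.  E is computed from
the ratio of region-mean lifetimes (not the mean of pixel ratios), is kept
when negative (clamping would bias cohort-level summaries) and is flagged
instead.  Autofluorescence, whose lifetime falls outside the plausible donor
window, is removed by a lifetime filter before averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "LifetimeImagePair", "FretResult", "FilterReport",
    "estimate_lifetime", "filter_lifetimes", "fret_efficiency",
    "patient_fret_covariates",
    "UnidentifiableDecayError", "EmptyAfterFilterError",
    "DEFAULT_LIFETIME_WINDOW", "MIN_REGION_PIXELS",
]

DEFAULT_LIFETIME_WINDOW = (1.5, 4.0)   # ns, plausible donor lifetimes
MIN_REGION_PIXELS = 10


class UnidentifiableDecayError(ValueError):
    """Decay histogram carries no lifetime information (single occupied bin)."""


class EmptyAfterFilterError(ValueError):
    """Lifetime filter removed every masked pixel."""


@dataclass
class LifetimeImagePair:
    tau_d_map: np.ndarray          # ns
    tau_da_map: np.ndarray         # ns
    donor_intensity_map: np.ndarray
    mask: np.ndarray               # bool
    region_labels: np.ndarray      # int, 0 = background

    def __post_init__(self) -> None:
        shapes = {np.asarray(m).shape for m in
                  (self.tau_d_map, self.tau_da_map, self.donor_intensity_map,
                   self.mask, self.region_labels)}
        if len(shapes) != 1:
            raise ValueError(f"image maps have mismatched shapes: {shapes}")
        self.mask = np.asarray(self.mask, dtype=bool)
        self.region_labels = np.asarray(self.region_labels, dtype=int)
        m = self.mask
        if m.any() and ((np.asarray(self.tau_d_map)[m] <= 0).any()
                        or (np.asarray(self.tau_da_map)[m] <= 0).any()):
            raise ValueError("lifetimes must be positive inside the mask")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.region_labels)
        return ids[ids > 0]


@dataclass
class FilterReport:
    n_removed: int
    n_kept: int
    window: tuple


@dataclass
class FretResult:
    region_id: int
    mean_tau_d: float
    mean_tau_da: float
    fret_efficiency: float         # NaN when undefined
    fret_x_her3: float
    n_pixels_used: int
    n_pixels_filtered: int
    qc_flags: list = field(default_factory=list)


def estimate_lifetime(decay_histogram: np.ndarray, bin_width: float) -> float:
    """Maximum-likelihood monoexponential lifetime from a binned decay.

    The model is an exponential decay truncated to the observation window
    ``[0, n_bins * bin_width]`` and integrated over each bin.  Returns the
    lifetime in the same time units as ``bin_width``.  A perfectly flat
    histogram has its likelihood maximized in the infinite-lifetime limit:
    ``inf`` is returned with a warning.
    """
    counts = np.asarray(decay_histogram, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if counts.ndim != 1 or counts.size < 2:
        raise UnidentifiableDecayError("need at least 2 bins")
    if (counts < 0).any() or counts.sum() <= 0:
        raise ValueError("counts must be non-negative with positive total")
    if np.count_nonzero(counts) < 2:
        raise UnidentifiableDecayError(
            "all photons in a single bin: lifetime not identifiable")

    n_bins = counts.size
    edges = np.arange(n_bins + 1) * bin_width
    window = n_bins * bin_width

    def nll(log_tau: float) -> float:
        tau = math.exp(log_tau)
        cdf = 1.0 - np.exp(-edges / tau)
        p = np.diff(cdf) / cdf[-1]
        return -float(counts @ np.log(np.clip(p, 1e-300, None)))

    hi = math.log(1e4 * window)
    res = minimize_scalar(nll, bounds=(math.log(1e-4 * window), hi),
                          method="bounded",
                          options={"xatol": 1e-12})
    tau = math.exp(res.x)
    if res.x > hi - 1e-3:
        warnings.warn("lifetime estimate did not converge (flat decay); "
                      "returning inf", RuntimeWarning, stacklevel=2)
        return math.inf
    return float(tau)


def filter_lifetimes(pair: LifetimeImagePair,
                     window: tuple = DEFAULT_LIFETIME_WINDOW
                     ) -> tuple[LifetimeImagePair, FilterReport]:
    """Clear the mask at pixels whose donor lifetime falls outside ``window``.

    This is the autofluorescence filter: contaminant fluorophores have
    lifetimes far from the donor's, so a plausibility window on the donor
    map removes them.  The DA map is untouched; only the mask shrinks.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy min < max")
    tau_d = np.asarray(pair.tau_d_map, dtype=float)
    keep = (tau_d >= lo) & (tau_d <= hi)
    new_mask = pair.mask & keep
    n_removed = int(pair.mask.sum() - new_mask.sum())
    if pair.mask.any() and not new_mask.any():
        raise EmptyAfterFilterError(
            f"lifetime window {window} ns removed every masked pixel")
    filtered = LifetimeImagePair(
        tau_d_map=pair.tau_d_map, tau_da_map=pair.tau_da_map,
        donor_intensity_map=pair.donor_intensity_map,
        mask=new_mask, region_labels=pair.region_labels)
    return filtered, FilterReport(n_removed=n_removed, n_kept=int(new_mask.sum()),
                                  window=(lo, hi))


def fret_efficiency(pair: LifetimeImagePair,
                    min_pixels: int = MIN_REGION_PIXELS) -> list[FretResult]:
    """Per-region FRET efficiency E = 1 - mean(tau_DA)/mean(tau_D).

    Regions whose surviving pixel count is below ``min_pixels`` get a
    LOW_PIXEL_COUNT flag and an undefined (NaN) efficiency; negative
    efficiencies are kept and flagged NEGATIVE_E.
    """
    ids = pair.region_ids
    if ids.size == 0:
        raise ValueError("no labelled regions in the image pair")
    results = []
    for rid in ids:
        region = pair.region_labels == rid
        used = region & pair.mask
        n_used = int(used.sum())
        n_filtered = int(region.sum()) - n_used
        flags: list[str] = []
        if n_used < min_pixels:
            flags.append("LOW_PIXEL_COUNT")
            results.append(FretResult(int(rid), math.nan, math.nan, math.nan,
                                      math.nan, n_used, n_filtered, flags))
            continue
        mean_d = float(np.mean(pair.tau_d_map[used]))
        mean_da = float(np.mean(pair.tau_da_map[used]))
        e = 1.0 - mean_da / mean_d
        if e < 0:
            flags.append("NEGATIVE_E")
        fxh = e * float(np.mean(pair.donor_intensity_map[used]))
        results.append(FretResult(int(rid), mean_d, mean_da, e, fxh,
                                  n_used, n_filtered, flags))
    return results


def patient_fret_covariates(results_by_patient: dict) -> pd.DataFrame:
    """Pixel-weighted per-patient (FRET, FRET x HER3) covariates.

    ``results_by_patient`` maps patient id -> list of FretResult.  Patients
    whose regions are all invalid keep a row with missing covariates rather
    than being dropped (missingness is data).
    """
    rows = []
    for pid, results in results_by_patient.items():
        valid = [r for r in results
                 if np.isfinite(r.fret_efficiency)]
        if not valid:
            rows.append({"patient_id": pid, "fret": np.nan, "fret_x_her3": np.nan,
                         "n_regions_used": 0})
            continue
        w = np.array([r.n_pixels_used for r in valid], dtype=float)
        w = w / w.sum()
        fret = float(w @ [r.fret_efficiency for r in valid])
        fxh = float(w @ [r.fret_x_her3 for r in valid])
        rows.append({"patient_id": pid, "fret": fret, "fret_x_her3": fxh,
                     "n_regions_used": len(valid)})
    return pd.DataFrame(rows)


def fret_results_table(results_by_patient: dict) -> pd.DataFrame:
    """Flatten per-region results into the exportable per-region table."""
    rows = []
    for pid, results in results_by_patient.items():
        for r in results:
            rows.append({
                "patient_id": pid, "region_id": r.region_id,
                "mean_tau_d": r.mean_tau_d, "mean_tau_da": r.mean_tau_da,
                "fret": r.fret_efficiency, "fret_x_her3": r.fret_x_her3,
                "n_used": r.n_pixels_used, "n_filtered": r.n_pixels_filtered,
                "flags": ";".join(r.qc_flags),
            })
    return pd.DataFrame(rows)
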