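"""Cross-dataset consistency check of anchor-spot imaging.

Anchor platforms are built from many copies of the same protein, so their
spots should look alike across experiments: their mean brightness tracks the
copy number and their mean second momentum tracks their structure and
mobility.  When imaging and platform assembly are consistent, the datasets'
(mean brightness, mean second momentum) points fall on a common trend; a
dataset far off that trend signals an artefactual acquisition.  The decision
rule fits a robust line across datasets and flags standardized residuals
beyond a threshold (default 3 robust SDs) that are also practically large
(beyond a relative floor), leaving the raw scatter available for human
inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["DatasetQCRecord", "dataset_qc"]


@dataclass(frozen=True)
class DatasetQCRecord:
    dataset_id: object
    mean_mass: float
    mean_second_momentum: float
    n_anchor_spots: int
    flags: tuple = ()


def _anchor_stats(spots: pd.DataFrame) -> tuple[float, float, int]:
    ch1 = spots[spots["channel"] == 1] if "channel" in spots else spots
    if len(ch1) == 0:
        raise InputError("dataset has no channel-1 (anchor) spots")
    return (float(ch1["mass"].mean()), float(ch1["m2_px2"].mean()), len(ch1))


def dataset_qc(spot_tables: Mapping[object, pd.DataFrame] | Sequence[pd.DataFrame],
               residual_threshold: float = 3.0,
               min_relative_deviation: float = 0.05,
               ) -> pd.DataFrame:
    """Compare anchor-spot brightness/second-momentum means across datasets.

    Returns one row per dataset (dataset_id, mean_mass,
    mean_second_momentum, n_anchor_spots, flagged, residual, note).  With a
    single dataset only the means are reported; with two, the trend is
    reported with a low-n note and no flags; from three on, datasets whose
    robust standardized residual from the cross-dataset linear trend exceeds
    ``residual_threshold`` (and deviates by more than
    ``min_relative_deviation`` of the mean second momentum) are flagged.
    """
    if not isinstance(spot_tables, Mapping):
        spot_tables = {i: t for i, t in enumerate(spot_tables)}
    ids = sorted(spot_tables, key=repr)
    per_ds = {i: _anchor_stats(spot_tables[i]) for i in ids}
    out = pd.DataFrame({
        "dataset_id": ids,
        "mean_mass": [per_ds[i][0] for i in ids],
        "mean_second_momentum": [per_ds[i][1] for i in ids],
        "n_anchor_spots": [per_ds[i][2] for i in ids],
    })
    out["flagged"] = False
    out["residual"] = np.nan
    out["note"] = ""
    n = len(out)
    if n == 1:
        out["note"] = "single dataset: no consistency scoring"
        return out
    x = out["mean_mass"].to_numpy()
    y = out["mean_second_momentum"].to_numpy()
    # Theil-Sen: robust to a minority of artefactual datasets
    slope, intercept, *_ = stats.theilslopes(y, x)
    resid = y - (intercept + slope * x)
    out["residual"] = resid
    if n == 2:
        warnings.warn("only two datasets: trend reported, no flags")
        out["note"] = "low-n: trend fit on 2 datasets, no flags"
        return out
    mad = np.median(np.abs(resid - np.median(resid)))
    robust_sd = 1.4826 * mad
    floor = min_relative_deviation * max(np.mean(y), 1e-12)
    if robust_sd > 0:
        z = np.abs(resid) / robust_sd
        out["flagged"] = (z > residual_threshold) & (np.abs(resid) > floor)
    else:
        out["flagged"] = np.abs(resid) > floor
    return out
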