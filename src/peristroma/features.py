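"""First-order histogram features per region and inter-region ratios.

Per region, eight histogram statistics of the valid ADC pixels: mean, min,
max, variance, interquartile range, range, skewness and kurtosis.  Over six
regions that is 48 statistic features; the ratio of each statistic between
each of the 15 unordered region pairs adds 120 ratio features, for 168 per
case.

Conventions (fixed, since several are underdetermined by the definitions):

* ADC statistics are reported in units of 1e-3 mm^2/s (skewness/kurtosis are
  dimensionless).
* variance uses the n-1 denominator; skewness is the moment ratio
  m3 / m2^(3/2) and kurtosis the excess m4 / m2^2 - 3, both without
  small-sample bias correction; a constant region has skewness = kurtosis = 0.
* IQR uses linear-interpolation quantiles (numpy's default, Hyndman-Fan
  type 7).
* a region with fewer than ``MIN_REGION_PIXELS`` valid pixels yields missing
  (NaN) statistics — third and fourth moments are meaningless below that.
* ratios are oriented inner-over-outer by the canonical region order
  (S_I, S_T, S_B, S_P, S_M, S_D); a ratio with a missing or ~zero
  denominator is missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .adc import ADC_REPORT_SCALE, ADCMap
from .segmentation import REGION_NAMES, RegionSet

STAT_NAMES = (
    "mean",
    "min",
    "max",
    "variance",
    "iqr",
    "range",
    "skewness",
    "kurtosis",
)

REGION_PAIRS = tuple(combinations(REGION_NAMES, 2))  # 15 unordered pairs

MIN_REGION_PIXELS = 5

#: denominators smaller than this (in reporting units) make a ratio missing
RATIO_DENOM_EPS = 1e-12


def statistic_feature_names() -> list[str]:
    return [f"{stat}__{region}" for region in REGION_NAMES for stat in STAT_NAMES]


def ratio_feature_names() -> list[str]:
    return [
        f"ratio__{stat}__{a}_over_{b}"
        for (a, b) in REGION_PAIRS
        for stat in STAT_NAMES
    ]


def feature_names() -> list[str]:
    """The 168 feature column names in canonical order (48 stats + 120 ratios)."""
    return statistic_feature_names() + ratio_feature_names()


@dataclass(frozen=True)
class RegionStatistics:
    """The 8 histogram statistics per region plus pixel counts."""

    values: dict[str, dict[str, float]] = field(repr=False)
    n_pixels: dict[str, int] = field(default_factory=dict)

    def get(self, region: str, stat: str) -> float:
        return self.values[region][stat]


def _histogram_stats(x: np.ndarray) -> dict[str, float]:
    q1, q3 = np.percentile(x, [25, 75])
    m2 = float(np.mean((x - x.mean()) ** 2))
    if m2 > 0 and np.ptp(x) > 0:
        with warnings.catch_warnings():
            # near-constant samples trip scipy's cancellation warning; the
            # m2 > 0 guard already handles the truly degenerate case
            warnings.simplefilter("ignore", RuntimeWarning)
            skew = float(sstats.skew(x, bias=True))
            kurt = float(sstats.kurtosis(x, fisher=True, bias=True))
    else:
        skew = kurt = 0.0
    return {
        "mean": float(x.mean()),
        "min": float(x.min()),
        "max": float(x.max()),
        "variance": float(x.var(ddof=1)) if x.size > 1 else 0.0,
        "iqr": float(q3 - q1),
        "range": float(x.max() - x.min()),
        "skewness": skew,
        "kurtosis": kurt,
    }


def region_statistics(adc: ADCMap, regions: RegionSet) -> RegionStatistics:
    """Histogram statistics of valid ADC pixels in each of the six regions."""
    values: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    any_usable = False
    for name in REGION_NAMES:
        pix = adc.adc[regions[name] & adc.valid_mask] * ADC_REPORT_SCALE
        counts[name] = int(pix.size)
        if pix.size < MIN_REGION_PIXELS:
            values[name] = {stat: np.nan for stat in STAT_NAMES}
        else:
            values[name] = _histogram_stats(pix)
            any_usable = True
    if not any_usable:
        raise ValueError("no region has enough valid ADC pixels")
    return RegionStatistics(values=values, n_pixels=counts)


def ratio_features(stats: RegionStatistics) -> dict[str, float]:
    """The 120 pairwise ratio features, inner region over outer region."""
    out: dict[str, float] = {}
    for a, b in REGION_PAIRS:
        for stat in STAT_NAMES:
            num, den = stats.get(a, stat), stats.get(b, stat)
            name = f"ratio__{stat}__{a}_over_{b}"
            if np.isnan(num) or np.isnan(den) or abs(den) < RATIO_DENOM_EPS:
                out[name] = np.nan
            else:
                out[name] = num / den
    return out


def case_features(stats: RegionStatistics) -> dict[str, float]:
    """All 168 features for one case, keyed by canonical column name."""
    row = {
        f"{stat}__{region}": stats.get(region, stat)
        for region in REGION_NAMES
        for stat in STAT_NAMES
    }
    row.update(ratio_features(stats))
    return row


def build_feature_table(
    cases: Iterable[tuple[str, str, RegionStatistics]] | Mapping[str, object],
) -> pd.DataFrame:
    """Assemble the cases x 168 feature table.

    ``cases`` yields ``(case_id, ki67_label, RegionStatistics)`` triples with
    ``ki67_label`` in {"high", "low"} (Ki-67 above/below the 14% cut).
    Missing statistics stay NaN here; imputation is a training-fold concern
    of the classifier, never of the table.
    """
    rows, ids, labels = [], [], []
    for case_id, label, stats in cases:
        if label not in ("high", "low"):
            raise ValueError(f"ki67_label must be 'high' or 'low', got {label!r}")
        if case_id in ids:
            raise ValueError(f"duplicate case_id {case_id!r}")
        ids.append(case_id)
        labels.append(label)
        rows.append(case_features(stats))
    table = pd.DataFrame(rows, columns=feature_names())
    table.insert(0, "case_id", ids)
    table["ki67_label"] = labels
    return table


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, names); y is 1 for high Ki-67."""
    names = feature_names()
    X = table[names].to_numpy(dtype=float)
    y = (table["ki67_label"] == "high").to_numpy(dtype=int)
    return X, y, names
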