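"""Cohort-level mLOY/GOY calling.

The primary method ("iqr") treats losses and gains of chromosome Y as
outliers of the cohort mLRR-Y distribution, thresholding at

    median(mLRR-Y) -/+ 1.2 * IQR(mLRR-Y)

The 1.2 multiplier leaves ~5% of a normal distribution below the lower
bound, so applied to a cohort with no true events the rule yields at most
~5% false discoveries (less for the under-dispersed distributions arrays
typically show). Because median and IQR have high breakdown points, a few
extreme gains (GOY, e.g. XYY clones) do not drag the loss threshold, unlike
reflection-based approaches.

Calls are cross-checked against B-deviation: a genuine Y loss or gain
unbalances the X-Y homologous regions, so a called sample with B-deviation
below 0.05 (or a normal sample above it) is flagged discordant for visual
inspection — never silently reclassified.

Competing methods implemented for comparison:

* ``forsberg_threshold`` — reflect the values above the median to build a
  symmetric null sample and call LOY below its one-sided 99% bound.
* ``mlrr_quant`` — use mLRR-Y directly as a continuous covariate.
* ``cellularity_from_mlrr`` — map mLRR-Y to a cellularity proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CallThresholds",
    "CohortCalls",
    "DegenerateDistributionWarning",
    "InsufficientDataError",
    "iqr_thresholds",
    "forsberg_threshold",
    "classify",
    "call_cohort",
    "mlrr_quant",
    "cellularity_from_bdev",
    "bdev_from_cellularity",
    "cellularity_from_mlrr",
    "CALL_COLUMNS",
]

#: Default expected mLRR-Y for a normal male (one copy of chromosome Y).
EXPECTED_ONE_COPY = -0.45

CALL_COLUMNS = [
    "sample_id",
    "mlrr_y",
    "bdev",
    "status",
    "bdev_supported",
    "discordance",
    "cellularity_bdev",
    "cellularity_mlrr",
]


class DegenerateDistributionWarning(UserWarning):
    """The cohort mLRR-Y distribution has zero spread; no calls are made."""


class InsufficientDataError(ValueError):
    """Too few values to estimate a calling threshold."""


@dataclass(frozen=True)
class CallThresholds:
    """Cohort calling bounds. ``lower``/``upper`` delimit the normal range;
    LOY strictly below ``lower``, GOY strictly above ``upper``."""

    median_mlrr: float
    iqr_mlrr: float
    lower: float
    upper: float
    method: str


@dataclass
class CohortCalls:
    thresholds: CallThresholds
    calls: pd.DataFrame
    n_loy: int
    n_goy: int
    n_normal: int


def _finite(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def iqr_thresholds(mlrr: Sequence[float], k_iqr: float = 1.2) -> CallThresholds:
    """Robust two-sided bounds median -/+ k_iqr * IQR.

    Quartiles use linear interpolation between order statistics. Requires
    at least 10 finite values; a zero IQR triggers a
    :class:`DegenerateDistributionWarning` (no sample can then be called).
    """
    vals = _finite(mlrr)
    if vals.size < 10:
        raise InsufficientDataError(
            f"need >= 10 finite mLRR-Y values to set thresholds, got {vals.size}"
        )
    q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])
    iqr = float(q75 - q25)
    if iqr == 0.0:
        warnings.warn(
            "cohort mLRR-Y IQR is zero; thresholds are degenerate and no calls will be made",
            DegenerateDistributionWarning,
            stacklevel=2,
        )
    return CallThresholds(
        median_mlrr=float(med),
        iqr_mlrr=iqr,
        lower=float(med - k_iqr * iqr),
        upper=float(med + k_iqr * iqr),
        method="iqr",
    )


def forsberg_threshold(
    mlrr: Sequence[float],
    ci: float = 0.99,
    estimator: Literal["z", "quantile"] = "z",
) -> CallThresholds:
    """Reflection threshold: assume no-LOY mLRR-Y is symmetric, rebuild the
    null from the values at or above the median reflected across it, and
    call LOY below the one-sided ``ci`` bound of that symmetric sample.

    ``estimator="z"`` uses center - z((1+ci)/2) * sd(reflected sample);
    ``estimator="quantile"`` uses the (1-ci)/2 empirical quantile. There is
    no gain category: the upper bound is +inf.
    """
    vals = _finite(mlrr)
    if vals.size < 10:
        raise InsufficientDataError(
            f"need >= 10 finite mLRR-Y values to set thresholds, got {vals.size}"
        )
    center = float(np.median(vals))
    upper_half = vals[vals >= center]
    if (vals > center).sum() < 3:
        raise InsufficientDataError("fewer than 3 values above the median; cannot reflect")
    reflected = np.concatenate([upper_half, 2.0 * center - upper_half])
    if estimator == "z":
        z = stats.norm.ppf(0.5 + ci / 2.0)
        lower = center - z * float(np.std(reflected, ddof=1))
    elif estimator == "quantile":
        lower = float(np.quantile(reflected, (1.0 - ci) / 2.0))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    q25, q75 = np.quantile(vals, [0.25, 0.75])
    return CallThresholds(
        median_mlrr=center,
        iqr_mlrr=float(q75 - q25),
        lower=lower,
        upper=float("inf"),
        method="forsberg",
    )


def classify(mlrr: Sequence[float], thresholds: CallThresholds) -> np.ndarray:
    """Status per value: 'LOY' strictly below lower, 'GOY' strictly above
    upper, otherwise 'normal'. Ties at a threshold and missing values are
    'normal' (calls require strict exceedance); a degenerate (zero-IQR)
    threshold set yields all 'normal'."""
    arr = np.asarray(mlrr, dtype=float)
    status = np.full(arr.shape, "normal", dtype=object)
    if thresholds.method == "iqr" and thresholds.iqr_mlrr == 0.0:
        return status
    finite = np.isfinite(arr)
    status[finite & (arr < thresholds.lower)] = "LOY"
    status[finite & (arr > thresholds.upper)] = "GOY"
    return status


def mlrr_quant(summaries: pd.DataFrame | Sequence[float], center: bool = False) -> np.ndarray:
    """mLRR-Y as a continuous covariate (optionally median-centered)."""
    if isinstance(summaries, pd.DataFrame):
        vals = summaries["mlrr_y"].to_numpy(dtype=float)
    else:
        vals = np.asarray(summaries, dtype=float)
    if center:
        return vals - np.nanmedian(vals)
    return vals.copy()


def bdev_from_cellularity(f: float, kind: Literal["loss", "gain"] = "loss") -> float:
    """Expected B-deviation at cellularity ``f`` in a disomic region.

    A one-copy loss in a fraction f of cells shifts a heterozygote's BAF to
    1/(2-f) (or its mirror), a deviation of f / (2*(2-f)); a one-copy gain
    shifts it to 1/(2+f), a deviation of f / (2*(2+f)).
    """
    if not 0 <= f <= 1:
        raise ValueError(f"cellularity must be in [0, 1], got {f}")
    if kind == "loss":
        return f / (2.0 * (2.0 - f))
    if kind == "gain":
        return f / (2.0 * (2.0 + f))
    raise ValueError(f"unknown kind {kind!r}")


def cellularity_from_bdev(bdev: float, kind: Literal["loss", "gain"] = "loss") -> float:
    """Invert the allelic-imbalance model: cellularity from B-deviation.

    For a loss, f = 4*b / (1 + 2*b); b >= 0.5 (complete loss, BAF at 0/1)
    clips to 1 with a warning. For a gain, f = 4*b / (1 - 2*b), clipped to
    [0, 1].
    """
    if not np.isfinite(bdev):
        return float("nan")
    if bdev < 0:
        raise ValueError(f"B-deviation must be >= 0, got {bdev}")
    if kind == "loss":
        if bdev >= 0.5:
            warnings.warn(
                f"B-deviation {bdev} >= 0.5 exceeds the complete-loss limit; clipping cellularity to 1",
                stacklevel=2,
            )
            return 1.0
        return float(np.clip(4.0 * bdev / (1.0 + 2.0 * bdev), 0.0, 1.0))
    if kind == "gain":
        if bdev >= 1.0 / 6.0:
            return 1.0
        return float(np.clip(4.0 * bdev / (1.0 - 2.0 * bdev), 0.0, 1.0))
    raise ValueError(f"unknown kind {kind!r}")


def cellularity_from_mlrr(
    mlrr_y: float,
    expected_one_copy: float = EXPECTED_ONE_COPY,
    response_factor: float = 1.0,
) -> float:
    """Cellularity proxy from the mLRR-Y drop below the one-copy level:
    f = 1 - 2**((mlrr_y - expected_one_copy) / response_factor), clipped to
    [0, 1] (values above the expected level map to 0).

    ``response_factor`` rescales the intensity response; array LRR is
    compressed relative to the ideal log2 copy-number response, and the
    appropriate factor is platform-dependent, so it is exposed rather than
    fixed.
    """
    if not response_factor > 0:
        raise ValueError("response_factor must be positive")
    if not np.isfinite(mlrr_y):
        return float("nan")
    f = 1.0 - 2.0 ** ((mlrr_y - expected_one_copy) / response_factor)
    return float(np.clip(f, 0.0, 1.0))


def call_cohort(
    summaries: pd.DataFrame,
    method: Literal["iqr", "forsberg"] = "iqr",
    k_iqr: float = 1.2,
    bdev_threshold: float = 0.05,
    expected_one_copy: float = EXPECTED_ONE_COPY,
    response_factor: float = 1.0,
    drop_lrr_only: bool = False,
) -> CohortCalls:
    """Call every sample from its mLRR-Y, with B-deviation cross-checks.

    ``summaries`` must carry ``sample_id``, ``mlrr_y`` and (optionally
    NaN) ``bdev`` columns, QC-filtered upstream. Status comes from the
    mLRR-Y thresholds alone. For non-normal calls with a B-deviation,
    ``bdev_supported`` records whether bdev >= ``bdev_threshold``;
    discordant combinations are flagged:

    * ``lrr_only`` — called LOY/GOY but bdev < threshold (inspect; may be a
      purely technical LRR shift),
    * ``bdev_only`` — normal mLRR-Y but bdev >= threshold (inspect; pattern
      of sample contamination).

    Samples with missing bdev get ``bdev_supported=None`` and are never
    reclassified. ``drop_lrr_only=True`` demotes lrr_only-discordant calls
    to 'normal' (off by default; flags are for inspection, not automatic
    filtering).
    """
    mlrr = summaries["mlrr_y"].to_numpy(dtype=float)
    if method == "iqr":
        thresholds = iqr_thresholds(mlrr, k_iqr=k_iqr)
    elif method == "forsberg":
        thresholds = forsberg_threshold(mlrr)
    else:
        raise ValueError(f"unknown calling method {method!r}")
    status = classify(mlrr, thresholds)

    bdev = (
        summaries["bdev"].to_numpy(dtype=float)
        if "bdev" in summaries.columns
        else np.full(len(summaries), np.nan)
    )
    has_bdev = np.isfinite(bdev)
    non_normal = status != "normal"

    bdev_supported = np.full(len(summaries), None, dtype=object)
    bdev_supported[non_normal & has_bdev] = bdev[non_normal & has_bdev] >= bdev_threshold

    discordance = np.full(len(summaries), "none", dtype=object)
    discordance[non_normal & has_bdev & (bdev < bdev_threshold)] = "lrr_only"
    discordance[~non_normal & has_bdev & (bdev >= bdev_threshold)] = "bdev_only"

    if drop_lrr_only:
        demote = discordance == "lrr_only"
        status = status.copy()
        status[demote] = "normal"
        bdev_supported[demote] = None

    cell_bdev = np.full(len(summaries), np.nan)
    for i in np.nonzero(non_normal & has_bdev)[0]:
        kind = "loss" if status[i] == "LOY" else "gain"
        if status[i] == "normal":
            continue
        cell_bdev[i] = cellularity_from_bdev(bdev[i], kind=kind)

    cell_mlrr = np.full(len(summaries), np.nan)
    loy = status == "LOY"
    for i in np.nonzero(loy & np.isfinite(mlrr))[0]:
        cell_mlrr[i] = cellularity_from_mlrr(mlrr[i], expected_one_copy, response_factor)

    calls = pd.DataFrame(
        {
            "sample_id": summaries["sample_id"].to_numpy(),
            "mlrr_y": mlrr,
            "bdev": bdev,
            "status": status,
            "bdev_supported": bdev_supported,
            "discordance": discordance,
            "cellularity_bdev": cell_bdev,
            "cellularity_mlrr": cell_mlrr,
        },
        columns=CALL_COLUMNS,
    )
    return CohortCalls(
        thresholds=thresholds,
        calls=calls,
        n_loy=int((status == "LOY").sum()),
        n_goy=int((status == "GOY").sum()),
        n_normal=int((status == "normal").sum()),
    )
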