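"""Per-sample summary statistics: trimmed autosomal LRR mean/sd, mLRR-Y
and B-deviation.

mLRR-Y is the median LRR over the male-specific region of chromosome Y
(MSY), normalized by subtracting the sample's trimmed-mean autosomal LRR
(a subtraction in log2 space, i.e. a ratio of intensities). In a normal
male it sits near the one-copy level of about -0.45; mosaic loss of Y
pushes it further down in proportion to the fraction of affected cells.

B-deviation is the trimmed mean of |BAF - 0.5| over heterozygous probes in
the X-Y homologous regions (PAR1, PAR2, XTR), which are disomic in males;
Y loss or gain unbalances the two alleles there and splits the
heterozygote BAF band symmetrically about 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    GenomicRegion,
    SampleData,
    default_regions,
    is_autosome,
    probes_in_region,
    probes_in_regions,
    xy_homologous_regions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedStatisticError",
    "SampleSummary",
    "trimmed_mean",
    "autosomal_reference",
    "compute_mlrr_y",
    "compute_bdev",
    "summarize_sample",
    "summarize_cohort",
    "SUMMARY_COLUMNS",
]

#: Genotype strings treated as heterozygous calls.
HET_GENOTYPES = frozenset({"AB", "BA"})

SUMMARY_COLUMNS = [
    "sample_id",
    "trimmed_mean_auto",
    "sd_auto",
    "mlrr_y",
    "bdev",
    "n_msy_probes",
    "n_het_par_probes",
    "trim_fraction_used",
]


class UndefinedStatisticError(ValueError):
    """A statistic was requested on an empty (or all-missing) input."""


@dataclass
class SampleSummary:
    """Per-sample statistics consumed by the calling methods.

    All LRR quantities are in log2 units; ``bdev`` lies in [0, 0.5] when
    defined. ``mlrr_y``/``bdev`` are NaN when fewer than the minimum number
    of informative probes were available.
    """

    sample_id: str
    trimmed_mean_auto: float
    sd_auto: float
    mlrr_y: float
    bdev: float
    n_msy_probes: int
    n_het_par_probes: int
    trim_fraction_used: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in SUMMARY_COLUMNS}


def trimmed_mean(values: Sequence[float], trim_fraction: float = 0.05) -> float:
    """Two-sided trimmed mean: sort, drop ``floor(n * trim_fraction)``
    values from each tail, average the rest. Missing values are removed
    first; an empty input raises :class:`UndefinedStatisticError`.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise UndefinedStatisticError("trimmed mean of empty input")
    return float(stats.trim_mean(arr, trim_fraction))


def _autosomal_lrr(data: SampleData) -> np.ndarray:
    df = data.probes
    mask = df["chrom"].map(is_autosome)
    vals = df.loc[mask, "lrr"].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def autosomal_reference(data: SampleData, trim_fraction: float = 0.05) -> tuple[float, float]:
    """Trimmed mean (bias reference) and untrimmed sd (QC statistic) of the
    autosomal LRR values.

    The trim guards the reference against genuine copy-number-altered
    regions; 5% suits constitutional samples, 25% tumor samples. The sd is
    computed on the untrimmed values so it reflects full technical noise.
    """
    vals = _autosomal_lrr(data)
    if vals.size == 0:
        raise UndefinedStatisticError(f"{data.sample_id}: no autosomal LRR values")
    mean = trimmed_mean(vals, trim_fraction)
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return mean, sd


def compute_mlrr_y(
    data: SampleData,
    msy: GenomicRegion | None = None,
    trim_fraction: float = 0.05,
    min_probes: int = 10,
    msy_summary: Literal["median", "trimmed"] = "median",
) -> float:
    """Normalized mLRR-Y: summary of MSY LRR minus the trimmed autosomal mean.

    The MSY summary is the median by default; a trimmed mean over MSY is
    available as ``msy_summary="trimmed"``. Returns NaN (with a log entry)
    when fewer than ``min_probes`` MSY probes carry LRR.
    """
    if msy is None:
        msy = default_regions()["MSY"]
    vals = probes_in_region(data, msy).probes["lrr"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < min_probes:
        logger.info(
            "%s: only %d MSY probes with LRR (min %d); mLRR-Y undefined",
            data.sample_id, vals.size, min_probes,
        )
        return float("nan")
    if msy_summary == "median":
        center = float(np.median(vals))
    elif msy_summary == "trimmed":
        center = trimmed_mean(vals, trim_fraction)
    else:
        raise ValueError(f"unknown msy_summary {msy_summary!r}")
    auto_mean, _ = autosomal_reference(data, trim_fraction)
    return center - auto_mean


def compute_bdev(
    data: SampleData,
    xy_homologous: Iterable[GenomicRegion] | None = None,
    hom_low: float = 0.2,
    hom_high: float = 0.8,
    trim_fraction: float = 0.05,
    min_het: int = 10,
    use_genotype: bool = False,
) -> float:
    """B-deviation: trimmed mean of |BAF - 0.5| over heterozygous probes in
    the X-Y homologous regions.

    Heterozygous probes are selected by the BAF window ``hom_low < BAF <
    hom_high`` (strict; boundary values are treated as homozygous). With
    ``use_genotype=True`` the genotype calls (AB) select heterozygotes
    instead, which stays informative at high event cellularity where the
    split BAF bands leave the window. Returns NaN when fewer than
    ``min_het`` heterozygous probes are found.
    """
    if not hom_low < hom_high:
        raise ValueError("hom_low must be < hom_high")
    if xy_homologous is None:
        xy_homologous = xy_homologous_regions()
    sub = probes_in_regions(data, list(xy_homologous)).probes
    baf = sub["baf"].to_numpy(dtype=float)
    finite = np.isfinite(baf)
    if use_genotype:
        gt = sub["genotype"].astype(str).str.upper().str.strip()
        het = gt.isin(HET_GENOTYPES).to_numpy() & finite
    else:
        het = finite & (baf > hom_low) & (baf < hom_high)
    dev = np.abs(baf[het] - 0.5)
    if dev.size < min_het:
        logger.info(
            "%s: only %d heterozygous X-Y homologous probes (min %d); B-deviation undefined",
            data.sample_id, dev.size, min_het,
        )
        return float("nan")
    return trimmed_mean(dev, trim_fraction)


def summarize_sample(
    data: SampleData,
    regions: Mapping[str, GenomicRegion] | None = None,
    trim_fraction: float = 0.05,
    min_msy_probes: int = 10,
    min_het: int = 10,
    het_selection: Literal["baf", "genotype", "auto"] = "auto",
    msy_summary: Literal["median", "trimmed"] = "median",
) -> SampleSummary:
    """Compute all per-sample statistics in one pass.

    ``het_selection="auto"`` uses genotype calls for B-deviation when the
    sample carries them and the BAF window otherwise. Undefined statistics
    propagate as NaN fields, never as exceptions, so one poor sample cannot
    abort a cohort run.
    """
    if regions is None:
        regions = default_regions()
    msy = regions["MSY"]
    hom = xy_homologous_regions(regions)

    try:
        auto_mean, sd_auto = autosomal_reference(data, trim_fraction)
    except UndefinedStatisticError:
        logger.warning("%s: no autosomal signal; summary mostly undefined", data.sample_id)
        auto_mean, sd_auto = float("nan"), float("nan")

    msy_lrr = probes_in_region(data, msy).probes["lrr"]
    n_msy = int(np.isfinite(msy_lrr.to_numpy(dtype=float)).sum())
    if n_msy >= min_msy_probes and np.isfinite(auto_mean):
        mlrr_y = compute_mlrr_y(data, msy, trim_fraction, min_msy_probes, msy_summary)
    else:
        mlrr_y = float("nan")

    if het_selection == "auto":
        gt = data.probes["genotype"]
        use_genotype = bool(gt.notna().any() and (gt.astype(str).str.strip() != "").any())
    else:
        use_genotype = het_selection == "genotype"
    bdev = compute_bdev(
        data, hom, trim_fraction=trim_fraction, min_het=min_het, use_genotype=use_genotype
    )
    sub = probes_in_regions(data, hom).probes
    baf = sub["baf"].to_numpy(dtype=float)
    if use_genotype:
        het_mask = (
            sub["genotype"].astype(str).str.upper().str.strip().isin(HET_GENOTYPES).to_numpy()
            & np.isfinite(baf)
        )
    else:
        het_mask = np.isfinite(baf) & (baf > 0.2) & (baf < 0.8)
    n_het = int(het_mask.sum())

    return SampleSummary(
        sample_id=data.sample_id,
        trimmed_mean_auto=auto_mean,
        sd_auto=sd_auto,
        mlrr_y=mlrr_y,
        bdev=bdev,
        n_msy_probes=n_msy,
        n_het_par_probes=n_het,
        trim_fraction_used=trim_fraction,
    )


def summarize_cohort(
    samples: Iterable[SampleData],
    regions: Mapping[str, GenomicRegion] | None = None,
    trim_fraction: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """Summarize every sample; returns one row per sample with the
    :data:`SUMMARY_COLUMNS` columns."""
    rows = [
        summarize_sample(s, regions=regions, trim_fraction=trim_fraction, **kwargs).as_dict()
        for s in samples
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
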