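"""PennCNV signal-file I/O and genome-region arithmetic (hg19/GRCh37).

A PennCNV signal file is a tab-separated text file with one row per SNP
probe and a header naming, at minimum, a probe-name column, a ``Chr``
column, a ``Position`` column and per-sample ``B Allele Freq`` and
``Log R Ratio`` columns (a genotype column such as ``GType`` is optional).
All coordinates handled here are 1-based, closed intervals on hg19.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PennCNVFormatError",
    "GenomicRegion",
    "SampleData",
    "normalize_chrom",
    "chrom_sort_key",
    "is_autosome",
    "read_penncnv",
    "write_penncnv",
    "probes_in_region",
    "probes_in_regions",
    "default_regions",
    "read_regions",
    "xy_homologous_regions",
]

PROBE_COLUMNS = ["name", "chrom", "position", "lrr", "baf", "genotype"]

#: Canonical chromosome labels in sort order. "XY" is the pseudoautosomal
#: pseudo-chromosome emitted by some genotyping pipelines.
CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y", "XY", "MT"]

_CHROM_ALIASES = {"23": "X", "24": "Y", "25": "XY", "26": "MT", "M": "MT"}
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}

# Large sentinel end coordinate meaning "whole chromosome"; longer than any
# hg19 chromosome (chr1 is ~249 Mb).
WHOLE_CHROM_END = 2_000_000_000


class PennCNVFormatError(ValueError):
    """Raised when a signal file lacks a mandatory column or is unparseable."""


def normalize_chrom(label: object) -> str:
    """Normalize a chromosome label: strip ``chr`` prefix, uppercase, map
    numeric sex-chromosome codes (23→X, 24→Y, 25→XY, 26→MT)."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper()
    return _CHROM_ALIASES.get(s, s)


def chrom_sort_key(chrom: str) -> int:
    """Rank for sorting: 1..22, X, Y, XY, MT, then anything unknown."""
    return _CHROM_RANK.get(normalize_chrom(chrom), len(CHROM_ORDER))


def is_autosome(chrom: str) -> bool:
    c = normalize_chrom(chrom)
    return c.isdigit() and 1 <= int(c) <= 22


@dataclass(frozen=True)
class GenomicRegion:
    """A named 1-based closed interval [start, end] on one chromosome."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"region {self.name}: start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")

    def contains(self, chrom: str, position: int) -> bool:
        """Closed-interval membership. Probes on the 'XY' pseudo-chromosome
        are matched against X-side regions by position."""
        c = normalize_chrom(chrom)
        if c != self.chrom and not (c == "XY" and self.chrom == "X"):
            return False
        return self.start <= position <= self.end


@dataclass
class SampleData:
    """One sample's per-probe LRR/BAF signal.

    ``probes`` is a DataFrame with columns ``name, chrom, position, lrr,
    baf, genotype``, sorted by (chromosome, position) with duplicate
    (chrom, position, name) rows dropped. Missing LRR/BAF are NaN.
    """

    sample_id: str
    probes: pd.DataFrame = field(repr=False)

    @classmethod
    def from_dataframe(cls, sample_id: str, df: pd.DataFrame) -> "SampleData":
        out = df.copy()
        for col in PROBE_COLUMNS:
            if col not in out.columns:
                out[col] = np.nan if col in ("lrr", "baf") else None
        out = out[PROBE_COLUMNS]
        out["name"] = out["name"].astype(str)
        out["chrom"] = out["chrom"].map(normalize_chrom)
        out["position"] = pd.to_numeric(out["position"], errors="coerce").astype("int64")
        if (out["position"] < 1).any():
            raise ValueError("probe positions must be >= 1")
        out["lrr"] = pd.to_numeric(out["lrr"], errors="coerce").astype(float)
        out["baf"] = pd.to_numeric(out["baf"], errors="coerce").astype(float)
        bad_baf = out["baf"].dropna()
        if ((bad_baf < 0) | (bad_baf > 1)).any():
            raise ValueError("BAF values must lie in [0, 1]")
        n0 = len(out)
        out = out.drop_duplicates(subset=["chrom", "position", "name"])
        if len(out) < n0:
            logger.warning("%s: dropped %d duplicate probe rows", sample_id, n0 - len(out))
        key = out["chrom"].map(chrom_sort_key)
        out = (
            out.assign(_key=key)
            .sort_values(["_key", "position", "name"], kind="mergesort")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
        return cls(sample_id=sample_id, probes=out)

    def __len__(self) -> int:
        return len(self.probes)


def _find_column(columns: Iterable[str], token: str) -> str | None:
    matches = [c for c in columns if token.lower() in c.lower()]
    return matches[0] if matches else None


def read_penncnv(path: str | Path, sample_id: str | None = None) -> SampleData:
    """Read a PennCNV-format signal file into a :class:`SampleData`.

    Non-numeric LRR/BAF fields (``NA``, ``NaN``, empty) are recorded as
    missing; unsorted input is sorted, not rejected.

    Raises
    ------
    PennCNVFormatError
        If a mandatory column (Chr, Position, B Allele Freq, Log R Ratio)
        is absent; the message names the missing column.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except pd.errors.EmptyDataError as exc:
        raise PennCNVFormatError(f"{path}: empty file, no header") from exc
    cols = list(raw.columns)
    mandatory = {
        "chrom": "Chr",
        "position": "Position",
        "baf": "B Allele Freq",
        "lrr": "Log R Ratio",
    }
    found: dict[str, str] = {}
    for key, token in mandatory.items():
        col = _find_column(cols, token)
        if col is None:
            raise PennCNVFormatError(f"{path}: missing mandatory column '{token}'")
        found[key] = col
    name_col = "Name" if "Name" in cols else cols[0]
    gt_col = _find_column(cols, "GType") or _find_column(cols, "Genotype")
    df = pd.DataFrame(
        {
            "name": raw[name_col],
            "chrom": raw[found["chrom"]],
            "position": raw[found["position"]],
            "lrr": raw[found["lrr"]],
            "baf": raw[found["baf"]],
            "genotype": raw[gt_col] if gt_col is not None else None,
        }
    )
    data = SampleData.from_dataframe(sample_id, df)
    n_miss = int(data.probes["lrr"].isna().sum() + data.probes["baf"].isna().sum())
    if n_miss:
        logger.debug("%s: %d missing LRR/BAF fields recorded as NaN", sample_id, n_miss)
    return data


def write_penncnv(data: SampleData, path: str | Path, float_fmt: str = "%.4f") -> None:
    """Write ``data`` as a tab-separated PennCNV signal file.

    Numeric fields are printed with ``float_fmt`` (4 decimals by default,
    the precision GenomeStudio exports); missing values are written as NA.
    """
    sid = data.sample_id
    out = pd.DataFrame(
        {
            "Name": data.probes["name"],
            "Chr": data.probes["chrom"],
            "Position": data.probes["position"],
            f"{sid}.B Allele Freq": data.probes["baf"],
            f"{sid}.Log R Ratio": data.probes["lrr"],
        }
    )
    if data.probes["genotype"].notna().any():
        out[f"{sid}.GType"] = data.probes["genotype"]
    out.to_csv(path, sep="\t", index=False, float_format=float_fmt, na_rep="NA")


def probes_in_region(data: SampleData, region: GenomicRegion) -> SampleData:
    """Subset to probes inside ``region`` (closed interval, both ends)."""
    df = data.probes
    chrom = df["chrom"]
    on_chrom = (chrom == region.chrom) | ((chrom == "XY") & (region.chrom == "X"))
    mask = on_chrom & (df["position"] >= region.start) & (df["position"] <= region.end)
    return SampleData(sample_id=data.sample_id, probes=df[mask].reset_index(drop=True))


def probes_in_regions(data: SampleData, regions: Iterable[GenomicRegion]) -> SampleData:
    """Subset to probes inside the union of ``regions``."""
    df = data.probes
    mask = pd.Series(False, index=df.index)
    for region in regions:
        chrom = df["chrom"]
        on_chrom = (chrom == region.chrom) | ((chrom == "XY") & (region.chrom == "X"))
        mask |= on_chrom & (df["position"] >= region.start) & (df["position"] <= region.end)
    return SampleData(sample_id=data.sample_id, probes=df[mask].reset_index(drop=True))


def default_regions() -> dict[str, GenomicRegion]:
    """Named hg19 regions used throughout.

    ``MSY`` (male-specific region of chromosome Y, excluding PAR1/PAR2 and
    the X-transposed region) and the full Y analysis span between the PARs
    follow the printed hg19 bounds. PAR1/PAR2 bounds are the standard hg19
    assembly definitions. The X-side XTR interval is approximate (the XTR
    is a ~3.5 Mb X–Y homology block on Xq21); all regions can be overridden
    with :func:`read_regions`.
    """
    regions = [
        GenomicRegion("MSY", "Y", 6_611_498, 24_510_581),
        GenomicRegion("Y_FULL", "Y", 2_694_521, 59_034_049),
        GenomicRegion("PAR1_Y", "Y", 10_001, 2_649_520),
        GenomicRegion("PAR1_X", "X", 60_001, 2_699_520),
        GenomicRegion("PAR2_Y", "Y", 59_034_050, 59_363_566),
        GenomicRegion("PAR2_X", "X", 154_931_044, 155_260_560),
        GenomicRegion("XTR_Y", "Y", 2_649_521, 6_611_497),
        GenomicRegion("XTR_X", "X", 88_400_000, 92_000_000),
    ]
    regions += [
        GenomicRegion(f"chr{i}", str(i), 1, WHOLE_CHROM_END) for i in range(1, 23)
    ]
    return {r.name: r for r in regions}


def xy_homologous_regions(regions: Mapping[str, GenomicRegion] | None = None) -> list[GenomicRegion]:
    """The X–Y homologous regions used for B-deviation (PAR1, PAR2, XTR).

    BAF is taken from the X side (plus 'XY' pseudo-chromosome probes, which
    map onto X coordinates): hemizygous Y probes carry no usable BAF.
    """
    if regions is None:
        regions = default_regions()
    return [regions[k] for k in ("PAR1_X", "PAR2_X", "XTR_X") if k in regions]


def read_regions(path: str | Path) -> dict[str, GenomicRegion]:
    """Read a region override file (TSV: name, chrom, start, end) and merge
    it over :func:`default_regions`."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    for col in ("name", "chrom", "start", "end"):
        if col not in df.columns:
            raise PennCNVFormatError(f"{path}: region file missing column '{col}'")
    regions = default_regions()
    for row in df.itertuples(index=False):
        regions[row.name] = GenomicRegion(row.name, row.chrom, int(row.start), int(row.end))
    return regions
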