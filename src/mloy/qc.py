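"""Sample quality control on autosomal LRR variability.

Samples whose autosomal LRR is highly variable tend to produce unreliable
mLRR-Y values (hybridization artifacts, degraded DNA), so they are flagged
before any calling. Two rules are provided:

* ``qc_fixed`` — fail when sd(autosomal LRR) strictly exceeds a fixed
  bound (default 0.28, the Illumina manufacturer recommendation).
* ``qc_relative`` — fail when a sample's sd lies more than ``k`` cohort
  standard deviations above the cohort mean sd (default k=2), suited to
  Affymetrix-style data where the absolute noise floor differs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["qc_fixed", "qc_relative", "QC_COLUMNS"]

QC_COLUMNS = ["sample_id", "sd_auto", "rule", "passed", "threshold_used", "reason"]


def _as_frame(summaries: pd.DataFrame) -> pd.DataFrame:
    if not {"sample_id", "sd_auto"}.issubset(summaries.columns):
        raise ValueError("summaries must have 'sample_id' and 'sd_auto' columns")
    return summaries


def qc_fixed(summaries: pd.DataFrame, sd_max: float = 0.28) -> pd.DataFrame:
    """Fixed-bound rule: a sample fails only when sd_auto > sd_max
    (strictly); sd_auto == sd_max passes. Missing sd_auto fails with
    reason "missing"."""
    if not sd_max > 0:
        raise ValueError("sd_max must be positive")
    df = _as_frame(summaries)
    sd = df["sd_auto"].to_numpy(dtype=float)
    missing = ~np.isfinite(sd)
    passed = ~missing & (sd <= sd_max)
    reason = np.where(missing, "missing", np.where(passed, "", "sd_auto above fixed bound"))
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy(),
            "sd_auto": sd,
            "rule": "fixed",
            "passed": passed,
            "threshold_used": sd_max,
            "reason": reason,
        },
        columns=QC_COLUMNS,
    )


def qc_relative(summaries: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Cohort-relative rule: pass when sd_auto <= mean(sd_auto) + k * sd(sd_auto)
    over the cohort's finite values.

    This reads the "within k times the standard deviation" rule as a
    one-sided mean + k*sd envelope (only high variability is pathological).
    A degenerate cohort (all sd equal) passes everyone. Missing sd_auto
    fails with reason "missing".
    """
    df = _as_frame(summaries)
    if len(df) < 3:
        raise ValueError("qc_relative needs a cohort of at least 3 samples")
    sd = df["sd_auto"].to_numpy(dtype=float)
    finite = sd[np.isfinite(sd)]
    if finite.size == 0:
        raise ValueError("qc_relative: no finite sd_auto values in cohort")
    spread = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
    threshold = float(np.mean(finite)) + k * spread
    missing = ~np.isfinite(sd)
    passed = ~missing & (sd <= threshold)
    reason = np.where(missing, "missing", np.where(passed, "", "sd_auto above cohort envelope"))
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"].to_numpy(),
            "sd_auto": sd,
            "rule": "relative",
            "passed": passed,
            "threshold_used": threshold,
            "reason": reason,
        },
        columns=QC_COLUMNS,
    )
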