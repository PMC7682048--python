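"""Association testing, Monte-Carlo power comparison of calling methods,
and the longitudinal blood/saliva follow-up summary.

Association uses generalized linear models: Gaussian (OLS) for continuous
outcomes, binomial (logistic) for case/control, with Wald two-sided
p-values and optional covariate adjustment. The power study repeatedly
simulates a labelled mLRR-Y mixture plus an outcome tied to the true
labels, re-calls mosaic status with each method, and records how often the
association test rejects at level alpha — quantifying how misclassification
by a calling method erodes power.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calling import forsberg_threshold, iqr_thresholds
from .simulate import simulate_mlrr_mixture, simulate_outcome

__all__ = [
    "AssociationResult",
    "associate_continuous",
    "associate_binary",
    "power_study",
    "summarize_longitudinal",
    "load_followup_table",
    "POWER_COLUMNS",
]

POWER_COLUMNS = [
    "scenario",
    "method",
    "kind",
    "effect",
    "n",
    "reps",
    "alpha",
    "power",
    "mc_se",
]

#: Fallback estimate magnitude reported for separated logistic fits.
_SEPARATION_ABS_ESTIMATE = 15.0


@dataclass(frozen=True)
class AssociationResult:
    """One regression result: slope (beta or log-OR), Wald SE and p."""

    estimate: float
    se: float
    p_value: float
    n: int
    predictor_kind: Literal["status", "quantitative"]
    separated: bool = False


def _design(predictor: Sequence[float], covariates) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(predictor, dtype=float)
    if covariates is None:
        X = x[:, None]
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([x, cov])
    return x, sm.add_constant(X, has_constant="add")


def _predictor_kind(x: np.ndarray) -> str:
    return "status" if np.isin(np.unique(x), [0.0, 1.0]).all() else "quantitative"


def associate_continuous(
    predictor: Sequence[float],
    outcome: Sequence[float],
    covariates: Sequence[float] | np.ndarray | None = None,
) -> AssociationResult:
    """Gaussian GLM (ordinary least squares) of outcome on predictor.

    The predictor may be a 0/1 status indicator or a quantitative value
    (e.g. mLRR-Y); covariates (such as age) enter as extra columns. The
    reported p-value is the two-sided t-test on the predictor slope.
    """
    x, X = _design(predictor, covariates)
    y = np.asarray(outcome, dtype=float)
    if y.size != x.size:
        raise ValueError("predictor and outcome lengths differ")
    if y.size < 10:
        raise ValueError("need n >= 10 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: association undefined")
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(y.size),
        predictor_kind=_predictor_kind(x),
    )


def associate_binary(
    predictor: Sequence[float],
    outcome: Sequence[float],
    covariates: Sequence[float] | np.ndarray | None = None,
) -> AssociationResult:
    """Binomial GLM (logistic regression, IRLS) of a 0/1 outcome.

    For a binary predictor without covariates the estimate equals the log
    odds ratio of the 2x2 table. Complete or quasi-complete separation is
    flagged (``separated=True``) with the estimate pinned at +/-inf.
    """
    x, X = _design(predictor, covariates)
    y = np.asarray(outcome, dtype=float)
    if y.size != x.size:
        raise ValueError("predictor and outcome lengths differ")
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
        raise ValueError("outcome must contain both classes 0 and 1")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: association undefined")
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    separated = (not np.isfinite(se)) or abs(est) >= _SEPARATION_ABS_ESTIMATE or se > 100
    if separated:
        est = float(np.sign(est) * np.inf) if est != 0 else float("nan")
    return AssociationResult(
        estimate=est,
        se=se,
        p_value=float(fit.pvalues[1]),
        n=int(y.size),
        predictor_kind=_predictor_kind(x),
        separated=separated,
    )


def _call_predictor(values: np.ndarray, method: str) -> np.ndarray:
    """Predictor vector for one calling method on a cohort mLRR-Y vector."""
    if method == "quant":
        return values
    if method == "iqr":
        thr = iqr_thresholds(values)
    elif method == "forsberg":
        thr = forsberg_threshold(values)
    else:
        raise ValueError(f"unknown calling method {method!r}")
    return (values < thr.lower).astype(float)


def power_study(
    effects: Sequence[float],
    ns: Sequence[int],
    kind: Literal["continuous", "binary"] = "continuous",
    methods: Sequence[str] = ("iqr", "forsberg", "quant"),
    reps: int = 500,
    alpha: float = 0.05,
    mixture_params: Mapping[str, float] | None = None,
    outcome_params: Mapping[str, float] | None = None,
    seed: int = 0,
    scenario: str = "default",
) -> pd.DataFrame:
    """Monte-Carlo power of each calling method over an (effect, n) grid.

    Per replicate: draw a labelled mLRR-Y mixture, derive the outcome from
    the *true* LOY labels, re-call status with each method (or keep mLRR-Y
    continuous for "quant"), test the called predictor against the outcome,
    and record p < alpha. Replicates where a method calls no sample (or
    all samples) count as non-rejections. Returns a tidy table with the
    Monte-Carlo standard error sqrt(power*(1-power)/reps) per cell.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable power estimate")
    mixture_params = dict(mixture_params or {})
    outcome_params = dict(outcome_params or {})
    ss = np.random.SeedSequence(seed)
    rows = []
    for effect in effects:
        for n in ns:
            hits = {m: 0 for m in methods}
            for child in ss.spawn(reps):
                rng = np.random.default_rng(child)
                values, labels = simulate_mlrr_mixture(n, seed=rng, **mixture_params)
                truth = labels == "LOY"
                outcome = simulate_outcome(truth, kind, effect, seed=rng, **outcome_params)
                for m in methods:
                    pred = _call_predictor(values, m)
                    if np.ptp(pred) == 0:
                        continue
                    if kind == "continuous":
                        res = associate_continuous(pred, outcome)
                    else:
                        if np.unique(outcome).size < 2:
                            continue
                        res = associate_binary(pred, outcome)
                    if np.isfinite(res.p_value) and res.p_value < alpha:
                        hits[m] += 1
            for m in methods:
                power = hits[m] / reps
                rows.append(
                    {
                        "scenario": scenario,
                        "method": m,
                        "kind": kind,
                        "effect": effect,
                        "n": n,
                        "reps": reps,
                        "alpha": alpha,
                        "power": power,
                        "mc_se": float(np.sqrt(power * (1.0 - power) / reps)),
                    }
                )
    return pd.DataFrame(rows, columns=POWER_COLUMNS)


def load_followup_table(path=None) -> pd.DataFrame:
    """Load a longitudinal follow-up table (default: the packaged 18-man
    blood/saliva cellularity table).

    Columns: sample_id, baseline_blood_pct, followup_blood_pct,
    saliva_pct; "ND" (not detectable) parses to NaN.
    """
    if path is None:
        ref = resources.files("mloy.data").joinpath("followup_blood_saliva.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", na_values=["ND"])
    else:
        df = pd.read_csv(path, sep="\t", na_values=["ND"])
    required = {"sample_id", "baseline_blood_pct", "followup_blood_pct", "saliva_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"follow-up table missing columns: {sorted(missing)}")
    for col in ("baseline_blood_pct", "followup_blood_pct", "saliva_pct"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValueError(f"{col}: percentages must lie in [0, 100]")
    return df


def summarize_longitudinal(records: pd.DataFrame) -> dict:
    """Count blood-cellularity trajectories and saliva detectability.

    Returns counts of samples whose blood cellularity increased, decreased
    or was unchanged between baseline and follow-up, how many had
    detectable mosaicism in saliva, and the corresponding percentages of
    the total record count.
    """
    if len(records) == 0:
        raise ValueError("empty follow-up table")
    base = records["baseline_blood_pct"].to_numpy(dtype=float)
    follow = records["followup_blood_pct"].to_numpy(dtype=float)
    saliva = records["saliva_pct"].to_numpy(dtype=float)
    n = len(records)
    increased = int((follow > base).sum())
    decreased = int((follow < base).sum())
    unchanged = int((follow == base).sum())
    saliva_detected = int(np.isfinite(saliva).sum())
    return {
        "n": n,
        "increased": increased,
        "decreased": decreased,
        "unchanged": unchanged,
        "saliva_detected": saliva_detected,
        "saliva_missing": n - saliva_detected,
        "pct_increased": 100.0 * increased / n,
        "pct_decreased": 100.0 * decreased / n,
        "pct_saliva_detected": 100.0 * saliva_detected / n,
    }
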