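"""Synthetic SNP-array cohorts with known mosaic chromosome-Y truth.

Two levels of simulation are provided:

* :func:`simulate_sample` / :func:`simulate_cohort` build full per-probe
  PennCNV-style signal (autosomes, MSY, PAR1) so the whole pipeline —
  parsing, summarization, QC, calling — can be exercised against known
  event labels and cellularities.
* :func:`simulate_mlrr_mixture` draws cohort mLRR-Y values directly from a
  labelled normal mixture, the cheap surrogate used by the power study.

Signal model. Autosomal and PAR LRR are Normal(0, sigma_auto); MSY LRR is
Normal(expected_one_copy + delta(f), sigma_y) where the LRR response to a
loss at cellularity f is the compressed-log shift

    delta(f) = loss_scale * log2(1 - f/2)

(mirrored in sign for a gain). The scale defaults to 0.45 so that a
complete loss lands a further -0.45 below the one-copy level of -0.45:
observed array LRR is compressed relative to the ideal log2 copy-number
response (one copy reads -0.45, not -1), and the same compression is
applied to the mosaic shift. Heterozygous PAR probes split their BAF
symmetrically about 0.5 by the allelic-imbalance deviation f/(2*(2-f))
for losses (f/(2*(2+f)) for gains); homozygous PAR probes sit at 0/1.

Default noise levels (sigma_auto=0.12, sigma_y=0.18, baf_noise=0.03) give
cohort mLRR-Y dispersion comparable to blood-derived array data and place
the detection floor near 5% cellularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .calling import EXPECTED_ONE_COPY, bdev_from_cellularity
from .io import SampleData, default_regions

__all__ = [
    "SignalModel",
    "CohortScenario",
    "lrr_shift",
    "simulate_sample",
    "simulate_cohort",
    "simulate_mlrr_mixture",
    "simulate_outcome",
]

Event = Literal["LOY", "GOY", "none"]


@dataclass(frozen=True)
class SignalModel:
    """Per-probe signal model parameters (LRR in log2 units)."""

    sigma_auto: float = 0.12
    sigma_y: float = 0.18
    expected_one_copy: float = EXPECTED_ONE_COPY
    baf_noise: float = 0.03
    het_fraction: float = 0.5
    n_auto_probes: int = 2000
    n_msy_probes: int = 120
    n_par_probes: int = 300
    loss_scale: float = 0.45

    def __post_init__(self) -> None:
        for name in ("sigma_auto", "sigma_y", "baf_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortScenario:
    """Cohort-level generative scenario.

    ``cellularity_law`` is ("uniform", low, high) or ("fixed", f) and
    governs the cellularity of event samples. Defaults reflect the
    blood-mosaicism range in which array detection operates comfortably.
    """

    n_samples: int
    loy_prevalence: float = 0.05
    goy_prevalence: float = 0.0
    cellularity_law: tuple = ("uniform", 0.2, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loy_prevalence + self.goy_prevalence > 1:
            raise ValueError("loy_prevalence + goy_prevalence must be <= 1")


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def lrr_shift(f: float, event: Event, model: SignalModel) -> float:
    """Mean MSY LRR shift from the one-copy level at cellularity ``f``."""
    if event == "none" or f == 0:
        return 0.0
    delta = model.loss_scale * float(np.log2(1.0 - f / 2.0))
    return delta if event == "LOY" else -delta


def _draw_cellularity(law: tuple, rng: np.random.Generator) -> float:
    kind = law[0]
    if kind == "uniform":
        return float(rng.uniform(law[1], law[2]))
    if kind == "fixed":
        return float(law[1])
    raise ValueError(f"unknown cellularity law {law!r}")


def simulate_sample(
    f: float,
    event: Event = "none",
    model: SignalModel | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    sample_id: str = "sim",
) -> tuple[SampleData, dict]:
    """Simulate one sample's probe-level signal; returns (data, truth).

    Probe layout: autosomal probes spread round-robin over chromosomes
    1-22, MSY probes evenly spaced inside the MSY interval, PAR probes
    evenly spaced inside PAR1 on X. Heterozygous PAR probes (first
    ``het_fraction`` of them, genotype AB) alternate deterministically
    between the upper and lower BAF bands so the split is exactly even.
    The truth dict records the event, cellularity and noiseless targets.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"cellularity must be in [0, 1], got {f}")
    if event == "none":
        f = 0.0
    model = model or SignalModel()
    rng = _rng(seed)
    regions = default_regions()
    msy = regions["MSY"]
    par1 = regions["PAR1_X"]

    frames = []

    # autosomes: diploid baseline, LRR centered at 0
    n_a = model.n_auto_probes
    chroms = [str(1 + (i % 22)) for i in range(n_a)]
    positions = 1 + 10_000 * (1 + np.arange(n_a) // 22)
    frames.append(
        pd.DataFrame(
            {
                "name": [f"rsA{i:06d}" for i in range(n_a)],
                "chrom": chroms,
                "position": positions,
                "lrr": rng.normal(0.0, model.sigma_auto, n_a),
                "baf": np.nan,
                "genotype": None,
            }
        )
    )

    # MSY: one copy plus the mosaic shift; BAF uninformative (hemizygous)
    n_y = model.n_msy_probes
    mean_y = model.expected_one_copy + lrr_shift(f, event, model)
    frames.append(
        pd.DataFrame(
            {
                "name": [f"rsY{i:06d}" for i in range(n_y)],
                "chrom": "Y",
                "position": np.linspace(msy.start, msy.end, n_y).astype(int),
                "lrr": rng.normal(mean_y, model.sigma_y, n_y),
                "baf": np.nan,
                "genotype": None,
            }
        )
    )

    # PAR1 (X side): disomic LRR; BAF carries the allelic imbalance
    n_p = model.n_par_probes
    n_het = int(round(model.het_fraction * n_p))
    bdev = bdev_from_cellularity(f, kind="loss" if event == "LOY" else "gain") if event != "none" else 0.0
    centers = np.empty(n_p)
    genotypes = np.empty(n_p, dtype=object)
    het_sign = np.where(np.arange(n_het) % 2 == 0, 1.0, -1.0)  # exact even split
    centers[:n_het] = 0.5 + het_sign * bdev
    genotypes[:n_het] = "AB"
    n_hom = n_p - n_het
    hom_centers = np.where(np.arange(n_hom) % 2 == 0, 0.0, 1.0)
    centers[n_het:] = hom_centers
    genotypes[n_het:] = np.where(hom_centers == 0.0, "AA", "BB")
    baf = np.clip(centers + rng.normal(0.0, model.baf_noise, n_p), 0.0, 1.0)
    frames.append(
        pd.DataFrame(
            {
                "name": [f"rsP{i:06d}" for i in range(n_p)],
                "chrom": "X",
                "position": np.linspace(par1.start, par1.end, n_p).astype(int),
                "lrr": rng.normal(0.0, model.sigma_auto, n_p),
                "baf": baf,
                "genotype": genotypes,
            }
        )
    )

    data = SampleData.from_dataframe(sample_id, pd.concat(frames, ignore_index=True))
    truth = {
        "sample_id": sample_id,
        "event": event,
        "cellularity": f,
        "bdev_true": bdev,
        "mlrr_true": mean_y,
    }
    return data, truth


def simulate_cohort(
    scenario: CohortScenario,
    model: SignalModel | None = None,
) -> tuple[list[SampleData], pd.DataFrame]:
    """Simulate a cohort; returns (samples, truth table).

    Events are drawn per the scenario prevalences; per-sample generators
    are spawned deterministically from the scenario seed, so the cohort is
    reproducible and each sample is independent.
    """
    model = model or SignalModel()
    ss = np.random.SeedSequence(scenario.seed)
    master = np.random.default_rng(ss)
    children = ss.spawn(scenario.n_samples)
    events = master.choice(
        ["LOY", "GOY", "none"],
        size=scenario.n_samples,
        p=[
            scenario.loy_prevalence,
            scenario.goy_prevalence,
            1.0 - scenario.loy_prevalence - scenario.goy_prevalence,
        ],
    )
    samples: list[SampleData] = []
    truth_rows = []
    for i, (event, child) in enumerate(zip(events, children)):
        f = _draw_cellularity(scenario.cellularity_law, master) if event != "none" else 0.0
        data, truth = simulate_sample(
            f, event, model=model, seed=child, sample_id=f"sim{i:04d}"
        )
        samples.append(data)
        truth_rows.append(truth)
    return samples, pd.DataFrame(truth_rows)


def simulate_mlrr_mixture(
    n: int,
    loy_prevalence: float,
    mean_normal: float = EXPECTED_ONE_COPY,
    sd_normal: float = 0.07,
    mean_loy: float = -1.1,
    sd_loy: float = 0.15,
    goy_prevalence: float = 0.0,
    mean_goy: float | None = None,
    sd_goy: float | None = None,
    normal_dist: Literal["normal", "uniform"] = "normal",
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw cohort mLRR-Y values from a labelled mixture.

    Returns (values, labels) with labels in {"normal", "LOY", "GOY"}.
    ``mean_goy`` defaults to the mirror of the LOY shift above the normal
    component; ``sd_goy`` defaults to ``sd_normal``. The no-event component
    is Gaussian by default; ``normal_dist="uniform"`` draws it uniform with
    the same mean and sd (support mean +/- sd*sqrt(3)), a platykurtic core
    emulating cohorts whose mLRR-Y dispersion is lighter-tailed than a
    Gaussian, as array data typically are.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    if mean_goy is None:
        mean_goy = mean_normal + (mean_normal - mean_loy)
    if sd_goy is None:
        sd_goy = sd_normal
    labels = rng.choice(
        ["LOY", "GOY", "normal"],
        size=n,
        p=[loy_prevalence, goy_prevalence, 1.0 - loy_prevalence - goy_prevalence],
    )
    if normal_dist == "uniform":
        half = sd_normal * np.sqrt(3.0)
        values = rng.uniform(mean_normal - half, mean_normal + half, n)
    elif normal_dist == "normal":
        values = rng.normal(mean_normal, sd_normal, n)
    else:
        raise ValueError(f"unknown normal_dist {normal_dist!r}")
    values[labels == "LOY"] = rng.normal(mean_loy, sd_loy, int((labels == "LOY").sum()))
    values[labels == "GOY"] = rng.normal(mean_goy, sd_goy, int((labels == "GOY").sum()))
    return values, labels


def simulate_outcome(
    loy_indicator: Sequence[bool],
    kind: Literal["continuous", "binary"],
    effect: float,
    noise_sd: float = 1.0,
    baseline_prob: float = 0.5,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Outcome conditional on true mLOY status.

    continuous: y = effect * 1[LOY] + Normal(0, noise_sd)  (effect = beta)
    binary:     logit P(y=1) = logit(baseline_prob) + log(effect) * 1[LOY]
                (effect = odds ratio, must be > 0)
    """
    ind = np.asarray(loy_indicator, dtype=float)
    rng = _rng(seed)
    if kind == "continuous":
        return effect * ind + rng.normal(0.0, noise_sd, ind.size)
    if kind == "binary":
        if not effect > 0:
            raise ValueError("odds-ratio effect must be > 0")
        logit = np.log(baseline_prob / (1.0 - baseline_prob)) + np.log(effect) * ind
        p = 1.0 / (1.0 + np.exp(-logit))
        return rng.binomial(1, p).astype(float)
    raise ValueError(f"unknown outcome kind {kind!r}")
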