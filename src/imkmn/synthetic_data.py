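"""Synthetic dose-response data generation.

Stands in for wet-lab measurements (clonogenic survival and micronucleus
scoring) and for Monte Carlo microdosimetry when exercising the model and
the fitting machinery.  Mean responses come from the closed-form model;
noise emulates typical assay scatter:

* survival: lognormal multiplicative noise on S (default CV 15%, typical of
  clonogenic assays), i.e. Gaussian noise on -ln S;
* MN frequency: Gaussian relative noise on the expected count (default CV
  10%), or Poisson sampling of MN over a finite number of scored cells
  (default 200 per culture).

Each dose point is measured in ``replicates`` independent replicates
(default 3); the tabulated value is the replicate mean and the recorded SD
is the standard error of that mean.  Dose-zero rows are normalisation
controls and are emitted noiseless (S = 1, MN = 0).  All generators are
reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    CellParameters,
    IrradiationSchedule,
    RadiationQuality,
    mn_frequency,
    protraction_factor_schedule,
    surviving_fraction,
)
from .inference import DataError, DoseResponseDataset

__all__ = [
    "NoiseModel",
    "simulate_survival_dataset",
    "simulate_mn_dataset",
    "simulate_survival_mn_pairs",
    "paper_doserate_schedules",
    "DEFAULT_DOSES",
]

#: Default dose grid, Gy: spans the range where both LQ coefficients are
#: identifiable in typical survival experiments.
DEFAULT_DOSES = np.arange(0.0, 9.0, 1.0)


@dataclass
class NoiseModel:
    """Assay noise description.

    ``kind``: "lognormal_s" (multiplicative on survival), "gaussian_lns"
    (additive on -ln S), or "gaussian_mn" (relative Gaussian on the MN
    count).  ``scale`` is the relative CV for the lognormal/MN kinds and the
    absolute SD on -ln S for "gaussian_lns".  ``replicates`` independent
    measurements are averaged per dose point.
    """

    kind: str = "lognormal_s"
    scale: float = 0.15
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal_s", "gaussian_lns", "gaussian_mn"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("noise scale must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _protraction(schedule: IrradiationSchedule | None, a_plus_c: float) -> float:
    if schedule is None:
        return 1.0
    return float(protraction_factor_schedule(schedule, a_plus_c))


def _aggregate(reps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replicate mean and its standard error (0 where replicates == 1)."""
    mean = reps.mean(axis=0)
    n = reps.shape[0]
    if n > 1:
        sem = reps.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return mean, sem


def simulate_survival_dataset(
    params: CellParameters,
    quality: RadiationQuality | None = None,
    schedule: IrradiationSchedule | None = None,
    doses=DEFAULT_DOSES,
    noise: NoiseModel | None = None,
    label: str = "",
) -> DoseResponseDataset:
    """Noisy clonogenic-survival dataset drawn around the model curve."""
    quality = quality or RadiationQuality()
    noise = noise or NoiseModel()
    doses = np.asarray(doses, dtype=float)
    f_factor = _protraction(schedule, params.a_plus_c)
    s_true = np.asarray(surviving_fraction(params, quality, doses, f_factor))
    rng = np.random.default_rng(noise.seed)
    if noise.scale == 0:
        values, sem = s_true.copy(), np.zeros_like(s_true)
    else:
        if noise.kind == "gaussian_mn":
            raise ValueError("gaussian_mn noise applies to MN datasets only")
        sigma = noise.scale  # both kinds act on the -ln S scale
        eps = rng.normal(0.0, sigma, size=(noise.replicates, doses.size))
        reps = s_true * np.exp(eps)
        values, sem = _aggregate(reps)
        control = doses == 0.0  # normalisation: S(0) is 1 by definition
        values[control], sem[control] = 1.0, 0.0
        values = np.clip(values, 1e-12, 1.0)
    return DoseResponseDataset(
        doses=doses,
        values=values,
        sd=sem,
        endpoint_kind="survival",
        quality=quality,
        schedule=schedule,
        label=label or f"synthetic survival {params.label}".strip(),
    )


def simulate_mn_dataset(
    params: CellParameters,
    quality: RadiationQuality | None = None,
    schedule: IrradiationSchedule | None = None,
    doses=DEFAULT_DOSES,
    noise: NoiseModel | None = None,
    poisson_cells: int | None = None,
    label: str = "",
) -> DoseResponseDataset:
    """Noisy micronucleus dataset (expected MN per cell) around the model curve.

    With ``poisson_cells`` set, each replicate scores that many cells and the
    recorded value is total MN / cells scored (Poisson sampling); otherwise
    Gaussian relative noise of CV ``noise.scale`` is applied.
    """
    quality = quality or RadiationQuality()
    noise = noise or NoiseModel(kind="gaussian_mn", scale=0.10)
    doses = np.asarray(doses, dtype=float)
    f_factor = _protraction(schedule, params.a_plus_c)
    mn_true = np.asarray(mn_frequency(params, quality, doses, f_factor))
    rng = np.random.default_rng(noise.seed)
    if poisson_cells is not None:
        if poisson_cells < 1:
            raise ValueError("must score at least one cell")
        counts = rng.poisson(mn_true * poisson_cells, size=(noise.replicates, doses.size))
        reps = counts / poisson_cells
        values, sem = _aggregate(reps)
    elif noise.scale == 0:
        values, sem = mn_true.copy(), np.zeros_like(mn_true)
    else:
        eps = rng.normal(0.0, noise.scale, size=(noise.replicates, doses.size))
        reps = np.clip(mn_true * (1.0 + eps), 0.0, None)
        values, sem = _aggregate(reps)
        control = doses == 0.0
        values[control], sem[control] = mn_true[control], 0.0
    return DoseResponseDataset(
        doses=doses,
        values=values,
        sd=sem,
        endpoint_kind="mn_per_cell",
        quality=quality,
        schedule=schedule,
        label=label or f"synthetic MN {params.label}".strip(),
    )


def simulate_survival_mn_pairs(
    h: float = 0.275,
    n_pairs: int = 50,
    lethal_lesion_range: tuple[float, float] = (0.1, 4.0),
    noise_cv: float = 0.10,
    seed: int = 0,
    groups: int = 1,
    group_h: np.ndarray | None = None,
) -> np.ndarray:
    """Paired (-ln S, MN per cell) observations across cell lines/qualities.

    Lethal-lesion counts are spread uniformly over ``lethal_lesion_range``
    and MN frequencies generated as h * <w> with Gaussian relative noise of
    CV ``noise_cv``.  With ``groups`` > 1 (and optionally distinct
    ``group_h``), the pairs emulate a pooled multi-cell-line compilation;
    the returned array then has a third column holding the group index.
    """
    if not 0.0 <= h <= 1.0:
        raise DataError("h must lie in [0, 1]")
    if n_pairs < 2:
        raise DataError("need at least two pairs")
    rng = np.random.default_rng(seed)
    w = np.linspace(*lethal_lesion_range, n_pairs)
    if groups == 1:
        mn = h * w * (1.0 + rng.normal(0.0, noise_cv, size=n_pairs))
        return np.column_stack([w, np.clip(mn, 0.0, None)])
    hs = np.asarray(group_h if group_h is not None else np.full(groups, h), dtype=float)
    idx = np.arange(n_pairs) % groups
    mn = hs[idx] * w * (1.0 + rng.normal(0.0, noise_cv, size=n_pairs))
    return np.column_stack([w, np.clip(mn, 0.0, None), idx.astype(float)])


def paper_doserate_schedules(total_dose: float = 4.0) -> list[IrradiationSchedule]:
    """The four X-ray delivery regimens of the dose-rate experiment.

    All regimens deliver ``total_dose`` Gy at an instantaneous beam-on rate
    of 1 Gy/min (60 Gy/h); the average dose rate is set by fractionation:

    * continuous delivery (average 1.0 Gy/min);
    * 0.5 Gy/fraction, 30 s on + 30 s off (average 0.5 Gy/min);
    * 0.1 Gy/fraction, 6 s on + 54 s off (average 0.1 Gy/min);
    * 0.05 Gy/fraction, 3 s on + 57 s off (average 0.05 Gy/min).
    """
    if total_dose <= 0:
        raise ValueError("total dose must be positive")
    beam_rate = 60.0  # Gy/h == 1 Gy/min
    schedules = [
        IrradiationSchedule.continuous(total_dose, total_dose / beam_rate, label="1.0 Gy/min"),
    ]
    for d_fr, on_s, off_s, label in (
        (0.5, 30.0, 30.0, "0.5 Gy/min"),
        (0.1, 6.0, 54.0, "0.1 Gy/min"),
        (0.05, 3.0, 57.0, "0.05 Gy/min"),
    ):
        n_fr = total_dose / d_fr
        if abs(n_fr - round(n_fr)) > 1e-9:
            raise ValueError(f"total dose {total_dose} not divisible into {d_fr} Gy fractions")
        schedules.append(
            IrradiationSchedule.fractionated(
                d_fr, int(round(n_fr)), on_s / 3600.0, off_s / 3600.0, label=label
            )
        )
    return schedules
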