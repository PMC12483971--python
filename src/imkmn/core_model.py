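"""Closed-form microdosimetric-kinetic (MK) predictions.

The model describes radiation-induced potentially lethal lesions (PLLs) in
sub-micrometre nuclear domains.  PLLs convert to lethal lesions (LLs) by
first-order misrepair or pairwise interaction, or are repaired at first-order
rate; solving the lesion kinetics gives the mean LL count per nucleus

    <w> = (alpha0 + z1D* * beta0) * D + F * beta0 * D^2,

with survival S = exp(-<w>).  Here ``z1D*`` carries radiation quality (LET)
and ``F`` is the Lea-Catcheside dose-protraction factor, which discounts the
quadratic (two-track) term when sublethal damage is repaired (composite rate
``a+c`` per hour) during a protracted or fractionated delivery.

Micronucleus (MN) formation is modelled as a fixed probability ``h`` that an
LL transformation yields an MN, so the expected MN count per cell is exactly
proportional to the lethal-lesion count:

    F_MN = h * <w>  =  (alpha_m0 + z1D* * beta_m0) D + F beta_m0 D^2,

with alpha_m0 = h*alpha0 and beta_m0 = h*beta0.  Relative biological
effectiveness is provided both for survival (ratio of 10%-survival doses,
``rbe_sf``) and for MN induction (ratio of initial slopes, ``rbe_mn``); the
latter is independent of h by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellParameters",
    "RadiationQuality",
    "IrradiationSchedule",
    "ScheduleError",
    "UndefinedDoseError",
    "protraction_factor_continuous",
    "protraction_factor_schedule",
    "mean_lethal_lesions",
    "surviving_fraction",
    "mn_frequency",
    "d10",
    "survival_dose",
    "rbe_sf",
    "rbe_mn",
    "relative_mn_vs_doserate",
]


class ScheduleError(ValueError):
    """Raised for malformed or inconsistent irradiation schedules."""


class UndefinedDoseError(ValueError):
    """Raised when an iso-effect dose is undefined (alpha = beta = 0)."""


@dataclass
class CellParameters:
    """Cell-line specific model parameters.

    alpha0 (Gy^-1) and beta0 (Gy^-2) are the intrinsic linear and quadratic
    lethal-lesion coefficients; ``a_plus_c`` (h^-1) the composite sublethal
    damage repair rate; ``r_d`` (um) the nuclear domain radius; ``h_mn`` the
    probability that a lethal-lesion transformation forms a micronucleus.
    """

    alpha0: float
    beta0: float
    a_plus_c: float = 2.19
    r_d: float = 0.42
    h_mn: float = 0.275
    label: str = ""

    def __post_init__(self) -> None:
        if self.alpha0 < 0 or self.beta0 < 0:
            raise ValueError("alpha0 and beta0 must be non-negative")
        if self.a_plus_c <= 0:
            raise ValueError("repair rate (a+c) must be positive")
        if not 0.0 <= self.h_mn <= 1.0:
            raise ValueError("MN formation probability h must lie in [0, 1]")

    @property
    def alpha_m0(self) -> float:
        """Linear MN coefficient h*alpha0, Gy^-1."""
        return self.h_mn * self.alpha0

    @property
    def beta_m0(self) -> float:
        """Quadratic MN coefficient h*beta0, Gy^-2."""
        return self.h_mn * self.beta0


@dataclass
class RadiationQuality:
    """Radiation quality as the saturation-corrected specific energy z1D* (Gy)."""

    z1dstar: float = 0.0
    label: str = "photon"

    def __post_init__(self) -> None:
        if self.z1dstar < 0:
            raise ValueError("z1D* must be non-negative")

    def alpha(self, params: CellParameters) -> float:
        """Effective linear coefficient alpha = alpha0 + z1D* beta0, Gy^-1."""
        return params.alpha0 + self.z1dstar * params.beta0


@dataclass
class IrradiationSchedule:
    """Piecewise-constant dose-rate time course.

    ``segments`` is an ordered list of (start_h, duration_h, doserate_Gy_per_h)
    tuples; segments must be chronological and non-overlapping.  ``t_end``
    optionally extends the bookkeeping delivery time past the last segment
    (e.g. a trailing beam-off interval of a fractionated regimen), so that
    ``average_dose_rate`` matches the nominal regimen value; it never affects
    the protraction factor, which only sees beam-on segments.
    """

    segments: list[tuple[float, float, float]]
    t_end: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ScheduleError("schedule needs at least one segment")
        prev_end = -math.inf
        for start, duration, rate in self.segments:
            if duration < 0 or rate < 0:
                raise ScheduleError("durations and dose rates must be non-negative")
            if start < prev_end - 1e-12:
                raise ScheduleError("segments overlap or are out of order")
            prev_end = start + duration
        if self.t_end is not None and self.t_end < prev_end - 1e-12:
            raise ScheduleError("t_end precedes the last segment")

    @classmethod
    def continuous(cls, dose: float, duration_h: float, label: str = "") -> "IrradiationSchedule":
        """Single uninterrupted exposure delivering ``dose`` Gy over ``duration_h`` h."""
        if duration_h <= 0:
            raise ScheduleError("continuous exposure needs positive duration")
        return cls([(0.0, duration_h, dose / duration_h)], label=label)

    @classmethod
    def acute(cls, dose: float, label: str = "acute") -> "IrradiationSchedule":
        """Effectively instantaneous delivery (1 ms), F = 1 for practical repair rates."""
        duration = 1e-3 / 3600.0
        return cls([(0.0, duration, dose / duration)], label=label)

    @classmethod
    def fractionated(
        cls,
        dose_per_fraction: float,
        n_fractions: int,
        delivery_h: float,
        interval_h: float,
        label: str = "",
    ) -> "IrradiationSchedule":
        """Equal fractions: each delivered over ``delivery_h``, then ``interval_h`` beam-off."""
        if n_fractions < 1:
            raise ScheduleError("need at least one fraction")
        if delivery_h <= 0:
            raise ScheduleError("fraction delivery time must be positive")
        period = delivery_h + interval_h
        rate = dose_per_fraction / delivery_h
        segments = [(k * period, delivery_h, rate) for k in range(n_fractions)]
        return cls(segments, t_end=n_fractions * period, label=label)

    @property
    def total_dose(self) -> float:
        """Total absorbed dose D, Gy."""
        return float(sum(d * r for _, d, r in self.segments))

    @property
    def total_time(self) -> float:
        """Overall delivery time T, h (first beam-on to t_end or last beam-off)."""
        start0 = self.segments[0][0]
        last = self.segments[-1][0] + self.segments[-1][1]
        return (self.t_end if self.t_end is not None else last) - start0

    @property
    def average_dose_rate(self) -> float:
        """Time-averaged dose rate D/T, Gy/h."""
        return self.total_dose / self.total_time


def _g_factor(x):
    """g(x) = 2 (x + e^-x - 1) / x^2, the continuous Lea-Catcheside kernel.

    Series for small x avoids catastrophic cancellation; g(0) = 1.
    """
    x = np.asarray(x, dtype=float)
    small = x < 1e-4
    xs = np.where(small, 0.0, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = 2.0 * (xs + np.expm1(-xs)) / xs**2
    series = 1.0 - x / 3.0 + x**2 / 12.0
    out = np.where(small, series, exact)
    return out if out.ndim else float(out)


def protraction_factor_continuous(a_plus_c: float, duration_h: float):
    """Lea-Catcheside factor F for a single continuous exposure of length T.

    F = 2/((a+c)^2 T^2) * [(a+c) T + exp(-(a+c) T) - 1];  F -> 1 as T -> 0
    (acute limit) and F ~ 2/((a+c)T) for long exposures.
    """
    if a_plus_c <= 0:
        raise ValueError("repair rate (a+c) must be positive")
    durations = np.asarray(duration_h, dtype=float)
    if np.any(durations < 0):
        raise ScheduleError("delivery time must be non-negative")
    return _g_factor(a_plus_c * durations)


def _schedule_pair_arrays(schedule: IrradiationSchedule) -> dict:
    """Cached per-schedule segment and ordered-pair arrays for F evaluation."""
    cache = getattr(schedule, "_pf_cache", None)
    if cache is not None:
        return cache
    segs = [(s, d, r) for (s, d, r) in schedule.segments if d > 0 and r > 0]
    starts = np.array([s for s, _, _ in segs])
    durs = np.array([d for _, d, _ in segs])
    rates = np.array([r for _, _, r in segs])
    i, j = np.triu_indices(len(segs), k=1)
    cache = {
        "durs": durs,
        "rates": rates,
        "di": durs[i],
        "dj": durs[j],
        "rij": rates[i] * rates[j],
        "gap": np.clip(starts[j] - (starts[i] + durs[i]), 0.0, None),
    }
    object.__setattr__(schedule, "_pf_cache", cache)
    return cache


def protraction_factor_schedule(schedule: IrradiationSchedule, a_plus_c) -> float:
    """Lea-Catcheside factor for an arbitrary piecewise-constant schedule.

    F = (2/D^2) * iint_{t'<t} R(t) R(t') exp(-(a+c)(t-t')) dt' dt

    evaluated in closed form per segment pair: the within-segment (triangle)
    term is R_i^2 T_i^2 g((a+c) T_i)/2 and each ordered pair i<j separated
    by a beam-off gap contributes
    R_i R_j (1-e^{-k T_i})(1-e^{-k T_j}) e^{-k gap} / k^2.  For one segment
    this reduces to :func:`protraction_factor_continuous`; for two short
    fractions D/2 separated by dt it gives the textbook split-dose value
    (1 + exp(-(a+c) dt))/2.  ``a_plus_c`` may be an array (vectorised over
    repair rates), returning an array of F values.
    """
    kappa = np.asarray(a_plus_c, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("repair rate (a+c) must be positive")
    dose = schedule.total_dose
    if dose <= 0:
        raise ScheduleError("schedule delivers zero dose")
    arrays = _schedule_pair_arrays(schedule)
    scalar = kappa.ndim == 0
    kcol = np.atleast_1d(kappa)[:, None]
    npairs = arrays["gap"].size

    def accumulate(kc):
        acc = np.sum(
            arrays["rates"] ** 2 * arrays["durs"] ** 2 * _g_factor(kc * arrays["durs"]) / 2.0,
            axis=-1,
        )
        if npairs:
            acc = acc + np.sum(
                arrays["rij"]
                * np.expm1(-kc * arrays["di"])
                * np.expm1(-kc * arrays["dj"])
                * np.exp(-kc * arrays["gap"])
                / kc**2,
                axis=-1,
            )
        return acc

    # chunk very large kappa batches to bound temporary-array memory
    if kcol.shape[0] * max(npairs, 1) > 4_000_000:
        parts = [accumulate(kcol[s : s + 1024]) for s in range(0, kcol.shape[0], 1024)]
        acc = np.concatenate(parts)
    else:
        acc = accumulate(kcol)
    out = 2.0 * acc / dose**2
    return float(out[0]) if scalar else out.reshape(np.shape(kappa))


def mean_lethal_lesions(
    params: CellParameters,
    quality: RadiationQuality,
    dose,
    protraction: float = 1.0,
):
    """Mean lethal lesions per nucleus <w> at absorbed dose D (Gy).

    <w> = (alpha0 + z1D* beta0) D + F beta0 D^2.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    alpha = params.alpha0 + quality.z1dstar * params.beta0
    w = alpha * dose + protraction * params.beta0 * dose**2
    return w if w.ndim else float(w)


def surviving_fraction(
    params: CellParameters,
    quality: RadiationQuality,
    dose,
    protraction: float = 1.0,
):
    """Surviving fraction S = exp(-<w>)."""
    w = mean_lethal_lesions(params, quality, dose, protraction)
    s = np.exp(-np.asarray(w))
    return s if s.ndim else float(s)


def mn_frequency(
    params: CellParameters,
    quality: RadiationQuality,
    dose,
    protraction: float = 1.0,
):
    """Expected micronuclei per cell, F_MN = h * <w>."""
    w = mean_lethal_lesions(params, quality, dose, protraction)
    out = params.h_mn * np.asarray(w)
    return out if out.ndim else float(out)


def survival_dose(alpha: float, beta: float, survival: float = 0.10) -> float:
    """Dose giving the requested surviving fraction under S = exp(-aD - bD^2).

    Solves alpha D + beta D^2 = -ln(survival) with S* = -ln(survival) via the
    rationalised quadratic root, which degrades gracefully to the linear
    limit S*/alpha as beta -> 0 and to sqrt(S*/beta) as alpha -> 0.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    if not 0.0 < survival < 1.0:
        raise ValueError("survival level must be in (0, 1)")
    s_star = -math.log(survival)
    if alpha == 0.0 and beta == 0.0:
        raise UndefinedDoseError("iso-effect dose undefined for alpha = beta = 0")
    # rationalised root 2 S*/(sqrt(a^2+4bS*)+a): no cancellation as beta -> 0
    return 2.0 * s_star / (math.sqrt(alpha**2 + 4.0 * beta * s_star) + alpha)


def d10(alpha: float, beta: float) -> float:
    """Dose leading to 10% survival, D10 = [sqrt(a^2+4b ln10) - a]/(2b)."""
    return survival_dose(alpha, beta, survival=0.10)


def rbe_sf(
    params: CellParameters,
    quality_test: RadiationQuality,
    quality_photon: RadiationQuality,
    survival: float = 0.10,
) -> float:
    """RBE for cell survival: iso-effect dose ratio at the given survival level.

    Acute irradiation is assumed (beta = beta0) so only the linear
    coefficient alpha = alpha0 + z1D* beta0 differs between qualities.
    """
    d_photon = survival_dose(quality_photon.alpha(params), params.beta0, survival)
    d_test = survival_dose(quality_test.alpha(params), params.beta0, survival)
    return d_photon / d_test


def rbe_mn(
    params: CellParameters,
    quality_test: RadiationQuality,
    quality_photon: RadiationQuality,
) -> float:
    """Maximum RBE for MN induction: initial-slope ratio alpha_m*/alpha_m(photon).

    Because alpha_m = h * alpha, the MN-formation probability h cancels and
    RBE_MN = (alpha0 + z1D*_test beta0) / (alpha0 + z1D*_photon beta0).
    """
    alpha_photon = quality_photon.alpha(params)
    if alpha_photon <= 0:
        raise UndefinedDoseError("photon reference has zero initial slope")
    return quality_test.alpha(params) / alpha_photon


def relative_mn_vs_doserate(
    params: CellParameters,
    quality: RadiationQuality,
    total_dose: float,
    schedules: list[IrradiationSchedule],
    reference_schedule: IrradiationSchedule,
    rtol: float = 1e-6,
) -> list[float]:
    """MN frequency of each schedule relative to a high-dose-rate reference.

    All schedules must deliver ``total_dose``; each value is
    F_MN(schedule) / F_MN(reference), so the reference maps to 1.0 and slower
    deliveries are discounted through the protraction factor.
    """
    for sched in list(schedules) + [reference_schedule]:
        if not math.isclose(sched.total_dose, total_dose, rel_tol=rtol):
            raise ScheduleError(
                f"schedule {sched.label!r} delivers {sched.total_dose:.6g} Gy, "
                f"expected {total_dose:.6g} Gy"
            )
    f_ref = protraction_factor_schedule(reference_schedule, params.a_plus_c)
    mn_ref = mn_frequency(params, quality, total_dose, f_ref)
    out = []
    for sched in schedules:
        f = protraction_factor_schedule(sched, params.a_plus_c)
        out.append(mn_frequency(params, quality, total_dose, f) / mn_ref)
    return out
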