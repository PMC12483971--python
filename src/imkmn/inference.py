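"""Bayesian parameter estimation for the microdosimetric-kinetic model.

Fitting follows a Metropolis scheme with uniform priors: the likelihood is
Gaussian on the transformed endpoint (-ln S for survival, the expected count
for micronuclei),

    P(d | theta) = prod_i (2 pi sigma_i^2)^(-1/2)
                   exp[-(y_i - y_model,i(theta))^2 / (2 sigma_i^2)],

and a candidate parameter set is accepted with probability
min(1, P(theta_cand | d) / P(theta_t | d)).  Candidates come from a Gaussian
random walk by default, with steps sized from the weighted least-squares
covariance; an independence sampler drawing candidates straight from the
uniform prior (acceptance ratio = likelihood ratio) is available but mixes
poorly when the posterior is much narrower than the prior.  Burn-in and
retained sample counts default to 10^3 and 10^4.

The module also provides the through-origin fit of MN frequency against the
lethal-lesion count (estimating the MN-formation probability h), grid-search
calibration of the domain radius r_d against multi-LET datasets, pointwise
credible-band propagation of posterior draws through any model prediction,
and the coefficient of determination R^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .core_model import (
    IrradiationSchedule,
    RadiationQuality,
    protraction_factor_schedule,
)
from .microdosimetry import DomainGeometry, MicrodosimetricSpectrum, compute_ystar, compute_z1dstar

__all__ = [
    "DoseResponseDataset",
    "FitConfig",
    "PosteriorSamples",
    "PredictionBand",
    "RdCalibration",
    "HEstimate",
    "ConfigError",
    "DataError",
    "SamplerDiagnosticsError",
    "log_likelihood",
    "mcmc_fit",
    "estimate_h",
    "calibrate_rd",
    "propagate_uncertainty",
    "r_squared",
]

_ENDPOINTS = ("survival", "mn_per_cell", "mn_fraction")

#: default uniform prior bounds per parameter
DEFAULT_PRIORS = {
    "alpha0": (0.0, 2.0),
    "beta0": (0.0, 0.5),
    "a_plus_c": (0.05, 10.0),
    "alpha_m0": (0.0, 2.0),
    "beta_m0": (0.0, 0.5),
    "h": (0.0, 1.0),
}


class ConfigError(ValueError):
    """Raised for invalid fit configuration."""


class DataError(ValueError):
    """Raised for datasets violating their invariants."""


class SamplerDiagnosticsError(RuntimeError):
    """Raised when the Metropolis chain fails to move at all."""


@dataclass
class DoseResponseDataset:
    """Dose-response observations for one irradiation condition.

    ``doses`` (Gy), ``values`` (surviving fraction or MN frequency) and
    optional per-point ``sd`` (uncertainty of the tabulated value, same scale
    as ``values``; NaN where unavailable).  ``quality`` and ``schedule``
    describe the condition; an absent schedule means acute delivery (F = 1).
    ``spectrum`` optionally carries the lineal-energy distribution the
    quality was derived from, which r_d calibration needs.
    """

    doses: np.ndarray
    values: np.ndarray
    sd: np.ndarray | None = None
    endpoint_kind: str = "survival"
    quality: RadiationQuality = field(default_factory=RadiationQuality)
    schedule: IrradiationSchedule | None = None
    spectrum: MicrodosimetricSpectrum | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.endpoint_kind not in _ENDPOINTS:
            raise DataError(f"unknown endpoint kind {self.endpoint_kind!r}")
        if self.doses.shape != self.values.shape or self.doses.ndim != 1:
            raise DataError("doses and values must be 1-D arrays of equal length")
        if np.any(self.doses < 0):
            raise DataError("doses must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.doses.shape:
                raise DataError("sd must match doses in length")
            if np.any(self.sd[np.isfinite(self.sd)] < 0):
                raise DataError("sd must be non-negative")
        bad: list[int] = []
        if self.endpoint_kind == "survival":
            bad = [i for i, v in enumerate(self.values) if not 0.0 < v <= 1.0]
        elif self.endpoint_kind == "mn_fraction":
            bad = [i for i, v in enumerate(self.values) if not 0.0 <= v < 1.0]
        else:
            bad = [i for i, v in enumerate(self.values) if v < 0.0]
        if bad:
            raise DataError(
                f"invalid {self.endpoint_kind} value(s) at row(s) {bad}: "
                f"{[float(self.values[i]) for i in bad]}"
            )

    def __len__(self) -> int:
        return int(self.doses.size)

    def require_fittable(self) -> None:
        if len(self) < 3:
            raise DataError("need at least 3 records for fitting")


@dataclass
class FitConfig:
    """Metropolis sampler configuration.

    ``priors`` maps parameter names to finite (lower, upper) uniform bounds;
    the keys define which parameters are sampled.  Naming ``sigma`` in the
    priors samples the (homoscedastic) noise SD jointly with the model
    parameters.  ``sigma_policy`` selects how the fixed noise SDs are built:
    "pooled" (default: one constant on the fitting scale, estimated from
    preliminary least-squares residuals — the likelihood carries a single
    sigma), "relative" (sigma_i proportional to the fitted mean, the correct
    weighting when scatter is a constant coefficient of variation, as in
    micronucleus scoring), or "per-point" (experimental SDs; beware that SDs
    estimated from very few replicates make unstable weights).  ``sigma0``
    fixes the pooled constant (or relative CV) explicitly.  ``proposal`` is
    "gaussian-walk" (default; steps sized from the weighted least-squares
    covariance when ``walk_scale`` is "auto", else the given fraction of
    each prior width) or "prior-independence" (candidates drawn from the
    prior itself; exact but inefficient when the posterior is much narrower
    than the prior).
    """

    priors: dict[str, tuple[float, float]]
    n_burn: int = 1000
    n_samples: int = 10000
    seed: int = 0
    proposal: str = "gaussian-walk"
    walk_scale: float | str = "auto"
    sigma_policy: str = "pooled"
    sigma0: float | None = None
    theta0: dict[str, float] | None = None
    mn_fraction_link: bool = False

    def __post_init__(self) -> None:
        if not self.priors:
            raise ConfigError("priors must name at least one parameter")
        for name, (lo, hi) in self.priors.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigError(f"prior bounds for {name!r} must be finite with lo < hi")
        if "sigma" in self.priors and self.priors["sigma"][0] <= 0:
            raise ConfigError("the prior on sigma must have a positive lower bound")
        if self.n_burn <= 0 or self.n_samples <= 0:
            raise ConfigError("n_burn and n_samples must be positive")
        if self.proposal not in ("prior-independence", "gaussian-walk"):
            raise ConfigError(f"unknown proposal {self.proposal!r}")
        if isinstance(self.walk_scale, str):
            if self.walk_scale != "auto":
                raise ConfigError("walk_scale must be a positive float or 'auto'")
        elif self.walk_scale <= 0:
            raise ConfigError("walk_scale must be a positive float or 'auto'")
        if self.sigma_policy not in ("per-point", "pooled", "relative"):
            raise ConfigError(f"unknown sigma policy {self.sigma_policy!r}")
        if self.sigma0 is not None and self.sigma0 <= 0:
            raise ConfigError("sigma0 must be positive")


@dataclass
class PosteriorSamples:
    """Retained Metropolis draws after burn-in."""

    draws: np.ndarray  # (n_samples, n_params)
    param_names: list[str]
    acceptance_rate: float
    config: FitConfig

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.param_names):
            raise ValueError("draws must be (n_samples, n_params)")

    def mean(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.draws.mean(axis=0)))

    def sd(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.draws.std(axis=0, ddof=1)))

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.param_names.index(name)]

    def summary(self) -> dict[str, dict[str, float]]:
        m, s = self.mean(), self.sd()
        return {k: {"mean": m[k], "sd": s[k]} for k in self.param_names}


@dataclass
class PredictionBand:
    """Pointwise posterior mean and equal-tailed credible band."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


@dataclass
class RdCalibration:
    """Result of the grid search for the domain radius."""

    r_d: float
    grid: np.ndarray
    rss_profile: np.ndarray
    flat: bool = False


@dataclass
class HEstimate:
    """MN-formation probability estimate with uncertainty."""

    mean: float
    sd: float
    samples: PosteriorSamples | None = None


# ---------------------------------------------------------------------------
# model evaluation shared by the likelihood and the samplers


def _dataset_target(dataset: DoseResponseDataset, allow_fraction_link: bool):
    """Observed values and per-point noise SD on the model's fitting scale.

    Survival is fitted on -ln S (sigma mapped by the delta method
    sigma_lnS = sd_S / S); MN counts are fitted directly.  MN-bearing-cell
    fractions are only fitted through the opt-in Poisson link
    F_MN = -ln(1 - fraction).
    """
    if dataset.endpoint_kind == "survival":
        y = -np.log(dataset.values)
        sd = None if dataset.sd is None else dataset.sd / dataset.values
    elif dataset.endpoint_kind == "mn_per_cell":
        y = dataset.values.copy()
        sd = None if dataset.sd is None else dataset.sd.copy()
    else:  # mn_fraction
        if not allow_fraction_link:
            raise ConfigError(
                "dataset holds MN-bearing-cell fractions; enable "
                "FitConfig.mn_fraction_link to fit them through the Poisson "
                "link F_MN = -ln(1 - fraction)"
            )
        y = -np.log1p(-dataset.values)
        sd = None if dataset.sd is None else dataset.sd / (1.0 - dataset.values)
    return y, sd


class _FitProblem:
    """Pre-digested datasets + fixed parameters for fast vectorised likelihoods."""

    def __init__(
        self,
        datasets: list[DoseResponseDataset],
        model_kind: str,
        config: FitConfig,
        fixed: dict[str, float] | None = None,
        min_records: int = 3,
    ):
        if model_kind not in ("survival", "mn"):
            raise ConfigError(f"unknown model kind {model_kind!r}")
        self.model_kind = model_kind
        self.config = config
        self.fixed = dict(fixed or {})
        self.datasets = list(datasets)
        if not self.datasets:
            raise DataError("no datasets supplied")
        expected = "survival" if model_kind == "survival" else ("mn_per_cell", "mn_fraction")
        if sum(len(ds) for ds in self.datasets) < min_records:
            raise DataError(
                f"need at least {min_records} records in total for fitting"
            )
        self._entries = []
        for ds in self.datasets:
            if model_kind == "survival" and ds.endpoint_kind != "survival":
                raise DataError(f"dataset {ds.label!r} is not a survival dataset")
            if model_kind == "mn" and ds.endpoint_kind not in expected:
                raise DataError(f"dataset {ds.label!r} is not an MN dataset")
            y, sd = _dataset_target(ds, config.mn_fraction_link)
            self._entries.append(
                {
                    "doses": ds.doses,
                    "y": y,
                    "sd": sd,
                    "z": ds.quality.z1dstar,
                    "schedule": ds.schedule,
                }
            )
        self.sampled = list(config.priors.keys())
        self._sigma = None  # resolved lazily, may need a preliminary fit
        self._sigma_scale = 1.0

    # -- parameter plumbing -------------------------------------------------
    def _get(self, theta: dict[str, np.ndarray], name: str):
        if name in theta:
            return theta[name]
        if name in self.fixed:
            return self.fixed[name]
        raise ConfigError(f"parameter {name!r} neither sampled nor fixed")

    def _coefficients(self, theta):
        if self.model_kind == "survival":
            return self._get(theta, "alpha0"), self._get(theta, "beta0")
        return self._get(theta, "alpha_m0"), self._get(theta, "beta_m0")

    def predict_one(self, theta: dict[str, np.ndarray], entry) -> np.ndarray:
        """Model curve for one dataset; broadcasts over candidate arrays."""
        lin, quad = self._coefficients(theta)
        lin = np.asarray(lin, dtype=float)
        quad = np.asarray(quad, dtype=float)
        if entry["schedule"] is None:
            f_factor = np.ones_like(lin * 1.0)
        else:
            kappa = np.asarray(self._get(theta, "a_plus_c"), dtype=float)
            f_factor = np.asarray(protraction_factor_schedule(entry["schedule"], kappa))
        doses = entry["doses"]
        # shape (n_candidates, n_doses) or (n_doses,) for scalar theta
        lin_eff = lin + entry["z"] * quad
        return np.multiply.outer(lin_eff, doses) + np.multiply.outer(
            f_factor * quad, doses**2
        )

    def predict(self, theta) -> list[np.ndarray]:
        return [self.predict_one(theta, e) for e in self._entries]

    # -- noise model --------------------------------------------------------
    def _preliminary_theta(self) -> dict[str, float]:
        """Bounded least-squares point estimate used for sigma pooling and chain start."""
        names = self.sampled
        lo = np.array([self.config.priors[n][0] for n in names])
        hi = np.array([self.config.priors[n][1] for n in names])
        x0 = 0.5 * (lo + hi)

        def residuals(x):
            theta = dict(zip(names, x))
            out = []
            for e in self._entries:
                out.append(e["y"] - self.predict_one(theta, e))
            return np.concatenate(out)

        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi))
            x = sol.x
        except Exception:  # fall back to the prior midpoint
            x = x0
        return dict(zip(names, x))

    def resolve_sigma(self) -> list[np.ndarray]:
        """Per-dataset noise SD vectors on the fitting scale.

        Weights are fixed before sampling (evaluated at the preliminary
        least-squares estimate for the "pooled" and "relative" policies), so
        the likelihood normalisation is common to all candidates.
        """
        if self._sigma is not None:
            return self._sigma
        n_model = len([n for n in self.sampled if n != "sigma"])

        def _residual_scale(transform):
            theta = self._preliminary_theta()
            scaled = []
            for e in self._entries:
                pred = self.predict_one(theta, e)
                scaled.append(transform(e["y"] - pred, pred))
            res = np.concatenate(scaled)
            dof = max(res.size - n_model, 1)
            return max(float(np.sqrt(np.sum(res**2) / dof)), 1e-6)

        if self.config.sigma_policy == "relative":
            theta = self._preliminary_theta()
            preds = [np.asarray(self.predict_one(theta, e)) for e in self._entries]
            floor = 0.05 * max(float(np.max(p)) for p in preds)
            floor = max(floor, 1e-9)
            cv = self.config.sigma0
            if cv is None:
                cv = _residual_scale(lambda r, p: r / np.maximum(p, floor))
            sigmas = [cv * np.maximum(p, floor) for p in preds]
            scale = cv
        elif self.config.sigma_policy == "pooled":
            pooled = self.config.sigma0
            if pooled is None:
                pooled = _residual_scale(lambda r, p: r)
            sigmas = [np.full_like(e["y"], pooled) for e in self._entries]
            scale = pooled
        else:  # per-point, with pooled fill-in for missing or zero SDs
            pooled = self.config.sigma0
            if pooled is None and any(
                e["sd"] is None or np.any(~np.isfinite(e["sd"]) | (e["sd"] <= 0))
                for e in self._entries
            ):
                pooled = _residual_scale(lambda r, p: r)
            sigmas = []
            for e in self._entries:
                if e["sd"] is None:
                    sigmas.append(np.full_like(e["y"], pooled))
                else:
                    sd = e["sd"].copy()
                    bad = ~np.isfinite(sd) | (sd <= 0)
                    if np.any(bad):
                        sd[bad] = pooled if pooled is not None else np.median(sd[~bad])
                    sigmas.append(sd)
            scale = 1.0  # sampled sigma multiplies the experimental SDs
        self._sigma = sigmas
        self._sigma_scale = scale
        return sigmas

    def sigma_shapes(self) -> tuple[list[np.ndarray], float]:
        """Noise-shape vectors w_i and reference scale; sigma_i = s * w_i.

        Used when the noise scale ``s`` is sampled: the policy fixes only
        the relative weighting ("relative" makes ``s`` a coefficient of
        variation, "pooled" an absolute SD, "per-point" a multiplier of the
        experimental SDs).
        """
        sigmas = self.resolve_sigma()
        scale = self._sigma_scale
        return [sig / scale for sig in sigmas], scale

    def start_and_steps(self) -> tuple[dict[str, float], np.ndarray]:
        """Weighted least-squares start point and random-walk step sizes.

        Steps follow the classic 2.38/sqrt(k) scaling of the estimated
        posterior SDs (from the Gauss-Newton covariance), clipped to sane
        fractions of the prior width; if the covariance is singular (an
        unidentified direction) the affected step falls back to 5% of the
        prior width.
        """
        names = [n for n in self.sampled if n != "sigma"]
        lo = np.array([self.config.priors[n][0] for n in names])
        hi = np.array([self.config.priors[n][1] for n in names])
        width = hi - lo
        sigmas = self.resolve_sigma()

        def residuals(x):
            theta = dict(zip(names, x))
            return np.concatenate(
                [
                    (e["y"] - self.predict_one(theta, e)) / sig
                    for e, sig in zip(self._entries, sigmas)
                ]
            )

        x0 = np.clip(
            np.array([(self.config.theta0 or {}).get(n, 0.5 * (l + u))
                      for n, l, u in zip(names, lo, hi)]),
            lo,
            hi,
        )
        steps = 0.05 * width
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi))
            x0 = sol.x
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj)
            sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            auto = 2.38 / math.sqrt(len(self.sampled)) * sd
            ok = np.isfinite(auto) & (auto > 0)
            steps = np.where(ok, np.clip(auto, 1e-6 * width, 0.5 * width), steps)
        except Exception:
            pass
        start = dict(zip(names, x0))
        step_map = dict(zip(names, steps))
        if "sigma" in self.sampled:
            s_lo, s_hi = self.config.priors["sigma"]
            start["sigma"] = min(max(float(self._sigma_scale), s_lo + 1e-12), s_hi)
            step_map["sigma"] = max(0.15 * start["sigma"], 0.01 * (s_hi - s_lo))
        full_steps = np.array([step_map[n] for n in self.sampled])
        return {n: start[n] for n in self.sampled}, full_steps

    # -- likelihood ---------------------------------------------------------
    def log_likelihood(self, theta) -> np.ndarray:
        """Gaussian log-likelihood; broadcasts over arrays of candidates.

        If ``sigma`` is a sampled parameter it is the homoscedastic noise SD
        on the fitting scale; otherwise the resolved (pooled or per-point)
        SDs are treated as fixed.
        """
        sampled_sigma = theta.get("sigma")
        total = 0.0
        if sampled_sigma is not None:
            s = np.asarray(sampled_sigma, dtype=float)
            shapes, _ = self.sigma_shapes()
            for e, w in zip(self._entries, shapes):
                pred = self.predict_one(theta, e)
                resid = (e["y"] - pred) / w
                total = total + (
                    -0.5 * np.sum(resid**2, axis=-1) / s**2
                    - e["y"].size * np.log(s)
                    - np.sum(np.log(w))
                    - 0.5 * e["y"].size * math.log(2.0 * math.pi)
                )
            return total
        sigmas = self.resolve_sigma()
        for e, sig in zip(self._entries, sigmas):
            pred = self.predict_one(theta, e)
            resid = (e["y"] - pred) / sig
            total = total + (
                -0.5 * np.sum(resid**2, axis=-1)
                - np.sum(np.log(sig))
                - 0.5 * e["y"].size * math.log(2.0 * math.pi)
            )
        return total


def _as_list(datasets) -> list[DoseResponseDataset]:
    if isinstance(datasets, DoseResponseDataset):
        return [datasets]
    return list(datasets)


def log_likelihood(
    dataset,
    theta: dict[str, float],
    sigma: float | None = None,
    model_kind: str = "survival",
    fixed: dict[str, float] | None = None,
) -> float:
    """Gaussian log-likelihood of ``theta`` for one or more datasets.

    ``sigma`` overrides the noise SD for every record; otherwise per-point
    experimental SDs are used.  ``theta`` must contain the model coefficients
    (alpha0/beta0 or alpha_m0/beta_m0, plus a_plus_c for protracted data),
    either directly or through ``fixed``.
    """
    if sigma is not None and sigma <= 0:
        raise ConfigError("sigma must be positive")
    names = sorted(theta.keys())
    cfg = FitConfig(
        priors={n: (-1e30, 1e30) for n in names},
        sigma0=sigma,
        sigma_policy="pooled" if sigma is not None else "per-point",
        mn_fraction_link=True,
    )
    prob = _FitProblem(_as_list(dataset), model_kind, cfg, fixed=fixed, min_records=1)
    return float(prob.log_likelihood({k: float(v) for k, v in theta.items()}))


# ---------------------------------------------------------------------------
# Metropolis samplers


def _run_independence(prob: _FitProblem, config: FitConfig, rng) -> tuple[np.ndarray, float]:
    names = prob.sampled
    lo = np.array([config.priors[n][0] for n in names])
    hi = np.array([config.priors[n][1] for n in names])
    n_total = config.n_burn + config.n_samples
    candidates = rng.uniform(lo, hi, size=(n_total, len(names)))
    theta_arrays = {n: candidates[:, j] for j, n in enumerate(names)}
    log_l = prob.log_likelihood(theta_arrays)  # vectorised over all candidates
    theta0 = config.theta0 or prob.start_and_steps()[0]
    x_cur = np.clip(np.array([theta0[n] for n in names]), lo, hi)
    ll_cur = float(prob.log_likelihood({n: np.array([x]) for n, x in zip(names, x_cur)})[0])
    log_u = np.log(rng.uniform(size=n_total))
    chain = np.empty((n_total, len(names)))
    accepted = 0
    for t in range(n_total):
        if log_u[t] < log_l[t] - ll_cur:
            x_cur = candidates[t]
            ll_cur = float(log_l[t])
            accepted += 1
        chain[t] = x_cur
    return chain, accepted / n_total


def _run_gaussian_walk(prob: _FitProblem, config: FitConfig, rng) -> tuple[np.ndarray, float]:
    names = prob.sampled
    lo = np.array([config.priors[n][0] for n in names])
    hi = np.array([config.priors[n][1] for n in names])
    start, auto_step = prob.start_and_steps()
    if config.walk_scale == "auto":
        step = auto_step
    else:
        step = float(config.walk_scale) * (hi - lo)
    n_total = config.n_burn + config.n_samples
    theta0 = config.theta0 or start
    x_cur = np.clip(np.array([theta0[n] for n in names]), lo, hi)

    def ll(x):
        return float(prob.log_likelihood({n: np.array([v]) for n, v in zip(names, x)})[0])

    ll_cur = ll(x_cur)
    steps = rng.normal(size=(n_total, len(names))) * step
    log_u = np.log(rng.uniform(size=n_total))
    chain = np.empty((n_total, len(names)))
    accepted = 0
    for t in range(n_total):
        cand = x_cur + steps[t]
        if np.all(cand >= lo) and np.all(cand <= hi):  # uniform prior support
            ll_cand = ll(cand)
            if log_u[t] < ll_cand - ll_cur:
                x_cur, ll_cur = cand, ll_cand
                accepted += 1
        chain[t] = x_cur
    return chain, accepted / n_total


def mcmc_fit(
    datasets,
    config: FitConfig,
    model_kind: str = "survival",
    fixed: dict[str, float] | None = None,
) -> PosteriorSamples:
    """Metropolis fit of the dose-response model to one or more datasets.

    Samples the parameters named in ``config.priors`` under uniform priors;
    everything else the model needs (e.g. a fixed repair rate for protracted
    schedules) comes from ``fixed``.  Returns the retained post-burn-in
    draws; the chain is reproducible bit-for-bit given ``config.seed``.
    """
    prob = _FitProblem(_as_list(datasets), model_kind, config, fixed=fixed)
    rng = np.random.default_rng(config.seed)
    if config.proposal == "prior-independence":
        chain, rate = _run_independence(prob, config, rng)
    else:
        chain, rate = _run_gaussian_walk(prob, config, rng)
    draws = chain[config.n_burn :]
    if rate == 0.0:
        raise SamplerDiagnosticsError(
            "Metropolis chain accepted no proposals; widen the noise model, "
            "narrow the priors, or switch to the gaussian-walk proposal"
        )
    return PosteriorSamples(draws, prob.sampled, rate, config)


# ---------------------------------------------------------------------------
# derived estimators


def estimate_h(
    pairs,
    config: FitConfig | None = None,
    method: str = "mcmc",
    sd: np.ndarray | None = None,
) -> HEstimate:
    """Estimate the MN-formation probability h from (-ln S, MN) pairs.

    Fits the through-origin proportionality F_MN = h * <w> where <w> = -ln S.
    ``method`` is "mcmc" (default; same Metropolis machinery, uniform prior
    on h in [0, 1]) or "wls" (closed-form weighted least squares).  ``sd``
    optionally gives per-pair noise SDs; otherwise a pooled constant is
    estimated from the residuals of the closed-form fit.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise DataError("pairs must be an (n >= 2, 2) array of (-ln S, MN)")
    w, mn = pairs[:, 0], pairs[:, 1]
    if np.any(w < 0) or np.any(mn < 0):
        raise DataError("lethal-lesion counts and MN frequencies must be non-negative")
    if not np.any(w > 0):
        raise DataError("all lethal-lesion counts are zero; h is unidentifiable")
    weights = 1.0 / sd**2 if sd is not None else np.ones_like(w)
    h_wls = float(np.sum(weights * w * mn) / np.sum(weights * w**2))
    resid = mn - h_wls * w
    if sd is None:
        pooled = max(float(np.sqrt(np.mean(resid**2))), 1e-9)
        sigma = np.full_like(w, pooled)
    else:
        sigma = np.asarray(sd, dtype=float)
    # closed-form Gaussian posterior moments under a flat prior (reference)
    var_wls = 1.0 / float(np.sum(w**2 / sigma**2))
    if method == "wls":
        return HEstimate(mean=h_wls, sd=math.sqrt(var_wls), samples=None)
    if method != "mcmc":
        raise ConfigError(f"unknown method {method!r}")
    config = config or FitConfig(priors={"h": DEFAULT_PRIORS["h"]})
    if "h" not in config.priors:
        raise ConfigError("estimate_h requires a prior on 'h'")
    ds = DoseResponseDataset(
        doses=w,
        values=mn,
        sd=sigma,
        endpoint_kind="mn_per_cell",
        quality=RadiationQuality(0.0, label="lesion-count axis"),
        label="survival-MN pairs",
    )
    # reuse the linear term of the MN model: F_MN = h * w  (beta_m0 fixed at 0)
    cfg = replace(config, priors={"alpha_m0": config.priors["h"], **{
        k: v for k, v in config.priors.items() if k not in ("h", "alpha_m0")
    }})
    samples = mcmc_fit(ds, cfg, model_kind="mn", fixed={"beta_m0": 0.0})
    h_col = samples.column("alpha_m0")
    renamed = PosteriorSamples(h_col[:, None], ["h"], samples.acceptance_rate, config)
    return HEstimate(mean=float(h_col.mean()), sd=float(h_col.std(ddof=1)), samples=renamed)


def calibrate_rd(
    datasets_by_quality: list[DoseResponseDataset],
    base_fit: PosteriorSamples | dict[str, float],
    rd_grid,
    y0: float = 150.0,
    rho: float = 1000.0,
    flat_rtol: float = 1e-9,
) -> RdCalibration:
    """Grid-search the domain radius r_d against multi-LET dose-response data.

    For each candidate radius, every dataset's z1D* is recomputed from its
    lineal-energy spectrum and the survival (or MN) curve predicted with the
    base-fit coefficients; the radius minimising the total residual sum of
    squares on the fitting scale wins, ties broken toward smaller r_d.
    Photon-only data leave the profile flat (z1D* ~ 0 regardless of r_d);
    this is reported via ``flat`` and a warning.
    """
    rd_grid = np.asarray(rd_grid, dtype=float)
    if rd_grid.size == 0:
        raise ConfigError("rd grid is empty")
    if np.any(rd_grid <= 0):
        raise ConfigError("rd grid values must be positive")
    datasets = _as_list(datasets_by_quality)
    theta = base_fit.mean() if isinstance(base_fit, PosteriorSamples) else dict(base_fit)
    model_kind = "survival" if datasets[0].endpoint_kind == "survival" else "mn"
    ystars = []
    for ds in datasets:
        if ds.spectrum is None:
            raise DataError(f"dataset {ds.label!r} carries no lineal-energy spectrum")
        ystars.append(compute_ystar(ds.spectrum, y0))
    rss = np.zeros(rd_grid.size)
    ss_data = 0.0
    for k, rd in enumerate(rd_grid):
        geom = DomainGeometry(r_d=float(rd), rho=rho, y0=y0)
        total = 0.0
        for ds, ystar in zip(datasets, ystars):
            z = compute_z1dstar(ystar, geom)
            shifted = replace(ds, quality=RadiationQuality(z, ds.quality.label))
            cfg = FitConfig(priors={k2: (-1e30, 1e30) for k2 in theta}, mn_fraction_link=True)
            prob = _FitProblem([shifted], model_kind, cfg, fixed=None, min_records=1)
            pred = prob.predict(theta)[0]
            total += float(np.sum((prob._entries[0]["y"] - pred) ** 2))
            if k == 0:
                ss_data += float(np.sum(prob._entries[0]["y"] ** 2))
        rss[k] = total
    spread = rss.max() - rss.min()
    # flat relative to the overall data scale, not to the (possibly ~zero) RSS
    flat = bool(spread <= flat_rtol * max(ss_data, 1e-300))
    if flat:
        warnings.warn(
            "r_d residual profile is flat; the domain radius is not "
            "identifiable from these data (photon-only z1D* insensitivity)",
            stacklevel=2,
        )
    # argmin with ties broken toward smaller r_d (grid assumed ascending-sorted here)
    order = np.argsort(rd_grid, kind="stable")
    sorted_rss = rss[order]
    best = order[int(np.argmin(sorted_rss))]
    return RdCalibration(float(rd_grid[best]), rd_grid, rss, flat=flat)


def propagate_uncertainty(
    samples: PosteriorSamples,
    prediction_fn,
    level: float = 0.68,
) -> PredictionBand:
    """Pointwise mean and equal-tailed credible band of a model prediction.

    ``prediction_fn(theta)`` receives one posterior draw as a name -> value
    dict and returns a scalar or 1-D prediction; it is evaluated for every
    retained draw.
    """
    if not 0.0 < level < 1.0:
        raise ConfigError("credible level must be in (0, 1)")
    if samples.draws.shape[0] == 0:
        raise DataError("posterior is empty")
    preds = np.asarray(
        [
            np.atleast_1d(prediction_fn(dict(zip(samples.param_names, row))))
            for row in samples.draws
        ],
        dtype=float,
    )
    tail = (1.0 - level) / 2.0
    return PredictionBand(
        mean=preds.mean(axis=0),
        lower=np.quantile(preds, tail, axis=0),
        upper=np.quantile(preds, 1.0 - tail, axis=0),
        level=level,
    )


def r_squared(observed, predicted) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1 or observed.size < 2:
        raise DataError("observed and predicted must be equal-length 1-D arrays (n >= 2)")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise DataError("R^2 undefined: observed values are all equal")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot
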