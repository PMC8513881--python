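"""Bayesian fitting of STP models and information-criterion model selection.

Posteriors are sampled with an adaptive component-wise random-walk
Metropolis-Hastings chain (numba-compiled) targeting prior x likelihood,
where the likelihood treats each observed amplitude as Gaussian around
the deterministic model amplitude A_n with an amplitude-dependent
spread: variance = noise_scale * A_n by default (a mean-variance scaling
typical of evoked-response noise), or sd = noise_scale * A_n behind the
``noise_model`` switch.
Model comparison uses AIC/BIC weights; goodness of fit uses Bayesian
posterior-predictive p-values with a squared-discrepancy statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .stp import (AmplitudeTrain, ConfigurationError, ModelSpec, STPParams,
                  StimulusTrain, iterate_stp)

__all__ = [
    "PriorSpec", "PosteriorSamples", "ModelComparison", "default_priors",
    "log_likelihood", "fit_mh", "information_criteria", "information_weights",
    "compare_models", "posterior_predictive_p", "posterior_covariance",
    "metropolis", "free_parameters",
]

_PRIOR_CODES = {"exponential": 0, "beta": 1, "uniform": 2}
_PARAM_INDEX = {f: i for i, f in enumerate(
    ["g_max", "tau_f", "f0", "a", "tau_d", "tau_a", "a0", "b_a",
     "f0_tilde", "tau_f0", "b_f0", "tau_g", "k_g"])}


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior families.

    Families: ``("exponential", scale)``, ``("beta", alpha, beta)``,
    ``("uniform", lo, hi)``. Defaults bias conductance and release
    parameters towards small values, as expected for strongly
    facilitating synapses with low basal release.
    """

    priors: Mapping[str, tuple]

    def family(self, name: str) -> tuple:
        try:
            return self.priors[name]
        except KeyError:
            raise KeyError(f"no prior declared for parameter {name!r}") from None

    def encode(self, names: Sequence[str]):
        codes = np.empty(len(names), dtype=np.int64)
        h1 = np.empty(len(names))
        h2 = np.empty(len(names))
        for i, n in enumerate(names):
            fam = self.family(n)
            codes[i] = _PRIOR_CODES[fam[0]]
            h1[i] = fam[1]
            h2[i] = fam[2] if len(fam) > 2 else 0.0
        return codes, h1, h2

    def sample(self, names: Sequence[str], rng: np.random.Generator) -> np.ndarray:
        out = np.empty(len(names))
        for i, n in enumerate(names):
            fam = self.family(n)
            if fam[0] == "exponential":
                out[i] = rng.exponential(fam[1])
            elif fam[0] == "beta":
                out[i] = rng.beta(fam[1], fam[2])
            else:
                out[i] = rng.uniform(fam[1], fam[2])
        return out


def default_priors() -> PriorSpec:
    """Exponential prior on conductance scales, Beta(1, 3) on baselines and
    increments, Uniform(0.01 s, 20 s) on time constants."""
    pri = {"g_max": ("exponential", 10.0), "k_g": ("exponential", 1.0)}
    for n in ("f0", "a", "a0", "b_a", "f0_tilde", "b_f0"):
        pri[n] = ("beta", 1.0, 3.0)
    for n in ("tau_f", "tau_d", "tau_a", "tau_f0", "tau_g"):
        pri[n] = ("uniform", 0.01, 20.0)
    return PriorSpec(pri)


def free_parameters(spec: ModelSpec) -> list[str]:
    """Free parameters of a model variant, in sampling order (g_max first)."""
    return ["g_max"] + spec.required_params()


@dataclass
class PosteriorSamples:
    """MCMC chain over the free parameters of one model fit."""

    param_names: list[str]
    chain: np.ndarray                 # (n_samples, n_params)
    log_likelihood: np.ndarray
    log_posterior: np.ndarray
    acceptance_rate: float
    n_burn: int
    n_keep: int
    thinning: int
    seed: int
    spec: Optional[ModelSpec] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.chain.shape[1] != len(self.param_names):
            raise ValueError("chain width must match parameter names")
        if self.chain.shape[0] != self.log_likelihood.shape[0]:
            raise ValueError("chain length inconsistent across fields")

    def map_estimate(self) -> dict[str, float]:
        """Parameter values at the highest-posterior sample in the chain."""
        i = int(np.argmax(self.log_posterior))
        return dict(zip(self.param_names, self.chain[i]))

    def posterior_mean(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.chain.mean(axis=0)))

    def credible_interval(self, name: str, level: float = 0.95):
        j = self.param_names.index(name)
        lo = 50.0 * (1.0 - level)
        return tuple(np.percentile(self.chain[:, j], [lo, 100.0 - lo]))

    def max_log_likelihood(self) -> float:
        return float(self.log_likelihood.max())

    def params_at(self, values: Mapping[str, float]) -> STPParams:
        base = dict(self.meta.get("fixed_params", {}))
        base.update(values)
        return STPParams(**base)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.chain, columns=self.param_names)
        df["log_likelihood"] = self.log_likelihood
        df["log_posterior"] = self.log_posterior
        return df


def _model_amplitudes_pa(params: STPParams, spec: ModelSpec,
                         stim: StimulusTrain, drive: float) -> np.ndarray:
    traj = iterate_stp(params, spec, stim)
    if params.g_max is None:
        raise ConfigurationError("g_max required for amplitude likelihoods")
    return params.g_max * traj.amplitudes * drive


def _spread(a: np.ndarray, noise_scale: float, sd_floor: float,
            noise_model: str) -> np.ndarray:
    """Observation-noise sd per amplitude under the configured model."""
    if noise_model == "variance":
        sd = np.sqrt(noise_scale * np.maximum(a, 0.0))
    elif noise_model == "sd":
        sd = noise_scale * a
    else:
        raise ValueError("noise_model must be 'variance' or 'sd'")
    return np.maximum(sd, sd_floor)


def log_likelihood(params: STPParams, spec: ModelSpec, stim: StimulusTrain,
                   observed: AmplitudeTrain, drive: float = 80.0,
                   noise_scale: float = 0.5, sd_floor: float = 1e-3,
                   noise_model: str = "variance") -> float:
    """Sum of normal log-densities of the observed amplitudes, with mean
    A_n (model amplitude, pA) and spread from the configured noise model,
    floored at ``sd_floor``."""
    if len(observed) != len(stim):
        raise ValueError("observed amplitudes must align with the stimulus train")
    a = _model_amplitudes_pa(params, spec, stim, drive)
    sd = _spread(a, noise_scale, sd_floor, noise_model)
    r = (observed.amplitudes - a) / sd
    return float(np.sum(-0.5 * r * r - np.log(sd) - 0.5 * math.log(2 * math.pi)))


def fit_mh(spec: ModelSpec, stim: StimulusTrain, observed,
           priors: Optional[PriorSpec] = None, n_steps: int = 50_000,
           n_burn: int = 10_000, thin: int = 1, seed: int = 0,
           drive: float = 80.0, noise_scale: float = 0.5,
           sd_floor: float = 1e-3, noise_model: str = "variance",
           fixed_params: Optional[Mapping[str, float]] = None) -> PosteriorSamples:
    """Fit an STP model to an amplitude train by Metropolis-Hastings.

    ``n_steps`` counts kept sweeps after ``n_burn`` burn-in sweeps (one
    sweep updates every free parameter once). ``observed`` may be an
    AmplitudeTrain or a plain array aligned to ``stim``; an empty array
    yields prior sampling.
    """
    priors = priors or default_priors()
    if isinstance(observed, AmplitudeTrain):
        y = observed.amplitudes
        if len(observed) != len(stim):
            raise ValueError("observed amplitudes must align with stimuli")
    else:
        y = np.asarray(observed, dtype=float)
        if y.size and y.size != len(stim):
            raise ValueError("observed amplitudes must align with stimuli")

    names = free_parameters(spec)
    fixed = dict(fixed_params or {})
    names = [n for n in names if n not in fixed]
    if not names:
        raise ConfigurationError("at least one free parameter required")
    free_idx = np.array([_PARAM_INDEX[n] for n in names], dtype=np.int64)
    pfull = np.zeros(13)
    for n, v in fixed.items():
        pfull[_PARAM_INDEX[n]] = v

    codes, h1, h2 = priors.encode(names)
    rng = np.random.default_rng(seed)
    theta0 = priors.sample(names, rng)
    # initial proposal scales: a fraction of each prior's spread
    step0 = np.empty(len(names))
    for i, n in enumerate(names):
        fam = priors.family(n)
        if fam[0] == "exponential":
            step0[i] = 0.25 * fam[1]
        elif fam[0] == "beta":
            step0[i] = 0.1
        else:
            step0[i] = 0.1 * (fam[2] - fam[1])

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    times = stim.times if y.size else np.empty(0)
    chain, lls, lposts, acc, steps = _kernels.mh_sample_stp(
        times, y, pfull, free_idx,
        spec.f_exponent, spec.d_active, spec.a_dynamic, spec.f0_dynamic,
        spec.g_dynamic, drive, noise_scale, sd_floor,
        1 if noise_model == "variance" else 0,
        codes, h1, h2, theta0, step0, n_steps, n_burn, thin, kernel_seed)
    if y.size and acc <= 0.0:
        raise RuntimeError("Metropolis-Hastings chain accepted no proposals "
                           "after adaptation; check data scaling and priors")
    return PosteriorSamples(
        param_names=names, chain=chain, log_likelihood=lls,
        log_posterior=lposts, acceptance_rate=float(acc), n_burn=n_burn,
        n_keep=n_steps, thinning=thin, seed=seed, spec=spec,
        meta={"drive": drive, "noise_scale": noise_scale,
              "sd_floor": sd_floor, "noise_model": noise_model,
              "fixed_params": fixed,
              "proposal_scales": steps.tolist(), "n_data": int(y.size)})


def information_criteria(fit: PosteriorSamples, n_data: Optional[int] = None) -> dict:
    """AIC and BIC at the maximum-likelihood sample of the chain."""
    if n_data is None:
        n_data = fit.meta.get("n_data")
    if not n_data:
        raise ValueError("n_data required for information criteria")
    k = len(fit.param_names)
    lmax = fit.max_log_likelihood()
    return {"aic": 2.0 * k - 2.0 * lmax,
            "bic": k * math.log(n_data) - 2.0 * lmax,
            "k": k, "max_log_likelihood": lmax, "n_data": int(n_data)}


@dataclass
class ModelComparison:
    """Per-model information criteria transformed to weight space."""

    models: list[str]
    aic: dict[str, float]
    bic: dict[str, float]
    aic_weights: dict[str, float]
    bic_weights: dict[str, float]

    def best(self, criterion: str = "bic") -> str:
        w = self.bic_weights if criterion == "bic" else self.aic_weights
        return max(w, key=w.get)

    def evidence_ratio(self, a: str, b: str, criterion: str = "bic") -> float:
        w = self.bic_weights if criterion == "bic" else self.aic_weights
        return w[a] / w[b]


def information_weights(criteria: Mapping[str, object]) -> dict[str, float]:
    """Akaike-style weights from per-model criterion values.

    Each value may be a scalar (one dataset, pooled) or an array of
    per-sample criteria; the deviation Delta_i is the mean over samples of
    |C_in - min_m C_mn| and w_i = exp(-Delta_i/2) / sum_k exp(-Delta_k/2).
    """
    if len(criteria) < 2:
        raise ValueError("need at least two models to compare")
    names = list(criteria)
    mat = np.vstack([np.atleast_1d(np.asarray(criteria[n], dtype=float))
                     for n in names])
    if mat.shape[1] < 1 or len({np.atleast_1d(criteria[n]).size for n in names}) != 1:
        raise ValueError("criterion arrays must share a common length")
    delta = np.abs(mat - mat.min(axis=0)).mean(axis=1)
    w = np.exp(-0.5 * (delta - delta.min()))
    w /= w.sum()
    return dict(zip(names, w))


def compare_models(fits: Mapping[str, PosteriorSamples],
                   n_data: Optional[int] = None) -> ModelComparison:
    ics = {m: information_criteria(f, n_data) for m, f in fits.items()}
    aic = {m: v["aic"] for m, v in ics.items()}
    bic = {m: v["bic"] for m, v in ics.items()}
    return ModelComparison(models=list(fits), aic=aic, bic=bic,
                           aic_weights=information_weights(aic),
                           bic_weights=information_weights(bic))


def posterior_predictive_p(samples: PosteriorSamples, spec: ModelSpec,
                           stim: StimulusTrain, observed: AmplitudeTrain,
                           n_draws: int = 500, seed: int = 0) -> float:
    """Pr[D(x_sim | theta) > D(x_obs | theta)] over posterior draws, with
    D(x | theta) = sum_j (x_j - e_j)^2 against the model expectations."""
    if samples.chain.shape[0] == 0:
        raise ValueError("empty posterior chain")
    rng = np.random.default_rng(seed)
    drive = samples.meta.get("drive", 80.0)
    noise_scale = samples.meta.get("noise_scale", 0.5)
    sd_floor = samples.meta.get("sd_floor", 1e-3)
    noise_model = samples.meta.get("noise_model", "variance")
    idx = rng.integers(0, samples.chain.shape[0], size=n_draws)
    y = observed.amplitudes
    exceed = 0
    for i in idx:
        params = samples.params_at(dict(zip(samples.param_names,
                                            samples.chain[i])))
        e = _model_amplitudes_pa(params, spec, stim, drive)
        sd = _spread(e, noise_scale, sd_floor, noise_model)
        x_sim = rng.normal(e, sd)
        if np.sum((x_sim - e) ** 2) > np.sum((y - e) ** 2):
            exceed += 1
    return exceed / n_draws


def posterior_covariance(samples: PosteriorSamples,
                         kind: str = "correlation") -> pd.DataFrame:
    """Covariance or correlation matrix of the free parameters."""
    if samples.chain.shape[0] < 2:
        raise ValueError("need a chain of length >= 2")
    if kind == "correlation":
        mat = np.corrcoef(samples.chain.T)
    elif kind == "covariance":
        mat = np.cov(samples.chain.T)
    else:
        raise ValueError("kind must be 'correlation' or 'covariance'")
    return pd.DataFrame(mat, index=samples.param_names,
                        columns=samples.param_names)


def metropolis(logpdf, x0, n_steps: int, seed: int = 0, step: float = 1.0,
               n_burn: int = 1000, adapt_every: int = 200):
    """Generic adaptive random-walk Metropolis sampler (pure python).

    Shares the proposal/adaptation scheme of the STP sampler; used for
    conjugate-toy validation and as a utility for arbitrary 1-d or small
    multivariate targets. ``x0`` may be a scalar or 1-d array.
    """
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    k = x.size
    scales = np.full(k, float(step))
    lp = logpdf(x if k > 1 else x[0])
    out = np.empty((n_steps, k))
    acc = np.zeros(k)
    prop = np.zeros(k)
    for it in range(n_burn + n_steps):
        for j in range(k):
            old = x[j]
            x[j] = old + scales[j] * rng.normal()
            lp_new = logpdf(x if k > 1 else x[0])
            prop[j] += 1
            if math.log(rng.random() + 1e-300) < lp_new - lp:
                lp = lp_new
                acc[j] += 1
            else:
                x[j] = old
        if it < n_burn and (it + 1) % adapt_every == 0:
            for j in range(k):
                r = acc[j] / max(prop[j], 1)
                if r > 0.4:
                    scales[j] *= 1.3
                elif r < 0.2:
                    scales[j] /= 1.3
            acc[:] = 0
            prop[:] = 0
        if it >= n_burn:
            out[it - n_burn] = x
    return out if k > 1 else out[:, 0]
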