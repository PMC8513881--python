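"""Stimulus and spike-train generators.

Covers the three input statistics used across the analyses: the doubly
stochastic Cox process emulating in-vivo dentate granule-cell firing
(bimodal ISI distribution), periodic-burst Poisson drive standing in for
mossy-fiber activity, and correlated homogeneous Poisson populations
standing in for perforant-path input. All generators are reproducible
bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stp import StimulusTrain

__all__ = [
    "CoxParams", "BurstDrivePattern", "CorrelatedPopulationPattern",
    "sample_cox_train", "sample_burst_drive", "sample_correlated_population",
]


@dataclass(frozen=True)
class CoxParams:
    """Two-component Cox process over ISIs.

    Each component draws a candidate ISI from Exponential(lambda_i) and
    rejects (resamples) it when smaller than a normal refractory sample
    N(mu_i, sigma_i^2); components are mixed with Bernoulli(p). Defaults
    reproduce the granule-cell-like naturalistic protocol (99 ISIs ->
    100 stimuli).
    """

    lambda1: float = 3.0      # Hz
    lambda2: float = 0.25     # Hz
    mu1: float = 0.006        # s
    mu2: float = 0.0025       # s
    sigma1: float = 0.12      # s
    sigma2: float = 0.01      # s
    p: float = 0.55
    n_intervals: int = 99
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 <= 0 or self.lambda2 <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n_intervals < 0:
            raise ValueError("n_intervals must be non-negative")


def sample_cox_train(params: CoxParams) -> StimulusTrain:
    """Draw a naturalistic stimulus train; first stimulus at t = 0."""
    rng = np.random.default_rng(params.seed)
    rates = (params.lambda1, params.lambda2)
    mus = (params.mu1, params.mu2)
    sigmas = (params.sigma1, params.sigma2)
    isis = np.empty(params.n_intervals)
    for i in range(params.n_intervals):
        comp = 0 if rng.random() < params.p else 1
        while True:
            r = rng.exponential(1.0 / rates[comp])
            x = rng.normal(mus[comp], sigmas[comp]) if sigmas[comp] > 0 \
                else mus[comp]
            if r > x:
                break
        isis[i] = r
    times = np.concatenate(([0.0], np.cumsum(isis)))
    return StimulusTrain(times)


@dataclass(frozen=True)
class BurstDrivePattern:
    """Inhomogeneous Poisson drive: periodic high-rate burst windows on a
    low basal rate (e.g. 50 Hz for 200 ms every 20 s on 0.2 Hz)."""

    base_rate: float = 0.2        # Hz
    burst_rate: float = 50.0      # Hz
    burst_duration: float = 0.2   # s
    burst_period: float = 20.0    # s
    duration: float = 400.0       # s
    phase: float = 0.0            # s, offset of the first burst window
    seed: int = 0

    def __post_init__(self):
        if not self.burst_rate > self.base_rate >= 0:
            raise ValueError("need burst_rate > base_rate >= 0")
        if not 0 < self.burst_duration < self.burst_period:
            raise ValueError("need 0 < burst_duration < burst_period")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


def sample_burst_drive(pattern: BurstDrivePattern) -> np.ndarray:
    """Spike times (s) of the burst-modulated Poisson process.

    Returned as a plain array because the train may legitimately be empty;
    wrap in StimulusTrain when non-empty input is required.
    """
    rng = np.random.default_rng(pattern.seed)
    edges = [0.0]
    rates = []
    t = pattern.phase % pattern.burst_period
    start = t - pattern.burst_period  # window possibly straddling t=0
    while start < pattern.duration:
        s = max(start, 0.0)
        e = min(start + pattern.burst_duration, pattern.duration)
        if e > s:
            if s > edges[-1]:
                rates.append(pattern.base_rate)
                edges.append(s)
            rates.append(pattern.burst_rate)
            edges.append(e)
        start += pattern.burst_period
    if edges[-1] < pattern.duration:
        rates.append(pattern.base_rate)
        edges.append(pattern.duration)

    spikes = []
    for (s, e), rate in zip(zip(edges[:-1], edges[1:]), rates):
        n = rng.poisson(rate * (e - s))
        if n:
            spikes.append(np.sort(rng.uniform(s, e, n)))
    if not spikes:
        return np.empty(0)
    times = np.concatenate(spikes)
    # Poisson points are almost surely distinct; enforce strictness anyway
    times = np.unique(times)
    return times


@dataclass(frozen=True)
class CorrelatedPopulationPattern:
    """Population of Poisson sources with a pairwise spike-count
    correlation target, e.g. 120 sources at 10 Hz, correlation 0.9."""

    n_sources: int = 120
    rate: float = 10.0        # Hz
    correlation: float = 0.9
    duration: float = 400.0   # s
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must lie in [0, 1]")
        if self.n_sources < 1 or self.rate < 0 or self.duration < 0:
            raise ValueError("invalid population pattern")


def sample_correlated_population(pattern: CorrelatedPopulationPattern) -> list[np.ndarray]:
    """Thinned-mother construction: every child keeps each mother spike
    with probability c (the correlation target), giving child rate
    ``rate`` when the mother fires at rate/c, and pairwise spike-count
    correlation exactly c for independently thinned children."""
    rng = np.random.default_rng(pattern.seed)
    c = pattern.correlation
    if c == 0.0:
        return [
            np.sort(rng.uniform(0, pattern.duration,
                                rng.poisson(pattern.rate * pattern.duration)))
            for _ in range(pattern.n_sources)
        ]
    mother_rate = pattern.rate / c
    n = rng.poisson(mother_rate * pattern.duration)
    mother = np.sort(rng.uniform(0, pattern.duration, n))
    if c == 1.0:
        return [mother.copy() for _ in range(pattern.n_sources)]
    return [mother[rng.random(n) < c] for _ in range(pattern.n_sources)]
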