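"""Spiking CA3 network: ensemble formation under neuromodulation.

A small all-to-all network of adaptive quadratic-integrate-and-fire
(Izhikevich-type) excitatory and fast-spiking inhibitory neurons with
exponential synapses. Excitatory cells are grouped into (possibly
overlapping, ring-arranged) ensembles, each driven by one facilitating
mossy-fiber input. EE and IE synapses follow a symmetric STDP rule
dw = eta * (exp(-|t_pre - t_post| / tau) - z) whose learning rate eta
(burst detector) and depression term z (rate tracker with ceiling
rho_max) are driven by postsynaptic spiking; this bounds firing while
letting brief synchronous bursts wire an ensemble together.

Conditions: "na" (noradrenaline) leaves the network at control
parameters but enables plasticity; "ach" additionally depolarises both
cell types, lowers spike-triggered adaptation and halves the recurrent
EE conductance; "control" (no neuromodulator) disables plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .patterns import BurstDrivePattern, sample_burst_drive

__all__ = [
    "NeuronParams", "SynapseParams", "PlasticityParams", "EnsembleSpec",
    "NeuromodCondition", "NetworkResult", "FrequencySweepResult",
    "OverlapSweepResult", "simulate_network", "stdp_update",
    "weight_matrix_error", "target_weight_matrix", "discrimination_index",
    "run_frequency_sweep", "run_overlap_sweep", "staggered_burst_drive",
]


@dataclass(frozen=True)
class NeuronParams:
    """Adaptive quadratic-integrate-and-fire parameters."""

    C_m: float        # pF
    k: float          # pA/mV^2
    a_rec: float      # Hz, recovery rate of the adaptation variable
    b_rec: float      # nS, voltage coupling of the adaptation variable
    c_reset: float    # mV
    d_jump: float     # pA
    v_rest: float     # mV
    v_t: float        # mV
    v_peak: float     # mV

    def __post_init__(self):
        if not self.v_rest < self.v_t < self.v_peak:
            raise ValueError("need v_rest < v_t < v_peak")

    @staticmethod
    def preset(name: str) -> "NeuronParams":
        return _NEURON_PRESETS[name]

    def vector(self) -> np.ndarray:
        # kernel layout, with the recovery rate converted to 1/ms
        return np.array([self.C_m, self.k, self.a_rec / 1000.0, self.b_rec,
                         self.c_reset, self.d_jump, self.v_rest, self.v_t,
                         self.v_peak])


_NEURON_PRESETS = {
    "CA3_E": NeuronParams(C_m=24.0, k=1.5, a_rec=10.0, b_rec=2.0,
                          c_reset=-63.0, d_jump=60.0, v_rest=-75.0,
                          v_t=-58.0, v_peak=29.0),
    "FS_I": NeuronParams(C_m=16.0, k=1.5, a_rec=900.0, b_rec=2.0,
                         c_reset=-80.0, d_jump=400.0, v_rest=-65.0,
                         v_t=-50.0, v_peak=28.0),
}


@dataclass(frozen=True)
class SynapseParams:
    """Exponential-synapse constants shared by the four connection types.

    Plastic weights are dimensionless in [0, 1]; the conductance
    delivered per presynaptic spike is g_tilde * w (nS), so a saturated
    plastic synapse delivers the full g_tilde and weight matrices are
    reported on the effective g_tilde * w scale.
    """

    g_tilde_e: float = 0.5      # nS, excitatory synapses (EE, EI)
    g_tilde_i: float = 1.0      # nS, inhibitory synapses (IE, II)
    tau_g_e: float = 10.0       # ms (EE, EI)
    tau_g_i: float = 20.0       # ms (IE, II)
    tau_g_ff: float = 20.0      # ms, feed-forward (mossy fiber) input
    v_rev_e: float = 10.0       # mV
    v_rev_i: float = -80.0      # mV
    w_fixed: float = 0.3        # non-plastic (EI, II) weight

    def __post_init__(self):
        if not 0.0 <= self.w_fixed <= 1.0:
            raise ValueError("w_fixed must lie in [0, 1]")


@dataclass(frozen=True)
class PlasticityParams:
    """Symmetric rate-scaled STDP constants."""

    xi: float = 0.02            # eta increment per postsynaptic spike
    tau_eta: float = 0.1        # s
    tau_z: float = 1.0          # s
    rho_max: float = 10.0       # Hz, postsynaptic rate ceiling
    tau_stdp: float = 0.02      # s, symmetric kernel time constant
    pair_window: float = 0.1    # s, soft cutoff for counting pre-post pairs
    eta_ie: float = 0.1         # fixed learning rate, IE synapses
    z_ie: float = 0.05          # fixed depression term, IE synapses
    # whether the triggering spike's own eta/z increments are visible to
    # the pair updates it causes: eta is a fast calcium-like burst
    # detector (included); z a slow rate tracker (excluded)
    eta_includes_trigger: bool = True
    z_includes_trigger: bool = False


@dataclass(frozen=True)
class EnsembleSpec:
    """Ring-overlapping assignment of excitatory cells to ensembles.

    Ensembles are consecutive blocks of ``ensemble_size`` cells; each
    shares ``overlap`` cells with its next ring neighbour, so
    n_excitatory = n_ensembles * (ensemble_size - overlap) and every
    cell belongs to at least one ensemble.
    """

    n_ensembles: int = 8
    ensemble_size: int = 8
    overlap: int = 0
    n_inhibitory: Optional[int] = None

    def __post_init__(self):
        if not 0 <= self.overlap < self.ensemble_size:
            raise ValueError("overlap must satisfy 0 <= overlap < ensemble_size")
        if self.n_ensembles < 1 or self.ensemble_size < 1:
            raise ValueError("need at least one ensemble of one cell")
        if self.overlap > 0 and self.n_ensembles < 2:
            raise ValueError("overlap requires at least two ensembles")

    @property
    def n_excitatory(self) -> int:
        return self.n_ensembles * (self.ensemble_size - self.overlap)

    @property
    def n_inh(self) -> int:
        if self.n_inhibitory is not None:
            return self.n_inhibitory
        return max(1, self.n_excitatory // 4)

    def members(self, e: int) -> np.ndarray:
        start = e * (self.ensemble_size - self.overlap)
        return (start + np.arange(self.ensemble_size)) % self.n_excitatory

    def membership_csr(self) -> tuple[np.ndarray, np.ndarray]:
        off = np.arange(self.n_ensembles + 1, dtype=np.int64) * self.ensemble_size
        memb = np.concatenate([self.members(e) for e in range(self.n_ensembles)])
        return off, memb.astype(np.int64)

    def co_ensemble_matrix(self) -> np.ndarray:
        """Boolean (nE, nE): True where i != j share at least one ensemble."""
        n = self.n_excitatory
        co = np.zeros((n, n), dtype=bool)
        for e in range(self.n_ensembles):
            m = self.members(e)
            co[np.ix_(m, m)] = True
        np.fill_diagonal(co, False)
        return co

    def neighbours(self, e: int) -> tuple[int, int]:
        return ((e - 1) % self.n_ensembles, (e + 1) % self.n_ensembles)


# Cholinergic parameter deltas (all other fields stay at control values).
_ACH_E = {"c_reset": -61.0, "d_jump": 50.0, "v_rest": -70.0}
_ACH_I = {"v_rest": -63.0}
_ACH_G_EE = 0.25


@dataclass(frozen=True)
class NeuromodCondition:
    """Network-level neuromodulator condition with optional ablations.

    Noradrenaline enables recurrent plasticity without changing network
    parameters; acetylcholine additionally applies the excitability and
    EE-conductance changes. Ablation flags remove individual
    acetylcholine deltas for the dissection experiments.
    """

    name: str = "na"                      # control | na | ach
    plasticity_enabled: Optional[bool] = None
    ablate_excitability: bool = False
    ablate_ee_conductance: bool = False

    def __post_init__(self):
        if self.name not in ("control", "na", "ach"):
            raise ValueError(f"unknown condition {self.name!r}")
        if self.plasticity_enabled is None:
            object.__setattr__(self, "plasticity_enabled", self.name != "control")

    def neuron_params(self) -> tuple[NeuronParams, NeuronParams]:
        e = NeuronParams.preset("CA3_E")
        i = NeuronParams.preset("FS_I")
        if self.name == "ach" and not self.ablate_excitability:
            e = replace(e, **_ACH_E)
            i = replace(i, **_ACH_I)
        return e, i

    def g_tilde_ee(self, syn: SynapseParams) -> float:
        if self.name == "ach" and not self.ablate_ee_conductance:
            return _ACH_G_EE
        return syn.g_tilde_e


def stdp_update(dt_pair: float, eta: float, z: float,
                params: PlasticityParams = PlasticityParams()) -> float:
    """Weight change for one pre-post spike pair at lag dt_pair (s).

    Symmetric in the sign of the lag: dw = eta * (exp(-|dt|/tau) - z).
    """
    return eta * (np.exp(-np.abs(dt_pair) / params.tau_stdp) - z)


def target_weight_matrix(ensembles: EnsembleSpec, w_max: float) -> np.ndarray:
    """Ideal block weight matrix: w_max within ensembles, zero elsewhere."""
    return np.where(ensembles.co_ensemble_matrix(), w_max, 0.0)


def weight_matrix_error(actual: np.ndarray, ensembles: EnsembleSpec,
                        w_max: float) -> float:
    """Summed absolute deviation from the ideal ensemble weight matrix."""
    target = target_weight_matrix(ensembles, w_max)
    if actual.shape != target.shape:
        raise ValueError(f"weight matrix shape {actual.shape} does not match "
                         f"{target.shape} for the ensemble layout")
    return float(np.abs(actual - target).sum())


def _interleaved_slots(n: int) -> dict:
    """Assign burst-phase slots so every cyclically ring-adjacent pair of
    ensembles -- which share cells when overlap > 0 -- bursts far apart in
    time (outside the mossy-fiber facilitation window), via a stride
    coprime to n; falls back to even/odd interleaving for tiny rings."""
    import math as _math
    for stride in range(3, n - 1):
        if _math.gcd(stride, n) == 1:
            return {e: (stride * e) % n for e in range(n)}
    order = list(range(0, n, 2)) + list(range(1, n, 2))
    return {e: i for i, e in enumerate(order)}


def staggered_burst_drive(ensembles: EnsembleSpec, frequency: float,
                          duration: float, seed: int,
                          burst_duration: float = 0.25,
                          burst_period: float = 20.0,
                          base_rate: float = 0.2) -> list[np.ndarray]:
    """One burst-modulated Poisson fiber per ensemble, phases staggered so
    no two ensembles burst at the same time."""
    if ensembles.n_ensembles * burst_duration > burst_period:
        raise ValueError("burst windows cannot avoid overlap at this period")
    rng = np.random.default_rng(seed)
    n = ensembles.n_ensembles
    phase_step = burst_period / n
    slot = _interleaved_slots(n)
    drives = []
    for e in range(n):
        pat = BurstDrivePattern(
            base_rate=base_rate, burst_rate=frequency,
            burst_duration=burst_duration, burst_period=burst_period,
            duration=duration, phase=slot[e] * phase_step,
            seed=int(rng.integers(0, 2**31 - 1)))
        drives.append(sample_burst_drive(pat))
    return drives


@dataclass
class NetworkResult:
    """Raster, weight-matrix snapshots and bookkeeping for one simulation."""

    spike_times: np.ndarray       # s
    spike_ids: np.ndarray
    snapshot_times: np.ndarray    # s
    wee_snapshots: np.ndarray     # (n_snap, nE, nE), dimensionless
    wie_snapshots: np.ndarray     # (n_snap, nI, nE), dimensionless
    w_max: float                  # effective EE weight ceiling (nS)
    w_max_ie: float
    ensembles: EnsembleSpec
    condition: NeuromodCondition
    dt: float
    seed: int
    drives: Optional[list] = None

    def weight_matrix(self, index: int = -1) -> np.ndarray:
        """Effective EE weight matrix (nS) at a snapshot."""
        return self.wee_snapshots[index] * self.w_max

    def wme_trajectory(self) -> np.ndarray:
        target = target_weight_matrix(self.ensembles, self.w_max)
        diffs = np.abs(self.wee_snapshots * self.w_max - target[None])
        return diffs.sum(axis=(1, 2))

    def wme_zero(self) -> float:
        """WME of an all-zero weight matrix (the starting point)."""
        return float(target_weight_matrix(self.ensembles, self.w_max).sum())

    def formed(self, window: float = 20.0, threshold: float = 0.02) -> bool:
        """Ensembles count as formed when the WME stays below
        ``threshold`` of its all-zero value for the final ``window`` s."""
        wme = self.wme_trajectory()
        sel = self.snapshot_times >= self.snapshot_times[-1] - window
        return bool(np.all(wme[sel] < threshold * self.wme_zero()))

    def excitatory_raster(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.spike_ids < self.ensembles.n_excitatory
        return self.spike_times[m], self.spike_ids[m]


def simulate_network(ensembles: EnsembleSpec, condition: NeuromodCondition,
                     drive: Optional[Sequence[np.ndarray]] = None,
                     duration: float = 400.0, dt: float = 1e-4,
                     seed: int = 0, frequency: float = 20.0,
                     syn: SynapseParams = SynapseParams(),
                     plast: PlasticityParams = PlasticityParams(),
                     g_mossy: float = 3.0, mf_f0: float = 0.3,
                     mf_a: float = 0.15, mf_tau_f: float = 3.3,
                     pp_drive: Optional[tuple[np.ndarray, float]] = None,
                     i_ext: Optional[np.ndarray] = None,
                     snapshot_interval: float = 1.0,
                     burst_duration: float = 0.25,
                     burst_period: float = 20.0,
                     base_rate: float = 0.2,
                     initial_wee: Optional[np.ndarray] = None,
                     max_rate_hint: float = 100.0) -> NetworkResult:
    """Simulate the CA3 network (times in seconds, dt <= 0.5 ms).

    ``drive`` is one spike-time array per ensemble; when omitted, a
    staggered burst drive at ``frequency`` Hz is generated from ``seed``.
    The mossy-fiber synapse facilitates with the excitatory f^2
    short-term-plasticity model (per-fiber state, never reset).
    ``pp_drive`` is an optional (times, weight_nS) shared static input to
    every excitatory cell; ``i_ext`` a constant per-neuron current (pA).
    """
    if dt > 5e-4:
        raise ValueError("dt must be <= 0.5 ms")
    nE = ensembles.n_excitatory
    nI = ensembles.n_inh
    if drive is None:
        drive = staggered_burst_drive(ensembles, frequency, duration, seed,
                                      burst_duration, burst_period, base_rate)
    if len(drive) != ensembles.n_ensembles:
        raise ValueError("need one drive train per ensemble")
    _check_no_burst_overlap(drive, burst_duration)

    ep, ip = condition.neuron_params()
    g_ee = condition.g_tilde_ee(syn)

    # flatten the per-fiber events into one time-sorted stream (ms)
    ts, fibs = [], []
    for e, tr in enumerate(drive):
        tr = np.asarray(tr, dtype=float)
        ts.append(tr * 1000.0)
        fibs.append(np.full(tr.size, e, dtype=np.int64))
    mf_t = np.concatenate(ts) if ts else np.empty(0)
    mf_fib = np.concatenate(fibs) if fibs else np.empty(0, dtype=np.int64)
    order = np.argsort(mf_t, kind="stable")
    mf_t = mf_t[order]
    mf_fib = mf_fib[order]
    memb_off, memb = ensembles.membership_csr()

    if pp_drive is not None:
        pp_t = np.asarray(pp_drive[0], dtype=float) * 1000.0
        pp_w = float(pp_drive[1])
    else:
        pp_t = np.empty(0)
        pp_w = 0.0

    n = nE + nI
    iext = np.zeros(n) if i_ext is None else np.asarray(i_ext, dtype=float)
    if iext.shape != (n,):
        raise ValueError(f"i_ext must have shape ({n},)")

    dt_ms = dt * 1000.0
    snap_every = max(1, int(round(snapshot_interval / dt)))
    n_steps = int(round(duration / dt))
    n_steps = (n_steps // snap_every) * snap_every  # end on a snapshot
    n_snap = n_steps // snap_every + 1

    wee = np.zeros((nE, nE)) if initial_wee is None else initial_wee.astype(float).copy()
    np.fill_diagonal(wee, 0.0)
    wie = np.zeros((nI, nE))
    wee_snap = np.empty((n_snap, nE, nE), dtype=np.float32)
    wie_snap = np.empty((n_snap, nI, nE), dtype=np.float32)

    max_spikes = int(n * duration * max_rate_hint) + 10000
    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, dtype=np.int64)

    n_sp, status = _kernels.run_ca3(
        dt_ms, n_steps, nE, nI, ep.vector(), ip.vector(),
        syn.v_rev_e, syn.v_rev_i,
        g_ee, syn.g_tilde_e, syn.g_tilde_i, syn.g_tilde_i, syn.w_fixed,
        syn.tau_g_e, syn.tau_g_i, syn.tau_g_ff,
        condition.plasticity_enabled, plast.tau_stdp * 1000.0,
        plast.pair_window * 1000.0,
        plast.tau_eta * 1000.0, plast.tau_z * 1000.0, plast.xi,
        1.0 / plast.rho_max, plast.eta_ie, plast.z_ie,
        (0 if not plast.eta_includes_trigger
         else (1 if plast.z_includes_trigger else 2)),
        wee, wie,
        mf_t, mf_fib, ensembles.n_ensembles, memb_off, memb,
        g_mossy, mf_f0, mf_a, mf_tau_f * 1000.0,
        pp_t, pp_w, iext,
        snap_every, wee_snap, wie_snap, spike_t, spike_id)
    if status == 2:
        raise FloatingPointError("membrane potential blew up; reduce dt")
    if status == 1:
        raise RuntimeError("spike buffer overflow; raise max_rate_hint")

    return NetworkResult(
        spike_times=spike_t[:n_sp] / 1000.0, spike_ids=spike_id[:n_sp].copy(),
        snapshot_times=np.arange(n_snap) * snap_every * dt,
        wee_snapshots=wee_snap, wie_snapshots=wie_snap,
        w_max=g_ee, w_max_ie=syn.g_tilde_i, ensembles=ensembles,
        condition=condition, dt=dt, seed=seed, drives=list(drive))


def _check_no_burst_overlap(drive, window: float) -> None:
    """Reject drive schedules whose high-rate episodes collide.

    Two ensembles bursting at once would wire spurious cross-ensemble
    weights; detection is heuristic (>= 5 spikes of two fibers inside a
    common window, which chance clusters of low-rate background spiking
    essentially never produce).
    """
    starts = []
    for e, tr in enumerate(drive):
        tr = np.asarray(tr)
        if tr.size >= 5:
            tight = np.flatnonzero(tr[4:] - tr[:-4] < window)
            for i in tight:
                starts.append((tr[i], tr[i + 4], e))
    starts.sort()
    for (s1, e1, a), (s2, e2, b) in zip(starts, starts[1:]):
        if a != b and s2 < e1:
            raise ValueError(
                f"ensembles {a} and {b} receive bursts at the same time")


def discrimination_index(spike_times: np.ndarray, spike_ids: np.ndarray,
                         ensembles: EnsembleSpec, target_ensemble: int,
                         kernel_width: float = 0.1,
                         window: Optional[tuple[float, float]] = None) -> float:
    """Ratio of the target ensemble's integrated population rate to the sum
    over itself and its two ring neighbours.

    Population rates are spike trains smoothed with a causal exponential
    kernel of time constant ``kernel_width`` (normalised to unit area);
    integrals over the window are computed exactly per spike. Raises if
    all three ensembles are silent in the window.
    """
    if ensembles.n_ensembles < 3:
        raise ValueError("ring neighbours require at least 3 ensembles")
    lo, hi = ensembles.neighbours(target_ensemble)
    groups = [target_ensemble, lo, hi] if lo != hi else [target_ensemble, lo]
    t0 = -np.inf if window is None else window[0]
    t1 = np.inf if window is None else window[1]

    def integral(ens: int) -> float:
        m = np.isin(spike_ids, ensembles.members(ens))
        t = spike_times[m]
        t = t[t <= t1]
        if not np.isfinite(t1):
            return float(t[t >= t0].size)
        left = np.maximum(t0 - t, 0.0)
        return float(np.sum(np.exp(-left / kernel_width)
                            - np.exp(-(t1 - t) / kernel_width)))

    num = integral(target_ensemble)
    den = sum(integral(g) for g in groups)
    if den == 0.0:
        raise ValueError("target and neighbour ensembles are all silent")
    return num / den


@dataclass
class FrequencySweepResult:
    frequencies: list[float]
    seeds: list[int]
    snapshot_times: np.ndarray
    wme: dict                 # (freq, seed) -> WME trajectory
    formed: dict              # (freq, seed) -> bool
    condition: NeuromodCondition

    def formation_frequency(self) -> Optional[float]:
        """Lowest tested frequency at which every seed forms ensembles."""
        for f in sorted(self.frequencies):
            if all(self.formed[(f, s)] for s in self.seeds):
                return f
        return None


def run_frequency_sweep(frequencies: Sequence[float],
                        condition: NeuromodCondition,
                        ensembles: Optional[EnsembleSpec] = None,
                        duration: float = 400.0, seeds: Sequence[int] = (0,),
                        dt: float = 1e-4, **kwargs) -> FrequencySweepResult:
    """WME trajectories across intra-burst frequencies (250 ms bursts
    every 20 s), for each seed."""
    ensembles = ensembles or EnsembleSpec()
    wme = {}
    formed = {}
    snap_times = None
    for f in frequencies:
        if f <= 0:
            raise ValueError("frequencies must be positive")
        for s in seeds:
            res = simulate_network(ensembles, condition, duration=duration,
                                   dt=dt, seed=s, frequency=f, **kwargs)
            wme[(f, s)] = res.wme_trajectory()
            formed[(f, s)] = res.formed()
            snap_times = res.snapshot_times
    return FrequencySweepResult(frequencies=list(frequencies),
                                seeds=list(seeds), snapshot_times=snap_times,
                                wme=wme, formed=formed, condition=condition)


@dataclass
class OverlapSweepResult:
    overlaps: list[int]
    seeds: list[int]
    wme: dict                 # (overlap, seed) -> trajectory
    formed: dict
    discrimination: dict      # (overlap, seed) -> mean D over ensembles
    condition: NeuromodCondition

    def max_stable_overlap(self) -> Optional[int]:
        """Largest overlap at which every seed forms discrete ensembles."""
        best = None
        for o in sorted(self.overlaps):
            if all(self.formed[(o, s)] for s in self.seeds):
                best = o
        return best


def run_overlap_sweep(overlaps: Sequence[int], condition: NeuromodCondition,
                      frequency: float = 30.0, duration: float = 400.0,
                      seeds: Sequence[int] = (0,), dt: float = 1e-4,
                      base_spec: Optional[EnsembleSpec] = None,
                      burst_duration: float = 0.25,
                      burst_period: float = 20.0,
                      **kwargs) -> OverlapSweepResult:
    """Ring-overlap experiment: variable network size, 8 ensembles of 8,
    with per-overlap formation outcome and retrieval discrimination.

    The discrimination index is evaluated around each ensemble's last
    drive burst and averaged over ensembles.
    """
    base_spec = base_spec or EnsembleSpec()
    wme, formed, disc = {}, {}, {}
    for o in overlaps:
        spec = replace(base_spec, overlap=int(o))
        for s in seeds:
            res = simulate_network(spec, condition, duration=duration, dt=dt,
                                   seed=s, frequency=frequency,
                                   burst_duration=burst_duration,
                                   burst_period=burst_period, **kwargs)
            wme[(o, s)] = res.wme_trajectory()
            formed[(o, s)] = res.formed()
            ds = []
            n_ens = spec.n_ensembles
            phase_step = burst_period / n_ens
            slot = _interleaved_slots(n_ens)
            for e in range(n_ens):
                start = slot[e] * phase_step
                start += np.floor((duration - start - burst_duration)
                                  / burst_period) * burst_period
                try:
                    ds.append(discrimination_index(
                        res.spike_times, res.spike_ids, spec, e,
                        window=(start, start + 2.0 * burst_duration)))
                except ValueError:
                    pass
            disc[(o, s)] = float(np.mean(ds)) if ds else np.nan
    return OverlapSweepResult(overlaps=[int(o) for o in overlaps],
                              seeds=list(seeds), wme=wme, formed=formed,
                              discrimination=disc, condition=condition)
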