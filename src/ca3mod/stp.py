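"""Tsodyks-Markram short-term plasticity model family for mossy-fiber synapses.

The model tracks a facilitation variable ``f`` (optionally entering the
amplitude squared), a depression variable ``d``, and optional slow
dynamics on the facilitation increment ``a``, the baseline ``f0`` and the
conductance scale. Between stimuli every variable relaxes exponentially
to its baseline, so the per-ISI update is exact (closed form); this is
the iterative form used for fitting and for all simulations here.

Conventions
-----------
* The amplitude reported for stimulus *n* is computed from the state
  *before* that stimulus increments the variables; the incremented
  values only propagate to stimulus *n+1*.
* Times and time constants in seconds, conductances in nS, potentials in
  mV, currents in pA (nS x mV).
* State variables are confined to [0, 1] for valid parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "STPParams", "ModelSpec", "StimulusTrain", "AmplitudeTrain",
    "RecordingConfig", "STPTrajectory", "iterate_stp", "steady_state",
    "burst_response", "amplitude_to_current", "ConfigurationError",
]


class ConfigurationError(ValueError):
    """Raised when a parameter set does not match the requested model."""


_UNIT_FIELDS = ("f0", "a", "a0", "b_a", "f0_tilde", "b_f0")
_TIME_FIELDS = ("tau_f", "tau_d", "tau_a", "tau_f0", "tau_g")


@dataclass
class STPParams:
    """Generative parameters of the STP family; unused fields stay ``None``.

    ``g_max`` scales normalised amplitudes to conductance (nS); ``k_g`` is
    the signed per-spike increment of the optional dynamic conductance.
    """

    g_max: Optional[float] = None
    tau_f: Optional[float] = None
    f0: Optional[float] = None
    a: Optional[float] = None
    tau_d: Optional[float] = None
    tau_a: Optional[float] = None
    a0: Optional[float] = None
    b_a: Optional[float] = None
    f0_tilde: Optional[float] = None
    tau_f0: Optional[float] = None
    b_f0: Optional[float] = None
    tau_g: Optional[float] = None
    k_g: Optional[float] = None

    def __post_init__(self):
        for name in _TIME_FIELDS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in _UNIT_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.g_max is not None and self.g_max < 0:
            raise ValueError("g_max must be non-negative")

    def updated(self, **kwargs) -> "STPParams":
        return replace(self, **kwargs)

    def as_vector(self) -> np.ndarray:
        """Full 13-element vector in the kernel layout (NaN for unset)."""
        vec = np.full(13, np.nan)
        for i, f in enumerate(fields(self)):
            v = getattr(self, f.name)
            if v is not None:
                vec[i] = v
        return vec


@dataclass(frozen=True)
class ModelSpec:
    """Which dynamic variables are active in an STP model variant."""

    f_active: bool = True
    f_exponent: int = 1
    d_active: bool = False
    a_dynamic: bool = False
    f0_dynamic: bool = False
    g_dynamic: bool = False
    name: str = ""

    def __post_init__(self):
        if self.f_exponent not in (1, 2):
            raise ValueError("f_exponent must be 1 or 2")
        if self.f_exponent == 2 and not self.f_active:
            raise ValueError("f_exponent = 2 requires f_active")

    @staticmethod
    def preset(name: str) -> "ModelSpec":
        try:
            return _PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown model preset {name!r}; available: {sorted(_PRESETS)}"
            ) from None

    def required_params(self) -> list[str]:
        req = ["tau_f"]
        req.append("f0_tilde" if self.f0_dynamic else "f0")
        if self.a_dynamic:
            req += ["tau_a", "a0", "b_a"]
        else:
            req.append("a")
        if self.d_active:
            req.append("tau_d")
        if self.f0_dynamic:
            req += ["tau_f0", "b_f0"]
        if self.g_dynamic:
            req += ["tau_g", "k_g", "g_max"]
        return req


_PRESETS = {
    # the excitatory (EPSC) winner: single facilitating variable, squared
    "f2": ModelSpec(f_active=True, f_exponent=2, name="f2"),
    # the inhibitory (IPSC) winner: facilitation + depression + dynamic a
    "afd": ModelSpec(f_active=True, d_active=True, a_dynamic=True, name="afd"),
    "f": ModelSpec(f_active=True, name="f"),
    "fd": ModelSpec(f_active=True, d_active=True, name="fd"),
    "af": ModelSpec(f_active=True, a_dynamic=True, name="af"),
}


@dataclass(frozen=True)
class StimulusTrain:
    """Strictly increasing stimulus (or spike) times in seconds."""

    times: np.ndarray

    def __init__(self, times: Sequence[float]):
        t = np.asarray(times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("stimulus train must be a non-empty 1-d sequence")
        if t[0] < 0:
            raise ValueError("stimulus times must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("stimulus times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass(frozen=True)
class AmplitudeTrain:
    """Per-stimulus evoked amplitudes aligned to a stimulus train."""

    stimulus_times: np.ndarray
    amplitudes: np.ndarray

    def __init__(self, stimulus_times, amplitudes):
        st = stimulus_times.times if isinstance(stimulus_times, StimulusTrain) \
            else np.asarray(stimulus_times, dtype=float)
        amp = np.asarray(amplitudes, dtype=float)
        if st.shape != amp.shape:
            raise ValueError("amplitudes must align one-to-one with stimuli")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "stimulus_times", st)
        object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return self.amplitudes.size


@dataclass(frozen=True)
class RecordingConfig:
    """Voltage-clamp configuration used to convert amplitudes to currents.

    Defaults follow the slice protocol: EPSCs isolated at the GABAergic
    reversal (-70 mV), IPSCs at the glutamatergic reversal (+10 mV).
    """

    v_mem: float = -70.0
    e_glut: float = 10.0
    e_gaba: float = -70.0

    def __post_init__(self):
        if not self.e_glut > self.e_gaba:
            raise ValueError("e_glut must exceed e_gaba")


@dataclass(frozen=True)
class STPTrajectory:
    """Pre-increment state sequence and normalised amplitudes."""

    f: np.ndarray
    d: np.ndarray
    a: np.ndarray
    f0: np.ndarray
    amplitudes: np.ndarray


def _validated_vector(params: STPParams, spec: ModelSpec) -> np.ndarray:
    missing = [n for n in spec.required_params() if getattr(params, n) is None]
    if missing:
        raise ConfigurationError(
            f"model {spec.name or spec!r} requires parameters {missing}"
        )
    vec = params.as_vector()
    return np.nan_to_num(vec, nan=0.0)


def iterate_stp(params: STPParams, spec: ModelSpec,
                stim: StimulusTrain,
                initial_state: Optional[dict] = None) -> STPTrajectory:
    """Run the exact per-ISI recurrence over a stimulus train.

    ``initial_state`` may override the pre-first-stimulus values of
    ``f``, ``d``, ``a`` and ``f0`` (used for steady-state-initialised
    burst protocols); defaults are the baselines.
    """
    if not isinstance(stim, StimulusTrain):
        stim = StimulusTrain(stim)
    vec = _validated_vector(params, spec)
    f0_init = vec[_kernels.IF0T] if spec.f0_dynamic else vec[_kernels.IF0]
    init = {
        "f": f0_init,
        "d": 1.0,
        "a": vec[_kernels.IA0] if spec.a_dynamic else vec[_kernels.IA],
        "f0": f0_init,
    }
    if initial_state:
        init.update(initial_state)
    f, d, a, f0, _, amps = _kernels.stp_states(
        stim.times, vec, spec.f_exponent, spec.d_active, spec.a_dynamic,
        spec.f0_dynamic, spec.g_dynamic,
        init["f"], init["d"], init["a"], init["f0"],
    )
    return STPTrajectory(f=f, d=d, a=a, f0=f0, amplitudes=amps)


def steady_state(params: STPParams, dt_between: float,
                 spec: Optional[ModelSpec] = None) -> tuple[float, float, float]:
    """Fixed point (a_inf, f_inf, d_inf) of the per-spike map under regular
    spiking at interval ``dt_between``.

    If ``spec`` is omitted, a variable is treated as active whenever its
    time constant is set. Closed forms exist except when the baseline
    ``f0`` is itself dynamic, in which case the map is iterated.
    """
    if dt_between <= 0:
        raise ValueError("dt_between must be positive")
    a_dyn = spec.a_dynamic if spec is not None else params.tau_a is not None
    d_act = spec.d_active if spec is not None else params.tau_d is not None
    f0_dyn = spec.f0_dynamic if spec is not None else params.tau_f0 is not None

    if a_dyn:
        r = params.b_a / np.expm1(min(dt_between / params.tau_a, 700.0))
        a_inf = (params.a0 + r) / (1.0 + r)
    else:
        a_inf = params.a

    if f0_dyn:
        spec_eff = spec or ModelSpec(f_active=True, d_active=d_act,
                                     a_dynamic=a_dyn, f0_dynamic=True)
        f_inf = _iterate_fixed_point(params, spec_eff, dt_between)
    else:
        r = a_inf / np.expm1(min(dt_between / params.tau_f, 700.0))
        f_inf = (params.f0 + r) / (1.0 + r)

    if d_act:
        ed = np.exp(-dt_between / params.tau_d)
        d_inf = (1.0 - ed) / (1.0 - (1.0 - f_inf) * ed)
    else:
        d_inf = 1.0
    return float(a_inf), float(f_inf), float(d_inf)


def _iterate_fixed_point(params, spec, dt, n_max=200000, tol=1e-14):
    """Long-run regular-train iteration of f when no closed form applies."""
    times = np.arange(2) * dt
    state = None
    prev = -1.0
    for _ in range(n_max // 2):
        traj = iterate_stp(params, spec, StimulusTrain(times), state)
        state = {"f": traj.f[-1], "d": traj.d[-1], "a": traj.a[-1],
                 "f0": traj.f0[-1]}
        # run pairs of spikes until the pre-spike f converges
        if abs(traj.f[-1] - prev) < tol:
            break
        prev = traj.f[-1]
    return state["f"]


def burst_response(params: STPParams, spec: ModelSpec, dt_between: float,
                   dt_within: float, n_pulses: int) -> AmplitudeTrain:
    """Amplitudes of a regular n-pulse burst embedded in background spiking.

    The state at the first pulse is the steady state of regular spiking at
    ``dt_between`` (the baseline-replacement a0 -> a_inf, f0 -> f_inf,
    d0 -> d_inf), after which the burst proceeds at ``dt_within``.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    a_inf, f_inf, d_inf = steady_state(params, dt_between, spec)
    times = np.arange(n_pulses, dtype=float) * dt_within
    traj = iterate_stp(params, spec, StimulusTrain(times),
                       {"f": f_inf, "d": d_inf, "a": a_inf})
    return AmplitudeTrain(times, traj.amplitudes)


def amplitude_to_current(norm_amplitude, params: STPParams,
                         rec: RecordingConfig, pathway: str):
    """Signed postsynaptic current (pA) from a normalised amplitude.

    current = g_max * amplitude * (v_mem - reversal), with the reversal
    picked by pathway ("excitatory" -> e_glut, "inhibitory" -> e_gaba).
    """
    if pathway not in ("excitatory", "inhibitory"):
        raise ValueError("pathway must be 'excitatory' or 'inhibitory'")
    if params.g_max is None:
        raise ConfigurationError("g_max required to convert amplitudes")
    rev = rec.e_glut if pathway == "excitatory" else rec.e_gaba
    return params.g_max * np.asarray(norm_amplitude) * (rec.v_mem - rev)
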