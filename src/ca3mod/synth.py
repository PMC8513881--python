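"""Synthetic evoked-amplitude datasets with known ground truth.

Stands in for slice recordings of mossy-fiber EPSCs/IPSCs: amplitudes
are generated from the fitted STP models (f^2 for the excitatory
pathway, afd for the disynaptic inhibitory pathway) at the published
best-fit parameter sets, with neuromodulator conditions realised as the
published parameter changes (acetylcholine halves the excitatory
conductance and reshapes the inhibitory pathway; noradrenaline slows
inhibitory recovery from depression). Observation noise follows the
fitting likelihood (amplitude-proportional variance A_n / 2 by default,
or proportional sd behind the same switch the likelihood exposes),
clipped at zero because evoked amplitudes are reported as non-negative
magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .patterns import CoxParams, sample_cox_train
from .stp import (AmplitudeTrain, ModelSpec, RecordingConfig, STPParams,
                  StimulusTrain, iterate_stp)

__all__ = [
    "ConditionSpec", "SyntheticDataset", "condition_spec", "generate_dataset",
    "make_fixture_suite", "EPSC_CONTROL", "IPSC_CONTROL", "MODULATIONS",
    "holding_potential", "driving_force",
]

# Best-fit parameter sets for the two winning model variants.
EPSC_CONTROL = STPParams(g_max=6.6, tau_f=3.3, f0=0.3, a=0.15)
IPSC_CONTROL = STPParams(g_max=26.0, tau_f=1.4, f0=0.05, tau_d=0.8,
                         tau_a=8.0, a0=0.08, b_a=0.11)

# Parameter overrides per (pathway, condition); only fields the
# neuromodulators change are allowed to appear here.
MODULATIONS = {
    ("excitatory", "control"): {},
    ("excitatory", "ACh"): {"g_max": 3.3},
    ("excitatory", "NA"): {},
    ("inhibitory", "control"): {},
    ("inhibitory", "ACh"): {"g_max": 6.7, "f0": 0.16},
    ("inhibitory", "NA"): {"tau_d": 1.6},
}

_REC = RecordingConfig()


def holding_potential(pathway: str) -> float:
    """EPSCs recorded at the GABAergic reversal, IPSCs at the glutamatergic."""
    return _REC.e_gaba if pathway == "excitatory" else _REC.e_glut


def driving_force(pathway: str, rec: RecordingConfig = _REC) -> float:
    """|holding - reversal| in mV for the given pathway."""
    if pathway == "excitatory":
        return abs(holding_potential(pathway) - rec.e_glut)
    return abs(holding_potential(pathway) - rec.e_gaba)


@dataclass(frozen=True)
class ConditionSpec:
    """A pathway x neuromodulator condition with its generative parameters."""

    condition: str                     # control | ACh | NA
    pathway: str                       # excitatory | inhibitory
    base_params: STPParams
    modulation: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.condition not in ("control", "ACh", "NA"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.pathway not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown pathway {self.pathway!r}")
        allowed = set(MODULATIONS[(self.pathway, self.condition)])
        extra = set(self.modulation) - allowed
        if extra:
            raise ValueError(
                f"{self.condition} modulation of the {self.pathway} pathway "
                f"may only change {sorted(allowed)}, got {sorted(extra)}")

    @property
    def params(self) -> STPParams:
        return self.base_params.updated(**self.modulation)

    @property
    def model(self) -> ModelSpec:
        return ModelSpec.preset("f2" if self.pathway == "excitatory" else "afd")


def condition_spec(pathway: str, condition: str) -> ConditionSpec:
    base = EPSC_CONTROL if pathway == "excitatory" else IPSC_CONTROL
    return ConditionSpec(condition=condition, pathway=pathway,
                         base_params=base,
                         modulation=dict(MODULATIONS[(pathway, condition)]))


@dataclass
class SyntheticDataset:
    """Labelled amplitude trains plus the ground truth that generated them."""

    condition: ConditionSpec
    protocol: StimulusTrain
    trains: list[AmplitudeTrain]
    truth: STPParams
    noise_scale: float
    seed: int

    @property
    def model_amplitudes(self) -> np.ndarray:
        """Noise-free model amplitudes in pA."""
        traj = iterate_stp(self.truth, self.condition.model, self.protocol)
        return self.truth.g_max * traj.amplitudes * driving_force(self.condition.pathway)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "protocol.csv", self.protocol.times,
                   header="time_s", comments="", fmt="%.9f")
        tag = f"{self.condition.condition}_{self.condition.pathway}"
        mat = np.column_stack([self.protocol.times]
                              + [t.amplitudes for t in self.trains])
        header = "time_s," + ",".join(
            f"amplitude_pA_rep{i}" for i in range(len(self.trains)))
        np.savetxt(out / f"amplitudes_{tag}.csv", mat, delimiter=",",
                   header=header, comments="", fmt="%.9f")
        truth = {k: v for k, v in self.truth.__dict__.items() if v is not None}
        (out / "truth.json").write_text(json.dumps({
            "condition": self.condition.condition,
            "pathway": self.condition.pathway,
            "model": self.condition.model.name,
            "params": truth,
            "noise_scale": self.noise_scale,
            "seed": self.seed,
        }, indent=2) + "\n")


def generate_dataset(condition: ConditionSpec, protocol: StimulusTrain,
                     n_replicates: int = 1, seed: int = 0,
                     noise: bool = True, noise_scale: float = 0.5,
                     noise_model: str = "variance") -> SyntheticDataset:
    """Model-mean amplitudes plus observation noise, one train per replicate."""
    params = condition.params
    traj = iterate_stp(params, condition.model, protocol)
    mean = params.g_max * traj.amplitudes * driving_force(condition.pathway)
    rng = np.random.default_rng(seed)
    if noise_model == "variance":
        sd = np.sqrt(noise_scale * mean)
    elif noise_model == "sd":
        sd = noise_scale * mean
    else:
        raise ValueError("noise_model must be 'variance' or 'sd'")
    trains = []
    for _ in range(n_replicates):
        if noise:
            y = rng.normal(mean, sd)
            y = np.clip(y, 0.0, None)
        else:
            y = mean.copy()
        trains.append(AmplitudeTrain(protocol, y))
    return SyntheticDataset(condition=condition, protocol=protocol,
                            trains=trains, truth=params,
                            noise_scale=noise_scale if noise else 0.0,
                            seed=seed)


def make_fixture_suite(seed: int = 0, out_dir: Optional[str] = None,
                       n_stimuli: int = 100) -> dict:
    """Small deterministic datasets covering every pathway x condition pair.

    One shared naturalistic protocol; per-pair sub-seeds derived from
    ``seed``. When ``out_dir`` is given, each dataset is written to its
    own sub-directory along with a manifest.
    """
    protocol = sample_cox_train(CoxParams(n_intervals=n_stimuli - 1, seed=seed))
    suite = {}
    for i, (pathway, condition) in enumerate(sorted(MODULATIONS)):
        spec = condition_spec(pathway, condition)
        suite[(pathway, condition)] = generate_dataset(
            spec, protocol, n_replicates=1, seed=seed * 1009 + i)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        entries = []
        for (pathway, condition), ds in suite.items():
            sub = out / f"{condition}_{pathway}"
            ds.write(sub)
            entries.append(sub.name)
        (out / "manifest.json").write_text(json.dumps({
            "seed": seed, "n_stimuli": n_stimuli, "datasets": sorted(entries),
        }, indent=2) + "\n")
    return suite
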