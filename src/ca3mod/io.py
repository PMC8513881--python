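"""Plain-text readers and writers for the package's data types.

Stimulus trains: single-column CSV (``time_s`` header) or bare newline
text. Amplitude trains: two-column CSV ``time_s,amplitude``. Parameter
sets and model specs: flat JSON with an optional preset name plus
overrides. Posterior chains: CSV (one column per parameter) + JSON
metadata sidecar.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorSamples
from .stp import AmplitudeTrain, ModelSpec, STPParams, StimulusTrain

__all__ = [
    "read_stimulus_train", "write_stimulus_train", "read_amplitude_train",
    "write_amplitude_train", "read_model_config", "write_model_config",
    "write_posterior", "read_posterior", "write_train_bundle",
]


def read_stimulus_train(path) -> StimulusTrain:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stimulus file not found: {path}")
    txt = path.read_text().strip()
    if not txt:
        raise ValueError(f"stimulus file is empty: {path}")
    lines = txt.splitlines()
    if any(c.isalpha() for c in lines[0]):
        lines = lines[1:]
    times = [float(l.split(",")[0]) for l in lines if l.strip()]
    if not times:
        raise ValueError(f"stimulus file contains no data rows: {path}")
    return StimulusTrain(times)


def write_stimulus_train(train: StimulusTrain, path) -> None:
    np.savetxt(path, train.times, header="time_s", comments="", fmt="%.9f")


def read_amplitude_train(path) -> AmplitudeTrain:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"amplitude file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"amplitude file contains no data rows: {path}")
    times = df.iloc[:, 0].to_numpy(float)
    amps = df.iloc[:, 1].to_numpy(float)
    return AmplitudeTrain(times, amps)


def write_amplitude_train(train: AmplitudeTrain, path) -> None:
    np.savetxt(path, np.column_stack([train.stimulus_times, train.amplitudes]),
               delimiter=",", header="time_s,amplitude", comments="",
               fmt="%.9f")


def write_train_bundle(trains: dict, path) -> None:
    """Multi-train JSON bundle {source_id: [times]}."""
    Path(path).write_text(json.dumps(
        {str(k): np.asarray(v).tolist() for k, v in trains.items()}) + "\n")


def read_model_config(path) -> tuple[STPParams, ModelSpec]:
    """Flat JSON: {"preset": "f2", "params": {...}} or explicit spec flags."""
    doc = json.loads(Path(path).read_text())
    if "preset" in doc:
        spec = ModelSpec.preset(doc["preset"])
    else:
        flags = {k: v for k, v in doc.items()
                 if k in ("f_active", "f_exponent", "d_active", "a_dynamic",
                          "f0_dynamic", "g_dynamic", "name")}
        spec = ModelSpec(**flags)
    params = STPParams(**doc.get("params", {}))
    return params, spec


def write_model_config(params: STPParams, spec: ModelSpec, path) -> None:
    doc = {"preset": spec.name} if spec.name else asdict(spec)
    doc["params"] = {k: v for k, v in asdict(params).items() if v is not None}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_posterior(samples: PosteriorSamples, stem) -> None:
    stem = Path(stem)
    samples.to_dataframe().to_csv(stem.with_suffix(".csv"), index=False)
    meta = {
        "param_names": samples.param_names,
        "acceptance_rate": samples.acceptance_rate,
        "n_burn": samples.n_burn, "n_keep": samples.n_keep,
        "thinning": samples.thinning, "seed": samples.seed,
        "spec": samples.spec.name if samples.spec else None,
        "meta": samples.meta,
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_posterior(stem) -> PosteriorSamples:
    stem = Path(stem)
    df = pd.read_csv(stem.with_suffix(".csv"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    names = meta["param_names"]
    spec = ModelSpec.preset(meta["spec"]) if meta.get("spec") else None
    return PosteriorSamples(
        param_names=names, chain=df[names].to_numpy(),
        log_likelihood=df["log_likelihood"].to_numpy(),
        log_posterior=df["log_posterior"].to_numpy(),
        acceptance_rate=meta["acceptance_rate"], n_burn=meta["n_burn"],
        n_keep=meta["n_keep"], thinning=meta["thinning"], seed=meta["seed"],
        spec=spec, meta=meta.get("meta", {}))
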