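"""End-to-end reproduction drivers.

Each pipeline is a pure function of (config, seed): it validates its
configuration, runs the underlying modules, writes numeric outputs and a
run manifest (config hash, seeds, versions, timing) to an output
directory, and returns the in-memory results. Defaults encode the
published setups, so an empty-override config reproduces them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .ei import BurstGrid, compute_ei_map
from .inference import compare_models, fit_mh, posterior_predictive_p
from .io import read_amplitude_train, read_stimulus_train, write_posterior
from .network import (EnsembleSpec, NeuromodCondition, run_frequency_sweep,
                      run_overlap_sweep, simulate_network)
from .patterns import (CorrelatedPopulationPattern, CoxParams,
                       sample_correlated_population, sample_cox_train)
from .stp import ModelSpec
from .synth import condition_spec, generate_dataset

log = logging.getLogger("ca3mod")

__all__ = ["RunManifest", "reproduce_stp_analysis",
           "reproduce_network_analysis", "reproduce_ei_analysis",
           "ConfigError"]


class ConfigError(ValueError):
    """A pipeline configuration failed schema validation."""


def _require(config: dict, keys: dict, pipeline: str) -> dict:
    """Minimal schema check: fill defaults, reject unknown keys."""
    unknown = set(config) - set(keys)
    if unknown:
        raise ConfigError(f"{pipeline}: unknown config keys {sorted(unknown)}")
    out = {}
    for k, default in keys.items():
        if default is _REQUIRED and k not in config:
            raise ConfigError(f"{pipeline}: missing required config key {k!r}")
        out[k] = config.get(k, default)
    return out


_REQUIRED = object()


@dataclass
class RunManifest:
    pipeline: str
    config: dict
    seed: int
    version: str = field(default_factory=lambda: __version__)
    started: float = field(default_factory=time.time)
    elapsed_s: float = 0.0
    outputs: list = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, out_dir) -> None:
        self.elapsed_s = time.time() - self.started
        doc = {"pipeline": self.pipeline, "config": self.config,
               "config_hash": self.config_hash, "seed": self.seed,
               "version": self.version, "elapsed_s": round(self.elapsed_s, 3),
               "outputs": self.outputs}
        Path(out_dir, "manifest.json").write_text(json.dumps(doc, indent=2) + "\n")


def reproduce_stp_analysis(config: Optional[dict] = None, seed: int = 0,
                           out_dir=None) -> dict:
    """Protocol -> fits for the candidate STP models -> AIC/BIC weights ->
    posterior-predictive goodness of fit.

    By default generates a synthetic dataset for the configured
    pathway/condition; set ``data`` / ``protocol`` paths to fit recorded
    amplitude trains instead.
    """
    cfg = _require(config or {}, {
        "pathway": "excitatory", "condition": "control",
        "models": ["f2", "af", "afd"], "n_steps": 20000, "n_burn": 5000,
        "data": None, "protocol": None, "n_stimuli": 100,
        "ppp_draws": 500,
    }, "stp_analysis")
    log.info("stp_analysis: seed=%d config=%s", seed, cfg)
    manifest = RunManifest("stp_analysis", cfg, seed)
    rng = np.random.default_rng(seed)

    if cfg["data"] is not None:
        protocol = read_stimulus_train(cfg["protocol"])
        observed = read_amplitude_train(cfg["data"])
        truth = None
    else:
        protocol = sample_cox_train(CoxParams(n_intervals=cfg["n_stimuli"] - 1,
                                              seed=int(rng.integers(2**31))))
        cond = condition_spec(cfg["pathway"], cfg["condition"])
        ds = generate_dataset(cond, protocol, seed=int(rng.integers(2**31)))
        observed = ds.trains[0]
        truth = ds.truth

    fits = {}
    for name in cfg["models"]:
        fits[name] = fit_mh(ModelSpec.preset(name), protocol, observed,
                            n_steps=cfg["n_steps"], n_burn=cfg["n_burn"],
                            seed=int(rng.integers(2**31)))
        log.info("stp_analysis: fitted %s (acceptance %.2f)", name,
                 fits[name].acceptance_rate)
    comparison = compare_models(fits, n_data=len(observed))
    best = comparison.best("bic")
    ppp = posterior_predictive_p(fits[best], ModelSpec.preset(best), protocol,
                                 observed, n_draws=cfg["ppp_draws"],
                                 seed=int(rng.integers(2**31)))
    result = {"fits": fits, "comparison": comparison, "best_model": best,
              "posterior_predictive_p": ppp, "protocol": protocol,
              "observed": observed, "truth": truth}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, fit in fits.items():
            write_posterior(fit, out / f"posterior_{name}")
            manifest.outputs.append(f"posterior_{name}.csv")
        (out / "comparison.json").write_text(json.dumps({
            "aic": comparison.aic, "bic": comparison.bic,
            "aic_weights": comparison.aic_weights,
            "bic_weights": comparison.bic_weights,
            "best_model": best, "posterior_predictive_p": ppp,
        }, indent=2) + "\n")
        manifest.outputs.append("comparison.json")
        manifest.write(out)
    return result


def reproduce_ei_analysis(config: Optional[dict] = None, seed: int = 0,
                          out_dir=None) -> dict:
    """Excitation-inhibition ratio maps for the three conditions."""
    cfg = _require(config or {}, {
        "conditions": ["control", "ACh", "NA"], "n_pulses": 10,
        "n_between": 25, "n_within": 25,
    }, "ei_analysis")
    manifest = RunManifest("ei_analysis", cfg, seed)
    grid = BurstGrid(
        between_intervals=np.logspace(np.log10(0.5), np.log10(60.0),
                                      cfg["n_between"]),
        within_intervals=np.logspace(np.log10(0.01), np.log10(1.0),
                                     cfg["n_within"]),
        n_pulses=cfg["n_pulses"])
    maps = {c: compute_ei_map(grid, condition_spec("excitatory", c),
                              condition_spec("inhibitory", c))
            for c in cfg["conditions"]}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.concat([m.to_dataframe() for m in maps.values()])
        df.to_csv(out / "ei_map.csv", index=False)
        manifest.outputs.append("ei_map.csv")
        manifest.write(out)
    return {"grid": grid, "maps": maps}


def reproduce_network_analysis(config: Optional[dict] = None, seed: int = 0,
                               out_dir=None) -> dict:
    """Network experiments: fig5-ladder, freq-sweep or overlap-sweep."""
    cfg = _require(config or {}, {
        "experiment": _REQUIRED,
        "condition": "na", "ablate": [], "duration": 400.0, "dt": 1e-4,
        "frequencies": [10.0, 20.0, 30.0, 40.0], "overlaps": [0, 1, 2, 3, 4],
        "frequency": 30.0, "n_seeds": 3,
    }, "network_analysis")
    log.info("network_analysis: seed=%d config=%s", seed, cfg)
    manifest = RunManifest("network_analysis", cfg, seed)
    condition = NeuromodCondition(
        name=cfg["condition"],
        ablate_excitability="excitability" in cfg["ablate"],
        ablate_ee_conductance="ee-conductance" in cfg["ablate"])
    seeds = [seed + i for i in range(cfg["n_seeds"])]
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

    if cfg["experiment"] == "freq-sweep":
        sweep = run_frequency_sweep(cfg["frequencies"], condition,
                                    duration=cfg["duration"], seeds=seeds,
                                    dt=cfg["dt"])
        result = {"sweep": sweep,
                  "formation_frequency": sweep.formation_frequency()}
        if out is not None:
            rows = [{"frequency": f, "seed": s, "time_s": t, "wme": w}
                    for (f, s), traj in sweep.wme.items()
                    for t, w in zip(sweep.snapshot_times, traj)]
            pd.DataFrame(rows).to_csv(out / "wme_frequency.csv", index=False)
            manifest.outputs.append("wme_frequency.csv")
    elif cfg["experiment"] == "overlap-sweep":
        sweep = run_overlap_sweep(cfg["overlaps"], condition,
                                  frequency=cfg["frequency"],
                                  duration=cfg["duration"], seeds=seeds,
                                  dt=cfg["dt"])
        result = {"sweep": sweep,
                  "max_stable_overlap": sweep.max_stable_overlap(),
                  "stability_table": {
                      o: all(sweep.formed[(o, s)] for s in seeds)
                      for o in sweep.overlaps}}
        if out is not None:
            rows = [{"overlap": o, "seed": s,
                     "formed": sweep.formed[(o, s)],
                     "discrimination": sweep.discrimination[(o, s)]}
                    for o in sweep.overlaps for s in seeds]
            pd.DataFrame(rows).to_csv(out / "overlap_stability.csv", index=False)
            manifest.outputs.append("overlap_stability.csv")
    elif cfg["experiment"] == "fig5-ladder":
        result = {"ladder": _fig5_ladder(cfg, seed)}
        if out is not None:
            (out / "ladder.json").write_text(
                json.dumps(result["ladder"], indent=2) + "\n")
            manifest.outputs.append("ladder.json")
    else:
        raise ConfigError(f"unknown experiment {cfg['experiment']!r}")
    if out is not None:
        manifest.write(out)
    return result


def _fig5_ladder(cfg: dict, seed: int) -> dict:
    """Build-up experiment: 2E, 10E, 10E+5I populations under mossy-fiber
    or correlated perforant-path drive; classify formation stability."""
    from .patterns import BurstDrivePattern, sample_burst_drive

    duration = cfg["duration"]
    dt = cfg["dt"]
    outcomes = {}
    layouts = {"2E": (2, 0), "10E": (10, 0), "10E+5I": (10, 5)}
    rng = np.random.default_rng(seed)
    for label, (n_exc, n_inh) in layouts.items():
        spec = EnsembleSpec(n_ensembles=1, ensemble_size=n_exc,
                            n_inhibitory=n_inh)
        cond = NeuromodCondition("na")
        # mossy-fiber drive: one shared facilitating fiber
        mf = sample_burst_drive(BurstDrivePattern(
            burst_rate=50.0, burst_duration=0.2, burst_period=20.0,
            duration=duration, seed=int(rng.integers(2**31))))
        res_mf = simulate_network(spec, cond, drive=[mf], duration=duration,
                                  dt=dt, seed=seed)
        # perforant-path drive: correlated population, static weak synapses
        pp = sample_correlated_population(CorrelatedPopulationPattern(
            n_sources=120, rate=10.0, correlation=0.9, duration=duration,
            seed=int(rng.integers(2**31))))
        pp_times = np.sort(np.concatenate(pp))
        res_pp = simulate_network(spec, cond,
                                  drive=[np.empty(0)], duration=duration,
                                  dt=dt, seed=seed,
                                  pp_drive=(pp_times, 0.1),
                                  max_rate_hint=200.0)
        outcomes[label] = {"mossy": _classify(res_mf),
                           "perforant": _classify(res_pp)}
    return outcomes


def _classify(res) -> str:
    """stable: formed and stays; unstable: weights rise then reset."""
    wme = res.wme_trajectory()
    zero = res.wme_zero()
    if res.formed():
        return "stable"
    reached = wme.min() < 0.5 * zero
    reset = reached and wme[-1] > wme.min() + 0.25 * zero
    if reached and (reset or not res.formed()):
        return "unstable"
    return "unformed"
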