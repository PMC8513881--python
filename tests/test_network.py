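"""CA3 spiking network: dynamics contracts, plasticity rule, metrics."""

import numpy as np
import pytest

from ca3mod.network import (EnsembleSpec, NeuromodCondition, PlasticityParams,
                            discrimination_index, simulate_network,
                            staggered_burst_drive, stdp_update,
                            target_weight_matrix, weight_matrix_error)

TWO_CELL = EnsembleSpec(n_ensembles=1, ensemble_size=2, n_inhibitory=0)


class TestStdpUpdate:
    def test_coincident_pair_gives_learning_rate(self):
        assert stdp_update(0.0, eta=0.3, z=0.0) == pytest.approx(0.3)

    def test_no_potentiation_at_rate_ceiling(self):
        assert stdp_update(0.0, eta=0.1, z=1.0) == pytest.approx(0.0)
        assert stdp_update(0.015, eta=0.1, z=1.0) < 0
        assert stdp_update(-0.2, eta=0.1, z=1.0) < 0

    def test_symmetric_in_lag_sign(self):
        rng = np.random.default_rng(0)
        for dt in rng.uniform(0, 0.3, 20):
            assert stdp_update(dt, 0.05, 0.3) == pytest.approx(
                stdp_update(-dt, 0.05, 0.3))


class TestWeightMatrixError:
    def test_zero_at_target(self):
        spec = EnsembleSpec()
        target = target_weight_matrix(spec, 0.5)
        assert weight_matrix_error(target, spec, 0.5) == 0.0

    def test_all_zero_counts_within_pairs(self):
        spec = EnsembleSpec()  # 8 ensembles of 8, no overlap
        wme = weight_matrix_error(np.zeros((64, 64)), spec, 0.25)
        assert wme == pytest.approx(0.25 * 8 * 8 * 7)  # = 112

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weight_matrix_error(np.zeros((10, 10)), EnsembleSpec(), 0.5)


class TestDiscriminationIndex:
    def _raster(self, spec, active, rate, t0=0.0, t1=1.0, seed=0):
        rng = np.random.default_rng(seed)
        times, ids = [], []
        for e, r in zip(active, rate):
            for c in spec.members(e):
                n = rng.poisson(r * (t1 - t0))
                times.extend(rng.uniform(t0, t1, n))
                ids.extend([c] * n)
        order = np.argsort(times)
        return np.asarray(times)[order], np.asarray(ids)[order]

    def test_silent_neighbours_give_one(self):
        spec = EnsembleSpec()
        t, i = self._raster(spec, [2], [20.0])
        assert discrimination_index(t, i, spec, 2) == pytest.approx(1.0)

    def test_equal_rates_give_one_third(self):
        spec = EnsembleSpec()
        t, i = self._raster(spec, [1, 2, 3], [20.0] * 3, seed=1)
        d = discrimination_index(t, i, spec, 2, window=(0.0, 1.0))
        assert d == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_decreases_with_shared_activity(self):
        spec = EnsembleSpec()
        ds = []
        for frac in (0.0, 0.5, 1.0):
            t, i = self._raster(spec, [2, 1, 3],
                                [20.0, 20.0 * frac, 20.0 * frac], seed=2)
            ds.append(discrimination_index(t, i, spec, 2, window=(0, 1)))
        assert ds[0] > ds[1] > ds[2]

    def test_all_silent_is_an_error(self):
        spec = EnsembleSpec()
        t, i = self._raster(spec, [6], [20.0])
        with pytest.raises(ValueError):
            discrimination_index(t, i, spec, 2)


class TestSimulateNetwork:
    def test_no_drive_means_no_spikes(self):
        res = simulate_network(TWO_CELL, NeuromodCondition("na"),
                               drive=[np.empty(0)], duration=5.0, seed=0)
        assert res.spike_times.size == 0

    def test_constant_current_spikes_with_reset(self):
        spec = EnsembleSpec(n_ensembles=1, ensemble_size=1, n_inhibitory=0)
        res = simulate_network(spec, NeuromodCondition("control"),
                               drive=[np.empty(0)], duration=2.0, seed=0,
                               i_ext=np.array([200.0]))
        assert res.spike_times.size > 5
        assert np.all(np.diff(res.spike_times) > 0.001)  # reset enforces ISI

    def test_two_cells_wire_to_maximum_and_stay(self):
        res = simulate_network(TWO_CELL, NeuromodCondition("na"),
                               duration=200.0, seed=1, frequency=50.0,
                               burst_duration=0.2)
        w = res.wee_snapshots[-1]
        assert w[0, 1] > 0.99 and w[1, 0] > 0.99
        assert res.formed()

    def test_plasticity_disabled_freezes_weights(self):
        res = simulate_network(TWO_CELL, NeuromodCondition("control"),
                               duration=50.0, seed=1, frequency=50.0,
                               burst_duration=0.2)
        assert not res.wee_snapshots.any()
        assert res.spike_times.size > 0  # the network still spikes

    def test_seed_determinism(self):
        a = simulate_network(TWO_CELL, NeuromodCondition("na"), duration=60.0,
                             seed=4, frequency=50.0, burst_duration=0.2)
        b = simulate_network(TWO_CELL, NeuromodCondition("na"), duration=60.0,
                             seed=4, frequency=50.0, burst_duration=0.2)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.wee_snapshots, b.wee_snapshots)

    def test_halving_dt_preserves_outcome(self):
        kw = dict(duration=100.0, seed=3, frequency=50.0, burst_duration=0.2)
        coarse = simulate_network(TWO_CELL, NeuromodCondition("na"), **kw)
        fine = simulate_network(TWO_CELL, NeuromodCondition("na"), dt=5e-5,
                                **kw)
        z = coarse.wme_zero()
        assert abs(coarse.wme_trajectory()[-1]
                   - fine.wme_trajectory()[-1]) < 0.05 * z

    def test_weight_bounds_and_finiteness(self):
        spec = EnsembleSpec(n_ensembles=8, ensemble_size=8, n_inhibitory=16)
        res = simulate_network(spec, NeuromodCondition("ach"), duration=25.0,
                               seed=0, frequency=30.0)
        assert np.all(res.wee_snapshots >= 0) and np.all(res.wee_snapshots <= 1)
        assert np.all(res.wie_snapshots >= 0) and np.all(res.wie_snapshots <= 1)
        assert np.isfinite(res.wee_snapshots).all()

    def test_overlapping_bursts_rejected(self):
        burst = np.arange(10) / 50.0
        with pytest.raises(ValueError):
            simulate_network(EnsembleSpec(n_ensembles=2, ensemble_size=2,
                                          n_inhibitory=0),
                             NeuromodCondition("na"),
                             drive=[burst, burst + 0.05], duration=2.0)

    def test_mossy_drive_is_stable_and_perforant_drive_resets(self):
        # sparse facilitating bursts wire a small ensemble quickly and
        # stably; dense correlated drive causes weight resetting
        spec = EnsembleSpec(n_ensembles=1, ensemble_size=2, n_inhibitory=0)
        res = simulate_network(spec, NeuromodCondition("na"), duration=150.0,
                               seed=5, frequency=50.0, burst_duration=0.2)
        assert res.formed()
        from ca3mod.patterns import (CorrelatedPopulationPattern,
                                     sample_correlated_population)
        pp = sample_correlated_population(CorrelatedPopulationPattern(
            duration=150.0, seed=6))
        pp_t = np.sort(np.concatenate(pp))
        res_pp = simulate_network(spec, NeuromodCondition("na"),
                                  drive=[np.empty(0)], duration=150.0, seed=5,
                                  pp_drive=(pp_t, 0.1), max_rate_hint=200.0)
        wme = res_pp.wme_trajectory() / res_pp.wme_zero()
        reached = wme.min() < 0.5
        reset = wme[np.argmin(wme):].max() > wme.min() + 0.25
        assert reached and reset


class TestEnsembleSpec:
    def test_ring_overlap_layout(self):
        spec = EnsembleSpec(overlap=2)
        assert spec.n_excitatory == 48
        m0, m1 = spec.members(0), spec.members(1)
        assert len(np.intersect1d(m0, m1)) == 2
        last = spec.members(7)
        assert len(np.intersect1d(last, m0)) == 2  # ring closure

    def test_every_cell_belongs_to_an_ensemble(self):
        for o in range(4):
            spec = EnsembleSpec(overlap=o)
            covered = np.unique(np.concatenate(
                [spec.members(e) for e in range(8)]))
            assert covered.size == spec.n_excitatory

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            EnsembleSpec(overlap=8)

    def test_staggered_drive_interleaves_neighbours(self):
        spec = EnsembleSpec()
        drives = staggered_burst_drive(spec, 30.0, 100.0, seed=0)
        # first burst onset per ensemble: ring neighbours >= 5 s apart
        onsets = []
        for tr in drives:
            tight = np.flatnonzero(tr[4:] - tr[:-4] < 0.25)
            onsets.append(tr[tight[0]] if tight.size else np.nan)
        onsets = np.asarray(onsets) % 20.0
        gaps = np.abs(np.diff(np.concatenate([onsets, onsets[:1]])))
        gaps = np.minimum(gaps, 20.0 - gaps)
        assert np.nanmin(gaps) > 5.0
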