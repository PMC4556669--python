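import hashlib
import json

import numpy as np
import pytest

from conftest import noise_free_config, recover_rate
from kaedeflux import (
    SimulationConfig,
    generate_ao_volume,
    generate_cohort,
    render_frames,
    simulate_axon,
    simulate_kinetics,
)
from kaedeflux.pipeline import RunConfig


class TestKinetics:
    def test_homogeneous_steady_state(self):
        cfg = SimulationConfig(
            k_local=0.0, soma_influx=0.0, transport_um_min=0.0, bleach_per_min=0.0,
            tip_advance_speed_um_min=0.0, residual_green_fraction=0.1,
        )
        truth = simulate_kinetics(cfg)
        assert all(np.allclose(g, 0.1, atol=1e-12) for g in truth.green)
        assert all(np.allclose(r, 1.0, atol=1e-12) for r in truth.red)

    def test_local_synthesis_grows_tip_green(self):
        truth = simulate_kinetics(SimulationConfig(k_local=0.01))
        tip = [g[-1] for g in truth.green]
        assert np.all(np.diff(tip) > 0)

    def test_mass_conservation_closed_boundaries(self):
        cfg = SimulationConfig(
            k_local=0.0, soma_influx=0.0, bleach_per_min=0.0,
            tip_advance_speed_um_min=0.0, residual_green_fraction=0.3,
        )
        truth = simulate_kinetics(cfg)
        for which in ("green", "red"):
            masses = [truth.total_mass(which, t) for t in range(truth.n_timepoints)]
            assert max(masses) - min(masses) <= 1e-3 * masses[0]

    def test_red_monotone_non_increasing(self):
        truth = simulate_kinetics(SimulationConfig(bleach_per_min=0.002))
        for t in range(truth.n_timepoints - 1):
            n = len(truth.red[t])
            assert np.all(truth.red[t + 1][:n] <= truth.red[t] + 1e-12)

    def test_grid_refinement_consistency(self):
        coarse_cfg = SimulationConfig()
        fine_cfg = SimulationConfig(ds_um=coarse_cfg.ds_um / 4.0)
        coarse = simulate_kinetics(coarse_cfg)
        fine = simulate_kinetics(fine_cfg)
        for t in range(coarse.n_timepoints):
            ref = np.interp(coarse.s[t], fine.s[t], fine.green[t])
            dev = np.max(np.abs(coarse.green[t] - ref)) / np.max(np.abs(fine.green[t]))
            assert dev < 0.02

    def test_tip_advances(self):
        truth = simulate_kinetics(SimulationConfig())
        lengths = [truth.tip_length_um(t) for t in range(truth.n_timepoints)]
        assert lengths[-1] > lengths[0]
        # ~0.12 um/min for 90 min
        assert lengths[-1] - lengths[0] == pytest.approx(10.8, rel=0.1)

    def test_substep_cap_enforced(self):
        cfg = SimulationConfig(diffusion_um2_min=50.0, ds_um=0.02,
                               max_substeps_per_frame=100)
        with pytest.raises(ValueError, match="substep"):
            simulate_kinetics(cfg)


class TestRender:
    def test_zero_noise_uniform_fields_give_unit_ratio(self):
        cfg = noise_free_config(
            k_local=0.0, soma_influx=0.0, transport_um_min=0.0,
            bleach_per_min=0.0, residual_green_fraction=1.0,
        )
        truth, stack, traces = simulate_axon(cfg)
        assert np.array_equal(stack.frames[:, 0], stack.frames[:, 1])
        rc = RunConfig(threshold_method="manual", manual_threshold=0.5)
        from kaedeflux.pipeline import quantify_axon

        profiles = quantify_axon(stack, traces, rc)
        assert np.max(np.abs(profiles.mean_ratio - 1.0)) < 1e-6

    def test_same_seed_bit_identical(self):
        truth = simulate_kinetics(SimulationConfig(rng_seed=7))
        s1, _ = render_frames(truth)
        s2, _ = render_frames(truth)
        assert np.array_equal(s1.frames, s2.frames)

    def test_k_local_sweep_monotone_noise_free(self):
        rates = []
        for k in (0.0, 0.005, 0.02):
            _, stack, traces = simulate_axon(noise_free_config(k_local=k, rng_seed=0))
            rates.append(recover_rate(stack, traces))
        assert rates[0] > rates[1] > rates[2]  # more synthesis, more negative

    def test_path_leaving_fov_rejected(self):
        cfg = SimulationConfig(image_shape=(96, 120))  # too short in x
        truth = simulate_kinetics(cfg)
        with pytest.raises(ValueError, match="field of view"):
            render_frames(truth, cfg)

    def test_traces_are_tip_anchored_and_long_enough(self):
        _, _, traces = simulate_axon(SimulationConfig())
        for tr in traces:
            assert tr.arc_length >= 149.0  # supports the 150-pixel profile


class TestCohort:
    def test_design_counts(self, tmp_path):
        manifest = generate_cohort(2, 1, seed=0, out_dir=tmp_path)
        assert len(manifest["axons"]) == 3
        design = (tmp_path / "design.csv").read_text().strip().splitlines()
        assert design[0] == "axon_id,condition"
        conds = [line.split(",")[1] for line in design[1:]]
        assert conds.count("+UTR") == 2 and conds.count("-UTR") == 1
        assert all((tmp_path / f"axon0{i}.tif").exists() for i in range(3))

    def test_manifest_reproducible(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(1, 1, seed=11, out_dir=d1)
        generate_cohort(1, 1, seed=11, out_dir=d2)
        for name in ("design.csv", "truth.json", "axon00.tif", "axon00_traces.csv"):
            h1 = hashlib.sha256((d1 / name).read_bytes()).hexdigest()
            h2 = hashlib.sha256((d2 / name).read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_truth_json_echoes_config(self, tmp_path):
        generate_cohort(1, 1, seed=3, out_dir=tmp_path)
        doc = json.loads((tmp_path / "truth.json").read_text())
        assert doc["seed"] == 3
        assert doc["config"]["n_timepoints"] == 10
        assert doc["axons"][1]["k_local"] == 0.0  # -UTR axon has no synthesis

    def test_counts_validated(self):
        with pytest.raises(ValueError, match=">= 1"):
            generate_cohort(0, 1)


class TestAOVolume:
    def test_zero_spots_background_only(self):
        vol, cents = generate_ao_volume(0, shape=(10, 20, 20), noise_sd=0.0,
                                        background=7.0, seed=0)
        assert cents.shape == (0, 3) and np.allclose(vol, 7.0)

    def test_planted_spots_well_separated(self):
        vol, cents = generate_ao_volume(20, seed=4)
        assert len(cents) == 20
        d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 2 * 3.0  # 2x the 3-um default radius (1 um voxels)

    def test_determinism(self):
        v1, c1 = generate_ao_volume(5, seed=9)
        v2, c2 = generate_ao_volume(5, seed=9)
        assert np.array_equal(v1, v2) and np.array_equal(c1, c2)

    def test_impossible_packing_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            generate_ao_volume(500, shape=(10, 12, 12), spot_radius_um=3.0, seed=0)
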