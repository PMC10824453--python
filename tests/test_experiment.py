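"""Study orchestration: configs, fixtures, conditions, full studies, CLI."""

from dataclasses import replace

import numpy as np
import pytest
import yaml

import tdcsim as t
from tdcsim.experiment import scoring_window
from tdcsim.stimulation import reverse_polarity


class TestSimulationConfig:
    def test_yaml_round_trip_preserves_hash(self, tmp_path):
        cfg = t.SimulationConfig(condition="add", n_runs=3, n_timepoints=12, onset=4, seed=9)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = t.SimulationConfig.from_yaml(path)
        assert back == cfg
        assert back.config_hash() == cfg.config_hash()

    def test_hash_sensitive_to_parameters(self):
        a = t.SimulationConfig(condition="add")
        b = t.SimulationConfig(condition="add", seed=1)
        assert a.config_hash() != b.config_hash()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"onset": 0},
            {"onset": 40},
            {"n_runs": 0},
            {"condition": "treated"},
            {"dt": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            t.SimulationConfig(**kwargs)

    def test_condition_parsing(self):
        cfg = t.SimulationConfig(condition="add+PO7a-AF4c")
        assert cfg.montage_id == "PO7a-AF4c"
        assert cfg.degeneration_active
        assert t.SimulationConfig(condition="healthy").montage_id is None


class TestFixtureGeneration:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        a = t.generate_fixture_study(7, tmp_path / "a")
        b = t.generate_fixture_study(7, tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_montage_pairs_satisfy_reverse_polarity(self, fixture_montages):
        by_id = {m.id: m for m in fixture_montages}
        for m in fixture_montages:
            rid = reverse_polarity(m).id
            if rid in by_id:
                twin = by_id[rid]
                assert twin.anodal_regions == m.cathodal_regions
                assert twin.cathodal_regions == m.anodal_regions

    def test_fixture_connectome_loads_and_has_hubs(self, fixture_network):
        deg = t.node_degree(fixture_network)
        assert fixture_network.n == 20
        assert deg.max() >= 2 * np.median(deg)

    def test_montage_file_with_coverage_table(self, tmp_path):
        payload = [
            {
                "id": "P5a-P6c",
                "coverage": {
                    0: {"fraction": 0.8, "nearest": "anode"},
                    1: {"fraction": 0.3, "nearest": "anode"},
                    2: {"fraction": 0.6, "nearest": "cathode"},
                },
            }
        ]
        path = tmp_path / "m.yaml"
        path.write_text(yaml.safe_dump(payload))
        (m,) = t.load_montages(path)
        assert m.anodal_regions == {0} and m.cathodal_regions == {2}

    def test_duplicate_montage_ids_rejected(self, tmp_path):
        payload = [{"id": "P5a-P6c"}, {"id": "P5a-P6c"}]
        path = tmp_path / "m.yaml"
        path.write_text(yaml.safe_dump(payload))
        with pytest.raises(ValueError, match="duplicate"):
            t.load_montages(path)


class TestRunCondition:
    def test_full_determinism(self, fixture_config, fixture_network):
        cfg = replace(fixture_config, condition="add", n_runs=2, n_timepoints=4, onset=2)
        a = t.run_condition(cfg, network=fixture_network)
        b = t.run_condition(cfg, network=fixture_network)
        assert np.array_equal(a.values, b.values)
        assert a.config_hash == b.config_hash

    def test_conditions_share_noise_streams(self, fixture_config, fixture_network):
        """Healthy and degeneration runs with the same master seed see the
        same thalamic noise, so their first (pre-damage) timepoint agrees."""
        h = t.run_condition(
            replace(fixture_config, condition="healthy", n_runs=1, n_timepoints=2, onset=1),
            network=fixture_network,
        )
        a = t.run_condition(
            replace(fixture_config, condition="add", n_runs=1, n_timepoints=2, onset=1),
            network=fixture_network,
        )
        assert np.allclose(h.values[0, 0], a.values[0, 0])

    def test_trajectory_shapes_and_finiteness(self, study_trajectories):
        for cond, res in study_trajectories.items():
            assert res.values.shape == (10, 20, len(t.ALL_MEASURES))
            assert np.all(np.isfinite(res.values))
            pli = res.measure("pli")
            assert np.all((pli >= 0) & (pli <= 1))
            aec = res.measure("aec")
            assert np.all((aec >= -1) & (aec <= 1))

    def test_healthy_leaves_coupling_untouched(self, study_trajectories):
        coupling = study_trajectories["healthy"].coupling
        assert np.allclose(coupling, coupling[:, :1])

    def test_montage_overlay_starts_at_onset(self, fixture_config, fixture_network, fixture_montages):
        """Before the onset the intervention condition is identical to the
        untreated one (shared seeds); from the onset it departs."""
        kw = dict(n_runs=1, n_timepoints=12, onset=6)
        add = t.run_condition(
            replace(fixture_config, condition="add", **kw),
            network=fixture_network,
        )
        stim = t.run_condition(
            replace(fixture_config, condition="add+PO7a-AF4c", **kw),
            network=fixture_network,
            montages=fixture_montages,
        )
        assert np.allclose(add.values[:, :6], stim.values[:, :6])
        assert not np.allclose(add.values[:, 6:], stim.values[:, 6:])

    def test_missing_montage_rejected(self, fixture_config, fixture_network):
        cfg = replace(fixture_config, condition="add+P5a-P6c", montages=None)
        with pytest.raises((KeyError, ValueError, TypeError)):
            t.run_condition(cfg, network=fixture_network, montages=[])


class TestTrajectoryResult:
    def test_tidy_round_trip(self, tmp_path, study_trajectories):
        res = study_trajectories["healthy"]
        path = tmp_path / "healthy.csv"
        res.save_csv(path)
        back = t.TrajectoryResult.load_csv(path, expect_hash=res.config_hash)
        assert back.condition == "healthy"
        assert np.allclose(back.values, res.values)

    def test_mismatched_hash_refused(self, tmp_path, study_trajectories):
        res = study_trajectories["healthy"]
        path = tmp_path / "healthy.csv"
        res.save_csv(path)
        with pytest.raises(ValueError, match="hash"):
            t.TrajectoryResult.load_csv(path, expect_hash="deadbeef")

    def test_tidy_format_columns(self, study_trajectories):
        df = study_trajectories["add"].to_tidy()
        assert set(df.columns) == {"condition", "run", "virtual_time", "measure", "value"}
        assert len(df) == 10 * 20 * len(t.ALL_MEASURES)


class TestFullStudy:
    def test_toy_study_shapes_and_ranges(self, fixture_config, fixture_network, fixture_montages):
        two = [m for m in fixture_montages if m.id in ("P5a-P6c", "P6a-P5c")]
        cfg = replace(fixture_config, n_runs=5, n_timepoints=12, onset=6)
        out = t.run_full_study(cfg, montages=two, network=fixture_network)
        table = out["table"]
        assert len(table) == 2
        assert table["Score"].between(-6, 6).all()
        assert set(out["results"]) == {"healthy", "add", "add+P5a-P6c", "add+P6a-P5c"}
        for col in ("Alpha1", "Alpha2", "TotalPower", "PeakFreq", "PLI", "AEC"):
            assert table[col].isin([-1, 0, 1]).all()

    def test_reversed_pair_has_reciprocal_region_ratio(self, fixture_montages):
        by_id = {m.id: m for m in fixture_montages}
        a = by_id["PO7a-AF4c"].region_count_ratio
        b = by_id["AF4a-PO7c"].region_count_ratio
        assert a == pytest.approx(1.0 / b)

    def test_duplicate_montages_rejected(self, fixture_config, fixture_network, fixture_montages):
        m = fixture_montages[0]
        with pytest.raises(ValueError, match="duplicate"):
            t.run_full_study(fixture_config, montages=[m, m], network=fixture_network)

    def test_scoring_window_clipped_to_protocol(self):
        cfg = t.SimulationConfig(condition="add", n_timepoints=15, onset=10)
        assert scoring_window(cfg) == slice(10, 15)
        cfg = t.SimulationConfig(condition="add", n_timepoints=40, onset=10)
        assert scoring_window(cfg) == slice(10, 21)


class TestCLI:
    def test_fixtures_and_simulate_commands(self, tmp_path):
        from click.testing import CliRunner

        from tdcsim.cli import main

        runner = CliRunner()
        fix = tmp_path / "fix"
        res = runner.invoke(main, ["fixtures", "--seed", "3", "--out", str(fix), "--regions", "12"])
        assert res.exit_code == 0, res.output
        cfg = t.SimulationConfig.from_yaml(fix / "study.yaml", n_runs=1, n_timepoints=3, onset=1)
        cfg_path = tmp_path / "tiny.yaml"
        cfg.to_yaml(cfg_path)
        out_dir = tmp_path / "results"
        res = runner.invoke(
            main,
            ["simulate", "--config", str(cfg_path), "--condition", "healthy", "--out", str(out_dir)],
        )
        assert res.exit_code == 0, res.output
        loaded = t.TrajectoryResult.load_csv(out_dir / "healthy.csv")
        assert loaded.values.shape[1] == 3
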