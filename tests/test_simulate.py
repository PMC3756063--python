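import numpy as np
import pandas as pd
import pytest

from revfiber.core import ValidationError
from revfiber.quantify import SIZE_CLASSES, section_traits
from revfiber.simulate import (
    MUSCLE_PROFILES,
    MuscleSim,
    SimConfig,
    config_from_dict,
    config_to_dict,
    default_design,
    generate_cohort,
    iter_cohort,
    make_tessellation,
    sample_sections,
    simulate_reversion,
)


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_fibers": 0},
            {"expansion_prob": 1.5},
            {"founder_rate": -1},
            {"extent_range_um": (50.0, 300.0)},
            {"extent_tail_max_um": 1200.0},
            {"section_spacing_um": 5.0},
            {"cycles_per_group": {1: 1}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SimConfig(**kwargs)

    def test_json_roundtrip(self):
        cfg = SimConfig(founder_rate=3.5, cycles_per_group={1: 1, 2: 2, 3: 3, 4: 9})
        assert config_from_dict(config_to_dict(cfg)) == cfg


class TestMakeTessellation:
    def test_single_fiber(self):
        t = make_tessellation(1, seed=0)
        assert t.n_fibers == 1 and t.edges == ()

    def test_two_fibers_adjacent(self):
        t = make_tessellation(2, seed=0)
        assert t.edges == ((1, 2),)

    def test_rejects_zero(self):
        with pytest.raises(ValidationError):
            make_tessellation(0)

    def test_determinism(self):
        a = make_tessellation(50, seed=7)
        b = make_tessellation(50, seed=7)
        assert np.array_equal(a.centroids, b.centroids)
        assert a.edges == b.edges

    def test_connected_with_plausible_degree(self):
        import networkx as nx

        degrees = []
        for seed in range(20):
            t = make_tessellation(100, seed=seed)
            g = nx.Graph(t.edges)
            g.add_nodes_from(range(1, 101))
            assert nx.is_connected(g)
            degrees.append(2 * len(t.edges) / t.n_fibers)
        assert 4 < np.mean(degrees) < 7

    def test_area_scales_with_mean_csa(self):
        t = make_tessellation(200, seed=1, mean_csa_um2=1500.0)
        assert t.area_mm2 == pytest.approx(200 * 1500 / 1e6, rel=0.1)


class TestSimulateReversion:
    def test_no_sources_no_revertants(self):
        t = make_tessellation(50, seed=0)
        cfg = SimConfig(n_fibers=50, founder_rate=0.0, denovo_rate=0.0)
        sim = simulate_reversion(t, cfg, 4, seed=1)
        assert len(sim.state.revertant_indices()) == 0

    def test_no_expansion_all_singletons(self):
        cfg = SimConfig(n_fibers=150, expansion_prob=0.0, founder_rate=10.0, denovo_rate=2.0)
        t = make_tessellation(150, seed=3)
        sim = simulate_reversion(t, cfg, 4, seed=4)
        clone_ids = sim.state.clone_id[sim.state.revertant_indices()]
        # every clone holds exactly one fiber
        assert len(clone_ids) == len(set(clone_ids.tolist()))

    def test_founder_count_poisson_mean(self):
        cfg = SimConfig(n_fibers=200, denovo_rate=0.0, expansion_prob=0.0)
        counts = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            t = make_tessellation(200, rng=rng)
            expected = cfg.founder_rate * t.area_mm2
            sim = simulate_reversion(t, cfg, 1, rng=rng)
            counts.append(len(sim.state.revertant_indices()) - expected)
        # Monte-Carlo check: mean deviation from the Poisson mean ~ 0
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts)) < 4 * se + 0.05

    def test_extents_within_muscle(self):
        cfg = SimConfig(n_fibers=150, founder_rate=20.0)
        t = make_tessellation(150, seed=5)
        sim = simulate_reversion(t, cfg, 4, seed=6)
        idx = sim.state.revertant_indices()
        assert (sim.state.z_lo[idx] >= 0).all()
        assert (sim.state.z_hi[idx] <= cfg.muscle_length_um).all()
        assert (sim.state.z_hi[idx] >= sim.state.z_lo[idx]).all()

    def test_monotone_in_rates(self):
        def mean_total(founder, denovo, p_exp, n_rep=150):
            cfg = SimConfig(
                n_fibers=120, founder_rate=founder, denovo_rate=denovo,
                expansion_prob=p_exp,
            )
            total = 0
            for seed in range(n_rep):
                rng = np.random.default_rng(seed)
                t = make_tessellation(120, rng=rng)
                sim = simulate_reversion(t, cfg, 3, rng=rng)
                total += len(sim.state.revertant_indices())
            return total / n_rep

        base = mean_total(3.0, 0.5, 0.1)
        assert mean_total(6.0, 0.5, 0.1) > base
        assert mean_total(3.0, 2.0, 0.1) > base
        assert mean_total(3.0, 0.5, 0.3) > base

    def test_pct_clustered_nondecreasing_in_cycles(self):
        # founders only, expansion on: clustering grows with cycle count
        means = []
        for group in (1, 2, 4):
            vals = []
            for seed in range(60):
                rng = np.random.default_rng(seed)
                cfg = SimConfig(
                    n_fibers=200, founder_rate=4.0, denovo_rate=0.0,
                    expansion_prob=0.2, cycles_per_group={1: 1, 2: 3, 3: 5, 4: 7},
                )
                t = make_tessellation(200, rng=rng)
                sim = simulate_reversion(t, cfg, group, rng=rng)
                s = sample_sections(sim, rng=rng)
                pcts = [
                    tr.pct_clustered
                    for tr in (section_traits(g) for g in s.sections)
                    if tr.n_rf > 0
                ]
                if pcts:
                    vals.append(np.mean(pcts))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_invalid_group(self):
        t = make_tessellation(10, seed=0)
        with pytest.raises(ValidationError):
            simulate_reversion(t, SimConfig(n_fibers=10), 5, seed=0)


class TestSampleSections:
    def test_section_count_and_spacing(self):
        cfg = SimConfig(n_fibers=80)
        t = make_tessellation(80, seed=2)
        sim = simulate_reversion(t, cfg, 2, seed=3)
        s = sample_sections(sim, seed=4)
        assert 10 <= len(s.sections) <= 12
        zs = [g.z_position for g in s.sections]
        assert np.allclose(np.diff(zs), cfg.section_spacing_um)

    def test_muscle_too_short_rejected(self):
        cfg = SimConfig(n_fibers=20, muscle_length_um=500.0)
        t = make_tessellation(20, seed=0)
        sim = simulate_reversion(t, cfg, 1, seed=0)
        with pytest.raises(ValidationError):
            sample_sections(sim, seed=0)

    def test_visibility_matches_interval_oracle(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            cfg = SimConfig(n_fibers=100, founder_rate=15.0, expansion_prob=0.2)
            t = make_tessellation(100, rng=rng)
            sim = simulate_reversion(t, cfg, 3, rng=rng)
            s = sample_sections(sim, rng=rng)
            state = sim.state
            for graph in s.sections:
                z, z_top = graph.z_position, graph.z_position + cfg.section_thickness_um
                expected = {
                    i + 1
                    for i in state.revertant_indices()
                    if state.z_lo[i] <= z_top and state.z_hi[i] >= z
                }
                assert graph.revertant_ids() == expected

    def test_clone_spanning_300um_hits_2_to_3_sections(self):
        cfg = SimConfig(n_fibers=5)
        t = make_tessellation(5, seed=0)
        state_sim = simulate_reversion(t, SimConfig(n_fibers=5, founder_rate=0, denovo_rate=0), 1, seed=0)
        # place one revertant segment of exactly 300 um mid-muscle
        state_sim.state.clone_id[0] = 0
        state_sim.state.z_lo[0] = 850.0
        state_sim.state.z_hi[0] = 1150.0
        for seed in range(25):
            s = sample_sections(MuscleSim(t, state_sim.state, cfg), seed=seed)
            hits = sum(1 for g in s.sections if g.revertant_ids())
            assert hits in (2, 3)

    def test_ground_truth_histogram_columns(self):
        cfg = SimConfig(n_fibers=60)
        t = make_tessellation(60, seed=9)
        sim = simulate_reversion(t, cfg, 4, seed=9)
        s = sample_sections(sim, seed=9)
        expected = {"section_id", "n_rf", "max_cluster_size"} | {
            f"n_{cls}" for cls in SIZE_CLASSES
        }
        assert expected == set(s.ground_truth.columns)


class TestHeartMode:
    def test_virtually_no_medium_or_larger_clusters(self):
        n_sections = 0
        n_with_medium = 0
        profile = MUSCLE_PROFILES["H"]
        for seed in range(80):
            rng = np.random.default_rng(seed)
            cfg = SimConfig(
                n_fibers=200,
                founder_rate=6.0 * profile.founder_scale,
                denovo_rate=0.8 * profile.denovo_scale,
                heart_mode=True,
            )
            t = make_tessellation(200, rng=rng)
            sim = simulate_reversion(t, cfg, 4, rng=rng)
            s = sample_sections(sim, rng=rng)
            for row in s.ground_truth.itertuples():
                n_sections += 1
                if row.n_medium + row.n_large + row.n_very_large > 0:
                    n_with_medium += 1
        assert n_with_medium / n_sections < 0.01


class TestGenerateCohort:
    def test_default_design_shape(self):
        d = default_design(10)
        assert len(d) == 4 * 10 * 11
        assert d.mouse_id.nunique() == 40

    def test_duplicate_mouse_ids_rejected(self):
        design = pd.DataFrame(
            {"mouse_id": ["m1", "m1"], "age_group": [1, 2], "muscle": ["TA", "TA"]}
        )
        with pytest.raises(ValidationError, match="duplicate"):
            list(iter_cohort(SimConfig(n_fibers=10), design=design, master_seed=0))

    def test_deterministic_and_byte_identical(self, tmp_path):
        cfg = SimConfig(n_fibers=60)
        kwargs = dict(n_mice=1, muscles=("TA", "H"), master_seed=11)
        a = generate_cohort(cfg, **kwargs)
        b = generate_cohort(cfg, **kwargs)
        for name in ("fibers", "edges", "design", "ground_truth"):
            pa, pb = tmp_path / f"a_{name}.csv", tmp_path / f"b_{name}.csv"
            getattr(a, name).to_csv(pa, index=False)
            getattr(b, name).to_csv(pb, index=False)
            assert pa.read_bytes() == pb.read_bytes()

    def test_structure_matches_design(self, tiny_cohort):
        design = tiny_cohort.design
        assert set(design.muscle) == {"TA", "D", "H"}
        assert set(design.age_group) == {1, 2, 3, 4}
        assert design.mouse_id.nunique() == 8
        per_muscle = design.groupby(["mouse_id", "muscle"]).size()
        assert per_muscle.between(10, 12).all()

    def test_roundtrip_cluster_histograms_exact(self, tiny_cohort):
        # quantify must reproduce the generator's own per-section histograms
        from revfiber.io import write_cohort, read_fiber_tables

        gt = tiny_cohort.ground_truth.set_index("section_id")
        count = 0
        for key, sample in iter_cohort(
            SimConfig(n_fibers=120), n_mice=2, muscles=("TA", "D", "H"),
            master_seed=424242,
        ):
            for graph in sample.sections:
                traits = section_traits(graph)
                row = gt.loc[graph.section_id]
                assert traits.n_rf == row.n_rf
                assert traits.max_cluster_size == row.max_cluster_size
                for cls in SIZE_CLASSES:
                    assert traits.cluster_size_counts[cls] == row[f"n_{cls}"]
                count += 1
        assert count == len(gt)
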