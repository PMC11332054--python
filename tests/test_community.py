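from dataclasses import replace

import numpy as np
import pytest

import mcmkit as mk
from conftest import scalar_species


class TestAggregateLoad:
    def test_empty_community_zero(self, toy):
        states = [np.zeros(1), np.zeros(1)]
        assert mk.aggregate_load(states, toy.species) == 0.0

    def test_unweighted_sum(self):
        sp = mk.SpeciesModel(
            "x", {"a": mk.StageMatrix(np.eye(3), ("1", "2", "3"))}, [1.0, 1.0, 1.0]
        )
        assert mk.aggregate_load([np.array([2.0, 3.0, 4.0])], [sp]) == 9.0

    def test_weighted_two_species(self):
        s1 = mk.SpeciesModel(
            "x", {"a": mk.StageMatrix(np.eye(2), ("1", "2"))}, [1.0, 2.0]
        )
        s2 = mk.SpeciesModel("y", {"a": mk.StageMatrix(np.eye(1), ("1",))}, [3.0])
        load = mk.aggregate_load([np.array([1.0, 1.0]), np.array([2.0])], [s1, s2])
        assert load == 9.0  # 1 + 2 + 6


class TestApplyDependency:
    @pytest.fixture
    def fec_matrix(self):
        return mk.StageMatrix(
            [[0.0, 2.0], [0.5, 0.6]],
            ("j", "a"),
            np.array([["P", "F"], ["G", "P"]]),
        )

    def test_zero_load_unchanged(self, fec_matrix):
        dep = mk.DependencyAssumption("biomass_limited_fecundity", K=10.0)
        out, cap, _ = mk.apply_dependency({"x": fec_matrix}, 0.0, dep)
        assert out["x"] is fec_matrix
        assert cap is None

    def test_load_at_K_zeroes_fecundity(self, fec_matrix):
        # at N = K reproduction reaches zero for every species
        dep = mk.DependencyAssumption("biomass_limited_fecundity", K=10.0)
        out, _, _ = mk.apply_dependency({"x": fec_matrix}, 10.0, dep)
        assert out["x"].entry(1, 2) == 0.0
        assert out["x"].entry(2, 1) == 0.5  # survival untouched

    def test_half_load_halves_fecundity(self, fec_matrix):
        dep = mk.DependencyAssumption("generic_scaling", K=10.0)
        out, _, _ = mk.apply_dependency({"x": fec_matrix}, 5.0, dep)
        assert out["x"].entry(1, 2) == pytest.approx(1.0)

    def test_overload_clamps_and_logs(self, fec_matrix):
        dep = mk.DependencyAssumption("biomass_limited_fecundity", K=10.0)
        out, _, events = mk.apply_dependency({"x": fec_matrix}, 15.0, dep)
        assert out["x"].entry(1, 2) == 0.0
        assert any(e["event"] == "overload" for e in events)

    def test_space_mode_returns_open_space(self, fec_matrix):
        dep = mk.DependencyAssumption("space_limited_recruitment", K=10.0)
        out, cap, _ = mk.apply_dependency({"x": fec_matrix}, 4.0, dep)
        assert cap == 6.0
        assert out["x"] is fec_matrix


class TestAllocateRecruitment:
    def test_unconstrained_gets_demand(self):
        assert np.array_equal(
            mk.allocate_recruitment(np.array([3.0, 3.0]), 10.0), [3.0, 3.0]
        )

    def test_proportional_split(self):
        out = mk.allocate_recruitment(np.array([6.0, 6.0]), 6.0, "proportional")
        assert np.allclose(out, [3.0, 3.0])

    def test_priority_rule(self):
        out = mk.allocate_recruitment(
            np.array([6.0, 6.0]), 6.0, "priority", priority_order=[0, 1]
        )
        assert np.allclose(out, [6.0, 0.0])

    def test_equal_shares_capped_at_demand(self):
        out = mk.allocate_recruitment(np.array([1.0, 9.0]), 6.0, "equal")
        assert np.allclose(out, [1.0, 5.0])

    def test_negative_demand_rejected(self):
        with pytest.raises(mk.StructuralError, match="nonnegative"):
            mk.allocate_recruitment(np.array([-1.0]), 5.0)


class TestProjectCommunity:
    def test_decoupled_equals_repeated_project_step(self, fish3):
        dec = replace(fish3, dependency=None, extinction_threshold=0.0)
        seq = mk.generate_sequence(fish3.regime, 100, seed=4)
        traj = mk.project_community(dec, 100, sequence=seq)
        for sp in dec.species:
            v = mk.StageVector(np.full(sp.n_stages, 1.0))
            for yt in seq:
                v = mk.project_step(sp.matrix_for(yt), v)
            assert np.array_equal(v.abundances, traj.final_state(sp.species_id))

    def test_load_at_K_means_no_recruits(self):
        # community pinned exactly at K with linear fecundity scaling:
        # zero recruits next step for every species
        sp = mk.SpeciesModel(
            "x",
            {"a": mk.StageMatrix([[0.0, 4.0], [0.5, 0.0]], ("j", "ad"),
                                 np.array([["P", "F"], ["G", "P"]]))},
            [1.0, 1.0],
        )
        com = mk.CommunityModel(
            [sp], mk.Regime.constant("a"),
            mk.DependencyAssumption("biomass_limited_fecundity", K=10.0),
        )
        traj = mk.project_community(com, 1, initial={"x": np.array([5.0, 5.0])})
        assert traj.final_state("x")[0] == 0.0  # no new juveniles
        assert traj.final_state("x")[1] == 2.5  # survival unaffected

    def test_ceiling_cap_never_exceeded(self):
        # two identical scalar species, K = 100, 1000 steps: load <= K always
        a = scalar_species("A", {"g": 0.8, "b": 0.8})
        b = scalar_species("B", {"g": 0.8, "b": 0.8})
        for s in (a, b):
            s.recruitment_years = frozenset({"g"})
        com = mk.CommunityModel(
            [a, b], mk.Regime.iid(("g", "b"), (0.5, 0.5)),
            mk.DependencyAssumption(
                "space_limited_recruitment", K=100.0, rescue_effect=True
            ),
        )
        for seed in range(3):
            traj = mk.project_community(com, 1000, seed=seed)
            assert (traj.loads <= 100.0 + 1e-9).all()

    def test_extinction_threshold_zeroes_and_logs(self):
        sp = scalar_species("A", {"a": 0.5})
        com = mk.CommunityModel(
            [sp], mk.Regime.constant("a"), dependency=None, extinction_threshold=1.0
        )
        traj = mk.project_community(com, 10, initial={"A": np.array([1.5])})
        assert traj.totals("A")[-1] == 0.0
        events = [e for e in traj.events if e["event"] == "extirpation"]
        assert len(events) == 1 and events[0]["time"] == 1  # 0.75 < 1 at t=1

    def test_permutation_equivariance(self, toy):
        swapped = replace(toy, species=list(reversed(toy.species)))
        seq = mk.generate_sequence(toy.regime, 300, seed=6)
        t1 = mk.project_community(toy, 300, sequence=seq)
        t2 = mk.project_community(swapped, 300, sequence=seq)
        for sid in toy.species_ids:
            assert np.array_equal(t1.states[sid], t2.states[sid])

    def test_monotone_harm_under_space_limitation(self, toy):
        # raising A's abundance never raises B's realised recruitment
        seq = ["good"]
        lo = mk.project_community(
            toy, 1, sequence=seq, initial={"A": np.array([10.0]), "B": np.array([10.0])}
        )
        hi = mk.project_community(
            toy, 1, sequence=seq, initial={"A": np.array([40.0]), "B": np.array([10.0])}
        )
        s_b = toy.species_by_id("B").matrix_for("good").entry(1, 1)
        rec_lo = lo.final_state("B")[0] - s_b * 10.0
        rec_hi = hi.final_state("B")[0] - s_b * 10.0
        assert rec_hi <= rec_lo

    def test_overflow_aborts_with_diagnostic(self):
        sp = scalar_species("boom", {"a": 1e300})
        com = mk.CommunityModel([sp], mk.Regime.constant("a"), dependency=None)
        with pytest.raises(mk.ProjectionError, match="boom"):
            mk.project_community(com, 10)

    def test_reproducible_under_seed(self, toy):
        t1 = mk.project_community(toy, 200, seed=5)
        t2 = mk.project_community(toy, 200, seed=5)
        assert t1.year_types == t2.year_types
        for sid in toy.species_ids:
            assert np.array_equal(t1.states[sid], t2.states[sid])

    def test_tidy_dataframe_contract(self, toy):
        df = mk.project_community(toy, 5, seed=0).to_dataframe()
        assert list(df.columns) == ["time", "year_type", "species", "stage", "abundance"]
        assert len(df) == 6 * 2  # (T+1) x 2 scalar species


class TestExclusionSummary:
    def test_single_species_below_K_persists(self):
        sp = scalar_species("A", {"g": 0.9})
        sp.recruitment_years = frozenset({"g"})
        com = mk.CommunityModel(
            [sp], mk.Regime.constant("g"),
            mk.DependencyAssumption("space_limited_recruitment", K=1000.0,
                                    rescue_effect=True),
        )
        summary = mk.exclusion_summary(com, horizon=200, replicates=5, seed=0)
        assert summary.persistence_prob["A"] == 1.0
        assert np.isnan(summary.median_extirpation_time["A"])

    def test_growth_advantage_decides_last_survivor(self):
        # A grows (log rate ~ +0.05), B shrinks (~ -0.05); under shared
        # biomass-limited fecundity A should be the usual last survivor
        a = scalar_species("A", {"g": np.exp(0.05)})
        b = scalar_species("B", {"g": np.exp(-0.05)})
        com = mk.CommunityModel(
            [a, b], mk.Regime.constant("g"),
            mk.DependencyAssumption("biomass_limited_fecundity", K=50.0),
            extinction_threshold=0.5,
        )
        summary = mk.exclusion_summary(
            com, horizon=500, replicates=10, seed=1,
            initial={"A": np.array([10.0]), "B": np.array([10.0])},
        )
        assert summary.modal_survivor == "A"
        assert summary.persistence_prob["B"] == 0.0

    def test_no_extirpation_without_threshold_and_growth(self):
        sp = scalar_species("A", {"g": 1.0})
        com = mk.CommunityModel([sp], mk.Regime.constant("g"), dependency=None)
        summary = mk.exclusion_summary(com, horizon=100, replicates=3, seed=0)
        assert summary.survivor_counts == {1: 3}
        assert all(np.isnan(t) for t in summary.median_extirpation_time.values())
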