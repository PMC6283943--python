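"""Synthetic generator: determinism, limits, calibration and recovery."""

import numpy as np
import pytest

from palaeopsin.dated_trees import CredibleInterval, write_dated_tree
from palaeopsin.errors import SimulationError
from palaeopsin.synthetic import (
    SimulationConfig,
    ecdysozoan_fixture,
    evaluate_recovery,
    scatter_fossils,
    simulate_age_posteriors,
    simulate_duplications,
    simulate_species_tree,
    simulate_truth_bundle,
)


class TestSimulationConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(birth_rate=-1)
        with pytest.raises(SimulationError):
            SimulationConfig(rho=0)
        with pytest.raises(SimulationError):
            SimulationConfig(ci_level=1.0)
        with pytest.raises(SimulationError):
            SimulationConfig(age_rel_sd=-0.1)


class TestSimulateSpeciesTree:
    def test_same_seed_gives_identical_tree(self):
        t1 = simulate_species_tree(SimulationConfig(seed=123))
        t2 = simulate_species_tree(SimulationConfig(seed=123))
        assert t1.approx_equals(t2)
        assert not t1.approx_equals(simulate_species_tree(SimulationConfig(seed=124)))

    def test_pure_birth_limit_has_only_extant_tips(self):
        cfg = SimulationConfig(death_rate=0.0, psi=0.0, rho=1.0, seed=5)
        tree = simulate_species_tree(cfg)
        assert all(lf.tip_kind == "extant" for lf in tree.leaves())
        assert len(tree.leaves()) >= 2

    def test_root_age_follows_gamma_prior_scale(self):
        ages = [
            simulate_species_tree(SimulationConfig(seed=s)).root.age for s in range(40)
        ]
        assert 500 < np.mean(ages) < 700  # prior mean 600, sd 26

    def test_tree_is_chronologically_valid(self):
        tree = simulate_species_tree(SimulationConfig(seed=9))
        tree.validate()
        fossils = [lf for lf in tree.leaves() if lf.tip_kind == "fossil"]
        assert fossils, "default fossil-recovery rate should yield fossil tips"

    def test_hopeless_parameters_raise_explicit_error(self):
        cfg = SimulationConfig(
            birth_rate=0.001, death_rate=0.2, psi=0.0, max_tries=5, seed=0
        )
        with pytest.raises(SimulationError, match="attempts"):
            simulate_species_tree(cfg)

    def test_fossil_counts_match_poisson_mean_on_fixed_tree(self):
        """E[#fossils] = psi × total branch length (Monte-Carlo check)."""
        tree = simulate_species_tree(SimulationConfig(seed=3, psi=0.0))
        total_len = sum(
            nd.parent.age - nd.age for nd in tree.preorder() if nd.parent is not None
        )
        psi = 0.05
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(400):
            events = scatter_fossils(tree.root, psi, rng)
            counts.append(sum(len(v) for v in events.values()))
        lam = psi * total_len
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 4 * se


class TestSimulateDuplications:
    def test_explicit_times_build_monotone_chain(self):
        tree = simulate_species_tree(SimulationConfig(seed=1))
        span = tree.root.age
        times = [span * f for f in (0.95, 0.7, 0.5, 0.2)]
        hist = simulate_duplications(tree, times=times)
        assert hist.times == tuple(times)
        assert hist.glt.n_duplications == 4
        assert hist.glt.root.ci == CredibleInterval(times[0], times[0])

    def test_time_outside_span_rejected(self):
        tree = simulate_species_tree(SimulationConfig(seed=1))
        with pytest.raises(SimulationError, match="outside"):
            simulate_duplications(tree, times=[tree.root.age + 10])

    def test_non_monotone_times_rejected(self):
        tree = simulate_species_tree(SimulationConfig(seed=1))
        with pytest.raises(SimulationError, match="decrease"):
            simulate_duplications(tree, times=[100, 200])

    def test_no_events_gives_single_gene_history(self):
        tree = simulate_species_tree(SimulationConfig(seed=1))
        for hist in (
            simulate_duplications(tree, times=[]),
            simulate_duplications(tree, rate=0.0),
        ):
            assert hist.times == ()
            assert hist.glt.root.is_leaf

    def test_rate_mode_is_seeded(self):
        tree = simulate_species_tree(SimulationConfig(seed=1))
        h1 = simulate_duplications(tree, rate=0.01, rng=np.random.default_rng(4))
        h2 = simulate_duplications(tree, rate=0.01, rng=np.random.default_rng(4))
        assert h1.times == h2.times


class TestAgePosteriors:
    def test_zero_noise_gives_degenerate_intervals(self):
        centers, cis = simulate_age_posteriors([600, 500], rel_sd=0.0)
        assert centers == [600, 500]
        assert all(ci.width == 0 for ci in cis)

    def test_same_seed_gives_identical_intervals(self):
        a = simulate_age_posteriors([600, 500], 0.02, rng=np.random.default_rng(7))
        b = simulate_age_posteriors([600, 500], 0.02, rng=np.random.default_rng(7))
        assert a == b

    def test_negative_sd_rejected(self):
        with pytest.raises(SimulationError):
            simulate_age_posteriors([600], rel_sd=-1)

    def test_chain_truncation_keeps_intervals_ordered(self):
        rng = np.random.default_rng(8)
        times = [600, 590, 580, 570]
        parents = [None, 0, 1, 2]
        _, cis = simulate_age_posteriors(times, 0.05, rng=rng, parents=parents)
        for child, parent in zip(cis[1:], cis[:-1]):
            assert child.old <= parent.old + 1e-9

    def test_nominal_coverage_of_95_percent_intervals(self):
        """Truth falls inside its own 95% CI about 95% of the time."""
        rng = np.random.default_rng(1234)
        truth = 550.0
        n = 1000
        hits = 0
        for _ in range(n):
            _, (ci,) = simulate_age_posteriors([truth], 0.03, n_samples=400, rng=rng)
            hits += ci.contains(truth)
        rate = hits / n
        # binomial 4-sigma band around 0.95 with n=1000
        assert abs(rate - 0.95) < 4 * np.sqrt(0.95 * 0.05 / n)


class TestEcdysozoanFixture:
    def test_chain_root_and_duplication_count(self):
        glt, divs = ecdysozoan_fixture()
        assert glt.root.name == "Rh7/UV/SWS/MWS/LWS"
        assert glt.n_duplications == 4
        assert set(divs) == {
            "Pambdelurion_split",
            "Opabinia_split",
            "Anomalocaris_split",
            "Fuxianhuia_split",
            "crown_Arthropoda",
        }

    def test_intervals_are_the_published_values(self):
        glt, divs = ecdysozoan_fixture()
        assert glt.root.ci == CredibleInterval(587, 615)
        assert glt.find("MWS/LWS").ci == CredibleInterval(577, 605)
        assert glt.find("Rh7/UV/SWS").ci == CredibleInterval(558, 585)
        assert glt.find("UV/SWS").ci == CredibleInterval(509, 527)
        assert divs["crown_Arthropoda"] == CredibleInterval(519, 540)


class TestTruthBundleAndRecovery:
    def test_bundle_is_deterministic_per_seed(self):
        b1 = simulate_truth_bundle(SimulationConfig(seed=77))
        b2 = simulate_truth_bundle(SimulationConfig(seed=77))
        assert [f.observed_ci for f in b1.foci] == [f.observed_ci for f in b2.foci]
        assert write_dated_tree(b1.species_true) == write_dated_tree(b2.species_true)

    def test_zero_noise_bundle_recovers_exactly(self):
        cfg = SimulationConfig(seed=31, age_rel_sd=0.0)
        m = evaluate_recovery(simulate_truth_bundle(cfg))
        assert (m.exact_rate, m.n_overclaim, m.n_underclaim) == (1.0, 0, 0)

    def test_duplication_at_divergence_time_never_overclaims(self):
        """Boundary conservativeness: simultaneous events stay ancestral."""
        cfg = SimulationConfig(seed=32, age_rel_sd=0.0)
        bundle = simulate_truth_bundle(cfg)
        # move every duplication exactly onto its focal divergence
        from dataclasses import replace

        times = [f.true_age for f in bundle.foci[: len(bundle.history.times)]]
        cfg2 = replace(cfg, duplication_times=tuple(times))
        b2 = simulate_truth_bundle(cfg2)
        m = evaluate_recovery(b2)
        assert m.n_overclaim == 0

    def test_observed_intervals_respect_chain_ordering(self):
        bundle = simulate_truth_bundle(SimulationConfig(seed=33, age_rel_sd=0.04))
        dups = bundle.glt_observed.duplications()
        for child, parent in zip(dups[1:], dups[:-1]):
            assert child.ci.old <= parent.ci.old + 1e-9
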