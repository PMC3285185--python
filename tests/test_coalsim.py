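"""Structured-coalescent simulator and demographic model builders."""

import itertools

import numpy as np
import pytest

from hetfit.coalsim import (
    DemographicModel,
    Event,
    LocusSimSpec,
    SimulatedLocus,
    build_bottleneck,
    build_hybridization,
    build_isolation_migration,
    build_two_island,
    read_ms,
    realize_sequences,
    simulate_locus,
    write_ms,
)
from hetfit.popgen_stats import locus_stats, locus_stats_from_matrix

PANMICTIC = DemographicModel(demes=[(1.0, 0.0)], migration=np.zeros((1, 1)))
SPEC = LocusSimSpec("locus", L=100)


def mean_pairwise(matrix):
    n = matrix.shape[0]
    c = matrix.sum(axis=0)
    return float((c * (n - c)).sum()) / (n * (n - 1) / 2)


class TestSimulateLocus:
    def test_zero_theta_no_segregating_sites(self, rng):
        for _ in range(20):
            sim = simulate_locus(PANMICTIC, SPEC, [10], rng, theta_locus=0.0)
            assert sim.S == 0

    def test_expected_segregating_sites_and_diversity(self, rng):
        theta, n, reps = 5.0, 10, 1500
        S, pi = [], []
        for _ in range(reps):
            sim = simulate_locus(PANMICTIC, SPEC, [n], rng, theta_locus=theta)
            S.append(sim.S)
            pi.append(mean_pairwise(sim.matrix))
        a1 = sum(1 / i for i in range(1, n))
        for obs, expected in ((S, theta * a1), (pi, theta)):
            se = np.std(obs) / np.sqrt(reps)
            assert abs(np.mean(obs) - expected) < 3 * se

    def test_infinite_sites_four_gamete_without_recombination(self, rng):
        """rho = 0: every pair of sites must be tree-compatible."""
        for _ in range(200):
            sim = simulate_locus(PANMICTIC, SPEC, [8], rng, theta_locus=5.0)
            m = sim.matrix
            for i, j in itertools.combinations(range(sim.S), 2):
                pairs = {(a, b) for a, b in zip(m[:, i], m[:, j])}
                assert len(pairs) < 4, "four-gamete violation without recombination"

    def test_recombination_changes_genealogies_but_not_mean_diversity(self, rng):
        pis = {}
        for rho in (0.0, 10.0):
            spec = LocusSimSpec("locus", L=100, rho_locus=rho)
            vals = [
                mean_pairwise(
                    simulate_locus(PANMICTIC, spec, [10], rng, theta_locus=5.0).matrix
                )
                for _ in range(1200)
            ]
            pis[rho] = (np.mean(vals), np.var(vals))
        # E[pi] is rho-invariant; the among-replicate variance shrinks
        assert pis[0.0][0] == pytest.approx(pis[10.0][0], rel=0.12)
        assert pis[10.0][1] < pis[0.0][1]

    def test_deterministic_given_seed(self):
        sims = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            sims.append(simulate_locus(PANMICTIC, SPEC, [10], rng, theta_locus=5.0))
        assert np.array_equal(sims[0].matrix, sims[1].matrix)
        assert np.array_equal(sims[0].positions, sims[1].positions)

    def test_unreachable_ancestry_rejected(self, rng):
        model = DemographicModel(
            demes=[(1.0, 0.0), (1.0, 0.0)], migration=np.zeros((2, 2))
        )
        with pytest.raises(ValueError, match="common ancestor"):
            simulate_locus(model, SPEC, [2, 2], rng, theta_locus=1.0)

    def test_island_within_deme_diversity_independent_of_migration(self, rng):
        """Symmetric island model: mean within-deme pairwise diversity is
        d * theta (d equal demes) at every migration rate — the classic
        strong-migration invariance."""
        means = []
        for M in (0.5, 5.0, 50.0):
            model = DemographicModel(
                demes=[(1.0, 0.0), (1.0, 0.0)],
                migration=np.array([[0.0, M], [M, 0.0]]),
            )
            vals = []
            for _ in range(900):
                sim = simulate_locus(model, SPEC, [5, 5], rng, theta_locus=2.0)
                vals.append(mean_pairwise(sim.matrix[:5]))
            means.append(np.mean(vals))
        for m in means:
            assert m == pytest.approx(4.0, rel=0.1)


class TestBuilders:
    def test_two_island_structure(self):
        model = build_two_island(
            {"Theta_OW": 0.01, "Theta_NW": 0.005, "M_OW": 1000, "M_NW": 2000}
        )
        assert model.n_demes == 2
        assert model.events == []
        assert model.demes[1][0] == pytest.approx(0.5)
        assert model.migration[0, 1] == pytest.approx(10.0)  # Theta_OW * M_OW
        assert model.migration[1, 0] == pytest.approx(20.0)

    def test_two_island_no_migration_rejected(self):
        with pytest.raises(ValueError, match="migration"):
            build_two_island(
                {"Theta_OW": 0.01, "Theta_NW": 0.005, "M_OW": 0, "M_NW": 0}
            )

    def test_phi_st_decreases_with_migration(self, rng):
        means = []
        for M in (0.1, 1.0, 10.0, 100.0):
            model = build_two_island(
                {"Theta_OW": 0.01, "Theta_NW": 0.01, "M_OW": M / 0.01, "M_NW": M / 0.01}
            )
            phis = []
            for _ in range(800):
                sim = simulate_locus(model, SPEC, [6, 6], rng, theta_locus=3.0)
                st = locus_stats_from_matrix(sim.matrix, sim.deme_of, 100)
                if st.phi_st is not None:
                    phis.append(st.phi_st)
            means.append(np.mean(phis))
        assert all(a > b for a, b in zip(means, means[1:]))

    IM_DRAW = {
        "theta_OW": 2.5, "theta_NW": 2.0, "theta_A": 1.5,
        "M_OW": 0.5, "M_NW": 2.0, "t": 0.8, "s": 0.3,
    }

    def test_im_structure_and_growth_solution(self):
        model = build_isolation_migration(self.IM_DRAW)
        t_sim = 0.8 / 2.5
        x_a = 1.5 / 2.5
        # daughter sizes at the split equal their founding fractions of theta_A
        for deme, frac, present in ((0, 0.7, 1.0), (1, 0.3, 2.0 / 2.5)):
            g = model.demes[deme][1]
            size_at_split = present * np.exp(-g * t_sim)
            assert size_at_split == pytest.approx(frac * x_a)
        kinds = [e.kind for e in model.events]
        assert "split_join" in kinds and "size_change" in kinds

    def test_im_invalid_founding_fraction(self):
        bad = dict(self.IM_DRAW, s=1.2)
        with pytest.raises(ValueError, match="founding fraction"):
            build_isolation_migration(bad)

    def test_im_recent_split_approaches_panmixia(self, rng):
        draw = dict(self.IM_DRAW, t=1e-4, s=0.5)
        model = build_isolation_migration(draw)
        within, between = [], []
        for _ in range(600):
            sim = simulate_locus(model, SPEC, [5, 5], rng, theta_locus=2.0)
            m = sim.matrix
            c_a, c_b = m[:5].sum(axis=0), m[5:].sum(axis=0)
            within.append((mean_pairwise(m[:5]) + mean_pairwise(m[5:])) / 2)
            between.append(float(((c_a * (5 - c_b)) + c_b * (5 - c_a)).sum()) / 25)
        assert np.mean(within) == pytest.approx(np.mean(between), rel=0.1)

    def test_im_founder_effect_reduces_daughter_diversity(self, rng):
        pis = {}
        for s in (0.022, 0.5):
            draw = dict(self.IM_DRAW, s=s, M_OW=0.0, M_NW=0.1)
            model = build_isolation_migration(draw)
            vals = []
            for _ in range(900):
                sim = simulate_locus(model, SPEC, [2, 8], rng, theta_locus=2.5)
                vals.append(mean_pairwise(sim.matrix[2:]))
            pis[s] = np.mean(vals)
        assert pis[0.022] < pis[0.5]

    def test_im_long_isolation_matches_two_island_limit(self, rng):
        """Large t, s=0.5, theta_A=theta_i=theta: statistics converge to the
        constant-size two-island model with the same parameters."""
        theta = 2.0
        im_draw = {
            "theta_OW": theta, "theta_NW": theta, "theta_A": theta,
            "M_OW": 1.0, "M_NW": 1.0, "t": 40.0, "s": 0.5,
        }
        im_model = build_isolation_migration(im_draw)
        ti_model = build_two_island(
            {"Theta_OW": theta, "Theta_NW": theta, "M_OW": 1.0, "M_NW": 1.0}
        )
        out = {}
        for name, model in (("im", im_model), ("ti", ti_model)):
            vals = [
                mean_pairwise(
                    simulate_locus(model, SPEC, [5, 5], rng, theta_locus=theta).matrix
                )
                for _ in range(900)
            ]
            out[name] = np.mean(vals)
        assert out["im"] == pytest.approx(out["ti"], rel=0.1)

    def test_bottleneck_time_bounds_and_size(self, rng):
        t_sim = self.IM_DRAW["t"] / self.IM_DRAW["theta_OW"]
        for _ in range(200):
            model = build_bottleneck(self.IM_DRAW, theta_ow_lamarc=0.9, rng=rng)
            sizes = [e for e in model.events if e.kind == "size_change"]
            recovery = sizes[-1]
            assert t_sim <= recovery.time <= 2 * t_sim
            assert recovery.payload["size"] == 0.9  # supplied value, verbatim

    def test_bottleneck_severity_monotone_in_diversity(self, rng):
        """Deeper bottlenecks (smaller theta_A relative to the recovery
        size) leave less diversity."""
        means = []
        for theta_a in (1.5, 0.4, 0.1):
            draw = dict(self.IM_DRAW, theta_A=theta_a)
            vals = []
            for _ in range(700):
                model = build_bottleneck(draw, theta_ow_lamarc=1.5, rng=rng)
                sim = simulate_locus(model, SPEC, [5, 5], rng, theta_locus=2.5)
                vals.append(mean_pairwise(sim.matrix))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    FD_DRAW = {
        "theta_fd_over_ow": 1.0,
        "theta_ow_M_ow": 1.0,
        "theta_ow_M_fd": 1.0,
        "t_fd_over_ow": 1.0,
    }

    def test_hybridization_structural_zeros(self):
        model = build_hybridization(self.IM_DRAW, self.FD_DRAW)
        assert model.n_demes == 3
        assert model.migration[1, 2] == 0.0 and model.migration[2, 1] == 0.0

    def test_hybridization_requires_older_fd_split(self):
        bad = dict(self.FD_DRAW, t_fd_over_ow=0.1)  # t_sim = 0.32
        with pytest.raises(ValueError, match="predate"):
            build_hybridization(self.IM_DRAW, bad)

    def test_hybridization_without_migration_reduces_to_im(self, rng):
        from scipy.stats import ks_2samp

        fd0 = dict(self.FD_DRAW, theta_ow_M_ow=0.0, theta_ow_M_fd=0.0)
        hyb = build_hybridization(self.IM_DRAW, fd0)
        im = build_isolation_migration(self.IM_DRAW)
        samples = {}
        for name, model, n_per in (("hyb", hyb, [5, 5, 0]), ("im", im, [5, 5])):
            samples[name] = [
                mean_pairwise(
                    simulate_locus(model, SPEC, n_per, rng, theta_locus=2.5).matrix
                )
                for _ in range(800)
            ]
        assert ks_2samp(samples["hyb"], samples["im"]).pvalue > 0.01

    def test_hybridization_introgression_raises_diversity(self, rng):
        big_fd = dict(self.FD_DRAW, theta_fd_over_ow=10.0, theta_ow_M_ow=2.0)
        no_mig = dict(self.FD_DRAW, theta_ow_M_ow=0.0, theta_ow_M_fd=0.0)
        out = {}
        for name, fd in (("intro", big_fd), ("none", no_mig)):
            model = build_hybridization(self.IM_DRAW, fd)
            vals = [
                mean_pairwise(
                    simulate_locus(model, SPEC, [6, 2, 0], rng, theta_locus=2.5).matrix[:6]
                )
                for _ in range(800)
            ]
            out[name] = np.mean(vals)
        assert out["intro"] > out["none"]


class TestRealizeSequences:
    def test_monomorphic_realisation(self, rng):
        sim = simulate_locus(PANMICTIC, SPEC, [6], rng, theta_locus=0.0)
        aln = realize_sequences(sim, 50, rng)
        assert len(set(aln.sequences)) == 1

    def test_exactly_s_polymorphic_columns(self, rng):
        sim = simulate_locus(PANMICTIC, SPEC, [8], rng, theta_locus=5.0)
        aln = realize_sequences(sim, 200, rng)
        mat = np.array([list(s) for s in aln.sequences])
        poly = sum(len(np.unique(mat[:, j])) > 1 for j in range(200))
        assert poly == sim.S

    def test_cross_module_pi_consistency(self, rng):
        for _ in range(10):
            sim = simulate_locus(PANMICTIC, SPEC, [8], rng, theta_locus=5.0)
            aln = realize_sequences(sim, 300, rng)
            st_aln = locus_stats(aln)
            st_mat = locus_stats_from_matrix(sim.matrix, sim.deme_of, 300)
            assert st_aln.pi == pytest.approx(st_mat.pi)
            assert st_aln.S == st_mat.S

    def test_too_many_sites_rejected(self, rng):
        sim = simulate_locus(PANMICTIC, SPEC, [10], rng, theta_locus=20.0)
        assert sim.S > 5
        with pytest.raises(ValueError, match="columns"):
            realize_sequences(sim, 5, rng)


class TestMsDialect:
    def test_round_trip(self, rng, tmp_path):
        sims = [
            simulate_locus(PANMICTIC, SPEC, [6], rng, theta_locus=3.0)
            for _ in range(5)
        ]
        path = tmp_path / "out.ms"
        write_ms(sims, path)
        back = read_ms(path)
        assert len(back) == 5
        for a, b in zip(sims, back):
            if a.S:
                assert np.array_equal(a.matrix, b.matrix)
                assert np.allclose(a.positions, b.positions, atol=1e-5)
            else:
                assert b.S == 0


@pytest.mark.parametrize("n,theta", [(10, 5.0)])
def test_cross_validation_against_msprime(rng, n, theta):
    """Distribution of S matches an independent coalescent simulator run
    with matching scaled parameters (oracle use only)."""
    msprime = pytest.importorskip("msprime")
    from scipy.stats import ks_2samp

    ours = [
        simulate_locus(PANMICTIC, SPEC, [n], rng, theta_locus=theta).S
        for _ in range(1500)
    ]
    theirs = []
    for seed in range(1, 1501):
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=0.5, random_seed=seed
        )
        mts = msprime.sim_mutations(
            ts, rate=theta, random_seed=seed, discrete_genome=False
        )
        theirs.append(mts.num_sites)
    assert ks_2samp(ours, theirs).pvalue > 0.01
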