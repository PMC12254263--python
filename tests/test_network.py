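"""Fourier profiles, correlation graph, BH, Louvain, CCM, NMI, eLSA."""

import numpy as np
import pandas as pd
import pytest

from conftest import coupled_logistic
from virotime.network import (
    bh_adjust,
    ccm_pair,
    edge_significance,
    elsa_pair,
    fourier_profile,
    louvain_modules,
    nmi_weight,
    profile_correlation_graph,
)

GRID = np.arange(48) * 30.5


class TestFourierProfile:
    def test_constant_series_is_dc_only(self):
        prof = fourier_profile(np.full(48, 3.7), GRID)
        assert abs(prof.coefficients[0]) == pytest.approx(48 * 3.7)
        assert np.abs(prof.coefficients[1:]).max() < 1e-9
        np.testing.assert_allclose(prof.reconstruction, 3.7, atol=1e-12)

    def test_single_harmonic_lands_on_one_coefficient(self):
        series = np.cos(2 * np.pi * 2 * np.arange(48) / 48)
        prof = fourier_profile(series, GRID)
        mags = np.abs(prof.coefficients)
        assert np.argmax(mags) == 2
        assert mags[np.arange(16) != 2].max() < 1e-9 * mags[2]

    def test_high_frequency_is_filtered_out(self):
        series = np.cos(2 * np.pi * 20 * np.arange(48) / 48)
        prof = fourier_profile(series, GRID)
        assert np.abs(prof.reconstruction).max() < 1e-9

    def test_reconstruction_exact_for_bandlimited_series(self):
        rng = np.random.default_rng(0)
        coeff = rng.normal(size=16) + 1j * rng.normal(size=16)
        full = np.zeros(25, dtype=complex)
        full[:16] = coeff
        series = np.fft.irfft(full, n=48)
        prof = fourier_profile(series, GRID)
        np.testing.assert_allclose(prof.reconstruction, series, atol=1e-9)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fourier_profile([1.0, 2.0, 3.0], [0.0, 30.5, 61.0])
        with pytest.raises(ValueError):
            fourier_profile(np.ones(10), np.arange(10) * 30.5)  # grid < 32


class TestCorrelationGraph:
    def profiles(self, rows):
        return [fourier_profile(r, GRID, entity_id=f"e{i}")
                for i, r in enumerate(rows)]

    def test_identical_retained_negated_and_orthogonal_not(self):
        t = np.arange(48)
        base = np.cos(2 * np.pi * 2 * t / 48)
        other = np.cos(2 * np.pi * 3 * t / 48)
        edges = profile_correlation_graph(
            self.profiles([base, base + 0.0, -base, other]), n_obs=48
        )
        kept = {tuple(sorted(p)) for p in zip(edges["a"], edges["b"])}
        assert ("e0", "e1") in kept
        assert all("e2" not in pair for pair in kept)   # r = -1, sign rule
        assert all("e3" not in pair for pair in kept)   # orthogonal, r ~ 0

    def test_zero_variance_profile_skipped_with_warning(self):
        t = np.arange(48)
        rows = [np.cos(2 * np.pi * t / 48), np.full(48, 2.0)]
        with pytest.warns(RuntimeWarning):
            edges = profile_correlation_graph(self.profiles(rows), n_obs=48)
        assert len(edges) == 0


class TestBhAdjust:
    @staticmethod
    def oracle(p):
        """Literal step-up definition: q_i = min_{j >= i} m p_(j) / j."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = np.inf
        for rank in range(m - 1, -1, -1):
            running = min(running, m * p[order[rank]] / (rank + 1))
            q[order[rank]] = min(running, 1.0)
        return q

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_cases(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 201))
            np.testing.assert_allclose(bh_adjust(p), self.oracle(p), atol=1e-12)


class TestLouvain:
    @staticmethod
    def edges_from(graph_edges):
        return pd.DataFrame(graph_edges, columns=["a", "b", "r"])

    def test_two_cliques(self):
        rows = []
        for base in ("x", "y"):
            nodes = [f"{base}{i}" for i in range(5)]
            rows += [(a, b, 1.0) for i, a in enumerate(nodes)
                     for b in nodes[i + 1:]]
        mods = louvain_modules(self.edges_from(rows), seed=0)
        assert len({mods[f"x{i}"] for i in range(5)}) == 1
        assert len({mods[f"y{i}"] for i in range(5)}) == 1
        assert mods["x0"] != mods["y0"]

    def test_complete_graph_single_module(self):
        nodes = [f"n{i}" for i in range(6)]
        rows = [(a, b, 1.0) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        mods = louvain_modules(self.edges_from(rows), seed=0)
        assert len(set(mods.values())) == 1

    def test_planted_partition_recovery(self):
        """4 blocks of 20, p_in = 0.6, p_out = 0.02: ARI >= 0.9 across seeds."""
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = []
            labels = {}
            for blk in range(4):
                for i in range(20):
                    labels[f"b{blk}n{i}"] = blk
            names = list(labels)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    p = 0.6 if labels[a] == labels[b] else 0.02
                    if rng.random() < p:
                        rows.append((a, b, 1.0))
            mods = louvain_modules(self.edges_from(rows), seed=seed)
            nodes = list(mods)
            aris.append(adjusted_rand_score([labels[n] for n in nodes],
                                            [mods[n] for n in nodes]))
        assert np.mean(aris) >= 0.9

    def test_determinism_and_validation(self):
        rows = [("a", "b", 0.9), ("b", "c", 0.8), ("c", "a", 0.7)]
        assert louvain_modules(self.edges_from(rows), seed=3) == \
            louvain_modules(self.edges_from(rows), seed=3)
        with pytest.raises(ValueError):
            louvain_modules(self.edges_from([]), seed=0)
        with pytest.raises(ValueError):
            louvain_modules(self.edges_from([("a", "b", -1.0)]), seed=0)


class TestCcm:
    def test_self_map_has_perfect_terminal_skill(self):
        x, _ = coupled_logistic(0)
        res = ccm_pair(x, x, E=2, seed=0)
        assert res.skills[-1] > 0.95
        assert (np.diff(res.skills) > -0.05).all()   # non-decreasing-ish
        assert res.skills[-1] - res.skills[0] >= -0.05

    def test_direction_recovery_small(self):
        fwd = rev = 0
        for s in range(10):
            x, y = coupled_logistic(s)
            fwd += ccm_pair(x, y, E=2, seed=s).convergent
            rev += ccm_pair(y, x, E=2, seed=s).convergent
        assert fwd >= 9
        assert rev <= 2

    def test_white_noise_is_not_a_driver(self):
        bad = 0
        for s in range(10):
            x, _ = coupled_logistic(s + 100)
            noise = np.random.default_rng(s).normal(size=400)
            res = ccm_pair(x, noise, E=2, seed=s)
            sk = res.skills[np.isfinite(res.skills)]
            if res.convergent or (sk.size and abs(sk[-1]) >= 0.3):
                bad += 1
        assert bad <= 1

    def test_constant_series_non_convergent(self):
        res = ccm_pair(np.ones(100), np.ones(100), E=2, seed=0)
        assert not res.convergent

    def test_skill_bounds_and_length_check(self):
        x, y = coupled_logistic(1, n=100)
        res = ccm_pair(x, y, E=2, seed=0)
        finite = res.skills[np.isfinite(res.skills)]
        assert ((finite >= -1) & (finite <= 1)).all()
        with pytest.raises(ValueError):
            ccm_pair(x[:20], y[:20], E=5)


class TestNmi:
    def test_identity_and_monotone_transform(self):
        x = np.random.default_rng(0).uniform(size=500)
        assert nmi_weight(x, x) == pytest.approx(1.0)
        assert nmi_weight(x, np.exp(5 * x)) == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        """Independent series: NMI small but not exactly 0 — with sqrt(n)
        equal-frequency bins the plug-in estimator keeps an O(bins^2/n)
        bias (~0.05 after Miller-Madow correction at n = 10^4)."""
        rng = np.random.default_rng(1)
        x, y = rng.uniform(size=10_000), rng.uniform(size=10_000)
        assert nmi_weight(x, y) < 0.1

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=300), rng.normal(size=300)
        assert abs(nmi_weight(x, y) - nmi_weight(y, x)) <= 1e-12

    def test_bounds_and_minimum_length(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = nmi_weight(rng.normal(size=50), rng.normal(size=50))
            assert 0.0 <= v <= 1.0
        with pytest.raises(ValueError):
            nmi_weight(np.ones(5), np.ones(5))


class TestEdgeSignificance:
    def test_identical_series_minimal_p(self):
        x = np.random.default_rng(0).uniform(size=100)
        p = edge_significance(x, x, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_constant_series_p_one(self):
        assert edge_significance(np.ones(50), np.arange(50.0)) == 1.0

    def test_circular_beats_shuffle_under_autocorrelation(self):
        """Full shuffling is anti-conservative on AR(1) pairs."""
        rng = np.random.default_rng(5)
        rej_c = rej_s = 0
        n_rep = 120
        for _ in range(n_rep):
            def ar1():
                e = rng.normal(size=80)
                out = np.empty(80)
                out[0] = e[0]
                for t in range(1, 80):
                    out[t] = 0.8 * out[t - 1] + e[t]
                return out
            x, y = ar1(), ar1()
            s = int(rng.integers(2**31 - 1))
            rej_c += edge_significance(x, y, n_perm=99, scheme="circular",
                                       seed=s) <= 0.05
            rej_s += edge_significance(x, y, n_perm=99, scheme="shuffle",
                                       seed=s) <= 0.05
        assert rej_s > rej_c
        # circular scheme roughly calibrated: binomial 99.9% bound at alpha=.05
        assert rej_c <= 18


class TestElsa:
    def test_identity_and_negation(self):
        x = np.random.default_rng(1).normal(size=100)
        ls, d, p = elsa_pair(x, x, n_perm=199, seed=0)
        assert d == 0 and ls > 0.5 and p == pytest.approx(1 / 200)
        ls_neg, d_neg, _ = elsa_pair(x, -x, n_perm=0)
        assert d_neg == 0 and ls_neg == pytest.approx(-ls)

    def test_lag_one_recovery(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(s)
            x = rng.normal(size=200)
            y = np.roll(x, 1)
            y[0] = rng.normal()
            _, d, _ = elsa_pair(x, y, n_perm=0)
            hits += d == 1
        assert hits >= 29

    def test_length_check(self):
        with pytest.raises(ValueError):
            elsa_pair(np.ones(4), np.ones(4))
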