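"""Generator contracts: determinism, forcing shapes, planted structure."""

import numpy as np
import pandas as pd
import pytest

from virotime import synth


class TestEnvironment:
    def test_seeded_determinism(self):
        a = synth.gen_environment(48, 30.5, seed=1)
        b = synth.gen_environment(48, 30.5, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_environment(48, 0.0, seed=1)
        with pytest.raises(ValueError):
            synth.gen_environment(3, 30.5, seed=1)

    def test_polar_night_window(self):
        """PAR is exactly zero for at least 120 consecutive days per year."""
        cfg = synth.EnvironmentConfig().scale_noise(0.0)
        env = synth.gen_environment(2 * 365 + 1, 1.0, seed=0, config=cfg)
        par0 = (env["par"].to_numpy() == 0.0).astype(int)
        padded = np.concatenate([[0], par0, [0]])
        switch = np.flatnonzero(np.diff(padded)).reshape(-1, 2)
        assert (np.diff(switch, axis=1) >= 120).any()

    def test_temperature_range_is_twice_amplitude(self):
        cfg = synth.EnvironmentConfig(
            temperature=synth.SeasonalSignal(3.0, 3.0, 0.0, 0.0)
        ).scale_noise(0.0)
        env = synth.gen_environment(731, 0.5, seed=0, config=cfg)
        t = env["temperature"]
        assert t.max() - t.min() == pytest.approx(6.0, abs=1e-9)

    def test_bounds(self, env48):
        assert (env48["par"] >= 0).all()
        assert env48["polar_water_fraction"].between(0, 1).all()
        assert (env48["mld"] > 0).all()
        assert np.all(np.diff(env48["date"]) > 0)


class TestCommunity:
    def test_virus_decays_without_coupling(self, quiet_env):
        comm = synth.gen_community(
            quiet_env, 1, 1, 1, coupling=0.0, seed=0, sigma_host=0.0,
            sigma_virus=0.0, predation=0.0, immigration=0.0,
        )
        v = comm.virus_abundance.to_numpy()[0]
        assert np.all(np.diff(v) < 0)
        assert v[-1] < 1e-3 * v[0]

    def test_host_peaks_with_its_niche(self, quiet_env):
        """A temperature-niche host peaks within one step of the warm peak."""
        comm = synth.gen_community(
            quiet_env, 1, 1, 1, coupling=0.0, seed=0, sigma_host=0.0,
            sigma_virus=0.0, predation=0.0, guild_phase_days=[210.0],
            center_jitter=0.0, sigma_interannual=0.0, sigma_phase_days=0.0,
            immigration=0.0,
        )
        h = comm.host_abundance.to_numpy()[0]
        temp = quiet_env["temperature"].to_numpy()
        for year in range(1, 4):
            sl = slice(12 * year, 12 * year + 12)
            assert abs(np.argmax(h[sl]) - np.argmax(temp[sl])) <= 1

    def test_seeded_determinism(self, env48):
        a = synth.gen_community(env48, 8, 16, 4, seed=1)
        b = synth.gen_community(env48, 8, 16, 4, seed=1)
        pd.testing.assert_frame_equal(a.virus_abundance, b.virus_abundance)
        assert a.lag_of == b.lag_of and a.host_of == b.host_of

    def test_guild_partition_is_conserved(self, quiet_env):
        """Noiseless same-guild trajectories co-vary more than cross-guild."""
        comm = synth.gen_community(quiet_env, 8, 16, 4, seed=1,
                                   sigma_host=0.0, sigma_virus=0.0)
        mat = np.vstack([comm.host_abundance.to_numpy(),
                         comm.virus_abundance.to_numpy()])
        ids = list(comm.host_abundance.index) + list(comm.virus_abundance.index)
        guild = np.array([comm.guild_of[i] for i in ids])
        r = np.corrcoef(mat)
        iu = np.triu_indices(len(ids), k=1)
        same = (guild[:, None] == guild[None, :])[iu]
        assert r[iu][same].mean() > r[iu][~same].mean()

    def test_invariants(self, community):
        assert set(community.lag_of.values()) <= {0, 1, 2}
        assert (community.virus_abundance.to_numpy() >= 0).all()
        assert set(community.host_of) == set(community.virus_abundance.index)
        with pytest.raises(ValueError):
            synth.gen_community(community.host_abundance, 4, 2, 1)


class TestCoverage:
    def test_zero_abundance_gives_zero_coverage_and_breadth(self, env48):
        comm = synth.gen_community(env48, 1, 1, 1, coupling=0.0, seed=0,
                                   immigration=0.0)
        comm.virus_abundance.iloc[0, :] = 0.0
        cov, _, _ = synth.gen_coverage(comm, seed=0)
        assert (cov["mean_coverage"] == 0).all()
        assert (cov["breadth"] == 0).all()

    def test_coverage_linear_in_depth(self, community):
        cov1, _, _ = synth.gen_coverage(community, sample_gbp=10.0,
                                        noise_sd=0.0, seed=0)
        cov2, _, _ = synth.gen_coverage(community, sample_gbp=20.0,
                                        noise_sd=0.0, seed=0)
        np.testing.assert_allclose(cov2["mean_coverage"],
                                   2.0 * cov1["mean_coverage"])

    def test_breadth_formula(self, community):
        cov, _, _ = synth.gen_coverage(community, noise_sd=0.0, seed=0)
        expected = np.minimum(1.0, 1.0 - np.exp(-0.75 * cov["mean_coverage"]))
        np.testing.assert_allclose(cov["breadth"], expected)
        # coverage 0.1 -> breadth 1 - exp(-0.075)
        assert 1.0 - np.exp(-0.075) == pytest.approx(0.07225, abs=1e-4)

    def test_rank_order_preserved_without_noise(self, community):
        cov, _, _ = synth.gen_coverage(community, noise_sd=0.0, seed=0)
        piv = cov.pivot(index="contig_id", columns="sample_id",
                        values="mean_coverage")
        sample = piv.columns[5]
        got = piv[sample].rank().sort_index()
        want = community.virus_abundance[sample].rank().sort_index()
        assert (got == want).all()

    def test_short_contigs_rejected(self, community):
        lengths = {v: 9000 for v in community.virus_abundance.index}
        with pytest.raises(ValueError):
            synth.gen_coverage(community, contig_lengths=lengths)


class TestProteins:
    def test_only_standard_residues(self):
        prot = synth.gen_proteins(pd.Series({"a": 0.0, "b": 10.0}),
                                  n_proteins=20, mean_length=60, seed=0)
        alphabet = set("ACDEFGHIKLMNPQRSTVWY")
        for seqs in prot.values():
            for _, seq in seqs:
                assert set(seq) <= alphabet
                assert len(seq) >= 30

    def test_zero_bias_composition_uniform_across_temperature(self):
        """Residue frequencies differ only by sampling noise when bias = 0."""
        from scipy.stats import chi2_contingency

        temps = pd.Series({"cold": -1.0, "warm": 19.0})
        prot = synth.gen_proteins(temps, n_proteins=700, mean_length=150,
                                  bias_strength=0.0, seed=3)
        counts = []
        for s in temps.index:
            joined = "".join(seq for _, seq in prot[s])
            counts.append([joined.count(a) for a in "ACDEFGHIKLMNPQRSTVWY"])
        _, p, _, _ = chi2_contingency(np.array(counts))
        assert p > 0.01

    def test_bias_raises_aliphatic_content_in_warm_sample(self):
        from virotime.aatraits import aliphatic_index

        temps = pd.Series({"cold": -1.0, "warm": 19.0})
        prot = synth.gen_proteins(temps, n_proteins=700, mean_length=150,
                                  bias_strength=0.5, seed=3)
        ai = {s: np.mean([aliphatic_index(seq) for _, seq in prot[s]])
              for s in temps.index}
        assert ai["warm"] > ai["cold"]


class TestLatitudeProfiles:
    def test_truth_labels_and_positivity(self):
        prof, truth = synth.gen_latitude_profiles(50, frac_bimodal=1.0, seed=0)
        assert truth["bimodal"].all()
        assert (prof["coverage_per_gbp"] >= 0).all()
        # bimodal truths have one peak per hemisphere
        for peaks in truth["peak_latitudes"]:
            assert len(peaks) == 2
            assert (peaks[0] > 0) != (peaks[1] > 0)

    def test_bimodal_count_binomial(self):
        _, truth = synth.gen_latitude_profiles(200, frac_bimodal=0.5, seed=1)
        # binomial(200, .5) 99% interval
        assert 81 <= truth["bimodal"].sum() <= 119

    def test_frac_validation(self):
        with pytest.raises(ValueError):
            synth.gen_latitude_profiles(10, frac_bimodal=1.5)
        with pytest.raises(ValueError):
            synth.gen_latitude_profiles(10, sd=0.0)
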