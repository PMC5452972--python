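"""Substitution-model construction: MG94, HB98, stationary distributions.

The expected-dN/dS oracle here is an independent implementation: explicit
Python loops over codon pairs with the textbook fixation-probability
formula, sharing no code with the vectorized path it checks.
"""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from siterates import (
    MutSelSiteProfile,
    SiteRateProfile,
    expected_dnds,
    hb98_matrix,
    hky_mutation_matrix,
    mg94_matrix,
    stationary_distribution,
)
from siterates.codon_models import (
    fitness_from_aa_frequencies,
    fixation_factor,
    lift_mutation,
    neutral_codon_matrix,
    profiles_from_tsv,
    profiles_to_tsv,
)
from siterates.genetic_code import (
    CODON_INDEX,
    CODON_TO_AA,
    SENSE_CODONS,
    is_neighbor,
    is_synonymous,
)

N = len(SENSE_CODONS)
UNIFORM = np.full(N, 1.0 / N)


class TestGeneticCode:
    def test_sixty_one_sense_codons(self):
        assert N == 61
        assert not {"TAA", "TAG", "TGA"} & set(SENSE_CODONS)

    def test_neighbor_predicate(self):
        assert is_neighbor("AAA", "AAC")
        assert not is_neighbor("AAA", "ACC")
        assert not is_neighbor("AAA", "AAA")
        assert is_synonymous("CTT", "CTC")
        assert not is_synonymous("ATG", "CTG")


class TestMG94:
    def test_neutral_uniform_all_neighbor_rates_equal(self):
        q = mg94_matrix(SiteRateProfile(dN=1.0, dS=1.0), UNIFORM)
        off = q[~np.eye(N, dtype=bool)]
        positive = off[off > 0]
        assert np.allclose(positive, positive[0])
        pi = stationary_distribution(q)
        np.testing.assert_allclose(pi, UNIFORM, atol=1e-12)

    def test_dn_zero_kills_nonsynonymous_entries(self):
        q = mg94_matrix(SiteRateProfile(dN=0.0, dS=1.0), UNIFORM)
        for a in ("AAA", "AAG"):  # K
            for b in ("AAC", "AAT"):  # N, single-nucleotide nonsyn neighbors
                assert q[CODON_INDEX[a], CODON_INDEX[b]] == 0.0

    def test_multinucleotide_change_has_rate_zero(self):
        q = mg94_matrix(SiteRateProfile(dN=1.3, dS=0.7), UNIFORM)
        assert q[CODON_INDEX["AAA"], CODON_INDEX["ACC"]] == 0.0

    def test_invalid_frequencies_rejected(self):
        bad = np.full(N, 1.0 / N)
        bad[0] = -bad[0]
        with pytest.raises(ValueError):
            mg94_matrix(SiteRateProfile(dN=1.0), bad)
        with pytest.raises(ValueError):
            mg94_matrix(SiteRateProfile(dN=1.0), np.full(N, 0.5))

    @pytest.mark.parametrize("dn,ds", [(0.1, 1.0), (1.6, 1.0), (0.3, 1.7), (0.0, 0.5)])
    def test_row_sums_zero(self, dn, ds):
        q = mg94_matrix(SiteRateProfile(dN=dn, dS=ds), UNIFORM)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_flux_ratio_recovers_omega(self):
        # where MG94 and the MutSel flux logic overlap, dN/dS is exact:
        # stationary nonsyn flux relative to the neutral model equals omega
        from siterates.codon_models import NONSYNONYMOUS

        omega = 0.37
        q = mg94_matrix(SiteRateProfile(dN=omega, dS=1.0), UNIFORM)
        q0 = mg94_matrix(SiteRateProfile(dN=1.0, dS=1.0), UNIFORM)
        flux = (UNIFORM[:, None] * q)[NONSYNONYMOUS].sum()
        flux0 = (UNIFORM[:, None] * q0)[NONSYNONYMOUS].sum()
        assert flux / flux0 == pytest.approx(omega, rel=1e-12)


class TestProfiles:
    def test_ratio_definition(self):
        p = SiteRateProfile(dN=0.9, dS=1.8)
        assert p.ratio == 0.9 / 1.8
        with pytest.raises(ValueError):
            SiteRateProfile(dN=1.0, dS=0.0)

    def test_nan_fitness_rejected(self):
        f = np.zeros(N)
        f[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            MutSelSiteProfile(fitness=f)

    def test_tsv_roundtrip(self, tmp_path, rng):
        rate_profiles = [SiteRateProfile(dN=d, dS=s) for d, s in [(0.2, 1.0), (1.1, 0.6)]]
        path = tmp_path / "rates.tsv"
        profiles_to_tsv(rate_profiles, path)
        back = profiles_from_tsv(path)
        assert [(p.dN, p.dS) for p in back] == [(0.2, 1.0), (1.1, 0.6)]

        mutsel = [MutSelSiteProfile(fitness=rng.normal(0, 1, N)) for _ in range(3)]
        path2 = tmp_path / "fitness.tsv"
        profiles_to_tsv(mutsel, path2)
        back2 = profiles_from_tsv(path2)
        np.testing.assert_allclose(back2[2].fitness, mutsel[2].fitness, atol=1e-12)


class TestHB98:
    def test_equal_fitness_reduces_to_mutation_process(self):
        mu = hky_mutation_matrix()
        q = hb98_matrix(MutSelSiteProfile(fitness=np.full(N, 3.7)), mu)
        q0, _ = neutral_codon_matrix(mu)
        np.testing.assert_allclose(q, q0, atol=1e-12)

    def test_fixation_factor_limits(self):
        assert fixation_factor(np.array([1e-12]))[0] == 1.0
        assert fixation_factor(np.array([0.0]))[0] == 1.0
        # exact values of S / (1 - exp(-S))
        assert fixation_factor(np.array([2.0]))[0] == pytest.approx(2 / (1 - np.exp(-2)))
        assert fixation_factor(np.array([-2.0]))[0] == pytest.approx(-2 / (1 - np.exp(2)))

    def test_detailed_balance_two_state_selection(self):
        rng = np.random.default_rng(1)
        f = np.where(rng.random(N) < 0.5, 1.0, -1.0)
        mu = hky_mutation_matrix()
        q = hb98_matrix(MutSelSiteProfile(fitness=f), mu)
        pi = MutSelSiteProfile(fitness=f).stationary(mu)
        flow = pi[:, None] * q
        assert np.abs(flow - flow.T).max() <= 1e-10

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_detailed_balance_random_fitness(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(0.0, 2.0, N)
        mu = hky_mutation_matrix(freqs=(0.4, 0.1, 0.2, 0.3))
        profile = MutSelSiteProfile(fitness=f)
        q = hb98_matrix(profile, mu)
        pi = profile.stationary(mu)
        flow = pi[:, None] * q
        assert np.abs(flow - flow.T).max() <= 1e-10
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_non_neighbors_have_zero_rate(self):
        mu = hky_mutation_matrix()
        q = hb98_matrix(MutSelSiteProfile(fitness=np.arange(N) * 0.01), mu)
        assert q[CODON_INDEX["AAA"], CODON_INDEX["ACC"]] == 0.0
        assert q[CODON_INDEX["AAA"], CODON_INDEX["CCC"]] == 0.0


class TestExpectedDnds:
    def test_neutral_profile_gives_one(self):
        mu = hky_mutation_matrix()
        value = expected_dnds(MutSelSiteProfile(fitness=np.zeros(N)), mu)
        assert value == pytest.approx(1.0, abs=1e-10)

    def test_strong_purifying_limit(self):
        # one amino acid 20 scaled-fitness units above all others
        f = np.array([20.0 if CODON_TO_AA[c] == "L" else 0.0 for c in SENSE_CODONS])
        value = expected_dnds(MutSelSiteProfile(fitness=f), hky_mutation_matrix())
        assert 0 <= value < 0.01

    def test_shift_invariance(self):
        rng = np.random.default_rng(7)
        f = rng.normal(0, 1, N)
        mu = hky_mutation_matrix()
        a = expected_dnds(MutSelSiteProfile(fitness=f), mu)
        b = expected_dnds(MutSelSiteProfile(fitness=f + 123.4), mu)
        assert a == pytest.approx(b, rel=1e-9)

    def test_two_class_profile_matches_bruteforce_oracle(self):
        # two amino-acid fitness classes at S = +/-1, uniform mutation
        f = np.array([0.5 if CODON_TO_AA[c] in "ACDEFGHIK" else -0.5 for c in SENSE_CODONS])
        mu = hky_mutation_matrix(freqs=(0.25, 0.25, 0.25, 0.25))
        value = expected_dnds(MutSelSiteProfile(fitness=f), mu)
        oracle = _expected_dnds_bruteforce(f, mu)
        assert value == pytest.approx(oracle, rel=1e-10)

    def test_random_profile_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        f = rng.normal(0, 1.5, N)
        mu = hky_mutation_matrix()
        value = expected_dnds(MutSelSiteProfile(fitness=f), mu)
        oracle = _expected_dnds_bruteforce(f, mu)
        assert value == pytest.approx(oracle, rel=1e-10)


class TestStationaryDistribution:
    def test_uniform_mg94(self):
        q = mg94_matrix(SiteRateProfile(dN=1.0, dS=1.0), UNIFORM)
        np.testing.assert_allclose(stationary_distribution(q), UNIFORM, atol=1e-10)

    def test_hb98_matches_profile_pi(self):
        rng = np.random.default_rng(3)
        profile = MutSelSiteProfile(fitness=rng.normal(0, 1, N))
        mu = hky_mutation_matrix()
        q = hb98_matrix(profile, mu)
        np.testing.assert_allclose(
            stationary_distribution(q), profile.stationary(mu), atol=1e-8
        )

    def test_random_q_matches_long_time_expm_oracle(self, rng):
        # small random reversible-ish chain: compare null-space solve against
        # the matrix-exponential limit exp(Q * T) for large T
        q = rng.random((5, 5))
        np.fill_diagonal(q, 0.0)
        q -= np.diag(q.sum(axis=1))
        v = stationary_distribution(q)
        limit = scipy.linalg.expm(q * 200.0)
        np.testing.assert_allclose(v, limit[0], atol=1e-8)
        assert np.abs(v @ q).max() <= 1e-10

    def test_reducible_matrix_rejected(self):
        q = np.zeros((4, 4))
        q[0, 1] = q[1, 0] = 1.0
        q[2, 3] = q[3, 2] = 1.0
        q -= np.diag(q.sum(axis=1))
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(q)


class TestFitnessFromAAFrequencies:
    def test_realizes_target_frequencies(self):
        rng = np.random.default_rng(5)
        g = rng.dirichlet(np.ones(20))
        mu = hky_mutation_matrix()
        f = fitness_from_aa_frequencies(g, mu)
        pi = MutSelSiteProfile(fitness=f).stationary(mu)
        from siterates.genetic_code import CODON_AA_INDEX

        aa_mass = np.bincount(CODON_AA_INDEX, weights=pi, minlength=20)
        np.testing.assert_allclose(aa_mass, g, atol=1e-10)


def _expected_dnds_bruteforce(fitness: np.ndarray, mu: np.ndarray) -> float:
    """Independent oracle: explicit double loop over all codon pairs."""
    nucs = "ACGT"
    # nucleotide stationary by brute normalization (reversible HKY-style mu)
    pnuc = np.real(scipy.linalg.null_space(mu.T)[:, 0])
    pnuc = pnuc / pnuc.sum()

    def mut_rate(a, b):
        sites = [p for p in range(3) if a[p] != b[p]]
        if len(sites) != 1:
            return 0.0
        (p,) = sites
        return mu[nucs.index(a[p]), nucs.index(b[p])]

    def codon_mass(c):
        return pnuc[nucs.index(c[0])] * pnuc[nucs.index(c[1])] * pnuc[nucs.index(c[2])]

    m = np.array([codon_mass(c) for c in SENSE_CODONS])
    m /= m.sum()
    w = m * np.exp(fitness - max(fitness))
    pi = w / w.sum()
    pi0 = m

    flux_sel = flux_neu = 0.0
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j or CODON_TO_AA[a] == CODON_TO_AA[b]:
                continue
            rate = mut_rate(a, b)
            if rate == 0.0:
                continue
            s = fitness[j] - fitness[i]
            fix = 1.0 if abs(s) < 1e-8 else s / (1.0 - np.exp(-s))
            flux_sel += pi[i] * rate * fix
            flux_neu += pi0[i] * rate
    return flux_sel / flux_neu
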