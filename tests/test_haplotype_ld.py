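"""EM phasing, pairwise LD and diplotype assignment."""

import itertools

import numpy as np
import pytest

from hircus.haplotype_ld import (
    HaplotypeTable,
    assign_diplotypes,
    classify_ld,
    em_haplotype_frequencies,
    filter_rare,
    ld_from_genotypes,
    pairwise_ld,
)
from hircus.synthetic_data import SimConfig, simulate_genotypes

from conftest import make_matrix


def two_locus_loglik(counts9: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Independent likelihood oracle for two biallelic loci.

    ``counts9[gA, gB]`` are genotype-class counts; ``f`` has shape (..., 4)
    ordered (f00, f01, f10, f11) by alt-allele indicators.  Never calls the
    EM code path.
    """
    f00, f01, f10, f11 = (f[..., k] for k in range(4))
    probs = [
        (0, 0, f00 * f00), (0, 2, f01 * f01), (2, 0, f10 * f10), (2, 2, f11 * f11),
        (0, 1, 2 * f00 * f01), (2, 1, 2 * f10 * f11),
        (1, 0, 2 * f00 * f10), (1, 2, 2 * f01 * f11),
        (1, 1, 2 * f00 * f11 + 2 * f01 * f10),
    ]
    ll = np.zeros(f.shape[:-1])
    for ga, gb, p in probs:
        c = counts9[ga, gb]
        if c:
            ll = ll + c * np.log(np.maximum(p, 1e-300))
    return ll


def grid_search_oracle(counts9: np.ndarray, coarse=0.02, fine=5e-4) -> np.ndarray:
    """Maximize the two-locus likelihood by dense grid search over the
    3-simplex (coarse pass, then local refinement to sub-1e-3 resolution)."""
    def best_on(grid):
        f = grid[grid.sum(axis=1) <= 1.0 + 1e-12]
        f = np.column_stack([f, 1.0 - f.sum(axis=1)])
        f = np.clip(f, 0.0, 1.0)
        ll = two_locus_loglik(counts9, f)
        return f[np.argmax(ll)]

    ax = np.arange(0.0, 1.0 + coarse / 2, coarse)
    coarse_grid = np.array(list(itertools.product(ax, ax, ax)))
    f_best = best_on(coarse_grid)
    lo = np.maximum(f_best[:3] - 1.5 * coarse, 0.0)
    hi = np.minimum(f_best[:3] + 1.5 * coarse, 1.0)
    axes = [np.arange(l, h + fine / 2, fine) for l, h in zip(lo, hi)]
    fine_grid = np.array(list(itertools.product(*axes)))
    return best_on(fine_grid)


def genotype_class_counts(dosage: np.ndarray) -> np.ndarray:
    counts9 = np.zeros((3, 3), dtype=int)
    for ga, gb in dosage:
        counts9[ga, gb] += 1
    return counts9


class TestEm:
    def test_phase_determined_equals_gamete_counting(self):
        # 10 double-homozygote wild and 10 double-homozygote variant animals
        dosage = np.array([[0, 0]] * 10 + [[2, 2]] * 10)
        t = em_haplotype_frequencies(make_matrix(dosage))
        assert t.converged
        assert t.frequency_of((0, 0)) == pytest.approx(0.5, abs=1e-9)
        assert t.frequency_of((1, 1)) == pytest.approx(0.5, abs=1e-9)
        assert t.frequency_of((0, 1)) == pytest.approx(0.0, abs=1e-9)

    def test_single_locus_reduces_to_allele_frequency(self):
        dosage = np.array([[0], [1], [1], [2]])
        t = em_haplotype_frequencies(make_matrix(dosage))
        assert t.frequency_of((1,)) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f_true = rng.dirichlet([2, 2, 2, 2])
        pairs = rng.choice(4, size=(20, 2), p=f_true)
        H = np.array(list(itertools.product((0, 1), repeat=2)))
        dosage = H[pairs[:, 0]] + H[pairs[:, 1]]
        t = em_haplotype_frequencies(make_matrix(dosage), tol=1e-10)
        em_f = np.array([t.frequency_of(tuple(h)) for h in H])
        oracle_f = grid_search_oracle(genotype_class_counts(dosage))
        assert np.max(np.abs(em_f - oracle_f)) < 1e-3

    def test_loglik_reported_matches_oracle(self):
        rng = np.random.default_rng(7)
        dosage = rng.integers(0, 3, size=(25, 2))
        t = em_haplotype_frequencies(make_matrix(dosage))
        em_f = np.array([t.frequency_of(h) for h in
                         itertools.product((0, 1), repeat=2)])
        assert t.log_likelihood == pytest.approx(
            float(two_locus_loglik(genotype_class_counts(dosage), em_f)), abs=1e-6
        )

    def test_missing_calls_are_complete_cased(self):
        dosage = np.array([[0, 0], [2, 2], [-1, 0], [0, -1]])
        t = em_haplotype_frequencies(make_matrix(dosage))
        assert t.frequency_of((0, 0)) == pytest.approx(0.5, abs=1e-9)

    def test_no_complete_individuals_errors(self):
        with pytest.raises(ValueError, match="complete"):
            em_haplotype_frequencies(make_matrix(np.array([[-1, 0], [0, -1]])))

    def test_non_convergence_flagged(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(30, 3))
        t = em_haplotype_frequencies(make_matrix(dosage), tol=0.0, max_iter=3)
        assert not t.converged and t.n_iterations == 3

    def test_recovers_known_frequencies_at_large_n(self):
        cfg = SimConfig(n_male=2500, n_female=2500, leak=0.02, seed=11)
        gm = simulate_genotypes(cfg)
        space, truth = cfg.haplotype_distribution()
        t = em_haplotype_frequencies(gm)
        est = np.array([t.frequency_of(h) for h in space])
        assert np.max(np.abs(est - truth)) < 0.02


class TestPairwiseLd:
    def test_independence_gives_zero(self):
        pA, pB = 0.3, 0.8
        f = np.array([[pA * pB, pA * (1 - pB)], [(1 - pA) * pB, (1 - pA) * (1 - pB)]])
        res = pairwise_ld(f)
        assert res.D == pytest.approx(0.0, abs=1e-12)
        assert res.D_prime == 0.0 and res.r2 == pytest.approx(0.0, abs=1e-12)
        assert not res.strong_ld

    def test_complete_coupling(self):
        res = pairwise_ld(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert res.D_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.strong_ld

    def test_closed_form_example(self):
        # pA=0.6, pB=0.7, f(AB)=0.5
        f = np.array([[0.5, 0.1], [0.2, 0.2]])
        res = pairwise_ld(f)
        assert res.D == pytest.approx(0.08, abs=1e-12)
        assert res.D_prime == pytest.approx(0.08 / 0.18, abs=1e-12)
        assert res.r2 == pytest.approx(0.0064 / 0.0504, abs=1e-12)

    def test_monomorphic_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_ld(np.array([[0.7, 0.3], [0.0, 0.0]]))

    def test_r2_bounded_by_dprime_squared_randomized(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 10_000:
            f = rng.dirichlet([1, 1, 1, 1]).reshape(2, 2)
            pA, pB = f[0].sum(), f[:, 0].sum()
            if min(pA, 1 - pA, pB, 1 - pB) <= 1e-6:
                continue
            res = pairwise_ld(f)
            assert 0.0 <= res.r2 <= res.D_prime**2 + 1e-9 <= 1.0 + 1e-9
            checked += 1


@pytest.mark.parametrize(
    "r2, strong", [(0.85, True), (0.34, True), (0.33, False), (0.0, False)]
)
def test_classify_ld_strict_threshold(r2, strong):
    assert classify_ld(r2) is strong


class TestDiplotypes:
    def _two_hap_table(self, loci):
        return HaplotypeTable(
            loci, [(1, 1, 1, 1), (0, 0, 0, 0)], np.array([0.5759, 0.4241])
        )

    def test_homozygous_everywhere_unique_pair(self):
        gm = make_matrix(np.array([[2, 2, 2, 2]]))
        t = self._two_hap_table(gm.loci)
        (d,) = assign_diplotypes(gm, t)
        assert d.posterior == pytest.approx(1.0)
        assert d.label == "Hap1/1" and not d.low_confidence

    def test_quad_heterozygote_resolves_to_dominant_pair(self):
        gm = make_matrix(np.array([[1, 1, 1, 1]]))
        t = self._two_hap_table(gm.loci)
        (d,) = assign_diplotypes(gm, t)
        assert d.label == "Hap1/2"
        assert d.posterior == pytest.approx(1.0)  # 7 competing pairs carry 0 mass

    def test_missing_locus_marginalized_posteriors_sum_to_one(self):
        gm = make_matrix(np.array([[1, 1, 1, -1]]))
        t = self._two_hap_table(gm.loci)
        (d,) = assign_diplotypes(gm, t)
        # exhaustive enumeration oracle over the full haplotype space
        freqs = {h: t.frequency_of(h) for h in
                 itertools.product((0, 1), repeat=4)}
        total, best = 0.0, 0.0
        for h1, h2 in itertools.combinations_with_replacement(freqs, 2):
            ok = all(
                g == -1 or a + b == g
                for g, a, b in zip([1, 1, 1, -1], h1, h2)
            )
            if ok:
                w = (1.0 if h1 == h2 else 2.0) * freqs[h1] * freqs[h2]
                total += w
                best = max(best, w)
        assert d.posterior == pytest.approx(best / total, abs=1e-9)

    def test_inconsistent_individual_flagged_low_confidence(self):
        # het at one locus only: no pair of the two full-length haplotypes fits
        gm = make_matrix(np.array([[1, 0, 0, 0]]))
        t = self._two_hap_table(gm.loci)
        (d,) = assign_diplotypes(gm, t)
        assert d.low_confidence and 0.0 < d.posterior <= 1.0

    def test_assignment_consistent_with_genotypes(self, default_cohort):
        _, gm, _ = default_cohort
        t = em_haplotype_frequencies(gm)
        for d in assign_diplotypes(gm, t):
            i = gm.individual_ids.index(d.individual_id)
            h1, h2 = d.haplotype_pair
            for j in range(gm.n_loci):
                g = gm.dosage[i, j]
                if g != -1:
                    assert h1[j] + h2[j] == g


class TestFilterRare:
    def _table(self, freqs):
        loci = make_matrix(np.zeros((1, 1), dtype=int)).loci
        haps = [(0,), (1,)] if len(freqs) == 2 else [(0,), (1,), (0,)]
        # distinct haplotypes required; build on enough loci instead
        import itertools as it

        L = max(1, int(np.ceil(np.log2(len(freqs)))))
        gm = make_matrix(np.zeros((1, L), dtype=int))
        haps = list(it.product((0, 1), repeat=L))[: len(freqs)]
        return HaplotypeTable(gm.loci, haps, np.asarray(freqs))

    def test_renormalization_arithmetic(self):
        t = filter_rare(self._table([0.575, 0.424, 0.001]))
        assert t.frequencies.tolist() == pytest.approx(
            [0.575 / 0.999, 0.424 / 0.999]
        )
        assert t.dropped_mass == pytest.approx(0.001)
        assert t.raw_frequencies.tolist() == pytest.approx([0.575, 0.424])

    def test_no_op_when_all_common(self):
        t = filter_rare(self._table([0.5759, 0.4241]))
        assert t.frequencies.tolist() == pytest.approx([0.5759, 0.4241])
        assert t.dropped_mass == 0.0

    def test_all_rare_errors(self):
        with pytest.raises(ValueError, match="below"):
            filter_rare(self._table([0.5, 0.5]), min_freq=0.6)


def test_ld_from_genotypes_strong_in_default_cohort(default_cohort):
    _, gm, _ = default_cohort
    res = ld_from_genotypes(gm, "g.15523T>C", "g.15530G>C")
    assert res.strong_ld and res.r2 > 0.5
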