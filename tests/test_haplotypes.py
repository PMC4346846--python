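"""EM haplotype inference, LD measures, diplotype assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cga.datamodel import GenotypeTable, LocusDef
from cga.haplotypes import (
    JointGenotypeCounts,
    assign_diplotypes,
    diplotype_class_counts,
    em_haplotype_frequencies,
    filter_haplotypes,
    ld_measures,
)
from cga.simulate import (
    STUDY_HAP_FREQS,
    SimConfig,
    genotype_table_from_joint,
    simulate_genotypes,
)

from ._oracles import grid_mle_haplotype_freqs

C, T = "C", "T"
LOCI = [LocusDef("L1", (C, T)), LocusDef("L2", (C, T))]


def random_joint_counts(rng, n_max=60):
    classes = [
        ((a1, b1), (a2, b2))
        for a1, b1 in [(C, C), (C, T), (T, T)]
        for a2, b2 in [(C, C), (C, T), (T, T)]
    ]
    counts = {cls: int(rng.integers(0, n_max)) for cls in classes}
    if sum(counts.values()) == 0:
        counts[classes[0]] = 1
    return JointGenotypeCounts(LOCI, counts)


class TestEM:
    def test_study_table_reproduces_published_frequencies(self, study_joint):
        em = em_haplotype_frequencies(study_joint)
        assert em.converged
        freqs = {"".join(h): f for h, f in em.freq_map().items()}
        assert round(freqs["CC"], 3) == 0.621
        assert round(freqs["CT"], 3) == 0.279
        assert round(freqs["TT"], 3) == 0.095
        assert round(freqs["TC"], 3) == 0.005
        assert em.hap_names[(C, C)] == "Hap1"
        assert em.hap_names[(T, C)] == "Hap4"

    def test_no_double_heterozygotes_equals_gamete_counting(self):
        counts = {
            ((C, C), (C, C)): 10,
            ((C, C), (C, T)): 6,
            ((C, T), (C, C)): 4,
            ((T, T), (T, T)): 2,
        }
        jg = JointGenotypeCounts(LOCI, counts)
        em = em_haplotype_frequencies(jg)
        n2 = 2 * jg.n_individuals
        # phase is unambiguous, so frequencies are direct gamete fractions
        expect = {
            (C, C): (20 + 6 + 4) / n2,
            (C, T): 6 / n2,
            (T, C): 4 / n2,
            (T, T): 4 / n2,
        }
        for h, f in expect.items():
            assert em.freq_of(h) == pytest.approx(f, abs=1e-9)

    def test_loglik_nondecreasing_and_simplex(self, rng):
        for _ in range(50):
            jg = random_joint_counts(rng)
            em = em_haplotype_frequencies(jg)
            trace = np.asarray(em.loglik_trace)
            assert np.all(np.diff(trace) >= -1e-9)
            assert em.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(em.frequencies >= 0)

    def test_matches_grid_search_mle(self, rng, study_joint):
        """EM agrees with an independent simplex-search MLE within 1e-3."""
        tables = [study_joint] + [random_joint_counts(rng) for _ in range(3)]
        for jg in tables:
            em = em_haplotype_frequencies(jg)
            oracle = grid_mle_haplotype_freqs(em.haplotypes, jg.counts)
            for h in em.haplotypes:
                assert em.freq_of(h) == pytest.approx(oracle[h], abs=1e-3)

    def test_init_modes_agree(self, study_joint):
        em1 = em_haplotype_frequencies(study_joint, init="marginal")
        em2 = em_haplotype_frequencies(study_joint, init="uniform")
        assert np.allclose(em1.frequencies, em2.frequencies, atol=1e-6)

    def test_locus_order_and_label_invariance(self, rng):
        jg = random_joint_counts(rng)
        em = em_haplotype_frequencies(jg)
        # reversed locus order
        rev = JointGenotypeCounts(
            LOCI[::-1], {cls[::-1]: n for cls, n in jg.counts.items()}
        )
        em_rev = em_haplotype_frequencies(rev)
        for h in em.haplotypes:
            assert em.freq_of(h) == pytest.approx(em_rev.freq_of(h[::-1]), abs=1e-9)
        # allele relabeling at locus 2: C<->T
        swap = {C: T, T: C}
        relabeled = JointGenotypeCounts(
            LOCI,
            {
                (cls[0], tuple(sorted((swap[cls[1][0]], swap[cls[1][1]])))): n
                for cls, n in jg.counts.items()
            },
        )
        em_sw = em_haplotype_frequencies(relabeled)
        for h in em.haplotypes:
            assert em.freq_of(h) == pytest.approx(
                em_sw.freq_of((h[0], swap[h[1]])), abs=1e-9
            )

    def test_not_converged_flag(self, study_joint):
        em = em_haplotype_frequencies(study_joint, tol=0.0, max_iter=2)
        assert not em.converged and em.n_iter == 2

    def test_recovery_from_simulated_genotypes(self):
        """EM recovers generator frequencies within 3 binomial SDs (n=468)."""
        for seed in range(5):
            gt, _ = simulate_genotypes(SimConfig(seed=seed))
            jg, _ = JointGenotypeCounts.from_table(gt)
            em = em_haplotype_frequencies(jg)
            for h, f_true in STUDY_HAP_FREQS.items():
                sd = np.sqrt(f_true * (1 - f_true) / (2 * 468))
                assert abs(em.freq_of(h) - f_true) <= 3 * sd + 1e-12


class TestLD:
    def test_study_frequencies_give_published_ld(self, study_joint):
        em = em_haplotype_frequencies(study_joint)
        ld = ld_measures(em.freq_map())
        assert round(ld.Dprime, 3) == 0.918
        assert round(ld.r2, 3) == 0.158

    def test_independence_gives_zero(self):
        pA, pB = 0.7, 0.4
        freqs = {
            (C, C): pA * pB,
            (C, T): pA * (1 - pB),
            (T, C): (1 - pA) * pB,
            (T, T): (1 - pA) * (1 - pB),
        }
        ld = ld_measures(freqs)
        assert ld.D == pytest.approx(0.0, abs=1e-12)
        assert ld.r2 == pytest.approx(0.0, abs=1e-12)
        assert ld.Dprime == 0.0

    def test_two_haplotypes_complete_ld(self):
        ld = ld_measures({(C, C): 0.6, (T, T): 0.4})
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_three_haplotypes_dprime_one(self):
        ld = ld_measures({(C, C): 0.5, (C, T): 0.3, (T, T): 0.2})
        assert ld.Dprime == pytest.approx(1.0)
        assert ld.r2 < 1.0

    def test_monomorphic_margin_is_nan(self):
        ld = ld_measures({(C, C): 0.6, (C, T): 0.4})
        assert np.isnan(ld.Dprime) and np.isnan(ld.r2)

    @given(
        f=st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4)
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_r2_bounded(self, f):
        tot = sum(f)
        freqs = dict(zip([(C, C), (C, T), (T, C), (T, T)], [x / tot for x in f]))
        ld = ld_measures(freqs)
        assert -1e-9 <= ld.r2 <= 1 + 1e-9
        assert -1e-9 <= ld.Dprime <= 1 + 1e-9


class TestFilterAndDiplotypes:
    def test_study_cutoff_keeps_three_of_four(self, study_joint):
        em = em_haplotype_frequencies(study_joint)
        retained, total = filter_haplotypes(em.freq_map(), 0.05)
        assert len(retained) == 3
        assert round(total, 3) == 0.995

    def test_cutoff_zero_keeps_all(self):
        retained, total = filter_haplotypes({(C, C): 0.9, (C, T): 0.1}, 0.0)
        assert len(retained) == 2 and total == pytest.approx(1.0)

    def test_cutoff_above_max_errors(self):
        with pytest.raises(ValueError, match="cutoff"):
            filter_haplotypes({(C, C): 0.6, (C, T): 0.4}, 0.7)

    def test_study_diplotype_class_sizes(self, study_joint, study_genotypes):
        em = em_haplotype_frequencies(study_joint)
        calls, skipped = assign_diplotypes(study_genotypes, em)
        assert not skipped
        counts = diplotype_class_counts(calls)
        assert counts == {
            "Hap1/Hap1": 188,
            "Hap1/Hap2": 168,
            "Hap1/Hap3": 34,
            "Hap1/Hap4": 4,
            "Hap2/Hap2": 18,
            "Hap2/Hap3": 56,
        }

    def test_double_heterozygote_posterior(self, study_joint):
        """(CT, CT) resolves to the common-haplotype pair with posterior
        f1·f3 / (f1·f3 + f2·f4) ≈ 0.977 under the fitted frequencies."""
        em = em_haplotype_frequencies(study_joint)
        gt = genotype_table_from_joint(
            JointGenotypeCounts(em.loci, {((C, T), (C, T)): 1})
        )
        calls, _ = assign_diplotypes(gt, em)
        call = calls[0]
        f = em.freq_map()
        expect = (
            f[(C, C)] * f[(T, T)]
            / (f[(C, C)] * f[(T, T)] + f[(C, T)] * f[(T, C)])
        )
        assert call.pair == ((C, C), (T, T))
        assert call.posterior == pytest.approx(expect, abs=1e-9)
        assert call.posterior == pytest.approx(0.977, abs=5e-3)
        assert sum(call.all_pairs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_full_homozygote_posterior_one(self, study_joint):
        em = em_haplotype_frequencies(study_joint)
        gt = genotype_table_from_joint(
            JointGenotypeCounts(em.loci, {((C, C), (C, C)): 1})
        )
        calls, _ = assign_diplotypes(gt, em)
        assert calls[0].pair == ((C, C), (C, C))
        assert calls[0].posterior == 1.0

    def test_missing_call_skipped(self, study_joint):
        from cga.datamodel import MISSING

        em = em_haplotype_frequencies(study_joint)
        gt = genotype_table_from_joint(
            JointGenotypeCounts(em.loci, {((C, C), (C, C)): 2})
        )
        gt.calls[0, 1] = MISSING
        calls, skipped = assign_diplotypes(gt, em)
        assert len(calls) == 1 and skipped == ["s0001"]

    def test_posterior_counts_match_em_expected_counts(self, study_joint):
        """Summing haplotype posteriors over samples reproduces the EM's
        final expected gamete counts (2n·f)."""
        em = em_haplotype_frequencies(study_joint, tol=1e-12)
        gt = genotype_table_from_joint(study_joint)
        calls, _ = assign_diplotypes(gt, em)
        acc = {h: 0.0 for h in em.haplotypes}
        for c in calls:
            for (a, b), w in c.all_pairs.items():
                acc[a] += w
                acc[b] += w
        n2 = 2 * study_joint.n_individuals
        for h in em.haplotypes:
            assert acc[h] / n2 == pytest.approx(em.freq_of(h), abs=1e-6)
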