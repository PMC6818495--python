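import itertools

import numpy as np
import pytest

from popvar.io import KnownSet, VariantRecord
from popvar.mutsig import (
    BASES,
    CONTEXT_LABELS,
    MutationContextMatrix,
    SignatureMatrix,
    build_context_matrix,
    classify_context,
    compare_signature_loads,
    denovo_nmf,
    extract_novel_singletons,
    refit_exposures,
    reverse_complement,
    signature_load_gwas,
)
from popvar.simulate import SimConfig, simulate_two_pop_genotypes


def snv(ref, alt, pos=10, chrom="chr1"):
    return VariantRecord(chrom, pos, ref, alt)


class TestClassifyContext:
    def test_pyrimidine_centered_direct(self):
        assert classify_context(snv("C", "T"), "ACG") == "A[C>T]G"

    def test_purine_reverse_complemented(self):
        # CGT with G>A: reverse complement ACG with C>T
        assert classify_context(snv("G", "A"), "CGT") == "A[C>T]G"

    def test_label_space_is_exactly_96(self):
        labels = set()
        for up, ref, down in itertools.product(BASES, repeat=3):
            for alt in BASES:
                if alt == ref:
                    continue
                labels.add(classify_context(snv(ref, alt), up + ref + down))
        assert labels == set(CONTEXT_LABELS)
        assert len(CONTEXT_LABELS) == 96

    def test_strand_involution(self):
        for up, ref, down in itertools.product(BASES, repeat=3):
            for alt in BASES:
                if alt == ref:
                    continue
                fwd = classify_context(snv(ref, alt), up + ref + down)
                rc_tri = reverse_complement(up + ref + down)
                rc = classify_context(
                    snv(reverse_complement(ref), reverse_complement(alt)), rc_tri
                )
                assert fwd == rc

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            classify_context(snv("C", "T"), "NCG")

    def test_mismatched_middle_base_rejected(self):
        with pytest.raises(ValueError):
            classify_context(snv("C", "T"), "AAG")


class TestSingletonExtraction:
    def test_kept_when_unique_supported_and_novel(self):
        calls = {"s1": [(snv("C", "T"), 12)], "s2": []}
        out = extract_novel_singletons(calls, KnownSet())
        assert len(out.by_sample["s1"]) == 1

    def test_dropped_when_shared(self):
        v = snv("C", "T")
        calls = {"s1": [(v, 50)], "s2": [(v, 50)]}
        out = extract_novel_singletons(calls, KnownSet())
        assert out.sample_counts() == {"s1": 0, "s2": 0}
        assert out.n_dropped_shared == 2

    def test_support_boundary_more_than_10_reads(self):
        calls = {"s1": [(snv("C", "T", pos=5), 10), (snv("C", "A", pos=8), 11)]}
        out = extract_novel_singletons(calls, KnownSet())
        kept = [v.alt_allele for v, _ in out.by_sample["s1"]]
        assert kept == ["A"]

    def test_known_variant_dropped(self):
        v = snv("C", "T")
        calls = {"s1": [(v, 20)]}
        out = extract_novel_singletons(calls, KnownSet([v.key]))
        assert out.sample_counts()["s1"] == 0
        assert out.n_dropped_known == 1


class TestContextMatrix:
    def test_zero_singletons_zero_row(self):
        from popvar.mutsig import SingletonSet

        m = build_context_matrix(SingletonSet({"s1": []}), {"chr1": "ACGT"})
        assert m.counts.sum() == 0

    def test_repeated_context_counts_in_one_column(self):
        from popvar.mutsig import SingletonSet

        ref = {"chr1": "AACGTACGTACGTACGTACG"}
        # positions of C with A upstream, G downstream: pos 3, 8, 13, 18 (1-based)
        vars_ = [(VariantRecord("chr1", p, "C", "T"), 15) for p in (3, 7, 11, 15)]
        m = build_context_matrix(SingletonSet({"s1": vars_}), ref)
        j = CONTEXT_LABELS.index("A[C>T]G")
        assert m.counts[0, j] == 4
        assert m.counts.sum() == 4

    def test_matches_independent_tally(self, rng):
        # random singletons tallied by a direct per-variant loop
        from popvar.mutsig import SingletonSet

        seq = "".join(rng.choice(list(BASES), 500))
        ref = {"chr1": seq}
        singles = []
        expected = np.zeros(96, dtype=int)
        for pos in rng.choice(np.arange(2, 500), 60, replace=False):
            pos = int(pos)
            r = seq[pos - 1]
            alt = rng.choice([b for b in BASES if b != r])
            singles.append((VariantRecord("chr1", pos, r, str(alt)), 20))
            label = classify_context(VariantRecord("chr1", pos, r, str(alt)), seq[pos - 2 : pos + 1])
            expected[CONTEXT_LABELS.index(label)] += 1
        m = build_context_matrix(SingletonSet({"s1": singles}), ref)
        np.testing.assert_array_equal(m.counts[0], expected)

    def test_position_outside_reference_errors(self):
        from popvar.mutsig import SingletonSet

        with pytest.raises(IndexError):
            build_context_matrix(
                SingletonSet({"s1": [(VariantRecord("chr1", 99, "C", "T"), 15)]}),
                {"chr1": "ACGT"},
            )


class TestRefitExposures:
    def test_pure_signature_exact(self, disjoint_signatures):
        m = MutationContextMatrix(
            ["s1"], (96 * disjoint_signatures.profiles[:, 1])[None, :]
        )
        expo = refit_exposures(m, disjoint_signatures)
        assert expo.loads[0, 1] == pytest.approx(96, rel=1e-6)
        assert expo.loads[0, 0] == pytest.approx(0, abs=1e-8)
        assert expo.residuals[0] == pytest.approx(0, abs=1e-8)

    def test_two_component_mixture(self, disjoint_signatures):
        s = disjoint_signatures.profiles
        m = MutationContextMatrix(["s1"], (60 * s[:, 0] + 40 * s[:, 1])[None, :] * 32)
        # scale keeps entries integral; exposures scale accordingly
        expo = refit_exposures(m, disjoint_signatures)
        assert expo.loads[0, 0] == pytest.approx(60 * 32, rel=1e-6)
        assert expo.loads[0, 1] == pytest.approx(40 * 32, rel=1e-6)

    def test_poisson_noise_recovery(self, disjoint_signatures, rng):
        truth = np.array([0.5, 0.3, 0.2])
        lam = 1000 * disjoint_signatures.profiles @ truth
        counts = rng.poisson(lam, size=(5, 96))
        expo = refit_exposures(MutationContextMatrix([f"s{i}" for i in range(5)], counts), disjoint_signatures)
        props = expo.proportions
        assert np.abs(props - truth).max() < 0.05

    def test_zero_row_flagged(self, disjoint_signatures):
        m = MutationContextMatrix(["s1", "s2"], np.vstack([np.zeros(96, int), np.ones(96, int)]))
        expo = refit_exposures(m, disjoint_signatures)
        assert expo.zero_samples == ["s1"]
        assert (expo.loads[0] == 0).all()

    def test_adding_signature_never_increases_residual(self, rng):
        profiles = rng.dirichlet(np.ones(96), size=4).T
        counts = rng.poisson(rng.uniform(0, 20, 96), size=(3, 96))
        m = MutationContextMatrix(["a", "b", "c"], counts)
        small = SignatureMatrix(["s1", "s2", "s3"], profiles[:, :3])
        large = SignatureMatrix(["s1", "s2", "s3", "s4"], profiles)
        r_small = refit_exposures(m, small).residuals
        r_large = refit_exposures(m, large).residuals
        assert (r_large <= r_small + 1e-9).all()

    def test_exposure_sum_bounded_by_mutation_count(self, disjoint_signatures, rng):
        counts = rng.poisson(5, size=(4, 96))
        m = MutationContextMatrix([f"s{i}" for i in range(4)], counts)
        expo = refit_exposures(m, disjoint_signatures)
        # column-normalised signatures cannot attribute more mass than observed
        assert (expo.loads.sum(axis=1) <= counts.sum(axis=1) * (1 + 1e-6)).all()


class TestDenovoNMF:
    def test_recovers_disjoint_signatures(self, disjoint_signatures, rng):
        two = SignatureMatrix(disjoint_signatures.names[:2], disjoint_signatures.profiles[:, :2])
        W_true = rng.uniform(100, 500, size=(20, 2))
        W_true[0] = (400.0, 0.0)  # pure samples make the factorization identifiable
        W_true[1] = (0.0, 400.0)
        X = W_true @ two.profiles.T  # noiseless mixture: exact low-rank structure
        m = MutationContextMatrix([f"s{i}" for i in range(20)], X)
        _, _, matches = denovo_nmf(m, rank=2, reference=two, seed=7)
        assert sorted(name for name, _ in matches) == ["sigA", "sigB"]
        assert all(sim >= 0.99 for _, sim in matches)

    def test_rank_one_proportional_to_mean_profile(self, rng):
        profile = rng.dirichlet(np.ones(96))
        X = rng.poisson(800 * profile, size=(10, 96))
        m = MutationContextMatrix([f"s{i}" for i in range(10)], X)
        _, H, _ = denovo_nmf(m, rank=1, seed=1)
        mean_profile = X.mean(axis=0) / X.mean(axis=0).sum()
        cos = np.dot(H[0], mean_profile) / (np.linalg.norm(H[0]) * np.linalg.norm(mean_profile))
        assert cos > 0.995

    def test_deterministic_under_seed(self, disjoint_signatures, rng):
        X = rng.poisson(10, size=(6, 96))
        m = MutationContextMatrix([f"s{i}" for i in range(6)], X)
        W1, H1, _ = denovo_nmf(m, rank=2, seed=42)
        W2, H2, _ = denovo_nmf(m, rank=2, seed=42)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)

    def test_rank_too_large_errors(self, rng):
        m = MutationContextMatrix(["a", "b"], rng.poisson(5, size=(2, 96)))
        with pytest.raises(ValueError):
            denovo_nmf(m, rank=3)


class TestCompareSignatureLoads:
    def test_identical_groups_p_one(self):
        props = np.tile(np.array([[0.2], [0.5], [0.8]]), (2, 1))
        p = compare_signature_loads(props, ["a"] * 3 + ["b"] * 3)
        assert p[0] == pytest.approx(1.0)

    def test_small_sample_exact_enumeration(self):
        # {1,2,3} vs {4,5,6}: 2 of C(6,3)=20 assignments as extreme -> 0.1
        props = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        p = compare_signature_loads(props, ["a"] * 3 + ["b"] * 3)
        assert p[0] == pytest.approx(0.1)

    def test_location_shift_detected(self, rng):
        a = rng.normal(0, 1, (50, 1))
        b = rng.normal(1, 1, (50, 1))
        p = compare_signature_loads(np.vstack([a, b]), ["a"] * 50 + ["b"] * 50)
        assert p[0] < 0.01

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            compare_signature_loads(np.ones((3, 1)), ["a", "a", "a"])


class TestSignatureLoadGwas:
    def _matrix(self, seed=13, n_sites=300, n1=100, n2=100):
        cfg = SimConfig(seed=seed, n_pop1=n1, n_pop2=n2, n_sites=n_sites, F=0.0)
        m, _ = simulate_two_pop_genotypes(cfg)
        return m

    def test_null_type_one_error_rate(self, rng):
        m = self._matrix(n_sites=1000)
        load = rng.normal(size=m.n_samples)
        res = signature_load_gwas(m, load, alpha=0.05)
        rate = res["significant"].mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_planted_effect_recovered(self, rng):
        m = self._matrix(seed=21, n_sites=50)
        g = np.nan_to_num(m.codes[:, 0])
        # effect explaining ~20% of variance
        beta = 1.0
        noise_sd = np.sqrt(beta**2 * g.var() * 4)
        load = beta * g + rng.normal(0, noise_sd, m.n_samples)
        res = signature_load_gwas(m, load, alpha=1e-5)
        row = res[res["id"] == m.variants[0].id].iloc[0]
        assert row["p"] < 1e-5
        assert row["slope"] > 0

    def test_maf_filter(self):
        codes = np.zeros((50, 1))
        codes[:4, 0] = 1.0  # MAF 0.04
        from tests.conftest import make_matrix

        m = make_matrix(codes)
        load = np.arange(50, dtype=float)
        res = signature_load_gwas(m, load, maf_min=0.05)
        assert res.empty
        res2 = signature_load_gwas(m, load, maf_min=0.03)
        assert len(res2) == 1

    def test_zero_variance_load_errors(self):
        m = self._matrix(n_sites=10)
        with pytest.raises(ValueError):
            signature_load_gwas(m, np.zeros(m.n_samples))
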