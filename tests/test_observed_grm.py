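import numpy as np
import pytest

from crossgrm import (
    AUTOSOMAL,
    X,
    Pedigree,
    PedigreeRecord,
    RelationshipMatrix,
    Sex,
    blend,
    centered_genotypes,
    expected_founder_matrix,
    gametic_moments,
    observed_founder_grm,
    rank_report,
    read_dense,
    read_triplets,
    write_dense,
    write_triplets,
)
from crossgrm.errors import LabelMismatchError
from crossgrm.founder_genotypes import FounderGenotypes, MarkerBlock
from test_moments import freqs_from_p


def make_genotypes(counts_aut, counts_x, sexes, lines, ids=None):
    founder_ids = ids or [f"F{i+1}" for i in range(len(sexes))]
    counts_aut = np.atleast_2d(np.asarray(counts_aut, float))
    counts_x = np.atleast_2d(np.asarray(counts_x, float))
    return FounderGenotypes(
        founder_ids=founder_ids,
        sexes=sexes,
        lines=lines,
        autosomal=MarkerBlock(
            [f"m{i}" for i in range(counts_aut.shape[1])],
            ["1"] * counts_aut.shape[1], counts_aut),
        x=MarkerBlock(
            [f"x{i}" for i in range(counts_x.shape[1])],
            ["X"] * counts_x.shape[1], counts_x),
    )


def test_single_locus_hand_case():
    """Genotypes AA and aa at one locus with p̄ = ½: Z0 = (1, −1), S = ½."""
    g = make_genotypes([[2], [0]], [[0], [0]], [Sex.FEMALE] * 2, ["A", "B"])
    freqs = freqs_from_p([[1.0], [0.0]])
    m = observed_founder_grm(g, freqs, AUTOSOMAL)
    np.testing.assert_allclose(m.dense(), [[2, -2], [-2, 2]])


def test_heterozygous_row_centers_to_zero():
    g = make_genotypes([[1, 1, 1], [2, 0, 2]], [[0], [0]],
                       [Sex.FEMALE] * 2, ["A", "B"])
    freqs = freqs_from_p([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
    m = observed_founder_grm(g, freqs, AUTOSOMAL)
    assert m.dense()[0, 0] == 0.0
    z = centered_genotypes(g, freqs, AUTOSOMAL)
    np.testing.assert_array_equal(z.values[0], 0.0)


def test_x_male_hand_case():
    """Two hemizygous males A and a at one X locus, p̄ = ½: z = ±½."""
    g = make_genotypes([[0], [0]], [[1], [0]], [Sex.MALE] * 2, ["A", "B"])
    freqs = freqs_from_p([[0.5], [0.5]], p_x=[[1.0], [0.0]])
    m = observed_founder_grm(g, freqs, X)
    np.testing.assert_allclose(m.dense(), [[0.5, -0.5], [-0.5, 0.5]])


def test_x_females_are_centered_like_autosomes(polymorphic_cross):
    ped, g, freqs = polymorphic_cross
    z = centered_genotypes(g, freqs, X)
    female = [i for i, s in enumerate(g.sexes) if s is Sex.FEMALE]
    pbar = freqs.x.pbar
    np.testing.assert_allclose(
        z.values[female], g.x.counts[female] - 2 * pbar[None, :]
    )


class TestBlend:
    def test_equal_inputs_fixed_point(self, polymorphic_cross):
        ped, g, freqs = polymorphic_cross
        g0 = observed_founder_grm(g, freqs, AUTOSOMAL)
        e0 = g0.copy(kind="expected-founder")
        # equal inputs: the convex combination is the input (to rounding)
        np.testing.assert_allclose(blend(g0, e0, 0.37).values, g0.dense(),
                                   rtol=1e-15, atol=0)

    def test_entry_arithmetic(self):
        g0 = RelationshipMatrix(np.array([[1.36]]), ["f"], AUTOSOMAL, "observed")
        e0 = RelationshipMatrix(np.array([[1.193]]), ["f"], AUTOSOMAL, "expected-founder")
        assert blend(g0, e0, 0.98).values[0, 0] == pytest.approx(1.35666)

    def test_endpoints_are_bitwise(self, polymorphic_cross):
        ped, g, freqs = polymorphic_cross
        g0 = observed_founder_grm(g, freqs, AUTOSOMAL)
        mom = gametic_moments(freqs, AUTOSOMAL)
        e0 = expected_founder_matrix(ped, mom, AUTOSOMAL)
        np.testing.assert_array_equal(blend(g0, e0, 1.0).values, g0.dense())
        np.testing.assert_array_equal(blend(g0, e0, 0.0).values, e0.dense())

    def test_repairs_rank_deficiency_from_duplicated_founder(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 3, size=(4, 40)).astype(float)
        counts[1] = counts[0]  # identical genotype rows -> singular G0
        p = np.vstack([counts[:2].mean(axis=0) / 2, counts[2:].mean(axis=0) / 2])
        p = np.clip(p, 0.05, 0.95)
        g = make_genotypes(counts, np.zeros((4, 1)), [Sex.FEMALE] * 4,
                           ["A", "A", "B", "B"])
        freqs = freqs_from_p(p)
        g0 = observed_founder_grm(g, freqs, AUTOSOMAL)
        assert rank_report(g0) == 3
        ped = Pedigree([
            PedigreeRecord(f"F{i+1}", None, None, Sex.FEMALE, l)
            for i, l in enumerate(["A", "A", "B", "B"])
        ])
        e0 = expected_founder_matrix(ped, gametic_moments(freqs, AUTOSOMAL), AUTOSOMAL)
        blended = blend(g0, e0, 0.98)
        assert np.isfinite(np.linalg.cond(blended.dense()))
        assert np.linalg.cond(blended.dense()) < 1e6

    def test_label_mismatch(self):
        g0 = RelationshipMatrix(np.eye(2), ["a", "b"], AUTOSOMAL, "observed")
        e0 = RelationshipMatrix(np.eye(2), ["a", "c"], AUTOSOMAL, "expected-founder")
        with pytest.raises(LabelMismatchError):
            blend(g0, e0)


def test_rank_report_identity_and_duplicate_row():
    m = RelationshipMatrix(np.eye(8), [f"f{i}" for i in range(8)], AUTOSOMAL, "observed")
    assert rank_report(m) == 8
    v = np.eye(8)
    v[7] = v[6]
    v[:, 7] = v[:, 6]
    m2 = RelationshipMatrix(0.5 * (v + v.T), [f"f{i}" for i in range(8)],
                            AUTOSOMAL, "observed")
    assert rank_report(m2) == 7


def test_observed_matrices_are_psd(polymorphic_cross):
    ped, g, freqs = polymorphic_cross
    for part in (AUTOSOMAL, X):
        m = observed_founder_grm(g, freqs, part)
        assert m.min_relative_eigenvalue() > -1e-8


def test_matrix_text_roundtrips(tmp_path, polymorphic_cross):
    ped, g, freqs = polymorphic_cross
    m = observed_founder_grm(g, freqs, AUTOSOMAL)
    write_dense(m, tmp_path / "d.txt")
    back = read_dense(tmp_path / "d.txt", AUTOSOMAL, "observed")
    assert back.ids == m.ids
    np.testing.assert_array_equal(back.dense(), m.dense())
    write_triplets(m, tmp_path / "t.txt")
    back2 = read_triplets(tmp_path / "t.txt", AUTOSOMAL, "observed")
    np.testing.assert_array_equal(back2.submatrix(m.ids).values, m.dense())


def test_mean_entry_bias_shrinks_and_matches_expectation():
    """Consistency of the centering: the unweighted mean of all G0 entries
    over HWE founder draws equals 2·Σ_ℓ n_ℓ(d_ℓ − r_ℓℓ)/F² (the two-line
    between-line terms cancel), which vanishes as founders per line grow."""
    rng = np.random.default_rng(42)
    p = rng.uniform(0.2, 0.8, size=(2, 60))
    freqs = freqs_from_p(p)
    mom = gametic_moments(freqs, AUTOSOMAL)

    def mean_entry(n_per_line, reps):
        vals = []
        for _ in range(reps):
            counts = np.vstack([
                rng.binomial(2, p[0], size=(n_per_line, 60)),
                rng.binomial(2, p[1], size=(n_per_line, 60)),
            ]).astype(float)
            g = make_genotypes(counts, np.zeros((2 * n_per_line, 1)),
                               [Sex.FEMALE] * (2 * n_per_line),
                               ["A"] * n_per_line + ["B"] * n_per_line)
            vals.append(observed_founder_grm(g, freqs, AUTOSOMAL).dense().mean())
        return np.mean(vals), np.std(vals) / np.sqrt(len(vals))

    for n in (4, 16):
        F = 2 * n
        expected = 2 * n * (mom.d - np.diag(mom.r)).sum() / F**2
        mean, se = mean_entry(n, 30)
        assert abs(mean - expected) < 3 * se + 1e-9
    # the analytic bias itself shrinks with founder count
    bias = lambda n: 2 * n * (mom.d - np.diag(mom.r)).sum() / (2 * n) ** 2
    assert abs(bias(16)) < abs(bias(4))
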