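import numpy as np
import pytest

from crossgrm import (
    AUTOSOMAL,
    X,
    Pedigree,
    PedigreeRecord,
    Sex,
    expected_founder_matrix,
    extend_autosomal,
    extend_x,
    f2_reference_summary,
    gamete_self,
    gametic_moments,
    line_composition,
    make_fixture,
)
from crossgrm.errors import NotTwoLinesError
from crossgrm.fixtures import FixtureSpec, LineSpec
from test_moments import freqs_from_p


def cross_pedigree():
    """A-male × B-female, two F1, one F2 pair child."""
    return Pedigree([
        PedigreeRecord("AM", None, None, Sex.MALE, "A"),
        PedigreeRecord("BF", None, None, Sex.FEMALE, "B"),
        PedigreeRecord("F1M", "AM", "BF", Sex.MALE),
        PedigreeRecord("F1F", "AM", "BF", Sex.FEMALE),
        PedigreeRecord("F2F", "F1M", "F1F", Sex.FEMALE),
        PedigreeRecord("F2M", "F1M", "F1F", Sex.MALE),
    ])


@pytest.fixture(scope="module")
def random_two_line():
    rng = np.random.default_rng(19)
    p = rng.uniform(0.05, 0.95, size=(2, 50))
    freqs = freqs_from_p(p, p_x=rng.uniform(0.05, 0.95, size=(2, 25)))
    return freqs


def build(freqs, partition, ped=None):
    ped = ped or cross_pedigree()
    mom = gametic_moments(freqs, partition)
    lc = line_composition(ped)
    e0 = expected_founder_matrix(ped, mom, partition)
    fn = extend_autosomal if partition == AUTOSOMAL else extend_x
    return ped, mom, lc, fn(ped, e0, mom, lc)


class TestAutosomal:
    def test_f1_self_is_dA_plus_dB_plus_2rAB(self, random_two_line):
        ped, mom, lc, m = build(random_two_line, AUTOSOMAL)
        expected = mom.d.sum() + 2 * mom.r[0, 1]
        assert m.dense()[2, 2] == pytest.approx(expected, abs=1e-12)

    def test_inbred_cross_f1_self_is_zero(self):
        freqs = freqs_from_p(np.vstack([np.ones(8), np.zeros(8)]))
        ped, mom, lc, m = build(freqs, AUTOSOMAL)
        assert m.dense()[2, 2] == pytest.approx(0.0, abs=1e-14)

    def test_f2_self_is_one_plus_half_parent_relationship(self, random_two_line):
        ped, mom, lc, m = build(random_two_line, AUTOSOMAL)
        v = m.dense()
        assert v[4, 4] == pytest.approx(1 + 0.5 * v[2, 3], abs=1e-12)

    def test_f1_to_founder_is_parent_average(self, random_two_line):
        ped, mom, lc, m = build(random_two_line, AUTOSOMAL)
        v = m.dense()
        assert v[2, 0] == pytest.approx(0.5 * (v[0, 0] + v[1, 0]), abs=1e-12)

    def test_gamete_self_constant_half_from_f1_onward(self):
        """Two-line uniform cross: every crossbred's transmitted gamete has
        composition (½, ½), so its self-relationship is ½(d_A + d_B) = 0.5
        in every generation (the F2-onward constancy claim)."""
        ped, _, truth = make_fixture(FixtureSpec(
            lines=[LineSpec("A", 2, 2, ("uniform",)),
                   LineSpec("B", 2, 2, ("uniform",))],
            n_autosomal=40, n_x=10, template="ail", generations=5,
            litter_size=4, seed=2))
        mom = gametic_moments(truth, AUTOSOMAL)
        s = gamete_self(ped, mom, line_composition(ped))
        np.testing.assert_allclose(s.values[ped.generations >= 1], 0.5, atol=1e-12)


class TestX:
    def test_f1_female_self_inbred_cross(self):
        freqs = freqs_from_p(np.vstack([np.ones(8), np.zeros(8)]))
        ped, mom, lc, m = build(freqs, X)
        # s_sire + s_dam + g(sire,dam) = 0.5 + 0.5 + 2r_AB = 0
        assert m.dense()[3, 3] == pytest.approx(0.0, abs=1e-14)

    def test_f1_male_self_is_dam_gamete_self(self, random_two_line):
        ped, mom, lc, m = build(random_two_line, X)
        assert m.dense()[2, 2] == pytest.approx(mom.d[1], abs=1e-12)

    def test_f1_female_off_diagonal_uses_full_sire_term(self, random_two_line):
        ped, mom, lc, m = build(random_two_line, X)
        v = m.dense()
        # F1F vs founder AM: g(sire,AM) + ½g(dam,AM)
        assert v[3, 0] == pytest.approx(v[0, 0] + 0.5 * v[1, 0], abs=1e-12)

    def test_male_off_diagonal_is_half_dam_term(self, random_two_line):
        ped, mom, lc, m = build(random_two_line, X)
        v = m.dense()
        assert v[2, 0] == pytest.approx(0.5 * v[1, 0], abs=1e-12)

    def test_identical_lines_give_constant_half_gamete_self(self):
        """When both lines share one frequency vector the founder male and
        female X pools coincide and the recursion reduces to the classical
        rules: every transmitted gamete has self-relationship 0.5."""
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, size=(1, 30))
        freqs = freqs_from_p(np.vstack([p, p]), p_x=np.vstack([p, p]))
        ped, _, _ = make_fixture(FixtureSpec(
            lines=[LineSpec("A", 2, 2, ("uniform",)),
                   LineSpec("B", 2, 2, ("uniform",))],
            n_autosomal=10, n_x=10, template="ail", generations=6,
            litter_size=4, seed=5))
        mom = gametic_moments(freqs, X)
        s = gamete_self(ped, mom, line_composition(ped))
        np.testing.assert_allclose(s.values, 0.5, atol=1e-12)

    def test_x_diagonal_generation_means_oscillate(self, random_two_line):
        ped, _, _ = make_fixture(FixtureSpec(
            lines=[LineSpec("A", 4, 0, ("uniform",)),
                   LineSpec("B", 0, 4, ("uniform",))],
            n_autosomal=10, n_x=10, template="ail", generations=7,
            litter_size=4, seed=9))
        mom = gametic_moments(random_two_line, X)
        lc = line_composition(ped)
        e0 = expected_founder_matrix(ped, mom, X)
        m = extend_x(ped, e0, mom, lc)
        diag = np.diag(m.dense())
        male = np.array([s is Sex.MALE for s in ped.sexes])
        means = np.array([
            diag[(ped.generations == g) & male].mean() for g in range(1, 8)
        ])
        deltas = np.diff(means)
        assert np.all(np.sign(deltas[:-1]) == -np.sign(deltas[1:]))
        assert np.all(np.abs(deltas[1:]) < np.abs(deltas[:-1]))


class TestStructure:
    @pytest.mark.parametrize("partition", [AUTOSOMAL, X])
    def test_founder_block_equals_seed_bitwise_and_symmetry(
        self, polymorphic_objects, partition
    ):
        ped, g, freqs, lc, moms = polymorphic_objects
        mom = moms[partition]
        e0 = expected_founder_matrix(ped, mom, partition)
        fn = extend_autosomal if partition == AUTOSOMAL else extend_x
        m = fn(ped, e0, mom, lc)
        F = ped.n_founders
        np.testing.assert_array_equal(m.dense()[:F, :F], e0.dense())
        v = m.dense()
        np.testing.assert_array_equal(v, v.T)

    def test_chunked_store_matches_in_memory(self, tmp_path, polymorphic_objects):
        ped, g, freqs, lc, moms = polymorphic_objects
        mom = moms[AUTOSOMAL]
        e0 = expected_founder_matrix(ped, mom, AUTOSOMAL)
        dense = extend_autosomal(ped, e0, mom, lc)
        stored = extend_autosomal(ped, e0, mom, lc, store=tmp_path / "a.h5")
        np.testing.assert_array_equal(stored.dense(), dense.dense())

    def test_non_inbred_diagonal_is_sum_of_gamete_selfs(self, polymorphic_objects):
        ped, g, freqs, lc, moms = polymorphic_objects
        mom = moms[AUTOSOMAL]
        e0 = expected_founder_matrix(ped, mom, AUTOSOMAL)
        m = extend_autosomal(ped, e0, mom, lc).dense()
        s = gamete_self(ped, mom, lc).values
        for k in np.where(~ped.is_founder)[0]:
            a, b = ped.sire_idx[k], ped.dam_idx[k]
            assert m[k, k] == pytest.approx(
                s[a] + s[b] + 0.5 * m[a, b], abs=1e-12
            )


class TestF2Summary:
    def test_mean_self_one_and_pairwise_zero(self, random_two_line):
        mom = gametic_moments(random_two_line, AUTOSOMAL)
        s = f2_reference_summary(mom)
        assert s.mean_self == pytest.approx(1.0, abs=1e-12)
        assert s.mean_pairwise == pytest.approx(0.0, abs=1e-12)

    def test_inbred_cross_segregation_proportion_is_one(self):
        freqs = freqs_from_p(np.vstack([np.ones(6), np.zeros(6)]))
        s = f2_reference_summary(gametic_moments(freqs, AUTOSOMAL))
        assert s.segregation_proportion == 1.0

    def test_requires_two_lines(self):
        rng = np.random.default_rng(0)
        freqs = freqs_from_p(rng.uniform(0.2, 0.8, size=(3, 10)),
                             weights=np.ones(3) / 3)
        with pytest.raises(NotTwoLinesError):
            f2_reference_summary(gametic_moments(freqs, AUTOSOMAL))
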