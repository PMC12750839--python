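"""Simplex arithmetic and ILR machinery."""

import numpy as np
import pytest
from scipy.stats import gmean

from coda24.coda import (
    CANONICAL_PARTS,
    Composition,
    IlrBasis,
    ZeroPartError,
    aitchison_distance,
    close,
    geometric_mean_composition,
    ilr_inverse,
    ilr_pivot,
    perturb,
    rotate_basis,
    variation_matrix,
)


class TestClosure:
    def test_study_centre_shares(self):
        """Closing the study's geometric-mean minutes to 100 gives its printed shares."""
        c = close([473.0, 680.9, 250.7, 35.3], 100)
        assert np.round(c.values, 1).tolist() == [32.8, 47.3, 17.4, 2.5]

    def test_symmetry_and_exact_ratios(self):
        assert np.allclose(close([1, 1, 1, 1], 1).values, 0.25)
        assert np.allclose(close([2, 1, 1, 1], 1440).values, [576, 288, 288, 288])

    def test_ratios_preserved(self):
        c = close([473.0, 680.9, 250.7, 35.3], 100)
        assert np.isclose(c.values[1] / c.values[3], 680.9 / 35.3)
        assert np.isclose(c.values.sum(), 100)

    def test_zero_part_error_names_the_part(self):
        with pytest.raises(ZeroPartError, match="lpa"):
            close([480, 700, 0, 40])
        with pytest.raises(ZeroPartError, match="mvpa"):
            close([480, 700, 200, -3])

    def test_reclose_changes_constant_not_ratios(self):
        c = close([473.0, 680.9, 250.7, 35.3])
        c100 = c.reclose(100)
        assert np.isclose(c100.values.sum(), 100)
        assert np.allclose(c100.values / c100.values[0], c.values / c.values[0])


class TestGeometricMean:
    def test_idempotent_on_identical_sample(self):
        x = close([470, 680, 250, 40])
        gm = geometric_mean_composition([x] * 7)
        assert np.allclose(gm.values, x.values)

    def test_handcomputed_two_samples(self):
        # part-wise gm of (4,1,1,1) and (1,4,1,1) is (2,2,1,1) before closure
        a = close([4, 1, 1, 1], 1440)
        b = close([1, 4, 1, 1], 1440)
        gm = geometric_mean_composition([a, b])
        assert np.allclose(gm.values / gm.values[2], [2, 2, 1, 1])

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            geometric_mean_composition([])

    def test_matches_partwise_gmean(self, random_compositions):
        sample = random_compositions[:50]
        gm = geometric_mean_composition(sample)
        raw = gmean([c.values for c in sample], axis=0)
        assert np.allclose(gm.values, raw * 1440 / raw.sum())


class TestVariationMatrix:
    def test_identical_sample_gives_zero(self):
        x = close([470, 680, 250, 40])
        vm = variation_matrix([x] * 5)
        assert np.allclose(vm.entries, 0)

    def test_two_part_hand_variance(self):
        # ln-ratios are {0, 2}: sample variance (n-1 denominator) = 2.0
        a = Composition(("a", "b"), np.array([1.0, 1.0]), 1.0)
        b = Composition(("a", "b"), np.array([np.e**2, 1.0]), 1.0)
        vm = variation_matrix([a, b])
        assert np.isclose(vm[("a", "b")], 2.0)
        assert np.allclose(np.diag(vm.entries), 0)

    def test_symmetric_nonneg_perturbation_invariant(self, random_compositions):
        sample = random_compositions[:40]
        vm = variation_matrix(sample)
        assert np.allclose(vm.entries, vm.entries.T)
        assert (vm.entries >= 0).all()
        p = close([300, 300, 700, 140])
        vm2 = variation_matrix([perturb(c, p) for c in sample])
        assert np.allclose(vm.entries, vm2.entries, atol=1e-10)

    def test_matches_bruteforce_pairwise(self, random_compositions):
        sample = random_compositions[:30]
        vm = variation_matrix(sample)
        logs = np.log([c.values for c in sample])
        for i in range(4):
            for j in range(4):
                expected = np.var(logs[:, i] - logs[:, j], ddof=1)
                assert np.isclose(vm.entries[i, j], expected)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            variation_matrix([close([470, 680, 250, 40])])


def _pivot_oracle(values, order_idx):
    """Scalar pivot-coordinate formula, computed part by part with gmean."""
    v = np.asarray(values, float)[list(order_idx)]
    D = len(v)
    return np.array(
        [
            np.sqrt((D - k) / (D - k + 1)) * np.log(v[k - 1] / gmean(v[k:]))
            for k in range(1, D)
        ]
    )


class TestIlr:
    def test_neutral_element(self):
        z = ilr_pivot(close([1, 1, 1, 1], 1))
        assert np.allclose(z.z, 0)

    def test_two_part_formula_collapse(self):
        x = Composition(("a", "b"), np.array([np.e, 1.0]), 1.0)
        z = ilr_pivot(x, IlrBasis(("a", "b")))
        assert np.isclose(z.z[0], np.sqrt(0.5))

    def test_agrees_with_scalar_oracle(self, random_compositions):
        basis = IlrBasis(CANONICAL_PARTS)
        worst = 0.0
        for c in random_compositions:
            z = ilr_pivot(c, basis).z
            expected = _pivot_oracle(c.values, range(4))
            worst = max(worst, np.abs(z - expected).max())
        assert worst < 1e-10

    def test_agrees_with_qr_constructed_contrast(self, random_compositions):
        """Orthonormalising the raw pivot contrasts reproduces the basis."""
        D = 4
        W = np.zeros((D, D - 1))
        for k in range(D - 1):
            W[k, k] = 1.0
            W[k + 1 :, k] = -1.0 / (D - 1 - k)
        Q, R = np.linalg.qr(W)
        Q = Q * np.sign(np.diag(R))  # fix sign so the pivot part loads positively
        V = IlrBasis(CANONICAL_PARTS).contrast_matrix(CANONICAL_PARTS)
        assert np.allclose(Q, V, atol=1e-12)
        for c in random_compositions[:100]:
            assert np.allclose(Q.T @ np.log(c.values), ilr_pivot(c).z, atol=1e-10)

    def test_closure_invariance(self, random_compositions):
        for c in random_compositions[:100]:
            for const in (1.0, 100.0, 1440.0):
                z = ilr_pivot(c.reclose(const))
                assert np.allclose(z.z, ilr_pivot(c).z, atol=1e-10)

    def test_positive_first_coordinate_means_large_pivot(self):
        big_lpa = close([400, 500, 500, 40])
        small_lpa = close([500, 600, 100, 240])
        basis = rotate_basis(CANONICAL_PARTS, "lpa")
        assert ilr_pivot(big_lpa, basis).z[0] > ilr_pivot(small_lpa, basis).z[0]

    def test_contrast_matrix_is_orthonormal_zero_sum(self):
        for pivot in CANONICAL_PARTS:
            V = rotate_basis(CANONICAL_PARTS, pivot).contrast_matrix(CANONICAL_PARTS)
            assert np.allclose(V.T @ V, np.eye(3), atol=1e-12)
            assert np.allclose(V.sum(axis=0), 0, atol=1e-12)


class TestIlrInverse:
    def test_zero_maps_to_equal_parts(self):
        c = ilr_inverse(np.zeros(3), 1440, basis=IlrBasis(CANONICAL_PARTS))
        assert np.allclose(c.values, 360)

    def test_roundtrip_on_random_compositions(self, random_compositions):
        basis = IlrBasis(CANONICAL_PARTS)
        worst = 0.0
        for c in random_compositions:
            back = ilr_inverse(ilr_pivot(c, basis))
            worst = max(worst, np.abs(back.values - c.values).max())
        assert worst < 1e-9

    def test_two_part_inverse(self):
        basis = IlrBasis(("a", "b"))
        c = ilr_inverse(np.array([np.sqrt(0.5)]), 1.0, basis=basis)
        assert np.isclose(c.values[0] / c.values[1], np.e)

    def test_cross_basis_roundtrip(self, random_compositions):
        """Coordinates in one basis, recovered, re-expressed in another, round-trip."""
        b1 = rotate_basis(CANONICAL_PARTS, "lpa")
        b2 = rotate_basis(CANONICAL_PARTS, "mvpa")
        for c in random_compositions[:50]:
            x1 = ilr_inverse(ilr_pivot(c, b1), parts=CANONICAL_PARTS)
            z2 = ilr_pivot(x1, b2)
            back = ilr_inverse(z2, parts=CANONICAL_PARTS)
            assert np.allclose(back.values, c.values, atol=1e-9)


class TestRotation:
    def test_lpa_pivot_order(self):
        basis = rotate_basis(CANONICAL_PARTS, "lpa")
        assert basis.pivot_order == ("lpa", "sleep", "sed", "mvpa")

    def test_sleep_pivot_is_canonical(self):
        assert rotate_basis(CANONICAL_PARTS, "sleep").pivot_order == CANONICAL_PARTS

    def test_four_distinct_bases_isolate_each_part(self):
        bases = [rotate_basis(CANONICAL_PARTS, p) for p in CANONICAL_PARTS]
        assert len({b.pivot_order for b in bases}) == 4
        assert [b.pivot for b in bases] == list(CANONICAL_PARTS)

    def test_unknown_pivot_errors(self):
        with pytest.raises(ValueError, match="unknown pivot"):
            rotate_basis(CANONICAL_PARTS, "screen_time")


class TestAitchisonDistance:
    def test_self_distance_zero(self, random_compositions):
        assert aitchison_distance(random_compositions[0], random_compositions[0]) == 0

    def test_invariant_across_rotations(self, random_compositions):
        pairs = zip(random_compositions[:100], random_compositions[100:200])
        for x, y in pairs:
            ds = []
            for pivot in CANONICAL_PARTS:
                b = rotate_basis(CANONICAL_PARTS, pivot)
                ds.append(np.linalg.norm(ilr_pivot(x, b).z - ilr_pivot(y, b).z))
            assert max(ds) - min(ds) < 1e-10
            assert np.isclose(aitchison_distance(x, y), ds[0], atol=1e-10)

    def test_translation_invariance_under_perturbation(self, random_compositions):
        p = close([200, 400, 600, 240])
        for x, y in zip(random_compositions[:30], random_compositions[30:60]):
            d0 = aitchison_distance(x, y)
            d1 = aitchison_distance(perturb(x, p), perturb(y, p))
            assert np.isclose(d0, d1, atol=1e-10)

    def test_part_mismatch_errors(self):
        x = close([470, 680, 250, 40])
        y = Composition(("a", "b", "c", "d"), np.array([470.0, 680, 250, 40]))
        with pytest.raises(ValueError):
            aitchison_distance(x, y)
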