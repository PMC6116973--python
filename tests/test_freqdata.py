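"""Data layer: parsers, missing-data filters, allelic covariance, distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spatialadmix import (FrequencyMatrix, allelic_covariance,
                          covariance_from_pi, filter_missing,
                          filter_singletons, pairwise_distances,
                          read_coordinates, read_frequencies,
                          write_frequencies)
from spatialadmix.freqdata import ParseError


# ---------------------------------------------------------------- parsing
class TestReadFrequencies:
    def test_delimited_frequencies_roundtrip(self, tmp_path):
        path = tmp_path / "f.csv"
        path.write_text("sample,l1,l2,l3\na,0.0,0.5,1.0\nb,0.25,NA,0.75\n")
        fm = read_frequencies(path)
        assert fm.sample_ids == ["a", "b"]
        assert fm.locus_ids == ["l1", "l2", "l3"]
        np.testing.assert_allclose(fm.frequencies[0], [0, 0.5, 1])
        assert fm.missing_mask[1, 1] and fm.missing_mask.sum() == 1

    def test_diploid_genotype_counts_become_frequencies(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("sample,l1,l2,l3\na,0,1,2\nb,2,2,0\n")
        fm = read_frequencies(path, ploidy=2)
        np.testing.assert_allclose(fm.frequencies[0], [0, 0.5, 1])
        np.testing.assert_allclose(fm.frequencies[1], [1, 1, 0])

    def test_short_row_is_a_parse_error_naming_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,l1,l2,l3\na,0.1,0.2,0.3\nb,0.1,0.2\n")
        with pytest.raises(Exception) as exc:
            read_frequencies(path)
        assert "3" in str(exc.value) or "b" in str(exc.value)

    def test_genotype_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample,l1\na,3\nb,1\n")
        with pytest.raises(ParseError):
            read_frequencies(path, ploidy=2)

    def test_structure_two_rows_per_diploid(self, tmp_path):
        # 3 individuals x 5 loci, two allele rows each; oracle: frequency of
        # the first-observed allele = mean of indicator over the two rows
        rows = [
            ("ind1", [1, 0, 1, 1, 0]), ("ind1", [1, 1, 0, 1, 0]),
            ("ind2", [0, 0, 1, 0, 1]), ("ind2", [1, 0, 0, 0, 1]),
            ("ind3", [0, 1, 1, 1, 0]), ("ind3", [0, 1, 0, 1, 1]),
        ]
        path = tmp_path / "str.txt"
        path.write_text("\n".join(
            name + " " + " ".join(map(str, alleles))
            for name, alleles in rows) + "\n")
        fm = read_frequencies(path, "structure-genotypes", ploidy=2)
        assert fm.n_samples == 3 and fm.n_loci == 5
        alleles = np.array([a for _, a in rows], dtype=float)
        ref = alleles[0]  # first row observed defines the reference allele
        expected = np.array([
            ((alleles[2 * i] == ref).astype(float)
             + (alleles[2 * i + 1] == ref)) / 2 for i in range(3)])
        np.testing.assert_allclose(fm.frequencies, expected)

    def test_structure_missing_code(self, tmp_path):
        path = tmp_path / "str.txt"
        path.write_text("i1 1 -9\ni1 0 -9\ni2 1 1\ni2 1 0\n")
        fm = read_frequencies(path, "structure-genotypes", ploidy=2)
        assert fm.missing_mask[0, 1] and not fm.missing_mask[1, 1]

    def test_write_then_read_roundtrip(self, tmp_path, haploid_fm):
        path = tmp_path / "rt.csv"
        write_frequencies(haploid_fm, path)
        back = read_frequencies(path)
        np.testing.assert_allclose(back.frequencies, haploid_fm.frequencies)

    def test_read_coordinates_matches_by_id(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("sample_id,x,y\nb,1.0,2.0\na,0.0,0.0\n")
        xy = read_coordinates(path, sample_ids=["a", "b"])
        np.testing.assert_allclose(xy, [[0, 0], [1, 2]])


# ---------------------------------------------------------------- filtering
class TestFilterMissing:
    def test_drop_any_missing_locus(self):
        f = np.full((3, 4), 0.5)
        f[1, 2] = np.nan
        fm = FrequencyMatrix(f)
        out, report = filter_missing(fm, "drop-any-missing")
        assert out.n_loci == 3
        assert report.n_loci_removed == 1

    def test_sample_threshold_is_strict(self):
        # 100 loci: one sample with 5% missing is dropped at threshold 0.04,
        # one with exactly 4% missing is kept (strict ">")
        f = np.full((3, 100), 0.5)
        f[0, :5] = np.nan
        f[1, :4] = np.nan
        fm = FrequencyMatrix(f)
        out, report = filter_missing(fm, "keep", sample_missing_threshold=0.04)
        assert out.n_samples == 2
        assert report.removed_sample_ids == ["sample_0"]

    def test_complete_matrix_unchanged(self, haploid_fm):
        out, report = filter_missing(haploid_fm, "drop-any-missing")
        np.testing.assert_array_equal(out.frequencies, haploid_fm.frequencies)
        assert report.n_loci_removed == 0 and report.n_samples_removed == 0

    def test_all_removed_raises(self):
        f = np.full((2, 2), np.nan)
        f[0, 0] = 0.5
        fm = FrequencyMatrix(f)
        with pytest.raises(ValueError):
            filter_missing(fm, "drop-any-missing")

    def test_singleton_filter(self):
        f = np.array([[0.0, 0.5, 0.0],
                      [0.0, 0.5, 0.0],
                      [0.0, 0.0, 0.5],
                      [1.0, 0.0, 0.5]])
        # locus 0: minor value 1.0 appears in exactly one sample -> singleton;
        # loci 1 and 2 have each value in two samples -> kept
        fm = FrequencyMatrix(f)
        out, report = filter_singletons(fm)
        assert report.n_loci_removed == 1
        assert out.locus_ids == ["locus_1", "locus_2"]


# ------------------------------------------------------ allelic covariance
class TestAllelicCovariance:
    def test_diagonal_is_exactly_one_quarter(self, haploid_fm):
        obs = allelic_covariance(haploid_fm)
        assert np.all(np.diag(obs.omega_hat) == 0.25)

    def test_half_frequencies_give_zero_off_diagonal(self):
        fm = FrequencyMatrix(np.full((2, 10), 0.5))
        obs = allelic_covariance(fm)
        assert obs.omega_hat[0, 1] == 0.0

    def test_hand_case_and_pi_crosscheck(self):
        # haploid L=4: f1=(1,1,0,0), f2=(1,1,1,0); per-locus products of the
        # centered values: (.25,.25,-.25,.25) -> mean 0.125; and pi = 1/4
        # mismatching sites gives (1-2/4)/4 = 0.125
        fm = FrequencyMatrix(np.array([[1, 1, 0, 0], [1, 1, 1, 0]], float))
        obs = allelic_covariance(fm)
        assert obs.omega_hat[0, 1] == pytest.approx(0.125)
        pi = np.array([[0, 0.25], [0.25, 0]])
        np.testing.assert_allclose(covariance_from_pi(pi).omega_hat,
                                   obs.omega_hat)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_haploid_matches_pi_formula(self, seed):
        # mismatch proportion pi and the covariance estimator agree exactly
        # on 0/1 data
        r = np.random.default_rng(seed)
        f = r.integers(0, 2, size=(4, 30)).astype(float)
        obs = allelic_covariance(FrequencyMatrix(f))
        pi = np.array([[np.mean(f[i] != f[j]) for j in range(4)]
                       for i in range(4)])
        np.testing.assert_allclose(obs.omega_hat,
                                   covariance_from_pi(pi).omega_hat,
                                   atol=1e-12)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_reference_allele_flip_invariance(self, seed):
        r = np.random.default_rng(seed)
        f = r.random((4, 20))
        flip = r.random(20) < 0.5
        g = np.where(flip, 1.0 - f, f)
        a = allelic_covariance(FrequencyMatrix(f)).omega_hat
        b = allelic_covariance(FrequencyMatrix(g)).omega_hat
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_pairwise_policy_uses_shared_loci(self):
        f = np.array([[1.0, 0.0, 1.0, np.nan],
                      [1.0, 1.0, np.nan, 0.0],
                      [0.0, 1.0, 1.0, 1.0]])
        fm = FrequencyMatrix(f)
        obs = allelic_covariance(fm, missing_policy="pairwise")
        # pair (0,1): shared loci 0,1 -> products (.25, -.25) -> 0
        assert obs.omega_hat[0, 1] == pytest.approx(0.0)
        assert obs.pair_loci[0, 1] == 2

    def test_pairwise_no_shared_loci_errors(self):
        f = np.array([[0.5, np.nan, 0.5],
                      [np.nan, 0.5, np.nan],
                      [0.5, 0.5, 0.5]])
        with pytest.raises(ValueError, match="share"):
            allelic_covariance(FrequencyMatrix(f), missing_policy="pairwise")

    def test_complete_case_requires_complete(self):
        f = np.array([[0.5, np.nan], [0.5, 0.5]])
        with pytest.raises(ValueError):
            allelic_covariance(FrequencyMatrix(f))


class TestCovarianceFromPi:
    @pytest.mark.parametrize("pi,expected", [(0.25, 0.125), (0.5, 0.0),
                                             (0.0, 0.25)])
    def test_known_values(self, pi, expected):
        m = np.array([[0.0, pi], [pi, 0.0]])
        out = covariance_from_pi(m)
        assert out.omega_hat[0, 1] == pytest.approx(expected)
        assert out.omega_hat[0, 0] == 0.25

    def test_domain_error(self):
        with pytest.raises(ValueError):
            covariance_from_pi(np.array([[0.0, 1.2], [1.2, 0.0]]))


# ---------------------------------------------------------------- distances
class TestPairwiseDistances:
    def test_euclidean_pythagoras(self):
        d = pairwise_distances(np.array([[0, 0], [3, 4]]), normalize=False)
        assert d.d[0, 1] == pytest.approx(5.0)

    def test_identical_coordinates_give_zero(self):
        d = pairwise_distances(np.array([[1, 1], [1, 1], [2, 2]]),
                               normalize=False)
        assert d.d[0, 1] == 0.0

    def test_great_circle_one_degree(self):
        # one degree of latitude at the equator with R = 6371 km
        d = pairwise_distances(np.array([[0, 0], [0, 1]]),
                               metric="great-circle", normalize=False)
        assert d.d[0, 1] == pytest.approx(6371 * np.pi / 180, rel=1e-6)

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            pairwise_distances(np.array([[0, 95], [0, 0]]),
                               metric="great-circle")

    def test_normalization_records_scale(self):
        coords = np.array([[0, 0], [0, 2], [0, 4]])
        d = pairwise_distances(coords, normalize=True)
        off = d.d[~np.eye(3, dtype=bool)]
        assert off.mean() == pytest.approx(1.0)
        np.testing.assert_allclose(d.d * d.scale_factor,
                                   pairwise_distances(coords,
                                                      normalize=False).d)
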