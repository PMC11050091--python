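"""Allele ratio, EM dosage calling, diploid collapse, marker subsetting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from tetrags import (
    FilterConfig,
    GenotypeMatrix,
    ReadCountMatrix,
    SimConfig,
    allele_ratio,
    call_tetraploid_dosage,
    collapse_diploid,
    make_annotation,
    simulate_population,
    subset_markers,
)
from tetrags.parametrization import (
    call_dosage_unfiltered,
    masked_allele_ratio,
    missing_filter,
    read_genotype_csv,
    write_genotype_csv,
)
from tetrags.synthetic_data import dosage_to_alt_fraction


def _rc(ref, alt, samples=None, loci=None):
    ref = np.atleast_2d(ref)
    samples = samples or [f"s{i}" for i in range(ref.shape[0])]
    loci = loci or [f"l{j}" for j in range(ref.shape[1])]
    return ReadCountMatrix(samples, loci, ref, np.atleast_2d(alt))


class TestAlleleRatio:
    def test_cell_values_and_depth_mask(self):
        rc = _rc([[9], [0], [25]], [[3], [25], [0]])
        vals = masked_allele_ratio(rc, 10)
        assert vals[0, 0] == pytest.approx(0.25)  # 3 / 12
        assert vals[1, 0] == 1.0 and vals[2, 0] == 0.0
        vals20 = masked_allele_ratio(rc, 20)
        assert np.isnan(vals20[0, 0])  # 12 reads < 20

    def test_missing_rate_filter_drops_markers(self):
        ref = np.array([[9, 9], [9, 1], [9, 1]])
        alt = np.array([[3, 3], [3, 1], [3, 1]])
        rc = _rc(ref, alt)
        g = allele_ratio(rc, FilterConfig(min_reads=10, max_missing=0.10))
        assert g.markers == ["l0"]  # second marker 2/3 missing
        g2 = allele_ratio(rc, FilterConfig(min_reads=10, max_missing=0.70))
        assert g2.markers == ["l0", "l1"]

    def test_empty_result_is_error(self):
        rc = _rc([[1]], [[1]])
        with pytest.raises(ValueError):
            allele_ratio(rc, FilterConfig(min_reads=10, max_missing=0.05))


class TestDosageCalling:
    def test_high_depth_calls_match_rounded_ratio(self):
        cfg = SimConfig(n_genotypes=40, n_loci=60, n_qtl=10, seed=17,
                        mean_depth=400.0, depth_dispersion=20.0,
                        bias_log_sd=0.0, seq_error=0.001,
                        missing_cell_rate=0.0)
        gt, rc, _ = simulate_population(cfg)
        f = FilterConfig(min_reads=10, max_missing=0.5)
        g, _ = call_tetraploid_dosage(rc, f)
        tot = rc.total_depth
        for j, m in enumerate(g.markers):
            col = rc.loci.index(m)
            called = ~np.isnan(g.values[:, j])
            expect = np.round(4.0 * rc.alt_depth[called, col] / tot[called, col])
            assert (g.values[called, j] == expect).all()

    def test_bias_filter_rejects_distorted_loci(self, rng):
        # half the loci carry a detection bias of e^1.5, outside [e^-1, e]
        n_s, n_l, depth = 40, 30, 200
        dos = rng.binomial(4, 0.4, size=(n_s, n_l))
        bias = np.where(np.arange(n_l) < 15, math.e ** 1.5, 1.0)
        xi = dosage_to_alt_fraction(dos, bias[None, :], 0.002)
        tot = np.full((n_s, n_l), depth)
        alt = rng.binomial(tot, xi)
        rc = _rc(tot - alt, alt)
        _, keep, bias_hat = call_dosage_unfiltered(rc, 10, FilterConfig())
        assert not keep[:15].any()   # biased loci all rejected
        assert keep[15:].mean() > 0.8
        assert np.nanmedian(bias_hat[:15]) > math.e

    def test_annotation_gains_bias_estimates(self, pop50):
        _, _, rc, ann = pop50
        g, ann2 = call_tetraploid_dosage(rc, FilterConfig(max_missing=0.5), ann)
        assert np.isfinite(ann2.loc[g.markers, "bias"]).all()

    def test_dosage_markers_subset_of_ratio_markers(self, pop50):
        _, _, rc, _ = pop50
        f = FilterConfig(min_reads=20, max_missing=0.2)
        ratio = allele_ratio(rc, f)
        tetra, _ = call_tetraploid_dosage(rc, f)
        assert set(tetra.markers) <= set(ratio.markers)


class TestDiploidCollapse:
    def test_heterozygote_classes_collapse_to_one(self):
        vals = np.array([[0.0, 1, 2, 3, 4, np.nan]])
        g = GenotypeMatrix(vals, ["s"], [f"m{i}" for i in range(6)],
                           "tetraploid")
        d = collapse_diploid(g)
        assert d.parametrization == "diploid"
        np.testing.assert_array_equal(d.values[0, :5], [0, 1, 1, 1, 2])
        assert np.isnan(d.values[0, 5])

    def test_marker_set_unchanged_including_all_missing_columns(self):
        vals = np.array([[0.0, np.nan], [4.0, np.nan]])
        g = GenotypeMatrix(vals, ["a", "b"], ["m1", "m2"], "tetraploid")
        d = collapse_diploid(g)
        assert d.markers == g.markers
        assert np.isnan(d.values[:, 1]).all()

    def test_rejects_non_tetraploid_input(self):
        g = GenotypeMatrix(np.array([[0.5]]), ["a"], ["m"], "ratio")
        with pytest.raises(ValueError):
            collapse_diploid(g)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (4, 6),
                      elements=st.sampled_from([0.0, 1.0, 2.0, 3.0, 4.0])))
    def test_collapse_maps_into_diploid_range(self, vals):
        g = GenotypeMatrix(vals, list("abcd"),
                           [f"m{i}" for i in range(6)], "tetraploid")
        d = collapse_diploid(g)
        assert set(np.unique(d.values)) <= {0.0, 1.0, 2.0}
        # homozygotes keep their identity, heterozygotes merge
        assert ((vals == 0) == (d.values == 0)).all()
        assert ((vals == 4) == (d.values == 2)).all()


class TestSubsetting:
    def test_all_is_identity_and_partition_holds(self, pop50):
        _, _, rc, ann = pop50
        g = allele_ratio(rc, FilterConfig(max_missing=0.5))
        assert subset_markers(g, ann, "all") is g
        genic = subset_markers(g, ann, "genic")
        non = subset_markers(g, ann, "non_genic")
        assert genic.n_markers + non.n_markers == g.n_markers
        assert set(genic.markers).isdisjoint(non.markers)

    def test_empty_subset_raises_naming_mode(self):
        ann = make_annotation(["m1"], "chr1", [1], genic=True)
        g = GenotypeMatrix(np.array([[0.5], [0.2]]), ["a", "b"], ["m1"],
                           "ratio")
        with pytest.raises(ValueError, match="non_genic"):
            subset_markers(g, ann, "non_genic")
        with pytest.raises(ValueError):
            subset_markers(g, ann, "weird")


def test_genotype_matrix_value_ranges_enforced():
    with pytest.raises(ValueError):
        GenotypeMatrix(np.array([[1.2]]), ["a"], ["m"], "ratio")
    with pytest.raises(ValueError):
        GenotypeMatrix(np.array([[2.5]]), ["a"], ["m"], "tetraploid")
    with pytest.raises(ValueError):
        GenotypeMatrix(np.array([[3.0]]), ["a"], ["m"], "diploid")


def test_genotype_csv_round_trip(pop50, tmp_path):
    _, _, rc, _ = pop50
    g = allele_ratio(rc, FilterConfig())
    path = tmp_path / "ratio.csv"
    write_genotype_csv(g, path)
    g2 = read_genotype_csv(path)
    assert g2.parametrization == "ratio"
    assert g2.markers == g.markers and g2.samples == g.samples
    np.testing.assert_allclose(g2.values, g.values, atol=1e-12)
    assert g2.filter.min_reads == g.filter.min_reads


def test_missing_filter_monotone_in_threshold(rng):
    vals = rng.random((30, 50))
    vals[rng.random((30, 50)) < 0.3] = np.nan
    kept = [missing_filter(vals, mm)[1].sum() for mm in (0.05, 0.1, 0.2, 0.5)]
    assert kept == sorted(kept)
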