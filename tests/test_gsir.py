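"""GSIR tests: surface sampling, cross-field constraints, recovery, and
the dense-grid oracle comparison."""

import numpy as np
import pytest

from rdsearch.gsir import (
    GsirConfig,
    SamplingBounds,
    _chi2_batch,
    apply_field_constraints,
    gsir_run,
    sample_surface,
    summarize_gsir,
)
from rdsearch.models import ThreeStateParams, chi2_total
from rdsearch.synthetic import GSIR_REFERENCE, GeneratorSpec, generate_dataset
from rdsearch.two_state import fit_two_state_individual


def _bounds_for(ds, **kw):
    fit = fit_two_state_individual(ds)
    return SamplingBounds.from_two_state(fit, **kw)


class TestSampleSurface:
    def test_collapsed_bounds_return_exact_point(self, one_residue):
        ds, truth = one_residue
        b = SamplingBounds(
            r20_center={800.0: truth.r20, 900.0: truth.r20}, r20_halfwidth=0.0,
            kex_range=(truth.kex, truth.kex), kzb_range=(truth.kzb, truth.kzb),
            dw_fc_range=(truth.dw_fc, truth.dw_fc),
            dw_bz_range=(truth.dw_bz, truth.dw_bz))
        t = sample_surface(ds, b, n_draws=1, seed=0)
        assert t["kex"][0] == truth.kex
        expected = chi2_total({ds.residue_id: truth}, [ds])
        assert t["chi2"][0] == pytest.approx(expected, abs=1e-12)

    def test_same_seed_identical_table(self, one_residue):
        ds, truth = one_residue
        b = _bounds_for(ds)
        a = sample_surface(ds, b, 500, seed=42)
        c = sample_surface(ds, b, 500, seed=42)
        for k in a:
            assert np.array_equal(a[k], c[k])

    def test_minimum_improves_with_draw_count(self, one_residue):
        """Monte-Carlo coverage: the best sampled chi^2 shrinks (on
        average over seeds) as the number of draws grows."""
        ds, _ = one_residue
        b = _bounds_for(ds)
        means = []
        for n in (100, 1000, 10000):
            mins = [sample_surface(ds, b, n, seed=s)["chi2"].min()
                    for s in range(5)]
            means.append(np.mean(mins))
        assert means[0] > means[1] > means[2]


class TestFieldConstraints:
    def test_identity_and_proportional_scaling(self):
        p = ThreeStateParams(r20=1.0, kex=500.0, dw_fc=400.0, kzb=5.0, dw_bz=800.0)
        assert apply_field_constraints(p, 800.0, 800.0) == p
        q = apply_field_constraints(p, 900.0, 800.0)
        assert q.dw_fc == pytest.approx(450.0)
        assert q.dw_bz == pytest.approx(900.0)
        assert (q.kex, q.kzb, q.r20) == (p.kex, p.kzb, p.r20)

    def test_round_trip_machine_precision(self):
        p = ThreeStateParams(r20=1.0, kex=500.0, dw_fc=123.456, kzb=5.0, dw_bz=789.1)
        rt = apply_field_constraints(apply_field_constraints(p, 900.0, 800.0), 800.0, 900.0)
        assert rt.dw_fc == pytest.approx(p.dw_fc, rel=1e-15)
        assert rt.dw_bz == pytest.approx(p.dw_bz, rel=1e-15)


class TestGsirRun:
    def test_noise_free_multi_field_recovery(self, one_residue):
        ds, truth = one_residue
        res = gsir_run(ds, _bounds_for(ds), GsirConfig(n_draws=50_000, seed=3))
        for name in ("kex", "kzb", "dw_fc", "dw_bz"):
            assert getattr(res.best, name) == pytest.approx(
                getattr(truth, name), rel=0.02), name
        assert res.best_chi2 == pytest.approx(0.0, abs=1e-12)

    def test_refinement_never_worse_than_raw_minimum(self, one_residue):
        ds, _ = one_residue
        res = gsir_run(ds, _bounds_for(ds), GsirConfig(n_draws=5_000, seed=1))
        assert res.best_chi2 <= res.raw_min_chi2 + 1e-12
        assert len(res.candidates) == 5
        assert res.best_chi2 <= min(c for _, c in res.candidates) + 1e-12

    def test_same_seed_bit_identical_result(self, one_residue):
        ds, _ = one_residue
        cfg = GsirConfig(n_draws=5_000, seed=9)
        a = gsir_run(ds, _bounds_for(ds), cfg)
        b = gsir_run(ds, _bounds_for(ds), cfg)
        assert a.best == b.best
        assert a.best_chi2 == b.best_chi2

    def test_excluding_truth_from_bounds_hurts(self, one_residue):
        """Constrained search (refinement clamped to the sampling box)
        cannot beat the unconstrained one when the box excludes truth."""
        from dataclasses import replace
        from rdsearch.gsir import RefineBounds
        ds, truth = one_residue
        good = _bounds_for(ds)
        bad = replace(good, kex_range=(1.0, truth.kex * 0.3))
        cfg_bad = GsirConfig(n_draws=20_000, seed=4,
                             refine=RefineBounds(kex=(1.0, truth.kex * 0.3)))
        cfg_good = GsirConfig(n_draws=20_000, seed=4)
        res_bad = gsir_run(ds, bad, cfg_bad)
        res_good = gsir_run(ds, good, cfg_good)
        assert res_bad.best_chi2 > res_good.best_chi2 + 1.0

    def test_multi_field_requires_two_fields(self, one_residue):
        ds, _ = one_residue
        solo = type(ds)(ds.residue_id, [ds.profiles[0]])
        with pytest.raises(ValueError, match="multi_field"):
            gsir_run(solo, _bounds_for(ds), GsirConfig(n_draws=10))

    def test_minimum_matches_dense_grid_on_2d_slice(self, one_residue):
        """With the other parameters pinned at truth, the search minimum
        over (kex, dw_bz) lands within one cell of a 500x500 grid scan."""
        ds, truth = one_residue
        res = gsir_run(ds, _bounds_for(ds), GsirConfig(n_draws=50_000, seed=3))
        kex_grid = np.linspace(600.0, 1200.0, 500)
        bz_grid = np.linspace(1000.0, 1800.0, 500)
        kk, zz = np.meshgrid(kex_grid, bz_grid, indexing="ij")
        n = kk.size
        chi2 = _chi2_batch(
            ds.profiles,
            np.full((n, 2), truth.r20), kk.ravel(), np.full(n, truth.kzb),
            np.full(n, truth.dw_fc), zz.ravel(), GsirConfig())
        i = np.unravel_index(np.argmin(chi2.reshape(kk.shape)), kk.shape)
        assert abs(res.best.kex - kex_grid[i[0]]) <= np.diff(kex_grid)[0]
        assert abs(res.best.dw_bz - bz_grid[i[1]]) <= np.diff(bz_grid)[0]


def test_single_field_estimates_disagree_more_than_joint_fit_errs():
    """The cross-field inconsistency of single-field searches: on noisy
    data the 800-vs-900 MHz kex estimates differ from each other by more
    (averaged over noise seeds) than the joint multi-field estimate
    differs from truth."""
    truth = ThreeStateParams(r20=2.0, kex=885.0, dw_fc=388.0, kzb=9.29, dw_bz=1440.0)
    gap_single, err_multi = [], []
    for s in range(10):
        spec = GeneratorSpec(residues={"Y": truth}, noise_sd=0.5, seed=100 + s)
        ds = generate_dataset(spec)[0][0]
        b = _bounds_for(ds)
        k800 = gsir_run(ds, b, GsirConfig(mode="single_field", field_mhz=800.0,
                                          n_draws=20_000, seed=s)).best.kex
        k900 = gsir_run(ds, b, GsirConfig(mode="single_field", field_mhz=900.0,
                                          n_draws=20_000, seed=s)).best.kex
        kmulti = gsir_run(ds, b, GsirConfig(n_draws=20_000, seed=s)).best.kex
        gap_single.append(abs(k800 - k900))
        err_multi.append(abs(kmulti - truth.kex))
    assert np.mean(gap_single) > np.mean(err_multi)


class TestSummary:
    def _result(self, rid, kex, kzb):
        from rdsearch.gsir import SearchResult
        p = ThreeStateParams(r20=0.0, kex=kex, kzb=kzb, dw_fc=100.0, dw_bz=500.0)
        return SearchResult(residue_id=rid, best=p, best_r20_by_field={},
                            best_chi2=0.0, candidates=[(p, 0.0)], raw_min_chi2=0.0,
                            provenance={})

    def test_closed_form_mean_and_sd(self):
        s = summarize_gsir([self._result("a", 600.0, 5.0),
                            self._result("b", 700.0, 5.0)])
        assert s.kex_mean == pytest.approx(650.0)
        assert s.kex_sd == pytest.approx(70.7107, rel=1e-4)
        assert s.kzb_sd == 0.0

    def test_outlier_exclusion(self):
        rs = [self._result("a", 600.0, 8.0), self._result("b", 700.0, 9.0),
              self._result("outlier", 650.0, 200.0)]
        s = summarize_gsir(rs, exclude=["outlier"])
        assert s.kzb_mean == pytest.approx(8.5)
        assert "outlier" in s.per_residue  # stays in the table
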