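import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nirtransfer as nt
from oracles import paired_t_oracle


@pytest.fixture(autouse=True)
def _quiet_size_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", nt.TransferSetSizeWarning)
        yield


class TestRMSEP:
    @pytest.mark.parametrize(
        "refs,preds,expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
            ([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], 1.0),
            ([0.0, 0.0, 0.0, 0.0], [1.0, -1.0, 1.0, -1.0], 1.0),
        ],
    )
    def test_known_values(self, refs, preds, expected):
        assert nt.rmsep(refs, preds) == pytest.approx(expected, abs=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(nt.ShapeError):
            nt.rmsep([1.0], [1.0, 2.0])

    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(3)
        r, p = rng.normal(size=8), rng.normal(size=8)
        idx = np.array(perm)
        assert nt.rmsep(r[idx], p[idx]) == pytest.approx(nt.rmsep(r, p))

    def test_scales_linearly_with_residuals(self, rng):
        r = rng.normal(size=20)
        resid = rng.normal(size=20)
        assert nt.rmsep(r, r + 3 * resid) == pytest.approx(
            3 * nt.rmsep(r, r + resid)
        )

    def test_report_recomputable(self, rng):
        refs, preds = rng.normal(size=10), rng.normal(size=10)
        rep = nt.EvaluationReport("x", refs, preds)
        manual = float(np.sqrt(np.mean((rep.predictions - rep.references) ** 2)))
        assert rep.rmsep == pytest.approx(manual, abs=1e-12)
        assert rep.n == 10


class TestPairedTTest:
    def test_identical_series(self):
        t, p = nt.paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference(self):
        t, p = nt.paired_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert p == 0.0
        assert t == -np.inf

    def test_matches_textbook_oracle_n42(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=42)
        b = a + rng.normal(0.1, 0.5, size=42)
        t, p = nt.paired_t_test(a, b)
        t_o, p_o = paired_t_oracle(a, b)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_antisymmetric(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        t1, p1 = nt.paired_t_test(a, b)
        t2, p2 = nt.paired_t_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_guards(self):
        with pytest.raises(nt.ShapeError):
            nt.paired_t_test([1.0, 2.0], [1.0])
        with pytest.raises(nt.ParameterError):
            nt.paired_t_test([1.0], [2.0])


class TestDifferenceSpectra:
    def test_identical_gives_zeros(self, small_set):
        d = nt.difference_spectra(small_set, small_set)
        np.testing.assert_array_equal(d.absorbance, 0.0)
        assert d.instrument_label == "difference"

    def test_constant_offset(self, small_set):
        import dataclasses

        shifted = small_set.with_absorbance(small_set.absorbance + 0.1)
        d = nt.difference_spectra(shifted, small_set)
        np.testing.assert_allclose(d.absorbance, 0.1, atol=1e-12)

    def test_axis_mismatch(self, small_set):
        other = nt.SpectrumSet(
            wavelengths=[1.0, 2.0, 3.0, 4.0], absorbance=small_set.absorbance
        )
        with pytest.raises(nt.ShapeError):
            nt.difference_spectra(small_set, other)

    def test_score_transfer_flatter_than_pds_in_interior(self, default_task):
        """On the bench/handheld task the score-space transfer's residual
        difference spectra stay below PDS's over the interior band."""
        task = default_task
        split = task.split
        tr_s = task.source.subset(split.transfer_idx)
        tr_t = task.target.subset(split.transfer_idx)
        val_s = task.source.subset(split.validation_idx)
        val_t = task.target.subset(split.validation_idx)
        m = nt.fit_ipca(tr_t, tr_s, 5)
        ipca_val = nt.apply_ipca(m, val_t)
        lo, hi = 1050.0, 1600.0
        d_ipca = nt.difference_spectra(
            nt.restrict_wavelengths(val_s, lo, hi),
            nt.restrict_wavelengths(ipca_val, lo, hi),
        )
        olo = max(task.source.wavelengths[0], task.target.wavelengths[0])
        ohi = min(task.source.wavelengths[-1], task.target.wavelengths[-1])
        src_o = nt.restrict_wavelengths(task.source, olo, ohi)
        tgt_o = nt.resample_to_axis(task.target, src_o.wavelengths)
        pm = nt.fit_pds(
            tgt_o.subset(split.transfer_idx),
            src_o.subset(split.transfer_idx),
            17,
            3,
        )
        pds_val = nt.apply_pds(pm, tgt_o.subset(split.validation_idx))
        d_pds = nt.difference_spectra(
            nt.restrict_wavelengths(src_o.subset(split.validation_idx), lo, hi),
            nt.restrict_wavelengths(pds_val, lo, hi),
        )
        assert (
            np.abs(d_ipca.absorbance).max() <= np.abs(d_pds.absorbance).max()
        )


class TestGridSearch:
    def test_single_cell_equals_direct_evaluation(self, task_subsets):
        ts = task_subsets
        surf = nt.grid_search(
            ts["cal_s"], (ts["tr_t"], ts["tr_s"]), ts["val_t"], [5], [3]
        )
        m = nt.fit_ipca(ts["tr_t"], ts["tr_s"], 5)
        transferred = nt.apply_ipca(m, ts["val_t"])
        pls = nt.fit_pls(ts["cal_s"], 3)
        direct = nt.rmsep(
            ts["val_t"].references, nt.predict(pls, transferred)
        )
        assert surf.rmsep_matrix[0, 0] == pytest.approx(direct, abs=1e-12)
        assert surf.best == (5, 3)

    def test_surface_drops_at_intrinsic_dimension(self, task_subsets):
        """Three chemical factors: nPC 1-2 cannot span the signal, nPC >= 3
        can — the surface must fall across that boundary."""
        ts = task_subsets
        surf = nt.grid_search(
            ts["cal_s"], (ts["tr_t"], ts["tr_s"]), ts["val_t"],
            range(1, 9), range(1, 7),
        )
        assert surf.rmsep_matrix[2:].min() < surf.rmsep_matrix[:2].min()

    def test_best_matches_bruteforce_reversed_order(self, task_subsets):
        ts = task_subsets
        pcs, lvs = [2, 4, 6], [2, 3]
        surf = nt.grid_search(
            ts["cal_s"], (ts["tr_t"], ts["tr_s"]), ts["val_t"], pcs, lvs
        )
        cells = {}
        for lv in reversed(lvs):  # independent loop order
            pls = nt.fit_pls(ts["cal_s"], lv)
            for pc in reversed(pcs):
                m = nt.fit_ipca(ts["tr_t"], ts["tr_s"], pc)
                preds = nt.predict(pls, nt.apply_ipca(m, ts["val_t"]))
                cells[(pc, lv)] = nt.rmsep(ts["val_t"].references, preds)
        best_brute = min(cells, key=lambda k: (cells[k], k))
        assert surf.best == best_brute
        for (pc, lv), v in cells.items():
            i, j = pcs.index(pc), lvs.index(lv)
            assert surf.rmsep_matrix[i, j] == pytest.approx(v, abs=1e-12)

    def test_grid_order_independence(self, task_subsets):
        ts = task_subsets
        a = nt.grid_search(
            ts["cal_s"], (ts["tr_t"], ts["tr_s"]), ts["val_t"], [3, 5], [2, 4]
        )
        b = nt.grid_search(
            ts["cal_s"], (ts["tr_t"], ts["tr_s"]), ts["val_t"], [5, 3], [4, 2]
        )
        assert a.best == b.best
        assert a.rmsep_matrix[0, 0] == b.rmsep_matrix[1, 1]

    def test_empty_grid_rejected(self, task_subsets):
        ts = task_subsets
        with pytest.raises(nt.ParameterError):
            nt.grid_search(
                ts["cal_s"], (ts["tr_t"], ts["tr_s"]), ts["val_t"], [], [1]
            )


class TestPercentChange:
    def test_improvement(self):
        assert nt.percent_change(2.0, 1.5) == pytest.approx(25.0)

    def test_degradation_is_negative(self):
        assert nt.percent_change(2.0, 2.5) == pytest.approx(-25.0)

    def test_zero_reference(self):
        with pytest.raises(nt.ParameterError):
            nt.percent_change(0.0, 1.0)
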