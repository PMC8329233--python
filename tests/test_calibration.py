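import numpy as np
import pandas as pd
import pytest

import retdeconv as rd
from retdeconv.markers import MarkerSet


def bulk_from(counts, groups, genes=None):
    cols = [f"s{i}" for i in range(counts.shape[1])]
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(np.asarray(counts, float), index=genes, columns=cols)
    return rd.BulkMatrix(counts=df, conditions=pd.Series(groups, index=cols))


def unit_sf(bulk):
    return pd.Series(1.0, index=bulk.counts.columns)


def marker_set(genes, cell_type="rods"):
    return {cell_type: MarkerSet(cell_type, pd.DataFrame(index=list(genes)))}


class TestBulkFoldChange:
    def test_direct_arithmetic(self):
        bulk = bulk_from(np.array([[10, 10, 20, 20]]), ["c", "c", "d", "d"])
        fc = rd.bulk_fold_change(bulk, "c", "d", sf=unit_sf(bulk))
        assert fc["FC"].iloc[0] == pytest.approx(2.0)

    def test_identical_groups_give_unity(self):
        counts = np.tile([[7], [3]], (1, 6))
        bulk = bulk_from(counts, ["c"] * 3 + ["d"] * 3)
        fc = rd.bulk_fold_change(bulk, "c", "d", sf=unit_sf(bulk))
        np.testing.assert_allclose(fc["FC"], 1.0)

    def test_matches_naive_loop_with_size_factors(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(30, size=(40, 8)) + 1
        bulk = bulk_from(counts, ["c"] * 4 + ["d"] * 4)
        sf = rd.size_factors(bulk.counts)
        fc = rd.bulk_fold_change(bulk, "c", "d", sf=sf)
        for gi in range(0, 40, 7):
            norm = counts[gi] / sf.to_numpy()
            expected = norm[4:].mean() / norm[:4].mean()
            assert fc["FC"].iloc[gi] == pytest.approx(expected)

    def test_zero_control_mean_flagged_undefined(self):
        counts = np.array([[0, 0, 5, 5], [2, 2, 2, 2]])
        bulk = bulk_from(counts, ["c", "c", "d", "d"])
        fc = rd.bulk_fold_change(bulk, "c", "d", sf=unit_sf(bulk))
        assert not fc["defined"].iloc[0] and fc["defined"].iloc[1]


class TestEstimateProportionChange:
    @staticmethod
    def frame(fcs):
        fcs = np.asarray(fcs, float)
        return pd.DataFrame({"FC": fcs, "log_FC": np.log(fcs), "defined": True})

    def test_null_composition(self):
        assert rd.estimate_proportion_change(self.frame([1, 1, 1])).PC == pytest.approx(1.0)

    def test_geometric_mean_closed_form(self):
        assert rd.estimate_proportion_change(self.frame([2, 8])).PC == pytest.approx(4.0)

    def test_pc_matches_exp_mean_of_contributing_logs(self):
        pc = rd.estimate_proportion_change(self.frame([0.5, 2.0, 1.7]))
        assert pc.PC == pytest.approx(np.exp(pc.contributing_log_FCs.mean()), abs=1e-12)

    def test_undefined_records_excluded(self):
        f = self.frame([2, 8, 3])
        f.loc[2, "defined"] = False
        pc = rd.estimate_proportion_change(f)
        assert pc.PC == pytest.approx(4.0) and pc.m_used == 2 and pc.n_undefined == 1

    def test_all_undefined_raises(self):
        f = self.frame([2.0])
        f["defined"] = False
        with pytest.raises(rd.AnalysisError):
            rd.estimate_proportion_change(f)

    def test_median_estimator_resists_contamination(self):
        fcs = [1.0] * 9 + [100.0]
        assert rd.estimate_proportion_change(self.frame(fcs), robust="median").PC == pytest.approx(1.0)
        assert rd.estimate_proportion_change(self.frame(fcs), robust="mean").PC > 1.5


class TestCalibrateExpression:
    def test_pc_one_is_identity(self):
        bulk = bulk_from(np.array([[10, 12, 14, 16]]), ["c", "c", "d", "d"])
        cal = rd.calibrate_expression(bulk, 1.0, "d", mode="scaled_counts")
        pd.testing.assert_frame_equal(cal.counts, bulk.counts)

    def test_corrected_scaling_direct(self):
        bulk = bulk_from(np.array([[10, 10, 10, 10]]), ["c", "c", "d", "d"])
        cal = rd.calibrate_expression(bulk, 0.5, "d", mode="scaled_counts")
        assert cal.counts.iloc[0].tolist() == [10, 10, 20, 20]

    def test_paper_literal_direction_multiplies(self):
        bulk = bulk_from(np.array([[10, 10, 10, 10]]), ["c", "c", "d", "d"])
        cal = rd.calibrate_expression(bulk, 0.5, "d", mode="scaled_counts", direction="paper_literal")
        assert cal.counts.iloc[0].tolist() == [10, 10, 5, 5]

    def test_offset_mode_encodes_log_pc_on_disease(self):
        bulk = bulk_from(np.ones((2, 4)), ["c", "c", "d", "d"])
        off = rd.calibrate_expression(bulk, 0.5, "d", mode="offset")
        np.testing.assert_allclose(off.to_numpy(), [0, 0, np.log(0.5), np.log(0.5)])

    def test_log_fc_decomposition_identity(self):
        # mean log FC over G_j = log PC + mean log calibrated FC, exactly,
        # on any fixed matrix (corrected direction, unrounded scaling)
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, size=(30, 10)) + 1
        bulk = bulk_from(counts, ["c"] * 5 + ["d"] * 5)
        sf = rd.size_factors(bulk.counts)
        fc = rd.bulk_fold_change(bulk, "c", "d", sf=sf)
        pc = rd.estimate_proportion_change(fc)
        cal = rd.calibrate_expression(bulk, pc, "d", mode="scaled_counts", round_counts=False)
        fc_cal = rd.bulk_fold_change(cal, "c", "d", sf=sf)
        resid = fc["log_FC"].mean() - np.log(pc.PC) - fc_cal["log_FC"].mean()
        assert abs(resid) < 1e-9

    def test_composition_only_calibrated_fc_centers_at_zero(self):
        p1, p2 = np.array([0.5, 0.5]), np.array([0.2, 0.8])
        cfg = rd.SimConfig(
            n_celltypes=2, n_genes=2000, cells_per_type=10, markers_per_type=200,
            marker_fc=1000.0, profile_jitter_sd=0.0, ctdeg_fraction=0.0,
            conditions=[("c", 20), ("d", 20)],
            proportions_by_condition={"c": p1, "d": p2},
            proportion_noise=1000.0, seed=21,
        )
        _, truth = rd.simulate_reference(cfg)
        bulk = rd.simulate_bulk(cfg, truth)
        genes = sorted(truth.markers_of("rods"))
        sf = rd.size_factors(bulk.counts)
        fc = rd.bulk_fold_change(bulk, "c", "d", genes=genes, sf=sf)
        pc = rd.estimate_proportion_change(fc)
        cal = rd.calibrate_expression(bulk, pc, "d", mode="scaled_counts", round_counts=False)
        fc_cal = rd.bulk_fold_change(cal, "c", "d", genes=genes, sf=sf)
        assert abs(fc_cal["log_FC"].mean()) < 0.02


class TestAntisymmetryAndInvariance:
    def test_label_swap_inverts_fc_and_pc(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(40, size=(25, 8)) + 1
        bulk = bulk_from(counts, ["c"] * 4 + ["d"] * 4)
        sf = rd.size_factors(bulk.counts)
        fwd = rd.bulk_fold_change(bulk, "c", "d", sf=sf)
        rev = rd.bulk_fold_change(bulk, "d", "c", sf=sf)
        np.testing.assert_allclose(fwd["FC"], 1 / rev["FC"], rtol=1e-12)
        pc_f = rd.estimate_proportion_change(fwd).PC
        pc_r = rd.estimate_proportion_change(rev).PC
        assert pc_f == pytest.approx(1 / pc_r, rel=1e-12)

    def test_pc_invariant_to_per_sample_library_rescaling(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(40, size=(50, 8)) + 1
        bulk = bulk_from(counts, ["c"] * 4 + ["d"] * 4)
        pc1 = rd.estimate_proportion_change(
            rd.bulk_fold_change(bulk, "c", "d", sf=rd.size_factors(bulk.counts)))
        scales = rng.uniform(0.5, 3.0, size=8)
        scaled = bulk_from(counts * scales[None, :], ["c"] * 4 + ["d"] * 4)
        pc2 = rd.estimate_proportion_change(
            rd.bulk_fold_change(scaled, "c", "d", sf=rd.size_factors(scaled.counts)))
        assert pc1.PC == pytest.approx(pc2.PC, rel=1e-9)


class TestDetectCtdegs:
    def test_pc_consistency_error_shrinks_with_n(self):
        p1, p2 = np.array([0.5, 0.5]), np.array([0.25, 0.75])
        errors = {}
        for n in (10, 200):
            errs = []
            for rep in range(5):
                cfg = rd.SimConfig(
                    n_celltypes=2, n_genes=1500, cells_per_type=10, markers_per_type=50,
                    marker_fc=1000.0, profile_jitter_sd=0.0, ctdeg_fraction=0.0,
                    conditions=[("c", n), ("d", n)],
                    proportions_by_condition={"c": p1, "d": p2},
                    proportion_noise=5000.0, seed=1000 * n + rep,
                )
                _, truth = rd.simulate_reference(cfg)
                bulk = rd.simulate_bulk(cfg, truth)
                fc = rd.bulk_fold_change(bulk, "c", "d", genes=sorted(truth.markers_of("rods")),
                                         sf=rd.size_factors(bulk.counts))
                pc = rd.estimate_proportion_change(fc)
                errs.append(abs(np.log(pc.PC / 0.5)))
            errors[n] = np.median(errs)
        assert errors[200] < errors[10]

    def test_attenuation_vs_naive_bulk_test(self):
        # a planted down-regulated gene in a shrinking cell type: the naive
        # bulk test conflates composition and expression change, so the
        # calibrated p-value is larger (attenuated significance)
        p1, p2 = np.array([0.5, 0.5]), np.array([0.2, 0.8])
        cfg = rd.SimConfig(
            n_celltypes=2, n_genes=1500, cells_per_type=10, markers_per_type=100,
            marker_fc=1000.0, profile_jitter_sd=0.0, ctdeg_fraction=0.05, ctdeg_fc=0.25,
            conditions=[("c", 20), ("d", 20)],
            proportions_by_condition={"c": p1, "d": p2},
            proportion_noise=1000.0, seed=33,
        )
        _, truth = rd.simulate_reference(cfg)
        bulk = rd.simulate_bulk(cfg, truth)
        ms = marker_set(sorted(truth.markers_of("rods")))
        calibrated = rd.detect_ctdegs(bulk, ms, "c", "d").table.set_index("gene")
        naive = rd.detect_ctdegs(
            bulk, ms, "c", "d",
            pcs={"rods": rd.ProportionChange("rods", 1.0, 0, np.array([]))},
        ).table.set_index("gene")
        planted = sorted(truth.ctdegs_of("rods"))
        assert (calibrated.loc[planted, "p_raw"].to_numpy()
                >= naive.loc[planted, "p_raw"].to_numpy()).mean() > 0.9

    def test_empty_candidates_warns(self):
        bulk = bulk_from(np.ones((3, 6)), ["c"] * 3 + ["d"] * 3)
        with pytest.warns(RuntimeWarning):
            res = rd.detect_ctdegs(bulk, marker_set(["absent_gene"]), "c", "d")
        assert res.table.empty
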