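"""Fingerprints, Tanimoto, the calibration formula, and the CV grid search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockclass import (
    CalibrationConfig,
    CompoundRecord,
    DatasetSimConfig,
    Fingerprint,
    SimilarityCalibratedClassifier,
    SimilarityCalibrator,
    apply_final_model,
    calibrate_scores,
    compute_fingerprint,
    cross_validate_calibration,
    similarity_matrix,
    simulate_classification_dataset,
    tanimoto,
)
from dockclass.calibration import DEFAULT_P_GRID


class TestComputeFingerprint:
    @pytest.mark.parametrize("kind", ["maccs_keys", "morgan_circular", "path_based"])
    def test_spelling_invariance(self, kind):
        a = compute_fingerprint("c1ccccc1O", kind)
        b = compute_fingerprint("Oc1ccccc1", kind)
        assert np.array_equal(a.bits, b.bits)

    def test_maccs_length_166(self):
        fp = compute_fingerprint("CCO", "maccs_keys")
        assert fp.bits.shape == (166,)

    def test_morgan_distinguishes_aromatic_aliphatic(self):
        benzene = compute_fingerprint("c1ccccc1", "morgan_circular")
        cyclohexane = compute_fingerprint("C1CCCCC1", "morgan_circular")
        assert not np.array_equal(benzene.bits, cyclohexane.bits)

    def test_unparseable_smiles_errors(self):
        with pytest.raises(ValueError, match="unparseable"):
            compute_fingerprint("not(((smiles", "maccs_keys")

    def test_unknown_kind_errors(self):
        with pytest.raises(ValueError, match="unknown fingerprint"):
            compute_fingerprint("CCO", "daylight")


class TestTanimoto:
    def test_identical_nonempty(self):
        fp = compute_fingerprint("c1ccccc1CCO", "morgan_circular")
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_bits(self):
        a = Fingerprint("morgan_circular", np.zeros(2048, dtype=bool))
        b = Fingerprint("morgan_circular", np.zeros(2048, dtype=bool))
        a.bits[[1, 2, 3]] = True
        b.bits[[10, 11]] = True
        assert tanimoto(a, b) == 0.0

    def test_half_overlap(self):
        a = Fingerprint("morgan_circular", np.zeros(2048, dtype=bool))
        b = Fingerprint("morgan_circular", np.zeros(2048, dtype=bool))
        a.bits[[1, 2, 3]] = True
        b.bits[[2, 3, 4]] = True
        assert tanimoto(a, b) == 0.5

    def test_kind_mismatch_errors(self):
        a = compute_fingerprint("CCO", "maccs_keys")
        b = compute_fingerprint("CCO", "morgan_circular")
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(a, b)

    def test_both_empty_warns_zero(self):
        a = Fingerprint("morgan_circular", np.zeros(2048, dtype=bool))
        with pytest.warns(UserWarning, match="empty"):
            assert tanimoto(a, a) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        on_a=st.sets(st.integers(0, 63), max_size=20),
        on_b=st.sets(st.integers(0, 63), max_size=20),
    )
    def test_range_symmetry_setcount(self, on_a, on_b):
        bits_a = np.zeros(2048, dtype=bool)
        bits_b = np.zeros(2048, dtype=bool)
        bits_a[list(on_a)] = True
        bits_b[list(on_b)] = True
        a = Fingerprint("morgan_circular", bits_a)
        b = Fingerprint("morgan_circular", bits_b)
        if not on_a and not on_b:
            return
        t = tanimoto(a, b)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(b, a)
        assert t == pytest.approx(
            len(on_a & on_b) / len(on_a | on_b) if (on_a | on_b) else 0.0
        )

    def test_matrix_matches_pairwise(self):
        smiles = ["CCO", "c1ccccc1", "CC(=O)O", "c1ccccc1O"]
        fps = [compute_fingerprint(s, "maccs_keys") for s in smiles]
        S = similarity_matrix(fps[:2], fps[2:])
        for i in range(2):
            for j in range(2):
                assert S.values[i, j] == pytest.approx(tanimoto(fps[i], fps[2 + j]))

    def test_rdkit_bulk_tanimoto_cross_check(self):
        """Our bitwise Tanimoto agrees with RDKit's DataStructs implementation."""
        from rdkit import Chem, DataStructs
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        smiles = ["CCO", "c1ccccc1O", "CC(C)Cc1ccc(C)cc1", "OCC1OC(O)C(O)C(O)C1O"]
        mols = [Chem.MolFromSmiles(s) for s in smiles]
        rd_fps = [gen.GetFingerprint(m) for m in mols]
        ours = [compute_fingerprint(s, "morgan_circular") for s in smiles]
        for i in range(len(smiles)):
            for j in range(len(smiles)):
                assert tanimoto(ours[i], ours[j]) == pytest.approx(
                    DataStructs.TanimotoSimilarity(rd_fps[i], rd_fps[j]), abs=1e-12
                )


def _calibrate_oracle(ds0, ds_ref, dg, S, p):
    """Naive double-loop reference implementation of the calibration sum."""
    out = np.empty(len(ds0))
    for j in range(len(ds0)):
        omega = 0.0
        acc = 0.0
        for i in range(len(ds_ref)):
            w = S[j, i] ** p
            omega += w
            acc += w * dg[i] / ds_ref[i]
        out[j] = ds0[j] * acc / omega if omega > 0 else ds0[j]
    return out


class TestCalibrateScores:
    def test_single_reference(self):
        cal = calibrate_scores([-9.0], [-8.0], [8.0], np.array([[1.0]]), p=12)
        assert cal[0] == pytest.approx(9.0)

    def test_constant_ratio_independent_of_p_and_s(self):
        # all references share dG/DS = c -> DSj = c * DSj0 for every query
        ds_ref = np.array([-8.0, -4.0, -10.0])
        dg = -ds_ref  # ratio -1 everywhere
        rng = np.random.default_rng(0)
        S = rng.random((5, 3)) * 0.9 + 0.05
        ds0 = rng.normal(-9, 1, 5)
        for p in (1, 4, 20, 60):
            np.testing.assert_allclose(calibrate_scores(ds0, ds_ref, dg, S, p), -ds0)

    def test_high_p_dominance(self):
        # S = (0.9, 0.3), p=60: the second weight is (1/3)^60 of the first
        ds0 = np.array([-9.0])
        ds_ref = np.array([-8.0, -6.0])
        dg = np.array([8.5, 5.0])
        S = np.array([[0.9, 0.3]])
        cal = calibrate_scores(ds0, ds_ref, dg, S, p=60)
        expected = -9.0 * (8.5 / -8.0)
        assert cal[0] == pytest.approx(expected, abs=1e-6)
        # and agrees with the full sum evaluated naively
        np.testing.assert_allclose(cal, _calibrate_oracle(ds0, ds_ref, dg, S, 60))

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            nq, nr = int(rng.integers(1, 12)), int(rng.integers(1, 20))
            ds0 = rng.normal(-9, 1, nq)
            ds_ref = rng.normal(-9, 1, nr)
            dg = rng.uniform(5, 10, nr)
            S = rng.random((nq, nr))
            p = int(rng.choice([1, 4, 12, 28, 60]))
            np.testing.assert_allclose(
                calibrate_scores(ds0, ds_ref, dg, S, p),
                _calibrate_oracle(ds0, ds_ref, dg, S, p),
                atol=1e-10,
            )

    def test_reference_order_invariance(self):
        rng = np.random.default_rng(2)
        ds0 = rng.normal(-9, 1, 4)
        ds_ref = rng.normal(-9, 1, 10)
        dg = rng.uniform(5, 10, 10)
        S = rng.random((4, 10))
        perm = rng.permutation(10)
        np.testing.assert_allclose(
            calibrate_scores(ds0, ds_ref, dg, S, 12),
            calibrate_scores(ds0, ds_ref[perm], dg[perm], S[:, perm], 12),
            atol=1e-12,
        )

    def test_duplicating_reference_doubles_weight(self):
        rng = np.random.default_rng(3)
        ds0 = rng.normal(-9, 1, 3)
        ds_ref = rng.normal(-9, 1, 5)
        dg = rng.uniform(5, 10, 5)
        S = rng.random((3, 5))
        # duplicate reference 0
        ds2 = np.concatenate([ds_ref, ds_ref[:1]])
        dg2 = np.concatenate([dg, dg[:1]])
        S2 = np.hstack([S, S[:, :1]])
        # oracle with an explicit doubled weight on reference 0
        W = S**12
        W[:, 0] *= 2
        expected = ds0 * (W @ (dg / ds_ref)) / W.sum(axis=1)
        np.testing.assert_allclose(
            calibrate_scores(ds0, ds2, dg2, S2, 12), expected, atol=1e-12
        )

    def test_sign_behavior_positive_outputs(self):
        rng = np.random.default_rng(4)
        ds0 = -rng.uniform(6, 12, 20)
        ds_ref = -rng.uniform(6, 12, 15)
        dg = rng.uniform(4, 10, 15)
        S = rng.random((20, 15)) * 0.98 + 0.01
        cal = calibrate_scores(ds0, ds_ref, dg, S, 8)
        assert (cal > 0).all()

    def test_monotone_dominance_in_p(self):
        """The weight fraction of the uniquely most-similar reference is
        non-decreasing (strictly increasing) in p."""
        S_row = np.array([0.8, 0.5, 0.3])
        fractions = []
        for p in (1, 4, 12, 28, 60):
            w = S_row**p
            fractions.append(w[0] / w.sum())
        assert all(b > a for a, b in zip(fractions, fractions[1:]))

    def test_zero_weight_query_flagged_uncalibrated(self):
        S = np.array([[0.0, 0.0], [0.5, 0.5]])
        with pytest.warns(UserWarning, match="zero total similarity"):
            cal, flags = calibrate_scores(
                [-9.0, -8.0], [-8.0, -7.0], [8.0, 7.0], S, 12, return_flags=True
            )
        assert flags.tolist() == [True, False]
        assert cal[0] == -9.0

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="does not match"):
            calibrate_scores([-9.0], [-8.0, -7.0], [8.0, 7.0], np.ones((1, 3)), 4)

    def test_zero_reference_score_errors(self):
        with pytest.raises(ValueError, match="excluded upstream"):
            calibrate_scores([-9.0], [0.0], [8.0], np.ones((1, 1)), 4)


def _records_from_dataset(n, seed, structure="S1"):
    cfg = DatasetSimConfig(n_compounds=n, dropout_rate=0.0, seed=seed)
    records, _, _ = simulate_classification_dataset(cfg)
    return [
        CompoundRecord(
            compound_id=r.compound_id,
            smiles=r.smiles,
            pchembl_values=list(r.pchembl_values),
            activity_label=r.activity_label,
            docking_scores={structure: r.docking_scores[structure]},
        )
        for r in records
    ]


class TestCrossValidateCalibration:
    def test_default_grid_has_eight_points(self):
        assert DEFAULT_P_GRID == tuple(range(4, 61, 8))
        records = _records_from_dataset(120, seed=0)
        cfg = CalibrationConfig(seed=0)
        result = cross_validate_calibration(records, cfg)
        assert len(result.per_p) == 8
        assert result.per_p["p"].tolist() == list(range(4, 61, 8))

    def test_deterministic_under_seed(self):
        records = _records_from_dataset(120, seed=1)
        cfg = CalibrationConfig(seed=7)
        r1 = cross_validate_calibration(records, cfg)
        r2 = cross_validate_calibration(records, cfg)
        assert r1.best_p == r2.best_p
        assert r1.final_threshold == r2.final_threshold
        pd.testing.assert_frame_equal(r1.per_p, r2.per_p)
        assert r1.fold_assignments == r2.fold_assignments

    def test_mean_threshold_is_fold_mean(self):
        records = _records_from_dataset(120, seed=2)
        result = cross_validate_calibration(records, CalibrationConfig(seed=2))
        assert result.final_threshold == pytest.approx(
            np.mean(result.fold_thresholds[result.best_p])
        )

    def test_calibration_beats_raw_scores_and_lands_near_pchembl_cutoff(self):
        """On data with a fragment-level structure-activity signal the
        calibrated model outperforms the raw-score threshold model, and
        fold thresholds land near the pChEMBL labeling cutoff of 8."""
        from dockclass import ConfusionCounts, classify, find_threshold, mcc

        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            records = _records_from_dataset(250, seed=seed)
            y = np.array([r.activity_label for r in records])
            raw = np.array([r.docking_scores["S1"] for r in records])
            model = find_threshold(raw[y == 1], raw[y == 0])
            raw_mcc = mcc(
                ConfusionCounts.from_predictions(y, classify(raw, model))
            )
            result = cross_validate_calibration(records, CalibrationConfig(seed=seed))
            best_mcc = result.per_p["mean_mcc"].max()
            if best_mcc > raw_mcc:
                wins += 1
            assert abs(result.final_threshold - 8.0) < 1.0
        assert wins >= 3


class TestApplyFinalModel:
    def test_generalizes_to_external_split(self):
        records = _records_from_dataset(300, seed=3)
        train, ext = records[:240], records[240:]
        cv = cross_validate_calibration(train, CalibrationConfig(seed=3))
        counts, metrics = apply_final_model(
            ext, cv.final_threshold, train, "morgan_circular", cv.best_p
        )
        cv_mcc = float(cv.per_p["mean_mcc"].max())
        assert abs(metrics["mcc"] - cv_mcc) < 0.4  # same generator, same scale

    def test_overlap_errors(self, labeled_records):
        with pytest.raises(ValueError, match="overlap"):
            apply_final_model(
                labeled_records, 8.0, labeled_records, "maccs_keys", 4
            )

    def test_empty_external_errors(self, labeled_records):
        with pytest.raises(ValueError, match="empty"):
            apply_final_model([], 8.0, labeled_records, "maccs_keys", 4)

    def test_identical_compound_dominance_limit(self, labeled_records):
        """An external compound identical to a reference has S=1; at high p
        its calibrated score approaches DSj0 * (dG_ref / DS_ref)."""
        ext = [
            CompoundRecord(
                "x", smiles="c1ccccc1O", pchembl_values=[9.0], activity_label=1,
                docking_scores={"S1": -9.5},
            )
        ]
        counts, _ = apply_final_model(ext, 8.0, labeled_records, "morgan_circular", 60)
        # reference twin: dG 9.0, DS -10.0 -> calibrated ~ -9.5 * (9.0/-10.0) = 8.55 > 8
        assert counts.tp == 1


class TestEstimators:
    def test_calibrator_transform_matches_function(self, labeled_records):
        frame = pd.DataFrame(
            {
                "smiles": [r.smiles for r in labeled_records],
                "score": [r.docking_scores["S1"] for r in labeled_records],
                "pchembl": [r.pchembl_values[0] for r in labeled_records],
            },
            index=[r.compound_id for r in labeled_records],
        )
        cal = SimilarityCalibrator(fingerprint_kind="maccs_keys", p=4).fit(frame)
        out = cal.transform(frame)
        assert out.shape == (3, 1)

    def test_classifier_end_to_end(self):
        records = _records_from_dataset(150, seed=9)
        frame = pd.DataFrame(
            {
                "smiles": [r.smiles for r in records],
                "score": [r.docking_scores["S1"] for r in records],
                "pchembl": [r.pchembl_values[0] for r in records],
            },
            index=[r.compound_id for r in records],
        )
        clf = SimilarityCalibratedClassifier(seed=0, p_grid=(4, 12)).fit(frame)
        assert clf.best_p_ in (4, 12)
        pred = clf.predict(frame)
        y = np.array([r.activity_label for r in records])
        from dockclass import ConfusionCounts, mcc

        assert mcc(ConfusionCounts.from_predictions(y, pred)) > 0.2

    def test_sklearn_clone(self):
        from sklearn.base import clone

        clf = SimilarityCalibratedClassifier(fingerprint_kind="maccs_keys", seed=3)
        assert clone(clf).get_params() == clf.get_params()
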