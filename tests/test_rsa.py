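"""Neural RDMs, RSA effects, contrasts, and per-run trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import hebbrsa as h
from hebbrsa.seqdist import ModelRDM


def _betas(arr, ids=None, phase="encoding"):
    arr = np.asarray(arr, dtype=float)
    ids = tuple(ids or (f"t{i}" for i in range(arr.shape[0])))
    return h.TrialBetas(arr, ids, phase)


def _model(mat, ids=None, kind="repeat"):
    mat = np.asarray(mat, dtype=float)
    ids = tuple(ids or (f"t{i}" for i in range(mat.shape[0])))
    return ModelRDM(mat, ids, kind)


class TestNeuralRDM:
    def test_identical_negated_and_orthogonal_patterns(self):
        a = np.array([1.0, -1.0, 2.0, 0.0])
        b = np.array([1.5, 0.5, -0.5, -1.5])  # centered and orthogonal to centered a
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.0, abs=1e-12)
        rdm = h.neural_rdm(_betas([a, a, -a, b]))
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.matrix[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert rdm.matrix[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_pattern_marked_missing(self):
        rdm = h.neural_rdm(_betas([[1, 2, 3], [5, 5, 5], [3, 1, 2]]))
        assert np.isnan(rdm.matrix[0, 1]) and np.isnan(rdm.matrix[1, 2])
        assert np.isfinite(rdm.matrix[0, 2])
        assert rdm.matrix[1, 1] == 0.0

    def test_entries_bounded_in_zero_two(self, rng):
        rdm = h.neural_rdm(_betas(rng.standard_normal((12, 8))))
        assert (rdm.matrix >= -1e-12).all() and (rdm.matrix <= 2 + 1e-12).all()
        np.testing.assert_allclose(rdm.matrix, rdm.matrix.T)

    def test_euclidean_option(self):
        rdm = h.neural_rdm(_betas([[0, 0], [3, 4]]), method="euclidean")
        assert rdm.matrix[0, 1] == pytest.approx(5.0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(h.InvalidInputError):
            h.neural_rdm(_betas([[1.0, 2.0]]))


class TestRSAEffect:
    def test_monotone_transform_of_model_gives_one(self, rng):
        m = np.abs(rng.standard_normal((8, 8)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        neural = h.NeuralRDM(np.sqrt(m) + m ** 2, tuple(f"t{i}" for i in range(8)))
        eff = h.rsa_effect(_model(m), neural)
        assert eff.value == pytest.approx(1.0, abs=1e-12)

    def test_permuted_neural_centers_on_zero(self, rng):
        n = 10
        m = np.abs(rng.standard_normal((n, n)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        vals = []
        ids = tuple(f"t{i}" for i in range(n))
        for _ in range(500):
            perm = rng.permutation(n)
            vals.append(h.rsa_effect(_model(m), h.NeuralRDM(m[np.ix_(perm, perm)], ids)).value)
        assert abs(np.mean(vals)) < 0.02

    def test_binary_model_equals_rank_contrast_oracle(self, rng):
        """With a two-valued model RDM the Spearman statistic equals the
        Pearson correlation of rank-transformed vectors computed directly."""
        n = 9
        ids = tuple(f"t{i}" for i in range(n))
        groups = rng.integers(0, 2, (n, n))
        m = np.triu(groups, 1) * 1.7
        m = m + m.T
        neural_mat = np.abs(rng.standard_normal((n, n)))
        neural_mat = (neural_mat + neural_mat.T) / 2
        np.fill_diagonal(neural_mat, 0)
        eff = h.rsa_effect(_model(m), h.NeuralRDM(neural_mat, ids))
        i, j = np.tril_indices(n, k=-1)
        rx, ry = rankdata(m[i, j]), rankdata(neural_mat[i, j])
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert eff.value == pytest.approx(oracle, abs=1e-12)
        # sign agrees with the between-minus-within mean-rank difference
        between = m[i, j] > 0
        mean_rank_diff = ry[between].mean() - ry[~between].mean()
        assert np.sign(eff.value) == np.sign(mean_rank_diff)

    def test_mismatched_trial_ids_rejected(self, rng):
        m = np.zeros((4, 4))
        neural = h.NeuralRDM(m, ("a", "b", "c", "d"))
        with pytest.raises(h.InvalidInputError):
            h.rsa_effect(_model(m, ids=("a", "b", "c", "x")), neural)

    def test_too_few_valid_pairs_undefined(self):
        m = np.zeros((3, 3))
        neural_mat = np.full((3, 3), np.nan)
        np.fill_diagonal(neural_mat, 0)
        ids = ("a", "b", "c")
        with pytest.raises(h.UndefinedStatisticError):
            h.rsa_effect(_model(m, ids=ids), h.NeuralRDM(neural_mat, ids))


class TestContrasts:
    def _effects(self, rep, nov):
        rows = []
        for s, (r, n) in enumerate(zip(rep, nov)):
            rows += [
                dict(subject=s, roi="R", phase="encoding", seq_type="repeat",
                     run="pooled", value=r),
                dict(subject=s, roi="R", phase="encoding", seq_type="novel",
                     run="pooled", value=n),
            ]
        return pd.DataFrame(rows)

    def test_identical_effects_contrast_to_zero(self):
        out = h.repeat_novel_contrast(self._effects([0.3, 0.1], [0.3, 0.1]))
        np.testing.assert_allclose(out["contrast"], 0.0)

    def test_contrast_antisymmetric_under_label_swap(self):
        eff = self._effects([0.5, 0.2], [0.1, 0.0])
        swapped = eff.copy()
        swapped["seq_type"] = swapped["seq_type"].map(
            {"repeat": "novel", "novel": "repeat"})
        a = h.repeat_novel_contrast(eff)["contrast"].to_numpy()
        b = h.repeat_novel_contrast(swapped)["contrast"].to_numpy()
        np.testing.assert_allclose(a, -b)

    def test_unmatched_cells_reported_missing(self):
        eff = self._effects([0.5], [0.1]).iloc[:1]        # repeat only
        out = h.repeat_novel_contrast(eff)
        assert out["contrast"].isna().all()


class TestPooledVsPerRun:
    def test_pooled_effect_is_not_mean_of_per_run_effects(self):
        """Pooling concatenates pair sets; it is not an average of per-run
        statistics (constructed counterexample)."""
        ids1, ids2 = ("a", "b", "c"), ("d", "e", "f")
        m1 = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        m2 = m1 * 10
        n1 = np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]])
        n2 = np.array([[0, .3, .2], [.3, 0, .25], [.2, .25, 0]])
        e1 = h.rsa_effect(_model(m1, ids1), h.NeuralRDM(n1, ids1)).value
        e2 = h.rsa_effect(_model(m2, ids2), h.NeuralRDM(n2, ids2)).value
        pooled_m = np.block([[m1, np.full((3, 3), 5.0)], [np.full((3, 3), 5.0), m2]])
        pooled_n = np.block([[n1, np.full((3, 3), 0.25)], [np.full((3, 3), 0.25), n2]])
        ids = ids1 + ids2
        pooled = h.rsa_effect(_model(pooled_m, ids), h.NeuralRDM(pooled_n, ids)).value
        assert pooled != pytest.approx((e1 + e2) / 2, abs=1e-6)

    def test_trajectory_table_shape(self, design_small):
        p = h.SimParams(seed=3, rois=("r1",), n_voxels_per_roi=10)
        runs, _ = h.simulate_subject(design_small, p, subject=0)
        eff = h.subject_rsa_effects(design_small, runs, subject=0,
                                    phases=("encoding",))
        traj = h.per_run_trajectory(eff)
        assert set(traj["run"]) == {1, 2}
        assert len(traj) == 2 * 2                      # run x seq_type
        pooled = eff[eff["run"] == "pooled"]
        assert len(pooled) == 2                        # seq_type


class TestSubjectPipeline:
    def test_multi_roi_effects_match_single_roi_runs(self, design_small):
        p = h.SimParams(seed=9, rois=("r1", "r2"), n_voxels_per_roi=8)
        runs, _ = h.simulate_subject(design_small, p, subject=0)
        both = h.subject_rsa_effects(design_small, runs, subject=0,
                                     roi=["r1", "r2"], phases=("encoding",),
                                     per_run=False)
        solo = h.subject_rsa_effects(design_small, runs, subject=0,
                                     roi="r1", phases=("encoding",),
                                     per_run=False)
        merged = both[both.roi == "r1"].reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, solo)

    def test_unknown_roi_rejected(self, design_small):
        p = h.SimParams(seed=9, rois=("r1",), n_voxels_per_roi=8)
        runs, _ = h.simulate_subject(design_small, p, subject=0)
        with pytest.raises(h.InvalidInputError):
            h.subject_rsa_effects(design_small, runs, roi="nope")
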