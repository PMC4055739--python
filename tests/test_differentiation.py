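"""Standardization, test selection, PCA/DFA, and the isolation metric."""

import numpy as np
import pandas as pd
import pytest

from odobenus import differentiation as diff
from odobenus.io import DataError, MorphoDataset
from tests.conftest import make_specimen


class TestRankStandardizers:
    def test_exact_allometry_outranks_noise(self):
        rng = np.random.default_rng(0)
        specs = []
        for i in range(20):
            age = float(rng.uniform(2, 26))
            sex = "M" if i % 2 else "F"
            specs.append(
                make_specimen(
                    f"s{i}", sex=sex, age=age,
                    CW=5 * age + 20 * (sex == "M") + 30,
                    NL=float(rng.uniform(50, 100)),
                )
            )
        ranked = diff.rank_standardizers(MorphoDataset(specs), ["CW", "NL"])
        assert ranked[0][0] == "CW"
        assert ranked[0][1] == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_scores_low(self):
        rng = np.random.default_rng(1)
        specs = [
            make_specimen(
                f"s{i}", sex="M" if i % 2 else "F", age=float(rng.uniform(2, 26)),
                CW=float(rng.uniform(150, 250)), NL=float(rng.uniform(50, 100)),
            )
            for i in range(100)
        ]
        ranked = diff.rank_standardizers(MorphoDataset(specs), ["CW", "NL"])
        assert all(score < 0.15 for _, score, _ in ranked)

    def test_single_candidate_always_rank_one(self):
        specs = [
            make_specimen(f"s{i}", sex="F", age=float(i + 2), NL=50.0 + i)
            for i in range(5)
        ]
        ranked = diff.rank_standardizers(MorphoDataset(specs), ["NL"])
        assert ranked[0][0] == "NL"

    def test_no_eligible_specimens(self):
        ds = MorphoDataset([make_specimen("s1", CW=200.0)])  # no age/sex
        with pytest.raises(DataError, match="eligible"):
            diff.rank_standardizers(ds, ["CW"])


class TestStandardize:
    def test_simple_ratio(self):
        ds = MorphoDataset([make_specimen("s1", CBL=350.0, CW=200.0)])
        mat = diff.standardize(ds)
        assert mat.data.loc["s1", "CBL"] == pytest.approx(1.75)

    def test_missing_standardizer_blanks_only_its_block(self):
        ds = MorphoDataset(
            [make_specimen("s1", CBL=350.0, MW=120.0, ML_L=216.0)]  # no CW
        )
        mat = diff.standardize(ds)
        assert np.isnan(mat.data.loc["s1", "CBL"])
        assert mat.data.loc["s1", "ML"] == pytest.approx(1.8)

    def test_standardizers_excluded_from_columns(self):
        ds = MorphoDataset([make_specimen("s1", CBL=350.0, CW=200.0)])
        cols = diff.standardize(ds).data.columns
        assert "CW" not in cols and "MW" not in cols

    def test_matrix_equals_hand_division(self):
        vals = {"CBL": 350.0, "IW": 90.0, "ZW": 190.0, "NL": 70.0}
        specs = [
            make_specimen(f"s{i}", CW=cw, **{k: v * (1 + 0.01 * i) for k, v in vals.items()})
            for i, cw in enumerate([200.0, 210.0, 195.0, 205.0])
        ]
        mat = diff.standardize(MorphoDataset(specs))
        for i, cw in enumerate([200.0, 210.0, 195.0, 205.0]):
            for k, v in vals.items():
                assert mat.data.loc[f"s{i}", k] == pytest.approx(v * (1 + 0.01 * i) / cw)


def two_group_matrix(a, b):
    data = pd.DataFrame({"X": np.concatenate([a, b])},
                        index=[f"s{i}" for i in range(len(a) + len(b))])
    regions = pd.Series(["MAR"] * len(a) + ["ATL"] * len(b), index=data.index)
    return diff.StandardizedMatrix(data, regions)


class TestCompareGroups:
    def test_normal_shift_uses_welch_and_detects(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        (rec,) = diff.compare_groups(two_group_matrix(a, b), "MAR", "ATL")
        assert rec.chosen_test == "welch_t"
        assert rec.significant

    def test_heavy_tails_fall_back_to_wilcoxon(self):
        rng = np.random.default_rng(6)
        pooled = rng.lognormal(0, 1.5, 60)
        rng.shuffle(pooled)
        (rec,) = diff.compare_groups(two_group_matrix(pooled[:30], pooled[30:]), "MAR", "ATL")
        assert rec.chosen_test == "wilcoxon"
        assert not rec.significant

    def test_identical_groups_not_significant(self):
        vals = np.array([1.0, 1.1, 1.2, 1.3, 1.4])
        (rec,) = diff.compare_groups(two_group_matrix(vals, vals.copy()), "MAR", "ATL")
        assert not rec.significant
        assert rec.p_value == pytest.approx(1.0, abs=0.05)

    def test_insufficient_data_flagged_untestable(self):
        (rec,) = diff.compare_groups(
            two_group_matrix(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0])),
            "MAR", "ATL",
        )
        assert rec.chosen_test == "untestable"
        assert not rec.significant


class TestPCA:
    def _matrix(self, X):
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])],
                          index=[f"s{i}" for i in range(X.shape[0])])
        return diff.StandardizedMatrix(df, pd.Series("MAR", index=df.index))

    def test_collinear_points_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 10)
        mat = self._matrix(np.column_stack([t, 2 * t]))
        res = diff.pca(mat, scaling="covariance")
        assert res.proportions[0] == pytest.approx(1.0)
        assert res.proportions[1] == pytest.approx(0.0, abs=1e-12)

    def test_known_covariance_eigenvalues(self):
        # data built to have sample covariance exactly [[2,1],[1,2]];
        # closed-form eigenvalues are 3 and 1
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
                         [1.0, 1.0], [-1.0, -1.0]])
        cov = np.cov(base.T)
        chol_target = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        chol_base = np.linalg.cholesky(cov)
        X = base @ np.linalg.inv(chol_base).T @ chol_target.T
        res = diff.pca(self._matrix(X), scaling="covariance")
        assert res.eigenvalues == pytest.approx([3.0, 1.0])

    def test_proportions_sum_to_one_and_reconstruction(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 5)) @ rng.normal(size=(5, 5))
        res = diff.pca(self._matrix(X), scaling="correlation")
        assert res.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        recon = res.scores.to_numpy() @ res.loadings.T
        scaled = (X - res.means) / res.scales
        assert np.abs(recon - scaled).max() < 1e-8

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(DataError, match="zero-variance"):
            diff.pca(self._matrix(X))

    def test_scores_have_zero_mean(self):
        rng = np.random.default_rng(10)
        res = diff.pca(self._matrix(rng.normal(size=(15, 4))))
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-12


def scores_frame(X, labels):
    idx = [f"s{i}" for i in range(len(X))]
    return (
        pd.DataFrame(X, index=idx, columns=[f"PC{i+1}" for i in range(X.shape[1])]),
        pd.Series(labels, index=idx),
    )


class TestDFA:
    def test_well_separated_groups(self):
        rng = np.random.default_rng(12)
        a = rng.normal([0, 0], 1, size=(30, 2))
        b = rng.normal([10, 0], 1, size=(30, 2))
        scores, labels = scores_frame(np.vstack([a, b]), ["MAR"] * 30 + ["ATL"] * 30)
        res = diff.dfa(scores, labels, n_components=None)
        assert res.eigenvalues[0] > 10
        ld1 = res.scores["LD1"].to_numpy()
        assert (np.sign(ld1[:30]) != np.sign(ld1[30:])).all()

    def test_permutation_destroys_separation(self):
        rng = np.random.default_rng(13)
        a = rng.normal([0, 0], 1, size=(30, 2))
        b = rng.normal([10, 0], 1, size=(30, 2))
        X = np.vstack([a, b])
        labels = np.array(["MAR"] * 30 + ["ATL"] * 30)
        scores, lab = scores_frame(X, labels)
        original = diff.dfa(scores, lab, n_components=None).eigenvalues[0]
        perm = labels.copy()
        rng.shuffle(perm)
        _, lab_perm = scores_frame(X, perm)
        permuted = diff.dfa(scores, lab_perm, n_components=None).eigenvalues[0]
        assert original / max(permuted, 1e-12) > 20

    def test_identical_groups_zero_eigenvalue(self):
        rng = np.random.default_rng(14)
        block = rng.normal(size=(10, 2))
        X = np.vstack([block, block])
        scores, lab = scores_frame(X, ["MAR"] * 10 + ["ATL"] * 10)
        res = diff.dfa(scores, lab, n_components=None)
        assert res.eigenvalues[0] == pytest.approx(0.0, abs=1e-9)

    def test_axis_count_bounded_by_groups(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 5))
        labels = ["MAR"] * 10 + ["ATL"] * 10 + ["PAC"] * 10
        scores, lab = scores_frame(X, labels)
        res = diff.dfa(scores, lab, n_components=None)
        assert res.eigenvalues.shape[0] == 2  # 3 groups - 1

    def test_matches_sklearn_lda_subspace(self):
        # independent route: sklearn's LDA transform spans the same axes
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(16)
        X = np.vstack(
            [rng.normal([0, 0, 0], 1, size=(25, 3)), rng.normal([3, 1, 0], 1, size=(25, 3))]
        )
        labels = ["MAR"] * 25 + ["ATL"] * 25
        scores, lab = scores_frame(X, labels)
        ours = diff.dfa(scores, lab, n_components=None).scores["LD1"].to_numpy()
        theirs = LinearDiscriminantAnalysis().fit_transform(X, labels).ravel()
        corr = np.corrcoef(ours, theirs)[0, 1]
        assert abs(corr) > 0.9999

    def test_small_groups_projected_not_estimated(self):
        rng = np.random.default_rng(17)
        X = np.vstack(
            [rng.normal(0, 1, size=(20, 2)), rng.normal(5, 1, size=(20, 2)),
             np.array([[100.0, 100.0]])]
        )
        labels = ["MAR"] * 20 + ["ATL"] * 20 + ["PAC"]
        scores, lab = scores_frame(X, labels)
        res = diff.dfa(scores, lab, n_components=None, min_group_size=2)
        assert "PAC" not in res.centroids.index  # excluded from scatter
        assert res.scores.shape[0] == 41  # but still projected


class TestIsolation:
    def _result(self, pts_a, pts_b):
        X = np.array(pts_a + pts_b, dtype=float)
        idx = [f"s{i}" for i in range(len(X))]
        scores = pd.DataFrame(X, index=idx, columns=["LD1", "LD2"][: X.shape[1]])
        groups = pd.Series(["MAR"] * len(pts_a) + ["ATL"] * len(pts_b), index=idx)
        return diff.DFAResult(
            eigenvalues=np.array([1.0]), coefficients=np.eye(X.shape[1]),
            scores=scores, groups=groups, centroids=pd.DataFrame(),
            n_components_used=X.shape[1],
        )

    def test_disjoint_triangles(self):
        res = self._result([(0, 0), (1, 0), (0, 1)], [(5, 5), (6, 5), (5, 6)])
        isolated, overlap = diff.assess_isolation(res, ("MAR", "ATL"))
        assert isolated and overlap == 0.0

    def test_identical_point_sets(self):
        pts = [(0, 0), (1, 0), (0, 1)]
        isolated, overlap = diff.assess_isolation(self._result(pts, list(pts)), ("MAR", "ATL"))
        assert not isolated and overlap == pytest.approx(0.5)

    def test_interlocking_squares_area(self):
        # unit squares offset by (0.5, 0.5): intersection is a 0.5 x 0.5 square
        sq = [(0, 0), (1, 0), (1, 1), (0, 1)]
        shifted = [(x + 0.5, y + 0.5) for x, y in sq]
        isolated, overlap = diff.assess_isolation(self._result(sq, shifted), ("MAR", "ATL"))
        assert not isolated
        assert overlap == pytest.approx(0.25)

    def test_small_group_falls_back_to_interval(self):
        res = self._result([(0, 0), (1, 0)], [(5, 5), (6, 5), (5, 6)])
        isolated, overlap = diff.assess_isolation(res, ("MAR", "ATL"))
        assert isolated and overlap == 0.0
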