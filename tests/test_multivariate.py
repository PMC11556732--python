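"""PERMANOVA, PCA, and PLS-DA/VIP against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from coraltrace.errors import DegenerateDataError
from coraltrace.multivariate import (
    euclidean_distances,
    pca,
    permanova,
    plsda_fit,
    vip_scores,
)
from coraltrace.pools import PoolMatrix


def frame(X, prefix="s"):
    return pd.DataFrame(X, index=[f"{prefix}{i}" for i in range(len(X))])


class TestDistances:
    def test_three_four_five(self):
        d = euclidean_distances(frame([[0.0, 0.0], [3.0, 4.0]]))
        assert d.d[0, 1] == pytest.approx(5.0)
        assert d.d[1, 0] == pytest.approx(5.0)
        assert d.d[0, 0] == 0.0

    def test_identical_rows_and_column_permutation(self, rng):
        X = rng.normal(size=(4, 6))
        X[1] = X[0]
        d1 = euclidean_distances(frame(X))
        assert d1.d[0, 1] == pytest.approx(0.0, abs=1e-12)
        d2 = euclidean_distances(frame(X[:, ::-1]))
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-12)

    def test_requires_log1p_state_for_pool(self):
        pool = PoolMatrix(frame([[1.0, 2.0], [3.0, 4.0]]))
        with pytest.raises(ValueError):
            euclidean_distances(pool)

    def test_rejects_missing_values(self):
        X = frame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            euclidean_distances(X)


class TestPermanova:
    def test_matches_scikit_bio_one_factor(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        X = rng.normal(size=(12, 5))
        X[6:, 0] += 2.0
        f = frame(X)
        design = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=f.index)
        dm = euclidean_distances(f)
        ours = permanova(dm, design, factors=["g"], n_perm=999, seed=5)
        ref = skbio_permanova(SkbioDM(dm.d, ids=dm.sample_ids), design["g"].to_numpy(),
                              permutations=999)
        assert ours.terms[0].pseudo_f == pytest.approx(ref["test statistic"], rel=1e-8)
        assert abs(ours.terms[0].p - ref["p-value"]) < 0.05

    def test_ss_decomposition_conserves_total(self, rng):
        X = rng.normal(size=(16, 4))
        f = frame(X)
        design = pd.DataFrame({
            "a": (["x"] * 4 + ["y"] * 4) * 2,
            "b": ["u"] * 8 + ["v"] * 8,
        }, index=f.index)
        res = permanova(euclidean_distances(f), design, factors=["a", "b"],
                        interaction=True, n_perm=99, seed=0)
        total = sum(t.ss for t in res.terms) + res.residual_ss
        assert total == pytest.approx(res.total_ss, abs=1e-8)
        assert res.residual_df == 16 - 4

    def test_p_value_never_zero_and_uses_plus_one_rule(self, rng):
        X = rng.normal(size=(10, 3))
        X[5:] += 50.0  # overwhelming separation
        design = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5}, index=[f"s{i}" for i in range(10)])
        res = permanova(euclidean_distances(frame(X)), design, n_perm=199, seed=1)
        # only permutations reproducing the exact partition can tie the
        # observed F; the +1 correction keeps p strictly positive
        assert 1 / 200 <= res.terms[0].p <= 4 / 200

    def test_no_between_group_structure_gives_small_f(self):
        X = np.tile(np.arange(4.0).reshape(-1, 1), (2, 3))
        design = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4}, index=[f"s{i}" for i in range(8)])
        res = permanova(euclidean_distances(frame(X)), design, n_perm=99, seed=0)
        assert res.terms[0].ss == pytest.approx(0.0, abs=1e-8)

    def test_single_level_factor_rejected(self):
        X = frame(np.random.default_rng(0).normal(size=(6, 3)))
        design = pd.DataFrame({"g": ["a"] * 6}, index=X.index)
        with pytest.raises(ValueError):
            permanova(euclidean_distances(X), design, n_perm=9, seed=0)

    def test_seeded_runs_are_reproducible(self, rng):
        X = frame(rng.normal(size=(12, 4)))
        design = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6}, index=X.index)
        r1 = permanova(euclidean_distances(X), design, n_perm=99, seed=7)
        r2 = permanova(euclidean_distances(X), design, n_perm=99, seed=7)
        assert r1.terms[0].p == r2.terms[0].p


class TestPca:
    def test_collinear_data_explained_by_pc1(self):
        X = frame(np.outer(np.arange(5.0), [1.0, 2.0]))
        res = pca(X)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_are_centered(self, rng):
        res = pca(frame(rng.normal(size=(8, 4))))
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_isotropic_noise_spreads_variance(self, rng):
        res = pca(frame(rng.normal(size=(2000, 4))))
        assert res.explained_variance_ratio.max() < 0.30

    def test_constant_column_with_scaling_is_degenerate(self):
        X = frame([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(DegenerateDataError):
            pca(X, scale=True)


def _discriminant_data(rng, n=24, p=20, snr=3.0, dense_axis=False):
    """Two groups separated along a known axis.

    ``dense_axis`` spreads the class difference over every variable (each
    shifted by ``snr`` within-group standard deviations, i.e. per-variable
    signal-to-noise ``snr``); otherwise the shift sits on the single variable
    m0. Returns the unit generative axis for cosine comparisons.
    """
    labels = pd.Series(["ambient"] * (n // 2) + ["high"] * (n // 2),
                       index=[f"s{i}" for i in range(n)])
    X = rng.normal(size=(n, p))
    if dense_axis:
        X[n // 2:] += snr
        axis = np.ones(p) / np.sqrt(p)
    else:
        X[n // 2:, 0] += snr
        axis = np.zeros(p)
        axis[0] = 1.0
    return pd.DataFrame(X, index=labels.index, columns=[f"m{j}" for j in range(p)]), labels, axis


class TestPlsda:
    def test_weight_concentrates_on_informative_variable(self, rng):
        X, labels, _ = _discriminant_data(rng, snr=5.0)
        model = plsda_fit(X, labels)
        w1 = np.abs(model.x_weights[:, 0])
        assert w1[0] == w1.max()
        assert w1[0] ** 2 > 0.4  # majority of the weight mass minus noise floor

    def test_recovers_known_discriminant_axis(self):
        # axis spread over all variables; noise floor leaves cos ~ sqrt(1/(1+p/(n*snr^2)))
        cosines = []
        for seed in range(10):
            local = np.random.default_rng(seed)
            X, labels, axis = _discriminant_data(local, n=24, p=20, snr=3.0,
                                                 dense_axis=True)
            model = plsda_fit(X, labels)
            w1 = model.x_weights[:, 0]
            cosines.append(abs(w1 @ axis) / np.linalg.norm(axis))
        assert np.mean(cosines) > 0.95

    def test_scores_orthogonal_and_deterministic(self, rng):
        X, labels, _ = _discriminant_data(rng)
        m1 = plsda_fit(X, labels)
        m2 = plsda_fit(X, labels)
        t = m1.x_scores
        assert abs(t[:, 0] @ t[:, 1]) < 1e-8
        np.testing.assert_array_equal(m1.x_weights, m2.x_weights)

    def test_matches_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.cross_decomposition import PLSRegression

        X, labels, _ = _discriminant_data(rng)
        model = plsda_fit(X, labels)
        Y = np.column_stack([(labels == c).to_numpy(float) for c in model.classes])
        ref = PLSRegression(n_components=2, scale=True).fit(X.to_numpy(), Y)
        for a in range(2):
            cos = abs(model.x_weights[:, a] @ ref.x_weights_[:, a])
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_label_permutation_destroys_discrimination(self, rng):
        # out-of-sample score separation: real labels separate held-out
        # samples; permuted labels do not (in-sample fit overfits either way)
        def heldout_separation(labels):
            train = [f"s{i}" for i in range(0, 24, 2)]
            test = [f"s{i}" for i in range(1, 24, 2)]
            model = plsda_fit(X.loc[train], labels.loc[train])
            t1 = pd.Series(model.transform(X.loc[test])[:, 0], index=test)
            by = t1.groupby(labels.loc[test])
            pooled = np.sqrt(by.var().mean())
            return abs(by.mean().diff().iloc[-1]) / pooled

        X, labels, _ = _discriminant_data(rng, snr=3.0, dense_axis=True)
        real = heldout_separation(labels)
        perms = []
        for _ in range(20):
            shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            perms.append(heldout_separation(shuffled))
        assert real > np.percentile(perms, 95)

    def test_explained_variance_fractions_valid(self, rng):
        X, labels, _ = _discriminant_data(rng)
        model = plsda_fit(X, labels)
        assert ((model.explained_x_variance >= 0) & (model.explained_x_variance <= 1)).all()
        assert model.explained_x_variance.sum() <= 1.0 + 1e-9

    def test_single_class_rejected(self, rng):
        X, labels, _ = _discriminant_data(rng)
        with pytest.raises(ValueError):
            plsda_fit(X, pd.Series("high", index=X.index))


class TestVip:
    def test_mean_square_normalization(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            X, labels, _ = _discriminant_data(local)
            table = vip_scores(plsda_fit(X, labels))
            assert (table["vip"] ** 2).sum() == pytest.approx(len(table), abs=1e-8)

    def test_informative_variable_scores_above_noise(self, rng):
        X, labels, _ = _discriminant_data(rng, snr=5.0)
        table = vip_scores(plsda_fit(X, labels)).set_index("metabolite")
        assert table.loc["m0", "vip"] > 1.0
        assert table.loc["m0", "selected"]
        assert table.drop("m0")["vip"].mean() < 1.0

    def test_threshold_is_inclusive(self, rng):
        X, labels, _ = _discriminant_data(rng)
        table = vip_scores(plsda_fit(X, labels), threshold=0.0)
        assert table["selected"].all()
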