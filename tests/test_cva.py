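"""Canonical variates: axes, classification, posteriors, distance tests."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import sciurmorph as sm

from conftest import tangent_dataset


def grouped_tangent_dataset(rng, offsets, n_per=20, noise=1.0, d=28):
    """Gaussian groups around a consensus; offsets maps group -> 2k vector."""
    c = rng.normal(size=d)
    c /= np.linalg.norm(c)
    rows, diets = [], []
    for grp, off in offsets.items():
        for _ in range(n_per):
            rows.append(c + np.asarray(off) + rng.normal(0, noise, d))
            diets.append(grp)
    return tangent_dataset(
        np.stack(rows), c.reshape(-1, 2), diets=diets,
        taxa=[f"t{i}" for i in range(len(rows))],
    )


DIET7 = ["fruits", "nuts", "seeds", "leaves", "herbivore_ss", "bark_gleaner",
         "insects"]


class TestFit:
    def test_two_group_axis_matches_closed_form(self, rng):
        """CV1 for two groups is proportional to W^-1 (mu1 - mu2), and the
        canonical separation equals the Mahalanobis distance; cross-checked
        against scikit-learn's LDA direction."""
        off = rng.normal(0, 0.5, 28)
        ds = grouped_tangent_dataset(
            rng, {"nuts": off, "seeds": -off}, n_per=40, noise=0.8
        )
        model = sm.fit_cva(ds, "diet")
        Z = model.reduce(ds.tangent_coords)
        labels = np.array(ds.diets)
        mu1 = Z[labels == "nuts"].mean(axis=0)
        mu2 = Z[labels == "seeds"].mean(axis=0)
        closed = model.winv @ (mu1 - mu2)
        v = model.axes_reduced[0]
        cos = abs(closed @ v) / (np.linalg.norm(closed) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-8)
        # canonical group separation = Mahalanobis distance between means
        d_canon = abs(
            (model.group_means_canonical[0] - model.group_means_canonical[1])[0]
        )
        d_mahal = np.sqrt((mu1 - mu2) @ model.winv @ (mu1 - mu2))
        assert d_canon == pytest.approx(d_mahal, rel=1e-8)
        # independent implementation: sklearn LDA coefficient direction
        lda = LinearDiscriminantAnalysis(solver="eigen").fit(Z, labels)
        w = lda.coef_[0]
        cos_lda = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
        assert cos_lda == pytest.approx(1.0, abs=1e-6)

    def test_axis_count_bounded_by_groups(self, rng):
        offsets = {g: rng.normal(0, 0.5, 28) for g in DIET7[:4]}
        model = sm.fit_cva(grouped_tangent_dataset(rng, offsets, n_per=15), "diet")
        assert model.axes_reduced.shape[0] <= 3

    def test_canonical_scores_have_unit_within_variance(self, rng):
        offsets = {g: rng.normal(0, 0.5, 28) for g in DIET7[:5]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=25)
        model = sm.fit_cva(ds, "diet")
        scores = model.canonical_scores(ds.tangent_coords)
        labels = np.array(ds.diets)
        n, g = len(labels), len(model.groups)
        pooled = np.zeros(scores.shape[1])
        for grp in model.groups:
            s = scores[labels == grp]
            pooled += ((s - s.mean(axis=0)) ** 2).sum(axis=0)
        np.testing.assert_allclose(pooled / (n - g), 1.0, atol=1e-9)

    def test_singleton_group_excluded_with_warning(self, rng):
        offsets = {g: rng.normal(0, 0.5, 28) for g in DIET7[:3]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=10)
        ds.specimens[0] = type(ds.specimens[0])(
            configuration=ds.specimens[0].configuration,
            taxon=ds.specimens[0].taxon,
            diet="insects",
            locomotion=ds.specimens[0].locomotion,
        )
        with pytest.warns(RuntimeWarning, match="insects"):
            model = sm.fit_cva(ds, "diet")
        assert "insects" not in model.groups

    def test_classification_invariant_to_linear_transform(self, rng):
        """Mahalanobis assignments are unchanged by an invertible linear map
        applied consistently to the tangent rows within the fitted subspace."""
        offsets = {g: rng.normal(0, 0.6, 28) for g in DIET7[:3]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=15)
        model = sm.fit_cva(ds, "diet")
        t1 = sm.classify_specimens(model, ds, "diet")
        # transform within the reduced subspace, then map back
        P = model.reduction_basis
        r = P.shape[0]
        A = rng.normal(size=(r, r)) + 3 * np.eye(r)
        Z = model.reduce(ds.tangent_coords)
        rows2 = (Z @ A.T) @ P + model.center
        ds2 = tangent_dataset(rows2, ds.consensus, diets=ds.diets,
                              taxa=ds.taxa)
        model2 = sm.fit_cva(ds2, "diet", subspace_cap=r)
        t2 = sm.classify_specimens(model2, ds2, "diet")
        assert (t1.table["predicted"] == t2.table["predicted"]).all()


class TestClassification:
    def test_specimen_at_group_mean_has_high_posterior(self, rng):
        offsets = {g: 10 * rng.normal(0, 1, 28) for g in DIET7[:3]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=20, noise=0.5)
        model = sm.fit_cva(ds, "diet")
        labels = np.array(ds.diets)
        Y = ds.tangent_coords
        for j, grp in enumerate(model.groups):
            mean_row = Y[labels == grp].mean(axis=0)[None, :]
            d2 = model.mahalanobis_sq(mean_row)
            w = np.exp(-(d2 - d2.min()) / 2)
            assert (w / w.sum())[0, j] > 0.99

    def test_posteriors_sum_to_one(self, rng):
        offsets = {g: rng.normal(0, 0.5, 28) for g in DIET7[:4]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=12)
        model = sm.fit_cva(ds, "diet")
        table = sm.classify_specimens(model, ds, "diet").table
        post = table[[f"p_{g}" for g in model.groups]].to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_equidistant_specimen_splits_posterior(self, rng):
        off = rng.normal(0, 2, 28)
        ds = grouped_tangent_dataset(
            rng, {"nuts": off, "seeds": -off, "leaves": 40 * off}, n_per=30,
            noise=0.5,
        )
        model = sm.fit_cva(ds, "diet")
        labels = np.array(ds.diets)
        Y = ds.tangent_coords
        mid = (
            Y[labels == "nuts"].mean(axis=0) + Y[labels == "seeds"].mean(axis=0)
        ) / 2
        d2 = model.mahalanobis_sq(mid[None, :])
        w = np.exp(-(d2 - d2.min()) / 2)
        post = (w / w.sum())[0]
        i_nuts = model.groups.index("nuts")
        i_seeds = model.groups.index("seeds")
        assert post[i_nuts] == pytest.approx(0.5, abs=0.05)
        assert post[i_seeds] == pytest.approx(0.5, abs=0.05)

    def test_ungrouped_specimen_classified_without_entering_fit(self, rng):
        offsets = {g: 5 * rng.normal(0, 1, 28) for g in DIET7[:3]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=15, noise=0.5)
        # relabel one specimen as ungrouped (the 'fossil')
        from dataclasses import replace

        target = ds.specimens[0]
        ds.specimens[0] = replace(target, diet="ungrouped")
        model = sm.fit_cva(ds, "diet")
        table = sm.classify_specimens(model, ds, "diet").table
        fossil = table.iloc[0]
        assert fossil["true_group"] == "ungrouped"
        assert fossil["predicted"] in model.groups
        assert fossil[f"p_{fossil['predicted']}"] > 1 / 3

    def test_loo_below_resubstitution_on_average(self, rng):
        """Cross-validated accuracy does not exceed resubstitution accuracy
        on average (moderately separated groups)."""
        diffs = []
        for s in range(15):
            r = np.random.default_rng(900 + s)
            offsets = {g: r.normal(0, 0.35, 28) for g in DIET7[:4]}
            ds = grouped_tangent_dataset(r, offsets, n_per=10)
            model = sm.fit_cva(ds, "diet")
            t = sm.classify_specimens(model, ds, "diet", cross_validate=True)
            diffs.append(t.percent_correct - t.percent_correct_cv)
        assert np.mean(diffs) >= 0

    def test_confusion_rows_sum_to_100(self, rng):
        offsets = {g: rng.normal(0, 0.5, 28) for g in DIET7[:4]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=12)
        model = sm.fit_cva(ds, "diet")
        t = sm.classify_specimens(model, ds, "diet", cross_validate=True)
        np.testing.assert_allclose(t.confusion.sum(axis=1), 100.0, atol=1e-9)
        np.testing.assert_allclose(t.confusion_cv.sum(axis=1), 100.0, atol=1e-9)


class TestGroupDistances:
    def test_matrix_symmetric_zero_diagonal(self, rng):
        offsets = {g: rng.normal(0, 0.05, 28) for g in DIET7[:4]}
        ds = grouped_tangent_dataset(rng, offsets, n_per=10, noise=0.02)
        dist, pvals = sm.group_distance_tests(ds, "diet", n_perm=99, seed=0)
        np.testing.assert_allclose(dist.to_numpy(), dist.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(dist.to_numpy()), 0, atol=1e-12)
        p = pvals.to_numpy()
        np.testing.assert_allclose(p, p.T, atol=0)

    def test_large_offset_reaches_minimal_p(self, rng):
        # offsets well above the noise but inside the small-shape regime
        off = rng.normal(0, 1, 28)
        off *= 0.05 / np.linalg.norm(off)
        ds = grouped_tangent_dataset(
            rng, {"nuts": off, "seeds": -off}, n_per=15, noise=0.002
        )
        _, pvals = sm.group_distance_tests(ds, "diet", n_perm=199, seed=0)
        assert pvals.loc["nuts", "seeds"] == pytest.approx(1 / 200)

    def test_null_split_p_uniform(self):
        """Splitting one homogeneous group at random gives uniform p
        (Kolmogorov-Smirnov over simulations)."""
        from scipy import stats

        ps = []
        for s in range(60):
            r = np.random.default_rng(40_000 + s)
            ds = grouped_tangent_dataset(
                r, {"nuts": np.zeros(28), "seeds": np.zeros(28)}, n_per=12,
                noise=1.0,
            )
            _, pvals = sm.group_distance_tests(ds, "diet", n_perm=99, seed=s)
            ps.append(pvals.loc["nuts", "seeds"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
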