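import itertools

import numpy as np
import pandas as pd
import pytest

from metabotyper import integrate as ig
from metabotyper.integrate import (ComponentModel, IntegrateError,
                                   apply_retention, cascade_reduce,
                                   combined_fa, compute_kmo, decorrelate,
                                   fit_mlfa, fit_pca, regression_scores,
                                   select_n_components, standardize,
                                   varimax_rotate)


def _table(X, prefix="v"):
    return pd.DataFrame(
        X, index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"{prefix}{j}" for j in range(X.shape[1])])


def _model_from_loadings(L, variables=None, method="mlfa"):
    variables = variables or [f"v{i}" for i in range(L.shape[0])]
    loadings = pd.DataFrame(np.asarray(L, float), index=variables,
                            columns=[f"F{j+1}" for j in range(L.shape[1])])
    share = (loadings ** 2).sum(axis=0).to_numpy() / len(variables)
    uniq = None
    if method == "mlfa":
        uniq = pd.Series(
            np.clip(1 - (loadings ** 2).sum(axis=1), 0.005, 1.0),
            index=variables)
    return ComponentModel(method=method, rotation="varimax",
                          variable_ids=variables, loadings=loadings,
                          variance_share=share,
                          cumulative_variance=float(share.sum()), kmo=0.8,
                          uniquenesses=uniq)


# ---------------------------------------------------------------------------
# decorrelation
# ---------------------------------------------------------------------------

def decorrelate_oracle(corr: pd.DataFrame, threshold: float) -> list[str]:
    """Literal restatement of the drop rule, recomputed from scratch."""
    alive = list(corr.columns)
    while True:
        best = None
        for a, b in itertools.combinations(alive, 2):
            r = abs(corr.loc[a, b])
            if r >= threshold and (best is None or r > best[0] + 1e-12 or
                                   (abs(r - best[0]) <= 1e-12
                                    and (a, b) < best[1])):
                best = (r, tuple(sorted((a, b))))
        if best is None:
            return alive
        a, b = best[1]
        others = [v for v in alive if v not in (a, b)]
        ma = np.mean([abs(corr.loc[a, o]) for o in others]) if others else 0
        mb = np.mean([abs(corr.loc[b, o]) for o in others]) if others else 0
        if not np.isclose(ma, mb):
            drop = a if ma > mb else b
        else:
            drop = max(a, b)
        alive.remove(drop)


class TestDecorrelate:
    def test_perfect_pair_drops_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = np.column_stack([x, x, rng.standard_normal(50)])
        tables, results = decorrelate({"p": standardize(_table(X))})
        assert len(tables["p"].columns) == 2
        intra = [r for r in results if r.stage == "intra"][0]
        assert len(intra.dropped_features) == 1

    def test_below_threshold_identity(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 5))
        tables, _ = decorrelate({"p": standardize(_table(X))})
        assert list(tables["p"].columns) == [f"v{j}" for j in range(5)]

    def test_planted_triplet_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(80)
        X = np.column_stack([
            base + 0.15 * rng.standard_normal(80),
            base + 0.15 * rng.standard_normal(80),
            base + 0.15 * rng.standard_normal(80),
            rng.standard_normal(80),
            rng.standard_normal(80),
            rng.standard_normal(80),
        ])
        Z = standardize(_table(X))
        tables, _ = decorrelate({"p": Z}, threshold=0.9)
        expected = decorrelate_oracle(Z.corr(), 0.9)
        assert list(tables["p"].columns) == expected

    def test_inter_matrix_stage_drops_cross_duplicates(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        A = standardize(_table(np.column_stack(
            [x, rng.standard_normal(50)]), "a"))
        B = standardize(_table(np.column_stack(
            [x + 0.01 * rng.standard_normal(50),
             rng.standard_normal(50), rng.standard_normal(50)]), "b"))
        tables, results = decorrelate({"A": A, "B": B}, threshold=0.9)
        total = sum(t.shape[1] for t in tables.values())
        assert total == 4
        inter = [r for r in results if r.stage == "inter"]
        assert sum(len(r.dropped_features) for r in inter) == 1

    def test_invalid_threshold(self):
        with pytest.raises(IntegrateError):
            decorrelate({"p": _table(np.eye(4))}, threshold=1.5)


# ---------------------------------------------------------------------------
# KMO
# ---------------------------------------------------------------------------

class TestKmo:
    def test_two_by_two_is_half(self):
        for r in (0.3, -0.8, 0.99):
            corr = np.array([[1.0, r], [r, 1.0]])
            assert compute_kmo(corr) == pytest.approx(0.5)

    def test_identity_errors(self):
        with pytest.raises(IntegrateError, match="no correlations"):
            compute_kmo(np.eye(4))

    def test_three_by_three_hand_inverse(self):
        # R = (1-r)I + r J with r=0.5: R^-1 has diagonal 1.5 and
        # off-diagonal -0.5; partials p_ij = 0.5/1.5 = 1/3
        r, p = 0.5, 1.0 / 3.0
        corr = np.full((3, 3), r)
        np.fill_diagonal(corr, 1.0)
        expected = (3 * r ** 2) / (3 * r ** 2 + 3 * p ** 2)
        assert compute_kmo(corr) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# component-number selection
# ---------------------------------------------------------------------------

class TestSelectNComponents:
    def test_kaiser_plus_cumvar_satisfied(self):
        n, diag = select_n_components([2.5, 1.2, 0.8, 0.5], n_variables=5)
        assert n == 2
        assert diag.kaiser_n == 2
        assert diag.cumulative_variance == pytest.approx(0.74)

    def test_floor_of_one(self):
        # Kaiser count is zero but at least one component is always kept
        n, diag = select_n_components([0.9], n_variables=1)
        assert n == 1
        assert diag.kaiser_n == 0

    def test_grows_toward_cumvar_capped_at_available(self):
        n, _ = select_n_components([1.5, 1.1, 1.0, 0.9, 0.5], n_variables=10)
        assert n == 5   # kaiser 2, cumvar never reached, capped at len

    def test_empty_errors(self):
        with pytest.raises(IntegrateError):
            select_n_components([], n_variables=3)


# ---------------------------------------------------------------------------
# varimax
# ---------------------------------------------------------------------------

class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.zeros((6, 2))
        L[:3, 0] = [0.9, 0.8, 0.85]
        L[3:, 1] = [0.7, 0.75, 0.8]
        R = varimax_rotate(L)
        np.testing.assert_allclose(R, L, atol=1e-6)

    def test_recovers_known_rotation_mixing(self):
        L = np.zeros((8, 2))
        L[:4, 0] = [0.9, 0.82, 0.86, 0.78]
        L[4:, 1] = [0.8, 0.72, 0.76, 0.68]
        theta = np.pi / 6
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        R = varimax_rotate(L @ rot)
        np.testing.assert_allclose(R, L, atol=1e-4)

    def test_preserves_row_communalities(self):
        rng = np.random.default_rng(5)
        L = rng.normal(0, 0.5, (12, 3))
        R = varimax_rotate(L)
        np.testing.assert_allclose((R ** 2).sum(axis=1),
                                   (L ** 2).sum(axis=1), atol=1e-10)

    def test_sign_and_order_convention(self):
        rng = np.random.default_rng(6)
        L = rng.normal(0, 0.5, (10, 3))
        R = varimax_rotate(L)
        for j in range(R.shape[1]):
            assert R[np.argmax(np.abs(R[:, j])), j] > 0
        ss = (R ** 2).sum(axis=0)
        assert np.all(np.diff(ss) <= 1e-12)

    def test_single_column_unchanged_up_to_sign(self):
        L = np.array([[0.5], [-0.9], [0.2]])
        R = varimax_rotate(L)
        np.testing.assert_allclose(R[:, 0], [-0.5, 0.9, -0.2])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestFitPca:
    def test_two_variable_closed_form(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(4000)
        X = np.column_stack([z, 0.8 * z + 0.6 * rng.standard_normal(4000)])
        model = fit_pca(_table(X), 1)
        # eigenvalues of a 2x2 correlation matrix are 1 +/- r
        assert model.eigenvalues[0] == pytest.approx(1.8, abs=0.03)

    def test_uncorrelated_data_flat_spectrum(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((600, 6))
        model = fit_pca(_table(X), 2)
        assert np.all(np.abs(model.eigenvalues - 1.0) < 0.25)

    def test_noiseless_block_eigenvalue_equals_block_size(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((300, 1))
        X = np.hstack([np.tile(z, (1, 4)) + 1e-6 * rng.standard_normal((300, 4)),
                       rng.standard_normal((300, 3))])
        model = fit_pca(_table(X), 2)
        assert model.eigenvalues[0] == pytest.approx(4.0, abs=0.1)

    def test_n_too_large_errors(self):
        X = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(IntegrateError):
            fit_pca(_table(X), 4)


# ---------------------------------------------------------------------------
# ML factor analysis
# ---------------------------------------------------------------------------

class TestFitMlfa:
    def test_single_factor_parameter_recovery(self):
        rng = np.random.default_rng(10)
        n = 5000
        z = rng.standard_normal((n, 1))
        lam = 0.8
        X = lam * z + np.sqrt(1 - lam ** 2) * rng.standard_normal((n, 6))
        model = fit_mlfa(_table(X), 1)
        np.testing.assert_allclose(np.abs(model.loadings.to_numpy()[:, 0]),
                                   lam, atol=0.05)

    def test_zero_factors_errors(self):
        X = np.random.default_rng(0).standard_normal((50, 5))
        with pytest.raises(IntegrateError):
            fit_mlfa(_table(X), 0)

    def test_fit_beats_principal_axis_start(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal((300, 2))
        L = np.zeros((7, 2))
        L[:4, 0] = 0.8
        L[4:, 1] = 0.7
        X = z @ L.T + 0.5 * rng.standard_normal((300, 7))
        Z = standardize(_table(X))
        S = np.corrcoef(Z.to_numpy(), rowvar=False)
        model = fit_mlfa(Z, 2)
        lam0, psi0 = ig._principal_axis_start(S, 2)
        f_start = ig._ml_discrepancy(S, lam0, psi0)
        lam_fit = model.loadings.to_numpy()
        psi_fit = model.uniquenesses.to_numpy()
        f_fit = ig._ml_discrepancy(S, lam_fit, psi_fit)
        assert f_fit <= f_start + 1e-6

    def test_communality_plus_uniqueness_is_one(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((120, 6))
        X[:, :3] += rng.standard_normal((120, 1))
        model = fit_mlfa(_table(X), 2)
        comm = (model.loadings ** 2).sum(axis=1)
        np.testing.assert_allclose(comm + model.uniquenesses, 1.0, atol=1e-6)

    def test_agrees_with_sklearn_factor_analysis(self):
        """Independent route: sklearn's ML factor analysis, same model."""
        from sklearn.decomposition import FactorAnalysis
        rng = np.random.default_rng(13)
        z = rng.standard_normal((2000, 2))
        L = np.zeros((8, 2))
        L[:4, 0] = 0.85
        L[4:, 1] = 0.75
        X = z @ L.T + 0.5 * rng.standard_normal((2000, 8))
        Z = standardize(_table(X))
        ours = fit_mlfa(Z, 2)
        fa = FactorAnalysis(n_components=2, svd_method="lapack")
        fa.fit(Z.to_numpy())
        ref = varimax_rotate(fa.components_.T)
        np.testing.assert_allclose(np.abs(ours.loadings.to_numpy()),
                                   np.abs(ref), atol=0.03)


# ---------------------------------------------------------------------------
# retention (double-saturation rule)
# ---------------------------------------------------------------------------

class TestApplyRetention:
    @pytest.mark.parametrize("row, retained, reason, component", [
        ((0.83, -0.08, -0.06, 0.03, 0.19, -0.09), True, "kept", 0),
        ((0.60, 0.55), False, "double_saturation", None),
        ((0.45, 0.10), False, "below_threshold", None),
        ((0.51, 0.41), True, "kept", 0),        # gap exactly 0.10 retained
        ((0.50, 0.10), False, "below_threshold", None),  # strict threshold
    ])
    def test_rule_boundaries(self, row, retained, reason, component):
        model = _model_from_loadings(np.array([row]))
        d = apply_retention(model)[0]
        assert d.retained is retained
        assert d.reason == reason
        assert d.assigned_component == component

    def test_single_component_gap_vacuous(self):
        model = _model_from_loadings(np.array([[0.7], [0.3]]))
        ds = apply_retention(model)
        assert ds[0].retained and not ds[1].retained

    def test_variable_permutation_only_permutes_decisions(self):
        rng = np.random.default_rng(14)
        L = rng.normal(0, 0.45, (9, 3))
        model = _model_from_loadings(L)
        perm = rng.permutation(9)
        model_p = _model_from_loadings(L[perm],
                                       variables=[f"v{i}" for i in perm])
        got = {d.variable: d.retained for d in apply_retention(model)}
        got_p = {d.variable: d.retained for d in apply_retention(model_p)}
        assert got == got_p


# ---------------------------------------------------------------------------
# cascade + combined FA + scores
# ---------------------------------------------------------------------------

def _block_table(rng, n=150, block=10, noise=0.45, extra=6):
    z = rng.standard_normal((n, 1))
    X = np.hstack([0.8 * z + noise * rng.standard_normal((n, block)),
                   rng.standard_normal((n, extra))])
    return standardize(_table(X))


class TestCascadeReduce:
    def test_clean_block_fully_retained_one_factor(self):
        rng = np.random.default_rng(15)
        table = _block_table(rng, extra=0)
        res = cascade_reduce(table, "toy")
        assert res.fa_model.n_components == 1
        assert res.retained_table.shape[1] == 10

    def test_pure_noise_retains_few_variables(self):
        kept = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            table = standardize(_table(rng.standard_normal((100, 20))))
            res = cascade_reduce(table, "noise")
            kept.append(res.retained_table.shape[1] / 20)
        assert np.mean(kept) <= 0.10

    def test_under_four_variables_contributes_nothing(self):
        rng = np.random.default_rng(16)
        table = standardize(_table(rng.standard_normal((50, 3))))
        res = cascade_reduce(table, "tiny")
        assert res.retained_table.shape[1] == 0


class TestCombinedFa:
    def test_single_table_pooling_matches_platform_fa(self):
        rng = np.random.default_rng(17)
        table = _block_table(rng, extra=0)
        cas = cascade_reduce(table, "one")
        model, decisions = combined_fa([cas.retained_table])
        assert model.n_components == cas.fa_model.n_components
        np.testing.assert_allclose(
            np.abs(model.loadings.to_numpy()),
            np.abs(cas.fa_model.loadings.loc[model.loadings.index].to_numpy()),
            atol=0.02)

    def test_noiseless_blocks_recover_exactly_one_factor_each(self):
        rng = np.random.default_rng(18)
        z = rng.standard_normal((200, 2))
        tables = []
        for f in range(2):
            X = (0.9 * z[:, [f]]
                 + 0.1 * rng.standard_normal((200, 5)))
            tables.append(standardize(_table(X, prefix=f"p{f}_")))
        model, decisions = combined_fa(tables)
        assert model.n_components == 2
        assigned = {d.variable: d.assigned_component for d in decisions
                    if d.retained}
        assert len(assigned) == 10
        for f in range(2):
            comps = {assigned[f"p{f}_{j}"] for j in range(5)}
            assert len(comps) == 1


class TestRegressionScores:
    def test_orthonormal_identity_closed_form(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((2000, 4))
        Z = standardize(_table(X))
        L = np.array([[1.0, 0], [0, 1.0], [0, 0], [0, 0]])
        model = _model_from_loadings(L, variables=list(Z.columns))
        scores = regression_scores(model, Z)
        # with orthonormal loadings and near-identity sample correlation the
        # regression scores reduce to Z @ Lambda
        np.testing.assert_allclose(scores.scores.to_numpy(),
                                   Z.to_numpy() @ L, atol=0.15)

    def test_column_means_are_zero(self):
        rng = np.random.default_rng(20)
        table = _block_table(rng)
        cas = cascade_reduce(table, "p")
        scores = regression_scores(cas.fa_model, table)
        assert np.abs(scores.scores.mean(axis=0)).max() < 1e-8
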