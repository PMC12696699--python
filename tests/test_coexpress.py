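"""Coexpression core: correlation, adjacency, soft threshold, TOM, modules."""

import numpy as np
import pandas as pd
import pytest

import modgrn as mg
from modgrn import coexpress
from modgrn.coexpress import (
    CorrelationError,
    scale_free_fit,
    select_key_genes,
)


def frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestPearson:
    def test_perfect_and_anti_linear(self):
        X = frame([[1, 2, 3], [2, 4, 6], [3, 2, 1]])
        C = mg.pearson_correlation(X)
        assert C.iloc[0, 1] == pytest.approx(1.0)
        assert C.iloc[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_matches_per_pair_covariance_formula(self, rng):
        X = frame(rng.normal(size=(10, 8)))
        C = mg.pearson_correlation(X).to_numpy()
        vals = X.to_numpy()
        for i in range(10):
            for j in range(10):
                xi, xj = vals[i], vals[j]
                cov = ((xi - xi.mean()) * (xj - xj.mean())).mean()
                r = cov / (xi.std() * xj.std())
                assert C[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_gene_rejected(self):
        X = frame([[1, 1, 1], [1, 2, 3]], genes=["flat", "ok"])
        with pytest.raises(CorrelationError, match="flat"):
            mg.pearson_correlation(X)


class TestSignedAdjacency:
    @pytest.mark.parametrize(
        "cor,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5**6)]
    )
    def test_spot_values_beta6(self, cor, expected):
        C = frame([[1.0, cor], [cor, 1.0]])
        A = mg.signed_adjacency(C, beta=6)
        assert A.iloc[0, 1] == pytest.approx(expected, abs=1e-15)

    def test_invalid_beta(self):
        C = frame(np.eye(2))
        with pytest.raises(ValueError):
            mg.signed_adjacency(C, beta=0)

    def test_offdiag_nonincreasing_in_beta(self, rng):
        C = mg.pearson_correlation(frame(rng.normal(size=(6, 12))))
        prev = None
        for b in (1, 2, 4, 6):
            A = mg.signed_adjacency(C, b).to_numpy()
            off = A[~np.eye(6, dtype=bool)]
            if prev is not None:
                assert (off <= prev + 1e-12).all()
            prev = off


class TestSoftThreshold:
    def test_smallest_beta_rule_with_injected_fits(self, monkeypatch, rng):
        fits = {2: 0.4, 4: 0.86, 6: 0.9}
        seq = iter([2, 4, 6])
        monkeypatch.setattr(
            coexpress, "scale_free_fit", lambda K, n_bins=10: fits[next(seq)]
        )
        X = frame(rng.normal(size=(8, 10)))
        scan = mg.pick_soft_threshold(X, betas=[2, 4, 6], fit_cut=0.85)
        assert scan.chosen_beta == 4

    def test_degenerate_connectivity_recorded_missing(self):
        # all K equal -> single bin -> fit undefined
        assert np.isnan(scale_free_fit(np.full(20, 3.0)))

    def test_fit_trend_and_connectivity_on_synth(self, synth_default_logX):
        scan = mg.pick_soft_threshold(synth_default_logX, betas=[1, 2, 4, 6])
        mk = scan.mean_connectivity
        assert all(mk[i] > mk[i + 1] for i in range(len(mk) - 1))
        fit = dict(zip(scan.betas, scan.fit_index))
        # soft thresholding drives the degree distribution toward scale-free
        assert fit[6] > fit[1]
        assert fit[2] < fit[4] < fit[6]

    def test_mean_connectivity_strictly_decreasing_forced(self, rng):
        C = mg.pearson_correlation(frame(rng.normal(size=(10, 15))))
        scan = mg.pick_soft_threshold(
            frame(rng.normal(size=(10, 15))), betas=[1, 3, 5], corr=C
        )
        assert scan.mean_connectivity[0] > scan.mean_connectivity[1] > scan.mean_connectivity[2]


def tom_triple_loop(A):
    """Independent oracle: explicit sums over the shared-neighbour index."""
    A = np.asarray(A, dtype=float)
    m = A.shape[0]
    T = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                T[i, j] = 1.0
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(m) if u not in (i, j))
            Ki = sum(A[i, u] for u in range(m) if u != i)
            Kj = sum(A[j, u] for u in range(m) if u != j)
            T[i, j] = (shared + A[i, j]) / (min(Ki, Kj) + 1 - A[i, j])
    return T


class TestTOM:
    def test_three_gene_spot_value(self):
        A = frame(np.full((3, 3), 0.5))
        np.fill_diagonal(A.values, 1.0)
        T = mg.tom(A)
        # K_i = 1; TOM_12 = (0.25 + 0.5) / (1 + 1 - 0.5)
        assert T.iloc[0, 1] == pytest.approx(0.5)

    def test_zero_adjacency_gives_zero_overlap(self):
        A = frame(np.eye(4))
        T = mg.tom(A).to_numpy()
        assert (T[~np.eye(4, dtype=bool)] == 0).all()

    def test_matrix_equals_triple_loop_oracle(self, rng):
        raw = rng.uniform(0, 1, size=(20, 20))
        A = (raw + raw.T) / 2
        np.fill_diagonal(A, 1.0)
        T = mg.tom(frame(A)).to_numpy()
        np.testing.assert_allclose(T, tom_triple_loop(A), atol=1e-10)

    def test_symmetry_and_range(self, rng):
        raw = rng.uniform(0, 1, size=(15, 15))
        A = (raw + raw.T) / 2
        np.fill_diagonal(A, 1.0)
        T = mg.tom(frame(A)).to_numpy()
        np.testing.assert_allclose(T, T.T, atol=1e-12)
        assert T.min() >= 0 and T.max() <= 1 + 1e-12

    def test_asymmetric_input_rejected(self):
        A = frame([[1.0, 0.2], [0.8, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mg.tom(A)


class TestModuleDetection:
    def _block_tom(self, rng, sizes, within=0.95, between=0.02):
        m = sum(sizes)
        T = np.full((m, m), between)
        start = 0
        for s in sizes:
            T[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(T, 1.0)
        genes = [f"g{i}" for i in range(m)]
        # expression consistent with the blocks, for eigengene computation
        X = np.repeat(rng.normal(size=(len(sizes), 40)), sizes, axis=0)
        X = X + 0.05 * rng.normal(size=X.shape)
        return frame(T, genes=genes, samples=None), frame(X, genes=genes)

    def test_two_perfect_blocks(self, rng):
        T, X = self._block_tom(rng, [5, 5])
        assign = mg.detect_modules(T, X, min_size=2)
        assert len(assign.modules) == 2
        assert (assign.labels != 0).all()
        first_block = set(assign.labels.iloc[:5])
        assert len(first_block) == 1

    def test_all_equal_tom_does_not_crash(self, rng):
        m = 6
        T = np.full((m, m), 0.5)
        np.fill_diagonal(T, 1.0)
        X = frame(rng.normal(size=(m, 30)))
        assign = mg.detect_modules(frame(T), X, min_size=2, kme_prune=0.0)
        assert set(assign.labels.unique()) <= {0, 1}

    def test_labels_invariant_under_gene_permutation(self, rng):
        T, X = self._block_tom(rng, [4, 4, 4], within=0.9)
        a1 = mg.detect_modules(T, X, min_size=2)
        perm = rng.permutation(12)
        Tp = T.iloc[perm, perm]
        a2 = mg.detect_modules(Tp, X.iloc[perm], min_size=2)
        from sklearn.metrics import adjusted_rand_score

        common = a1.labels.index
        assert adjusted_rand_score(a1.labels[common], a2.labels[common]) == pytest.approx(1.0)

    def test_min_size_larger_than_matrix_rejected(self, rng):
        T, X = self._block_tom(rng, [3, 3])
        with pytest.raises(ValueError):
            mg.detect_modules(T, X, min_size=10)

    def test_recovers_planted_modules_small_fixture(self, synth_small, synth_small_logX):
        X = synth_small_logX
        T = mg.tom(mg.signed_adjacency(mg.pearson_correlation(X), 6))
        assign = mg.detect_modules(T, X, min_size=10)
        res = mg.truth_eval(assign, synth_small.truth)
        assert res["ari"] >= 0.8


class TestEigengene:
    def test_rank_one_module(self, rng):
        p = rng.normal(size=50)
        X = frame(np.vstack([2 * p + 1, -0.5 * p + 3, 4 * p]), samples=None)
        eig = mg.module_eigengene(X, list(X.index))
        r = np.corrcoef(eig, p)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_sign_contract_with_opposed_profiles(self, rng):
        p = rng.normal(size=30)
        X = frame(np.vstack([p, -p, p + 0.01 * rng.normal(size=30)]))
        eig = mg.module_eigengene(X, list(X.index))
        Z = (X - X.mean(axis=1).values[:, None]).div(X.std(axis=1, ddof=1), axis=0)
        assert np.corrcoef(eig, Z.mean(axis=0))[0, 1] >= 0

    def test_unit_norm_and_explained_variance(self, rng):
        X = frame(rng.normal(size=(30, 50)))
        eig = mg.module_eigengene(X, list(X.index)).to_numpy()
        assert np.linalg.norm(eig) == pytest.approx(1.0)
        # oracle: top-eigenvalue fraction of the member correlation matrix
        Z = X.to_numpy()
        Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, ddof=1, keepdims=True)
        evals = np.linalg.eigvalsh(Z @ Z.T)
        frac_oracle = evals[-1] / evals.sum()
        proj = Z @ eig
        frac = (proj**2).sum() / (Z**2).sum()
        assert frac == pytest.approx(frac_oracle, abs=1e-10)

    def test_constant_members(self, rng):
        X = frame(np.vstack([np.ones(10), rng.normal(size=10), rng.normal(size=10)]))
        with pytest.warns(UserWarning, match="constant"):
            mg.module_eigengene(X, list(X.index))
        Xc = frame(np.ones((3, 10)))
        with pytest.raises(CorrelationError):
            mg.module_eigengene(Xc, list(Xc.index))


class TestModuleTrait:
    def _assignment(self, rng):
        T, X = TestModuleDetection()._block_tom(rng, [5, 5, 5], within=0.9)
        return mg.detect_modules(T, X, min_size=2), X

    def test_trait_equal_to_eigengene(self, rng):
        assign, _ = self._assignment(rng)
        trait = assign.eigengenes.iloc[0]
        out = mg.module_trait_correlation(assign, trait)
        assert out.iloc[0]["module"] == assign.eigengenes.index[0]
        assert abs(out.iloc[0]["cor"]) == pytest.approx(1.0)

    def test_orthogonal_trait_gives_zero(self, rng):
        assign, _ = self._assignment(rng)
        E = assign.eigengenes.to_numpy()
        v = rng.normal(size=E.shape[1])
        # residualize v against the intercept and all eigengenes jointly
        design = np.column_stack([np.ones(E.shape[1]), E.T])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        v = v - design @ beta
        out = mg.module_trait_correlation(assign, pd.Series(v, index=assign.eigengenes.columns))
        np.testing.assert_allclose(out["cor"], 0.0, atol=1e-8)

    def test_constant_trait_rejected(self, rng):
        assign, _ = self._assignment(rng)
        trait = pd.Series(1.0, index=assign.eigengenes.columns)
        with pytest.raises(ValueError, match="variance"):
            mg.module_trait_correlation(assign, trait)

    def test_planted_trait_module_ranks_first(self, synth_small, synth_small_logX):
        X = synth_small_logX
        T = mg.tom(mg.signed_adjacency(mg.pearson_correlation(X), 6))
        assign = mg.detect_modules(T, X, min_size=10)
        out = mg.module_trait_correlation(assign, synth_small.trait)
        top = int(out.iloc[0]["module"])
        members = set(assign.members(top))
        truth = synth_small.truth.module_labels
        planted = set(truth.index[truth == synth_small.config.trait_module])
        assert len(members & planted) / len(planted) > 0.9


class TestKeyGeneScreen:
    def test_constructed_table_selection(self):
        table = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(1, 7)],
                "GS": [0.9, 0.5, 0.3, 0.25, 0.1, 0.05],
                "MM": [0.9, 0.85, 0.95, 0.7, 0.9, 0.99],
            }
        )
        # gene 4 fails MM, genes 5-6 fail GS
        assert select_key_genes(table, 0.2, 0.8, 3) == ["g1", "g2", "g3"]

    def test_tie_break_by_mm_then_id(self):
        table = pd.DataFrame(
            {
                "gene_id": ["b", "a", "c"],
                "GS": [0.5, 0.5, 0.5],
                "MM": [0.9, 0.9, 0.95],
            }
        )
        assert select_key_genes(table, 0.2, 0.8, 3) == ["c", "a", "b"]

    def test_gene_identical_to_trait_always_selected(self, rng):
        n = 40
        p = rng.normal(size=n)
        rows = [p] + [p + 0.3 * rng.normal(size=n) for _ in range(4)]
        X = frame(np.vstack(rows))
        T = mg.tom(mg.signed_adjacency(mg.pearson_correlation(X), 2))
        assign = mg.detect_modules(T, X, min_size=2)
        trait = pd.Series(p, index=X.columns)
        screen = mg.screen_key_genes(X, assign, trait, top_n=3)
        assert "g0" in screen.key_genes
        row = screen.table.set_index("gene_id").loc["g0"]
        assert row["GS"] == pytest.approx(1.0)

    def test_vacuous_thresholds_give_empty_warning(self, synth_small, synth_small_logX):
        X = synth_small_logX
        T = mg.tom(mg.signed_adjacency(mg.pearson_correlation(X), 6))
        assign = mg.detect_modules(T, X, min_size=10)
        with pytest.warns(UserWarning, match="no genes"):
            screen = mg.screen_key_genes(
                X, assign, synth_small.trait, gs_threshold=1.0, mm_threshold=1.0
            )
        assert screen.key_genes == []

    def test_scores_within_unit_interval(self, synth_small, synth_small_logX):
        X = synth_small_logX
        T = mg.tom(mg.signed_adjacency(mg.pearson_correlation(X), 6))
        assign = mg.detect_modules(T, X, min_size=10)
        screen = mg.screen_key_genes(X, assign, synth_small.trait)
        assert ((screen.table[["GS", "MM"]] >= 0) & (screen.table[["GS", "MM"]] <= 1)).all().all()
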