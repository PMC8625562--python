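"""Network module detection: adjacency, TOM, scale-free fit, tree cut."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cordbmi.modules import (
    GREY,
    adjacency,
    detect_modules,
    module_eigenscore,
    pick_power,
    scale_free_fit,
    tom_similarity,
)
from conftest import planted_block_frame


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Double-loop oracle for the topological overlap measure."""
    p = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(p) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTom:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        corr = np.corrcoef(rng.standard_normal((60, 50)), rowvar=False)
        a = adjacency(corr, 3)
        tom = tom_similarity(a)
        assert np.max(np.abs(tom - tom_bruteforce(a))) < 1e-10

    def test_symmetric_unit_interval(self):
        rng = np.random.default_rng(5)
        a = adjacency(np.corrcoef(rng.standard_normal((80, 40)), rowvar=False), 6)
        tom = tom_similarity(a)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestScaleFreeFit:
    def test_exact_power_law_is_perfect(self):
        # one distinct k per bin with frequency exactly proportional to 1/k:
        # the log-log regression is an exact line
        k_values = np.arange(10.0, 101.0, 10.0)
        counts = (25200 / k_values).astype(int)  # all integral for these k
        connectivity = np.repeat(k_values, counts)
        assert scale_free_fit(connectivity, n_bins=10) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_connectivity_undefined(self):
        assert np.isnan(scale_free_fit(np.full(100, 3.0)))

    def test_poisson_connectivity_fits_poorly(self):
        rng = np.random.default_rng(11)
        k = rng.poisson(20, 300).astype(float)
        assert scale_free_fit(k) < 0.5


class TestPickPower:
    def test_identity_correlation_falls_back(self):
        beta, diag = pick_power(np.eye(40))
        assert beta in range(1, 21)
        assert len(diag) == 20

    def test_block_structure_yields_usable_power(self, default_cohort):
        from cordbmi.metabolome import prepare_panel

        X = prepare_panel(default_cohort.panel).retained_matrix()
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        beta, diag = pick_power(corr)
        assert 1 <= beta <= 20
        # the selected network must not be empty
        assert diag.loc[diag["power"] == beta, "mean_k"].iloc[0] >= 1.0


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self):
        X, truth = planted_block_frame(500, [20, 18, 16, 15, 22], rho=0.7, seed=3)
        part = detect_modules(X, beta=7)
        assert adjusted_rand_score(truth, part.membership.to_numpy()) == 1.0
        assert part.n_grey == 0
        assert part.diagnostics["n_modules"] == 5

    def test_sub_min_size_block_goes_grey(self):
        X, truth = planted_block_frame(500, [20, 18, 16, 15, 22], rho=0.7, seed=3)
        Xs, _ = planted_block_frame(500, [10], rho=0.7, seed=4)
        Xs.columns = [f"small_{c}" for c in Xs.columns]
        part = detect_modules(pd.concat([X, Xs], axis=1), beta=7)
        assert (part.membership[Xs.columns] == GREY).all()

    def test_independent_metabolites_all_grey(self):
        X, _ = planted_block_frame(300, [15, 15, 15, 15], rho=0.0, seed=9)
        part = detect_modules(X, beta=7)
        assert part.n_grey == X.shape[1]
        assert part.diagnostics["n_modules"] == 0

    def test_invariant_to_metabolite_ordering_and_column_sign(self):
        X, _ = planted_block_frame(400, [20, 18, 16], rho=0.7, seed=12)
        part1 = detect_modules(X, beta=7)
        rng = np.random.default_rng(1)
        perm = rng.permutation(X.columns)
        flipped = X[perm].copy()
        flipped.iloc[:, ::2] *= -1.0  # unsigned network ignores column sign
        part2 = detect_modules(flipped, beta=7)
        assert adjusted_rand_score(
            part1.membership[X.columns].to_numpy(),
            part2.membership[X.columns].to_numpy(),
        ) == 1.0

    def test_zero_variance_metabolite_rejected(self):
        X, _ = planted_block_frame(100, [16], rho=0.7, seed=2)
        X["flat"] = 1.0
        with pytest.raises(ValueError):
            detect_modules(X, beta=7)

    def test_colors_assigned_in_size_order(self):
        X, _ = planted_block_frame(500, [30, 20, 16], rho=0.7, seed=6)
        part = detect_modules(X, beta=7)
        sizes = part.membership.value_counts()
        assert sizes["turquoise"] == 30
        assert sizes["blue"] == 20
        assert sizes["brown"] == 16


class TestEigenscore:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        X = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        score, ve = module_eigenscore(X, ["a", "b"])
        assert ve == pytest.approx(1.0)
        assert np.corrcoef(score, x)[0, 1] == pytest.approx(1.0)
        assert score.std(ddof=0) == pytest.approx(1.0)

    def test_orientation_stable_under_member_negation(self):
        X, _ = planted_block_frame(600, [20], rho=0.7, seed=8)
        score1, _ = module_eigenscore(X, list(X.columns))
        X2 = X.copy()
        X2.iloc[:, 0] *= -1.0
        score2, _ = module_eigenscore(X2, list(X2.columns))
        assert np.corrcoef(score1, score2)[0, 1] > 0.99

    def test_equicorrelated_block_variance_explained(self):
        # equicorrelation rho=0.7, m=20: leading eigenvalue fraction
        # (1 + (m-1) rho)/m = 0.715
        X, _ = planted_block_frame(900, [20], rho=0.7, seed=15)
        _, ve = module_eigenscore(X, list(X.columns))
        assert ve == pytest.approx(0.715, abs=0.05)

    def test_single_member_rejected(self):
        X, _ = planted_block_frame(50, [16], rho=0.7, seed=2)
        with pytest.raises(ValueError):
            module_eigenscore(X, [X.columns[0]])
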