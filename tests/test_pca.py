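"""Covariance PCA, Varimax/Promax rotation, selection and amplitude measures."""

import numpy as np
import pandas as pd
import pytest

from pawnpipe import (component_amplitude, default_ground_truth,
                      generate_erp_case_matrix, generate_oscillation_spectra,
                      half_sample, pca_covariance, rotate_solution,
                      select_components, varimax, varimax_criterion)


class TestHalfSample:
    def test_600_to_300(self):
        assert half_sample(np.zeros(600)).shape == (300,)

    def test_constant(self):
        assert np.all(half_sample(np.full(600, 2.5)) == 2.5)

    def test_pointwise_selection_of_sinusoid(self):
        t = np.arange(600) / 1000.0
        x = np.sin(2 * np.pi * 30 * t)
        assert np.array_equal(half_sample(x), x[::2])


class TestPcaCovariance:
    def test_single_varying_column(self, rng):
        X = np.zeros((50, 4))
        X[:, 2] = rng.normal(0, 1, 50)
        sol = pca_covariance(X)
        assert sol.explained_pct[0] == pytest.approx(100.0)

    def test_reconstruction_identity(self, rng):
        X = rng.normal(0, 1, (40, 6))
        sol = pca_covariance(X)
        rec = sol.scores @ sol.loadings.T
        assert np.allclose(rec, X - X.mean(axis=0), atol=1e-8)

    def test_two_variable_toy_covariance(self, rng):
        # covariance [[2,1],[1,2]] -> eigenvalues 3 and 1, shares 75%/25%
        L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        X = rng.normal(0, 1, (200000, 2)) @ L.T
        sol = pca_covariance(X)
        assert sol.eigenvalues[0] == pytest.approx(3.0, rel=0.02)
        assert sol.explained_pct[0] == pytest.approx(75.0, abs=1.0)

    def test_total_variance_partition(self, rng):
        X = rng.normal(0, 2, (60, 8))
        sol = pca_covariance(X)
        assert sol.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)


def _grid_varimax_2f(L, step=0.001):
    """Brute-force single-angle varimax for 2 factors."""
    best, best_val = None, -np.inf
    for th in np.arange(0.0, np.pi / 2, step):
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        v = varimax_criterion(L @ R)
        if v > best_val:
            best, best_val = L @ R, v
    return best, best_val


def _align(A, B):
    """Column permutation/sign alignment of B onto A."""
    k = A.shape[1]
    out = np.zeros_like(A)
    used = set()
    for i in range(k):
        scores = [abs(A[:, i] @ B[:, j]) if j not in used else -1 for j in range(k)]
        j = int(np.argmax(scores))
        used.add(j)
        s = np.sign(A[:, i] @ B[:, j]) or 1.0
        out[:, i] = s * B[:, j]
    return out


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        rot, R, conv = varimax(L, kaiser_normalize=False)
        assert np.allclose(np.abs(_align(L, rot)), np.abs(L), atol=1e-6)

    def test_criterion_never_decreases(self, rng):
        for _ in range(10):
            L = rng.normal(0, 1, (10, 3))
            rot, R, conv = varimax(L, kaiser_normalize=False)
            assert varimax_criterion(rot) >= varimax_criterion(L) - 1e-12

    def test_rotation_is_orthogonal_and_preserves_communality(self, rng):
        L = rng.normal(0, 1, (20, 5))
        rot, R, conv = varimax(L)
        assert np.allclose(R.T @ R, np.eye(5), atol=1e-8)
        assert np.allclose((rot**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-8)

    def test_two_factor_grid_oracle(self):
        L = np.array([[0.83, 0.29], [0.79, 0.41], [0.33, 0.80], [0.20, 0.74]])
        rot, _, _ = varimax(L, kaiser_normalize=False)
        oracle, oracle_val = _grid_varimax_2f(L)
        assert varimax_criterion(rot) >= oracle_val - 1e-6
        assert np.allclose(np.abs(_align(rot, oracle)), np.abs(rot), atol=1e-3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            varimax(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestPromax:
    def _solution(self, X):
        sol = pca_covariance(X)
        return rotate_solution(sol, method="promax")

    def test_orthogonal_simple_structure_phi_identity(self, rng):
        F = rng.normal(0, 1, (2000, 2))
        L = np.array([[1.0, 0.0], [0.9, 0.0], [0.0, 0.8], [0.0, 0.7]])
        X = F @ L.T + rng.normal(0, 0.05, (2000, 4))
        sol = self._solution(X)
        sel = select_components(sol, 5.0)
        sub = sol.phi[np.ix_(sel, sel)]
        assert np.allclose(sub, np.eye(len(sel)), atol=0.1)

    def test_structure_equals_pattern_times_phi(self, rng):
        X = rng.normal(0, 1, (100, 6)) @ rng.normal(0, 1, (6, 6))
        sol = self._solution(X)
        assert np.allclose(sol.structure, sol.rotated_loadings @ sol.phi,
                           atol=1e-8)
        assert np.allclose(np.diag(sol.phi), 1.0, atol=1e-10)

    def test_planted_factor_correlation_recovered(self):
        errs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            L = np.zeros((10, 2))
            L[:5, 0] = np.linspace(1.0, 0.5, 5)
            L[5:, 1] = np.linspace(0.9, 0.4, 5)
            F = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=1000)
            X = F @ L.T + rng.normal(0, 0.3, (1000, 10))
            sol = self._solution(X)
            sel = select_components(sol, 5.0)[:2]
            errs.append(abs(sol.phi[sel[0], sel[1]]) - 0.5)
        assert abs(np.mean(errs)) < 0.1

    def test_variance_partition_sums_to_total(self, rng):
        X = rng.normal(0, 1, (200, 8)) @ rng.normal(0, 1, (8, 8))
        sol = self._solution(X)
        assert sol.rotated_explained_pct.sum() == pytest.approx(100.0, abs=0.5)


class TestSelection:
    def test_cutoff_examples(self, rng):
        X = rng.normal(0, 1, (100, 4)) * np.array([40.0, 30.0, 10.0, 1.2])
        sol = pca_covariance(X)
        rotate_solution(sol, method="varimax")
        pct = sol.rotated_explained_pct
        sel = select_components(sol, 1.5)
        assert all(pct[i] >= 1.5 for i in sel)
        assert len(select_components(sol, 0.0)) == 4
        assert pct[sel[0]] == max(pct)


class TestComponentAmplitude:
    def _forward(self, rng, n_part=8, n_ch=5):
        amps = rng.uniform(1, 5, n_part)
        wave = np.exp(-0.5 * ((np.arange(31) - 10.0) / 1.5) ** 2)
        topo = rng.uniform(0.5, 1.0, n_ch)
        rows, meta = [], []
        for i in range(n_part):
            rows.append(np.outer(topo * amps[i], wave))
            meta.extend((i, c) for c in range(n_ch))
        X = np.vstack(rows) + rng.normal(0, 1e-4, (n_part * n_ch, 31))
        return X, pd.DataFrame(meta, columns=["participant", "channel"]), amps, topo

    def test_forward_constructed_amplitude(self, rng):
        X, meta, amps, topo = self._forward(rng)
        sol = pca_covariance(X, case_meta=meta)
        rotate_solution(sol, method="varimax")
        sel = select_components(sol, 5.0)
        df = component_amplitude(sol, sel, meta)
        got = df.iloc[:, 0].to_numpy()
        # amplitudes are centred (scores are mean-zero), so compare deviations
        expect = amps * topo.mean()
        expect = expect - expect.mean()
        got_centred = got - got.mean()
        assert np.corrcoef(got_centred, expect)[0, 1] > 0.995
        assert np.allclose(got_centred, expect, atol=0.10 * np.abs(expect).max())

    def test_doubling_data_doubles_amplitudes(self, rng):
        X, meta, _, _ = self._forward(rng)
        sol1 = rotate_solution(pca_covariance(X, case_meta=meta), "varimax")
        sol2 = rotate_solution(pca_covariance(2 * X, case_meta=meta), "varimax")
        a1 = component_amplitude(sol1, select_components(sol1, 5.0), meta)
        a2 = component_amplitude(sol2, select_components(sol2, 5.0), meta)
        assert np.allclose(2 * a1.to_numpy(), a2.to_numpy(), rtol=1e-6)

    def test_unknown_component_rejected(self, rng):
        X, meta, _, _ = self._forward(rng)
        sol = rotate_solution(pca_covariance(X, case_meta=meta), "varimax")
        with pytest.raises(ValueError):
            component_amplitude(sol, [99], meta)


class TestEndToEndRecovery:
    def test_planted_bands_recovered(self):
        """Selected f-PCA components peak within +-1 Hz of the planted
        2/8/10/15/25 Hz band centres in >=90% of seeded runs."""
        truth = default_ground_truth(30)
        centres = sorted(b.centre_hz for b in truth.bands)
        hits = 0
        for seed in range(20):
            X, meta, _ = generate_oscillation_spectra(47, 30, truth.bands, seed=seed)
            sol = pca_covariance(X, variable_values=np.arange(31.0), case_meta=meta)
            rotate_solution(sol, method="promax")
            sel = select_components(sol, 1.5)
            peaks = sorted(sol.peak_variable(c) for c in sel)
            if len(peaks) == len(centres) and \
                    all(abs(p - c) <= 1.0 for p, c in zip(peaks, centres)):
                hits += 1
        assert hits >= 18

    def test_planted_erp_latencies_recovered(self):
        truth = default_ground_truth(30)
        comps = [c for c in truth.erp_components if c.condition == "go"]
        latencies = sorted(c.latency_ms for c in comps)
        times = np.arange(-100, 500, 2.0)
        for seed in range(2):
            X, meta, _ = generate_erp_case_matrix(47, 30, comps, seed=seed)
            sol = pca_covariance(X, variable_values=times, case_meta=meta)
            rotate_solution(sol, method="varimax")
            sel = select_components(sol, 1.5)
            peaks = sorted(sol.peak_variable(c) for c in sel)
            assert len(peaks) == len(latencies)
            assert all(abs(p - l) <= 10.0 for p, l in zip(peaks, latencies))
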