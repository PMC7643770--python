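import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qimcmda.qkernel import (QKernelParams, build_sm_sd, integrate_similarity,
                             qkernel_distance, qkernel_similarity_matrix)
from qimcmda.simulate import FixtureSpec, generate_fixture
from qimcmda.types import AssociationMatrix, SimilarityMatrix

DEFAULTS = QKernelParams()  # c=0.1, q=0.6, omega=0.01


class TestQKernelDistance:
    def test_worked_value(self):
        # ||x-y||=1, c=1, q=0.5 -> 2*(2 - 2**(1/sqrt(2)))
        got = qkernel_distance(np.array([0.0]), np.array([1.0]),
                               QKernelParams(c=1.0, q=0.5))
        assert got == pytest.approx(2.0 * (2.0 - 2.0 ** (1.0 / np.sqrt(2.0))),
                                    abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8),
           st.floats(0.05, 1.0), st.floats(0.05, 0.95))
    def test_vanishes_at_equal_profiles(self, xs, c, q):
        x = np.asarray(xs)
        assert qkernel_distance(x, x, QKernelParams(c=c, q=q)) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_nonnegative_monotone(self):
        params = DEFAULTS
        x = np.zeros(4)
        prev = -1.0
        for d in np.linspace(0.0, 5.0, 40):
            y = np.zeros(4)
            y[0] = d
            h = qkernel_distance(x, y, params)
            assert h >= prev - 1e-15  # increasing in ||x - y||
            assert h == pytest.approx(qkernel_distance(y, x, params))
            assert h >= 0
            prev = h

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            QKernelParams(q=1.0)
        with pytest.raises(ValueError):
            QKernelParams(c=0.0)
        with pytest.raises(ValueError):
            qkernel_distance(np.zeros(2), np.zeros(3), DEFAULTS)


class TestQKernelSimilarityMatrix:
    def test_identical_pair_gets_similarity_one(self):
        profiles = np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        sim = qkernel_similarity_matrix(profiles, ["a", "b", "c"], DEFAULTS)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 2] == pytest.approx(0.0)  # unique max distance

    def test_all_identical_profiles_degenerate_branch(self, caplog):
        profiles = np.ones((3, 4))
        with caplog.at_level(logging.WARNING):
            sim = qkernel_similarity_matrix(profiles, list("abc"), DEFAULTS)
        np.testing.assert_array_equal(sim.values, np.ones((3, 3)))
        assert any("degenerate" in r.message for r in caplog.records)

    def test_matches_minmax_oracle(self, rng):
        """Recompute min-max scaling independently from raw kernel distances."""
        profiles = rng.uniform(size=(6, 5))
        sim = qkernel_similarity_matrix(profiles, [f"p{i}" for i in range(6)],
                                        DEFAULTS)
        n = 6
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    dist[i, j] = qkernel_distance(profiles[i], profiles[j], DEFAULTS)
        off = ~np.eye(n, dtype=bool)
        lo, hi = dist[off].min(), dist[off].max()
        expect = 1.0 - (dist - lo) / (hi - lo)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(sim.values, expect, atol=1e-12)

    def test_invariant_under_row_permutation(self, rng):
        profiles = rng.uniform(size=(5, 7))
        names = [f"p{i}" for i in range(5)]
        sim = qkernel_similarity_matrix(profiles, names, DEFAULTS)
        perm = rng.permutation(5)
        sim_p = qkernel_similarity_matrix(profiles[perm], [names[i] for i in perm],
                                          DEFAULTS)
        np.testing.assert_allclose(sim_p.values, sim.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_output_invariants(self, rng):
        profiles = rng.uniform(size=(8, 6))
        sim = qkernel_similarity_matrix(profiles, [f"p{i}" for i in range(8)],
                                        DEFAULTS)
        np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        assert sim.values.min() >= -1e-12 and sim.values.max() <= 1 + 1e-12
        assert sim.fully_observed


class TestIntegrateSimilarity:
    def _pair(self, rng, n=4):
        base_vals = rng.uniform(0.0, 1.0, size=(n, n))
        base_vals = (base_vals + base_vals.T) / 2
        np.fill_diagonal(base_vals, 1.0)
        mask = rng.uniform(size=(n, n)) < 0.5
        mask = mask | mask.T
        np.fill_diagonal(mask, True)
        names = [f"x{i}" for i in range(n)]
        base = SimilarityMatrix(np.where(mask, base_vals, 0.0), names, mask)
        k_vals = rng.uniform(0.0, 1.0, size=(n, n))
        k_vals = (k_vals + k_vals.T) / 2
        np.fill_diagonal(k_vals, 1.0)
        kernel = SimilarityMatrix(k_vals, names)
        return base, kernel

    def test_omega_zero_returns_kernel(self, rng):
        base, kernel = self._pair(rng)
        out = integrate_similarity(base, kernel, omega=0.0)
        np.testing.assert_allclose(out.values, kernel.values, atol=1e-12)

    def test_omega_one_fully_observed_returns_base(self, rng):
        base, kernel = self._pair(rng)
        full = SimilarityMatrix(np.where(base.mask, base.values, kernel.values)
                                .round(12), base.names)
        out = integrate_similarity(full, kernel, omega=1.0)
        np.testing.assert_allclose(out.values, full.values, atol=1e-12)

    def test_blend_arithmetic(self):
        names = ["a", "b"]
        base = SimilarityMatrix(np.array([[1.0, 0.8], [0.8, 1.0]]), names)
        kernel = SimilarityMatrix(np.array([[1.0, 0.2], [0.2, 1.0]]), names)
        out = integrate_similarity(base, kernel, omega=0.01)
        assert out.values[0, 1] == pytest.approx(0.01 * 0.8 + 0.99 * 0.2)
        assert out.values[0, 1] == pytest.approx(0.206)

    def test_identity_when_base_equals_kernel(self, rng):
        _, kernel = self._pair(rng)
        for omega in (0.0, 0.3, 1.0):
            out = integrate_similarity(kernel, kernel, omega)
            np.testing.assert_allclose(out.values, kernel.values, atol=1e-12)

    def test_label_mismatch_rejected(self, rng):
        base, kernel = self._pair(rng)
        kernel = SimilarityMatrix(kernel.values, ["z" + n for n in kernel.names])
        with pytest.raises(ValueError, match="label"):
            integrate_similarity(base, kernel, 0.5)


class TestBuildSmSd:
    def test_unobserved_fs_collapses_to_kernel(self, planted):
        A, fs, ss = planted["A"], planted["fs"], planted["ss"]
        fs_empty = SimilarityMatrix(np.zeros(fs.values.shape), fs.names,
                                    np.zeros(fs.mask.shape, dtype=bool))
        sm, _ = build_sm_sd(A, fs_empty, ss, DEFAULTS)
        qm = qkernel_similarity_matrix(A.values.T, A.mirna_names, DEFAULTS)
        np.testing.assert_allclose(sm.values, qm.values, atol=1e-12)

    def test_all_zero_associations_degenerate(self, planted):
        fs, ss = planted["fs"], planted["ss"]
        A0 = AssociationMatrix(np.zeros(planted["A"].shape),
                               planted["A"].disease_names,
                               planted["A"].mirna_names)
        sm, sd = build_sm_sd(A0, fs, ss, DEFAULTS)
        # identical profiles -> kernel all ones -> observed FS entries blended
        omega = DEFAULTS.omega
        expect = np.where(fs.mask, omega * fs.values + (1 - omega), 1.0)
        np.fill_diagonal(expect, 1.0)
        np.testing.assert_allclose(sm.values, expect, atol=1e-12)

    def test_outputs_valid_for_multiplicative_updates(self, planted):
        sm, sd = build_sm_sd(planted["A"], planted["fs"], planted["ss"], DEFAULTS)
        for s in (sm, sd):
            assert (s.values >= 0).all()
            np.testing.assert_allclose(s.values, s.values.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(s.values), 1.0)
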