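"""Saliency invariants, connectivity propagation and ZCA whitening."""

import warnings

import numpy as np
import pytest

import restsal as rs
from restsal.preprocess import RegionTimeseries, standardize
from restsal.rnn import forward_batch
from restsal.saliency import (
    aggregate_fc_saliency,
    build_saliency_networks,
    fc_saliency,
    input_saliency,
    mean_saliency_variance,
    saliency_temporal_variance,
    zca,
    zca_saliency,
)


def _session(rng, t=12, r=4):
    return RegionTimeseries(rng.standard_normal((t, r)), tr=1.0)


class TestInputSaliency:
    def test_zero_sum_and_orthogonality_invariants(self, tiny_params, rng):
        sess = _session(rng)
        sal = input_saliency(tiny_params, sess)
        T = sal.n_timepoints
        z = standardize(sess).values
        assert np.abs(sal.values.sum(axis=0)).max() < 1e-8 * T
        assert np.abs((sal.values * z).sum(axis=0)).max() < 1e-8 * T

    def test_standardized_flag_keeps_invariants(self, tiny_params, rng):
        z = standardize(_session(rng)).values
        sal = input_saliency(tiny_params, z, standardized=True)
        assert np.abs(sal.values.sum(axis=0)).max() < 1e-7
        assert np.abs((sal.values * z).sum(axis=0)).max() < 1e-7

    def test_ignored_region_has_zero_column(self, rng):
        spec = rs.ArchitectureSpec(input_dim=4, hidden_dim=3)
        params = rs.init_ensemble(spec, [5])
        for d in ("f", "b"):
            params.arrays[f"W1{d}"][:, :, 1] = 0.0
        sal = input_saliency(params, _session(rng))
        # gradients w.r.t. the ignored region vanish before projection; the
        # projection only mixes within a column, so the column stays zero
        assert np.abs(sal.values[:, 1]).max() < 1e-12

    def test_matches_finite_differences_through_standardization(
        self, tiny_params, rng
    ):
        sess = _session(rng, t=10, r=4)
        sal = input_saliency(tiny_params, sess)
        eps = 1e-5

        def output(values):
            z = standardize(
                RegionTimeseries(values, tr=1.0, region_ids=sess.region_ids)
            ).values
            return float(forward_batch(tiny_params, z[None])[0].mean())

        worst = 0.0
        for t in range(10):
            for r in range(4):
                vp, vm = sess.values.copy(), sess.values.copy()
                vp[t, r] += eps
                vm[t, r] -= eps
                fd = (output(vp) - output(vm)) / (2 * eps)
                scale = max(1.0, abs(sal.values[t, r]))
                worst = max(worst, abs(fd - sal.values[t, r]) / scale)
        assert worst < 1e-4

    def test_ensemble_saliency_is_mean_of_members(self, tiny_params, rng):
        sess = _session(rng)
        ens = input_saliency(tiny_params, sess).values
        mem = np.mean(
            [
                input_saliency(tiny_params, sess, member=m).values
                for m in range(tiny_params.n_members)
            ],
            axis=0,
        )
        assert np.allclose(ens, mem, atol=1e-12)


class TestTemporalVariance:
    def test_zero_tensor(self):
        assert np.all(saliency_temporal_variance(np.zeros((5, 3))) == 0.0)

    def test_hand_case(self):
        col = np.array([[1.0], [-1.0], [0.0]])
        assert saliency_temporal_variance(col)[0] == pytest.approx(1.0)

    def test_equals_generic_variance_for_zero_mean_columns(self, rng):
        vals = rng.standard_normal((30, 5))
        vals -= vals.mean(axis=0)
        ref = vals.var(axis=0, ddof=1)
        assert np.allclose(saliency_temporal_variance(vals), ref, atol=1e-12)

    def test_mean_saliency_variance_matches_per_session(self, tiny_params, rng):
        X = rng.standard_normal((3, 12, 4))
        X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        batch = mean_saliency_variance(tiny_params, X)
        singles = [
            saliency_temporal_variance(
                input_saliency(tiny_params, X[i], standardized=True)
            )
            for i in range(3)
        ]
        assert np.allclose(batch, np.mean(singles, axis=0), atol=1e-10)


class TestSaliencyNetworks:
    def test_duplicate_sizes_collapse_and_nest(self, rng):
        var = rng.uniform(size=20)
        nets = build_saliency_networks(var, [2, 2, 15, 15, 5])
        assert sorted(nets) == [2, 5, 15]
        assert set(nets[2]) <= set(nets[5]) <= set(nets[15])

    def test_tie_break_by_region_order(self):
        nets = build_saliency_networks(np.ones(6), [3])
        assert nets[3] == [0, 1, 2]

    def test_size_exceeding_regions_raises(self):
        with pytest.raises(ValueError):
            build_saliency_networks(np.ones(4), [5])

    def test_partition_sizes_accepted(self):
        part = rs.make_partition(10, sizes=[4, 6])
        nets = build_saliency_networks(np.arange(10.0), part, region_ids=[f"r{i:03d}" for i in range(10)])
        assert sorted(nets) == [4, 6]
        assert nets[4] == ["r009", "r008", "r007", "r006"]


class TestFCSaliency:
    def test_zero_direction_gives_zero(self, rng):
        X = rng.standard_normal((30, 5))
        assert np.all(fc_saliency(X, np.zeros_like(X)) == 0.0)

    def test_symmetric_and_linear(self, rng):
        X = rng.standard_normal((30, 5))
        D1 = rng.standard_normal((30, 5))
        D2 = rng.standard_normal((30, 5))
        dc = fc_saliency(X, 2.0 * D1 - 0.5 * D2)
        assert np.allclose(dc, dc.T, atol=1e-12)
        ref = 2.0 * fc_saliency(X, D1) - 0.5 * fc_saliency(X, D2)
        assert np.allclose(dc, ref, atol=1e-12)

    def test_first_order_term_matches_finite_difference(self, rng):
        T, R = 50, 6
        X = rng.standard_normal((T, R))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        D = rng.standard_normal((T, R))
        eta = 1e-5

        def corr_num(v):  # unnormalized second moment, divisor T-1
            return v.T @ v / (T - 1)

        fd = (corr_num(X + eta * D) - corr_num(X)) / eta
        dc = fc_saliency(X, D)
        assert np.abs(fd - dc).max() / np.abs(dc).max() < 1e-3

    def test_ensemble_delta_c_is_mean_of_member_delta_c(self, tiny_params, rng):
        sess = _session(rng, t=15)
        z = standardize(sess).values
        ens = fc_saliency(z, input_saliency(tiny_params, sess).values)
        mem = np.mean(
            [
                fc_saliency(z, input_saliency(tiny_params, sess, member=m).values)
                for m in range(tiny_params.n_members)
            ],
            axis=0,
        )
        assert np.allclose(ens, mem, atol=1e-12)

    def test_categorization_top_fraction(self, rng):
        samples = []
        for _ in range(6):
            X = rng.standard_normal((40, 6))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            samples.append((X, rng.standard_normal((40, 6))))
        agg = aggregate_fc_saliency(samples, top_fraction=0.2)
        n_pairs = 6 * 5 // 2
        assert len(agg.categories) == int(np.ceil(0.2 * n_pairs))
        assert set(agg.categories["category"]) <= {"IMPC", "DMPC", "DMNC", "IMNC"}


class TestZCA:
    def test_identities_on_random_input(self, rng):
        X = rng.standard_normal((60, 5))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        f = rs.zca(X)
        assert np.abs(f.Z.T @ f.Z - np.eye(5)).max() < 1e-8
        assert np.abs(X - f.Z @ f.W).max() / np.abs(X).max() < 1e-10
        assert np.allclose(f.W, f.W.T, atol=1e-10)
        assert np.linalg.eigvalsh(f.W).min() > 0

    def test_two_region_closed_form(self):
        rho = 0.6
        T = 4000
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
        X = rng.standard_normal((T, 2)) @ L.T
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        f = rs.zca(X)
        emp_rho = float((X[:, 0] * X[:, 1]).sum() / (T - 1))
        a = (np.sqrt(1 + emp_rho) + np.sqrt(1 - emp_rho)) / 2
        b = (np.sqrt(1 + emp_rho) - np.sqrt(1 - emp_rho)) / 2
        ref = np.array([[a, b], [b, a]])
        assert np.allclose(f.W / np.sqrt(T - 1), ref, atol=1e-10)

    def test_orthogonal_columns_rescale(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((40, 4)))
        X = q * np.array([3.0, 2.0, 1.5, 1.0])
        f = rs.zca(X)
        # Z should be X with each column rescaled to unit norm (up to sign)
        ref = X / np.linalg.norm(X, axis=0)
        assert np.allclose(np.abs(f.Z), np.abs(ref), atol=1e-8)

    def test_idempotence(self, rng):
        X = rng.standard_normal((50, 4))
        Z = rs.zca(X).Z
        Z2 = rs.zca(Z).Z
        assert np.allclose(np.abs(Z2), np.abs(Z), atol=1e-8)

    def test_degenerate_inputs_raise(self, rng):
        with pytest.raises(ValueError):
            rs.zca(rng.standard_normal((4, 6)))
        X = rng.standard_normal((20, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(np.linalg.LinAlgError):
            rs.zca(X)


class TestZCASaliency:
    def test_zero_direction(self, rng):
        X = rng.standard_normal((30, 4))
        dZ, var = zca_saliency(X, np.zeros_like(X))
        assert np.all(dZ == 0.0) and np.all(var == 0.0)

    def test_matches_finite_differences(self, rng):
        T, R = 50, 6
        X = rng.standard_normal((T, R))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        D = rng.standard_normal((T, R))
        dZ, _ = zca_saliency(X, D)
        eta = 1e-5
        fd = (rs.zca(X + eta * D).Z - rs.zca(X - eta * D).Z) / (2 * eta)
        assert np.abs(fd - dZ).max() / np.abs(dZ).max() < 1e-3

    def test_degenerate_spectrum_warns_and_falls_back(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((30, 3)))
        X = q * 2.0  # all singular values equal
        D = rng.standard_normal((30, 3)) * 0.1
        with pytest.warns(RuntimeWarning, match="degenerate"):
            dZ, _ = zca_saliency(X, D)
        assert np.all(np.isfinite(dZ))

    def test_white_input_concentrates_on_perturbed_region(self, rng):
        T, R = 200, 6
        X = rng.standard_normal((T, R))
        Z = rs.zca(X).Z  # already white
        D = np.zeros_like(Z)
        D[:, 2] = rng.standard_normal(T)
        with warnings.catch_warnings():
            # an exactly-white input has a fully degenerate spectrum
            warnings.simplefilter("ignore", RuntimeWarning)
            _, var = zca_saliency(Z, D)
        assert var[2] / var.sum() >= 0.9
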