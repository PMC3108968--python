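"""Optimizer behavior: descent guarantees, multistart, determinism, recovery."""

import numpy as np
import pytest

from minkmds.engine import (
    EngineSettings,
    classical_scaling_start,
    fit_single,
    fit_three_way,
    tau_schedule,
)
from minkmds.metrics import Configuration, pairwise_distances
from minkmds.survey import ThreeWayDissimilarities


def _exact_data(n=6, q=2, p=1.0, seed=12, n_experts=2):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-1.0, 1.0, (n, q))
    cfg = Configuration([f"P{i}" for i in range(n)], coords, metric_p=p)
    d = pairwise_distances(cfg)
    return coords, ThreeWayDissimilarities.from_matrices(
        cfg.labels, [d] * n_experts, profile_metric_p=p
    )


class TestFitSingle:
    def test_schedule_validation(self, small_cityblock_data):
        _, data = small_cityblock_data
        m = data.matrices[0]
        start = np.zeros((6, 2))
        with pytest.raises(ValueError, match="strictly decreasing"):
            fit_single(m, m, 1.0, 2, 100.0, np.array([0.1, 0.1, 0.0]), start)
        with pytest.raises(ValueError, match="end at exactly 0"):
            fit_single(m, m, 1.0, 2, 100.0, np.array([0.2, 0.1]), start)
        with pytest.raises(ValueError, match="1 <= p <= 2"):
            fit_single(m, m, 3.0, 2, 100.0, np.array([0.1, 0.0]), start)

    def test_noiseless_cityblock_from_classical_start(self, small_cityblock_data):
        _, data = small_cityblock_data
        m = data.matrices[0]
        med = np.median(m[np.triu_indices(6, 1)])
        sched = tau_schedule(1.0)
        cfg, stress, trace = fit_single(
            m / med, m / med, 1.0, 2, 100.0, sched, classical_scaling_start(m / med, 2)
        )
        assert stress.value < 0.01
        assert cfg.metric_p == 1.0

    def test_three_points_embed_exactly(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.4, 1.1]])
        for p in (1.0, 1.5, 2.0):
            cfg = Configuration(list("abc"), pts, metric_p=p)
            d = pairwise_distances(cfg)
            data = ThreeWayDissimilarities.from_matrices(list("abc"), [d], profile_metric_p=p)
            res = fit_three_way(data, p=p, q=2, n_starts=2, seed=0)
            assert res.mean_stress < 1e-4

    def test_lambda_zero_ignores_constraint(self, small_cityblock_data):
        _, data = small_cityblock_data
        m = data.matrices[0]
        rng = np.random.default_rng(3)
        other = np.abs(rng.normal(size=(6, 6)))
        other = (other + other.T) / 2
        np.fill_diagonal(other, 0.0)
        start = rng.uniform(-1, 1, (6, 2))
        sched = tau_schedule(1.0)
        cfg_a, s_a, _ = fit_single(m, m, 1.0, 2, 0.0, sched, start)
        cfg_b, s_b, _ = fit_single(m, other, 1.0, 2, 0.0, sched, start)
        assert np.array_equal(cfg_a.coords, cfg_b.coords)
        assert s_a.value == s_b.value

    def test_loss_trace_monotone_within_each_phase(self, small_cityblock_data):
        _, data = small_cityblock_data
        m = data.matrices[0]
        rng = np.random.default_rng(9)
        start = rng.uniform(-1, 1, (6, 2))
        for p in (1.0, 1.4, 2.0):
            _, _, trace = fit_single(m, m, p, 2, 100.0, tau_schedule(1.0), start)
            for phase in trace.phases:
                assert np.all(np.diff(phase) <= 1e-12)


class TestFitThreeWay:
    def test_noiseless_self_consistency(self):
        _, data = _exact_data(n=10, p=1.0, n_experts=3)
        res = fit_three_way(data, p=1.0, q=2, n_starts=3, seed=1)
        assert res.mean_stress < 0.01

    def test_multistart_best_is_nonincreasing_in_n_starts(self, small_cityblock_data):
        _, data = small_cityblock_data
        best_stress, best_loss = [], []
        for ns in (1, 2, 4):
            res = fit_three_way(data, p=1.0, q=2, n_starts=ns, seed=7)
            recs = res.expert_fits[0].starts
            best_stress.append(min(r.stress for r in recs))
            best_loss.append(min(r.loss for r in recs))
        assert best_stress[0] >= best_stress[1] >= best_stress[2]
        assert best_loss[0] >= best_loss[1] >= best_loss[2]

    def test_seeded_runs_bit_identical(self, small_cityblock_data):
        _, data = small_cityblock_data
        a = fit_three_way(data, p=1.0, q=2, n_starts=3, seed=5)
        b = fit_three_way(data, p=1.0, q=2, n_starts=3, seed=5)
        for fa, fb in zip(a.expert_fits, b.expert_fits):
            assert np.array_equal(fa.config.coords, fb.config.coords)
            assert fa.stress == fb.stress
            for pa, pb in zip(
                next(r for r in fa.starts if r.name == fa.best_start).trace.phases,
                next(r for r in fb.starts if r.name == fb.best_start).trace.phases,
            ):
                assert np.array_equal(pa, pb)

    def test_stress_reported_is_exact_stress1(self, small_cityblock_data):
        """Reported stress recomputes from the configuration alone."""
        from minkmds.nonmetric import monotone_disparities, stress1

        _, data = small_cityblock_data
        res = fit_three_way(data, p=1.0, q=2, n_starts=2, seed=2)
        for k, ef in enumerate(res.expert_fits):
            d = pairwise_distances(ef.config)
            disp = monotone_disparities(data.matrices[k], d)
            assert stress1(disp.values, d) == pytest.approx(ef.stress, abs=1e-12)

    def test_party_permutation_leaves_stress_unchanged(self, small_cityblock_data):
        coords, data = small_cityblock_data
        perm = np.array([4, 2, 0, 5, 1, 3])
        permuted = ThreeWayDissimilarities.from_matrices(
            [data.parties[i] for i in perm],
            [m[np.ix_(perm, perm)] for m in data.matrices],
            profile_metric_p=1.0,
        )
        st = EngineSettings()
        a = fit_three_way(data, p=1.0, q=2, n_starts=1, seed=0, settings=st)
        b = fit_three_way(permuted, p=1.0, q=2, n_starts=1, seed=0, settings=st)
        # single deterministic (classical-scaling) start: stress must agree
        assert b.expert_fits[0].stress == pytest.approx(a.expert_fits[0].stress, abs=1e-4)

    def test_dominance_metric_rejected_by_engine(self, small_cityblock_data):
        _, data = small_cityblock_data
        with pytest.raises(ValueError, match="1 <= p <= 2"):
            fit_three_way(data, p=np.inf, q=2, n_starts=1, seed=0)

    def test_results_summary_has_expert_rows(self, small_cityblock_data):
        _, data = small_cityblock_data
        res = fit_three_way(data, p=1.0, q=2, n_starts=2, seed=3)
        text = str(res.summary())
        assert "stress-1" in text and "expert_1" in text
        frame = res.stress_frame()
        assert set(frame.columns) >= {"expert", "stress", "loss"}
        assert res.stress_se == pytest.approx(
            res.stress_per_expert.std(ddof=1) / np.sqrt(res.n_experts)
        )


class TestConfigurationRecovery:
    def test_cityblock_axes_recovered_without_rotation(self):
        """Low-noise city-block data: fitted axes match the generating axes
        up to translation, axis permutation and reflection (the city-block
        symmetry group), with |r| > 0.9 per dimension.  13 parties give the
        78 pair ranks needed to pin the axes down."""
        from minkmds.synthetic import SyntheticSpec, generate, latent_dissimilarities

        ds = generate(
            SyntheticSpec(seed=7, n_parties=13, latent_metric_p=1.0, expert_jitter_sd=0.02)
        )
        fit = fit_three_way(latent_dissimilarities(ds), p=1.0, q=2, n_starts=6, seed=3)
        for k in range(ds.survey.n_experts):
            true = ds.truth.latent[k]
            est = fit.expert_fits[k].config.coords
            best = max(
                min(
                    abs(np.corrcoef(true[:, i], est[:, perm[i]])[0, 1])
                    for i in range(2)
                )
                for perm in ([0, 1], [1, 0])
            )
            assert best > 0.9


class TestClassicalScalingStart:
    def test_recovers_euclidean_configuration_shape(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(7, 2))
        cfg = Configuration([str(i) for i in range(7)], coords, metric_p=2.0)
        d = pairwise_distances(cfg)
        start = classical_scaling_start(d, 2)
        d2 = pairwise_distances(Configuration([str(i) for i in range(7)], start, metric_p=2.0))
        assert np.allclose(d2, d, atol=1e-8)
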