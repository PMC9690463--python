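"""Known-variance mixture EM, AIC model selection, MQTL extraction."""

import itertools

import numpy as np
import pytest

from metaqtl.errors import ModelError
from metaqtl.meta import (
    analyze_chromosome,
    extract_mqtls,
    fit_mixture,
    select_model,
    weighted_mean_fit,
)
from metaqtl.projection import ProjectedQTL

from conftest import make_map, make_record

_LOG_2PI = np.log(2 * np.pi)


def closed_form_loglik(x, s, mu):
    return float(np.sum(-0.5 * ((np.asarray(x) - mu) / np.asarray(s)) ** 2
                        - np.log(s) - 0.5 * _LOG_2PI))


def make_projected(positions, sds, stresses=None, r2s=None, chromosome="1H"):
    out = []
    for i, (pos, sd) in enumerate(zip(positions, sds)):
        stress = (stresses or ["drought"] * len(positions))[i]
        r2 = (r2s or [0.1] * len(positions))[i]
        rec = make_record(qtl_id=f"q{i}", stress=stress, chromosome=chromosome,
                          peak_cm=pos, r2=r2)
        out.append(ProjectedQTL(
            source=rec, ci_cm=sd * 3.92, consensus_chromosome=chromosome,
            consensus_peak_cm=pos, consensus_ci_lo_cm=pos - 1.96 * sd,
            consensus_ci_hi_cm=pos + 1.96 * sd, projection_scale=1.0,
        ))
    return out


class TestFitMixture:
    def test_single_component_closed_form(self):
        """Coincident points at 50: mean 50 and the closed-form likelihood."""
        x = [50.0] * 8
        s = [1.0, 2.0, 0.5, 1.5, 3.0, 1.0, 2.5, 0.8]
        fit = fit_mixture(x, s, K=1)
        assert fit.means[0] == pytest.approx(50.0, abs=1e-12)
        assert fit.log_likelihood == pytest.approx(closed_form_loglik(x, s, 50.0), abs=1e-9)

    def test_k1_matches_weighted_mean_oracle(self, rng):
        x = rng.uniform(0, 100, 15)
        s = rng.uniform(0.5, 8.0, 15)
        fit = fit_mixture(x, s, K=1)
        mu, ll = weighted_mean_fit(x, s)
        # independent closed form: precision-weighted mean
        mu_direct = np.sum(x / s**2) / np.sum(1 / s**2)
        assert mu == pytest.approx(mu_direct, abs=1e-12)
        assert fit.means[0] == pytest.approx(mu, abs=1e-9)
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-9)
        assert fit.aic == pytest.approx(-2 * ll + 2, abs=1e-9)

    def test_two_well_separated_groups(self, rng):
        x = np.r_[20 + rng.normal(0, 1, 10), 80 + rng.normal(0, 1, 10)]
        s = np.full(20, 2.0)
        fit = fit_mixture(x, s, K=2)
        assert fit.means[0] == pytest.approx(20, abs=1.0)
        assert fit.means[1] == pytest.approx(80, abs=1.0)
        assert fit.mixing_weights[0] == pytest.approx(0.5, abs=0.05)
        assert fit.converged

    def test_matches_exhaustive_assignment_on_six_points(self):
        """Hard-assignment brute force over all 2-partitions agrees on the
        component means for well-separated data."""
        x = np.array([19.0, 20.0, 21.0, 79.0, 80.0, 81.0])
        s = np.full(6, 2.0)
        best = None
        for labels in itertools.product([0, 1], repeat=6):
            labels = np.array(labels)
            if labels.min() == labels.max():
                continue
            means = []
            ll = 0.0
            for k in (0, 1):
                sel = labels == k
                w = 1 / s[sel] ** 2
                mu = np.sum(w * x[sel]) / np.sum(w)
                means.append(mu)
                ll += closed_form_loglik(x[sel], s[sel], mu)
            if best is None or ll > best[0]:
                best = (ll, sorted(means))
        fit = fit_mixture(x, s, K=2)
        assert sorted(fit.means) == pytest.approx(best[1], abs=0.1)

    def test_delta_loglik_matches_grid_oracle(self):
        """lnL(K=2) - lnL(K=1) against a brute-force grid over (mu1, mu2, pi)."""
        x = np.array([18.0, 20.0, 22.0, 78.0, 80.0, 82.0])
        s = np.full(6, 2.0)
        mu1 = np.linspace(15, 25, 201)
        mu2 = np.linspace(75, 85, 201)
        pi = np.linspace(0.01, 0.99, 99)
        def comp_ll(mu):
            # (n, len(mu)) matrix of log N(x | mu, s^2)
            return (-0.5 * ((x[:, None] - mu[None, :]) / s[:, None]) ** 2
                    - np.log(s)[:, None] - 0.5 * _LOG_2PI)
        l1 = comp_ll(mu1)[:, :, None, None]
        l2 = comp_ll(mu2)[:, None, :, None]
        logpi = np.log(pi)[None, None, None, :]
        log1m = np.log1p(-pi)[None, None, None, :]
        mix = np.logaddexp(logpi + l1, log1m + l2).sum(axis=0)
        grid_best = mix.max()
        fit2 = fit_mixture(x, s, K=2)
        _, ll1 = weighted_mean_fit(x, s)
        assert fit2.log_likelihood - ll1 == pytest.approx(grid_best - ll1, abs=1e-3)

    def test_loglik_monotone_every_iteration(self, rng):
        x = rng.uniform(0, 100, 30)
        s = rng.uniform(0.5, 5.0, 30)
        for K in (1, 2, 3, 4):
            fit = fit_mixture(x, s, K)
            h = fit.loglik_history
            assert np.all(np.diff(h) >= -1e-8)

    def test_responsibilities_and_weights_normalised(self, rng):
        x = rng.uniform(0, 100, 25)
        s = rng.uniform(1, 4, 25)
        fit = fit_mixture(x, s, K=3)
        assert fit.mixing_weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert fit.responsibilities.sum(axis=1) == pytest.approx(np.ones(25), abs=1e-9)

    def test_degenerate_coincident_data_flagged(self):
        fit = fit_mixture([50.0] * 5, [1.0] * 5, K=2)
        assert fit.degenerate

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ModelError):
            fit_mixture([1.0, 2.0], [1.0, 1.0], K=3)


class TestSelectModel:
    def test_tight_cluster_prefers_k1(self, rng):
        x = 50 + rng.normal(0, 1, 20)
        s = np.full(20, 2.0)
        best, _ = select_model(x, s, K_max=4)
        assert best == 1

    def test_two_coincident_points_analytic(self):
        """n=2 identical positions: AIC penalty decides, and the gap is
        exactly the parameter-count difference (likelihoods are equal)."""
        best, fits = select_model([50.0, 50.0], [2.0, 2.0], K_max=2)
        assert best == 1
        assert fits[2].log_likelihood == pytest.approx(fits[1].log_likelihood, abs=1e-6)
        assert fits[2].aic - fits[1].aic == pytest.approx(4.0, abs=1e-5)

    def test_three_planted_clusters_recovered(self, rng):
        hits = 0
        for trial in range(20):
            centers = [25.0, 75.0, 125.0]
            x = np.concatenate([c + rng.normal(0, 2, 10) for c in centers])
            s = np.full(30, 2.0)
            best, _ = select_model(x, s, K_max=6)
            hits += best == 3
        assert hits >= 18

    def test_label_permutation_invariance(self, rng):
        """Means come out sorted; membership partition is order-free."""
        x = np.r_[rng.normal(20, 1, 8), rng.normal(60, 1, 8)]
        s = np.full(16, 1.5)
        f1 = fit_mixture(x, s, K=2, seed=1)
        f2 = fit_mixture(x, s, K=2, seed=99)
        assert np.all(np.diff(f1.means) >= 0)
        assert np.array_equal(f1.map_assignment(), f2.map_assignment())
        assert f1.aic == pytest.approx(f2.aic, abs=1e-6)


class TestExtractMQTLs:
    def test_meta_r2_is_mean_of_members(self):
        proj = make_projected([50.0, 50.5], [1.0, 1.0], r2s=[0.10, 0.30])
        fit = fit_mixture([p.consensus_peak_cm for p in proj], [1.0, 1.0], K=1)
        mqtls, dropped = extract_mqtls(fit, proj, "1H")
        assert len(mqtls) == 1 and not dropped
        assert mqtls[0].meta_r2 == pytest.approx(0.20)
        assert mqtls[0].meta_r2_max == pytest.approx(0.30)

    def test_stress_bookkeeping(self):
        stresses = ["drought", "salinity", "salinity", "mineral", "waterlogging",
                    "low_temperature", "drought"]
        proj = make_projected([50.0] * 7, [1.0] * 7, stresses=stresses)
        fit = fit_mixture([50.0] * 7, [1.0] * 7, K=1)
        mqtls, _ = extract_mqtls(fit, proj, "1H")
        counts = mqtls[0].stress_counts
        assert counts == {"drought": 2, "salinity": 2, "waterlogging": 1,
                          "mineral": 1, "low_temperature": 1}
        assert sum(counts.values()) == mqtls[0].n_members

    def test_membership_partitions_input(self, rng):
        x = np.r_[rng.normal(20, 1, 9), rng.normal(80, 1, 11)]
        proj = make_projected(x, [2.0] * 20)
        fit = fit_mixture(x, [2.0] * 20, K=2)
        mqtls, _ = extract_mqtls(fit, proj, "1H")
        ids = [m for mq in mqtls for m in mq.members]
        assert sorted(ids) == sorted(p.qtl_id for p in proj)

    def test_naming_and_flanking_markers(self):
        cons = make_map("cons", {"3H": {"a": 0.0, "b": 40.0, "c": 90.0}})
        x = [20.0, 21.0, 70.0, 71.0]
        proj = make_projected(x, [2.0] * 4, chromosome="3H")
        fit = fit_mixture(x, [2.0] * 4, K=2)
        mqtls, _ = extract_mqtls(fit, proj, "3H", consensus=cons)
        assert [m.mqtl_id for m in mqtls] == ["MQTL3.1", "MQTL3.2"]
        assert mqtls[0].peak_cm < mqtls[1].peak_cm
        assert mqtls[0].flank_left[0] == "a"
        assert mqtls[0].flank_right[0] == "b"
        assert mqtls[1].flank_left[0] == "b"

    def test_component_ci_from_pooled_precision(self):
        proj = make_projected([50.0] * 4, [2.0] * 4)
        fit = fit_mixture([50.0] * 4, [2.0] * 4, K=1)
        mqtls, _ = extract_mqtls(fit, proj, "1H")
        half = 1.96 / np.sqrt(4 / 2.0**2)
        assert mqtls[0].ci95_hi_cm - mqtls[0].peak_cm == pytest.approx(half, abs=1e-9)


class TestAnalyzeChromosome:
    def test_end_to_end_on_synthetic_positions(self, rng):
        x = np.r_[rng.normal(30, 2, 12), rng.normal(100, 2, 12)]
        proj = make_projected(x, [2.0] * 24)
        mqtls, fit, trace = analyze_chromosome(proj, "1H", K_max=5)
        assert fit.K == 2
        assert len(mqtls) == 2
        assert set(trace) == {1, 2, 3, 4, 5}
        assert min(trace, key=trace.get) == 2
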