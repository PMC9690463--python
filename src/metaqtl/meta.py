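"""Meta-QTL detection: Gaussian-mixture clustering of projected QTL positions.

Each projected QTL contributes one observation x_i, its consensus-map peak,
with a *known* standard deviation s_i derived from its recalculated 95%
confidence interval (s_i = CI/3.92).  A chromosome's QTLs are modelled as

    x_i ~ sum_k pi_k * Normal(mu_k, s_i^2)

a mixture over K putative "real" QTL positions with heteroscedastic known
variances: only the K component means and the K-1 free mixing weights are
estimated, by expectation-maximisation.  The number of components is chosen
by the Akaike information criterion, AIC = -2 lnL + 2 (2K - 1), computed
for K = 1..K_max; ties favour the smaller K.  Each QTL is finally assigned
to its maximum-responsibility component, and a component's 95% CI follows
from its inverse-variance-weighted precision:

    mu_k +/- 1.96 / sqrt( sum_i r_ik / s_i^2 ).

Chromosomes are analysed independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from metaqtl.catalog import STRESS_CLASSES
from metaqtl.errors import ModelError
from metaqtl.linkage import LinkageMap
from metaqtl.projection import ProjectedQTL

_LOG_2PI = float(np.log(2.0 * np.pi))

DEFAULT_SEED = 17
DEFAULT_RESTARTS = 10
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-6


@dataclass
class MixtureFit:
    """Result of one EM fit at a fixed number of components K."""

    K: int
    means: np.ndarray
    mixing_weights: np.ndarray
    log_likelihood: float
    aic: float
    responsibilities: np.ndarray
    converged: bool
    n_iter: int
    n_restarts_used: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.zeros(0))
    degenerate: bool = False

    def map_assignment(self) -> np.ndarray:
        """Hard (maximum-responsibility) component index per observation."""
        return np.asarray(self.responsibilities).argmax(axis=1)


def _n_parameters(K: int) -> int:
    # K means + (K - 1) free mixing weights; per-observation variances are
    # data, not parameters
    return 2 * K - 1


def _log_density_matrix(x: np.ndarray, s: np.ndarray, means: np.ndarray) -> np.ndarray:
    """log Normal(x_i | mu_k, s_i^2), shape (n, K)."""
    z = (x[:, None] - means[None, :]) / s[:, None]
    return -0.5 * z**2 - np.log(s)[:, None] - 0.5 * _LOG_2PI


def _em_once(
    x: np.ndarray,
    s: np.ndarray,
    means0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, np.ndarray]:
    K = len(means0)
    means = means0.astype(float).copy()
    weights = np.full(K, 1.0 / K)
    inv_var = 1.0 / s**2
    prev_ll = -np.inf
    history: list[float] = []
    converged = False
    resp = np.full((len(x), K), 1.0 / K)
    for it in range(1, max_iter + 1):
        log_dens = _log_density_matrix(x, s, means) + np.log(weights)[None, :]
        norm = logsumexp(log_dens, axis=1)
        ll = float(norm.sum())
        history.append(ll)
        resp = np.exp(log_dens - norm[:, None])
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll
        weights = resp.mean(axis=0)
        weights = np.clip(weights, 1e-12, None)
        weights /= weights.sum()
        num = resp.T @ (x * inv_var)
        den = resp.T @ inv_var
        means = np.where(den > 0, num / np.where(den > 0, den, 1.0), means)
    return means, weights, resp, history[-1], converged, len(history), np.array(history)


def fit_mixture(
    positions: Sequence[float],
    sds: Sequence[float],
    K: int,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> MixtureFit:
    """Fit the K-component known-variance normal mixture by EM.

    EM runs from quantile-spaced initial means plus ``n_restarts - 1``
    jittered restarts (seeded); the best log-likelihood is kept.  The
    log-likelihood is nondecreasing over the iterations of the winning
    restart (``loglik_history``).  K = 1 needs no iteration: the weighted
    mean with weights 1/s_i^2 maximises the likelihood and EM reaches it in
    one step.
    """
    x = np.asarray(positions, dtype=float)
    s = np.asarray(sds, dtype=float)
    if x.ndim != 1 or x.shape != s.shape:
        raise ModelError("positions and sds must be 1-D and the same length")
    if np.any(s <= 0):
        raise ModelError("all standard deviations must be positive")
    if K < 1 or K > len(x):
        raise ModelError(f"K={K} invalid for {len(x)} observations")

    rng = np.random.default_rng(seed)
    spread = max(x.max() - x.min(), 1.0)
    base = np.quantile(x, (np.arange(1, K + 1)) / (K + 1.0))
    best = None
    used = 0
    for r in range(max(1, n_restarts)):
        means0 = base if r == 0 else np.sort(base + rng.normal(0.0, 0.1 * spread, K))
        result = _em_once(x, s, means0, max_iter, tol)
        used += 1
        if best is None or result[3] > best[3]:
            best = result
        if K == 1:
            break  # likelihood is unimodal in the single mean
    means, weights, resp, ll, converged, n_iter, history = best
    order = np.argsort(means, kind="stable")
    means, weights, resp = means[order], weights[order], resp[:, order]
    aic = -2.0 * ll + 2.0 * _n_parameters(K)
    degenerate = bool(K > 1 and np.any(np.diff(np.sort(means)) < 1e-8))
    return MixtureFit(
        K=K,
        means=means,
        mixing_weights=weights,
        log_likelihood=ll,
        aic=aic,
        responsibilities=resp,
        converged=converged,
        n_iter=n_iter,
        n_restarts_used=used,
        loglik_history=history,
        degenerate=degenerate,
    )


def weighted_mean_fit(positions: Sequence[float], sds: Sequence[float]) -> tuple[float, float]:
    """Closed-form K = 1 solution: (weighted mean, log-likelihood).

    Weights are the precisions 1/s_i^2.  Useful as an independent check on
    the EM path.
    """
    x = np.asarray(positions, dtype=float)
    s = np.asarray(sds, dtype=float)
    w = 1.0 / s**2
    mu = float((w * x).sum() / w.sum())
    ll = float((-0.5 * ((x - mu) / s) ** 2 - np.log(s) - 0.5 * _LOG_2PI).sum())
    return mu, ll


def select_model(
    positions: Sequence[float],
    sds: Sequence[float],
    K_max: int,
    seed: int = DEFAULT_SEED,
    **fit_kwargs,
) -> tuple[int, dict[int, MixtureFit]]:
    """Fit K = 1..K_max and pick the AIC-minimising K (ties -> smaller K)."""
    n = len(positions)
    if K_max < 1:
        raise ModelError("K_max must be at least 1")
    K_max = min(K_max, n)
    fits = {
        K: fit_mixture(positions, sds, K, seed=seed, **fit_kwargs)
        for K in range(1, K_max + 1)
    }
    best_K = min(fits, key=lambda K: (fits[K].aic, K))
    return best_K, fits


@dataclass
class MQTL:
    """A meta-QTL: one mixture component with its assigned member QTLs."""

    mqtl_id: str
    chromosome: str
    peak_cm: float
    ci95_lo_cm: float
    ci95_hi_cm: float
    members: list[str]
    stress_counts: dict[str, int]
    meta_r2: float
    meta_r2_max: float
    flank_left: tuple[str, float] | None = None
    flank_right: tuple[str, float] | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_stresses(self) -> int:
        return sum(1 for v in self.stress_counts.values() if v > 0)


def extract_mqtls(
    fit: MixtureFit,
    projected: Sequence[ProjectedQTL],
    chromosome: str,
    consensus: LinkageMap | None = None,
    naming_offset: int = 0,
) -> tuple[list[MQTL], list[int]]:
    """Turn a mixture fit into named meta-QTLs with membership bookkeeping.

    QTLs are hard-assigned to their maximum-responsibility component; empty
    components are dropped and their indices reported.  MQTLs are numbered
    by ascending peak as ``MQTL<chr>.<rank>`` (``naming_offset`` shifts the
    first rank).  Summed over the returned MQTLs, memberships partition the
    projected set.  ``meta_r2`` is the arithmetic mean of member R² with
    the maximum reported alongside, and the closest consensus markers on
    either side of the peak are attached when a consensus map is given.
    """
    if len(projected) != fit.responsibilities.shape[0]:
        raise ModelError("projected records and fit responsibilities disagree in length")
    assign = fit.map_assignment()
    s = np.array([p.position_sd_cm for p in projected])
    chrom_label = chromosome.rstrip("H").lstrip("chr") or chromosome

    order = np.argsort(fit.means, kind="stable")
    mqtls: list[MQTL] = []
    dropped: list[int] = []
    rank = naming_offset
    for k in order:
        member_idx = np.flatnonzero(assign == k)
        if member_idx.size == 0:
            dropped.append(int(k))
            continue
        rank += 1
        precision = float((fit.responsibilities[:, k] / s**2).sum())
        half = 1.96 / np.sqrt(precision)
        mu = float(fit.means[k])
        members = [projected[i] for i in member_idx]
        r2s = [m.r2 for m in members if m.r2 is not None]
        stress_counts = {st: 0 for st in STRESS_CLASSES}
        for m in members:
            stress_counts[m.stress] += 1
        flank_left = flank_right = None
        if consensus is not None and chromosome in consensus:
            below = [(m.name, m.pos_cm) for m in consensus.loci(chromosome) if m.pos_cm <= mu]
            above = [(m.name, m.pos_cm) for m in consensus.loci(chromosome) if m.pos_cm > mu]
            flank_left = below[-1] if below else None
            flank_right = above[0] if above else None
        mqtls.append(
            MQTL(
                mqtl_id=f"MQTL{chrom_label}.{rank}",
                chromosome=chromosome,
                peak_cm=mu,
                ci95_lo_cm=mu - half,
                ci95_hi_cm=mu + half,
                members=[m.qtl_id for m in members],
                stress_counts=stress_counts,
                meta_r2=float(np.mean(r2s)) if r2s else float("nan"),
                meta_r2_max=float(np.max(r2s)) if r2s else float("nan"),
                flank_left=flank_left,
                flank_right=flank_right,
            )
        )
    return mqtls, dropped


def analyze_chromosome(
    projected: Sequence[ProjectedQTL],
    chromosome: str,
    K_max: int = 10,
    seed: int = DEFAULT_SEED,
    consensus: LinkageMap | None = None,
    extra_sd_cm: float = 0.0,
    **fit_kwargs,
) -> tuple[list[MQTL], MixtureFit, dict[int, float]]:
    """Model-select and extract MQTLs for one chromosome's projected QTLs.

    ``extra_sd_cm`` is an additional measurement-noise standard deviation
    added in quadrature to each QTL's CI-implied sd — the map-transfer
    (projection) error, typically estimated from the consensus build's
    residuals.  Without it, QTLs with very narrow recalculated CIs claim
    more positional precision than the consensus coordinates can support,
    which biases the AIC toward spurious extra components.  Returns
    ``(mqtls, best_fit, aic_trace)`` where the trace maps each K to its
    AIC.
    """
    recs = [p for p in projected if p.consensus_chromosome == chromosome]
    if not recs:
        raise ModelError(f"no projected QTLs on chromosome {chromosome}")
    x = [p.consensus_peak_cm for p in recs]
    s = [float(np.hypot(p.position_sd_cm, extra_sd_cm)) for p in recs]
    best_K, fits = select_model(x, s, K_max, seed=seed, **fit_kwargs)
    mqtls, _ = extract_mqtls(fits[best_K], recs, chromosome, consensus=consensus)
    return mqtls, fits[best_K], {K: f.aic for K, f in fits.items()}
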