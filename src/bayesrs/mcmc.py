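"""Gibbs sampler for whole-genome regression with a four-component mixture
prior on SNP effects (BayesR) and segment-specific Dirichlet priors on the
mixture proportions (BayesRS).

Model
-----
``y = mu 1 + W g + a + e`` with, for marker j in segment s,

* ``g_j | k_j = c ~ N(0, gamma_c * sigma_g2)`` where
  ``gamma = (0, 0.0001, 0.001, 0.01)`` and ``sigma_g2 = r_y^2 Var(y)``,
* ``P(k_j = c) = pi_sc`` and ``pi_s ~ Dirichlet(alpha_s)``,
* ``a ~ N(0, A sigma_a2)`` (optional residual polygenic term),
* ``e ~ N(0, I sigma_e2)``; flat priors on mu, sigma_e2, sigma_a2.

BayesR is the special case of a single genome-wide pi segment with
``alpha = (1, 1, 1, 1)``; both models run through the same code path, so a
BayesRS run with that degenerate prior is bit-identical to BayesR for the
same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from . import _kernels
from .genotype_prep import RelationshipMatrix, StandardizedGenotypes
from .io_formats import MarkerMap
from .segments import (
    SegmentPartition,
    SegmentVarianceAccumulator,
    SegmentVarianceProfile,
    partition,
)

__all__ = [
    "MixtureSpec",
    "GibbsConfig",
    "ChainState",
    "PosteriorSummary",
    "genome_partition",
    "init_chain",
    "update_mu",
    "update_snp_effects",
    "update_pi",
    "posterior_pi_params",
    "update_polygenic",
    "update_sigma_e",
    "run_chain",
    "fit_bayesr",
    "fit_bayesrs",
    "component_marginals_fixed_hyperparams",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Variance scalers of the four-component mixture and its anchor sigma_g2.

    ``scalers`` multiply ``sigma_g2`` to give the per-component effect
    variances; the first component is the exact zero. ``sigma_g2`` is fixed
    at ``r_y^2 * Var(y)`` (reliability times phenotypic variance), computed
    once from the reference phenotypes — it is not sampled.
    """

    sigma_g2: float
    scalers: tuple = (0.0, 1e-4, 1e-3, 1e-2)

    def __post_init__(self):
        sc = tuple(float(s) for s in self.scalers)
        # ties among the non-zero scalers are allowed (they merge components)
        if (len(sc) != 4 or sc[0] != 0.0 or sc[1] <= 0.0
                or any(b < a for a, b in zip(sc, sc[1:]))):
            raise ValueError("scalers must be 4 non-decreasing values starting at 0")
        if not self.sigma_g2 > 0:
            raise ValueError("sigma_g2 must be positive")
        object.__setattr__(self, "scalers", sc)

    @property
    def variances(self) -> np.ndarray:
        return np.array(self.scalers) * self.sigma_g2

    @classmethod
    def from_phenotypes(cls, y, reliability: float, scalers=(0.0, 1e-4, 1e-3, 1e-2)):
        y = np.asarray(y, dtype=float)
        if not (0 < reliability <= 1):
            raise ValueError("reliability must be in (0, 1]")
        return cls(sigma_g2=float(reliability * y.var()), scalers=scalers)


@dataclass(frozen=True)
class GibbsConfig:
    """Chain settings.

    Defaults follow the convention for a few-thousand-animal reference
    (20,000 sweeps, 10,000 burn-in); small references mix more slowly and
    are better served by 100,000/50,000.
    """

    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 1
    seed: int = 0
    include_polygenic: bool = False
    permute_scan: bool = False

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0 <= int(self.seed) < 2**31):
            raise ValueError("seed must be a non-negative 31-bit integer")


@dataclass
class ChainState:
    """Current Gibbs state; ``e`` always equals ``y - mu 1 - W g - a``."""

    mu: float
    g: np.ndarray
    k: np.ndarray
    pi: np.ndarray
    a: np.ndarray
    sigma_e2: float
    sigma_a2: float
    e: np.ndarray
    rng: np.random.Generator

    def residual_error(self, y, Wt) -> float:
        """Max abs deviation of e from its definition (bookkeeping check)."""
        e_exact = exact_residual(y, self.mu, self.g, self.a, Wt)
        return float(np.max(np.abs(self.e - e_exact)))


def exact_residual(y, mu, g, a, Wt) -> np.ndarray:
    nz = np.flatnonzero(g)
    wg = Wt[nz].T @ g[nz] if nz.size else 0.0
    return y - mu - wg - a


@dataclass
class PosteriorSummary:
    """Posterior means and occupancy bookkeeping from a finished chain."""

    mu_mean: float
    g_mean: np.ndarray
    a_mean: np.ndarray | None
    pi_mean: np.ndarray
    occupancy: np.ndarray          # (m, 4) per-marker occupancy frequencies
    seg_counts: np.ndarray         # (S_report, 4) mean indicator counts per segment
    segment_variances: SegmentVarianceProfile
    report_partition: SegmentPartition
    pi_partition: SegmentPartition
    sigma_e2_mean: float
    sigma_a2_mean: float | None
    sigma_g2: float
    config: GibbsConfig
    map: MarkerMap
    freq_provenance: str = "own"
    n_draws: int = 0


def genome_partition(mmap: MarkerMap) -> SegmentPartition:
    """Single segment spanning all markers (the BayesR pi partition)."""
    return SegmentPartition(((0, len(mmap)),), len(mmap), mmap)


def _as_alpha_matrix(alpha, n_segments: int) -> np.ndarray:
    mat = np.asarray(getattr(alpha, "alphas", alpha), dtype=float)
    if mat.ndim == 1:
        mat = np.tile(mat, (n_segments, 1))
    if mat.shape != (n_segments, 4):
        raise ValueError(
            f"Dirichlet prior table has shape {mat.shape}, expected ({n_segments}, 4)"
        )
    if np.any(mat <= 0):
        raise ValueError("Dirichlet parameters must be strictly positive")
    return mat


def init_chain(
    W: StandardizedGenotypes,
    y: np.ndarray,
    mixture: MixtureSpec,
    part_pi: SegmentPartition,
    alpha,
    A: RelationshipMatrix | None,
    cfg: GibbsConfig,
) -> ChainState:
    """Deterministic initial state: g = 0, k = 0, pi = normalized alpha.

    sigma_e2 starts at ``Var(y) (1 - r_y^2)`` (floored), sigma_a2 at
    ``0.05 Var(y)`` when the polygenic term is on. Both the compiled
    kernel's RNG and the Python-side generator are seeded from cfg.seed.
    """
    y = np.asarray(y, dtype=float)
    n, m = W.W.shape
    if y.shape != (n,):
        raise ValueError("phenotype length does not match W")
    alpha_mat = _as_alpha_matrix(alpha, part_pi.n_segments)
    r_y2 = min(mixture.sigma_g2 / y.var(), 1.0) if y.var() > 0 else 1.0
    mu = float(y.mean())
    state = ChainState(
        mu=mu,
        g=np.zeros(m),
        k=np.zeros(m, dtype=np.int64),
        pi=alpha_mat / alpha_mat.sum(axis=1, keepdims=True),
        a=np.zeros(n),
        sigma_e2=max(float(y.var() * (1.0 - r_y2)), 1e-8),
        sigma_a2=float(0.05 * y.var()) if cfg.include_polygenic else 0.0,
        e=y - mu,
        rng=np.random.default_rng([int(cfg.seed), 0xB5]),
    )
    _kernels.seed_rng(int(cfg.seed))
    return state


def update_mu(state: ChainState, n: int | None = None) -> ChainState:
    """Conjugate draw of the overall mean under its flat prior."""
    n = len(state.e) if n is None else n
    center = float(state.e.mean()) + state.mu
    mu_new = float(state.rng.normal(center, np.sqrt(state.sigma_e2 / n)))
    state.e += state.mu - mu_new
    state.mu = mu_new
    return state


def update_snp_effects(
    state: ChainState,
    Wt: np.ndarray,
    cj: np.ndarray,
    mixture: MixtureSpec,
    seg_of_pi: np.ndarray,
    order: np.ndarray | None = None,
) -> ChainState:
    """One compiled scan over all markers (indicator and effect jointly)."""
    if order is None:
        order = np.arange(Wt.shape[0])
    with np.errstate(divide="ignore"):
        log_pi = np.log(state.pi)
    status = _kernels.sweep_snp_effects(
        Wt, state.e, state.g, state.k, cj, log_pi, seg_of_pi,
        mixture.variances, state.sigma_e2, order,
    )
    if status >= 0:
        raise FloatingPointError(
            f"non-finite component weight at marker index {status}"
        )
    return state


def posterior_pi_params(alpha_row: np.ndarray, counts_row: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial conjugacy: posterior parameters alpha + counts."""
    return np.asarray(alpha_row, dtype=float) + np.asarray(counts_row, dtype=float)


def indicator_counts(k: np.ndarray, seg_of: np.ndarray, n_segments: int) -> np.ndarray:
    counts = np.zeros((n_segments, 4))
    np.add.at(counts, (seg_of, k), 1.0)
    return counts


def update_pi(state: ChainState, alpha_mat: np.ndarray, seg_of_pi: np.ndarray) -> ChainState:
    counts = indicator_counts(state.k, seg_of_pi, alpha_mat.shape[0])
    for s in range(alpha_mat.shape[0]):
        state.pi[s] = state.rng.dirichlet(posterior_pi_params(alpha_mat[s], counts[s]))
    return state


def update_polygenic(state: ChainState, A_inv: np.ndarray) -> ChainState:
    """Joint draw of the polygenic vector, then its variance component.

    ``a | rest ~ N(P^-1 r / sigma_e2, P^-1)`` with
    ``P = I/sigma_e2 + A^-1/sigma_a2`` and ``r = y - mu 1 - W g = e + a``;
    then ``sigma_a2 ~ InvGamma(q/2 - 1, a' A^-1 a / 2)`` under the flat prior.
    """
    q = len(state.a)
    if q <= 4:
        raise ValueError("polygenic update needs more than 4 individuals under a flat prior")
    r = state.e + state.a
    P = np.eye(q) / state.sigma_e2 + A_inv / state.sigma_a2
    c, low = cho_factor(P, lower=True)
    mean = cho_solve((c, low), r / state.sigma_e2)
    z = state.rng.standard_normal(q)
    a_new = mean + solve_triangular(c, z, lower=low, trans="T")
    state.e += state.a - a_new
    state.a = a_new
    quad = float(a_new @ A_inv @ a_new)
    state.sigma_a2 = float((quad / 2.0) / state.rng.standard_gamma(q / 2.0 - 1.0))
    return state


def update_sigma_e(state: ChainState) -> ChainState:
    """Residual variance draw: InvGamma(n/2 - 1, e'e/2) under the flat prior."""
    n = len(state.e)
    if n <= 4:
        raise ValueError("residual-variance update needs more than 4 records")
    sse = float(state.e @ state.e)
    if sse == 0.0:
        raise ValueError("zero residual sum of squares: degenerate data")
    state.sigma_e2 = float((sse / 2.0) / state.rng.standard_gamma(n / 2.0 - 1.0))
    return state


def run_chain(
    W: StandardizedGenotypes,
    y: np.ndarray,
    mixture: MixtureSpec,
    part_pi: SegmentPartition,
    alpha,
    part_report: SegmentPartition,
    A: RelationshipMatrix | None = None,
    cfg: GibbsConfig = GibbsConfig(),
) -> PosteriorSummary:
    """Run the full Gibbs cycle and accumulate posterior summaries.

    Update order per sweep: mu, marker effects/indicators, pi, polygenic
    term and sigma_a2 (if enabled), sigma_e2. After burn-in, every
    ``thin``-th sweep contributes to the posterior means, to the per-segment
    indicator occupancy on ``part_report`` (the counts transferable as a
    Dirichlet prior) and to the segment-variance profile. The residual is
    recomputed from scratch every 100 sweeps and checked against its
    incremental bookkeeping to 1e-6.
    """
    y = np.asarray(y, dtype=float)
    n, m = W.W.shape
    alpha_mat = _as_alpha_matrix(alpha, part_pi.n_segments)
    state = init_chain(W, y, mixture, part_pi, alpha_mat, A, cfg)

    Wt = np.ascontiguousarray(W.W.T)
    cj = np.einsum("ji,ji->j", Wt, Wt)
    seg_of_pi = part_pi.segment_of_marker()
    seg_of_rep = part_report.segment_of_marker()

    A_inv = None
    if cfg.include_polygenic:
        if A is None:
            raise ValueError("include_polygenic requires a relationship matrix")
        Am = np.asarray(A.A, dtype=float)
        if Am.shape != (n, n):
            raise ValueError("relationship matrix does not match sample count")
        try:
            A_inv = np.linalg.inv(Am)
        except np.linalg.LinAlgError:
            A_inv = np.linalg.inv(Am + 1e-8 * np.eye(n))

    acc_var = SegmentVarianceAccumulator(part_report)
    mu_sum = 0.0
    g_sum = np.zeros(m)
    a_sum = np.zeros(n)
    pi_sum = np.zeros_like(state.pi)
    occ = np.zeros((m, 4))
    se_sum = 0.0
    sa_sum = 0.0
    n_draws = 0
    rows = np.arange(m)

    scan_order = np.arange(m)
    for sweep in range(1, cfg.n_iter + 1):
        update_mu(state)
        if cfg.permute_scan:
            scan_order = state.rng.permutation(m)
        update_snp_effects(state, Wt, cj, mixture, seg_of_pi, scan_order)
        update_pi(state, alpha_mat, seg_of_pi)
        if cfg.include_polygenic:
            update_polygenic(state, A_inv)
        update_sigma_e(state)

        if sweep % 100 == 0:
            e_exact = exact_residual(y, state.mu, state.g, state.a, Wt)
            drift = float(np.max(np.abs(state.e - e_exact)))
            if drift > 1e-6:
                raise FloatingPointError(
                    f"residual bookkeeping drift {drift:.3g} at sweep {sweep}"
                )
            state.e = e_exact

        if sweep > cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0:
            n_draws += 1
            mu_sum += state.mu
            g_sum += state.g
            a_sum += state.a
            pi_sum += state.pi
            occ[rows, state.k] += 1.0
            se_sum += state.sigma_e2
            sa_sum += state.sigma_a2
            acc_var.add_draw(W.W, state.g)

    if n_draws == 0:
        raise ValueError("no post-burn-in draws collected")
    occ /= n_draws
    seg_counts = np.zeros((part_report.n_segments, 4))
    np.add.at(seg_counts, seg_of_rep, occ)
    g_mean = g_sum / n_draws
    if not np.all(np.isfinite(g_mean)):
        raise FloatingPointError("non-finite posterior mean effect")
    return PosteriorSummary(
        mu_mean=mu_sum / n_draws,
        g_mean=g_mean,
        a_mean=(a_sum / n_draws) if cfg.include_polygenic else None,
        pi_mean=pi_sum / n_draws,
        occupancy=occ,
        seg_counts=seg_counts,
        segment_variances=acc_var.profile(),
        report_partition=part_report,
        pi_partition=part_pi,
        sigma_e2_mean=se_sum / n_draws,
        sigma_a2_mean=(sa_sum / n_draws) if cfg.include_polygenic else None,
        sigma_g2=mixture.sigma_g2,
        config=cfg,
        map=W.source_map,
        freq_provenance=W.freq_provenance,
        n_draws=n_draws,
    )


def fit_bayesr(
    W: StandardizedGenotypes,
    y: np.ndarray,
    mixture: MixtureSpec,
    part_report: SegmentPartition,
    A: RelationshipMatrix | None = None,
    cfg: GibbsConfig = GibbsConfig(),
) -> PosteriorSummary:
    """BayesR: one genome-wide pi with the uniform Dirichlet(1,1,1,1) prior."""
    part_pi = genome_partition(W.source_map)
    return run_chain(W, y, mixture, part_pi, np.ones(4), part_report, A, cfg)


def fit_bayesrs(
    W: StandardizedGenotypes,
    y: np.ndarray,
    mixture: MixtureSpec,
    prior,
    part_pi: SegmentPartition,
    part_report: SegmentPartition | None = None,
    A: RelationshipMatrix | None = None,
    cfg: GibbsConfig = GibbsConfig(),
) -> PosteriorSummary:
    """BayesRS: per-segment Dirichlet priors alpha_s on the pi partition."""
    if part_report is None:
        part_report = part_pi
    return run_chain(W, y, mixture, part_pi, prior, part_report, A, cfg)


def component_marginals_fixed_hyperparams(
    W, yc, pi, mixture: MixtureSpec, sigma_e2: float,
    n_sweeps: int, seed: int, burn_in: int = 0,
) -> np.ndarray:
    """Per-marker occupancy frequencies with mu, pi, sigma_e2 held fixed.

    Diagnostic used to check the marker update against exhaustive
    enumeration of indicator configurations on tiny instances. ``yc`` is the
    already-centered response.
    """
    Wm = W.W if hasattr(W, "W") else np.asarray(W, dtype=float)
    Wt = np.ascontiguousarray(Wm.T)
    with np.errstate(divide="ignore"):  # pi entries of 0 are legal (-inf weight)
        log_pi = np.log(np.asarray(pi, dtype=float))
    return _kernels.fixed_hyperparam_marginals(
        Wt, np.asarray(yc, dtype=float), log_pi, mixture.variances,
        float(sigma_e2), int(n_sweeps), int(burn_in), int(seed),
    )
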