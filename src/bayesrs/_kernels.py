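"""Numba kernels for the marker-effect Gibbs sweep.

The per-marker update is inherently sequential (each draw conditions on the
current residual), so the hot loop is compiled. The kernels use numba's
internal NumPy-compatible RNG, seeded once per chain via :func:`seed_rng`;
given the same seed and inputs the draw sequence is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_rng", "sweep_snp_effects", "fixed_hyperparam_marginals"]


@njit(cache=True)
def seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def sweep_snp_effects(Wt, e, g, k, cj, log_pi, seg_of, v, sigma_e2, order):
    """One full scan over markers (in ``order``), updating effects/indicators
    in place.

    For marker j with column w_j (row j of the marker-major ``Wt``), the
    right-hand side is ``rhs = w_j'e + c_j g_j`` (the regression of the
    residual *excluding* marker j on w_j, without forming that residual).
    Component c > 0 has effect-integrated log weight
    ``log pi_sc - 0.5 log((c_j v_c + s2e)/s2e) + 0.5 rhs^2 v_c /(s2e (c_j v_c + s2e))``
    and component 0 has ``log pi_s0``. Given the sampled component, the
    effect is drawn from its conjugate normal conditional (or set to 0).

    Returns -1 on success, or the index of the first marker whose weights
    were non-finite.
    """
    m, n = Wt.shape
    for jj in range(m):
        j = order[jj]
        wj = Wt[j]
        gj = g[j]
        rhs = cj[j] * gj
        for i in range(n):
            rhs += wj[i] * e[i]
        s = seg_of[j]
        lw0 = log_pi[s, 0]
        v1 = v[1]
        d1 = cj[j] * v1 + sigma_e2
        lw1 = log_pi[s, 1] - 0.5 * np.log(d1 / sigma_e2) \
            + 0.5 * rhs * rhs * v1 / (sigma_e2 * d1)
        v2 = v[2]
        d2 = cj[j] * v2 + sigma_e2
        lw2 = log_pi[s, 2] - 0.5 * np.log(d2 / sigma_e2) \
            + 0.5 * rhs * rhs * v2 / (sigma_e2 * d2)
        v3 = v[3]
        d3 = cj[j] * v3 + sigma_e2
        lw3 = log_pi[s, 3] - 0.5 * np.log(d3 / sigma_e2) \
            + 0.5 * rhs * rhs * v3 / (sigma_e2 * d3)
        mx = lw0
        if lw1 > mx:
            mx = lw1
        if lw2 > mx:
            mx = lw2
        if lw3 > mx:
            mx = lw3
        if not np.isfinite(mx):
            return j
        w0 = np.exp(lw0 - mx)
        w1 = np.exp(lw1 - mx)
        w2 = np.exp(lw2 - mx)
        w3 = np.exp(lw3 - mx)
        tot = w0 + w1 + w2 + w3
        if not np.isfinite(tot) or tot <= 0.0:
            return j
        u = np.random.random() * tot
        if u <= w0:
            knew = 0
        elif u <= w0 + w1:
            knew = 1
        elif u <= w0 + w1 + w2:
            knew = 2
        else:
            knew = 3
        if knew == 0:
            gnew = 0.0
        else:
            vc = v[knew]
            dc = cj[j] * vc + sigma_e2
            mean = rhs * vc / dc
            sd = np.sqrt(sigma_e2 * vc / dc)
            gnew = mean + sd * np.random.normal(0.0, 1.0)
        if gnew != gj:
            diff = gnew - gj
            for i in range(n):
                e[i] -= wj[i] * diff
        g[j] = gnew
        k[j] = knew
    return -1


@njit(cache=True)
def fixed_hyperparam_marginals(Wt, yc, log_pi_row, v, sigma_e2, n_sweeps, burn_in,
                               seed):
    """Marginal component occupancy with mu, pi, sigma_e2 held fixed.

    Runs ``n_sweeps`` indicator/effect scans on the centered response ``yc``
    and returns the (m, 4) matrix of post-burn-in occupancy frequencies —
    the sampler-side quantity that exhaustive enumeration over indicator
    configurations (with effects integrated analytically) must reproduce.
    """
    np.random.seed(seed)
    m, n = Wt.shape
    e = yc.copy()
    g = np.zeros(m)
    k = np.zeros(m, dtype=np.int64)
    cj = np.empty(m)
    for j in range(m):
        c = 0.0
        for i in range(n):
            c += Wt[j, i] * Wt[j, i]
        cj[j] = c
    log_pi = np.empty((1, 4))
    for c in range(4):
        log_pi[0, c] = log_pi_row[c]
    seg_of = np.zeros(m, dtype=np.int64)
    order = np.arange(m)
    occ = np.zeros((m, 4))
    kept = 0
    for sweep in range(n_sweeps):
        status = sweep_snp_effects(Wt, e, g, k, cj, log_pi, seg_of, v, sigma_e2,
                                   order)
        if status >= 0:
            raise ValueError("non-finite component weight in fixed-hyperparameter sweep")
        if sweep >= burn_in:
            kept += 1
            for j in range(m):
                occ[j, k[j]] += 1.0
    return occ / kept
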