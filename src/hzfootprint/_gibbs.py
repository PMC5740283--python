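"""Numba kernel for the admixture Gibbs sampler.

State per sweep: allele-copy origins z (categorical given Q and population
allele frequencies), population frequencies (Dirichlet(1 + counts)), and
individual ancestry vectors Q (Dirichlet(alpha + counts)).  Reference
individuals in supervised mode have their allele origins pinned to their
species, but their Q is still sampled, so the spread of reference Q values
remains observable (it feeds the admixture threshold rule).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _dirichlet_row(alpha_plus_counts, out):
    total = 0.0
    for j in range(alpha_plus_counts.shape[0]):
        g = np.random.gamma(alpha_plus_counts[j], 1.0)
        if g < 1e-300:
            g = 1e-300
        out[j] = g
        total += g
    for j in range(alpha_plus_counts.shape[0]):
        out[j] /= total


@njit(cache=True)
def gibbs_admixture(alleles, n_alleles, K, alpha, sweeps, burnin, thin, fixed_pop, seed):
    """Run the sampler; returns (posterior-mean Q, thinned lnL trace,
    indices of trace entries, final freqs).

    alleles : (N, L, 2) int32, -1 = missing
    fixed_pop : (N,) int32, -1 = unsupervised individual
    """
    np.random.seed(seed)
    N, L, _ = alleles.shape
    Amax = 0
    for l in range(L):
        if n_alleles[l] > Amax:
            Amax = n_alleles[l]

    Q = np.full((N, K), 1.0 / K)
    freqs = np.full((K, L, Amax), 0.0)
    for k in range(K):
        for l in range(L):
            tmp = np.full(n_alleles[l], 1.0)
            _dirichlet_row(tmp, freqs[k, l, : n_alleles[l]])

    q_mean = np.zeros((N, K))
    n_trace = (sweeps + thin - 1) // thin
    trace = np.empty(n_trace)
    trace_sweep = np.empty(n_trace, dtype=np.int64)
    t_idx = 0

    freq_counts = np.zeros((K, L, Amax))
    q_counts = np.zeros((N, K))
    w = np.empty(K)

    for sweep in range(sweeps):
        freq_counts[:, :, :] = 0.0
        q_counts[:, :] = 0.0
        for i in range(N):
            fp = fixed_pop[i]
            for l in range(L):
                for c in range(2):
                    a = alleles[i, l, c]
                    if a < 0:
                        continue
                    if fp >= 0:
                        z = fp
                    else:
                        tot = 0.0
                        for k in range(K):
                            wk = Q[i, k] * freqs[k, l, a]
                            w[k] = wk
                            tot += wk
                        u = np.random.random() * tot
                        z = K - 1
                        acc = 0.0
                        for k in range(K - 1):
                            acc += w[k]
                            if u <= acc:
                                z = k
                                break
                    freq_counts[z, l, a] += 1.0
                    q_counts[i, z] += 1.0
        # conjugate updates
        for k in range(K):
            for l in range(L):
                na = n_alleles[l]
                tmp = np.empty(na)
                for a in range(na):
                    tmp[a] = 1.0 + freq_counts[k, l, a]
                _dirichlet_row(tmp, freqs[k, l, :na])
        for i in range(N):
            tmp = np.empty(K)
            for k in range(K):
                tmp[k] = alpha + q_counts[i, k]
            _dirichlet_row(tmp, Q[i])

        if sweep % thin == 0:
            lnl = 0.0
            for i in range(N):
                for l in range(L):
                    for c in range(2):
                        a = alleles[i, l, c]
                        if a < 0:
                            continue
                        p = 0.0
                        for k in range(K):
                            p += Q[i, k] * freqs[k, l, a]
                        if p < 1e-300:
                            p = 1e-300
                        lnl += np.log(p)
            trace[t_idx] = lnl
            trace_sweep[t_idx] = sweep
            t_idx += 1

        if sweep >= burnin:
            for i in range(N):
                for k in range(K):
                    q_mean[i, k] += Q[i, k]

    denom = sweeps - burnin
    if denom > 0:
        for i in range(N):
            for k in range(K):
                q_mean[i, k] /= denom
    return q_mean, trace[:t_idx], trace_sweep[:t_idx], freqs
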