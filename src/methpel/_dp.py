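"""Transfer-matrix kernels for the nearest-neighbour Ising methylation model.

Every kernel works on a single estimation region described by its per-site
fields ``alpha`` (length ``N``) and nearest-neighbour couplings ``beta``
(length ``N - 1``), with spins ``s = 2x - 1`` in {-1, +1} for methylation
states x in {0, 1}.  The unnormalized pattern weight is

    w(x) = exp( sum_n alpha_n s_n  +  sum_n beta_n s_n s_{n+1} )

so the potential is V(x) = -log w(x) and P(x) = w(x) / Z.

Messages are kept in log space throughout; the level-distribution DP uses a
rescaled linear-space table instead (only ratios survive the final
normalization).  Kernels are numba-jitted when numba imports; the plain-Python
path is identical, only slower.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def _lae(x: float, y: float) -> float:
    """log(exp(x) + exp(y)) stable against overflow and -inf arguments."""
    if x < y:
        x, y = y, x
    if y == -np.inf:
        return x
    return x + np.log1p(np.exp(y - x))


@njit(cache=True)
def forward_messages(alpha, beta):
    """f[n, j] = log sum of weights of prefixes x_0..x_n ending in state j.

    Column j=0 is spin -1 (unmethylated), j=1 is spin +1 (methylated).
    """
    n_sites = alpha.shape[0]
    f = np.empty((n_sites, 2))
    f[0, 0] = -alpha[0]
    f[0, 1] = alpha[0]
    for n in range(1, n_sites):
        for j in range(2):
            s = 2.0 * j - 1.0
            f[n, j] = alpha[n] * s + _lae(
                f[n - 1, 1] + beta[n - 1] * s, f[n - 1, 0] - beta[n - 1] * s
            )
    return f


@njit(cache=True)
def backward_messages(alpha, beta):
    """b[n, j] = log sum of weights of suffixes x_n..x_{N-1} given spin j at n,
    excluding site n's own field term (so b[N-1, :] = 0)."""
    n_sites = alpha.shape[0]
    b = np.zeros((n_sites, 2))
    for n in range(n_sites - 2, -1, -1):
        for j in range(2):
            s = 2.0 * j - 1.0
            b[n, j] = _lae(
                b[n + 1, 1] + beta[n] * s + alpha[n + 1],
                b[n + 1, 0] - beta[n] * s - alpha[n + 1],
            )
    return b


@njit(cache=True)
def log_partition(alpha, beta):
    f = forward_messages(alpha, beta)
    n = alpha.shape[0]
    return _lae(f[n - 1, 0], f[n - 1, 1])


@njit(cache=True)
def window_log_weight(alpha, beta, f, b, start, clamp):
    """Log total weight of patterns consistent with a clamped window.

    ``clamp`` holds int8 codes over the window starting at chain index
    ``start``: +1 forces methylated, -1 forces unmethylated, 0 leaves the
    site free (unobserved).  ``f``/``b`` are the full-chain messages, so the
    sites outside the window are summed out implicitly.
    """
    width = clamp.shape[0]
    g0 = -np.inf
    g1 = -np.inf
    if clamp[0] <= 0:
        g0 = f[start, 0]
    if clamp[0] >= 0:
        g1 = f[start, 1]
    for m in range(1, width):
        n = start + m
        h0 = -np.inf
        h1 = -np.inf
        if clamp[m] <= 0:
            h0 = -alpha[n] + _lae(g1 - beta[n - 1], g0 + beta[n - 1])
        if clamp[m] >= 0:
            h1 = alpha[n] + _lae(g1 + beta[n - 1], g0 - beta[n - 1])
        g0 = h0
        g1 = h1
    last = start + width - 1
    return _lae(g0 + b[last, 0], g1 + b[last, 1])


@njit(cache=True)
def reads_log_likelihood(alpha, beta, starts, clamps, offsets, lengths, counts):
    """Total log-likelihood of a set of (deduplicated) read fragments.

    Fragment r occupies chain indices starts[r] .. starts[r]+lengths[r]-1 and
    its clamp codes live in clamps[offsets[r] : offsets[r]+lengths[r]];
    counts[r] is its multiplicity.
    """
    f = forward_messages(alpha, beta)
    b = backward_messages(alpha, beta)
    n = alpha.shape[0]
    log_z = _lae(f[n - 1, 0], f[n - 1, 1])
    total = 0.0
    for r in range(starts.shape[0]):
        cl = clamps[offsets[r] : offsets[r] + lengths[r]]
        total += counts[r] * (window_log_weight(alpha, beta, f, b, starts[r], cl) - log_z)
    return total


@njit(cache=True)
def level_distribution_dp(alpha, beta, in_subset):
    """Exact P(k methylated sites among the flagged subset), k = 0..K.

    Augments the transfer matrix with a methylation counter restricted to the
    sites where ``in_subset`` is nonzero; O(N*K) time.  Returns a normalized
    probability vector of length K+1.
    """
    n_sites = alpha.shape[0]
    k_total = 0
    for n in range(n_sites):
        if in_subset[n]:
            k_total += 1
    table = np.zeros((2, k_total + 1))
    k0 = 1 if in_subset[0] else 0
    table[0, 0] = np.exp(-alpha[0])
    table[1, k0] = np.exp(alpha[0])
    for n in range(1, n_sites):
        nxt = np.zeros((2, k_total + 1))
        kinc = 1 if in_subset[n] else 0
        eb = np.exp(beta[n - 1])
        ebm = np.exp(-beta[n - 1])
        ea = np.exp(alpha[n])
        eam = np.exp(-alpha[n])
        for k in range(k_total + 1):
            nxt[0, k] = eam * (table[1, k] * ebm + table[0, k] * eb)
            if k + kinc <= k_total:
                nxt[1, k + kinc] = ea * (table[1, k] * eb + table[0, k] * ebm)
        scale = nxt.max()
        if scale > 0.0:
            nxt /= scale
        table = nxt
    weights = table[0] + table[1]
    return weights / weights.sum()


@njit(cache=True)
def sample_windows(alpha, beta, f, b, starts, width, unif):
    """Draw exact Ising samples of ``width`` consecutive sites per read.

    Forward-filter/backward-sample over the chain marginal of each window:
    the first spin follows f+b at the window start, subsequent spins follow
    the conditional p(s_{n} | s_{n-1}) shaped by the backward message, so the
    draw is an exact sample of the window marginal of the full chain.
    ``unif`` supplies uniforms of shape (n_reads, width).  Returns int8 spins.
    """
    n_reads = starts.shape[0]
    out = np.empty((n_reads, width), dtype=np.int8)
    for r in range(n_reads):
        i = starts[r]
        p1 = 1.0 / (1.0 + np.exp((f[i, 0] + b[i, 0]) - (f[i, 1] + b[i, 1])))
        s = 1 if unif[r, 0] < p1 else -1
        out[r, 0] = s
        for m in range(1, width):
            n = i + m
            l1 = alpha[n] + beta[n - 1] * s + b[n, 1]
            l0 = -alpha[n] - beta[n - 1] * s + b[n, 0]
            p1 = 1.0 / (1.0 + np.exp(l0 - l1))
            s = 1 if unif[r, m] < p1 else -1
            out[r, m] = s
    return out
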