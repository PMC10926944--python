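"""Potential-energy landscapes of CpG methylation: the 1D Ising model core.

A genomic estimation region with N CpG sites carries a joint distribution
over methylation patterns x in {0,1}^N of Boltzmann form

    P(x) = exp(-V(x)) / Z,
    V(x) = - sum_n alpha_n s_n - sum_{n<N} beta_n s_n s_{n+1},   s = 2x - 1,

where the per-site field alpha_n = a + b * rho_n is modulated by local CpG
density rho_n, and the nearest-neighbour coupling beta_n = c / d_n decays
with the genomic distance d_n (bp) between adjacent CpGs.  A region is thus
summarized by three parameters (a, b, c): ``a`` sets the baseline propensity
to methylate (positive favours methylation), ``b`` its dependence on CpG
density, and ``c`` the cooperativity between neighbouring sites (large
positive c -> ordered, low-entropy landscapes).

Exact quantities (partition function, marginals of partially observed reads,
methylation-level distributions) are computed by transfer-matrix dynamic
programming in O(N); parameters are estimated by maximum likelihood over the
reads of a region with a multi-start Nelder-Mead search inside a box.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _dp

logger = logging.getLogger(__name__)

#: box constraints on (a, b, c)
PARAM_BOUNDS = ((-10.0, 10.0), (-10.0, 10.0), (-20.0, 20.0))
#: adjacent-CpG distances are capped here before entering beta = c / d
MAX_COUPLING_DISTANCE = 1000.0
#: fixed multi-start grid for the Nelder-Mead search (deterministic order)
START_GRID = tuple(
    (a0, b0, c0) for a0 in (-5.0, 0.0, 5.0) for b0 in (-5.0, 0.0, 5.0) for c0 in (-10.0, 0.0, 10.0)
)

_CALL_CODE = {"U": -1, "M": 1, ".": 0}


@dataclass(frozen=True)
class IsingParameters:
    """Region-level (a, b, c) with the derived per-site fields/couplings."""

    a: float
    b: float
    c: float

    def alpha(self, rho: np.ndarray) -> np.ndarray:
        """Per-site field alpha_n = a + b * rho_n."""
        return self.a + self.b * np.asarray(rho, dtype=float)

    def beta(self, d: np.ndarray) -> np.ndarray:
        """Per-pair coupling beta_n = c / min(d_n, cap)."""
        d = np.minimum(np.asarray(d, dtype=float), MAX_COUPLING_DISTANCE)
        return self.c / d

    def validate(self) -> None:
        if not np.all(np.isfinite([self.a, self.b, self.c])):
            raise ValueError("Ising parameters must be finite")


@dataclass
class LevelDistribution:
    """Probability mass over methylation levels k/K for a K-CpG subregion."""

    K: int
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.K + 1,):
            raise ValueError(f"level distribution over K={self.K} needs {self.K + 1} masses")
        if np.any(self.p < -1e-12) or abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("level distribution must be a probability vector")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.K + 1) / self.K if self.K > 0 else np.zeros(1)


@dataclass
class RegionReads:
    """Deduplicated read fragments of one estimation region, packed flat.

    Fragment r covers chain indices ``starts[r] .. starts[r]+lengths[r]-1``
    with clamp codes (+1 methylated, -1 unmethylated, 0 unobserved) stored in
    ``clamps[offsets[r]:offsets[r]+lengths[r]]``; ``counts[r]`` is how many
    identical fragments were observed.
    """

    n_sites: int
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    clamps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    offsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    lengths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_calls(self) -> int:
        """Total observed (M or U) calls across all fragments."""
        per_frag = np.add.reduceat(
            np.abs(self.clamps), self.offsets, dtype=np.int64
        ) if len(self.offsets) else np.empty(0, dtype=np.int64)
        return int((per_frag * self.counts).sum())

    def coverage(self) -> np.ndarray:
        """Number of reads with an observed call at each site."""
        cov = np.zeros(self.n_sites, dtype=np.int64)
        for r in range(len(self.starts)):
            cl = self.clamps[self.offsets[r] : self.offsets[r] + self.lengths[r]]
            cov[self.starts[r] : self.starts[r] + self.lengths[r]] += self.counts[r] * (cl != 0)
        return cov


def pack_fragments(fragments: list[tuple[int, str]], n_sites: int) -> RegionReads:
    """Pack (start, calls) fragments into a deduplicated :class:`RegionReads`.

    Fully unobserved fragments contribute no information and are dropped;
    fragments extending past the region raise.
    """
    tally: dict[tuple[int, str], int] = {}
    for start, calls in fragments:
        stripped = calls.lstrip(".")
        start += len(calls) - len(stripped)
        calls = stripped.rstrip(".")
        if not calls:
            continue
        if start < 0 or start + len(calls) > n_sites:
            raise ValueError(f"fragment at {start} (+{len(calls)}) exceeds region of {n_sites} sites")
        key = (start, calls)
        tally[key] = tally.get(key, 0) + 1
    if not tally:
        return RegionReads(n_sites=n_sites)
    items = sorted(tally.items())
    starts = np.array([k[0] for k, _ in items], dtype=np.int64)
    lengths = np.array([len(k[1]) for k, _ in items], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1])).astype(np.int64)
    counts = np.array([v for _, v in items], dtype=np.int64)
    clamps = np.fromiter(
        (_CALL_CODE[ch] for _, calls in ((k[0], k[1]) for k, _ in items) for ch in calls),
        dtype=np.int8,
        count=int(lengths.sum()),
    )
    return RegionReads(n_sites, starts, clamps, offsets, lengths, counts)


def potential(params: IsingParameters, pattern: np.ndarray, rho: np.ndarray, d: np.ndarray) -> float:
    """Potential V(x) of one methylation pattern; lower V = more probable."""
    pattern = np.asarray(pattern)
    rho = np.asarray(rho, dtype=float)
    if pattern.shape != rho.shape:
        raise ValueError("pattern length must match the region's site count")
    s = 2.0 * pattern - 1.0
    alpha = params.alpha(rho)
    beta = params.beta(d)
    return float(-(alpha * s).sum() - (beta * s[:-1] * s[1:]).sum())


def log_partition_function(params: IsingParameters, rho: np.ndarray, d: np.ndarray) -> float:
    """log Z by 2x2 transfer-matrix products in log space, O(N)."""
    rho = np.asarray(rho, dtype=float)
    if rho.size < 1:
        raise ValueError("region must contain at least one CpG site")
    return float(_dp.log_partition(params.alpha(rho), params.beta(d)))


def partition_function(params: IsingParameters, rho: np.ndarray, d: np.ndarray) -> float:
    return float(np.exp(log_partition_function(params, rho, d)))


def read_log_likelihood(
    params: IsingParameters, start: int, calls: str, rho: np.ndarray, d: np.ndarray
) -> float:
    """Log marginal probability of one read's observed calls.

    ``calls`` uses M/U/. over consecutive CpG units beginning at chain index
    ``start``; '.' sites (and all sites outside the read) are summed out by
    the forward-backward recursion.
    """
    clamp = np.array([_CALL_CODE[ch] for ch in calls], dtype=np.int8)
    if np.all(clamp == 0):
        raise ValueError("read has no observed calls")
    rho = np.asarray(rho, dtype=float)
    alpha = params.alpha(rho)
    beta = params.beta(d)
    f = _dp.forward_messages(alpha, beta)
    b = _dp.backward_messages(alpha, beta)
    log_z = _dp.log_partition(alpha, beta)
    return float(_dp.window_log_weight(alpha, beta, f, b, start, clamp) - log_z)


def reads_log_likelihood(
    params: IsingParameters, reads: RegionReads, rho: np.ndarray, d: np.ndarray
) -> float:
    """Total log-likelihood of a packed fragment set under ``params``."""
    if len(reads.starts) == 0:
        return 0.0
    return float(
        _dp.reads_log_likelihood(
            params.alpha(np.asarray(rho, dtype=float)),
            params.beta(d),
            reads.starts,
            reads.clamps,
            reads.offsets,
            reads.lengths,
            reads.counts,
        )
    )


def level_distribution(
    params: IsingParameters,
    rho: np.ndarray,
    d: np.ndarray,
    subset: np.ndarray | None = None,
) -> LevelDistribution:
    """Exact distribution of the methylation level over a site subset.

    ``subset`` gives the chain indices of the analysis subregion (defaults to
    all sites); the DP tracks the methylated count restricted to those sites.
    """
    rho = np.asarray(rho, dtype=float)
    n = rho.size
    mask = np.zeros(n, dtype=np.uint8)
    if subset is None:
        mask[:] = 1
    else:
        subset = np.asarray(subset, dtype=np.int64)
        if subset.size == 0:
            raise ValueError("subregion with K=0 CpGs has no level distribution")
        mask[subset] = 1
    p = _dp.level_distribution_dp(params.alpha(rho), params.beta(d), mask)
    return LevelDistribution(K=int(mask.sum()), p=p)


@dataclass
class FitResult:
    """Maximum-likelihood fit of one estimation region."""

    params: IsingParameters
    log_likelihood: float
    n_reads: int
    converged: bool
    start_index: int
    n_evaluations: int


def fit_parameters(
    reads: RegionReads,
    rho: np.ndarray,
    d: np.ndarray,
    starts: tuple[tuple[float, float, float], ...] = START_GRID,
    fatol: float = 1e-6,
    maxiter: int = 400,
    fix_b: float | None = None,
) -> FitResult:
    """Fit (a, b, c) by maximum likelihood over a region's read fragments.

    Derivative-free Nelder-Mead from a fixed start grid inside the box
    constraints; the best objective wins, ties broken by lowest start index,
    so the result is deterministic for a given fragment set.  ``fix_b`` pins
    the density coefficient (useful where rho is nearly constant across the
    region and b is unidentifiable).
    """
    if reads.n_reads == 0:
        raise ValueError("cannot fit a region with no informative reads")
    rho = np.asarray(rho, dtype=float)
    d_capped = np.minimum(np.asarray(d, dtype=float), MAX_COUPLING_DISTANCE)

    def neg_loglik(a: float, b: float, c: float) -> float:
        return -_dp.reads_log_likelihood(
            a + b * rho, c / d_capped,
            reads.starts, reads.clamps, reads.offsets, reads.lengths, reads.counts,
        )

    if fix_b is None:
        objective = lambda t: neg_loglik(t[0], t[1], t[2])
        bounds = PARAM_BOUNDS
        start_points = [np.asarray(x0, dtype=float) for x0 in starts]
    else:
        objective = lambda t: neg_loglik(t[0], fix_b, t[1])
        bounds = (PARAM_BOUNDS[0], PARAM_BOUNDS[2])
        seen: list = []
        start_points = []
        for x0 in starts:
            pt = (x0[0], x0[-1])
            if pt not in seen:
                seen.append(pt)
                start_points.append(np.asarray(pt, dtype=float))

    best = None
    total_evals = 0
    for idx, x0 in enumerate(start_points):
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"fatol": fatol, "xatol": 1e-4, "maxiter": maxiter},
        )
        total_evals += res.nfev
        if best is None or res.fun < best[0].fun:
            best = (res, idx)
    res, idx = best
    if not np.isfinite(res.fun):
        raise RuntimeError("optimizer failed on every start; region should be excluded")
    theta = res.x if fix_b is None else np.array([res.x[0], fix_b, res.x[1]])
    return FitResult(
        params=IsingParameters(*np.clip(theta, [b[0] for b in PARAM_BOUNDS], [b[1] for b in PARAM_BOUNDS])),
        log_likelihood=-float(res.fun),
        n_reads=reads.n_reads,
        converged=bool(res.success),
        start_index=idx,
        n_evaluations=total_evals,
    )
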