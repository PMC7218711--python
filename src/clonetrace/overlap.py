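"""Set-overlap null models for clonal sharing between sorted populations.

A barcode shared between two or three sorted populations is evidence that
one clone fed them all. The null is that each population's barcode set is
an independent uniform fixed-size subset of a finite pool: for two sets
the intersection size is hypergeometric; for m sets the tail is either
estimated by Monte-Carlo random draws or computed exactly by folding
hypergeometric intersection distributions (the running intersection of a
fixed set of size j with a fresh uniform n_i-subset is hypergeometric, so
the m-way intersection law follows by sequential conditioning).

All tests are one-sided enrichment tests: P(intersection >= k_obs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .patterns import DEFAULT_LIBRARY_SIZE


@dataclass(frozen=True)
class OverlapResult:
    """Observed k-way intersection with its null tail probability."""

    labels: tuple[str, ...]
    k: int
    pool_size: int
    set_sizes: tuple[int, ...]
    p_value: float
    method: str                 # hypergeometric | monte_carlo | exact_fold
    iterations: int | None = None
    mc_se: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.set_sizes):
            raise ValueError("k must lie in [0, min set size]")
        if any(n > self.pool_size for n in self.set_sizes):
            raise ValueError("set sizes cannot exceed the pool size")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")
        if self.mc_se is not None and self.mc_se < 0:
            raise ValueError("mc_se must be non-negative")

    def to_dict(self) -> dict:
        out = {
            "labels": list(self.labels),
            "k": self.k,
            "pool_size": self.pool_size,
            "set_sizes": list(self.set_sizes),
            "p_value": self.p_value,
            "method": self.method,
        }
        if self.iterations is not None:
            out["iterations"] = self.iterations
            out["mc_se"] = self.mc_se
            out["seed"] = self.seed
        return out


def _check_sizes(N: int, sizes: Sequence[int], k: int) -> None:
    if N <= 0:
        raise ValueError("pool size must be positive")
    if len(sizes) < 2:
        raise ValueError("at least two sets required")
    if any(n < 0 or n > N for n in sizes):
        raise ValueError("set sizes must lie in [0, pool size]")
    if not 0 <= k <= min(sizes):
        raise ValueError("k must lie in [0, min set size]")


def hypergeom_overlap_p(
    N: int = DEFAULT_LIBRARY_SIZE,
    nA: int = 0,
    nB: int = 0,
    k: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> OverlapResult:
    """Two-way overlap enrichment: P(|A ∩ B| >= k) for uniform subsets.

    With A fixed of size nA, a uniform nB-subset B of an N-pool has
    |A ∩ B| ~ Hypergeometric(N, nA, nB); the returned p is the upper tail
    at the observed intersection size. The default pool is the 725-barcode
    library.
    """
    _check_sizes(N, (nA, nB), k)
    # scipy evaluates the tail in log-space internally; stable for large N
    p = float(stats.hypergeom.sf(k - 1, N, nA, nB))
    return OverlapResult(
        labels=labels, k=k, pool_size=N, set_sizes=(nA, nB),
        p_value=min(p, 1.0), method="hypergeometric",
    )


def intersection_pmf(N: int, sizes: Sequence[int]) -> np.ndarray:
    """Exact pmf of the m-way intersection size of uniform fixed-size subsets.

    Folds the sets one at a time: if the running intersection has size j,
    intersecting with a fresh uniform n-subset gives a size that is
    Hypergeometric(N, j, n), independently of how j arose. Returns an
    array p[x] = P(|intersection| = x) for x = 0..min(sizes).
    """
    _check_sizes(N, sizes, 0)
    pmf = np.zeros(min(sizes) + 1)
    # start from the first set: the running intersection is the set itself
    run = np.zeros(sizes[0] + 1)
    run[sizes[0]] = 1.0
    for n in sizes[1:]:
        j = np.arange(len(run))
        x = np.arange(min(len(run) - 1, n) + 1)
        kernel = stats.hypergeom.pmf(x[:, None], N, j[None, :], n)
        run = kernel @ run
    pmf[: len(run)] = run[: len(pmf)]
    return pmf


def multiway_overlap_p_exact(
    N: int,
    sizes: Sequence[int],
    k_obs: int,
    labels: tuple[str, ...] | None = None,
) -> OverlapResult:
    """Exact m-way overlap tail P(intersection >= k_obs) by pmf folding."""
    _check_sizes(N, sizes, k_obs)
    if k_obs == 0:
        p = 1.0  # tail from zero; avoids float round-off in the pmf sum
    else:
        pmf = intersection_pmf(N, sizes)
        p = float(pmf[k_obs:].sum())
    return OverlapResult(
        labels=labels or tuple(f"S{i+1}" for i in range(len(sizes))),
        k=k_obs, pool_size=N, set_sizes=tuple(sizes),
        p_value=min(max(p, 0.0), 1.0), method="exact_fold",
    )


def sample_intersection_sizes(
    N: int, sizes: Sequence[int], M: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw M realisations of the m-way intersection size under the null.

    Uses the sequential-conditioning identity: drawing m independent
    uniform subsets and intersecting is distributionally identical to a
    chain of hypergeometric draws, which vectorises to O(m) array
    operations per batch and makes 10^7 iterations cheap.
    """
    cur = np.full(M, sizes[0], dtype=np.int64)
    for n in sizes[1:]:
        cur = rng.hypergeometric(ngood=cur, nbad=N - cur, nsample=n)
    return cur


def multiway_overlap_p_mc(
    N: int,
    sizes: Sequence[int],
    k_obs: int,
    M: int = 10_000_000,
    seed: int = 0,
    correction: bool = True,
    labels: tuple[str, ...] | None = None,
) -> OverlapResult:
    """Monte-Carlo m-way overlap tail (random-draw simulation).

    Each iteration realises independent uniform subsets of the given sizes
    from the N-pool and records whether their m-way intersection reaches
    ``k_obs``. With ``correction`` (default) the estimate is
    (hits+1)/(M+1), which never reports exactly 0; ``correction=False``
    gives the raw unbiased hits/M. ``mc_se`` is the binomial standard
    error sqrt(p(1-p)/M). The default M of 10,000,000 matches the original
    analysis; 10^5-10^6 is ample for p-values down to ~10^-4.
    """
    _check_sizes(N, sizes, k_obs)
    if M <= 0:
        raise ValueError("M must be positive")
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 2_000_000
    remaining = M
    while remaining > 0:
        b = min(chunk, remaining)
        hits += int((sample_intersection_sizes(N, sizes, b, rng) >= k_obs).sum())
        remaining -= b
    p = (hits + 1) / (M + 1) if correction else hits / M
    return OverlapResult(
        labels=labels or tuple(f"S{i+1}" for i in range(len(sizes))),
        k=k_obs, pool_size=N, set_sizes=tuple(sizes),
        p_value=float(p), method="monte_carlo",
        iterations=M, mc_se=float(np.sqrt(p * (1 - p) / M)), seed=seed,
    )


def venn_counts(sets: Mapping[str, frozenset | set]) -> dict[str, int]:
    """Disjoint membership-region counts for 2 or 3 sets.

    Region keys join member labels with '&' (e.g. "NMP&MB&EB"); the 2^m - 1
    regions are disjoint and sum to the size of the union.
    """
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError("venn_counts supports exactly 2 or 3 sets")
    universe = set().union(*sets.values())
    regions: dict[str, int] = {}
    m = len(labels)
    for mask in range(1, 2 ** m):
        members = [labels[i] for i in range(m) if mask >> i & 1]
        others = [labels[i] for i in range(m) if not mask >> i & 1]
        region = set(universe)
        for lab in members:
            region &= set(sets[lab])
        for lab in others:
            region -= set(sets[lab])
        regions["&".join(members)] = len(region)
    return regions
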