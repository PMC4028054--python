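"""Rarefaction (gene-discovery) curves and saturation assessment.

A sequencing library is summarized as a multiset: gene *i* is supported by
``N_i`` reads, ``N = sum N_i`` reads in total over ``S`` distinct genes.
The expected number of distinct genes seen in a uniform without-replacement
subsample of ``n`` reads is the classical (Hurlbert) rarefaction expectation

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ]

evaluated here through log-gamma so that libraries with millions of reads do
not overflow.  A Monte-Carlo path reproduces the resampling procedure used
historically (1,000 random subsamples averaged per depth); its mean is an
unbiased estimate of the analytic expectation and is validated against it.

Sequencing is judged saturated when the curve has flattened: the slope over
the last decile of the grid (genes discovered per additional read) falls
below a threshold θ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "RarefactionLibrary",
    "RarefactionCurve",
    "SaturationCall",
    "expected_richness_analytic",
    "rarefaction_curve_analytic",
    "rarefaction_curve_mc",
    "merge_libraries",
    "assess_saturation",
    "default_grid",
    "plot_curves",
]


@dataclass
class RarefactionLibrary:
    """Gene -> read-support multiset for one library."""

    support: dict[str, int]

    def __post_init__(self) -> None:
        if not self.support:
            raise ValueError("library has no genes")
        for g, n in self.support.items():
            if int(n) != n or n < 1:
                raise ValueError(f"read support must be a positive integer (gene {g!r}: {n!r})")
        self.support = {g: int(n) for g, n in self.support.items()}

    @property
    def N(self) -> int:
        """Total reads."""
        return sum(self.support.values())

    @property
    def S(self) -> int:
        """Distinct genes."""
        return len(self.support)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "RarefactionLibrary":
        """Build from a count table, dropping zero-support genes."""
        return cls({g: int(n) for g, n in counts.items() if n > 0})


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def expected_richness_analytic(lib: RarefactionLibrary, n: int) -> float:
    """Exact E[S_n] for a without-replacement subsample of ``n`` reads."""
    N = lib.N
    if n < 0 or n > N:
        raise ValueError(f"subsample size {n} outside [0, N={N}]")
    if n == 0:
        return 0.0
    # aggregate genes sharing the same support; the term depends on N_i only
    supports, multiplicity = np.unique(
        np.fromiter(lib.support.values(), dtype=np.int64), return_counts=True
    )
    log_cn = _log_comb(float(N), float(n))
    remain = N - supports  # reads left if gene i is wholly excluded
    miss = np.zeros(len(supports))
    feasible = remain >= n
    miss[feasible] = np.exp(_log_comb(remain[feasible].astype(float), float(n)) - log_cn)
    return float(np.sum(multiplicity * (1.0 - miss)))


def default_grid(N: int, points: int = 50) -> np.ndarray:
    """Evenly spaced integer subsample sizes from 0 to N (deduplicated)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return np.unique(np.linspace(0, N, points).round().astype(np.int64))


@dataclass
class RarefactionCurve:
    """Expected richness versus subsample depth on a grid."""

    grid: np.ndarray
    expected_richness: np.ndarray
    mc_sd: np.ndarray | None = None
    N: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int64)
        self.expected_richness = np.asarray(self.expected_richness, dtype=float)
        if self.grid.shape != self.expected_richness.shape:
            raise ValueError("grid and expected richness differ in length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.expected_richness) < -1e-9):
            raise ValueError("expected richness must be nondecreasing in depth")


def rarefaction_curve_analytic(
    lib: RarefactionLibrary, grid: Sequence[int] | None = None, label: str = ""
) -> RarefactionCurve:
    """Closed-form curve on ``grid`` (default: 50 even points from 0 to N)."""
    if grid is None:
        grid = default_grid(lib.N)
    grid = np.asarray(grid, dtype=np.int64)
    values = np.array([expected_richness_analytic(lib, int(n)) for n in grid])
    return RarefactionCurve(grid=grid, expected_richness=values, N=lib.N, label=label)


def rarefaction_curve_mc(
    lib: RarefactionLibrary,
    grid: Sequence[int] | None = None,
    reps: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
    label: str = "",
) -> RarefactionCurve:
    """Resampled curve: mean and SD of distinct-gene counts over ``reps``
    without-replacement subsamples at each grid depth (reads are the
    subsampling unit).  Deterministic for a given seed."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if grid is None:
        grid = default_grid(lib.N)
    grid = np.asarray(grid, dtype=np.int64)
    N = lib.N
    if np.any(grid < 0) or np.any(grid > N):
        raise ValueError("grid point outside [0, N]")
    rng = np.random.default_rng(seed)
    genes = np.repeat(
        np.arange(lib.S, dtype=np.int64),
        np.fromiter(lib.support.values(), dtype=np.int64),
    )
    sums = np.zeros(len(grid))
    sumsq = np.zeros(len(grid))
    for _ in range(reps):
        perm = rng.permutation(genes)
        # position of each gene's first occurrence in the shuffled read list;
        # richness at depth n = number of first occurrences before n
        _, first_idx = np.unique(perm, return_index=True)
        first_idx.sort()
        richness = np.searchsorted(first_idx, grid, side="left").astype(float)
        sums += richness
        sumsq += richness**2
    mean = sums / reps
    var = np.maximum(sumsq / reps - mean**2, 0.0)
    if reps > 1:
        var = var * reps / (reps - 1)
    return RarefactionCurve(
        grid=grid, expected_richness=mean, mc_sd=np.sqrt(var), N=N, label=label
    )


def merge_libraries(lib_a: RarefactionLibrary, lib_b: RarefactionLibrary) -> RarefactionLibrary:
    """Pool two libraries: supports add per gene, genes union."""
    merged = dict(lib_a.support)
    for g, n in lib_b.support.items():
        merged[g] = merged.get(g, 0) + n
    return RarefactionLibrary(merged)


@dataclass
class SaturationCall:
    """Tail-slope plateau decision for a rarefaction curve."""

    tail_slope: float
    threshold: float
    is_saturated: bool

    def __post_init__(self) -> None:
        if self.is_saturated != (self.tail_slope < self.threshold):
            raise ValueError("inconsistent saturation call")


def assess_saturation(curve: RarefactionCurve, theta: float = 1e-3) -> SaturationCall:
    """Saturated iff the slope over the last grid decile is below ``theta``
    (genes per read).  The slope is taken between the last grid point and the
    grid point nearest 90% of the final depth."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if len(curve.grid) < 2:
        raise ValueError("need at least two grid points to assess saturation")
    n_last = int(curve.grid[-1])
    if n_last <= 0:
        raise ValueError("degenerate grid: final depth is zero")
    target = 0.9 * n_last
    idx = int(np.argmin(np.abs(curve.grid[:-1] - target)))
    n_ref = int(curve.grid[idx])
    if n_ref == n_last:
        raise ValueError("degenerate grid for tail-slope estimation")
    slope = float(
        (curve.expected_richness[-1] - curve.expected_richness[idx]) / (n_last - n_ref)
    )
    return SaturationCall(tail_slope=slope, threshold=theta, is_saturated=slope < theta)


def plot_curves(curves: Iterable[RarefactionCurve], path) -> None:
    """Write a PNG of one or more rarefaction curves (depth vs expected genes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = list(curves)
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.grid, curve.expected_richness, label=curve.label or None)
        if curve.mc_sd is not None:
            lo = curve.expected_richness - curve.mc_sd
            hi = curve.expected_richness + curve.mc_sd
            ax.fill_between(curve.grid, lo, hi, alpha=0.2)
    ax.set_xlabel("reads sampled")
    ax.set_ylabel("expected distinct genes")
    if any(c.label for c in curves):
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
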