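"""Statistical evaluation of bleb-site predictions against observations.

Observed blebs matched to predicted sites yield a rank-frequency
distribution.  Its null counterpart -- the distribution expected if all
candidate sites on each contour were equally likely -- is computed exactly:
a bleb on a frame with n candidate sites contributes 1/n to every rank
1..n.  The two are compared with a Pearson chi-square test (class width 1,
expected counts below 5 pooled into the tail) plus per-class
standardized-residual flags at level 0.001 with Bonferroni correction.
Prediction quality is summarized by the area under the rank CDF as a
percentage of the theoretical maximum (100% when every observed bleb sits
at the rank-1 site).  Circular statistics (polar histograms, front-half
fractions, the rotation-invariant two-sample Kuiper test) and the
Mann-Whitney U test cover the orientation and shape comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RankDistribution",
    "ChiSquareResult",
    "AngularHistogram",
    "random_test_distribution",
    "chi_square_rank_test",
    "cdf_area",
    "angular_histogram",
    "kuiper_two_sample",
    "mann_whitney_u",
]


@dataclass
class RankDistribution:
    """Observed bleb counts per model rank (class width 1).

    ``counts[r-1]`` is the number of blebs matched to rank ``r``;
    ``per_frame_site_counts`` holds the number of candidate sites n_f of
    every contour that contributed, and unmatched blebs are tracked
    separately so the counts always sum to the matched total.
    """

    counts: np.ndarray
    per_frame_site_counts: list = field(default_factory=list)
    unmatched: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def max_rank(self) -> int:
        return len(self.counts)

    @classmethod
    def from_matches(
        cls,
        ranks: Sequence[Optional[int]],
        per_frame_site_counts: Sequence[int],
    ) -> "RankDistribution":
        """Build from matched ranks (``None`` = unmatched)."""
        matched = [r for r in ranks if r is not None]
        unmatched = len(ranks) - len(matched)
        max_rank = max(
            [max(matched, default=0), max(per_frame_site_counts, default=0)]
        )
        counts = np.zeros(max(max_rank, 1))
        for r in matched:
            counts[r - 1] += 1
        return cls(counts, list(per_frame_site_counts), unmatched)


def random_test_distribution(
    per_frame_site_counts: Sequence[int],
    blebs_per_frame: Sequence[int],
    mode: str = "exact",
    n_draws: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Expected rank counts if every candidate site were equally likely.

    Exact mode: each bleb on a frame with n_f sites contributes 1/n_f to
    every rank 1..n_f.  Monte-Carlo mode draws ``n_draws`` random
    assignments (seeded ``rng``) and rescales to the observed bleb total,
    for resampling-based checks.
    """
    if len(per_frame_site_counts) != len(blebs_per_frame):
        raise ValueError("per-frame site counts and bleb counts differ in length")
    nfs = np.asarray(per_frame_site_counts, dtype=int)
    if (nfs < 1).any():
        raise ValueError("every frame must have at least one candidate site")
    blebs = np.asarray(blebs_per_frame, dtype=int)
    max_rank = int(nfs.max())
    expected = np.zeros(max_rank)
    if mode == "exact":
        for n_f, n_b in zip(nfs, blebs):
            expected[:n_f] += n_b / n_f
        return expected
    if mode != "montecarlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = rng or np.random.default_rng()
    total = int(blebs.sum())
    counts = np.zeros(max_rank)
    for _ in range(n_draws):
        for n_f, n_b in zip(nfs, blebs):
            if n_b:
                drawn = rng.integers(0, n_f, size=n_b)
                np.add.at(counts, drawn, 1.0)
    return counts * (total / counts.sum()) if counts.sum() else counts


@dataclass
class ChiSquareResult:
    chi2: float
    p_value: float
    class_flags: np.ndarray  # True where a pooled class deviates at 0.001/Bonferroni
    pooled_observed: np.ndarray
    pooled_expected: np.ndarray
    n_pooled_classes: int


def _pool_tail(observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0):
    obs = list(np.asarray(observed, dtype=float))
    exp = list(np.asarray(expected, dtype=float))
    pooled = False
    while len(exp) > 1 and exp[-1] < min_expected:
        last_e, last_o = exp.pop(), obs.pop()
        exp[-1] += last_e
        obs[-1] += last_o
        pooled = True
    if pooled:
        logger.info("chi-square: tail classes pooled to reach expected >= %g", min_expected)
    return np.array(obs), np.array(exp)


def chi_square_rank_test(
    observed: "RankDistribution | np.ndarray",
    expected: np.ndarray,
    class_alpha: float = 0.001,
) -> ChiSquareResult:
    """Pearson chi-square of observed vs expected rank counts.

    Class width is 1; tail classes with expected counts below 5 are pooled
    (logged).  Per-class flags use standardized residuals (O-E)/sqrt(E),
    two-sided at ``class_alpha`` with Bonferroni correction over the number
    of pooled classes.
    """
    obs = observed.counts if isinstance(observed, RankDistribution) else np.asarray(
        observed, dtype=float
    )
    exp = np.asarray(expected, dtype=float)
    if len(obs) != len(exp):
        n = max(len(obs), len(exp))
        obs = np.pad(obs, (0, n - len(obs)))
        exp = np.pad(exp, (0, n - len(exp)))
    if obs.sum() <= 0:
        raise ValueError("empty observed distribution")
    obs_p, exp_p = _pool_tail(obs, exp)
    exp_scaled = exp_p * (obs_p.sum() / exp_p.sum())
    chi2, p = stats.chisquare(obs_p, f_exp=exp_scaled)
    m = len(obs_p)
    z = (obs_p - exp_scaled) / np.sqrt(exp_scaled)
    z_crit = stats.norm.isf(class_alpha / (2.0 * m))
    flags = np.abs(z) > z_crit
    return ChiSquareResult(
        chi2=float(chi2),
        p_value=float(p),
        class_flags=flags,
        pooled_observed=obs_p,
        pooled_expected=exp_scaled,
        n_pooled_classes=m,
    )


def cdf_area(
    observed: "RankDistribution | Sequence[int]", max_rank: Optional[int] = None
) -> float:
    """Area under the rank CDF as a percentage of the theoretical maximum.

    CDF(r) is the fraction of matched blebs with rank <= r for r = 1..R
    (R = ``max_rank`` or the highest rank class); the area is the mean of
    the CDF over r, and 100% corresponds to CDF == 1 everywhere (every bleb
    at the rank-1 site).  All blebs spread uniformly over ranks 1..R give
    100 (R+1)/(2R) percent.
    """
    if isinstance(observed, RankDistribution):
        counts = observed.counts
    else:
        ranks = np.asarray(list(observed), dtype=int)
        if ranks.size == 0:
            raise ValueError("empty rank distribution")
        counts = np.bincount(ranks, minlength=ranks.max() + 1)[1:].astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty rank distribution")
    R = int(max_rank) if max_rank is not None else len(counts)
    full = np.zeros(R)
    full[: min(R, len(counts))] = counts[:R]
    cdf = np.cumsum(full) / total
    return 100.0 * float(cdf.mean())


@dataclass
class AngularHistogram:
    counts: np.ndarray
    bin_edges: np.ndarray  # degrees
    front_fraction: float  # fraction of angles in [0, 90) + (270, 360)


def angular_histogram(
    angles_deg: Sequence[float], bin_width: float = 15.0
) -> AngularHistogram:
    """Polar histogram of angular positions plus the front-half fraction."""
    if not (0 < bin_width <= 360) or 360.0 % bin_width != 0:
        raise ValueError("bin_width must divide 360")
    a = np.mod(np.asarray(list(angles_deg), dtype=float), 360.0)
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    if a.size == 0:
        front = float("nan")
    else:
        front = float(np.mean((a < 90.0) | (a > 270.0)))
    return AngularHistogram(counts, edges, front)


def _kuiper_sf(lam: float) -> float:
    """Asymptotic survival function of the Kuiper statistic."""
    if lam < 0.4:
        return 1.0
    j = np.arange(1, 101, dtype=float)
    terms = (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
    return float(np.clip(2.0 * terms.sum(), 0.0, 1.0))


def kuiper_two_sample(
    angles_a: Sequence[float], angles_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kuiper test on circular data (degrees).

    V = max(Fa - Fb) + max(Fb - Fa) over the circle, which is invariant to
    a common rotation of both samples; the p-value uses the standard
    asymptotic series with the two-sample effective size
    n_e = n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.mod(np.asarray(list(angles_a), dtype=float), 360.0)) / 360.0
    b = np.sort(np.mod(np.asarray(list(angles_b), dtype=float), 360.0)) / 360.0
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    d_right = (
        np.searchsorted(a, grid, side="right") / a.size
        - np.searchsorted(b, grid, side="right") / b.size
    )
    d_left = (
        np.searchsorted(a, grid, side="left") / a.size
        - np.searchsorted(b, grid, side="left") / b.size
    )
    d_all = np.concatenate([d_right, d_left, [0.0]])
    v = float(d_all.max() - d_all.min())
    ne = a.size * b.size / (a.size + b.size)
    lam = (math.sqrt(ne) + 0.155 + 0.24 / math.sqrt(ne)) * v
    return v, _kuiper_sf(lam)


def mann_whitney_u(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for min(n) <= 8 without
    ties, normal approximation with tie correction otherwise."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
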