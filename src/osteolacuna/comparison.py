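"""Statistical comparison of an attachment cube against a reference cube.

Four quantities discriminate attachment types in this analysis:

* the lacuna number-density ratio between the two cubes,
* a two-sided Mann-Whitney (Wilcoxon rank-sum) test on the lacuna
  volume samples,
* a Pearson chi-square homogeneity test on the counts of lacunae whose
  maximum length coincides with each referential axis (X, Y, Z),
* the fraction of stellate lacunae in the attachment cube.

The rank-sum test uses the exact null distribution (dynamic-programming
enumeration) for small tie-free samples and a normal approximation with
midranks, tie correction and continuity correction otherwise.  Verdicts
are emitted in the vocabulary "similar" / "different" so reports can be
read against published comparison tables directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .morphometry import AXES, RegionProfile

DEFAULT_ALPHA = 0.05  # two-sided, 95 % confidence limits
DEFAULT_STELLATE_CUT = 0.5  # attachment called stellate if >= half its lacunae are

EXACT_MAX_N = 10  # exact rank-sum null up to this per-group size (no ties)


class ComparisonError(Exception):
    pass


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # rank_sum_exact | rank_sum_normal_approx | chi2_homogeneity
    df: int | None = None
    n1: int | None = None
    n2: int | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class ComparisonResult:
    density_ratio: float
    orientation: str  # "similar" | "different"
    orientation_test: TestResult
    volume: str  # "similar" | "different"
    volume_test: TestResult
    stellate: str  # "yes" | "no"
    stellate_fraction: float
    alpha: float
    qq_data: tuple[np.ndarray, np.ndarray] | None = None


@lru_cache(maxsize=None)
def _count_u_le(u: int, m: int, n: int) -> int:
    """Number of ways to interleave m and n tie-free observations with
    Mann-Whitney statistic of the first group <= u (cumulative count of
    the exact null distribution, standard recurrence)."""
    if u < 0:
        return 0
    if m == 0 or n == 0:
        return 1
    u = min(u, m * n)
    # condition on whether the largest pooled observation is in group 1
    return _count_u_le(u - n, m - 1, n) + _count_u_le(u, m, n - 1)


def exact_rank_sum_p(u: float, n1: int, n2: int) -> float:
    """Two-sided exact p-value for Mann-Whitney U with tie-free data:
    2·P(U <= min(U1, U2)) under the null, capped at 1."""
    u_min = min(u, n1 * n2 - u)
    p = 2.0 * _count_u_le(int(np.floor(u_min)), n1, n2) / _comb(n1 + n2, n1)
    return min(p, 1.0)


def _comb(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def mann_whitney_volumes(a, b, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Two-sided Mann-Whitney test on two volume samples.

    Uses the exact null distribution when both samples have at most
    ``EXACT_MAX_N`` observations and there are no ties; otherwise the
    normal approximation with midrank ties, tie correction of the
    variance and a 0.5 continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ComparisonError("empty sample")
    if not 0 < alpha < 1:
        raise ComparisonError("alpha must be in (0, 1)")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    notes: list[str] = []
    if not has_ties and n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        p = exact_rank_sum_p(u1, n1, n2)
        return TestResult(u1, p, "rank_sum_exact", n1=n1, n2=n2, notes=notes)
    mu = n1 * n2 / 2.0
    N = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float((t**3 - t).sum())
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        # all observations identical: no evidence of a difference
        notes.append("degenerate: all pooled values tied")
        return TestResult(u1, 1.0, "rank_sum_normal_approx", n1=n1, n2=n2, notes=notes)
    if has_ties:
        notes.append("tie correction applied")
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * sps.norm.sf(z)
    return TestResult(u1, min(p, 1.0), "rank_sum_normal_approx", n1=n1, n2=n2, notes=notes)


def chi2_orientation(counts_a, counts_b, alpha: float = DEFAULT_ALPHA) -> TestResult:
    """Pearson chi-square homogeneity test on two axis-count histograms.

    *counts_a*, *counts_b* map axis labels (subset of X, Y, Z) to counts.
    Axis categories with a zero column total in both samples are dropped;
    df = (remaining categories) − 1.  A note flags expected counts < 5.
    """
    ca = np.array([float(counts_a.get(ax, 0)) for ax in AXES])
    cb = np.array([float(counts_b.get(ax, 0)) for ax in AXES])
    if ca.sum() == 0 or cb.sum() == 0:
        raise ComparisonError("all-zero orientation table")
    keep = (ca + cb) > 0
    ca, cb = ca[keep], cb[keep]
    k = int(keep.sum())
    obs = np.stack([ca, cb])
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = k - 1
    notes = []
    if (expected < 5).any():
        notes.append("expected count < 5 in at least one cell")
    if df == 0:
        # one shared category: the two samples are trivially homogeneous
        return TestResult(0.0, 1.0, "chi2_homogeneity", df=0,
                          n1=int(ca.sum()), n2=int(cb.sum()),
                          notes=notes + ["single category, df=0"])
    p = float(sps.chi2.sf(chi2, df))
    return TestResult(chi2, p, "chi2_homogeneity", df=df,
                      n1=int(ca.sum()), n2=int(cb.sum()), notes=notes)


def qq_normal_diagnostic(sample) -> tuple[np.ndarray, np.ndarray]:
    """Paired quantiles for a normal qq diagnostic of a volume sample.

    Returns (ordered sample values, fitted normal quantiles) using
    plotting positions (i − 0.5)/n and the sample mean/sd.  A lacuna
    volume distribution is right-skewed, so the upper tail of the ordered
    values rises above the fitted line — the basis for preferring
    rank-based tests over t-tests here.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 3:
        raise ComparisonError("qq diagnostic needs n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ComparisonError("zero variance sample")
    probs = (np.arange(1, n + 1) - 0.5) / n
    theoretical = x.mean() + sd * sps.norm.ppf(probs)
    return x, theoretical


def compare_regions(
    attachment: RegionProfile,
    reference: RegionProfile,
    alpha: float = DEFAULT_ALPHA,
    stellate_cut: float = DEFAULT_STELLATE_CUT,
    with_qq: bool = False,
) -> ComparisonResult:
    """Compare an attachment cube profile against a reference profile.

    Density ratio is attachment density over reference density; the
    orientation and volume verdicts are "different" when the respective
    test rejects at *alpha*, else "similar"; the stellate verdict is
    "yes" when the attachment's stellate fraction reaches *stellate_cut*.
    """
    if attachment.cube_extents != reference.cube_extents:
        raise ComparisonError(
            f"mismatched cube sizes: {attachment.cube_extents} vs {reference.cube_extents}"
        )
    if reference.n_retained == 0:
        raise ComparisonError("reference cube empty")
    if attachment.n_retained == 0:
        raise ComparisonError("attachment cube empty")
    vol_test = mann_whitney_volumes(attachment.volume_sample_um3, reference.volume_sample_um3, alpha)
    ori_test = chi2_orientation(attachment.axis_counts, reference.axis_counts, alpha)
    qq = qq_normal_diagnostic(attachment.volume_sample_um3) if with_qq else None
    return ComparisonResult(
        density_ratio=attachment.density_per_mm3 / reference.density_per_mm3,
        orientation="different" if ori_test.p_value < alpha else "similar",
        orientation_test=ori_test,
        volume="different" if vol_test.p_value < alpha else "similar",
        volume_test=vol_test,
        stellate="yes" if attachment.stellate_fraction >= stellate_cut else "no",
        stellate_fraction=attachment.stellate_fraction,
        alpha=alpha,
        qq_data=qq,
    )
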