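"""Inferential procedures used by the morphometry and qPCR pipelines.

Paired and unpaired (Welch by default) t tests, one-way ANOVA, and Dunnett's
many-to-one post-hoc comparison. Dunnett adjusted p-values are computed by
seeded Monte Carlo over the joint null distribution of the k-1 correlated
t statistics (group means sharing the reference group and a pooled variance
estimate), so their accuracy is bounded by the draw count rather than by a
quadrature rule. All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    comparison_label: str = ""


@dataclass
class AnovaDunnettResult:
    """One-way ANOVA plus Dunnett comparisons of each group vs the reference."""

    anova: TestResult
    comparisons: list[TestResult]


@dataclass
class PairedSample:
    """Two equal-length measurement vectors matched by ``pairing_keys``."""

    x1: np.ndarray
    x2: np.ndarray
    pairing_keys: list | None = None

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape or self.x1.ndim != 1:
            raise ValueError("x1 and x2 must be equal-length 1-D vectors")
        if self.x1.size < 2:
            raise ValueError("need at least 2 pairs")
        if self.pairing_keys is not None and len(set(self.pairing_keys)) != self.x1.size:
            raise ValueError("pairing keys must be unique")


def paired_t(s: PairedSample, label: str = "") -> TestResult:
    """Paired t test: t = mean(d) / (sd(d)/sqrt(n)), d = x1 - x2, df = n-1.

    Identical pairs (all differences zero) return t = 0, p = 1; a
    zero-variance difference vector with nonzero mean has no defined t and
    raises.
    """
    d = s.x1 - s.x2
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == d[0]) and d[0] == 0.0:
            return TestResult(0.0, n - 1, 1.0, label)
        raise ValueError("differences have zero variance but nonzero mean")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), float(n - 1), float(p), label)


def unpaired_t(
    x: np.ndarray, y: np.ndarray, equal_var: bool = False, label: str = ""
) -> TestResult:
    """Two-sample t test, Welch (unequal variances) by default.

    With ``equal_var=True`` the classical pooled-variance statistic with
    df = n1 + n2 - 2 is used; otherwise the Welch statistic with
    Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if x.mean() == y.mean():
            raise ValueError("both groups constant with equal means: t undefined")
        raise ValueError("both groups have zero variance")
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2.0
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (x.mean() - y.mean()) / se
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return TestResult(float(t), float(df), float(p), label)


@lru_cache(maxsize=64)
def dunnett_null_max_t(
    sizes: tuple[int, ...], reference_index: int, n_draws: int, seed: int
) -> np.ndarray:
    """Sorted Monte Carlo sample of max_i |T_i| under the Dunnett joint null.

    T_i compares group i's mean to the reference group's mean, standardized
    by a pooled variance estimate with df = N - k. The statistics are
    correlated through the shared reference mean and the shared variance
    estimate; this sample captures that correlation exactly (up to Monte
    Carlo error) for arbitrary, possibly unbalanced, group sizes.
    """
    rng = np.random.default_rng(seed)
    sizes_arr = np.asarray(sizes, dtype=float)
    k = sizes_arr.size
    df = int(sizes_arr.sum()) - k
    means = rng.standard_normal((n_draws, k)) / np.sqrt(sizes_arr)
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    others = [i for i in range(k) if i != reference_index]
    se = np.sqrt(1.0 / sizes_arr[others] + 1.0 / sizes_arr[reference_index])
    t = (means[:, others] - means[:, [reference_index]]) / (s[:, None] * se)
    out = np.abs(t).max(axis=1)
    out.sort()
    return out


def anova_dunnett(
    groups: list[np.ndarray],
    reference_index: int = 0,
    alpha: float = 0.05,
    n_draws: int = 100_000,
    seed: int = 0,
    null_max_t: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> AnovaDunnettResult:
    """One-way ANOVA followed by Dunnett's comparisons against a reference.

    Each non-reference group is compared to ``groups[reference_index]``
    using the pooled-variance t statistic; the family-wise adjusted p-value
    of comparison j is the Monte Carlo estimate of
    P(max_i |T_i| >= |t_j|) under the joint null. Pass a precomputed
    ``null_max_t`` (from :func:`dunnett_null_max_t`) to reuse the null
    sample across many calls with the same design.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if not 0 <= reference_index < k:
        raise ValueError("reference index out of range")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    sizes = tuple(g.size for g in groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]

    f_stat, f_p = sps.f_oneway(*groups)
    n_total = sum(sizes)
    anova = TestResult(float(f_stat), float(k - 1), float(f_p), "one-way ANOVA")
    anova.df = float(k - 1)  # numerator df; denominator is n_total - k

    dof = n_total - k
    mse = sum((g.size - 1) * g.var(ddof=1) for g in groups) / dof
    if null_max_t is None:
        null_max_t = dunnett_null_max_t(sizes, reference_index, n_draws, seed)
    r = null_max_t.size

    comparisons: list[TestResult] = []
    ref = groups[reference_index]
    for i, g in enumerate(groups):
        if i == reference_index:
            continue
        se = np.sqrt(mse * (1.0 / g.size + 1.0 / ref.size))
        t = (g.mean() - ref.mean()) / se
        n_ge = r - np.searchsorted(null_max_t, abs(t), side="left")
        p_adj = n_ge / r
        comparisons.append(
            TestResult(
                float(t), float(dof), float(p_adj),
                f"{labels[i]} vs {labels[reference_index]}",
            )
        )
    return AnovaDunnettResult(anova=anova, comparisons=comparisons)
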