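"""Estimation statistics: bootstrap median differences, permutation tests, chi-square.

The behavioral comparisons are reported in the estimation-statistics style:
for each test group against a shared control, the unpaired median difference
(test minus control) with a 5000-resample percentile bootstrap 95% CI and a
two-sided permutation p-value on the median difference, plus the per-group
median +/- SD and the full resampled-difference distribution needed to draw
Gardner-Altman / Cumming plots.  Phenotype score tables are compared with the
plain Pearson chi-square test of independence.

The permutation p-value uses the identity-inclusive (add-one) estimator in
Monte-Carlo mode, so it can never be exactly zero; instances small enough to
enumerate are computed exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from startletrack.errors import DegenerateTableError, ParameterError


@dataclass
class GroupSample:
    """A labelled sample of real-valued measurements."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ParameterError(f"group {self.label!r} is empty")
        if not np.isfinite(self.values).all():
            raise ParameterError(f"group {self.label!r} contains non-finite values")


@dataclass
class EffectSizeResult:
    """Unpaired median difference (test - control) with bootstrap CI and permutation p."""

    median_difference: float
    ci_low: float
    ci_high: float
    p_value: float | None
    n_resamples: int
    seed: int | None
    alpha: float = 0.05
    bootstrap_distribution: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self, include_distribution: bool = False) -> dict:
        d = {
            "median_difference": self.median_difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_resamples": self.n_resamples,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        if include_distribution and self.bootstrap_distribution is not None:
            d["bootstrap_distribution"] = [float(x) for x in self.bootstrap_distribution]
        return d


def median_difference(a: GroupSample, b: GroupSample) -> float:
    """median(b) - median(a): the test group minus the shared control."""
    return float(np.median(b.values) - np.median(a.values))


def bootstrap_median_difference(
    a: GroupSample,
    b: GroupSample,
    n_resamples: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "percentile",
) -> EffectSizeResult:
    """Percentile bootstrap CI for the unpaired median difference.

    Each group is resampled with replacement at its own size ``n_resamples``
    times; the CI is the [alpha/2, 1-alpha/2] percentile interval of the
    resampled differences.  ``method='bca'`` switches to SciPy's
    bias-corrected-and-accelerated interval.
    """
    if n_resamples < 1000:
        raise ParameterError("n_resamples must be >= 1000 for CI reporting")
    rng = np.random.default_rng(seed)
    effect = median_difference(a, b)
    if method == "bca":
        res = stats.bootstrap(
            (a.values, b.values),
            lambda x, y, axis=-1: np.median(y, axis=axis) - np.median(x, axis=axis),
            n_resamples=n_resamples,
            confidence_level=1 - alpha,
            method="BCa",
            random_state=rng,
            vectorized=True,
        )
        diffs = res.bootstrap_distribution
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    elif method == "percentile":
        na, nb = a.values.size, b.values.size
        med_a = np.median(a.values[rng.integers(0, na, size=(n_resamples, na))], axis=1)
        med_b = np.median(b.values[rng.integers(0, nb, size=(n_resamples, nb))], axis=1)
        diffs = med_b - med_a
        lo, hi = (float(q) for q in np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)]))
    else:
        raise ParameterError(f"unknown bootstrap method {method!r}")
    return EffectSizeResult(
        median_difference=effect,
        ci_low=lo,
        ci_high=hi,
        p_value=None,
        n_resamples=n_resamples,
        seed=seed,
        alpha=alpha,
        bootstrap_distribution=np.asarray(diffs, dtype=float),
    )


def permutation_test_median(
    a: GroupSample,
    b: GroupSample,
    n_perms: int = 5000,
    seed: int | None = None,
    exhaustive_limit: int = 20000,
) -> float:
    """Two-sided permutation p-value for the absolute median difference.

    Group labels are permuted over the pooled values preserving group sizes.
    When the number of distinct assignments C(n, n_a) is at most
    ``exhaustive_limit`` the p-value is exact (fraction of assignments whose
    |median difference| is at least the observed one); otherwise a Monte-Carlo
    estimate with the add-one rule, p = (1 + #{perm >= obs}) / (1 + n_perms).
    """
    pooled = np.concatenate([a.values, b.values])
    n, na = pooled.size, a.values.size
    if n < 2:
        raise ParameterError("combined sample size must be >= 2")
    observed = abs(median_difference(a, b))
    tol = 1e-12 * max(1.0, abs(observed))
    n_assignments = comb(n, na)
    if n_assignments <= exhaustive_limit:
        count = 0
        for idx_a in combinations(range(n), na):
            sel = np.fromiter(idx_a, dtype=int)
            mask = np.zeros(n, dtype=bool)
            mask[sel] = True
            stat = abs(np.median(pooled[~mask]) - np.median(pooled[mask]))
            if stat >= observed - tol:
                count += 1
        return count / n_assignments
    if n_perms < 100:
        raise ParameterError("n_perms must be >= 100 in Monte-Carlo mode")
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: each row is one permutation of the pooled values
    order = np.argsort(rng.random((n_perms, n)), axis=1)
    shuffled = pooled[order]
    stat = np.abs(np.median(shuffled[:, na:], axis=1) - np.median(shuffled[:, :na], axis=1))
    exceed = int(np.count_nonzero(stat >= observed - tol))
    return (1 + exceed) / (1 + n_perms)


def two_group_effect(
    a: GroupSample,
    b: GroupSample,
    n_resamples: int = 5000,
    n_perms: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> EffectSizeResult:
    """Bootstrap CI plus permutation p-value in one result object."""
    res = bootstrap_median_difference(a, b, n_resamples=n_resamples, alpha=alpha, seed=seed)
    res.p_value = permutation_test_median(a, b, n_perms=n_perms, seed=seed)
    return res


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


def chi_square_max_statistic(table: np.ndarray) -> float:
    """Algebraic upper bound of the Pearson statistic: n * (min(r, c) - 1)."""
    table = np.asarray(table)
    return float(table.sum() * (min(table.shape) - 1))


def chi_square_independence(
    table, reference_statistic: float | None = None
) -> tuple[float, int, float]:
    """Plain Pearson chi-square test of independence (no continuity correction).

    Returns (statistic, df, p).  When a ``reference_statistic`` (e.g. a value
    quoted elsewhere for the same table) exceeds the algebraic maximum
    n*(min(r,c)-1), a ValueError flags the inconsistency instead of silently
    comparing against an impossible number.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ParameterError("contingency table must be at least 2x2")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ParameterError("contingency table must hold non-negative finite counts")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise DegenerateTableError("every row and column total must be > 0")
    if reference_statistic is not None and reference_statistic > chi_square_max_statistic(arr):
        raise ValueError(
            f"reference statistic {reference_statistic} exceeds the algebraic maximum "
            f"{chi_square_max_statistic(arr)} for this table — it cannot derive from these counts"
        )
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# plot data
# ---------------------------------------------------------------------------


def cumming_plot_data(
    groups: list[GroupSample],
    control_label: str,
    n_resamples: int = 5000,
    n_perms: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    include_distributions: bool = True,
) -> dict:
    """JSON-serializable bundle behind a Cumming estimation plot.

    Per group: raw values, median and SD.  Per test group versus the shared
    control: the effect size result and the full resampled-difference
    distribution for plotting the bootstrap sampling distribution.
    """
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ParameterError(f"control label {control_label!r} not among groups {labels}")
    control = groups[labels.index(control_label)]
    bundle: dict = {"control": control_label, "alpha": alpha, "seed": seed, "groups": {}, "comparisons": {}}
    for g in groups:
        bundle["groups"][g.label] = {
            "values": [float(v) for v in g.values],
            "n": int(g.values.size),
            "median": float(np.median(g.values)),
            "sd": float(np.std(g.values, ddof=1)) if g.values.size > 1 else 0.0,
        }
    for g in groups:
        if g.label == control_label:
            continue
        res = two_group_effect(
            control, g, n_resamples=n_resamples, n_perms=n_perms, alpha=alpha, seed=seed
        )
        bundle["comparisons"][g.label] = res.to_dict(include_distribution=include_distributions)
    return bundle
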