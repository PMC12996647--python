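"""Permutation inference for within-subject comparisons.

Every comparison of interest here is paired (the same subjects measured
under two algorithms, two preprocessing variants, or two run groupings),
so the null is built by independent random sign flips of the paired
differences.  P-values use the add-one estimator
p = (1 + #{|T_perm| >= |T_obs|}) / (n_iter + 1), which never returns 0
and counts the observed statistic in its own null.

The default test statistic is the median difference; the mean is
available.  Tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_N_ITER = 10_000


class PermutationError(ValueError):
    pass


@dataclass
class PermutationResult:
    statistic_name: str
    observed: float
    p_value: float
    n_iter: int
    seed: int
    alpha_corrected: float | None = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        alpha = self.alpha_corrected if self.alpha_corrected is not None else 0.05
        return self.p_value < alpha


_STATS = {"median_diff": np.median, "mean_diff": np.mean}


def _stat_fn(name: str):
    if name not in _STATS:
        raise PermutationError(f"unknown statistic {name!r}; choose from {sorted(_STATS)}")
    return _STATS[name]


def sign_flip_test(
    diffs: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    statistic: str = "median_diff",
    seed: int = 0,
    alpha_corrected: float | None = None,
    statistic_name: str | None = None,
) -> PermutationResult:
    """Two-sided sign-flip permutation test on a vector of paired
    differences."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim != 1 or len(diffs) < 2:
        raise PermutationError("need a 1D vector of >= 2 paired differences")
    if np.any(~np.isfinite(diffs)):
        raise PermutationError("differences contain NaN/inf")
    fn = _stat_fn(statistic)
    observed = float(fn(diffs))
    degenerate = bool(np.all(diffs == 0))
    if degenerate:
        return PermutationResult(
            statistic_name=statistic_name or statistic,
            observed=0.0, p_value=1.0, n_iter=n_iter, seed=seed,
            alpha_corrected=alpha_corrected, degenerate=True,
        )
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, len(diffs)))
    null = fn(signs * diffs, axis=1)
    exceed = int(np.sum(np.abs(null) >= abs(observed)))
    p = (1 + exceed) / (n_iter + 1)
    return PermutationResult(
        statistic_name=statistic_name or statistic,
        observed=observed, p_value=float(p), n_iter=n_iter, seed=seed,
        alpha_corrected=alpha_corrected,
    )


def paired_permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    statistic: str = "median_diff",
    seed: int = 0,
    alpha_corrected: float | None = None,
) -> PermutationResult:
    """Paired two-sample test: sign-flip permutation on x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PermutationError(f"paired samples differ in shape: {x.shape} vs {y.shape}")
    return sign_flip_test(x - y, n_iter=n_iter, statistic=statistic, seed=seed,
                          alpha_corrected=alpha_corrected)


def exhaustive_sign_flip_p(diffs: np.ndarray, statistic: str = "median_diff") -> float:
    """Exact two-sided p over all 2^n sign patterns (small n only).

    Uses the same add-one-free exact convention: the identity pattern is
    part of the enumeration, so p >= 1/2^n.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n > 20:
        raise PermutationError("exhaustive enumeration limited to n <= 20")
    fn = _stat_fn(statistic)
    observed = abs(float(fn(diffs)))
    count = 0
    for bits in range(2**n):
        signs = np.array([1.0 if bits & (1 << k) else -1.0 for k in range(n)])
        if abs(float(fn(signs * diffs))) >= observed - 1e-12:
            count += 1
    return count / 2**n


@dataclass
class TwoFactorResult:
    main_effect_a: PermutationResult
    main_effect_b: PermutationResult
    interaction: PermutationResult


def two_factor_permutation(
    table: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    statistic: str = "median_diff",
    seed: int = 0,
    alpha_corrected: float | None = None,
    factor_names: tuple[str, str] = ("A", "B"),
) -> TwoFactorResult:
    """Within-subject 2x2 factorial permutation tests.

    ``table`` is (n_subjects, 2, 2): axis 1 = factor A levels, axis 2 =
    factor B levels.  Main effect of A: sign-flip test on the per-subject
    difference of factor-B-averaged values; symmetrically for B.
    Interaction: sign-flip test on the per-subject double difference
    (A1B1 - A1B2) - (A2B1 - A2B2).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3 or table.shape[1:] != (2, 2):
        raise PermutationError(f"expected (n, 2, 2) table, got {table.shape}")
    if np.any(~np.isfinite(table)):
        raise PermutationError("incomplete 2x2 table (NaN present)")
    a_diff = table.mean(axis=2)[:, 0] - table.mean(axis=2)[:, 1]
    b_diff = table.mean(axis=1)[:, 0] - table.mean(axis=1)[:, 1]
    inter = (table[:, 0, 0] - table[:, 0, 1]) - (table[:, 1, 0] - table[:, 1, 1])
    kw = dict(n_iter=n_iter, statistic=statistic, alpha_corrected=alpha_corrected)
    return TwoFactorResult(
        main_effect_a=sign_flip_test(a_diff, seed=seed,
                                     statistic_name=f"main_{factor_names[0]}", **kw),
        main_effect_b=sign_flip_test(b_diff, seed=seed + 1,
                                     statistic_name=f"main_{factor_names[1]}", **kw),
        interaction=sign_flip_test(inter, seed=seed + 2,
                                   statistic_name="interaction", **kw),
    )


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold alpha / m."""
    if m < 1:
        raise PermutationError(f"m must be >= 1, got {m}")
    if not 0 < alpha <= 1:
        raise PermutationError(f"alpha must be in (0, 1], got {alpha}")
    return alpha / m
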