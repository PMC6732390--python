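"""Permutation tests and resampled confidence intervals.

All p-values use the add-one convention p = (#{null >= observed} + 1) /
(n_perm + 1), which is exchangeability-exact and never returns zero; the
attainable floor is 1/(n_perm + 1). Two-sided tests compare absolute values.
Each function takes either an integer seed or a ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_QUANTS = (0.025, 0.5, 0.975)


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class PermutationResult:
    observed_stat: float
    n_perm: int
    p_value: float
    null_quantiles: dict = field(default_factory=dict)


@dataclass
class ResampledCI:
    point: float
    lower: float
    upper: float
    level: float = 95.0
    n_resamples: int = 0


def _finish(observed, null, n_perm, two_sided=True) -> PermutationResult:
    # tolerance so that exact ties (same statistic reached by a different
    # summation order) count as >=, keeping Monte-Carlo p conservative and
    # equal to exhaustive enumeration on tiny instances
    atol = 1e-12 * max(1.0, abs(observed))
    if two_sided:
        count = int(np.sum(np.abs(null) >= abs(observed) - atol))
    else:
        count = int(np.sum(null >= observed - atol))
    p = (count + 1) / (n_perm + 1)
    qs = {q: float(np.quantile(null, q)) for q in _QUANTS}
    return PermutationResult(observed_stat=float(observed), n_perm=n_perm,
                             p_value=float(p), null_quantiles=qs)


def _permuted_indices(rng, n, n_perm) -> np.ndarray:
    """(n_perm, n) matrix of independent permutations of arange(n)."""
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


def perm_corr_test(x, y, n_perm: int = 10000, seed=None) -> PermutationResult:
    """Permutation test of the Pearson correlation between species vectors.

    The null shuffles `y` over `x`; the p-value is two-sided on r.
    """
    rng = _rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx, sy = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r_obs = (xc @ yc) / (sx * sy)
    perm = _permuted_indices(rng, x.size, n_perm)
    r_null = (yc[perm] @ xc) / (sx * sy)
    return _finish(r_obs, r_null, n_perm)


def perm_sex_diff_test(values, sexes, n_perm: int = 10000, seed=None) -> PermutationResult:
    """Within-species female-male mean difference, null by relabelling sexes.

    `values` are the species' size-corrected raker lengths; `sexes` the
    matching labels ("female"/"male"). Requires >= 2 specimens per sex.
    """
    rng = _rng(seed)
    values = np.asarray(values, dtype=float)
    sexes = np.asarray(sexes)
    is_f = sexes == "female"
    is_m = sexes == "male"
    n_f, n_m = int(is_f.sum()), int(is_m.sum())
    if n_f < 2 or n_m < 2:
        raise ValueError("need at least 2 specimens of each sex")
    vals = np.concatenate([values[is_f], values[is_m]])
    obs = vals[:n_f].mean() - vals[n_f:].mean()
    perm = _permuted_indices(rng, vals.size, n_perm)
    shuffled = vals[perm]
    null = shuffled[:, :n_f].mean(axis=1) - shuffled[:, n_f:].mean(axis=1)
    return _finish(obs, null, n_perm)


def perm_mean_zero_test(diffs, n_perm: int = 10000, seed=None) -> PermutationResult:
    """Does the grand mean of per-species signed differences deviate from 0?

    Under H0 each species' difference is symmetric about zero, so the null
    flips the sign of every species independently (there are no labels to
    permute within a single breeding mode).
    """
    rng = _rng(seed)
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least 2 species")
    obs = diffs.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    null = (signs * diffs).mean(axis=1)
    return _finish(obs, null, n_perm)


def _anova_f(values: np.ndarray, group_slices) -> float:
    """One-way fixed-effects F from a flat array and per-group slices."""
    n = values.size
    k = len(group_slices)
    gm = values.mean()
    ssb = sum((s.stop - s.start) * (values[s].mean() - gm) ** 2 for s in group_slices)
    sst = ((values - gm) ** 2).sum()
    ssw = sst - ssb
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def perm_anova(values, groups, n_perm: int = 10000, seed=None, pairwise: bool = True):
    """Permutation one-way ANOVA across breeding modes (one-sided on F).

    The null permutes group labels over species. Returns the omnibus
    :class:`PermutationResult`; with ``pairwise=True`` also a dict
    ``{(g1, g2): PermutationResult}`` using the same machinery on each pair
    of groups (no multiplicity adjustment here).
    """
    rng = _rng(seed)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: int((groups == g).sum()) for g in levels}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")

    order = np.concatenate([np.flatnonzero(groups == g) for g in levels])
    vals = values[order]
    slices, start = [], 0
    for g in levels:
        slices.append(slice(start, start + sizes[g]))
        start += sizes[g]

    obs = _anova_f(vals, slices)
    perm = _permuted_indices(rng, vals.size, n_perm)
    shuffled = vals[perm]
    # vectorized F over permutations
    n, k = vals.size, len(levels)
    gm = shuffled.mean(axis=1)
    ssb = np.zeros(n_perm)
    for s in slices:
        ng = s.stop - s.start
        ssb += ng * (shuffled[:, s].mean(axis=1) - gm) ** 2
    sst = ((shuffled - gm[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):  # SSW = 0 -> F = inf
        null = (ssb / (k - 1)) / ((sst - ssb) / (n - k))
    omnibus = _finish(obs, null, n_perm, two_sided=False)

    if not pairwise:
        return omnibus
    pair_results = {}
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            g1, g2 = levels[i], levels[j]
            mask = (groups == g1) | (groups == g2)
            pair_results[(g1, g2)] = perm_anova(
                values[mask], groups[mask], n_perm=n_perm, seed=rng, pairwise=False)
    return omnibus, pair_results


def bootstrap_ci(values, statistic=np.mean, n_boot: int = 10000, level: float = 95.0,
                 seed=None) -> ResampledCI:
    """Percentile bootstrap confidence interval of `statistic` over `values`."""
    rng = _rng(seed)
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    point = float(statistic(values))
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    try:
        boot = np.asarray(statistic(values[idx], axis=1), dtype=float)
    except TypeError:  # statistic without axis support
        boot = np.array([statistic(values[row]) for row in idx], dtype=float)
    alpha = (100.0 - level) / 200.0
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    return ResampledCI(point=point, lower=float(min(lo, point)),
                       upper=float(max(hi, point)), level=level, n_resamples=n_boot)


def bootstrap_diff_ci(f_values, m_values, n_boot: int = 10000, level: float = 95.0,
                      seed=None) -> ResampledCI:
    """Percentile bootstrap CI for mean(female) - mean(male) within a species.

    Females and males are resampled independently with replacement.
    """
    rng = _rng(seed)
    f = np.asarray(f_values, dtype=float)
    m = np.asarray(m_values, dtype=float)
    point = float(f.mean() - m.mean())
    fi = rng.integers(0, f.size, size=(n_boot, f.size))
    mi = rng.integers(0, m.size, size=(n_boot, m.size))
    boot = f[fi].mean(axis=1) - m[mi].mean(axis=1)
    alpha = (100.0 - level) / 200.0
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    return ResampledCI(point=point, lower=float(min(lo, point)),
                       upper=float(max(hi, point)), level=level, n_resamples=n_boot)
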