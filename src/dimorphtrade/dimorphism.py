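"""Per-species and per-breeding-mode sexual dimorphism statistics.

The focal quantity is the female minus male difference of species-specific
size-corrected gill raker length (mm); its absolute value measures the
*extent* of dimorphism irrespective of direction. Inference is by the
resampling module: label permutation within species, independent bootstrap
of the two sexes for the species CI, sign-flip permutation and species-level
bootstrap for the per-mode grand means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dimorphtrade import resampling


def dimorphism_table(sc_table: pd.DataFrame, n_perm: int = 10000,
                     n_boot: int = 10000, seed=None):
    """Per-species signed and absolute dimorphism with CI and permutation p.

    Parameters
    ----------
    sc_table : DataFrame
        Species-specific size-corrected table (``species``, ``sex``,
        ``raker_sc``, ``breeding_mode``). Specimens with sex "unknown" are
        ignored; species without >= 2 specimens of each sex are excluded and
        reported.

    Returns
    -------
    (DataFrame, list[tuple[str, str]])
        One row per tested species: ``species, breeding_mode, signed_diff,
        abs_diff, n_female, n_male, ci_lower, ci_upper, p_value``; plus the
        exclusions as (species, reason).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, excluded = [], []
    for sp, grp in sc_table.groupby("species", sort=False):
        f = grp.loc[grp["sex"] == "female", "raker_sc"].to_numpy(dtype=float)
        m = grp.loc[grp["sex"] == "male", "raker_sc"].to_numpy(dtype=float)
        if f.size < 2 or m.size < 2:
            excluded.append((sp, f"needs >=2 per sex (female={f.size}, male={m.size})"))
            continue
        sexes = np.array(["female"] * f.size + ["male"] * m.size)
        vals = np.concatenate([f, m])
        perm = resampling.perm_sex_diff_test(vals, sexes, n_perm=n_perm, seed=rng)
        ci = resampling.bootstrap_diff_ci(f, m, n_boot=n_boot, seed=rng)
        signed = float(f.mean() - m.mean())
        rows.append({
            "species": sp,
            "breeding_mode": grp["breeding_mode"].iloc[0],
            "signed_diff": signed,
            "abs_diff": abs(signed),
            "n_female": int(f.size),
            "n_male": int(m.size),
            "ci_lower": ci.lower,
            "ci_upper": ci.upper,
            "p_value": perm.p_value,
        })
    return pd.DataFrame(rows), excluded


def grand_means_by_mode(records: pd.DataFrame, n_perm: int = 10000,
                        n_boot: int = 10000, seed=None):
    """Per-breeding-mode grand means of signed and absolute dimorphism.

    For each mode with >= 2 tested species: the mean signed difference with
    a species-level bootstrap CI and a sign-flip permutation p-value for
    "mean deviates from zero", plus the mean absolute difference with its
    bootstrap CI. Modes with < 2 species are excluded and reported.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, excluded = [], []
    for mode, grp in records.groupby("breeding_mode", sort=False):
        diffs = grp["signed_diff"].to_numpy(dtype=float)
        if diffs.size < 2:
            excluded.append((mode, "fewer than 2 tested species"))
            continue
        test = resampling.perm_mean_zero_test(diffs, n_perm=n_perm, seed=rng)
        ci = resampling.bootstrap_ci(diffs, np.mean, n_boot=n_boot, seed=rng)
        abs_diffs = grp["abs_diff"].to_numpy(dtype=float)
        ci_abs = resampling.bootstrap_ci(abs_diffs, np.mean, n_boot=n_boot, seed=rng)
        rows.append({
            "breeding_mode": mode,
            "n_species": int(diffs.size),
            "mean_signed_diff": float(diffs.mean()),
            "signed_ci_lower": ci.lower,
            "signed_ci_upper": ci.upper,
            "p_mean_zero": test.p_value,
            "mean_abs_diff": float(abs_diffs.mean()),
            "abs_ci_lower": ci_abs.lower,
            "abs_ci_upper": ci_abs.upper,
        })
    return pd.DataFrame(rows), excluded
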