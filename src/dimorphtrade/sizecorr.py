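"""Size correction of gill raker length against standard length (SL).

Two flavours, matching the two uses downstream:

* a *common* linear model across all specimens, whose residuals (shifted to
  be nonnegative, in mm) feed the phenotype-environment analyses;
* *species-specific* linear models (sexes pooled) whose raw residuals feed
  the within-species sex comparisons - differences of residuals are
  invariant to any per-species shift, so none is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FitSummary:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    shift: float
    n: int


def positive_shift(residuals: np.ndarray) -> float:
    """Shift that restores nonnegativity.

    The largest residual is added when that suffices (min + max >= 0);
    otherwise |min residual| is used. The shift cancels in every downstream
    statistic and only keeps values on an interpretable mm scale.
    """
    residuals = np.asarray(residuals, dtype=float)
    mx, mn = residuals.max(), residuals.min()
    return float(mx) if mn + mx >= 0 else float(-mn)


def common_size_correct(df: pd.DataFrame, shift: str = "auto"):
    """Regress raker length on SL across all specimens; return shifted residuals.

    Parameters
    ----------
    df : DataFrame
        Canonical specimen table (``standard_length``, ``raker_length``).
    shift : {"auto", "none"}
        "auto" applies :func:`positive_shift`; "none" returns raw residuals.

    Returns
    -------
    (DataFrame, FitSummary)
        Input columns plus ``raker_sc`` and ``method`` = "common".
    """
    if len(df) < 3:
        raise ValueError("need at least 3 specimens for the common model")
    sl = df["standard_length"].to_numpy(dtype=float)
    y = df["raker_length"].to_numpy(dtype=float)
    if np.ptp(sl) == 0:
        raise ValueError("standard length is constant; slope unidentifiable")
    fit = stats.linregress(sl, y)
    resid = y - (fit.intercept + fit.slope * sl)
    s = positive_shift(resid) if shift == "auto" else 0.0
    out = df.copy()
    out["raker_sc"] = resid + s
    out["method"] = "common"
    summary = FitSummary(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
        shift=s, n=len(df),
    )
    return out, summary


def per_species_size_correct(df: pd.DataFrame, min_n: int = 3):
    """Residuals from each species' own raker ~ SL regression (sexes pooled).

    Species with fewer than `min_n` specimens or without SL variation are
    excluded and reported. No positivity shift is applied.

    Returns
    -------
    (DataFrame, list[tuple[str, str]])
        Rows of surviving species with ``raker_sc`` (raw residual) and
        ``method`` = "per_species"; and (species, reason) exclusions.
    """
    pieces, excluded = [], []
    for sp, grp in df.groupby("species", sort=False):
        sl = grp["standard_length"].to_numpy(dtype=float)
        y = grp["raker_length"].to_numpy(dtype=float)
        if len(grp) < min_n:
            excluded.append((sp, f"fewer than {min_n} specimens"))
            continue
        if np.ptp(sl) == 0:
            excluded.append((sp, "no variation in standard length"))
            continue
        fit = stats.linregress(sl, y)
        out = grp.copy()
        out["raker_sc"] = y - (fit.intercept + fit.slope * sl)
        out["method"] = "per_species"
        pieces.append(out)
    if not pieces:
        raise ValueError("no species with enough specimens for size correction")
    return pd.concat(pieces, ignore_index=True), excluded
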