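"""Benthic-pelagic trophic axis from stable isotopes.

delta13C tracks the benthic-pelagic carbon source and delta15N the trophic
level; their leading principal component (on standardized variables) gives a
single trophic score per observation, oriented so that higher scores mean
more pelagic feeding / higher trophic position. For two standardized
variables the loadings are forced to +-1/sqrt(2) and PC1 explains
(1 + |r|)/2 of the variance, where r is the isotope correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TrophicAxis:
    """Leading PC of standardized (d13C, d15N): loadings, variance, scores."""

    loading_d13C: float
    loading_d15N: float
    pct_variance_pc1: float
    scores: np.ndarray          # per input observation
    mean_: np.ndarray           # standardization parameters (d13C, d15N)
    sd_: np.ndarray

    def transform(self, d13C, d15N) -> np.ndarray:
        """Project new observations onto the fitted axis."""
        z = (np.column_stack([d13C, d15N]) - self.mean_) / self.sd_
        return z @ np.array([self.loading_d13C, self.loading_d15N])


def compute_trophic_axis(d13C, d15N) -> TrophicAxis:
    """PCA of the standardized isotope pair, oriented so d15N loads positive.

    Raises ``ValueError`` for fewer than 3 observations or zero variance in
    either isotope.
    """
    d13C = np.asarray(d13C, dtype=float)
    d15N = np.asarray(d15N, dtype=float)
    if d13C.shape != d15N.shape or d13C.ndim != 1:
        raise ValueError("d13C and d15N must be 1-d arrays of equal length")
    n = d13C.size
    if n < 3:
        raise ValueError("need at least 3 isotope observations")
    mean_ = np.array([d13C.mean(), d15N.mean()])
    sd_ = np.array([d13C.std(ddof=1), d15N.std(ddof=1)])
    if np.any(sd_ == 0):
        raise ValueError("zero variance in an isotope variable")
    z = (np.column_stack([d13C, d15N]) - mean_) / sd_
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)          # ascending
    v = eigvec[:, -1]
    if v[1] < 0:                                   # orientation: d15N positive
        v = -v
    scores = z @ v
    return TrophicAxis(
        loading_d13C=float(v[0]),
        loading_d15N=float(v[1]),
        pct_variance_pc1=float(eigval[-1] / 2.0 * 100.0),
        scores=scores,
        mean_=mean_,
        sd_=sd_,
    )


def species_pc1_scores(axis: TrophicAxis, table: pd.DataFrame):
    """Per-species mean PC1 score.

    `table` must carry ``species``, ``d13C``, ``d15N``; rows with missing
    isotope values are excluded and the affected species reported.

    Returns
    -------
    (Series, list[str])
        species -> mean score (species order of first appearance), and the
        species excluded for lack of any isotope data.
    """
    ok = table[["d13C", "d15N"]].notna().all(axis=1)
    sub = table.loc[ok]
    scores = axis.transform(sub["d13C"].to_numpy(), sub["d15N"].to_numpy())
    per = pd.Series(scores, index=sub["species"].to_numpy()).groupby(level=0, sort=False).mean()
    excluded = [sp for sp in table["species"].unique() if sp not in per.index]
    per.index.name = "species"
    per.name = "trophic_pc1"
    return per, excluded
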