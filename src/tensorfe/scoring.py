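"""Chi-square attribution of P-values to features from factor loadings.

Under the null hypothesis that a feature is uninformative, its loadings on
the selected singular components are Gaussian with the component-wise
spread sigma_l (the standard deviation of column l over all features of
that modality, population divisor).  The statistic

    T_f = sum_{l in selected} (u[f, l] / sigma_l)^2

is then chi-square with one degree of freedom per component, and the raw
P-value is the upper tail P[chi2_df > T_f].  P-values are corrected per
modality with the Benjamini-Hochberg step-up procedure and features with
adjusted P below the threshold (default 0.01, strict inequality) are
selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FeatureScores:
    """Per-feature chi-square statistics and raw / adjusted P-values."""

    feature_ids: list[str]
    statistic: np.ndarray
    df: int
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    threshold: float

    @property
    def selected(self) -> np.ndarray:
        return self.p_adjusted < self.threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "statistic": self.statistic,
                "df": self.df,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "selected": self.selected,
            }
        )


def bh_adjust(p_raw: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values.

    Sort ascending, multiply p_(r) by m/r, enforce monotonicity from the
    largest rank downwards, cap at 1, and restore the input order.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def chi2_scores(
    factor: np.ndarray,
    components: np.ndarray | Sequence[int],
    feature_ids: Sequence[str] | None = None,
    threshold: float = 0.01,
    center: bool = False,
) -> FeatureScores:
    """Score every feature of one modality from its factor-matrix loadings.

    Parameters
    ----------
    factor : (n_features, n_components) factor matrix of the feature mode
    components : selected component (column) indices; df = their number
    center : subtract each column's mean before dividing by sigma_l.  The
        literal formula does not centre; the flag exists because the
        Gaussian null is about spread, not location.
    """
    comps = np.asarray(components, dtype=int)
    if comps.size == 0:
        raise ValueError("component set must be nonempty")
    if comps.min() < 0 or comps.max() >= factor.shape[1]:
        raise ValueError("component index out of range")
    cols = factor[:, comps]
    sigma = cols.std(axis=0)  # population divisor over all features
    zero = np.flatnonzero(sigma == 0)
    if zero.size:
        raise ValueError(f"constant factor column(s) {comps[zero].tolist()}: sigma is zero")
    if center:
        cols = cols - cols.mean(axis=0, keepdims=True)
    statistic = ((cols / sigma) ** 2).sum(axis=1)
    df = comps.size
    p_raw = stats.chi2.sf(statistic, df=df)
    p_adj = bh_adjust(p_raw)
    ids = list(feature_ids) if feature_ids is not None else [str(i) for i in range(factor.shape[0])]
    if len(ids) != factor.shape[0]:
        raise ValueError("feature_ids length does not match the factor matrix")
    return FeatureScores(ids, statistic, df, p_raw, p_adj, threshold)


def select_features(scores: FeatureScores) -> list[str]:
    """Identifiers with adjusted P below threshold, best statistic first."""
    idx = np.flatnonzero(scores.selected)
    idx = idx[np.argsort(scores.statistic[idx], kind="stable")[::-1]]
    return [scores.feature_ids[i] for i in idx]
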