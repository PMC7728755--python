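"""Reproducible selection of informative singular components.

The published analyses of this kind identify sample-mode components that
separate treatment groups or timepoints "by visual inspection", and then
keep the feature-mode components coupled to them through large core-tensor
entries.  Here both steps are automated:

* sample-mode columns are tested with a two-sample t-test (group) and a
  one-way ANOVA (timepoint); columns that essentially point along the
  uniform vector — the overall expression-scale direction, including the
  degenerate constant column of a centred tensor — are set aside as
  *scale-like* and never treated as contrasts;
* feature-mode components are scored by their largest absolute core entry
  against the selected sample components, a component is discarded when its
  coupling to the scale-like sample components dominates that score (it
  reconstructs the expression profile, not the contrast), and the number
  kept is chosen either by a fixed count (``top_k``) or by the smallest
  prefix of the score-sorted list holding a fraction of the squared-score
  energy (``energy``, the default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hosvd import HOSVDResult
from .io import SampleDesign

logger = logging.getLogger(__name__)

RULES = ("top_k", "energy")


@dataclass
class SampleComponent:
    """Association of one sample-mode singular column with the design."""

    index: int
    kind: str  # 'group' | 'time' | 'scale' | 'none'
    p_group: float
    p_time: float

    @property
    def p(self) -> float:
        return min(self.p_group, self.p_time)


@dataclass
class ComponentSelection:
    """The l2 / l1 / l3 index sets feeding the feature scoring stage."""

    sample_components: list[SampleComponent]
    mrna_components: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    mirna_components: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    mrna_scores: np.ndarray | None = None
    mirna_scores: np.ndarray | None = None

    @property
    def selected_sample(self) -> list[int]:
        return [c.index for c in self.sample_components if c.kind in ("group", "time")]

    @property
    def scale_sample(self) -> list[int]:
        return [c.index for c in self.sample_components if c.kind == "scale"]


def _column_pvalues(col: np.ndarray, treated: np.ndarray, tidx: np.ndarray) -> tuple[float, float]:
    # degenerate (constant) column: no association by convention
    if col.std() < 1e-12:
        return 1.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(col[treated], col[~treated])
        groups = [col[tidx == t_] for t_ in np.unique(tidx)]
        a = stats.f_oneway(*groups)
    pg = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
    pt = 1.0 if np.isnan(a.pvalue) else float(a.pvalue)
    return pg, pt


def associate_sample_components(
    u2: np.ndarray,
    design: SampleDesign,
    alpha: float = 0.05,
    scale_cosine: float = 0.9,
) -> list[SampleComponent]:
    """Label every sample-mode column as group-, time-, scale-like or none.

    A column whose absolute cosine with the uniform vector exceeds
    ``scale_cosine`` is labelled ``scale``: it measures overall expression
    magnitude rather than a contrast (for raw data this is the leading
    component; for centred data it is the numerically null uniform
    direction).  Remaining columns are labelled by their smaller
    association P-value when it is below ``alpha``.
    """
    m = u2.shape[0]
    if u2.shape[0] != design.n_samples:
        raise ValueError("u2 rows are not aligned to the design samples")
    treated = design.group_mask
    if treated.sum() < 2 or (~treated).sum() < 2:
        raise ValueError("need at least 2 samples per group")
    tidx = design.timepoint_index
    out = []
    for l2 in range(u2.shape[1]):
        col = u2[:, l2]
        norm = np.linalg.norm(col)
        cosine = abs(col.sum()) / (np.sqrt(m) * norm) if norm > 0 else 1.0
        if cosine > scale_cosine:
            out.append(SampleComponent(l2, "scale", 1.0, 1.0))
            continue
        pg, pt = _column_pvalues(col, treated, tidx)
        if min(pg, pt) < alpha:
            kind = "group" if pg <= pt else "time"
        else:
            kind = "none"
        out.append(SampleComponent(l2, kind, pg, pt))
    n_sel = sum(c.kind in ("group", "time") for c in out)
    logger.info("sample components: %d selected (%d group, %d time), %d scale-like",
                n_sel, sum(c.kind == "group" for c in out),
                sum(c.kind == "time" for c in out),
                sum(c.kind == "scale" for c in out))
    return out


def _feature_mode_scores(
    hosvd_result: HOSVDResult, feature_axis: int, sample_idx: list[int], scale_idx: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """max |G| per feature-mode component against contrast and scale l2 sets."""
    dim = hosvd_result.shape[feature_axis - 1]
    cand = np.arange(dim)
    axes = {1: (1, 2, 3), 3: (0, 1, 3)}[feature_axis]
    if feature_axis == 1:
        block = hosvd_result.core_block(l1=cand, l2=sample_idx)
        scale_block = hosvd_result.core_block(l1=cand, l2=scale_idx) if scale_idx else None
    else:
        block = hosvd_result.core_block(l3=cand, l2=sample_idx)
        scale_block = hosvd_result.core_block(l3=cand, l2=scale_idx) if scale_idx else None
    score = np.max(np.abs(block), axis=axes) if sample_idx else np.zeros(dim)
    scale = (
        np.max(np.abs(scale_block), axis=axes) if scale_block is not None else np.zeros(dim)
    )
    return score, scale


def _apply_rule(score: np.ndarray, scale: np.ndarray, rule: str, k: int,
                energy_fraction: float, scale_dominance: float | None) -> np.ndarray:
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if not np.any(score > 0):
        logger.warning("all-zero core scores: empty component selection")
        return np.array([], dtype=int)
    if rule == "top_k":
        if k > score.size:
            raise ValueError(f"k={k} exceeds the mode dimension {score.size}")
        order = np.argsort(score, kind="stable")[::-1]
        return np.sort(order[:k])
    candidates = np.arange(score.size)
    if scale_dominance is not None:
        keep = scale <= scale_dominance * score
        candidates = candidates[keep]
        if candidates.size == 0:
            logger.warning("scale-dominance filter removed all candidates")
            return np.array([], dtype=int)
    order = candidates[np.argsort(score[candidates], kind="stable")[::-1]]
    energy = np.cumsum(score[order] ** 2) / np.sum(score[order] ** 2)
    n_keep = int(np.searchsorted(energy, energy_fraction) + 1)
    return np.sort(order[:n_keep])


def select_feature_components(
    hosvd_result: HOSVDResult,
    sample_components: list[SampleComponent],
    rule: str = "energy",
    k: int = 4,
    energy_fraction: float = 0.8,
    scale_dominance: float | None = 3.0,
) -> ComponentSelection:
    """Choose the mRNA-mode (l1) and miRNA-mode (l3) component sets.

    ``rule='top_k'`` reproduces the literal fixed-count selection of the
    mode components with the largest core weight (the dominance filter is
    not applied, so exactly ``k`` components are returned).  The default
    ``rule='energy'`` keeps the smallest score-sorted prefix holding
    ``energy_fraction`` of the squared-score energy, after discarding
    components whose coupling to scale-like sample components exceeds
    ``scale_dominance`` times their contrast score.
    """
    sel = [c.index for c in sample_components if c.kind in ("group", "time")]
    if not sel:
        raise ValueError("no group- or time-associated sample components to select against")
    scale = [c.index for c in sample_components if c.kind == "scale"]
    dominance = None if rule == "top_k" else scale_dominance
    s1, x1 = _feature_mode_scores(hosvd_result, 1, sel, scale)
    s3, x3 = _feature_mode_scores(hosvd_result, 3, sel, scale)
    l1 = _apply_rule(s1, x1, rule, k, energy_fraction, dominance)
    l3 = _apply_rule(s3, x3, rule, k, energy_fraction, dominance)
    logger.info("feature components: l1=%s l3=%s (rule=%s)",
                [int(i) for i in l1], [int(i) for i in l3], rule)
    return ComponentSelection(
        sample_components=list(sample_components),
        mrna_components=l1,
        mirna_components=l3,
        mrna_scores=s1,
        mirna_scores=s3,
    )
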