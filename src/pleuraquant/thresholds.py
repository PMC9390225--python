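"""ROC-based selection of the hyperdensity and rim-width thresholds.

Candidate HU cutoffs for hyperdense fluid (8.5, 15.6, 30 HU) and candidate
rim widths for pleural thickening (4, 5, 8 mm) are compared by the AUC of
the corresponding recomputed feature against the case labels; the winner is
the candidate with the highest AUC, ties broken toward the least permissive
candidate (highest HU cutoff, smallest rim width).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import FeatureConfig, compute_hyper_features, split_sides, detect_effusion

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSweepResult", "auc", "sweep_thresholds",
            "HU_CANDIDATES", "RIM_CANDIDATES"]

HU_CANDIDATES = (8.5, 15.6, 30.0)
RIM_CANDIDATES = (4.0, 5.0, 8.0)


@dataclass
class ThresholdSweepResult:
    feature: str  # 'hyper' (HU cutoff) or 'rim' (width in mm)
    candidates: tuple
    aucs: tuple
    selected: float
    tie: bool
    rule: str = "argmax AUC; ties -> least permissive"


def auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative.

    Mann-Whitney rank formulation; ties count one half. Raises if only one
    class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _case_scores(cases, candidate, feature, base: FeatureConfig):
    """Per-case score recomputed at one candidate (max over sides)."""
    if feature == "hyper":
        config = replace(base, hu_hyper=candidate)
    else:
        config = replace(base, rim_mm=candidate)
    scores = []
    for ct, mask in cases:
        best = 0.0
        for side_mask in split_sides(mask).values():
            present, _ = detect_effusion(side_mask, config)
            if not present:
                continue
            h = compute_hyper_features(ct, side_mask, config)
            val = h["f_hyper"] if feature == "hyper" else h["f_pleura_rate"]
            if not np.isnan(val):
                best = max(best, val)
        scores.append(best)
    return np.asarray(scores)


def sweep_thresholds(
    cases,
    labels,
    candidates,
    feature: str = "hyper",
    config: FeatureConfig = FeatureConfig(),
) -> ThresholdSweepResult:
    """Evaluate candidate thresholds and select the best by AUC.

    ``cases`` is either a list of ``(CTVolume, LabelMask)`` pairs (features
    are recomputed per candidate) or a DataFrame with one cached score
    column per candidate named ``{feature}@{candidate:g}``.

    For the HU sweep the per-case score is the absolute hyperdense volume;
    for the rim sweep it is the rim hyperdensity rate. Cases are scored by
    the maximum over sides with an effusion.
    """
    if feature not in ("hyper", "rim"):
        raise ValueError("feature must be 'hyper' or 'rim'")
    labels = np.asarray(labels, dtype=int)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise ValueError("need at least 2 cases per class")
    aucs = []
    for cand in candidates:
        if isinstance(cases, pd.DataFrame):
            scores = cases[f"{feature}@{cand:g}"].to_numpy(dtype=float)
        else:
            scores = _case_scores(cases, cand, feature, config)
        if np.ptp(scores) == 0:
            warnings.warn(
                f"candidate {cand:g}: all scores identical; AUC 0.5 recorded"
            )
            aucs.append(0.5)
        else:
            aucs.append(auc(scores, labels))
    aucs = tuple(aucs)
    best = max(aucs)
    winners = [c for c, a in zip(candidates, aucs) if a == best]
    tie = len(winners) > 1
    # least permissive: highest HU cutoff, smallest rim width
    selected = max(winners) if feature == "hyper" else min(winners)
    if tie:
        logger.warning(
            "AUC tie among %s; selected least permissive %g", winners, selected
        )
    return ThresholdSweepResult(
        feature=feature, candidates=tuple(candidates), aucs=aucs,
        selected=float(selected), tie=tie,
    )
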