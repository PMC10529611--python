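"""Positional editing-bias correction and control-anchored score scaling.

Editing rates vary smoothly with distance from the Cas9 cut site, which
tilts raw day-14/day-3 log2 ratios along the amplicon.  The trend is
estimated with a tricube-weighted local linear regression (loess) fitted
only on near-neutral variants — those within a configurable fold of no
change — so genuine biological dropout does not bend the fit.  The fitted
value at each position is subtracted from every variant's log2 ratio.

Corrected scores are then anchored on the internal controls: within each
exon an affine map takes the (synonymous median, nonsense median) onto the
global medians across exons, so scores are comparable across exons and
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_SPAN = 0.75
DEFAULT_INCLUSION_FOLD = 1.25
MIN_FIT_POINTS = 10
#: coarse pre-selection half-width (log2 units) around the neutral mode
COARSE_WINDOW = 1.0


def _sorted_unique(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and average duplicate x for np.interp."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inv, ys)
    np.add.at(counts, inv, 1)
    return ux, uy / counts


class BiasFitError(ValueError):
    """Too few near-neutral variants to model the positional trend."""


class AnchorError(ValueError):
    """Degenerate control anchors (synonymous median not above nonsense)."""


@dataclass
class LoessModel:
    """Fitted smooth of log2 post/pre ratio against position.

    Outside the fitted range predictions clamp to the nearest fitted value.
    """

    x: np.ndarray
    fitted: np.ndarray
    span: float
    inclusion_fold: float
    n_used: int

    def predict(self, positions) -> np.ndarray:
        return np.interp(np.asarray(positions, dtype=float), self.x, self.fitted)


def fit_position_bias(
    positions,
    log2_ratios,
    span: float = DEFAULT_SPAN,
    inclusion_fold: float = DEFAULT_INCLUSION_FOLD,
    one_sided: bool = False,
) -> LoessModel:
    """Fit the positional trend on near-neutral variants only.

    ``inclusion_fold`` bounds which variants inform the fit: those whose
    log2 ratio lies within ``log2(inclusion_fold)`` of a provisional
    neutral trend.  The provisional trend anchors on the main mode of the
    score distribution (the neutral cluster, found by KDE), coarse-selects
    everything within one log2 unit of it, and smooths that subset.
    Measuring the inclusion window against this trend rather than against
    zero keeps near-neutral variants in the fit even when the trend
    itself, or a global renormalization shift, exceeds the window — the
    rule's job is to exclude variants with genuine biological dropout or
    enrichment, which sit far from the local majority.  With
    ``one_sided=True`` the alternative absolute reading — ratio at least
    ``inclusion_fold`` — is used instead.
    """
    pos = np.asarray(positions, dtype=float)
    lr = np.asarray(log2_ratios, dtype=float)
    finite = np.isfinite(pos) & np.isfinite(lr)
    bound = np.log2(inclusion_fold)
    if one_sided:
        mask = finite & (lr >= bound)
    elif finite.sum() >= MIN_FIT_POINTS:
        # provisional neutral trend: anchor on the main (neutral) mode of
        # the score distribution, coarse-include everything within one
        # log2 unit of it (trend amplitudes are well below the 3-unit
        # dropout separation), and smooth that subset
        if np.ptp(lr[finite]) < 1e-12:
            mode = float(np.median(lr[finite]))
        else:
            kde = gaussian_kde(lr[finite])
            grid = np.linspace(lr[finite].min(), lr[finite].max(), 256)
            mode = grid[int(np.argmax(kde(grid)))]
        coarse = finite & (np.abs(lr - mode) <= COARSE_WINDOW)
        if coarse.sum() >= MIN_FIT_POINTS:
            t = lowess(lr[coarse], pos[coarse], frac=span, return_sorted=False)
            trend = np.interp(pos, *_sorted_unique(pos[coarse], t))
        else:
            trend = np.full(lr.shape, mode)
        mask = finite & (np.abs(lr - trend) <= bound)
    else:
        mask = finite & (np.abs(lr) <= bound)
    n_used = int(mask.sum())
    if n_used < MIN_FIT_POINTS:
        raise BiasFitError(
            f"only {n_used} variants pass the {inclusion_fold}-fold inclusion "
            f"rule; need at least {MIN_FIT_POINTS} to fit the positional trend"
        )
    sm = lowess(lr[mask], pos[mask], frac=span, return_sorted=True)
    x, y = sm[:, 0], sm[:, 1]
    # collapse duplicate x for interpolation
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.zeros_like(ux)
    counts = np.zeros_like(ux)
    np.add.at(uy, inv, y)
    np.add.at(counts, inv, 1)
    uy /= counts
    return LoessModel(ux, uy, span, inclusion_fold, n_used)


def correct_scores(positions, log2_ratios, model: LoessModel) -> np.ndarray:
    """Subtract the fitted positional trend from each log2 ratio."""
    lr = np.asarray(log2_ratios, dtype=float)
    return lr - model.predict(positions)


@dataclass
class ScalingAnchors:
    """Synonymous/nonsense score medians used as affine anchor points."""

    syn_median: float
    nonsense_median: float

    def __post_init__(self) -> None:
        if not self.syn_median > self.nonsense_median:
            raise AnchorError(
                "degenerate anchors: synonymous median "
                f"({self.syn_median}) must exceed nonsense median "
                f"({self.nonsense_median})"
            )


def anchors_of(scores: pd.Series, consequence: pd.Series) -> ScalingAnchors:
    syn = scores[consequence == "synonymous"]
    non = scores[consequence == "nonsense"]
    if len(syn) < 1 or len(non) < 1:
        raise AnchorError("need at least one synonymous and one nonsense control")
    return ScalingAnchors(float(syn.median()), float(non.median()))


def scale_within_exon(
    scores: pd.Series,
    exon_anchors: ScalingAnchors,
    global_anchors: ScalingAnchors,
) -> pd.Series:
    """Two-point affine map taking the exon's control medians onto the
    global medians; order-preserving, applied to every variant of the exon."""
    slope = (global_anchors.syn_median - global_anchors.nonsense_median) / (
        exon_anchors.syn_median - exon_anchors.nonsense_median
    )
    return (scores - exon_anchors.syn_median) * slope + global_anchors.syn_median


def normalize_across_exons(
    scores: pd.Series,
    exon: pd.Series,
    consequence: pd.Series,
) -> pd.Series:
    """Anchor every exon's scores to the pooled control medians.

    After normalization each exon's synonymous median equals the global
    synonymous median, and likewise for nonsense, to numerical tolerance.
    With a single exon the map is the identity.
    """
    global_anchors = anchors_of(scores, consequence)
    out = scores.astype(float).copy()
    for name, idx in scores.groupby(exon).groups.items():
        ex_anchors = anchors_of(scores.loc[idx], consequence.loc[idx])
        out.loc[idx] = scale_within_exon(scores.loc[idx], ex_anchors, global_anchors)
    return out
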