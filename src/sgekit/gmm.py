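"""Gaussian-mixture variant classification and evidence calibration.

The SNV-saturation path scores each variant with a single normalized
function score whose distribution is bimodal.  Classification is
model-based discriminant analysis: a Gaussian is fitted to each labelled
control class (functional / non-functional) and a variant's posterior
probability of pathogenicity is the non-functional component's
responsibility at its score.  Posterior > 0.99 is called pathogenic,
< 0.05 benign, anything between intermediate.

Classifier evidence is summarized the way clinical assay calibration
expects it: sensitivity/specificity on the controls, positive/negative
likelihood ratios, and OddsPath mapped to ACMG PS3/BS3 evidence strength
bands (Bayesian adaptation thresholds 2.1 / 4.3 / 18.7 / 350 and their
reciprocals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

POSTERIOR_PATHOGENIC_MIN = 0.99  # strict: must exceed
POSTERIOR_BENIGN_MAX = 0.05      # strict: must be below

#: OddsPath thresholds of the Bayesian ACMG adaptation (supporting,
#: moderate, strong, very strong); benign bands use the reciprocals.
_PS3_BANDS = ((350.0, "PS3_very_strong"), (18.7, "PS3_strong"),
              (4.3, "PS3_moderate"), (2.1, "PS3_supporting"))
_BS3_BANDS = ((1 / 350.0, "BS3_very_strong"), (1 / 18.7, "BS3_strong"),
              (1 / 4.3, "BS3_moderate"), (1 / 2.1, "BS3_supporting"))


@dataclass
class GmmModel:
    """Class-conditional Gaussians for the functional / non-functional classes."""

    mean_functional: float
    sd_functional: float
    mean_nonfunctional: float
    sd_nonfunctional: float
    prior_functional: float
    prior_nonfunctional: float
    n_functional: int
    n_nonfunctional: int

    def __post_init__(self) -> None:
        if self.sd_functional <= 0 or self.sd_nonfunctional <= 0:
            raise ValueError("class SDs must be positive")
        if abs(self.prior_functional + self.prior_nonfunctional - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")


def fit_gmm(
    scores,
    labels,
    equal_priors: bool = False,
    pooled_variance: bool = False,
) -> GmmModel:
    """Supervised fit: per-class sample mean/SD from labelled controls.

    ``labels`` mark each score "functional" or "non_functional".  Priors
    default to the training proportions; ``equal_priors=True`` sets both
    to 0.5.  A class with zero spread raises, suggesting
    ``pooled_variance=True`` which shares one SD across classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    f = scores[labels == "functional"]
    nf = scores[labels == "non_functional"]
    if len(f) < 2 or len(nf) < 2:
        raise ValueError("need at least 2 control variants per class")
    sd_f, sd_nf = f.std(ddof=1), nf.std(ddof=1)
    if pooled_variance:
        pooled = math.sqrt(
            ((len(f) - 1) * sd_f**2 + (len(nf) - 1) * sd_nf**2)
            / (len(f) + len(nf) - 2)
        )
        sd_f = sd_nf = pooled
    if sd_f == 0 or sd_nf == 0:
        raise ValueError(
            "a control class has zero variance; consider pooled_variance=True"
        )
    if equal_priors:
        pf = pnf = 0.5
    else:
        pf = len(f) / (len(f) + len(nf))
        pnf = 1.0 - pf
    return GmmModel(float(f.mean()), float(sd_f), float(nf.mean()),
                    float(sd_nf), pf, pnf, len(f), len(nf))


def posterior_pathogenic(model: GmmModel, scores) -> np.ndarray:
    """Posterior responsibility of the non-functional component.

    ``pi_nf phi_nf(s) / (pi_nf phi_nf(s) + pi_f phi_f(s))``, computed in
    log space for stability in the tails.
    """
    s = np.atleast_1d(np.asarray(scores, dtype=float))
    log_nf = np.log(model.prior_nonfunctional) + norm.logpdf(
        s, model.mean_nonfunctional, model.sd_nonfunctional
    )
    log_f = np.log(model.prior_functional) + norm.logpdf(
        s, model.mean_functional, model.sd_functional
    )
    m = np.maximum(log_nf, log_f)
    w_nf = np.exp(log_nf - m)
    w_f = np.exp(log_f - m)
    return w_nf / (w_nf + w_f)


def categorize_gmm(posterior) -> np.ndarray:
    """Three-way call: >0.99 pathogenic, <0.05 benign, else intermediate."""
    p = np.atleast_1d(np.asarray(posterior, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    return np.where(
        p > POSTERIOR_PATHOGENIC_MIN,
        "pathogenic",
        np.where(p < POSTERIOR_BENIGN_MAX, "benign", "intermediate"),
    )


# ---------------------------------------------------------------------------
# evaluation metrics


def compute_sensitivity_specificity(
    categories,
    labels,
    intermediate_policy: str = "count_against",
) -> tuple[float, float, dict[str, int]]:
    """Percent sensitivity/specificity of three-way calls against labels.

    ``labels``: "non_functional" (positive) or "functional" (negative).
    Intermediate calls either count as misclassifications of their true
    class (default, conservative) or are excluded entirely.
    Returns ``(sensitivity, specificity, confusion)``.
    """
    cat = np.asarray(categories)
    lab = np.asarray(labels)
    positive_calls = np.isin(cat, ("pathogenic", "non_functional"))
    negative_calls = np.isin(cat, ("benign", "functional"))
    if intermediate_policy == "exclude":
        keep = positive_calls | negative_calls
        cat, lab = cat[keep], lab[keep]
        positive_calls, negative_calls = positive_calls[keep], negative_calls[keep]
    elif intermediate_policy != "count_against":
        raise ValueError("intermediate_policy must be count_against or exclude")
    pos = lab == "non_functional"
    neg = lab == "functional"
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("both label classes required for sensitivity/specificity")
    tp = int((pos & positive_calls).sum())
    fn = int(pos.sum()) - tp
    tn = int((neg & negative_calls).sum())
    fp = int(neg.sum()) - tn
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return sens, spec, {"TP": tp, "FN": fn, "TN": tn, "FP": fp}


def compute_likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """LR+ = sens/(100-spec); LR- = (100-sens)/spec, on the percent scale.

    Perfect specificity yields LR+ = inf; zero specificity yields
    LR- = inf.
    """
    for v in (sensitivity, specificity):
        if not 0.0 <= v <= 100.0:
            raise ValueError("sensitivity/specificity must be percentages")
    lr_plus = math.inf if specificity == 100.0 else sensitivity / (100.0 - specificity)
    lr_minus = math.inf if specificity == 0.0 else (100.0 - sensitivity) / specificity
    return lr_plus, lr_minus


@dataclass
class OddsPathResult:
    p1: float
    p2_pathogenic: float
    p2_benign: float
    op_pathogenic: float
    op_benign: float
    evidence_pathogenic: str
    evidence_benign: str


def _ps3_label(op: float) -> str:
    for threshold, label in _PS3_BANDS:
        if op >= threshold:
            return label
    return "none"


def _bs3_label(op: float) -> str:
    for threshold, label in _BS3_BANDS:
        if op <= threshold:
            return label
    return "none"


def compute_oddspath(
    n_pathogenic_controls: int,
    n_total_controls: int,
    n_predicted_pathogenic: int,
    n_predicted_benign: int,
) -> OddsPathResult:
    """Odds of pathogenicity from control proportions and prediction counts.

    P1 is the prior proportion of pathogenic controls; the +1 in the P2
    formulas is the standard small-count correction.  OddsPath values are
    mapped to ACMG PS3/BS3 evidence strength bands.
    """
    if n_total_controls <= 0 or min(n_pathogenic_controls,
                                    n_predicted_pathogenic,
                                    n_predicted_benign) < 0:
        raise ValueError("counts must be non-negative with total controls > 0")
    p1 = n_pathogenic_controls / n_total_controls
    if p1 in (0.0, 1.0):
        raise ValueError("OddsPath undefined when P1 is 0 or 1")
    p2_path = n_predicted_pathogenic / (n_predicted_pathogenic + 1)
    p2_ben = 1.0 / (n_predicted_benign + 1)
    op_path = (p2_path * (1 - p1)) / ((1 - p2_path) * p1)
    # zero predicted-benign makes P2_benign = 1 and the odds degenerate
    if p2_ben == 1.0:
        op_ben = math.inf
    else:
        op_ben = (p2_ben * (1 - p1)) / ((1 - p2_ben) * p1)
    return OddsPathResult(
        p1, p2_path, p2_ben, op_path, op_ben,
        _ps3_label(op_path), _bs3_label(op_ben),
    )


def compute_roc_auc(posteriors, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve (threshold sweep) and trapezoidal AUC.

    Positive class is "non_functional".  Returns a DataFrame of
    (threshold, fpr, tpr) and the AUC.
    """
    post = np.asarray(posteriors, dtype=float)
    lab = np.asarray(labels)
    y = (lab == "non_functional").astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC requires both classes")
    fpr, tpr, thresholds = roc_curve(y, post)
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return roc, float(_trapezoid_auc(fpr, tpr))
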