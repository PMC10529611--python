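"""High-level pipeline compositions.

Two study designs are supported end to end:

* the codon-saturation path — count table -> frequencies -> per-arm
  function scores -> three-assay probit PIF classifier;
* the SNV-saturation path — count table -> frequencies -> weighted global
  ratio -> loess positional-bias correction -> control-anchored scaling ->
  Gaussian-mixture classifier with LR/OddsPath/AUC metrics.

Both take a :class:`~sgekit.simulate.GroundTruth` plus its count table (or
any count table with a consequence annotation) and return plain dicts of
intermediate tables and metrics, which the CLI, the examples and the test
suite all share.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sgekit.bias import correct_scores, fit_position_bias, normalize_across_exons
from sgekit.gmm import (
    categorize_gmm,
    compute_likelihood_ratios,
    compute_oddspath,
    compute_roc_auc,
    compute_sensitivity_specificity,
    fit_gmm,
    posterior_pathogenic,
)
from sgekit.probit import (
    categorize_pif,
    compute_pif,
    fit_probit,
    kfold_cv,
    model_fit_accuracy,
)
from sgekit.scoring import (
    apply_codon_filters,
    apply_exon13_filters,
    compute_fs,
    compute_global_ratio,
    normalize_frequencies,
)
from sgekit.tables import CountTable

FS_COLS = ["fs_DMSO", "fs_cisplatin", "fs_olaparib"]

CONTROL_LABELS = {"synonymous": "functional", "nonsense": "non_functional"}


def control_labels(consequence: pd.Series) -> pd.Series:
    """Map synonymous/nonsense consequences to control class labels."""
    return consequence.map(CONTROL_LABELS).dropna()


def run_codon_pipeline(table: CountTable, consequence: pd.Series,
                       cv_folds: tuple[int, ...] = (), seed: int = 0) -> dict:
    """Counts -> FS -> probit PIF for a codon-saturation experiment."""
    freq = normalize_frequencies(table)
    report = apply_codon_filters(freq)
    fs = compute_fs(freq)
    keep = report.surviving
    controls = control_labels(consequence).reindex(keep.intersection(
        consequence.index)).dropna()
    X_train = fs.loc[controls.index, FS_COLS].to_numpy()
    y_train = (controls == "non_functional").astype(float).to_numpy()
    model = fit_probit(X_train, y_train, predictor_names=FS_COLS)
    pif = pd.Series(compute_pif(model, fs.loc[keep, FS_COLS].to_numpy()),
                    index=keep, name="pif")
    category = pd.Series(categorize_pif(pif), index=keep, name="category")
    out = {
        "freq": freq,
        "fs": fs,
        "filter_report": report,
        "controls": controls,
        "model": model,
        "pif": pif,
        "category": category,
        "train_accuracy": model_fit_accuracy(model, X_train, y_train),
    }
    out["cv"] = {
        k: kfold_cv(X_train, y_train, k, seed=seed) for k in cv_folds
    }
    return out


def run_snv_pipeline(table: CountTable, consequence: pd.Series,
                     positions: pd.Series, exon: pd.Series | None = None,
                     span: float = 0.75) -> dict:
    """Counts -> global ratio -> bias correction -> anchoring -> GMM."""
    freq = normalize_frequencies(table)
    fs = compute_fs(freq)
    controls_all = control_labels(consequence)
    report = apply_exon13_filters(freq, fs, controls_all)
    keep = report.surviving
    global_ratio = compute_global_ratio(fs.loc[keep])
    raw_score = np.log2(global_ratio)
    pos = positions.reindex(keep)
    model = fit_position_bias(pos, raw_score, span=span)
    corrected = pd.Series(correct_scores(pos, raw_score, model), index=keep)
    exon = exon.reindex(keep) if exon is not None else pd.Series("exon", index=keep)
    score = normalize_across_exons(corrected, exon, consequence.reindex(keep))
    controls = controls_all.reindex(keep.intersection(controls_all.index)).dropna()
    gmm = fit_gmm(score.loc[controls.index], controls)
    posterior = pd.Series(posterior_pathogenic(gmm, score), index=keep,
                          name="posterior")
    category = pd.Series(categorize_gmm(posterior), index=keep, name="category")
    sens, spec, confusion = compute_sensitivity_specificity(
        category.loc[controls.index], controls)
    lr_plus, lr_minus = compute_likelihood_ratios(sens, spec)
    roc, auc = compute_roc_auc(posterior.loc[controls.index], controls)
    odds = compute_oddspath(
        int((controls == "non_functional").sum()), len(controls),
        int((category == "pathogenic").sum()),
        int((category == "benign").sum()),
    )
    return {
        "freq": freq,
        "fs": fs,
        "filter_report": report,
        "raw_score": raw_score,
        "bias_model": model,
        "corrected": corrected,
        "score": score,
        "controls": controls,
        "gmm": gmm,
        "posterior": posterior,
        "category": category,
        "metrics": {
            "sensitivity": sens,
            "specificity": spec,
            "lr_plus": lr_plus,
            "lr_minus": lr_minus,
            "auc": auc,
            "confusion": confusion,
            "oddspath": odds,
        },
        "roc": roc,
    }


def classification_performance(category: pd.Series, true_class: pd.Series,
                               positive: str, negative: str) -> dict:
    """Sensitivity/specificity of three-way calls against ground truth,
    over non-hypomorph variants; intermediates count as errors."""
    tc = true_class.reindex(category.index)
    scored = tc[tc != "hypomorph"].index
    pos = tc.loc[scored] == "non_functional"
    pred_pos = category.loc[scored].isin(["non_functional", "pathogenic"])
    pred_neg = category.loc[scored].isin(["functional", "benign"])
    return {
        "sensitivity": 100.0 * float((pred_pos & pos).sum() / pos.sum()),
        "specificity": 100.0 * float((pred_neg & ~pos).sum() / (~pos).sum()),
        "n": int(len(scored)),
    }
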