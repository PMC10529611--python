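"""Probit probability-of-impact-on-function (PIF) classifier.

A linear probit regression is trained on the internal controls
(synonymous variants labelled functional = 0, nonsense labelled
non-functional = 1), with the three per-arm function scores (DMSO,
cisplatin, olaparib) as predictors.  For any variant,
``PIF = Phi(b0 + b . FS)`` is the modelled probability of being
non-functional; PIF <= 0.05 is called functional, PIF > 0.99
non-functional, anything between is intermediate.

Because the control classes are usually perfectly separated in FS space,
the unpenalized maximum-likelihood fit can diverge; when separation is
detected the model is refit with a small quadratic (ridge) penalty, which
keeps coefficients finite while preserving the sharp classification.
Uncertainty on each PIF comes from refitting under small Gaussian
perturbations of the training predictors and taking percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr

PIF_FUNCTIONAL_MAX = 0.05   # closed boundary: 0.05 itself is functional
PIF_NONFUNCTIONAL_MIN = 0.99  # open boundary: must exceed 0.99
CV_CUTOFF = 0.5
RIDGE_PENALTY = 1e-4
_COEF_LIMIT = 50.0


@dataclass
class ProbitModel:
    """Fitted probit coefficients (intercept first)."""

    params: np.ndarray
    predictor_names: tuple[str, ...]
    converged: bool
    separation: bool

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> np.ndarray:
        return self.params[1:]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _plain_nll(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    Xd = np.column_stack([np.ones(len(X)), X])
    sign = np.where(y == 1, 1.0, -1.0)
    return float(-log_ndtr(sign * (Xd @ beta)).sum())


def _ridge_probit(X: np.ndarray, y: np.ndarray,
                  penalty: float = RIDGE_PENALTY) -> np.ndarray:
    """Penalized probit MLE via BFGS with analytic gradient."""
    Xd = np.column_stack([np.ones(len(X)), X])
    sign = np.where(y == 1, 1.0, -1.0)

    def nll(beta: np.ndarray) -> float:
        z = sign * (Xd @ beta)
        return -log_ndtr(z).sum() + penalty * (beta @ beta)

    def grad(beta: np.ndarray) -> np.ndarray:
        z = sign * (Xd @ beta)
        # d/dz log Phi(z) = phi(z) / Phi(z), computed in log space
        log_phi = -0.5 * z * z - 0.5 * np.log(2 * np.pi)
        ratio = np.exp(log_phi - log_ndtr(z))
        return -(Xd * (sign * ratio)[:, None]).sum(axis=0) + 2 * penalty * beta

    res = minimize(nll, np.zeros(Xd.shape[1]), jac=grad, method="BFGS",
                   options={"maxiter": 500, "gtol": 1e-8})
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError("penalized probit fit failed")
    return res.x


def fit_probit(X, y, predictor_names: Sequence[str] | None = None) -> ProbitModel:
    """Maximum-likelihood probit fit with ridge-stabilized fallback.

    ``y`` holds labels with non-functional = 1, functional = 0.  If the
    plain fit fails to converge or diverges (quasi-separation), the model
    is refit with a quadratic penalty of 1e-4 and flagged.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("training labels must contain both classes (0 and 1)")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 training examples per class")
    names = tuple(predictor_names or [f"x{i}" for i in range(X.shape[1])])
    Xd = sm.add_constant(X, has_constant="add")
    params = None
    converged = False
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is expected with clean controls and handled below
            warnings.simplefilter("ignore")
            res = sm.Probit(y, Xd).fit(disp=0, maxiter=200, warn_convergence=False)
        params = np.asarray(res.params, dtype=float)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        pass
    ridge_params = _ridge_probit(X, y)
    plain_ok = (
        params is not None
        and converged
        and np.all(np.isfinite(params))
        and np.max(np.abs(params)) <= _COEF_LIMIT
        # under (quasi-)separation the Newton fit can stall at a poor
        # stationary point; trust it only if it beats the stabilized fit
        and _plain_nll(params, X, y) <= _plain_nll(ridge_params, X, y) + 1e-8
    )
    if plain_ok:
        return ProbitModel(params, names, True, False)
    return ProbitModel(ridge_params, names, True, True)


def compute_pif(model: ProbitModel, X) -> np.ndarray:
    """PIF = Phi(intercept + X @ beta) for each row of X."""
    X = _as_matrix(X)
    if X.shape[1] != len(model.coefficients):
        raise ValueError(
            f"expected {len(model.coefficients)} predictors, got {X.shape[1]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("missing or non-finite predictor values")
    return ndtr(model.intercept + X @ model.coefficients)


def categorize_pif(pif) -> np.ndarray:
    """Three-way call: <=0.05 functional, >0.99 non-functional, else intermediate."""
    p = np.atleast_1d(np.asarray(pif, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("PIF values must lie in [0, 1]")
    out = np.where(
        p <= PIF_FUNCTIONAL_MAX,
        "functional",
        np.where(p > PIF_NONFUNCTIONAL_MIN, "non_functional", "intermediate"),
    )
    return out


@dataclass
class CvReport:
    """K-fold cross-validation metrics (percent scale)."""

    k: int
    seed: int
    fold_accuracy: list[float]
    accuracy: float
    sensitivity: float
    specificity: float


def kfold_cv(X, y, k: int, seed: int = 0) -> CvReport:
    """Random (unstratified) K-fold cross-validation at the 0.5 cutoff.

    Folds differ in size by at most one.  Accuracy is the unweighted mean
    of per-fold accuracies; sensitivity (non-functional recalled) and
    specificity (functional recalled) are averaged over the folds where
    the respective class appears.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError(f"K must be between 2 and n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    accs, senss, specs = [], [], []
    for fold in folds:
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        model = fit_probit(X[~mask], y[~mask])
        pred = (compute_pif(model, X[mask]) > CV_CUTOFF).astype(float)
        truth = y[mask]
        accs.append(float((pred == truth).mean()))
        if (truth == 1).any():
            senss.append(float((pred[truth == 1] == 1).mean()))
        if (truth == 0).any():
            specs.append(float((pred[truth == 0] == 0).mean()))
    return CvReport(
        k=k,
        seed=seed,
        fold_accuracy=[100 * a for a in accs],
        accuracy=100 * float(np.mean(accs)),
        sensitivity=100 * float(np.mean(senss)) if senss else float("nan"),
        specificity=100 * float(np.mean(specs)) if specs else float("nan"),
    )


def model_fit_accuracy(model: ProbitModel, X, y) -> float:
    """Percent of training labels recovered at the 0.5 cutoff."""
    pred = (compute_pif(model, X) > CV_CUTOFF).astype(float)
    return 100.0 * float((pred == np.asarray(y, dtype=float)).mean())


def pif_confidence_intervals(
    X_train,
    y_train,
    X_full,
    n_sims: int = 10_000,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile 95% CIs for every PIF under training-set perturbation.

    Each simulation adds independent Normal(0, ``noise_sd``) noise to every
    training predictor value (never to the full-table predictors), refits
    the (ridge-stabilized) probit, and recomputes all PIFs; the 2.5th and
    97.5th percentiles over simulations form the interval.  Failed refits
    are skipped; more than 1% failures raises a warning.
    """
    X_train = _as_matrix(X_train)
    X_full = _as_matrix(X_full)
    y_train = np.asarray(y_train, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, len(X_full)))
    failures = 0
    kept = 0
    for s in range(n_sims):
        Xp = X_train + rng.normal(0.0, noise_sd, X_train.shape)
        try:
            params = _ridge_probit(Xp, y_train)
        except RuntimeError:
            failures += 1
            continue
        sims[kept] = ndtr(params[0] + X_full @ params[1:])
        kept += 1
    if failures > 0.01 * n_sims:
        import warnings

        warnings.warn(f"{failures}/{n_sims} perturbation refits failed")
    lo, hi = np.percentile(sims[:kept], [2.5, 97.5], axis=0)
    return pd.DataFrame({"ci_low": lo, "ci_high": hi})


def one_variable_models(
    X_train, y_train, X_full, predictor_names: Sequence[str] | None = None
) -> dict[str, dict]:
    """One-predictor probit models, one per FS column.

    Returns, per predictor, the fitted model, the full-table PIFs and
    categories, and the model-fit (training) accuracy in percent.
    """
    X_train = _as_matrix(X_train)
    X_full = _as_matrix(X_full)
    names = list(predictor_names or [f"x{i}" for i in range(X_train.shape[1])])
    out: dict[str, dict] = {}
    for j, name in enumerate(names):
        model = fit_probit(X_train[:, [j]], y_train, predictor_names=[name])
        pif = compute_pif(model, X_full[:, [j]])
        out[name] = {
            "model": model,
            "pif": pif,
            "category": categorize_pif(pif),
            "accuracy": model_fit_accuracy(model, X_train[:, [j]], y_train),
        }
    return out
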