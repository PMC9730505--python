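"""Lasso-penalized Cox selection of TcEMMs with post-selection inference.

The selection model maximizes the Cox partial log-likelihood (Breslow ties)
minus an L1 penalty on the mismatch indicator coefficients; clinical and
recipient-DRB1 covariates are unpenalized (penalty factor 0) and binary
mismatch columns are not standardized, so every mismatch faces the same
penalty. The penalty weight is chosen by event-stratified 10-fold
cross-validation minimizing held-out partial-likelihood deviance. The
coordinate-descent path is computed by scikit-survival's Coxnet; the CV
fold loop, KKT verification and inference are in-package.

Post-selection inference defaults to sample splitting: selection is re-run
on a random half of the cohort, and an unpenalized Cox model with the
selected mismatches plus all unpenalized covariates is fit on the held-out
half, giving valid Wald confidence intervals. A ``naive`` mode refits on
the full data and is reported with a validity warning.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)

__all__ = [
    "LassoPath",
    "SelectionResult",
    "breslow_partial_loglik",
    "breslow_gradient",
    "fit_cox_lasso",
    "cv_select_lambda",
    "posi_inference",
    "check_kkt",
    "CoxLassoSelector",
    "selection_summary",
]


def _rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    )


# --- Breslow partial likelihood (used for CV deviance and KKT checks) -------

def _breslow_parts(time, event, eta):
    order = np.argsort(-time, kind="mergesort")  # descending time
    t, d, e = time[order], event[order], eta[order]
    r = np.exp(e - e.max())
    cum = np.cumsum(r)  # risk-set sums (descending order => cumulative)
    # ties: every member of a tie block shares the full block's risk set
    denom = cum.copy()
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        denom[i : j + 1] = cum[j]
        i = j + 1
    return order, t, d, e, r, denom, e.max()


def breslow_partial_loglik(time, event, eta) -> float:
    """Cox partial log-likelihood with Breslow handling of ties."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    eta = np.asarray(eta, float)
    if not event.any():
        return 0.0
    _, t, d, e, r, denom, emax = _breslow_parts(time, event, eta)
    return float(np.sum(e[d] - (np.log(denom[d]) + emax)))


def breslow_gradient(time, event, X, beta) -> np.ndarray:
    """Gradient of the Breslow partial log-likelihood at ``beta``."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    X = np.asarray(X, float)
    eta = X @ beta
    order, t, d, e, r, denom, _ = _breslow_parts(time, event, eta)
    Xs = X[order]
    num = np.cumsum(Xs * r[:, None], axis=0)
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        num[i : j + 1] = num[j]
        i = j + 1
    expected = num[d] / denom[d, None]
    return (Xs[d] - expected).sum(axis=0)


@dataclass
class LassoPath:
    """Cross-validated coefficient path for the penalized Cox model."""

    lambdas: np.ndarray  # decreasing grid
    coefficients: np.ndarray  # (n_features, n_lambdas), full-data fit
    feature_names: List[str]
    cv_mean: np.ndarray  # mean 10-fold partial-likelihood deviance per lambda
    cv_se: np.ndarray
    lambda_min: float

    @property
    def lambda_min_index(self) -> int:
        return int(np.argmin(np.abs(self.lambdas - self.lambda_min)))

    def selected_at(self, lam: float, penalty_flags: np.ndarray) -> List[str]:
        j = int(np.argmin(np.abs(self.lambdas - lam)))
        nz = np.flatnonzero((np.abs(self.coefficients[:, j]) > 0) & penalty_flags)
        return [self.feature_names[k] for k in nz]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lambdas, "cv_mean_deviance": self.cv_mean, "cv_se": self.cv_se}
        )


def _coxnet(alphas, penalty_factor, tol=1e-7):
    return CoxnetSurvivalAnalysis(
        alphas=alphas,
        penalty_factor=penalty_factor,
        l1_ratio=1.0,
        normalize=False,
        tol=tol,
        max_iter=200000,
        fit_baseline_model=False,
    )


def _lam_max(time, event, X: np.ndarray, pf: np.ndarray, y) -> float:
    """Smallest penalty weight at which every penalized coefficient is zero.

    Computed from the KKT condition at the unpenalized-covariates-only
    solution: activation of coordinate j occurs when |g_j|/n reaches
    lam * n_features / n_penalized (the coordinate solver rescales the 0/1
    penalty factors to sum to n_features).
    """
    pen = pf > 0
    huge = _coxnet(alphas=[1e9], penalty_factor=pf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        huge.fit(X, y)
    beta0 = huge.coef_[:, -1]
    g = breslow_gradient(time, np.asarray(event, bool), X, beta0) / X.shape[0]
    scale = len(pf) / max(pen.sum(), 1)
    return float(np.abs(g[pen]).max() / scale) if pen.any() else 0.0


def _fit_explicit_path(time, event, X, pf, alphas, y):
    """Coxnet fit over a requested alpha grid, robust to grid points above
    the data's own lam_max (the solver returns spuriously empty models when
    an explicit path *starts* above lam_max, so the path is anchored there).
    Returns (fitted_alphas, coef_matrix)."""
    alphas = np.sort(np.asarray(alphas, float))[::-1]
    lmax = _lam_max(time, event, X, pf, y)
    path = [lmax * 0.9999] + [a for a in alphas if a < lmax * 0.9999]
    model = None
    while path:
        try:
            model = _coxnet(alphas=path, penalty_factor=pf)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, y)
            break
        except ArithmeticError:
            # the low end of the path diverges (p >> n); drop it and retry
            cut = max(1, len(path) // 4)
            path = path[:-cut]
            model = None
    if model is None:
        raise RuntimeError("penalized Cox path failed to converge at any penalty")
    fitted = np.asarray(model.alphas_)
    coefs = np.empty((X.shape[1], len(alphas)))
    at_lmax = model.coef_[:, 0].copy()
    at_lmax[pf > 0] = 0.0  # exactly zero penalized coefficients above lam_max
    lo = fitted.min()
    for j, a in enumerate(alphas):
        if a >= lmax * 0.9999:
            coefs[:, j] = at_lmax
        elif a < lo * 0.999:
            coefs[:, j] = np.nan  # diverged, dropped from the path
        else:
            coefs[:, j] = model.coef_[:, int(np.argmin(np.abs(fitted - a)))]
    return alphas, coefs


def fit_cox_lasso(
    time,
    event,
    design: pd.DataFrame,
    penalty_flags: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Coefficients of the L1-penalized Cox model at one penalty weight.

    ``penalty_flags`` marks the penalized (TcEMM) columns; flagged-off
    columns (clinical, DRB1) are unpenalized. Fit along a warm-start path
    from the data's lam_max down to ``lam``; the solution at ``lam`` is
    returned.
    """
    X = design.to_numpy(float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    pf = np.where(np.asarray(penalty_flags, bool), 1.0, 0.0)
    lam = float(lam)
    if lam <= 0:
        lam = 1e-9
    lmax = _lam_max(time, event, X, pf, y)
    if lam >= lmax:
        grid = np.array([lam])
    else:
        grid = np.geomspace(lmax * 0.999, lam, 10)
    _, coefs = _fit_explicit_path(time, event, X, pf, grid, y)
    beta = coefs[:, -1].copy()
    if np.any(np.isnan(beta)):
        valid = np.flatnonzero(~np.isnan(coefs).any(axis=0))
        if len(valid) == 0:
            raise RuntimeError("penalized Cox fit diverged at every penalty")
        logger.warning("fit diverged at lam=%g; returning smallest converged penalty", lam)
        beta = coefs[:, valid[-1]].copy()
    return beta


def _stratified_folds(event: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment with events spread evenly across folds."""
    rng = _rng(seed, "cv_folds")
    fold = np.empty(len(event), int)
    for mask in (event.astype(bool), ~event.astype(bool)):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def cv_select_lambda(
    time,
    event,
    design: pd.DataFrame,
    penalty_flags: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 100,
    alpha_min_ratio: float = 0.01,
) -> LassoPath:
    """Choose the penalty weight by k-fold cross-validated partial-likelihood deviance.

    Folds are event-stratified and deterministic given ``seed``. The
    held-out deviance for a fold is -2 x the Breslow partial log-likelihood
    of the fold's own data at the training-fit coefficients.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < n_folds:
        raise ValueError("need at least one event per fold")
    X = design.to_numpy(float)
    names = list(design.columns)
    pf = np.where(np.asarray(penalty_flags, bool), 1.0, 0.0)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    ratio = alpha_min_ratio
    full = None
    for _ in range(5):
        try:
            full = CoxnetSurvivalAnalysis(
                n_alphas=n_alphas, alpha_min_ratio=ratio, penalty_factor=pf,
                l1_ratio=1.0, normalize=False, tol=1e-7, max_iter=200000,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full.fit(X, y)
            break
        except ArithmeticError:
            ratio = min(ratio * 5.0, 0.9)  # shorten the path; low end diverges
            full = None
    if full is None:
        raise RuntimeError("penalized Cox path failed to converge")
    alphas = np.asarray(full.alphas_)
    coefs = full.coef_.copy()

    folds = _stratified_folds(event, n_folds, seed)
    dev = np.full((n_folds, len(alphas)), np.nan)
    for k in range(n_folds):
        tr, te = folds != k, folds == k
        if event[te].sum() == 0:
            raise RuntimeError("a fold has no events despite stratification")
        y_tr = Surv.from_arrays(event=event[tr].astype(bool), time=time[tr])
        grid, coefs_k = _fit_explicit_path(time[tr], event[tr], X[tr], pf, alphas, y_tr)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(grid - a)))
            if np.isnan(coefs_k[:, jj]).any():
                continue
            eta_te = X[te] @ coefs_k[:, jj]
            dev[k, j] = -2.0 * breslow_partial_loglik(time[te], event[te], eta_te)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_mean = np.nanmean(dev, axis=0)
        cv_se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(dev), axis=0).clip(1))
    usable = np.isfinite(cv_mean)
    if not usable.any():
        raise RuntimeError("cross-validation produced no usable penalty")
    lam_min = float(alphas[np.flatnonzero(usable)[np.argmin(cv_mean[usable])]])
    return LassoPath(
        lambdas=alphas,
        coefficients=coefs,
        feature_names=names,
        cv_mean=cv_mean,
        cv_se=cv_se,
        lambda_min=lam_min,
    )


def check_kkt(
    time, event, design: pd.DataFrame, penalty_flags, beta: np.ndarray, lam: float,
    tol: float = 0.02,
) -> bool:
    """Verify the KKT conditions of the penalized Cox objective at ``beta``.

    Convention (glmnet-style): the objective is (1/n) x Breslow partial
    log-likelihood minus lam_eff * sum of penalized |beta_j|, where the
    0/1 penalty factors are rescaled to sum to the number of features, so
    lam_eff = lam * n_features / n_penalized. For penalized coordinates the
    scaled score must satisfy |g_j| <= lam_eff (+tol) at zero coefficients
    and g_j = lam_eff * sign(beta_j) (+-tol) at active ones; unpenalized
    coordinates must have g_j ~ 0.
    """
    X = design.to_numpy(float)
    n = X.shape[0]
    g = breslow_gradient(np.asarray(time, float), np.asarray(event, int), X, beta) / n
    pen = np.asarray(penalty_flags, bool)
    lam_eff = lam * len(pen) / max(pen.sum(), 1)
    slack = tol * lam_eff + 1e-8  # tolerance relative to the penalty level
    ok = True
    for j in range(X.shape[1]):
        if not pen[j]:
            ok &= abs(g[j]) <= slack
        elif beta[j] == 0:
            ok &= abs(g[j]) <= lam_eff + slack
        else:
            ok &= abs(g[j] - lam_eff * np.sign(beta[j])) <= slack
    return bool(ok)


@dataclass
class SelectionResult:
    """Lasso-selected mismatches with post-selection inference."""

    selected: List[str]
    table: pd.DataFrame  # tcemm, hr, ci_lo, ci_hi, p, posi_significant
    method: str

    @property
    def posi_significant(self) -> List[str]:
        if self.table.empty:
            return []
        return list(self.table.loc[self.table["posi_significant"], "tcemm"])


def _cox_refit(
    time, event, design: pd.DataFrame, features: Sequence[str], unpen_cols: Sequence[str]
) -> pd.DataFrame:
    cols = list(features) + [c for c in unpen_cols if c not in features]
    df = design[cols].copy()
    df = df.loc[:, df.nunique() > 1]
    # linkage disequilibrium can make selected mismatch columns identical on
    # a half-sample; keep the first of each duplicate group
    seen: Dict[bytes, str] = {}
    drop = []
    for c in df.columns:
        key = df[c].to_numpy(float).tobytes()
        if key in seen:
            drop.append(c)
            logger.info("refit: dropping %s (duplicate of %s)", c, seen[key])
        else:
            seen[key] = c
    df = df.drop(columns=drop)
    kept = [f for f in features if f in df.columns]
    df["time"] = np.asarray(time, float)
    df["event"] = np.asarray(event, int)
    cph = None
    for penalizer in (1e-8, 1e-3, 1e-1):
        try:
            cph = CoxPHFitter(penalizer=penalizer).fit(df, "time", "event")
            break
        except Exception as exc:  # noqa: BLE001 - lifelines ConvergenceError etc.
            logger.warning("Cox refit failed at penalizer=%g: %s", penalizer, exc)
    if cph is None:
        raise RuntimeError("post-selection Cox refit failed to converge")
    s = cph.summary
    rows = []
    for f in kept:
        rows.append(
            {
                "tcemm": f,
                "hr": float(np.exp(s.loc[f, "coef"])),
                "ci_lo": float(np.exp(s.loc[f, "coef lower 95%"])),
                "ci_hi": float(np.exp(s.loc[f, "coef upper 95%"])),
                "p": float(s.loc[f, "p"]),
            }
        )
    out = pd.DataFrame(rows, columns=["tcemm", "hr", "ci_lo", "ci_hi", "p"])
    out["posi_significant"] = (out["ci_lo"] > 1.0) | (out["ci_hi"] < 1.0)
    return out


def posi_inference(
    time,
    event,
    design: pd.DataFrame,
    penalty_flags,
    selection: Optional[Set[str]] = None,
    method: str = "split",
    seed: int = 0,
    n_folds: int = 10,
    n_alphas: int = 100,
    reselect: bool = True,
) -> SelectionResult:
    """Post-selection inference for Lasso-selected mismatches.

    ``split``: selection is re-run (CV Lasso) on a random event-stratified
    half; an unpenalized Cox model with the selected mismatches + all
    unpenalized covariates is fit on the held-out half (valid Wald CIs).
    With ``reselect=False`` the provided ``selection`` is used as-is on the
    held-out half (for validity experiments with a fixed feature set).
    ``naive``: the provided ``selection`` is refit on the full data; the
    intervals do not account for selection and are flagged accordingly.
    """
    if method not in ("split", "naive"):
        raise ValueError("method must be 'split' or 'naive'")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    pen = np.asarray(penalty_flags, bool)
    unpen_cols = [c for c, f in zip(design.columns, pen) if not f]

    if method == "naive":
        if selection is None:
            raise ValueError("naive method requires an explicit selection")
        sel = sorted(selection)
        warnings.warn(
            "naive post-selection refit: intervals ignore the selection step",
            UserWarning,
            stacklevel=2,
        )
        if not sel:
            return SelectionResult(selected=[], table=pd.DataFrame(
                columns=["tcemm", "hr", "ci_lo", "ci_hi", "p", "posi_significant"]), method=method)
        table = _cox_refit(time, event, design, sel, unpen_cols)
        return SelectionResult(selected=sel, table=table, method=method)

    half = _stratified_folds(event, 2, seed ^ 0x5EED)
    a, b = half == 0, half == 1
    if reselect:
        path = cv_select_lambda(
            time[a], event[a], design.iloc[np.flatnonzero(a)].reset_index(drop=True),
            pen, n_folds=n_folds, seed=seed, n_alphas=n_alphas,
        )
        sel = path.selected_at(path.lambda_min, pen)
    else:
        if selection is None:
            raise ValueError("reselect=False requires an explicit selection")
        sel = sorted(selection)
    if not sel:
        return SelectionResult(selected=[], table=pd.DataFrame(
            columns=["tcemm", "hr", "ci_lo", "ci_hi", "p", "posi_significant"]), method=method)
    n_events_b = int(event[b].sum())
    if len(sel) > n_events_b / 10:
        warnings.warn(
            f"{len(sel)} selected mismatches vs {n_events_b} held-out events: "
            "refit may be unstable",
            UserWarning,
            stacklevel=2,
        )
    design_b = design.iloc[np.flatnonzero(b)].reset_index(drop=True)
    table = _cox_refit(time[b], event[b], design_b, sel, unpen_cols)
    return SelectionResult(selected=sel, table=table, method=method)


class CoxLassoSelector(BaseEstimator):
    """Lasso-Cox mismatch selector with CV penalty choice and inference.

    sklearn-style estimator. ``fit(X, y)`` takes a DataFrame whose columns
    are binary TcEMM indicators plus unpenalized covariates
    (``unpenalized_cols``) and a scikit-survival structured array ``y``.

    Fitted attributes: ``path_`` (LassoPath), ``lambda_min_``,
    ``selected_`` (nonzero penalized coefficients at lambda_min),
    ``result_`` (SelectionResult with post-selection inference) and
    ``kkt_ok_``.
    """

    def __init__(
        self,
        unpenalized_cols: Sequence[str] = (),
        n_folds: int = 10,
        seed: int = 0,
        posi_method: str = "split",
        n_alphas: int = 100,
        alpha_min_ratio: float = 0.01,
        run_posi: bool = True,
    ):
        self.unpenalized_cols = unpenalized_cols
        self.n_folds = n_folds
        self.seed = seed
        self.posi_method = posi_method
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.run_posi = run_posi

    def fit(self, X: pd.DataFrame, y) -> "CoxLassoSelector":
        event = np.asarray(y["event"], int)
        time = np.asarray(y["time"], float)
        pen = np.array([c not in set(self.unpenalized_cols) for c in X.columns])
        self.penalty_flags_ = pen
        self.path_ = cv_select_lambda(
            time, event, X, pen,
            n_folds=self.n_folds, seed=self.seed,
            n_alphas=self.n_alphas, alpha_min_ratio=self.alpha_min_ratio,
        )
        self.lambda_min_ = self.path_.lambda_min
        self.selected_ = self.path_.selected_at(self.lambda_min_, pen)
        j = self.path_.lambda_min_index
        self.kkt_ok_ = check_kkt(
            time, event, X, pen, self.path_.coefficients[:, j], self.lambda_min_
        )
        if not self.kkt_ok_:
            logger.warning("KKT conditions not satisfied at lambda_min within tolerance")
        if self.run_posi:
            self.result_ = posi_inference(
                time, event, X, pen,
                selection=set(self.selected_),
                method=self.posi_method,
                seed=self.seed,
                n_folds=self.n_folds,
                n_alphas=self.n_alphas,
            )
        return self


def selection_summary(
    result: SelectionResult, class_origin: Dict[str, frozenset]
) -> Dict[str, int]:
    """Counts of selected / posi-significant mismatches by HLA class of origin."""
    def count(cores, cls):
        return sum(1 for c in cores if cls in class_origin.get(c, frozenset()))

    sel, sig = result.selected, result.posi_significant
    return {
        "n_selected": len(sel),
        "n_selected_classI": count(sel, "I"),
        "n_selected_classII": count(sel, "II"),
        "n_significant": len(sig),
        "n_significant_classI": count(sig, "I"),
        "n_significant_classII": count(sig, "II"),
    }
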