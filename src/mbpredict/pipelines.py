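"""The three predictive strategies and their leakage-safe evaluation protocols.

* ``strategy_lasso`` — LASSO multinomial logistic regression on all
  transformed OTUs plus fixed factors (and random-factor dummies when
  requested), λ selected by CV on the training portion only;
* ``strategy_screen_glm`` — per-OTU GLMM likelihood-ratio screening on
  the training portion, then an unpenalized multinomial logistic fit
  (with a fixed tiny ridge as a separation guard) on the selected OTUs
  plus covariates;
* ``strategy_screen_lasso`` — the same screen followed by a LASSO fit
  on the selected subset;
* ``oracle_benchmark`` — the upper bound: an unpenalized fit given the
  true signal OTUs of a simulation.

Simulations use one stratified 80/20 split per replicate; user data use
external cross-validation, in which screening, λ selection and
standardization are all re-done inside each training fold, so nothing
about a held-out sample ever informs its own prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_filters import OTUTable, SampleCovariates
from .lasso import (
    cv_select_lambda,
    fit_lasso_mlr,
    fit_mlr_ridge,
    lambda_grid,
    predict_proba,
)
from .metrics import argmax_predict, report
from .screening import screen_all, select_otus
from .transforms import apply_design, build_design, transform_counts


@dataclass
class PredictionResult:
    """Out-of-sample predictions of one strategy run."""

    proba: np.ndarray  # rows align with the evaluated (test / all) samples
    yhat: np.ndarray
    y_true: np.ndarray
    classes: np.ndarray
    strategy: str
    selected_otus: list[np.ndarray] = field(default_factory=list)
    selected_lambda: float | None = None
    n_otus_in_model: int | None = None

    def metrics(self, positive_class=None):
        return report(self.proba, self.y_true, self.classes, positive_class=positive_class)


def split_train_test(n: int, train_frac: float, stratify_labels, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split; disjoint, exhaustive."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    y = np.asarray(stratify_labels)
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        k = int(round(train_frac * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _design_pair(table, covs, train_idx, test_idx, otu_subset, transform, include_random):
    """Training design + consistently-encoded test rows, training stats only."""
    sub = table.take_taxa(otu_subset) if otu_subset is not None else table
    zt = transform_counts(sub, transform)
    design = build_design(zt[train_idx], covs.take(train_idx), include_random=include_random,
                         standardize=True, taxon_ids=sub.taxon_ids)
    X_test = apply_design(design, zt[test_idx], covs.take(test_idx),
                          include_random=include_random, taxon_ids=sub.taxon_ids)
    return design, X_test


def _majority_col(y_train, classes):
    counts = [(y_train == c).sum() for c in classes]
    return int(np.argmax(counts))


def strategy_lasso(
    table: OTUTable,
    covs: SampleCovariates,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    transform: str = "asin",
    include_random: bool = True,
    cv_scheme: str = "kfold",
    cv_k: int = 10,
    n_lambda: int = 200,
    seed: int = 0,
) -> PredictionResult:
    """Strategy 1: LASSO-MLR on all transformed OTUs + covariates."""
    y = np.asarray(covs.phenotype)
    classes = np.unique(y[train_idx])
    design, X_test = _design_pair(table, covs, train_idx, test_idx, None, transform, include_random)
    X_tr = design.values
    pen = design.penalized_mask
    grid = lambda_grid(X_tr, y[train_idx], n_lambda=n_lambda, penalized=pen)
    lam, cv_er = cv_select_lambda(X_tr, y[train_idx], grid, scheme=cv_scheme, k=cv_k,
                                  seed=seed, penalized=pen)
    coef, _ = fit_lasso_mlr(X_tr, y[train_idx], lam, penalized=pen, classes=classes)
    proba = predict_proba(coef, X_test)
    yhat = argmax_predict(proba, classes, majority_first=_majority_col(y[train_idx], classes))
    otu_cols = design.columns_with_role("otu")
    active = otu_cols[(coef[:, otu_cols] != 0).any(axis=0)]
    # otu columns start right after the intercept, so column index - 1 = OTU index
    active_otus = active - 1
    return PredictionResult(proba, yhat, y[test_idx], classes, "lasso",
                            selected_otus=[active_otus], selected_lambda=lam,
                            n_otus_in_model=int(active_otus.size))


def strategy_screen_glm(
    table: OTUTable,
    covs: SampleCovariates,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    model: str = "tpnb",
    q_cutoff: float = 0.05,
    transform: str = "asin",
    include_random: bool = True,
    screening=None,
) -> PredictionResult:
    """Strategy 2: train-only screening, then an unpenalized GLM on the selection.

    ``screening`` can supply a precomputed train-only ScreeningResult
    (for studies that share the screen across strategies); it must have
    been computed on exactly ``train_idx``.
    """
    y = np.asarray(covs.phenotype)
    classes = np.unique(y[train_idx])
    if screening is None:
        screening = screen_all(table.take_samples(train_idx), covs.take(train_idx),
                               model=model, include_random=include_random)
    sel = select_otus(screening, q_cutoff)
    subset = sel if sel.size else None
    design, X_test = _design_pair(table, covs, train_idx, test_idx, subset, transform, include_random)
    if subset is None:  # fallback: covariates-only GLM
        keep = design.columns_with_role("otu")
        mask = np.ones(design.n_columns, dtype=bool)
        mask[keep] = False
        X_tr, X_te = design.values[:, mask], X_test[:, mask]
    else:
        X_tr, X_te = design.values, X_test
    coef = fit_mlr_ridge(X_tr, y[train_idx], ridge=1e-6, classes=classes)
    proba = predict_proba(coef, X_te)
    yhat = argmax_predict(proba, classes, majority_first=_majority_col(y[train_idx], classes))
    return PredictionResult(proba, yhat, y[test_idx], classes, f"{model}+glm",
                            selected_otus=[sel], n_otus_in_model=int(sel.size))


def strategy_screen_lasso(
    table: OTUTable,
    covs: SampleCovariates,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    model: str = "tpnb",
    q_cutoff: float = 0.05,
    transform: str = "asin",
    include_random: bool = True,
    cv_scheme: str = "kfold",
    cv_k: int = 10,
    n_lambda: int = 200,
    seed: int = 0,
    screening=None,
) -> PredictionResult:
    """Strategy 3: train-only screening, then LASSO-MLR on the selection."""
    y = np.asarray(covs.phenotype)
    classes = np.unique(y[train_idx])
    if screening is None:
        screening = screen_all(table.take_samples(train_idx), covs.take(train_idx),
                               model=model, include_random=include_random)
    sel = select_otus(screening, q_cutoff)
    subset = sel if sel.size else None
    design, X_test = _design_pair(table, covs, train_idx, test_idx, subset, transform, include_random)
    if subset is None:  # covariates-only LASSO
        keep = design.columns_with_role("otu")
        mask = np.ones(design.n_columns, dtype=bool)
        mask[keep] = False
        X_tr, X_te = design.values[:, mask], X_test[:, mask]
        pen = design.penalized_mask[mask]
    else:
        X_tr, X_te = design.values, X_test
        pen = design.penalized_mask
    grid = lambda_grid(X_tr, y[train_idx], n_lambda=n_lambda, penalized=pen)
    lam, _ = cv_select_lambda(X_tr, y[train_idx], grid, scheme=cv_scheme, k=cv_k,
                              seed=seed, penalized=pen)
    coef, _ = fit_lasso_mlr(X_tr, y[train_idx], lam, penalized=pen, classes=classes)
    proba = predict_proba(coef, X_te)
    yhat = argmax_predict(proba, classes, majority_first=_majority_col(y[train_idx], classes))
    return PredictionResult(proba, yhat, y[test_idx], classes, f"{model}+lasso",
                            selected_otus=[sel], selected_lambda=lam, n_otus_in_model=int(sel.size))


def oracle_benchmark(
    table: OTUTable,
    covs: SampleCovariates,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    truth,
    transform: str = "asin",
    include_random: bool = True,
) -> PredictionResult:
    """Unpenalized fit on exactly the true signal OTUs + X1, X2 (+ W dummies)."""
    y = np.asarray(covs.phenotype)
    classes = np.unique(y[train_idx])
    sig = np.asarray(truth.signal_indices)
    subset = sig if sig.size else None
    design, X_test = _design_pair(table, covs, train_idx, test_idx, subset, transform, include_random)
    if subset is None:
        keep = design.columns_with_role("otu")
        mask = np.ones(design.n_columns, dtype=bool)
        mask[keep] = False
        X_tr, X_te = design.values[:, mask], X_test[:, mask]
    else:
        X_tr, X_te = design.values, X_test
    coef = fit_mlr_ridge(X_tr, y[train_idx], ridge=1e-6, classes=classes)
    proba = predict_proba(coef, X_te)
    yhat = argmax_predict(proba, classes, majority_first=_majority_col(y[train_idx], classes))
    return PredictionResult(proba, yhat, y[test_idx], classes, "oracle",
                            selected_otus=[sig], n_otus_in_model=int(sig.size))


def external_cv(
    table: OTUTable,
    covs: SampleCovariates,
    strategy,
    scheme: str = "loocv",
    k: int = 10,
    seed: int = 0,
) -> PredictionResult:
    """External cross-validation: the whole strategy re-runs per fold.

    ``strategy`` is a closure (table, covs, train_idx, test_idx) ->
    PredictionResult; out-of-fold probabilities are assembled over all
    samples, so each sample is predicted exactly once out-of-sample.
    """
    y = np.asarray(covs.phenotype)
    n = y.size
    classes = np.unique(y)
    if scheme == "loocv":
        folds = np.arange(n)
        n_folds = n
    elif scheme == "kfold":
        from .lasso import stratified_folds

        folds = stratified_folds(y, k, np.random.default_rng(seed))
        n_folds = k
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    proba = np.full((n, classes.size), np.nan)
    yhat = np.empty(n, dtype=y.dtype)
    selections = []
    failures = 0
    for f in range(n_folds):
        te = np.flatnonzero(folds == f)
        tr = np.flatnonzero(folds != f)
        try:
            res = strategy(table, covs, tr, te)
        except Exception:
            failures += 1
            continue
        cols = [int(np.flatnonzero(classes == c)[0]) for c in res.classes]
        proba[te[:, None], np.asarray(cols)[None, :]] = res.proba
        yhat[te] = res.yhat
        if res.selected_otus:
            selections.append(res.selected_otus[0])
    ok = ~np.isnan(proba).any(axis=1)
    if failures:
        import logging

        logging.getLogger(__name__).warning("external CV: %d fold(s) failed", failures)
    return PredictionResult(proba[ok], yhat[ok], y[ok], classes, "external-cv",
                            selected_otus=selections)


# ---------------------------------------------------------------------------
# simulation study driver

def screening_power_row(screening, truth, q_cutoff: float = 0.05) -> dict:
    """Per-replicate signal recovery of one screen.

    ``n_true_selected`` counts signal OTUs at q ≤ cutoff; ``power_raw``
    divides by all signals, ``power_testable`` by the signals that were
    not dropped by the zero-proportion rule (both conventions are
    reported because the printed tables are ambiguous about the
    denominator).
    """
    sig = np.asarray(truth.signal_indices)
    sel = set(select_otus(screening, q_cutoff).tolist())
    hits = sum(1 for j in sig if j in sel)
    testable = sum(1 for j in sig if screening.regime[j] != "dropped")
    return {
        "n_true_selected": hits,
        "n_selected": len(sel),
        "n_testable_signals": testable,
        "power_raw": hits / sig.size,
        "power_testable": hits / testable if testable else 0.0,
    }


def run_simulation_study(
    config,
    reps: int,
    models: tuple[str, ...] = ("tpnb",),
    transforms: tuple[str, ...] = ("asin",),
    strategies: tuple[str, ...] = ("lasso",),
    include_random: bool = True,
    with_oracle: bool = True,
    q_cutoff: float = 0.05,
    cv_k: int = 10,
    n_lambda: int = 200,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Reduced-scale regeneration of the simulation tables.

    Returns {"screening": per-model signal recovery table,
    "prediction": mean (SD) of ER/AUC/AUPRC per method × transform}.
    """
    from .synthetic import generate_dataset

    if reps < 2:
        raise ValueError("reps must be >= 2")
    screen_rows = []
    pred_rows = []
    need_screens = any(s.startswith("screen") for s in strategies)
    for r in range(reps):
        table, covs, truth = generate_dataset(config, replicate=r)
        y = np.asarray(covs.phenotype)
        tr, te = split_train_test(y.size, 0.8, y, seed=seed + 7919 * r)
        # the power table screens full replicates (as the signal-recovery
        # tables do); the strategies below re-screen on training rows only
        screens = {}
        for model in models:
            scr_full = screen_all(table, covs, model=model, include_random=include_random)
            row = screening_power_row(scr_full, truth, q_cutoff)
            row.update({"model": model, "replicate": r})
            screen_rows.append(row)
            if need_screens:
                screens[model] = screen_all(table.take_samples(tr), covs.take(tr),
                                            model=model, include_random=include_random)
        if with_oracle:
            res = oracle_benchmark(table, covs, tr, te, truth, include_random=include_random)
            m = res.metrics()
            pred_rows.append({"method": "oracle", "transform": "asin", "replicate": r,
                              "er": m.er, "auc": m.auc, "auprc": m.auprc,
                              "n_true_selected": _truth_overlap(res, truth)})
        for transform in transforms:
            for strat in strategies:
                if strat == "lasso":
                    res = strategy_lasso(table, covs, tr, te, transform=transform,
                                         include_random=include_random, cv_k=cv_k,
                                         n_lambda=n_lambda, seed=seed + r)
                    _append_pred(pred_rows, "LASSO", transform, r, res, truth)
                elif strat == "screen_glm":
                    for model in models:
                        res = strategy_screen_glm(table, covs, tr, te, model=model,
                                                  q_cutoff=q_cutoff, transform=transform,
                                                  include_random=include_random,
                                                  screening=screens[model])
                        _append_pred(pred_rows, f"{model.upper()}+GLM", transform, r, res, truth)
                elif strat == "screen_lasso":
                    for model in models:
                        res = strategy_screen_lasso(table, covs, tr, te, model=model,
                                                    q_cutoff=q_cutoff, transform=transform,
                                                    include_random=include_random, cv_k=cv_k,
                                                    n_lambda=n_lambda, seed=seed + r,
                                                    screening=screens[model])
                        _append_pred(pred_rows, f"{model.upper()}+LASSO", transform, r, res, truth)
                else:
                    raise ValueError(f"unknown strategy {strat!r}")
    screening_df = pd.DataFrame(screen_rows)
    prediction_df = pd.DataFrame(pred_rows)
    return {
        "screening": screening_df,
        "prediction": prediction_df,
        "screening_summary": _summarize(screening_df, ["model"],
                                        ["n_true_selected", "n_selected", "power_raw", "power_testable"])
        if screen_rows else pd.DataFrame(),
        "prediction_summary": _summarize(prediction_df, ["method", "transform"],
                                         ["er", "auc", "auprc", "n_true_selected"])
        if pred_rows else pd.DataFrame(),
    }


def _truth_overlap(res: PredictionResult, truth) -> int:
    if not res.selected_otus:
        return 0
    sel = set(np.asarray(res.selected_otus[0]).tolist())
    return sum(1 for j in np.asarray(truth.signal_indices) if j in sel)


def _append_pred(rows, method, transform, r, res, truth):
    m = res.metrics()
    rows.append({"method": method, "transform": transform, "replicate": r,
                 "er": m.er, "auc": m.auc, "auprc": m.auprc,
                 "n_true_selected": _truth_overlap(res, truth)})


def _summarize(df: pd.DataFrame, by: list[str], cols: list[str]) -> pd.DataFrame:
    agg = df.groupby(by)[cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()
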