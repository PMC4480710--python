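"""Response stratification and biomarker-search machinery.

Two layers live here.  The first is the headline check: after curation,
does sensitivity to MDM2 inhibition separate *perfectly* by TP53 functional
status (every wild-type line more sensitive than every mutant line)?

The second is the expression-biomarker search used to look for predictors of
residual heterogeneity among wild-type lines, built so that its negative
result is trustworthy: lines are labelled responders when their IC50 falls
in the lower quartile; expression batches are combined by per-probe-set
linear calibration on shared lines; a per-probe-set ANOVA with a tissue
factor ranks features; the single top feature feeds a ridge-penalized
logistic classifier (responder iff fitted probability > 0.5); performance is
estimated by leave-one-out cross-validation that repeats feature selection
inside every fold (no selection leakage); and significance is judged against
a permutation null that shuffles labels only within tissue, preserving
per-tissue class margins.  Mutation associations are screened per gene with
one-way ANOVA and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CvResult",
    "PermutationResult",
    "check_complete_separation",
    "categorize_response",
    "combine_expression_batches",
    "anova_feature_select",
    "logistic_predict",
    "ridge_logistic_fit",
    "loo_cross_validate",
    "permutation_percentile",
    "restrict_balanced_tissues",
    "mutation_association",
    "bh_adjust",
    "expression_association",
]


# ---------------------------------------------------------------------------
# Separation and response labels
# ---------------------------------------------------------------------------


def _ordering_ic50(ic50: np.ndarray, censored: np.ndarray) -> np.ndarray:
    vals = np.asarray(ic50, dtype=float).copy()
    vals[np.asarray(censored, dtype=bool)] = np.inf
    return vals


def check_complete_separation(curated: pd.DataFrame) -> tuple[bool, tuple[float, float]]:
    """True iff every WT IC50 is strictly below every mutant IC50.

    Censored IC50s rank at +inf.  Returns the separating interval
    (max WT IC50, min mutant IC50); raises when either class is empty.
    """
    wt = curated[curated["status"] == "WT"]
    mut = curated[curated["status"] == "MUTANT"]
    if wt.empty or mut.empty:
        raise ValidationError("complete-separation check needs both classes")
    wt_vals = _ordering_ic50(wt["ic50_um"].to_numpy(), wt["censored"].to_numpy())
    mut_vals = _ordering_ic50(mut["ic50_um"].to_numpy(), mut["censored"].to_numpy())
    hi_wt, lo_mut = float(wt_vals.max()), float(mut_vals.min())
    return hi_wt < lo_mut, (hi_wt, lo_mut)


def categorize_response(
    ic50: Sequence[float], censored: Sequence[bool] | None = None
) -> tuple[np.ndarray, float]:
    """Responder labels: IC50 at or below the lower quartile of all IC50s.

    Q1 uses the linear-interpolation quantile convention; censored values
    rank above every numeric value and are never responders (all-censored
    input yields no responders).  Returns (labels, Q1).
    """
    ic50 = np.asarray(ic50, dtype=float)
    if ic50.size < 4:
        raise ValidationError("need >= 4 lines to categorize response")
    cens = (
        np.zeros(ic50.size, dtype=bool)
        if censored is None
        else np.asarray(censored, dtype=bool)
    )
    vals = _ordering_ic50(ic50, cens)
    if not np.isfinite(vals).any():
        return np.zeros(ic50.size, dtype=bool), math.inf
    q1 = float(np.quantile(vals, 0.25))  # inf when >75% of values censored
    labels = (~cens) & (vals <= q1)
    return labels, q1


def restrict_balanced_tissues(
    labels: pd.Series, tissue: pd.Series
) -> list:
    """Line ids from tissues containing both responders and non-responders."""
    keep = []
    for t, idx in labels.groupby(tissue).groups.items():
        sub = labels.loc[idx]
        if sub.any() and not sub.all():
            keep.extend(idx)
    if not keep:
        logger.warning("no tissue has both classes; balanced subset is empty")
    return sorted(keep)


# ---------------------------------------------------------------------------
# Expression handling
# ---------------------------------------------------------------------------


def combine_expression_batches(
    batch1: pd.DataFrame, batch2: pd.DataFrame, shared_lines: Sequence[str]
) -> pd.DataFrame:
    """Merge two expression batches via per-probe-set linear calibration.

    For each probe set an intercept+slope mapping batch2 -> batch1 is fitted
    by least squares on the shared lines, then applied to the batch2-only
    lines.  Shared lines keep their batch1 values.  Matrices are probe sets
    x lines with identical probe-set indices.
    """
    shared = [l for l in shared_lines if l in batch1.columns and l in batch2.columns]
    if len(shared) < 2:
        raise ValidationError("batch combination needs >= 2 shared lines")
    if not batch1.index.equals(batch2.index):
        raise ValidationError("batches must share the probe-set index")
    x = batch2[shared].to_numpy(float)  # p x s
    y = batch1[shared].to_numpy(float)
    xm, ym = x.mean(axis=1, keepdims=True), y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 1.0)
    intercept = ym.ravel() - slope * xm.ravel()

    only2 = [l for l in batch2.columns if l not in set(shared)]
    overlap = [l for l in only2 if l in batch1.columns]
    if overlap:
        raise ValidationError(
            f"lines present in both batches must be listed as shared: {overlap}"
        )
    corrected = batch2[only2].to_numpy(float) * slope[:, None] + intercept[:, None]
    out = pd.concat(
        [batch1, pd.DataFrame(corrected, index=batch2.index, columns=only2)], axis=1
    )
    return out


def _design_matrix(
    y: np.ndarray, tissue_codes: np.ndarray
) -> tuple[np.ndarray, int]:
    """Intercept + label column + tissue dummies (first present level
    dropped); returns (X, index of the label column)."""
    cols = [np.ones_like(y, dtype=float), y.astype(float)]
    present = np.unique(tissue_codes)
    for level in present[1:]:
        cols.append((tissue_codes == level).astype(float))
    return np.column_stack(cols), 1


def _label_p_values(
    expr: np.ndarray, y: np.ndarray, tissue_codes: np.ndarray
) -> np.ndarray:
    """Two-sided p-value of the response term per probe set (rows of expr),
    from OLS of expression on label + tissue.  Constant or untestable probe
    sets get NaN."""
    X, li = _design_matrix(y, tissue_codes)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    dof = n - rank
    if dof <= 0:
        return np.full(expr.shape[0], np.nan)
    xtx_inv = np.linalg.pinv(X.T @ X)
    proj = xtx_inv @ X.T  # k x n
    B = proj @ expr.T  # k x p
    resid = expr.T - X @ B  # n x p
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / dof
    var_b = sigma2 * xtx_inv[li, li]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(var_b > 0, B[li] / np.sqrt(np.where(var_b > 0, var_b, 1.0)), np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p[~np.isfinite(t)] = np.nan
    p[expr.var(axis=1) == 0] = np.nan  # constant probe: untestable
    return p


def anova_feature_select(
    expr: pd.DataFrame, labels: pd.Series, tissue: pd.Series
) -> pd.DataFrame:
    """Rank probe sets by the response-term p-value of a two-factor
    (response + tissue-of-origin) ANOVA on expression.

    ``expr`` is probe sets x lines; ``labels`` boolean responder labels and
    ``tissue`` tissue of origin, both indexed by line.  Single-tissue input
    degrades gracefully to a one-way model.  Returns a DataFrame indexed by
    probe set, sorted ascending by p-value with deterministic probe-id
    tie-break; untestable (e.g. constant) probe sets sort last.
    """
    lines = list(labels.index)
    E = expr[lines].to_numpy(float)
    y = labels.loc[lines].to_numpy(bool).astype(float)
    tcodes = pd.Categorical(tissue.loc[lines]).codes
    p = _label_p_values(E, y, tcodes)
    out = pd.DataFrame({"p_value": p}, index=expr.index)
    out["_id"] = out.index.astype(str)
    out = out.sort_values(["p_value", "_id"], na_position="last").drop(columns="_id")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Ridge logistic classifier
# ---------------------------------------------------------------------------


def ridge_logistic_fit(
    X: np.ndarray, y: np.ndarray, lam: float = 1.0, max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Newton/IRLS fit of logistic regression with an L2 penalty
    ``lam/2 * ||beta||^2`` on all non-intercept coefficients.

    The penalty keeps the optimum finite under complete separation, which is
    routine at biomarker-search sample sizes.  ``X`` must contain the
    intercept column first.
    """
    n, k = X.shape
    pen = lam * np.eye(k)
    pen[0, 0] = 0.0
    beta = np.zeros(k)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p) - pen @ beta
        H = X.T @ (X * w[:, None]) + pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _tissue_dummy(codes: np.ndarray, levels: np.ndarray) -> np.ndarray:
    return np.column_stack([(codes == l).astype(float) for l in levels[1:]]) if (
        levels.size > 1
    ) else np.empty((codes.size, 0))


def logistic_predict(
    train_feature: Sequence[float],
    train_labels: Sequence[bool],
    train_tissue: Sequence,
    new_feature: float,
    new_tissue,
    lam: float = 1.0,
) -> tuple[bool, float]:
    """Fit the single-gene + tissue ridge logistic model and classify one
    held-out line.

    Returns (responder?, fitted probability); responder iff probability is
    strictly greater than 0.5.  A tissue unseen in training contributes only
    the intercept and gene term.
    """
    xf = np.asarray(train_feature, dtype=float)
    y = np.asarray(train_labels, dtype=bool).astype(float)
    if np.unique(y).size < 2:
        raise ValidationError("training data must contain both classes")
    t = np.asarray(train_tissue)
    levels = np.unique(t)
    codes = np.searchsorted(levels, t)
    X = np.column_stack(
        [np.ones_like(xf), xf, _tissue_dummy(codes, np.arange(levels.size))]
    )
    beta = ridge_logistic_fit(X, y, lam=lam)
    if new_tissue in levels:
        ncode = int(np.searchsorted(levels, new_tissue))
        ndum = _tissue_dummy(np.array([ncode]), np.arange(levels.size))
    else:
        ndum = np.zeros((1, max(levels.size - 1, 0)))
    xnew = np.concatenate([[1.0, float(new_feature)], ndum.ravel()])
    prob = float(expit(xnew @ beta))
    return prob > 0.5, prob


# ---------------------------------------------------------------------------
# Cross-validation and permutation null
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    percent_correct: float
    predictions: pd.Series  # per left-out line
    top_features: pd.Series  # feature chosen in each fold
    flagged_folds: list = field(default_factory=list)


def loo_cross_validate(
    expr: pd.DataFrame, labels: pd.Series, tissue: pd.Series, lam: float = 1.0
) -> CvResult:
    """Leave-one-out cross-validation of the full model-building process.

    For every left-out line, feature selection *and* classifier fitting are
    redone on the remaining n-1 lines, so selection bias cannot leak into
    the performance estimate.  Folds whose training labels collapse to a
    single class fall back to the majority (sole) class and are flagged.
    """
    lines = list(labels.index)
    if len(lines) < 3:
        raise ValidationError("LOO needs >= 3 lines")
    E = expr[lines].to_numpy(float)
    probes = expr.index.to_numpy()
    y = labels.loc[lines].to_numpy(bool)
    t = np.asarray(tissue.loc[lines])
    levels = np.unique(t)
    codes = np.searchsorted(levels, t)

    preds, tops, flagged = {}, {}, []
    for i, line in enumerate(lines):
        mask = np.ones(len(lines), dtype=bool)
        mask[i] = False
        ytr, ttr = y[mask], codes[mask]
        if np.unique(ytr).size < 2:
            preds[line] = bool(ytr[0])
            tops[line] = None
            flagged.append(line)
            continue
        p = _label_p_values(E[:, mask], ytr.astype(float), ttr)
        # argmin with deterministic probe-id tie-break; NaN p sorts last
        key = np.where(np.isnan(p), np.inf, p)
        pmin = key.min()
        cand = np.nonzero(key == pmin)[0]
        best = cand[np.argsort(probes[cand].astype(str))[0]]
        tops[line] = probes[best]

        xtr = E[best, mask]
        X = np.column_stack(
            [np.ones(mask.sum()), xtr, _tissue_dummy(ttr, np.arange(levels.size))]
        )
        beta = ridge_logistic_fit(X, ytr.astype(float), lam=lam)
        ndum = _tissue_dummy(np.array([codes[i]]), np.arange(levels.size))
        xnew = np.concatenate([[1.0, E[best, i]], ndum.ravel()])
        preds[line] = bool(expit(xnew @ beta) > 0.5)

    pred_s = pd.Series(preds).loc[lines]
    pct = 100.0 * float((pred_s.to_numpy() == y).mean())
    return CvResult(pct, pred_s, pd.Series(tops).loc[lines], flagged)


@dataclass
class PermutationResult:
    observed: float
    permuted: np.ndarray
    percentile: float
    tie: str


def _shuffle_within_tissue(
    y: np.ndarray, codes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = y.copy()
    for level in np.unique(codes):
        idx = np.nonzero(codes == level)[0]
        out[idx] = out[rng.permutation(idx)]
    return out


def permutation_percentile(
    expr: pd.DataFrame,
    labels: pd.Series,
    tissue: pd.Series,
    n_perm: int = 199,
    seed: int | None = None,
    lam: float = 1.0,
    tie: str = "mid",
) -> PermutationResult:
    """Percentile of the observed LOO accuracy within a stratified
    permutation null.

    Labels are shuffled only within tissue strata (singleton strata stay
    fixed), preserving per-tissue responder counts exactly, and the full LOO
    procedure is rerun per permutation.  ``tie='mid'`` (default) counts ties
    between permuted and observed results as half, which keeps the null
    percentile distribution calibrated for the discrete accuracy statistic;
    ``tie='strict'`` counts only strictly smaller permuted results.
    """
    if n_perm < 19:
        raise ValidationError("n_perm must be >= 19")
    rng = np.random.default_rng(seed)
    lines = list(labels.index)
    y = labels.loc[lines].to_numpy(bool)
    t = np.asarray(tissue.loc[lines])
    codes = np.searchsorted(np.unique(t), t)
    if any((codes == l).sum() == 1 for l in np.unique(codes)):
        logger.info("tissue stratum of size 1: its label is unshufflable")

    observed = loo_cross_validate(expr, labels, tissue, lam=lam).percent_correct
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        yb = _shuffle_within_tissue(y, codes, rng)
        lb = pd.Series(yb, index=lines)
        permuted[b] = loo_cross_validate(expr, lb, tissue, lam=lam).percent_correct
    if tie == "mid":
        score = (permuted < observed).sum() + 0.5 * (permuted == observed).sum()
    elif tie == "strict":
        score = float((permuted < observed).sum())
    else:
        raise ValidationError(f"unknown tie rule {tie!r}")
    return PermutationResult(observed, permuted, 100.0 * score / n_perm, tie)


# ---------------------------------------------------------------------------
# Association screens
# ---------------------------------------------------------------------------


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mutation_association(
    response_metric: pd.Series, mutation_matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene one-way ANOVA of a response metric on mutation status.

    ``mutation_matrix`` is lines x genes, binary.  Genes with at least one
    mutant line are tested; genes mutated in every line (zero variance) are
    dropped with a log message.  Returns gene, n_mutant, p_value and
    BH-adjusted q_value across the retained genes.
    """
    lines = response_metric.index
    rows = []
    for gene in mutation_matrix.columns:
        m = mutation_matrix.loc[lines, gene].astype(bool)
        if not m.any():
            continue
        if m.all():
            logger.info("gene %s mutated in all lines; dropped", gene)
            continue
        grp_mut = response_metric[m].to_numpy(float)
        grp_wt = response_metric[~m].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = stats.f_oneway(grp_mut, grp_wt)
        rows.append((gene, int(m.sum()), float(p)))
    out = pd.DataFrame(rows, columns=["gene", "n_mutant", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = []
    return out


def expression_association(
    response_metric: Sequence[float], expr_vector: Sequence[float]
) -> tuple[float, float]:
    """OLS slope and two-sided p-value of response metric on expression."""
    y = np.asarray(response_metric, dtype=float)
    x = np.asarray(expr_vector, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        logger.warning("zero-variance regressor; association undefined")
        return math.nan, math.nan
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)
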