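"""Tuning-parameter selection for clump-and-threshold scores.

Three criteria are supported.  The CV criterion splits the training cohort
into K (default 5) equal-sized subsets with no related individuals between
them (kinship components are assigned whole, largest first, each to the
currently smallest fold), fits the hypertension association model in each
fold, and picks the candidate minimizing the coefficient of variation
sd/mean of the K log-OR estimates — i.e. the score whose effect is
consistently high in independent data.  A candidate whose mean fold effect
is non-positive, or whose fit fails in any fold, is disqualified (CV = +inf).
The PVAL criterion picks the candidate with the smallest full-sample
association p-value.  The genome-wide-significant score uses the fixed
parameters p < 5e-8, r² = 0.1, window = 1000 kb with no selection at all.

Ties are broken deterministically: smaller p-threshold, then smaller r²,
then larger window, then fewer SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _glmm
from .assoc import build_design
from .genodata import GenotypeDataset, KinshipGraph, kinship_components
from .prs_build import (
    GWS_PARAMS,
    PRSCandidate,
    PRSValues,
    TuningParams,
    apply_threshold,
    clump,
)
from .sumstats import SumStats

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Kinship-disjoint fold membership for the training samples."""

    assignment: dict[str, int]  # sample -> fold in 1..K
    n_folds: int
    seed: int

    def fold_samples(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


@dataclass
class SelectionResult:
    """Chosen tuning parameters plus the full per-candidate report."""

    trait: str
    criterion: str  # CV | PVAL | GWS
    chosen: TuningParams
    chosen_candidate: PRSCandidate
    table: pd.DataFrame


def split_kinship_folds(
    samples: list[str],
    kinship: KinshipGraph,
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Assign kinship components whole to K folds, balancing fold sizes.

    Components are placed largest-first into the currently smallest fold;
    ties in component size are broken by a seed-shuffled order, so the
    split is reproducible.  No kinship edge ever crosses folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    comps = sorted(sorted(c) for c in kinship_components(kinship.subgraph(samples), samples))
    rng = np.random.default_rng(seed)
    rng.shuffle(comps)
    comps.sort(key=len, reverse=True)  # stable: ties stay in shuffled order

    n = len(samples)
    if comps and len(comps[0]) > n / n_folds:
        logger.warning(
            "split_kinship_folds: largest component (%d) exceeds n/K = %.1f",
            len(comps[0]), n / n_folds,
        )
    sizes = np.zeros(n_folds, dtype=int)
    assignment: dict[str, int] = {}
    for comp in comps:
        fold = int(np.argmin(sizes))
        sizes[fold] += len(comp)
        for s in comp:
            assignment[s] = fold + 1
    assert not any(
        assignment[a] != assignment[b] for a, b in kinship.subgraph(samples).edges
    ), "kinship edge crosses folds"
    return FoldAssignment(assignment=assignment, n_folds=n_folds, seed=seed)


def effect_cv(betas) -> float:
    """Coefficient of variation of per-fold log-OR estimates.

    sample sd (n-1 denominator) divided by the mean; a non-positive mean
    disqualifies the candidate (returns +inf): a score anti-associated with
    its own trait is never the intended selection.
    """
    betas = np.asarray(betas, dtype=float)
    betas = betas[np.isfinite(betas)]
    if len(betas) < 2:
        raise ValueError("effect_cv needs at least 2 finite estimates")
    mean = betas.mean()
    if mean <= 0:
        return float("inf")
    return float(betas.std(ddof=1) / mean)


_TIE_KEY_COLS = ["cv", "p_threshold", "r2_max", "neg_window", "n_snps"]


def _candidate_row(cand: PRSCandidate) -> dict:
    return {
        "trait": cand.trait,
        "p_threshold": cand.params.p_threshold,
        "r2_max": cand.params.r2_max,
        "window_kb": cand.params.window_kb,
        "neg_window": -cand.params.window_kb,
        "n_snps": cand.n_snps,
    }


def _fold_designs(outcome, covars, sample_ids, folds):
    """Pre-build per-fold design matrices with a placeholder PRS column."""
    ids = np.asarray(sample_ids)
    designs = []
    for f in range(1, folds.n_folds + 1):
        members = set(folds.fold_samples(f))
        mask = np.array([s in members for s in ids])
        sub_cov = covars.reset_index(drop=True).loc[mask].reset_index(drop=True) if covars is not None else None
        X, names, keep = build_design(sub_cov, int(mask.sum()), extra={"prs": np.zeros(int(mask.sum()))})
        y = np.asarray(outcome, dtype=float)[mask][keep]
        if len(np.unique(y)) < 2:
            raise ValueError(f"fold {f} lacks cases or controls")
        designs.append((mask, keep, X, names.index("prs"), y))
    return designs


def _fold_beta(X, j, y, prs_sub):
    X = X.copy()
    X[:, j] = prs_sub
    fit = _glmm.fit_logistic_ml(X, y)
    return float(fit.beta[j])


def select_cv_prs(
    candidates: list[PRSCandidate],
    scores: list[PRSValues],
    folds: FoldAssignment,
    outcome: np.ndarray,
    covars: pd.DataFrame | None,
    sample_ids: list[str],
) -> SelectionResult:
    """Pick the candidate minimizing the CV of per-fold log-OR estimates.

    ``scores`` are the candidates' full-cohort-standardized values aligned
    with ``sample_ids`` (the training cohort).  A fold fit that fails to
    converge disqualifies the candidate.
    """
    designs = _fold_designs(outcome, covars, sample_ids, folds)
    rows = []
    for cand, prs in zip(candidates, scores):
        row = _candidate_row(cand)
        fold_betas = []
        if cand.degenerate:
            row["cv"] = float("inf")
        else:
            z = np.asarray(prs.standardized, dtype=float)
            ok = True
            for mask, keep, X, j, y in designs:
                try:
                    fold_betas.append(_fold_beta(X, j, y, z[mask][keep]))
                except (_glmm.ConvergenceError, _glmm.SeparationError, np.linalg.LinAlgError) as exc:
                    logger.warning("fold fit failed for %s: %s", cand.params, exc)
                    ok = False
                    break
            row["cv"] = effect_cv(fold_betas) if ok else float("inf")
        for i, b in enumerate(fold_betas, start=1):
            row[f"beta_fold{i}"] = b
        rows.append(row)
    table = pd.DataFrame(rows)
    if not np.isfinite(table["cv"]).any():
        raise ValueError("all candidates are degenerate or disqualified")
    best = table.sort_values(_TIE_KEY_COLS, kind="mergesort").index[0]
    chosen = candidates[best]
    table = table.drop(columns=["neg_window"])
    return SelectionResult(
        trait=chosen.trait, criterion="CV", chosen=chosen.params, chosen_candidate=chosen, table=table
    )


def select_pval_prs(
    candidates: list[PRSCandidate],
    scores: list[PRSValues],
    outcome: np.ndarray,
    covars: pd.DataFrame | None,
    sample_ids: list[str],
) -> SelectionResult:
    """Pick the candidate with the smallest full-sample association p."""
    from scipy import stats

    n = len(sample_ids)
    X0, names, keep = build_design(covars, n, extra={"prs": np.zeros(n)})
    j = names.index("prs")
    y = np.asarray(outcome, dtype=float)[keep]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    rows = []
    for cand, prs in zip(candidates, scores):
        row = _candidate_row(cand)
        if cand.degenerate:
            row.update(pooled_beta=np.nan, pooled_p=np.nan, cv=np.nan)
            rows.append(row)
            continue
        X = X0.copy()
        X[:, j] = np.asarray(prs.standardized, dtype=float)[keep]
        try:
            fit = _glmm.fit_logistic_ml(X, y)
            z = fit.beta[j] / fit.se[j]
            row.update(pooled_beta=float(fit.beta[j]), pooled_p=float(stats.chi2.sf(z * z, df=1)))
        except (_glmm.ConvergenceError, _glmm.SeparationError, np.linalg.LinAlgError):
            row.update(pooled_beta=np.nan, pooled_p=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["pooled_p"].isna().all():
        raise ValueError("no valid candidate: all degenerate or failed")
    order_cols = ["pooled_p", "p_threshold", "r2_max", "neg_window", "n_snps"]
    best = table.sort_values(order_cols, kind="mergesort", na_position="last").index[0]
    chosen = candidates[best]
    table = table.drop(columns=["neg_window"])
    return SelectionResult(
        trait=chosen.trait, criterion="PVAL", chosen=chosen.params, chosen_candidate=chosen, table=table
    )


def gws_prs(ss: SumStats, ref: GenotypeDataset) -> PRSCandidate:
    """The genome-wide-significant score: fixed (5e-8, r²=0.1, 1000 kb)."""
    params = TuningParams(*GWS_PARAMS)
    retained = clump(ss, ref, params.r2_max, params.window_kb)
    weights = apply_threshold(ss, retained, params.p_threshold)
    return PRSCandidate(trait=ss.trait, params=params, weights=weights)
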