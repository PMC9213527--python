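"""Clump-and-threshold PRS construction, scoring, and PRSsum combination.

The score for a tuning-parameter combination (p-value threshold, clumping
r² cutoff, clumping window in kb) is built in two steps.  Clumping greedily
keeps the most significant variant in each LD neighborhood: the smallest-p
unclaimed variant becomes an index, and every unclaimed variant on the same
chromosome within the window whose dosage r² with the index exceeds the
cutoff is removed.  Thresholding then keeps clumped variants with
p < threshold, whose GWAS betas become the score weights.

Clumping is run once per (r², window) pair on all harmonized variants and
p-thresholds are applied afterwards to the clumped set — the PRSice
convention — so the default 12 x 3 x 3 grid costs nine clumping passes.

Scores are standardized with a pre-computed mean and SD (by convention the
full combined cohort), so effect sizes per 1 SD are comparable across
analysis subsets.  PRSsum combines standardized trait scores by unweighted
summation and re-standardizes the sum with its own full-cohort constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genodata import GenotypeDataset, allele_freq
from .sumstats import SumStats, VariantKey

logger = logging.getLogger(__name__)

#: p-value thresholds of the default tuning grid
P_THRESHOLDS = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 0.1, 0.2, 0.3, 0.4, 0.5)
#: clumping r² cutoffs of the default grid
R2_LEVELS = (0.1, 0.2, 0.3)
#: clumping windows (kb) of the default grid
WINDOW_KB_LEVELS = (250.0, 500.0, 1000.0)

#: fixed parameters of the genome-wide-significant score
GWS_PARAMS = (5e-8, 0.1, 1000.0)


@dataclass(frozen=True, order=True)
class TuningParams:
    """One cell of the tuning grid."""

    p_threshold: float
    r2_max: float
    window_kb: float

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not 0 < self.r2_max < 1:
            raise ValueError(f"r2_max must be in (0, 1), got {self.r2_max}")
        if not self.window_kb > 0:
            raise ValueError(f"window_kb must be positive, got {self.window_kb}")


@dataclass
class PRSCandidate:
    """A tuning-parameter combination with its resolved variant weights."""

    trait: str
    params: TuningParams
    weights: dict[VariantKey, float]

    @property
    def degenerate(self) -> bool:
        return len(self.weights) == 0

    @property
    def n_snps(self) -> int:
        return len(self.weights)


@dataclass
class PRSValues:
    """Per-sample raw and standardized score."""

    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray | None = None
    standardization: tuple[float, float, str] | None = None  # (mean, sd, source)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.sample_ids),):
            raise ValueError("raw score length must match sample_ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw": self.raw,
                "standardized": self.standardized,
            }
        )


def default_grid() -> list[TuningParams]:
    """The 108-cell Cartesian grid: 12 p-thresholds x 3 r² x 3 windows."""
    return [TuningParams(p, r2, w) for p, r2, w in product(P_THRESHOLDS, R2_LEVELS, WINDOW_KB_LEVELS)]


# ---------------------------------------------------------------------------
# clumping


def _standardized_dosages(ss: SumStats, ref: GenotypeDataset):
    """Mean-imputed, standardized dosage matrix in smallest-p record order."""
    recs = sorted(ss.records, key=lambda r: (r.pvalue, r.key.chrom, r.key.pos))
    cols = np.array([ref.variant_index(r.key) for r in recs])
    X = ref.dosages[:, cols].astype(float)
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    if inds[0].size:
        X[inds] = np.take(mu, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    monomorphic = sd == 0
    sd[monomorphic] = 1.0
    X /= sd
    return recs, X, monomorphic


def clump(
    ss: SumStats,
    ref: GenotypeDataset,
    r2_max: float,
    window_kb: float,
    _prepared=None,
) -> set[VariantKey]:
    """Greedy LD clumping; returns the retained (index) variants.

    Ties in p are broken by (chrom, pos) order.  The window is measured
    index-to-candidate in kb, inclusive; the removal condition is strictly
    r² > ``r2_max``; cross-chromosome pairs never clump.
    """
    recs, X, monomorphic = _prepared if _prepared is not None else _standardized_dosages(ss, ref)
    chrom_codes = pd.factorize(np.array([r.key.chrom for r in recs]))[0]
    pos = np.array([r.key.pos for r in recs], dtype=float)
    window = window_kb * 1000.0

    n = len(recs)
    alive = np.ones(n, dtype=bool)
    index_vars: set[VariantKey] = set()
    nsamp = X.shape[0]
    for i in range(n):
        if not alive[i]:
            continue
        alive[i] = False
        index_vars.add(recs[i].key)
        near = alive & (chrom_codes == chrom_codes[i]) & (np.abs(pos - pos[i]) <= window)
        if not near.any() or monomorphic[i]:
            continue
        j = np.where(near)[0]
        r = X[:, j].T @ X[:, i] / nsamp
        r[monomorphic[j]] = 0.0
        alive[j[r * r > r2_max]] = False
    return index_vars


def apply_threshold(
    ss: SumStats,
    retained: set[VariantKey],
    p_threshold: float,
) -> dict[VariantKey, float]:
    """Weights for clumped variants passing the p-value threshold."""
    weights = {r.key: r.beta for r in ss.records if r.key in retained and r.pvalue < p_threshold}
    if not weights:
        logger.warning("apply_threshold: no variants pass p < %g — degenerate candidate", p_threshold)
    return weights


def build_candidates(
    ss: SumStats,
    ref: GenotypeDataset,
    grid: Sequence[TuningParams] | None = None,
) -> list[PRSCandidate]:
    """Build every candidate in the grid, sharing clumping runs."""
    grid = list(grid) if grid is not None else default_grid()
    prepared = _standardized_dosages(ss, ref)
    clump_cache: dict[tuple[float, float], set[VariantKey]] = {}
    out = []
    for params in grid:
        ck = (params.r2_max, params.window_kb)
        if ck not in clump_cache:
            clump_cache[ck] = clump(ss, ref, *ck, _prepared=prepared)
        out.append(
            PRSCandidate(
                trait=ss.trait,
                params=params,
                weights=apply_threshold(ss, clump_cache[ck], params.p_threshold),
            )
        )
    return out


# ---------------------------------------------------------------------------
# scoring


def score_grid(
    g: GenotypeDataset,
    ss: SumStats,
    candidates: Sequence[PRSCandidate],
) -> list[PRSValues]:
    """Score a full candidate grid, sharing work within each clump family.

    Candidates sharing (r², window) have nested weight sets ordered by
    p-value, so each family needs a single pass over its union of variants.
    Results match :func:`score` candidate-by-candidate.
    """
    pmap = {r.key: r.pvalue for r in ss.records}
    freqs = None
    out: list[PRSValues | None] = [None] * len(candidates)
    families: dict[tuple[float, float], list[int]] = {}
    for i, c in enumerate(candidates):
        families.setdefault((c.params.r2_max, c.params.window_kb), []).append(i)
    for idx_list in families.values():
        largest = max(idx_list, key=lambda i: len(candidates[i].weights))
        union = candidates[largest].weights
        if not union:
            for i in idx_list:
                out[i] = PRSValues(list(g.sample_ids), np.zeros(g.n_samples))
            continue
        keys = sorted(union, key=lambda k: pmap[k])
        pvals = np.array([pmap[k] for k in keys])
        cols = np.array([g.variant_index(k) for k in keys])
        w = np.array([union[k] for k in keys])
        X = g.dosages[:, cols].astype(float)
        if np.isnan(X).any():
            if freqs is None:
                freqs = allele_freq(g)
            fill = 2.0 * np.array([freqs[k] for k in keys])
            nan_idx = np.where(np.isnan(X))
            X[nan_idx] = np.take(fill, nan_idx[1])
        contrib = X * w
        csum = np.cumsum(contrib, axis=1)
        for i in idx_list:
            k = int(np.searchsorted(pvals, candidates[i].params.p_threshold, side="left"))
            if len(candidates[i].weights) != k:  # candidate not a pure p-prefix: fall back
                out[i] = score(g, candidates[i].weights)
            else:
                out[i] = PRSValues(list(g.sample_ids), csum[:, k - 1] if k else np.zeros(g.n_samples))
    return out  # type: ignore[return-value]


def score(g: GenotypeDataset, weights: Mapping[VariantKey, float]) -> PRSValues:
    """Weighted allele-dosage sum; missing dosages imputed as 2 x frequency."""
    missing = [v for v in weights if v not in g._variant_idx]
    if missing:
        raise KeyError(f"weight variants absent from genotypes: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if not weights:
        return PRSValues(list(g.sample_ids), np.zeros(g.n_samples))
    cols = np.array([g.variant_index(v) for v in weights])
    w = np.array([weights[v] for v in weights], dtype=float)
    X = g.dosages[:, cols].astype(float)
    if np.isnan(X).any():
        freqs = allele_freq(g)
        fill = 2.0 * np.array([freqs[v] for v in weights])
        inds = np.where(np.isnan(X))
        X[inds] = np.take(fill, inds[1])
    return PRSValues(list(g.sample_ids), X @ w)


def standardize(prs: PRSValues, mean: float, sd: float, source: str = "full-cohort") -> PRSValues:
    """Apply a pre-computed (mean, sd) standardization; records its source."""
    if not sd > 0:
        raise ValueError(f"standardization sd must be positive, got {sd}")
    return PRSValues(
        sample_ids=list(prs.sample_ids),
        raw=prs.raw.copy(),
        standardized=(prs.raw - mean) / sd,
        standardization=(float(mean), float(sd), source),
    )


def cohort_standardize(prs: PRSValues, source: str = "full-cohort") -> PRSValues:
    """Standardize with the score's own mean/SD over the full cohort."""
    return standardize(prs, float(prs.raw.mean()), float(prs.raw.std(ddof=0)), source)


def prssum(components: Sequence[PRSValues]) -> PRSValues:
    """Unweighted sum of standardized component scores, re-standardized.

    All components must be standardized on the same sample set; the sum is
    taken element-wise over the standardized values and then standardized
    with its own full-cohort constants.
    """
    if not components:
        raise ValueError("prssum requires at least one component")
    ids = components[0].sample_ids
    for c in components:
        if c.standardized is None:
            raise ValueError("prssum components must be standardized")
        if c.sample_ids != ids:
            raise ValueError("prssum components have mismatched sample sets")
    total = np.sum([c.standardized for c in components], axis=0)
    return cohort_standardize(PRSValues(list(ids), total), source="full-cohort")
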