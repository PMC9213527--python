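"""Staged-workflow orchestration: train, select, evaluate, trajectories.

The pipeline mirrors a three-stage design: tuning parameters are selected
on the stage-1 (training) samples with the CV criterion, the combined score
is evaluated on the kinship-disjoint stage-2 samples (prevalent and
incident hypertension, decile trends), and stage-3 samples provide
age-trajectory fits within PRS strata.  Stage membership is assigned at the
kinship-component level, so no related pair ever spans stages.

Every run writes its artifacts with a manifest of input hashes, seeds, and
the package version; a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import compute_auc, cochran_q, fit_logistic, decile_trend, stratum_effects_joint
from .bp_pheno import (
    BPCategory,
    incident_cohort,
    longitudinal_category,
    visit_pairs_from_frame,
)
from .genodata import (
    GenotypeDataset,
    KinshipGraph,
    allele_freq,
    kinship_components,
    load_genotypes,
    load_kinship,
    unrelated_set,
    write_dosage_tsv,
)
from .prs_build import (
    PRSValues,
    TuningParams,
    build_candidates,
    cohort_standardize,
    prssum,
    score,
    score_grid,
)
from .sumstats import SumStats, filter_maf, harmonize_alleles, read_sumstats
from .synthdata import SimConfig, TRAITS, simulate_cohort, simulate_sumstats
from .trajectory import fit_trajectory, or_by_age, prs_strata
from .tuning import gws_prs, select_cv_prs, select_pval_prs, split_kinship_folds

logger = logging.getLogger(__name__)

DEFAULT_STAGE_FRACTIONS = (0.3, 0.5, 0.2)


class ConfigError(ValueError):
    """The run configuration violates the documented schema."""


@dataclass
class StagePlan:
    """Pairwise-disjoint stage sample sets with kinship-level separation."""

    stage1: list[str]
    stage2: list[str]
    stage3: list[str]

    def validate(self, kinship: KinshipGraph) -> None:
        sets = [set(self.stage1), set(self.stage2), set(self.stage3)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ConfigError(
                        f"stage-{i + 1}/stage-{j + 1} overlap: {sorted(overlap)[:5]}"
                    )
        for a, b in kinship.edges:
            for i in range(3):
                for j in range(3):
                    if i != j and a in sets[i] and b in sets[j]:
                        raise ConfigError(
                            f"kinship edge ({a}, {b}) crosses stage {i + 1} and stage {j + 1}"
                        )


def plan_stages(
    samples: list[str],
    kinship: KinshipGraph,
    fractions: tuple[float, float, float] = DEFAULT_STAGE_FRACTIONS,
    seed: int = 0,
) -> StagePlan:
    """Assign kinship components whole to the three stages.

    Components are shuffled by seed, sorted largest first, and placed in the
    stage with the largest remaining deficit relative to its target size.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("stage fractions must sum to 1")
    comps = sorted(sorted(c) for c in kinship_components(kinship, samples))
    rng = np.random.default_rng(seed)
    rng.shuffle(comps)
    comps.sort(key=len, reverse=True)
    targets = np.array(fractions) * len(samples)
    filled = np.zeros(3)
    stages: list[list[str]] = [[], [], []]
    for comp in comps:
        k = int(np.argmax(targets - filled))
        stages[k].extend(comp)
        filled[k] += len(comp)
    plan = StagePlan(*(sorted(s) for s in stages))
    plan.validate(kinship)
    return plan


# ---------------------------------------------------------------------------
# configuration

_KNOWN_SECTIONS = {"inputs", "simulate", "grid", "selection", "association", "trajectory", "stages", "seed"}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(path_or_dict)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ConfigError("configuration requires a top-level seed")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("configuration requires either a simulate or an inputs section")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Accumulates artifacts and writes the manifest."""

    def __init__(self, out_dir: Path, seed: int):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.seed = seed
        self.artifacts: dict[str, str] = {}

    def write_table(self, df: pd.DataFrame, name: str) -> Path:
        path = self.out_dir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        self.artifacts[name] = _sha256(path)
        return path

    def register(self, path: Path) -> None:
        self.artifacts[str(path.relative_to(self.out_dir))] = _sha256(path)

    def write_manifest(self, config: dict) -> Path:
        manifest = {
            "package_version": __version__,
            "seed": self.seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "artifacts": dict(sorted(self.artifacts.items())),
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return path


def run_pipeline(config, out_dir) -> dict:
    """Execute the full staged workflow; returns a results dictionary.

    Steps: harmonize summary statistics → build the candidate grid →
    select tuning parameters per trait → PRSsum → full-cohort
    standardization → stage-2 association suite → stage-3 trajectories.
    On a mid-stage failure, artifacts written so far are kept and a
    FAILED marker names the stage.
    """
    cfg = load_config(config)
    run = _Run(Path(out_dir), seed=int(cfg["seed"]))
    stage_name = "setup"
    try:
        return _run_pipeline_inner(cfg, run)
    except Exception:
        (run.out_dir / "FAILED").write_text(f"stage: {stage_name}\n")
        raise


def _run_pipeline_inner(cfg: dict, run: _Run) -> dict:
    seed = int(cfg["seed"])
    results: dict = {}

    # --- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", seed)
        sim = SimConfig(**sim_kwargs)
        genotypes, kinship, truth, visits, covars = simulate_cohort(sim)
        sumstats = {t: simulate_sumstats(sim, truth, t) for t in TRAITS}
        inputs_dir = run.out_dir / "inputs"
        inputs_dir.mkdir(parents=True, exist_ok=True)
        write_dosage_tsv(genotypes, inputs_dir / "dosages.tsv")
        pd.DataFrame(
            [(a, b, d["kinship"]) for a, b, d in kinship.graph.edges(data=True)],
            columns=["id1", "id2", "kinship"],
        ).to_csv(inputs_dir / "kinship.tsv", sep="\t", index=False)
        visits.to_csv(inputs_dir / "phenotypes.csv", index=False, float_format="%.8g")
        covars.to_csv(inputs_dir / "covariates.csv", index=False, float_format="%.8g")
        truth.to_frame().to_csv(inputs_dir / "ground_truth.tsv", sep="\t", index=False, float_format="%.8g")
        for t in TRAITS:
            sumstats[t].to_frame().to_csv(
                inputs_dir / f"sumstats_{t.lower()}.tsv", sep="\t", index=False, float_format="%.10g"
            )
        for p in sorted(inputs_dir.iterdir()):
            run.register(p)
    else:
        inp = cfg["inputs"]
        genotypes = load_genotypes(inp["genotypes"])
        kinship = load_kinship(inp["kinship"], genotypes.sample_ids)
        visits = pd.read_csv(inp["phenotypes"])
        covars = pd.read_csv(inp["covariates"])
        sumstats = {
            t: read_sumstats(inp["sumstats"][t.lower()], trait=t) for t in TRAITS
        }

    covars = covars.set_index("sample_id", drop=False)

    # --- stage plan -------------------------------------------------------
    fractions = tuple(cfg.get("stages", {}).get("fractions", DEFAULT_STAGE_FRACTIONS))
    plan = plan_stages(genotypes.sample_ids, kinship, fractions, seed=seed)

    # --- harmonize --------------------------------------------------------
    maf = float(cfg.get("grid", {}).get("maf", 0.01))
    freqs = allele_freq(genotypes)
    harmonized: dict[str, SumStats] = {}
    harm_rows = []
    for t in TRAITS:
        ss = filter_maf(sumstats[t], freqs, threshold=maf)
        ss, counts = harmonize_alleles(ss, genotypes.variants)
        harmonized[t] = ss
        harm_rows.extend({"trait": t, "category": k, "count": v} for k, v in counts.items())
    run.write_table(pd.DataFrame(harm_rows), "harmonization_report.tsv")

    # --- candidate grid + selection per trait -----------------------------
    grid_cfg = cfg.get("grid", {})
    grid = None
    if "p_thresholds" in grid_cfg or "r2" in grid_cfg or "window_kb" in grid_cfg:
        from .prs_build import P_THRESHOLDS, R2_LEVELS, WINDOW_KB_LEVELS
        from itertools import product as _product

        grid = [
            TuningParams(p, r2, w)
            for p, r2, w in _product(
                grid_cfg.get("p_thresholds", P_THRESHOLDS),
                grid_cfg.get("r2", R2_LEVELS),
                grid_cfg.get("window_kb", WINDOW_KB_LEVELS),
            )
        ]

    sel_cfg = cfg.get("selection", {})
    criterion = sel_cfg.get("criterion", "cv").lower()
    n_folds = int(sel_cfg.get("n_folds", 5))

    pairs = visit_pairs_from_frame(visits)
    from .bp_pheno import BPVisit, bp_category as _bp_cat

    htn_baseline: dict[str, int] = {}
    for s, grp in visits.groupby("sample_id"):
        r = grp[grp["visit"] == 1].iloc[0]
        v = BPVisit(r.sbp, r.dbp, bool(r.treated), bool(r.self_report_htn), float(r.age), float(r.time))
        htn_baseline[str(s)] = int(_bp_cat(v) is BPCategory.HYPERTENSION)

    stage1 = plan.stage1
    folds = split_kinship_folds(stage1, kinship, n_folds=n_folds, seed=seed)
    covar_cols = ["sex", "age", "age2", "bmi", "smoking", "site", "background"] + [
        c for c in covars.columns if c.startswith("pc")
    ]
    cov1 = covars.loc[stage1, covar_cols].reset_index(drop=True)
    y1 = np.array([htn_baseline[s] for s in stage1])

    selected: dict[str, PRSValues] = {}
    selection_rows = []
    for t in TRAITS:
        candidates = build_candidates(harmonized[t], genotypes, grid)
        raw_scores = score_grid(genotypes, harmonized[t], candidates)
        cand_scores_full = [
            cohort_standardize(r) if not c.degenerate else None
            for c, r in zip(candidates, raw_scores)
        ]
        usable = [(c, s) for c, s in zip(candidates, cand_scores_full) if s is not None]
        cands = [c for c, _ in usable]
        full_scores = [s for _, s in usable]
        idx = {s: i for i, s in enumerate(genotypes.sample_ids)}
        s1_rows = [idx[s] for s in stage1]
        stage1_scores = [
            PRSValues(stage1, s.raw[s1_rows], s.standardized[s1_rows], s.standardization)
            for s in full_scores
        ]
        if criterion == "cv":
            sel = select_cv_prs(cands, stage1_scores, folds, y1, cov1, stage1)
        elif criterion == "pval":
            sel = select_pval_prs(cands, stage1_scores, y1, cov1, stage1)
        elif criterion == "gws":
            gcand = gws_prs(harmonized[t], genotypes)
            sel = None
            chosen_scores = cohort_standardize(score(genotypes, gcand.weights))
            selected[t] = chosen_scores
            selection_rows.append(
                {"trait": t, "criterion": "GWS", **_params_row(gcand.params), "n_snps": gcand.n_snps}
            )
            continue
        else:
            raise ConfigError(f"unknown selection criterion {criterion!r}")
        run.write_table(sel.table, f"selection_{t.lower()}.tsv")
        chosen_i = cands.index(sel.chosen_candidate)
        selected[t] = full_scores[chosen_i]
        selection_rows.append(
            {
                "trait": t,
                "criterion": sel.criterion,
                **_params_row(sel.chosen),
                "n_snps": sel.chosen_candidate.n_snps,
            }
        )

    run.write_table(pd.DataFrame(selection_rows), "selected_params.tsv")

    combined = prssum([selected[t] for t in TRAITS])
    run.write_table(combined.to_frame(), "htn_prs.tsv")

    # --- stage-2 association suite ----------------------------------------
    stage2 = plan.stage2
    idx = {s: i for i, s in enumerate(genotypes.sample_ids)}
    s2_rows = [idx[s] for s in stage2]
    prs2 = combined.standardized[s2_rows]
    cov2 = covars.loc[stage2, covar_cols].reset_index(drop=True)
    y2 = np.array([htn_baseline[s] for s in stage2])
    kin2 = kinship.subgraph(stage2)
    unrel2 = unrelated_set(kin2, seed=seed, samples=stage2)

    assoc_rows = []
    est = fit_logistic(y2, prs2, cov2, stratum="all")
    auc = compute_auc(y2, prs2, unrelated=unrel2, sample_ids=stage2, kinship=kin2)
    assoc_rows.append(_assoc_row("prevalent", est, auc))
    results["prevalent"] = {"or": est.or_point, "auc": auc, "p": est.pvalue, "n": est.n}

    # heterogeneity across background groups
    strata2 = covars.loc[stage2, "background"].to_numpy()
    if len(pd.unique(strata2)) > 1:
        labels, betas, covb = stratum_effects_joint(
            y2, prs2, strata2, cov2.drop(columns=["background"])
        )
        q, df, pq = cochran_q(betas, covb)
        results["heterogeneity"] = {"Q": q, "df": df, "p": pq}
        run.write_table(
            pd.DataFrame({"stratum": labels, "beta": betas, "se": np.sqrt(np.diag(covb))}),
            "background_effects.tsv",
        )

    # incident cohorts
    pairs2 = {s: pairs[s] for s in stage2 if s in pairs}
    for base_cat, tag in ((BPCategory.NORMAL, "incident-normal"), (BPCategory.ELEVATED, "incident-elevated")):
        cohort = incident_cohort(pairs2, base_cat)
        if cohort.empty or cohort["incident_htn"].nunique() < 2:
            logger.warning("skipping %s: no usable cohort", tag)
            continue
        ids_c = cohort["sample_id"].tolist()
        rows_c = [idx[s] for s in ids_c]
        cov_c = covars.loc[ids_c, covar_cols].reset_index(drop=True)
        cov_c["time_between_exams"] = cohort["time_between_exams"].to_numpy()
        est_c = fit_logistic(
            cohort["incident_htn"].to_numpy(), combined.standardized[rows_c], cov_c, stratum=tag
        )
        kin_c = kinship.subgraph(ids_c)
        unrel_c = unrelated_set(kin_c, seed=seed, samples=ids_c)
        try:
            auc_c = compute_auc(
                cohort["incident_htn"].to_numpy(),
                combined.standardized[rows_c],
                unrelated=unrel_c,
                sample_ids=ids_c,
                kinship=kin_c,
            )
        except ValueError:
            auc_c = np.nan
        assoc_rows.append(_assoc_row(tag, est_c, auc_c))
        results[tag] = {"or": est_c.or_point, "auc": auc_c, "p": est_c.pvalue, "n": est_c.n}

    run.write_table(pd.DataFrame(assoc_rows), "associations.tsv")

    # decile trend of longitudinal categories
    cats2 = np.array([longitudinal_category(*pairs[s]).name for s in stage2 if s in pairs])
    prs_for_cats = np.array([combined.standardized[idx[s]] for s in stage2 if s in pairs])
    trend = decile_trend(prs_for_cats, cats2, seed=seed)
    run.write_table(
        pd.DataFrame(
            [{"category": c, "slope": s, "p": p} for c, (s, p) in sorted(trend.items())]
        ),
        "decile_trend.tsv",
    )
    results["decile_trend"] = trend

    # --- stage-3 trajectories ---------------------------------------------
    stage3 = plan.stage3
    traj_cfg = cfg.get("trajectory", {})
    ref_age = float(traj_cfg.get("ref_age", min(visits["age"].min(), 17.0)))
    s3_rows = [idx[s] for s in stage3]
    strata3 = prs_strata(combined.standardized[s3_rows], stage3, seed=seed)
    visits3 = visits[visits["sample_id"].isin(stage3)].copy()
    from .bp_pheno import BPVisit as _V

    visits3["htn"] = [
        int(
            _bp_cat(_V(r.sbp, r.dbp, bool(r.treated), bool(r.self_report_htn), float(r.age), float(r.time)))
            is BPCategory.HYPERTENSION
        )
        for r in visits3.itertuples(index=False)
    ]
    pc_cols = [c for c in covars.columns if c.startswith("pc")]
    traj_cov = covars[["sex"] + pc_cols]
    ages_grid = np.arange(ref_age, float(traj_cfg.get("max_age", visits["age"].max())) + 1)
    curve_frames = []
    for k in range(1, strata3.n_strata + 1):
        members = strata3.labels[strata3.labels == k].index.tolist()
        sub = visits3[visits3["sample_id"].isin(members)]
        if sub.empty or sub["htn"].nunique() < 2:
            logger.warning("trajectory stratum %d skipped: degenerate outcome", k)
            continue
        try:
            fit = fit_trajectory(sub, traj_cov, ref_age=ref_age, stratum=strata3.stratum_name(k))
        except Exception as exc:
            logger.warning("trajectory stratum %d failed: %s", k, exc)
            continue
        curve_frames.append(or_by_age(fit, ages_grid).to_frame())
    if curve_frames:
        run.write_table(pd.concat(curve_frames, ignore_index=True), "trajectories.tsv")

    manifest_path = run.write_manifest(cfg)
    results["manifest"] = str(manifest_path)
    results["stage_plan"] = {"stage1": len(stage1), "stage2": len(stage2), "stage3": len(stage3)}
    return results


def _params_row(p: TuningParams) -> dict:
    return {"p_threshold": p.p_threshold, "r2_max": p.r2_max, "window_kb": p.window_kb}


def _assoc_row(model: str, est, auc) -> dict:
    lo, hi = est.ci
    return {
        "model": model,
        "stratum": est.stratum,
        "n": est.n,
        "OR": est.or_point,
        "CI_low": lo,
        "CI_high": hi,
        "p": est.pvalue,
        "AUC": auc,
    }
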