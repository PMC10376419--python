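"""End-to-end orchestration: stratify by sex, then run cohort summary,
diversity, differential abundance, SEM construction/pruning, blinded factor
scoring and the logistic risk model, writing one artifact bundle per stratum.

Every stage is a pure function of (inputs, config, seeds); re-running a
bundle with the same config reproduces it byte-for-byte (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compositional import clr_point_estimate, dirichlet_clr, ensemble_mean
from .data_io import (CountTable, align, read_count_table, read_metadata,
                      write_results)
from .diff_abundance import (DEFAULT_THRESHOLD, classify, cohort_summary,
                             effect_sizes)
from .diversity import alpha_diversity, bray_curtis, nmds, permanova, write_ordination
from .exceptions import (ConfigurationError, GutsemError, PruningFailureError,
                         SpecificationError)
from .risk_model import fit_cv, roc_auc
from .sem_risk import (DEFAULT_COLLAPSE_THRESHOLD, DEFAULT_FIT_TARGETS,
                       blinded_factor_scores, build_spec, check_latent_collapse,
                       fit_dwls, mixed_correlations, prune_indicators)
from .synthetic_data import SyntheticConfig, generate_sexed, write_dataset

logger = logging.getLogger(__name__)

STRATA = ("mixed", "male", "female")


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    metadata_path: str | None = None
    outdir: str = "gutsem_out"
    strata: str = "all"                      # mixed | male | female | all
    effect_threshold: float = DEFAULT_THRESHOLD
    clr_prior: float = 0.5
    clr_instances: int = 128
    clr_mode: str = "mc-mean"                # point | mc-mean | single-instance
    sem_mode: str = "auto"                   # auto | one_lv | two_lv
    sem_targets: dict = field(default_factory=lambda: dict(DEFAULT_FIT_TARGETS))
    sem_min_per_lv: int = 3
    sem_prune: bool = True
    on_pruning_failure: str = "best"         # best | halt
    collapse_threshold: float = DEFAULT_COLLAPSE_THRESHOLD
    n_folds: int = 10
    n_permutations: int = 999
    nmds_k: int = 2
    nmds_restarts: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.strata not in STRATA + ("all",):
            raise ConfigurationError(f"strata must be one of {STRATA + ('all',)}")
        if self.clr_mode not in ("point", "mc-mean", "single-instance"):
            raise ConfigurationError("clr_mode must be point | mc-mean | single-instance")
        if self.sem_mode not in ("auto", "one_lv", "two_lv"):
            raise ConfigurationError("sem_mode must be auto | one_lv | two_lv")
        if self.on_pruning_failure not in ("best", "halt"):
            raise ConfigurationError("on_pruning_failure must be best | halt")

    def hash(self) -> str:
        params = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            yaml.safe_dump(params, sort_keys=True).encode()).hexdigest()[:12]


def _stratum_seed(master: int, stratum: str) -> int:
    return (master * 7919 + {"mixed": 1, "male": 2, "female": 3}[stratum]) % (2 ** 31)


def _clr_frame(counts: CountTable, cfg: PipelineConfig, seed: int) -> pd.DataFrame:
    if cfg.clr_mode == "point":
        mat = clr_point_estimate(counts, prior=cfg.clr_prior)
    else:
        ens = dirichlet_clr(counts, cfg.clr_instances, cfg.clr_prior, seed)
        mat = ens.instances[0] if cfg.clr_mode == "single-instance" else ensemble_mean(ens)
    return pd.DataFrame(mat, index=counts.sample_ids, columns=counts.taxon_ids)


def _run_stratum(counts: CountTable, meta, cfg: PipelineConfig,
                 outdir: Path, stratum: str) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    seed = _stratum_seed(cfg.seed, stratum)
    groups = np.array([m.group for m in meta])
    disease = (groups == "case").astype(int)
    stage = "cohort_summary"
    try:
        alpha = alpha_diversity(counts)
        summary = cohort_summary(meta, alpha)
        write_results(summary, outdir / "cohort_summary.tsv", "tsv")
        alpha.rename_axis("sample_id").reset_index().to_csv(
            outdir / "alpha_diversity.tsv", sep="\t", index=False)

        stage = "beta_diversity"
        dist = bray_curtis(counts)
        ordn = nmds(dist, k=cfg.nmds_k, n_restarts=cfg.nmds_restarts, seed=seed)
        write_ordination(ordn, outdir / "ordination.tsv")
        perm = permanova(dist, groups, n_permutations=cfg.n_permutations, seed=seed)
        write_results({"pseudo_F": perm.pseudo_F, "p_value": perm.p_value,
                       "n_permutations": perm.n_permutations,
                       "nmds_stress": ordn.stress},
                      outdir / "beta_diversity.json", "json")

        stage = "differential_abundance"
        ens = dirichlet_clr(counts, cfg.clr_instances, cfg.clr_prior, seed)
        effects = effect_sizes(ens, groups, seed=seed)
        effects = classify(effects, cfg.effect_threshold)
        effects.insert(len(effects.columns), "stratum", stratum)
        write_results(effects, outdir / "effects.tsv", "tsv")

        stage = "sem"
        clr = _clr_frame(counts, cfg, seed)
        sem_report = _sem_stage(effects, clr, disease, cfg, seed)
        write_results(sem_report, outdir / "sem.json", "json")
        if sem_report.get("error"):
            raise SpecificationError(sem_report["error"])

        stage = "factor_scores"
        final_spec = sem_report["_final_spec"]
        meas_fit, scores = blinded_factor_scores(final_spec, clr, seed=seed)
        scores.rename_axis("sample_id").reset_index().to_csv(
            outdir / "factor_scores.tsv", sep="\t", index=False)

        stage = "risk_model"
        model, oof = fit_cv(scores, disease, n_folds=cfg.n_folds, seed=seed)
        roc = roc_auc(oof, disease)
        apparent = roc_auc(
            scores.to_numpy() @ np.array([model.coefficients[c] for c in scores.columns])
            + model.coefficients["intercept"], disease)
        risk = {"coefficients": model.coefficients,
                "per_fold_auc": model.per_fold_auc,
                "oof_auc": roc.auc,
                "apparent_auc": apparent.auc,
                "separation_flagged": model.separation_flagged,
                "n_folds": len(model.folds)}
        write_results(risk, outdir / "risk_model.json", "json")
        pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                      "tpr": roc.tpr}).to_csv(outdir / "roc.tsv", sep="\t", index=False)
    except GutsemError as err:
        raise GutsemError(f"stage {stage!r} failed in stratum {stratum!r}: {err}") from err

    sem_public = {k: v for k, v in sem_report.items() if not k.startswith("_")}
    return {"stratum": stratum, "n_samples": counts.n_samples,
            "permanova_p": perm.p_value, "nmds_stress": ordn.stress,
            "n_more": int((effects["class"] == "more").sum()),
            "n_less": int((effects["class"] == "less").sum()),
            "sem": sem_public, "risk": risk,
            "_scores": scores, "_effects": effects, "_disease": disease}


def _fit_with_pruning(spec, corr, cfg: PipelineConfig, seed: int):
    """Prune against the fit targets; on failure fall back per config."""
    if not cfg.sem_prune:
        return spec, fit_dwls(spec, corr, seed=seed), []
    try:
        return prune_indicators(spec, corr, targets=cfg.sem_targets,
                                min_per_lv=cfg.sem_min_per_lv, seed=seed)
    except PruningFailureError as err:
        if cfg.on_pruning_failure == "halt":
            raise
        logger.warning("pruning targets unreachable; keeping best-fit model")
        # replay the trajectory to the smallest model, which had the best
        # composite at every greedy step
        pruned = spec
        for step in err.trajectory:
            if "dropped" in step:
                pruned = pruned.without(step["dropped"])
        return pruned, fit_dwls(pruned, corr, seed=seed), err.trajectory


def _sem_stage(effects: pd.DataFrame, clr: pd.DataFrame, disease, cfg, seed) -> dict:
    report: dict = {"mode_requested": cfg.sem_mode}
    n_more = int((effects["class"] == "more").sum())
    n_less = int((effects["class"] == "less").sum())
    mode = cfg.sem_mode
    if mode == "auto":
        mode = "two_lv" if n_less >= cfg.sem_min_per_lv else "one_lv"
        if n_more < cfg.sem_min_per_lv:
            report["error"] = (f"only {n_more} case-enriched taxa classified; "
                               f"need >= {cfg.sem_min_per_lv}")
            return report
    try:
        spec = build_spec(effects, mode=mode)
    except SpecificationError as err:
        report["error"] = str(err)
        return report
    corr = mixed_correlations(clr[spec.indicators], disease)
    spec, fit, log = _fit_with_pruning(spec, corr, cfg, seed)
    report.update({"mode": mode, "pruning_log": log, "fit": fit.to_dict()})

    if mode == "two_lv":
        decision = check_latent_collapse(fit, cfg.collapse_threshold)
        report["collapse_decision"] = decision
        if decision == "collapse_to_one" and cfg.sem_mode == "auto":
            logger.info("lv1-lv2 correlation %.2f >= %.2f: collapsing to one latent",
                        fit.latent_correlation, cfg.collapse_threshold)
            spec = build_spec(effects, mode="one_lv")
            corr = mixed_correlations(clr[spec.indicators], disease)
            spec, fit, log = _fit_with_pruning(spec, corr, cfg, seed)
            report.update({"mode": "one_lv", "pruning_log_one_lv": log,
                           "fit": fit.to_dict()})
    report["_final_spec"] = spec
    return report


def run(cfg: PipelineConfig, counts: CountTable | None = None,
        meta=None) -> dict:
    """Run the full pipeline; returns the report and writes the bundle."""
    cfg.validate()
    if counts is None:
        if cfg.counts_path is None or cfg.metadata_path is None:
            raise ConfigurationError("counts_path and metadata_path are required")
        counts = read_count_table(cfg.counts_path)
        meta = read_metadata(cfg.metadata_path)
    counts, meta = align(counts, meta)

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = list(STRATA) if cfg.strata == "all" else [cfg.strata]
    report = {"version": __version__, "seed": cfg.seed, "config_hash": cfg.hash(),
              "strata": {}}
    for stratum in wanted:
        if stratum == "mixed":
            sub_counts, sub_meta = counts, meta
        else:
            keep = [m.sample_id for m in meta if m.sex == stratum]
            if len(keep) < 4:
                logger.warning("skipping stratum %r (%d samples)", stratum, len(keep))
                continue
            sub_counts, sub_meta = align(counts.subset_samples(keep), meta)
        result = _run_stratum(sub_counts, sub_meta, cfg, outdir / stratum, stratum)
        report["strata"][stratum] = {k: v for k, v in result.items()
                                     if not k.startswith("_")}
        report["strata"][stratum]["_private"] = result
    public = {k: {s: {kk: vv for kk, vv in r.items() if not kk.startswith("_")}
                  for s, r in v.items()} if k == "strata" else v
              for k, v in report.items()}
    write_results(public, outdir / "report.json", "json")
    return report


def simulate_and_run(male_cfg: SyntheticConfig, female_cfg: SyntheticConfig,
                     cfg: PipelineConfig) -> dict:
    """Generate a sexed synthetic cohort, run the pipeline, and append
    truth-recovery diagnostics (effect-sign agreement, score-truth
    correlation, out-of-fold AUC, no-signal flag)."""
    ds = generate_sexed(male_cfg, female_cfg)
    write_dataset(ds, Path(cfg.outdir) / "synthetic")
    report = run(cfg, counts=ds.counts, meta=ds.metadata)

    z = pd.Series(ds.latent_scores, index=ds.counts.sample_ids)
    sex = pd.Series([m.sex for m in ds.metadata], index=ds.counts.sample_ids)
    truth_cfg = {"male": male_cfg, "female": female_cfg, "mixed": female_cfg}
    recovery = {}
    for stratum, res in report["strata"].items():
        priv = res.pop("_private")
        effects = priv["_effects"].set_index("taxon")
        tc = truth_cfg[stratum]
        planted = [(f"g{j:03d}", +1) for j in tc.lv1_taxa] + \
                  [(f"g{j:03d}", -1) for j in tc.lv2_taxa]
        signs = [np.sign(effects.loc[t, "effect"]) == s for t, s in planted
                 if t in effects.index]
        scores = priv["_scores"]
        mask = sex.loc[scores.index] == stratum if stratum != "mixed" else \
            pd.Series(True, index=scores.index)
        corr = float(np.corrcoef(scores.loc[mask].iloc[:, 0],
                                 z.loc[scores.index][mask])[0, 1])
        auc = res["risk"]["oof_auc"]
        recovery[stratum] = {
            "effect_sign_agreement": float(np.mean(signs)) if signs else float("nan"),
            "score_truth_correlation": corr,
            "oof_auc": auc,
            "no_signal": bool(abs(auc - 0.5) < 0.1),
        }
    report["recovery"] = recovery
    write_results({"recovery": recovery}, Path(cfg.outdir) / "recovery.json", "json")
    return report


# minimal structural schema for the public report bundle
REPORT_SCHEMA = {
    "required": ["version", "seed", "config_hash", "strata"],
    "stratum_required": ["stratum", "n_samples", "permanova_p", "nmds_stress",
                         "n_more", "n_less", "sem", "risk"],
}


def validate_report(report: dict) -> None:
    """Check the report bundle against the published structural schema."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ConfigurationError(f"report missing key {key!r}")
    for stratum, res in report["strata"].items():
        for key in REPORT_SCHEMA["stratum_required"]:
            if key not in res:
                raise ConfigurationError(f"stratum {stratum!r} missing key {key!r}")


def load_report(bundle_dir) -> dict:
    with open(Path(bundle_dir) / "report.json") as fh:
        return json.load(fh)
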