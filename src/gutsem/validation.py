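"""Calibration and recovery experiments on planted-truth synthetic data.

These routines exercise the full analysis against known ground truth: null
calibration of effect sizes and PERMANOVA, recovery of planted latent
structure by the DWLS factor models, and end-to-end out-of-fold AUC of the
risk model. They are used by the acceptance checks and are part of the
public API so users can rerun them at other settings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compositional import dirichlet_clr, ensemble_mean
from .diff_abundance import classify, effect_sizes
from .diversity import bray_curtis, permanova
from .exceptions import PruningFailureError
from .pipeline import PipelineConfig, _sem_stage
from .risk_model import fit_cv, roc_auc
from .sem_risk import (SemSpec, blinded_factor_scores, fit_dwls,
                       mixed_correlations, prune_indicators)
from .synthetic_data import SyntheticConfig, generate, generate_null


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 100_003 + k) % (2 ** 31)


# ---------------------------------------------------------------------------
# differential abundance calibration
# ---------------------------------------------------------------------------

def null_effect_medians(n_replicates: int = 300, n_per_group: int = 20,
                        n_instances: int = 64, seed: int = 0) -> np.ndarray:
    """Per-taxon median effect size over replicate null datasets."""
    effects = []
    for r in range(n_replicates):
        cfg = SyntheticConfig(n_case=n_per_group, n_control=n_per_group,
                              loading_strength=0.0, seed=_sub_seed(seed, r))
        ds = generate(cfg)
        ens = dirichlet_clr(ds.counts, n_instances, seed=_sub_seed(seed, r + 50_000))
        eff = effect_sizes(ens, ds.groups(), seed=_sub_seed(seed, r + 100_000))
        effects.append(eff["effect"].to_numpy())
    return np.median(effects, axis=0)


def planted_classification_rate(n_replicates: int = 20, n_per_group: int = 20,
                                threshold: float = 0.2, n_instances: int = 128,
                                seed: int = 0) -> float:
    """Fraction of planted taxa classified with the correct sign at the
    effect threshold, pooled over taxa and replicates."""
    hits = total = 0
    for r in range(n_replicates):
        cfg = SyntheticConfig(n_case=n_per_group, n_control=n_per_group,
                              loading_strength=1.0, seed=_sub_seed(seed, r))
        ds = generate(cfg)
        ens = dirichlet_clr(ds.counts, n_instances, seed=_sub_seed(seed, r + 50_000))
        eff = classify(effect_sizes(ens, ds.groups(),
                                    seed=_sub_seed(seed, r + 100_000)), threshold)
        eff = eff.set_index("taxon")
        for j in cfg.lv1_taxa:
            hits += eff.loc[f"g{j:03d}", "class"] == "more"
            total += 1
        for j in cfg.lv2_taxa:
            hits += eff.loc[f"g{j:03d}", "class"] == "less"
            total += 1
    return hits / total


def label_swap_antisymmetry_error(seed: int = 0) -> float:
    """Max |effect(case) + effect(control-as-case)| — exact antisymmetry is 0."""
    ds = generate(SyntheticConfig(n_case=12, n_control=15, seed=seed))
    ens = dirichlet_clr(ds.counts, 32, seed=seed)
    a = effect_sizes(ens, ds.groups(), case_label="case", seed=seed)
    b = effect_sizes(ens, ds.groups(), case_label="control", seed=seed)
    return float(np.max(np.abs(a["effect"].to_numpy() + b["effect"].to_numpy())))


# ---------------------------------------------------------------------------
# PERMANOVA calibration
# ---------------------------------------------------------------------------

def permanova_type1_rejections(n_replicates: int = 200, n_per_group: int = 10,
                               n_permutations: int = 999, alpha: float = 0.05,
                               seed: int = 0) -> tuple[int, int]:
    """Number of null datasets rejected at ``alpha``; should track alpha."""
    rejections = 0
    for r in range(n_replicates):
        cfg = SyntheticConfig(n_case=n_per_group, n_control=n_per_group,
                              loading_strength=0.0, seed=_sub_seed(seed, r))
        ds = generate_null(cfg)
        res = permanova(bray_curtis(ds.counts), ds.groups(),
                        n_permutations=n_permutations,
                        seed=_sub_seed(seed, r + 50_000))
        rejections += res.p_value <= alpha
    return rejections, n_replicates


# ---------------------------------------------------------------------------
# latent-variable model recovery
# ---------------------------------------------------------------------------

def one_factor_sample(n: int, loadings, seed: int = 0, noise_cols: int = 0
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Indicators sampled from a one-factor normal model (+ optional noise)."""
    loadings = np.asarray(loadings, dtype=float)
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    X = loadings[None, :] * z[:, None] + \
        np.sqrt(1 - loadings ** 2)[None, :] * rng.normal(size=(n, len(loadings)))
    cols = [f"c{i}" for i in range(len(loadings))]
    if noise_cols:
        X = np.hstack([X, rng.normal(size=(n, noise_cols))])
        cols += [f"noise{i}" for i in range(noise_cols)]
    return pd.DataFrame(X, columns=cols), z


def dwls_population_recovery_error(p: int = 6, loading: float = 0.8) -> float:
    """Max |fitted - true| loading on the exact population correlation matrix."""
    from .sem_risk import MixedCorrelations
    lam = np.full(p, loading)
    R = np.outer(lam, lam)
    np.fill_diagonal(R, 1.0)
    taxa = [f"t{i}" for i in range(p)]
    corr = MixedCorrelations(taxa, R, None, None,
                             np.maximum((1 - R ** 2) ** 2, 1e-8),
                             None, None, 5000)
    fit = fit_dwls(SemSpec({"lv1": taxa}), corr, n=5000)
    return max(abs(fit.loadings[t] - loading) for t in taxa)


def dwls_sampled_recovery(n: int = 5000, p: int = 6, loading: float = 0.8,
                          seed: int = 0):
    """Fit on sampled one-factor data; returns (max loading error, fit)."""
    df, _ = one_factor_sample(n, [loading] * p, seed=seed)
    fit = fit_dwls(SemSpec({"lv1": list(df.columns)}), mixed_correlations(df))
    return max(abs(fit.loadings[c] - loading) for c in df.columns), fit


def noise_pruning_order(n: int = 200, n_clean: int = 6, n_noise: int = 3,
                        loading: float = 0.8, seed: int = 0):
    """Force ``n_noise`` drops and report which indicators were pruned.

    Returns (dropped, replay_identical): the pruning trajectory run twice on
    unreachable targets so exactly the noise columns should go first.
    """
    df, _ = one_factor_sample(n, [loading] * n_clean, seed=seed,
                              noise_cols=n_noise)
    corr = mixed_correlations(df)
    spec = SemSpec({"lv1": list(df.columns)})
    targets = {"gfi_min": 2.0, "agfi_min": 2.0, "rmsea_max": -1.0}

    def trajectory():
        try:
            _, _, log = prune_indicators(spec, corr, targets=targets,
                                         min_per_lv=n_clean)
            return [s["dropped"] for s in log if "dropped" in s]
        except PruningFailureError as err:
            return [s["dropped"] for s in err.trajectory if "dropped" in s]

    dropped = trajectory()
    return dropped, dropped == trajectory()


def score_truth_correlation(n_per_group: int = 100, n_indicators: int = 8,
                            seed: int = 0) -> float:
    """Correlation between blinded empirical-Bayes scores and the true
    planted latent, through the full compositional route."""
    cfg = SyntheticConfig(n_case=n_per_group, n_control=n_per_group,
                          n_taxa=50, lv1_taxa=tuple(range(n_indicators)),
                          lv2_taxa=(), loading_strength=1.0, seed=seed)
    ds = generate(cfg)
    ens = dirichlet_clr(ds.counts, 128, seed=_sub_seed(seed, 1))
    clr = pd.DataFrame(ensemble_mean(ens), index=ds.counts.sample_ids,
                       columns=ds.counts.taxon_ids)
    spec = SemSpec({"lv1": [f"g{j:03d}" for j in cfg.lv1_taxa]})
    _, scores = blinded_factor_scores(spec, clr, seed=_sub_seed(seed, 2))
    return float(np.corrcoef(scores["lv1"], ds.latent_scores)[0, 1])


# ---------------------------------------------------------------------------
# end-to-end risk-model recovery
# ---------------------------------------------------------------------------

def end_to_end_auc(n_case: int = 18, n_control: int = 23, null: bool = False,
                   seed: int = 0) -> float:
    """One replicate of the full chain at cohort scale: counts -> CLR ->
    effect classification -> SEM (auto mode, pruning and latent collapse as
    in the pipeline) -> blinded scores -> SMOTE-balanced 10-fold logistic CV
    -> out-of-fold AUC."""
    cfg = SyntheticConfig(n_case=n_case, n_control=n_control, seed=seed)
    ds = generate_null(cfg) if null else generate(cfg)
    groups = ds.groups()
    disease = (groups == "case").astype(int)
    ens = dirichlet_clr(ds.counts, 128, seed=_sub_seed(seed, 1))
    eff = classify(effect_sizes(ens, groups, seed=_sub_seed(seed, 2)))
    clr = pd.DataFrame(ensemble_mean(ens), index=ds.counts.sample_ids,
                       columns=ds.counts.taxon_ids)
    pcfg = PipelineConfig()
    sem_report = _sem_stage(eff, clr, disease, pcfg, _sub_seed(seed, 3))
    if sem_report.get("error"):
        # degenerate classification (can occur on null draws): no model,
        # chance discrimination by definition
        return 0.5
    _, scores = blinded_factor_scores(sem_report["_final_spec"], clr,
                                      seed=_sub_seed(seed, 4))
    _, oof = fit_cv(scores, disease, n_folds=10, seed=_sub_seed(seed, 5))
    return roc_auc(oof, disease).auc


def end_to_end_auc_replicates(n_replicates: int = 20, null: bool = False,
                              seed: int = 0, **kw) -> list[float]:
    return [end_to_end_auc(null=null, seed=_sub_seed(seed, 7777 + r), **kw)
            for r in range(n_replicates)]
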