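"""ALDEx2-style differential abundance and cohort-level group statistics.

Per genus, the effect size is the median over Dirichlet Monte-Carlo
instances of the between-group difference in CLR medians divided by the
larger within-group dispersion — a standardized, sample-size-free measure.
Taxa with effect > +threshold are "more" abundant in cases, < -threshold
"less", following the +/-0.2 convention; p-values come from the tie-corrected
rank-sum normal approximation without continuity correction, averaged over
instances, with Benjamini-Hochberg adjustment across taxa.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compositional import ClrEnsemble
from .exceptions import ConfigurationError, DomainError, InsufficientDataError

DEFAULT_THRESHOLD = 0.2


def effect_sizes(ens: ClrEnsemble, labels, case_label: str = "case",
                 seed: int = 0) -> pd.DataFrame:
    """Per-taxon effect size, dispersion, Wilcoxon p and BH q.

    Within-group dispersion pairs each sample with a random same-group
    sample (one fresh permutation per Monte-Carlo instance); the pairing is
    drawn per group membership, not per case/control role, so swapping the
    group labels negates every effect exactly.
    """
    labels = np.asarray(labels)
    case_idx = np.flatnonzero(labels == case_label)
    ctl_idx = np.flatnonzero(labels != case_label)
    if len(case_idx) < 2 or len(ctl_idx) < 2:
        raise InsufficientDataError("both groups need >= 2 samples")

    inst = ens.instances  # (K, n, p)
    K = inst.shape[0]
    arr_case = inst[:, case_idx, :]
    arr_ctl = inst[:, ctl_idx, :]
    med_case = np.median(arr_case, axis=1)
    med_ctl = np.median(arr_ctl, axis=1)
    diff_btw = med_case - med_ctl  # (K, p)

    # canonical group order (by smallest member index) keeps the RNG stream
    # identical under a case/control label swap
    rng = np.random.default_rng(seed)
    ordered = sorted([(case_idx, arr_case), (ctl_idx, arr_ctl)],
                     key=lambda t: int(t[0][0]))
    disp = {}
    for idx, arr in ordered:
        m = arr.shape[1]
        perms = np.stack([rng.permutation(m) for _ in range(K)])
        partner = arr[np.arange(K)[:, None], perms, :]
        disp[id(arr)] = np.median(np.abs(arr - partner), axis=1)  # (K, p)
    disp_max = np.maximum(disp[id(arr_case)], disp[id(arr_ctl)])
    disp_max = np.maximum(disp_max, np.finfo(float).eps)
    effect = diff_btw / disp_max

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(arr_case, arr_ctl, axis=1,
                                 use_continuity=False, method="asymptotic")
    p_inst = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)

    p = np.minimum(p_inst.mean(axis=0), 1.0)
    out = pd.DataFrame({
        "taxon": ens.taxon_ids,
        "effect": np.median(effect, axis=0),
        "diff_btw": np.median(diff_btw, axis=0),
        "dispersion": np.median(disp_max, axis=0),
        "p_wilcoxon": p,
        "q_bh": bh_adjust(p),
    })
    return classify(out)


def classify(effects: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Three-way more/less/none call at +/-threshold on the effect size."""
    if threshold <= 0:
        raise ConfigurationError("threshold must be > 0")
    effects = effects.copy()
    effects["class"] = np.select(
        [effects["effect"] > threshold, effects["effect"] < -threshold],
        ["more", "less"], default="none")
    return effects


def wilcoxon_rank_sum(x, y, continuity: bool = False, exact: bool = False) -> float:
    """Two-sided rank-sum p-value.

    Default is the tie-corrected normal approximation with no continuity
    correction (R's wilcox.test with correct = FALSE); ``exact`` enumerates
    every assignment of the pooled values (intended for n_x + n_y <= 10) and
    returns the symmetric-tail probability of the U statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise InsufficientDataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if exact:
        n1, n = len(x), len(pooled)
        ranks = stats.rankdata(pooled)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * (n - n1) / 2
        hits = total = 0
        for idx in combinations(range(n), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, use_continuity=continuity, method="asymptotic")
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = True
                   ) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default, df = 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise DomainError("cell counts must be >= 0")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DomainError("zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), float(p)


def cohort_summary(meta, alpha: pd.DataFrame) -> pd.DataFrame:
    """Per-variable group means +/- SD and tests (Table-1-style report).

    Continuous variables (age, BMI, alpha-diversity indices) are compared
    with the rank-sum test; the sex x group composition with the
    Yates-corrected chi-square.
    """
    groups = np.array([m.group for m in meta])
    case = groups == "case"
    rows = []

    sexes = np.array([m.sex for m in meta])
    if len(np.unique(sexes)) == 2:
        a = int(((sexes == "male") & case).sum())
        b = int(((sexes == "female") & case).sum())
        c = int(((sexes == "male") & ~case).sum())
        d = int(((sexes == "female") & ~case).sum())
        _, p = chi_square_2x2(a, b, c, d)
        rows.append({"variable": "sex (male/female)", "case": f"{a}/{b}",
                     "control": f"{c}/{d}", "p_value": p, "test": "chi-square"})

    def cont_row(name, values):
        values = np.asarray(values, dtype=float)
        ok = ~np.isnan(values)
        xv, yv = values[case & ok], values[~case & ok]
        if len(xv) < 2 or len(yv) < 2:
            return
        rows.append({"variable": name,
                     "case": f"{xv.mean():.2f} ± {xv.std(ddof=1):.2f}",
                     "control": f"{yv.mean():.2f} ± {yv.std(ddof=1):.2f}",
                     "p_value": wilcoxon_rank_sum(xv, yv),
                     "test": "wilcoxon"})

    ages = [m.age if m.age is not None else np.nan for m in meta]
    bmis = [m.bmi if m.bmi is not None else np.nan for m in meta]
    if not np.all(np.isnan(ages)):
        cont_row("age", ages)
    if not np.all(np.isnan(bmis)):
        cont_row("bmi", bmis)
    for col in ("shannon", "simpson", "richness", "pielou"):
        cont_row(col, alpha[col].to_numpy())
    return pd.DataFrame(rows)
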