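"""Latent-variable (SEM/CFA) dysbiosis models fit by diagonally weighted
least squares, with indicator pruning and empirical-Bayes factor scores.

The model: CLR abundances of selected genera are indicators of one or two
latent "dysbiosis" factors (lv1 = taxa enriched in cases, lv2 = depleted),
identified by fixing latent variances to 1 and standardizing observed
variables. The binary disease status enters as an ordered indicator — a
thresholded standard-normal latent response — so the input moments are
Pearson correlations among CLR columns plus polyserial correlations between
each CLR column and the disease response. DWLS minimizes

    F(theta) = sum_k w_k (s_k - sigma_k(theta))^2

over the non-redundant moments, with w_k the inverse asymptotic variance of
the sqrt(n)-scaled statistic; chi2 = (n - 1) F_min, GFI/AGFI compare F_min
to the zero-model discrepancy, RMSEA = sqrt(max((chi2 - df)/(df (n-1)), 0)).

Factor scores are posterior means under the fitted normal model (the
"regression" / empirical-Bayes method): score = Psi Lambda' Sigma^{-1} x.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (DegenerateVariableError, InsufficientDataError,
                         NonConvergenceError, NumericalError,
                         PruningFailureError, SpecificationError)

logger = logging.getLogger(__name__)

DEFAULT_FIT_TARGETS = {"gfi_min": 0.94, "agfi_min": 0.89, "rmsea_max": 0.01}
DEFAULT_COLLAPSE_THRESHOLD = 0.85


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class SemSpec:
    """Structure of a latent-variable model over CLR taxon columns.

    lv_indicators maps each latent variable (lv1, lv2) to its ordered taxon
    list; disease_indicator (if set) is the binary ordered outcome every
    latent regresses onto; the lv1-lv2 correlation is free in two-lv models.
    """

    lv_indicators: dict[str, list[str]]
    disease_indicator: str | None = None
    latent_correlation_free: bool = True

    @property
    def latent_names(self) -> list[str]:
        return list(self.lv_indicators)

    @property
    def indicators(self) -> list[str]:
        return [t for lv in self.lv_indicators.values() for t in lv]

    def validate(self) -> None:
        seen: set[str] = set()
        for lv, taxa in self.lv_indicators.items():
            if len(taxa) < 3:
                raise SpecificationError(
                    f"{lv} has {len(taxa)} indicator(s); need >= 3 for identification")
            overlap = seen & set(taxa)
            if overlap:
                raise SpecificationError(
                    f"taxa assigned to more than one latent variable: {sorted(overlap)}")
            seen |= set(taxa)
        if self.disease_indicator in seen:
            raise SpecificationError("disease indicator cannot also be a taxon indicator")

    def without(self, taxon: str) -> "SemSpec":
        new = copy.deepcopy(self)
        for lv in new.lv_indicators:
            new.lv_indicators[lv] = [t for t in new.lv_indicators[lv] if t != taxon]
        return new

    def to_text(self) -> str:
        """Human-readable syntax: ``lv1 =~ taxonA + taxonB``."""
        lines = [f"{lv} =~ " + " + ".join(taxa)
                 for lv, taxa in self.lv_indicators.items()]
        if self.disease_indicator:
            lines.append(f"{self.disease_indicator} ~ " + " + ".join(self.lv_indicators))
        if len(self.lv_indicators) == 2 and self.latent_correlation_free:
            a, b = self.latent_names
            lines.append(f"{a} ~~ {b}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return asdict(self)


def build_spec(effects: pd.DataFrame, mode: str = "two_lv",
               disease_indicator: str = "disease_flg") -> SemSpec:
    """Assign classified taxa to latent variables.

    two_lv: class == "more" -> lv1, class == "less" -> lv2, free lv1-lv2
    correlation, both regress on the disease path. one_lv: "more" -> lv1 only.
    """
    more = effects.loc[effects["class"] == "more", "taxon"].tolist()
    less = effects.loc[effects["class"] == "less", "taxon"].tolist()
    if mode == "two_lv":
        spec = SemSpec({"lv1": more, "lv2": less}, disease_indicator)
    elif mode == "one_lv":
        spec = SemSpec({"lv1": more}, disease_indicator)
    else:
        raise SpecificationError(f"unknown mode {mode!r}")
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# mixed (Pearson + polyserial) correlation input
# ---------------------------------------------------------------------------

@dataclass
class MixedCorrelations:
    """Sample moments handed to DWLS: correlations, threshold, weights.

    avar_* are asymptotic variances of the sqrt(n)-scaled statistics
    (delta-method (1-r^2)^2 for Pearson; unit variance for polyserial — a
    documented simplification; p(1-p)/phi(tau)^2 for the threshold).
    """

    variables: list[str]
    pearson: np.ndarray                 # (p, p)
    polyserial: np.ndarray | None       # (p,)
    threshold: float | None
    avar_pearson: np.ndarray            # (p, p)
    avar_polyserial: np.ndarray | None  # (p,)
    avar_threshold: float | None
    n: int

    def subset(self, variables: list[str]) -> "MixedCorrelations":
        idx = [self.variables.index(v) for v in variables]
        return MixedCorrelations(
            list(variables),
            self.pearson[np.ix_(idx, idx)],
            None if self.polyserial is None else self.polyserial[idx],
            self.threshold,
            self.avar_pearson[np.ix_(idx, idx)],
            None if self.avar_polyserial is None else self.avar_polyserial[idx],
            self.avar_threshold,
            self.n,
        )


def polyserial_corr(x: np.ndarray, y: np.ndarray, tau: float) -> float:
    """Two-step ML polyserial correlation of standardized x with the normal
    latent response underlying binary y, threshold ``tau`` held fixed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)

    def negll(rho: float) -> float:
        s = np.sqrt(max(1.0 - rho * rho, 1e-12))
        z = (tau - rho * x) / s
        p1 = stats.norm.sf(z)
        p1 = np.clip(p1, 1e-300, 1.0)
        p0 = np.clip(1.0 - p1, 1e-300, 1.0)
        return -(np.where(y == 1, np.log(p1), np.log(p0))).sum()

    res = optimize.minimize_scalar(negll, bounds=(-0.995, 0.995),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def mixed_correlations(clr: pd.DataFrame, disease=None) -> MixedCorrelations:
    """Pearson correlations among CLR columns plus, when a binary disease
    vector is given, polyserial correlations and the probit threshold."""
    variables = list(clr.columns)
    X = clr.to_numpy(dtype=float)
    n = X.shape[0]
    sd = X.std(axis=0, ddof=1)
    for v, s in zip(variables, sd):
        if s <= 0 or not np.isfinite(s):
            raise DegenerateVariableError(f"constant CLR column: {v!r}")
    Xs = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Xs, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    avar_R = (1.0 - R ** 2) ** 2
    avar_R = np.maximum(avar_R, 1e-8)

    if disease is None:
        return MixedCorrelations(variables, R, None, None, avar_R, None, None, n)

    y = np.asarray(disease, dtype=int)
    if y.min() == y.max():
        raise InsufficientDataError("disease indicator must have both classes")
    p_case = y.mean()
    tau = float(stats.norm.ppf(1.0 - p_case))  # P(y* > tau) = case proportion
    ps = np.array([polyserial_corr(Xs[:, j], y, tau) for j in range(len(variables))])
    avar_ps = np.ones_like(ps)  # unit per-observation variance (fallback rule)
    avar_tau = p_case * (1 - p_case) / max(stats.norm.pdf(tau) ** 2, 1e-12)
    return MixedCorrelations(variables, R, ps, tau, avar_R, avar_ps,
                             float(avar_tau), n)


# ---------------------------------------------------------------------------
# DWLS fitting
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    loadings: dict[str, float]
    residual_variances: dict[str, float]
    path_coefficients: dict[str, float]
    latent_correlation: float | None
    threshold: float | None
    chi2: float
    df: int
    gfi: float
    agfi: float
    rmsea: float
    f_min: float
    n: int
    n_moments: int
    converged: bool
    spec: SemSpec = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spec"] = self.spec.to_dict() if self.spec else None
        return d


def _model_matrices(spec: SemSpec, params: np.ndarray, p: int, q: int,
                    lv_index: np.ndarray, has_disease: bool):
    lam = params[:p]
    pos = p
    psi = np.eye(q)
    if q == 2 and spec.latent_correlation_free:
        psi[0, 1] = psi[1, 0] = params[pos]
        pos += 1
    beta = params[pos:pos + q] if has_disease else None
    Lam = np.zeros((p, q))
    Lam[np.arange(p), lv_index] = lam
    return lam, Lam, psi, beta


def _implied_moments(Lam, psi, beta, iu):
    sxx = (Lam @ psi @ Lam.T)[iu]
    if beta is None:
        return sxx, None
    sxy = Lam @ (psi @ beta)
    return sxx, sxy


def fit_dwls(spec: SemSpec, corr: MixedCorrelations, n: int | None = None,
             n_restarts: int = 5, seed: int = 0, tol: float = 1e-10) -> SemFit:
    """Fit the model by diagonally weighted least squares.

    The correlation matrix is used as given (ridge-repaired to positive
    semidefinite if needed); the probit threshold is a saturated parameter
    fitting its sample moment exactly.
    """
    spec.validate()
    n = corr.n if n is None else n
    sub = corr.subset(spec.indicators)
    p = len(sub.variables)
    q = len(spec.latent_names)
    lv_index = np.zeros(p, dtype=int)
    offset = 0
    for k, lv in enumerate(spec.latent_names):
        m = len(spec.lv_indicators[lv])
        lv_index[offset:offset + m] = k
        offset += m
    has_disease = spec.disease_indicator is not None and sub.polyserial is not None

    R = sub.pearson
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < 0:
        logger.info("ridge repair of correlation matrix (min eigenvalue %.3g)", eigmin)
        R = (R + (1e-6 - eigmin) * np.eye(p)) / (1.0 + 1e-6 - eigmin)

    iu = np.triu_indices(p, 1)
    s_xx = R[iu]
    w_xx = 1.0 / sub.avar_pearson[iu]
    if has_disease:
        s_xy = sub.polyserial
        w_xy = 1.0 / sub.avar_polyserial
    psi_free = q == 2 and spec.latent_correlation_free
    n_free = p + (1 if psi_free else 0) + (q if has_disease else 0) \
        + (1 if has_disease else 0)  # + threshold (saturated)
    n_moments = p * (p - 1) // 2 + (p + 1 if has_disease else 0)
    df = n_moments - n_free

    cross = (lv_index[:, None] != lv_index[None, :]).astype(float)

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        """DWLS discrepancy and its analytic gradient."""
        lam, Lam, psi, beta = _model_matrices(spec, params, p, q, lv_index, has_disease)
        sxx, sxy = _implied_moments(Lam, psi, beta, iu)
        rxx = s_xx - sxx
        f = float(np.sum(w_xx * rxx ** 2))

        # symmetric weighted-residual matrix for the Pearson block
        E = np.zeros((p, p))
        E[iu] = w_xx * rxx
        E = E + E.T
        psi_exp = psi[np.ix_(lv_index, lv_index)]
        g_lam = -2.0 * ((E * psi_exp) @ lam)
        g_psi = -float(lam @ (E * cross) @ lam) if psi_free else None
        g_beta = None

        if has_disease:
            u = psi @ beta                       # cov(latent, disease response)
            ry = s_xy - sxy
            f += float(np.sum(w_xy * ry ** 2))
            wr = w_xy * ry
            g_lam += -2.0 * wr * u[lv_index]
            g_beta = -2.0 * np.array(
                [np.sum(wr * lam * psi[lv_index, m]) for m in range(q)])
            if psi_free:
                other = 1 - lv_index            # q = 2: the other latent
                g_psi += -2.0 * float(np.sum(wr * lam * beta[other]))
            # keep the disease latent response a valid correlation structure
            ev = float(beta @ psi @ beta)
            if ev > 0.999:
                f += 1e3 * (ev - 0.999) ** 2
                g_beta += 4e3 * (ev - 0.999) * u
                if psi_free:
                    g_psi += 2e3 * (ev - 0.999) * 2.0 * beta[0] * beta[1]

        grad = list(g_lam)
        if psi_free:
            grad.append(g_psi)
        if has_disease:
            grad.extend(g_beta)
        return f, np.asarray(grad)

    # data-driven start: loadings from correlation with the lv's first indicator
    lam0 = np.empty(p)
    offset = 0
    for lv in spec.latent_names:
        m = len(spec.lv_indicators[lv])
        block = slice(offset, offset + m)
        lam0[offset] = 0.7
        if m > 1:
            lam0[offset + 1:offset + m] = np.clip(R[offset, offset + 1:offset + m] / 0.7,
                                                  -0.9, 0.9)
        offset += m
    x0 = list(lam0)
    if psi_free:
        blocks = [np.flatnonzero(lv_index == k) for k in range(q)]
        cross_mean = R[np.ix_(blocks[0], blocks[1])].mean()
        x0.append(float(np.clip(cross_mean / 0.49, -0.9, 0.9)))
    if has_disease:
        x0.extend([0.2] * q)
    x0 = np.asarray(x0)

    bounds = [(-0.995, 0.995)] * p
    if psi_free:
        bounds.append((-0.995, 0.995))
    if has_disease:
        bounds.extend([(-3.0, 3.0)] * q)

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        start = x0 if r == 0 else np.clip(
            x0 + rng.normal(0, 0.15, x0.shape),
            [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(objective, start, method="L-BFGS-B", jac=True,
                                bounds=bounds,
                                options={"maxiter": 2000, "ftol": tol, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise NonConvergenceError("DWLS optimization failed in all restarts",
                                  best_objective=None if best is None else best.fun)

    lam, Lam, psi, beta = _model_matrices(spec, best.x, p, q, lv_index, has_disease)
    lam = lam.copy()
    psi = psi.copy()
    beta = None if beta is None else beta.copy()
    # sign convention: first indicator of each latent loads non-negatively
    offset = 0
    for k, lv in enumerate(spec.latent_names):
        m = len(spec.lv_indicators[lv])
        if lam[offset] < 0:
            lam[offset:offset + m] *= -1.0
            psi[k, :] *= -1.0
            psi[:, k] *= -1.0
            psi[k, k] = 1.0
            if beta is not None:
                beta[k] *= -1.0
        offset += m

    f_min = float(best.fun)
    chi2 = max((n - 1) * f_min, 0.0)
    f_base = float(np.sum(w_xx * s_xx ** 2))
    if has_disease:
        f_base += float(np.sum(w_xy * s_xy ** 2))
        f_base += (sub.threshold ** 2) / sub.avar_threshold
    gfi = 1.0 - f_min / f_base if f_base > 0 else 1.0
    if df > 0:
        agfi = 1.0 - (1.0 - gfi) * n_moments / df
        rmsea = float(np.sqrt(max((chi2 - df) / (df * (n - 1)), 0.0)))
    else:
        logger.info("saturated model (df = 0): fit indices reported by convention")
        gfi, agfi, rmsea = 1.0, float("nan"), 0.0

    taxa = sub.variables
    loadings = {t: float(v) for t, v in zip(taxa, lam)}
    resid = {t: float(max(1.0 - v * v, 0.0)) for t, v in zip(taxa, lam)}
    paths = ({lv: float(beta[k]) for k, lv in enumerate(spec.latent_names)}
             if beta is not None else {})
    latent_corr = float(psi[0, 1]) if q == 2 else None
    return SemFit(loadings, resid, paths, latent_corr,
                  sub.threshold if has_disease else None,
                  chi2, int(df), float(gfi), float(agfi), float(rmsea),
                  f_min, n, int(n_moments), bool(best.success), spec)


# ---------------------------------------------------------------------------
# pruning, collapse, measurement extraction
# ---------------------------------------------------------------------------

def _targets_met(fit: SemFit, targets: dict) -> bool:
    if fit.df == 0:
        return True
    return (fit.gfi >= targets["gfi_min"] and fit.agfi >= targets["agfi_min"]
            and fit.rmsea <= targets["rmsea_max"])


def _composite(fit: SemFit) -> float:
    agfi = fit.agfi if np.isfinite(fit.agfi) else fit.gfi
    return fit.gfi + agfi - fit.rmsea


def prune_indicators(spec: SemSpec, corr: MixedCorrelations,
                     targets: dict | None = None, min_per_lv: int = 3,
                     n: int | None = None, seed: int = 0
                     ) -> tuple[SemSpec, SemFit, list[dict]]:
    """Backward indicator reduction against fit-index targets.

    While the targets (GFI, AGFI minima; RMSEA maximum) are unmet, the
    weakest removable indicator — the one with the smallest absolute
    standardized loading in the current fit — is dropped and the model
    refit. An uninformative indicator carries no shared variance, so it is
    always sacrificed before a well-loading one; the rule is deterministic
    given the data (ties break on indicator order). Raises
    PruningFailureError with the full trajectory when the minimum model
    size is reached before the targets are met.
    """
    targets = dict(DEFAULT_FIT_TARGETS if targets is None else targets)
    log: list[dict] = []
    current = copy.deepcopy(spec)
    fit = fit_dwls(current, corr, n=n, seed=seed)
    while not _targets_met(fit, targets):
        candidates = [t for lv, taxa in current.lv_indicators.items()
                      if len(taxa) > min_per_lv for t in taxa]
        if not candidates:
            raise PruningFailureError(
                "fit targets unreachable at minimum indicators per latent variable",
                trajectory=log + [{"spec": current.to_dict(),
                                   "gfi": fit.gfi, "agfi": fit.agfi,
                                   "rmsea": fit.rmsea}])
        drop = min(candidates, key=lambda t: abs(fit.loadings[t]))
        current = current.without(drop)
        fit = fit_dwls(current, corr, n=n, seed=seed)
        log.append({"dropped": drop, "gfi": fit.gfi, "agfi": fit.agfi,
                    "rmsea": fit.rmsea, "chi2": fit.chi2, "df": fit.df,
                    "composite": _composite(fit)})
    return current, fit, log


def check_latent_collapse(fit: SemFit,
                          corr_threshold: float = DEFAULT_COLLAPSE_THRESHOLD) -> str:
    """Recommend collapsing to one latent when |lv1-lv2 correlation| >= threshold."""
    if fit.latent_correlation is None:
        raise SpecificationError("latent collapse check requires a two-lv fit")
    return ("collapse_to_one" if abs(fit.latent_correlation) >= corr_threshold
            else "keep_two")


def extract_measurement_model(spec: SemSpec) -> SemSpec:
    """Drop the disease indicator and structural paths; keep the latent
    correlation in the two-lv case. Idempotent."""
    new = copy.deepcopy(spec)
    new.disease_indicator = None
    return new


# ---------------------------------------------------------------------------
# factor scores
# ---------------------------------------------------------------------------

def _score_matrices(fit: SemFit):
    spec = fit.spec
    taxa = spec.indicators
    q = len(spec.latent_names)
    p = len(taxa)
    Lam = np.zeros((p, q))
    offset = 0
    for k, lv in enumerate(spec.latent_names):
        for t in spec.lv_indicators[lv]:
            Lam[taxa.index(t), k] = fit.loadings[t]
    psi = np.eye(q)
    if q == 2 and fit.latent_correlation is not None:
        psi[0, 1] = psi[1, 0] = fit.latent_correlation
    theta = np.diag([fit.residual_variances[t] for t in taxa])
    return taxa, Lam, psi, theta


def factor_scores(fit: SemFit, clr: pd.DataFrame,
                  standardize: bool = True) -> pd.DataFrame:
    """Empirical-Bayes (regression-method) latent scores.

    score = Psi Lambda' (Lambda Psi Lambda' + Theta)^{-1} x per standardized
    sample row x; deterministic given the fit and data.
    """
    taxa, Lam, psi, theta = _score_matrices(fit)
    X = clr[taxa].to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    sigma = Lam @ psi @ Lam.T + theta
    cond = np.linalg.cond(sigma)
    if not np.isfinite(cond) or cond > 1e12:
        raise NumericalError(f"implied covariance is singular (condition number {cond:.3g})")
    B = np.linalg.solve(sigma, Lam @ psi)  # (p, q)
    scores = X @ B
    return pd.DataFrame(scores, index=clr.index, columns=fit.spec.latent_names)


def blinded_factor_scores(spec: SemSpec, clr: pd.DataFrame,
                          seed: int = 0) -> tuple[SemFit, pd.DataFrame]:
    """Refit the measurement model with disease status withheld, then score.

    This is the disease-blinded scoring step: the pure CFA is re-estimated on
    the CLR data alone (not sliced from the joint fit) and empirical-Bayes
    scores are computed from that refit.
    """
    meas = extract_measurement_model(spec)
    corr = mixed_correlations(clr[meas.indicators])
    fit = fit_dwls(meas, corr, seed=seed)
    return fit, factor_scores(fit, clr)
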