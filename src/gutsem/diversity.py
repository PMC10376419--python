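"""Alpha diversity, Bray-Curtis beta diversity, NMDS ordination, PERMANOVA.

Diversity is computed on raw genus-level proportions (not CLR). The
PERMANOVA pseudo-F follows Anderson's formulation on squared Bray-Curtis
distances, with either Monte-Carlo label permutations or exhaustive
enumeration of group assignments for tiny designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .data_io import CountTable
from .exceptions import DomainError, InsufficientDataError

logger = logging.getLogger(__name__)


def _as_matrix(counts) -> np.ndarray:
    if isinstance(counts, CountTable):
        return counts.counts.astype(float)
    return np.asarray(counts, dtype=float)


def alpha_diversity(counts) -> pd.DataFrame:
    """Per-sample Shannon (nats), Simpson (1 - sum p^2), richness, Pielou.

    Pielou is H / ln(richness) and is reported as NaN when richness = 1.
    """
    x = _as_matrix(counts)
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        raise DomainError("all-zero sample row")
    p = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (p ** 2).sum(axis=1)
    richness = (x > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(richness > 1, shannon / np.log(richness), np.nan)
    index = counts.sample_ids if isinstance(counts, CountTable) else None
    return pd.DataFrame({"shannon": shannon, "simpson": simpson,
                         "richness": richness, "pielou": pielou}, index=index)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    @property
    def n(self) -> int:
        return self.values.shape[0]


def bray_curtis(counts) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on counts: 1 - 2 sum(min) / (sum A + sum B)."""
    x = _as_matrix(counts)
    if np.any(x.sum(axis=1) <= 0):
        raise DomainError("all-zero sample row")
    d = squareform(pdist(x, metric="braycurtis"))
    ids = (list(counts.sample_ids) if isinstance(counts, CountTable)
           else [f"s{i}" for i in range(x.shape[0])])
    return DistanceMatrix(ids, d)


@dataclass
class Ordination:
    coordinates: np.ndarray  # (n_samples, k), centered
    stress: float            # Kruskal stress-1
    n_restarts: int
    sample_ids: list[str]


def nmds(d: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         seed: int = 0, max_iter: int = 300, tol: float = 1e-7) -> Ordination:
    """Non-metric MDS minimizing Kruskal stress-1, best of ``n_restarts`` starts."""
    if k >= d.n:
        raise DomainError(f"k = {k} must be < n_samples = {d.n}")
    model = MDS(n_components=k, metric_mds=False, n_init=n_restarts,
                init="random", max_iter=max_iter, eps=tol, metric="precomputed",
                random_state=seed, normalized_stress=True)
    coords = model.fit_transform(d.values)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return Ordination(coords, float(model.stress_), n_restarts, list(d.sample_ids))


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(d: DistanceMatrix, labels, n_permutations: int = 9999,
              seed: int = 0, exhaustive: bool = False) -> PermanovaResult:
    """Permutation PERMANOVA on squared distances (Anderson's pseudo-F).

    p = (1 + #{perm F >= observed}) / (1 + n_permutations) for Monte-Carlo
    label permutations; with ``exhaustive`` every distinct assignment of
    labels is enumerated and p is the exact tail proportion.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2 or counts.min() < 2:
        raise InsufficientDataError("need >= 2 groups with >= 2 samples each")
    d2 = d.values ** 2
    f_obs = _pseudo_f(d2, labels, groups)

    if exhaustive:
        if len(groups) != 2:
            raise InsufficientDataError("exhaustive enumeration supports 2 groups")
        n = len(labels)
        n1 = counts[0]
        hits = total = 0
        for idx in combinations(range(n), n1):
            perm = np.full(n, groups[1], dtype=labels.dtype)
            perm[list(idx)] = groups[0]
            total += 1
            if _pseudo_f(d2, perm, groups) >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(f_obs, hits / total, total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _pseudo_f(d2, perm, groups) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(f_obs, p, n_permutations)


def write_ordination(ord_: Ordination, path) -> None:
    cols = {f"nmds{i + 1}": ord_.coordinates[:, i]
            for i in range(ord_.coordinates.shape[1])}
    df = pd.DataFrame({"sample_id": ord_.sample_ids, **cols})
    df.attrs["stress"] = ord_.stress
    with open(path, "w") as fh:
        fh.write(f"# stress\t{ord_.stress:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)


def plot_ordination(ord_: Ordination, labels, path) -> None:
    """Optional 2-D scatter with 95% confidence ellipses per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for g, color in zip(np.unique(labels), ("tab:red", "tab:blue", "tab:green")):
        pts = ord_.coordinates[labels == g][:, :2]
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=color, label=str(g))
        if len(pts) >= 3:
            cov = np.cov(pts.T)
            vals, vecs = np.linalg.eigh(cov)
            angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
            w, h = 2 * np.sqrt(np.maximum(vals, 0) * 5.991)  # chi2_2 95%
            ax.add_patch(Ellipse(pts.mean(axis=0), w, h, angle=angle,
                                 fill=False, color=color, lw=1))
    ax.set_xlabel("NMDS1")
    ax.set_ylabel("NMDS2")
    ax.legend(frameon=False)
    ax.set_title(f"stress = {ord_.stress:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
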