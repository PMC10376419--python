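"""Centered log-ratio (CLR) transforms of count compositions.

Sequencing counts only carry relative information, so downstream statistics
operate on log-ratio coordinates. Two variants are provided: a deterministic
point estimate with a pseudo-count prior, and a Dirichlet Monte-Carlo
ensemble in which each instance draws the latent composition from the
posterior Dirichlet(x + prior) before applying the CLR — the representation
the differential-abundance effect sizes are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import CountTable
from .exceptions import ConfigurationError, DomainError

DEFAULT_PRIOR = 0.5
DEFAULT_N_INSTANCES = 128


@dataclass
class ClrEnsemble:
    """Monte-Carlo instances of CLR matrices sharing shape and taxon order."""

    instances: np.ndarray  # (n_instances, n_samples, n_taxa)
    prior: float
    seed: int
    sample_ids: list[str]
    taxon_ids: list[str]

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]


def _as_matrix(counts) -> np.ndarray:
    if isinstance(counts, CountTable):
        return counts.counts.astype(float)
    return np.asarray(counts, dtype=float)


def clr_point_estimate(counts, prior: float = DEFAULT_PRIOR) -> np.ndarray:
    """CLR of (counts + prior): ln(x_i + prior) - mean_j ln(x_j + prior)."""
    x = _as_matrix(counts)
    if prior < 0:
        raise ConfigurationError("prior must be >= 0")
    if prior == 0 and np.any(x <= 0):
        raise DomainError("zero count with prior = 0")
    lx = np.log(x + prior)
    return lx - lx.mean(axis=-1, keepdims=True)


def dirichlet_clr(counts, n_instances: int = DEFAULT_N_INSTANCES,
                  prior: float = DEFAULT_PRIOR, seed: int = 0) -> ClrEnsemble:
    """Dirichlet Monte-Carlo CLR ensemble (ALDEx2-style transform).

    Instance k draws, per sample x, p ~ Dirichlet(x + prior) and returns
    CLR(p). Reproducible from ``seed``.
    """
    if n_instances < 1:
        raise ConfigurationError("n_instances must be >= 1")
    if prior <= 0:
        raise ConfigurationError("Dirichlet prior must be > 0")
    x = _as_matrix(counts)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    alpha = x + prior
    # gamma draws normalize to Dirichlet; CLR only needs logs so the
    # normalizing constant cancels in the centering step
    g = rng.standard_gamma(alpha[None, :, :].repeat(n_instances, axis=0))
    g = np.maximum(g, np.finfo(float).tiny)
    lg = np.log(g)
    inst = lg - lg.mean(axis=-1, keepdims=True)
    if isinstance(counts, CountTable):
        sids, tids = list(counts.sample_ids), list(counts.taxon_ids)
    else:
        sids = [f"s{i}" for i in range(n)]
        tids = [f"t{j}" for j in range(p)]
    return ClrEnsemble(inst, prior, seed, sids, tids)


def ensemble_mean(ens: ClrEnsemble) -> np.ndarray:
    """Element-wise mean across instances; rows still sum to zero."""
    return ens.instances.mean(axis=0)
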