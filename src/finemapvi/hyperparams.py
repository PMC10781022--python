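"""Local-heritability-based hyperparameters.

Instead of estimating the effect-size variance and residual variance inside
the variational loop, both precisions are derived once from an estimate of
the locus' local heritability h² (the share of trait variance explained by
all variants in the locus), obtained from summary statistics alone:

    ĥ² = (zᵀ R⁺ z − p) / (N − p)

with R⁺ the eigenvalue-truncated pseudo-inverse of the LD matrix and p the
number of retained eigenvalues.  For a trait standardized to unit variance,
K effects sharing h² give

    τ_y = 1 / (1 − h²)        (residual precision)
    τ_β = K / h²              (per-effect prior precision, variance h²/K)

An alternative ``strategy="full"`` assigns the whole h² to each effect
(τ_β = 1/h²) for users who prefer a less shrunk prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import LocusData

log = logging.getLogger(__name__)

H2_FLOOR = 1e-6
H2_CEIL = 0.9


class DegenerateLDError(ValueError):
    """All LD eigenvalues fall below the truncation threshold."""


@dataclass(frozen=True)
class Hyperparameters:
    """Precisions of the sparse-effect model, in standardized-trait units."""

    h2_local: float
    tau_beta: float
    tau_y: float
    k_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.h2_local < 1):
            raise ValueError(f"h2_local must be in [0, 1), got {self.h2_local}")
        if self.tau_beta <= 0 or self.tau_y <= 0:
            raise ValueError("precisions must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


def estimate_local_h2(locus: LocusData, eig_threshold: float = 1e-3) -> float:
    """Estimate local heritability from z-scores and the LD matrix.

    Eigenvalues below ``eig_threshold`` times the largest eigenvalue are
    truncated from the pseudo-inverse.  The estimate is clipped to
    [1e-6, 0.9]: a negative estimate (common under the null) is floored
    rather than re-estimated, and values near 1 would blow up τ_y.
    """
    if locus.ld is None:
        raise ValueError("locus has no LD matrix attached")
    if not (0 < eig_threshold <= 1):
        raise ValueError("eig_threshold must be in (0, 1]")
    vals, vecs = np.linalg.eigh(locus.ld)
    keep = vals >= eig_threshold * vals.max()
    p = int(keep.sum())
    if p == 0:
        raise DegenerateLDError("no LD eigenvalue above the truncation threshold")
    proj = vecs[:, keep].T @ locus.z            # coordinates in retained eigenspace
    quad = float(np.sum(proj**2 / vals[keep]))  # zᵀ R⁺ z
    n = locus.n
    h2 = (quad - p) / (n - p)
    if h2 < H2_FLOOR:
        log.info("local h2 estimate %.3g below floor; clipped to %.0e", h2, H2_FLOOR)
    return float(np.clip(h2, H2_FLOOR, H2_CEIL))


def derive_precisions(h2_local: float, k: int, strategy: str = "split") -> Hyperparameters:
    """Convert local heritability into model precisions.

    ``strategy="split"`` (default) gives each of the K effects prior variance
    h²/K; ``strategy="full"`` gives each effect the full h².
    """
    if not (0 < h2_local < 1):
        raise ValueError(f"h2_local must be in (0, 1), got {h2_local}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if strategy == "split":
        tau_beta = k / h2_local
    elif strategy == "full":
        tau_beta = 1.0 / h2_local
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return Hyperparameters(
        h2_local=h2_local,
        tau_beta=tau_beta,
        tau_y=1.0 / (1.0 - h2_local),
        k_max=k,
    )


def estimate_hyperparameters(
    locus: LocusData, k: int, eig_threshold: float = 1e-3, strategy: str = "split"
) -> Hyperparameters:
    """Convenience composition: local h² estimate then precision derivation."""
    return derive_precisions(estimate_local_h2(locus, eig_threshold), k, strategy)
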