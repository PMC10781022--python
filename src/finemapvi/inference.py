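"""Paired mean-field variational inference for the sum-of-single-effects model.

The trait is modelled as y ~ N(X S β, τ_y⁻¹ I) where S = [s_1, …, s_K]
holds K one-hot selection indicators s_k ~ Multinomial(1, π̃) and each
effect size β_k ~ N(0, τ_β⁻¹).  With genotypes and trait standardized,
only summary-level sufficient statistics enter the updates:

    XᵀX ≈ N·R        (R the LD matrix of Pearson correlations)
    Xᵀy ≈ z·√N       (z the GWAS z-scores)
    yᵀy ≈ N

Coordinate ascent over the K groups maximizes the evidence lower bound
(ELBO); each group update is available in closed form.  No matrix is ever
inverted, so rank-deficient LD matrices run to completion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hyperparams import Hyperparameters
from .io import LocusData

log = logging.getLogger(__name__)

_REFRESH_EVERY = 10  # sweeps between from-scratch residual refreshes


class NumericalError(FloatingPointError):
    """A selection score became non-finite during inference."""


@dataclass
class EffectGroupPosterior:
    """Variational posterior of one effect group.

    ``gamma`` is the selection distribution over the G variants (simplex);
    ``mu`` and ``s2`` are the effect mean and variance *conditional on* the
    group selecting each variant.
    """

    gamma: np.ndarray
    mu: np.ndarray
    s2: np.ndarray

    def validate(self) -> None:
        if abs(self.gamma.sum() - 1.0) > 1e-8 or np.any(self.gamma < 0):
            raise ValueError("gamma must be a probability simplex")
        if np.any(self.s2 <= 0):
            raise ValueError("posterior variances must be positive")

    @property
    def mean_effect(self) -> np.ndarray:
        """E[s_k β_k] per variant."""
        return self.gamma * self.mu


@dataclass
class ModelState:
    """Full variational state for one locus."""

    groups: list[EffectGroupPosterior]
    priors: np.ndarray                 # π̃, length G
    hyper: Hyperparameters
    xty: np.ndarray                    # b = z·√N
    elbo: float = -np.inf
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def k(self) -> int:
        return len(self.groups)

    def pip(self) -> np.ndarray:
        from .summary import compute_pip

        return compute_pip(self.groups)


def _init_state(locus: LocusData, priors: np.ndarray, hyper: Hyperparameters, k: int) -> ModelState:
    g = locus.g
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (g,) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-8:
        raise ValueError("priors must be a length-G probability vector")
    tau_star = locus.n * hyper.tau_y + hyper.tau_beta
    groups = [
        EffectGroupPosterior(
            gamma=np.full(g, 1.0 / g),
            mu=np.zeros(g),
            s2=np.full(g, 1.0 / tau_star),
        )
        for _ in range(k)
    ]
    return ModelState(
        groups=groups, priors=priors, hyper=hyper, xty=locus.z * np.sqrt(locus.n)
    )


def update_effect_group(
    state: ModelState,
    locus: LocusData,
    k: int,
    r_total: np.ndarray | None = None,
) -> np.ndarray | None:
    """Closed-form coordinate update of group ``k`` (0-based); mutates state.

    ``r_total`` may carry the precomputed vector R @ Σ_k E[s_k β_k]; when
    given it is updated in place and returned, saving a matrix-vector
    product per call.
    """
    if not (0 <= k < state.k):
        raise IndexError(f"group index {k} out of range for K={state.k}")
    hyper = state.hyper
    n = locus.n
    grp = state.groups[k]

    if r_total is None:
        m_all = sum(g.mean_effect for g in state.groups)
        r_total = locus.ld @ m_all
    m_k_old = grp.mean_effect
    r_others = state.xty - n * (r_total - locus.ld @ m_k_old)

    tau_star = n * hyper.tau_y + hyper.tau_beta
    mu = hyper.tau_y * r_others / tau_star
    u = np.log(state.priors, where=state.priors > 0, out=np.full(locus.g, -np.inf))
    u += 0.5 * np.log(hyper.tau_beta / tau_star) + 0.5 * mu**2 * tau_star
    if not np.all(np.isfinite(u[state.priors > 0])):
        bad = int(np.argmax(~np.isfinite(u)))
        raise NumericalError(
            f"non-finite selection score for variant {locus.variants[bad].id}"
        )
    u -= u.max()
    gamma = np.exp(u)
    gamma /= gamma.sum()

    grp.gamma = gamma
    grp.mu = mu
    grp.s2 = np.full(locus.g, 1.0 / tau_star)
    r_total += locus.ld @ (grp.mean_effect - m_k_old)
    return r_total


def compute_elbo(state: ModelState, locus: LocusData) -> float:
    """Evidence lower bound assembled from summary-statistic moments.

    Deterministic in the state; the expected log-likelihood uses
    E[s_kβ_k] and E[(s_kβ_k)²] with yᵀy = N, and the KL terms are the
    categorical KL of each gamma against π̃ plus the conditional Gaussian
    KL of each effect size against N(0, τ_β⁻¹).
    """
    hyper = state.hyper
    n = locus.n
    m = np.array([g.mean_effect for g in state.groups])          # (K, G)
    v = np.array([g.gamma * (g.mu**2 + g.s2) for g in state.groups])

    rm = m @ locus.ld                                            # (K, G)
    cross_all = float(np.einsum("kg,jg->", rm, m))
    cross_self = float(np.einsum("kg,kg->", rm, m))
    quad = n * (cross_all - cross_self) + n * float(v.sum())

    ll = 0.5 * n * np.log(hyper.tau_y / (2 * np.pi)) - 0.5 * hyper.tau_y * (
        n - 2.0 * float(m.sum(axis=0) @ state.xty) + quad
    )

    kl = 0.0
    logp = np.log(state.priors, where=state.priors > 0, out=np.full(locus.g, -np.inf))
    for grp in state.groups:
        gz = grp.gamma > 0
        kl += float(np.sum(grp.gamma[gz] * (np.log(grp.gamma[gz]) - logp[gz])))
        kl_gauss = 0.5 * (
            hyper.tau_beta * (grp.mu**2 + grp.s2) - 1.0 - np.log(hyper.tau_beta * grp.s2)
        )
        kl += float(np.sum(grp.gamma * kl_gauss))
    return ll - kl


def fit(
    locus: LocusData,
    priors: np.ndarray | None = None,
    hyper: Hyperparameters | None = None,
    k: int = 10,
    tol: float = 1e-2,
    pip_tol: float = 1e-4,
    max_iter: int = 100,
    track: str = "sweep",
) -> ModelState:
    """Coordinate-ascent fit of the K-effect-group model on one locus.

    Groups are initialized with uniform gamma and zero effect means and
    swept in order 1..K until the ELBO gain drops below ``tol`` nats or the
    maximum absolute PIP change drops below ``pip_tol``.  Non-convergence
    sets ``converged=False`` on the result instead of raising.

    ``track="update"`` records the ELBO after every coordinate update
    (slower); the default records it once per sweep.  The trace is
    non-decreasing either way.
    """
    if locus.ld is None:
        raise ValueError("locus has no LD matrix attached")
    if k < 1:
        raise ValueError("k must be >= 1")
    if hyper is None:
        from .hyperparams import estimate_hyperparameters

        hyper = estimate_hyperparameters(locus, k)
    if priors is None:
        priors = np.full(locus.g, 1.0 / locus.g)

    state = _init_state(locus, priors, hyper, k)
    state.elbo = compute_elbo(state, locus)
    state.elbo_trace.append(state.elbo)

    r_total = locus.ld @ sum(g.mean_effect for g in state.groups)
    prev_pip = state.pip()
    gain = np.inf
    for sweep in range(max_iter):
        if sweep and sweep % _REFRESH_EVERY == 0:
            r_total = locus.ld @ sum(g.mean_effect for g in state.groups)
        for kk in range(state.k):
            r_total = update_effect_group(state, locus, kk, r_total)
            if track == "update":
                state.elbo_trace.append(compute_elbo(state, locus))
        new_elbo = state.elbo_trace[-1] if track == "update" else compute_elbo(state, locus)
        if track != "update":
            state.elbo_trace.append(new_elbo)
        gain = new_elbo - state.elbo
        state.elbo = new_elbo
        pip = state.pip()
        dpip = float(np.max(np.abs(pip - prev_pip)))
        prev_pip = pip
        state.n_iter = sweep + 1
        if gain < tol or dpip < pip_tol:
            state.converged = True
            break
    if not state.converged:
        log.warning(
            "inference did not converge in %d sweeps (last ELBO gain %.3g)",
            max_iter, gain,
        )
    return state
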