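"""Functionally-informed priors from annotation enrichment.

Causal-variant prior inclusion probabilities are parameterized through a
softmax over annotation scores,

    π̃_g = exp(A_gᵀ w) / Σ_g' exp(A_g'ᵀ w),

where A is a binary variant-by-annotation matrix and w the log-scale
enrichment weights (exp(w_m) is annotation m's fold-enrichment among causal
variants).  Weights are estimated jointly from fine-mapping PIPs by
maximizing the PIP-weighted cross-entropy Q(w) = Σ_g PIP_g · log π̃_g(w),
a concave M-estimation problem; standard errors come from the inverse
observed information.  A per-annotation G-test on PIP-weighted soft counts
screens annotations before they are allowed to sharpen the prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from .hyperparams import Hyperparameters, estimate_hyperparameters
from .io import AnnotationMatrix, FineMapResult, LocusData
from .summary import build_credible_sets, signal_pip

log = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-5
WEIGHT_CAP = 10.0


@dataclass
class EnrichmentModel:
    """Jointly estimated enrichment weights with per-annotation G-tests."""

    names: list[str]
    weights: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    g_stat: np.ndarray
    p_value: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        fin = np.isfinite(self.se)
        if np.any(self.ci_low[fin] > self.weights[fin]) or np.any(
            self.weights[fin] > self.ci_high[fin]
        ):
            raise ValueError("confidence bounds must bracket the weights")
        if np.any(self.g_stat < 0):
            raise ValueError("G statistics must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ANNOTATION": self.names,
                "WEIGHT": self.weights,
                "SE": self.se,
                "CI_LOW": self.ci_low,
                "CI_HIGH": self.ci_high,
                "G_STAT": self.g_stat,
                "P_VALUE": self.p_value,
                "SELECTED": self.selected.astype(int),
            }
        )


def softmax_prior(anno: AnnotationMatrix | np.ndarray, w: np.ndarray) -> np.ndarray:
    """Prior inclusion probabilities π̃ from annotation scores (max-subtracted)."""
    a = anno.values if isinstance(anno, AnnotationMatrix) else np.asarray(anno)
    w = np.asarray(w, dtype=float)
    scores = a @ w
    scores -= scores.max()
    e = np.exp(scores)
    return e / e.sum()


def weight_to_fold(w: float, se: float = 0.0) -> tuple[float, float, float]:
    """Fold-enrichment exp(w) with 95% CI exp(w ± 1.96·se)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return float(np.exp(w)), float(np.exp(w - 1.96 * se)), float(np.exp(w + 1.96 * se))


def g_test(anno_col: np.ndarray, pip: np.ndarray) -> tuple[float, float]:
    """Likelihood-ratio test of causal-mass enrichment in one annotation.

    Observed soft counts are the PIP mass inside/outside the annotation;
    expected counts allocate the total PIP mass by annotation prevalence.
    G = 2·Σ O·log(O/E) is referred to a chi-square with 1 df.  All-0 or
    all-1 annotations (and zero total PIP) return (0, 1) with a warning.
    """
    a = np.asarray(anno_col)
    pip = np.asarray(pip, dtype=float)
    g = a.size
    n1 = int(a.sum())
    total = float(pip.sum())
    if n1 == 0 or n1 == g:
        log.warning("G-test undefined for an all-%d annotation; returning p=1", a.flat[0])
        return 0.0, 1.0
    if total <= 0:
        log.warning("G-test undefined with zero total PIP mass; returning p=1")
        return 0.0, 1.0
    o1 = float(pip[a == 1].sum())
    o0 = total - o1
    e1 = total * n1 / g
    e0 = total - e1
    stat = 0.0
    for o, e in ((o1, e1), (o0, e0)):
        if o > 0:
            stat += o * np.log(o / e)
    stat *= 2.0
    stat = max(stat, 0.0)
    return float(stat), float(chi2.sf(stat, df=1))


def _neg_q(w: np.ndarray, a: np.ndarray, pip: np.ndarray, total: float):
    scores = a @ w
    lse = logsumexp(scores)
    val = -(pip @ scores - total * lse)
    pi = np.exp(scores - lse)
    grad = -(a.T @ pip - total * (a.T @ pi))
    return val, grad


def _q_hess(w: np.ndarray, a: np.ndarray, pip: np.ndarray, total: float) -> np.ndarray:
    scores = a @ w
    pi = np.exp(scores - logsumexp(scores))
    ap = a.T * pi
    return total * (ap @ a - np.outer(ap.sum(axis=1), ap.sum(axis=1) / pi.sum()))


def estimate_weights(
    anno: AnnotationMatrix,
    pip: np.ndarray,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> EnrichmentModel:
    """Jointly estimate enrichment weights from PIPs for all M annotations.

    Maximizes the concave PIP-weighted softmax cross-entropy to gradient
    norm < 1e-6; a perfectly separating annotation (all causal mass inside
    or outside it) has its weight capped at ±10 with an infinite SE.
    """
    a = anno.values.astype(float)
    pip = np.asarray(pip, dtype=float)
    total = float(pip.sum())
    if total <= 0:
        raise ValueError("total PIP mass must be positive to estimate enrichment")
    m = anno.m

    sep = np.zeros(m, dtype=bool)
    for j in range(m):
        o1 = float(pip[a[:, j] == 1].sum())
        if o1 == 0.0 or o1 == total:
            sep[j] = True
    if sep.any():
        log.warning(
            "annotation(s) %s perfectly separate the causal mass; weights capped at ±%.0f",
            [anno.names[j] for j in np.flatnonzero(sep)], WEIGHT_CAP,
        )

    res = optimize.minimize(
        _neg_q,
        x0=np.zeros(m),
        args=(a, pip, total),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-WEIGHT_CAP, WEIGHT_CAP)] * m,
        options={"gtol": 1e-8, "ftol": 0.0, "maxiter": 500},
    )
    w = res.x
    # polish with Newton steps toward gradient norm < 1e-6 (interior only)
    for _ in range(50):
        _, grad = _neg_q(w, a, pip, total)
        if np.linalg.norm(grad) < 1e-6:
            break
        h = _q_hess(w, a, pip, total)
        try:
            step = np.linalg.solve(h + 1e-10 * np.eye(m), -grad)
        except np.linalg.LinAlgError:
            break
        w_new = np.clip(w + step, -WEIGHT_CAP, WEIGHT_CAP)
        if _neg_q(w_new, a, pip, total)[0] > _neg_q(w, a, pip, total)[0]:
            break
        w = w_new

    h = _q_hess(w, a, pip, total)
    se = np.full(m, np.inf)
    try:
        cov = np.linalg.inv(h)
        d = np.diag(cov)
        ok = d > 0
        se[ok] = np.sqrt(d[ok])
    except np.linalg.LinAlgError:
        log.warning("singular observed information; standard errors set to inf")
    se[sep] = np.inf
    w[sep] = np.sign(w[sep]) * WEIGHT_CAP

    gs = np.empty(m)
    pv = np.empty(m)
    for j in range(m):
        gs[j], pv[j] = g_test(anno.values[:, j], pip)
    return EnrichmentModel(
        names=list(anno.names),
        weights=w,
        se=se,
        ci_low=w - 1.96 * se,
        ci_high=w + 1.96 * se,
        g_stat=gs,
        p_value=pv,
        selected=pv < p_threshold,
    )


def null_enrichment(names: list[str]) -> EnrichmentModel:
    """The no-information enrichment model: zero weights, nothing selected."""
    m = len(names)
    return EnrichmentModel(
        names=list(names),
        weights=np.zeros(m),
        se=np.full(m, np.inf),
        ci_low=np.full(m, -np.inf),
        ci_high=np.full(m, np.inf),
        g_stat=np.zeros(m),
        p_value=np.ones(m),
        selected=np.zeros(m, dtype=bool),
    )


def _result_from_state(state, locus: LocusData, prior, rho, r2_min, flat) -> FineMapResult:
    sets = build_credible_sets(state.groups, locus.ld, z=locus.z, rho=rho, r2_min=r2_min)
    return FineMapResult(
        variant_ids=locus.ids,
        pip=state.pip(),
        credible_sets=sets,
        elbo_trace=list(state.elbo_trace),
        hyper=state.hyper,
        prior=np.asarray(prior, dtype=float),
        gamma=np.array([g.gamma for g in state.groups]),
        converged=state.converged,
        flat_prior=flat,
    )


def functional_finemap(
    locus: LocusData,
    anno: AnnotationMatrix | None = None,
    hyper: Hyperparameters | None = None,
    k: int = 10,
    rho: float = 0.95,
    r2_min: float = 0.25,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    mode: str = "screened",
    em_rounds: int = 1,
    tol: float = 1e-2,
    max_iter: int = 100,
) -> tuple[FineMapResult, EnrichmentModel | None]:
    """Two-stage functionally-informed fine-mapping of one locus.

    Pass 1 fits with a flat prior (the statistical-evidence-only output).
    Enrichment weights and G-tests are then estimated from the pass-1
    signal PIPs (posterior mass of effect groups passing the
    attainable-coverage filter, so spare groups' uniform leakage does not
    dilute the soft counts); if any annotation survives the screen
    (``mode="screened"``, p below ``p_threshold``) the prior is rebuilt
    from the selected annotations' jointly re-estimated weights and the
    locus is re-fitted.  With ``mode="all"`` every annotation is used
    unscreened; with no selected annotation (or no signal at all) the
    pass-1 result is returned with ``flat_prior=True``.  ``em_rounds`` > 1
    iterates the estimate→re-fit cycle.
    """
    from .inference import fit

    if mode not in ("screened", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    if hyper is None:
        hyper = estimate_hyperparameters(locus, k)
    flat = np.full(locus.g, 1.0 / locus.g)
    state = fit(locus, priors=flat, hyper=hyper, k=k, tol=tol, max_iter=max_iter)
    result = _result_from_state(state, locus, flat, rho, r2_min, flat=True)
    if anno is None:
        return result, None

    def weights_from(state_):
        sp = signal_pip(state_.groups, locus.ld, att_min=rho, r2_min=r2_min)
        if sp is None or sp.sum() <= 0:
            return None
        return estimate_weights(anno, sp, p_threshold), sp

    est = weights_from(state)
    if est is None:
        return result, null_enrichment(anno.names)
    enr, sp = est
    for _ in range(em_rounds):
        sel = np.ones(anno.m, dtype=bool) if mode == "all" else enr.selected
        if not sel.any():
            return result, enr
        sub = AnnotationMatrix(
            [anno.names[j] for j in np.flatnonzero(sel)], anno.values[:, sel]
        )
        enr_sel = estimate_weights(sub, sp, p_threshold)
        prior = softmax_prior(sub, enr_sel.weights)
        state = fit(locus, priors=prior, hyper=hyper, k=k, tol=tol, max_iter=max_iter)
        result = _result_from_state(state, locus, prior, rho, r2_min, flat=False)
        est = weights_from(state)
        if est is None:
            break
        enr, sp = est
    return result, enr
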