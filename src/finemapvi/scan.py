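"""Genome-wide fine-mapping over sliding windows with central-core retention.

Variants are fine-mapped in 3-Mb windows that slide by 1 Mb (so neighboring
windows overlap by 2 Mb), and only results for the central 1-Mb core of each
window are retained: PIPs for core variants, and credible sets whose lead
variant lies in the core.  The cores tile the chromosome exactly, so every
variant is reported once, and every retained variant (outside the chromosome
ends) was fine-mapped with at least 1 Mb of flanking context.

Enrichment weights are estimated once genome-wide from the pooled core PIPs
of the flat-prior pass, screened with the G-test, and a second pass re-fits
each window with the shared functionally-informed prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .enrichment import (
    DEFAULT_P_THRESHOLD,
    EnrichmentModel,
    estimate_weights,
    softmax_prior,
)
from .hyperparams import estimate_hyperparameters
from .inference import fit
from .io import AnnotationMatrix, LocusData
from .summary import CredibleSet, build_credible_sets, signal_pip

log = logging.getLogger(__name__)

WINDOW_BP = 3_000_000
STEP_BP = 1_000_000


@dataclass(frozen=True)
class WindowSpec:
    """A fine-mapping window with its retained central core (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    core_start: int
    core_end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.core_start <= self.core_end <= self.end):
            raise ValueError("core interval must lie inside the window")

    def in_window(self, pos) -> np.ndarray:
        pos = np.asarray(pos)
        return (pos >= self.start) & (pos <= self.end)

    def in_core(self, pos) -> np.ndarray:
        pos = np.asarray(pos)
        return (pos >= self.core_start) & (pos <= self.core_end)


@dataclass
class ScanResult:
    """Merged genome-wide output: one row per variant, each reported once."""

    variant_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    pip: np.ndarray
    prior: np.ndarray
    credible_sets: list[CredibleSet]   # members indexed into the merged arrays
    enrichment: EnrichmentModel | None
    flat_prior: bool


def make_windows(
    chrom_length: int,
    window: int = WINDOW_BP,
    step: int = STEP_BP,
    chrom: str = "1",
) -> list[WindowSpec]:
    """Sliding windows whose cores exactly partition [1, chrom_length].

    Interior cores are the step-wide band one step into the window (the
    central 1 Mb for the default 3-Mb/1-Mb geometry); the first and last
    windows extend their cores to the chromosome ends.  A chromosome
    shorter than one window yields a single whole-chromosome window.
    """
    if chrom_length < 1:
        raise ValueError("chrom_length must be positive")
    if window < 2 * step:
        raise ValueError("window must be at least twice the step")
    if chrom_length <= window:
        return [WindowSpec(chrom, 1, chrom_length, 1, chrom_length)]
    out = []
    i = 0
    while True:
        s = 1 + i * step
        e = s + window - 1
        core_s = 1 if i == 0 else s + step
        if e >= chrom_length:
            out.append(WindowSpec(chrom, s, chrom_length, core_s, chrom_length))
            break
        out.append(WindowSpec(chrom, s, e, core_s, s + 2 * step - 1))
        i += 1
    return out


def slice_chromosome(
    locus: LocusData,
    windows: Sequence[WindowSpec],
    anno: AnnotationMatrix | None = None,
) -> tuple[dict[int, LocusData], dict[int, AnnotationMatrix] | None]:
    """Cut one chromosome-wide locus (with LD) into per-window inputs."""
    pos = np.array([v.pos for v in locus.variants])
    loci = {}
    annos = {} if anno is not None else None
    for i, w in enumerate(windows):
        idx = np.flatnonzero(w.in_window(pos))
        if idx.size == 0:
            continue
        loci[i] = locus.subset(idx)
        if anno is not None:
            annos[i] = anno.subset(idx)
    return loci, annos


def _fit_window(locus, prior, k, tol, max_iter):
    hyper = estimate_hyperparameters(locus, k)
    return fit(locus, priors=prior, hyper=hyper, k=k, tol=tol, max_iter=max_iter)


def scan(
    windows: Sequence[WindowSpec],
    loci: Mapping[int, LocusData],
    annos: Mapping[int, AnnotationMatrix] | None = None,
    k: int = 10,
    rho: float = 0.95,
    r2_min: float = 0.25,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    mode: str = "screened",
    tol: float = 1e-2,
    max_iter: int = 100,
) -> ScanResult:
    """Fine-map every window, retain cores, and merge genome-wide.

    ``loci`` maps window index -> LocusData (with LD); windows without an
    entry are skipped with a warning.  When annotations are supplied,
    enrichment is estimated once from the pooled core PIPs of the flat
    pass and each window is re-fitted with the informed prior.
    """
    avail = [i for i in range(len(windows)) if i in loci]
    for i in range(len(windows)):
        if i not in loci:
            log.warning("window %d (%s:%d-%d) has no inputs; skipped",
                        i, windows[i].chrom, windows[i].start, windows[i].end)

    states = {}
    core_masks = {}
    for i in avail:
        locus = loci[i]
        pos = np.array([v.pos for v in locus.variants])
        core_masks[i] = windows[i].in_core(pos)
        states[i] = _fit_window(locus, None, k, tol, max_iter)

    enr = None
    flat = True
    if annos is not None and avail:
        # enrichment from pooled core *signal* PIPs: spare groups' uniform
        # leakage would otherwise swamp the genome-wide soft counts
        sig = []
        for i in avail:
            sp = signal_pip(states[i].groups, loci[i].ld, att_min=rho, r2_min=r2_min)
            sig.append((sp if sp is not None else np.zeros(loci[i].g))[core_masks[i]])
        pooled_pip = np.concatenate(sig)
        pooled_anno = AnnotationMatrix(
            annos[avail[0]].names,
            np.vstack([annos[i].values[core_masks[i]] for i in avail]),
        )
        if pooled_pip.sum() <= 0:
            from .enrichment import null_enrichment

            enr = null_enrichment(pooled_anno.names)
            sel = enr.selected  # nothing to estimate from: stay flat
        else:
            enr = estimate_weights(pooled_anno, pooled_pip, p_threshold)
            sel = np.ones(pooled_anno.m, dtype=bool) if mode == "all" else enr.selected
        if sel.any():
            sub = AnnotationMatrix(
                [pooled_anno.names[j] for j in np.flatnonzero(sel)],
                pooled_anno.values[:, sel],
            )
            w_sel = estimate_weights(sub, pooled_pip, p_threshold).weights
            flat = False
            for i in avail:
                scores = annos[i].values[:, sel].astype(float) @ w_sel
                prior = softmax_prior(scores.reshape(-1, 1), np.ones(1))
                states[i] = _fit_window(loci[i], prior, k, tol, max_iter)

    ids: list[str] = []
    chroms: list[str] = []
    pos_all: list[int] = []
    pip_all: list[float] = []
    prior_all: list[float] = []
    for i in avail:
        locus = loci[i]
        state = states[i]
        mask = core_masks[i]
        ids.extend(np.array(locus.ids)[mask])
        chroms.extend(v.chrom for v, m in zip(locus.variants, mask) if m)
        pos_all.extend(v.pos for v, m in zip(locus.variants, mask) if m)
        pip_all.extend(state.pip()[mask])
        prior_all.extend(state.priors[mask])

    # credible sets with a core lead, members re-keyed to merged indices
    id_index = {vid: j for j, vid in enumerate(ids)}
    final_sets: list[CredibleSet] = []
    for i in avail:
        locus = loci[i]
        state = states[i]
        mask = core_masks[i]
        for cs in build_credible_sets(state.groups, locus.ld, z=locus.z,
                                      rho=rho, r2_min=r2_min):
            if not mask[cs.lead]:
                continue
            if any(locus.ids[m] not in id_index for m in cs.members):
                # can only happen when a neighboring window was skipped
                log.warning("credible set in window %d references variants from a "
                            "skipped window; set dropped", i)
                continue
            members = [id_index[locus.ids[m]] for m in cs.members]
            final_sets.append(
                CredibleSet(
                    group_index=cs.group_index,
                    members=members,
                    member_probs=cs.member_probs,
                    rho=cs.rho,
                    attainable=cs.attainable,
                    lead=members[0],
                )
            )

    return ScanResult(
        variant_ids=ids,
        chrom=chroms,
        pos=np.array(pos_all),
        pip=np.array(pip_all),
        prior=np.array(prior_all),
        credible_sets=final_sets,
        enrichment=enr,
        flat_prior=flat,
    )
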