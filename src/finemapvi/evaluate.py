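"""Evaluation metrics for fine-mapping output against simulated truth.

AUPRC ranks variants by PIP against causal status; credible sets are scored
by coverage (fraction of reported sets containing a true causal variant),
power (fraction of causal variants captured) and mean size; calibration
bins compare mean PIP to the observed causal fraction; logRR summarizes
prior informativeness as log(max π̃ / min π̃).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .summary import CredibleSet


@dataclass
class EvalReport:
    auprc: float
    coverage: float | None      # None when no sets were reported
    power: float
    mean_size: float | None
    calibration: list[tuple[float, float, int]]  # (mean PIP, observed precision, count)
    log_rr: float

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def calibration_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.calibration, columns=["EXPECTED", "OBSERVED", "COUNT"]
        )


def auprc(pip: np.ndarray, truth: np.ndarray) -> float:
    """Area under the precision-recall curve with tie-grouped thresholds.

    Equal scores are collapsed into one threshold; the area is trapezoidal
    over recall, anchored at (recall=0, precision of the top group), so a
    constant ranking scores exactly the prevalence.
    """
    pip = np.asarray(pip, dtype=float)
    truth = np.asarray(truth)
    if truth.sum() == 0:
        raise ValueError("AUPRC undefined: no positive in truth")
    order = np.argsort(-pip, kind="stable")
    sp, st = pip[order], truth[order]
    # last index of each tie group of equal scores
    last = np.flatnonzero(np.r_[sp[1:] != sp[:-1], True])
    tp = np.cumsum(st)[last]
    npred = last + 1.0
    precision = tp / npred
    recall = tp / truth.sum()
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    return float(np.trapezoid(precision, recall))


def set_metrics(
    sets: Sequence[CredibleSet], truth: np.ndarray
) -> tuple[float | None, float, float | None]:
    """(coverage, power, mean size) of reported credible sets.

    With zero reported sets, coverage and size are None (an empty report
    makes no coverage claim) and power is 0.
    """
    truth = np.asarray(truth)
    causal = set(np.flatnonzero(truth).tolist())
    if not sets:
        return None, 0.0, None
    hit = sum(1 for s in sets if causal & set(s.members))
    union = set().union(*(s.members for s in sets))
    power = len(causal & union) / len(causal) if causal else 0.0
    mean_size = float(np.mean([s.size for s in sets]))
    return hit / len(sets), power, mean_size


def calibration(
    pip: np.ndarray, truth: np.ndarray, bins: int = 5
) -> list[tuple[float, float, int]]:
    """Equal-width PIP bins on [0,1]: (mean PIP, observed causal fraction, n).

    Empty bins are omitted.
    """
    pip = np.asarray(pip, dtype=float)
    truth = np.asarray(truth, dtype=float)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(pip, edges[1:-1]), 0, bins - 1)
    out = []
    for b in range(bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        out.append((float(pip[mask].mean()), float(truth[mask].mean()), n))
    return out


def log_rr(priors: np.ndarray) -> float:
    """log of the ratio between the largest and smallest prior probability."""
    priors = np.asarray(priors, dtype=float)
    if np.any(priors <= 0):
        raise ValueError("priors must be strictly positive")
    return float(np.log(priors.max() / priors.min()))


def evaluate(
    pip: np.ndarray,
    sets: Sequence[CredibleSet],
    truth: np.ndarray,
    priors: np.ndarray | None = None,
    bins: int = 5,
) -> EvalReport:
    """Assemble the full evaluation report for one (or a pooled) locus."""
    coverage, power, mean_size = set_metrics(sets, truth)
    return EvalReport(
        auprc=auprc(pip, truth),
        coverage=coverage,
        power=power,
        mean_size=mean_size,
        calibration=calibration(pip, truth, bins),
        log_rr=0.0 if priors is None else log_rr(priors),
    )
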