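"""Domain types and file IO for locus fine-mapping.

The unit of analysis is a *locus*: an ordered list of variants with GWAS
summary statistics (per-variant z-scores and a sample size N) and an LD
matrix of Pearson correlations in the same order.  Everything is plain
tab/whitespace-separated text so fixtures and pipelines stay inspectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default header names for summary-statistics columns
DEFAULT_COLUMNS = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "allele_effect": "A1",
    "allele_other": "A2",
    "beta": "BETA",
    "se": "SE",
    "z": "Z",
    "n": "N",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumstatsFormatError(ValueError):
    """Summary-statistics file does not match the expected format."""


class LDFormatError(ValueError):
    """LD matrix file is malformed or inconsistent with the locus."""


class AlleleMatchError(ValueError):
    """No variants could be matched against the reference panel."""


@dataclass(frozen=True)
class Variant:
    """A single bi-allelic (or indel) variant; ``pos`` is 1-based."""

    id: str
    chrom: str
    pos: int
    allele_effect: str
    allele_other: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"variant {self.id}: pos must be positive, got {self.pos}")
        if not self.allele_effect or not self.allele_other:
            raise ValueError(f"variant {self.id}: empty allele string")
        if self.allele_effect == self.allele_other:
            raise ValueError(f"variant {self.id}: effect and other allele are identical")

    @property
    def is_strand_ambiguous(self) -> bool:
        """True for A/T and C/G pairs, which cannot be strand-resolved."""
        a, b = self.allele_effect, self.allele_other
        return (
            len(a) == 1
            and len(b) == 1
            and a in _COMPLEMENT
            and _COMPLEMENT[a] == b
        )


@dataclass
class LocusData:
    """Summary statistics and (optionally) LD for one locus.

    Attributes
    ----------
    variants : list of Variant, length G
    z : (G,) array of GWAS z-scores
    n : effective GWAS sample size (one number per locus)
    ld : (G, G) array of Pearson correlations r, or None before LD is attached
    """

    variants: list[Variant]
    z: np.ndarray
    n: float
    ld: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.validate()

    @property
    def g(self) -> int:
        return len(self.variants)

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def validate(self) -> None:
        g = len(self.variants)
        if self.z.shape != (g,):
            raise ValueError(f"z has shape {self.z.shape}, expected ({g},)")
        if self.n < 2:
            raise ValueError(f"sample size n must be >= 2, got {self.n}")
        if self.ld is not None:
            r = np.asarray(self.ld, dtype=float)
            if r.shape != (g, g):
                raise LDFormatError(f"LD has shape {r.shape}, expected ({g}, {g})")
            if not np.allclose(r, r.T, atol=1e-8):
                raise LDFormatError("LD matrix is not symmetric within 1e-8")
            if not np.allclose(np.diag(r), 1.0, atol=1e-6):
                raise LDFormatError("LD diagonal deviates from 1 beyond 1e-6")
            if np.any(np.abs(r) > 1 + 1e-6):
                raise LDFormatError("LD entries exceed |r| = 1 beyond tolerance")
            self.ld = r

    def subset(self, idx: np.ndarray) -> "LocusData":
        """Restrict the locus to the given variant indices (order preserved)."""
        idx = np.asarray(idx)
        return LocusData(
            variants=[self.variants[i] for i in idx],
            z=self.z[idx],
            n=self.n,
            ld=None if self.ld is None else self.ld[np.ix_(idx, idx)],
        )


@dataclass
class AnnotationMatrix:
    """Binary variant-by-annotation indicator matrix."""

    names: list[str]
    values: np.ndarray  # (G, M) in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError(
                f"annotation matrix shape {self.values.shape} does not match "
                f"{len(self.names)} annotation names"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("annotation entries must be 0/1")
        self.values = self.values.astype(np.int8)

    @property
    def m(self) -> int:
        return len(self.names)

    def subset(self, idx: np.ndarray) -> "AnnotationMatrix":
        return AnnotationMatrix(self.names, self.values[np.asarray(idx)])


@dataclass
class FineMapResult:
    """Output of one fine-mapping run on a locus.

    ``credible_sets`` holds :class:`~finemapvi.summary.CredibleSet` objects;
    ``prior`` is the prior inclusion-probability vector that produced the fit
    (uniform when no functional information was used).
    """

    variant_ids: list[str]
    pip: np.ndarray
    credible_sets: list
    elbo_trace: list[float]
    hyper: object
    prior: np.ndarray
    gamma: np.ndarray  # (K, G) per-effect-group selection probabilities
    converged: bool = True
    flat_prior: bool = True

    def __post_init__(self) -> None:
        self.pip = np.asarray(self.pip, dtype=float)
        if np.any(self.pip < -1e-12) or np.any(self.pip > 1 + 1e-12):
            raise ValueError("PIP values outside [0, 1]")
        self.pip = np.clip(self.pip, 0.0, 1.0)


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing mandatory column(s) {missing}")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    n: float | None = None,
) -> LocusData:
    """Read GWAS summary statistics into a :class:`LocusData` (without LD).

    The file must be tab- or whitespace-separated with a header and contain
    either a z-score column or beta + SE columns (z is computed as beta/SE).
    ``n`` overrides / replaces a per-variant N column; when per-variant N
    values differ, their median is used as the single locus-level N.
    """
    cm = dict(DEFAULT_COLUMNS)
    if column_map:
        cm.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    _require(df, [cm["id"], cm["chrom"], cm["pos"], cm["allele_effect"], cm["allele_other"]], path)

    if cm["z"] in df.columns:
        z_raw = df[cm["z"]]
        z = pd.to_numeric(z_raw, errors="coerce").to_numpy()
    elif cm["beta"] in df.columns and cm["se"] in df.columns:
        beta = pd.to_numeric(df[cm["beta"]], errors="coerce").to_numpy()
        se = pd.to_numeric(df[cm["se"]], errors="coerce").to_numpy()
        z = beta / se
    else:
        raise SumstatsFormatError(
            f"{path}: need either a '{cm['z']}' column or "
            f"'{cm['beta']}' and '{cm['se']}' columns"
        )

    bad = np.flatnonzero(~np.isfinite(z))
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise SumstatsFormatError(f"{path}: non-numeric or undefined z at line(s) {lines}")

    if n is None:
        if cm["n"] not in df.columns:
            raise SumstatsFormatError(
                f"{path}: no '{cm['n']}' column; pass the sample size explicitly"
            )
        n_col = pd.to_numeric(df[cm["n"]], errors="coerce").to_numpy()
        if np.any(~np.isfinite(n_col)):
            raise SumstatsFormatError(f"{path}: non-numeric sample size values")
        n = float(np.median(n_col))
        if not np.all(n_col == n_col[0]):
            log.warning("%s: per-variant N varies; using the median N = %g", path, n)

    variants = [
        Variant(
            id=str(r[cm["id"]]),
            chrom=str(r[cm["chrom"]]),
            pos=int(r[cm["pos"]]),
            allele_effect=str(r[cm["allele_effect"]]).upper(),
            allele_other=str(r[cm["allele_other"]]).upper(),
        )
        for r in df.to_dict("records")
    ]
    return LocusData(variants=variants, z=z, n=n, ld=None)


def read_ld(path, expected_g: int | None = None) -> np.ndarray:
    """Read a square LD matrix (whitespace-delimited text, or .npy/.npz).

    Asymmetries up to 1e-8 are symmetrized as (R + Rᵀ)/2; anything larger,
    a non-square file, or a dimension mismatch with ``expected_g`` raises
    :class:`LDFormatError`.  Text is the canonical fixture format; the
    binary container is for large windows.
    """
    name = str(path)
    if name.endswith((".npy", ".npz")):
        loaded = np.load(path)
        r = loaded[loaded.files[0]] if hasattr(loaded, "files") else loaded
        r = np.asarray(r, dtype=float)
    else:
        try:
            rows = [np.fromstring(line, sep=" ") for line in open(path) if line.strip()]
        except OSError as e:
            raise LDFormatError(f"cannot read LD file {path}: {e}") from e
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise LDFormatError(f"{path}: ragged matrix, row widths {sorted(widths)}")
        r = np.vstack(rows)
    if r.ndim != 2:
        raise LDFormatError(f"{path}: expected a matrix, got ndim={r.ndim}")
    if r.shape[0] != r.shape[1]:
        raise LDFormatError(f"{path}: matrix is {r.shape[0]}x{r.shape[1]}, not square")
    if expected_g is not None and r.shape[0] != expected_g:
        raise LDFormatError(
            f"{path}: LD dimension {r.shape[0]} does not match the {expected_g} variants"
        )
    if not np.allclose(r, r.T, atol=1e-8):
        raise LDFormatError(f"{path}: asymmetry exceeds 1e-8")
    r = (r + r.T) / 2.0
    if not np.allclose(np.diag(r), 1.0, atol=1e-6):
        raise LDFormatError(f"{path}: diagonal deviates from 1 beyond 1e-6")
    return r


def read_annotations(path, ids: Sequence[str] | None = None) -> AnnotationMatrix:
    """Read a TSV with variant IDs in the first column and 0/1 annotations after.

    When ``ids`` is given the rows are reordered to match; unmatched locus
    variants get all-zero annotation rows.
    """
    df = pd.read_csv(path, sep=r"\s+")
    id_col = df.columns[0]
    names = list(df.columns[1:])
    if ids is not None:
        df = df.set_index(df[id_col].astype(str))
        vals = np.zeros((len(ids), len(names)), dtype=np.int8)
        hit = [i for i, v in enumerate(ids) if v in df.index]
        if len(hit) < len(ids):
            log.warning(
                "%s: %d locus variants missing from the annotation file; "
                "treated as unannotated", path, len(ids) - len(hit),
            )
        for i in hit:
            vals[i] = df.loc[ids[i], names].to_numpy()
        return AnnotationMatrix(names, vals)
    return AnnotationMatrix(names, df[names].to_numpy())


def match_alleles(
    sumstats: LocusData, reference: Sequence[Variant]
) -> tuple[LocusData, list[tuple[str, str]]]:
    """Harmonize summary statistics against a reference variant panel.

    Variants whose effect/other alleles are swapped relative to the reference
    get their z sign flipped; strand-ambiguous pairs (A/T, C/G) and variants
    not present in the reference are dropped.  The output follows the
    reference order.  Returns (harmonized locus, drop log of (id, reason)).
    """
    by_key: dict[tuple, int] = {}
    for i, v in enumerate(sumstats.variants):
        by_key[(v.chrom, v.pos, frozenset((v.allele_effect, v.allele_other)))] = i

    seen: set[int] = set()
    out_variants: list[Variant] = []
    out_z: list[float] = []
    dropped: list[tuple[str, str]] = []
    for ref in reference:
        key = (ref.chrom, ref.pos, frozenset((ref.allele_effect, ref.allele_other)))
        i = by_key.get(key)
        if i is None:
            continue
        seen.add(i)
        v = sumstats.variants[i]
        if v.is_strand_ambiguous:
            dropped.append((v.id, "strand_ambiguous"))
            continue
        if v.allele_effect == ref.allele_effect and v.allele_other == ref.allele_other:
            sign = 1.0
        else:  # same unordered allele pair (guaranteed by the key), so swapped
            sign = -1.0
        out_variants.append(ref)
        out_z.append(sign * sumstats.z[i])

    for i, v in enumerate(sumstats.variants):
        if i not in seen:
            dropped.append((v.id, "not_in_reference"))

    if not out_variants:
        raise AlleleMatchError("no overlap between summary statistics and reference panel")
    for vid, reason in dropped:
        log.info("dropped %s (%s)", vid, reason)
    return LocusData(variants=out_variants, z=np.array(out_z), n=sumstats.n, ld=None), dropped


def write_results(result: FineMapResult, prefix, enrichment=None) -> list[str]:
    """Write per-variant, credible-set and (optionally) enrichment TSVs.

    Returns the list of paths written.  Values are written with 6 significant
    digits so a write/read round trip is lossless at that precision.
    """
    prefix = str(prefix)
    paths = []

    best_group = np.argmax(result.gamma, axis=0)
    best_prob = result.gamma[best_group, np.arange(result.gamma.shape[1])]
    pv = pd.DataFrame(
        {
            "SNP": result.variant_ids,
            "PIP": result.pip,
            "GROUP": best_group,
            "GROUP_PROB": best_prob,
        }
    )
    p = prefix + ".pip.tsv"
    pv.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths.append(p)

    rows = []
    for cs in result.credible_sets:
        for rank, (gi, prob) in enumerate(zip(cs.members, cs.member_probs)):
            rows.append(
                {
                    "CS": cs.group_index,
                    "RHO": cs.rho,
                    "ATTAINABLE": cs.attainable,
                    "SNP": result.variant_ids[gi],
                    "PROB": prob,
                    "RANK": rank,
                }
            )
    cs_df = pd.DataFrame(rows, columns=["CS", "RHO", "ATTAINABLE", "SNP", "PROB", "RANK"])
    p = prefix + ".cs.tsv"
    cs_df.to_csv(p, sep="\t", index=False, float_format="%.6g")
    paths.append(p)

    if enrichment is not None:
        p = prefix + ".anno.tsv"
        enrichment.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths.append(p)
    return paths
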