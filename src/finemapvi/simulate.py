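"""Synthetic GWAS locus generator with LD-structured genotypes.

Genotypes are built from a latent Gaussian model: each haplotype draws a
multivariate-normal vector with AR(1) correlation decay^|i−j| (optionally
block-diagonal), thresholded at per-variant minor-allele-frequency
quantiles; dosages sum two independent haplotypes.  Thresholding attenuates
correlations, so the *theoretical* LD returned alongside the dosages is
computed on the dosage scale from bivariate-normal orthant probabilities
(via Owen's T function), not the latent correlation.

Causal variants are sampled with probability proportional to
exp(A_gᵀ w_sim), where the simulated weight vector carries the enrichment
log-odds W at the enriched annotations and 0 elsewhere.  A continuous trait
is composed of a genetic component rescaled to an exact heritability h² and
orthogonalized Gaussian noise; per-variant univariate regressions then give
GWAS z-scores, with LD computed in-sample from the same genotypes.

Default configuration mirrors a biobank-scale single-locus design:
n = 353,570 individuals and per-locus heritability h² = K × 1e-4 (so each
causal variant carries noncentrality N·h²/K ≈ 35).  ``SimulationConfig.reduced``
scales n down for desk-size runs while preserving that per-causal
noncentrality, which is the quantity that controls fine-mapping difficulty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, owens_t
from scipy.stats import norm

from .io import AnnotationMatrix, LocusData, Variant

log = logging.getLogger(__name__)

#: per-causal-variant noncentrality of the full-scale design: 353,570 × 1e-4
FULL_SCALE_NCP = 353_570 * 1e-4


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated locus.

    ``h2=None`` resolves to the design default K × 1e-4.  ``ld_decay`` is
    the AR(1) latent correlation between adjacent variants; ``n_blocks``
    splits the locus into independent LD blocks of equal size.
    """

    g: int = 1000
    n: int = 353_570
    k_causal: int = 5
    w_intensity: float = 2.0
    h2: float | None = None
    ld_decay: float = 0.95
    maf_range: tuple[float, float] = (0.05, 0.5)
    m_anno: int = 10
    enriched_idx: tuple[int, ...] = (0, 1, 2, 3, 4)
    seed: int = 0
    n_blocks: int = 1

    def __post_init__(self) -> None:
        if not (0 <= (self.h2 or 0.0) < 1):
            raise ValueError("h2 must be in [0, 1)")
        if not (1 <= self.k_causal <= self.g):
            raise ValueError("k_causal must be in [1, g]")
        if not (0 <= self.ld_decay < 1):
            raise ValueError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if any(j >= self.m_anno for j in self.enriched_idx):
            raise ValueError("enriched_idx out of range for m_anno")

    @property
    def h2_resolved(self) -> float:
        return self.k_causal * 1e-4 if self.h2 is None else self.h2

    @property
    def w_sim(self) -> np.ndarray:
        w = np.zeros(self.m_anno)
        w[list(self.enriched_idx)] = self.w_intensity
        return w

    @classmethod
    def reduced(cls, n: int = 25_000, g: int = 200, **kw) -> "SimulationConfig":
        """Desk-scale configuration preserving the per-causal noncentrality.

        The full-scale design has N·h²/K ≈ 35.4 per causal variant; reducing
        N alone would erase the signal, so h² is raised to compensate.
        """
        cfg = cls(n=n, g=g, **{k: v for k, v in kw.items() if k != "h2"})
        if "h2" not in kw or kw["h2"] is None:
            cfg = replace(cfg, h2=cfg.k_causal * FULL_SCALE_NCP / n)
        else:
            cfg = replace(cfg, h2=kw["h2"])
        return cfg


@dataclass
class SimulatedLocus:
    """A fully observed simulated locus with ground truth attached."""

    locus: LocusData
    anno: AnnotationMatrix
    causal_idx: np.ndarray
    true_beta: np.ndarray
    genotypes: np.ndarray
    trait: np.ndarray
    ld_true: np.ndarray
    w_sim: np.ndarray

    @property
    def truth(self) -> np.ndarray:
        """Binary causal-status vector of length G."""
        t = np.zeros(self.locus.g, dtype=int)
        t[self.causal_idx] = 1
        return t


# ---------------------------------------------------------------------------
# bivariate-normal orthant probability (for the theoretical dosage LD)

def bvn_upper_orthant(h, k, rho):
    """P(X > h, Y > k) for standard bivariate normals with correlation rho.

    Vectorized Owen (1956) formula using Owen's T function; near-singular
    correlations are handled by their exact limits.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h, k, rho = np.broadcast_arrays(h, k, rho)
    # avoid division by zero in the Owen terms
    hs = np.where(np.abs(h) < 1e-10, 1e-10, h)
    ks = np.where(np.abs(k) < 1e-10, 1e-10, k)
    r = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    den = np.sqrt(1.0 - r**2)
    ah = (ks - r * hs) / (hs * den)
    ak = (hs - r * ks) / (ks * den)
    delta = np.where(hs * ks > 0, 0.0, 0.5)  # hs, ks are nudged away from 0
    cdf = 0.5 * (ndtr(hs) + ndtr(ks)) - owens_t(hs, ah) - owens_t(ks, ak) - delta
    upper = 1.0 - ndtr(hs) - ndtr(ks) + cdf

    hi = np.maximum(h, k)
    upper = np.where(rho > 1 - 1e-9, 1.0 - ndtr(hi), upper)
    upper = np.where(rho < -1 + 1e-9, np.maximum(1.0 - ndtr(h) - ndtr(k), 0.0), upper)
    return np.clip(upper, 0.0, 1.0)


def _latent_corr(g: int, decay: float, n_blocks: int) -> np.ndarray:
    idx = np.arange(g)
    c = decay ** np.abs(idx[:, None] - idx[None, :])
    if n_blocks > 1:
        block = idx * n_blocks // g
        c = np.where(block[:, None] == block[None, :], c, 0.0)
    return c


def _theoretical_dosage_ld(thresholds: np.ndarray, latent: np.ndarray) -> np.ndarray:
    q = 1.0 - ndtr(thresholds)  # per-haplotype allele frequency
    p11 = bvn_upper_orthant(thresholds[:, None], thresholds[None, :], latent)
    sd = np.sqrt(q * (1 - q))
    r = (p11 - np.outer(q, q)) / np.outer(sd, sd)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _draw_haplotype(rng, n: int, g: int, decay: float, n_blocks: int) -> np.ndarray:
    x = np.empty((n, g), dtype=np.float32)
    innov = np.sqrt(1.0 - decay**2)
    block = np.arange(g) * n_blocks // g
    x[:, 0] = rng.standard_normal(n, dtype=np.float32)
    for j in range(1, g):
        eps = rng.standard_normal(n, dtype=np.float32)
        if block[j] != block[j - 1]:
            x[:, j] = eps
        else:
            x[:, j] = decay * x[:, j - 1] + innov * eps
    return x


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an (n, g) dosage matrix in {0,1,2} and its theoretical LD."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    maf = rng.uniform(*cfg.maf_range, size=cfg.g)
    t = norm.isf(maf)  # P(latent > t) = maf per haplotype
    dosage = np.zeros((cfg.n, cfg.g), dtype=np.int8)
    for _ in range(2):
        hap = _draw_haplotype(rng, cfg.n, cfg.g, cfg.ld_decay, cfg.n_blocks)
        dosage += (hap > t.astype(np.float32)).astype(np.int8)
    ld_true = _theoretical_dosage_ld(t, _latent_corr(cfg.g, cfg.ld_decay, cfg.n_blocks))
    return dosage, ld_true


def simulate_annotations(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> AnnotationMatrix:
    """M binary annotations with 10–30% prevalence and pairwise overlap.

    Overlap between annotations is induced by a shared 10% core set whose
    members each annotation includes with probability 1/2, on top of an
    independent background Bernoulli draw.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    core = rng.random(cfg.g) < 0.10
    vals = np.zeros((cfg.g, cfg.m_anno), dtype=np.int8)
    prevalences = rng.uniform(0.10, 0.30, size=cfg.m_anno)
    for j in range(cfg.m_anno):
        base = rng.random(cfg.g) < prevalences[j]
        shared = core & (rng.random(cfg.g) < 0.5)
        vals[:, j] = base | shared
    names = [
        f"anno{j}_{'enriched' if j in cfg.enriched_idx else 'null'}"
        for j in range(cfg.m_anno)
    ]
    return AnnotationMatrix(names, vals)


def assign_causal(
    cfg: SimulationConfig,
    anno: AnnotationMatrix,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample k distinct causal variants with probability ∝ exp(A_gᵀ w_sim)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    scores = anno.values @ cfg.w_sim
    scores -= scores.max()
    p = np.exp(scores)
    p /= p.sum()
    return np.sort(rng.choice(cfg.g, size=cfg.k_causal, replace=False, p=p))


def simulate_trait(
    genotypes: np.ndarray,
    causal_idx: np.ndarray,
    h2: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous trait with an exactly realized heritability.

    Causal effects are standard normal on standardized dosages; the genetic
    component is rescaled to sample variance exactly h² and the independent
    Gaussian noise to exactly 1 − h², so the genetic variance share
    h²/(h² + (1 − h²)) equals the target by construction.  The trait is
    centered; its variance is 1 up to the O(n^-1/2) sample covariance of
    the two components, which is left untouched so that the GWAS sampling
    distribution stays unbiased.
    """
    if not (0 <= h2 < 1):
        raise ValueError("h2 must be in [0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = genotypes.shape[0]
    k = len(causal_idx)

    noise = rng.standard_normal(n)
    beta = rng.standard_normal(k)
    xc = genotypes[:, causal_idx].astype(float)
    sd = xc.std(axis=0)
    if h2 > 0 and np.all(sd > 0):
        xc = (xc - xc.mean(axis=0)) / sd
        gcomp = xc @ beta
        gvar = gcomp.var()
        if gvar > 0:
            scale = np.sqrt(h2 / gvar)
        else:  # effects cancel exactly; treat as a null trait
            log.warning("degenerate genetic component; simulating a null trait")
            scale, h2 = 0.0, 0.0
        gcomp *= scale
        beta = beta * scale
    else:
        if h2 > 0:
            log.warning("monomorphic causal variant; simulating a null trait")
        gcomp = np.zeros(n)
        beta = np.zeros(k)
        h2 = 0.0

    noise -= noise.mean()
    noise *= np.sqrt((1.0 - h2) / noise.var())
    trait = gcomp - gcomp.mean() + noise
    return trait, beta


def run_gwas(
    genotypes: np.ndarray,
    trait: np.ndarray,
    chrom: str = "1",
    positions: np.ndarray | None = None,
    spacing: int = 1000,
) -> LocusData:
    """Per-variant univariate regression z-scores plus in-sample LD."""
    x = genotypes.astype(float)
    n, g = x.shape
    y = (trait - trait.mean()) / trait.std()
    xm = x.mean(axis=0)
    xs = x.std(axis=0)
    mono = xs == 0
    if mono.any():
        log.warning("%d monomorphic variant(s); z set to 0", int(mono.sum()))
        xs = np.where(mono, 1.0, xs)
    r = ((x - xm) / xs).T @ y / n
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = r * np.sqrt((n - 2) / (1.0 - r**2))
    z[mono] = 0.0

    ld = np.corrcoef(x, rowvar=False)
    if mono.any():
        ld[np.isnan(ld)] = 0.0
    np.fill_diagonal(ld, 1.0)

    if positions is None:
        positions = (np.arange(g) + 1) * spacing
    variants = [
        Variant(
            id=f"rs{chrom}_{positions[i]}",
            chrom=chrom,
            pos=int(positions[i]),
            allele_effect="A",
            allele_other="G",
        )
        for i in range(g)
    ]
    return LocusData(variants=variants, z=z, n=float(n), ld=ld)


def simulate_locus(
    cfg: SimulationConfig,
    chrom: str = "1",
    positions: np.ndarray | None = None,
) -> SimulatedLocus:
    """End-to-end locus simulation, fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genotypes, ld_true = simulate_genotypes(cfg, rng)
    anno = simulate_annotations(cfg, rng)
    causal_idx = assign_causal(cfg, anno, rng)
    trait, beta = simulate_trait(genotypes, causal_idx, cfg.h2_resolved, rng)
    locus = run_gwas(genotypes, trait, chrom=chrom, positions=positions)
    return SimulatedLocus(
        locus=locus,
        anno=anno,
        causal_idx=causal_idx,
        true_beta=beta,
        genotypes=genotypes,
        trait=trait,
        ld_true=ld_true,
        w_sim=cfg.w_sim,
    )


def write_simulated(sim: SimulatedLocus, prefix) -> list[str]:
    """Write a simulated locus in the formats the fine-mapping reader expects."""
    prefix = str(prefix)
    locus = sim.locus
    ss = pd.DataFrame(
        {
            "SNP": locus.ids,
            "CHR": [v.chrom for v in locus.variants],
            "POS": [v.pos for v in locus.variants],
            "A1": [v.allele_effect for v in locus.variants],
            "A2": [v.allele_other for v in locus.variants],
            "Z": locus.z,
            "N": int(locus.n),
        }
    )
    paths = [prefix + ".ss.tsv", prefix + ".ld.txt", prefix + ".anno.tsv",
             prefix + ".truth.tsv", prefix + ".wtruth.tsv"]
    ss.to_csv(paths[0], sep="\t", index=False, float_format="%.6g")
    np.savetxt(paths[1], locus.ld, fmt="%.6g")
    anno_df = pd.DataFrame(sim.anno.values, columns=sim.anno.names)
    anno_df.insert(0, "SNP", locus.ids)
    anno_df.to_csv(paths[2], sep="\t", index=False)
    truth = np.zeros(locus.g)
    truth[sim.causal_idx] = 1
    beta_full = np.zeros(locus.g)
    beta_full[sim.causal_idx] = sim.true_beta
    pd.DataFrame({"SNP": locus.ids, "CAUSAL": truth.astype(int), "TRUE_BETA": beta_full}).to_csv(
        paths[3], sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame({"ANNOTATION": sim.anno.names, "W_SIM": sim.w_sim}).to_csv(
        paths[4], sep="\t", index=False, float_format="%.6g"
    )
    return paths
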