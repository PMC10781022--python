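import numpy as np
import pytest

from finemapvi import LocusData, Variant


def make_locus(z, ld=None, n=10_000, chrom="1", spacing=1000):
    """Build a LocusData from raw arrays with auto-generated variant metadata."""
    z = np.asarray(z, dtype=float)
    g = z.size
    variants = [
        Variant(id=f"v{i}", chrom=chrom, pos=(i + 1) * spacing,
                allele_effect="A", allele_other="G")
        for i in range(g)
    ]
    if ld is None:
        ld = np.eye(g)
    return LocusData(variants=variants, z=z, n=float(n), ld=np.asarray(ld, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def sumstats_file(tmp_path):
    """3-row summary-statistics fixture with BETA/SE columns."""
    p = tmp_path / "ss.tsv"
    p.write_text(
        "SNP\tCHR\tPOS\tA1\tA2\tBETA\tSE\tN\n"
        "rs1\t1\t100\tA\tG\t0.02\t0.01\t5000\n"
        "rs2\t1\t200\tC\tT\t-0.01\t0.02\t5000\n"
        "rs3\t1\t300\tG\tA\t0.0\t0.05\t5000\n"
    )
    return p
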