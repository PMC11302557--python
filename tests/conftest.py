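import numpy as np
import pytest

from tsmr.harmonize import HarmonizedSNP
from tsmr.io import SummaryStatRecord


def make_snps(bx, by, sx=0.01, sy=0.05, prefix="rs"):
    """Build harmonized instruments from effect arrays (scalars broadcast)."""
    bx = np.atleast_1d(np.asarray(bx, dtype=float))
    J = len(bx)
    by = np.broadcast_to(np.asarray(by, dtype=float), (J,))
    sx = np.broadcast_to(np.asarray(sx, dtype=float), (J,))
    sy = np.broadcast_to(np.asarray(sy, dtype=float), (J,))
    return [
        HarmonizedSNP(
            variant_id=f"{prefix}{j + 1}",
            bx=float(bx[j]), sx=float(sx[j]), by=float(by[j]), sy=float(sy[j]),
        )
        for j in range(J)
    ]


def make_record(
    variant_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pvalue=1e-8,
    eaf=0.3,
    n=10_000,
    chromosome="1",
    position=1_000_000,
):
    return SummaryStatRecord(
        variant_id=variant_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n=n,
        chromosome=chromosome,
        position=position,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
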