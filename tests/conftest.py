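import numpy as np
import pytest

from adiposcore.io_and_qc import GenotypeMatrix, QcConfig, VariantRecord


def make_gm(dosages, mafs=None, imp_r2=None, chrom_pos=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array for tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    variants = []
    for j in range(m):
        ref, alt = pairs[j % len(pairs)]
        chrom, pos = (str(j % 22 + 1), 1000 + j * 100) if chrom_pos is None else chrom_pos[j]
        variants.append(VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            imputation_quality=1.0 if imp_r2 is None else imp_r2[j]))
    return GenotypeMatrix(sample_ids=[f"S{i}" for i in range(n)],
                          variants=variants, dosages=dosages)


@pytest.fixture
def cfg() -> QcConfig:
    return QcConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
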