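import numpy as np
import pytest

from asmqtl.core import KinshipMatrix, PairCounts


@pytest.fixture
def toy_pair() -> PairCounts:
    """Three individuals, genotypes (0, 1, 2); the het has allele data."""
    y_allele = np.full((3, 2), np.nan)
    r_allele = np.full((3, 2), np.nan)
    y_allele[1] = [2, 5]
    r_allele[1] = [8, 9]
    return PairCounts(
        pair_id="p1",
        individual_ids=["a", "b", "c"],
        genotype=np.array([0.0, 1.0, 2.0]),
        y_total=np.array([3.0, 7.0, 10.0]),
        r_total=np.array([12.0, 17.0, 14.0]),
        y_allele=y_allele, r_allele=r_allele,
    )


@pytest.fixture
def identity_kinship():
    def make(n, ids=None):
        return KinshipMatrix(ids or [f"ind{i}" for i in range(n)], np.eye(n))
    return make


def make_pair(genotype, y, r, y_allele=None, r_allele=None, pair_id="p",
              **kw):
    n = len(genotype)
    ids = kw.pop("ids", [f"ind{i}" for i in range(n)])
    return PairCounts(pair_id=pair_id, individual_ids=ids,
                      genotype=np.asarray(genotype, float),
                      y_total=np.asarray(y, float),
                      r_total=np.asarray(r, float),
                      y_allele=None if y_allele is None else np.asarray(y_allele, float),
                      r_allele=None if r_allele is None else np.asarray(r_allele, float),
                      **kw)
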