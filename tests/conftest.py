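import numpy as np
import pytest

from mrbidir.harmonization import HarmonizedInstrument
from mrbidir.gwas_io import VariantAssociation


def make_insts(beta_exp, beta_out, se_exp=None, se_out=None):
    """Build harmonized instruments from plain arrays (test helper)."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    n = len(beta_exp)
    se_exp = np.full(n, 0.01) if se_exp is None else np.asarray(se_exp, float)
    se_out = np.full(n, 0.01) if se_out is None else np.asarray(se_out, float)
    return [
        HarmonizedInstrument(
            snp_id=f"rs{j + 1:04d}",
            beta_exp=float(beta_exp[j]), se_exp=float(se_exp[j]),
            beta_out=float(beta_out[j]), se_out=float(se_out[j]))
        for j in range(n)
    ]


def make_variant(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.02,
                 pvalue=None, eaf=0.3, chrom="1", pos=1000):
    from scipy import stats
    if pvalue is None:
        pvalue = float(max(2 * stats.norm.sf(abs(beta) / se), 1e-300))
    return VariantAssociation(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                              beta=beta, se=se, pvalue=pvalue, eaf=eaf,
                              chrom=chrom, pos=pos)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
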