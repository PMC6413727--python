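import pytest

import mr2s


@pytest.fixture(scope="session")
def table1_instruments():
    """The bundled 52-SNP instrument set, missing outcome beta imputed."""
    return mr2s.load_table1_instruments()


@pytest.fixture(scope="session")
def table1_ratios(table1_instruments):
    return mr2s.wald_ratios(table1_instruments)


def make_instrument(snp="rs1", bx=0.02, sx=0.003, by=0.01, sy=0.02,
                    px=1e-9, py=0.5, chrom="1", pos=1_000_000, **kw):
    return mr2s.HarmonizedInstrument(
        snp_id=snp, beta_exposure=bx, se_exposure=sx, beta_outcome=by,
        se_outcome=sy, pval_exposure=px, pval_outcome=py,
        chrom=chrom, pos=pos, **kw,
    )
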