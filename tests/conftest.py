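import numpy as np
import pytest

from causalmr.sumstats import HarmonizedInstrumentSet, SummaryStatRecord


@pytest.fixture
def three_variant_hset() -> HarmonizedInstrumentSet:
    """Hand-checkable fixture: IVW weighted average equals 165/725."""
    return HarmonizedInstrumentSet(
        variant_ids=["rs1", "rs2", "rs3"],
        beta_exposure=np.array([0.1, 0.2, 0.3]),
        se_exposure=np.array([0.01, 0.01, 0.01]),
        beta_outcome=np.array([0.02, 0.05, 0.06]),
        se_outcome=np.array([0.01, 0.01, 0.02]),
    )


def make_record(vid="rs1", ea="A", oa="G", beta=0.1, se=0.01, **kw) -> SummaryStatRecord:
    return SummaryStatRecord(variant_id=vid, effect_allele=ea, other_allele=oa,
                             beta=beta, se=se, **kw)


@pytest.fixture
def concordant_pair():
    """Five shared variants with identical allele coding on both sides."""
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C")]
    expo = [make_record(f"rs{i}", ea, oa, beta=0.1 * (i + 1), se=0.01, eaf=0.3)
            for i, (ea, oa) in enumerate(alleles)]
    outc = [make_record(f"rs{i}", ea, oa, beta=0.02 * (i + 1), se=0.02, eaf=0.3)
            for i, (ea, oa) in enumerate(alleles)]
    return expo, outc
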