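import numpy as np
import pytest

from mrcoloc import AssociationSet, Region, VariantRecord
from mrcoloc.sumstats import zscore_pvalue


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=100,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.05,
    pvalue=None,
    eaf=0.3,
    n=1000.0,
    **kwargs,
):
    """A valid VariantRecord with p consistent with beta/se by default."""
    if pvalue is None:
        pvalue = float(zscore_pvalue(beta / se))
    return VariantRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pvalue=pvalue,
        eaf=eaf,
        n=n,
        **kwargs,
    )


def make_set(records, trait_id="trait", chrom="1"):
    positions = [r.pos for r in records]
    region = Region(chrom, min(positions), max(positions))
    aset = AssociationSet(trait_id=trait_id, records=records, region=region)
    aset.validate()
    return aset


def set_from_stats(
    betas, ses, trait_id="trait", snp_ids=None, chrom="1", eafs=None
):
    """An AssociationSet from parallel beta/se arrays."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    n = len(betas)
    snp_ids = snp_ids or [f"rs{i + 1}" for i in range(n)]
    eafs = eafs if eafs is not None else [0.3] * n
    records = [
        make_record(
            snp_id=snp_ids[i],
            pos=100 + i,
            beta=float(betas[i]),
            se=float(ses[i]),
            eaf=float(eafs[i]),
            chrom=chrom,
        )
        for i in range(n)
    ]
    return make_set(records, trait_id=trait_id, chrom=chrom)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
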