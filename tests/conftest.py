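import numpy as np
import pytest

from pairedmet.loh_model import MafObservation
from pairedmet.types import SnpObservation, VariantRecord


def make_variant(
    chrom="chr1",
    pos=100,
    ref_base="C",
    alt_base="T",
    germline_ref=199,
    germline_alt=1,
    tumor_ref=32,
    tumor_alt=8,
    tumor_alt_fwd=4,
    tumor_alt_rev=4,
    **kwargs,
):
    """A variant that passes the default exome-wide filter unless overridden."""
    kwargs.setdefault("consequence", "nonsynonymous")
    return VariantRecord(
        chrom=chrom, pos=pos, ref_base=ref_base, alt_base=alt_base,
        germline_ref=germline_ref, germline_alt=germline_alt,
        tumor_ref=tumor_ref, tumor_alt=tumor_alt,
        tumor_alt_fwd=tumor_alt_fwd, tumor_alt_rev=tumor_alt_rev,
        **kwargs,
    )


def make_snp(chrom="chr1", pos=1, ref_count=30, alt_count=30, sample_id="s"):
    return SnpObservation(chrom=chrom, pos=pos, ref_count=ref_count,
                          alt_count=alt_count, sample_id=sample_id)


def make_maf(pos, maf, major="ref", chrom="chr1", coverage=100):
    return MafObservation(chrom=chrom, pos=pos, maf=maf,
                          major_allele=major, coverage=coverage)


def sample_mixture_mafs(n, pi_loh, purity, mu=0.505, sigma=0.02,
                        concentration=50.0, seed=0):
    """Draw MAFs directly from the Beta-Normal generative model."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    comp = rng.random(n) < pi_loh
    alo, ahi = (0.5 - mu) / sigma, (1.0 - mu) / sigma
    het = stats.truncnorm.rvs(alo, ahi, loc=mu, scale=sigma, size=n, random_state=rng)
    m01 = purity  # beta mean on [0,1] scale == 2*beta_mean_maf - 1
    loh = 0.5 + 0.5 * rng.beta(m01 * concentration, (1 - m01) * concentration, size=n)
    values = np.clip(np.where(comp, loh, het), 0.5, 1.0)
    mafs = [make_maf(i + 1, float(v)) for i, v in enumerate(values)]
    return mafs, comp


@pytest.fixture
def passing_variant():
    return make_variant()
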