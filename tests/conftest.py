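"""Shared fixtures: small hand-built summary statistics and the demo study."""

import numpy as np
import pytest

from mrmoloc.sumstats import (
    HarmonizedPair,
    LDMatrix,
    SumStats,
    VariantAssociation,
    pval_from_z,
)


def make_variant(variant_id="rs1", chromosome="1", position=1_000_000,
                 effect_allele="A", other_allele="G", eaf=0.3, beta=0.1,
                 se=0.05, pval=None, n=5000, trait_id="trait",
                 trait_type="quantitative"):
    """VariantAssociation with a self-consistent p-value unless given."""
    if pval is None:
        pval = max(float(pval_from_z(beta / se)), 1e-300) if se > 0 else 0.5
    return VariantAssociation(
        variant_id=variant_id, chromosome=chromosome, position=position,
        effect_allele=effect_allele, other_allele=other_allele, eaf=eaf,
        beta=beta, se=se, pval=pval, n=n, trait_id=trait_id,
        trait_type=trait_type)


def make_pair(variant_id="rs1", beta_exposure=0.5, se_exposure=0.02,
              beta_outcome=0.1, se_outcome=0.05, eaf_exposure=0.3,
              eaf_outcome=0.3, n_exposure=5000, n_outcome=5000,
              status="aligned"):
    return HarmonizedPair(
        variant_id=variant_id, beta_exposure=beta_exposure,
        se_exposure=se_exposure, beta_outcome=beta_outcome,
        se_outcome=se_outcome, eaf_exposure=eaf_exposure,
        eaf_outcome=eaf_outcome, n_exposure=n_exposure, n_outcome=n_outcome,
        status=status)


@pytest.fixture
def small_sumstats():
    """Three-variant quantitative-trait table."""
    records = [
        make_variant("rs1", position=1_000_000, beta=0.30, se=0.02),
        make_variant("rs2", position=1_050_000, beta=0.01, se=0.02, eaf=0.45),
        make_variant("rs3", position=1_100_000, beta=-0.12, se=0.03, eaf=0.10),
    ]
    return SumStats.from_records(records, trait_id="exposure")


@pytest.fixture
def identity_ld():
    def _make(variant_ids):
        return LDMatrix(variant_ids=list(variant_ids),
                        r=np.eye(len(variant_ids)))
    return _make


@pytest.fixture(scope="session")
def demo_report(tmp_path_factory):
    """The packaged demo study, run once per session."""
    from mrmoloc.pipeline import make_demo_study, run_study

    outdir = tmp_path_factory.mktemp("demo")
    config = make_demo_study(outdir, seed=7)
    return run_study(config), config, outdir
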