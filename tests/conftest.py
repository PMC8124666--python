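import numpy as np
import pytest

from clonepair.datasets import demo_pathway_db
from clonepair.io_formats import VariantCall
from clonepair.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def pathway_db():
    return demo_pathway_db()


@pytest.fixture(scope="session")
def small_cohort(pathway_db):
    """A 4-patient noisy cohort with planted artifacts, CNV regions and one
    planted exclusive pathway pair."""
    cfg = SimulationConfig(
        n_patients=4,
        depth=500,
        pathway_db=pathway_db,
        planted_exclusive_pairs=(("PW_RRNA", "PW_OGLYC"),),
        seed=42,
    )
    return cfg, *simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort(pathway_db):
    cfg = SimulationConfig(
        n_patients=4,
        depth=500,
        noise="none",
        pathway_db=pathway_db,
        seed=43,
    )
    return cfg, *simulate_cohort(cfg)


def make_call(chrom="chr1", pos=100, ref="A", alt="C", alt_count=20, depth=100,
              patient_id="P01", sample_id="TU1", **kw):
    return VariantCall(
        patient_id=patient_id, sample_id=sample_id, chrom=chrom, pos=pos,
        ref=ref, alt=alt, alt_count=alt_count, depth=depth, **kw
    )
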