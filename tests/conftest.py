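import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cfmethsim import SimConfig, make_toy_atlas, simulate_sample
from cfmethsim.simulate import FragmentRecord, JagSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: ground-truth tissue mixture used by the recovery studies
MIXTURE = {"tissueA": 0.6, "tissueB": 0.3, "tissueC": 0.1}


@pytest.fixture(scope="session")
def toy_atlases():
    """Matched (site atlas, marker-block atlas): 3 tissues x 10 sites."""
    return make_toy_atlas(3, 10, high_beta=0.9, low_beta=0.1, seed=1)


@pytest.fixture(scope="session")
def site_atlas(toy_atlases):
    return toy_atlases[0]


@pytest.fixture(scope="session")
def block_atlas(toy_atlases):
    return toy_atlases[1]


@pytest.fixture(scope="session")
def sslp_sample(site_atlas):
    """A moderately deep single-stranded sample with jagged input fragments."""
    cfg = SimConfig(
        mixture=MIXTURE,
        n_fragments=20_000,
        library="ssLP",
        jag_prob=0.8,
        jag_length=JagSpec(mean=25.0),
        seed=1,
    )
    return simulate_sample(cfg, site_atlas)


@pytest.fixture(scope="session")
def dslp_sample(site_atlas):
    """The matched double-stranded sample (same seed, same latent fragments)."""
    cfg = SimConfig(
        mixture=MIXTURE,
        n_fragments=20_000,
        library="dsLP",
        jag_prob=0.8,
        jag_length=JagSpec(mean=25.0),
        seed=1,
    )
    return simulate_sample(cfg, site_atlas)


def make_record(
    pattern: str,
    r1pos=None,
    r2pos=None,
    positions=None,
    chrom: str = "chrS1",
    start: int = 0,
    end: int = 200,
    tissue: str = "tissueA",
) -> FragmentRecord:
    """Hand-build a FragmentRecord for unit tests.

    ``r1pos``/``r2pos`` default to no read coverage; pass lists with -1 for
    uncovered CpGs.
    """
    n = len(pattern)
    if positions is None:
        positions = np.arange(n) * 10 + 100
    r1 = np.full(n, -1, dtype=int) if r1pos is None else np.asarray(r1pos, dtype=int)
    r2 = np.full(n, -1, dtype=int) if r2pos is None else np.asarray(r2pos, dtype=int)
    return FragmentRecord(
        chrom=chrom,
        start=start,
        end=end,
        tissue_origin=tissue,
        cpg_positions=np.asarray(positions, dtype=int),
        pattern=pattern,
        repair_mask=np.zeros(n, dtype=bool),
        read1_pos=r1,
        read2_pos=r2,
    )
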