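import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mendelmap.genotypes import GenotypeMatrix
from mendelmap.intervals import GenomicInterval
from mendelmap.simulate import SimulationConfig, make_transcript_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CODE = {"AA": 0, "AB": 1, "BB": 2, "..": -1}


def make_gm(calls_by_sample: dict[str, list], positions=None, chrom: str = "1"):
    """Small genotype matrix from readable per-sample call strings/codes."""
    n = len(next(iter(calls_by_sample.values())))
    if positions is None:
        positions = [(i + 1) * 100_000 for i in range(n)]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "a1": "A", "a2": "C"}
    )
    samples = list(calls_by_sample)
    rows = []
    for s in samples:
        rows.append([CODE[c] if isinstance(c, str) else c for c in calls_by_sample[s]])
    return GenotypeMatrix(markers, samples, np.array(rows, dtype=np.int8))


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale study: 2x6 Mb genome, 1,200 markers, two seeded tracts."""
    defaults = dict(
        genome_layout=[("1", 6_000_000), ("2", 6_000_000)],
        n_markers=1_200,
        seeded_ibd_regions=[
            GenomicInterval("1", 2_000_000, 4_000_000),
            GenomicInterval("2", 1_000_000, 5_000_000),
        ],
        n_control_genomes=20,
        n_popdb_genomes=50,
        n_population_controls=150,
        n_background_coding_variants=60,
        n_background_genes=8,
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def fixture_transcripts():
    """The two-transcript causal gene plus background genes (default scale)."""
    return make_transcript_fixture(SimulationConfig(rng_seed=7))


@pytest.fixture
def config():
    return small_config()
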