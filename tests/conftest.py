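import numpy as np
import pandas as pd
import pytest

from founderscan.model import GenotypePanel, SampleManifest
from founderscan.simulate import SimulationConfig, simulate_study


def make_panel(call_strings, positions=None, chrom="chr1", sample_ids=None):
    """Build a small panel from per-sample call strings like 'AA,AB,--'."""
    code = {"AA": 0, "AB": 1, "BB": 2, "--": -1, "NA": -1}
    rows = [[code[c] for c in s.split(",")] for s in call_strings]
    n_markers = len(rows[0])
    if positions is None:
        positions = [(i + 1) * 1000 for i in range(n_markers)]
    markers = pd.DataFrame({
        "marker_id": [f"snp{i + 1}" for i in range(n_markers)],
        "chrom": chrom,
        "pos": positions,
    })
    samples = sample_ids or [f"S{i + 1}" for i in range(len(rows))]
    return GenotypePanel(markers, samples, np.array(rows, dtype=np.int8))


def make_manifest(rows):
    """rows: list of dicts with at least sample_id/family_id/status/role."""
    return SampleManifest(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_config():
    """A compact study: one 40 Mb chromosome, 2 Mb planted block,
    20 controls — fast enough for per-test simulation."""
    return SimulationConfig(
        chromosome_lengths={"chr1": 40_000_000},
        pathogenic_block=("chr1", 19_000_000, 21_000_000),
        n_population_controls=20,
        exome_variant_rate=2000.0,
        novel_fraction=0.05,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
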