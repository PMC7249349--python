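import numpy as np
import pytest
from hypothesis import settings

from scsim import (SnvModelParams, assign_substitutions, make_fixture_reference,
                   place_snv_sites)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


RESULTS_DESIGN_YAML = """\
region: {start: 0, length: 1000000}
prototypes:
  K: 3
  n_snv: 100
  margin_fraction: 0.1
alpha: [0.1, 0.3, 0.6]
units:
  - id: unit1
    beta: 0.1
    samples:
      - {id: u1_bulk, type: bulk, gamma: 0.1, coverage: 24, n_bulk_reads: 1000000}
      - {id: u1_sc, type: single_cell, gamma: 0.1, coverage: 24}
  - id: unit2
    beta: 0.1
    samples:
      - {id: u2_sc1, type: single_cell, gamma: 0.1, coverage: 24}
      - {id: u2_sc2, type: single_cell, gamma: 0.1, coverage: 24}
  - id: unit3
    beta: 0.1
    samples:
      - {id: u3_bulk1, type: bulk, gamma: 0.1, coverage: 24, n_bulk_reads: 1000000}
      - {id: u3_bulk2, type: bulk, gamma: 0.1, coverage: 24, n_bulk_reads: 1000000}
  - id: unit4
    beta: 0.1
    samples:
      - {id: u4_bulk, type: bulk, gamma: 0.1, coverage: 24, n_bulk_reads: 1000000}
      - {id: u4_sc, type: single_cell, gamma: 0.1, coverage: 24}
wga: {ado_rate: 0.2, fp_rate: 3.2e-5}
reads: {length: 100, fragment_mean: 500, fragment_sd: 50, error_rate: 0.001, base_quality: 30}
seed: 42
"""


@pytest.fixture(scope="session")
def results_design_yaml() -> str:
    """The published demonstration protocol: K=3, 100 SNVs over 1 Mbp,
    alpha=(0.1,0.3,0.6), 4 units x 2 samples, coverage 24x."""
    return RESULTS_DESIGN_YAML


@pytest.fixture(scope="session")
def small_reference() -> str:
    """50 kb random reference sequence (GC 0.41)."""
    _, seq = make_fixture_reference(50_000, gc_fraction=0.41, seed=101)
    return seq


@pytest.fixture(scope="session")
def assigned_sites(small_reference):
    """60 fully assigned SNV sites over the small reference, K=3."""
    sites = place_snv_sites(len(small_reference), 60, K=3, seed=202)
    return assign_substitutions(sites, small_reference, SnvModelParams(), seed=203)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
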