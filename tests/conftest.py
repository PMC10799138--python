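import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from poolimpute import decoding, imputation, magic_sim, metrics, pooling


@pytest.fixture(scope="session")
def small_truth():
    """Small synthetic MAGIC population: 32 lines x 120 markers."""
    cfg = magic_sim.MagicSimConfig(n_lines=32, n_markers=120, seed=7)
    return magic_sim.simulate(cfg)


@pytest.fixture(scope="session")
def full_scale_run():
    """Default study conditions end to end: 16 founders, 496 inbred lines,
    1170 markers; pool -> decode -> impute with the founders as panel."""
    cfg = magic_sim.MagicSimConfig(seed=1)
    truth = magic_sim.simulate(cfg)
    design = pooling.assign_blocks(truth.lines.sample_ids, seed=1)
    outcomes = pooling.simulate_pools_all(truth.lines.dosages, design)
    decoded, summary = decoding.decode_all(
        outcomes, design, truth.lines.n_samples, truth_dosages=truth.lines.dosages
    )
    distances = imputation._pair_distances(truth.markers["cm"].to_numpy())
    posteriors = imputation.impute_population(
        decoded, truth.founders, distances, imputation.HMMParams()
    )
    report = metrics.evaluate(
        truth.lines.dosages, posteriors, decoded_simplexes=decoded
    )
    return {
        "truth": truth,
        "design": design,
        "decoded": decoded,
        "decode_summary": summary,
        "posteriors": posteriors,
        "report": report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
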