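import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ighrep import SimulationConfig, build_synthetic_reference, simulate_sample
from ighrep.annotate import annotate_sample, collapse_duplicates, quality_filter

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_ref():
    """A compact synthetic reference for unit-level annotation tests."""
    return build_synthetic_reference(
        n_v=8, n_d=6, n_j=3, n_c=4, min_pairwise_divergence=0.15, seed=7
    )


@pytest.fixture(scope="session")
def sim_bundle(small_ref):
    """One simulated sample pushed through filter -> annotate -> collapse.

    Sequencing error on, SHM on: the generic fixture exercised by several
    modules.  Returns a dict of every intermediate.
    """
    config = SimulationConfig(
        reference=small_ref,
        reads_per_sample=600,
        clone_count=120,
        shm_rate_by_isotype={"default": 0.01},
        seq_error_rate=0.001,
        seed=5,
    )
    reads, truth = simulate_sample(config, sample_id="fix")
    kept, filter_counts = quality_filter(reads)
    annotated, rejects, counts = annotate_sample(kept, small_ref)
    collapsed = collapse_duplicates(annotated[annotated["productive"]])
    return {
        "config": config,
        "reads": reads,
        "truth": truth,
        "kept": kept,
        "filter_counts": filter_counts,
        "annotated": annotated,
        "rejects": rejects,
        "counts": counts,
        "collapsed": collapsed,
    }
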