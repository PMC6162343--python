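import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import structmethseq as sm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_sim():
    """A small simulated IP experiment with a strong planted structural
    preference, shared by enrichment/profile tests."""
    oligos = sm.generate_oligo_library(n=1200, seed=42)
    model = sm.SelectionModel(
        p_ip_structured=0.9,
        p_ip_background=0.05,
        input_depth=20_000,
        ip_depth=20_000,
        seed=42,
    )
    return sm.simulate_ip_experiment(oligos, None, model)


@pytest.fixture(scope="session")
def planted_pipeline(planted_sim):
    """Filtered reads, structures and enrichment results for planted_sim."""
    kept = {
        lib: sm.filter_reads([s for _, s in recs])[0]
        for lib, recs in planted_sim.reads.items()
    }
    structures = sm.fold_many({s for seqs in kept.values() for s in seqs})
    table = sm.aggregate_structures(
        kept, {s: st.dot_bracket for s, st in structures.items()}
    )
    results = sm.differential_representation(table)
    return {"kept": kept, "structures": structures, "table": table, "results": results}


@pytest.fixture(scope="session")
def random_structures():
    """Native folds of random 30-mers (valid structures by construction)."""
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGU"))
    seqs = ["".join(bases[rng.integers(0, 4, 30)]) for _ in range(300)]
    return [sm.mfe_fold(s) for s in seqs]
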