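import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from argos import (
    SimulationConfig,
    TrueGeneParams,
    compute_size_factors,
    encode_copy_number,
    simulate_study,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_truth(scores_by_gene, base_rng=None, **kwargs):
    """TrueGeneParams list for a single-tissue cohort."""
    truth = []
    for gene, score in scores_by_gene.items():
        base = 500.0 if base_rng is None else float(base_rng.uniform(100, 2000))
        truth.append(
            TrueGeneParams(
                gene_id=gene,
                base_mean_by_tissue={"tissue1": base},
                true_score=score,
                **kwargs,
            )
        )
    return truth


def background_truth(n, rng, prefix="null"):
    return make_truth(
        {f"{prefix}{i + 1:03d}": 0.0 for i in range(n)}, base_rng=rng
    )


@pytest.fixture(scope="session")
def small_cohort():
    """50-gene cell-line cohort with planted compensated/scaling/hyper genes.

    The 47 null genes give the median-of-ratios size factors a realistic
    mostly-unperturbed gene population.
    """
    rng = np.random.default_rng(0)
    truth = background_truth(47, rng) + make_truth(
        {"comp": -1.0, "scal": 0.0, "hyper": 1.0}
    )
    cohort = simulate_study(SimulationConfig(seed=11), truth)
    design = encode_copy_number(cohort.log2_copy)
    info = cohort.sample_info.copy()
    info["size_factor"] = compute_size_factors(cohort.counts)
    return cohort, design, info


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    """A written fixture set for a small cohort with screens attached."""
    from argos import write_fixture_set

    rng = np.random.default_rng(3)
    truth = background_truth(8, rng) + make_truth(
        {"comp": -1.0, "hyper": 1.0}, true_toxicity_lfc=-1.0
    )
    config = SimulationConfig(
        seed=21, samples_per_tissue=60, n_screens=2, barcodes_per_gene=3
    )
    cohort = simulate_study(config, truth)
    out = tmp_path_factory.mktemp("fixture_set")
    manifest = write_fixture_set(cohort, out)
    return cohort, out, manifest
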