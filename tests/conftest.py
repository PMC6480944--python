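import numpy as np
import pytest

import gicasel as g


@pytest.fixture(scope="session")
def tiny_grid():
    """Smallest grid that still fits a full block design (7 fixations + 6 blocks)."""
    return g.GridSpec(nx=10, ny=12, nz=8, n_timepoints=48)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_grid):
    return g.make_atlas(tiny_grid, n_regions=8, seed=5)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_grid, tiny_atlas):
    """4+4 subjects, 1 run, 2 planted sources; effect on source 0's regions."""
    supports = g.plan_source_supports(tiny_atlas, 2, seed=5)
    spec = g.CohortSpec(
        n_healthy=4, n_patient=4, n_runs=1, n_sources=2,
        effect_regions=supports[0], effect_size=0.8, noise_sd=0.3, seed=5,
    )
    scans, manifest = g.simulate_cohort(spec, tiny_atlas, tiny_grid)
    return spec, scans, manifest, supports


@pytest.fixture(scope="session")
def tiny_gica(tiny_cohort):
    _, scans, _, _ = tiny_cohort
    return g.run_group_ica(scans, n_components=2, config=g.GicaConfig(seed=0))


def separable_features(n_per_class=8, n_noise=9, gap=6.0, seed=0):
    """FeatureMatrix with one feature separating the classes by `gap` sds."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([-1] * n_per_class + [1] * n_per_class)
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] = rng.normal(size=n) + gap * (y > 0)
    return g.FeatureMatrix(
        values=X,
        column_descriptors=[(f"Region_{i:03d}", "mean") for i in range(n_noise + 1)],
        subject_ids=[f"sub-{i:03d}" for i in range(n)],
        group_labels=y,
    )
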