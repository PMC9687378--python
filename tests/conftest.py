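import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bayesabc as B
from bayesabc.synthetic_data import PlantedEffect, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def sharp_model():
    """Well-separated equal-weight two-component mixture (log scale)."""
    return B.GaussianMixtureModel(
        (B.GaussianComponent(0.5, 1.0, 0.3), B.GaussianComponent(0.5, 4.0, 0.3))
    )


@pytest.fixture
def skew_model():
    """Unequal-weight moderately separated mixture used for formula oracles."""
    return B.GaussianMixtureModel(
        (B.GaussianComponent(0.6, 1.0, 0.5), B.GaussianComponent(0.4, 4.0, 0.5))
    )


@pytest.fixture
def tiny_matrix():
    return B.ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2"],
        values=np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
    )


def small_sim_config(seed=7, **overrides):
    """A fast, strongly structured simulation for pipeline-level tests."""
    layout = [("APL", "AML1", 6), ("APL", "AML2", 12), ("AML1", "AML2", 6)]
    de, gene = [], 0
    for a, b, count in layout:
        for k in range(count):
            de.append(
                PlantedEffect(gene=gene, group_a=a, group_b=b,
                              direction=1 if k % 2 == 0 else -1, effect=1.0)
            )
            gene += 1
    base = dict(
        n_genes=150,
        group_sizes={"APL": 8, "AML1": 30, "AML2": 12, "normal": 10},
        m_low=1.0, s_low=0.3, m_high=4.0, s_high=0.3, w_low=0.5,
        de_spec=tuple(de),
        het_genes=tuple(range(24, 114)),
        het_shift=0.45,
        noise_sd=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the reference config (shared: it is slow)."""
    cfg = B.default_config()
    return B.run(B.PipelineConfig(simulation=cfg, seed=cfg.seed))


def true_posteriors(cfg, matrix):
    """Posteriors under the generating mixture (no fitting): fast oracle."""
    model = B.GaussianMixtureModel(
        (
            B.GaussianComponent(cfg.w_low, cfg.m_low, cfg.s_low),
            B.GaussianComponent(1.0 - cfg.w_low, cfg.m_high, cfg.s_high),
        )
    )
    log_values = B.log_transform(matrix.values, cfg.log_base, cfg.pseudocount)
    return pd.DataFrame(
        B.normalize_to_posteriors(model, log_values),
        index=matrix.gene_ids,
        columns=matrix.sample_ids,
    )
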