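import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def corpus_pipeline():
    """One full pipeline run on a corpus-like synthetic repository.

    17 meta-analyses with the default template (K median ~11, series length
    median ~52, autocorrelation median ~0.22), shared across tests that
    only need a realistic end-to-end result.
    """
    from itsmeta import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(synth_n_meta=17, seed=1))


@pytest.fixture(scope="session")
def null_pipeline():
    """Pipeline run in the method-indifferent regime.

    No autocorrelation, long series, no between-study heterogeneity: every
    ITS estimator and meta-analysis method should approximately agree.
    """
    from itsmeta import PipelineConfig, run_pipeline
    from itsmeta.types import RepositoryTemplate, SeriesTemplate

    tpl = RepositoryTemplate(
        k_fixed=12,
        tau2_level=0.0,
        tau2_slope=0.0,
        series=SeriesTemplate(
            n_points_fixed=120,
            rho_fixed=0.0,
            sigma_w=1.0,
            interruption_frac=(0.4, 0.6),
            interval_unit="month",
        ),
    )
    return run_pipeline(PipelineConfig(synth_n_meta=17, synth_template=tpl, seed=42))
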