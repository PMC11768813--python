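import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_bundle():
    """A small noiseless synthetic dataset shared across tests."""
    from ppcpscreen.synthetic import GeneratorConfig, generate

    return generate(GeneratorConfig(seed=11, n_chemicals=40,
                                    noise_cv=0.0, loq=0.0))


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """The small bundle written to disk and run through the full pipeline."""
    from ppcpscreen.pipeline import PipelineConfig, run_pipeline
    from ppcpscreen.synthetic import write_bundle

    root = tmp_path_factory.mktemp("smallrun")
    paths = write_bundle(small_bundle, root / "data")
    config = PipelineConfig(
        records_csv=str(paths["records"]),
        predictions_csv=str(paths["predictions"]),
        ed_csv=str(paths["ed_flags"]),
        ca_csv=str(paths["ca"]),
        out_dir=str(root / "out"),
    )
    return run_pipeline(config)
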