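import pytest

from incns import SimulationConfig, build_cohort, cohort_to_frame, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized synthetic cohort shared across tests (defaults, seed 42)."""
    cfg = SimulationConfig(n_patients=500, seed=42)
    timelines, latent = generate_cohort(cfg, return_latent=True)
    rows, exclusions = build_cohort(timelines)
    return {
        "config": cfg,
        "timelines": timelines,
        "latent": latent,
        "rows": rows,
        "exclusions": exclusions,
        "frame": cohort_to_frame(rows),
    }
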