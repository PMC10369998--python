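import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_records():
    """Six reporter-het samples with a clear reference bias."""
    from casekit import AllelicCountRecord

    counts = [(15, 5), (12, 8), (18, 2), (11, 9), (16, 4), (14, 6)]
    return [
        AllelicCountRecord(f"S{i:03d}", "rep1", "chr8", 118_185_000, r, a)
        for i, (r, a) in enumerate(counts, start=1)
    ]


@pytest.fixture
def mediation_run():
    """One simulated mediation scenario with everything downstream needs."""
    import casekit.simulate as sim
    from casekit import case

    scen = sim.mediation_scenario(seed=7)
    gm, records, truth = sim.simulate_dataset(scen.config)
    samples = case.sample_z_table(records, min_cov=10)
    r_z = case.combine_weighted_z(samples)
    return scen, gm, records, truth, r_z
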