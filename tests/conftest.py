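import pytest

from rwas.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact null study shared across tests (no planted effects)."""
    cfg = SimConfig(n_enhancers=300, n_chrom=1, chrom_length=1_500_000,
                    n_ref_samples=300)
    return simulate_study(cfg, seed=1)


@pytest.fixture(scope="session")
def small_assoc(small_study):
    from rwas.region import run_region_assoc

    st = small_study
    return run_region_assoc(st.enhancers, st.gwas, st.snp_locs, st.panel)
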