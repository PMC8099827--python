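import numpy as np
import pandas as pd
import pytest

from colocpipe import ScenarioConfig, simulate_haplotype_panel, simulate_two_trait_scenario


def make_records(ids, betas, ses, chrom="1", start=1_000_000, spacing=2_000,
                 ref="C", alt="T", freq=0.3, n_cases=10_000, n_controls=10_000):
    """Hand-built summary-statistic frame in the package's TSV schema."""
    n = len(ids)
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    from colocpipe.assoc_stats import wald_p
    return pd.DataFrame({
        "SNP": ids,
        "CHR": chrom,
        "BP": start + spacing * np.arange(n),
        "REF": ref, "ALT": alt,
        "ALT_FRQ": freq,
        "BETA": betas, "SE": ses,
        "P": wald_p(betas, ses),
        "N_CASES": n_cases, "N_CONTROLS": n_controls,
        "FLAG": ".",
    })


@pytest.fixture(scope="session")
def small_panel():
    """50-variant AR(1) haplotype panel shared across read-only tests."""
    config = ScenarioConfig(n_variants=50, ld_rho=0.8, seed=11,
                            n_panel_haplotypes=4_000)
    return simulate_haplotype_panel(config)


@pytest.fixture(scope="session")
def shared_causal_run():
    """One simulated shared-causal scenario reused by read-only tests."""
    config = ScenarioConfig(
        n_variants=80, ld_rho=0.9, seed=5,
        causal_spec_trait1=[(40, float(np.log(1.4)))],
        causal_spec_trait2=[(40, float(-np.log(1.4)))],
        n_cases=(6_000, 6_000), n_controls=(6_000, 6_000),
        n_panel_haplotypes=6_000,
    )
    cohort1, cohort2, truth, panel = simulate_two_trait_scenario(config)
    return config, cohort1, cohort2, truth, panel
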