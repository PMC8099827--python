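"""Reference scenario experiments used for calibration and validation.

Each runner simulates seeded replicates of a canonical two-trait study
condition — one 0.4 Mb AR(1) region of 200 variants, 10,000 cases and
10,000 controls per trait, per-allele odds ratio 1.3 at planted causal
variants — and measures how the colocalisation machinery behaves on them:

* shared-causal replicates (one variant causal for both traits, discordant
  by default) — how often PP4 reaches the 0.9 decision threshold and what
  direction is called;
* distinct-causal replicates (two unlinked causal variants, one per trait)
  — how often PP3 correctly exceeds PP4;
* null replicates (no causal variant in either trait) — PP4 false-positive
  calibration;
* conditional-secondary replicates (trait 1 carries a primary signal plus a
  secondary one that is shared with trait 2) — whether conditioning on the
  primary exposes the shared secondary signal, the situation that motivates
  testing every conditionally independent signal pair rather than only the
  marginal pair;
* a five-locus "headline" genome (four discordant shared loci and one
  concordant) driven through the full pipeline.

All functions are deterministic given their seed; replicate seeds are
``base_seed + replicate`` and stay below 2**31.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc_stats import score_variants
from .coloc_core import ColocPriors, classify_direction, coloc_posteriors
from .conditional import enumerate_signals
from .ld_reference import index_ld
from .pipeline import AnalysisParams, PipelineResult, run_pipeline
from .region_select import Region
from .synthetic_data import ScenarioConfig, simulate_two_trait_scenario

#: Canonical region/cohort conditions for the scenario experiments.
REGION_N_VARIANTS = 200
REGION_LD_RHO = 0.9
COHORT_SIZE = 10_000
EFFECT_LOG_OR = float(np.log(1.3))
N_PANEL_HAPLOTYPES = 10_000


def _region_config(seed: int, causal1, causal2, n_cases=COHORT_SIZE,
                   n_controls=COHORT_SIZE) -> ScenarioConfig:
    return ScenarioConfig(
        n_variants=REGION_N_VARIANTS, ld_rho=REGION_LD_RHO, seed=seed,
        causal_spec_trait1=causal1, causal_spec_trait2=causal2,
        n_cases=(n_cases, n_cases), n_controls=(n_controls, n_controls),
        n_panel_haplotypes=N_PANEL_HAPLOTYPES,
    )


def _marginal_coloc(config: ScenarioConfig, priors: ColocPriors, prior_sd_w: float):
    cohort1, cohort2, truth, panel = simulate_two_trait_scenario(config)
    rec1 = score_variants(cohort1)
    rec2 = score_variants(cohort2)
    result = coloc_posteriors(rec1, rec2, priors=priors, prior_sd_w=prior_sd_w)
    return rec1, rec2, truth, panel, result


def run_shared_causal(seed: int, n_reps: int, beta: float = EFFECT_LOG_OR,
                      discordant: bool = True,
                      priors: ColocPriors = ColocPriors(),
                      prior_sd_w: float = 0.2) -> pd.DataFrame:
    """Shared-causal replicates: one variant causal for both traits.

    Returns one row per replicate with the five posteriors, the direction
    call for replicates passing the 0.9 threshold, and the truth direction.
    """
    sign = -1.0 if discordant else 1.0
    rows = []
    for rep in range(n_reps):
        config = _region_config(seed + rep, [(100, beta)], [(100, sign * beta)])
        rec1, rec2, truth, _, res = _marginal_coloc(config, priors, prior_sd_w)
        call = classify_direction(rec1, rec2, res) if res.pp4 >= 0.9 else "."
        rows.append({"rep": rep, "pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
                     "pp3": res.pp3, "pp4": res.pp4, "direction": call,
                     "truth_direction": truth.direction[truth.shared_ids[0]]})
    return pd.DataFrame(rows)


def run_distinct_causal(seed: int, n_reps: int, beta: float = EFFECT_LOG_OR,
                        priors: ColocPriors = ColocPriors(),
                        prior_sd_w: float = 0.2) -> pd.DataFrame:
    """Distinct-causal replicates: unlinked causal variants, one per trait.

    The two causal variants sit 100 variants apart in the AR(1) region, far
    beyond the LD decay length; each replicate records their realised r²
    alongside the posteriors.
    """
    rows = []
    for rep in range(n_reps):
        config = _region_config(seed + rep, [(50, beta)], [(150, beta)])
        _, _, truth, panel, res = _marginal_coloc(config, priors, prior_sd_w)
        r2 = index_ld(panel, truth.causal_trait1[0][0], truth.causal_trait2[0][0])
        rows.append({"rep": rep, "pp3": res.pp3, "pp4": res.pp4, "causal_r2": r2})
    return pd.DataFrame(rows)


def run_null(seed: int, n_reps: int, priors: ColocPriors = ColocPriors(),
             prior_sd_w: float = 0.2) -> pd.DataFrame:
    """Null replicates: no association with either trait anywhere."""
    rows = []
    for rep in range(n_reps):
        config = _region_config(seed + rep, [], [])
        *_, res = _marginal_coloc(config, priors, prior_sd_w)
        rows.append({"rep": rep, "pp0": res.pp0, "pp4": res.pp4})
    return pd.DataFrame(rows)


def run_conditional_secondary(seed: int, n_reps: int,
                              primary_beta: float = float(np.log(1.5)),
                              secondary_beta: float = EFFECT_LOG_OR,
                              priors: ColocPriors = ColocPriors(),
                              prior_sd_w: float = 0.2,
                              p_enter: float = 1e-5) -> pd.DataFrame:
    """Two trait-1 signals, the secondary shared (discordantly) with trait 2.

    Trait 1 carries a primary causal variant (index 60) and an unlinked
    secondary one (index 140); trait 2's only causal variant is the
    secondary.  Each replicate stepwise-dissects trait 1, then colocalises
    both the unconditioned primary pair and the conditional secondary pair
    against trait 2's signal.
    """
    rows = []
    for rep in range(n_reps):
        config = _region_config(seed + rep,
                                [(60, primary_beta), (140, secondary_beta)],
                                [(140, -secondary_beta)])
        cohort1, cohort2, truth, panel = simulate_two_trait_scenario(config)
        region = Region(chrom=config.chrom, start=int(config.positions[0]),
                        end=int(config.positions[-1]), seed_variant="seed")
        sig1 = enumerate_signals(cohort1, region, "trait1", p_enter)
        sig2 = enumerate_signals(cohort2, region, "trait2", p_enter)
        row = {"rep": rep, "n_signals_trait1": len(sig1),
               "primary_pp4": np.nan, "secondary_pp4": np.nan}
        if sig1 and sig2:
            rec2 = sig2[0].conditional_records
            row["primary_pp4"] = coloc_posteriors(
                sig1[0].conditional_records, rec2, priors=priors,
                prior_sd_w=prior_sd_w).pp4
            if len(sig1) > 1:
                row["secondary_pp4"] = coloc_posteriors(
                    sig1[1].conditional_records, rec2, priors=priors,
                    prior_sd_w=prior_sd_w).pp4
        rows.append(row)
    return pd.DataFrame(rows)


HEADLINE_N_LOCI = 5
HEADLINE_CONCORDANT_LOCUS = 4          # the last locus acts concordantly
HEADLINE_EFFECT = float(np.log(1.4))


def headline_config(seed: int, locus_size: int = 100,
                    gap_bp: int = 1_300_000) -> ScenarioConfig:
    """Five shared-causal loci on one chromosome: 4 discordant, 1 concordant.

    Loci are ``gap_bp`` apart (beyond the 0.5 Mb windows and the AR(1) LD
    range), each with a causal variant at its centre affecting both traits.
    """
    spacing = 2_000
    positions = []
    for locus in range(HEADLINE_N_LOCI):
        start = 1_000_000 + locus * (locus_size * spacing + gap_bp)
        positions.extend(start + spacing * np.arange(locus_size))
    causal1, causal2 = [], []
    for locus in range(HEADLINE_N_LOCI):
        idx = locus * locus_size + locus_size // 2
        causal1.append((idx, HEADLINE_EFFECT))
        sign = 1.0 if locus == HEADLINE_CONCORDANT_LOCUS else -1.0
        causal2.append((idx, sign * HEADLINE_EFFECT))
    return ScenarioConfig(
        n_variants=HEADLINE_N_LOCI * locus_size, ld_rho=REGION_LD_RHO, seed=seed,
        positions=np.array(positions), causal_spec_trait1=causal1,
        causal_spec_trait2=causal2,
        n_cases=(COHORT_SIZE, COHORT_SIZE), n_controls=(COHORT_SIZE, COHORT_SIZE),
        n_panel_haplotypes=N_PANEL_HAPLOTYPES,
    )


@dataclass
class HeadlineOutcome:
    """Recovery of the planted five-locus structure by the full pipeline."""

    result: PipelineResult
    n_loci_detected: int              # planted loci with a PP4 >= 0.9 pair
    directions_correct: bool          # every detected locus labelled correctly
    n_regions: int
    n_signal_pairs: int


def run_headline(seed: int, params: AnalysisParams | None = None) -> HeadlineOutcome:
    config = headline_config(seed)
    result = run_pipeline(scenario=config, params=params)
    truth_dir = result.truth.direction
    table = result.table
    detected = 0
    correct = True
    for vid, direction in truth_dir.items():
        pos = int(vid.split("_")[-1])
        locus_rows = table[(table["BP"] - pos).abs() < 300_000]
        hits = locus_rows[locus_rows["PP4"] >= 0.9]
        if len(hits):
            detected += 1
            if not (hits["DIRECTION"] == direction).all():
                correct = False
    return HeadlineOutcome(result=result, n_loci_detected=detected,
                           directions_correct=correct,
                           n_regions=result.manifest["n_regions"],
                           n_signal_pairs=result.manifest["n_signal_pairs"])
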