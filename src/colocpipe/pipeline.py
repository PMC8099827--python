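"""End-to-end orchestration of the cross-disease colocalisation analysis.

Stages, in order: simulate (or load) two case-control cohorts sharing an LD
panel; per-variant association scans; genome-wide Benjamini–Hochberg FDR per
trait; selection of ~0.5 Mb regions containing variants significant in both
traits; forward stepwise dissection of each region into conditionally
independent signals per trait; Bayesian co-localisation of every trait-1
signal against every trait-2 signal (full cross); a regional CLPP
corroboration from LD-aware fine-mapping; and direction-of-effect
classification of every co-localising pair.

Results are reported from the perspective of trait 2's index variant (the
designated "large GWAS" in config) with respect to the ALT allele, with 95%
confidence intervals exp(beta +/- 1.96 se).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .assoc_stats import attach_q, harmonize, score_variants, write_sumstats
from .clpp_core import (DEFAULT_MAX_CAUSAL, DEFAULT_PRIOR_GAMMA, DEFAULT_PRIOR_SIGMA,
                        clpp, finemap)
from .coloc_core import (DEFAULT_H4_THRESHOLD, DEFAULT_PRIOR_SD_W, ColocPriors,
                         classify_direction, coloc_posteriors)
from .conditional import DEFAULT_P_ENTER, Signal, enumerate_signals, write_signal_records
from .ld_reference import LDPanel, correlation_matrix, index_ld
from .region_select import (DEFAULT_FDR, DEFAULT_WINDOW_BP, Region, build_regions,
                            find_overlap_variants, region_variant_mask, write_bed)
from .synthetic_data import Cohort, ScenarioConfig, TruthRecord, simulate_two_trait_scenario

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "REGION", "SNP", "CHR", "BP", "REF", "ALT",
    "T2_CONDITIONED_ON", "T2_OR", "T2_CI_LO", "T2_CI_HI", "T2_P",
    "R2_TO_T1_INDEX", "T1_INDEX", "T1_CONDITIONED_ON",
    "T1_OR", "T1_CI_LO", "T1_CI_HI", "T1_P",
    "SIGNAL_RANK_1", "SIGNAL_RANK_2", "N_VARIANTS",
    "PP0", "PP1", "PP2", "PP3", "PP4", "REGIONAL_CLPP", "DIRECTION",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and region."""


@dataclass
class AnalysisParams:
    """Tunable thresholds of the analysis, with their conventional defaults."""

    fdr: float = DEFAULT_FDR
    window_bp: int = DEFAULT_WINDOW_BP
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 5e-6
    h4_threshold: float = DEFAULT_H4_THRESHOLD
    prior_sd_w: float = DEFAULT_PRIOR_SD_W
    p_enter: float = DEFAULT_P_ENTER
    max_causal: int = DEFAULT_MAX_CAUSAL
    clpp_gamma: float = DEFAULT_PRIOR_GAMMA
    clpp_sigma: float = DEFAULT_PRIOR_SIGMA
    run_clpp: bool = True

    @property
    def coloc_priors(self) -> ColocPriors:
        return ColocPriors(p1=self.p1, p2=self.p2, p12=self.p12)


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    table: pd.DataFrame
    regions: list[Region]
    signals: dict[str, list[Signal]]       # region name -> trait1+trait2 signals
    manifest: dict
    records1: pd.DataFrame
    records2: pd.DataFrame
    truth: TruthRecord | None = None
    panel: LDPanel | None = None


def _signal_stats_at(signal: Signal, variant_id: str, fallback_own_index: bool = True):
    """(OR, lo, hi, p) of a signal's conditional records at a variant."""
    rec = signal.conditional_records
    hit = rec.loc[rec["SNP"] == variant_id]
    if (hit.empty or not np.isfinite(hit["BETA"].iloc[0])) and fallback_own_index:
        hit = rec.loc[rec["SNP"] == signal.index_variant]
    if hit.empty or not np.isfinite(hit["BETA"].iloc[0]):
        return np.nan, np.nan, np.nan, np.nan
    beta = float(hit["BETA"].iloc[0])
    se = float(hit["SE"].iloc[0])
    return (np.exp(beta), np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se),
            float(hit["P"].iloc[0]))


def _regional_clpp(region: Region, records1: pd.DataFrame, records2: pd.DataFrame,
                   panel: LDPanel, params: AnalysisParams) -> float:
    mask1 = region_variant_mask(region, records1)
    sub1 = records1.loc[mask1 & records1["BETA"].notna()]
    sub2 = records2.loc[records2["SNP"].isin(set(sub1["SNP"])) & records2["BETA"].notna()]
    common = [v for v in sub1["SNP"] if v in set(sub2["SNP"])]
    if not common:
        return float("nan")
    r, kept = correlation_matrix(panel, common)
    sub1 = sub1.set_index("SNP").loc[kept].reset_index()
    sub2 = sub2.set_index("SNP").loc[kept].reset_index()
    post1 = finemap(sub1, r, params.max_causal, params.clpp_gamma, params.clpp_sigma)
    post2 = finemap(sub2, r, params.max_causal, params.clpp_gamma, params.clpp_sigma)
    return clpp(post1, post2).regional


def run_pipeline(scenario: ScenarioConfig | None = None,
                 params: AnalysisParams | None = None,
                 cohort1: Cohort | None = None,
                 cohort2: Cohort | None = None,
                 panel: LDPanel | None = None,
                 outdir: str | None = None) -> PipelineResult:
    """Run the full two-trait colocalisation analysis.

    Inputs are either a seeded :class:`ScenarioConfig` (cohorts and panel
    simulated) or pre-built cohorts plus an LD panel.  Deterministic given
    the scenario seed.  With ``outdir`` set, writes the results TSV, regions
    BED, per-trait summary statistics, signal TSVs and a manifest.
    """
    params = params or AnalysisParams()
    truth = None
    stage = "inputs"
    try:
        if scenario is not None:
            stage = "simulate"
            cohort1, cohort2, truth, panel = simulate_two_trait_scenario(scenario, panel)
        if cohort1 is None or cohort2 is None or panel is None:
            raise PipelineError("provide either a scenario config or two cohorts + panel")

        stage = "assoc"
        rec1 = attach_q(score_variants(cohort1))
        rec2 = attach_q(score_variants(cohort2))
        rec1, rec2 = harmonize(rec1, rec2)

        stage = "regions"
        overlap = find_overlap_variants(rec1, rec2, params.fdr)
        regions = build_regions(overlap, params.window_bp)
        logger.info("regions: %d overlap variant(s) in %d region(s)",
                    len(overlap), len(regions))

        rows: list[dict] = []
        region_signals: dict[str, list[Signal]] = {}
        n_pairs = 0
        for region in regions:
            stage = f"signals[{region.name}]"
            sig1 = enumerate_signals(cohort1, region, "trait1", params.p_enter)
            sig2 = enumerate_signals(cohort2, region, "trait2", params.p_enter)
            region_signals[region.name] = sig1 + sig2
            if not sig1 or not sig2:
                logger.warning("region %s: no stepwise signal for one trait "
                               "(%d trait-1, %d trait-2) — no pairs analysed",
                               region.name, len(sig1), len(sig2))
                continue

            stage = f"clpp[{region.name}]"
            regional_clpp = (_regional_clpp(region, rec1, rec2, panel, params)
                             if params.run_clpp else float("nan"))

            stage = f"coloc[{region.name}]"
            for s1 in sig1:
                for s2 in sig2:
                    n_pairs += 1
                    result = coloc_posteriors(
                        s1.conditional_records, s2.conditional_records,
                        priors=params.coloc_priors, prior_sd_w=params.prior_sd_w,
                        threshold=params.h4_threshold,
                    )
                    direction = "."
                    if result.colocalises:
                        direction = classify_direction(
                            s1.conditional_records, s2.conditional_records,
                            result, fallback_index=s2.index_variant)
                    meta = cohort2.variants.set_index("id").loc[s2.index_variant]
                    or2 = _signal_stats_at(s2, s2.index_variant)
                    or1 = _signal_stats_at(s1, s2.index_variant)
                    rows.append({
                        "REGION": region.name,
                        "SNP": s2.index_variant,
                        "CHR": str(meta["chrom"]), "BP": int(meta["pos"]),
                        "REF": meta["ref"], "ALT": meta["alt"],
                        "T2_CONDITIONED_ON": ",".join(s2.conditioning_set) or "-",
                        "T2_OR": or2[0], "T2_CI_LO": or2[1], "T2_CI_HI": or2[2],
                        "T2_P": or2[3],
                        "R2_TO_T1_INDEX": index_ld(panel, s2.index_variant, s1.index_variant),
                        "T1_INDEX": s1.index_variant,
                        "T1_CONDITIONED_ON": ",".join(s1.conditioning_set) or "-",
                        "T1_OR": or1[0], "T1_CI_LO": or1[1], "T1_CI_HI": or1[2],
                        "T1_P": or1[3],
                        "SIGNAL_RANK_1": s1.rank, "SIGNAL_RANK_2": s2.rank,
                        "N_VARIANTS": result.n_variants,
                        "PP0": result.pp0, "PP1": result.pp1, "PP2": result.pp2,
                        "PP3": result.pp3, "PP4": result.pp4,
                        "REGIONAL_CLPP": regional_clpp,
                        "DIRECTION": direction,
                    })

        table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        if len(table):
            table = table.sort_values(["CHR", "BP", "SIGNAL_RANK_1", "SIGNAL_RANK_2"],
                                      kind="mergesort").reset_index(drop=True)
        manifest = {
            "package_version": _pkg_version,
            "seed": scenario.seed if scenario is not None else None,
            "params": asdict(params),
            "n_overlap_variants": int(len(overlap)),
            "n_regions": len(regions),
            "n_signal_pairs": n_pairs,
            "n_colocalising": int((table["PP4"] >= params.h4_threshold).sum()) if len(table) else 0,
            "signals_per_region": {
                name: {
                    "trait1": sum(s.trait == "trait1" for s in sigs),
                    "trait2": sum(s.trait == "trait2" for s in sigs),
                }
                for name, sigs in region_signals.items()
            },
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = PipelineResult(table=table, regions=regions, signals=region_signals,
                            manifest=manifest, records1=rec1, records2=rec2,
                            truth=truth, panel=panel)
    if outdir is not None:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(result: PipelineResult, outdir: str) -> None:
    import os
    import shutil
    import tempfile

    os.makedirs(outdir, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix="colocpipe-", dir=outdir)
    try:
        result.table.to_csv(os.path.join(tmp, "results.tsv"), sep="\t",
                            index=False, na_rep=".")
        write_bed(result.regions, os.path.join(tmp, "regions.bed"))
        write_sumstats(result.records1, os.path.join(tmp, "trait1.sumstats.tsv"))
        write_sumstats(result.records2, os.path.join(tmp, "trait2.sumstats.tsv"))
        for name, sigs in result.signals.items():
            if sigs:
                safe = name.replace(":", "_").replace("-", "_")
                write_signal_records(sigs, os.path.join(tmp, f"signals.{safe}.tsv"))
        if result.truth is not None:
            result.truth.write_tsv(os.path.join(tmp, "truth.tsv"))
        with open(os.path.join(tmp, "manifest.json"), "w") as fh:
            json.dump(result.manifest, fh, indent=1, default=str)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)  # no partial outputs
        raise
    for fname in os.listdir(tmp):
        os.replace(os.path.join(tmp, fname), os.path.join(outdir, fname))
    shutil.rmtree(tmp, ignore_errors=True)


# ---------------------------------------------------------------------------
# regional plot data

def make_regional_plot_data(records1: pd.DataFrame, records2: pd.DataFrame,
                            panel: LDPanel, index_id: str,
                            gene_track: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aligned -log10 p series for both traits plus r² to an index variant.

    The returned frame (POS, SNP, NLOG10P_T1, NLOG10P_T2, R2_INDEX) is
    TSV-ready for any plotting layer; ``render_regional_plot`` draws a
    minimal two-panel figure from it.  If the index variant is monomorphic
    in the panel the r² column is NaN and a warning is logged.
    """
    r1, r2 = harmonize(records1, records2) if not records1["SNP"].equals(records2["SNP"]) \
        else (records1, records2)
    if index_id not in set(r1["SNP"]):
        raise KeyError(f"index variant {index_id!r} not among shared records")
    df = pd.DataFrame({
        "POS": r1["BP"].to_numpy(),
        "SNP": r1["SNP"].to_numpy(),
        "NLOG10P_T1": -np.log10(r1["P"].to_numpy(dtype=float)),
        "NLOG10P_T2": -np.log10(r2["P"].to_numpy(dtype=float)),
    })
    try:
        r, kept = correlation_matrix(panel, [index_id] + df["SNP"].tolist())
        if kept and kept[0] == index_id:
            lookup = dict(zip(kept, r[0] ** 2))
            df["R2_INDEX"] = [lookup.get(v, np.nan) for v in df["SNP"]]
        else:
            raise ValueError("index monomorphic in panel")
    except (ValueError, KeyError):
        logger.warning("index variant %s unusable in panel; r² column missing", index_id)
        df["R2_INDEX"] = np.nan
    if gene_track is not None:
        df.attrs["gene_track"] = gene_track
    return df.sort_values("POS", kind="mergesort").reset_index(drop=True)


def render_regional_plot(plot_data: pd.DataFrame, path: str,
                         trait_labels=("trait 1", "trait 2")) -> None:
    """Minimal two-panel regional association plot, points coloured by r²."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    color = plot_data.get("R2_INDEX")
    for ax, col, label in zip(axes, ("NLOG10P_T1", "NLOG10P_T2"), trait_labels):
        sc = ax.scatter(plot_data["POS"] / 1e6, plot_data[col], c=color,
                        cmap="viridis", vmin=0, vmax=1, s=12)
        ax.set_ylabel(f"-log10 p ({label})")
    axes[1].set_xlabel("position (Mb)")
    fig.colorbar(sc, ax=axes, label="r² to index")
    fig.savefig(path, dpi=120)
    plt.close(fig)
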