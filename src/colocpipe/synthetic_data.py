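"""Simulation of LD-structured two-trait case-control GWAS data.

The generator produces everything the downstream pipeline consumes:

1. a haplotype reference panel whose latent Gaussian copula has AR(1)
   correlation, thresholded per variant at its allele frequency — one
   parameter (``ld_rho``) reproduces the monotone LD decay of a real locus;
2. case-control cohorts ascertained by rejection sampling from a population
   logistic disease model ``logit P(case) = alpha + sum_k beta_k g_k``, with
   the intercept solved so the population prevalence matches the requested
   baseline;
3. two-trait scenarios: cohorts for two diseases drawn on the SAME haplotype
   panel but with independently drawn individuals (no sample overlap, as
   coloc assumes), with causal variants shared or distinct between traits and
   concordant or discordant effect directions, plus a truth record for
   parameter-recovery tests.

Effect sizes are per-allele log odds ratios.  Dosages are hard calls in
{0, 1, 2}; imputation uncertainty, relatedness and covariates are out of
scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .ld_reference import LDPanel

logger = logging.getLogger(__name__)

#: Default spacing of variants on the 1-based coordinate grid (bp).  2 kb
#: makes a 200-variant region span ~0.4 Mb, so the 0.5 Mb windowing of the
#: region-selection stage is exercised at realistic scale.
DEFAULT_SPACING_BP = 2_000

#: Cap on the total number of individuals drawn while rejection-sampling a
#: cohort, as a multiple of the requested cohort size.
MAX_DRAW_FACTOR = 2_000


class SimulationError(RuntimeError):
    """Requested cohort could not be assembled within the draw budget."""


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic two-trait experiment.

    ``causal_spec_trait1`` / ``causal_spec_trait2`` are lists of
    ``(variant_index, log_odds_ratio)`` pairs.  ``seed`` is mandatory;
    every random draw descends from it.
    """

    n_variants: int
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_spec_trait1: list[tuple[int, float]] = field(default_factory=list)
    causal_spec_trait2: list[tuple[int, float]] = field(default_factory=list)
    baseline_prevalence: tuple[float, float] = (0.1, 0.1)
    n_cases: tuple[int, int] = (10_000, 10_000)
    n_controls: tuple[int, int] = (10_000, 10_000)
    seed: int = 0
    n_panel_haplotypes: int = 10_000
    chrom: str = "1"
    start_bp: int = 1_000_000
    spacing_bp: int = DEFAULT_SPACING_BP
    positions: np.ndarray | None = None
    build: str = "synthetic-grid"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        for spec in (self.causal_spec_trait1, self.causal_spec_trait2):
            for idx, beta in spec:
                if not 0 <= idx < self.n_variants:
                    raise ValueError(f"causal index {idx} outside [0, {self.n_variants})")
                if not np.isfinite(beta):
                    raise ValueError(f"non-finite log-OR at variant {idx}")
        for k in self.baseline_prevalence:
            if not 0.0 < k < 1.0:
                raise ValueError("baseline prevalence must be in (0, 1)")
        if self.positions is None:
            self.positions = self.start_bp + self.spacing_bp * np.arange(self.n_variants)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.positions) != self.n_variants:
            raise ValueError("positions length must equal n_variants")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @classmethod
    def from_json(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "seed" not in raw:
            raise ValueError("scenario config file must specify a seed")
        for key in ("causal_spec_trait1", "causal_spec_trait2"):
            if key in raw:
                raw[key] = [(int(i), float(b)) for i, b in raw[key]]
        for key in ("maf_range", "baseline_prevalence", "n_cases", "n_controls"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path: str) -> None:
        raw = asdict(self)
        raw["positions"] = self.positions.tolist()
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=1, default=float)


@dataclass
class Cohort:
    """Individual-level case-control data for one trait."""

    genotypes: np.ndarray          # (n_individuals, n_variants), dosage 0/1/2
    phenotype: np.ndarray          # (n_individuals,), 0 = control, 1 = case
    variants: pd.DataFrame         # id, chrom, pos, ref, alt, alt_freq

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.phenotype = np.asarray(self.phenotype)
        if self.genotypes.shape[1] != len(self.variants):
            raise ValueError("genotype columns do not match variant metadata")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.phenotype) - self.phenotype.sum())


def _variant_metadata(config: ScenarioConfig, freqs: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"rs{config.chrom}_{p}" for p in config.positions],
            "chrom": config.chrom,
            "pos": config.positions,
            "ref": "C",
            "alt": "T",
            "alt_freq": freqs,
        }
    )


def _draw_haplotypes(rng: np.random.Generator, n_hap: int, thresholds: np.ndarray,
                     rho: float) -> np.ndarray:
    """Latent AR(1) Gaussians thresholded to 0/1 alleles, row per haplotype."""
    m = len(thresholds)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return (z < thresholds).astype(np.int8)


def simulate_haplotype_panel(config: ScenarioConfig, n_haplotypes: int | None = None) -> LDPanel:
    """Simulate the LD reference panel of a scenario.

    Returns ``2N`` haplotypes whose latent Gaussian copula is AR(1) with
    parameter ``ld_rho``; variant ``j`` carries the alternative allele when
    its latent Gaussian falls below ``Phi^{-1}(f_j)``, with allele
    frequencies ``f_j`` drawn uniformly in ``maf_range``.  Deterministic
    given the config seed.
    """
    n_hap = int(n_haplotypes if n_haplotypes is not None else config.n_panel_haplotypes)
    if n_hap < 2 or n_hap % 2:
        raise ValueError("panel haplotype count must be a positive even number")
    rng = np.random.default_rng([config.seed, 1])
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_variants)
    thresholds = ndtri(freqs)
    hap = _draw_haplotypes(rng, n_hap, thresholds, config.ld_rho)
    return LDPanel(
        matrix=hap,
        variants=_variant_metadata(config, freqs),
        is_haplotypes=True,
        population="synthetic-AR1",
        copula={"ld_rho": config.ld_rho, "allele_freq": freqs},
    )


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Intercept alpha with mean expit(alpha + score) == prevalence."""
    if np.allclose(scores, 0.0):
        return float(np.log(prevalence / (1.0 - prevalence)))

    def gap(alpha: float) -> float:
        return float(expit(alpha + scores).mean() - prevalence)

    lo, hi = -40.0, 40.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_case_control(panel: LDPanel, causal_spec, baseline_prevalence: float,
                          n_cases: int, n_controls: int, seed,
                          batch_size: int = 50_000) -> Cohort:
    """Ascertain a case-control cohort from the population disease model.

    Individuals are formed by pairing two haplotypes drawn uniformly with
    replacement from the panel; disease status is Bernoulli with
    ``logit P = alpha + sum_k beta_k g_k`` where ``alpha`` solves the baseline
    prevalence on the panel's genotype distribution.  Drawing continues until
    the requested case and control counts are filled; a bounded draw budget
    turns an unreachable request (e.g. prevalence ~ 0) into a
    :class:`SimulationError` rather than a hang.
    """
    if not 0.0 < baseline_prevalence < 1.0:
        raise ValueError("baseline prevalence must be in (0, 1)")
    causal_idx = np.array([i for i, _ in causal_spec], dtype=int)
    causal_beta = np.array([b for _, b in causal_spec], dtype=float)
    if causal_idx.size and not np.isfinite(causal_beta).all():
        raise ValueError("causal effects must be finite")

    rng = np.random.default_rng(seed)
    n_hap = panel.n_samples

    # intercept from a reference draw of the genotype distribution
    ref_pairs = rng.integers(0, n_hap, size=(min(50_000, 25 * n_hap), 2))
    if causal_idx.size:
        ref_scores = (
            (panel.matrix[ref_pairs[:, 0]][:, causal_idx]
             + panel.matrix[ref_pairs[:, 1]][:, causal_idx]).astype(float) @ causal_beta
        )
    else:
        ref_scores = np.zeros(len(ref_pairs))
    alpha = _solve_intercept(ref_scores, baseline_prevalence)

    need = {"case": n_cases, "control": n_controls}
    got_g, got_y = [], []
    drawn = 0
    budget = MAX_DRAW_FACTOR * (n_cases + n_controls) + batch_size
    while need["case"] > 0 or need["control"] > 0:
        if drawn >= budget:
            raise SimulationError(
                f"cohort unreachable: {need} still missing after {drawn} draws "
                f"(prevalence {baseline_prevalence})"
            )
        pairs = rng.integers(0, n_hap, size=(batch_size, 2))
        g = panel.matrix[pairs[:, 0]] + panel.matrix[pairs[:, 1]]
        if causal_idx.size:
            score = g[:, causal_idx].astype(float) @ causal_beta
        else:
            score = np.zeros(batch_size)
        y = (rng.random(batch_size) < expit(alpha + score)).astype(np.int8)
        drawn += batch_size
        for label, val in (("case", 1), ("control", 0)):
            if need[label] > 0:
                take = np.flatnonzero(y == val)[: need[label]]
                got_g.append(g[take])
                got_y.append(np.full(len(take), val, dtype=np.int8))
                need[label] -= len(take)

    genotypes = np.concatenate(got_g, axis=0)
    phenotype = np.concatenate(got_y)
    order = rng.permutation(len(phenotype))  # interleave cases and controls
    return Cohort(genotypes=genotypes[order], phenotype=phenotype[order],
                  variants=panel.variants.copy())


@dataclass
class TruthRecord:
    """Ground truth of a simulated scenario, keyed for recovery tests."""

    causal_trait1: list[tuple[str, float]]  # (variant id, log-OR)
    causal_trait2: list[tuple[str, float]]
    shared_ids: list[str]
    direction: dict[str, str]               # shared id -> concordant/discordant

    @property
    def is_null(self) -> bool:
        return not (self.causal_trait1 or self.causal_trait2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for trait, spec in (("trait1", self.causal_trait1), ("trait2", self.causal_trait2)):
            for vid, b in spec:
                rows.append({"id": vid, "trait": trait, "log_or": b,
                             "shared": vid in self.shared_ids,
                             "direction": self.direction.get(vid, ".")})
        return pd.DataFrame(rows, columns=["id", "trait", "log_or", "shared", "direction"])

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _truth_from_config(config: ScenarioConfig, variants: pd.DataFrame) -> TruthRecord:
    ids = variants["id"].tolist()
    c1 = [(ids[i], b) for i, b in config.causal_spec_trait1]
    c2 = [(ids[i], b) for i, b in config.causal_spec_trait2]
    b1 = dict(c1)
    b2 = dict(c2)
    shared = [v for v in b1 if v in b2]
    direction = {
        v: ("concordant" if b1[v] * b2[v] > 0 else "discordant") for v in shared
    }
    return TruthRecord(causal_trait1=c1, causal_trait2=c2, shared_ids=shared,
                       direction=direction)


def simulate_two_trait_scenario(config: ScenarioConfig,
                                panel: LDPanel | None = None
                                ) -> tuple[Cohort, Cohort, TruthRecord, LDPanel]:
    """Simulate both traits' cohorts on one shared haplotype panel.

    The two cohorts share LD structure (same panel) but contain
    independently drawn individuals.  The returned :class:`TruthRecord`
    states which variants are causal for which trait and whether shared
    variants act concordantly or discordantly.
    """
    if panel is None:
        panel = simulate_haplotype_panel(config)
    cohort1 = simulate_case_control(
        panel, config.causal_spec_trait1, config.baseline_prevalence[0],
        config.n_cases[0], config.n_controls[0], seed=[config.seed, 2],
    )
    cohort2 = simulate_case_control(
        panel, config.causal_spec_trait2, config.baseline_prevalence[1],
        config.n_cases[1], config.n_controls[1], seed=[config.seed, 3],
    )
    truth = _truth_from_config(config, panel.variants)
    return cohort1, cohort2, truth, panel


# ---------------------------------------------------------------------------
# on-disk formats: VCF genotypes + one-column phenotype file

def write_cohort_vcf(cohort: Cohort, vcf_path: str, phenotype_path: str | None = None) -> None:
    """Write a cohort as an uncompressed VCF (GT only) + phenotype text file."""
    n = len(cohort.phenotype)
    samples = [f"S{i:06d}" for i in range(n)]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in cohort.variants.iterrows():
            calls = "\t".join(gt_strings[int(d)] for d in cohort.genotypes[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n")
    if phenotype_path is not None:
        np.savetxt(phenotype_path, cohort.phenotype, fmt="%d")


def read_cohort_vcf(vcf_path: str, phenotype_path: str) -> Cohort:
    """Load a cohort written by :func:`write_cohort_vcf` (or equivalent)."""
    from .ld_reference import read_vcf_panel

    panel = read_vcf_panel(vcf_path)
    phenotype = np.loadtxt(phenotype_path, dtype=np.int8).reshape(-1)
    if len(phenotype) != panel.n_samples:
        raise ValueError("phenotype length does not match VCF sample count")
    return Cohort(genotypes=panel.matrix, phenotype=phenotype, variants=panel.variants)
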