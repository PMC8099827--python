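"""Dissection of regions into conditionally independent association signals.

Two modes are provided, mirroring how such analyses run in practice:

* individual-level: forward stepwise logistic regression inside a region
  (add the variant with the smallest conditional Wald p while it beats the
  entry threshold), plus full conditional scans given any conditioning set;
* summary-level: COJO-style conditioning of marginal summary statistics on a
  set of index variants using an LD reference — for the trait whose
  individual-level data are unavailable.

A :class:`Signal` bundles an index variant, its conditioning set (the index
variants of the signals ranked above it) and the conditional summary
statistics of the whole region given that set; signal pairs across traits
are what the co-localisation stage consumes.

The summary-level conditional estimates use the standard multivariate-normal
approximation for z-scores, ``z_C ~ N(R_tC R_CC^-1 z_C, Schur)``: the
conditional z of variant j is ``(z_j - R_jC R_CC^-1 z_C) / sqrt(s_j)`` with
``s_j = 1 - R_jC R_CC^-1 R_jC`` its Schur complement, the conditional SE is
``se_j / sqrt(s_j)``, and the conditional log-OR is their product — the same
convention an individual-level joint fit reports, so the two modes agree on
synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc_stats import SUMSTAT_COLUMNS, fit_logistic_irls, score_variants, wald_p
from .region_select import Region, region_variant_mask
from .synthetic_data import Cohort

logger = logging.getLogger(__name__)

#: Default stepwise entry threshold on the conditional Wald p-value.  A
#: conventional locus-wide bound; surfaced in config and logs.
DEFAULT_P_ENTER = 1e-5

#: Candidates whose dosage correlates with the span of the current model at
#: |r| above this are skipped (logistic fits are unstable beyond it).
COLLINEARITY_R = 0.99

#: Ridge added to a singular conditioning LD block in summary mode.
COJO_RIDGE = 1e-6

#: Records whose alt frequency differs from the LD panel's by more than this
#: are dropped in summary mode.
FREQ_MISMATCH_MAX = 0.2

MAX_SIGNALS_PER_REGION = 10


@dataclass
class Signal:
    """One conditionally independent association in one trait and region."""

    trait: str
    region: Region
    index_variant: str
    conditioning_set: list[str] = field(default_factory=list)
    conditional_records: pd.DataFrame | None = None
    rank: int = 1

    def __post_init__(self) -> None:
        if self.index_variant in self.conditioning_set:
            raise ValueError("index variant cannot be in its own conditioning set")

    @property
    def label(self) -> str:
        return f"{self.trait}:{self.region.name}:rank{self.rank}"


def _subcohort(cohort: Cohort, region: Region) -> tuple[Cohort, np.ndarray]:
    mask = region_variant_mask(region, cohort.variants.rename(
        columns={"id": "SNP", "chrom": "CHR", "pos": "BP"}))
    if not mask.any():
        raise ValueError(f"no cohort variants inside region {region.name}")
    sub = Cohort(genotypes=cohort.genotypes[:, mask], phenotype=cohort.phenotype,
                 variants=cohort.variants.loc[mask].reset_index(drop=True))
    return sub, mask


def _multiple_r(g: np.ndarray, G_c: np.ndarray) -> float:
    """|multiple correlation| of one dosage column with the span of others."""
    if G_c.shape[1] == 0:
        return 0.0
    X = np.column_stack([np.ones(len(g)), G_c])
    coef, *_ = np.linalg.lstsq(X, g, rcond=None)
    fitted = X @ coef
    denom = g.std()
    if denom == 0:
        return 1.0
    resid_var = np.var(g - fitted)
    r2 = max(0.0, 1.0 - resid_var / g.var())
    return float(np.sqrt(min(r2, 1.0)))


def _aggregate_patterns(columns: list[np.ndarray], y: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse (dosage..., phenotype) rows to unique patterns with counts."""
    k = len(columns)
    n_codes = 2 * 3**k
    if n_codes <= 2_000_000:
        code = y.astype(np.int64).copy()
        mult = 2
        for col in columns:
            code += mult * col.astype(np.int64)
            mult *= 3
        counts = np.bincount(code, minlength=n_codes)
        nz = np.flatnonzero(counts)
        w = counts[nz].astype(float)
        yy = (nz % 2).astype(float)
        rest = nz // 2
        X = np.empty((len(nz), k))
        for i in range(k):
            X[:, i] = rest % 3
            rest = rest // 3
        return X, yy, w
    stacked = np.column_stack(columns + [y])
    uniq, counts = np.unique(stacked, axis=0, return_counts=True)
    return uniq[:, :-1].astype(float), uniq[:, -1].astype(float), counts.astype(float)


def conditional_scan(cohort: Cohort, region: Region, condition_on=()) -> pd.DataFrame:
    """Region-wide association scan conditional on a set of index variants.

    For every region variant j not in the conditioning set, fits a logistic
    regression of phenotype on dosage_j plus the conditioning dosages and
    reports the j term's beta, SE and Wald p.  With an empty conditioning
    set this reduces exactly to the marginal scan.  Candidates collinear
    with the conditioning span (|r| > 0.99) are flagged and skipped, as are
    monomorphic and separated fits.
    """
    condition_on = list(condition_on)
    sub, _ = _subcohort(cohort, region)
    if not condition_on:
        return score_variants(sub)

    all_ids = cohort.variants["id"].tolist()
    pos = {v: i for i, v in enumerate(all_ids)}
    missing = [v for v in condition_on if v not in pos]
    if missing:
        raise KeyError(f"conditioning variants not in cohort: {missing}")
    G_c = cohort.genotypes[:, [pos[v] for v in condition_on]]
    y = cohort.phenotype

    records = score_variants(sub)  # template: ids, positions, freqs, flags
    beta = np.full(len(records), np.nan)
    se = np.full(len(records), np.nan)
    flag = records["FLAG"].to_numpy().copy()
    c_cols = [G_c[:, i] for i in range(G_c.shape[1])]
    gf = G_c.astype(float)

    for j, vid in enumerate(records["SNP"]):
        if vid in condition_on:
            flag[j] = "conditioned"
            continue
        if flag[j] != ".":
            continue
        g = cohort.genotypes[:, pos[vid]]
        if _multiple_r(g.astype(float), gf) > COLLINEARITY_R:
            flag[j] = "collinear"
            logger.info("conditional_scan: %s collinear with conditioning set %s",
                        vid, condition_on)
            continue
        X, yy, w = _aggregate_patterns([g] + c_cols, y)
        design = np.column_stack([np.ones(len(yy)), X])
        coef, cov, ok = fit_logistic_irls(design, yy, w)
        if not ok:
            flag[j] = "separation"
            continue
        beta[j] = coef[1]
        se[j] = np.sqrt(cov[1, 1])

    out = records.copy()
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = np.where(np.isfinite(beta), wald_p(beta, se), np.nan)
    out["FLAG"] = flag
    keep = out["FLAG"] != "conditioned"
    return out.loc[keep].reset_index(drop=True)


def forward_stepwise(cohort: Cohort, region: Region,
                     p_enter: float = DEFAULT_P_ENTER) -> list[str]:
    """Forward stepwise logistic selection of index variants in a region.

    Iteratively adds the variant with the smallest conditional Wald p among
    those not yet in the model while that p is below ``p_enter``; returns
    the ordered selected ids (possibly empty).
    """
    selected: list[str] = []
    if p_enter <= 0:
        return selected
    while len(selected) < MAX_SIGNALS_PER_REGION:
        scan = conditional_scan(cohort, region, selected)
        clean = scan[scan["FLAG"] == "."]
        if clean.empty or not clean["P"].notna().any():
            break
        best = clean.loc[clean["P"].idxmin()]
        if not best["P"] < p_enter:
            break
        selected.append(best["SNP"])
        logger.info("forward_stepwise %s: + %s (conditional p=%.3g)",
                    region.name, best["SNP"], best["P"])
    return selected


def enumerate_signals(cohort: Cohort, region: Region, trait: str,
                      p_enter: float = DEFAULT_P_ENTER) -> list[Signal]:
    """Stepwise-dissect a region into ranked signals with conditional records.

    The rank-r signal's conditioning set is the index variants of ranks
    1..r-1, and its conditional records are the region scan given that set
    (for rank 1 this is the marginal scan), so each signal carries the
    summary statistics under which it is the top association.
    """
    selected = forward_stepwise(cohort, region, p_enter)
    signals = []
    for r, vid in enumerate(selected, start=1):
        conditioning = selected[: r - 1]
        records = conditional_scan(cohort, region, conditioning)
        signals.append(Signal(trait=trait, region=region, index_variant=vid,
                              conditioning_set=conditioning,
                              conditional_records=records, rank=r))
    return signals


# ---------------------------------------------------------------------------
# summary-statistic (COJO-style) mode

def cojo_conditional(records: pd.DataFrame, ld: np.ndarray, ld_ids,
                     condition_on, panel_freq=None) -> pd.DataFrame:
    """Conditional summary statistics from marginal ones plus LD.

    ``records`` must be harmonized to the LD panel's allele frame and row-
    aligned by SNP id with ``ld_ids`` (any order; matching is by id).  With
    an empty conditioning set the input is returned unchanged.  A singular
    conditioning block is ridge-regularised (logged); variants whose alt
    frequency disagrees with the panel's by more than 0.2 are dropped.
    """
    condition_on = list(condition_on)
    out = records.copy().reset_index(drop=True)
    if not condition_on:
        return out

    ld_index = {v: i for i, v in enumerate(ld_ids)}
    missing = [v for v in out["SNP"] if v not in ld_index]
    if missing:
        raise KeyError(f"records not present in LD panel: {missing[:5]}")
    missing_c = [v for v in condition_on if v not in ld_index]
    if missing_c:
        raise KeyError(f"conditioning variants not in LD panel: {missing_c}")

    if panel_freq is not None:
        pf = np.asarray([panel_freq[ld_index[v]] for v in out["SNP"]])
        mismatch = np.abs(out["ALT_FRQ"].to_numpy() - pf) > FREQ_MISMATCH_MAX
        if mismatch.any():
            logger.warning("cojo_conditional: dropping %d variant(s) with panel "
                           "frequency mismatch > %.2f", int(mismatch.sum()),
                           FREQ_MISMATCH_MAX)
            out = out.loc[~mismatch].reset_index(drop=True)

    c_idx = np.array([ld_index[v] for v in condition_on])
    r_cc = ld[np.ix_(c_idx, c_idx)]
    try:
        k_cc = np.linalg.inv(r_cc)
        if np.linalg.cond(r_cc) > 1e8:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.warning("cojo_conditional: conditioning LD block near-singular; "
                       "applying ridge epsilon %g", COJO_RIDGE)
        k_cc = np.linalg.inv(r_cc + COJO_RIDGE * np.eye(len(c_idx)))

    cond_set = set(condition_on)
    z = out["BETA"].to_numpy() / out["SE"].to_numpy()
    z_c = np.array([records.set_index("SNP")["BETA"][v]
                    / records.set_index("SNP")["SE"][v] for v in condition_on])

    beta = np.full(len(out), np.nan)
    se = np.full(len(out), np.nan)
    flag = out.get("FLAG", pd.Series(["."] * len(out))).to_numpy().copy()
    kz = k_cc @ z_c
    for j, vid in enumerate(out["SNP"]):
        if vid in cond_set:
            flag[j] = "conditioned"
            continue
        if not np.isfinite(z[j]):
            continue
        r_jc = ld[ld_index[vid], c_idx]
        s_j = 1.0 - float(r_jc @ k_cc @ r_jc)
        if s_j < 1.0 - COLLINEARITY_R**2:
            flag[j] = "collinear"
            continue
        z_cond = (z[j] - float(r_jc @ kz)) / np.sqrt(s_j)
        se[j] = out["SE"].iloc[j] / np.sqrt(s_j)
        beta[j] = z_cond * se[j]

    out["BETA"] = beta
    out["SE"] = se
    out["P"] = np.where(np.isfinite(beta), wald_p(beta, se), np.nan)
    out["FLAG"] = flag
    return out.loc[out["FLAG"] != "conditioned"].reset_index(drop=True)


def write_signal_records(signals: list[Signal], path: str) -> None:
    """Conditional summary TSV with SIGNAL_RANK and CONDITIONED_ON columns.

    CONDITIONED_ON is comma-joined ids, '-' for an unconditioned signal.
    """
    frames = []
    for s in signals:
        df = s.conditional_records.copy()
        df["SIGNAL_RANK"] = s.rank
        df["CONDITIONED_ON"] = ",".join(s.conditioning_set) if s.conditioning_set else "-"
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    cols = SUMSTAT_COLUMNS + ["SIGNAL_RANK", "CONDITIONED_ON"]
    combined.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep=".")
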