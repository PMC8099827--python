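"""Linkage-disequilibrium reference panels.

An :class:`LDPanel` holds a haplotype (0/1) or genotype-dosage (0/1/2) matrix
together with per-variant metadata, and provides allelic correlation (r) and
squared-correlation (r²) matrices for any subset of its variants.  Panels are
either simulated (:mod:`colocpipe.synthetic_data`) or ingested from a VCF of
reference genotypes.

When haplotypes are available r is the haplotypic allelic correlation; on
genotype dosages it is the composite (Burrows-style) correlation computed
directly on dosages.  Both are invariant to allele relabeling (x -> 2 - x or
1 - x), which flips the sign of r and leaves r² unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns every variant-metadata frame carries, in order.
VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "alt_freq"]

#: Eigenvalue floor applied when a correlation matrix must be positive
#: semi-definite (fine-mapping, summary-level conditioning).
EIGENVALUE_FLOOR = 1e-8


@dataclass
class LDPanel:
    """Reference panel of haplotypes or genotype dosages.

    Parameters
    ----------
    matrix
        ``(n_samples, n_variants)`` array; entries in {0, 1} for haplotypes
        or {0, 1, 2} for genotype dosages.
    variants
        Metadata frame with columns :data:`VARIANT_COLUMNS`.
    is_haplotypes
        True when rows are phased haplotypes rather than diploid genotypes.
    population
        Free-text label of the population the panel represents.
    """

    matrix: np.ndarray
    variants: pd.DataFrame
    is_haplotypes: bool = True
    population: str = "synthetic"
    #: latent AR(1) copula parameters when the panel was simulated
    copula: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("panel matrix must be 2-D (samples x variants)")
        if len(self.variants) != self.matrix.shape[1]:
            raise ValueError(
                f"metadata length {len(self.variants)} does not match "
                f"{self.matrix.shape[1]} matrix columns"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata missing columns: {missing}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def column_index(self, variant_ids) -> np.ndarray:
        """Positions of ``variant_ids`` in the panel (error on absence)."""
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not in panel") from None

    def dosages(self) -> np.ndarray:
        """Diploid dosage matrix; pairs consecutive haplotypes if phased."""
        if not self.is_haplotypes:
            return self.matrix
        if self.n_samples % 2:
            raise ValueError("odd haplotype count cannot be paired")
        return self.matrix[0::2] + self.matrix[1::2]


def _polymorphic_mask(sub: np.ndarray) -> np.ndarray:
    return sub.std(axis=0) > 0


def correlation_matrix(panel: LDPanel, variant_ids=None) -> tuple[np.ndarray, list[str]]:
    """Signed allelic correlation matrix for the requested variants.

    Monomorphic variants are excluded (logged); returns the matrix and the
    ids actually used, in request order.
    """
    if variant_ids is None:
        variant_ids = panel.variant_ids
    idx = panel.column_index(variant_ids)
    sub = panel.matrix[:, idx].astype(float)
    keep = _polymorphic_mask(sub)
    if not keep.all():
        dropped = [variant_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("excluding %d monomorphic variant(s): %s", len(dropped), dropped)
    kept_ids = [v for v, k in zip(variant_ids, keep) if k]
    sub = sub[:, keep]
    if sub.shape[1] == 0:
        return np.empty((0, 0)), []
    r = np.corrcoef(sub, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0), kept_ids


def r2_matrix(panel: LDPanel, variant_ids=None) -> tuple[np.ndarray, list[str]]:
    """Symmetric matrix of squared allelic correlations in [0, 1]."""
    r, kept = correlation_matrix(panel, variant_ids)
    return r**2, kept


def index_ld(panel: LDPanel, id_a: str, id_b: str) -> float:
    """r² between two variants of the panel (1.0 when identical)."""
    if id_a == id_b:
        panel.column_index([id_a])  # existence check
        return 1.0
    r2, kept = r2_matrix(panel, [id_a, id_b])
    if len(kept) < 2:
        raise ValueError(f"monomorphic variant in pair ({id_a}, {id_b})")
    return float(r2[0, 1])


def nearest_psd(r: np.ndarray, floor: float = EIGENVALUE_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to PSD by flooring its eigenvalues."""
    r = (r + r.T) / 2.0
    w, v = np.linalg.eigh(r)
    if w.min() >= floor:
        return r
    w = np.maximum(w, floor)
    out = (v * w) @ v.T
    return (out + out.T) / 2.0


def read_vcf_panel(path: str, population: str = "unknown") -> LDPanel:
    """Load a genotype LD panel from a VCF.

    Restricted to biallelic SNVs with a GT field; other records are skipped
    and counted in the log.  Missing genotypes are not supported (panels are
    reference data).
    """
    from cyvcf2 import VCF

    rows, meta = [], []
    skipped = 0
    vcf = VCF(path)
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        g = rec.genotype.array()
        if g is None:
            skipped += 1
            continue
        dos = g[:, 0] + g[:, 1]
        if (g[:, :2] < 0).any():
            skipped += 1
            continue
        rows.append(dos.astype(np.int8))
        meta.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "alt_freq": float(dos.mean() / 2.0),
            }
        )
    if skipped:
        logger.info("read_vcf_panel: skipped %d non-biallelic-SNV/incomplete records", skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNVs in {path}")
    matrix = np.stack(rows, axis=1)
    return LDPanel(matrix=matrix, variants=pd.DataFrame(meta), is_haplotypes=False,
                   population=population)


def write_ld_matrix(path: str, r: np.ndarray, variant_ids) -> None:
    """Write an LD matrix as whitespace-delimited text plus a ``.ids`` sidecar."""
    np.savetxt(path, r, fmt="%.8g")
    with open(str(path) + ".ids", "w") as fh:
        fh.write("\n".join(variant_ids) + "\n")


def read_ld_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    r = np.atleast_2d(np.loadtxt(path))
    with open(str(path) + ".ids") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if len(ids) != r.shape[0]:
        raise ValueError("LD matrix dimension does not match id sidecar")
    return r, ids
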