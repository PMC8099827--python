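"""Selection of genomic regions associated with both traits.

Variants significant at FDR < threshold in *both* traits seed analysis
windows of approximately 0.5 Mb.  Windowing is greedy: the overlap variant
with the smallest max(q1, q2) anchors a window of seed position +/- half the
window size, absorbing every overlap variant inside it; the procedure
repeats on the remainder and finally merges windows that overlap or abut,
keeping the better (smaller max-q) seed.  Coordinates are 1-based inclusive
internally; BED output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW_BP = 500_000
DEFAULT_FDR = 0.01


@dataclass
class Region:
    """A merged analysis window anchored at its most significant variant."""

    chrom: str
    start: int                      # 1-based inclusive
    end: int                        # 1-based inclusive
    seed_variant: str
    member_variants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region bounds [{self.start}, {self.end}]")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def find_overlap_variants(records1: pd.DataFrame, records2: pd.DataFrame,
                          threshold: float = DEFAULT_FDR) -> pd.DataFrame:
    """Variants with q strictly below ``threshold`` in BOTH traits.

    Inputs are harmonized, Q-annotated record frames (aligned or not);
    matching is on SNP id.  Returns a frame with SNP, CHR, BP, Q1, Q2 and
    QMAX, sorted by chromosome then position; empty frames are allowed.
    """
    cols = ["SNP", "CHR", "BP", "Q"]
    a = records1.loc[records1["Q"].notna(), cols]
    b = records2.loc[records2["Q"].notna(), ["SNP", "Q"]]
    merged = a.merge(b, on="SNP", suffixes=("1", "2"))
    hits = merged[(merged["Q1"] < threshold) & (merged["Q2"] < threshold)].copy()
    hits["QMAX"] = hits[["Q1", "Q2"]].max(axis=1)
    return hits.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)


def build_regions(overlap: pd.DataFrame, window_bp: int = DEFAULT_WINDOW_BP) -> list[Region]:
    """Greedy windowing + merge of overlap variants into regions.

    Every overlap variant ends up in exactly one region; the result is
    independent of input order (sorting by position is canonical, seeds by
    joint significance).  Windows are clipped at position 1.
    """
    regions: list[Region] = []
    half = window_bp // 2
    for chrom, chunk in overlap.groupby("CHR", sort=True):
        chunk = chunk.sort_values("BP", kind="mergesort")
        pending = chunk.copy()
        windows = []  # (start, end, seed_id, seed_qmax, member ids)
        while len(pending):
            seed = pending.loc[pending["QMAX"].idxmin()]
            start = max(1, int(seed["BP"]) - half + 1)  # width exactly window_bp
            end = int(seed["BP"]) + half
            inside = pending["BP"].between(start, end)
            members = pending.loc[inside, "SNP"].tolist()
            windows.append([start, end, seed["SNP"], float(seed["QMAX"]), members])
            pending = pending.loc[~inside]
        windows.sort(key=lambda w: w[0])
        merged = []
        for w in windows:
            if merged and w[0] <= merged[-1][1] + 1:  # overlap or abut
                last = merged[-1]
                last[1] = max(last[1], w[1])
                last[4].extend(w[4])
                if w[3] < last[3]:
                    last[2], last[3] = w[2], w[3]
            else:
                merged.append(w)
        for start, end, seed_id, _, members in merged:
            pos_of = dict(zip(chunk["SNP"], chunk["BP"]))
            members = sorted(set(members), key=lambda v: pos_of[v])
            regions.append(Region(chrom=str(chrom), start=start, end=end,
                                  seed_variant=seed_id, member_variants=members))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def region_variant_mask(region: Region, records: pd.DataFrame) -> np.ndarray:
    """Boolean mask of the records lying inside a region."""
    return ((records["CHR"].astype(str) == region.chrom)
            & records["BP"].between(region.start, region.end)).to_numpy()


def write_bed(regions: list[Region], path: str) -> None:
    """Write regions as BED: 0-based half-open, so start-1 and end."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.seed_variant}\n")


def read_bed(path: str) -> list[Region]:
    """Read regions from BED, converting back to 1-based inclusive."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            seed = parts[3] if len(parts) > 3 else f"{chrom}:{start0 + 1}"
            regions.append(Region(chrom=chrom, start=start0 + 1, end=end, seed_variant=seed))
    return regions
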