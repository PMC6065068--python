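"""Chromosomal landscape of introgression: prevalence, relative position,
chromosome morphology, and position correlations.

Introgression prevalence at a SNP is the number of introgression tracts
(across all individuals) overlapping it.  Relative chromosomal position is
measured either to the chromosome centre (|pos - L/2| / (L/2)) or to the
centromere (distance / containing-arm length).  Chromosomes are classed by
the Levan arm-ratio thresholds.  Correlations between prevalence (or a
recombination-rate track) and relative position use Spearman's rank test on
SNPs greedily subsampled to >= 50 kb spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ChromosomeDef:
    """One chromosome: length, centromere position and morphology class."""

    name: str
    length: int
    centromere: int
    excluded: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.centromere <= self.length):
            raise ValueError("centromere outside chromosome")

    @property
    def arm_short(self) -> int:
        return min(self.centromere, self.length - self.centromere)

    @property
    def arm_long(self) -> int:
        return max(self.centromere, self.length - self.centromere)

    @property
    def morphology(self) -> str:
        return classify_chromosome(self.arm_long, self.arm_short)


def classify_chromosome(arm_long: float, arm_short: float) -> str:
    """Levan morphology class from the long/short arm ratio.

    [1, 1.7) metacentric, [1.7, 3) submetacentric, [3, 7) subtelocentric,
    >= 7 acrocentric; a zero-length short arm is telocentric.
    """
    if arm_short < 0 or arm_long < arm_short:
        raise ValueError("need arm_long >= arm_short >= 0")
    if arm_short == 0:
        return "telocentric"
    ratio = arm_long / arm_short
    if ratio < 1.7:
        return "metacentric"
    if ratio < 3:
        return "submetacentric"
    if ratio < 7:
        return "subtelocentric"
    return "acrocentric"


def prevalence_per_snp(tract_starts, tract_ends, snp_positions) -> np.ndarray:
    """Tracts (any individual) overlapping each SNP, by interval stabbing.

    Tracts are half-open [start, end); a SNP at position p is overlapped by
    tracts with start <= p < end.  Counts = #(start <= p) - #(end <= p).
    """
    starts = np.sort(np.asarray(tract_starts, dtype=np.int64))
    ends = np.sort(np.asarray(tract_ends, dtype=np.int64))
    if len(starts) != len(ends):
        raise ValueError("starts and ends differ in length")
    pos = np.asarray(snp_positions, dtype=np.int64)
    return (np.searchsorted(starts, pos, side="right")
            - np.searchsorted(ends, pos, side="right"))


def relative_position(pos, chrom: ChromosomeDef, reference: str = "center"):
    """Relative distance of a position to the chromosome centre or centromere.

    centre: |pos - L/2| / (L/2) in [0, 1]; centromere: |pos - c| / length of
    the arm containing the position.  A position on a zero-length arm
    (telocentric short arm) is undefined and returns NaN.
    """
    pos = np.asarray(pos, dtype=float)
    L = chrom.length
    if np.any((pos < 0) | (pos > L)):
        raise ValueError("position outside chromosome")
    if reference == "center":
        return np.abs(pos - L / 2) / (L / 2)
    if reference == "centromere":
        c = chrom.centromere
        arm = np.where(pos < c, c, L - c).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(arm > 0, np.abs(pos - c) / arm, np.nan)
        return out
    raise ValueError("reference must be 'center' or 'centromere'")


def subsample_positions(positions: np.ndarray, min_spacing: int = 50_000) -> np.ndarray:
    """Greedy left-to-right subsampling at >= ``min_spacing`` bp (deterministic)."""
    positions = np.sort(np.asarray(positions, dtype=np.int64))
    keep = []
    last = -np.inf
    for p in positions:
        if p - last >= min_spacing:
            keep.append(p)
            last = p
    return np.array(keep, dtype=np.int64)


def position_correlation(table: pd.DataFrame, value: str, chroms: dict,
                         reference: str = "center", subsample_bp: int = 50_000,
                         binned: bool = False, bin_width: float | None = None):
    """Spearman correlation of a per-SNP value with relative chromosome position.

    ``table`` needs columns ``chrom``, ``pos`` and ``value``; ``chroms`` maps
    chromosome name to :class:`ChromosomeDef` (entries flagged ``excluded``
    are dropped).  SNPs are greedily subsampled to >= ``subsample_bp``
    spacing per chromosome.  With ``binned=True`` (the centromere-style
    analysis) SNPs are grouped into relative-distance bins of ``bin_width``
    — which must then be given explicitly — and the value re-computed as the
    within-bin sum before correlating.
    """
    if table.empty:
        raise ValueError("empty table")
    rel_all, val_all = [], []
    for name, sub in table.groupby("chrom"):
        cd = chroms.get(name)
        if cd is None or cd.excluded:
            continue
        sub = sub.sort_values("pos")
        keep_pos = subsample_positions(sub["pos"].to_numpy(), subsample_bp)
        sub = sub[sub["pos"].isin(keep_pos)]
        rel = relative_position(sub["pos"].to_numpy(), cd, reference)
        ok = ~np.isnan(rel)
        rel_all.append(rel[ok])
        val_all.append(sub[value].to_numpy()[ok])
    if not rel_all:
        raise ValueError("no usable chromosomes")
    rel = np.concatenate(rel_all)
    val = np.concatenate(val_all)
    if binned:
        if bin_width is None:
            raise ValueError("binned analysis requires an explicit bin_width")
        idx = np.floor(rel / bin_width).astype(int)
        df = pd.DataFrame({"bin": idx, "val": val}).groupby("bin")["val"].sum()
        rel = df.index.to_numpy() * bin_width + bin_width / 2
        val = df.to_numpy()
    if len(rel) < 3:
        raise ValueError("fewer than 3 retained points")
    rho, p = sps.spearmanr(rel, val)
    return float(rho), float(p)
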