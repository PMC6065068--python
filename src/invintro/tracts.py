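"""Ancestry tracts: dosage-to-tract conversion, admixture dating, IBS tracts.

Introgression tract lengths decay with time since admixture through
recombination: under a single-pulse model the lengths are exponential with
mean ``1/(r*t)`` (``r`` recombination rate per bp per generation, ``t``
generations since admixture), so the admixture age is estimated as
``t = 1/(r*L)`` from the observed mean tract length ``L``.

Identity-by-state (IBS) tracts — runs of sequence identity between two
haplotypes delimited by mismatching sites — carry the same kind of timing
information at deeper scales; here they are extracted and binned on a
geometric ``(3/2)^n`` grid (the input of downstream demographic fitting,
which is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Tract:
    """Half-open genomic interval of donor ancestry on one haplotype/individual."""

    chrom: str
    start: int
    end: int
    hap: int | str | None = None
    state: str = "DONOR"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("tract start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def dosage_to_tracts(positions, dosages, het_range=(0.8, 1.8), hom_min=1.8,
                     chrom: str = "chr1", individual=None) -> list[Tract]:
    """Convert per-site donor-ancestry dosages into tracts.

    A site is introgressed when its dosage (expected donor allele count, in
    [0, 2]) is at least ``het_range[0]``: heterozygous within
    ``[het_range[0], het_range[1]]``, homozygous above ``hom_min``.  Maximal
    runs of introgressed sites become tracts spanning first to last
    introgressed site (half-open end = last site + 1).  A run is labelled
    ``hom`` only if every site in it is homozygous, otherwise ``het``.
    """
    positions = np.asarray(positions, dtype=np.int64)
    dosages = np.asarray(dosages, dtype=float)
    if len(positions) != len(dosages):
        raise ValueError("positions and dosages differ in length")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    intro = dosages >= het_range[0]
    hom = dosages > hom_min
    tracts = []
    i = 0
    n = len(positions)
    while i < n:
        if not intro[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and intro[j + 1]:
            j += 1
        state = "hom" if np.all(hom[i:j + 1]) else "het"
        tracts.append(Tract(chrom=chrom, start=int(positions[i]),
                            end=int(positions[j]) + 1, hap=individual, state=state))
        i = j + 1
    return tracts


@dataclass
class DatingResult:
    """Admixture age from the exponential tract-length model ``t = 1/(r*L)``."""

    t_generations: float
    t_years: float
    mean_tract_length: float
    r: float
    generation_years: float


def date_admixture_exponential(L: float, r: float = 1.0e-8,
                               generation_years: float = 2.0) -> DatingResult:
    """Date an admixture pulse from the mean introgression tract length.

    ``L`` is the arithmetic mean tract length in bp pooled across all
    individuals' tracts; ``r`` the per-bp per-generation recombination rate.
    """
    if L <= 0:
        raise ValueError("mean tract length must be positive")
    if r <= 0:
        raise ValueError("recombination rate must be positive")
    t = 1.0 / (r * L)
    return DatingResult(t_generations=t, t_years=t * generation_years,
                        mean_tract_length=L, r=r, generation_years=generation_years)


@dataclass
class IBSTracts:
    """Interior and terminal IBS tract lengths between one haplotype pair.

    Interior tracts are delimited by two mismatching sites (length = distance
    between the flanking mismatches minus 1); terminal runs touch a sequence
    end and are censored, so they are reported separately and excluded from
    binning by default.
    """

    interior: np.ndarray
    terminal: np.ndarray
    n_mismatches: int
    n_discarded: int = 0


def ibs_tracts(hap_a, hap_b, exclusion_mask=None) -> IBSTracts:
    """Extract IBS tracts between two aligned haplotypes.

    ``exclusion_mask`` is a boolean per-position array marking low-confidence
    regions (assembly gaps, sparse-SNP regions); any tract whose span
    intersects a masked position is discarded.  Positions where either
    sequence is 'N' are treated as masked.
    """
    a = _as_byte_array(hap_a)
    b = _as_byte_array(hap_b)
    if len(a) != len(b):
        raise ValueError("haplotypes differ in length")
    L = len(a)
    mask = np.zeros(L, dtype=bool) if exclusion_mask is None \
        else np.asarray(exclusion_mask, dtype=bool)
    if len(mask) != L:
        raise ValueError("exclusion mask length mismatch")
    nn = (a == ord("N")) | (b == ord("N"))
    mask = mask | nn

    mism = np.nonzero((a != b) & ~mask)[0]
    interior, discarded = [], 0
    # cumulative masked positions for O(1) intersection queries
    cmask = np.concatenate([[0], np.cumsum(mask)])

    def masked_in(lo, hi):  # [lo, hi)
        return cmask[hi] - cmask[lo] > 0

    for k in range(len(mism) - 1):
        lo, hi = mism[k] + 1, mism[k + 1]       # candidate tract span [lo, hi)
        if hi <= lo:
            continue                            # adjacent mismatches: no run
        if masked_in(lo, hi):
            discarded += 1
            continue
        interior.append(hi - lo)

    terminal = []
    if len(mism) == 0:
        if not masked_in(0, L):
            terminal.append(L)
    else:
        if mism[0] > 0 and not masked_in(0, mism[0]):
            terminal.append(mism[0])
        if mism[-1] < L - 1 and not masked_in(mism[-1] + 1, L):
            terminal.append(L - 1 - mism[-1])
    return IBSTracts(interior=np.array(interior, dtype=np.int64),
                     terminal=np.array(terminal, dtype=np.int64),
                     n_mismatches=len(mism), n_discarded=discarded)


def _as_byte_array(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8) if seq.dtype != np.uint8 else seq
    return np.frombuffer(str(seq).upper().encode(), dtype=np.uint8)


@dataclass
class IBSBinning:
    """Tract counts on the geometric grid [(3/2)^n, (3/2)^(n+1))."""

    bin_n: np.ndarray          # bin indices n
    low: np.ndarray            # (3/2)^n
    high: np.ndarray           # (3/2)^(n+1)
    counts: np.ndarray
    min_len: float
    max_len: float | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"bin_n": self.bin_n, "low": self.low,
                             "high": self.high, "count": self.counts})


def bin_ibs(lengths, min_len: float = 300, max_len: float | None = None) -> IBSBinning:
    """Bin IBS tract lengths by powers of 3/2 after a minimum-length filter.

    The two filter variants of interest are ``min_len=300`` and
    ``min_len=10_000`` (longer tracts being the more informative about recent
    gene flow); they are never combined implicitly.  Bin of a length L is
    ``n = floor(log(L)/log(1.5))``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    kept = lengths[lengths >= min_len]
    if max_len is not None:
        kept = kept[kept < max_len]
    lo_n = int(np.floor(np.log(max(min_len, 1.0)) / np.log(1.5)))
    if len(kept) == 0:
        bins = np.arange(lo_n, lo_n + 1)
        return IBSBinning(bin_n=bins, low=1.5 ** bins, high=1.5 ** (bins + 1),
                          counts=np.zeros(len(bins), dtype=np.int64),
                          min_len=min_len, max_len=max_len)
    n = np.floor(np.log(kept) / np.log(1.5)).astype(np.int64)
    hi_n = int(n.max())
    bins = np.arange(lo_n, hi_n + 1)
    counts = np.bincount(n - lo_n, minlength=len(bins))
    return IBSBinning(bin_n=bins, low=1.5 ** bins, high=1.5 ** (bins + 1),
                      counts=counts.astype(np.int64), min_len=min_len, max_len=max_len)


def tracts_to_dosage(tracts: list[Tract], positions) -> np.ndarray:
    """Inverse of :func:`dosage_to_tracts` on a site grid (for round-trips):
    2.0 inside hom tracts, 1.0 inside het/DONOR tracts, 0 elsewhere."""
    positions = np.asarray(positions, dtype=np.int64)
    dos = np.zeros(len(positions), dtype=float)
    for tr in tracts:
        inside = (positions >= tr.start) & (positions < tr.end)
        dos[inside] = 2.0 if tr.state == "hom" else 1.0
    return dos


def mean_tract_length(tracts: list[Tract]) -> float:
    """Arithmetic mean length pooled across all individuals' tracts."""
    if not tracts:
        raise ValueError("no tracts")
    return float(np.mean([t.length for t in tracts]))
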