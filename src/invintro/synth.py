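"""Synthetic three-species phased haplotypes with planted introgression.

Generates the kind of data the genome scan consumes without any external
download: a focal species (20 haplotypes = 10 diploids), a donor species and
an outgroup, related as ((focal, donor), outgroup), with sequence divergence
and within-species diversity calibrated to the hare system (focal-donor
uncorrected distance ~0.69%, donor more diverse than the focal invader,
pi ~0.0022 vs ~0.0014).  Introgression tracts are *planted*: donor-derived
sequence (donor consensus plus shallow noise mimicking a recent coalescence
inside the donor tree) replaces the orthologous interval on a chosen set of
focal haplotypes, so the truth is known exactly.

Sites are independent (no linkage beyond the planted tracts) — adequate for
testing window statistics, and stated openly as a simplification.  Haplotypes
0-9 belong to the five southern individuals, 10-19 to the five northern ones;
geographic tract patterns (northern-only, mtDNA-like, high-frequency outlier)
are defined with respect to that split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescent import AncestryMatrix, SampleMap
from .invasion import POPULATIONS
from .stats import SpectrumResult, frequency_spectrum
from .tracts import Tract

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PATTERNS = ("uniform", "northern-only", "mtdna-like", "outlier")


@dataclass
class TractPlan:
    """One planned introgressed window: interval, target frequency, geography."""

    chrom: str
    start: int
    end: int
    frequency: float
    pattern: str = "uniform"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("tract start must be < end")
        if not (0 < self.frequency <= 1):
            raise ValueError("frequency must lie in (0, 1]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class SynthPlan:
    """Targets and layout of one synthetic dataset."""

    n_focal: int = 20
    n_donor: int = 6
    n_outgroup: int = 2
    chromosomes: dict = field(default_factory=lambda: {"chr1": 500_000})
    centromeres: dict = field(default_factory=dict)
    d_focal_donor: float = 0.0069
    pi_focal: float = 0.0014
    pi_donor: float = 0.0022
    pi_outgroup: float = 0.0010
    donor_outgroup_factor: float = 2.0
    tract_plan: list = field(default_factory=list)
    n_null_markers: int = 0
    tract_noise: float | None = None   # per-site divergence of planted tracts
    seed: int = 0

    def branch_lengths(self):
        """Per-site mutation probabilities on the ((focal, donor), outgroup)
        tree solving the pairwise-distance targets under the star-shaped
        within-species model (each haplotype carries pi/2 private mutations)."""
        b_fd = self.d_focal_donor - self.pi_focal / 2 - self.pi_donor / 2
        if b_fd <= 0:
            raise ValueError("within-species diversity exceeds the divergence target")
        b_f = b_d = b_fd / 2
        d_do = self.donor_outgroup_factor * self.d_focal_donor
        b_o = d_do - b_d - self.pi_donor / 2 - self.pi_outgroup / 2
        if b_o <= 0:
            raise ValueError("donor-outgroup target below the donor branch")
        return b_f, b_d, b_o


@dataclass
class SynthData:
    """Realized haplotype matrices per chromosome plus the exact truth."""

    plan: SynthPlan
    focal: dict                 # chrom -> (n_focal, L) uint8
    donor: dict
    outgroup: dict
    truth: list                 # list[Tract] with hap indices
    realized: list              # list[(TractPlan, np.ndarray hap indices)]

    def truth_matrix(self) -> AncestryMatrix:
        """Window-level truth as an ancestry matrix (one marker per planned
        tract plus the plan's null markers)."""
        n = len(self.realized) + self.plan.n_null_markers
        origin = np.zeros((n, self.plan.n_focal), dtype=np.uint8)
        for m, (_, haps) in enumerate(self.realized):
            origin[m, haps] = 1
        return AncestryMatrix(origin=origin, samples=_synthetic_samples(self.plan))


def _synthetic_samples(plan: SynthPlan) -> SampleMap:
    n_ind = plan.n_focal // 2
    pops = list(POPULATIONS[:n_ind]) if n_ind <= len(POPULATIONS) \
        else [f"P{i}" for i in range(n_ind)]
    return SampleMap(populations=pops, demes=np.arange(n_ind),
                     distance_km=np.arange(n_ind) * 100.0, n_lineages=2)


def _mutate(rng, seq: np.ndarray, prob: float) -> np.ndarray:
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < prob)[0]
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit))
        idx = np.searchsorted(BASES, out[hit])
        out[hit] = BASES[(idx + shift) % 4]
    return out


def _choose_haplotypes(rng, plan: SynthPlan, tp: TractPlan) -> np.ndarray:
    n = plan.n_focal
    k = int(round(tp.frequency * n))
    if k < 1:
        raise ValueError(f"frequency {tp.frequency} rounds to zero haplotypes")
    south = np.arange(n // 2)
    north = np.arange(n // 2, n)
    if tp.pattern == "uniform":
        pool = np.arange(n)
    elif tp.pattern in ("northern-only", "mtdna-like"):
        pool = north
        if k > len(north):
            raise ValueError(
                f"{tp.pattern} tract at frequency {tp.frequency} needs {k} "
                f"haplotypes but only {len(north)} are northern")
        if tp.pattern == "mtdna-like" and k < 2:
            raise ValueError("mtdna-like pattern needs >= 2 introgressed haplotypes")
    elif tp.pattern == "outlier":
        pool = np.arange(n)
        if k / n <= 0.8:
            raise ValueError("outlier pattern requires frequency > 80%")
    else:  # pragma: no cover
        raise ValueError(tp.pattern)
    return np.sort(rng.choice(pool, size=k, replace=False))


def simulate_haplotypes(plan: SynthPlan) -> SynthData:
    """Generate the three species' haplotypes and plant the planned tracts.

    Same seed, same plan => byte-identical output.  Planted tract frequencies
    are realized exactly (haplotype counts are chosen, not sampled).
    """
    rng = np.random.default_rng(plan.seed)
    b_f, b_d, b_o = plan.branch_lengths()

    # reject overlapping planned tracts (they would stack on haplotypes)
    by_chrom: dict[str, list[TractPlan]] = {}
    for tp in plan.tract_plan:
        by_chrom.setdefault(tp.chrom, []).append(tp)
    for chrom, tps in by_chrom.items():
        tps_sorted = sorted(tps, key=lambda t: t.start)
        for a, b in zip(tps_sorted, tps_sorted[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping planned tracts on {chrom}")

    focal, donor, outgroup = {}, {}, {}
    truth, realized = [], []
    for chrom, L in plan.chromosomes.items():
        anc = BASES[rng.integers(0, 4, size=L)]
        cons_f = _mutate(rng, anc, b_f)
        cons_d = _mutate(rng, anc, b_d)
        cons_o = _mutate(rng, anc, b_o)
        focal[chrom] = np.stack([_mutate(rng, cons_f, plan.pi_focal / 2)
                                 for _ in range(plan.n_focal)])
        donor[chrom] = np.stack([_mutate(rng, cons_d, plan.pi_donor / 2)
                                 for _ in range(plan.n_donor)])
        outgroup[chrom] = np.stack([_mutate(rng, cons_o, plan.pi_outgroup / 2)
                                    for _ in range(plan.n_outgroup)])

        noise = plan.tract_noise if plan.tract_noise is not None else plan.pi_donor / 4
        for tp in by_chrom.get(chrom, []):
            if tp.end > L:
                raise ValueError(f"tract {tp} beyond chromosome {chrom}")
            haps = _choose_haplotypes(rng, plan, tp)
            for h in haps:
                donor_like = _mutate(rng, cons_d[tp.start:tp.end], noise)
                focal[chrom][h, tp.start:tp.end] = donor_like
                truth.append(Tract(chrom=chrom, start=tp.start, end=tp.end,
                                   hap=int(h)))
            realized.append((tp, haps))

    return SynthData(plan=plan, focal=focal, donor=donor, outgroup=outgroup,
                     truth=truth, realized=realized)


def make_empirical_like_spectrum(plan: SynthPlan) -> SpectrumResult:
    """Deterministic spectrum implied by the tract plan (one marker per
    planned tract, ``n_null_markers`` introgression-free markers), for use as
    the 'empirical' input of outlier-threshold tests.

    Equals :func:`invintro.stats.frequency_spectrum` applied to the realized
    truth matrix, because planted frequencies are exact.
    """
    n = plan.n_focal
    freqs = [round(tp.frequency * n) / n * 100.0 for tp in plan.tract_plan]
    freqs += [0.0] * plan.n_null_markers
    if not freqs:
        raise ValueError("plan has no markers")
    origin = np.zeros((len(freqs), n), dtype=np.uint8)
    for m, f in enumerate(freqs):
        origin[m, :int(round(f / 100 * n))] = 1
    am = AncestryMatrix(origin=origin, samples=_synthetic_samples(plan))
    return frequency_spectrum(am)
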