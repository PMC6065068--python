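"""Windowed RND/RNDmin introgression scan with truth-based FDR calibration.

For each non-overlapping window, every focal haplotype's average divergence
(Dxy) to the donor panel is standardized by the donor-outgroup divergence of
the same window, cancelling local mutation-rate variation: RND(h) =
Dxy(h, donor) / Dxy(donor, outgroup).  A recently introgressed haplotype
coalesces inside the donor tree, so its RND drops to the scaled within-donor
diversity — far below the native interspecific background — and the
per-window minimum over focal haplotypes (RNDmin) detects introgression at
any population frequency.

Haplotype sets are aligned byte matrices (``(n_hap, L)`` uint8 of ACGTN, as
produced by :mod:`invintro.synth` or read from FASTA via
:func:`invintro.io.read_haplotypes`).  Coordinates are 0-based half-open and
the window grid is anchored at 0.

An *informative site* is a position with no missing state in any of the three
species sets and at least one difference among them; windows carrying fewer
than ``min_informative`` such sites report no statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = ord("N")


@dataclass
class WindowRND:
    """Per-window RND values of every focal haplotype and their minimum."""

    chrom: str
    start: int
    end: int
    n_informative: int
    rnd: np.ndarray            # (n_focal,) per-haplotype RND
    rnd_min: float

    def calls(self, tau: float) -> np.ndarray:
        """Per-haplotype introgression calls at threshold ``tau`` (RND < tau)."""
        return self.rnd < tau

    def frequency(self, tau: float) -> float:
        return float(self.calls(tau).mean())


def _as_matrix(haps) -> np.ndarray:
    arr = np.asarray(haps)
    if arr.dtype != np.uint8:
        if arr.dtype.kind in "US":
            arr = np.array([np.frombuffer(str(s).upper().encode(), dtype=np.uint8)
                            for s in haps])
        else:
            arr = arr.astype(np.uint8)
    if arr.ndim != 2:
        raise ValueError("haplotype set must be a 2-D (n_hap, L) matrix")
    return arr


def informative_sites(focal, donor, outgroup, start: int, end: int) -> np.ndarray:
    """Positions in [start, end) with full data and at least one difference
    among the pooled haplotypes of the three species."""
    f, d, o = focal[:, start:end], donor[:, start:end], outgroup[:, start:end]
    pooled = np.concatenate([f, d, o], axis=0)
    no_missing = (pooled != MISSING).all(axis=0)
    varying = (pooled != pooled[0]).any(axis=0)
    return np.nonzero(no_missing & varying)[0] + start


def window_dxy(group_a, group_b, sites: np.ndarray, n_accessible: int | None = None) -> float:
    """Average pairwise per-site divergence between two haplotype sets.

    ``sites`` are the accessible positions; identical columns elsewhere
    contribute no differences, so restricting the comparison to ``sites``
    and dividing by ``n_accessible`` (defaults to ``len(sites)``) equals a
    full-sequence average over accessible sites.
    """
    n_acc = len(sites) if n_accessible is None else n_accessible
    if n_acc == 0:
        raise ValueError("no accessible sites in window")
    a = _as_matrix(group_a)[:, sites]
    b = _as_matrix(group_b)[:, sites]
    diff = (a[:, None, :] != b[None, :, :]).sum(axis=2)
    return float(diff.mean() / n_acc)


def rnd_profile(focal, donor, outgroup, window_len: int,
                min_informative: int = 50, chrom: str = "chr1",
                seq_len: int | None = None) -> list[WindowRND]:
    """RND of every focal haplotype in non-overlapping windows.

    RND(h) = Dxy(h, donor) / Dxy(donor, outgroup); the denominator is
    averaged over all donor x outgroup pairs per window.  Windows with fewer
    than ``min_informative`` informative sites, or with a zero denominator,
    are omitted.
    """
    focal = _as_matrix(focal)
    donor = _as_matrix(donor)
    outgroup = _as_matrix(outgroup)
    L = seq_len or focal.shape[1]
    if donor.shape[1] != focal.shape[1] or outgroup.shape[1] != focal.shape[1]:
        raise ValueError("haplotype sets must share coordinates")

    out = []
    for start in range(0, L, window_len):
        end = min(start + window_len, L)
        sites = informative_sites(focal, donor, outgroup, start, end)
        if len(sites) < min_informative:
            continue
        f = focal[:, sites]
        d = donor[:, sites]
        o = outgroup[:, sites]
        n = len(sites)
        den = float((d[:, None, :] != o[None, :, :]).sum(axis=2).mean() / n)
        if den <= 0:
            continue
        num = (f[:, None, :] != d[None, :, :]).sum(axis=2).mean(axis=1) / n
        rnd = num / den
        out.append(WindowRND(chrom=chrom, start=start, end=end,
                             n_informative=n, rnd=rnd, rnd_min=float(rnd.min())))
    return out


# ---------------------------------------------------------------------------
# truth-based calibration


@dataclass
class CalibrationResult:
    """FDR/power of the RNDmin scan calibrated against a truth tract set."""

    threshold: float
    fdr: float
    power: float
    power_by_length: dict
    n_true_windows: int
    n_null_windows: int
    max_truth_freq: float
    sweep: np.ndarray = field(default=None)   # (n_tau, 3): tau, fdr, power


def _window_truth_labels(windows, truth, n_focal: int, max_truth_freq: float):
    """Label windows from per-haplotype truth tracts.

    A window is truly introgressed when at least one truth tract covers it
    entirely; windows only partially overlapped by a tract are excluded from
    calibration, as are true windows whose truth frequency (fully covering
    haplotypes / n_focal) exceeds ``max_truth_freq``.  Returns (labels,
    lengths) with label 1 = true, 0 = null, -1 = excluded, and the covering
    tract length for true windows.
    """
    labels = np.zeros(len(windows), dtype=np.int8)
    lengths = np.zeros(len(windows))
    for w, win in enumerate(windows):
        cover = 0
        partial = False
        cov_len = 0
        for tr in truth:
            if getattr(tr, "chrom", win.chrom) != win.chrom:
                continue
            if tr.end <= win.start or tr.start >= win.end:
                continue
            if tr.start <= win.start and tr.end >= win.end:
                cover += 1
                cov_len = max(cov_len, tr.length)
            else:
                partial = True
        if cover > 0:
            freq = cover / n_focal
            labels[w] = -1 if freq > max_truth_freq else 1
            lengths[w] = cov_len
        elif partial:
            labels[w] = -1
    return labels, lengths


def calibrate_threshold(windows: list[WindowRND], truth, target_fdr: float = 0.10,
                        max_truth_freq: float = 0.65) -> CalibrationResult:
    """Choose the largest RNDmin threshold with estimated FDR <= target.

    Sweeps the threshold over the observed RNDmin values; at each tau a
    window is called introgressed iff RNDmin <= tau, FDR = false calls /
    calls and power = detected true windows / true windows.  Per-length-class
    power is reported for the distinct covering-tract lengths of the truth
    set.
    """
    if not windows:
        raise ValueError("no windows")
    n_focal = len(windows[0].rnd)
    labels, lengths = _window_truth_labels(windows, truth, n_focal, max_truth_freq)
    true_mask = labels == 1
    null_mask = labels == 0
    n_true = int(true_mask.sum())
    if n_true == 0:
        raise ValueError("no truth windows among the scanned windows")

    rndmin = np.array([w.rnd_min for w in windows])
    taus = np.unique(rndmin[true_mask | null_mask])
    sweep = []
    best = None
    for tau in taus:
        called = rndmin <= tau
        n_calls = int((called & (true_mask | null_mask)).sum())
        if n_calls == 0:
            continue
        false_calls = int((called & null_mask).sum())
        fdr = false_calls / n_calls
        power = int((called & true_mask).sum()) / n_true
        sweep.append((tau, fdr, power))
        if fdr <= target_fdr:
            best = (tau, fdr, power)
    if best is None:
        # even the smallest threshold violates the target: report it anyway
        best = min(sweep, key=lambda s: s[1])
    tau, fdr, power = best

    power_by_length = {}
    called = rndmin <= tau
    for lng in sorted(set(lengths[true_mask])):
        m = true_mask & (lengths == lng)
        power_by_length[float(lng)] = float((called & m).sum() / m.sum())
    return CalibrationResult(threshold=float(tau), fdr=float(fdr), power=float(power),
                             power_by_length=power_by_length,
                             n_true_windows=n_true, n_null_windows=int(null_mask.sum()),
                             max_truth_freq=max_truth_freq,
                             sweep=np.array(sweep))


# ---------------------------------------------------------------------------
# artificial-introgression harness


def plant_artificial_tracts(recipients, donor_hap, lengths=(10_000, 30_000, 50_000),
                            n_per_length: int = 200, min_informative: int = 100,
                            centromere: tuple[int, int] | None = None,
                            seed: int = 0, chrom: str = "chr1"):
    """Plant donor tracts into random recipient haplotypes; return truth.

    For each tract length the chromosome is partitioned into length-sized
    slots; slots overlapping the centromere or carrying fewer than
    ``min_informative`` informative sites (positions where the donor
    haplotype differs from at least one recipient) are ineligible.
    ``n_per_length`` eligible slots are chosen at random per length; each has
    its interval replaced by the donor sequence on one randomly chosen
    recipient haplotype.  Raises with the shortfall if too few slots are
    eligible.  Returns ``(modified_recipients, truth_tracts)``.
    """
    from .tracts import Tract

    rec = _as_matrix(recipients).copy()
    don = np.asarray(donor_hap)
    if don.dtype != np.uint8:
        don = np.frombuffer(str(donor_hap).upper().encode(), dtype=np.uint8)
    L = rec.shape[1]
    if len(don) != L:
        raise ValueError("donor haplotype must be aligned to the recipients")
    rng = np.random.default_rng(seed)
    informative = (rec != don[None, :]).any(axis=0) & (don != MISSING)
    cum = np.concatenate([[0], np.cumsum(informative)])

    truth = []
    for tl in lengths:
        slots = []
        for s in range(0, L - tl + 1, tl):
            e = s + tl
            if centromere is not None and not (e <= centromere[0] or s >= centromere[1]):
                continue
            if cum[e] - cum[s] < min_informative:
                continue
            slots.append(s)
        if len(slots) < n_per_length:
            raise ValueError(
                f"only {len(slots)} eligible non-overlapping slots of {tl} bp "
                f"(need {n_per_length}; shortfall {n_per_length - len(slots)})")
        chosen = rng.choice(len(slots), size=n_per_length, replace=False)
        for ci in chosen:
            s = slots[ci]
            h = int(rng.integers(rec.shape[0]))
            rec[h, s:s + tl] = don[s:s + tl]
            truth.append(Tract(chrom=chrom, start=s, end=s + tl, hap=h))
    return rec, truth


def plant_artificial_datasets(recipients, donor_hap, lengths=(10_000, 30_000, 50_000),
                              n_per_length: int = 200, n_datasets: int = 5,
                              min_informative: int = 100,
                              centromere: tuple[int, int] | None = None,
                              seed: int = 0, chrom: str = "chr1"):
    """Independent replicate planting datasets (default 5 per tract length,
    i.e. 1000 planted tracts per length in total), for power estimation."""
    ss = np.random.SeedSequence(seed)
    return [plant_artificial_tracts(recipients, donor_hap, lengths=lengths,
                                    n_per_length=n_per_length,
                                    min_informative=min_informative,
                                    centromere=centromere, seed=int(s),
                                    chrom=chrom)
            for s in ss.generate_state(n_datasets)]
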