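"""Introgression summary statistics, geographic tests, and the
simulation-calibrated outlier threshold.

The central object is a marker x haplotype ancestry matrix (simulated truth or
empirical calls).  A marker's introgression frequency is the fraction of
sampled haplotypes with donor ancestry; frequencies live on a 5% grid (20
haplotypes).  The outlier threshold is the minimum grid frequency at which the
empirical proportion of introgressed markers exceeds what neutral demographic
simulations produce in at least ``q`` of replicates — markers above it carry
more high-frequency introgression than drift during the invasion can explain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .coalescent import AncestryMatrix

FREQ_GRID_STEP = 5.0  # percent


@dataclass
class SpectrumResult:
    """Introgression-frequency spectrum of one ancestry matrix.

    ``grid`` holds bin centres 0..100 in 5% steps; ``proportions[i]`` the
    fraction of markers whose frequency rounds to ``grid[i]``.  Frequencies
    are counted over haplotypes by default (20 for ten diploid individuals);
    ``dosage_proportions`` gives the individual-dosage variant (a marker
    counted in an individual if either haplotype is introgressed).
    """

    grid: np.ndarray
    proportions: np.ndarray
    per_individual_pct: np.ndarray
    populations: list[str]
    mean_pct: float
    max_freq_pct: float
    n_markers: int
    replicate: int = 0
    dosage_proportions: np.ndarray | None = None

    def tail_proportion(self, f_pct: float) -> float:
        """Proportion of markers with frequency >= ``f_pct`` (boundary inclusive)."""
        return float(self.proportions[self.grid >= f_pct - 1e-9].sum())


def individual_proportions(am: AncestryMatrix) -> np.ndarray:
    """Percent of lineage-markers with donor origin, per individual."""
    n_ind = am.samples.n_individuals
    k = am.samples.n_lineages
    return am.origin.reshape(am.n_markers, n_ind, k).mean(axis=(0, 2)) * 100.0


def frequency_spectrum(am: AncestryMatrix, replicate: int | None = None) -> SpectrumResult:
    """Bin marker introgression frequencies on the 5% grid.

    The marker frequency is DONOR haplotypes / total haplotypes; with 20
    haplotypes every frequency falls exactly on the grid, otherwise it is
    rounded to the nearest grid point.
    """
    nh = am.n_haplotypes
    freq_pct = am.origin.sum(axis=1) * (100.0 / nh)
    grid = np.arange(0.0, 100.0 + FREQ_GRID_STEP, FREQ_GRID_STEP)
    idx = np.clip(np.round(freq_pct / FREQ_GRID_STEP).astype(int), 0, len(grid) - 1)
    proportions = np.bincount(idx, minlength=len(grid)) / am.n_markers

    # individual-dosage variant: a marker counts for an individual if at
    # least one of its haplotypes is introgressed
    n_ind = am.samples.n_individuals
    k = am.samples.n_lineages
    ind_any = am.origin.reshape(am.n_markers, n_ind, k).max(axis=2)
    dfreq_pct = ind_any.sum(axis=1) * (100.0 / n_ind)
    didx = np.clip(np.round(dfreq_pct / FREQ_GRID_STEP).astype(int), 0, len(grid) - 1)
    dprop = np.bincount(didx, minlength=len(grid)) / am.n_markers

    return SpectrumResult(
        grid=grid,
        proportions=proportions,
        per_individual_pct=individual_proportions(am),
        populations=list(am.samples.populations),
        mean_pct=float(am.origin.mean() * 100.0),
        max_freq_pct=float(freq_pct.max()) if am.n_markers else 0.0,
        n_markers=am.n_markers,
        replicate=replicate if replicate is not None else am.replicate,
        dosage_proportions=dprop,
    )


def spectrum_from_frequencies(freq_pct: np.ndarray, populations=None) -> SpectrumResult:
    """Spectrum from raw marker frequencies (%) without an ancestry matrix."""
    freq_pct = np.asarray(freq_pct, dtype=float)
    grid = np.arange(0.0, 100.0 + FREQ_GRID_STEP, FREQ_GRID_STEP)
    idx = np.clip(np.round(freq_pct / FREQ_GRID_STEP).astype(int), 0, len(grid) - 1)
    proportions = np.bincount(idx, minlength=len(grid)) / len(freq_pct)
    return SpectrumResult(grid=grid, proportions=proportions,
                          per_individual_pct=np.array([]),
                          populations=list(populations or []),
                          mean_pct=float(freq_pct.mean()),
                          max_freq_pct=float(freq_pct.max()),
                          n_markers=len(freq_pct))


@dataclass
class ThresholdResult:
    """Simulation-calibrated significance threshold on the frequency grid.

    ``sign_threshold_pct`` is the minimum grid frequency at which the
    empirical tail proportion exceeds the simulated tail in at least ``q`` of
    replicates (None if the empirical spectrum never exceeds the
    simulations); the global threshold over several parameter sets is their
    maximum.
    """

    sign_threshold_pct: float | None
    q: float
    n_replicates: int
    grid_step: float = FREQ_GRID_STEP
    per_grid_exceeded: dict = field(default_factory=dict)


def outlier_threshold(empirical: SpectrumResult, sims: list[SpectrumResult],
                      q: float = 0.95) -> ThresholdResult:
    """Minimum grid frequency whose empirical tail beats >= q of simulations.

    For each grid frequency f the empirical proportion of markers with
    frequency >= f is compared against the same proportion in every simulated
    replicate; f qualifies when the number of replicates strictly below the
    empirical value is at least ``ceil(q * n_replicates)`` (ties count
    against qualification, which can only raise the threshold — the
    conservative resolution).
    """
    if len(sims) < 2:
        raise ValueError("need at least 2 simulated replicates")
    n = len(sims)
    need = int(np.ceil(q * n))
    grid = empirical.grid
    exceeded = {}
    threshold = None
    for f in grid[grid > 0]:
        emp = empirical.tail_proportion(f)
        lower = sum(s.tail_proportion(f) < emp for s in sims)
        ok = lower >= need
        exceeded[float(f)] = ok
        if ok and threshold is None:
            threshold = float(f)
    return ThresholdResult(sign_threshold_pct=threshold, q=q, n_replicates=n,
                           per_grid_exceeded=exceeded)


def global_threshold(results: list[ThresholdResult]) -> float | None:
    """Conservative threshold across parameter sets: the maximum per-set one."""
    vals = [r.sign_threshold_pct for r in results]
    if any(v is None for v in vals):
        return None
    return max(vals)


# ---------------------------------------------------------------------------
# geographic and group tests


_PERM_CACHE: dict[int, np.ndarray] = {}


def _permutation_matrix(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an int8 matrix (cached; n <= 10)."""
    if n not in _PERM_CACHE:
        _PERM_CACHE[n] = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    return _PERM_CACHE[n]


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Spearman p by full enumeration of permutations.

    Ties are mid-ranked; the null distribution enumerates all n! orderings of
    one rank vector.  Practical to n = 10 (3.6M permutations, vectorized).
    """
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    obs = abs(np.corrcoef(rx, ry)[0, 1])

    perms = _permutation_matrix(n)
    rx_perm = rx.astype(np.float32)[perms]           # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    r = ((rx_perm - rx.mean()) @ ry_c.astype(np.float32)) / denom
    return float(np.mean(np.abs(r) >= obs - 1e-12))


def gradient_test(values, distances, exact_max_n: int = 10):
    """Spearman rank correlation of per-individual values against transect
    distance; exact two-sided p for n <= ``exact_max_n``, asymptotic beyond.

    Returns ``(rho, p)``; constant input gives ``(nan, nan)`` (rho undefined).
    """
    values = np.asarray(values, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(values) == 0 or np.ptp(distances) == 0:
        return float("nan"), float("nan")
    rho, p_asym = sps.spearmanr(values, distances)
    if len(values) <= exact_max_n:
        p = _spearman_exact_p(values, distances)
    else:
        p = float(p_asym)
    return float(rho), p


def group_compare(values_a, values_b):
    """Two-sided Mann-Whitney U (exact for small samples without ties)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (len(a) <= 25 and len(b) <= 25
                         and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mtdna_like_screen(calls: np.ndarray, southern: np.ndarray,
                      min_northern: int = 2):
    """Flag windows whose introgression geography mimics the mitochondrial one.

    ``calls[w, h]`` is the per-haplotype introgression call for window ``w``
    (0/1; NaN for missing).  ``southern[h]`` marks haplotypes from the
    southern half of the transect.  A window qualifies iff no southern
    haplotype is introgressed and at least ``min_northern`` northern
    haplotypes are.  Windows with missing calls are skipped (returned masked)
    with a notice list.
    """
    calls = np.asarray(calls, dtype=float)
    southern = np.asarray(southern, dtype=bool)
    if calls.ndim != 2 or calls.shape[1] != len(southern):
        raise ValueError("calls must be (n_windows, n_haplotypes)")
    missing = np.isnan(calls).any(axis=1)
    south_clean = np.nansum(calls[:, southern], axis=1) == 0
    north_hits = np.nansum(calls[:, ~southern], axis=1) >= min_northern
    flags = np.ma.masked_array(south_clean & north_hits, mask=missing)
    skipped = list(np.nonzero(missing)[0])
    return flags, skipped
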