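"""Backward lineage tracing through a recorded invasion demography.

Sampled lineages start in the focal layer at sampling time and walk backward
generation by generation.  Within each backward generation the event order is
fixed: an admixture layer switch (possible only while the deme is co-occupied),
then migration to the parental deme (drawn from the recorded inflow masses,
including the stay-at-home mass), then pairwise coalescence among co-located
lineages of the same marker with per-pair probability ``1/(c*N)`` (``c`` = 2
for nuclear autosomes, 1 for mtDNA).  A lineage's ancestry is the layer it
occupies at generation 0: donor layer = introgressed (DONOR), focal layer =
native (FOCAL).  Markers are independent: no recombination within a marker and
no linkage between markers.

The per-generation switch probability for a lineage in layer ``i`` is
``A_(j->i) * N_j / (N_i + N_j)``, i.e. the admixture rate weighted by the
relative density of the other layer, and zero when the deme is not
co-occupied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .invasion import DONOR, FOCAL, POPULATIONS, SAMPLE_DEMES, DemographyHistory, SimParams


class EmptyDemeError(ValueError):
    """A lineage cannot occupy a deme/layer with zero abundance."""


@dataclass
class SampleMap:
    """Sampled individuals: locality labels, deme indices and transect distances.

    ``demes[i]`` is the land-deme index of individual ``i``; ``populations[i]``
    its locality label; ``distance_km[i]`` the straight-line distance to the
    southernmost sample.  ``n_lineages`` is 2 for nuclear autosomes and 1 for
    mtDNA.
    """

    populations: list[str]
    demes: np.ndarray
    distance_km: np.ndarray
    n_lineages: int = 2

    @property
    def n_individuals(self) -> int:
        return len(self.demes)

    @property
    def n_haplotypes(self) -> int:
        return self.n_individuals * self.n_lineages


def default_samples(grid, n_lineages: int = 2) -> SampleMap:
    """Ten individuals on the SW->NE transect: five south of the donor
    boundary, five inside the initial donor range, mimicking the empirical
    sampling design."""
    demes = np.array([grid.deme_at(r, c) for r, c in SAMPLE_DEMES])
    rc = grid.coords[demes].astype(float)
    d0 = rc[0]
    dist = np.sqrt(((rc - d0) ** 2).sum(axis=1)) * grid.config.cell_km
    return SampleMap(populations=list(POPULATIONS), demes=demes,
                     distance_km=dist, n_lineages=n_lineages)


@dataclass
class TransitionDistribution:
    """Backward one-step law at (t, deme, layer): layer-switch probability and
    the parental-source distribution over (stay, 4 neighbours)."""

    switch_prob: float
    source_probs: np.ndarray   # (5,) probabilities, slot 0 = stay
    source_demes: np.ndarray   # (5,) deme indices (slot 0 = same deme, -1 pad)


def backward_kernel(history: DemographyHistory, t: int, deme: int, layer: int) -> TransitionDistribution:
    """The backward transition law for a lineage at generation ``t``.

    Raises :class:`EmptyDemeError` if the queried deme/layer held no
    individuals at ``t`` (a lineage cannot be there).  ``t`` must be >= 1 so a
    parental generation exists.
    """
    if t < 1 or t > history.T:
        raise ValueError(f"generation {t} outside history range 1..{history.T}")
    N_l = float(history.N[t, deme, layer])
    if N_l <= 0:
        raise EmptyDemeError(f"deme {deme} layer {layer} empty at generation {t}")
    other = 1 - layer
    N_o = float(history.N[t, deme, other])
    A = history.params.A_fd if layer == FOCAL else history.params.A_df
    switch = A * N_o / (N_l + N_o) if N_o > 0 else 0.0

    masses = history.flow[t - 1, deme, layer].astype(float)
    total = masses.sum()
    if total <= 0:
        raise EmptyDemeError(f"no recorded inflow for deme {deme} layer {layer} at {t}")
    probs = masses / total
    demes = np.concatenate([[deme], history.grid.nbr[deme]])
    return TransitionDistribution(switch_prob=switch, source_probs=probs,
                                  source_demes=demes)


@dataclass
class AncestryMatrix:
    """FOCAL/DONOR origin per marker x sampled haplotype.

    ``origin[m, h]`` is 0 (FOCAL) or 1 (DONOR).  Haplotypes are ordered by
    individual (``n_lineages`` consecutive haplotypes per individual), and
    individuals follow the sample map's SW->NE order.
    """

    origin: np.ndarray          # (n_markers, n_haplotypes) uint8
    samples: SampleMap
    replicate: int = 0
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return self.origin.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.origin.shape[1]

    def haplotype_individual(self) -> np.ndarray:
        return np.repeat(np.arange(self.samples.n_individuals), self.samples.n_lineages)

    def to_frame(self):
        import pandas as pd

        m, h = np.nonzero(np.ones_like(self.origin))
        return pd.DataFrame({
            "marker": m,
            "haplotype": h,
            "origin": np.where(self.origin[m, h] == DONOR, "DONOR", "FOCAL"),
        })


# ---------------------------------------------------------------------------
# numba kernel


@njit(cache=True)
def _trace_kernel(Nh, flowcum, nbr, co_any, A_fd, A_df, cploid,
                  deme0, marker_start, seed, do_coal):  # pragma: no cover - jit
    np.random.seed(seed)
    T = Nh.shape[0] - 1
    D = Nh.shape[1]
    L = deme0.shape[0]
    n_markers = marker_start.shape[0] - 1

    deme = deme0.copy()
    layer = np.zeros(L, dtype=np.int8)
    active = np.ones(L, dtype=np.bool_)
    parent = np.full(L, -1, dtype=np.int64)

    # lineage count per (marker, deme, layer) for coalescence bookkeeping
    cellcount = np.zeros((n_markers, D * 2), dtype=np.int16)
    for m in range(n_markers):
        for i in range(marker_start[m], marker_start[m + 1]):
            cellcount[m, deme[i] * 2] += 1

    cand = np.empty(64, dtype=np.int64)  # scratch for pair picking

    for t in range(T, 0, -1):
        check_adm = co_any[t]
        for m in range(n_markers):
            # migration/admixture of this marker's lineages, then coalescence,
            # while the marker's state is cache-hot
            for i in range(marker_start[m], marker_start[m + 1]):
                if not active[i]:
                    continue
                d = deme[i]
                l = layer[i]
                # admixture switch at generation t
                if check_adm:
                    No = Nh[t, d, 1 - l]
                    if No > 0.0:
                        Nl = Nh[t, d, l]
                        A = A_fd if l == 0 else A_df
                        if np.random.random() < A * No / (Nl + No):
                            cellcount[m, d * 2 + l] -= 1
                            l = 1 - l
                            layer[i] = l
                            cellcount[m, d * 2 + l] += 1
                # migration to the parental deme (recorded inflows)
                u = np.random.random()
                kk = 4
                for k in range(5):
                    if u < flowcum[t - 1, d, l, k]:
                        kk = k
                        break
                # skip zero-mass slots (float roundoff at the upper edge)
                while kk > 0:
                    lo = flowcum[t - 1, d, l, kk - 1]
                    if flowcum[t - 1, d, l, kk] > lo:
                        break
                    kk -= 1
                if kk > 0:
                    nd = nbr[d, kk - 1]
                    cellcount[m, d * 2 + l] -= 1
                    deme[i] = nd
                    cellcount[m, nd * 2 + l] += 1

            if not do_coal:
                continue
            # pairwise coalescence at generation t-1, at most one merger per
            # marker per generation (mergers are rare at these densities)
            lam = 0.0
            for i in range(marker_start[m], marker_start[m + 1]):
                if not active[i]:
                    continue
                cell = deme[i] * 2 + layer[i]
                cc = cellcount[m, cell]
                if cc > 1:
                    nloc = Nh[t - 1, deme[i], layer[i]]
                    if nloc > 0:
                        lam += (cc - 1) / (2.0 * cploid * nloc)
            if lam <= 0.0:
                continue
            p = lam if lam < 1.0 else 1.0
            if np.random.random() >= p:
                continue
            # pick the cell with probability proportional to its pair rate
            r = np.random.random() * lam
            acc = 0.0
            chosen_cell = -1
            for i in range(marker_start[m], marker_start[m + 1]):
                if not active[i]:
                    continue
                cell = deme[i] * 2 + layer[i]
                cc = cellcount[m, cell]
                if cc > 1:
                    nloc = Nh[t - 1, deme[i], layer[i]]
                    if nloc > 0:
                        acc += (cc - 1) / (2.0 * cploid * nloc)
                        if acc >= r:
                            chosen_cell = cell
                            break
            if chosen_cell < 0:
                continue
            # uniform pair among the lineages in the chosen cell
            nc = 0
            for i in range(marker_start[m], marker_start[m + 1]):
                if active[i] and deme[i] * 2 + layer[i] == chosen_cell:
                    if nc < cand.shape[0]:
                        cand[nc] = i
                    nc += 1
            if nc < 2:
                continue
            nuse = nc if nc < cand.shape[0] else cand.shape[0]
            a = np.random.randint(0, nuse)
            b = np.random.randint(0, nuse - 1)
            if b >= a:
                b += 1
            i1 = cand[a]
            i2 = cand[b]
            active[i2] = False
            parent[i2] = i1
            cellcount[m, chosen_cell] -= 1

    # ancestry = layer at generation 0, shared through mergers
    anc = np.zeros(L, dtype=np.uint8)
    for i in range(L):
        j = i
        while parent[j] >= 0:
            j = parent[j]
        anc[i] = layer[j]
    return anc


def _prepare_history(history: DemographyHistory):
    """Cumulative backward-source probabilities and co-occupancy flags."""
    flow = history.flow
    total = flow.sum(axis=3, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(total > 0, flow / total, 0.0)
    flowcum = np.cumsum(probs, axis=3).astype(np.float32)
    co_any = np.zeros(history.T + 1, dtype=np.bool_)
    occ = (history.N[:, :, FOCAL] > 0) & (history.N[:, :, DONOR] > 0)
    co_any[:] = occ.any(axis=1)
    return flowcum, co_any


def trace_ancestry(history: DemographyHistory, samples: SampleMap,
                   params: SimParams | None = None, seed: int = 0,
                   n_markers: int | None = None, coalescence: bool = True,
                   _prepared=None) -> AncestryMatrix:
    """Trace one replicate of independent markers backward to generation 0.

    Returns the marker x haplotype ancestry matrix for the sampled
    individuals.  ``coalescence=False`` disables lineage mergers (the marginal
    per-haplotype ancestry distribution is unchanged; only across-haplotype
    correlation is lost), which is used by the property tests.
    """
    params = params or history.params
    if not history.replaced:
        raise RuntimeError("history flagged: donor not extinct at sampling time "
                           "(statistics refuse flagged histories)")
    n_markers = n_markers if n_markers is not None else params.n_markers
    cploid = 1 if params.mode == "mtdna" else 2

    nh = samples.n_haplotypes
    deme0 = np.empty(n_markers * nh, dtype=np.int64)
    hap_demes = np.repeat(samples.demes, samples.n_lineages)
    for m in range(n_markers):
        deme0[m * nh:(m + 1) * nh] = hap_demes
    marker_start = np.arange(n_markers + 1, dtype=np.int64) * nh

    flowcum, co_any = _prepared if _prepared is not None else _prepare_history(history)
    anc = _trace_kernel(history.N, flowcum, history.grid.nbr, co_any,
                        float(params.A_fd), float(params.A_df), float(cploid),
                        deme0, marker_start, int(seed) % (2 ** 31), coalescence)
    origin = anc.reshape(n_markers, nh)
    return AncestryMatrix(origin=origin, samples=samples, seed=seed)


def trace_replicates(history: DemographyHistory, samples: SampleMap,
                     params: SimParams | None = None, seed: int = 0,
                     n_reps: int | None = None, n_markers: int | None = None,
                     coalescence: bool = True) -> list[AncestryMatrix]:
    """Independent coalescent replicates on one demographic history."""
    params = params or history.params
    n_reps = n_reps if n_reps is not None else params.n_reps
    prepared = _prepare_history(history)
    ss = np.random.SeedSequence(seed)
    out = []
    for r, child_seed in enumerate(ss.generate_state(n_reps)):
        am = trace_ancestry(history, samples, params, seed=int(child_seed),
                            n_markers=n_markers, coalescence=coalescence,
                            _prepared=prepared)
        am.replicate = r
        out.append(am)
    return out


def simulate_mtdna(history: DemographyHistory, samples: SampleMap,
                   params: SimParams | None = None, n_reps: int = 1000,
                   seed: int = 0, n_per_locality: int = 20,
                   empirical: np.ndarray | None = None):
    """Mitochondrial introgression frequencies per locality and replicate.

    Each replicate is one non-recombining maternal marker: ``n_per_locality``
    haploid lineages per sampled locality are traced backward on the
    philopatric low-K history.  Returns a dict with the per-replicate,
    per-locality introgression frequency matrix, per-locality medians and
    IQRs, and the distribution of north-minus-south mean frequency
    differences.  If an empirical per-locality frequency table is supplied,
    per-replicate Spearman correlations against it are included; otherwise the
    correlation summary is skipped with a notice field.
    """
    params = params or history.params
    if params.mode != "mtdna":
        raise ValueError("simulate_mtdna requires params.mode='mtdna'")
    npop = samples.n_individuals
    mt_samples = SampleMap(
        populations=list(np.repeat(samples.populations, n_per_locality)),
        demes=np.repeat(samples.demes, n_per_locality),
        distance_km=np.repeat(samples.distance_km, n_per_locality),
        n_lineages=1,
    )
    reps = trace_replicates(history, mt_samples, params, seed=seed,
                            n_reps=n_reps, n_markers=1)
    freq = np.empty((n_reps, npop))
    for r, am in enumerate(reps):
        per_hap = am.origin[0]
        freq[r] = per_hap.reshape(npop, n_per_locality).mean(axis=1)

    south = freq[:, :npop // 2].mean(axis=1)
    north = freq[:, npop // 2:].mean(axis=1)
    result = {
        "freq": freq,
        "populations": list(samples.populations),
        "median": np.median(freq, axis=0),
        "iqr": np.percentile(freq, 75, axis=0) - np.percentile(freq, 25, axis=0),
        "north_south_diff": north - south,
    }
    if empirical is not None:
        from scipy.stats import spearmanr

        emp = np.asarray(empirical, dtype=float)
        rhos = np.full(n_reps, np.nan)
        pvals = np.full(n_reps, np.nan)
        for r in range(n_reps):
            if np.ptp(freq[r]) > 0:
                rho, p = spearmanr(freq[r], emp)
                rhos[r], pvals[r] = rho, p
        result["spearman_rho"] = rhos
        result["spearman_p"] = pvals
        ok = ~np.isnan(rhos)
        result["prop_significant_positive"] = float(
            np.mean(ok & (rhos > 0) & (pvals < 0.05)))
    else:
        result["notice"] = "no empirical frequency table supplied; correlation summary skipped"
    return result
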