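"""Two-layer deme-world forward demography of an invasive range replacement.

The world is a grid of 50 x 50 km demes covering an Iberia-like landmass.
Layer 0 holds the invading focal species (*L. granatensis*-like), layer 1 the
resident donor species (*L. timidus*-like) initially confined to a northern
band.  The focal species expands from a single southwestern source deme,
growing logistically and competing with the resident by joint density
(Lotka-Volterra with both competition coefficients equal to 1).  Because the
focal carrying capacity is twice the donor's, the invader deterministically
excludes the resident wherever both co-occur, reproducing a complete range
replacement by the time of sampling.

Demography is deterministic and real-valued; abundances below one individual
are truncated to zero, which gives the colonization wave a finite speed and a
well-defined donor extinction time.  All randomness of the model lives in the
backward coalescent stage (:mod:`invintro.coalescent`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

FOCAL = 0
DONOR = 1

#: population labels of the ten sampled localities, southwest to northeast
POPULATIONS = ("ALT", "SEV", "PAN", "CBR", "CRE", "VLP", "MAD", "VAL", "SOR", "NAV")


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


@dataclass
class ScenarioConfig:
    """World geometry and timing of the invasion scenario.

    Parameters
    ----------
    n_cols, n_rows
        Grid dimensions in demes; row 0 is the southern edge.
    land_mask, donor_mask
        Boolean ``(n_rows, n_cols)`` arrays.  ``donor_mask`` is the initial
        range of the resident donor species and must be a subset of the land.
    source_deme
        ``(row, col)`` of the focal expansion origin (southwest); must be on
        land and outside the donor range.
    cell_km
        Deme side length in km (default 50).
    t_start_gen
        Forward duration in generations (default 10,000 = 20 ky at 2 y/gen).
    generation_years
        Years per generation (default 2).
    """

    n_cols: int
    n_rows: int
    land_mask: np.ndarray
    donor_mask: np.ndarray
    source_deme: tuple[int, int]
    cell_km: float = 50.0
    t_start_gen: int = 10_000
    generation_years: float = 2.0

    def __post_init__(self) -> None:
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.donor_mask = np.asarray(self.donor_mask, dtype=bool)
        if self.land_mask.shape != (self.n_rows, self.n_cols):
            raise ConfigurationError("land_mask shape does not match grid dimensions")
        if self.donor_mask.shape != (self.n_rows, self.n_cols):
            raise ConfigurationError("donor_mask shape does not match grid dimensions")
        if self.t_start_gen <= 0:
            raise ConfigurationError("t_start_gen must be positive")
        if not self.land_mask.any():
            raise ConfigurationError("no land demes")
        if np.any(self.donor_mask & ~self.land_mask):
            raise ConfigurationError("donor_mask must be a subset of land_mask")
        r, c = self.source_deme
        if not (0 <= r < self.n_rows and 0 <= c < self.n_cols) or not self.land_mask[r, c]:
            raise ConfigurationError("source deme must be on land")
        if self.donor_mask[r, c]:
            raise ConfigurationError("source deme must lie outside the donor range")


@dataclass
class SimParams:
    """Demographic parameters of one simulation set (Table-style par1..par8).

    ``K_G``/``K_T`` are the focal/donor deme carrying capacities, ``G`` the
    intrinsic logistic growth rate per generation, ``M`` the per-generation
    emigration fraction, and ``A_fd``/``A_df`` the admixture rates into the
    focal layer from the donor and vice versa.  ``mode`` selects nuclear
    (diploid, 2 lineages per individual) or mtdna (haploid, maternally
    transmitted) genealogy bookkeeping downstream.
    """

    K_G: float
    K_T: float
    G: float = 0.5
    M: float = 0.2
    A_fd: float = 0.005
    A_df: float = 0.005
    mode: str = "nuclear"
    n_markers: int = 2_000
    n_reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.M < 1):
            raise ConfigurationError("M must satisfy 0 <= M < 1")
        if not (0 <= self.A_fd <= 1 and 0 <= self.A_df <= 1):
            raise ConfigurationError("admixture rates must lie in [0, 1]")
        if self.G <= 0:
            raise ConfigurationError("G must be positive")
        if self.K_G < 1 or self.K_T < 1:
            raise ConfigurationError("carrying capacities must be >= 1")
        if self.mode not in ("nuclear", "mtdna"):
            raise ConfigurationError("mode must be 'nuclear' or 'mtdna'")


#: Table-style parameter sets; (K_G, K_T, G, M, A) with bidirectional A.
PARAMETER_SETS: dict[str, dict[str, float]] = {
    "par1": dict(K_G=1000, K_T=500, G=0.5, M=0.2, A=0.005),
    "par2": dict(K_G=1000, K_T=500, G=0.5, M=0.02, A=0.005),
    "par3": dict(K_G=1000, K_T=500, G=0.5, M=0.2, A=0.03),
    "par4": dict(K_G=1000, K_T=500, G=0.5, M=0.02, A=0.03),
    "par5": dict(K_G=10000, K_T=5000, G=0.5, M=0.2, A=0.005),
    "par6": dict(K_G=10000, K_T=5000, G=0.5, M=0.02, A=0.005),
    "par7": dict(K_G=10000, K_T=5000, G=0.5, M=0.2, A=0.03),
    "par8": dict(K_G=10000, K_T=5000, G=0.5, M=0.02, A=0.03),
}


def params_for(name: str, **overrides) -> SimParams:
    """Build :class:`SimParams` for a named parameter set (``par1``..``par8``)."""
    base = PARAMETER_SETS[name]
    kw = dict(K_G=base["K_G"], K_T=base["K_T"], G=base["G"], M=base["M"],
              A_fd=base["A"], A_df=base["A"])
    kw.update(overrides)
    return SimParams(**kw)


def mtdna_params(**overrides) -> SimParams:
    """Parameters of the mitochondrial mode: K reduced to 1/4 of the nuclear
    values (250/125), minimal inter-deme migration (M = 0.005) mimicking
    female philopatry, and asymmetric admixture (0.025 donor->focal, 0.001
    focal->donor) mimicking male-biased colonization."""
    kw = dict(K_G=250, K_T=125, G=0.5, M=0.005, A_fd=0.025, A_df=0.001, mode="mtdna")
    kw.update(overrides)
    return SimParams(**kw)


@dataclass
class DemeGrid:
    """Indexed land demes with 4-neighbour adjacency and initial state."""

    config: ScenarioConfig
    coords: np.ndarray          # (D, 2) int, (row, col) of each land deme
    index: np.ndarray           # (n_rows, n_cols) int, -1 for sea
    nbr: np.ndarray             # (D, 4) int, land neighbours, -1 padded
    donor_deme: np.ndarray      # (D,) bool, deme within the donor habitat
    source: int                 # deme index of the expansion origin
    N0: np.ndarray = field(default=None)  # (D, 2) initial abundances

    @property
    def n_demes(self) -> int:
        return len(self.coords)

    def deme_at(self, row: int, col: int) -> int:
        i = int(self.index[row, col])
        if i < 0:
            raise KeyError(f"({row}, {col}) is not a land deme")
        return i


def build_grid(config: ScenarioConfig, K_G: float = 1.0, K_T: float = 1.0) -> DemeGrid:
    """Index land demes, build the 4-neighbour adjacency and initial state.

    The initial state places the donor at ``K_T`` throughout its range and the
    focal species at ``K_G`` in the source deme only.  ``K_G``/``K_T`` default
    to 1 so a grid can be built once and rescaled by the caller.
    """
    rows, cols = np.nonzero(config.land_mask)
    coords = np.stack([rows, cols], axis=1).astype(np.int64)
    D = len(coords)
    index = np.full((config.n_rows, config.n_cols), -1, dtype=np.int64)
    index[rows, cols] = np.arange(D)

    nbr = np.full((D, 4), -1, dtype=np.int64)
    for d, (r, c) in enumerate(coords):
        for k, (dr, dc) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
            rr, cc = r + dr, c + dc
            if 0 <= rr < config.n_rows and 0 <= cc < config.n_cols:
                nbr[d, k] = index[rr, cc]

    donor_deme = config.donor_mask[rows, cols]
    source = int(index[config.source_deme])

    N0 = np.zeros((D, 2))
    N0[donor_deme, DONOR] = K_T
    N0[source, FOCAL] = K_G
    return DemeGrid(config=config, coords=coords, index=index, nbr=nbr,
                    donor_deme=donor_deme, source=source, N0=N0)


def step_logistic(N: float, K: float, G: float) -> float:
    """One deterministic logistic update ``N + G*N*(1 - N/K)``, floored at 0."""
    if N < 0:
        raise ValueError("abundance must be non-negative")
    return max(0.0, N + G * N * (1.0 - N / K))


def compete_step(N_f: float, N_d: float, K_f: float, K_d: float, G: float):
    """Joint-density Lotka-Volterra update of a co-occupied deme.

    Both competition coefficients are 1:
    ``N_i' = N_i + G*N_i*(1 - (N_f + N_d)/K_i)``.  With ``K_f > K_d`` the
    focal layer deterministically excludes the donor.
    """
    tot = N_f + N_d
    nf = max(0.0, N_f + G * N_f * (1.0 - tot / K_f))
    nd = max(0.0, N_d + G * N_d * (1.0 - tot / K_d))
    return nf, nd


@dataclass
class DemographyHistory:
    """Per-generation abundances and backward migrant-source distributions.

    ``N[t, d, l]`` is the abundance of layer ``l`` in deme ``d`` at generation
    ``t`` (0 = start of invasion, ``T`` = sampling).  ``flow[t, d, l, k]`` is
    the realized contribution mass of source ``k`` (0 = stayed, 1..4 = from
    ``grid.nbr[d, k-1]``) to ``(d, l)`` during the update from ``t`` to
    ``t+1``; normalized over ``k`` it is the backward one-step migration
    distribution of a lineage at ``(d, l)`` in generation ``t+1``.
    """

    grid: DemeGrid
    params: SimParams
    N: np.ndarray              # (T+1, D, 2) float32
    flow: np.ndarray           # (T, D, 2, 5) float32
    replaced: bool

    @property
    def T(self) -> int:
        return self.N.shape[0] - 1

    def co_occupied(self, t: int) -> np.ndarray:
        return (self.N[t, :, FOCAL] > 0) & (self.N[t, :, DONOR] > 0)

    def first_colonized(self) -> np.ndarray:
        """First generation with focal presence per deme (T+1 if never)."""
        occ = self.N[:, :, FOCAL] > 0
        first = np.where(occ.any(axis=0), occ.argmax(axis=0), self.T + 1)
        return first

    def to_frame(self):
        """Long-format table (generation, row, col, layer, N) of nonzero cells."""
        import pandas as pd

        t, d, l = np.nonzero(self.N)
        return pd.DataFrame({
            "generation": t,
            "row": self.grid.coords[d, 0],
            "col": self.grid.coords[d, 1],
            "layer": np.where(l == FOCAL, "focal", "donor"),
            "N": self.N[t, d, l],
        })


MIN_ABUNDANCE = 1.0  # sub-individual abundances are truncated to zero


def run_forward(grid: DemeGrid, params: SimParams, seed: int | None = 0,
                raise_on_incomplete: bool = False) -> DemographyHistory:
    """Run the forward demography for ``t_start_gen`` generations.

    Per generation: growth/competition, then emigration of a fraction ``M``
    split equally among each layer's habitable land neighbours (the donor is
    confined to its initial range; edge demes lose nothing to sea), then
    truncation of sub-individual abundances.  Inflows (including the
    stay-at-home mass) are recorded for the backward coalescent.

    Growth is deterministic and real-valued; emigrant counts are stochastically
    rounded to integers (floor plus a Bernoulli draw on the fractional part)
    so that colonization proceeds by whole founders even when ``M * N`` per
    neighbour falls below one individual, as in the philopatric mtDNA setting.
    Passing ``seed=None`` disables the rounding and keeps flows real-valued
    (useful for the deterministic wave-front properties).

    If the donor is not extinct everywhere at sampling time the history is
    flagged (``replaced=False``) and downstream statistics refuse it.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    D = grid.n_demes
    T = grid.config.t_start_gen
    K = np.array([params.K_G, params.K_T])

    # habitat masks; the donor is confined to its initial range
    habitat = np.ones((D, 2), dtype=bool)
    habitat[:, DONOR] = grid.donor_deme
    nbr = grid.nbr
    has_nbr = nbr >= 0
    # out-degree: neighbours of d that are habitable destinations for layer l
    deg = np.zeros((D, 2), dtype=np.int64)
    for l in (FOCAL, DONOR):
        deg[:, l] = (has_nbr & np.where(has_nbr, habitat[nbr.clip(0), l], False)).sum(axis=1)
    # recv[d, k, l]: deme d can receive layer-l migrants from neighbour k
    recv = has_nbr[:, :, None] & habitat[:, None, :]

    N = np.zeros((T + 1, D, 2), dtype=np.float32)
    flow = np.zeros((T, D, 2, 5), dtype=np.float32)
    cur = np.zeros((D, 2))
    cur[grid.donor_deme, DONOR] = params.K_T
    cur[grid.source, FOCAL] = params.K_G
    N[0] = cur

    for t in range(T):
        tot = cur.sum(axis=1, keepdims=True)
        grown = cur + params.G * cur * (1.0 - tot / K)
        np.clip(grown, 0.0, None, out=grown)

        out = np.where(deg > 0, params.M * grown, 0.0)          # (D, 2)
        share = np.zeros((D, 2))
        np.divide(out, deg, out=share, where=deg > 0)           # per-neighbour share

        # per-(source, neighbour-slot, layer) emigrant packets
        packets = np.zeros((D, 4, 2))
        for k in range(4):
            # source deme sends `share` along each of its valid out-edges;
            # enumerate them from the receiver side below, so here build the
            # sender-side packet matrix: packet from d along slot k exists iff
            # nbr[d, k] is a habitable destination.
            dst = nbr[:, k]
            ok = has_nbr[:, k][:, None] & np.where(has_nbr[:, k][:, None],
                                                   habitat[dst.clip(0), :], False)
            packets[:, k, :] = np.where(ok, share, 0.0)
        if rng is not None:
            frac = packets - np.floor(packets)
            packets = np.floor(packets) + (rng.random(packets.shape) < frac)
        sent = packets.sum(axis=1)                              # (D, 2)
        stay = np.maximum(grown - sent, 0.0)

        nxt = stay.copy()
        fl = np.zeros((D, 2, 5))
        fl[:, :, 0] = stay
        # receiver side: deme d's neighbour slot k holds src = nbr[d, k];
        # the packet src -> d is the one src addressed to d.  Find, for each
        # (d, k), which slot of src points back at d.
        # slots are ordered (S, N, W, E); the slot of src pointing back at d
        # is the opposite of slot k
        for k, back in enumerate((1, 0, 3, 2)):
            src = nbr[:, k]
            for l in (FOCAL, DONOR):
                ok = recv[:, k, l]
                contrib = np.where(ok, packets[src.clip(0), back, l], 0.0)
                nxt[:, l] += contrib
                fl[:, l, k + 1] = contrib

        nxt[nxt < MIN_ABUNDANCE] = 0.0
        fl[nxt == 0] = 0.0
        cur = nxt
        N[t + 1] = cur
        flow[t] = fl

    replaced = bool(np.all(N[T, :, DONOR] == 0))
    if not replaced and raise_on_incomplete:
        raise RuntimeError("donor layer not extinct at sampling time")
    return DemographyHistory(grid=grid, params=params, N=N, flow=flow, replaced=replaced)


# ---------------------------------------------------------------------------
# default Iberia-like world


def iberia_config(t_start_gen: int = 10_000) -> ScenarioConfig:
    """Rasterized Iberia-like polygon of ~200 land demes (50 km cells).

    The landmass is an 18 x 13 grid with the southeastern corner cut along a
    diagonal (Mediterranean coast) and an irregular northern coastline.  The
    donor range is the northern 45% of grid rows (rows >= 7), approximating
    the resident species' reconstructed glacial range; the focal source deme
    sits in the far southwest.
    """
    n_cols, n_rows = 18, 13
    land = np.ones((n_rows, n_cols), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            if c - r > 12:          # SE diagonal cut
                land[r, c] = False
    land[12, 10:] = False           # northern coastline notch
    land[11, 16:] = False
    donor = np.zeros_like(land)
    donor[7:, :] = True
    donor &= land
    return ScenarioConfig(n_cols=n_cols, n_rows=n_rows, land_mask=land,
                          donor_mask=donor, source_deme=(0, 1),
                          t_start_gen=t_start_gen)


#: default sampled localities (row, col), southwest to northeast; the first
#: five lie south of the donor boundary, the last five inside the donor range.
SAMPLE_DEMES = ((0, 2), (1, 4), (3, 5), (4, 7), (5, 9),
                (7, 10), (8, 11), (9, 12), (10, 13), (11, 14))


# ---------------------------------------------------------------------------
# YAML scenario IO


def load_scenario(path) -> ScenarioConfig:
    """Load a scenario config from YAML; masks given as rows of 0/1 strings."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    def parse_mask(rows):
        return np.array([[ch == "1" for ch in row.split()] if " " in row
                         else [ch == "1" for ch in row] for row in rows], dtype=bool)[::-1]
    land = parse_mask(doc["land_mask"])
    donor = parse_mask(doc["donor_mask"])
    n_rows, n_cols = land.shape
    return ScenarioConfig(
        n_cols=n_cols, n_rows=n_rows, land_mask=land, donor_mask=donor,
        source_deme=tuple(doc["source_deme"]),
        cell_km=float(doc.get("cell_km", 50.0)),
        t_start_gen=int(doc.get("t_start_gen", 10_000)),
        generation_years=float(doc.get("generation_years", 2.0)),
    )


def dump_scenario(config: ScenarioConfig, path) -> None:
    def fmt(mask):
        return ["".join("1" if v else "0" for v in row) for row in mask[::-1]]
    doc = {
        "land_mask": fmt(config.land_mask),
        "donor_mask": fmt(config.donor_mask),
        "source_deme": list(config.source_deme),
        "cell_km": config.cell_km,
        "t_start_gen": config.t_start_gen,
        "generation_years": config.generation_years,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
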