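"""End-to-end experiment drivers: run a named parameter set (forward
demography + coalescent replicates + spectra) or the mitochondrial
discordance comparison, on the default Iberia-like world.

These are the units the analysis scripts, the test suite and the acceptance
script all share, so every reported number comes from the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coalescent as co
from . import invasion as inv
from . import stats


def _child_seed(seed: int, *keys) -> int:
    """Deterministic sub-seed below 2**31 derived from a root seed and keys."""
    import zlib

    ints = [zlib.crc32(str(k).encode()) % (2 ** 31) for k in keys]
    h = np.random.SeedSequence([int(seed)] + ints)
    return int(h.generate_state(1)[0] % (2 ** 31))


@dataclass
class ParamSetResult:
    """Scaled reproduction of one simulated parameter set."""

    name: str
    params: inv.SimParams
    spectra: list                   # per-replicate SpectrumResult
    mean_pct: float                 # mean introgression over reps x markers x haps
    per_population_pct: np.ndarray  # (10,) mean per sampled individual/locality
    populations: list
    distance_km: np.ndarray
    max_freq_pct: float             # max marker frequency over all reps
    n_markers: int
    n_reps: int

    def gradient(self):
        """Spearman rho/p of per-individual introgression vs transect distance."""
        return stats.gradient_test(self.per_population_pct, self.distance_km)


def run_parameter_set(name: str, n_markers: int = 2_000, n_reps: int = 10,
                      seed: int = 0, grid=None, samples=None) -> ParamSetResult:
    """Forward + backward simulation of one parameter set at desk scale.

    ``name`` is ``par1``..``par8``.  The forward history is simulated once
    (its only stochasticity is emigrant rounding); replicates are independent
    coalescent draws of ``n_markers`` markers each.
    """
    grid = grid if grid is not None else inv.build_grid(inv.iberia_config())
    samples = samples if samples is not None else co.default_samples(grid)
    params = inv.params_for(name, n_markers=n_markers, n_reps=n_reps, seed=seed)
    history = inv.run_forward(grid, params, seed=_child_seed(seed, name, "fwd"))
    reps = co.trace_replicates(history, samples, params,
                               seed=_child_seed(seed, name, "coal"),
                               n_reps=n_reps, n_markers=n_markers)
    spectra = [stats.frequency_spectrum(am) for am in reps]
    per_pop = np.mean([sp.per_individual_pct for sp in spectra], axis=0)
    return ParamSetResult(
        name=name, params=params, spectra=spectra,
        mean_pct=float(np.mean([sp.mean_pct for sp in spectra])),
        per_population_pct=per_pop,
        populations=list(samples.populations),
        distance_km=samples.distance_km.copy(),
        max_freq_pct=float(max(sp.max_freq_pct for sp in spectra)),
        n_markers=n_markers, n_reps=n_reps)


def max_low_admixture_frequency(n_markers: int = 2_000, n_reps: int = 10,
                                seed: int = 0, sets=("par1", "par2", "par5", "par6")):
    """Maximum marker introgression frequency (%) across the low-admixture
    (A = 0.005) parameter sets — the bound that defines outlier regions."""
    grid = inv.build_grid(inv.iberia_config())
    samples = co.default_samples(grid)
    results = {s: run_parameter_set(s, n_markers, n_reps,
                                    seed=_child_seed(seed, s), grid=grid,
                                    samples=samples) for s in sets}
    overall = max(r.max_freq_pct for r in results.values())
    return overall, results


def run_mtdna_comparison(n_reps: int = 400, seed: int = 0,
                         empirical: np.ndarray | None = None):
    """Paired mtDNA-vs-nuclear comparison on the philopatric low-K history.

    Runs the mitochondrial mode (haploid, asymmetric admixture) and, with the
    same seed and world, a nuclear-mode trace (diploid, symmetric low
    admixture) on a matching history, returning both north-minus-south
    frequency-difference summaries.
    """
    grid = inv.build_grid(inv.iberia_config())
    samples = co.default_samples(grid, n_lineages=1)

    mt_params = inv.mtdna_params()
    mt_hist = inv.run_forward(grid, mt_params, seed=_child_seed(seed, "mt", "fwd"))
    mt = co.simulate_mtdna(mt_hist, samples, mt_params, n_reps=n_reps,
                           seed=_child_seed(seed, "mt", "coal"),
                           empirical=empirical)

    nuc_params = inv.SimParams(K_G=250, K_T=125, G=0.5, M=0.005,
                               A_fd=0.005, A_df=0.005, mode="nuclear")
    nuc_hist = inv.run_forward(grid, nuc_params, seed=_child_seed(seed, "mt", "fwd"))
    nuc_samples = co.default_samples(grid, n_lineages=2)
    am = co.trace_ancestry(nuc_hist, nuc_samples, nuc_params,
                           seed=_child_seed(seed, "nuc", "coal"),
                           n_markers=max(200, n_reps))
    per_pop = stats.individual_proportions(am) / 100.0
    nuc_diff = float(per_pop[5:].mean() - per_pop[:5].mean())
    return {
        "mtdna": mt,
        "mt_north_south_diff": mt["north_south_diff"],
        "nuclear_per_population": per_pop,
        "nuclear_north_south_diff": nuc_diff,
    }
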