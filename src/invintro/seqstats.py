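"""Sequence-level statistics and the gene-alignment filter cascade.

Diversity statistics operate on aligned haplotype byte matrices: nucleotide
diversity pi (mean pairwise difference per accessible site within a species),
uncorrected interspecific distance (mean cross-species pairwise difference),
and Hudson's FST (1 - within/between diversity, computed from allele
frequencies with sample-size correction and averaged genome-wide as a ratio
of means).

The gene filter cascade reproduces a conservative coding-alignment cleanup:
triallelic sites masked, alignments with strong Hardy-Weinberg distortion
discarded (paralogy guard), high-missingness sequences dropped, introgressed
focal haplotypes excluded, poorly covered sites masked, and finally short or
stop-containing alignments rejected.  Surviving alignments feed the
Nei-Gojobori/Jukes-Cantor pairwise dN/dS estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, log

import numpy as np

MISSING = ord("N")
STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _codon_aa(codon: str) -> str:
    """Amino acid of a codon (standard code), '*' for stops."""
    if not _CODON_TABLE:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        for c, aa in table.forward_table.items():
            _CODON_TABLE[c] = aa
        for c in table.stop_codons:
            _CODON_TABLE[c] = "*"
    return _CODON_TABLE.get(codon, "X")


def _as_matrix(haps) -> np.ndarray:
    arr = np.asarray(haps)
    if arr.dtype != np.uint8:
        if arr.dtype.kind in "US":
            arr = np.array([np.frombuffer(str(s).upper().encode(), dtype=np.uint8)
                            for s in haps])
        else:
            arr = arr.astype(np.uint8)
    return arr


# ---------------------------------------------------------------------------
# diversity / divergence / FST


@dataclass
class DiversityResult:
    pi_a: float
    pi_b: float
    dxy: float
    fst_mean: float
    fst_per_site: np.ndarray
    n_accessible: int


def _pairwise_pi(mat: np.ndarray, acc: np.ndarray) -> float:
    sub = mat[:, acc]
    n = sub.shape[0]
    tot = 0
    for i in range(n):
        tot += (sub[i + 1:] != sub[i]).sum()
    return tot / comb(n, 2) / acc.sum() if n >= 2 else 0.0


def diversity(haps_a, haps_b, accessible=None) -> DiversityResult:
    """pi per species, uncorrected interspecific distance, Hudson FST.

    FST per site is Hudson's ``1 - Hw/Hb`` with ``Hw`` the mean within-species
    heterozygosity and ``Hb`` the between-species heterozygosity at the site;
    the genome-wide mean is the ratio of means (``1 - sum(Hw)/sum(Hb)``) over
    polymorphic accessible sites, negatives left untruncated.  Requires >= 2
    haplotypes per species.
    """
    a = _as_matrix(haps_a)
    b = _as_matrix(haps_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes per species for FST")
    if a.shape[1] != b.shape[1]:
        raise ValueError("alignments differ in length")
    L = a.shape[1]
    acc = np.ones(L, dtype=bool) if accessible is None else np.asarray(accessible, bool)
    acc = acc & (a != MISSING).all(axis=0) & (b != MISSING).all(axis=0)
    n_acc = int(acc.sum())
    if n_acc == 0:
        raise ValueError("no accessible sites")

    pi_a = _pairwise_pi(a, acc)
    pi_b = _pairwise_pi(b, acc)
    dxy = float((a[:, acc][:, None, :] != b[:, acc][None, :, :]).mean())

    # Hudson FST from biallelic frequencies; use the major allele of the
    # pooled sample as reference at each accessible site
    sub_a, sub_b = a[:, acc], b[:, acc]
    pooled = np.concatenate([sub_a, sub_b], axis=0)
    ref = pooled[0]  # arbitrary reference allele per site
    p1 = (sub_a == ref).mean(axis=0)
    p2 = (sub_b == ref).mean(axis=0)
    hw = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    poly = hb > 0
    fst_site = np.full(n_acc, np.nan)
    fst_site[poly] = 1.0 - hw[poly] / hb[poly]
    fst_mean = float(1.0 - hw[poly].sum() / hb[poly].sum()) if poly.any() else float("nan")
    return DiversityResult(pi_a=float(pi_a), pi_b=float(pi_b), dxy=dxy,
                           fst_mean=fst_mean, fst_per_site=fst_site,
                           n_accessible=n_acc)


# ---------------------------------------------------------------------------
# exact Hardy-Weinberg test


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional enumeration).

    Enumerates all heterozygote counts compatible with the observed allele
    counts; the p value sums the probabilities of configurations no more
    likely than the observed one (probability-mass ordering).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_Aa          # minor-ish allele count
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # P(het = h | allele counts) over h with h ≡ rare (mod 2)
    hs = np.arange(rare % 2, rare + 1, 2)
    logp = np.empty(len(hs))
    from scipy.special import gammaln

    def lfact(x):
        return gammaln(np.asarray(x) + 1.0)

    common = 2 * n - rare
    for k, h in enumerate(hs):
        n_rr = (rare - h) // 2
        n_cc = n - n_rr - h
        logp[k] = (h * log(2) + lfact(n) - lfact(n_rr) - lfact(h) - lfact(n_cc)
                   + lfact(rare) + lfact(common) - lfact(2 * n))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_Aa
    p_obs = p[hs == obs][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# gene-alignment filter cascade


@dataclass
class GeneAlignment:
    """Codon-aligned haplotype sequences per species with a filter log."""

    gene_id: str
    seqs: dict                      # species -> list[(name, str)]
    filter_log: list = field(default_factory=list)

    def length(self) -> int:
        for recs in self.seqs.values():
            if recs:
                return len(recs[0][1])
        return 0


class AlignmentRejected(Exception):
    """The alignment failed the cascade; ``.log`` lists the reasons."""

    def __init__(self, gene_id: str, log):
        self.gene_id = gene_id
        self.log = log
        super().__init__(f"{gene_id}: rejected ({log[-1][0]})")


def filter_gene_alignment(gene_id: str, seqs: dict, introgressed=(),
                          focal: str = "focal", donor: str = "donor",
                          outgroup: str = "outgroup", hwe_alpha: float = 0.01,
                          min_codons: int = 100) -> GeneAlignment:
    """Apply the coding-alignment filter cascade, in its stated order.

    1. sites with more than two alleles masked;
    2. alignment discarded if any SNP deviates from Hardy-Weinberg
       proportions at p < ``hwe_alpha`` in the focal or donor species
       (possible paralog collapse);
    3. sequences with > 50% missing data removed;
    4. focal haplotypes listed in ``introgressed`` (donor-origin) excluded;
    5. sites with < 4 informative haplotypes in focal or donor, or with no
       outgroup information, masked;
    6. rejection if fewer than ``min_codons`` comparable codons remain or a
       premature stop codon survives.

    Raises :class:`AlignmentRejected` on discard; otherwise returns the
    filtered :class:`GeneAlignment` with a log of every removal.
    """
    log = []
    mats = {sp: _as_matrix([s for _, s in recs]) for sp, recs in seqs.items()}
    names = {sp: [n for n, _ in recs] for sp, recs in seqs.items()}
    L = next(iter(mats.values())).shape[1]
    if L % 3:
        raise ValueError("alignment length must be a multiple of 3")

    # 1. multi-allelic sites
    pooled = np.concatenate(list(mats.values()), axis=0)
    n_alleles = np.zeros(L, dtype=int)
    for base in b"ACGT":
        n_alleles += (pooled == base).any(axis=0)
    multi = n_alleles > 2
    if multi.any():
        for sp in mats:
            mats[sp][:, multi] = MISSING
        log.append(("multiallelic_sites_masked", int(multi.sum())))

    # 2. Hardy-Weinberg screen per species (haplotypes paired into diploids)
    for sp in (focal, donor):
        mat = mats.get(sp)
        if mat is None or mat.shape[0] < 4:
            continue
        n_dip = mat.shape[0] // 2
        g1 = mat[0:2 * n_dip:2]
        g2 = mat[1:2 * n_dip:2]
        for site in np.nonzero(((mat != MISSING).all(axis=0)) & (n_alleles == 2))[0]:
            alleles = np.unique(mat[:, site])
            A = alleles[0]
            a1 = g1[:, site] == A
            a2 = g2[:, site] == A
            nAA = int(np.sum(a1 & a2))
            naa = int(np.sum(~a1 & ~a2))
            nAa = n_dip - nAA - naa
            if hwe_exact(nAA, nAa, naa) < hwe_alpha:
                log.append(("hwe_deviation_discard", f"{sp}:site{site}"))
                raise AlignmentRejected(gene_id, log)

    # 3. high-missingness sequences
    for sp in list(mats):
        keep = (mats[sp] == MISSING).mean(axis=1) <= 0.5
        if not keep.all():
            log.append(("missingness_removed",
                        [names[sp][i] for i in np.nonzero(~keep)[0]]))
            mats[sp] = mats[sp][keep]
            names[sp] = [n for n, k in zip(names[sp], keep) if k]

    # 4. introgressed focal haplotypes
    if introgressed and focal in mats:
        keep = [n not in set(introgressed) for n in names[focal]]
        if not all(keep):
            log.append(("introgressed_excluded",
                        [n for n, k in zip(names[focal], keep) if not k]))
            mats[focal] = mats[focal][np.array(keep)]
            names[focal] = [n for n, k in zip(names[focal], keep) if k]

    # 5. under-covered sites
    def n_info(sp):
        return (mats[sp] != MISSING).sum(axis=0) if sp in mats and len(mats[sp]) \
            else np.zeros(L, dtype=int)

    bad = (n_info(focal) < 4) | (n_info(donor) < 4) | (n_info(outgroup) < 1)
    if bad.any():
        for sp in mats:
            mats[sp][:, bad] = MISSING
        log.append(("undercovered_sites_masked", int(bad.sum())))

    # 6. length and premature stops on comparable codons
    codon_ok = np.ones(L // 3, dtype=bool)
    for sp in (focal, donor):
        if sp in mats and len(mats[sp]):
            codon_ok &= ((mats[sp] != MISSING).all(axis=0)).reshape(-1, 3).all(axis=1)
    n_codons = int(codon_ok.sum())
    if n_codons < min_codons:
        log.append(("too_short", n_codons))
        raise AlignmentRejected(gene_id, log)
    for sp in mats:
        for row in mats[sp]:
            s = row.tobytes().decode()
            for c in range(0, L - 3, 3):
                cod = s[c:c + 3]
                if cod in STOP_CODONS:
                    log.append(("premature_stop", f"{sp}:{c}"))
                    raise AlignmentRejected(gene_id, log)

    out = {sp: list(zip(names[sp], [r.tobytes().decode() for r in mats[sp]]))
           for sp in mats}
    return GeneAlignment(gene_id=gene_id, seqs=out, filter_log=log)


# ---------------------------------------------------------------------------
# Nei-Gojobori / Jukes-Cantor dN/dS


def _codon_sites(codon: str):
    """Synonymous/non-synonymous site counts of one codon (NG86).

    Each position contributes the fraction of its three possible changes that
    are synonymous; changes to stop codons count as non-synonymous.
    """
    aa = _codon_aa(codon)
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if _codon_aa(mut) == aa and _codon_aa(mut) != "*":
                s += 1.0 / 3.0
    return s, 3.0 - s


def _codon_differences(c1: str, c2: str):
    """Synonymous/non-synonymous difference counts between two codons,
    averaged over all minimal mutational pathways (NG86)."""
    from itertools import permutations

    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd = nd = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        path_s = path_n = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _codon_aa(nxt) == _codon_aa(cur):
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        sd += path_s
        nd += path_n
        n_paths += 1
    return sd / n_paths, nd / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 distance ``-3/4 ln(1 - 4p/3)``; undefined (ValueError) at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError("Jukes-Cantor correction undefined for p >= 3/4")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairDnDs:
    dn: float | None
    ds: float | None
    pn: float
    ps: float
    S: float
    N: float
    defined: bool


def pairwise_dnds(seq_a: str, seq_b: str) -> PairDnDs:
    """Nei-Gojobori counting with Jukes-Cantor correction for one pair.

    Codons containing missing data in either sequence are skipped.  When a
    proportion reaches the Jukes-Cantor singularity (p >= 3/4) the pair is
    flagged undefined so gene-level aggregation can exclude and count it.
    """
    a, b = str(seq_a).upper(), str(seq_b).upper()
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be equal-length codon alignments")
    S = N = sd = nd = 0.0
    for i in range(0, len(a), 3):
        c1, c2 = a[i:i + 3], b[i:i + 3]
        if "N" in c1 or "N" in c2 or "-" in c1 or "-" in c2:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        dsd, dnd = _codon_differences(c1, c2)
        sd += dsd
        nd += dnd
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    try:
        ds = jukes_cantor(ps)
        dn = jukes_cantor(pn)
        return PairDnDs(dn=dn, ds=ds, pn=pn, ps=ps, S=S, N=N, defined=True)
    except ValueError:
        return PairDnDs(dn=None, ds=None, pn=pn, ps=ps, S=S, N=N, defined=False)


@dataclass
class DnDsResult:
    dn: float
    ds: float
    dnds: float
    n_pairs: int
    n_excluded: int


def gene_dnds(alignment: GeneAlignment, focal: str = "focal",
              donor: str = "donor") -> DnDsResult:
    """Average-of-pairs dN/dS between the focal and donor species.

    Pairs with undefined Jukes-Cantor correction or dS = 0 (ratio undefined)
    are excluded and counted.
    """
    pairs = []
    excluded = 0
    for _, sa in alignment.seqs.get(focal, []):
        for _, sb in alignment.seqs.get(donor, []):
            r = pairwise_dnds(sa, sb)
            if not r.defined or r.ds == 0:
                excluded += 1
                continue
            pairs.append(r)
    if not pairs:
        return DnDsResult(dn=float("nan"), ds=float("nan"), dnds=float("nan"),
                          n_pairs=0, n_excluded=excluded)
    dn = float(np.mean([r.dn for r in pairs]))
    ds = float(np.mean([r.ds for r in pairs]))
    ratio = float(np.mean([r.dn / r.ds for r in pairs]))
    return DnDsResult(dn=dn, ds=ds, dnds=ratio, n_pairs=len(pairs),
                      n_excluded=excluded)


# ---------------------------------------------------------------------------
# mutation rate


def mutation_rate(D_XY: float, T_D_generations: float, Ne: float) -> float:
    """Per-generation mutation rate ``mu = D_XY / (2*T_D + 4*Ne)``.

    ``D_XY`` is the mean autosomal divergence to a distant outgroup lineage,
    ``T_D_generations`` the split time in generations, ``Ne`` the ancestral
    effective population size (the ``4*Ne`` term absorbs ancestral
    coalescence time).
    """
    if D_XY <= 0 or T_D_generations <= 0 or Ne < 0:
        raise ValueError("inputs must be positive (Ne non-negative)")
    return D_XY / (2.0 * T_D_generations + 4.0 * Ne)
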