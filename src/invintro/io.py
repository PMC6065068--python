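"""File IO: FASTA haplotype alignments, BED tracts, plain-text VCF output,
and TSV tables for the simulator results."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tracts import Tract


def write_haplotypes(path, names, matrix) -> None:
    """Write an aligned haplotype byte matrix as FASTA (one record per haplotype)."""
    matrix = np.asarray(matrix, dtype=np.uint8)
    records = [SeqRecord(Seq(row.tobytes().decode()), id=str(name), description="")
               for name, row in zip(names, matrix)]
    SeqIO.write(records, str(path), "fasta")


def read_haplotypes(path):
    """Read an aligned FASTA into (names, (n_hap, L) uint8 matrix)."""
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8))
    if not rows:
        raise ValueError(f"no sequences in {path}")
    L = {len(r) for r in rows}
    if len(L) != 1:
        raise ValueError("haplotypes are not aligned (unequal lengths)")
    return names, np.stack(rows)


def write_bed(path, tracts: list[Tract]) -> None:
    """Tracts as BED (0-based half-open); name column carries hap/state."""
    with open(path, "w") as fh:
        for t in tracts:
            name = f"{t.hap}" if t.hap is not None else "."
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t0\t+\t{t.state}\n")


def read_bed(path) -> list[Tract]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            hap = parts[3] if len(parts) > 3 and parts[3] != "." else None
            if hap is not None:
                try:
                    hap = int(hap)
                except ValueError:
                    pass
            state = parts[6] if len(parts) > 6 else "DONOR"
            out.append(Tract(chrom=chrom, start=start, end=end, hap=hap, state=state))
    return out


def write_vcf(path, chrom_matrices: dict, sample_names: list[str]) -> None:
    """Write diploid genotypes (haplotype pairs) at variable sites as VCF.

    ``chrom_matrices`` maps chromosome -> (2*n_samples, L) haplotype matrix;
    haplotypes 2i, 2i+1 form individual i, phased.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, mat in chrom_matrices.items():
            fh.write(f"##contig=<ID={chrom},length={mat.shape[1]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        for chrom, mat in chrom_matrices.items():
            mat = np.asarray(mat, dtype=np.uint8)
            var_sites = np.nonzero((mat != mat[0]).any(axis=0))[0]
            for pos in var_sites:
                col = mat[:, pos]
                alleles = [chr(b) for b in pd.unique(col)]
                ref, alts = alleles[0], alleles[1:]
                code = {ord(a): i for i, a in enumerate(alleles)}
                gts = []
                for i in range(0, len(col), 2):
                    gts.append(f"{code[col[i]]}|{code[col[i + 1]]}")
                fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t.\t"
                         f"PASS\t.\tGT\t" + "\t".join(gts) + "\n")


def synth_to_files(data, outdir) -> dict:
    """Write a :class:`invintro.synth.SynthData` bundle to FASTA/VCF/BED."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for species in ("focal", "donor", "outgroup"):
        mats = getattr(data, species)
        for chrom, mat in mats.items():
            p = outdir / f"{species}_{chrom}.fa"
            write_haplotypes(p, [f"{species}_h{i}" for i in range(mat.shape[0])], mat)
            paths[f"{species}_{chrom}"] = p
    n_ind = data.plan.n_focal // 2
    vcf = outdir / "focal.vcf"
    write_vcf(vcf, data.focal, [f"ind{i}" for i in range(n_ind)])
    paths["vcf"] = vcf
    bed = outdir / "truth.bed"
    write_bed(bed, data.truth)
    paths["truth_bed"] = bed
    return paths
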