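"""Cohort sampling, genotype matrices, region masking, and PED/MAP/VCF IO.

At generation 0 a cohort of diploid individuals is drawn from the final
population states (either from a single deme or equally from all demes) and
its biallelic SNP dosages are assembled into a :class:`GenotypeMatrix`:
individuals x SNPs in {0, 1, 2} copies of the derived allele, with physical
and genetic positions and a chromosome label per SNP.  Each replicate
chromosome of a run is one "chromosome" of the cohort, and the same sampled
individual indices are reused across replicate chromosomes so that the
matrix mimics one genotyped cohort.

Coordinates are 0-based half-open internally; PLINK PED/MAP and VCF exports
are 1-based.  Alleles are written A (ancestral, REF) / T (derived),
unphased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .config import GenomeConfig, SampleSpec


class GenotypeError(ValueError):
    pass


class ParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path, self.line_no = str(path), line_no


@dataclass
class SampleDraw:
    """Indices of the sampled individuals (shared across chromosomes)."""

    indices: np.ndarray
    deme_ids: np.ndarray


@dataclass
class GenotypeMatrix:
    """Sampled cohort x biallelic-SNP dosage matrix."""

    dosages: np.ndarray            # (n_individuals, n_snps) uint8 in {0,1,2}
    positions_bp: np.ndarray       # int64, 0-based within chromosome
    chromosomes: np.ndarray        # int32, 1-based labels
    genetic_positions: np.ndarray  # Morgans
    sample_ids: list
    deme_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.uint8)
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        self.chromosomes = np.asarray(self.chromosomes, dtype=np.int32)
        self.genetic_positions = np.asarray(self.genetic_positions, dtype=float)
        self.deme_ids = np.asarray(self.deme_ids, dtype=np.int64)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != self.positions_bp.size:
            raise GenotypeError("dosage matrix and position vector disagree")
        key = self.chromosomes.astype(np.int64) * (self.positions_bp.max(initial=0) + 1) \
            + self.positions_bp
        if key.size and np.any(np.diff(key) <= 0):
            raise GenotypeError("SNP columns must be sorted by (chromosome, position)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_counts(self) -> np.ndarray:
        return self.dosages.sum(axis=0, dtype=np.int64)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_counts() / (2 * self.n_individuals)
        return np.minimum(p, 1 - p)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def draw_sample(states, spec: SampleSpec, rng) -> SampleDraw:
    """Draw the genotyped cohort from the final generation.

    Uniform sampling without replacement within each targeted deme; the
    same individual indices apply to every replicate chromosome.
    """
    sizes = states[0].deme_sizes
    for st in states[1:]:
        if st.deme_sizes != sizes:
            raise GenotypeError("replicate chromosomes disagree on deme sizes")
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    if spec.scheme == "single_deme":
        d = spec.focal_deme
        if d >= len(sizes):
            raise GenotypeError(f"focal deme {d} does not exist at generation 0")
        if sizes[d] < spec.total_sample:
            raise GenotypeError(
                f"deme {d} has {sizes[d]} individuals, fewer than the requested "
                f"{spec.total_sample}")
        idx = offsets[d] + rng.choice(sizes[d], size=spec.total_sample, replace=False)
        idx.sort()
        return SampleDraw(idx, np.full(idx.size, d, dtype=np.int64))
    # pooled_equal
    n_demes = len(sizes)
    if spec.total_sample % n_demes:
        raise GenotypeError(
            f"pooled_equal needs total_sample divisible by the {n_demes} demes")
    per = spec.total_sample // n_demes
    parts, demes = [], []
    for d in range(n_demes):
        if sizes[d] < per:
            raise GenotypeError(f"deme {d} has {sizes[d]} individuals, fewer than {per}")
        sub = offsets[d] + rng.choice(sizes[d], size=per, replace=False)
        sub.sort()
        parts.append(sub)
        demes.append(np.full(per, d, dtype=np.int64))
    return SampleDraw(np.concatenate(parts), np.concatenate(demes))


def build_genotype_matrix(states, draw: SampleDraw, genome: GenomeConfig,
                          maf_min: float = 0.05) -> GenotypeMatrix:
    """Assemble sampled haplotypes into a filtered dosage matrix.

    Keeps the union of positions segregating in the sample, removing sites
    with sample minor-allele frequency below ``maf_min`` (monomorphic sites
    always go).
    """
    idx = draw.indices
    n = idx.size
    blocks, pos_all, chrom_all = [], [], []
    for ci, st in enumerate(states):
        H = st.haplotypes
        dos = (H[2 * idx].astype(np.uint8) + H[2 * idx + 1]).astype(np.uint8)
        count = dos.sum(axis=0, dtype=np.int64)
        p = count / (2 * n)
        keep = (count > 0) & (count < 2 * n) & (np.minimum(p, 1 - p) >= maf_min)
        blocks.append(dos[:, keep])
        pos_all.append(st.positions[keep])
        chrom_all.append(np.full(int(keep.sum()), ci + 1, dtype=np.int32))
    dosages = np.concatenate(blocks, axis=1)
    if dosages.shape[1] == 0:
        raise GenotypeError(
            "no SNPs survive filtering; simulate a larger genome, more "
            "chromosomes, or lower maf_min")
    positions = np.concatenate(pos_all)
    chroms = np.concatenate(chrom_all)
    sample_ids = [f"ind{j}" for j in range(n)]
    return GenotypeMatrix(dosages, positions, chroms,
                          positions * genome.map_rate, sample_ids, draw.deme_ids)


def mask_region(gm: GenotypeMatrix, interval_bp) -> GenotypeMatrix:
    """Remove every SNP whose position lies inside the closed interval."""
    a, b = interval_bp
    keep = (gm.positions_bp < a) | (gm.positions_bp > b)
    return GenotypeMatrix(gm.dosages[:, keep], gm.positions_bp[keep],
                          gm.chromosomes[keep], gm.genetic_positions[keep],
                          list(gm.sample_ids), gm.deme_ids)


def subset_individuals(gm: GenotypeMatrix, rows, maf_min: float = 0.05) -> GenotypeMatrix:
    """Restrict the cohort to ``rows`` and re-filter monomorphic/low-MAF sites."""
    rows = np.asarray(rows)
    dos = gm.dosages[rows]
    n = rows.size
    count = dos.sum(axis=0, dtype=np.int64)
    p = count / (2 * n)
    keep = (count > 0) & (count < 2 * n) & (np.minimum(p, 1 - p) >= maf_min)
    if not keep.any():
        raise GenotypeError("no SNPs survive filtering in the restricted cohort")
    return GenotypeMatrix(dos[:, keep], gm.positions_bp[keep], gm.chromosomes[keep],
                          gm.genetic_positions[keep],
                          [gm.sample_ids[r] for r in rows], gm.deme_ids[rows])


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

_ALLELES = {0: "A A", 1: "A T", 2: "T T"}


def _snp_ids(gm: GenotypeMatrix):
    return [f"c{c}_p{p + 1}" for c, p in zip(gm.chromosomes, gm.positions_bp)]


def write_ped_map(gm: GenotypeMatrix, prefix) -> tuple:
    """Write PLINK text ``<prefix>.ped`` / ``<prefix>.map`` (unphased).

    MAP columns: chromosome, SNP id, genetic position in cM, 1-based bp.
    PED columns: FID (deme id) IID PAT MAT SEX PHENO then two allele columns
    per SNP.
    """
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    ids = _snp_ids(gm)
    with open(map_path, "w") as fh:
        for c, sid, g, p in zip(gm.chromosomes, ids, gm.genetic_positions,
                                gm.positions_bp):
            fh.write(f"{c}\t{sid}\t{g * 100:.8g}\t{p + 1}\n")
    lut = np.array([_ALLELES[0], _ALLELES[1], _ALLELES[2]])
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(gm.sample_ids):
            geno = " ".join(lut[gm.dosages[i]])
            fh.write(f"{gm.deme_ids[i]} {sid} 0 0 0 -9 {geno}\n")
    return ped_path, map_path


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read PLINK text PED/MAP back into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    chroms, positions, genetic = [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(map_path, ln, f"expected 4 columns, got {len(parts)}")
            try:
                chroms.append(int(parts[0]))
                genetic.append(float(parts[2]) / 100.0)
                positions.append(int(parts[3]) - 1)
            except ValueError as exc:
                raise ParseError(map_path, ln, str(exc)) from None
    n_snps = len(chroms)
    rows, sample_ids, deme_ids = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(ped_path, ln,
                                 f"expected {6 + 2 * n_snps} columns, got {len(parts)}")
            try:
                deme_ids.append(int(parts[0]))
            except ValueError:
                deme_ids.append(-1)
            sample_ids.append(parts[1])
            alleles = np.array(parts[6:])
            bad = ~np.isin(alleles, ("A", "T"))
            if bad.any():
                raise ParseError(ped_path, ln,
                                 f"unexpected allele {alleles[bad][0]!r}")
            rows.append((alleles == "T").reshape(-1, 2).sum(axis=1).astype(np.uint8))
    return GenotypeMatrix(np.vstack(rows), np.array(positions, dtype=np.int64),
                          np.array(chroms, dtype=np.int32), np.array(genetic),
                          sample_ids, np.array(deme_ids, dtype=np.int64))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> Path:
    """Write an unphased VCF v4.2 (REF = ancestral A, ALT = derived T)."""
    path = Path(path)
    ids = _snp_ids(gm)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=structne\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in np.unique(gm.chromosomes):
            length = int(gm.positions_bp[gm.chromosomes == c].max()) + 2
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.sample_ids) + "\n")
        for j, sid in enumerate(ids):
            gts = "\t".join(_GT[d] for d in gm.dosages[:, j])
            fh.write(f"{gm.chromosomes[j]}\t{gm.positions_bp[j] + 1}\t{sid}\t"
                     f"A\tT\t.\t.\t.\tGT\t{gts}\n")
    return path


def read_vcf(path, map_rate: float = 1e-8) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` (genetic positions derived
    from ``map_rate``, Morgans per bp)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    chroms, positions, rows = [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    lut = np.array([0, 1, 0, 2], dtype=np.uint8)
    for variant in vcf:
        chroms.append(int(variant.CHROM))
        positions.append(variant.POS - 1)
        rows.append(lut[variant.gt_types])
    vcf.close()
    if not rows:
        raise GenotypeError(f"no variants in {path}")
    positions = np.array(positions, dtype=np.int64)
    dosages = np.vstack(rows).T.astype(np.uint8)
    return GenotypeMatrix(dosages, positions, np.array(chroms, dtype=np.int32),
                          positions * map_rate, sample_ids,
                          np.full(len(sample_ids), -1, dtype=np.int64))
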