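"""Genotype data model and readers/writers for VCF, FASTA and population maps.

The central in-memory container is :class:`GenotypeMatrix`: diploid genotypes
for N individuals at S biallelic SNPs, coded as alt-allele dosages
(0/1/2, with -1 for missing), together with per-site metadata
(scaffold, 1-based position, ref/alt alleles, site QUAL) and optional
per-genotype depth (DP) and genotype quality (GQ) layers.

VCF reading goes through cyvcf2; writing emits a minimal VCF v4.2 by hand so
that round-trips are byte-predictable. Only biallelic SNP records are
retained on read; multi-allelic and non-SNP records are counted and reported.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

_SITE_COLUMNS = ["scaffold", "pos", "ref", "alt", "qual"]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for N individuals x S sites.

    Attributes
    ----------
    individuals : list of str
        Ordered sample labels (length N).
    sites : pandas.DataFrame
        One row per site with columns ``scaffold`` (str), ``pos`` (1-based
        int), ``ref``, ``alt`` (single ACGT bases) and ``qual`` (float).
        Sites are sorted by (scaffold, pos) and unique on that pair.
    genotypes : ndarray of int8, shape (N, S)
        Alt-allele dosage 0/1/2, or -1 for missing.
    dp, gq : ndarray of int32, shape (N, S), optional
        Per-genotype sequencing depth and genotype quality.
    """

    individuals: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, s = self.genotypes.shape
        if len(self.individuals) != n:
            raise ValueError(f"{len(self.individuals)} labels for {n} genotype rows")
        if len(self.sites) != s:
            raise ValueError(f"{len(self.sites)} site records for {s} genotype columns")
        valid = np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        for layer in (self.dp, self.gq):
            if layer is not None and layer.shape != (n, s):
                raise ValueError("DP/GQ layer shape mismatch")
        self.sites = self.sites.reset_index(drop=True)
        key = self.sites[["scaffold", "pos"]]
        if key.duplicated().any():
            raise ValueError("duplicate (scaffold, position) in site table")
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["scaffold"].to_numpy()))
        if not np.array_equal(order, np.arange(s)):
            self.sites = self.sites.iloc[order].reset_index(drop=True)
            self.genotypes = self.genotypes[:, order]
            if self.dp is not None:
                self.dp = self.dp[:, order]
            if self.gq is not None:
                self.gq = self.gq[:, order]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def is_missing(self) -> np.ndarray:
        return self.genotypes == MISSING

    def subset(self, individuals=None, site_mask=None) -> "GenotypeMatrix":
        """Restrict to the given individuals and/or a boolean site mask."""
        gm = self
        if individuals is not None:
            idx = [gm.individuals.index(i) for i in individuals]
            gm = GenotypeMatrix(
                [gm.individuals[i] for i in idx],
                gm.sites.copy(),
                gm.genotypes[idx],
                None if gm.dp is None else gm.dp[idx],
                None if gm.gq is None else gm.gq[idx],
            )
        if site_mask is not None:
            site_mask = np.asarray(site_mask, dtype=bool)
            gm = GenotypeMatrix(
                list(gm.individuals),
                gm.sites[site_mask].reset_index(drop=True),
                gm.genotypes[:, site_mask],
                None if gm.dp is None else gm.dp[:, site_mask],
                None if gm.gq is None else gm.gq[:, site_mask],
            )
        return gm

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individuals),
            self.sites.copy(),
            self.genotypes.copy(),
            None if self.dp is None else self.dp.copy(),
            None if self.gq is None else self.gq.copy(),
        )


def subset(gm: GenotypeMatrix, individuals=None, site_mask=None) -> GenotypeMatrix:
    """Functional alias for :meth:`GenotypeMatrix.subset`."""
    return gm.subset(individuals=individuals, site_mask=site_mask)


@dataclass
class PopulationMap:
    """Mapping individual label -> population label."""

    mapping: dict[str, str]
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for pop in self.mapping.values():
            if pop not in seen:
                seen.append(pop)
        if not self.populations:
            self.populations = seen
        missing = set(seen) - set(self.populations)
        if missing:
            raise ValueError(f"populations {missing} mapped but not listed")

    def individuals(self, population: str) -> list[str]:
        out = [ind for ind, pop in self.mapping.items() if pop == population]
        if not out:
            raise ValueError(f"population {population!r} has no individuals")
        return out

    def indices(self, gm: GenotypeMatrix, population: str) -> np.ndarray:
        """Row indices in ``gm`` of the individuals of ``population``."""
        labels = self.individuals(population)
        absent = [i for i in labels if i not in gm.individuals]
        if absent:
            raise ValueError(f"individuals {absent} not present in matrix")
        return np.array([gm.individuals.index(i) for i in labels], dtype=int)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        absent = [i for i in self.mapping if i not in gm.individuals]
        if absent:
            raise ValueError(f"individuals {absent} not present in matrix")


def read_popmap(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "population"], dtype=str)
    return PopulationMap(dict(zip(df["individual"], df["population"])))


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for ind, pop in popmap.mapping.items():
            fh.write(f"{ind}\t{pop}\n")


@dataclass
class SeqAlignment:
    """Equal-length nucleotide sequences over the alphabet ACGTN-."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels/sequences length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        alphabet = set("ACGTN-")
        for lab, seq in zip(self.labels, self.sequences):
            bad = set(seq) - alphabet
            if bad:
                raise ValueError(f"sequence {lab!r} contains invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def as_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


def read_fasta(path) -> SeqAlignment:
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    return SeqAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: SeqAlignment, path, width: int = 70) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for lab, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{lab}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class VcfReadReport:
    """Tally of records handled while reading a VCF."""

    retained: int = 0
    multiallelic: int = 0
    non_snp: int = 0


def read_vcf(path, report: VcfReadReport | None = None) -> GenotypeMatrix:
    """Read a VCF v4.2 into a :class:`GenotypeMatrix`.

    Only biallelic SNP records (single ACGT ref and alt) are retained;
    others are tallied in ``report``. Phased separators are treated as
    unphased, and half-missing genotypes as fully missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    if report is None:
        report = VcfReadReport()
    bases = {"A", "C", "G", "T"}
    scaff, pos, ref, alt, qual = [], [], [], [], []
    gts, dps, gqs = [], [], []
    has_dp = "DP" in vcf
    has_gq = "GQ" in vcf
    for v in vcf:
        if len(v.ALT) != 1:
            report.multiallelic += 1
            continue
        if v.REF not in bases or v.ALT[0] not in bases:
            report.non_snp += 1
            continue
        report.retained += 1
        scaff.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        qual.append(np.nan if v.QUAL is None else float(v.QUAL))
        # gts012: 0/1/2 = alt dosage, 3 = unknown; half-missing calls
        # (one absent allele) are demoted to fully missing
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        alleles = np.asarray(v.genotypes, dtype=np.int8)
        g[(alleles[:, :2] == -1).any(axis=1)] = MISSING
        gts.append(g)
        if has_dp:
            d = v.format("DP")
            dps.append(np.full(len(individuals), -1, np.int32) if d is None else d[:, 0])
        if has_gq:
            q = v.format("GQ")
            gqs.append(np.full(len(individuals), -1, np.int32) if q is None else q[:, 0])
    n = len(individuals)
    if report.retained == 0:
        genotypes = np.zeros((n, 0), dtype=np.int8)
        dp = gq = None
    else:
        genotypes = np.stack(gts, axis=1)
        dp = np.stack(dps, axis=1).astype(np.int32) if has_dp and dps else None
        gq = np.stack(gqs, axis=1).astype(np.int32) if has_gq and gqs else None
    sites = pd.DataFrame(
        {"scaffold": scaff, "pos": pos, "ref": ref, "alt": alt, "qual": qual},
        columns=_SITE_COLUMNS,
    )
    return GenotypeMatrix(individuals, sites, genotypes, dp, gq)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT[:DP[:GQ]]; missing genotype './.')."""
    opener = gzip.open if str(path).endswith(".gz") else open
    fmt_fields = ["GT"]
    if gm.dp is not None:
        fmt_fields.append("DP")
    if gm.gq is not None:
        fmt_fields.append("GQ")
    fmt = ":".join(fmt_fields)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if gm.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for contig in pd.unique(gm.sites["scaffold"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.individuals) + "\n")
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            q = row["qual"]
            qual = "." if pd.isna(q) else (f"{q:g}" if q != int(q) else str(int(q)))
            cols = [str(row["scaffold"]), str(row["pos"]), ".", row["ref"], row["alt"], qual, ".", ".", fmt]
            for i in range(gm.n_individuals):
                parts = [gt_str[int(gm.genotypes[i, j])]]
                if gm.dp is not None:
                    parts.append(str(int(gm.dp[i, j])))
                if gm.gq is not None:
                    parts.append(str(int(gm.gq[i, j])))
                cols.append(":".join(parts))
            fh.write("\t".join(cols) + "\n")
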