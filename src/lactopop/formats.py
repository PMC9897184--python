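"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 1-based inclusive internally, matching VCF and
GFF3.  Any half-open conversion happens only inside a computation and is
documented on the operation that does it.

The central container is :class:`VariantTable`, a multi-sample haploid
genotype matrix over reference positions.  Genotypes are stored as allele
indices (0 = reference, 1.. = alternate) with ``-1`` marking a missing call.
Diploid-called strains can be ingested in ``haploid_mode``: heterozygous
genotypes are recorded in ``het_flags`` and collapsed to missing, which is
what downstream per-strain statistics expect for a haplontic organism whose
rare diploids carry <1% heterozygous calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "VariantTable",
    "GeneAnnotation",
    "SequenceSet",
    "read_vcf",
    "write_vcf",
    "read_gff",
    "write_gff",
    "read_freec_segments",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class VariantTable:
    """Multi-sample haploid genotype matrix over reference positions.

    Attributes
    ----------
    sample_names : list of str
        Ordered strain identifiers.
    chrom : ndarray of object
        Chromosome name per site.
    pos : ndarray of int
        1-based position per site, strictly increasing within a chromosome.
    ref : ndarray of object
        Reference allele per site.
    alt : list of tuple of str
        Alternate alleles per site (index 1.. in the genotype matrix).
    genotypes : ndarray of int16, shape (n_sites, n_samples)
        Allele indices; ``MISSING`` (-1) marks an absent call.
    het_flags : ndarray of bool or None
        Marks calls that were heterozygous in a diploid-called input.
    """

    sample_names: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: list[tuple[str, ...]]
    genotypes: np.ndarray
    het_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ref = np.asarray(self.ref, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.shape != (self.n_sites, self.n_samples):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{self.n_sites} sites x {self.n_samples} samples"
            )
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        n_alleles = np.fromiter((1 + len(a) for a in self.alt), dtype=np.int64,
                                count=self.n_sites)
        bad = (self.genotypes >= n_alleles[:, None]) | (
            (self.genotypes < 0) & (self.genotypes != MISSING)
        )
        if bad.any():
            raise ValueError("genotype matrix contains invalid allele indices")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def sample_index(self, names) -> np.ndarray:
        """Column indices for the given sample names (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.sample_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"unknown sample name: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene feature; ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SequenceSet:
    """Named nucleotide sequences over the alphabet {A, C, G, T, N}."""

    sequences: dict[str, str] = field(default_factory=dict)

    _ALPHABET = frozenset("ACGTN")

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            extra = set(seq.upper()) - self._ALPHABET
            if extra:
                raise ValueError(
                    f"sequence {name!r} contains letters outside ACGTN: {sorted(extra)}"
                )
            self.sequences[name] = seq.upper()

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def names(self) -> list[str]:
        return list(self.sequences)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path, haploid_mode: bool = True, snps_only: bool = False) -> VariantTable:
    """Read a VCF v4.x file with GT fields into a :class:`VariantTable`.

    In ``haploid_mode`` diploid genotype calls are collapsed: homozygous
    calls keep their allele, heterozygous calls are flagged in ``het_flags``
    and recorded as missing.  Multi-allelic sites are kept with alternate
    indices preserved.  With ``snps_only`` sites whose ref or any called alt
    allele is longer than 1 bp are dropped (diversity statistics use SNPs).
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    gt_rows: list[list[int]] = []
    het_rows: list[list[bool]] = []
    for rec in vcf:
        alt_alleles = tuple(a for a in (rec.alts or ()))
        if snps_only:
            if len(rec.ref) != 1 or any(len(a) != 1 for a in alt_alleles):
                continue
        row: list[int] = []
        het: list[bool] = []
        if len(rec.samples) != len(samples):
            raise FormatError(
                f"{path}:{rec.chrom}:{rec.pos}: sample count mismatch"
            )
        for s in samples:
            alleles = rec.samples[s].get("GT", (None,))
            called = [a for a in alleles if a is not None]
            if not called:
                row.append(MISSING)
                het.append(False)
            elif len(set(called)) > 1:
                # heterozygous diploid call
                if haploid_mode:
                    row.append(MISSING)
                    het.append(True)
                else:
                    row.append(called[0])
                    het.append(True)
            else:
                row.append(called[0])
                het.append(False)
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(rec.ref)
        alts.append(alt_alleles)
        gt_rows.append(row)
        het_rows.append(het)
    vcf.close()
    n_sites = len(positions)
    genotypes = (
        np.array(gt_rows, dtype=np.int16)
        if n_sites
        else np.zeros((0, len(samples)), dtype=np.int16)
    )
    het_flags = (
        np.array(het_rows, dtype=bool)
        if n_sites
        else np.zeros((0, len(samples)), dtype=bool)
    )
    return VariantTable(
        sample_names=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=alts,
        genotypes=genotypes,
        het_flags=het_flags,
    )


def write_vcf(table: VariantTable, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`VariantTable` as a minimal haploid VCF v4.2 file."""
    if contig_lengths is None:
        contig_lengths = {}
        for c in pd.unique(table.chrom):
            contig_lengths[str(c)] = int(table.pos[table.chrom == c].max()) + 1
    lines = ["##fileformat=VCFv4.2"]
    for c, length in contig_lengths.items():
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.sample_names)
    )
    for i in range(table.n_sites):
        alt = ",".join(table.alt[i]) if table.alt[i] else "."
        gts = [
            "." if g == MISSING else str(int(g)) for g in table.genotypes[i]
        ]
        lines.append(
            f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t{alt}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Read features of one type from a GFF3 file.

    Coordinates are kept 1-based inclusive; the ``ID`` attribute becomes
    ``gene_id``.  A missing ``ID`` or a duplicated one is an error.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            if fields[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise FormatError(f"{path}:{lineno}: {feature_type} record lacks ID attribute")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate ID {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                )
            )
    return genes


def write_gff(genes: list[GeneAnnotation], path, source: str = "lactopop") -> None:
    """Write gene annotations as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Control-FREEC-style segment tables

def read_freec_segments(path):
    """Read a Control-FREEC-style segment table.

    Expected columns (tab-separated, with or without a header line):
    chromosome, start, end, predicted copy number.  Returns a
    :class:`~lactopop.cnvscan.CopyNumberSegments` sorted by (chrom, start).
    Overlapping segments are tolerated (real segmenters occasionally emit
    them) and logged; downstream gene assignment resolves them.
    """
    from .cnvscan import CopyNumberSegments, Segment

    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected >= 4 tab-separated columns")
    # Drop a header row if the numeric columns fail to parse there.
    first = df.iloc[0]
    try:
        int(first[1]), int(first[2]), float(first[3])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    segments = []
    for _, row in df.iterrows():
        try:
            start, end = int(row[1]), int(row[2])
            cn = float(row[3])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric segment fields in row {tuple(row)}") from exc
        if cn != int(cn) or cn < 0:
            raise FormatError(f"{path}: copy number {cn} is not a non-negative integer")
        segments.append(Segment(str(row[0]), start, end, int(cn)))
    segments.sort(key=lambda s: (s.chrom, s.start, s.end))
    for a, b in zip(segments, segments[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            logger.warning("overlapping segments %s and %s accepted", a, b)
    return CopyNumberSegments(strain=str(path), segments=segments)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    """Write a :class:`SequenceSet` as FASTA."""
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path) -> None:
    """Write a tree (dendropy.Tree) as a Newick file."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_newick(path):
    """Read a Newick file into an unrooted dendropy Tree."""
    import dendropy

    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Generic TSV tables

def read_table(path, **kwargs) -> pd.DataFrame:
    """Read a TSV table with a header row."""
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read table {path}: {exc}") from exc


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a DataFrame as a TSV table with a header row."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
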