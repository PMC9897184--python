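"""Diversity and divergence statistics on haploid genotype matrices.

Implements the classical summary statistics for a haploid SNP cohort:
segregating sites S, nucleotide diversity pi (mean per-site pairwise
difference), Watterson's theta ``S / (a_n * L)``, Tajima's D with the
standard 1989 variance constants, per-pair divergence (differing sites over
total genome size), Hudson-style F_ST ``1 - Hw/Hb``, per-strain consensus
sequences, and the heterozygosity-based ploidy sanity check.

Missing-data convention: a site missing in either member of a pair is
skipped for that pair; denominators (L, genome_length) are NOT adjusted,
matching a fixed-genome-size divergence definition.  All per-site statistics
normalize by the surveyed length L, which for cohort-level work defaults to
the reference genome length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .formats import MISSING, SequenceSet, VariantTable

__all__ = [
    "DiversitySummary",
    "DistanceMatrix",
    "segregating_sites",
    "nucleotide_diversity",
    "watterson_theta",
    "harmonic_number",
    "tajimas_d",
    "diversity_summary",
    "consensus_sequences",
    "pairwise_divergence_matrix",
    "hudson_fst",
    "heterozygosity_fraction",
]


@dataclass
class DiversitySummary:
    """Summary of diversity statistics for one sample set.

    ``tajimas_d`` is ``nan`` (the undefined marker) when S = 0.
    """

    n: int
    L: int
    S: int
    pi: float
    theta_w: float
    tajimas_d: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.pi < 0 or self.theta_w < 0:
            raise ValueError("S, pi and theta_w must be non-negative")
        if self.S == 0 and (self.pi != 0 or self.theta_w != 0):
            raise ValueError("S = 0 requires pi = theta_w = 0")


@dataclass
class DistanceMatrix:
    """Symmetric per-site divergence matrix over named strains."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match name count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("divergences must be non-negative")

    def submatrix(self, names) -> "DistanceMatrix":
        idx = [self.names.index(n) for n in names]
        return DistanceMatrix(list(names), self.values[np.ix_(idx, idx)])

    def to_phylip(self, path) -> None:
        """Write as a PHYLIP square distance matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.names)}\n")
            for name, row in zip(self.names, self.values):
                fh.write(name + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            names, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                names.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(names, np.array(rows))


def _subset_genotypes(table: VariantTable, samples) -> np.ndarray:
    if samples is None:
        return table.genotypes
    idx = table.sample_index(samples)
    if idx.size == 0:
        raise ValueError("sample subset is empty")
    return table.genotypes[:, idx]


def segregating_sites(table: VariantTable, samples=None) -> int:
    """Number of sites with >= 2 distinct non-missing alleles in the subset."""
    g = _subset_genotypes(table, samples)
    if g.shape[0] == 0:
        return 0
    valid = g != MISSING
    big = np.where(valid, g, np.iinfo(np.int16).max)
    small = np.where(valid, g, np.iinfo(np.int16).min)
    return int(np.sum((big.min(axis=1) != small.max(axis=1)) & valid.any(axis=1)))


def _pair_diff_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise differing-site counts for all column pairs.

    Returns (n_samples x n_samples) matrices of differing-site counts and of
    jointly-called site counts.  Sites missing in either member are skipped
    for that pair.
    """
    n = g.shape[1]
    diffs = np.zeros((n, n), dtype=np.int64)
    called = np.zeros((n, n), dtype=np.int64)
    valid = g != MISSING
    for i in range(n):
        vi = valid[:, i]
        gi = g[:, i]
        both = vi[:, None] & valid[:, i + 1 :]
        diffs_i = ((gi[:, None] != g[:, i + 1 :]) & both).sum(axis=0)
        diffs[i, i + 1 :] = diffs_i
        called[i, i + 1 :] = both.sum(axis=0)
    diffs += diffs.T
    called += called.T
    return diffs, called


def nucleotide_diversity(table: VariantTable, samples=None, L: int | None = None) -> float:
    """Average per-site pairwise difference pi.

    Sum over sample pairs of differing sites, divided by C(n,2) and the
    surveyed length L.  Sites missing in either member of a pair are skipped
    for that pair without adjusting L.
    """
    g = _subset_genotypes(table, samples)
    n = g.shape[1]
    if n < 2:
        raise ValueError("nucleotide diversity needs >= 2 samples")
    if L is None or L < 1:
        raise ValueError("surveyed length L must be >= 1")
    diffs, _ = _pair_diff_counts(g)
    total = diffs[np.triu_indices(n, k=1)].sum()
    n_pairs = n * (n - 1) // 2
    return float(total) / n_pairs / L


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's denominator)."""
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator S / (a_n * L) per site."""
    if n < 2:
        raise ValueError("Watterson's theta needs n >= 2")
    if L < 1:
        raise ValueError("surveyed length L must be >= 1")
    if S == 0:
        return 0.0
    return S / (harmonic_number(n) * L)


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = harmonic_number(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def tajimas_d(table: VariantTable, samples=None, L: int | None = None) -> float:
    """Tajima's D: the normalized difference between pi and Watterson's theta.

    Returns ``nan`` when there are no segregating sites.  Computed with the
    standard 1989 variance constants from S and the mean pairwise difference.
    """
    g = _subset_genotypes(table, samples)
    n = g.shape[1]
    if n < 2:
        raise ValueError("Tajima's D needs n >= 2")
    if n < 4:
        warnings.warn("Tajima's D with n < 4 is unstable", stacklevel=2)
    if L is None or L < 1:
        raise ValueError("surveyed length L must be >= 1")
    S = segregating_sites(table, samples)
    if S == 0:
        return math.nan
    pi_total = nucleotide_diversity(table, samples, L) * L
    a1 = harmonic_number(n)
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    numerator = pi_total - S / a1
    if var <= 0:
        # the variance constants vanish for n < 4; a zero numerator is still
        # a well-defined zero statistic, anything else is undefined
        return 0.0 if abs(numerator) < 1e-12 else math.nan
    return float(numerator / math.sqrt(var))


def diversity_summary(table: VariantTable, samples=None, L: int | None = None) -> DiversitySummary:
    """S, pi, Watterson's theta and Tajima's D in one pass."""
    g = _subset_genotypes(table, samples)
    n = g.shape[1]
    S = segregating_sites(table, samples)
    if S == 0:
        return DiversitySummary(n=n, L=L, S=0, pi=0.0, theta_w=0.0, tajimas_d=math.nan)
    return DiversitySummary(
        n=n,
        L=L,
        S=S,
        pi=nucleotide_diversity(table, samples, L),
        theta_w=watterson_theta(S, n, L),
        tajimas_d=tajimas_d(table, samples, L),
    )


def consensus_sequences(
    reference: SequenceSet, table: VariantTable, chrom_order: list[str] | None = None
) -> SequenceSet:
    """Per-strain representative sequences.

    Substitutes each strain's alternate alleles into the reference
    chromosomes and concatenates them in ``chrom_order`` (default: the
    reference's declared order) into one sequence per strain.  Missing
    genotypes become N.  Only single-base alleles substitute in place;
    a reference-allele mismatch is an error naming the position.
    """
    if chrom_order is None:
        chrom_order = reference.names()
    pieces: dict[str, list[str]] = {s: [] for s in table.sample_names}
    for chrom in chrom_order:
        ref_seq = np.frombuffer(reference[chrom].encode(), dtype="S1")
        on_chrom = np.flatnonzero(table.chrom == chrom)
        for s_i, strain in enumerate(table.sample_names):
            seq = ref_seq.copy()
            for site in on_chrom:
                pos = int(table.pos[site])
                if pos < 1 or pos > len(seq):
                    raise ValueError(f"{chrom}:{pos} outside reference bounds")
                ref_allele = str(table.ref[site])
                if len(ref_allele) == 1 and seq[pos - 1] != ref_allele.encode():
                    raise ValueError(
                        f"{chrom}:{pos}: reference allele mismatch "
                        f"({seq[pos - 1].decode()} in reference, {ref_allele} in table)"
                    )
                gt = int(table.genotypes[site, s_i])
                if gt == MISSING:
                    seq[pos - 1] = b"N"
                elif gt > 0:
                    alt = table.alt[site][gt - 1]
                    if len(alt) == 1:
                        seq[pos - 1] = alt.encode()
            pieces[strain].append(seq.tobytes().decode())
    return SequenceSet({s: "".join(p) for s, p in pieces.items()})


def pairwise_divergence_matrix(table: VariantTable, genome_length: int) -> DistanceMatrix:
    """Per-pair divergence: differing non-missing sites / genome_length.

    Positions not in the table are implicitly identical, so the denominator
    is the full genome size, matching a divergence defined as the ratio of
    non-equal positions to total genome length.
    """
    if table.n_sites and genome_length < int(table.pos.max()):
        raise ValueError("genome_length smaller than covered positions")
    diffs, _ = _pair_diff_counts(table.genotypes)
    return DistanceMatrix(list(table.sample_names), diffs / float(genome_length))


def hudson_fst(table: VariantTable, pop_labels: dict[str, str]) -> float:
    """Hudson-style F_ST = 1 - Hw/Hb for exactly two populations.

    Hw is the mean per-pair differing-site count within populations (the two
    populations averaged with equal weight); Hb the mean over between-
    population pairs.  The per-site normalization cancels.  Returns ``nan``
    when Hb = 0; negative estimates are reported, not clamped.
    """
    pops = sorted(set(pop_labels.values()))
    if len(pops) != 2:
        raise ValueError(f"exactly 2 populations required, got {pops}")
    members = {p: [s for s in table.sample_names if pop_labels.get(s) == p] for p in pops}
    for p, m in members.items():
        if len(m) < 2:
            raise ValueError(f"population {p!r} needs >= 2 members")
    idx = {p: table.sample_index(members[p]) for p in pops}
    diffs, _ = _pair_diff_counts(table.genotypes)

    def mean_within(cols) -> float:
        sub = diffs[np.ix_(cols, cols)]
        k = len(cols)
        return sub[np.triu_indices(k, k=1)].mean()

    hw = 0.5 * (mean_within(idx[pops[0]]) + mean_within(idx[pops[1]]))
    hb = diffs[np.ix_(idx[pops[0]], idx[pops[1]])].mean()
    if hb == 0:
        return math.nan
    return float(1.0 - hw / hb)


def heterozygosity_fraction(
    table: VariantTable, sample: str, threshold: float = 0.01
) -> tuple[float, str]:
    """Fraction of heterozygous calls and a ploidy-consistency classification.

    A strain whose heterozygous fraction is below the threshold (default 1%)
    is classified "homozygous-consistent" — the level seen in genuinely
    haploid strains — otherwise "heterozygous".  Returns ``(nan, "undefined")``
    when the strain has no called variant sites.
    """
    if table.het_flags is None:
        raise ValueError("variant table has no het_flags")
    col = table.sample_index([sample])[0]
    het = table.het_flags[:, col]
    called = (table.genotypes[:, col] != MISSING) | het
    total = int(called.sum())
    if total == 0:
        return math.nan, "undefined"
    frac = float(het.sum()) / total
    return frac, ("homozygous-consistent" if frac < threshold else "heterozygous")
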