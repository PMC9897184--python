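"""Synthetic-cohort generator.

Produces every input the analysis pipeline consumes — a multi-strain haploid
SNP table with deep clade structure, a gene annotation tiling, per-window
read-depth profiles with planted copy-number variants, transposable-element
coverage profiles, and 48-h microplate growth curves — together with a
ground-truth record for recovery tests.

The neutral engine is a Kingman coalescent in units of 2N generations: with
``k`` ancestral lineages the waiting time to the next merger is exponential
with rate ``k(k-1)/2``, the merging pair is uniform, and mutations fall on
branches as a Poisson process of total rate ``theta_site * L / 2`` per unit
branch length under the infinite-sites model.  With this scaling the expected
number of segregating sites is ``theta_site * L * a_n`` where
``a_n = sum_{i<n} 1/i``, which is exactly what the Watterson estimator in
:mod:`lactopop.popgen` inverts.

Population structure is a star backbone without migration: each clade is an
independent coalescent sample plus a set of clade-private fixed differences,
so between-clade divergence is the sum of the two clades' backbone fractions
plus the within-clade heterozygosity each side contributes.  This mirrors a
deeply structured, non-outcrossing cohort — five clades, one of them a
low-diversity "dairy" clade carrying a planted presence cluster of three
genes and a set of enriched copy-number gains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GeneAnnotation, SequenceSet, VariantTable

__all__ = [
    "CoalescentSample",
    "CladeSpec",
    "PlantedGeneCNV",
    "GrowthEffect",
    "CohortSpec",
    "CohortTruth",
    "simulate_coalescent",
    "simulate_structured_cohort",
    "simulate_reference",
    "simulate_depth_windows",
    "simulate_growth",
    "simulate_te_coverage",
    "default_cohort_spec",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CoalescentSample:
    """One neutral coalescent sample under the infinite-sites model."""

    n: int
    haplotypes: np.ndarray  # (n, S) binary
    site_positions: np.ndarray  # strictly increasing, in (0, L]
    theta_site: float
    L: int
    seed: int

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] != self.n:
            raise ValueError("haplotype row count != n")
        if np.any(np.diff(self.site_positions) <= 0):
            raise ValueError("site positions not strictly increasing")
        if self.haplotypes.size:
            counts = self.haplotypes.sum(axis=0)
            if np.any(counts == 0) or np.any(counts == self.n):
                raise ValueError("non-segregating column in haplotype matrix")

    @property
    def S(self) -> int:
        return self.haplotypes.shape[1]

    def to_variant_table(self, chrom: str = "chr1", prefix: str = "hap"):
        """View the sample as a biallelic :class:`~lactopop.formats.VariantTable`.

        Continuous site positions are snapped to distinct integer positions
        (strictly increasing); ancestral state becomes the reference allele.
        """
        from .formats import VariantTable

        pos = np.floor(self.site_positions).astype(np.int64) + 1
        if pos.size:
            pos = np.maximum(pos, np.arange(pos.size) + 1)  # break collisions
            for i in range(1, pos.size):
                if pos[i] <= pos[i - 1]:
                    pos[i] = pos[i - 1] + 1
        names = [f"{prefix}{i + 1:03d}" for i in range(self.n)]
        return VariantTable(
            sample_names=names,
            chrom=np.array([chrom] * self.S, dtype=object),
            pos=pos,
            ref=np.array(["A"] * self.S, dtype=object),
            alt=[("T",)] * self.S,
            genotypes=self.haplotypes.T.astype(np.int16),
            het_flags=np.zeros((self.S, self.n), dtype=bool),
        )


def _kingman_tree(n: int, rng: np.random.Generator):
    """Simulate a Kingman genealogy; return (branch lengths, leaf-descendant sets).

    Nodes 0..n-1 are leaves; nodes n..2n-2 are coalescences in time order.
    Branch length of node v is time(parent(v)) - time(v).
    """
    n_nodes = 2 * n - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        time[nxt] = t
        parent[a] = parent[b] = nxt
        # remove higher index first
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(nxt)
        nxt += 1
    blen = np.zeros(n_nodes)
    has_parent = parent >= 0
    blen[has_parent] = time[parent[has_parent]] - time[has_parent]
    desc = np.zeros((n_nodes, n), dtype=bool)
    desc[np.arange(n), np.arange(n)] = True
    for v in range(n, n_nodes):
        kids = np.flatnonzero(parent == v)
        desc[v] = desc[kids[0]] | desc[kids[1]]
    return blen, desc


def simulate_coalescent(n: int, theta_site: float, L: int, seed: int) -> CoalescentSample:
    """Simulate one neutral constant-size coalescent sample.

    Parameters
    ----------
    n : sample size (>= 2)
    theta_site : scaled mutation rate per site (2N*mu for haploids)
    L : locus length in bp
    seed : RNG seed; the result is deterministic given the seed
    """
    if n < 2:
        raise ValueError(f"need n >= 2 lineages, got {n}")
    if theta_site < 0 or L < 1:
        raise ValueError("theta_site must be >= 0 and L >= 1")
    rng = np.random.default_rng(seed)
    blen, desc = _kingman_tree(n, rng)
    total = blen.sum()
    n_mut = rng.poisson(theta_site * L / 2.0 * total)
    if n_mut == 0:
        return CoalescentSample(
            n=n,
            haplotypes=np.zeros((n, 0), dtype=np.int8),
            site_positions=np.zeros(0),
            theta_site=theta_site,
            L=L,
            seed=seed,
        )
    branches = rng.choice(len(blen), size=n_mut, p=blen / total)
    positions = rng.uniform(0.0, L, size=n_mut)
    # infinite sites: enforce distinct positions (ties have measure zero but
    # the invariant demands strict increase)
    while len(np.unique(positions)) < n_mut:
        _, idx = np.unique(positions, return_index=True)
        dup = np.setdiff1d(np.arange(n_mut), idx)
        positions[dup] = rng.uniform(0.0, L, size=len(dup))
    order = np.argsort(positions)
    haplotypes = desc[branches[order]].T.astype(np.int8)
    return CoalescentSample(
        n=n,
        haplotypes=haplotypes,
        site_positions=positions[order],
        theta_site=theta_site,
        L=L,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Structured cohort


@dataclass
class CladeSpec:
    """One clade: size, within-clade diversity, and backbone divergence.

    ``backbone_divergence`` is the expected fraction of genome positions that
    are fixed differences private to this clade (its branch on the star
    backbone).  Expected pairwise divergence between a member of clade i and
    one of clade j is approximately
    ``b_i + b_j + theta_i*(1-1/n_i) + theta_j*(1-1/n_j)``.
    """

    name: str
    size: int
    theta_site: float
    backbone_divergence: float = 0.0
    dairy: bool = False

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"clade {self.name}: size must be >= 1")
        if not 0.0 <= self.backbone_divergence <= 1.0:
            raise ValueError(f"clade {self.name}: backbone divergence outside [0,1]")


@dataclass
class PlantedGeneCNV:
    """A gene whose copy number is planted per clade (unlisted clades keep 1)."""

    gene_index: int
    cn_by_clade: dict[str, int]
    role: str = "enriched"  # "presence" for the dairy-only presence cluster


@dataclass
class GrowthEffect:
    """Multiplier on carrying capacity K and rate r for a clade x condition."""

    k_mult: float = 1.0
    r_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.k_mult < 0 or self.r_mult < 0:
            raise ValueError("negative growth-effect multiplier")


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    clades: list[CladeSpec]
    genome_length: int = 2_400_000
    n_genes: int = 300
    gene_length: int = 6_000
    gene_gap: int = 2_000
    chrom: str = "chr1"
    planted: list[PlantedGeneCNV] = field(default_factory=list)
    # condition -> clade name -> GrowthEffect; the reference condition is
    # implicit (all multipliers 1)
    growth_effects: dict[str, dict[str, GrowthEffect]] = field(default_factory=dict)
    reference_condition: str = "glucose-2%"
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.clades]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clade names")
        need = self.n_genes * (self.gene_length + self.gene_gap)
        if need > self.genome_length:
            raise ValueError(
                f"{self.n_genes} genes of {self.gene_length} bp (+{self.gene_gap} gap) "
                f"do not fit in {self.genome_length} bp"
            )
        for c in self.clades:
            if 0 < c.backbone_divergence * self.genome_length < 1:
                raise ValueError(
                    f"clade {c.name}: backbone divergence {c.backbone_divergence} "
                    f"yields < 1 expected difference on {self.genome_length} bp"
                )

    @property
    def n_strains(self) -> int:
        return sum(c.size for c in self.clades)

    def strain_names(self) -> list[str]:
        return [f"{c.name}_{i:02d}" for c in self.clades for i in range(1, c.size + 1)]


@dataclass
class CohortTruth:
    """Ground truth realized by :func:`simulate_structured_cohort`."""

    strains: list[str]
    clade_of: dict[str, str]
    dairy: dict[str, bool]
    gene_cn: pd.DataFrame  # genes x strains, integer copy numbers
    presence_gene_ids: list[str]
    enriched_gene_ids: list[str]
    growth_effects: dict[str, dict[str, GrowthEffect]]
    reference_condition: str
    seed: int

    def cnv_segments(self, genes: list[GeneAnnotation], strain: str):
        """Planted CNVs of one strain as (chrom, start, end, cn) segments."""
        by_id = {g.gene_id: g for g in genes}
        segs = []
        col = self.gene_cn[strain]
        for gene_id, cn in col.items():
            if cn != 1:
                g = by_id[gene_id]
                segs.append((g.chrom, g.start, g.end, int(cn)))
        return segs

    def to_file(self, path) -> None:
        payload = {
            "strains": self.strains,
            "clade_of": self.clade_of,
            "dairy": self.dairy,
            "gene_cn": {s: self.gene_cn[s].to_dict() for s in self.gene_cn.columns},
            "presence_gene_ids": self.presence_gene_ids,
            "enriched_gene_ids": self.enriched_gene_ids,
            "growth_effects": {
                cond: {cl: [e.k_mult, e.r_mult] for cl, e in d.items()}
                for cond, d in self.growth_effects.items()
            },
            "reference_condition": self.reference_condition,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "CohortTruth":
        with open(path) as fh:
            payload = json.load(fh)
        gene_cn = pd.DataFrame(
            {s: pd.Series(d) for s, d in payload["gene_cn"].items()}
        ).astype(int)
        return cls(
            strains=payload["strains"],
            clade_of=payload["clade_of"],
            dairy=payload["dairy"],
            gene_cn=gene_cn,
            presence_gene_ids=payload["presence_gene_ids"],
            enriched_gene_ids=payload["enriched_gene_ids"],
            growth_effects={
                cond: {cl: GrowthEffect(*v) for cl, v in d.items()}
                for cond, d in payload["growth_effects"].items()
            },
            reference_condition=payload["reference_condition"],
            seed=payload["seed"],
        )


def simulate_reference(genome_length: int, chrom: str, seed: int) -> SequenceSet:
    """Random reference sequence with uniform base composition."""
    rng = np.random.default_rng(seed)
    seq = "".join(_BASES[rng.integers(0, 4, size=genome_length)])
    return SequenceSet({chrom: seq})


def _gene_tiling(spec: CohortSpec) -> list[GeneAnnotation]:
    pitch = spec.gene_length + spec.gene_gap
    genes = []
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        start = i * pitch + spec.gene_gap // 2 + 1
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{i + 1:0{width}d}",
                chrom=spec.chrom,
                start=start,
                end=start + spec.gene_length - 1,
                strand="+" if i % 2 == 0 else "-",
            )
        )
    return genes


def simulate_structured_cohort(
    spec: CohortSpec,
) -> tuple[VariantTable, list[GeneAnnotation], CohortTruth]:
    """Simulate a clade-structured haploid SNP cohort with planted gene CNVs.

    Each clade is an independent coalescent sample at its own ``theta_site``;
    clade-private fixed differences (a star backbone, no migration) create
    the deep between-clade divergence.  Returns the variant table, a
    non-overlapping gene tiling, and the ground-truth record.
    """
    rng = np.random.default_rng(spec.seed)
    strains = spec.strain_names()
    n_strains = len(strains)
    L = spec.genome_length

    blocks = []  # (site_count, column_fill) where column_fill is (rows, cols01)
    col_of = {}
    start_col = 0
    clade_cols = {}
    for clade in spec.clades:
        clade_cols[clade.name] = np.arange(start_col, start_col + clade.size)
        for i in range(clade.size):
            col_of[f"{clade.name}_{i + 1:02d}"] = start_col + i
        start_col += clade.size

    hap_blocks: list[tuple[np.ndarray, np.ndarray]] = []  # (cols, hap SxK)
    for clade in spec.clades:
        # within-clade polymorphism
        if clade.size >= 2 and clade.theta_site > 0:
            sub = simulate_coalescent(
                clade.size, clade.theta_site, L, seed=int(rng.integers(2**31))
            )
            if sub.S:
                hap_blocks.append((clade_cols[clade.name], sub.haplotypes.T))
        # clade-private fixed differences
        if clade.backbone_divergence > 0:
            n_fix = rng.binomial(L, clade.backbone_divergence)
            if n_fix:
                hap_blocks.append(
                    (
                        clade_cols[clade.name],
                        np.ones((n_fix, clade.size), dtype=np.int8),
                    )
                )

    n_sites = sum(h.shape[0] for _, h in hap_blocks)
    if n_sites > L:
        raise ValueError("more variant sites than genome positions; lower divergence")
    genotypes = np.zeros((n_sites, n_strains), dtype=np.int16)
    row = 0
    for cols, hap in hap_blocks:
        genotypes[row : row + hap.shape[0], cols] = hap
        row += hap.shape[0]
    positions = rng.choice(L, size=n_sites, replace=False) + 1
    order = np.argsort(positions)
    positions = positions[order]
    genotypes = genotypes[order]

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    table = VariantTable(
        sample_names=strains,
        chrom=np.array([spec.chrom] * n_sites, dtype=object),
        pos=positions.astype(np.int64),
        ref=_BASES[ref_idx].astype(object),
        alt=[(b,) for b in _BASES[alt_idx]],
        genotypes=genotypes,
        het_flags=np.zeros((n_sites, n_strains), dtype=bool),
    )

    genes = _gene_tiling(spec)
    gene_ids = [g.gene_id for g in genes]
    gene_cn = pd.DataFrame(1, index=gene_ids, columns=strains, dtype=int)
    presence_ids, enriched_ids = [], []
    for planted in spec.planted:
        gid = gene_ids[planted.gene_index]
        (presence_ids if planted.role == "presence" else enriched_ids).append(gid)
        for clade_name, cn in planted.cn_by_clade.items():
            if cn < 0:
                raise ValueError(f"negative planted copy number for {gid}")
            for c in clade_cols[clade_name]:
                gene_cn.loc[gid, strains[c]] = cn

    clade_of = {}
    dairy = {}
    for clade in spec.clades:
        for c in clade_cols[clade.name]:
            clade_of[strains[c]] = clade.name
            dairy[strains[c]] = clade.dairy
    truth = CohortTruth(
        strains=strains,
        clade_of=clade_of,
        dairy=dairy,
        gene_cn=gene_cn,
        presence_gene_ids=presence_ids,
        enriched_gene_ids=enriched_ids,
        growth_effects=spec.growth_effects,
        reference_condition=spec.reference_condition,
        seed=spec.seed,
    )
    return table, genes, truth


# ---------------------------------------------------------------------------
# Read depth


def simulate_depth_windows(
    genome_length: int,
    window_bp: int,
    cnv_truth,
    mean_cov: float = 100.0,
    dispersion: float = 20.0,
    seed: int = 0,
    chrom: str = "chr1",
    strain: str = "strain",
):
    """Per-window read depth with planted copy-number segments.

    Depth in a window of local copy number ``c`` is negative binomial with
    mean ``mean_cov * c`` and gamma-Poisson dispersion ``dispersion`` (the
    variance is ``m + m^2/dispersion``; ``dispersion = inf`` gives Poisson).
    ``cnv_truth`` is a list of non-overlapping ``(chrom, start, end, cn)``
    segments in 1-based inclusive coordinates; everything else has copy
    number 1.  Windows whose bases straddle a segment boundary take the
    base-average multiplier.
    """
    from .cnvscan import DepthProfile

    if mean_cov <= 0:
        raise ValueError("mean_cov must be > 0")
    rng = np.random.default_rng(seed)
    n_windows = genome_length // window_bp
    mult = np.ones(genome_length)
    segs = sorted(
        [s for s in cnv_truth if s[0] == chrom], key=lambda s: (s[1], s[2])
    )
    for (c1, s1, e1, _), (c2, s2, e2, _) in zip(segs, segs[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping truth CNVs on {chrom}: {(s1, e1)} and {(s2, e2)}")
    for _, start, end, cn in segs:
        mult[start - 1 : end] = cn
    win_mult = mult[: n_windows * window_bp].reshape(n_windows, window_bp).mean(axis=1)
    means = mean_cov * win_mult
    depth = np.zeros(n_windows)
    pos = means > 0
    if np.isinf(dispersion):
        depth[pos] = rng.poisson(means[pos])
    else:
        lam = rng.gamma(shape=dispersion, scale=means[pos] / dispersion)
        depth[pos] = rng.poisson(lam)
    starts = np.arange(n_windows) * window_bp + 1
    windows = [
        (chrom, int(s), int(s + window_bp - 1), float(d))
        for s, d in zip(starts, depth)
    ]
    return DepthProfile(strain=strain, windows=windows, window_bp=window_bp)


# ---------------------------------------------------------------------------
# Growth curves


def simulate_growth(
    strains,
    conditions,
    effects: dict[str, dict[str, GrowthEffect]],
    seed: int = 0,
    *,
    strain_group: dict[str, str] | None = None,
    reference_condition: str = "glucose-2%",
    baseline: float = 0.1,
    K: float = 1.0,
    r: float = 0.004,
    t0: float = 720.0,
    duration_h: float = 48.0,
    interval_min: float = 10.0,
    noise_sd: float = 0.01,
    strain_k_sd: float = 0.05,
    cond_k_sd: float = 0.1,
):
    """Simulate OD600 logistic growth curves on a microplate grid.

    One curve per strain x condition: ``OD(t) = baseline + K/(1+exp(-r(t-t0)))``
    plus homoscedastic Gaussian noise, sampled every ``interval_min`` minutes
    for ``duration_h`` hours (289 points at the 10-min / 48-h defaults).
    ``effects[condition][group]`` scales K and r; the reference condition is
    left at multiplier 1.  Two lognormal variability terms act on K: a
    per-strain factor (sd ``strain_k_sd``) shared across that strain's
    conditions, emulating inoculum and well-position effects that normalize
    out of growth ratios, and a per-strain-per-condition factor (sd
    ``cond_k_sd``) emulating biological variability in condition response,
    which does not normalize out.
    """
    from .growthfit import GrowthCurve

    if K <= 0 or r <= 0:
        raise ValueError("K and r must be positive")
    if reference_condition not in conditions:
        raise ValueError(f"conditions must include the reference {reference_condition!r}")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h * 60.0 + interval_min / 2, interval_min)
    curves: dict[tuple[str, str], GrowthCurve] = {}
    strain_factor = {s: float(np.exp(rng.normal(0.0, strain_k_sd))) for s in strains}
    for s in strains:
        group = strain_group.get(s, s) if strain_group else s
        for cond in conditions:
            eff = GrowthEffect()
            cond_factor = 1.0
            if cond != reference_condition:
                eff = effects.get(cond, {}).get(group, GrowthEffect())
                cond_factor = float(np.exp(rng.normal(0.0, cond_k_sd)))
            k_eff = K * eff.k_mult * strain_factor[s] * cond_factor
            r_eff = r * eff.r_mult
            if r_eff > 0:
                logistic = k_eff / (1.0 + np.exp(-r_eff * (times - t0)))
            else:
                logistic = np.zeros_like(times)
            od = baseline + logistic + rng.normal(0.0, noise_sd, size=times.size)
            curves[(s, cond)] = GrowthCurve(
                strain=s, condition=cond, times=times.copy(), od=np.maximum(od, 0.0)
            )
    return curves


# ---------------------------------------------------------------------------
# TE coverage


def simulate_te_coverage(
    query_lengths: dict[str, int],
    copy_truth: dict[str, dict[str, float]],
    genome_median: float = 100.0,
    covered_fraction: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
):
    """Per-base depth over TE query sequences.

    ``copy_truth[strain][query]`` gives the true copy number; depth over the
    covered fraction of the query is Poisson with mean
    ``genome_median * copies`` and exactly zero elsewhere.  Returns
    ``{(strain, query): TEQueryCoverage}``.
    """
    from .tescan import TEQueryCoverage

    if genome_median <= 0:
        raise ValueError("genome_median must be > 0")
    rng = np.random.default_rng(seed)
    out = {}
    for strain, per_query in copy_truth.items():
        for query, copies in per_query.items():
            if copies < 0:
                raise ValueError(f"negative copy number for {strain}/{query}")
            qlen = query_lengths[query]
            frac = 1.0
            if covered_fraction:
                frac = covered_fraction.get(strain, {}).get(query, 1.0)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"covered fraction {frac} outside [0,1]")
            depth = np.zeros(qlen)
            n_cov = int(round(frac * qlen))
            if copies > 0 and n_cov:
                depth[:n_cov] = rng.poisson(genome_median * copies, size=n_cov)
            out[(strain, query)] = TEQueryCoverage(
                strain=strain,
                query_name=query,
                depth=depth,
                genome_median_depth=genome_median,
            )
    return out


# ---------------------------------------------------------------------------
# Paper-like default cohort


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default 41-strain, 5-clade cohort.

    One low-diversity dairy clade of 19 strains (within-clade diversity
    0.06%) and four wild clades totalling 22 strains (within 0.5%), with
    backbone divergences placing every between-clade divergence above 3% and
    the two most diverged wild clades near 8.5%.  Planted gene content: a
    3-gene presence cluster found only in the dairy clade (emulating the
    introgressed LAC4/LAC12/FLO cluster) and ten dairy-enriched gene gains.
    Growth effects give dairy strains full lactose growth while wild strains
    decline with lactose concentration.
    """
    clades = [
        CladeSpec("dairy", 19, 6e-4, 0.013, dairy=True),
        CladeSpec("wild1", 6, 5e-3, 0.015),
        CladeSpec("wild2", 6, 5e-3, 0.018),
        CladeSpec("asia", 5, 5e-3, 0.040),
        CladeSpec("na2", 5, 5e-3, 0.045),
    ]
    wild = ["wild1", "wild2", "asia", "na2"]
    n_genes = int(overrides.get("n_genes", 300))
    cluster_at = n_genes // 8
    gain_step = max(2, (n_genes - cluster_at - 10) // 11)
    planted = [
        # dairy-only presence cluster: present (CN 1) in dairy, absent elsewhere
        PlantedGeneCNV(cluster_at + k, {w: 0 for w in wild}, role="presence")
        for k in range(3)
    ] + [
        # dairy-enriched gains: CN 2 in dairy, 1 elsewhere
        PlantedGeneCNV(cluster_at + 6 + gain_step * k, {"dairy": 2}, role="enriched")
        for k in range(10)
    ]
    growth_effects = {
        "lactose-2%": {w: GrowthEffect(0.90, 1.0) for w in wild},
        "lactose-5%": {w: GrowthEffect(0.65, 0.9) for w in wild},
        "lactose-10%": {w: GrowthEffect(0.40, 0.8) for w in wild},
    }
    kwargs = dict(
        clades=clades,
        planted=planted,
        growth_effects=growth_effects,
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)
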