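"""Window-based copy-number calling and the dairy-vs-wild differential screen.

The caller is deliberately simple: per-window depth is normalized by the
genome-wide median (robust to the CNVs themselves), rounded to the nearest
integer copy number at the given baseline ploidy, merged into segments, and
smoothed by reassigning runs shorter than ``min_windows`` to the flank whose
mean ratio is closest.  GC-bias correction is out of scope (the synthetic
depth has no GC trend).

Gene-level assignment follows the half-overlap rule: a gene is under CNV
only if at least half of its length lies in segments whose copy number
deviates from the baseline ploidy; its copy number is then that of the
single deviating segment covering the largest fraction of the gene (ties
resolved toward the ploidy, then leftmost).

The differential screen applies a two-sample Kolmogorov–Smirnov test to each
gene's copy numbers across the two strain groups and flags genes with
p below alpha (raw p-values by default; Benjamini–Hochberg optional).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GeneAnnotation
from .stattests import ks_two_sample

logger = logging.getLogger(__name__)

__all__ = [
    "DepthProfile",
    "Segment",
    "CopyNumberSegments",
    "GeneCopyNumberTable",
    "call_windows",
    "detect_segmental_duplications",
    "gene_copy_numbers",
    "build_gene_cn_table",
    "differential_cnv",
]


@dataclass
class DepthProfile:
    """Per-window mean read depth for one strain.

    ``windows`` is a sorted, non-overlapping list of
    ``(chrom, start, end, depth)`` with 1-based inclusive coordinates.
    """

    strain: str
    windows: list[tuple[str, int, int, float]]
    window_bp: int

    def __post_init__(self) -> None:
        prev: dict[str, int] = {}
        for chrom, start, end, depth in self.windows:
            if depth < 0:
                raise ValueError(f"negative depth in window {chrom}:{start}-{end}")
            if start <= prev.get(chrom, 0):
                raise ValueError(f"windows overlap or are unsorted on {chrom}")
            prev[chrom] = end

    def depths(self) -> np.ndarray:
        return np.array([w[3] for w in self.windows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.windows, columns=["chrom", "start", "end", "depth"])

    @classmethod
    def from_frame(cls, strain: str, df: pd.DataFrame, window_bp: int | None = None):
        windows = [
            (str(r.chrom), int(r.start), int(r.end), float(r.depth))
            for r in df.itertuples()
        ]
        if window_bp is None:
            window_bp = windows[0][2] - windows[0][1] + 1
        return cls(strain=strain, windows=windows, window_bp=window_bp)


@dataclass(frozen=True)
class Segment:
    """One copy-number segment, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    copy_number: int
    ratio: float = float("nan")

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CopyNumberSegments:
    """Sorted copy-number segments for one strain."""

    strain: str
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start, s.end))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.chrom, s.start, s.end, s.copy_number, s.ratio) for s in self.segments],
            columns=["chrom", "start", "end", "copy_number", "ratio"],
        )


@dataclass
class GeneCopyNumberTable:
    """Integer copy numbers, genes x strains, with per-strain baseline ploidy."""

    values: pd.DataFrame
    ploidy: dict[str, int]

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("copy numbers must be >= 0")
        missing = set(self.values.columns) - set(self.ploidy)
        if missing:
            raise ValueError(f"no baseline ploidy for strains: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def call_windows(
    profile: DepthProfile,
    ploidy: int = 1,
    min_windows: int = 3,
    reestimate: bool = True,
) -> CopyNumberSegments:
    """Copy-number segments from a per-window depth profile.

    Ratio = window depth / genome-wide median depth; per-window copy number
    is ``round(ratio * ploidy)`` (half rounds up); adjacent equal-CN windows
    merge into segments; runs shorter than ``min_windows`` are reassigned to
    the flanking copy number with the closer mean ratio, so isolated noisy
    windows do not spawn segments.

    With ``reestimate`` (default) the segmentation is made robust to
    overdispersed depth: windows are first classified deviating / baseline,
    baseline interruptions shorter than ``min_windows`` inside a deviating
    stretch are closed and deviating blips shorter than ``min_windows`` are
    opened away, and each surviving deviating stretch takes the copy number
    rounded from its mean ratio — segment means are far less noisy than
    single windows.  Stretches whose internal sub-run means still jump by a
    full copy or more are split at those jumps.
    """
    if len(profile.windows) < 10:
        raise ValueError("need >= 10 windows for a stable baseline")
    depths = profile.depths()
    median = np.median(depths)
    if median <= 0:
        raise ValueError("all-zero (or majority-zero) depth: no baseline")
    ratios = depths / median
    cn = _round_half_up(ratios * ploidy)

    segments: list[Segment] = []
    chroms = [w[0] for w in profile.windows]
    for chrom in dict.fromkeys(chroms):  # preserves order
        idx = [i for i, c in enumerate(chroms) if c == chrom]
        scaled = ratios[idx] * ploidy
        if reestimate:
            runs = _segment_robust(cn[idx], scaled, ploidy, min_windows)
        else:
            runs = _smooth_runs(_runs(cn[idx]), scaled, min_windows)
        for lo, hi, value in runs:
            start = profile.windows[idx[lo]][1]
            end = profile.windows[idx[hi]][2]
            mean_ratio = float(np.mean(ratios[idx[lo] : idx[hi] + 1]))
            segments.append(Segment(chrom, start, end, int(value), mean_ratio))
    return CopyNumberSegments(strain=profile.strain, segments=segments)


def _segment_robust(
    cn: np.ndarray,
    scaled: np.ndarray,
    ploidy: int,
    min_windows: int,
    split_gap: float = 1.2,
) -> list[list[int]]:
    """Segment via the deviating-window mask with morphological smoothing.

    Close baseline interruptions shorter than ``min_windows`` inside
    deviating stretches, open away deviating blips shorter than
    ``min_windows``, then call each surviving stretch's copy number from its
    mean scaled ratio.  A stretch is split where the means of its internal
    window-CN sub-runs, after greedy closest-pair merging, still differ by
    ``split_gap`` or more (a genuine internal breakpoint; the default of
    1.2 copies keeps selection-biased sub-run means from splitting a
    homogeneous segment, at the declared cost of not resolving directly
    adjacent segments one copy apart).
    """
    n = len(cn)
    deviating = cn != ploidy
    # close: short baseline gaps strictly inside deviating context
    for lo, hi, value in _runs(deviating.astype(int)):
        if value == 0 and hi - lo + 1 < min_windows and lo > 0 and hi < n - 1:
            deviating[lo : hi + 1] = True
    # open: short deviating blips go back to baseline
    for lo, hi, value in _runs(deviating.astype(int)):
        if value == 1 and hi - lo + 1 < min_windows:
            deviating[lo : hi + 1] = False

    runs: list[list[int]] = []

    def add_run(lo: int, hi: int, value: int) -> None:
        if runs and runs[-1][2] == value:
            runs[-1][1] = hi
        else:
            runs.append([lo, hi, value])

    for lo, hi, value in _runs(deviating.astype(int)):
        if value == 0:
            add_run(lo, hi, ploidy)
            continue
        for s_lo, s_hi in _split_stretch(cn, scaled, lo, hi, split_gap):
            seg_cn = int(math.floor(float(scaled[s_lo : s_hi + 1].mean()) + 0.5))
            add_run(s_lo, s_hi, seg_cn)
    return runs


def _split_stretch(
    cn: np.ndarray, scaled: np.ndarray, lo: int, hi: int, split_gap: float
) -> list[tuple[int, int]]:
    """Split one deviating stretch at internal jumps of >= split_gap copies."""
    sub = [[r[0] + lo, r[1] + lo, r[2]] for r in _runs(cn[lo : hi + 1])]

    def mean_of(run):
        return float(scaled[run[0] : run[1] + 1].mean())

    def merge_at(k: int) -> None:
        sub[k] = [sub[k][0], sub[k + 1][1], sub[k][2]]
        del sub[k + 1]

    min_windows = 3  # fragments below this cannot stand as segments
    while len(sub) > 1:
        gaps = [abs(mean_of(a) - mean_of(b)) for a, b in zip(sub, sub[1:])]
        k = int(np.argmin(gaps))
        if gaps[k] < split_gap:
            merge_at(k)
            continue
        # no sub-quantum gaps left: absorb fragments too short to stand
        sizes = [r[1] - r[0] + 1 for r in sub]
        j = int(np.argmin(sizes))
        if sizes[j] >= min_windows:
            break
        if j == 0:
            merge_at(0)
        elif j == len(sub) - 1:
            merge_at(j - 1)
        else:
            left_gap = abs(mean_of(sub[j - 1]) - mean_of(sub[j]))
            right_gap = abs(mean_of(sub[j]) - mean_of(sub[j + 1]))
            merge_at(j - 1 if left_gap <= right_gap else j)
    return [(r[0], r[1]) for r in sub]


def _merge_equal(runs: list[list[int]]) -> list[list[int]]:
    merged: list[list[int]] = []
    for run in runs:
        if merged and merged[-1][2] == run[2]:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return merged


def _runs(values: np.ndarray) -> list[list[int]]:
    """Maximal runs of equal values as [first, last, value]."""
    runs = []
    lo = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[lo]:
            runs.append([lo, i - 1, int(values[lo])])
            lo = i
    return runs


def _smooth_runs(runs: list[list[int]], scaled_ratios: np.ndarray,
                 min_windows: int) -> list[list[int]]:
    """Reassign runs shorter than min_windows to the nearer flank's CN."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        short = [
            k for k, (lo, hi, _) in enumerate(runs) if hi - lo + 1 < min_windows
        ]
        if not short:
            break
        # handle the shortest first (leftmost among equals)
        k = min(short, key=lambda k: (runs[k][1] - runs[k][0], k))
        lo, hi, _ = runs[k]
        mean_ratio = float(np.mean(scaled_ratios[lo : hi + 1]))
        candidates = []
        if k > 0:
            candidates.append((abs(mean_ratio - runs[k - 1][2]), k - 1))
        if k < len(runs) - 1:
            candidates.append((abs(mean_ratio - runs[k + 1][2]), k + 1))
        _, target = min(candidates)
        runs[k][2] = runs[target][2]
        runs = _merge_equal(runs)
    return runs


def detect_segmental_duplications(
    profile: DepthProfile,
    seg_window_bp: int = 10_000,
    min_ratio: float = 1.5,
    min_run: int = 2,
) -> pd.DataFrame:
    """Segmental duplications from rebinned depth.

    Rebins the profile to ``seg_window_bp`` windows, normalizes by the
    genome-wide median of the rebinned depth, and reports maximal runs of
    at least ``min_run`` windows with ratio >= ``min_ratio`` (duplication at
    haploid baseline).  Returns a table (chrom, start, end, mean_ratio).
    """
    factor = max(1, seg_window_bp // profile.window_bp)
    bins: list[tuple[str, int, int, float]] = []
    chroms = [w[0] for w in profile.windows]
    for chrom in dict.fromkeys(chroms):
        rows = [w for w in profile.windows if w[0] == chrom]
        for i in range(0, len(rows), factor):
            chunk = rows[i : i + factor]
            bins.append(
                (chrom, chunk[0][1], chunk[-1][2], float(np.mean([w[3] for w in chunk])))
            )
    depths = np.array([b[3] for b in bins])
    median = np.median(depths)
    if median <= 0:
        raise ValueError("all-zero depth: no baseline")
    ratios = depths / median
    regions = []
    i = 0
    while i < len(bins):
        if ratios[i] >= min_ratio:
            j = i
            while (
                j + 1 < len(bins)
                and bins[j + 1][0] == bins[i][0]
                and ratios[j + 1] >= min_ratio
            ):
                j += 1
            if j - i + 1 >= min_run:
                regions.append(
                    (
                        bins[i][0],
                        bins[i][1],
                        bins[j][2],
                        float(np.mean(ratios[i : j + 1])),
                    )
                )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "mean_ratio"])


def gene_copy_numbers(
    segments: CopyNumberSegments,
    genes: list[GeneAnnotation],
    ploidy: int = 1,
) -> pd.Series:
    """Project copy-number segments onto genes (the half-overlap rule).

    A gene keeps the baseline ploidy unless at least half of its length lies
    inside segments whose copy number deviates from the ploidy; it then takes
    the copy number of the single deviating segment covering the largest
    fraction of the gene.  Equal coverage ties resolve to the copy number
    closer to the ploidy, then to the leftmost segment.
    """
    known_chroms = {s.chrom for s in segments.segments}
    out = {}
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments.segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for gene in genes:
        if gene.chrom not in known_chroms:
            raise ValueError(f"gene {gene.gene_id} on unknown chromosome {gene.chrom!r}")
        deviating = []
        covered = np.zeros(gene.length, dtype=bool)
        for seg in by_chrom[gene.chrom]:
            if seg.copy_number == ploidy:
                continue
            lo = max(seg.start, gene.start)
            hi = min(seg.end, gene.end)
            if lo > hi:
                continue
            overlap = hi - lo + 1
            covered[lo - gene.start : hi - gene.start + 1] = True
            deviating.append((overlap, seg))
        if not deviating or 2 * int(covered.sum()) < gene.length:
            out[gene.gene_id] = ploidy
            continue
        best = max(
            deviating,
            key=lambda item: (
                item[0],                                   # largest coverage
                -abs(item[1].copy_number - ploidy),        # CN closer to ploidy
                -item[1].start,                            # leftmost
                -item[1].copy_number,                      # final determinism
            ),
        )
        out[gene.gene_id] = best[1].copy_number
    return pd.Series(out, name=segments.strain, dtype=int)


def build_gene_cn_table(
    segments_by_strain: dict[str, CopyNumberSegments],
    genes: list[GeneAnnotation],
    ploidy: int | dict[str, int] = 1,
) -> GeneCopyNumberTable:
    """Gene x strain copy-number matrix from per-strain segments."""
    if isinstance(ploidy, int):
        ploidy = {s: ploidy for s in segments_by_strain}
    cols = {
        strain: gene_copy_numbers(segs, genes, ploidy[strain])
        for strain, segs in segments_by_strain.items()
    }
    return GeneCopyNumberTable(values=pd.DataFrame(cols), ploidy=ploidy)


def differential_cnv(
    table: GeneCopyNumberTable,
    labels: dict[str, str],
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-gene two-group Kolmogorov–Smirnov screen on copy numbers.

    ``labels`` maps each strain to one of exactly two group names (e.g.
    "dairy" / "non-dairy").  Returns a table (gene, D, p, flagged, and the
    two group means) sorted by p.  ``flagged`` marks p < alpha on raw
    p-values; with ``bh_correction`` the Benjamini–Hochberg adjusted
    p-values are used instead.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly 2 groups required, got {groups}")
    cols = {g: [s for s in table.strains if labels.get(s) == g] for g in groups}
    for g, members in cols.items():
        if not members:
            raise ValueError(f"group {g!r} is empty")
    a = table.values[cols[groups[0]]].to_numpy()
    b = table.values[cols[groups[1]]].to_numpy()
    if (table.values.to_numpy() == table.values.to_numpy()[0, 0]).all():
        warnings.warn("constant copy-number table: nothing can be flagged",
                      stacklevel=2)
    rows = []
    for i, gene in enumerate(table.gene_ids):
        res = ks_two_sample(a[i], b[i])
        rows.append((gene, res.statistic, res.p_value, a[i].mean(), b[i].mean()))
    df = pd.DataFrame(
        rows, columns=["gene", "D", "p", f"mean_{groups[0]}", f"mean_{groups[1]}"]
    )
    if bh_correction:
        df["p_adj"] = _benjamini_hochberg(df["p"].to_numpy())
        df["flagged"] = df["p_adj"] < alpha
    else:
        df["flagged"] = df["p"] < alpha
    return df.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
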