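"""Coverage-based transposable-element copy number and presence estimation.

Short reads mapped against a panel of TE query sequences give a per-base
depth profile per strain x query.  Breadth of coverage (fraction of query
positions at depth >= ``min_depth``) classifies the element as present
(breadth >= 0.8), partial (>= 0.2), or absent; the copy number estimate is
the trimmed mean depth over covered positions divided by the strain's
genome-wide median depth — depth twice the genomic baseline means two
copies.  The 5%-per-tail trim resists pileups at element termini.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["TEQueryCoverage", "te_copy_number", "te_landscape"]


@dataclass
class TEQueryCoverage:
    """Per-base depth over one TE query sequence for one strain."""

    strain: str
    query_name: str
    depth: np.ndarray
    genome_median_depth: float

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("depths must be >= 0")
        if self.genome_median_depth <= 0:
            raise ValueError("genome median depth must be > 0")


def te_copy_number(
    cov: TEQueryCoverage,
    min_depth: float = 5.0,
    present_breadth: float = 0.8,
    partial_breadth: float = 0.2,
    trim: float = 0.05,
) -> tuple[float, float, str]:
    """Copies, breadth, and presence status for one strain x query.

    breadth = fraction of positions with depth >= ``min_depth``;
    copies = trimmed mean depth over those covered positions divided by the
    genome median (0 when breadth is 0); status thresholds on breadth.
    """
    if len(cov.depth) < 100:
        raise ValueError("query shorter than 100 bases")
    covered = cov.depth >= min_depth
    breadth = float(covered.mean())
    if breadth == 0.0:
        copies = 0.0
    else:
        copies = float(
            stats.trim_mean(cov.depth[covered], trim) / cov.genome_median_depth
        )
    if breadth >= present_breadth:
        status = "present"
    elif breadth >= partial_breadth:
        status = "partial"
    else:
        status = "absent"
    return copies, breadth, status


def te_landscape(
    covs: dict[tuple[str, str], TEQueryCoverage],
    strains: list[str] | None = None,
    queries: list[str] | None = None,
    populations: dict[str, str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Strains x queries landscape of TE copies and presence status.

    Missing strain/query combinations are recorded as absent with a warning.
    Returns a long table (strain, query, copies, breadth, status[, population]).
    """
    if strains is None:
        strains = sorted({s for s, _ in covs})
    if queries is None:
        queries = sorted({q for _, q in covs})
    rows = []
    for strain in strains:
        for query in queries:
            cov = covs.get((strain, query))
            if cov is None:
                logger.warning("no coverage for %s x %s: recorded absent", strain, query)
                copies, breadth, status = 0.0, 0.0, "absent"
            else:
                copies, breadth, status = te_copy_number(cov, **kwargs)
            rows.append((strain, query, copies, breadth, status))
    df = pd.DataFrame(rows, columns=["strain", "query", "copies", "breadth", "status"])
    if populations is not None:
        df["population"] = df["strain"].map(populations)
    return df
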