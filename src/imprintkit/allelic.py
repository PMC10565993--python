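"""Read-level allelic-methylation analysis in partially methylated domains.

A partially methylated domain (PMD) candidate is a gap-chained CpG cluster
overlapping a promoter CpG island whose pooled mean methylation ratio falls
in [0.3, 0.7] — the intermediate band expected when one allele is methylated
and the other is not.  Fragments overlapping a PMD qualify when they carry
at least 3 CpG calls inside it; a PMD with more than 30 qualified reads is
analyzed, and it is called allelically methylated when more than 30% of
qualified reads are hypomethylated (level in [0, 0.2]) AND more than 30% are
hypermethylated (level in [0.8, 1.0]).  Interval endpoints are closed (a
read at exactly 0.2 counts as hypomethylated) and the 30-read / 30-percent
thresholds are strict.

The report carries a read x CpG call matrix (reads sorted by methylation
level then id, columns in genomic order) suitable for QUMA-style lollipop
plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dmr import _clusters
from .io import MethylomeTable, ReadMethProfile

log = logging.getLogger(__name__)

__all__ = ["PmdCandidate", "AllelicRegionReport", "find_pmds", "qualify_reads",
           "classify_allelic", "plot_lollipop"]


@dataclass
class PmdCandidate:
    """A CpG cluster with intermediate pooled methylation."""

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_ratio: float
    positions: tuple[int, ...]


@dataclass
class AllelicRegionReport:
    """Bimodality classification of qualified reads in one PMD."""

    pmd: PmdCandidate
    n_qualified_reads: int
    pct_hypo: float
    pct_hyper: float
    verdict: str  # allelic | not_allelic | insufficient_reads
    read_matrix: pd.DataFrame = field(default_factory=pd.DataFrame)


def find_pmds(
    table: MethylomeTable,
    islands: pd.DataFrame,
    lo: float = 0.3,
    hi: float = 0.7,
    min_cpgs: int = 11,
    max_gap: int = 300,
    samples: Sequence[str] | None = None,
) -> list[PmdCandidate]:
    """Island-anchored PMD candidates from pooled methylation ratios.

    ``islands`` is a BED-like frame (chrom, start, end).  Ratios are pooled
    over ``samples`` (default: all samples in the table).
    """
    if islands is None or len(islands) == 0:
        log.warning("find_pmds: empty island set, no PMDs to report")
        return []
    pooled = table.pooled_ratio(samples)
    ok = ~np.isnan(pooled)
    out: list[PmdCandidate] = []
    df = table.df
    for chrom in df["chrom"].unique():
        isl = islands[islands["chrom"] == chrom]
        if isl.empty:
            continue
        sel = (df["chrom"] == chrom).to_numpy() & ok
        pos = df.loc[sel, "pos"].to_numpy()
        ratio = pooled[sel]
        for cluster in _clusters(pos, max_gap):
            if len(cluster) < min_cpgs:
                continue
            c_start, c_end = int(pos[cluster[0]]), int(pos[cluster[-1]]) + 1
            hits = (isl["start"].to_numpy() < c_end) & (isl["end"].to_numpy() > c_start)
            if not hits.any():
                continue
            mean_ratio = float(np.mean(ratio[cluster]))
            if lo <= mean_ratio <= hi:
                out.append(
                    PmdCandidate(
                        chrom=chrom, start=c_start, end=c_end,
                        n_cpgs=len(cluster), mean_ratio=mean_ratio,
                        positions=tuple(int(p) for p in pos[cluster]),
                    )
                )
    return out


def qualify_reads(
    pmd: PmdCandidate,
    profiles: Sequence[ReadMethProfile],
    min_cpgs_per_read: int = 3,
) -> list[ReadMethProfile]:
    """Reads with >= ``min_cpgs_per_read`` CpG calls inside the PMD.

    Qualified profiles are restricted to the member CpGs, so levels are
    recomputed over in-PMD positions only.
    """
    out = []
    for p in profiles:
        if p.chrom != pmd.chrom:
            continue
        sub = p.restrict(pmd.start, pmd.end)
        if sub is not None and len(sub.positions) >= min_cpgs_per_read:
            out.append(sub)
    return out


def classify_allelic(
    pmd: PmdCandidate,
    qualified: Sequence[ReadMethProfile],
    min_reads: int = 30,
    pct_threshold: float = 30.0,
    hypo_max: float = 0.2,
    hyper_min: float = 0.8,
) -> AllelicRegionReport:
    """Bimodality verdict: allelic iff both read modes exceed 30%.

    ``min_reads`` is the "more than 30" gate: a PMD with <= 30 qualified
    reads is reported as insufficient_reads.
    """
    n = len(qualified)
    levels = np.array([p.level for p in qualified]) if n else np.empty(0)
    pct_hypo = 100.0 * float(np.sum(levels <= hypo_max)) / n if n else 0.0
    pct_hyper = 100.0 * float(np.sum(levels >= hyper_min)) / n if n else 0.0
    if n <= min_reads:
        verdict = "insufficient_reads"
    elif pct_hypo > pct_threshold and pct_hyper > pct_threshold:
        verdict = "allelic"
    else:
        verdict = "not_allelic"

    order = sorted(range(n), key=lambda i: (qualified[i].level, qualified[i].read_id))
    matrix = pd.DataFrame(
        np.nan, index=[qualified[i].read_id for i in order], columns=list(pmd.positions)
    )
    for i in order:
        p = qualified[i]
        matrix.loc[p.read_id, list(p.positions)] = list(p.calls)
    matrix.index.name = "read_id"
    return AllelicRegionReport(
        pmd=pmd,
        n_qualified_reads=n,
        pct_hypo=pct_hypo,
        pct_hyper=pct_hyper,
        verdict=verdict,
        read_matrix=matrix,
    )


def plot_lollipop(report: AllelicRegionReport, path: str) -> None:
    """QUMA-style lollipop plot: open = unmethylated, filled = methylated."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = report.read_matrix
    fig, ax = plt.subplots(
        figsize=(max(3.0, 0.18 * m.shape[1]), max(2.0, 0.12 * m.shape[0]))
    )
    for y, (_, row) in enumerate(m.iterrows()):
        vals = row.to_numpy(dtype=float)
        x = np.arange(len(vals))
        obs = ~np.isnan(vals)
        ax.plot(x[obs], [y] * obs.sum(), color="0.7", lw=0.5, zorder=1)
        filled = obs & (vals == 1)
        open_ = obs & (vals == 0)
        ax.scatter(x[filled], [y] * filled.sum(), s=12, facecolor="black",
                   edgecolor="black", zorder=2)
        ax.scatter(x[open_], [y] * open_.sum(), s=12, facecolor="white",
                   edgecolor="black", zorder=2)
    ax.set_xticks(np.arange(m.shape[1]))
    ax.set_xticklabels([str(c) for c in m.columns], rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("CpG position")
    ax.set_title(
        f"{report.pmd.chrom}:{report.pmd.start}-{report.pmd.end} "
        f"({report.verdict}, hypo {report.pct_hypo:.1f}%, hyper {report.pct_hyper:.1f}%)",
        fontsize=7,
    )
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
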