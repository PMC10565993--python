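"""Methylated-region segmentation and PA/CN differential methylation calling.

A candidate methylated region (MR) is a contiguous run of CpGs in which
consecutive CpGs are less than ``max_gap`` bp apart (default 300), the run
holds more than 10 CpGs (>= 11) and the absolute difference of group mean
methylation exceeds 0.2.  Runs are enumerated inside gap-chained clusters and
only inclusion-maximal qualifying runs are kept (a run contained in a longer
qualifying run is dropped).  Thresholds are strict inequalities: a gap of
exactly ``max_gap`` breaks the chain, exactly 10 CpGs or a difference of
exactly 0.2 are rejected.

The per-region statistic is a two-sided Mann-Whitney U on the vectors of
per-CpG group-mean ratios (normal approximation with tie correction; all
values tied gives p = 1 exactly).  CpGs are treated as exchangeable units —
with two replicates per group, replicate-level tests are powerless, so the
per-CpG test trades positional correlation for reproducible power; the
resulting p-values are anti-conservative under strong spatial correlation
and should be read as a ranking device controlled genome-wide by
Benjamini-Hochberg (DMR = region with q < 0.05).

Direction semantics follow the uniparental design: group A is the PA group,
so A-hypermethylation indicates maternal methylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import MethylomeTable

__all__ = ["MethRegion", "DmrCall", "segment_regions", "test_region", "call_dmrs",
           "dmrs_to_bed"]


@dataclass
class MethRegion:
    """A contiguous CpG run with a group methylation contrast."""

    chrom: str
    start: int  # first member CpG
    end: int  # last member CpG + 1 (half-open)
    n_cpgs: int
    mean_a: float
    mean_b: float
    positions: tuple[int, ...]
    p_value: float | None = None

    @property
    def mean_diff(self) -> float:
        return self.mean_a - self.mean_b

    @property
    def direction(self) -> str:
        return "A_hyper" if self.mean_diff > 0 else "B_hyper"


@dataclass
class DmrCall:
    """A MethRegion that survived the genome-wide FDR cut."""

    region: MethRegion
    q_value: float
    imprint_direction: str  # maternal_hyper | paternal_hyper


def _clusters(pos: np.ndarray, max_gap: int) -> list[np.ndarray]:
    """Split sorted positions into chains with inter-CpG gap < max_gap."""
    if len(pos) == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) >= max_gap)
    return np.split(np.arange(len(pos)), breaks + 1)


def _maximal_runs(diff: np.ndarray, min_cpgs: int, min_diff: float) -> list[tuple[int, int]]:
    """Inclusion-maximal runs [i, j] with >= min_cpgs CpGs and |mean diff| > min_diff."""
    n = len(diff)
    if n < min_cpgs:
        return []
    csum = np.concatenate([[0.0], np.cumsum(diff)])
    runs: list[tuple[int, int]] = []
    for i in range(n - min_cpgs + 1):
        j = np.arange(i + min_cpgs - 1, n)
        means = (csum[j + 1] - csum[i]) / (j - i + 1)
        for jj in j[np.abs(means) > min_diff]:
            runs.append((i, int(jj)))
    runs.sort(key=lambda r: (r[0], -r[1]))
    kept: list[tuple[int, int]] = []
    best_j = -1
    for i, j in runs:
        if j > best_j:
            kept.append((i, j))
            best_j = j
    return kept


def segment_regions(
    table: MethylomeTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    max_gap: int = 300,
    min_cpgs: int = 11,
    min_diff: float = 0.2,
) -> list[MethRegion]:
    """Candidate methylated regions between two sample groups.

    The table should be strand-merged and coverage-filtered; CpGs with no
    covered sample in either group are skipped.
    """
    if not group_a or not group_b:
        raise InputError("segment_regions: both groups need at least one sample")
    mean_a = table.group_mean_ratio(group_a)
    mean_b = table.group_mean_ratio(group_b)
    ok = ~(np.isnan(mean_a) | np.isnan(mean_b))

    regions: list[MethRegion] = []
    df = table.df
    for chrom in df["chrom"].unique():
        sel = (df["chrom"] == chrom).to_numpy() & ok
        pos = df.loc[sel, "pos"].to_numpy()
        ma, mb = mean_a[sel], mean_b[sel]
        for cluster in _clusters(pos, max_gap):
            d = ma[cluster] - mb[cluster]
            for i, j in _maximal_runs(d, min_cpgs, min_diff):
                member = cluster[i : j + 1]
                regions.append(
                    MethRegion(
                        chrom=chrom,
                        start=int(pos[member[0]]),
                        end=int(pos[member[-1]]) + 1,
                        n_cpgs=len(member),
                        mean_a=float(np.mean(ma[member])),
                        mean_b=float(np.mean(mb[member])),
                        positions=tuple(int(p) for p in pos[member]),
                    )
                )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def test_region(
    region: MethRegion,
    table: MethylomeTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> float:
    """Two-sided Mann-Whitney U p-value on per-CpG group-mean ratios."""
    df = table.df
    sel = (df["chrom"] == region.chrom).to_numpy() & df["pos"].isin(region.positions).to_numpy()
    if sel.sum() != region.n_cpgs:
        raise InputError(
            f"region {region.chrom}:{region.start}-{region.end}: "
            "member CpGs not all present in table"
        )
    a = table.group_mean_ratio(group_a)[sel]
    b = table.group_mean_ratio(group_b)[sel]
    values = np.concatenate([a, b])
    if np.all(values == values[0]):
        return 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(min(1.0, res.pvalue))


def call_dmrs(
    regions: Sequence[MethRegion],
    alpha: float = 0.05,
    group_a_is_pa: bool = True,
) -> list[DmrCall]:
    """Benjamini-Hochberg over all tested regions; keep q < alpha.

    With group A = PA, A-hypermethylation maps to maternal_hyper and
    B-hypermethylation to paternal_hyper (flipped if ``group_a_is_pa`` is
    False).
    """
    regions = [r for r in regions]
    if not regions:
        return []
    if any(r.p_value is None for r in regions):
        raise InputError("call_dmrs: regions must carry p-values")
    pvals = np.array([r.p_value for r in regions])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    calls = []
    for r, q in zip(regions, qvals):
        if q < alpha:
            a_hyper = r.mean_diff > 0
            maternal = a_hyper if group_a_is_pa else not a_hyper
            calls.append(
                DmrCall(
                    region=r,
                    q_value=float(q),
                    imprint_direction="maternal_hyper" if maternal else "paternal_hyper",
                )
            )
    return calls


def dmrs_to_bed(calls: Sequence[DmrCall]) -> pd.DataFrame:
    """BED6+ representation: score = round(-10 log10 q), extras appended."""
    rows = []
    for i, c in enumerate(calls):
        r = c.region
        score = 0 if c.q_value <= 0 else int(round(-10.0 * math.log10(c.q_value)))
        rows.append(
            {"chrom": r.chrom, "start": r.start, "end": r.end, "name": f"dmr{i + 1}",
             "score": min(1000, max(0, score)), "strand": ".",
             "n_cpgs": r.n_cpgs, "mean_diff": round(r.mean_diff, 6),
             "p": r.p_value, "q": c.q_value,
             "imprint_direction": c.imprint_direction}
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "n_cpgs", "mean_diff", "p", "q", "imprint_direction"],
    )
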