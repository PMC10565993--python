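"""Readers, writers and containers for per-CpG methylation data.

Coordinate conventions
----------------------
Internally everything is 0-based half-open on the forward strand (the position
of the CpG cytosine on the ``+`` strand).  Bismark-style cytosine coverage
files are 1-based inclusive on disk; BED and bedGraph are 0-based half-open.
Each reader converts on the way in, each writer on the way out, so the
containers never mix conventions.

Two containers live here: :class:`MethylomeTable` (per-CpG methylated /
unmethylated counts for one or more samples) and :class:`ReadMethProfile`
(the ordered CpG calls of a single sequencing fragment, the unit of the
read-level allelic-methylation analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParseError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "MethylomeTable",
    "ReadMethProfile",
    "read_coverage_file",
    "write_coverage_file",
    "read_bedgraph",
    "write_bedgraph",
    "read_read_profiles",
    "write_read_profiles",
    "read_profiles_from_sam",
    "read_bed",
    "write_bed",
    "read_snp_vcf",
    "write_snp_vcf",
    "merge_symmetric_cpg",
    "filter_by_coverage",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadMethProfile:
    """CpG methylation calls of one sequencing fragment.

    ``positions`` are strictly increasing 0-based CpG cytosine positions;
    ``calls`` are 1 (methylated) / 0 (unmethylated), one per position.
    """

    read_id: str
    chrom: str
    positions: tuple[int, ...]
    calls: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.calls):
            raise ValidationError(
                f"read {self.read_id}: {len(self.positions)} positions "
                f"but {len(self.calls)} calls"
            )
        if len(self.positions) < 1:
            raise ValidationError(f"read {self.read_id}: empty profile")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValidationError(
                f"read {self.read_id}: positions not strictly increasing"
            )
        if any(c not in (0, 1) for c in self.calls):
            raise ValidationError(f"read {self.read_id}: calls must be 0/1")

    @property
    def level(self) -> float:
        """Fraction of methylated calls on this fragment."""
        return float(sum(self.calls)) / len(self.calls)

    def restrict(self, start: int, end: int) -> "ReadMethProfile | None":
        """Profile limited to CpGs in ``[start, end)``; None if empty."""
        keep = [(p, c) for p, c in zip(self.positions, self.calls) if start <= p < end]
        if not keep:
            return None
        pos, calls = zip(*keep)
        return ReadMethProfile(self.read_id, self.chrom, pos, calls)


class MethylomeTable:
    """Per-CpG methylated/unmethylated counts for one or more samples.

    Backed by a DataFrame with columns ``chrom``, ``pos`` and, for each
    sample ``s``, ``meth_<s>`` and ``unmeth_<s>``.  Rows are sorted by
    (chrom, pos) and unique per position.
    """

    def __init__(self, df: pd.DataFrame, samples: Sequence[str]):
        samples = list(samples)
        cols = ["chrom", "pos"]
        for s in samples:
            cols += [f"meth_{s}", f"unmeth_{s}"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(f"MethylomeTable missing columns {missing}")
        df = df[cols].copy()
        df["pos"] = df["pos"].astype(np.int64)
        count_cols = cols[2:]
        counts = df[count_cols].to_numpy()
        if (counts < 0).any():
            raise ValidationError("negative methylation counts")
        df[count_cols] = counts.astype(np.int64)
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValidationError("duplicate (chrom, pos) rows; merge samples instead")
        self.df = df
        self.samples = samples

    # -- basic access -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylomeTable):
            return NotImplemented
        return self.samples == other.samples and self.df.equals(other.df)

    def count_columns(self) -> list[str]:
        return [f"{k}_{s}" for s in self.samples for k in ("meth", "unmeth")]

    def counts(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.df[f"meth_{sample}"].to_numpy(),
            self.df[f"unmeth_{sample}"].to_numpy(),
        )

    def coverage(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """(n_cpgs, n_samples) array of per-sample coverage."""
        samples = list(samples or self.samples)
        return np.stack(
            [self.df[f"meth_{s}"].to_numpy() + self.df[f"unmeth_{s}"].to_numpy()
             for s in samples],
            axis=1,
        )

    def ratios(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-sample methylation ratio per CpG (NaN where coverage is 0)."""
        samples = list(samples or self.samples)
        out = self.df[["chrom", "pos"]].copy()
        for s in samples:
            m = self.df[f"meth_{s}"].to_numpy(dtype=float)
            cov = m + self.df[f"unmeth_{s}"].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[s] = np.where(cov > 0, m / cov, np.nan)
        return out

    def group_mean_ratio(self, samples: Sequence[str]) -> np.ndarray:
        """Mean of per-sample ratios per CpG (NaN-aware)."""
        r = self.ratios(samples)[list(samples)].to_numpy()
        with np.errstate(invalid="ignore"):
            return np.nanmean(r, axis=1)

    def pooled_ratio(self, samples: Sequence[str] | None = None) -> np.ndarray:
        """Ratio of summed counts across samples per CpG."""
        samples = list(samples or self.samples)
        m = sum(self.df[f"meth_{s}"].to_numpy(dtype=float) for s in samples)
        cov = m + sum(self.df[f"unmeth_{s}"].to_numpy(dtype=float) for s in samples)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, m / cov, np.nan)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        chrom: Sequence[str],
        pos: Sequence[int],
        counts: Mapping[str, tuple[Sequence[int], Sequence[int]]],
    ) -> "MethylomeTable":
        """Build from parallel arrays: ``counts[sample] = (meth, unmeth)``."""
        df = pd.DataFrame({"chrom": list(chrom), "pos": list(pos)})
        for s, (m, u) in counts.items():
            df[f"meth_{s}"] = list(m)
            df[f"unmeth_{s}"] = list(u)
        return cls(df, list(counts))

    @staticmethod
    def merge_samples(tables: Sequence["MethylomeTable"]) -> "MethylomeTable":
        """Outer-join single/multi-sample tables; absent CpGs get 0 counts."""
        if not tables:
            raise InputError("merge_samples: no tables given")
        samples: list[str] = []
        merged: pd.DataFrame | None = None
        for t in tables:
            for s in t.samples:
                if s in samples:
                    raise InputError(f"duplicate sample id {s!r}")
            samples += t.samples
            merged = (
                t.df
                if merged is None
                else merged.merge(t.df, on=["chrom", "pos"], how="outer")
            )
        assert merged is not None
        count_cols = [f"{k}_{s}" for s in samples for k in ("meth", "unmeth")]
        merged[count_cols] = merged[count_cols].fillna(0)
        return MethylomeTable(merged, samples)


# ---------------------------------------------------------------------------
# Bismark coverage / bedGraph
# ---------------------------------------------------------------------------


def read_coverage_file(path: str | Path, sample_id: str) -> MethylomeTable:
    """Read a Bismark-style cytosine coverage file (1-based inclusive).

    Columns: chrom, start, end, methylation%, count_methylated,
    count_unmethylated.  Duplicate positions are summed with a warning
    (mirrors strand-merge semantics for files carrying both cytosines).
    """
    path = Path(path)
    rows: dict[tuple[str, int], list[int]] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(parts)}"
                )
            chrom, start_s, _end, _pct, m_s, u_s = parts
            try:
                start, m, u = int(start_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if m < 0 or u < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative counts ({m}, {u})"
                )
            key = (chrom, start - 1)  # to 0-based
            if key in rows:
                n_dup += 1
                rows[key][0] += m
                rows[key][1] += u
            else:
                rows[key] = [m, u]
    if not rows:
        log.warning("%s: empty coverage file", path)
        return MethylomeTable.from_arrays([], [], {sample_id: ([], [])})
    if n_dup:
        log.warning("%s: summed counts at %d duplicated positions", path, n_dup)
    keys = sorted(rows)
    return MethylomeTable.from_arrays(
        [k[0] for k in keys],
        [k[1] for k in keys],
        {sample_id: ([rows[k][0] for k in keys], [rows[k][1] for k in keys])},
    )


def write_coverage_file(table: MethylomeTable, sample_id: str, path: str | Path) -> None:
    """Write one sample as a Bismark-style coverage file (1-based inclusive)."""
    m, u = table.counts(sample_id)
    with open(path, "w") as fh:
        for chrom, pos, mi, ui in zip(table.df["chrom"], table.df["pos"], m, u):
            cov = mi + ui
            pct = 100.0 * mi / cov if cov else 0.0
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{mi}\t{ui}\n")


def write_bedgraph(table: MethylomeTable, sample_id: str, path: str | Path) -> None:
    """Write one sample's methylation percentage as bedGraph (0-based half-open)."""
    m, u = table.counts(sample_id)
    with open(path, "w") as fh:
        for chrom, pos, mi, ui in zip(table.df["chrom"], table.df["pos"], m, u):
            cov = mi + ui
            pct = 100.0 * mi / cov if cov else 0.0
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{pct:.6g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        comment="#",
    )
    return df


# ---------------------------------------------------------------------------
# read-profile TSV dialect and SAM ingestion
# ---------------------------------------------------------------------------


def write_read_profiles(profiles: Iterable[ReadMethProfile], path: str | Path) -> None:
    """TSV dialect: read_id, chrom, comma-joined 0-based positions, comma-joined calls."""
    with open(path, "w") as fh:
        for p in profiles:
            fh.write(
                f"{p.read_id}\t{p.chrom}\t"
                f"{','.join(map(str, p.positions))}\t"
                f"{','.join(map(str, p.calls))}\n"
            )


def read_read_profiles(path: str | Path) -> list[ReadMethProfile]:
    path = Path(path)
    out: list[ReadMethProfile] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            read_id, chrom, pos_s, call_s = parts
            try:
                positions = tuple(int(x) for x in pos_s.split(","))
                calls = tuple(int(x) for x in call_s.split(","))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            out.append(ReadMethProfile(read_id, chrom, positions, calls))
    return out


def read_profiles_from_sam(path: str | Path) -> list[ReadMethProfile]:
    """Extract per-fragment CpG profiles from a Bismark-style SAM/BAM.

    Uses the ``XM`` methylation string (``Z`` methylated CpG, ``z``
    unmethylated CpG).  Mates of one fragment are combined; at CpGs covered
    by both mates the first mate's call is kept, so a fragment contributes
    each CpG once.  Reverse-strand CpG calls (at the G of the forward-strand
    CpG) are shifted by -1 onto the forward-strand cytosine.
    """
    import pysam

    path = str(path)
    mode = "rb" if path.endswith(".bam") else "r"
    frag: dict[str, dict[int, tuple[int, bool]]] = {}
    chrom_of: dict[str, str] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or not aln.has_tag("XM"):
                continue
            xm = aln.get_tag("XM")
            shift = -1 if aln.is_reverse else 0
            name = aln.query_name
            chrom_of.setdefault(name, aln.reference_name)
            calls = frag.setdefault(name, {})
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                code = xm[qpos]
                if code not in "Zz":
                    continue
                pos = rpos + shift
                prev = calls.get(pos)
                # keep read1's call where mates overlap
                if prev is not None and not (prev[1] and not aln.is_read2):
                    continue
                calls[pos] = (1 if code == "Z" else 0, aln.is_read2)
    out = []
    for name, calls in frag.items():
        pos = tuple(sorted(calls))
        out.append(
            ReadMethProfile(name, chrom_of[name], pos, tuple(calls[p][0] for p in pos))
        )
    return out


# ---------------------------------------------------------------------------
# BED / VCF
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (0-based half-open); returns chrom/start/end plus any extras."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]] + [
        f"extra_{i}" for i in range(max(0, df.shape[1] - len(names)))
    ]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_snp_vcf(snps: pd.DataFrame, path: str | Path, sample: str = "embryo") -> None:
    """Write heterozygous SNPs as minimal VCF 4.2 with a GT field.

    ``snps`` columns: chrom, pos (0-based), id, ref, alt, gt (e.g. ``0|1``).
    """
    contigs = list(dict.fromkeys(snps["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for row in snps.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{row.gt}\n"
            )


def read_snp_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF with one sample and GT; positions converted to 0-based."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples[next(iter(rec.samples))]
            gt = sample["GT"]
            sep = "|" if sample.phased else "/"
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.start,
                    "id": rec.id,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "gt": sep.join("." if a is None else str(a) for a in gt),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "gt"])


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def merge_symmetric_cpg(table: MethylomeTable) -> MethylomeTable:
    """Pool counts of the two symmetric cytosines of each CpG dinucleotide.

    Rows at positions ``p`` and ``p+1`` (forward and reverse-strand C of one
    CpG) are summed onto ``p``, left to right.  Idempotent; total counts are
    conserved.
    """
    cols = table.count_columns()
    chroms_out: list[str] = []
    pos_out: list[int] = []
    counts_out: list[np.ndarray] = []
    for chrom, sub in table.df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        counts = sub[cols].to_numpy()
        i = 0
        while i < len(pos):
            if i + 1 < len(pos) and pos[i + 1] == pos[i] + 1:
                chroms_out.append(chrom)
                pos_out.append(int(pos[i]))
                counts_out.append(counts[i] + counts[i + 1])
                i += 2
            else:
                chroms_out.append(chrom)
                pos_out.append(int(pos[i]))
                counts_out.append(counts[i])
                i += 1
    df = pd.DataFrame({"chrom": chroms_out, "pos": pos_out})
    block = (
        np.vstack(counts_out)
        if counts_out
        else np.empty((0, len(cols)), dtype=np.int64)
    )
    for j, c in enumerate(cols):
        df[c] = block[:, j]
    return MethylomeTable(df, table.samples)


def filter_by_coverage(table: MethylomeTable, min_cov: int = 5) -> MethylomeTable:
    """Keep CpGs where every sample has coverage >= ``min_cov``."""
    if min_cov < 1:
        raise InputError(f"min_cov must be >= 1, got {min_cov}")
    keep = (table.coverage() >= min_cov).all(axis=1)
    return MethylomeTable(table.df.loc[keep].reset_index(drop=True), table.samples)
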