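"""Synthetic PA/CN multi-omic data with known parent-of-origin truth.

The generator emulates the uniparental-embryo study design: parthenogenetic
(PA) embryos carry two maternal genomes, biparental control (CN) embryos one
maternal and one paternal genome, and a ``somatic`` sample kind (one allele
from each parent) serves as the positive control for read-level allelic
methylation.  Each gene gets one promoter CpG island inside the strand-aware
[TSS-2000, TSS+1000) window; imprinted genes carry a maternally methylated
germline DMR (igDMR) over that island and are expressed from the paternal
allele only — the configuration observed at the KBTBD6 locus.

Bisulfite reads are single-allele fragments spanning consecutive island
CpGs; per-CpG coverage is exactly Poisson(coverage_mean) by construction
(read starts uniform over the n_cpgs + span - 1 windows, read count Poisson
with mean coverage_mean * n_windows / span).  Expression counts are negative
binomial with an allele-dose mean; a silenced gene leaks at
``leak_fraction`` of its base mean rather than being exactly zero.

All randomness flows from ``SimConfig.seed`` through per-(kind, replicate,
locus) substreams, so partial re-runs are reproducible and same-seed runs are
byte-identical on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io import MethylomeTable, ReadMethProfile

__all__ = [
    "LocusSpec",
    "SimConfig",
    "SimAnnotation",
    "generate_annotation",
    "simulate_methylome",
    "simulate_expression",
    "write_truth_table",
    "read_truth_table",
]

SampleKind = Literal["PA", "CN", "somatic"]

# which parental genomes each sample kind carries, one per allele slot
_ALLELES: dict[str, tuple[str, str]] = {
    "PA": ("maternal", "maternal"),
    "CN": ("maternal", "paternal"),
    "somatic": ("maternal", "paternal"),
}
_KIND_CODE = {"PA": 1, "CN": 2, "somatic": 3}


@dataclass(frozen=True)
class LocusSpec:
    """One gene locus: annotation plus per-allele methylation/expression state."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    body_start: int
    body_end: int
    cpg_positions: tuple[int, ...]
    igdmr_interval: tuple[int, int] | None
    igdmr_parent: str  # maternal | paternal | none
    maternal_meth: float
    paternal_meth: float
    background_meth: float
    expressed_allele: str  # both | paternal_only | maternal_only
    base_expression: float
    snp_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if (self.igdmr_parent == "none") != (self.igdmr_interval is None):
            raise ConfigurationError(
                f"{self.gene_id}: igdmr_parent 'none' iff igdmr_interval absent"
            )
        if self.expressed_allele != "both" and self.igdmr_parent == "none":
            raise ConfigurationError(
                f"{self.gene_id}: imprinted expression requires an igDMR"
            )
        for name in ("maternal_meth", "paternal_meth", "background_meth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{self.gene_id}: {name}={v} outside [0,1]")
        if self.base_expression <= 0:
            raise ConfigurationError(f"{self.gene_id}: base_expression must be > 0")
        if self.strand not in "+-":
            raise ConfigurationError(f"{self.gene_id}: strand must be + or -")

    def meth_prob(self, parent: str) -> np.ndarray:
        """Per-CpG methylation probability on the given parental allele."""
        pos = np.asarray(self.cpg_positions)
        p = np.full(len(pos), self.background_meth)
        if self.igdmr_interval is not None:
            lo, hi = self.igdmr_interval
            inside = (pos >= lo) & (pos < hi)
            allele_p = self.maternal_meth if parent == "maternal" else self.paternal_meth
            p[inside] = allele_p
        return p

    def allele_dose(self, kind: str) -> int:
        """Number of actively expressed alleles in a sample of this kind."""
        active = {
            "both": {"maternal", "paternal"},
            "maternal_only": {"maternal"},
            "paternal_only": {"paternal"},
        }[self.expressed_allele]
        return sum(parent in active for parent in _ALLELES[kind])


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic PA/CN design.

    Defaults match the simulated study conditions: 2 biological replicates
    per group (as in the embryo WGBS/RNA-seq design), 30x CpG coverage,
    0.95/0.05 allele methylation at igDMRs, base expression 500 with a 2%
    leak from silenced alleles.
    """

    n_genes: int = 20
    n_imprinted: int = 1
    cpgs_per_island: int = 30
    cpg_spacing: int = 50
    coverage_mean: float = 30.0
    read_cpg_span: int = 5
    bisulfite_error: float = 0.01
    reps_per_group: int = 2
    nb_dispersion: float = 0.05
    snps_per_gene: int = 2
    snp_depth_mean: float = 30.0
    maternal_meth: float = 0.95
    paternal_meth: float = 0.05
    background_meth: float = 0.05
    base_expression: float = 500.0
    leak_fraction: float = 0.02
    seed: int = 0

    # genome layout constants
    gene_span: int = 20_000
    body_length: int = 4_000

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 0 <= self.n_imprinted <= self.n_genes:
            raise ConfigurationError(
                f"n_imprinted must be in [0, n_genes], got {self.n_imprinted}"
            )
        if self.coverage_mean <= 0:
            raise ConfigurationError(
                f"coverage_mean must be > 0, got {self.coverage_mean}"
            )
        if not 0.0 <= self.bisulfite_error < 0.5:
            raise ConfigurationError(
                f"bisulfite_error must be in [0, 0.5), got {self.bisulfite_error}"
            )
        if self.cpgs_per_island < 1 or self.cpg_spacing < 2:
            raise ConfigurationError("cpgs_per_island >= 1 and cpg_spacing >= 2 required")
        if self.cpgs_per_island * self.cpg_spacing > 1900:
            raise ConfigurationError(
                "cpgs_per_island * cpg_spacing must fit the promoter window (<= 1900 bp)"
            )
        if self.read_cpg_span < 1:
            raise ConfigurationError(f"read_cpg_span must be >= 1, got {self.read_cpg_span}")
        if self.reps_per_group < 1:
            raise ConfigurationError(f"reps_per_group must be >= 1, got {self.reps_per_group}")
        if self.nb_dispersion <= 0:
            raise ConfigurationError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        for name in ("maternal_meth", "paternal_meth", "background_meth"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        if self.leak_fraction < 0:
            raise ConfigurationError(f"leak_fraction must be >= 0, got {self.leak_fraction}")

    def rng(self, *stream: int) -> np.random.Generator:
        """Substream generator keyed on small integers (per kind/rep/locus)."""
        return np.random.default_rng([int(self.seed)] + [int(s) for s in stream])


@dataclass
class SimAnnotation:
    """Annotation bundle emitted by :func:`generate_annotation`."""

    genes: pd.DataFrame  # BED6: chrom start end name score strand
    islands: pd.DataFrame  # BED4: chrom start end name
    snps: pd.DataFrame  # chrom pos id ref alt gt gene_id
    truth: pd.DataFrame  # gene_id igdmr_parent expressed_allele igdmr_start igdmr_end
    loci: list[LocusSpec] = field(default_factory=list)


def generate_annotation(config: SimConfig) -> SimAnnotation:
    """Lay out a toy single-chromosome genome with one promoter island per gene.

    Genes are non-overlapping, strands alternate, and each island lies inside
    the strand-aware [TSS-2000, TSS+1000) window.  ``config.n_imprinted``
    genes (chosen by the seeded generator) get a maternal igDMR over the
    island and paternal-only expression.
    """
    config.validate()
    rng = config.rng(0)
    chrom = "chrS1"
    imprinted = set(
        rng.choice(config.n_genes, size=config.n_imprinted, replace=False).tolist()
    )
    island_span = config.cpgs_per_island * config.cpg_spacing
    bases = np.array(list("ACGT"))

    genes_rows, island_rows, snp_rows, truth_rows, loci = [], [], [], [], []
    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        offset = 5_000 + g * config.gene_span
        strand = "+" if g % 2 == 0 else "-"
        if strand == "+":
            tss = offset
            body = (tss, tss + config.body_length)
        else:
            body = (offset, offset + config.body_length)
            tss = body[1] - 1
        island_start = tss - island_span // 2
        cpg_positions = tuple(
            island_start + k * config.cpg_spacing for k in range(config.cpgs_per_island)
        )
        island = (island_start, cpg_positions[-1] + 2)

        is_imprinted = g in imprinted
        igdmr_interval = island if is_imprinted else None
        igdmr_parent = "maternal" if is_imprinted else "none"
        expressed = "paternal_only" if is_imprinted else "both"

        # heterozygous exonic SNPs, evenly placed in the gene body
        snp_positions = []
        for k in range(config.snps_per_gene):
            p = body[0] + (k + 1) * config.body_length // (config.snps_per_gene + 1)
            ref, alt = rng.choice(bases, size=2, replace=False)
            snp_id = f"snp_{gene_id}_{k}"
            snp_rows.append(
                {"chrom": chrom, "pos": p, "id": snp_id, "ref": ref, "alt": alt,
                 "gt": "0|1", "gene_id": gene_id}
            )
            snp_positions.append(p)

        genes_rows.append(
            {"chrom": chrom, "start": body[0], "end": body[1], "name": gene_id,
             "score": 0, "strand": strand}
        )
        island_rows.append(
            {"chrom": chrom, "start": island[0], "end": island[1],
             "name": f"island_{gene_id}"}
        )
        truth_rows.append(
            {"gene_id": gene_id, "igdmr_parent": igdmr_parent,
             "expressed_allele": expressed,
             "igdmr_start": igdmr_interval[0] if igdmr_interval else pd.NA,
             "igdmr_end": igdmr_interval[1] if igdmr_interval else pd.NA}
        )
        loci.append(
            LocusSpec(
                gene_id=gene_id, chrom=chrom, tss=tss, strand=strand,
                body_start=body[0], body_end=body[1],
                cpg_positions=cpg_positions,
                igdmr_interval=igdmr_interval, igdmr_parent=igdmr_parent,
                maternal_meth=config.maternal_meth,
                paternal_meth=config.paternal_meth,
                background_meth=config.background_meth,
                expressed_allele=expressed,
                base_expression=config.base_expression,
                snp_positions=tuple(snp_positions),
            )
        )

    truth = pd.DataFrame(truth_rows).astype(
        {"igdmr_start": "Int64", "igdmr_end": "Int64"}
    )
    return SimAnnotation(
        genes=pd.DataFrame(genes_rows),
        islands=pd.DataFrame(island_rows),
        snps=pd.DataFrame(snp_rows),
        truth=truth,
        loci=loci,
    )


def simulate_methylome(
    loci: Sequence[LocusSpec],
    config: SimConfig,
    sample_kind: str,
    rep: int = 0,
    sample_id: str | None = None,
    with_profiles: bool = True,
) -> tuple[MethylomeTable, list[ReadMethProfile]]:
    """Simulate one WGBS sample: a count table plus its per-read profiles.

    Reads are single-allele, span up to ``read_cpg_span`` consecutive island
    CpGs, and every covered CpG call is flipped with probability
    ``bisulfite_error``.  The returned table is the exact column-sum marginal
    of the emitted read profiles.
    """
    if not loci:
        raise InputError("simulate_methylome: empty locus list")
    if sample_kind not in _ALLELES:
        raise InputError(f"unknown sample_kind {sample_kind!r}")
    config.validate()
    sample_id = sample_id or f"{sample_kind}{rep + 1}"
    span = config.read_cpg_span

    chroms: list[str] = []
    positions: list[int] = []
    meth: list[np.ndarray] = []
    unmeth: list[np.ndarray] = []
    profiles: list[ReadMethProfile] = []

    parents = _ALLELES[sample_kind]
    for li, locus in enumerate(loci):
        rng = config.rng(_KIND_CODE[sample_kind], rep, li)
        pos = np.asarray(locus.cpg_positions)
        n = len(pos)
        p_by_parent = np.stack(
            [locus.meth_prob(parents[0]), locus.meth_prob(parents[1])]
        )
        n_windows = n + span - 1
        n_reads = rng.poisson(config.coverage_mean * n_windows / span)

        m_counts = np.zeros(n, dtype=np.int64)
        cov_counts = np.zeros(n, dtype=np.int64)
        if n_reads > 0:
            starts = rng.integers(-(span - 1), n, size=n_reads)
            allele = rng.integers(0, 2, size=n_reads)
            idx = starts[:, None] + np.arange(span)[None, :]
            valid = (idx >= 0) & (idx < n)
            idx_c = np.clip(idx, 0, n - 1)
            probs = p_by_parent[allele[:, None], idx_c]
            calls = rng.random((n_reads, span)) < probs
            if config.bisulfite_error > 0:
                flips = rng.random((n_reads, span)) < config.bisulfite_error
                calls = calls ^ flips
            np.add.at(cov_counts, idx_c[valid], 1)
            np.add.at(m_counts, idx_c[valid], calls[valid].astype(np.int64))
            if with_profiles:
                for r in range(n_reads):
                    v = valid[r]
                    profiles.append(
                        ReadMethProfile(
                            f"{sample_id}_{locus.gene_id}_r{r}",
                            locus.chrom,
                            tuple(int(x) for x in pos[idx_c[r][v]]),
                            tuple(int(x) for x in calls[r][v]),
                        )
                    )
        chroms += [locus.chrom] * n
        positions += [int(x) for x in pos]
        meth.append(m_counts)
        unmeth.append(cov_counts - m_counts)

    table = MethylomeTable.from_arrays(
        chroms,
        positions,
        {sample_id: (np.concatenate(meth), np.concatenate(unmeth))},
    )
    return table, profiles


def simulate_expression(
    loci: Sequence[LocusSpec],
    config: SimConfig,
    group: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate RNA-seq gene counts and per-SNP allele counts for one group.

    Per gene and replicate, counts are NB(mean = base_expression x allele
    dose, dispersion = nb_dispersion); a dose of 0 is floored at
    ``leak_fraction`` x base (low-level leakage from the silenced maternal
    alleles).  SNP allele counts are multinomial over the expressed alleles
    only (maternal alleles carry the ref base, paternal the alt).
    """
    if not loci:
        raise InputError("simulate_expression: empty locus list")
    if group not in ("PA", "CN"):
        raise InputError(f"group must be PA or CN, got {group!r}")
    config.validate()
    reps = config.reps_per_group
    parents = _ALLELES[group]
    sample_ids = [f"{group}{r + 1}" for r in range(reps)]

    counts = np.zeros((len(loci), reps), dtype=np.int64)
    snp_rows = []
    for li, locus in enumerate(loci):
        rng = config.rng(_KIND_CODE[group], 900, li)
        dose = locus.allele_dose(group)
        mean = locus.base_expression * (dose if dose > 0 else config.leak_fraction)
        if mean > 0:
            r_nb = 1.0 / config.nb_dispersion
            p_nb = r_nb / (r_nb + mean)
            counts[li] = rng.negative_binomial(r_nb, p_nb, size=reps)
        # expressed parental alleles at this locus in this sample kind
        active = {
            "both": {"maternal", "paternal"},
            "maternal_only": {"maternal"},
            "paternal_only": {"paternal"},
        }[locus.expressed_allele]
        expressed = [p for p in parents if p in active]
        leak_only = not expressed
        if leak_only:
            expressed = [p for p in parents if p == "maternal"] or list(parents)
        frac_maternal = sum(p == "maternal" for p in expressed) / len(expressed)
        rel = dose if dose > 0 else config.leak_fraction
        for k, snp_pos in enumerate(locus.snp_positions):
            for r, sid in enumerate(sample_ids):
                total = int(rng.poisson(config.snp_depth_mean * rel))
                ref_count = int(rng.binomial(total, frac_maternal)) if total else 0
                snp_rows.append(
                    {"snp_id": f"snp_{locus.gene_id}_{k}", "gene_id": locus.gene_id,
                     "chrom": locus.chrom, "pos": snp_pos, "sample": sid,
                     "ref_count": ref_count, "alt_count": total - ref_count}
                )

    count_df = pd.DataFrame(counts, index=[l.gene_id for l in loci], columns=sample_ids)
    count_df.index.name = "gene_id"
    snp_df = pd.DataFrame(
        snp_rows,
        columns=["snp_id", "gene_id", "chrom", "pos", "sample", "ref_count", "alt_count"],
    )
    return count_df, snp_df


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    return df.astype({"igdmr_start": "Int64", "igdmr_end": "Int64"})
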