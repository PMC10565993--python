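"""DMR-to-gene matching and per-gene imprinting verdicts.

A DMR supports imprinting of a gene when it overlaps the strand-aware 3-kb
promoter window (2 kb upstream + 1 kb downstream of the TSS) by at least
one base.  Verdicts combine methylation direction with expression asymmetry
under the uniparental interpretation: maternal hypermethylation (PA > CN)
plus paternal-biased expression (CN > PA DEG) calls a paternally expressed
imprinted gene, and symmetrically for maternal expression.  A matched DMR
whose expression evidence is absent or contradictory yields "inconsistent";
genes without a matched DMR are "not_imprinted".  Allelic-expression
evidence from heterozygous SNPs only annotates verdicts, it never overturns
them (the parent of origin of a monoallelically expressed haplotype is not
identifiable without parental genotypes).

``run_pipeline`` wires the whole analysis on simulated data: annotation ->
WGBS simulation -> strand merge + coverage filter -> segmentation + MWU +
BH -> expression simulation -> NB exact-test DEGs -> SNP allelic calls ->
imprinting verdicts, optionally writing every intermediate artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as mio
from .allelic import AllelicRegionReport, classify_allelic, find_pmds, qualify_reads
from .dmr import DmrCall, call_dmrs, segment_regions, test_region, dmrs_to_bed
from .errors import InputError
from .expression import (CountMatrix, DegResult, SnpAllelicCall, call_degs,
                         classify_allelic_expression)
from .simulate import SimConfig, generate_annotation, simulate_expression, \
    simulate_methylome, write_truth_table

log = logging.getLogger(__name__)

__all__ = ["GeneAnnotation", "ImprintingCall", "tss_window", "match_dmr_to_tss",
           "call_imprinting", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if not self.body_start <= self.tss <= self.body_end:
            raise InputError(
                f"{self.gene_id}: TSS {self.tss} outside body "
                f"[{self.body_start}, {self.body_end}]"
            )


@dataclass
class ImprintingCall:
    gene_id: str
    matched_dmr: DmrCall | None
    dmr_direction: str  # maternal_hyper | paternal_hyper | none
    expression_pattern: str  # paternal_biased | maternal_biased | balanced
    allelic_support: str  # monoallelic | biallelic | unknown
    verdict: str


def tss_window(tss: int, strand: str, upstream: int = 2000, downstream: int = 1000
               ) -> tuple[int, int]:
    """Half-open promoter window: [tss-up, tss+down) on +, mirrored on -."""
    if strand == "+":
        return tss - upstream, tss + downstream
    if strand == "-":
        return tss - downstream + 1, tss + upstream + 1
    raise InputError(f"strand must be + or -, got {strand!r}")


def match_dmr_to_tss(
    dmrs: Sequence[DmrCall],
    genes: Sequence[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 1000,
) -> dict[str, DmrCall]:
    """Best DMR per gene by strand-aware promoter-window overlap.

    Any overlap (>= 1 bp) matches; among several matches the one with the
    largest overlap wins, ties broken by smaller q then leftmost start.
    DMRs on chromosomes absent from the annotation are skipped with a
    warning.
    """
    known_chroms = {g.chrom for g in genes}
    for d in dmrs:
        if d.region.chrom not in known_chroms:
            log.warning("DMR on unknown chromosome %s skipped", d.region.chrom)
    matches: dict[str, DmrCall] = {}
    for gene in genes:
        w_start, w_end = tss_window(gene.tss, gene.strand, upstream, downstream)
        best: tuple[float, float, int] | None = None
        best_dmr: DmrCall | None = None
        for d in dmrs:
            r = d.region
            if r.chrom != gene.chrom:
                continue
            overlap = min(r.end, w_end) - max(r.start, w_start)
            if overlap < 1:
                continue
            key = (-overlap, d.q_value, r.start)
            if best is None or key < best:
                best, best_dmr = key, d
        if best_dmr is not None:
            matches[gene.gene_id] = best_dmr
    return matches


def _expression_pattern(deg: DegResult) -> str:
    if deg.is_deg and deg.log2fc > 0:
        return "paternal_biased"  # CN > PA
    if deg.is_deg and deg.log2fc < 0:
        return "maternal_biased"  # PA > CN
    return "balanced"


def _allelic_support(calls: Sequence[SnpAllelicCall]) -> str:
    verdicts = {c.verdict for c in calls}
    if "biallelic" in verdicts:
        return "biallelic"
    if "monoallelic" in verdicts:
        return "monoallelic"
    return "unknown"


def call_imprinting(
    matches: Mapping[str, DmrCall],
    degs: Sequence[DegResult],
    allelic: Sequence[SnpAllelicCall] | None = None,
) -> list[ImprintingCall]:
    """Integrate DMR direction and expression asymmetry per gene.

    Every gene carrying a matched DMR must appear in ``degs``.
    """
    deg_by_gene = {d.gene_id: d for d in degs}
    missing = set(matches) - set(deg_by_gene)
    if missing:
        raise InputError(f"genes with a matched DMR but no DEG result: {sorted(missing)}")
    allelic_by_gene: dict[str, list[SnpAllelicCall]] = {}
    for c in allelic or []:
        allelic_by_gene.setdefault(c.gene_id, []).append(c)

    out = []
    for gene_id, deg in deg_by_gene.items():
        dmr = matches.get(gene_id)
        direction = dmr.imprint_direction if dmr else "none"
        pattern = _expression_pattern(deg)
        if dmr is None:
            verdict = "not_imprinted"
        elif direction == "maternal_hyper" and pattern == "paternal_biased":
            verdict = "paternally_expressed_imprinted"
        elif direction == "paternal_hyper" and pattern == "maternal_biased":
            verdict = "maternally_expressed_imprinted"
        else:
            verdict = "inconsistent"
        out.append(
            ImprintingCall(
                gene_id=gene_id,
                matched_dmr=dmr,
                dmr_direction=direction,
                expression_pattern=pattern,
                allelic_support=_allelic_support(allelic_by_gene.get(gene_id, [])),
                verdict=verdict,
            )
        )
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline on simulated data
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: SimConfig
    truth: pd.DataFrame
    table: "mio.MethylomeTable"
    regions: list
    dmrs: list[DmrCall]
    degs: list[DegResult]
    snp_calls: list[SnpAllelicCall]
    matches: dict[str, DmrCall]
    calls: list[ImprintingCall]
    allelic_reports: list[AllelicRegionReport] = field(default_factory=list)

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        deg_by_gene = {d.gene_id: d for d in self.degs}
        for c in self.calls:
            r = c.matched_dmr.region if c.matched_dmr else None
            rows.append(
                {"gene_id": c.gene_id,
                 "dmr": f"{r.chrom}:{r.start}-{r.end}" if r else "NA",
                 "dmr_direction": c.dmr_direction,
                 "log2fc": deg_by_gene[c.gene_id].log2fc,
                 "q": deg_by_gene[c.gene_id].q_value,
                 "expression_pattern": c.expression_pattern,
                 "allelic_support": c.allelic_support,
                 "verdict": c.verdict}
            )
        return pd.DataFrame(rows)


def run_pipeline(
    config: SimConfig,
    outdir: str | Path | None = None,
    min_cov: int = 5,
    strand_merge: bool = True,
    max_gap: int = 300,
    min_cpgs: int = 11,
    min_diff: float = 0.2,
    alpha: float = 0.05,
    with_allelic_methylation: bool = False,
) -> PipelineResult:
    """Simulate a PA/CN experiment and run every analysis stage on it.

    With ``outdir`` set, writes every intermediate artifact (annotation BEDs,
    SNP VCF, per-sample coverage files and read profiles, DMR BED, DEG and
    allelic-call TSVs, imprinting calls, run manifest).  Deterministic for a
    fixed config; rerunning with the same seed reproduces the files
    byte-for-byte.
    """
    t0 = time.time()
    ann = generate_annotation(config)
    stage = "simulate_methylome"
    try:
        tables = []
        profiles_by_sample: dict[str, list] = {}
        sample_groups: dict[str, str] = {}
        for kind in ("PA", "CN"):
            for rep in range(config.reps_per_group):
                sid = f"{kind}{rep + 1}"
                tab, profs = simulate_methylome(
                    ann.loci, config, kind, rep=rep, sample_id=sid,
                    with_profiles=with_allelic_methylation or outdir is not None,
                )
                tables.append(tab)
                profiles_by_sample[sid] = profs
                sample_groups[sid] = kind
        table = mio.MethylomeTable.merge_samples(tables)
        if strand_merge:
            table = mio.merge_symmetric_cpg(table)
        filtered = mio.filter_by_coverage(table, min_cov=min_cov)

        stage = "dmr_caller"
        pa = [s for s, g in sample_groups.items() if g == "PA"]
        cn = [s for s, g in sample_groups.items() if g == "CN"]
        regions = segment_regions(filtered, pa, cn, max_gap=max_gap,
                                  min_cpgs=min_cpgs, min_diff=min_diff)
        for r in regions:
            r.p_value = test_region(r, filtered, pa, cn)
        dmrs = call_dmrs(regions, alpha=alpha)

        stage = "allelic_methylation"
        allelic_reports: list[AllelicRegionReport] = []
        if with_allelic_methylation:
            som_tab, som_profs = simulate_methylome(
                ann.loci, config, "somatic", sample_id="somatic1",
            )
            for pmd in find_pmds(som_tab, ann.islands):
                qualified = qualify_reads(pmd, som_profs)
                allelic_reports.append(classify_allelic(pmd, qualified))

        stage = "expression_analysis"
        counts_pa, snps_pa = simulate_expression(ann.loci, config, "PA")
        counts_cn, snps_cn = simulate_expression(ann.loci, config, "CN")
        counts = pd.concat([counts_pa, counts_cn], axis=1)
        lengths = pd.Series(
            (ann.genes["end"] - ann.genes["start"]).to_numpy(dtype=float),
            index=ann.genes["name"].to_numpy(),
        )
        groups = {s: ("PA" if s.startswith("PA") else "CN") for s in counts.columns}
        cm = CountMatrix(counts=counts, lengths=lengths, groups=groups)
        degs = call_degs(cm, group_a="PA", group_b="CN", alpha=alpha)

        # allelic expression from the biparental (CN) replicates only
        geno = {row.id: (row.ref, row.alt) for row in ann.snps.itertuples(index=False)}
        agg = (
            snps_cn.groupby(["snp_id", "gene_id"], sort=True)[["ref_count", "alt_count"]]
            .sum()
            .reset_index()
        )
        snp_calls = [
            classify_allelic_expression(
                row.snp_id, row.gene_id, geno[row.snp_id],
                int(row.ref_count), int(row.alt_count),
            )
            for row in agg.itertuples(index=False)
        ]

        stage = "imprinting_caller"
        gene_ann = [
            GeneAnnotation(
                gene_id=l.gene_id, chrom=l.chrom, strand=l.strand, tss=l.tss,
                body_start=l.body_start, body_end=l.body_end,
            )
            for l in ann.loci
        ]
        matches = match_dmr_to_tss(dmrs, gene_ann)
        calls = call_imprinting(matches, degs, snp_calls)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        config=config, truth=ann.truth, table=filtered, regions=regions,
        dmrs=dmrs, degs=degs, snp_calls=snp_calls, matches=matches,
        calls=calls, allelic_reports=allelic_reports,
    )
    if outdir is not None:
        _write_artifacts(Path(outdir), ann, tables, profiles_by_sample, result)
    log.info("pipeline finished in %.1f s (%d DMRs, %d DEGs)",
             time.time() - t0, len(dmrs), sum(d.is_deg for d in degs))
    return result


def _write_artifacts(outdir, ann, tables, profiles_by_sample, result):
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_bed(ann.genes, outdir / "genes.bed")
    mio.write_bed(ann.islands, outdir / "cpg_islands.bed")
    mio.write_snp_vcf(ann.snps[["chrom", "pos", "id", "ref", "alt", "gt"]],
                      outdir / "snps.vcf")
    write_truth_table(ann.truth, outdir / "truth.tsv")
    for tab in tables:
        sid = tab.samples[0]
        mio.write_coverage_file(tab, sid, outdir / f"{sid}.cov.tsv")
        mio.write_bedgraph(tab, sid, outdir / f"{sid}.bedGraph")
        if profiles_by_sample.get(sid):
            mio.write_read_profiles(profiles_by_sample[sid],
                                    outdir / f"{sid}.reads.tsv")
    mio.write_bed(dmrs_to_bed(result.dmrs), outdir / "dmrs.bed")
    pd.DataFrame([asdict(d) for d in result.degs]).to_csv(
        outdir / "degs.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(c) for c in result.snp_calls]).to_csv(
        outdir / "allelic_expression.tsv", sep="\t", index=False)
    result.calls_frame().to_csv(outdir / "imprinting_calls.tsv", sep="\t", index=False)
    for i, rep in enumerate(result.allelic_reports):
        rep.read_matrix.to_csv(
            outdir / f"amr_{i}_{rep.pmd.chrom}_{rep.pmd.start}.matrix.tsv",
            sep="\t", na_rep="NA")
    manifest = {"config": asdict(result.config),
                "n_dmrs": len(result.dmrs),
                "n_degs": int(sum(d.is_deg for d in result.degs))}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
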