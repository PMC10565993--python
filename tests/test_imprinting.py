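"""TSS-window matching, verdict logic, and end-to-end truth recovery."""

import numpy as np
import pytest

from imprintkit.dmr import DmrCall, MethRegion
from imprintkit.errors import InputError
from imprintkit.expression import DegResult, SnpAllelicCall
from imprintkit.imprinting import (GeneAnnotation, call_imprinting,
                                   match_dmr_to_tss, run_pipeline, tss_window)
from imprintkit.simulate import SimConfig


def _dmr(chrom, start, end, q=0.01, direction="maternal_hyper"):
    region = MethRegion(chrom, start, end, 15, 0.9, 0.1,
                        tuple(range(start, end, 50))[:15], p_value=q / 10)
    return DmrCall(region=region, q_value=q, imprint_direction=direction)


def _gene(gene_id="g1", chrom="chr1", strand="+", tss=10_000):
    if strand == "+":
        body = (tss, tss + 4000)
    else:
        body = (tss - 3999, tss + 1)
    return GeneAnnotation(gene_id, chrom, strand, tss, body[0], body[1])


def _deg(gene_id="g1", log2fc=0.0, is_deg=False, q=0.5):
    return DegResult(gene_id, log2fc, q / 10, q, is_deg)


class TestTssWindow:
    @pytest.mark.parametrize("strand", "+-")
    @pytest.mark.parametrize("tss", [0, 5_000, 123_457])
    def test_window_is_three_kb(self, strand, tss):
        start, end = tss_window(tss, strand)
        assert end - start == 3000
        assert start <= tss < end

    def test_plus_strand_bounds(self):
        assert tss_window(10_000, "+") == (8_000, 11_000)

    def test_minus_strand_bounds(self):
        # upstream lies to the right on the minus strand
        start, end = tss_window(10_000, "-")
        assert (start, end) == (9_001, 12_001)


class TestMatchDmrToTss:
    def test_upstream_dmr_matches_plus_gene(self):
        matches = match_dmr_to_tss([_dmr("chr1", 8_500, 9_000)], [_gene()])
        assert "g1" in matches

    def test_beyond_downstream_no_match(self):
        matches = match_dmr_to_tss([_dmr("chr1", 11_001, 11_500)], [_gene()])
        assert matches == {}

    def test_minus_strand_upstream_matches(self):
        gene = _gene(strand="-")
        matches = match_dmr_to_tss([_dmr("chr1", 11_500, 11_900)], [gene])
        assert "g1" in matches

    def test_single_bp_overlap_suffices(self):
        matches = match_dmr_to_tss([_dmr("chr1", 10_999, 11_400)], [_gene()])
        assert "g1" in matches

    def test_best_match_by_overlap_then_q(self):
        big = _dmr("chr1", 8_000, 9_500, q=0.04)
        small_better_q = _dmr("chr1", 10_500, 10_900, q=0.001)
        matches = match_dmr_to_tss([small_better_q, big], [_gene()])
        assert matches["g1"] is big
        # equal overlap -> smaller q wins
        a = _dmr("chr1", 9_000, 9_400, q=0.04)
        b = _dmr("chr1", 10_000, 10_400, q=0.001)
        matches = match_dmr_to_tss([a, b], [_gene()])
        assert matches["g1"] is b

    def test_unknown_chrom_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            matches = match_dmr_to_tss([_dmr("chrUn", 8_500, 9_000)], [_gene()])
        assert matches == {} and "unknown chromosome" in caplog.text

    def test_strand_reflection_mirrors_matches(self):
        rng = np.random.default_rng(0)
        length = 100_000
        genes, dmrs = [], []
        for i in range(8):
            strand = "+" if i % 2 == 0 else "-"
            tss = int(rng.integers(6_000, 90_000))
            genes.append(_gene(f"g{i}", strand=strand, tss=tss))
            s = int(rng.integers(1_000, 95_000))
            dmrs.append(_dmr("chr1", s, s + int(rng.integers(200, 1500))))
        flip = {"+": "-", "-": "+"}
        genes_m = [
            GeneAnnotation(g.gene_id, g.chrom, flip[g.strand], length - 1 - g.tss,
                           length - g.body_end, length - g.body_start)
            for g in genes
        ]
        dmrs_m = [
            _dmr("chr1", length - d.region.end, length - d.region.start,
                 q=d.q_value)
            for d in dmrs
        ]
        fwd = match_dmr_to_tss(dmrs, genes)
        mir = match_dmr_to_tss(dmrs_m, genes_m)
        fwd_set = {(g, m.region.start, m.region.end) for g, m in fwd.items()}
        mir_set = {(g, length - m.region.end, length - m.region.start)
                   for g, m in mir.items()}
        assert fwd_set == mir_set


class TestCallImprinting:
    def test_kbtbd6_configuration(self):
        # maternal promoter methylation + CN-exclusive expression
        matches = {"g1": _dmr("chr1", 8_500, 9_000, direction="maternal_hyper")}
        degs = [_deg("g1", log2fc=3.5, is_deg=True, q=0.001)]
        (call,) = call_imprinting(matches, degs)
        assert call.verdict == "paternally_expressed_imprinted"

    def test_reverse_configuration(self):
        matches = {"g1": _dmr("chr1", 8_500, 9_000, direction="paternal_hyper")}
        degs = [_deg("g1", log2fc=-2.0, is_deg=True, q=0.001)]
        (call,) = call_imprinting(matches, degs)
        assert call.verdict == "maternally_expressed_imprinted"

    def test_no_dmr_balanced_not_imprinted(self):
        (call,) = call_imprinting({}, [_deg("g1")])
        assert call.verdict == "not_imprinted"

    def test_contradiction_is_inconsistent(self):
        matches = {"g1": _dmr("chr1", 8_500, 9_000, direction="maternal_hyper")}
        degs = [_deg("g1", log2fc=-2.0, is_deg=True, q=0.001)]
        (call,) = call_imprinting(matches, degs)
        assert call.verdict == "inconsistent"

    def test_dmr_without_deg_is_inconsistent(self):
        matches = {"g1": _dmr("chr1", 8_500, 9_000)}
        (call,) = call_imprinting(matches, [_deg("g1")])
        assert call.verdict == "inconsistent"

    def test_missing_deg_for_matched_gene_errors(self):
        matches = {"g1": _dmr("chr1", 8_500, 9_000)}
        with pytest.raises(InputError):
            call_imprinting(matches, [_deg("g2")])

    def test_allelic_support_annotates_not_overturns(self):
        matches = {"g1": _dmr("chr1", 8_500, 9_000, direction="maternal_hyper")}
        degs = [_deg("g1", log2fc=3.0, is_deg=True, q=0.001)]
        allelic = [SnpAllelicCall("s1", "g1", ("A", "G"), 0, 40, 1.0, "monoallelic"),
                   SnpAllelicCall("s2", "g1", ("C", "T"), 3, 2, 0.6, "indeterminate")]
        (call,) = call_imprinting(matches, degs, allelic)
        assert call.verdict == "paternally_expressed_imprinted"
        assert call.allelic_support == "monoallelic"
        biallelic = [SnpAllelicCall("s1", "g1", ("A", "G"), 20, 22, 0.52, "biallelic")]
        (call,) = call_imprinting(matches, degs, biallelic)
        assert call.verdict == "paternally_expressed_imprinted"
        assert call.allelic_support == "biallelic"


class TestPipeline:
    def test_planted_gene_recovered(self):
        result = run_pipeline(SimConfig(seed=1))
        truth = result.truth.set_index("gene_id")
        planted = truth[truth["igdmr_parent"] == "maternal"].index[0]
        verdicts = {c.gene_id: c for c in result.calls}
        assert verdicts[planted].verdict == "paternally_expressed_imprinted"
        assert verdicts[planted].allelic_support == "monoallelic"
        others = [c for c in result.calls if c.gene_id != planted]
        assert all(not c.verdict.endswith("_expressed_imprinted") for c in others)

    def test_dmr_overlaps_truth_interval(self):
        result = run_pipeline(SimConfig(seed=1))
        truth = result.truth.set_index("gene_id")
        row = truth[truth["igdmr_parent"] == "maternal"].iloc[0]
        lo, hi = int(row["igdmr_start"]), int(row["igdmr_end"])
        jac = max(
            (min(d.region.end, hi) - max(d.region.start, lo))
            / (max(d.region.end, hi) - min(d.region.start, lo))
            for d in result.dmrs
        )
        assert jac >= 0.5

    def test_no_imprinting_no_verdicts(self):
        result = run_pipeline(SimConfig(seed=2, n_imprinted=0))
        assert all(not c.verdict.endswith("_expressed_imprinted") for c in result.calls)

    def test_rerun_same_seed_identical_outputs(self, tmp_path):
        blobs = []
        for run in range(2):
            d = tmp_path / f"run{run}"
            run_pipeline(SimConfig(seed=3, n_genes=6), outdir=d,
                         with_allelic_methylation=True)
            blobs.append(
                {p.name: p.read_bytes() for p in sorted(d.iterdir())
                 if p.suffix != ".log"}
            )
        assert blobs[0] == blobs[1]
        assert "imprinting_calls.tsv" in blobs[0]
        assert "manifest.json" in blobs[0]
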