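"""Synthetic-data generator: composition, determinism, allele-dose laws."""

import numpy as np
import pytest
from scipy import stats

from imprintkit import io as mio
from imprintkit.errors import ConfigurationError, InputError
from imprintkit.imprinting import tss_window
from imprintkit.simulate import (SimConfig, generate_annotation,
                                 read_truth_table, simulate_expression,
                                 simulate_methylome, write_truth_table)


class TestAnnotation:
    def test_no_imprinting_requested(self):
        ann = generate_annotation(SimConfig(n_genes=1, n_imprinted=0, seed=7))
        assert len(ann.loci) == 1
        assert ann.truth["igdmr_parent"].tolist() == ["none"]

    def test_requested_composition(self):
        ann = generate_annotation(SimConfig(n_genes=20, n_imprinted=1, seed=1))
        imp = ann.truth[ann.truth["igdmr_parent"] == "maternal"]
        assert len(imp) == 1
        assert imp["expressed_allele"].tolist() == ["paternal_only"]
        assert (ann.truth["igdmr_parent"] != "maternal").sum() == 19

    def test_islands_inside_promoter_window(self):
        ann = generate_annotation(SimConfig(n_genes=10, seed=3))
        islands = ann.islands.set_index("name")
        for locus in ann.loci:
            w_start, w_end = tss_window(locus.tss, locus.strand)
            row = islands.loc[f"island_{locus.gene_id}"]
            assert w_start <= row["start"] and row["end"] <= w_end

    def test_genes_non_overlapping(self):
        ann = generate_annotation(SimConfig(n_genes=15, seed=5))
        g = ann.genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_byte_identical_outputs_under_fixed_seed(self, tmp_path):
        blobs = []
        for run in range(2):
            cfg = SimConfig(n_genes=5, n_imprinted=1, seed=11)
            ann = generate_annotation(cfg)
            tab, profs = simulate_methylome(ann.loci, cfg, "PA", sample_id="PA1")
            counts, snps = simulate_expression(ann.loci, cfg, "CN")
            d = tmp_path / f"run{run}"
            d.mkdir()
            mio.write_bed(ann.genes, d / "genes.bed")
            mio.write_snp_vcf(ann.snps[["chrom", "pos", "id", "ref", "alt", "gt"]],
                              d / "snps.vcf")
            mio.write_coverage_file(tab, "PA1", d / "cov.tsv")
            mio.write_read_profiles(profs, d / "reads.tsv")
            counts.to_csv(d / "counts.tsv", sep="\t")
            write_truth_table(ann.truth, d / "truth.tsv")
            blobs.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
        assert blobs[0] == blobs[1]

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="bisulfite_error"):
            generate_annotation(SimConfig(bisulfite_error=0.7))
        with pytest.raises(ConfigurationError, match="n_imprinted"):
            generate_annotation(SimConfig(n_genes=2, n_imprinted=3))

    def test_truth_table_round_trip(self, tmp_path):
        ann = generate_annotation(SimConfig(n_genes=6, n_imprinted=2, seed=2))
        path = tmp_path / "truth.tsv"
        write_truth_table(ann.truth, path)
        back = read_truth_table(path)
        assert back.equals(ann.truth)


class TestMethylomeSimulation:
    CFG = SimConfig(n_genes=2, n_imprinted=1, seed=4,
                    maternal_meth=1.0, paternal_meth=0.0, bisulfite_error=0.0)

    def _igdmr_mask(self, ann, table):
        truth = ann.truth.set_index("gene_id")
        gid = truth[truth["igdmr_parent"] == "maternal"].index[0]
        lo = int(truth.loc[gid, "igdmr_start"])
        hi = int(truth.loc[gid, "igdmr_end"])
        pos = table.df["pos"].to_numpy()
        return (pos >= lo) & (pos < hi)

    def test_pa_igdmr_ratio_degenerate_at_one(self):
        ann = generate_annotation(self.CFG)
        tab, _ = simulate_methylome(ann.loci, self.CFG, "PA", sample_id="s")
        ratios = tab.pooled_ratio()[self._igdmr_mask(ann, tab)]
        assert np.all(ratios == 1.0)

    def test_cn_igdmr_ratio_near_half(self):
        cfg = SimConfig(n_genes=1, n_imprinted=1, seed=8, maternal_meth=1.0,
                        paternal_meth=0.0, bisulfite_error=0.0,
                        coverage_mean=2000.0)
        ann = generate_annotation(cfg)
        tab, profs = simulate_methylome(ann.loci, cfg, "CN", sample_id="s")
        assert len(profs) > 10_000
        m, u = tab.counts("s")
        mean_ratio = m.sum() / (m + u).sum()
        # allele choice is per read, so the binomial unit is the read
        assert abs(mean_ratio - 0.5) < 3 * 0.5 / np.sqrt(len(profs))

    def test_cn_reads_are_single_allele(self):
        ann = generate_annotation(self.CFG)
        _, profs = simulate_methylome(ann.loci, self.CFG, "CN", sample_id="s")
        truth = ann.truth.set_index("gene_id")
        gid = truth[truth["igdmr_parent"] == "maternal"].index[0]
        lo, hi = int(truth.loc[gid, "igdmr_start"]), int(truth.loc[gid, "igdmr_end"])
        for p in profs:
            sub = p.restrict(lo, hi)
            if sub is not None:
                assert sub.level in (0.0, 1.0)

    def test_table_is_marginal_of_profiles(self, default_config, annotation):
        tab, profs = simulate_methylome(annotation.loci, default_config, "CN",
                                        sample_id="CN1")
        m_exp = {}
        cov_exp = {}
        for p in profs:
            for pos, c in zip(p.positions, p.calls):
                cov_exp[pos] = cov_exp.get(pos, 0) + 1
                m_exp[pos] = m_exp.get(pos, 0) + c
        m, u = tab.counts("CN1")
        for pos, mi, ui in zip(tab.df["pos"], m, u):
            assert m_exp.get(pos, 0) == mi
            assert cov_exp.get(pos, 0) - m_exp.get(pos, 0) == ui

    def test_per_cpg_coverage_is_poisson_mean(self):
        cfg = SimConfig(n_genes=1, n_imprinted=0, seed=9, coverage_mean=50.0)
        ann = generate_annotation(cfg)
        tab, _ = simulate_methylome(ann.loci, cfg, "PA", sample_id="s",
                                    with_profiles=False)
        cov = tab.coverage().ravel()
        se = np.sqrt(50.0 / len(cov))
        assert abs(cov.mean() - 50.0) < 4 * se * np.sqrt(len(cov) / len(cov))
        assert abs(cov.mean() - 50.0) < 4 * np.sqrt(50.0 / len(cov))

    def test_empty_spec_rejected(self, default_config):
        with pytest.raises(InputError):
            simulate_methylome([], default_config, "PA")
        ann = generate_annotation(default_config)
        with pytest.raises(InputError):
            simulate_methylome(ann.loci, default_config, "oocyte")


class TestExpressionSimulation:
    def test_paternal_only_gene_silent_in_pa_without_leak(self):
        cfg = SimConfig(n_genes=3, n_imprinted=1, seed=5, leak_fraction=0.0,
                        reps_per_group=4)
        ann = generate_annotation(cfg)
        counts, _ = simulate_expression(ann.loci, cfg, "PA")
        truth = ann.truth.set_index("gene_id")
        gid = truth[truth["expressed_allele"] == "paternal_only"].index[0]
        assert (counts.loc[gid] == 0).all()

    def test_biallelic_gene_same_law_in_both_groups(self):
        cfg = SimConfig(n_genes=1, n_imprinted=0, seed=6, reps_per_group=50)
        ann = generate_annotation(cfg)
        pa, _ = simulate_expression(ann.loci, cfg, "PA")
        cn, _ = simulate_expression(ann.loci, cfg, "CN")
        res = stats.mannwhitneyu(pa.iloc[0], cn.iloc[0], alternative="two-sided")
        assert res.pvalue > 0.01

    def test_cn_monoallelic_snp_counts_on_paternal_allele(self):
        cfg = SimConfig(n_genes=3, n_imprinted=1, seed=7)
        ann = generate_annotation(cfg)
        _, snps = simulate_expression(ann.loci, cfg, "CN")
        truth = ann.truth.set_index("gene_id")
        gid = truth[truth["expressed_allele"] == "paternal_only"].index[0]
        sub = snps[snps["gene_id"] == gid]
        assert sub["alt_count"].sum() > 0
        assert (sub["ref_count"] == 0).all()  # paternal haplotype carries alt

    def test_pa_snp_counts_all_maternal(self):
        cfg = SimConfig(n_genes=2, n_imprinted=0, seed=8)
        ann = generate_annotation(cfg)
        _, snps = simulate_expression(ann.loci, cfg, "PA")
        assert (snps["alt_count"] == 0).all()
        assert snps["ref_count"].sum() > 0
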