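"""Generator contracts: determinism, exact category accounting, planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmet import synthetic_data as sd
from mirmet.core import SyntheticTruth

from conftest import null_two_group_design


class TestGenerateReference:
    def test_counts_and_clades(self):
        refs = sd.generate_reference(5, 0, seed=1)
        assert len(refs) == 5
        assert all(r.clade_tag == "target" for r in refs)
        refs2 = sd.generate_reference(3, 2, seed=7)
        assert sum(r.clade_tag == "contaminant" for r in refs2) == 2

    def test_deterministic(self):
        a = sd.generate_reference(8, 2, seed=1)
        b = sd.generate_reference(8, 2, seed=1)
        assert a == b

    def test_pairwise_separation(self, refs):
        seqs = [r.mature_seq for r in refs]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert sd._seq_distance(seqs[i], seqs[j]) >= 3

    def test_near_duplicates_on_request(self):
        refs = sd.generate_reference(4, 0, seed=3, n_near_duplicates=2)
        assert len(refs) == 6
        base = {r.annotation_id: r.mature_seq for r in refs}
        for k in (1, 2):
            orig = base[f"Mir-{k}_5p"]
            var = base[f"Mir-{k}_5p-v2"]
            assert sum(a != b for a, b in zip(orig, var)) == 1

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_reference(0, 2, seed=1)


class TestSimulateCounts:
    def test_zero_effect_poisson_groups_differ_only_by_libsize(self):
        design = null_two_group_design(seed=2, n_per_group=40, n_mirnas=50,
                                       dispersion=0.0)
        design.concentration = 1e9  # effectively no mixing noise
        cm, _ = sd.simulate_counts(design)
        norm = cm.counts / cm.counts.sum(axis=0)
        g1 = norm[cm.tissue_samples("pCRC")].mean(axis=1)
        g2 = norm[cm.tissue_samples("nCR")].mean(axis=1)
        # proportions agree once library size is divided out
        ratio = np.log2(g1 / g2)
        assert np.abs(ratio[g1 > 1e-4]).max() < 0.2

    def test_planted_lfc_recovered_in_group_means(self):
        errs = []
        for seed in range(20):
            design = null_two_group_design(
                seed=seed, n_per_group=20, n_mirnas=80, dispersion=0.01,
                tissues=("pCRC", "mLi"))
            m = design.mirnas[0]
            design.celltype_programs.loc[m] = 500.0
            design.planted_met_effects = {m: {"mLi": 1.0}}
            cm, truth = sd.simulate_counts(design)
            norm = cm.counts / cm.counts.sum(axis=0)
            lfc = np.log2(norm.loc[m, cm.tissue_samples("mLi")].mean()
                          / norm.loc[m, cm.tissue_samples("pCRC")].mean())
            errs.append(lfc - 1.0)
            assert (m, "mLi", 1) in truth.met_de
        assert abs(np.mean(errs)) < 0.2

    def test_fixed_library_size(self):
        design = null_two_group_design(seed=3, n_per_group=2, n_mirnas=100,
                                       dispersion=0.0)
        design.libsize_range = (1e6, 1e6)
        cm, _ = sd.simulate_counts(design)
        totals = cm.counts.sum(axis=0)
        assert ((totals - 1e6).abs() / 1e6 < 0.01).all()

    def test_deterministic(self):
        design = null_two_group_design(seed=11, n_per_group=3, n_mirnas=30)
        cm1, _ = sd.simulate_counts(design)
        cm2, _ = sd.simulate_counts(design)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)

    def test_empty_tissue_list_rejected(self):
        design = null_two_group_design(seed=1, n_per_group=3, n_mirnas=20)
        with pytest.raises(ValueError):
            sd.SimulationDesign(
                tissues={},
                celltype_programs=design.celltype_programs,
                mixing_mean=design.mixing_mean,
            )


class TestSimulateReads:
    def test_exact_category_counts(self, refs):
        reads, truth = sd.simulate_reads(
            refs, {"mirna": 1.0}, 100, seed=1)
        assert len(reads) == 100
        assert (truth["category"] == "mirna").all()

        reads, truth = sd.simulate_reads(
            refs, {"mirna": 0.5, "short": 0.5}, 10, seed=1)
        counts = truth["category"].value_counts()
        assert counts["mirna"] == 5 and counts["short"] == 5

    def test_largest_remainder_conserves_total(self, refs):
        fr = {"mirna": 1 / 3, "short": 1 / 3, "low_quality": 1 / 3}
        reads, truth = sd.simulate_reads(refs, fr, 100, seed=4)
        assert len(reads) == 100
        assert truth["category"].value_counts().sum() == 100

    def test_deterministic_bytes(self, refs, tmp_path):
        out = []
        for _ in range(2):
            reads, _ = sd.simulate_reads(
                refs, {"mirna": 0.6, "other_rna": 0.4}, 50, seed=9)
            p = tmp_path / "x.fastq"
            sd.write_fastq(reads, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_category_construction_contracts(self, refs):
        reads, truth = sd.simulate_reads(
            refs, {"mirna": 0.3, "low_quality": 0.2, "short": 0.2,
                   "low_complexity": 0.2, "other_rna": 0.1}, 200, seed=5)
        by_id = {r.read_id: r for r in reads}
        for _, row in truth.iterrows():
            read = by_id[row.read_id]
            if row.category == "low_quality":
                assert np.mean(read.qual > 20) < 0.5
            elif row.category == "short":
                assert row.trimmed_len < 18
            elif row.category == "low_complexity":
                insert = read.seq[:row.trimmed_len]
                assert len(set(insert)) <= 2
            elif row.category == "mirna":
                assert row.trimmed_len >= 18
                assert np.mean(read.qual > 20) >= 0.5

    def test_bad_fractions_rejected(self, refs):
        with pytest.raises(ValueError):
            sd.simulate_reads(refs, {"mirna": 0.7}, 10, seed=1)


class TestSimulateInteractions:
    def test_no_suppression_means_independence(self):
        mirnas = [f"Mir-{i}_5p" for i in range(1, 41)]
        truth = SyntheticTruth()
        ok = 0
        for seed in range(20):
            inter, sets = sd.simulate_interactions_and_sets(
                500, mirnas, truth, seed=seed)
            in_union = {g for members in sets.values() for g in members}
            n_in = len(in_union)
            links_in = inter["gene_id"].isin(in_union).sum()
            links_out = len(inter) - links_in
            exp = np.array([n_in, 500 - n_in]) / 500 * len(inter)
            p = stats.chisquare([links_in, links_out], exp).pvalue
            ok += p > 0.01
        assert ok >= 18

    def test_suppressed_set_enriched_in_smrna(self):
        from mirmet import gsea
        mirnas = [f"Mir-{i}_5p" for i in range(1, 41)]
        truth = SyntheticTruth(
            met_de={(m, "mLi", 1) for m in mirnas[:8]},
            suppressed_gene_sets={"SET_01"})
        inter, sets = sd.simulate_interactions_and_sets(
            500, mirnas, truth, seed=2)
        scores = pd.Series({m: 3.0 if m in mirnas[:8] else 0.0
                            for m in mirnas})
        smrna = gsea.s_mrna(scores, inter)
        inside = smrna.reindex(sets["SET_01"]).fillna(0).mean()
        outside = smrna.reindex(
            sorted(set(smrna.index) - set(sets["SET_01"]))).mean()
        assert inside > outside

    def test_gmt_round_trip(self, tmp_path):
        from mirmet.gsea import read_gmt, write_gmt
        mirnas = ["Mir-1_5p"]
        inter, sets = sd.simulate_interactions_and_sets(
            50, mirnas, SyntheticTruth(), seed=1, n_sets=5, set_size=8)
        p = tmp_path / "sets.gmt"
        write_gmt(sets, p)
        assert read_gmt(p) == sets

    def test_suppression_without_up_mirna_rejected(self):
        truth = SyntheticTruth(suppressed_gene_sets={"SET_01"})
        with pytest.raises(ValueError):
            sd.simulate_interactions_and_sets(50, ["Mir-1_5p"], truth, seed=1)


class TestSimulateQPCR:
    def test_replicate_structure(self):
        df = sd.simulate_qpcr(5, delta=-1.0, sd=0.5, seed=1)
        reps = df.groupby(["sample_id", "assay"])["replicate"].count()
        assert (reps == 2).all()
        assert set(df["group"]) == {"case", "control"}

    def test_expected_delta(self):
        # mean dCq difference over many seeds approaches the planted delta
        diffs = []
        for seed in range(100):
            df = sd.simulate_qpcr(6, delta=-2.0, sd=0.5, seed=seed)
            from mirmet.qpcr import delta_cq
            dcq = delta_cq(df)
            diffs.append(dcq[dcq.group == "case"].dcq.mean()
                         - dcq[dcq.group == "control"].dcq.mean())
        assert abs(np.mean(diffs) - (-2.0)) < 0.15

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sd.simulate_qpcr(1, delta=0.0, sd=0.5, seed=1)
        with pytest.raises(ValueError):
            sd.simulate_qpcr(5, delta=0.0, sd=0.0, seed=1)
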