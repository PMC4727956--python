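"""Trimming, frame assignment, codon alignment, the exclusion filters,
gene trees and parsimony-informative-site counting."""

import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exoncap import alignfilter as af
from exoncap.config import AlignFilterParams

from conftest import random_dna


def aln(rows_by_taxon, gene_id="g1", **kw):
    taxa = list(rows_by_taxon)
    return af.GeneAlignment(gene_id, taxa, [rows_by_taxon[t] for t in taxa], **kw)


class TestTrimToReference:
    def test_no_reference_gaps_unchanged(self):
        a = aln({"ref": "ACGTAC", "x": "AC--AC"})
        out = af.trim_to_reference(a, "ref")
        assert out.rows == a.rows

    def test_inserted_columns_removed(self):
        a = aln({"ref": "AC----GTAC", "x": "ACGGGGGTAC"})
        out = af.trim_to_reference(a, "ref")
        assert out.row("ref") == "ACGTAC"
        assert out.row("x") == "ACGTAC"
        assert out.n_columns == 6

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError):
            af.trim_to_reference(aln({"x": "ACGT"}), "ref")

    def test_idempotent_and_reference_gap_free(self, rng):
        base = random_dna(rng, 60)
        ref = list(base)
        other = list(base)
        for j in sorted(rng.choice(60, size=10, replace=False)):
            ref[j] = "-"
            other[j] = "ACGT"[int(rng.integers(4))]
        a = aln({"ref": "".join(ref), "x": "".join(other)})
        once = af.trim_to_reference(a, "ref")
        twice = af.trim_to_reference(once, "ref")
        assert "-" not in once.row("ref")
        assert once.rows == twice.rows


class TestReadingFrame:
    def test_identical_sequence_no_flag(self, rng):
        cds = random_dna(rng, 120)
        framed, flag = af.assign_reading_frame(cds, cds, 0)
        assert framed == cds and not flag

    def test_single_base_deletion_flags(self, rng):
        cds = random_dna(rng, 120)
        framed, flag = af.assign_reading_frame(cds[:60] + cds[61:], cds, 0)
        assert flag

    def test_codon_deletion_no_flag(self, rng):
        cds = random_dna(rng, 120)
        _, flag = af.assign_reading_frame(cds[:60] + cds[63:], cds, 0)
        assert not flag

    def test_frame_offset_trims_to_codon_start(self, rng):
        cds = random_dna(rng, 120)
        framed, _ = af.assign_reading_frame(cds, cds, frame_offset=1)
        assert framed == cds[2 : 2 + 117]
        assert len(framed) % 3 == 0


class TestCodonAlign:
    def test_identical_sequences_gapless(self, rng):
        s = random_dna(rng, 60)
        arr = list(s)
        for i in range(0, 60, 3):       # scrub in-frame stops
            if "".join(arr[i:i+3]) in ("TAA", "TAG", "TGA"):
                arr[i:i+3] = "GCT"
        s = "".join(arr)
        a, anomalies = af.codon_align({"t1": s, "t2": s, "t3": s})
        assert anomalies == {}
        assert a.rows == [s, s, s]

    def test_one_codon_deletion_single_triplet_gap(self):
        ref = "ATGGCTGCAAAAGGT"          # M A A K G
        short = "ATGGCTAAAGGT"           # M A K G (one codon removed)
        a, _ = af.codon_align({"ref": ref, "x": short}, reference_taxon="ref")
        assert a.row("ref") == ref
        x = a.row("x")
        assert x.count("-") == 3
        i = x.index("-")
        assert i % 3 == 0 and x[i : i + 3] == "---"

    def test_round_trip_lossless(self, rng):
        """Stripping gaps from every row reproduces the inputs exactly,
        including an insertion relative to the reference."""
        ref = "ATGGCTAAAGGT"
        longer = "ATGGCTCCCAAAGGT"
        a, _ = af.codon_align({"ref": ref, "x": longer}, reference_taxon="ref")
        assert a.row("ref").replace("-", "") == ref
        assert a.row("x").replace("-", "") == longer
        assert a.n_columns % 3 == 0

    def test_internal_stop_flagged(self):
        good = "ATGGCTGCAAAAGGT"
        stopped = "ATGGCTTAAAAAGGT"      # TAA at codon 3
        a, anomalies = af.codon_align({"ref": good, "x": stopped},
                                      reference_taxon="ref")
        assert anomalies == {"x": "internal_stop"}
        assert a.taxa == ["ref"]


class TestSpliceIntrons:
    def test_empty_interval_list_identity(self, rng):
        s = random_dna(rng, 100)
        assert af.splice_introns(s, []) == s

    def test_single_intron_length(self, rng):
        s = random_dna(rng, 500)
        out = af.splice_introns(s, [(100, 200)])
        assert len(out) == 400
        assert out == s[:100] + s[200:]

    def test_two_introns_match_manual_slicing(self, rng):
        s = random_dna(rng, 300)
        out = af.splice_introns(s, [(50, 80), (200, 260)])
        assert out == s[:50] + s[80:200] + s[260:]

    @pytest.mark.parametrize("bad", [[(100, 50)], [(-5, 10)], [(290, 310)],
                                     [(10, 50), (40, 60)]])
    def test_invalid_intervals_rejected(self, rng, bad):
        with pytest.raises(ValueError):
            af.splice_introns(random_dna(rng, 300), bad)


class TestCoverageOutliers:
    def test_hand_computed_mad_example(self):
        """[10,12,11,13,300]: median 12, MAD 1, threshold 16."""
        flags = af.coverage_outlier_filter(
            {"a": 10, "b": 12, "c": 11, "d": 13, "e": 300})
        assert set(flags) == {"e"}

    def test_equal_coverages_none_flagged(self):
        assert af.coverage_outlier_filter({f"e{i}": 50.0 for i in range(10)}) == {}

    def test_hard_cutoff_applies_regardless_of_mad(self):
        flags = af.coverage_outlier_filter({f"e{i}": 250.0 for i in range(5)})
        assert all(r == "coverage_gt_200" for r in flags.values())
        assert len(flags) == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            af.coverage_outlier_filter({})

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 199.0), min_size=1, max_size=50))
    def test_matches_bruteforce_median_mad(self, vals):
        covs = {f"e{i}": v for i, v in enumerate(vals)}
        flags = af.coverage_outlier_filter(covs, hard_cutoff=200.0,
                                           mad_multiplier=4.0)
        med = sorted(vals)[len(vals) // 2] if len(vals) % 2 else \
            sum(sorted(vals)[len(vals) // 2 - 1 : len(vals) // 2 + 1]) / 2
        devs = sorted(abs(v - med) for v in vals)
        mad = devs[len(vals) // 2] if len(vals) % 2 else \
            sum(devs[len(vals) // 2 - 1 : len(vals) // 2 + 1]) / 2
        expected = {k for k, v in covs.items()
                    if mad > 0 and v > med + 4 * mad}
        assert set(flags) == expected


class TestContaminantScreen:
    def test_verbatim_library_subsequence_classified(self, rng):
        plastid = random_dna(rng, 5000)
        cls = af.contaminant_screen({"g1": plastid[1000:1400]},
                                    {"plastid": [plastid]})
        assert cls == {"g1": "plastid"}

    def test_random_sequence_clean(self, rng):
        cls = af.contaminant_screen({"g1": random_dna(rng, 400)},
                                    {"plastid": [random_dna(rng, 5000)]})
        assert cls == {"g1": "clean"}

    def test_chimera_assigned_by_shared_fraction(self, rng):
        """50% plastid / 50% novel at min_shared 0.3: the exact shared
        k-mer fraction drives the call."""
        plastid = random_dna(rng, 2000)
        gene = plastid[100:300] + random_dna(rng, 200)
        from exoncap.dna import kmer_set, revcomp, shared_kmer_fraction
        lib = kmer_set(plastid, 21) | {revcomp(k) for k in kmer_set(plastid, 21)}
        frac = shared_kmer_fraction(gene, lib, 21)
        cls = af.contaminant_screen({"g1": gene}, {"plastid": [plastid]},
                                    k=21, min_shared_fraction=0.3)
        assert frac >= 0.3
        assert cls == {"g1": "plastid"}

    def test_empty_libraries_all_clean(self, rng):
        assert af.contaminant_screen({"g1": random_dna(rng, 300)}, {}) == \
            {"g1": "clean"}


class TestTreeLengthSkew:
    def tree(self, nwk):
        return dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)

    def test_balanced_terminals_not_flagged(self):
        nwk = "(" + ",".join(f"t{i}:0.01" for i in range(10)) + ");"
        t = self.tree(nwk)
        # pad internal structure: total 0.1, each terminal 10%... use star
        flagged, _, frac = af.tree_length_skew_filter(t, 0.15)
        assert not flagged

    def test_20pct_terminal_flagged_with_offender(self):
        t = self.tree("((a:0.2,b:0.1):0.2,(c:0.2,d:0.1):0.2);")
        flagged, taxon, frac = af.tree_length_skew_filter(t, 0.15)
        assert flagged and taxon == "a"
        assert frac == pytest.approx(0.2 / 1.0)

    def test_boundary_15pct_not_flagged(self):
        t = self.tree("((a:0.15,b:0.1):0.25,(c:0.15,d:0.1):0.25);")
        flagged, _, frac = af.tree_length_skew_filter(t, 0.15)
        assert frac == pytest.approx(0.15)
        assert not flagged

    def test_zero_length_tree_not_flagged(self):
        t = self.tree("((a:0,b:0):0,(c:0,d:0):0);")
        flagged, taxon, frac = af.tree_length_skew_filter(t)
        assert (flagged, taxon, frac) == (False, None, 0.0)


def _tree_distances(tree, taxa):
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(tns.get_taxon(taxa[i]),
                                             tns.get_taxon(taxa[j]))
    return D


class TestGeneTrees:
    def test_nj_exact_on_additive_matrix(self, rng):
        """NJ on exactly additive distances reproduces the generating
        topology and branch lengths to 1e-9 (8 leaves)."""
        taxa = [f"t{i}" for i in range(8)]
        nwk = ("(((t0:0.11,t1:0.07):0.05,(t2:0.03,t3:0.09):0.04):0.02,"
               "((t4:0.06,t5:0.12):0.08,(t6:0.05,t7:0.1):0.03):0.02);")
        true = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        D = _tree_distances(true, taxa)
        rec = af.nj_tree(D, taxa)
        from exoncap.phylo import bipartitions
        assert bipartitions(rec, taxa) == bipartitions(true, taxa)
        D2 = _tree_distances(rec, taxa)
        assert np.abs(D2 - D).max() < 1e-9

    def test_identical_sequences_star_tree(self, rng):
        s = random_dna(rng, 100)
        t = af.build_gene_tree(aln({"a": s, "b": s, "c": s}))
        assert sum(e.length or 0 for e in t.edges()) == pytest.approx(0.0)

    def test_four_taxon_topology_recovered(self, rng):
        """Long sequences simulated on a known quartet recover it."""
        from exoncap import simdata
        cfg = simdata.SimulationConfig(seed=21, n_genes=2, n_families=4,
                                       taxa_per_family=1, violations={},
                                       exon_len_mean=3000, exon_len_min=3000,
                                       tree_depth=0.08)
        tree, fams = simdata.simulate_species_tree(cfg)
        seqs, _ = simdata.evolve_exons(tree, cfg)
        taxa = sorted(t for f in fams.values() for t in f)
        a = aln({t: seqs[("g001", t)] for t in taxa})
        rec = af.build_gene_tree(a)
        from exoncap.phylo import bipartitions
        assert bipartitions(rec, taxa) == bipartitions(tree, taxa)

    def test_disjoint_pair_raises_overlap_error(self):
        a = aln({"a": "AAAANNNN", "b": "NNNNAAAA", "c": "AAAAAAAA"})
        with pytest.raises(af.PairwiseOverlapError):
            af.jc_distance_matrix(a)


def brute_pi(rows):
    n_pi = 0
    for col in zip(*rows):
        counts = {}
        for c in col:
            if c in "ACGT":
                counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n_pi += 1
    return n_pi


class TestPiSites:
    @pytest.mark.parametrize("rows,expected", [
        (["A", "A", "G", "G"], 1),          # two states, twice each
        (["A", "A", "A", "G"], 0),          # singleton
        (["A", "A", "A", "A"], 0),          # constant
        (["A", "A", "G", "G", "N"], 1),     # ambiguity never a state
        (["A", "A", "R", "R"], 0),          # IUPAC codes excluded
        (["-", "-", "G", "G"], 0),          # gaps never a state
    ])
    def test_column_definitions(self, rows, expected):
        n_cols, n_pi, frac = af.count_pi_sites(rows)
        assert (n_cols, n_pi) == (1, expected)

    def test_all_identical_alignment_zero(self, rng):
        s = random_dna(rng, 200)
        assert af.count_pi_sites([s] * 6)[1] == 0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 20), st.integers(5, 200))
    def test_matches_bruteforce_on_random_matrices(self, seed, n_taxa, n_cols):
        r = np.random.default_rng(seed)
        chars = np.array(list("ACGTN-RY"))
        rows = ["".join(chars[r.integers(0, 8, size=n_cols)])
                for _ in range(n_taxa)]
        n_c, n_pi, frac = af.count_pi_sites(rows)
        assert n_c == n_cols
        assert n_pi == brute_pi(rows)
        if n_pi:
            assert frac == pytest.approx(n_pi / n_cols)


class TestCascade:
    def test_clean_set_all_retained(self, rng):
        genes = []
        for i in range(6):
            s = random_dna(rng, 120)
            genes.append(af.GeneRecord(f"g{i}", aln({"a": s, "b": s, "c": s},
                                                    gene_id=f"g{i}"), 30.0))
        retained, report = af.run_filter_cascade(genes)
        assert len(retained) == 6
        assert (report["status"] == "retained").all()

    def test_double_violation_removed_once_both_reasons(self, rng):
        plastid = random_dna(rng, 3000)
        s = plastid[500:800]
        genes = [af.GeneRecord("bad", aln({"a": s, "b": s, "c": s},
                                          gene_id="bad"),
                               mean_coverage=500.0),
                 af.GeneRecord("ok", aln({"a": random_dna(rng, 300)} | {},
                                         gene_id="ok"), 30.0)]
        genes[1].alignment.taxa.extend(["b", "c"])
        genes[1].alignment.rows.extend([genes[1].alignment.rows[0]] * 2)
        retained, report = af.run_filter_cascade(
            genes, contaminant_libraries={"plastid": [plastid]})
        row = report[report.gene_id == "bad"].iloc[0]
        assert row.status == "removed"
        assert "coverage_gt_200" in row.reasons
        assert "contaminant_plastid" in row.reasons
        assert (report[report.gene_id == "bad"].shape[0] == 1)

    def test_summary_reproduces_ledger_arithmetic(self):
        """Aggregating a report with per-reason counts 20/37/4/63 gives
        a removed total of 124; retained = input - removed."""
        import pandas as pd
        rows = []
        reasons = (["coverage_gt_200"] * 20 + ["tree_length_skew"] * 37 +
                   ["frameshift"] * 4 + ["contaminant_plastid"] * 63)
        for i, r in enumerate(reasons):
            rows.append({"gene_id": f"r{i}", "status": "removed", "reasons": r})
        for i in range(418 - len(reasons)):
            rows.append({"gene_id": f"k{i}", "status": "retained", "reasons": ""})
        report = pd.DataFrame(rows)
        summary = af.summarize_filter_report(report)
        as_map = dict(zip(summary.reason, summary.n_removed))
        assert as_map["total_removed"] == 124
        assert as_map["total_retained"] == 294
        assert as_map["coverage_gt_200"] == 20
        assert as_map["tree_length_skew"] == 37
        assert as_map["frameshift"] == 4
        assert as_map["contaminant_plastid"] == 63
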