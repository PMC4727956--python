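"""Read cleaning, reference adjustment, strict mapping, duplicate
removal, variant calling and the coverage-rule consensus."""

import numpy as np
import pytest

from exoncap import readproc as rp
from exoncap import simdata

from conftest import random_dna


def pair(i, s1, s2, q=38):
    return rp.ReadPair(f"r{i}", s1, s2, [q] * len(s1), [q] * len(s2))


class TestCleanReads:
    def test_clean_input_unchanged(self, rng):
        pairs = [pair(i, random_dna(rng, 100), random_dna(rng, 100))
                 for i in range(5)]
        out = rp.clean_reads(pairs)
        assert [(p.seq1, p.seq2) for p in out] == \
               [(p.seq1, p.seq2) for p in pairs]

    def test_exact_duplicate_pairs_collapse(self, rng):
        s1, s2 = random_dna(rng, 100), random_dna(rng, 100)
        out = rp.clean_reads([pair(1, s1, s2), pair(2, s1, s2)])
        assert len(out) == 1 and out[0].id == "r1"

    def test_adapter_suffix_trimmed_at_junction(self, rng):
        """read = 80 bp insert + 20 bp adapter prefix -> trimmed to 80."""
        adapter = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
        insert = random_dna(rng, 80)
        read = insert + adapter[:20]
        out = rp.clean_reads([pair(1, read, random_dna(rng, 100))],
                             adapters=[adapter])
        assert out[0].seq1 == insert

    def test_short_after_trim_dropped(self, rng):
        adapter = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
        read = random_dna(rng, 10) + adapter[:90]
        out = rp.clean_reads([pair(1, read, random_dna(rng, 100))],
                             adapters=[adapter])
        assert out == []

    def test_low_complexity_read_dropped(self, rng):
        out = rp.clean_reads([pair(1, "AT" * 50, random_dna(rng, 100))])
        assert out == []

    def test_mismatched_quality_length_rejected(self):
        with pytest.raises(ValueError):
            rp.ReadPair("r1", "ACGT", "ACGT", [38] * 3, [38] * 4)


def tile_pairs(ref, n, read_len=40, fragment=80, rng=None, start_step=None):
    """Error-free pairs tiled across a reference."""
    from exoncap.dna import revcomp
    pairs = []
    L = len(ref)
    starts = (np.arange(n) * (L - fragment)) // max(1, n - 1) if n > 1 else [0]
    for i, s in enumerate(starts):
        frag = ref[s : s + fragment]
        pairs.append(pair(i, frag[:read_len], revcomp(frag[-read_len:])))
    return pairs


class TestIterativeReferenceUpdate:
    def test_identical_reads_fixed_point(self, rng):
        ref = random_dna(rng, 200)
        pairs = tile_pairs(ref, 10)
        adj = rp.iterative_reference_update(pairs, ref)
        assert adj.sequence == ref
        assert adj.n_changes == 0 and adj.rounds == 1 and adj.converged

    def test_homozygous_substitution_recovered(self, rng):
        ref = random_dna(rng, 200)
        truth = ref[:100] + ("A" if ref[100] != "A" else "C") + ref[101:]
        pairs = tile_pairs(truth, 30)
        adj = rp.iterative_reference_update(pairs, ref)
        assert adj.sequence == truth

    def test_divergent_reads_converge_near_truth(self, rng):
        """~8% divergent individual, lenient 0.70, 3 rounds: adjusted
        reference within 1% of the truth."""
        ref = random_dna(rng, 300)
        truth = list(ref)
        for j in rng.choice(300, size=24, replace=False):
            truth[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[truth[j]]
        truth = "".join(truth)
        pairs = tile_pairs(truth, 80, read_len=50, fragment=100)
        adj = rp.iterative_reference_update(pairs, ref, max_rounds=3,
                                            lenient_identity=0.70)
        mism = sum(a != b for a, b in zip(adj.sequence, truth))
        assert mism / 300 < 0.01

    def test_no_mapping_reads_flagged_unadjusted(self, rng):
        ref = random_dna(rng, 200)
        pairs = [pair(1, random_dna(rng, 100), random_dna(rng, 100))]
        adj = rp.iterative_reference_update(pairs, ref)
        assert adj.sequence == ref and not adj.adjusted

    def test_flank_extension_recovers_context(self, rng):
        genome = random_dna(rng, 400)
        core = genome[100:300]
        pairs = tile_pairs(genome, 60, read_len=50, fragment=100)
        adj = rp.iterative_reference_update(pairs, core, extend_flanks=True)
        assert core in adj.sequence
        assert len(adj.sequence) > len(core)
        assert adj.sequence in genome


class TestStrictMap:
    def test_single_read_depth_one_on_span(self, rng):
        ref = random_dna(rng, 200)
        p = pair(0, ref[:100], ref[100:200])
        counts = rp.strict_map([p], ref)
        depth = counts.sum(axis=0)
        assert (depth == 1).all()

    def test_low_identity_read_contributes_nothing(self, rng):
        ref = random_dna(rng, 200)
        noisy = list(ref[:100])
        for j in rng.choice(100, size=20, replace=False):
            noisy[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[j]]
        counts = rp.strict_map([pair(0, "".join(noisy), ref[100:])],
                               ref, strict_identity=0.93)
        assert counts.sum(axis=0)[:100].sum() == 0

    def test_uniform_tiling_mean_depth_closed_form(self, rng):
        """n error-free reads of length l on an L-long reference give
        mean depth n*l/L exactly (every base lands once)."""
        ref = random_dna(rng, 300)
        pairs = tile_pairs(ref, 50, read_len=60, fragment=120)
        counts = rp.strict_map(pairs, ref)
        mean = counts.sum(axis=0).mean()
        expected = 50 * 120 / 300
        assert mean == pytest.approx(expected, rel=0.05)


class TestDuplicates:
    def _aligned(self, rng, ref, specs):
        """specs: list of (id, start, fragment, qual)."""
        pairs = []
        from exoncap.dna import revcomp
        for rid, s, f, q in specs:
            frag = ref[s : s + f]
            pairs.append(rp.ReadPair(rid, frag[:50], revcomp(frag[-50:]),
                                     [q] * 50, [q] * 50))
        return rp.strict_align(pairs, ref)

    def test_distinct_coordinates_unchanged(self, rng):
        ref = random_dna(rng, 300)
        aligned = self._aligned(rng, ref, [("a", 0, 120, 38), ("b", 50, 120, 38),
                                           ("c", 100, 120, 38)])
        assert len(rp.remove_pcr_duplicates(aligned)) == 3

    def test_five_identical_coordinates_keep_best_quality(self, rng):
        ref = random_dna(rng, 300)
        specs = [(f"d{i}", 40, 120, 30 + i) for i in range(5)]
        kept = rp.remove_pcr_duplicates(self._aligned(rng, ref, specs))
        assert len(kept) == 1 and kept[0].pair.id == "d4"

    def test_quality_tie_breaks_to_first_id(self, rng):
        ref = random_dna(rng, 300)
        specs = [("z", 40, 120, 38), ("a", 40, 120, 38)]
        kept = rp.remove_pcr_duplicates(self._aligned(rng, ref, specs))
        assert kept[0].pair.id == "a"

    def test_simulated_duplicate_rate_recovered(self):
        """Retained fraction after dedupe matches the simulator's
        distinct-fragment truth."""
        cfg = simdata.SimulationConfig(seed=5, n_genes=6, violations={},
                                       duplicate_rate=0.3,
                                       on_target_fraction=1.0, error_rate=0.0)
        ds = simdata.simulate_dataset(cfg)
        ind = ds.taxa[0]
        pairs, fragment_of, _ = simdata.simulate_capture_reads(ds, ind)
        n_distinct = len(set(fragment_of.values()))
        exon = ds.exons[0]
        sub = [p for p in pairs if f"|{exon.exon_id}|" in p.id]
        aligned = rp.strict_align(sub, exon.sequence, 0.90)
        kept = rp.remove_pcr_duplicates(aligned)
        distinct_here = len({fragment_of[p.id] for p in sub})
        assert len(kept) == pytest.approx(distinct_here, rel=0.05)


class TestCallVariantsAndConsensus:
    def _counts(self, ref, depths_alts, alt_base="A"):
        """(depth, n_alt) per position -> count matrix."""
        counts = np.zeros((5, len(ref)), dtype=np.int32)
        row = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, (d, a) in enumerate(depths_alts):
            alt = alt_base if ref[j] != alt_base else "C"
            counts[row[ref[j]], j] = d - a
            counts[row[alt], j] = a
        return counts

    def test_hom_alt_at_96pct(self):
        ref = "G" * 30
        counts = self._counts(ref, [(25, 24)] + [(25, 0)] * 29)
        calls = rp.call_variants(counts, ref, min_depth=20,
                                 min_alt_fraction=0.25)
        assert len(calls) == 1
        assert calls[0].genotype_class == "hom_alt"
        assert calls[0].alt_fraction == pytest.approx(0.96)

    def test_het_at_40pct(self):
        ref = "G" * 10
        counts = self._counts(ref, [(25, 10)] + [(25, 0)] * 9)
        calls = rp.call_variants(counts, ref, min_depth=20, min_alt_fraction=0.25)
        assert len(calls) == 1 and calls[0].genotype_class == "het"

    def test_no_call_below_20x_regardless_of_composition(self):
        ref = "G" * 5
        counts = self._counts(ref, [(10, 10), (19, 19), (10, 5), (19, 10),
                                    (10, 3)])
        assert rp.call_variants(counts, ref, min_depth=20, min_alt_fraction=0.25) == []

    def test_consensus_rules_positionwise(self):
        """>=20x: calls applied (hom -> alt, het -> IUPAC); 5-20x with
        variant signal -> N, without -> reference; <5x -> discarded."""
        ref = "GGGGGGG"
        spec = [(25, 24),   # hom alt -> A
                (25, 10),   # het -> R (G/A)
                (25, 0),    # plain reference
                (10, 5),    # mid-depth variant signal -> N
                (10, 1),    # mid-depth no signal -> G
                (3, 0),     # discarded
                (0, 0)]     # discarded
        counts = self._counts(ref, spec)
        calls = rp.call_variants(counts, ref, min_depth=20, min_alt_fraction=0.25)
        cons = rp.make_consensus(ref, calls, counts)
        assert cons.sequence == "ARGNG--"
        assert cons.retained_fraction == pytest.approx(5 / 7)

    def test_length_conservation_and_depth_invariant(self, rng):
        """Retained + discarded always equals the reference length, and
        no retained position sits below the keep threshold."""
        ref = random_dna(rng, 50)
        depths = rng.integers(0, 40, size=50)
        counts = np.zeros((5, 50), dtype=np.int32)
        row = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, d in enumerate(depths):
            counts[row[ref[j]], j] = d
        cons = rp.make_consensus(ref, [], counts)
        assert len(cons.sequence) == 50
        n_disc = cons.sequence.count("-")
        assert n_disc == int((depths < 5).sum())
        for j, ch in enumerate(cons.sequence):
            if ch != "-":
                assert depths[j] >= 5


class TestCaptureReport:
    def test_all_on_target_is_100(self, rng):
        r = rp.IndividualResult("i1", {}, {"e1": 30.0}, total_bases=1000,
                                on_target_bases=1000)
        df = rp.capture_efficiency_report([r])
        assert df.loc[0, "pct_on_target_nuclear"] == 100.0

    def test_empty_read_set_no_division_error(self):
        r = rp.IndividualResult("i1", {}, {}, 0, 0, 0)
        df = rp.capture_efficiency_report([r])
        assert (df.loc[0, ["pct_on_target_nuclear", "mean_coverage"]] == 0).all()

    def test_high_coverage_exons_excluded_from_second_mean(self):
        r = rp.IndividualResult("i1", {}, {"a": 30.0, "b": 400.0},
                                total_bases=10, on_target_bases=5)
        df = rp.capture_efficiency_report([r])
        assert df.loc[0, "mean_coverage"] == pytest.approx(215.0)
        assert df.loc[0, "mean_coverage_excl_high"] == pytest.approx(30.0)

    def test_simulated_on_target_fraction_recovered(self):
        """Report within sampling error of the configured on-target
        fraction (0.30)."""
        cfg = simdata.SimulationConfig(seed=9, n_genes=8, violations={},
                                       on_target_fraction=0.30)
        ds = simdata.simulate_dataset(cfg)
        ind = ds.taxa[0]
        pairs = simdata.reads_for(ds, ind)
        res = rp.process_individual(pairs, ds.exons, individual=ind)
        df = rp.capture_efficiency_report([res])
        assert df.loc[0, "pct_on_target_nuclear"] == pytest.approx(30.0, abs=3.0)


def test_pileup_column_view_depth_consistent(rng):
    ref = random_dna(rng, 80)
    pairs = tile_pairs(ref, 10, read_len=40, fragment=80)
    counts = rp.strict_map(pairs, ref)
    cols = rp.pileup_columns(counts, "e1")
    assert all(c.depth == sum(c.base_counts.values()) for c in cols)
    assert [c.position for c in cols] == list(range(80))
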