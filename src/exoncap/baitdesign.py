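"""Bait design: from reference exons plus per-lineage transcriptome
evidence to a filtered, per-lineage tiled probe set.

The workflow mirrors array-based exon capture design for deep
radiations: transcriptome evidence from each lineage is mapped leniently
onto the reference exon set, a per-lineage consensus is built for every
exon, and candidate exons are filtered for (1) evidence coverage in all
non-reference lineages, (2) length, (3) GC content, (4) cross-gene
uniqueness, and (5) absence of repeats / low-complexity sequence.
Surviving exons are tiled into fixed-length probes for every lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import BaitDesignParams
from .dna import gc_fraction, iupac_code, kmer_set, low_complexity_fraction, \
    shared_kmer_fraction, revcomp
from .mapping import TargetIndex, best_alignment, pileup_from_alignments

log = logging.getLogger(__name__)

FILTER_REASONS = ("missing_family_coverage", "too_short", "gc_out_of_range",
                  "non_unique", "repeat_hit")


@dataclass
class TargetExon:
    """One annotated candidate exon from the reference genome."""
    exon_id: str
    gene_id: str
    chromosome: str          # may be "unknown"
    start: int               # 0-based half-open genomic coordinates
    end: int
    sequence: str
    cds_frame_offset: int = 0

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError(f"exon {self.exon_id}: empty sequence")
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"exon {self.exon_id}: coordinates do not match "
                             f"sequence length")
        if self.cds_frame_offset not in (0, 1, 2):
            raise ValueError(f"exon {self.exon_id}: frame offset must be 0-2")

    def __len__(self):
        return len(self.sequence)


@dataclass
class LineageConsensus:
    """Per-lineage bait sequence for one exon, N where uncovered."""
    lineage: str
    exon_id: str
    sequence: str
    covered_fraction: float
    min_identity_to_reference: float


@dataclass
class ProbeSet:
    probes: list            # (lineage, exon_id, offset, sequence, replicate_count)
    probe_length: int
    tiling_step: int
    skipped: list = field(default_factory=list)   # (lineage, exon_id, why)

    @property
    def n_records(self) -> int:
        """Total printed records, counting replicates."""
        return sum(p[4] for p in self.probes)


@dataclass
class ExonFilterDecision:
    exon_id: str
    reasons: set

    @property
    def passed(self) -> bool:
        return not self.reasons


# ---------------------------------------------------------------------------
# Lineage consensus

def build_lineage_consensus(transcript_evidence, exon: TargetExon,
                            min_identity: float = 0.70,
                            lineage: str = "") -> LineageConsensus:
    """Majority-rule consensus of evidence sequences mapped onto one exon.

    Positions with no mapped evidence base are N; ties among majority
    bases become IUPAC ambiguity codes. ``min_identity_to_reference`` is
    the exact-match identity of the consensus to the reference over
    non-N positions (1.0 when nothing is covered).
    """
    if len(exon.sequence) == 0:
        raise ValueError("exon of length 0")
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    alignments = []
    for seq in transcript_evidence:
        aln = best_alignment(seq.upper(), exon.sequence, min_identity)
        if aln is not None:
            alignments.append(aln)
    counts = pileup_from_alignments(alignments, len(exon.sequence))
    base_counts = counts[:4]
    consensus = []
    for j in range(len(exon.sequence)):
        col = base_counts[:, j]
        top = col.max()
        if top == 0:
            consensus.append("N")
            continue
        winners = ["ACGT"[i] for i in range(4) if col[i] == top]
        consensus.append(winners[0] if len(winners) == 1 else iupac_code(winners))
    seq = "".join(consensus)
    n_count = seq.count("N")
    covered = 1.0 - n_count / len(seq)
    non_n = len(seq) - n_count
    if non_n:
        ident = sum(1 for a, b in zip(seq, exon.sequence) if a == b and a != "N") / non_n
    else:
        ident = 1.0
    return LineageConsensus(lineage=lineage, exon_id=exon.exon_id, sequence=seq,
                            covered_fraction=covered, min_identity_to_reference=ident)


# ---------------------------------------------------------------------------
# The five candidate-exon filters

def filter_length(exon: TargetExon, min_len: int = 150) -> bool:
    """Pass iff the exon is strictly longer than ``min_len``."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return len(exon.sequence) > min_len


def filter_gc(exon: TargetExon, lo: float = 0.30, hi: float = 0.70) -> bool:
    """Pass iff GC content over unambiguous bases lies in [lo, hi]
    (inclusive bounds). An all-N sequence has undefined GC and fails."""
    gc = gc_fraction(exon.sequence)
    if gc is None:
        return False
    return lo <= gc <= hi


def filter_family_coverage(consensi, n_required: int = 7,
                           min_overlap_fraction: float = 0.90) -> bool:
    """Pass iff at least ``n_required`` distinct lineages reach
    ``min_overlap_fraction`` evidence coverage for this exon."""
    seen = {c.lineage for c in consensi if c.covered_fraction >= min_overlap_fraction}
    return len(seen) >= n_required


def filter_unique(exons, identity_threshold: float = 0.90,
                  coverage_threshold: float = 0.80,
                  prescreen_k: int = 15) -> dict:
    """Cross-gene uniqueness via all-vs-all k-mer-seeded pairwise alignment.

    An exon fails when another exon from a *different* gene aligns to it
    at ``identity_threshold`` identity over ``coverage_threshold`` of its
    length and the two are reciprocally each other's best non-self hit.
    Returns exon_id -> passed.
    """
    exons = list(exons)
    if not exons:
        raise ValueError("need at least one exon")
    kmers = {e.exon_id: kmer_set(e.sequence, prescreen_k) |
             {revcomp(k) for k in kmer_set(e.sequence, prescreen_k)}
             for e in exons}
    # best qualifying non-self cross-gene hit per exon
    best_hit: dict[str, tuple[float, str]] = {}
    for i, a in enumerate(exons):
        for b in exons[i + 1:]:
            if a.gene_id == b.gene_id:
                continue
            if not (kmers[a.exon_id] & kmers[b.exon_id]):
                continue
            short, long_ = (a, b) if len(a) <= len(b) else (b, a)
            aln = best_alignment(short.sequence, long_.sequence, identity_threshold)
            if aln is None:
                continue
            overlap = len(short)
            for x, y in ((a, b), (b, a)):
                if overlap / len(x) < coverage_threshold:
                    continue
                cur = best_hit.get(x.exon_id)
                if cur is None or aln.identity > cur[0]:
                    best_hit[x.exon_id] = (aln.identity, y.exon_id)
    result = {}
    for e in exons:
        hit = best_hit.get(e.exon_id)
        reciprocal = (hit is not None
                      and best_hit.get(hit[1], (0, None))[1] == e.exon_id)
        result[e.exon_id] = not reciprocal
    return result


def filter_repeats(exon: TargetExon, repeat_library, k: int = 15,
                   max_shared_kmer_fraction: float = 0.25,
                   low_complexity_max_fraction: float = 0.50,
                   low_complexity_min_entropy: float = 2.0) -> bool:
    """Pass unless the exon shares too many k-mers with a repeat library
    or is dominated by low-complexity (simple-repeat) windows. An empty
    library makes the repeat test vacuous; the complexity screen still
    applies."""
    if k < 8:
        raise ValueError("k must be >= 8")
    lib = set()
    for seq in repeat_library:
        s = kmer_set(seq.upper(), k)
        lib |= s
        lib |= {revcomp(x) for x in s}
    if lib and shared_kmer_fraction(exon.sequence, lib, k) >= max_shared_kmer_fraction:
        return False
    lc = low_complexity_fraction(exon.sequence,
                                 min_entropy=low_complexity_min_entropy)
    return lc <= low_complexity_max_fraction


# ---------------------------------------------------------------------------
# Probe tiling

def design_probes(consensi, probe_length: int = 60, step: int = 1,
                  replicates: int = 2) -> ProbeSet:
    """Tile each lineage consensus into probes at offsets 0..L-probe_length
    stepping by ``step``. Probes containing N are dropped; consensi
    shorter than the probe length are skipped with a warning."""
    probes, skipped = [], []
    for c in consensi:
        if len(c.sequence) < probe_length:
            log.warning("consensus %s/%s shorter than probe length; skipped",
                        c.lineage, c.exon_id)
            skipped.append((c.lineage, c.exon_id, "shorter_than_probe"))
            continue
        for off in range(0, len(c.sequence) - probe_length + 1, step):
            p = c.sequence[off : off + probe_length]
            if "N" in p:
                skipped.append((c.lineage, c.exon_id, f"n_at_offset_{off}"))
                continue
            probes.append((c.lineage, c.exon_id, off, p, replicates))
    return ProbeSet(probes=probes, probe_length=probe_length, tiling_step=step,
                    skipped=skipped)


# ---------------------------------------------------------------------------
# End-to-end driver

def run_bait_design(exons, evidence_by_lineage: dict, params: BaitDesignParams
                    | None = None, repeat_library=()) -> tuple[ProbeSet, list]:
    """Full probe-design workflow.

    ``evidence_by_lineage`` maps lineage name -> iterable of transcriptome
    sequences (reads or contigs). Evidence is assigned to exons with a
    k-mer index, consensi are built per lineage, the five filters run in
    declared order recording every reason, and probes are tiled from the
    consensi of exons that pass everywhere.
    """
    params = params or BaitDesignParams()
    params.validate()
    exons = list(exons)
    index = TargetIndex({e.exon_id: e.sequence for e in exons})
    by_exon = {e.exon_id: e for e in exons}

    # assign evidence and build per-lineage consensi
    consensi: dict[str, list[LineageConsensus]] = {e.exon_id: [] for e in exons}
    for lineage, seqs in evidence_by_lineage.items():
        grouped: dict[str, list[str]] = {}
        for seq in seqs:
            tid = index.assign(seq.upper(), params.min_identity)
            if tid is not None:
                grouped.setdefault(tid, []).append(seq.upper())
        for exon_id, e in by_exon.items():
            cons = build_lineage_consensus(grouped.get(exon_id, []), e,
                                           min_identity=params.min_identity,
                                           lineage=lineage)
            consensi[exon_id].append(cons)

    unique_pass = filter_unique(exons, params.unique_identity,
                                params.unique_coverage)
    decisions = []
    for e in exons:
        reasons = set()
        if not filter_family_coverage(consensi[e.exon_id],
                                      params.n_required_families,
                                      params.min_overlap_fraction):
            reasons.add("missing_family_coverage")
        if not filter_length(e, params.min_len):
            reasons.add("too_short")
        if not filter_gc(e, params.gc_lo, params.gc_hi):
            reasons.add("gc_out_of_range")
        if not unique_pass[e.exon_id]:
            reasons.add("non_unique")
        if not filter_repeats(e, repeat_library, params.repeat_k,
                              params.max_shared_kmer_fraction,
                              params.low_complexity_max_fraction,
                              params.low_complexity_min_entropy):
            reasons.add("repeat_hit")
        decisions.append(ExonFilterDecision(exon_id=e.exon_id, reasons=reasons))

    passing = {d.exon_id for d in decisions if d.passed}
    # the reference sequence itself is printed alongside every lineage bait
    keep = [LineageConsensus("reference", exon_id, by_exon[exon_id].sequence,
                             1.0, 1.0) for exon_id in sorted(passing)]
    keep += [c for exon_id in passing for c in consensi[exon_id]
             if c.covered_fraction >= params.min_overlap_fraction]
    probeset = design_probes(keep, params.probe_length, params.tiling_step,
                             params.probe_replicates)
    for reason in FILTER_REASONS:
        n = sum(1 for d in decisions if reason in d.reasons)
        log.info("bait design filter %s: %d exon(s) flagged", reason, n)
    log.info("bait design: %d/%d exons retained, %d probe records",
             len(passing), len(exons), probeset.n_records)
    return probeset, decisions


def decisions_to_dataframe(decisions) -> pd.DataFrame:
    rows = [{"exon_id": d.exon_id,
             "passed": d.passed,
             "reasons": ";".join(sorted(d.reasons))} for d in decisions]
    return pd.DataFrame(rows, columns=["exon_id", "passed", "reasons"])
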