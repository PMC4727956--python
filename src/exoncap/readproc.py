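"""Assembly-free read processing: clean reads, iteratively adjust the
reference per individual, map strictly, remove PCR duplicates, call
variants, and emit per-exon consensus sequences under explicit coverage
rules (variant sites need >=20x; sites at 5-20x with variant signal
become N; sites under 5x are discarded).

The per-individual reference adjustment lets divergent individuals be
genotyped against a distant reference without de novo assembly: each
round maps reads leniently, substitutes majority differences into the
reference, and remaps until a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ReadProcParams
from .dna import iupac_code, low_complexity_fraction, revcomp
from .mapping import Alignment, TargetIndex, best_alignment, encode_seq, \
    pileup_from_alignments

log = logging.getLogger(__name__)

_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: list | None = None
    qual2: list | None = None
    copies: int = 1       # exact duplicates collapsed into this pair

    def __post_init__(self):
        if self.qual1 is not None and len(self.qual1) != len(self.seq1):
            raise ValueError(f"read {self.id}: qual1 length mismatch")
        if self.qual2 is not None and len(self.qual2) != len(self.seq2):
            raise ValueError(f"read {self.id}: qual2 length mismatch")

    def mean_quality(self) -> float:
        if not hasattr(self, "_mq"):
            vals = list(self.qual1 or []) + list(self.qual2 or [])
            self._mq = float(np.mean(vals)) if vals else 40.0
        return self._mq


@dataclass
class PileupColumn:
    exon_id: str
    position: int
    depth: int
    base_counts: dict     # A, C, G, T, D(eletion)


@dataclass
class VariantCall:
    exon_id: str
    position: int
    ref_base: str
    alt_base: str
    depth: int
    alt_fraction: float
    genotype_class: str   # "hom_alt" | "het"


@dataclass
class IndividualGeneSequence:
    individual: str
    exon_id: str
    sequence: str         # N = masked, '-' = discarded (<5x) region
    mean_coverage: float
    retained_fraction: float
    depth: object = None  # optional per-position coverage provenance


@dataclass
class AdjustedReference:
    sequence: str
    rounds: int
    n_changes: int
    adjusted: bool        # False when no reads mapped in round 1
    converged: bool = False
    # final-round per-pair alignments (pair, aln1, aln2), valid for
    # ``sequence`` only when the last round introduced zero changes
    pair_alignments: list | None = None


@dataclass
class AlignedPair:
    pair: ReadPair
    aln1: Alignment | None
    aln2: Alignment | None

    @property
    def fragment_key(self):
        """(start, end, orientation) of the sequenced fragment, the
        coordinate signature used for PCR-duplicate detection."""
        alns = [a for a in (self.aln1, self.aln2) if a is not None]
        start = min(a.start for a in alns)
        end = max(a.end for a in alns)
        orient = alns[0].strand
        return (start, end, orient)


# ---------------------------------------------------------------------------
# Read cleaning

def _trim_adapter(seq, qual, adapters, max_mismatch_frac=0.1, min_overlap=5):
    best_cut = len(seq)
    for adapter in adapters:
        a = adapter.upper()
        lo = max(0, len(seq) - len(a) - 20)
        for i in range(lo, len(seq) - min_overlap + 1):
            ov = min(len(seq) - i, len(a))
            mism = sum(1 for x, y in zip(seq[i : i + ov], a[:ov]) if x != y)
            if mism <= max_mismatch_frac * ov:
                best_cut = min(best_cut, i)
                break
    if best_cut < len(seq):
        return seq[:best_cut], (qual[:best_cut] if qual is not None else None)
    return seq, qual


def _looks_low_complexity(seq: str) -> bool:
    counts = sorted((seq.count(b) for b in "ACGT"), reverse=True)
    n = len(seq) or 1
    # cheap prescreen; exact triplet-entropy screen only on suspects
    if counts[0] < 0.45 * n and counts[0] + counts[1] < 0.85 * n:
        return False
    return low_complexity_fraction(seq) > 0.5


def clean_reads(pairs, adapters=(), min_read_len: int = 40):
    """Adapter-trim, drop short/low-complexity reads, and collapse exact
    duplicate pairs (identical seq1+seq2) onto the first occurrence,
    which records the multiplicity in ``copies``."""
    seen: dict[tuple, ReadPair] = {}
    out = []
    for p in pairs:
        s1, q1 = p.seq1.upper(), p.qual1
        s2, q2 = p.seq2.upper(), p.qual2
        if adapters:
            s1, q1 = _trim_adapter(s1, q1, adapters)
            s2, q2 = _trim_adapter(s2, q2, adapters)
        if len(s1) < min_read_len or len(s2) < min_read_len:
            continue
        if _looks_low_complexity(s1) or _looks_low_complexity(s2):
            continue
        key = (s1, s2)
        if key in seen:
            seen[key].copies += 1
            continue
        kept = ReadPair(p.id, s1, s2, q1, q2)
        seen[key] = kept
        out.append(kept)
    return out


# ---------------------------------------------------------------------------
# Iterative per-individual reference adjustment

def _map_pairs(pairs, reference, min_identity):
    out = []
    for p in pairs:
        a1 = best_alignment(p.seq1, reference, min_identity, read_id=p.id)
        a2 = best_alignment(p.seq2, reference, min_identity, read_id=p.id)
        if a1 is not None or a2 is not None:
            out.append((p, a1, a2))
    return out


def _extend_flanks(reference, pairs, k=21, min_support=2, max_extension=300):
    """Greedy k-mer overlap extension of both reference flanks."""
    reads = []
    for p in pairs:
        reads.append(p.seq1)
        reads.append(p.seq2)
    reads += [revcomp(r) for r in reads]
    for _ in range(max_extension):
        tail = reference[-k:]
        nxt: dict[str, int] = {}
        for r in reads:
            j = r.find(tail)
            if 0 <= j < len(r) - k:
                b = r[j + k]
                nxt[b] = nxt.get(b, 0) + 1
        if not nxt:
            break
        b, c = max(nxt.items(), key=lambda kv: (kv[1], kv[0]))
        if c < min_support:
            break
        reference = reference + b
    for _ in range(max_extension):
        head = reference[:k]
        prv: dict[str, int] = {}
        for r in reads:
            j = r.find(head)
            if j > 0:
                b = r[j - 1]
                prv[b] = prv.get(b, 0) + 1
        if not prv:
            break
        b, c = max(prv.items(), key=lambda kv: (kv[1], kv[0]))
        if c < min_support:
            break
        reference = b + reference
    return reference


def iterative_reference_update(pairs, reference: str, max_rounds: int = 3,
                               lenient_identity: float = 0.70,
                               adjust_min_depth: int = 2,
                               extend_flanks: bool = False) -> AdjustedReference:
    """Alternate lenient mapping and majority-difference substitution
    until the reference stops changing (or ``max_rounds``)."""
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    ref = reference.upper()
    total_changes = 0
    rounds = 0
    any_mapped = False
    converged = False
    mapped_pairs = None
    for rounds in range(1, max_rounds + 1):
        mapped_pairs = _map_pairs(pairs, ref, lenient_identity)
        alns = [a for _, a1, a2 in mapped_pairs for a in (a1, a2)
                if a is not None]
        if not alns:
            break
        any_mapped = True
        counts = pileup_from_alignments(alns, len(ref))[:4]
        depth = counts.sum(axis=0)
        top = counts.argmax(axis=0)
        top_n = counts.max(axis=0)
        ref_codes = encode_seq(ref)
        pos_idx = np.arange(len(ref))
        valid_ref = ref_codes != 255
        ref_n = np.zeros(len(ref), dtype=counts.dtype)
        ref_n[valid_ref] = counts[ref_codes[valid_ref], pos_idx[valid_ref]]
        change = (depth >= adjust_min_depth) & (top != ref_codes) & (top_n > ref_n)
        changes = int(change.sum())
        if changes:
            arr = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
            arr[change] = np.frombuffer(b"ACGT", dtype=np.uint8)[top[change]]
            ref = arr.tobytes().decode()
        total_changes += changes
        if changes == 0:
            converged = True
            break
    if extend_flanks and any_mapped:
        ref = _extend_flanks(ref, pairs, min_support=adjust_min_depth)
        converged = False
    if not any_mapped:
        log.debug("no reads mapped; reference unadjusted")
        return AdjustedReference(reference.upper(), rounds, 0, adjusted=False)
    return AdjustedReference(ref, rounds, total_changes, adjusted=True,
                             converged=converged,
                             pair_alignments=mapped_pairs if converged else None)


# ---------------------------------------------------------------------------
# Strict mapping, duplicate removal, pileup

def strict_align(pairs, reference: str, strict_identity: float = 0.93):
    """Map both mates at the strict identity threshold; pairs with
    neither mate placed are dropped."""
    out = []
    for p in pairs:
        a1 = best_alignment(p.seq1, reference, strict_identity, read_id=p.id)
        a2 = best_alignment(p.seq2, reference, strict_identity, read_id=p.id)
        if a1 is None and a2 is None:
            continue
        out.append(AlignedPair(p, a1, a2))
    return out


def remove_pcr_duplicates(aligned_pairs):
    """Among pairs sharing an identical fragment (start, end, orientation),
    keep the one with the highest mean base quality (ties: first by id)."""
    groups: dict[tuple, AlignedPair] = {}
    for ap in aligned_pairs:
        key = ap.fragment_key
        cur = groups.get(key)
        if cur is None:
            groups[key] = ap
        else:
            q_new, q_old = ap.pair.mean_quality(), cur.pair.mean_quality()
            if q_new > q_old or (q_new == q_old and ap.pair.id < cur.pair.id):
                groups[key] = ap
    return sorted(groups.values(), key=lambda ap: ap.pair.id)


def pileup_from_pairs(aligned_pairs, ref_len: int) -> np.ndarray:
    alns = []
    for ap in aligned_pairs:
        if ap.aln1 is not None:
            alns.append(ap.aln1)
        if ap.aln2 is not None:
            alns.append(ap.aln2)
    return pileup_from_alignments(alns, ref_len)


def strict_map(pairs, reference: str, strict_identity: float = 0.93,
               dedupe: bool = False) -> np.ndarray:
    """Strict mapping straight to a (5, L) pileup count matrix."""
    aligned = strict_align(pairs, reference, strict_identity)
    if dedupe:
        aligned = remove_pcr_duplicates(aligned)
    return pileup_from_pairs(aligned, len(reference))


def pileup_columns(counts: np.ndarray, exon_id: str = ""):
    """View a count matrix as a list of :class:`PileupColumn`."""
    cols = []
    for j in range(counts.shape[1]):
        bc = {b: int(counts[_ROW[b], j]) for b in "ACGT"}
        bc["D"] = int(counts[4, j])
        cols.append(PileupColumn(exon_id, j, int(counts[:, j].sum()), bc))
    return cols


# ---------------------------------------------------------------------------
# Variant calling and consensus

def call_variants(counts: np.ndarray, reference: str, exon_id: str = "",
                  min_depth: int = 20, min_alt_fraction: float = 0.25,
                  hom_fraction: float = 0.80):
    """Frequency-threshold diploid substitution caller. Depth includes
    deletion-supporting reads; only A/C/G/T alternates are called."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = counts.sum(axis=0)
    alt_top, alt_n = _best_alternates(counts, reference)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt_n / depth, 0.0)
    hits = np.nonzero((depth >= min_depth) & (alt_n > 0)
                      & (frac >= min_alt_fraction))[0]
    calls = []
    for j in hits:
        cls = "hom_alt" if frac[j] >= hom_fraction else "het"
        calls.append(VariantCall(exon_id, int(j), reference[j],
                                 "ACGT"[alt_top[j]], int(depth[j]),
                                 float(frac[j]), cls))
    return calls


def _best_alternates(counts: np.ndarray, reference: str):
    """Per position, the most frequent non-reference base (code) and its
    count."""
    base = counts[:4].copy()
    ref_codes = encode_seq(reference)
    pos = np.arange(len(reference))
    valid = ref_codes != 255
    base[ref_codes[valid], pos[valid]] = 0
    return base.argmax(axis=0), base.max(axis=0)


def make_consensus(reference: str, variants, counts: np.ndarray,
                   individual: str = "", exon_id: str = "",
                   min_depth_call: int = 20, min_depth_keep: int = 5,
                   min_alt_fraction: float = 0.25) -> IndividualGeneSequence:
    """Apply the coverage rules position by position.

    depth >= ``min_depth_call``: variant calls applied (hom -> alt base,
    het -> IUPAC code of ref+alt). ``min_depth_keep`` <= depth <
    ``min_depth_call``: reference base, but any variant signal becomes N.
    depth < ``min_depth_keep``: discarded, written as '-' so coordinates
    stay aligned to the reference.
    """
    L = len(reference)
    depth = counts.sum(axis=0)
    arr = np.frombuffer(reference.encode(), dtype=np.uint8).copy()
    _, alt_n = _best_alternates(counts, reference)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt_n / depth, 0.0)
    mid = (depth >= min_depth_keep) & (depth < min_depth_call)
    arr[mid & (frac >= min_alt_fraction)] = ord("N")
    for v in variants:
        if depth[v.position] >= min_depth_call:
            ch = v.alt_base if v.genotype_class == "hom_alt" \
                else iupac_code({v.ref_base, v.alt_base})
            arr[v.position] = ord(ch)
    arr[depth < min_depth_keep] = ord("-")
    seq = arr.tobytes().decode()
    retained = 1.0 - seq.count("-") / L
    return IndividualGeneSequence(individual, exon_id, seq,
                                  float(depth.mean()), retained,
                                  depth=depth.astype(np.int32))


# ---------------------------------------------------------------------------
# Per-individual pipeline and capture-efficiency reporting

@dataclass
class IndividualResult:
    individual: str
    consensi: dict                  # exon_id -> IndividualGeneSequence
    mean_coverage: dict             # exon_id -> mean pileup depth
    total_bases: int = 0
    on_target_bases: int = 0
    plastid_bases: int = 0
    stage_counts: dict = field(default_factory=dict)


def process_individual(pairs, exons, params: ReadProcParams | None = None,
                       individual: str = "", adapters=(),
                       plastid_role_ids=frozenset()) -> IndividualResult:
    """Full pipeline for one individual over a set of reference exons
    (objects with ``exon_id`` and ``sequence`` attributes)."""
    params = params or ReadProcParams()
    params.validate()
    raw = list(pairs)
    total_bases = sum(len(p.seq1) + len(p.seq2) for p in raw)
    cleaned = clean_reads(raw, adapters=adapters, min_read_len=params.min_read_len)

    index = TargetIndex({e.exon_id: e.sequence for e in exons}, k=params.seed_k)
    grouped: dict[str, list[ReadPair]] = {}
    for p in cleaned:
        tid = index.assign(p.seq1, params.lenient_identity)
        if tid is None:
            tid = index.assign(p.seq2, params.lenient_identity)
        if tid is not None:
            grouped.setdefault(tid, []).append(p)

    consensi: dict[str, IndividualGeneSequence] = {}
    mean_cov: dict[str, float] = {}
    on_target = plastid = 0
    for e in exons:
        assigned = grouped.get(e.exon_id, [])
        adj = iterative_reference_update(
            assigned, e.sequence, max_rounds=params.max_rounds,
            lenient_identity=params.lenient_identity,
            adjust_min_depth=params.adjust_min_depth,
            extend_flanks=params.extend_flanks)
        if adj.converged and adj.pair_alignments is not None:
            # the last lenient round used the final reference, so the
            # strict pass reduces to an identity filter on its alignments
            aligned = []
            for p, a1, a2 in adj.pair_alignments:
                b1 = a1 if a1 and a1.identity >= params.strict_identity else None
                b2 = a2 if a2 and a2.identity >= params.strict_identity else None
                if b1 is not None or b2 is not None:
                    aligned.append(AlignedPair(p, b1, b2))
        else:
            aligned = strict_align(assigned, adj.sequence, params.strict_identity)
        # on-target accounting is "prior to PCR duplicate removal":
        # exact duplicates collapsed during cleaning count via `copies`
        mapped_bases = sum(
            len(a.oriented_seq) * ap.pair.copies for ap in aligned
            for a in (ap.aln1, ap.aln2) if a is not None)
        if e.exon_id in plastid_role_ids:
            plastid += mapped_bases
        else:
            on_target += mapped_bases
        deduped = remove_pcr_duplicates(aligned)
        counts = pileup_from_pairs(deduped, len(adj.sequence))
        calls = call_variants(counts, adj.sequence, e.exon_id,
                              params.min_depth_call, params.min_alt_fraction,
                              params.hom_fraction)
        cons = make_consensus(adj.sequence, calls, counts, individual,
                              e.exon_id, params.min_depth_call,
                              params.min_depth_keep, params.min_alt_fraction)
        consensi[e.exon_id] = cons
        mean_cov[e.exon_id] = cons.mean_coverage
    stage_counts = {"raw_pairs": len(raw), "cleaned_pairs": len(cleaned),
                    "assigned_pairs": sum(len(v) for v in grouped.values())}
    log.info("individual %s: %s", individual, stage_counts)
    return IndividualResult(individual, consensi, mean_cov, total_bases,
                            on_target, plastid, stage_counts)


def capture_efficiency_report(results, high_coverage_cutoff: float = 200.0
                              ) -> pd.DataFrame:
    """Per-individual on-target statistics: percent of sequenced bases on
    nuclear and plastid-role targets, and mean per-exon coverage before
    and after excluding exons above ``high_coverage_cutoff``."""
    rows = []
    for r in results:
        tot = r.total_bases
        covs = np.array(list(r.mean_coverage.values()), dtype=float)
        low = covs[covs <= high_coverage_cutoff] if covs.size else covs
        rows.append({
            "individual": r.individual,
            "pct_on_target_nuclear": 100.0 * r.on_target_bases / tot if tot else 0.0,
            "pct_on_target_plastid": 100.0 * r.plastid_bases / tot if tot else 0.0,
            "mean_coverage": float(covs.mean()) if covs.size else 0.0,
            "mean_coverage_excl_high": float(low.mean()) if low.size else 0.0,
        })
    return pd.DataFrame(rows, columns=["individual", "pct_on_target_nuclear",
                                       "pct_on_target_plastid", "mean_coverage",
                                       "mean_coverage_excl_high"])
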