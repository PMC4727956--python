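"""Internal read/contig mapper: k-mer seeded target assignment plus
semi-global alignment (edlib) with an identity threshold.

This deliberately small mapper stands in for a production aligner: it
places a query within a single target sequence, reports an identity
fraction (1 - edit distance / query length), and exposes the per-position
base contributions needed to build pileups. Queries whose best placement
falls below the identity threshold are rejected rather than clipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np

from .dna import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: pileup row order: A, C, G, T, deletion relative to the reference
PILEUP_ROWS = "ACGTD"


@dataclass
class Alignment:
    read_id: str
    target_id: str
    start: int            # 0-based on the target
    end: int              # half-open
    strand: str           # '+' or '-'
    identity: float
    ops: list             # [(op, length), ...] with op in =,X,I,D
    oriented_seq: str     # query in target orientation


def _parse_cigar(cigar: str):
    return [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]


def best_alignment(seq: str, target: str, min_identity: float,
                   read_id: str = "", target_id: str = "",
                   both_strands: bool = True) -> Alignment | None:
    """Best semi-global placement of ``seq`` within ``target`` at or above
    ``min_identity``; ``None`` if no placement qualifies."""
    if not seq or not target:
        return None
    max_dist = int((1.0 - min_identity) * len(seq))
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))) if both_strands else (("+", seq),):
        res = edlib.align(s, target, mode="HW", task="distance", k=max_dist)
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], strand, s)
    if best is None:
        return None
    dist, strand, s = best
    res = edlib.align(s, target, mode="HW", task="path", k=max_dist)
    loc = res["locations"][0]
    start, end = loc[0], loc[1] + 1
    ops = _parse_cigar(res["cigar"])
    identity = 1.0 - res["editDistance"] / len(seq)
    # prefer the substitution representation on cost ties: clustered
    # substitutions can also be explained as insertion+deletion shifts,
    # which would corrupt reference-coordinate pileups downstream
    if end - start == len(s) and any(op in "ID" for op, _ in ops):
        window = target[start:end]
        hamming = sum(1 for a, b in zip(s, window) if a != b)
        if hamming <= res["editDistance"]:
            ops = _runs_from_overlay(s, window)
            identity = 1.0 - hamming / len(seq)
    return Alignment(read_id=read_id, target_id=target_id, start=start, end=end,
                     strand=strand, identity=identity,
                     ops=ops, oriented_seq=s)


def _runs_from_overlay(query: str, window: str):
    """=/X run-length ops from a gap-free overlay of equal-length strings."""
    ops = []
    cur = None
    n = 0
    for a, b in zip(query, window):
        op = "=" if a == b else "X"
        if op == cur:
            n += 1
        else:
            if cur is not None:
                ops.append((cur, n))
            cur, n = op, 1
    ops.append((cur, n))
    return ops


class TargetIndex:
    """Exact k-mer index over target sequences for read assignment.

    Both strands of every target are indexed; queries are seeded densely
    (every ``stride`` positions) and assignment stops after a few seed
    hits, so divergent-but-real queries are recovered while off-target
    queries are rejected after a bounded number of lookups. The short
    default k tolerates the cross-lineage divergence the lenient mapping
    stage is designed for.
    """

    def __init__(self, targets: dict[str, str], k: int = 11,
                 stride: int | None = None):
        self.k = k
        self.stride = stride if stride is not None else max(1, k // 3)
        self.targets = dict(targets)
        self._index: dict[str, set[str]] = {}
        idx = self._index
        for tid, seq in targets.items():
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - k + 1):
                    idx.setdefault(s[i : i + k], set()).add(tid)

    def candidates(self, seq: str, max_candidates: int = 3,
                   max_seed_hits: int = 10) -> list[str]:
        k = self.k
        if len(seq) < k:
            return []
        votes: dict[str, int] = {}
        last_vote: dict[str, int] = {}
        idx = self._index
        hits = 0
        for off in range(0, len(seq) - k + 1, self.stride):
            hit = idx.get(seq[off : off + k])
            if hit:
                hits += 1
                for tid in hit:
                    # overlapping seeds are one piece of evidence, not
                    # several: vote once per target per k-wide window
                    if off - last_vote.get(tid, -k) >= k:
                        votes[tid] = votes.get(tid, 0) + 1
                        last_vote[tid] = off
                if hits >= max_seed_hits:
                    break
        ranked = sorted(votes, key=lambda t: (-votes[t], t))
        return ranked[:max_candidates]

    def assign(self, seq: str, min_identity: float) -> str | None:
        """Target id of the best alignment among seed candidates, or
        ``None``. Disambiguates multi-candidate queries by identity."""
        cands = self.candidates(seq)
        if not cands:
            return None
        if len(cands) == 1:
            return cands[0]
        best_tid, best_ident = None, -1.0
        for tid in cands:
            aln = best_alignment(seq, self.targets[tid], min_identity)
            if aln is not None and aln.identity > best_ident:
                best_tid, best_ident = tid, aln.identity
        return best_tid

    def map_read(self, seq: str, min_identity: float,
                 read_id: str = "") -> Alignment | None:
        best = None
        for tid in self.candidates(seq):
            aln = best_alignment(seq, self.targets[tid], min_identity,
                                 read_id=read_id, target_id=tid)
            if aln and (best is None or aln.identity > best.identity):
                best = aln
        return best


_SEQ_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _SEQ_LUT[ord(_b)] = _i


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0..T=3, 255 for anything else)."""
    return _SEQ_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def add_to_pileup(aln: Alignment, counts: np.ndarray) -> None:
    """Accumulate one alignment into a (5, L) pileup count matrix
    (rows A, C, G, T, deletion)."""
    codes = encode_seq(aln.oriented_seq)
    pos = aln.start
    qpos = 0
    for op, length in aln.ops:
        if op in "=XM":
            seg = codes[qpos : qpos + length]
            idx = np.nonzero(seg != 255)[0]
            np.add.at(counts, (seg[idx], pos + idx), 1)
            pos += length
            qpos += length
        elif op == "I":
            qpos += length
        elif op == "D":
            counts[4, pos : pos + length] += 1
            pos += length


def pileup_from_alignments(alignments, ref_len: int) -> np.ndarray:
    counts = np.zeros((5, ref_len), dtype=np.int32)
    for aln in alignments:
        add_to_pileup(aln, counts)
    return counts
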