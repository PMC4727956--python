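"""Alignment and ortholog/contaminant filtering.

Per-gene sequences from all individuals are trimmed to the reference,
placed into coding frame, codon-aligned, and then screened by the
post-capture exclusion cascade: coverage outliers (hard cutoff OR a
median + k*MAD rule), contaminant hits (plastid / mitochondrial / rDNA /
transposon k-mer containment), frameshifts and alignment anomalies, and
gene-tree terminal-branch-length skew (a paralogy signal: one taxon
contributing an outsized share of total tree length).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .config import AlignFilterParams
from .dna import kmer_set, revcomp, shared_kmer_fraction

log = logging.getLogger(__name__)

REMOVAL_REASONS = ("coverage_gt_200", "mad_outlier", "tree_length_skew",
                   "frameshift", "contaminant_plastid", "contaminant_mito",
                   "contaminant_rdna", "contaminant_transposon",
                   "alignment_anomaly")

_CODON_TABLE = {}


def _translate(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE.get(codon, "X")


class PairwiseOverlapError(ValueError):
    """A taxon pair shares no unambiguous alignment column."""


@dataclass
class GeneAlignment:
    gene_id: str
    taxa: list
    rows: list                 # aligned, equal-length DNA strings
    codon_offset: int = 0
    is_plastid_role: bool = False

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.gene_id}: unequal row lengths")
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"{self.gene_id}: taxa/rows mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


# ---------------------------------------------------------------------------
# Trimming, frame assignment, codon alignment, splicing

def trim_to_reference(aln: GeneAlignment, reference_taxon: str) -> GeneAlignment:
    """Drop every column where the reference row has a gap; the result's
    column count equals the ungapped reference length."""
    if reference_taxon not in aln.taxa:
        raise ValueError(f"reference taxon {reference_taxon!r} not in alignment")
    ref = aln.row(reference_taxon)
    keep = [j for j, c in enumerate(ref) if c != "-"]
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    return GeneAlignment(aln.gene_id, list(aln.taxa), rows,
                         aln.codon_offset, aln.is_plastid_role)


def assign_reading_frame(seq: str, reference_cds: str,
                         frame_offset: int = 0) -> tuple[str, bool]:
    """Inherit codon boundaries from the reference and flag frameshifts.

    A frameshift is any indel relative to the reference whose length is
    not a multiple of 3. The returned sequence starts at the first
    complete codon and is truncated to whole codons.
    """
    seq = seq.upper().replace("-", "")
    res = edlib.align(seq, reference_cds.upper(), mode="NW", task="path")
    frameshift = False
    import re
    for m in re.finditer(r"(\d+)([=XIDM])", res["cigar"] or ""):
        if m.group(2) in "ID" and int(m.group(1)) % 3 != 0:
            frameshift = True
            break
    lead = (3 - frame_offset) % 3
    framed = seq[lead:]
    framed = framed[: len(framed) - len(framed) % 3]
    return framed, frameshift


def codon_align(sequences: dict, gene_id: str = "",
                reference_taxon: str | None = None,
                codon_offset: int = 0) -> tuple[GeneAlignment, dict]:
    """Translate-align-back-thread codon alignment.

    Each framed nucleotide sequence is translated, aligned to the
    reference peptide (global pairwise), and its codons threaded back
    through the amino-acid alignment, so gaps only ever occur in
    multiples of 3 at codon boundaries and stripping gaps from any row
    reproduces its input exactly. Sequences with internal stop codons
    are excluded and reported as anomalies.
    """
    anomalies: dict[str, str] = {}
    taxa = list(sequences)
    if reference_taxon is None:
        reference_taxon = taxa[0]
    codons = {}
    peptides = {}
    for t in taxa:
        s = sequences[t].upper()
        if len(s) % 3:
            raise ValueError(f"{t}: length not a multiple of 3 (assign frames first)")
        cs = [s[i : i + 3] for i in range(0, len(s), 3)]
        pep = "".join(_translate(c) for c in cs)
        if "*" in pep[:-1]:
            anomalies[t] = "internal_stop"
            continue
        codons[t] = cs
        peptides[t] = pep      # a terminal stop stays threaded with its row
    if reference_taxon not in peptides:
        raise ValueError(f"reference taxon {reference_taxon!r} unusable "
                         f"({anomalies.get(reference_taxon)})")
    ref_pep = peptides[reference_taxon]
    R = len(ref_pep)
    # per sequence: matches[r] = codon or None, inserts[r] = codons before ref pos r
    matches: dict[str, list] = {}
    inserts: dict[str, list] = {}
    import re as _re
    for t, pep in peptides.items():
        m = [None] * R
        ins = [[] for _ in range(R + 1)]
        res = edlib.align(pep, ref_pep, mode="NW", task="path")
        qi = ri = 0
        for grp in _re.finditer(r"(\d+)([=XIDM])", res["cigar"]):
            n, op = int(grp.group(1)), grp.group(2)
            if op in "=XM":
                for _ in range(n):
                    m[ri] = codons[t][qi]
                    qi += 1
                    ri += 1
            elif op == "I":      # insertion in query relative to reference
                ins[ri].extend(codons[t][qi : qi + n])
                qi += n
            elif op == "D":
                ri += n
        matches[t] = m
        inserts[t] = ins
    widths = [max(len(inserts[t][r]) for t in peptides) for r in range(R + 1)]
    rows = {}
    for t in peptides:
        parts = []
        for r in range(R + 1):
            ins = inserts[t][r]
            parts.append("".join(ins) + "---" * (widths[r] - len(ins)))
            if r < R:
                parts.append(matches[t][r] or "---")
        rows[t] = "".join(parts)
    kept = [t for t in taxa if t in rows]
    aln = GeneAlignment(gene_id, kept, [rows[t] for t in kept],
                        codon_offset=codon_offset)
    return aln, anomalies


def splice_introns(sequence: str, introns) -> str:
    """Remove 0-based half-open intron intervals; intervals must be
    in-bounds and non-overlapping."""
    ivs = sorted((int(a), int(b)) for a, b in introns)
    prev_end = 0
    for a, b in ivs:
        if a < 0 or b > len(sequence) or a > b:
            raise ValueError(f"intron [{a},{b}) out of bounds")
        if a < prev_end:
            raise ValueError(f"intron [{a},{b}) overlaps previous interval")
        prev_end = b
    out = []
    pos = 0
    for a, b in ivs:
        out.append(sequence[pos:a])
        pos = b
    out.append(sequence[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Exclusion filters

def coverage_outlier_filter(mean_coverages: dict, hard_cutoff: float = 200.0,
                            mad_multiplier: float = 4.0) -> dict:
    """Flag exons whose mean coverage exceeds the hard cutoff OR
    median + ``mad_multiplier`` * MAD. When MAD is 0 only the hard cutoff
    applies. Returns exon_id -> reason ("coverage_gt_200" | "mad_outlier")
    for flagged exons only."""
    if not mean_coverages:
        raise ValueError("need at least one exon")
    vals = np.array(list(mean_coverages.values()), dtype=float)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    out = {}
    for exon, cov in mean_coverages.items():
        if cov > hard_cutoff:
            out[exon] = "coverage_gt_200"
        elif mad > 0 and cov > med + mad_multiplier * mad:
            out[exon] = "mad_outlier"
    return out


def contaminant_screen(gene_sequences: dict, libraries: dict,
                       k: int = 21, min_shared_fraction: float = 0.30) -> dict:
    """Classify each gene by k-mer containment against labeled
    contaminant libraries; returns gene -> class label or "clean"."""
    lib_kmers = {}
    for label, seqs in libraries.items():
        s = set()
        for seq in seqs:
            km = kmer_set(seq.upper(), k)
            s |= km
            s |= {revcomp(x) for x in km}
        lib_kmers[label] = s
    out = {}
    for gene, seq in gene_sequences.items():
        best_label, best_frac = "clean", 0.0
        for label, kms in lib_kmers.items():
            if not kms:
                continue
            frac = shared_kmer_fraction(seq.upper(), kms, k)
            if frac > best_frac:
                best_label, best_frac = label, frac
        out[gene] = best_label if best_frac >= min_shared_fraction else "clean"
    return out


def tree_length_skew_filter(tree: dendropy.Tree, threshold: float = 0.15):
    """Flag a gene tree when any single terminal branch accounts for more
    than ``threshold`` of the total tree length (strict >). Returns
    (flagged, offending_taxon, fraction)."""
    total = sum(e.length or 0.0 for e in tree.edges())
    if total <= 0:
        log.warning("tree has zero total length; skew filter not applied")
        return False, None, 0.0
    worst_taxon, worst = None, -1.0
    for leaf in tree.leaf_node_iter():
        bl = leaf.edge.length or 0.0
        if bl > worst:
            worst, worst_taxon = bl, leaf.taxon.label
    frac = worst / total
    return frac > threshold, worst_taxon, frac


# ---------------------------------------------------------------------------
# Distances, gene trees, informative sites

def _encode(rows) -> np.ndarray:
    """Alignment rows to uint8 codes 0..3 for A,C,G,T and 255 otherwise."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    return lut[mat]


def jc_distance_matrix(aln: GeneAlignment, max_distance: float = 5.0) -> np.ndarray:
    """Pairwise Jukes-Cantor distances over mutually unambiguous columns.

    Raises :class:`PairwiseOverlapError` when a pair shares no usable
    column. Saturated pairs (p >= 3/4) are capped at ``max_distance``.
    """
    codes = _encode(aln.rows)
    n = len(aln.taxa)
    valid = codes != 255
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise PairwiseOverlapError(
                    f"{aln.gene_id}: {aln.taxa[i]} and {aln.taxa[j]} share no "
                    f"unambiguous columns")
            p = float((codes[i][both] != codes[j][both]).sum()) / m
            if p >= 0.75:
                d = max_distance
            else:
                d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = min(d, max_distance)
    return D


def nj_tree(distances: np.ndarray, taxa: list) -> dendropy.Tree:
    """Neighbor-joining tree (negative branch lengths clamped to 0)."""
    dm = DistanceMatrix(distances, ids=list(taxa))
    tn = _skbio_nj(dm)
    return dendropy.Tree.get(data=str(tn), schema="newick", preserve_underscores=True)


def build_gene_tree(aln: GeneAlignment) -> dendropy.Tree:
    """NJ tree on JC-corrected distances over mutually unambiguous
    positions; the tree the skew filter consumes."""
    if len(aln.taxa) < 3:
        raise ValueError("need at least 3 taxa for a gene tree")
    return nj_tree(jc_distance_matrix(aln), aln.taxa)


def count_pi_sites(aln) -> tuple[int, int, float]:
    """Parsimony-informative sites: columns where >=2 distinct
    unambiguous states (A/C/G/T only) each occur in >=2 taxa. Accepts a
    GeneAlignment or a plain list of rows; returns
    (n_columns, n_informative, fraction)."""
    rows = aln.rows if isinstance(aln, GeneAlignment) else list(aln)
    if not rows or not rows[0]:
        return 0, 0, 0.0
    codes = _encode(rows)
    n_cols = codes.shape[1]
    counts = np.stack([(codes == i).sum(axis=0) for i in range(4)])  # (4, L)
    informative = ((counts >= 2).sum(axis=0) >= 2)
    n_pi = int(informative.sum())
    return n_cols, n_pi, n_pi / n_cols


def pi_percent(n_informative: int, n_columns: int) -> float:
    """Parsimony-informative fraction as the percentage convention used
    in matrix summaries (one decimal place)."""
    return round(100.0 * n_informative / n_columns, 1)


# ---------------------------------------------------------------------------
# The exclusion cascade

@dataclass
class GeneRecord:
    """Per-gene bundle entering the exclusion cascade."""
    gene_id: str
    alignment: GeneAlignment
    mean_coverage: float
    frameshift: bool = False
    anomalies: dict = field(default_factory=dict)   # taxon -> reason
    representative: str = ""                        # sequence for BLAST-role screen

    def __post_init__(self):
        if not self.representative and self.alignment.rows:
            self.representative = self.alignment.rows[0].replace("-", "")


def run_filter_cascade(genes, params: AlignFilterParams | None = None,
                       contaminant_libraries: dict | None = None
                       ) -> tuple[list, pd.DataFrame]:
    """Apply coverage-outlier, contaminant, frameshift/anomaly and
    tree-length-skew filters over a list of :class:`GeneRecord`.

    Every reason is evaluated and recorded for every gene; a gene is
    removed when it carries at least one reason. Returns (retained
    GeneRecord list, report DataFrame).
    """
    params = params or AlignFilterParams()
    params.validate()
    genes = list(genes)
    cov_flags = coverage_outlier_filter(
        {g.gene_id: g.mean_coverage for g in genes},
        params.coverage_hard_cutoff, params.mad_multiplier)
    cls = contaminant_screen(
        {g.gene_id: g.representative for g in genes},
        contaminant_libraries or {},
        params.contaminant_k, params.contaminant_min_shared)

    kept_contaminants = {"rdna", "mito"} if params.keep_rdna_mito else set()
    rows = []
    retained = []
    for g in genes:
        reasons = []
        metrics = []
        if g.gene_id in cov_flags:
            reasons.append(cov_flags[g.gene_id])
            metrics.append(f"coverage={g.mean_coverage:.1f}")
        label = cls.get(g.gene_id, "clean")
        if label != "clean" and label not in kept_contaminants:
            reasons.append(f"contaminant_{label}")
            metrics.append(f"class={label}")
        if g.frameshift:
            reasons.append("frameshift")
        anomalies = dict(g.anomalies)
        gappy = [t for t, r in zip(g.alignment.taxa, g.alignment.rows)
                 if r.count("-") > params.max_gap_row_fraction * len(r)]
        # a single data-poor row is missing data, not an alignment problem;
        # flag only when a substantial share of rows is gap-dominated
        if len(gappy) > params.max_gappy_row_share * len(g.alignment.rows):
            anomalies.setdefault("_rows", f"{len(gappy)}_gappy_rows")
        # taxa with almost no called sequence are missing data, not
        # evidence of an alignment problem: the gene tree is built on
        # the data-bearing rows only
        informative = [(t, r) for t, r in zip(g.alignment.taxa,
                                              g.alignment.rows)
                       if sum(r.count(b) for b in "ACGT")
                       >= params.min_row_content * len(r)]
        skew_frac = None
        if len(informative) >= 3:
            sub = GeneAlignment(g.gene_id, [t for t, _ in informative],
                                [r for _, r in informative],
                                g.alignment.codon_offset)
            try:
                tree = build_gene_tree(sub)
                flagged, taxon, frac = tree_length_skew_filter(
                    tree, params.skew_threshold)
                skew_frac = frac
                if flagged:
                    reasons.append("tree_length_skew")
                    metrics.append(f"taxon={taxon};fraction={frac:.3f}")
            except PairwiseOverlapError as e:
                anomalies.setdefault("_overlap", str(e))
        if anomalies:
            reasons.append("alignment_anomaly")
            metrics.append(";".join(f"{t}:{r}" for t, r in anomalies.items()))
        status = "removed" if reasons else "retained"
        if status == "retained":
            retained.append(g)
        rows.append({"gene_id": g.gene_id, "status": status,
                     "reasons": ";".join(reasons), "metric": ";".join(metrics),
                     "mean_coverage": g.mean_coverage,
                     "skew_fraction": skew_frac})
    report = pd.DataFrame(rows, columns=["gene_id", "status", "reasons",
                                         "metric", "mean_coverage",
                                         "skew_fraction"])
    for reason in REMOVAL_REASONS:
        n = int(report["reasons"].str.contains(reason, regex=False).sum())
        if n:
            log.info("cascade: %d gene(s) flagged %s", n, reason)
    return retained, report


def summarize_filter_report(report: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a filter report into a per-reason accounting table, with
    totals for removed and retained genes."""
    rows = []
    removed = report[report["status"] == "removed"]
    for reason in REMOVAL_REASONS:
        n = int(removed["reasons"].str.contains(reason, regex=False).sum())
        rows.append({"reason": reason, "n_removed": n})
    rows.append({"reason": "total_removed", "n_removed": len(removed)})
    rows.append({"reason": "total_retained",
                 "n_removed": int((report["status"] == "retained").sum())})
    return pd.DataFrame(rows)
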