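"""Synthetic data generator for the full capture pipeline.

Emulates the statistical structure the method assumes: an ancient rapid
radiation (8 families whose stems diverge within a short basal window),
coding exons evolved under HKY along the tree, per-lineage transcriptome
evidence, paired-end capture reads whose depth decays with divergence
from the bait lineage, PCR duplicates, sequencing error, and planted
violations giving every downstream filter a positive control — together
with machine-readable truth tables.

Defaults describe a desk-scale study: 48 individuals, 200 coding exons
of ~300 bp, ~30x target depth, 26% of sequenced bases on target.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.linalg

from .baitdesign import TargetExon
from .dna import revcomp
from .readproc import ReadPair

log = logging.getLogger(__name__)

VIOLATION_CLASSES = ("short", "gc", "non_unique", "repeat", "high_copy",
                     "skewed_taxon", "contaminant_plastid", "contaminant_mito",
                     "contaminant_rdna", "contaminant_transposon")

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimulationConfig:
    seed: int = 0
    # taxon sampling
    n_families: int = 8
    taxa_per_family: int = 6
    # loci
    n_genes: int = 200
    exon_len_mean: int = 300
    exon_len_sd: int = 60
    exon_len_min: int = 180
    # HKY substitution model
    kappa: float = 3.0
    base_freqs: tuple = (0.27, 0.23, 0.23, 0.27)   # A, C, G, T
    # tree shape (expected substitutions per site)
    tree_depth: float = 0.06
    family_crown_fraction: float = 0.20
    radiation_fraction: float = 0.15   # basal-split window as share of depth
    # indels (off by default: the consensus caller is reference-coordinate
    # based; indel handling is exercised at the alignment stage)
    indel_rate: float = 0.0            # events per site per branch
    indel_mean_codons: float = 1.5
    # capture / sequencing model
    mean_depth: float = 30.0
    depth_lognorm_sigma: float = 0.3           # per-individual library factor
    exon_capturability_range: tuple = (0.8, 1.2)
    capture_decay: float = 3.0                 # exp(-decay * div-to-bait)
    fragment_mean: int = 150
    fragment_sd: int = 20
    read_length: int = 100
    on_target_fraction: float = 0.26
    duplicate_rate: float = 0.15
    error_rate: float = 0.002
    base_quality: int = 37
    # planted-violation knobs
    high_copy_multiplier: float = 10.0
    paralog_divergence: float = 0.22
    contaminant_divergence: float = 0.01
    non_unique_divergence: float = 0.02
    violations: dict = field(default_factory=lambda: {
        "short": 3, "gc": 3, "non_unique": 2, "repeat": 3, "high_copy": 3,
        "skewed_taxon": 3, "contaminant_plastid": 2, "contaminant_mito": 2,
        "contaminant_rdna": 2, "contaminant_transposon": 2})

    def validate(self) -> None:
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        for key in self.violations:
            if key not in VIOLATION_CLASSES:
                raise ValueError(f"unknown violation class {key!r}")
        # each non_unique event consumes a second (donor) gene
        needed = sum(self.violations.values()) + self.violations.get("non_unique", 0)
        if needed > self.n_genes:
            raise ValueError("more planted violations than genes")
        for frac in (self.on_target_fraction, self.duplicate_rate,
                     self.error_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class TruthTable:
    """Machine-readable ground truth for every emitted record."""
    sequences: dict          # (gene_id, taxon) -> true exonic sequence
    gene_violations: dict    # gene_id -> list of violation classes ([] = clean)
    skew_taxon: dict         # gene_id -> taxon carrying the planted paralog
    high_copy: set           # gene_ids with inflated capture depth
    fragment_of: dict        # read id -> fragment id (duplicate accounting)
    on_target: dict          # individual -> true on-target base fraction


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: dendropy.Tree
    taxa: list
    families: dict                 # family -> ordered taxon list
    reference_taxon: str
    exons: list                    # TargetExon candidates (reference copies)
    evidence_by_lineage: dict      # family -> list of transcript contigs
    repeat_library: list
    contaminant_libraries: dict    # class -> list of sequences
    truth: TruthTable
    capturability: dict = field(default_factory=dict)   # exon_id -> factor
    _pdm_cache: dict = field(default_factory=dict, repr=False)

    @property
    def individuals(self) -> list:
        return list(self.taxa)

    def family_of(self, taxon: str) -> str:
        return taxon.rsplit("_", 1)[0]

    def bait_divergence(self, taxon: str) -> float:
        """Patristic distance from an individual to its family's bait
        (the lineage whose transcriptome seeded the probes)."""
        if taxon not in self._pdm_cache:
            bait = self.families[self.family_of(taxon)][0]
            self._pdm_cache[taxon] = 0.0 if taxon == bait else \
                _patristic_distance(self.tree, taxon, bait)
        return self._pdm_cache[taxon]


# ---------------------------------------------------------------------------
# HKY machinery

def hky_rate_matrix(kappa: float, base_freqs) -> np.ndarray:
    """HKY85 rate matrix (order A,C,G,T) scaled to one expected
    substitution per site per unit branch length."""
    pi = np.asarray(base_freqs, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}   # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


def hky_transition_matrix(t: float, kappa: float, base_freqs) -> np.ndarray:
    """P(t) = exp(Qt) for the scaled HKY model."""
    return scipy.linalg.expm(hky_rate_matrix(kappa, base_freqs) * t)


def expected_p_distance(t: float, kappa: float, base_freqs) -> float:
    """Expected proportion of differing sites between two sequences
    separated by total path length ``t``."""
    P = hky_transition_matrix(t, kappa, base_freqs)
    pi = np.asarray(base_freqs)
    return float(1.0 - (pi * np.diag(P)).sum())


def _sample_root(length: int, base_freqs, rng, coding: bool) -> np.ndarray:
    seq = rng.choice(4, size=length, p=np.asarray(base_freqs))
    if coding:
        _remove_stops(seq, rng, base_freqs)
    return seq


def _codon_str(arr) -> str:
    return "".join("ACGT"[b] for b in arr)


def _remove_stops(seq: np.ndarray, rng, base_freqs) -> None:
    """Resample in-frame stop codons (purifying-selection stand-in)."""
    for i in range(0, len(seq) - len(seq) % 3, 3):
        while _codon_str(seq[i : i + 3]) in _STOPS:
            seq[i : i + 3] = rng.choice(4, size=3, p=np.asarray(base_freqs))


def evolve_branch(parent: np.ndarray, t: float, kappa: float, base_freqs,
                  rng, coding: bool = True) -> np.ndarray:
    """One HKY draw per site along a branch of length ``t``; with
    ``coding`` any codon mutated into a stop reverts to the parent codon."""
    if t <= 0:
        return parent.copy()
    P = hky_transition_matrix(t, kappa, base_freqs)
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(parent))
    child = (u[:, None] > cum[parent]).sum(axis=1).astype(np.int8)
    if coding:
        for i in range(0, len(child) - len(child) % 3, 3):
            if _codon_str(child[i : i + 3]) in _STOPS:
                child[i : i + 3] = parent[i : i + 3]
    return child


def apply_indels(seq: np.ndarray, rate: float, mean_codons: float, rng,
                 coding: bool = True, base_freqs=(0.25,) * 4) -> np.ndarray:
    """Geometric-length indels; in coding mode lengths are whole codons."""
    if rate <= 0:
        return seq
    n_events = rng.poisson(rate * len(seq))
    out = seq
    for _ in range(n_events):
        n_units = rng.geometric(1.0 / mean_codons)
        length = 3 * n_units if coding else n_units
        pos = int(rng.integers(0, max(1, len(out))))
        if coding:
            pos -= pos % 3
        if rng.random() < 0.5 and len(out) > length + 3:
            out = np.concatenate([out[:pos], out[pos + length:]])
        else:
            ins = rng.choice(4, size=length, p=np.asarray(base_freqs))
            out = np.concatenate([out[:pos], ins, out[pos:]])
    return out


# ---------------------------------------------------------------------------
# Species tree

def simulate_species_tree(config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[dendropy.Tree, dict]:
    """Ultrametric species tree with an ancient-radiation backbone: the
    family stems split within a short basal window, then radiate into
    shallow family crowns. Returns (tree, family -> taxa)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    D = config.tree_depth
    crown = D * config.family_crown_fraction
    window = D * config.radiation_fraction
    nf = config.n_families
    families = {f"Fam{i + 1:02d}": [f"Fam{i + 1:02d}_t{j + 1}"
                                    for j in range(config.taxa_per_family)]
                for i in range(nf)}

    def crown_newick(taxa):
        # sequential random joins at sorted uniform heights -> ultrametric
        if len(taxa) == 1:
            return taxa[0], 0.0
        heights = np.sort(rng.uniform(crown * 0.2, crown, size=len(taxa) - 1))
        clusters = [(t, 0.0) for t in taxa]
        for h in heights:
            i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
            (na, ha), (nb, hb) = clusters[i], clusters[j]
            merged = (f"({na}:{h - ha:.10f},{nb}:{h - hb:.10f})", float(h))
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
            clusters.append(merged)
        return clusters[0]

    order = list(rng.permutation(sorted(families)))
    # caterpillar backbone: splits at D, D-delta, ..., D-window
    delta = window / max(1, nf - 2)
    subtrees = []
    for fam in order:
        nwk, h = crown_newick(families[fam])
        subtrees.append((nwk, h))
    node_nwk, node_h = subtrees[-1]
    for k in range(nf - 2, 0, -1):
        split_h = D - k * delta
        stem_nwk, stem_h = subtrees[k]
        node_nwk = (f"({stem_nwk}:{split_h - stem_h:.10f},"
                    f"{node_nwk}:{split_h - node_h:.10f})")
        node_h = split_h
    first_nwk, first_h = subtrees[0]
    newick = (f"({first_nwk}:{D - first_h:.10f},"
              f"{node_nwk}:{D - node_h:.10f});")
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return tree, families


# ---------------------------------------------------------------------------
# Sequence evolution over the tree

def evolve_exons(tree: dendropy.Tree, config: SimulationConfig,
                 rng: np.random.Generator | None = None,
                 coding: bool = True) -> tuple[dict, dict]:
    """Evolve one sequence per gene per leaf. Returns
    (sequences: (gene, taxon) -> str, roots: gene -> str)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sequences: dict[tuple, str] = {}
    roots: dict[str, str] = {}
    for gi in range(config.n_genes):
        gene = f"g{gi + 1:03d}"
        L = int(np.clip(rng.normal(config.exon_len_mean, config.exon_len_sd),
                        config.exon_len_min, 4 * config.exon_len_mean))
        L -= L % 3
        root = _sample_root(L, config.base_freqs, rng, coding)
        roots[gene] = _codon_str(root)
        states = {id(tree.seed_node): root}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = states[id(node.parent_node)]
            child = evolve_branch(parent, node.edge.length or 0.0,
                                  config.kappa, config.base_freqs, rng, coding)
            child = apply_indels(child, config.indel_rate,
                                 config.indel_mean_codons, rng, coding,
                                 config.base_freqs)
            states[id(node)] = child
            if node.is_leaf():
                sequences[(gene, node.taxon.label)] = _codon_str(child)
    return sequences, roots


# ---------------------------------------------------------------------------
# Libraries and planted violations

def _random_seq(rng, length, gc=0.46, stop_free=False):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(4, size=length, p=p)
    if stop_free:
        _remove_stops(seq, rng, p)
    return _codon_str(seq)


def make_libraries(config: SimulationConfig,
                   rng: np.random.Generator | None = None):
    """Repeat library plus labeled contaminant libraries (plastid-role
    genome, mitochondrial, rDNA, transposon).

    Contaminant libraries are generated stop-free in frame 0 so that
    codon-aligned windows of them can be planted as captured
    contaminant loci without disturbing their k-mer content.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    repeat_library = [_random_seq(rng, 500) for _ in range(10)]
    contaminant = {
        "plastid": [_random_seq(rng, 20001, stop_free=True)],
        "mito": [_random_seq(rng, 2001, stop_free=True) for _ in range(5)],
        "rdna": [_random_seq(rng, 3000, stop_free=True) for _ in range(3)],
        "transposon": [_random_seq(rng, 1500, stop_free=True)
                       for _ in range(5)],
    }
    return repeat_library, contaminant


def _seq_to_arr(s: str) -> np.ndarray:
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([lut[c] for c in s], dtype=np.int8)


def plant_violations(sequences: dict, roots: dict, taxa: list,
                     config: SimulationConfig, repeat_library,
                     contaminant_libraries,
                     rng: np.random.Generator | None = None,
                     exclude_taxa: frozenset = frozenset()) -> TruthTable:
    """Deterministically (seeded) select genes and apply each configured
    violation class, mutating ``sequences``/``roots`` in place and
    recording everything in the returned truth table."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = sorted(roots)
    chosen: dict[str, list] = {g: [] for g in genes}
    pool = list(rng.permutation(genes))
    skew_taxon: dict[str, str] = {}
    high_copy: set[str] = set()

    def take(n):
        picked = pool[:n]
        del pool[:n]
        return picked

    def reevolve(gene, root_str, divergence_scale=1.0, coding=True):
        """Replace a gene's root and re-derive all taxa at low divergence
        (used for contaminant/non-unique copies)."""
        roots[gene] = root_str
        arr = _seq_to_arr(root_str)
        for t in taxa:
            child = evolve_branch(arr, config.contaminant_divergence *
                                  divergence_scale, config.kappa,
                                  config.base_freqs, rng, coding)
            sequences[(gene, t)] = _codon_str(child)

    v = config.violations
    for gene in take(v.get("short", 0)):
        chosen[gene].append("short")
        L = int(rng.integers(90, 141))
        L -= L % 3
        roots[gene] = roots[gene][:L]
        for t in taxa:
            sequences[(gene, t)] = sequences[(gene, t)][:L]

    for gene in take(v.get("gc", 0)):
        chosen[gene].append("gc")
        gc = 0.15 if rng.random() < 0.5 else 0.85
        L = len(roots[gene])
        root = _random_seq(rng, L, gc=gc)
        arr = _seq_to_arr(root)
        _remove_stops(arr, rng, config.base_freqs)
        roots[gene] = _codon_str(arr)
        for t in taxa:
            child = evolve_branch(arr, config.tree_depth, config.kappa,
                                  config.base_freqs, rng, coding=True)
            sequences[(gene, t)] = _codon_str(child)

    # each non_unique event duplicates one gene into another: both copies
    # become reciprocal best hits and both fail the uniqueness filter
    for _ in range(v.get("non_unique", 0)):
        donor, copy = take(2)
        chosen[donor].append("non_unique")
        chosen[copy].append("non_unique")
        roots[copy] = roots[donor]
        for t in taxa:
            arr = _seq_to_arr(sequences[(donor, t)])
            child = evolve_branch(arr, config.non_unique_divergence,
                                  config.kappa, config.base_freqs, rng, True)
            sequences[(copy, t)] = _codon_str(child)

    for gene in take(v.get("repeat", 0)):
        chosen[gene].append("repeat")
        L = len(roots[gene])
        seg_len = L // 2
        lib_seq = repeat_library[int(rng.integers(0, len(repeat_library)))]
        start = int(rng.integers(0, len(lib_seq) - seg_len))
        seg = lib_seq[start : start + seg_len]
        ins = L // 4 - (L // 4) % 3
        for t in list(taxa):
            s = sequences[(gene, t)]
            sequences[(gene, t)] = s[:ins] + seg + s[ins + seg_len:]
        roots[gene] = roots[gene][:ins] + seg + roots[gene][ins + seg_len:]

    for gene in take(v.get("high_copy", 0)):
        chosen[gene].append("high_copy")
        high_copy.add(gene)

    # the paralog never lands on a bait/reference individual: a paralog
    # bait would degrade capture for the whole lineage, a different
    # (and at bait-design time already screened) failure mode
    hosts = [t for t in taxa if t not in exclude_taxa] or list(taxa)
    for gene in take(v.get("skewed_taxon", 0)):
        chosen[gene].append("skewed_taxon")
        taxon = hosts[int(rng.integers(0, len(hosts)))]
        arr = _seq_to_arr(sequences[(gene, taxon)])
        paralog = evolve_branch(arr, config.paralog_divergence, config.kappa,
                                config.base_freqs, rng, coding=True)
        sequences[(gene, taxon)] = _codon_str(paralog)
        skew_taxon[gene] = taxon

    for klass in ("plastid", "mito", "rdna", "transposon"):
        for gene in take(v.get(f"contaminant_{klass}", 0)):
            chosen[gene].append(f"contaminant_{klass}")
            L = len(roots[gene])
            lib = contaminant_libraries[klass]
            src = lib[int(rng.integers(0, len(lib)))]
            # codon-aligned window of the stop-free library sequence
            start = 3 * int(rng.integers(0, max(1, (len(src) - L) // 3)))
            reevolve(gene, src[start : start + L])

    return TruthTable(sequences=sequences, gene_violations=chosen,
                      skew_taxon=skew_taxon, high_copy=high_copy,
                      fragment_of={}, on_target={})


# ---------------------------------------------------------------------------
# Capture-read simulation

def _patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    return pdm.distance(tns.get_taxon(a), tns.get_taxon(b))


def simulate_capture_reads(dataset: "SimulatedDataset", individual: str,
                           rng: np.random.Generator | None = None
                           ) -> tuple[list, dict, float]:
    """Paired-end reads for one individual across all candidate exons.

    Per-exon fragment counts are Poisson around a mean depth scaled by a
    bounded per-exon capturability factor, a lognormal per-individual
    library factor, exponential decay with divergence from the bait
    lineage, and the high-copy multiplier for planted high-copy exons.
    PCR duplicates re-emit a fragment; sequencing errors are uniform
    substitutions. Returns (pairs, read_id -> fragment_id, true on-target
    base fraction).
    """
    cfg = dataset.config
    if rng is None:
        idx = dataset.taxa.index(individual)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5, idx]))
    div = dataset.bait_divergence(individual)
    lib_factor = float(rng.lognormal(mean=-0.5 * cfg.depth_lognorm_sigma ** 2,
                                     sigma=cfg.depth_lognorm_sigma))
    decay = float(np.exp(-cfg.capture_decay * div))
    rl = cfg.read_length
    pairs: list[ReadPair] = []
    fragment_of: dict[str, str] = {}
    on_bases = 0
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)

    def emit(seq_arr, rid, frag_id):
        nonlocal on_bases
        err = rng.random(seq_arr.shape) < cfg.error_rate
        if err.any():
            seq_arr = seq_arr.copy()
            seq_arr[err] = (seq_arr[err] + rng.integers(1, 4, size=int(err.sum()),
                                                        dtype=np.int8)) % 4
        frag = lut[seq_arr].tobytes().decode()
        r1 = frag[:rl]                 # may be the whole fragment when
        r2 = revcomp(frag[-rl:])       # the locus is shorter than a read
        pairs.append(ReadPair(rid, r1, r2, [cfg.base_quality] * len(r1),
                              [cfg.base_quality] * len(r2)))
        fragment_of[rid] = frag_id

    for e in dataset.exons:
        gene = e.gene_id
        true_seq = dataset.truth.sequences[(gene, individual)]
        L = len(true_seq)
        cap = dataset.capturability[e.exon_id]
        mult = cfg.high_copy_multiplier if gene in dataset.truth.high_copy else 1.0
        depth = cfg.mean_depth * cap * lib_factor * decay * mult
        n_frag = rng.poisson(depth * L / (2.0 * rl))
        if n_frag == 0:
            continue
        arr = _seq_to_arr(true_seq)
        flens = np.clip(rng.normal(cfg.fragment_mean, cfg.fragment_sd,
                                   size=n_frag).astype(int), rl, L)
        starts = (rng.random(n_frag) * (L - flens + 1)).astype(int)
        for i in range(n_frag):
            frag_id = f"{individual}|{e.exon_id}|f{i}"
            frag = arr[starts[i] : starts[i] + flens[i]]
            emit(frag, frag_id + "|0", frag_id)
            on_bases += 2 * rl
            d = 0
            while rng.random() < cfg.duplicate_rate:
                d += 1
                emit(frag, f"{frag_id}|{d}", frag_id)
                on_bases += 2 * rl
    # off-target background to hit the configured on-target fraction
    off_bases = 0
    if cfg.on_target_fraction < 1.0 and on_bases:
        target_off = on_bases * (1.0 - cfg.on_target_fraction) / cfg.on_target_fraction
        bg = rng.choice(4, size=100_000).astype(np.int8)
        i = 0
        while off_bases < target_off:
            s = int(rng.integers(0, len(bg) - cfg.fragment_mean))
            frag_id = f"{individual}|off|f{i}"
            emit(bg[s : s + cfg.fragment_mean], frag_id + "|0", frag_id)
            off_bases += 2 * rl
            i += 1
    total = on_bases + off_bases
    on_frac = on_bases / total if total else 0.0
    return pairs, fragment_of, on_frac


# ---------------------------------------------------------------------------
# Top-level dataset assembly

def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Build the complete synthetic study: tree, evolved exons, planted
    violations, candidate exon set, transcriptome evidence, libraries."""
    config = config or SimulationConfig()
    config.validate()
    tree, families = simulate_species_tree(config)
    taxa = [t for fam in sorted(families) for t in families[fam]]
    sequences, roots = evolve_exons(tree, config)
    repeat_library, contaminant_libraries = make_libraries(config)
    bait_taxa = frozenset(families[f][0] for f in families)
    truth = plant_violations(sequences, roots, taxa, config,
                             repeat_library, contaminant_libraries,
                             exclude_taxa=bait_taxa)
    reference_taxon = families[sorted(families)[0]][0]
    exons = []
    offset = 0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    for gi, gene in enumerate(sorted(roots)):
        seq = sequences[(gene, reference_taxon)]
        chrom = f"chr{gi % 11 + 1}" if rng.random() > 0.03 else "unknown"
        exons.append(TargetExon(exon_id=f"{gene}_e1", gene_id=gene,
                                chromosome=chrom, start=offset,
                                end=offset + len(seq), sequence=seq,
                                cds_frame_offset=0))
        offset += len(seq) + 1000
    evidence = {}
    for fam in sorted(families)[1:]:
        rep = families[fam][0]
        evidence[fam] = [sequences[(g, rep)] for g in sorted(roots)]
    cap_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    capturability = {e.exon_id: float(cap_rng.uniform(
        *config.exon_capturability_range)) for e in exons}
    return SimulatedDataset(config=config, tree=tree, taxa=taxa,
                            families=families, reference_taxon=reference_taxon,
                            exons=exons, evidence_by_lineage=evidence,
                            repeat_library=repeat_library,
                            contaminant_libraries=contaminant_libraries,
                            truth=truth, capturability=capturability)


def reads_for(dataset: SimulatedDataset, individual: str):
    """Deterministic per-individual read set plus truth updates."""
    pairs, fragment_of, on_frac = simulate_capture_reads(dataset, individual)
    dataset.truth.fragment_of.update(fragment_of)
    dataset.truth.on_target[individual] = on_frac
    return pairs
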