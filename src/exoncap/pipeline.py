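"""End-to-end driver: simulate -> design baits -> process reads ->
align & filter -> build supermatrix, with truth-based evaluation
helpers for the synthetic study."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignfilter, baitdesign, phylo, readproc, simdata
from .config import PipelineConfig

log = logging.getLogger(__name__)

#: planted violation class -> removal reasons that count as detection
DETECTION_MAP = {
    "short": {"too_short"},
    "gc": {"gc_out_of_range"},
    "non_unique": {"non_unique"},
    "repeat": {"repeat_hit"},
    "high_copy": {"coverage_gt_200", "mad_outlier"},
    "skewed_taxon": {"tree_length_skew"},
    "contaminant_plastid": {"contaminant_plastid"},
    "contaminant_mito": {"contaminant_mito"},
    "contaminant_rdna": {"contaminant_rdna"},
    "contaminant_transposon": {"contaminant_transposon"},
}


@dataclass
class PipelineResult:
    dataset: simdata.SimulatedDataset
    probes: baitdesign.ProbeSet
    bait_decisions: list
    individual_results: list                  # readproc.IndividualResult
    gene_records: list                        # alignfilter.GeneRecord
    retained: list
    filter_report: pd.DataFrame
    supermatrix: phylo.Supermatrix | None
    partition_scheme: phylo.PartitionScheme | None
    stage_counts: dict = field(default_factory=dict)


def run_end_to_end(sim_config: simdata.SimulationConfig | None = None,
                   pipeline_config: PipelineConfig | None = None,
                   individuals: list | None = None) -> PipelineResult:
    """Run every stage on a freshly simulated dataset.

    ``individuals`` restricts read processing to a subset of taxa (the
    full default is all simulated individuals).
    """
    sim_config = sim_config or simdata.SimulationConfig()
    cfg = (pipeline_config or PipelineConfig()).validate()
    ds = simdata.simulate_dataset(sim_config)
    log.info("simulated %d genes x %d taxa", sim_config.n_genes, len(ds.taxa))

    probes, decisions = baitdesign.run_bait_design(
        ds.exons, ds.evidence_by_lineage, cfg.baitdesign, ds.repeat_library)
    passing = {d.exon_id for d in decisions if d.passed}
    target_exons = [e for e in ds.exons if e.exon_id in passing]
    log.info("bait design: %d/%d exons carried to capture",
             len(target_exons), len(ds.exons))

    who = individuals if individuals is not None else ds.individuals
    results = []
    for ind in who:
        pairs = simdata.reads_for(ds, ind)
        results.append(readproc.process_individual(
            pairs, target_exons, cfg.readproc, individual=ind))

    gene_records = []
    for e in target_exons:
        taxa, rows, covs = [], [], []
        for r in results:
            cons = r.consensi[e.exon_id]
            taxa.append(r.individual)
            rows.append(cons.sequence)
            covs.append(cons.mean_coverage)
        aln = alignfilter.GeneAlignment(e.gene_id, taxa, rows, codon_offset=0)
        rep = max(results, key=lambda r: r.consensi[e.exon_id].retained_fraction)
        gene_records.append(alignfilter.GeneRecord(
            gene_id=e.gene_id, alignment=aln,
            mean_coverage=float(np.mean(covs)),
            representative=rep.consensi[e.exon_id].sequence.replace("-", "")))

    retained, report = alignfilter.run_filter_cascade(
        gene_records, cfg.alignfilter, ds.contaminant_libraries)

    sm = scheme = None
    if retained:
        sm = phylo.concatenate([g.alignment for g in retained],
                               missing_char=cfg.phylo.missing_char)
        scheme = phylo.initial_partitions(sm)
    stage_counts = {
        "candidate_exons": len(ds.exons),
        "bait_pass": len(target_exons),
        "individuals": len(results),
        "cascade_in": len(gene_records),
        "cascade_retained": len(retained),
    }
    log.info("pipeline complete: %s", stage_counts)
    return PipelineResult(ds, probes, decisions, results, gene_records,
                          retained, report, sm, scheme, stage_counts)


# ---------------------------------------------------------------------------
# Truth-based evaluation

def violation_recovery(res: PipelineResult) -> dict:
    """Recall of planted violations and false removals of clean genes.

    A planted violation counts as recovered when the gene was flagged at
    the appropriate stage with a matching reason. A clean gene counts as
    a false removal when it fails bait design or is removed by the
    cascade.
    """
    truth = res.dataset.truth
    bait_reasons = {d.exon_id.rsplit("_e", 1)[0]: d.reasons
                    for d in res.bait_decisions}
    cascade = {row.gene_id: set(row.reasons.split(";")) if row.reasons else set()
               for row in res.filter_report.itertuples()}
    per_class = {}
    recovered = total = 0
    for gene, classes in truth.gene_violations.items():
        flags = bait_reasons.get(gene, set()) | cascade.get(gene, set())
        for klass in classes:
            total += 1
            hit = bool(DETECTION_MAP[klass] & flags)
            recovered += hit
            stats = per_class.setdefault(klass, [0, 0])
            stats[0] += hit
            stats[1] += 1
    clean = [g for g, c in truth.gene_violations.items() if not c]
    false_removals = [g for g in clean
                      if bait_reasons.get(g) or cascade.get(g)]
    return {
        "recall": recovered / total if total else 1.0,
        "n_planted": total,
        "n_recovered": recovered,
        "per_class": {k: tuple(v) for k, v in per_class.items()},
        "clean_false_removals": sorted(false_removals),
        "n_clean": len(clean),
    }


def consensus_accuracy(res: PipelineResult, min_depth: int = 20) -> dict:
    """Fraction of consensus positions at or above ``min_depth`` that
    match the planted truth, over clean genes."""
    truth = res.dataset.truth
    clean = {g for g, c in truth.gene_violations.items() if not c}
    match = total = 0
    for r in res.individual_results:
        for exon_id, cons in r.consensi.items():
            gene = exon_id.rsplit("_e", 1)[0]
            if gene not in clean or cons.depth is None:
                continue
            true_seq = truth.sequences[(gene, r.individual)]
            depth = np.asarray(cons.depth)
            for j in np.nonzero(depth >= min_depth)[0]:
                total += 1
                match += cons.sequence[j] == true_seq[j]
    return {"accuracy": match / total if total else 1.0,
            "n_positions": total, "n_match": match}


def family_bipartitions(ds: simdata.SimulatedDataset) -> set:
    """True bipartitions whose sides are unions of whole families — the
    family-level topology of the generating tree."""
    fams = {f: frozenset(t) for f, t in ds.families.items()}
    out = set()
    for b in phylo.bipartitions(ds.tree, ds.taxa):
        side = set(b)
        used = [f for f, members in fams.items() if members <= side]
        if used and side == set().union(*(fams[f] for f in used)):
            out.add(b)
    return out


def family_topology_support(res: PipelineResult, n_replicates: int = 200,
                            seed: int = 0) -> dict:
    """NJ tree + bootstrap on the retained supermatrix, scored against
    the generating family-level topology."""
    ds = res.dataset
    sm = res.supermatrix
    true_bips = family_bipartitions(ds)
    ref_tree = phylo.nj_builder(sm)
    nj_bips = phylo.bipartitions(ref_tree, sm.taxa)
    recovered = true_bips <= nj_bips
    st = phylo.bootstrap_support(sm, phylo.nj_builder,
                                 n_replicates=n_replicates, seed=seed,
                                 reference_tree=ref_tree)
    supports = [st.supports[b] for b in true_bips if b in st.supports]
    min_support = min(supports) if recovered and supports else 0.0
    return {"topology_recovered": recovered,
            "n_true_bipartitions": len(true_bips),
            "min_true_support": min_support}


def mp_family_topology(res: PipelineResult, seed: int = 0,
                       n_addition_replicates: int = 2) -> bool:
    """Parsimony check: does the MP tree on the full supermatrix contain
    every family-level bipartition of the generating tree? Dense taxon
    sampling matters here — parsimony on one representative per family
    is systematically misled by the long family stems."""
    ds = res.dataset
    sm = res.supermatrix
    true_fam = family_bipartitions(ds)
    trees, _ = phylo.mp_search(sm, n_addition_replicates=n_addition_replicates,
                               seed=seed)
    return any(true_fam <= phylo.bipartitions(t, sm.taxa) for t in trees)

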