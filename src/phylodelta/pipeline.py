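"""End-to-end experiments: completeness sweep, Low-Coverage vs Filtered
comparison, and the modern-sample ablation experiment.

All three are deterministic given their configuration and seed; writers emit
TSV tables and newick trees so identical runs produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import (ConcatenatedAlignment, PartitionMap, SampleMetadata,
                        EmptyResultError, completeness_trim,
                        convert_pis_to_missing, pis_mask,
                        sample_missing_report)
from .inference import bootstrap_support, estimate_tree
from .models import PartitionedModel, SubstitutionModel
from .outliers import (SITE_BINS, ComparisonPair, bin_sites, delta_site_table,
                       make_masked_alignments)
from .treecmp import mds_embed, rf_distance, tree_distance_matrix, \
    type_clustering_score
from .trees import PhyloTree

log = logging.getLogger("phylodelta")

__all__ = ["build_model", "SweepResult", "run_completeness_sweep",
           "AnalysisConfig", "ComparisonReport", "run_full_comparison",
           "run_manipulation_experiment", "ManipulationResult",
           "write_comparison_report"]


def build_model(spec: str = "jc") -> SubstitutionModel:
    """Small model-spec parser: 'jc', 'jc+g', 'hky', 'hky+g', 'gtr', 'gtr+g'."""
    spec = spec.lower().strip()
    gamma = spec.endswith("+g") or spec.endswith("+g4")
    base = spec.split("+")[0]
    family = {"jc": "JC69", "jc69": "JC69", "hky": "HKY85", "hky85": "HKY85",
              "gtr": "GTR"}.get(base)
    if family is None:
        raise ValueError(f"unknown model spec {spec!r}")
    return SubstitutionModel(family, gamma_shape=0.5 if gamma else None)


def _pmodel_for(aln: ConcatenatedAlignment, model: SubstitutionModel
                ) -> PartitionedModel:
    return PartitionedModel.single(model, aln.partitions.locus_ids)


def _hash_alignment(aln: ConcatenatedAlignment) -> str:
    h = hashlib.sha256()
    h.update("|".join(aln.taxa).encode())
    h.update(aln.matrix.tobytes())
    return h.hexdigest()[:16]


# ------------------------------------------------------- completeness sweep

@dataclass
class SweepResult:
    table: pd.DataFrame                     # one row per threshold
    trees: dict[int, Optional[PhyloTree]]


def run_completeness_sweep(aln: ConcatenatedAlignment,
                           model_spec: str = "jc",
                           reference_tree: Optional[PhyloTree] = None,
                           metadata: Optional[dict[str, SampleMetadata]] = None,
                           thresholds: Sequence[int] = tuple(range(0, 101, 10)),
                           **search_kwargs) -> SweepResult:
    """Trim the alignment at each completeness threshold and re-estimate.

    Locus partitions are not retained after trimming: each trimmed alignment
    is analysed as a single partition under one model.  Thresholds that
    empty the alignment are recorded as degenerate rows.
    """
    model = build_model(model_spec)
    rows = []
    trees: dict[int, Optional[PhyloTree]] = {}
    for thr in thresholds:
        row = {"threshold": thr, "length": 0, "pis": 0,
               "rf_to_reference": np.nan, "type_score": np.nan,
               "degenerate": False}
        try:
            trimmed = completeness_trim(aln, thr).alignment
        except EmptyResultError:
            row["degenerate"] = True
            trees[thr] = None
            rows.append(row)
            log.info("sweep threshold %d%%: alignment empty", thr)
            continue
        single = ConcatenatedAlignment(
            list(trimmed.taxa), trimmed.matrix,
            PartitionMap([("all", 0, trimmed.n_columns)]))
        row["length"] = single.n_columns
        row["pis"] = int(pis_mask(single).sum())
        tree, lnl = estimate_tree(single, _pmodel_for(single, model),
                                  **search_kwargs)
        trees[thr] = tree
        row["lnL"] = lnl
        if reference_tree is not None:
            row["rf_to_reference"] = rf_distance(tree, reference_tree)
        if metadata is not None:
            row["type_score"] = type_clustering_score(tree, metadata)
        log.info("sweep threshold %d%%: %d bp, %d PIS", thr, row["length"],
                 row["pis"])
        rows.append(row)
    return SweepResult(pd.DataFrame(rows), trees)


# --------------------------------------------------------- full comparison

@dataclass
class AnalysisConfig:
    model_spec: str = "jc"
    bootstrap_B: int = 0                    # 0 disables bootstrapping
    site_bins: Sequence[str] = SITE_BINS
    mask_bins: Sequence[str] = (">2",)      # bins whose masked trees are
                                            # re-estimated
    seed: int = 0
    search_kwargs: dict = field(default_factory=dict)


@dataclass
class ComparisonReport:
    t1: PhyloTree                           # Low Coverage tree
    t2: PhyloTree                           # Filtered tree
    site_table: "object"
    bin_members: dict[str, np.ndarray]
    bin_summary: pd.DataFrame
    masked_trees: dict[str, PhyloTree]
    rf_t1_t2: int
    rf_masked_t2: dict[str, int]
    type_scores: dict[str, float]
    missing_report_outliers: Optional[object]
    mds: Optional[pd.DataFrame]
    summary: pd.DataFrame = None


def run_full_comparison(bundle, config: AnalysisConfig = AnalysisConfig()
                        ) -> ComparisonReport:
    """The Low-Coverage versus Filtered experiment on one study bundle.

    Estimates both trees, computes the Δ s-lk table on the Low Coverage
    alignment with its locus partition, bins and masks outlier sites,
    re-estimates trees from the masked alignments, and summarises
    missing-data asymmetry at the positive-outlier sites.
    """
    model = build_model(config.model_spec)
    low, filt = bundle.low_coverage, bundle.filtered
    common = [t for t in low.taxa if t in filt.taxa]
    if len(common) < len(low.taxa) or len(common) < len(filt.taxa):
        low = low.subset_taxa(common)
        filt = filt.subset_taxa(common)
    log.info("comparison: %d taxa, low=%s filt=%s", len(common),
             _hash_alignment(low), _hash_alignment(filt))

    t1, _ = estimate_tree(low, _pmodel_for(low, model),
                          **config.search_kwargs)
    t2, _ = estimate_tree(filt, _pmodel_for(filt, model),
                          **config.search_kwargs)
    pair = ComparisonPair(t1, t2, low, _pmodel_for(low, model))
    site_table = delta_site_table(pair)
    members, summary = bin_sites(site_table, config.site_bins,
                                 metadata=bundle.metadata, aln=low)
    to_mask = {k: v for k, v in members.items()
               if k in config.mask_bins and v.size}
    masked = make_masked_alignments(low, to_mask)
    masked_trees = {}
    rf_masked = {}
    for label, (m_aln, _manifest) in masked.items():
        mt, _ = estimate_tree(m_aln, _pmodel_for(m_aln, model),
                              **config.search_kwargs)
        masked_trees[label] = mt
        rf_masked[label] = rf_distance(mt, t2)

    type_scores = {}
    if bundle.metadata:
        type_scores["low_coverage"] = type_clustering_score(t1, bundle.metadata)
        type_scores["filtered"] = type_clustering_score(t2, bundle.metadata)
        for label, mt in masked_trees.items():
            type_scores[f"masked_{label}"] = type_clustering_score(
                mt, bundle.metadata)

    missing_out = None
    pos = members.get(">2", np.array([], dtype=int))
    if bundle.metadata and pos.size:
        missing_out = sample_missing_report(low, bundle.metadata,
                                            column_subset=pos)

    mds_df = None
    if config.bootstrap_B > 0:
        _, bs1 = bootstrap_support(low, _pmodel_for(low, model), t1,
                                   B=config.bootstrap_B, seed=config.seed,
                                   **config.search_kwargs)
        _, bs2 = bootstrap_support(filt, _pmodel_for(filt, model), t2,
                                   B=config.bootstrap_B,
                                   seed=config.seed + 1,
                                   **config.search_kwargs)
        trees = bs1.replicates + bs2.replicates
        labels = ([f"low_{i}" for i in range(len(bs1.replicates))] +
                  [f"filtered_{i}" for i in range(len(bs2.replicates))])
        dm = tree_distance_matrix(trees, labels)
        emb = mds_embed(dm.matrix)
        mds_df = pd.DataFrame({
            "tree_id": labels,
            "source": ["low_coverage"] * len(bs1.replicates) +
                      ["filtered"] * len(bs2.replicates),
            "x": emb.coords[:, 0], "y": emb.coords[:, 1]})

    return ComparisonReport(
        t1=t1, t2=t2, site_table=site_table, bin_members=members,
        bin_summary=summary, masked_trees=masked_trees,
        rf_t1_t2=rf_distance(t1, t2), rf_masked_t2=rf_masked,
        type_scores=type_scores, missing_report_outliers=missing_out,
        mds=mds_df)


def write_comparison_report(report: ComparisonReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "low_coverage.nwk").write_text(report.t1.to_newick() + "\n")
    (out / "filtered.nwk").write_text(report.t2.to_newick() + "\n")
    report.site_table.table.to_csv(out / "site_deltas.tsv", sep="\t",
                                   index=False, float_format="%.6f")
    report.bin_summary.to_csv(out / "bin_summary.tsv", sep="\t", index=False,
                              float_format="%.6f")
    for label, tree in report.masked_trees.items():
        safe = label.replace(">", "gt").replace("<", "lt").replace("-", "m")
        (out / f"masked_{safe}.nwk").write_text(tree.to_newick() + "\n")
    rows = [{"metric": "rf_t1_t2", "value": report.rf_t1_t2}]
    rows += [{"metric": f"rf_masked_{k}_t2", "value": v}
             for k, v in report.rf_masked_t2.items()]
    rows += [{"metric": f"type_score_{k}", "value": v}
             for k, v in report.type_scores.items()]
    pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    if report.mds is not None:
        report.mds.to_csv(out / "mds.tsv", sep="\t", index=False,
                          float_format="%.6f")


# -------------------------------------------------- manipulation experiment

@dataclass
class ManipulationResult:
    baseline_tree: PhyloTree
    replicate_trees: list[PhyloTree]
    table: pd.DataFrame                     # one row per replicate x target


def _nearest_neighbor_type(tree: PhyloTree, tip_name: str,
                           metadata: dict[str, SampleMetadata]) -> str:
    """Majority sample type among the topologically nearest other tips."""
    tip = next(n for n in tree.postorder() if n.is_tip and n.name == tip_name)
    seen = {id(tip)}
    queue = deque([(tip, 0)])
    best_depth, found = None, []
    while queue:
        node, d = queue.popleft()
        if best_depth is not None and d > best_depth:
            break
        if node.is_tip and node.name != tip_name:
            best_depth = d
            found.append(node.name)
            continue
        for nb in list(node.children) + ([node.parent] if node.parent else []):
            if nb is not None and id(nb) not in seen:
                seen.add(id(nb))
                queue.append((nb, d + 1))
    types = [metadata[n].sample_type for n in found]
    return max(sorted(set(types)), key=types.count) if types else "none"


def run_manipulation_experiment(aln: ConcatenatedAlignment,
                                metadata: dict[str, SampleMetadata],
                                target_samples: Sequence[str],
                                model_spec: str = "jc",
                                fraction: float = 0.999,
                                replicates: int = 10, seed: int = 0,
                                **search_kwargs) -> ManipulationResult:
    """Convert a fraction of the targets' parsimony-informative sites to
    missing data, independently per replicate, and re-estimate the tree.

    Reports, per replicate and target, the RF displacement from the baseline
    tree and whether the target's nearest-neighbour sample type flipped
    (the diagnostic for whether a starved modern sample drifts into
    historical neighbourhoods).
    """
    model = build_model(model_spec)
    for t in target_samples:
        if metadata.get(t) and metadata[t].sample_type != "modern":
            log.warning("target %s is not a modern sample", t)
    baseline, _ = estimate_tree(aln, _pmodel_for(aln, model), **search_kwargs)
    base_nn = {t: _nearest_neighbor_type(baseline, t, metadata)
               for t in target_samples}
    rows = []
    rep_trees = []
    for r in range(replicates):
        ablated = convert_pis_to_missing(aln, list(target_samples), fraction,
                                         seed=seed + r)
        tree, _ = estimate_tree(ablated, _pmodel_for(ablated, model),
                                **search_kwargs)
        rep_trees.append(tree)
        rf = rf_distance(baseline, tree)
        for t in target_samples:
            nn = _nearest_neighbor_type(tree, t, metadata)
            rows.append({"replicate": r, "target": t, "rf_to_baseline": rf,
                         "baseline_nn_type": base_nn[t],
                         "replicate_nn_type": nn,
                         "nn_type_changed": nn != base_nn[t]})
    return ManipulationResult(baseline, rep_trees, pd.DataFrame(rows))
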