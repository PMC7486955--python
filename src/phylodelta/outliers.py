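"""Two-topology site-wise and locus-wise log-likelihood outlier analysis.

Given two candidate topologies T1 (estimated with missing/low-coverage
characters included) and T2 (estimated after stringent filtering), branch
lengths are re-optimised independently for each topology on a common
evaluation alignment and the per-site difference

    Δ s-lk = lnL(site | T1) − lnL(site | T2)

is tabulated.  Sites (and per-locus sums, Δ l-lk) are binned at fixed
thresholds; the bins drive masked-alignment and locus-exclusion re-analyses
that test whether missing-data asymmetry, not signal, placed the differing
clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import (ConcatenatedAlignment, PartitionMap, SampleMetadata,
                        completeness_trim, mask_columns)
from .likelihood import optimize_branch_lengths, site_log_likelihoods
from .models import PartitionedModel
from .trees import PhyloTree, TreeError, root_with_outgroup

__all__ = [
    "SITE_BINS", "LOCUS_BINS", "ComparisonPair", "SiteDeltaTable",
    "LocusDeltaTable", "delta_site_table", "bin_sites", "bin_loci",
    "make_masked_alignments", "delta_locus_table", "make_excluded_alignments",
    "subclade_workflow", "SubcladeResult",
]

SITE_BINS = (">20", ">10", ">2", "<-2", "<-10", "<-20")
LOCUS_BINS = (">2", ">10", ">20", "<-2", "<-10")


def _bin_members(values: np.ndarray, label: str) -> np.ndarray:
    thr = float(label.replace(">", "").replace("<", ""))
    if label.startswith(">"):
        return np.nonzero(values > thr)[0]
    return np.nonzero(values < thr)[0]


@dataclass
class ComparisonPair:
    """T1/T2 topologies plus the alignment and model they are scored on."""
    t1: PhyloTree
    t2: PhyloTree
    aln: ConcatenatedAlignment
    pmodel: PartitionedModel

    def __post_init__(self):
        tips1, tips2 = set(self.t1.tip_names()), set(self.t2.tip_names())
        if tips1 != tips2:
            raise TreeError("T1 and T2 have different tip sets")
        if not tips1 <= set(self.aln.taxa):
            raise TreeError("topology tips missing from the evaluation alignment")


@dataclass
class SiteDeltaTable:
    table: pd.DataFrame                     # site, locus_id, lnl_t1, lnl_t2, delta
    total_t1: float
    total_t2: float
    t1_optimized: PhyloTree
    t2_optimized: PhyloTree

    @property
    def deltas(self) -> np.ndarray:
        return self.table["delta"].to_numpy()

    @property
    def total_delta(self) -> float:
        return self.total_t1 - self.total_t2


@dataclass
class LocusDeltaTable:
    table: pd.DataFrame                     # locus_id, delta, length

    @property
    def deltas(self) -> np.ndarray:
        return self.table["delta"].to_numpy()


def delta_site_table(pair: ComparisonPair, opt_tol: float = 1e-3,
                     max_opt_rounds: int = 10) -> SiteDeltaTable:
    """Per-site Δ log-likelihood between the pair's two topologies.

    Branch lengths (not topologies) are re-optimised independently for T1
    and T2 on the evaluation alignment before per-site scoring, mirroring
    fixed-topology evaluation in standard ML software.
    """
    aln = pair.aln
    t1, _ = optimize_branch_lengths(pair.t1, pair.pmodel, aln,
                                    tol=opt_tol, max_rounds=max_opt_rounds)
    t2, _ = optimize_branch_lengths(pair.t2, pair.pmodel, aln,
                                    tol=opt_tol, max_rounds=max_opt_rounds)
    s1, tot1 = site_log_likelihoods(t1, pair.pmodel, aln)
    s2, tot2 = site_log_likelihoods(t2, pair.pmodel, aln)
    locus_idx = aln.partitions.locus_of_site()
    locus_ids = np.array(aln.partitions.locus_ids)[locus_idx]
    df = pd.DataFrame({
        "site": np.arange(aln.partitions.total_length),
        "locus_id": locus_ids,
        "lnl_t1": s1,
        "lnl_t2": s2,
        "delta": s1 - s2,
    })
    return SiteDeltaTable(df, tot1, tot2, t1, t2)


def bin_sites(site_table: SiteDeltaTable, bins: Sequence[str] = SITE_BINS,
              metadata: Optional[dict[str, SampleMetadata]] = None,
              aln: Optional[ConcatenatedAlignment] = None
              ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Strict-threshold site bins, with an optional per-bin missing-data
    summary by sample type at the member sites."""
    deltas = site_table.deltas
    members = {label: _bin_members(deltas, label) for label in bins}
    rows = []
    for label, idx in members.items():
        row = {"bin": label, "n_sites": int(idx.size)}
        if metadata is not None and aln is not None and idx.size:
            codes = aln.codes()[:, idx]
            miss = (codes == 4).sum(axis=1)
            per_type: dict[str, list[int]] = {}
            for i, taxon in enumerate(aln.taxa):
                per_type.setdefault(metadata[taxon].sample_type, []).append(
                    int(miss[i]))
            for stype, vals in per_type.items():
                row[f"mean_missing_{stype}"] = float(np.mean(vals))
            h = row.get("mean_missing_historical")
            m = row.get("mean_missing_modern")
            if h is None or m is None:
                row["historical_modern_ratio"] = np.nan
            elif m == 0:
                row["historical_modern_ratio"] = np.inf if h > 0 else np.nan
            else:
                row["historical_modern_ratio"] = float(h / m)
        rows.append(row)
    return members, pd.DataFrame(rows)


def make_masked_alignments(aln: ConcatenatedAlignment,
                           site_bins: dict[str, np.ndarray]
                           ) -> dict[str, tuple[ConcatenatedAlignment, dict]]:
    """One alignment per bin with the member sites masked to N everywhere,
    plus a provenance manifest."""
    out = {}
    for label, idx in site_bins.items():
        masked = mask_columns(aln, idx)
        out[label] = (masked, {"bin": label, "n_sites_masked": int(len(idx))})
    return out


def delta_locus_table(site_table: SiteDeltaTable, partitions: PartitionMap
                      ) -> LocusDeltaTable:
    """Per-locus Δ l-lk = sum of member-site Δ s-lk; the locus sums are
    checked against the site total (conservation)."""
    df = site_table.table
    unknown = set(df["locus_id"]) - set(partitions.locus_ids)
    if unknown:
        raise ValueError(f"sites assigned to unknown loci: {sorted(unknown)}")
    sums = df.groupby("locus_id", sort=False)["delta"].sum()
    lengths = partitions.lengths()
    rows = [{"locus_id": lid, "delta": float(sums.get(lid, 0.0)),
             "length": lengths[lid]} for lid in partitions.locus_ids]
    table = pd.DataFrame(rows)
    if not np.isclose(table["delta"].sum(), df["delta"].sum(), atol=1e-6):
        raise AssertionError("locus deltas do not sum to the site total")
    return LocusDeltaTable(table)


def bin_loci(locus_table: LocusDeltaTable, bins: Sequence[str] = LOCUS_BINS
             ) -> dict[str, list[str]]:
    deltas = locus_table.deltas
    ids = locus_table.table["locus_id"].to_numpy()
    return {label: [str(x) for x in ids[_bin_members(deltas, label)]]
            for label in bins}


def make_excluded_alignments(aln: ConcatenatedAlignment,
                             locus_bins: dict[str, list[str]]
                             ) -> dict[str, ConcatenatedAlignment]:
    """One alignment per bin with the member loci removed and the partition
    map rebuilt."""
    out = {}
    for label, loci in locus_bins.items():
        unknown = set(loci) - set(aln.partitions.locus_ids)
        if unknown:
            raise ValueError(f"unknown loci in bin {label}: {sorted(unknown)}")
        drop = set(loci)
        keep_cols = []
        entries = []
        pos = 0
        for lid, start, end in aln.partitions.entries:
            if lid in drop:
                continue
            keep_cols.append(np.arange(start, end))
            entries.append((lid, pos, pos + end - start))
            pos += end - start
        if not entries:
            raise ValueError(f"bin {label} removes every locus")
        cols = np.concatenate(keep_cols)
        out[label] = ConcatenatedAlignment(list(aln.taxa),
                                           aln.matrix[:, cols],
                                           PartitionMap(entries))
    return out


@dataclass
class SubcladeResult:
    t1: PhyloTree                           # with-missing tree, rooted
    t2: PhyloTree                           # no-missing tree, rooted
    locus_table: LocusDeltaTable
    locus_bins: dict[str, list[str]]
    excluded_trees: dict[str, PhyloTree]
    site_table: SiteDeltaTable


def subclade_workflow(aln: ConcatenatedAlignment, clade_taxa: Sequence[str],
                      outgroup_taxon: str, pmodel_factory,
                      bins: Sequence[str] = LOCUS_BINS,
                      reestimate_bins: Optional[Sequence[str]] = None,
                      **search_kwargs) -> SubcladeResult:
    """With-/without-missing-data comparison for one subclade.

    T1 is estimated from the subclade's full alignment, T2 from its
    100%-completeness trim (columns with any missing character removed);
    both are rooted on the outgroup.  Δ l-lk is computed on the with-missing
    alignment and loci are binned and excluded per bin, re-estimating trees
    for the requested bins.

    ``pmodel_factory(aln) -> PartitionedModel`` supplies the model for each
    (sub)alignment analysed.
    """
    from .alignment import EmptyResultError
    from .inference import estimate_tree

    taxa = list(clade_taxa) + [outgroup_taxon]
    if len(taxa) < 4:
        raise TreeError("subclade workflow needs at least 4 taxa")
    sub = aln.subset_taxa(taxa)
    try:
        trimmed = completeness_trim(sub, 100.0).alignment
    except EmptyResultError as err:
        raise EmptyResultError(
            f"clade {sorted(clade_taxa)[:3]}...: every column has at least "
            f"one missing character; the no-missing comparison is undefined"
        ) from err
    t1_un, _ = estimate_tree(sub, pmodel_factory(sub), **search_kwargs)
    t2_un, _ = estimate_tree(trimmed, pmodel_factory(trimmed), **search_kwargs)
    pair = ComparisonPair(t1_un, t2_un, sub, pmodel_factory(sub))
    site_table = delta_site_table(pair)
    locus_table = delta_locus_table(site_table, sub.partitions)
    locus_bins = bin_loci(locus_table, bins)
    targets = list(reestimate_bins) if reestimate_bins is not None else list(bins)
    excluded = make_excluded_alignments(
        sub, {k: v for k, v in locus_bins.items() if k in targets and v})
    excluded_trees = {}
    for label, ex_aln in excluded.items():
        tree, _ = estimate_tree(ex_aln, pmodel_factory(ex_aln), **search_kwargs)
        excluded_trees[label] = root_with_outgroup(tree, outgroup_taxon)
    return SubcladeResult(
        t1=root_with_outgroup(t1_un, outgroup_taxon),
        t2=root_with_outgroup(t2_un, outgroup_taxon),
        locus_table=locus_table,
        locus_bins=locus_bins,
        excluded_trees=excluded_trees,
        site_table=site_table,
    )
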