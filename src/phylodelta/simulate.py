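"""Synthetic UCE-like studies with museum-specimen degradation.

The generator emulates the statistical structure of sequence-capture data
mixing fresh-tissue ("modern") and degraded skin ("historical") samples:

* UCE-like loci (truncated-normal lengths, mean ≈ 500 bp) whose substitution
  rate is lowest at the conserved core and rises toward the flanks, so
  variable and parsimony-informative sites concentrate in the flanks;
* a true tree that is either a Yule tree or a "radiation": one designated
  clade with near-zero internal branches, the regime in which missing-data
  bias is strongest;
* a per-site Poisson read-depth observation model: historical samples get a
  lower depth and lose their locus flanks entirely (short fragments), and
  two datasets are emitted per study — "Low Coverage" (any covered base is
  kept) and "Filtered" (bases below a depth threshold are masked to N).

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .alignment import (ConcatenatedAlignment, FilterConfig, LocusAlignment,
                        SampleMetadata, SequenceRecord, concatenate,
                        drop_high_missing_sequences, write_concatenated,
                        write_metadata)
from .models import EigenSystem, SubstitutionModel
from .trees import Node, PhyloTree

__all__ = ["ObservationConfig", "StudyConfig", "StudyBundle",
           "simulate_tree", "simulate_alignment", "apply_observation_model",
           "generate_paired_study", "write_bundle", "default_model"]


class SimulationError(ValueError):
    pass


@dataclass
class ObservationConfig:
    """Read-depth observation model.

    Depth is Poisson per sample x site (independent across sites); historical
    samples keep only the central ``flank_retention_historical`` fraction of
    each locus (flanks -> N) before depth is applied.  Sites with zero depth
    are missing in both regimes; sites with 0 < depth < ``depth_threshold``
    are kept in the Low Coverage dataset (miscalled with probability
    ``miscall_prob_low_depth``) and masked in the Filtered dataset.
    """
    depth_lambda_modern: float = 30.0
    depth_lambda_historical: float = 3.0
    flank_retention_historical: float = 0.4
    depth_threshold: int = 6
    miscall_prob_low_depth: float = 0.0
    seed: int = 0

    def __post_init__(self):
        problems = []
        if self.depth_lambda_modern <= 0 or self.depth_lambda_historical <= 0:
            problems.append("depth lambdas must be positive")
        if not (0.0 < self.flank_retention_historical <= 1.0):
            problems.append("flank_retention_historical must be in (0, 1]")
        if not (0.0 <= self.miscall_prob_low_depth <= 1.0):
            problems.append("miscall_prob_low_depth must be in [0, 1]")
        if self.depth_threshold < 1:
            problems.append("depth_threshold must be >= 1")
        if problems:
            raise SimulationError("; ".join(problems))


def default_model() -> SubstitutionModel:
    """Default simulation model: HKY85 with a mild transition bias and
    bird-nuclear-like AT-rich frequencies."""
    return SubstitutionModel("HKY85", freqs=np.array([0.3, 0.2, 0.2, 0.3]),
                             kappa=3.0)


@dataclass
class StudyConfig:
    """Full configuration for one paired Low-Coverage/Filtered study."""
    n_taxa: int = 18
    tree_mode: str = "radiation"            # "yule" | "radiation"
    clade_size: int = 16
    historical_fraction_of_clade: float = 0.5
    n_loci: int = 30
    model: SubstitutionModel = field(default_factory=default_model)
    observation: ObservationConfig = field(default_factory=ObservationConfig)
    filters: FilterConfig = field(
        default_factory=lambda: FilterConfig(max_individual_missing=0.95,
                                             min_occupancy=0.5))
    core_profile: bool = True
    seed: int = 0


@dataclass
class StudyBundle:
    true_tree: PhyloTree
    truth_loci: list[LocusAlignment]
    low_coverage: ConcatenatedAlignment
    filtered: ConcatenatedAlignment
    metadata: dict[str, SampleMetadata]
    depth_summary: pd.DataFrame
    config: StudyConfig


# ------------------------------------------------------------------- trees

def _random_topology(names: Sequence[str], rng: np.random.Generator) -> Node:
    """Random binary topology by sequential joins; lengths left at 0."""
    nodes = [Node(n) for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = Node()
    for x in nodes:
        root.add(x)
    return root


def simulate_tree(n_taxa: int, mode: str = "yule", params: Optional[dict] = None,
                  seed: int = 0) -> PhyloTree:
    """Simulate a binary true tree.

    ``yule``: pure-birth tree (birth rate ``params['birth_rate']``, default
    2.0, in units of substitutions^-1 so typical branches land around
    0.02-0.2 substitutions/site); tips named t01, t02, ...  Pure birth
    occasionally yields near-zero internodes on which no finite alignment
    carries topological signal; ``params['min_internal']`` (default 0)
    floors internal branch lengths to keep every internode resolvable when
    a clean-signal study is wanted.

    ``radiation``: one clade of ``params['clade_size']`` tips (named r01...)
    whose internal branches are at most ``params['eps_internal']`` (default
    0.002) with pendant branches ~ U(0.01, 0.05) — a rapid radiation in which
    topological signal is scarce; remaining tips (b01..., plus outgroup
    'out') hang off a backbone with moderate branch lengths.
    """
    if n_taxa < 4:
        raise SimulationError("need at least 4 taxa")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if mode == "yule":
        rate = float(params.get("birth_rate", 2.0))
        min_internal = float(params.get("min_internal", 0.0))
        tips = [Node(f"t{i + 1:02d}") for i in range(n_taxa)]
        heights = {id(t): 0.0 for t in tips}
        active = list(tips)
        t = 0.0
        while len(active) > 1:
            k = len(active)
            t += rng.exponential(1.0 / (rate * k))
            i, j = sorted(rng.choice(k, size=2, replace=False))
            parent = Node()
            for child in (active[i], active[j]):
                child.length = t - heights[id(child)]
                parent.add(child)
            heights[id(parent)] = t
            active = [x for m, x in enumerate(active) if m not in (i, j)]
            active.append(parent)
        root = active[0]
        if min_internal > 0:
            for node in PhyloTree(root, rooted=True).postorder():
                if node is not root and not node.is_tip:
                    node.length = max(node.length, min_internal)
        return PhyloTree(root, rooted=True).unroot()
    if mode == "radiation":
        clade_size = int(params.get("clade_size", max(4, n_taxa - 2)))
        eps = float(params.get("eps_internal", 0.002))
        if clade_size > n_taxa - 1:
            raise SimulationError("clade_size must leave room for an outgroup")
        clade_root = _random_topology([f"r{i + 1:02d}" for i in range(clade_size)],
                                      rng)
        for node in PhyloTree(clade_root, rooted=True).postorder():
            if node is clade_root:
                continue
            node.length = (rng.uniform(0.01, 0.05) if node.is_tip
                           else rng.uniform(0.2 * eps, eps))
        n_back = n_taxa - clade_size - 1
        root = Node()
        root.add(Node("out", rng.uniform(0.08, 0.12)))
        cur = root
        for i in range(n_back):
            nxt = Node()
            nxt.length = rng.uniform(0.02, 0.05)
            cur.add(nxt)
            nxt.add(Node(f"b{i + 1:02d}", rng.uniform(0.02, 0.08)))
            cur = nxt
        clade_root.length = rng.uniform(0.02, 0.05)
        cur.add(clade_root)
        return PhyloTree(root, rooted=True).unroot()
    raise SimulationError(f"unknown tree mode {mode!r}")


# -------------------------------------------------------------- alignments

def _core_rate_profile(length: int, r_min: float = 0.05, power: float = 2.0
                       ) -> np.ndarray:
    """Relative site rates along a locus: minimal at the conserved centre,
    rising toward the flanks; normalised to mean one."""
    u = (np.arange(length) + 0.5) / length
    prof = r_min + (1.0 - r_min) * np.abs(2.0 * u - 1.0) ** power
    return prof / prof.mean()


def default_length_sampler(rng: np.random.Generator) -> int:
    """Truncated-normal locus length: mean 500, sd 150, bounds [140, 1708]."""
    a, b = (140 - 500) / 150, (1708 - 500) / 150
    return int(round(truncnorm.rvs(a, b, loc=500, scale=150,
                                   random_state=rng)))


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel,
                       n_loci: int,
                       length_sampler: Optional[Callable] = None,
                       seed: int = 0, core_profile: bool = True
                       ) -> list[LocusAlignment]:
    """Evolve ``n_loci`` clean loci (no missing data) down the tree.

    Per-site rates combine the optional conserved-core profile with
    discrete-Γ rates when the model carries a shape parameter.
    """
    rng = np.random.default_rng(seed)
    sampler = length_sampler or default_length_sampler
    eig = EigenSystem.from_model(model)
    freqs = model.freqs
    gamma_cats = model.category_rates()
    loci = []
    for li in range(n_loci):
        L = int(sampler(rng))
        rates = np.ones(L)
        if core_profile:
            rates = rates * _core_rate_profile(L)
        if gamma_cats.size > 1:
            rates = rates * rng.choice(gamma_cats, size=L)
        states: dict[int, np.ndarray] = {}
        root = tree.root
        states[id(root)] = rng.choice(4, size=L, p=freqs)
        for node in tree.preorder():
            if node is root:
                continue
            parent_states = states[id(node.parent)]
            E = np.exp(np.multiply.outer(node.length * rates, eig.eigvals))
            M = eig.left[parent_states, :] * E          # (L, 4)
            probs = np.clip(M @ eig.right, 0.0, None)   # (L, 4)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(L)
            drawn = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            states[id(node)] = np.minimum(drawn, 3)
        alpha = "ACGT"
        records = [SequenceRecord(tip.name,
                                  "".join(alpha[s] for s in states[id(tip)]))
                   for tip in tree.tips()]
        loci.append(LocusAlignment(f"uce{li + 1:04d}", records))
    return loci


# -------------------------------------------------------- observation model

def apply_observation_model(true_loci: Sequence[LocusAlignment],
                            metadata: dict[str, SampleMetadata],
                            config: ObservationConfig
                            ) -> tuple[list[LocusAlignment],
                                       list[LocusAlignment], pd.DataFrame]:
    """Degrade clean loci into paired Low-Coverage and Filtered versions.

    Returns ``(low_coverage, filtered, depth_summary)`` where the summary
    has one row per (locus, sample) with site counts by depth class.
    """
    rng = np.random.default_rng(config.seed)
    low_out, filt_out, rows = [], [], []
    thr = config.depth_threshold
    for locus in true_loci:
        L = locus.length
        keep = int(round(config.flank_retention_historical * L))
        flank_lo = (L - keep) // 2
        flank_hi = flank_lo + keep
        low_recs, filt_recs = [], []
        for rec in locus.records:
            md = metadata[rec.taxon]
            lam = (config.depth_lambda_historical
                   if md.sample_type == "historical"
                   else config.depth_lambda_modern)
            depth = rng.poisson(lam, size=L)
            chars = np.frombuffer(rec.chars.encode(), dtype="S1").copy()
            truncated = np.zeros(L, dtype=bool)
            if md.sample_type == "historical":
                truncated[:flank_lo] = True
                truncated[flank_hi:] = True
            low = chars.copy()
            low_depth = (depth > 0) & (depth < thr)
            if config.miscall_prob_low_depth > 0:
                flip = low_depth & (rng.random(L) < config.miscall_prob_low_depth)
                if flip.any():
                    codes = np.frombuffer(b"ACGT", dtype="S1")
                    cur = low[flip]
                    shift = rng.integers(1, 4, size=int(flip.sum()))
                    idx = np.array([b"ACGT".index(c) for c in cur])
                    low[flip] = codes[(idx + shift) % 4]
            low[(depth == 0) | truncated] = b"N"
            filt = low.copy()
            filt[depth < thr] = b"N"
            low_recs.append(SequenceRecord(rec.taxon, low.tobytes().decode()))
            filt_recs.append(SequenceRecord(rec.taxon, filt.tobytes().decode()))
            obs = ~truncated
            rows.append({
                "locus_id": locus.locus_id, "sample_id": rec.taxon,
                "sample_type": md.sample_type, "n_sites": L,
                "n_truncated": int(truncated.sum()),
                "n_depth0": int(((depth == 0) & obs).sum()),
                "n_below_threshold": int(((depth < thr) & obs).sum()),
            })
        low_out.append(LocusAlignment(locus.locus_id, low_recs))
        filt_out.append(LocusAlignment(locus.locus_id, filt_recs))
    return low_out, filt_out, pd.DataFrame(rows)


# ------------------------------------------------------------ paired study

def generate_paired_study(config: StudyConfig) -> StudyBundle:
    """Simulate one full paired study: true tree, clean loci, degraded
    Low-Coverage/Filtered datasets, filtering, and concatenation.

    Historical samples are drawn from the radiation clade (or from all taxa
    in yule mode); the per-individual missing-fraction rule and the locus
    occupancy rule are applied to both datasets independently, mirroring the
    order of a real sequence-capture pipeline.
    """
    rng = np.random.default_rng(config.seed)
    if config.tree_mode == "radiation":
        tree = simulate_tree(config.n_taxa, "radiation",
                             {"clade_size": config.clade_size},
                             seed=config.seed)
        pool = [n for n in tree.tip_names() if n.startswith("r")]
    else:
        tree = simulate_tree(config.n_taxa, "yule", seed=config.seed)
        pool = [n for n in tree.tip_names() if n != "out"]
    n_hist = int(round(config.historical_fraction_of_clade * len(pool)))
    historical = set(rng.choice(sorted(pool), size=n_hist, replace=False))
    metadata = {}
    for name in tree.tip_names():
        if name in historical:
            metadata[name] = SampleMetadata(
                name, "historical", int(rng.integers(1880, 1966)))
        else:
            metadata[name] = SampleMetadata(
                name, "modern", int(rng.integers(1995, 2021)))

    truth = simulate_alignment(tree, config.model, config.n_loci,
                               seed=config.seed + 1,
                               core_profile=config.core_profile)
    obs = ObservationConfig(**{**asdict(config.observation),
                               "seed": config.seed + 2})
    low_loci, filt_loci, depth_summary = apply_observation_model(
        truth, metadata, obs)

    taxa = sorted(tree.tip_names())
    low_kept, _ = drop_high_missing_sequences(low_loci, config.filters)
    filt_kept, _ = drop_high_missing_sequences(filt_loci, config.filters)
    low_concat = concatenate(low_kept, taxa, config.filters)
    filt_concat = concatenate(filt_kept, taxa, config.filters)
    return StudyBundle(tree, truth, low_concat, filt_concat, metadata,
                       depth_summary, config)


def write_bundle(bundle: StudyBundle, out_dir) -> None:
    """Write a bundle as plain-text study files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth.nwk").write_text(bundle.true_tree.to_newick() + "\n")
    write_concatenated(bundle.low_coverage, out / "low_coverage.fasta",
                       out / "low_coverage.partitions")
    write_concatenated(bundle.filtered, out / "filtered.fasta",
                       out / "filtered.partitions")
    write_metadata(bundle.metadata, out / "metadata.tsv")
    bundle.depth_summary.to_csv(out / "depths.tsv", sep="\t", index=False)
    cfg = bundle.config
    lines = [
        f"seed={cfg.seed}", f"n_taxa={cfg.n_taxa}",
        f"tree_mode={cfg.tree_mode}", f"clade_size={cfg.clade_size}",
        f"historical_fraction_of_clade={cfg.historical_fraction_of_clade}",
        f"n_loci={cfg.n_loci}", f"core_profile={cfg.core_profile}",
        f"model_family={cfg.model.family}", f"model_kappa={cfg.model.kappa}",
        f"depth_lambda_modern={cfg.observation.depth_lambda_modern}",
        f"depth_lambda_historical={cfg.observation.depth_lambda_historical}",
        f"flank_retention_historical={cfg.observation.flank_retention_historical}",
        f"depth_threshold={cfg.observation.depth_threshold}",
        f"miscall_prob_low_depth={cfg.observation.miscall_prob_low_depth}",
        f"max_individual_missing={cfg.filters.max_individual_missing}",
        f"min_occupancy={cfg.filters.min_occupancy}",
    ]
    (out / "config.txt").write_text("\n".join(lines) + "\n")
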