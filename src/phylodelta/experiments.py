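"""Canned replication experiments at desk scale.

Each function simulates its own study conditions, runs the relevant part of
the pipeline, and returns a summary dictionary plus per-replicate detail.
They are what `scripts/acceptance.py` and the acceptance test suite execute;
the problem sizes are chosen so a full run completes on one CPU in minutes.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .alignment import FilterConfig, concatenate
from .inference import estimate_tree
from .models import PartitionedModel, SubstitutionModel
from .pipeline import (AnalysisConfig, build_model, run_completeness_sweep,
                       run_full_comparison, write_comparison_report)
from .predictive import mlp_replicates
from .simulate import (ObservationConfig, StudyConfig,
                       apply_observation_model, generate_paired_study,
                       simulate_alignment, simulate_tree)
from .treecmp import rf_distance

__all__ = ["topology_recovery_experiment", "bias_experiment",
           "sweep_experiment", "observation_model_check",
           "predictive_experiment", "determinism_check"]


def topology_recovery_experiment(n_replicates: int = 20, n_taxa: int = 12,
                                 n_loci: int = 50, locus_length: int = 400,
                                 model_spec: str = "jc+g", seed: int = 0
                                 ) -> dict:
    """Exact-topology recovery on clean-signal Yule studies.

    Moderate branch lengths (pure birth with internal branches floored at
    0.02 substitutions/site), no missing data; analysis under a single
    rate-heterogeneous model.
    """
    sim_model = SubstitutionModel("HKY85", kappa=3.0,
                                  freqs=[0.3, 0.2, 0.2, 0.3])
    model = build_model(model_spec)
    rfs = []
    for i in range(n_replicates):
        rep_seed = seed * 1000 + i
        tree = simulate_tree(n_taxa, "yule",
                             {"birth_rate": 2.0, "min_internal": 0.02},
                             seed=rep_seed)
        loci = simulate_alignment(tree, sim_model, n_loci,
                                  length_sampler=lambda r: locus_length,
                                  seed=rep_seed + 1)
        aln = concatenate(loci, sorted(tree.tip_names()),
                          FilterConfig(min_occupancy=0.0))
        pm = PartitionedModel.single(model, aln.partitions.locus_ids)
        est, _ = estimate_tree(aln, pm)
        rfs.append(rf_distance(est, tree))
    rfs = np.array(rfs)
    return {"recovery_rate": float((rfs == 0).mean()),
            "n": n_replicates, "rf_values": rfs.tolist()}


def bias_experiment(n_seeds: int = 20, seed: int = 0,
                    config: Optional[StudyConfig] = None) -> dict:
    """The paired Low-Coverage/Filtered comparison over many studies.

    Per seed: both trees, the Δ s-lk table, the >2 site bin, the
    masked-bin re-estimate, Fitch type-clustering scores, and the
    historical/modern missing ratio at the positive outlier sites.
    """
    rows = []
    for i in range(n_seeds):
        cfg = config or StudyConfig()
        cfg = StudyConfig(**{**cfg.__dict__, "seed": seed * 1000 + i})
        bundle = generate_paired_study(cfg)
        report = run_full_comparison(bundle,
                                     AnalysisConfig(seed=cfg.seed))
        mro = report.missing_report_outliers
        rows.append({
            "seed": cfg.seed,
            "type_score_low": report.type_scores["low_coverage"],
            "type_score_filtered": report.type_scores["filtered"],
            "rf_t1_t2": report.rf_t1_t2,
            "rf_masked_t2": report.rf_masked_t2.get(">2", np.nan),
            "n_sites_gt2": int(report.bin_members[">2"].size),
            "missing_ratio_gt2": (mro.historical_modern_ratio
                                  if mro is not None else np.nan),
        })
    df = pd.DataFrame(rows)
    ratio = df["missing_ratio_gt2"]
    masked_better = df["rf_masked_t2"] < df["rf_t1_t2"]
    return {
        "per_seed": df,
        "clustering_rate": float(
            (df["type_score_low"] < df["type_score_filtered"]).mean()),
        "masking_reduction_rate": float(masked_better.fillna(False).mean()),
        "missing_ratio_gt1_rate": float((ratio > 1).mean()),
        "n": n_seeds,
    }


def sweep_experiment(n_seeds: int = 10, seed: int = 0) -> dict:
    """Completeness sweeps on biased bundles: monotonicity of length/PIS
    and whether some intermediate threshold does at least as well (RF to
    the true tree) as keeping everything."""
    rows = []
    for i in range(n_seeds):
        cfg = StudyConfig(seed=seed * 1000 + i)
        bundle = generate_paired_study(cfg)
        res = run_completeness_sweep(bundle.low_coverage, "jc",
                                     reference_tree=bundle.true_tree,
                                     metadata=bundle.metadata)
        tab = res.table[~res.table["degenerate"]]
        lengths = tab["length"].to_numpy()
        pis = tab["pis"].to_numpy()
        rf = tab["rf_to_reference"].to_numpy()
        intermediate = tab["threshold"].between(10, 90)
        rows.append({
            "seed": cfg.seed,
            "monotone": bool(np.all(np.diff(lengths) <= 0) and
                             np.all(np.diff(pis) <= 0)),
            "rf_at_0": float(rf[0]),
            "best_intermediate_rf": float(np.nanmin(
                rf[intermediate.to_numpy()])),
        })
    df = pd.DataFrame(rows)
    return {
        "per_seed": df,
        "monotone_rate": float(df["monotone"].mean()),
        "intermediate_improves_rate": float(
            (df["best_intermediate_rf"] <= df["rf_at_0"]).mean()),
        "n": n_seeds,
    }


def observation_model_check(lam: float = 3.0, threshold: int = 6,
                            n_sites: int = 100_000, seed: int = 0) -> dict:
    """Empirical below-threshold masking fraction vs the Poisson CDF."""
    tree = simulate_tree(4, "yule", seed=seed)
    loci = simulate_alignment(tree, SubstitutionModel("JC69"), 1,
                              length_sampler=lambda r: n_sites,
                              seed=seed + 1)
    from .alignment import SampleMetadata
    md = {n: SampleMetadata(n, "historical", 1920)
          for n in tree.tip_names()}
    cfg = ObservationConfig(depth_lambda_historical=lam,
                            flank_retention_historical=1.0,
                            depth_threshold=threshold, seed=seed + 2)
    _, _, summary = apply_observation_model(loci, md, cfg)
    row = summary.iloc[0]
    p_hat = float(row["n_below_threshold"] / row["n_sites"])
    p_expected = float(poisson.cdf(threshold - 1, lam))
    se = float(np.sqrt(p_expected * (1 - p_expected) / n_sites))
    return {"empirical_fraction": p_hat, "expected_fraction": p_expected,
            "standard_error": se,
            "z": (p_hat - p_expected) / se if se else np.nan,
            "n": n_sites}


def _predictive_fixture(seed: int, n_loci: int = 120):
    """Locus statistics where Δ l-lk is a noisy monotone function of the
    parsimony-informative-site count."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "alignment_length": rng.integers(140, 1200, n_loci),
        "undetermined": rng.integers(0, 2000, n_loci),
        "pis": rng.integers(0, 60, n_loci),
        "variable_sites": rng.integers(0, 100, n_loci),
        "gc_content": rng.uniform(0.3, 0.6, n_loci),
    })
    signal = 2.0 * X["pis"].to_numpy().astype(float)
    y = signal + rng.normal(scale=0.3 * signal.std(), size=n_loci)
    return X, y


def predictive_experiment(n_seeds: int = 5, n_replicates: int = 100,
                          n_loci: int = 120, seed: int = 0) -> dict:
    """MLP regression of Δ l-lk on the five locus statistics, on fixture
    data where the informative-site count carries the signal."""
    r2s, top = [], []
    for i in range(n_seeds):
        s = seed * 1000 + i
        X, y = _predictive_fixture(s, n_loci)
        report = mlp_replicates(X, y, n_replicates=n_replicates, seed=s)
        r2s.append(report.mean_r2)
        top.append(report.importance.idxmax())
    return {"mean_r2": float(np.mean(r2s)),
            "per_seed_r2": r2s,
            "pis_top_rate": float(np.mean([t == "pis" for t in top])),
            "top_features": top,
            "n": n_seeds}


def determinism_check(seed: int = 0) -> dict:
    """Run a small full pipeline twice and compare every output byte."""
    cfg = StudyConfig(n_taxa=10, clade_size=8, n_loci=6, seed=seed)
    acfg = AnalysisConfig(seed=seed, bootstrap_B=4)
    with tempfile.TemporaryDirectory() as tmp:
        dirs = []
        for sub in ("run1", "run2"):
            bundle = generate_paired_study(cfg)
            report = run_full_comparison(bundle, acfg)
            out = Path(tmp) / sub
            write_comparison_report(report, out)
            dirs.append(out)
        names = sorted(p.name for p in dirs[0].iterdir())
        identical = names == sorted(p.name for p in dirs[1].iterdir()) and \
            all((dirs[0] / n).read_bytes() == (dirs[1] / n).read_bytes()
                for n in names)
    return {"identical": bool(identical), "n_files": len(names)}
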