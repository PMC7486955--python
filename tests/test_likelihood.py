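"""Pruning likelihoods against brute-force enumeration and closed forms."""

import numpy as np
import pytest

from phylodelta.alignment import ConcatenatedAlignment, PartitionMap
from phylodelta.likelihood import (LikelihoodError, fit_models,
                                   optimize_branch_lengths,
                                   site_log_likelihoods, BRANCH_MIN)
from phylodelta.models import PartitionedModel, SubstitutionModel
from phylodelta.simulate import simulate_alignment, simulate_tree
from phylodelta.trees import PhyloTree, root_with_outgroup

from conftest import make_concat
from oracles import brute_force_site_lnl


def random_alignment(taxa, length, rng, p_missing=0.12):
    p = [(1 - p_missing) / 4] * 4 + [p_missing / 3] * 3
    chars = rng.choice(list("ACGTN-?"), size=(len(taxa), length), p=p)
    return ConcatenatedAlignment(list(taxa), np.array(chars, dtype="S1"),
                                 PartitionMap([("l1", 0, length)]))


class TestPruningOracle:
    def test_matches_brute_force_on_random_small_instances(self, rng):
        """Random <=5-taxon instances vs state-enumeration, rel err < 1e-9
        (the full 200-instance check lives in the acceptance suite)."""
        n_instances = 0
        while n_instances < 40:
            n_taxa = int(rng.integers(4, 6))
            tree = simulate_tree(n_taxa, "yule",
                                 seed=int(rng.integers(2**31)))
            taxa = tree.tip_names()
            aln = random_alignment(taxa, 4, rng)
            family = ["JC69", "HKY85", "GTR"][n_instances % 3]
            model = SubstitutionModel(
                family,
                freqs=rng.dirichlet(np.ones(4) * 8),
                kappa=float(rng.uniform(1, 6)),
                exchangeabilities=rng.uniform(0.3, 3.0, 6),
                gamma_shape=(None if n_instances % 2 else
                             float(rng.uniform(0.3, 2.0))))
            pm = PartitionedModel.single(model, ["l1"])
            per_site, total = site_log_likelihoods(tree, pm, aln)
            for j in range(aln.n_columns):
                col = [aln.matrix[i, j].decode() for i in range(len(taxa))]
                expected = brute_force_site_lnl(tree, model, taxa, col)
                rel = abs(per_site[j] - expected) / max(abs(expected), 1e-12)
                assert rel < 1e-9
                n_instances += 1
            assert total == pytest.approx(per_site.sum(), abs=1e-9)

    def test_all_missing_column_is_zero(self):
        tree = PhyloTree.from_newick("((A:0.1,B:0.2):0.1,(C:0.1,D:0.4):0.1);")
        aln = make_concat({t: "N-?A" for t in "ABCD"})
        pm = PartitionedModel.single(SubstitutionModel("JC69"), ["l1"])
        per_site, _ = site_log_likelihoods(tree, pm, aln)
        assert per_site[0] == 0.0
        assert per_site[1] == 0.0
        assert per_site[2] == 0.0
        assert per_site[3] < 0.0

    def test_two_taxon_jc_closed_form(self):
        d = 0.27
        tree = PhyloTree.from_newick(f"(X:{d / 2},Y:{d / 2});")
        aln = make_concat({"X": "AA", "Y": "AC"})
        pm = PartitionedModel.single(SubstitutionModel("JC69"), ["l1"])
        per_site, _ = site_log_likelihoods(tree, pm, aln)
        same = np.log(0.25 * (0.25 + 0.75 * np.exp(-4 * d / 3)))
        diff = np.log(0.25 * (0.25 - 0.25 * np.exp(-4 * d / 3)))
        assert per_site[0] == pytest.approx(same, abs=1e-12)
        assert per_site[1] == pytest.approx(diff, abs=1e-12)

    def test_rerooting_invariance(self, rng):
        tree = simulate_tree(7, "yule", seed=21)
        taxa = tree.tip_names()
        aln = random_alignment(taxa, 50, rng)
        model = SubstitutionModel("GTR", freqs=[0.4, 0.1, 0.2, 0.3],
                                  exchangeabilities=[1, 3, 0.5, 1.2, 4, 1],
                                  gamma_shape=0.8)
        pm = PartitionedModel.single(model, ["l1"])
        _, base = site_log_likelihoods(tree, pm, aln)
        for tip in taxa[:3]:
            rooted = root_with_outgroup(tree, tip)
            _, lnl = site_log_likelihoods(rooted, pm, aln)
            assert lnl == pytest.approx(base, abs=1e-10)

    def test_all_missing_taxon_does_not_change_lnl(self, rng):
        tree = simulate_tree(5, "yule", seed=33)
        taxa = tree.tip_names()
        aln = random_alignment(taxa, 40, rng)
        model = SubstitutionModel("HKY85", kappa=3.0,
                                  freqs=[0.3, 0.2, 0.2, 0.3])
        pm = PartitionedModel.single(model, ["l1"])
        _, base = site_log_likelihoods(tree, pm, aln)
        # graft an all-missing tip onto the first internal edge
        grown = tree.copy()
        target = next(n for n in grown.postorder()
                      if n.parent is not None and not n.is_tip)
        from phylodelta.trees import Node
        new_internal = Node(length=target.length / 2)
        ghost = Node("ghost", 0.37)
        parent = target.parent
        parent.children[parent.children.index(target)] = new_internal
        new_internal.parent = parent
        new_internal.add(ghost)
        new_internal.add(target)
        target.length /= 2
        grown2 = PhyloTree(grown.root, rooted=grown.rooted)
        aln2 = ConcatenatedAlignment(
            taxa + ["ghost"],
            np.vstack([aln.matrix, np.full((1, 40), b"N", dtype="S1")]),
            PartitionMap([("l1", 0, 40)]))
        _, lnl = site_log_likelihoods(grown2, pm, aln2)
        assert lnl == pytest.approx(base, abs=1e-10)

    def test_partitioned_total_is_sum_of_partition_totals(self, rng):
        tree = simulate_tree(6, "yule", seed=3)
        taxa = tree.tip_names()
        chars = rng.choice(list("ACGTN"), size=(6, 30))
        aln = ConcatenatedAlignment(
            taxa, np.array(chars, dtype="S1"),
            PartitionMap([("a", 0, 12), ("b", 12, 30)]))
        ma = SubstitutionModel("JC69")
        mb = SubstitutionModel("HKY85", kappa=4.0, freqs=[0.3, 0.2, 0.2, 0.3])
        pm = PartitionedModel(models={"a": ma, "b": mb},
                              multipliers={"a": 0.5, "b": 2.0})
        per_site, total = site_log_likelihoods(tree, pm, aln)
        assert total == pytest.approx(per_site.sum(), abs=1e-9)
        # against single-partition runs
        aa = ConcatenatedAlignment(taxa, np.array(chars[:, :12], dtype="S1"),
                                   PartitionMap([("a", 0, 12)]))
        ab = ConcatenatedAlignment(taxa, np.array(chars[:, 12:], dtype="S1"),
                                   PartitionMap([("b", 0, 18)]))
        _, ta = site_log_likelihoods(
            tree, PartitionedModel({"a": ma}, {"a": 0.5}), aa)
        _, tb = site_log_likelihoods(
            tree, PartitionedModel({"b": mb}, {"b": 2.0}), ab)
        assert total == pytest.approx(ta + tb, abs=1e-8)

    def test_missing_tree_taxon_raises(self, rng):
        tree = simulate_tree(5, "yule", seed=1)
        aln = random_alignment(["x", "y", "z", "w", "v"], 10, rng)
        pm = PartitionedModel.single(SubstitutionModel("JC69"), ["l1"])
        with pytest.raises(LikelihoodError):
            site_log_likelihoods(tree, pm, aln)


class TestBranchOptimisation:
    def test_two_taxon_jc_mle_closed_form(self, rng):
        L, p = 3000, 0.15
        base = rng.choice(list("ACGT"), L)
        other = base.copy()
        idx = rng.choice(L, int(p * L), replace=False)
        shift = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for i in idx:
            other[i] = shift[other[i]]
        aln = make_concat({"X": "".join(base), "Y": "".join(other)})
        tree = PhyloTree.from_newick("(X:0.4,Y:0.01);")
        pm = PartitionedModel.single(SubstitutionModel("JC69"), ["l1"])
        opt, _ = optimize_branch_lengths(tree, pm, aln)
        total = sum(n.length for n in opt.postorder() if n.parent is not None)
        expected = -0.75 * np.log(1 - 4 * p / 3)
        assert total == pytest.approx(expected, abs=1e-4)

    def test_invariant_alignment_lengths_at_lower_bound(self):
        tree = simulate_tree(5, "yule", seed=2)
        aln = make_concat({t: "ACGTACGT" for t in tree.tip_names()})
        pm = PartitionedModel.single(SubstitutionModel("JC69"), ["l1"])
        opt, _ = optimize_branch_lengths(tree, pm, aln)
        for n in opt.postorder():
            if n.parent is not None:
                assert n.length == pytest.approx(BRANCH_MIN, abs=1e-7)

    def test_never_decreases_lnl_and_restarts_agree(self):
        tree = simulate_tree(6, "yule", seed=17)
        model = SubstitutionModel("HKY85", kappa=3.0,
                                  freqs=[0.3, 0.2, 0.2, 0.3])
        loci = simulate_alignment(tree, model, 2,
                                  length_sampler=lambda r: 400, seed=18)
        from phylodelta.alignment import FilterConfig, concatenate
        aln = concatenate(loci, sorted(tree.tip_names()),
                          FilterConfig(min_occupancy=0.0))
        pm = PartitionedModel.single(model, aln.partitions.locus_ids)
        finals = []
        for start_len in (0.01, 0.3):
            t = tree.copy()
            for n in t.postorder():
                if n.parent is not None:
                    n.length = start_len
            _, start_lnl = site_log_likelihoods(t, pm, aln)
            opt, lnl = optimize_branch_lengths(t, pm, aln, tol=1e-8,
                                               max_rounds=50)
            assert lnl >= start_lnl
            finals.append(lnl)
        assert finals[0] == pytest.approx(finals[1], abs=1e-4)


class TestFitModels:
    def _sim(self, model, seed, n_loci=1, L=600):
        tree = simulate_tree(6, "yule", seed=seed)
        loci = simulate_alignment(tree, model, n_loci,
                                  length_sampler=lambda r: L, seed=seed + 1,
                                  core_profile=False)
        from phylodelta.alignment import FilterConfig, concatenate
        aln = concatenate(loci, sorted(tree.tip_names()),
                          FilterConfig(min_occupancy=0.0))
        return tree, aln

    def test_jc_data_selects_jc(self):
        hits = 0
        for seed in range(10):
            tree, aln = self._sim(SubstitutionModel("JC69"), seed * 7 + 1)
            res = fit_models(aln, tree)
            fam = res.model.models[aln.partitions.locus_ids[0]].family
            hits += fam == "JC69"
        assert hits >= 9

    def test_strong_kappa_rejects_jc(self):
        hits = 0
        for seed in range(10):
            tree, aln = self._sim(
                SubstitutionModel("HKY85", kappa=8.0,
                                  freqs=[0.3, 0.2, 0.2, 0.3]), seed * 11 + 3)
            res = fit_models(aln, tree)
            fam = res.model.models[aln.partitions.locus_ids[0]].family
            hits += fam in ("HKY85", "GTR")
        assert hits >= 9

    def test_bic_penalty_arithmetic(self):
        # hand check: BIC = -2 lnL + k ln L; with L=600:
        # JC (k=1): -2(-1000) + ln 600        = 2006.397
        # HKY (k=2): -2(-997)  + 2 ln 600     = 2006.794 -> JC wins
        L = 600
        bic_jc = -2 * -1000.0 + 1 * np.log(L)
        bic_hky = -2 * -997.0 + 2 * np.log(L)
        assert bic_jc < bic_hky
        # and a 5-unit lnL gain flips the decision
        bic_hky2 = -2 * -994.0 + 2 * np.log(L)
        assert bic_hky2 < bic_jc
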