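"""Enrichment score against a definitional oracle; permutation calibration;
the two cluster-level contrast families."""

import numpy as np
import pandas as pd
import pytest

import isrpipe as ip
from isrpipe.gsea import gsea_preranked


def brute_force_es(genes, stats, gene_set, weight_exponent=1.0):
    """Explicit running-sum recomputation from the definition."""
    genes = list(genes)
    members = set(gene_set)
    n = len(genes)
    k = sum(g in members for g in genes)
    weights = [abs(s) ** weight_exponent for g, s in zip(genes, stats)
               if g in members]
    wsum = sum(weights)
    running, best = 0.0, 0.0
    wi = 0
    for g, s in zip(genes, stats):
        if g in members:
            if wsum > 0:
                running += abs(s) ** weight_exponent / wsum
            else:
                running += 1.0 / k
            wi += 1
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best):
            best = running
    return best


def ranked_frame(genes, stats):
    return pd.DataFrame({"gene": genes, "stat": stats})


class TestEnrichmentScore:
    def test_top_three_hand_case(self):
        genes = [f"g{i}" for i in range(10)]
        stats = list(range(10, 0, -1))
        es = ip.enrichment_score(ranked_frame(genes, stats), genes[:3])
        assert es == pytest.approx(1.0)

    def test_bottom_three_hand_case(self):
        genes = [f"g{i}" for i in range(10)]
        stats = list(range(10, 0, -1))
        es = ip.enrichment_score(ranked_frame(genes, stats), genes[-3:])
        assert es == pytest.approx(-1.0)

    def test_weight_zero_is_classic_ks(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        stats = rng.normal(size=50)
        stats = np.sort(stats)[::-1]
        members = list(rng.choice(genes, 12, replace=False))
        es = ip.enrichment_score(
            ranked_frame(genes, stats), members, weight_exponent=0.0
        )
        # classic KS: hits step 1/k, misses 1/(N-k)
        k, n = 12, 50
        running, best = 0.0, 0.0
        mem = set(members)
        for g in genes:
            running += 1 / k if g in mem else -1 / (n - k)
            if abs(running) > abs(best):
                best = running
        assert es == pytest.approx(best)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_exactly(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(10, 80))
        genes = [f"g{i}" for i in range(n)]
        stats = rng.normal(size=n)
        if trial % 4 == 0:
            stats[rng.random(n) < 0.3] = 0.0  # ties and zero stats
        stats = np.sort(stats)[::-1]
        k = int(rng.integers(1, n - 1))
        members = list(rng.choice(genes, k, replace=False))
        p = float(rng.choice([0.0, 1.0, 2.0]))
        es = ip.enrichment_score(ranked_frame(genes, stats), members,
                                 weight_exponent=p)
        # equality up to floating-point associativity of the running sum
        assert es == pytest.approx(
            brute_force_es(genes, stats, members, p), rel=1e-12, abs=1e-13
        )

    def test_empty_intersection_raises(self):
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError, match="no overlap"):
            ip.enrichment_score(ranked_frame(genes, [3, 2, 1]), ["z"])

    def test_whole_universe_raises(self):
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError, match="entire"):
            ip.enrichment_score(ranked_frame(genes, [3, 2, 1]), genes)


class TestPreranked:
    def test_null_pvalues_calibrated(self):
        """Random sets under a null ranking reject at 0.05 at roughly the
        nominal rate (500 replicate sets here; the full 2000-replicate
        check runs with the acceptance suite)."""
        rng = np.random.default_rng(11)
        n = 1500
        genes = [f"g{i}" for i in range(n)]
        stats = np.sort(rng.normal(size=n))[::-1]
        frame = ranked_frame(genes, stats)
        rejections = 0
        for r in range(500):
            members = [genes[i] for i in rng.choice(n, 25, replace=False)]
            res = gsea_preranked(
                frame, ip.GeneSetCollection(sets={"s": members}),
                n_perm=300, seed=r, adjust_batch=False,
            )
            rejections += float(res["p_value"].iloc[0]) <= 0.05
        rate = rejections / 500
        assert 0.02 <= rate <= 0.08

    def test_planted_shift_detected_control_not(self):
        rng = np.random.default_rng(12)
        n = 1000
        genes = [f"g{i}" for i in range(n)]
        stats = rng.normal(size=n)
        shifted = rng.choice(n, 60, replace=False)
        stats[shifted] += 1.5
        control = rng.choice(
            np.setdiff1d(np.arange(n), shifted), 60, replace=False
        )
        order = np.argsort(-stats)
        frame = ranked_frame(
            [genes[i] for i in order], stats[order]
        )
        coll = ip.GeneSetCollection(sets={
            "planted": [genes[i] for i in shifted],
            "control": [genes[i] for i in control],
        })
        res = gsea_preranked(frame, coll, n_perm=500, seed=3).set_index(
            "gene_set"
        )
        assert res.loc["planted", "es"] > 0
        assert res.loc["planted", "p_value"] < 0.01
        assert res.loc["control", "p_value"] > 0.05

    def test_pvalues_converge_with_more_permutations(self):
        rng = np.random.default_rng(13)
        n = 800
        genes = [f"g{i}" for i in range(n)]
        stats = np.sort(rng.normal(size=n))[::-1]
        members = [genes[i] for i in rng.choice(n, 40, replace=False)]
        coll = ip.GeneSetCollection(sets={"s": members})
        frame = ranked_frame(genes, stats)
        p1 = gsea_preranked(frame, coll, n_perm=1000, seed=1)["p_value"][0]
        p2 = gsea_preranked(frame, coll, n_perm=2000, seed=2)["p_value"][0]
        se = np.sqrt(p1 * (1 - p1) / 1000) + np.sqrt(p2 * (1 - p2) / 2000)
        assert abs(p1 - p2) <= max(2 * se, 0.01)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(14)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        stats = np.sort(rng.normal(size=n))[::-1]
        coll = ip.GeneSetCollection(
            sets={"s": [genes[i] for i in range(0, 60, 2)]}
        )
        frame = ranked_frame(genes, stats)
        a = gsea_preranked(frame, coll, n_perm=200, seed=5)
        b = gsea_preranked(frame, coll, n_perm=200, seed=5)
        assert a.equals(b)


class TestContrastFamilies:
    def test_families_flag_planted_types(self, default_sim, default_run):
        """Basal family flags the elevated-basal types (positive ES,
        q < 0.05); genotype family flags exactly the genotype-shifted
        types."""
        from conftest import majority_type

        enr = default_run["enrichment"]
        assignment = default_run["assignment"]
        truth = default_sim["truth"]
        type_of = {
            str(assignment.leaf_labels[c]): majority_type(
                truth, assignment, c
            )
            for c in range(assignment.n_clusters)
        }
        for family, planted in (
            ("basal", set(truth.basal_signature_types)),
            ("genotype", set(truth.genotype_signature_types)),
        ):
            fam = enr[enr["family"] == family]
            flagged = {
                type_of[str(row.cluster)]
                for row in fam.itertuples()
                if row.q_value < 0.05 and row.es > 0
            }
            assert flagged == planted

    def test_shuffled_genotypes_rarely_flag(self, default_sim, default_run):
        """Permuting genotype labels empties the genotype family."""
        rng = np.random.default_rng(15)
        truth = default_sim["truth"]
        norm = default_run["normalized"]
        assignment = default_run["assignment"]
        genotypes = truth.barcodes.loc[norm.barcode_ids, "genotype"].to_numpy()
        shuffled = rng.permutation(genotypes)
        enr = ip.cluster_signature_analysis(
            norm, assignment, shuffled, default_sim["gene_sets"],
            n_perm=500, seed=0,
        )
        fam = enr[enr["family"] == "genotype"]
        n_flagged = int(((fam["q_value"] < 0.05) & (fam["es"] > 0)).sum())
        assert n_flagged <= max(1, len(fam) // 10)

    def test_missing_genotype_cluster_skipped(self, caplog):
        import scipy.sparse as sp
        from isrpipe.cluster import ClusterAssignment
        from isrpipe.containers import NormalizedMatrix

        rng = np.random.default_rng(16)
        dense = np.abs(rng.normal(1, 0.5, size=(30, 40)))
        norm = NormalizedMatrix(
            gene_ids=[f"g{i}" for i in range(30)],
            barcode_ids=[f"b{j}" for j in range(40)],
            values=sp.csr_matrix(dense),
        )
        labels = np.repeat([0, 1], 20)
        asg = ClusterAssignment(
            barcode_ids=norm.barcode_ids,
            hierarchical=[str(l) for l in labels],
        )
        genotypes = np.array(["WT"] * 20 + ["MUT"] * 10 + ["WT"] * 10)
        coll = ip.GeneSetCollection(sets={"s": [f"g{i}" for i in range(8)]})
        with caplog.at_level("WARNING"):
            enr = ip.cluster_signature_analysis(
                norm, asg, genotypes, coll, n_perm=100, seed=0
            )
        fam = enr[enr["family"] == "genotype"]
        assert set(fam["cluster"]) == {"1"}  # cluster 0 is all-WT, skipped
        assert any("skipped" in r.message for r in caplog.records)
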