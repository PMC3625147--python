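import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from metacmp.gh import (
    CATEGORIES,
    category_subtotals,
    cluster_profiles,
    dendrogram_newick,
    gh_profile,
    heatmap_matrix,
    inventory_table,
    load_gh_mapping,
)
from metacmp.model import ValidationError

from conftest import make_metagenome

MAPPING = load_gh_mapping()
FAMS = {m.gh_family: m for m in MAPPING}


class TestShippedMapping:
    def test_families_categories_and_search_only_rows(self):
        assert len(MAPPING) == 33
        assert {m.category for m in MAPPING} == set(CATEGORIES)
        # families identified by sequence search carry no pfam domain
        assert {m.gh_family for m in MAPPING if not m.pfam_ids} == {
            "GH44",
            "GH51",
            "GH74",
        }
        assert FAMS["GH2"].pfam_ids == ("PF00703", "PF02836", "PF02837")
        assert FAMS["GH5"].pfam_ids == ("PF00150",)

    def test_every_family_in_exactly_one_category(self):
        seen = [m.gh_family for m in MAPPING]
        assert len(seen) == len(set(seen))


class TestGHProfile:
    def test_single_family_is_all_of_total(self):
        mg = make_metagenome(
            "s",
            [("c1", 1000, 1.0)],
            [(f"g{i}", "c1", ["pfam:PF00150"]) for i in range(3)],
        )
        inv = gh_profile(mg, MAPPING)
        assert inv.percentages["GH5"] == pytest.approx(100.0)
        assert inv.subtotals["cellulases"] == pytest.approx(100.0)

    def test_equal_masses_split_fifty_fifty(self):
        mg = make_metagenome(
            "s",
            [("c1", 1000, 2.0), ("c2", 1000, 1.0)],
            [
                ("g1", "c1", ["pfam:PF00150"]),  # GH5 mass 2
                ("g2", "c2", ["pfam:PF00331"]),  # GH10 mass 1
                ("g3", "c2", ["pfam:PF00331"]),  # GH10 mass 1
            ],
        )
        inv = gh_profile(mg, MAPPING)
        assert inv.percentages["GH5"] == pytest.approx(50.0)
        assert inv.percentages["GH10"] == pytest.approx(50.0)

    def test_multi_domain_gene_counts_once_per_family(self):
        # a GH2 gene carrying all three GH2 domains counts once
        mg = make_metagenome(
            "s",
            [("c1", 1000, 3.0)],
            [
                ("g1", "c1", ["pfam:PF00703", "pfam:PF02836", "pfam:PF02837"]),
                ("g2", "c1", ["pfam:PF00150"]),
            ],
        )
        inv = gh_profile(mg, MAPPING)
        assert inv.percentages["GH2"] == pytest.approx(50.0)

    def test_blast_identified_family_via_gh_annotation(self):
        mg = make_metagenome(
            "s",
            [("c1", 1000, 1.0)],
            [("g1", "c1", ["GH_family:GH51"]), ("g2", "c1", ["pfam:PF00150"])],
        )
        inv = gh_profile(mg, MAPPING)
        assert inv.percentages["GH51"] == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        pfams = [pf for m in MAPPING for pf in m.pfam_ids]
        contigs = [
            (f"c{i}", 1000, float(rng.uniform(0.5, 10))) for i in range(6)
        ]
        genes = [
            (
                f"g{j}",
                f"c{int(rng.integers(0, 6))}",
                [f"pfam:{rng.choice(pfams)}"],
            )
            for j in range(60)
        ]
        mg = make_metagenome("s", contigs, genes)
        inv = gh_profile(mg, MAPPING)
        # naive recount
        pf2fam = {pf: m.gh_family for m in MAPPING for pf in m.pfam_ids}
        mass = {}
        for gid, cid, units in genes:
            fam = pf2fam[units[0].split(":")[1]]
            depth = dict((c[0], c[2]) for c in contigs)[cid]
            mass[fam] = mass.get(fam, 0.0) + depth
        total = sum(mass.values())
        for fam, v in mass.items():
            assert inv.percentages[fam] == pytest.approx(100 * v / total)
        assert sum(inv.percentages.values()) == pytest.approx(100.0)
        assert sum(inv.subtotals.values()) == pytest.approx(100.0)

    def test_no_gh_genes_is_an_error(self):
        mg = make_metagenome("s", [("c1", 1000, 1.0)], [("g1", "c1", ["COG:X"])])
        with pytest.raises(ValidationError, match="no GH genes"):
            gh_profile(mg, MAPPING)

    def test_invariant_to_uniform_depth_scaling(self):
        specs = [("g1", "c1", ["pfam:PF00150"]), ("g2", "c2", ["pfam:PF04616"])]
        mg1 = make_metagenome("s", [("c1", 1000, 2.0), ("c2", 1000, 6.0)], specs)
        mg2 = make_metagenome("s", [("c1", 1000, 10.0), ("c2", 1000, 30.0)], specs)
        assert gh_profile(mg1, MAPPING).percentages == pytest.approx(
            gh_profile(mg2, MAPPING).percentages
        )


class TestCategorySubtotals:
    def test_published_cellulase_subtotal_cow_dung_termite(self):
        vals = {"GH5": 10.4, "GH6": 0, "GH7": 0, "GH9": 4.2, "GH44": 0.3, "GH45": 0.8, "GH48": 0}
        subs = category_subtotals(vals, MAPPING)
        assert subs["cellulases"] == pytest.approx(15.7, abs=1e-9)

    def test_published_debranching_subtotal_wood_termite(self):
        vals = {"GH51": 0.8, "GH54": 0, "GH62": 0, "GH67": 2.0, "GH78": 0.4}
        subs = category_subtotals(vals, MAPPING)
        assert subs["debranching"] == pytest.approx(3.2, abs=1e-9)

    def test_empty_category_is_zero(self):
        subs = category_subtotals({"GH5": 100.0}, MAPPING)
        assert subs["debranching"] == 0.0 and subs["oligosaccharide_degrading"] == 0.0


class TestHeatmapMatrix:
    def _matrix(self):
        return pd.DataFrame(
            {"s1": [5.0, 2.0, 0.5], "s2": [1.0, 0.1, 0.4], "s3": [0.0, 1.9, 1.0]},
            index=["GH5", "GH10", "GH43"],
        )

    def test_min_pct_zero_keeps_all(self):
        assert heatmap_matrix(self._matrix(), 0.0).shape[0] == 3

    def test_boundary_is_inclusive(self):
        kept = heatmap_matrix(self._matrix(), 2.0)
        assert list(kept.index) == ["GH5", "GH10"]  # GH10 hits exactly 2.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(31)
        mat = pd.DataFrame(
            rng.uniform(0, 5, size=(20, 3)),
            index=[f"GH{i}" for i in range(20)],
            columns=["a", "b", "c"],
        )
        kept = heatmap_matrix(mat, 2.0)
        expected = [
            fam for fam in mat.index if any(mat.loc[fam, s] >= 2.0 for s in mat.columns)
        ]
        assert list(kept.index) == expected

    def test_all_removed_is_an_error(self):
        with pytest.raises(ValidationError):
            heatmap_matrix(self._matrix(), 99.0)

    def test_needs_two_samples(self):
        with pytest.raises(ValidationError):
            heatmap_matrix(self._matrix()[["s1"]], 1.0)


def naive_agglomerate(D, method):
    """O(n^3) reference agglomeration (UPGMA / complete) over a distance matrix."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(active) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters[i] + clusters[j]
        active = [k for k in active if k not in (i, j)]
        new_d = {}
        for k in active:
            pairs = [D[a, b] for a in merged for b in clusters[k]]
            if method == "average":
                d = float(np.mean(pairs))
            else:
                d = float(np.max(pairs))
            new_d[k] = d
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        clusters[nxt] = merged
        for k in active:
            dist[(min(k, nxt), max(k, nxt))] = new_d[k]
        active.append(nxt)
        nxt += 1
    return heights


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["f1", "f2"])
        Z, labels = cluster_profiles(mat, "euclidean", "average")
        assert labels == ["a", "b"] and Z[0, 2] == pytest.approx(0.0)

    def test_identical_pair_merges_first(self):
        mat = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 0.0]}, index=["f1", "f2"]
        )
        Z, _ = cluster_profiles(mat, "braycurtis", "average")
        assert sorted(Z[0, :2]) == [0, 1]  # columns a and b

    @pytest.mark.parametrize("method", ["average", "complete"])
    @pytest.mark.parametrize("seed", range(5))
    def test_heights_match_naive_oracle(self, method, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(
            rng.uniform(0.1, 5, size=(12, 5)), columns=list("abcde")
        )
        Z, _ = cluster_profiles(mat, "euclidean", method)
        D = squareform(pdist(mat.to_numpy().T, metric="euclidean"))
        assert list(Z[:, 2]) == pytest.approx(naive_agglomerate(D, method))

    def test_constant_matrix_correlation_undefined(self):
        mat = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}, index=["f1", "f2"])
        with pytest.raises(ValidationError, match="undefined"):
            cluster_profiles(mat, "correlation", "average")

    def test_newick_render(self):
        mat = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.1, 2.1], "c": [9.0, 0.0]}, index=["f1", "f2"]
        )
        Z, labels = cluster_profiles(mat, "euclidean", "average")
        nwk = dendrogram_newick(Z, labels)
        assert nwk.endswith(";") and all(l in nwk for l in labels)
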