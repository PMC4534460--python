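"""Database reading, validation, grouping and tree construction."""

import textwrap

import dendropy
import numpy as np
import pytest

import famdrift as fd
from famdrift.corpus import SchemaError, ValidationError

from conftest import make_family

HEADER = "language,autotyp_family,glottolog_family,area,subsystem,ergative"


def write_csv(tmp_path, rows, header=HEADER):
    p = tmp_path / "db.csv"
    p.write_text("\n".join([header] + rows) + "\n")
    return p


class TestReadDatabase:
    def test_round_trip(self, tmp_path, benchmark_world):
        records, _ = benchmark_world
        out = tmp_path / "rt.csv"
        fd.write_database(records, out)
        assert fd.read_database(out) == records

    def test_missing_column_names_it(self, tmp_path):
        p = write_csv(tmp_path, [], header="language,area,subsystem,ergative")
        with pytest.raises(SchemaError, match="autotyp_family"):
            fd.read_database(p)

    def test_unknown_area_strict_raises(self, tmp_path):
        p = write_csv(tmp_path, ["x,f,f,Atlantis,whole-language,0"])
        with pytest.raises(ValidationError, match="Atlantis"):
            fd.read_database(p, strict=True)

    def test_unknown_area_nonstrict_skips_with_warning(self, tmp_path):
        rows = [
            "a,f,f,Eurasia,whole-language,0",
            "b,f,f,Atlantis,whole-language,1",
            "c,f,f,Pacific,whole-language,1",
        ]
        p = write_csv(tmp_path, rows)
        with pytest.warns(UserWarning, match="Atlantis"):
            recs = fd.read_database(p, strict=False)
        assert [r.language_id for r in recs] == ["a", "c"]

    def test_duplicate_language_subsystem_rejected(self, tmp_path):
        rows = ["a,f,f,Eurasia,whole-language,0",
                "a,f,f,Eurasia,whole-language,1"]
        p = write_csv(tmp_path, rows)
        with pytest.raises(ValidationError, match="duplicate"):
            fd.read_database(p)

    def test_nonbinary_ergative_rejected(self, tmp_path):
        p = write_csv(tmp_path, ["a,f,f,Eurasia,whole-language,2"])
        with pytest.raises(ValidationError, match="0 or 1"):
            fd.read_database(p)

    def test_empty_file_with_header_warns(self, tmp_path):
        p = write_csv(tmp_path, [])
        with pytest.warns(UserWarning, match="no valid records"):
            assert fd.read_database(p) == []

    def test_column_map_translates_foreign_headers(self, tmp_path):
        p = write_csv(tmp_path, ["a,f,g,Eurasia,whole-language,1"],
                      header="lang,fam_a,fam_g,area,subsystem,ergative")
        recs = fd.read_database(p, column_map={
            "lang": "language", "fam_a": "autotyp_family",
            "fam_g": "glottolog_family"})
        assert recs[0].language_id == "a"
        assert recs[0].family_glottolog == "g"


class TestGrouping:
    def test_straddling_family_split_per_area(self):
        recs = []
        for i, area in enumerate(["Eurasia"] * 3 + ["Pacific"] * 2):
            recs.append(fd.SubsystemRecord(f"l{i}", "Austro", "Austro", area,
                                           "whole-language", 0))
        fams = fd.group_families(recs, "autotyp")
        assert sorted((f.area, f.n_languages) for f in fams) == [
            ("Eurasia", 3), ("Pacific", 2)]
        # split sub-families get area-tagged ids, so ids stay unique
        assert {f.family_id for f in fams} == {
            "Austro[Eurasia]", "Austro[Pacific]"}

    def test_partition_exhaustive_and_disjoint(self, benchmark_world):
        records, _ = benchmark_world
        for tax in ("autotyp", "glottolog"):
            fams = fd.group_families(records, tax)
            assert sum(f.n_trials for f in fams) == len(records)
            langs = [l for f in fams for l in f.languages]
            assert len(langs) == len(set(langs))
            assert len(set(langs)) == len({r.language_id for r in records})

    def test_large_flag_follows_cutoff(self, benchmark_world):
        records, truth = benchmark_world
        fams = fd.group_families(records, "autotyp", cutoff=5)
        by_id = {f.family_id: f for f in fams}
        for _, row in truth.iterrows():
            assert by_id[row["family"]].is_large == (row["size"] >= 5)

    def test_unknown_taxonomy(self):
        with pytest.raises(ValueError):
            fd.group_families([], "ethnologue")


class TestErgativeProportion:
    @pytest.mark.parametrize("trials, expected", [
        ([1, 0, 0, 0], 0.25),   # Hindi-style: ergative only in perfective+main
        ([0], 0.0),
        ([1, 1, 1, 0], 0.75),
    ])
    def test_proportions(self, trials, expected):
        assert fd.ergative_proportion(trials) == expected

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            fd.ergative_proportion([])


class TestFamilyTree:
    def test_flat_classification_gives_star_tree(self):
        fam = make_family({f"l{i}": [0] for i in range(4)})
        ft = fd.build_family_tree(fam)
        assert ft.n_tips == 4
        root = ft.tree.seed_node
        assert len(root.child_nodes()) == 4
        assert all(c.edge.length == 1.0 for c in root.child_nodes())

    def test_mixed_subsystems_become_polymorphic_tip(self):
        fam = make_family({"hindi": [1, 0, 0, 0], "other": [0]})
        ft = fd.build_family_tree(fam)
        assert ft.tip_states["hindi"] == "polymorphic"
        assert ft.tip_states["other"] == 0

    def test_nested_classification_nests_tips(self):
        fam = make_family({"a": [0], "b": [0], "c": [1], "d": [1]})
        cls = {"a": ("west",), "b": ("west",), "c": ("east",), "d": ("east",)}
        ft = fd.build_family_tree(fam, classification=cls)
        assert len(ft.tree.seed_node.child_nodes()) == 2
        pdm = ft.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in ft.tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == 2.0
        assert pdm.distance(taxa["a"], taxa["c"]) == 4.0

    def test_singleton_family_has_no_tree(self):
        fam = make_family({"only": [1]})
        with pytest.raises(ValueError, match="at least 2"):
            fd.build_family_tree(fam)

    def test_external_newick_pruning_preserves_path_lengths(self, tmp_path, rng):
        big = fd.gen_tree(10, rng)
        for node in big.tree.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length = float(rng.uniform(0.5, 3.0))
        pdm = big.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in big.tree.taxon_namespace}
        keep = ["t0", "t2", "t5", "t7"]
        before = {(a, b): pdm.distance(taxa[a], taxa[b])
                  for a in keep for b in keep if a < b}
        nwk = tmp_path / "big.nwk"
        big.tree.write(path=str(nwk), schema="newick")
        fam = make_family({k: [0] for k in keep})
        ft = fd.build_family_tree(fam, external_newick=nwk)
        assert sorted(ft.tip_labels()) == keep
        pdm2 = ft.tree.phylogenetic_distance_matrix()
        taxa2 = {t.label: t for t in ft.tree.taxon_namespace}
        for (a, b), d in before.items():
            assert pdm2.distance(taxa2[a], taxa2[b]) == pytest.approx(d)

    def test_external_newick_low_coverage_errors(self, tmp_path, rng):
        small = fd.gen_tree(3, rng)
        nwk = tmp_path / "small.nwk"
        small.tree.write(path=str(nwk), schema="newick")
        fam = make_family({f"x{i}": [0] for i in range(8)})
        with pytest.raises(ValueError, match="fewer than half"):
            fd.build_family_tree(fam, external_newick=nwk)
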