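import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idscn.atlas import (
    EdgeIndex,
    dk_atlas,
    edge_enumeration,
    export_network,
    load_ct_table,
    load_network_csv,
    save_ct_table,
)
from idscn.synthetic import CohortConfig, generate_cohort


class TestRegistry:
    def test_cardinalities(self, atlas):
        assert atlas.n_regions == 68
        assert sum(r.hemisphere == "left" for r in atlas.regions) == 34
        assert sum(r.hemisphere == "right" for r in atlas.regions) == 34

    def test_uniqueness_and_ordering(self, atlas):
        names = [(r.name, r.hemisphere) for r in atlas.regions]
        assert len(set(names)) == 68
        abbrevs = [(r.abbreviation, r.hemisphere) for r in atlas.regions]
        assert len(set(abbrevs)) == 68
        # left hemisphere first, alphabetical within hemisphere
        assert all(r.hemisphere == "left" for r in atlas.regions[:34])
        left_names = [r.name for r in atlas.regions[:34]]
        assert left_names == sorted(left_names)
        assert [r.name for r in atlas.regions[34:]] == left_names

    def test_lookup_transverse_temporal(self, atlas):
        r = atlas.lookup("TrT", "left")
        assert r.name == "transversetemporal"
        assert 0 <= r.region_id < 68
        assert atlas.from_short("L TrT") is r

    def test_report_abbreviations_cover_published_codes(self, atlas):
        published = {
            "TrT", "ST", "LOrF", "Op", "RoMF", "SF", "IP", "SM", "SP", "LO",
            "IT", "IstCg", "PreCu", "PoC", "Tr", "En", "Or", "CMF", "PerCa",
            "FPol", "Cu", "Lg", "MT", "PaH", "PaC", "Ins",
        }
        have = {r.abbreviation for r in atlas.regions}
        assert published <= have

    def test_lobes_give_eight_blocks(self, atlas):
        assert len(set(atlas.lobes())) == 8


class TestEdgeIndex:
    @pytest.mark.parametrize(
        "n,convention,expected",
        [(68, "full_grid", 4624), (68, "unique_pairs", 2278),
         (4, "full_grid", 16), (4, "unique_pairs", 6)],
    )
    def test_edge_counts(self, n, convention, expected):
        assert EdgeIndex(n, convention).n_edges == expected

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            EdgeIndex(68, "lower_triangle")

    @settings(deadline=None, max_examples=60)
    @given(
        n=st.integers(4, 70),
        convention=st.sampled_from(["full_grid", "unique_pairs"]),
        data=st.data(),
    )
    def test_flatten_unflatten_are_inverse(self, n, convention, data):
        ei = EdgeIndex(n, convention)
        k = data.draw(st.integers(0, ei.n_edges - 1))
        i, j = ei.unflatten(k)
        assert ei.flatten(i, j) == k
        if convention == "unique_pairs":
            assert i < j
            assert ei.flatten(j, i) == k  # unordered

    def test_extract_matches_pair_enumeration(self, atlas, edges):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(68, 68))
        m = (m + m.T) / 2
        flat = edges.extract(m)
        for k in [0, 1, 67, 68, 2277]:
            i, j = edges.unflatten(k)
            assert flat[k] == m[i, j]
        back = edges.to_matrix(flat)
        off = ~np.eye(68, dtype=bool)
        assert np.array_equal(back[off], m[off])


class TestTableIO:
    def _toy_frame(self, atlas, n=3):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            rng.uniform(1.5, 3.5, size=(n, 68)), columns=atlas.columns
        )
        df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
        df.insert(1, "group", ["FPS", "MOBA", "CONTROL"][:n])
        return df

    def test_round_trip(self, atlas, tmp_path):
        df = self._toy_frame(atlas)
        path = tmp_path / "toy.csv"
        df.to_csv(path, index=False)
        table = load_ct_table(path, atlas)
        assert table.thickness.shape == (3, 68)
        out = tmp_path / "again.tsv"
        save_ct_table(table, out)
        table2 = load_ct_table(out, atlas)
        assert np.array_equal(table.thickness, table2.thickness)
        assert table.subject_ids == table2.subject_ids

    def test_missing_region_column(self, atlas, tmp_path):
        df = self._toy_frame(atlas).drop(columns=["lh_transversetemporal"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="lh_transversetemporal"):
            load_ct_table(path, atlas)

    def test_na_cell_names_subject_and_region(self, atlas, tmp_path):
        df = self._toy_frame(atlas)
        df["rh_cuneus"] = df["rh_cuneus"].astype(object)
        df.loc[1, "rh_cuneus"] = "NA"
        path = tmp_path / "na.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match=r"s1.*rh_cuneus"):
            load_ct_table(path, atlas)

    def test_duplicate_subject_id(self, atlas, tmp_path):
        df = self._toy_frame(atlas)
        df.loc[2, "subject_id"] = "s0"
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            load_ct_table(path, atlas)

    def test_nonpositive_thickness_rejected(self, atlas, tmp_path):
        df = self._toy_frame(atlas)
        df.loc[0, "lh_insula"] = -0.1
        path = tmp_path / "neg.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="lh_insula"):
            load_ct_table(path, atlas)


class TestExports:
    def test_csv_round_trip_bit_identical(self, atlas, tmp_path):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(68, 68))
        m = (m + m.T) / 2
        (path,) = export_network(m, atlas, tmp_path / "net", format="csv")
        assert np.array_equal(load_network_csv(path), m)

    def test_brainnet_files(self, atlas, tmp_path):
        m = np.eye(68)
        node, edge = export_network(m, atlas, tmp_path / "net", format="brainnet")
        node_lines = node.read_text().strip().split("\n")
        assert len(node_lines) == 68
        assert all(len(line.split()) == 6 for line in node_lines)
        edge_rows = edge.read_text().strip().split("\n")
        assert len(edge_rows) == 68
        assert all(len(row.split()) == 68 for row in edge_rows)
        # left-hemisphere display coordinates mirror to negative x
        assert float(node_lines[0].split()[0]) < 0 < float(node_lines[34].split()[0])

    def test_exports_deterministic(self, atlas, tmp_path):
        cohort = generate_cohort(CohortConfig(seed=3, group_sizes=(5, 5, 5)))
        m = np.corrcoef(cohort.table.thickness.T)
        a = export_network(m, atlas, tmp_path / "a", format="brainnet")
        b = export_network(m, atlas, tmp_path / "b", format="brainnet")
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_dimension_mismatch(self, atlas, tmp_path):
        with pytest.raises(ValueError, match="does not match"):
            export_network(np.eye(10), atlas, tmp_path / "x", format="csv")
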