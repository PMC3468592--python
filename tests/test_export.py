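"""Selection semantics and the TSV/NEXUS/IMa2/Migrate writers."""

import numpy as np
import pytest

from locusqc import export, metrics
from locusqc.export import ExportConfig, ExportError, SelectionSpec

from conftest import make_dataset, random_membership_dataset


def selection_oracle(dataset, spec):
    """Direct set-comprehension over locus memberships."""
    names = []
    for name in sorted(dataset.loci):
        members = dataset.loci[name].individual_ids
        if spec.mode == "individuals":
            ok = all(m in members for m in spec.members)
        else:
            pops = {dataset.individuals[i].population for i in members}
            ok = all(p in pops for p in spec.members)
        if ok:
            names.append(name)
    return names


class TestSelectLoci:
    def test_individuals_mode_requires_all_members(self):
        ds = make_dataset(
            {"L1": ["A", "B", "C"], "L2": ["A", "C"]},
            {"A": "p", "B": "p", "C": "q"},
        )
        got = export.select_loci(ds, SelectionSpec("individuals", ("A", "B")))
        assert [l.name for l in got] == ["L1"]

    def test_populations_mode_requires_each_population(self):
        ds = make_dataset(
            {"L1": ["A"], "L2": ["A", "C"]},
            {"A": "north", "B": "north", "C": "south"},
        )
        got = export.select_loci(ds, SelectionSpec("populations", ("north", "south")))
        assert [l.name for l in got] == ["L2"]

    def test_unknown_member_is_hard_error(self):
        ds = make_dataset({"L1": ["A"]}, {"A": "p"})
        with pytest.raises(ExportError, match="'Z'"):
            export.select_loci(ds, SelectionSpec("individuals", ("Z",)))
        with pytest.raises(ExportError, match="'nowhere'"):
            export.select_loci(ds, SelectionSpec("populations", ("nowhere",)))

    def test_matches_oracle_on_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            ds = random_membership_dataset(rng)
            inds = list(ds.individuals)
            pops = ds.populations()
            k = int(rng.integers(1, len(inds) + 1))
            chosen = list(rng.choice(inds, size=k, replace=False))
            spec = SelectionSpec("individuals", tuple(chosen))
            assert [l.name for l in export.select_loci(ds, spec)] == selection_oracle(
                ds, spec
            )
            kp = int(rng.integers(1, len(pops) + 1))
            spec = SelectionSpec(
                "populations", tuple(rng.choice(pops, size=kp, replace=False))
            )
            assert [l.name for l in export.select_loci(ds, spec)] == selection_oracle(
                ds, spec
            )

    def test_monotonic_under_member_addition(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            ds = random_membership_dataset(rng)
            inds = list(ds.individuals)
            base = [inds[0]]
            prev = {
                l.name for l in export.select_loci(ds, SelectionSpec("individuals", tuple(base)))
            }
            for extra in inds[1:]:
                base.append(extra)
                cur = {
                    l.name
                    for l in export.select_loci(ds, SelectionSpec("individuals", tuple(base)))
                }
                assert cur <= prev
                prev = cur

    def test_singleton_populations_equal_individuals_mode(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ds = random_membership_dataset(rng, max_populations=4)
            singleton_pops = [
                p for p in ds.populations() if len(ds.members_of(p)) == 1
            ]
            if not singleton_pops:
                continue
            members = [ds.members_of(p)[0] for p in singleton_pops]
            by_pop = export.select_loci(
                ds, SelectionSpec("populations", tuple(singleton_pops))
            )
            by_ind = export.select_loci(
                ds, SelectionSpec("individuals", tuple(members))
            )
            assert [l.name for l in by_pop] == [l.name for l in by_ind]

    def test_manifest_selections(self, synth, synth_dataset):
        for sel in synth.manifest.selections:
            spec = SelectionSpec(sel["mode"], tuple(sel["members"]))
            got = sorted(l.name for l in export.select_loci(synth_dataset, spec))
            assert got == sel["loci"]


class TestTsv:
    def test_empty_dataset_header_only(self, tmp_path):
        path = export.write_tsv([], tmp_path / "s.tsv")
        assert path.read_text().splitlines() == ["\t".join(export.SUMMARY_COLUMNS)]

    def test_summary_line_count_and_roundtrip(self, synth_dataset, tmp_path):
        rows = metrics.summary_table(synth_dataset)
        path = export.write_tsv(rows, tmp_path / "s.tsv")
        assert len(path.read_text().splitlines()) == len(rows) + 1
        back = export.read_summary_tsv(path)
        for orig, parsed in zip(rows, back):
            assert (
                parsed.individual_id,
                parsed.population,
                parsed.num_loci,
                parsed.total_reads,
                parsed.used_reads,
            ) == (
                orig.individual_id,
                orig.population,
                orig.num_loci,
                orig.total_reads,
                orig.used_reads,
            )
            # percentUsed is printed at one decimal percent
            assert abs(parsed.percent_used - orig.percent_used) <= 0.0005

    def test_locus_table_roundtrip(self, synth_dataset, tmp_path):
        iid = synth_dataset.individual_order[0]
        rows = metrics.locus_table(synth_dataset, iid)
        path = export.write_tsv(rows, tmp_path / "l.tsv")
        assert export.read_locus_tsv(path) == rows


class TestNexus:
    def test_dimensions_and_roundtrip(self, synth_dataset, tmp_path):
        loci = list(synth_dataset.loci.values())
        paths = export.write_nexus(loci, synth_dataset, tmp_path)
        assert len(paths) == len(loci)
        for locus, path in zip(loci, paths):
            parsed = export.read_nexus(path)
            assert len(parsed) == len(locus.alleles)
            for a in locus.alleles:
                assert parsed[f"{a.individual_id}_{a.allele_index}"] == a.sequence

    def test_validates_under_dendropy(self, example_dataset, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        loci = list(example_dataset.loci.values())
        for locus, path in zip(loci, export.write_nexus(loci, example_dataset, tmp_path)):
            matrix = dendropy.DnaCharacterMatrix.get(path=path, schema="nexus")
            assert len(matrix) == len(locus.alleles)
            # NEXUS reads unquoted underscores as spaces; undo for comparison
            seqs = {
                t.label.replace(" ", "_"): str(matrix[t]).replace(" ", "")
                for t in matrix.taxon_namespace
            }
            for a in locus.alleles:
                assert seqs[f"{a.individual_id}_{a.allele_index}"] == a.sequence

    def test_label_with_space_is_quoted(self, tmp_path):
        ds = make_dataset({"L1": ["my ind"]}, {"my ind": "p"})
        (path,) = export.write_nexus([ds.loci["L1"]], ds, tmp_path)
        text = path.read_text()
        assert "'my ind_0'" in text
        parsed = export.read_nexus(path)
        assert "my ind_0" in parsed

    def test_concatenated_matrix_pads_missing(self, tmp_path):
        ds = make_dataset(
            {"L1": ["A", "B"], "L2": ["A"]}, {"A": "p", "B": "p"}, locus_length=5
        )
        (path,) = export.write_nexus(
            [ds.loci["L1"], ds.loci["L2"]], ds, tmp_path, concat=True
        )
        parsed = export.read_nexus(path)
        assert parsed["B_0"].endswith("?????")
        assert len(parsed["A_0"]) == 10

    def test_unique_filenames_on_repeat(self, example_dataset, tmp_path):
        loci = list(example_dataset.loci.values())
        first = export.write_nexus(loci, example_dataset, tmp_path)
        second = export.write_nexus(loci, example_dataset, tmp_path)
        assert set(first).isdisjoint(second)


def two_pop_dataset():
    return make_dataset(
        {"LOCUS_101": ["A", "B", "C"], "LOCUS_102": ["A", "C"]},
        {"A": "north", "B": "north", "C": "south"},
        locus_length=20,
    )


class TestIma2:
    def test_header_and_locus_lines(self, tmp_path):
        ds = two_pop_dataset()
        spec = SelectionSpec("populations", ("north", "south"))
        loci = export.select_loci(ds, spec)
        cfg = ExportConfig(ima2_population_tree="(0,1):2")
        path = export.write_ima2(loci, ds, spec, cfg, tmp_path / "ima2.txt")
        lines = path.read_text().splitlines()
        assert lines[1] == "2"
        assert lines[2].split() == ["north", "south"]
        assert lines[3] == "(0,1):2"
        assert lines[4] == "2"
        assert lines[5].split() == ["LOCUS_101", "4", "2", "20", "H", "1"]

    def test_roundtrip_and_population_counts(self, synth_dataset, tmp_path):
        ds = synth_dataset
        pops = ds.populations()
        spec = SelectionSpec("populations", tuple(pops))
        loci = export.select_loci(ds, spec)
        if not loci:
            pytest.skip("random dataset has no locus covering all populations")
        cfg = ExportConfig(ima2_population_tree="(0,1):3" if len(pops) > 1 else None)
        path = export.write_ima2(loci, ds, spec, cfg, tmp_path / "ima2.txt")
        parsed = export.read_ima2(path)
        assert parsed["populations"] == pops
        assert len(parsed["loci"]) == len(loci)
        for locus, entry in zip(loci, parsed["loci"]):
            assert entry["name"] == locus.name
            assert entry["length"] == locus.length
            assert sum(entry["counts"]) == len(locus.alleles)
            written = [
                seq for p in pops for (_lab, seq) in entry["sequences"][p]
            ]
            assert sorted(written) == sorted(a.sequence for a in locus.alleles)
            for p, n in zip(pops, entry["counts"]):
                expected = sum(
                    1
                    for a in locus.alleles
                    if ds.individuals[a.individual_id].population == p
                )
                assert n == expected == len(entry["sequences"][p])

    def test_missing_population_tree_is_error(self, tmp_path):
        ds = two_pop_dataset()
        spec = SelectionSpec("populations", ("north", "south"))
        loci = export.select_loci(ds, spec)
        with pytest.raises(ExportError, match="population_tree"):
            export.write_ima2(loci, ds, spec, ExportConfig(), tmp_path / "x.txt")

    def test_single_population_tree_degenerates_to_zero(self, tmp_path):
        ds = two_pop_dataset()
        spec = SelectionSpec("populations", ("north",))
        loci = export.select_loci(ds, spec)
        path = export.write_ima2(loci, ds, spec, ExportConfig(), tmp_path / "x.txt")
        assert path.read_text().splitlines()[3] == "0"

    def test_long_names_truncated_uniquely(self, tmp_path):
        long_a = "individual_alpha_long"
        long_b = "individual_alpha_longer"
        ds = make_dataset(
            {"L1": [long_a, long_b]}, {long_a: "p", long_b: "p"}, locus_length=8
        )
        spec = SelectionSpec("populations", ("p",))
        path = export.write_ima2(
            export.select_loci(ds, spec), ds, spec, ExportConfig(), tmp_path / "x.txt"
        )
        parsed = export.read_ima2(path)
        labels = [lab for lab, _ in parsed["loci"][0]["sequences"]["p"]]
        assert len(labels) == len(set(labels)) == 4


class TestMigrate:
    def test_header_echo(self, tmp_path):
        ds = two_pop_dataset()
        spec = SelectionSpec("populations", ("north", "south"))
        loci = export.select_loci(ds, spec)
        path = export.write_migrate(loci, ds, spec, tmp_path / "m.txt")
        lines = path.read_text().splitlines()
        assert lines[0] == "2 2"
        assert lines[1] == "20 20"

    def test_roundtrip_and_per_population_counts(self, synth_dataset, tmp_path):
        ds = synth_dataset
        pops = ds.populations()
        spec = SelectionSpec("populations", tuple(pops))
        loci = export.select_loci(ds, spec)
        if not loci:
            pytest.skip("random dataset has no locus covering all populations")
        path = export.write_migrate(loci, ds, spec, tmp_path / "m.txt")
        parsed = export.read_migrate(path)
        assert parsed["populations"] == pops
        assert parsed["lengths"] == [l.length for l in loci]
        for p in pops:
            for locus, block in zip(loci, parsed["sequences"][p]):
                expected = sorted(
                    a.sequence
                    for a in locus.alleles
                    if ds.individuals[a.individual_id].population == p
                )
                assert sorted(seq for _lab, seq in block) == expected

    def test_empty_selection_is_error(self, tmp_path):
        ds = two_pop_dataset()
        spec = SelectionSpec("populations", ("north",))
        with pytest.raises(ExportError):
            export.write_migrate([], ds, spec, tmp_path / "m.txt")
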