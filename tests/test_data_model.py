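"""Marker manifests, pedigrees, genotype tables, haplotype round-trips."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mjdhap.families import (
    GenotypeError,
    PedigreeError,
    load_genotypes,
    load_pedigree,
)
from mjdhap.fixtures import load_fixture
from mjdhap.haplotypes import (
    HaplotypeError,
    SnpHaplotype,
    StrHaplotype,
    read_snp_haplotypes,
    read_str_haplotypes,
    write_haplotypes,
)
from mjdhap.markers import ManifestError, MarkerKind, load_marker_manifest

MANIFEST_HEADER = "marker_id\trs_id\tkind\toffset_kb\tdomain\n"


def write_manifest(tmp_path, rows):
    path = tmp_path / "panel.tsv"
    path.write_text(MANIFEST_HEADER + "".join(r + "\n" for r in rows))
    return path


class TestMarkerManifest:
    def test_default_panel_has_27_markers_with_anchor_in_place(self, panel):
        assert len(panel) == 27
        assert len(panel.snps()) == 20
        assert len(panel.strs()) == 7
        # the CAG repeat sits between the last upstream and first
        # downstream SNP of the published order
        assert panel.markers[panel.anchor_index - 1].marker_id == "rs10467856"
        assert panel.markers[panel.anchor_index].marker_id == "rs12895357"

    def test_markers_sorted_by_physical_offset(self, panel):
        offsets = [m.offset_kb for m in panel]
        assert offsets == sorted(offsets)

    def test_singleton_manifest(self, tmp_path):
        path = write_manifest(tmp_path, ["rs1\trs1\tSNP\t0.5\tA,G"])
        p = load_marker_manifest(path)
        assert len(p) == 1 and p.anchor_index == 0

    def test_duplicate_marker_rejected(self, tmp_path):
        path = write_manifest(
            tmp_path,
            ["rs12895357\trs12895357\tSNP\t0.1\tC,G",
             "rs12895357\trs12895357\tSNP\t0.2\tC,G"],
        )
        with pytest.raises(ManifestError, match="duplicate"):
            load_marker_manifest(path)

    @pytest.mark.parametrize(
        "row, match",
        [
            ("rs1\trs1\tINDEL\t0.1\tA,G", "unknown marker kind"),
            ("rs1\trs1\tSNP\tnear\tA,G", "unparseable offset"),
            ("rs1\trs1\tSNP\t0.1\tA,Z", "non-base"),
        ],
    )
    def test_malformed_rows_rejected(self, tmp_path, row, match):
        path = write_manifest(tmp_path, [row])
        with pytest.raises(ManifestError, match=match):
            load_marker_manifest(path)

    def test_expansion_pseudo_marker_sits_at_anchor(self, panel):
        work = panel.with_expansion()
        assert len(work) == 28
        pseudo = work.markers[work.anchor_index]
        assert pseudo.marker_id == "CAG_expansion"
        assert pseudo.allele_domain == frozenset({"E", "N"})


class TestPedigree:
    def test_trio_loads(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text(
            "f1 dad 0 0 1 1 0\nf1 mum 0 0 2 1 0\nf1 kid dad mum 1 2 1\n"
        )
        (ped,) = load_pedigree(path)
        assert len(ped) == 3
        assert ped["kid"].expansion_carrier.value == "yes"
        father, mother = ped.parents_of("kid")
        assert father.individual_id == "dad" and mother.individual_id == "mum"

    def test_homozygous_patient_family(self, tmp_path):
        # both parents carry one expansion, the patient two, plus a sister
        path = tmp_path / "fam.ped"
        path.write_text(
            "f9 dad 0 0 1 2 1\nf9 mum 0 0 2 2 1\n"
            "f9 patient dad mum 1 2 2\nf9 sister dad mum 2 1 0\n"
        )
        (ped,) = load_pedigree(path, study_mode=True)
        assert len(ped) == 4
        assert ped["patient"].expansion_count == 2
        assert ped.n_generations() == 2

    def test_self_parent_rejected(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text("f1 kid kid 0 1 1\n")
        with pytest.raises(PedigreeError, match="own parent"):
            load_pedigree(path)

    def test_cycle_rejected(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text("f1 a c 0 1 1\nf1 b a 0 1 1\nf1 c b 0 1 1\n")
        with pytest.raises(PedigreeError, match="cyclic"):
            load_pedigree(path)

    def test_undefined_parent_rejected(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text("f1 kid ghost 0 1 1\n")
        with pytest.raises(PedigreeError, match="not defined"):
            load_pedigree(path)

    def test_study_mode_requires_two_generations(self, tmp_path):
        path = tmp_path / "fam.ped"
        path.write_text("f1 a 0 0 1 1\nf1 b 0 0 2 1\nf1 c 0 0 1 1\nf1 d 0 0 2 1\n")
        with pytest.raises(PedigreeError, match="generations"):
            load_pedigree(path, study_mode=True)

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_cyclic_parent_graphs_always_rejected(self, tmp_path_factory, data):
        """Any parent assignment containing a directed cycle must fail."""
        n = data.draw(st.integers(min_value=2, max_value=6))
        ids = [f"i{k}" for k in range(n)]
        fathers = [
            data.draw(st.sampled_from(ids + ["0"]), label=f"father_{k}")
            for k in range(n)
        ]
        g = nx.DiGraph()
        g.add_nodes_from(ids)
        for child, father in zip(ids, fathers):
            if father != "0":
                g.add_edge(child, father)
        has_cycle = not nx.is_directed_acyclic_graph(g)
        self_parent = any(c == f for c, f in zip(ids, fathers))
        path = tmp_path_factory.mktemp("ped") / "fam.ped"
        path.write_text(
            "".join(f"f1 {c} {f} 0 1 1\n" for c, f in zip(ids, fathers))
        )
        if has_cycle or self_parent:
            with pytest.raises(PedigreeError):
                load_pedigree(path)
        else:
            (ped,) = load_pedigree(path)
            assert len(ped) == n


class TestGenotypeTable:
    def test_pair_missing_and_domain(self, tmp_path, panel):
        path = tmp_path / "geno.tsv"
        path.write_text(
            "individual_id\trs56268847\tTAT_223\n"
            "p1\tA/G\t10/12\n"
            "p2\t.\t.\n"
        )
        table = load_genotypes(path, panel)
        assert table.get("p1", "rs56268847") == ("A", "G")
        assert table.get("p1", "TAT_223") == (10, 12)
        assert table.get("p2", "rs56268847") is None

    @pytest.mark.parametrize(
        "header, cell, match",
        [
            ("rs56268847", "A/N", "outside domain"),
            ("TAT_223", "12/Z", "not an integer"),
            ("rs99999999", "A/G", "unknown marker column"),
        ],
    )
    def test_bad_cells_rejected(self, tmp_path, panel, header, cell, match):
        path = tmp_path / "geno.tsv"
        path.write_text(f"individual_id\t{header}\np1\t{cell}\n")
        with pytest.raises(GenotypeError, match=match):
            load_genotypes(path, panel)


class TestHaplotypeRoundTrip:
    def test_str_round_trip_identity(self, tmp_path, table4):
        haps = table4.haplotypes("D")
        path = tmp_path / "d.tsv"
        write_haplotypes(haps, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) - 1 == 8  # published lineage D size
        back = read_str_haplotypes(path)
        assert [h.repeats for h in back] == [h.repeats for h in haps]
        assert all(h.disease_flag for h in back)

    def test_snp_round_trip_identity(self, tmp_path, table1):
        haps = [
            SnpHaplotype(table1.haplotypes[lab], disease_flag=True,
                         source_family=lab)
            for lab in ("A", "B", "M")
        ]
        path = tmp_path / "snp.tsv"
        write_haplotypes(haps, path)
        back = read_snp_haplotypes(path)
        assert [h.alleles for h in back] == [h.alleles for h in haps]

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(HaplotypeError, match="empty"):
            write_haplotypes([], tmp_path / "x.tsv")

    def test_mixed_types_rejected(self, tmp_path):
        mixed = [
            StrHaplotype((10, 20, 10, 13, 7, 16, 15)),
            SnpHaplotype(("A", "C")),
        ]
        with pytest.raises(HaplotypeError, match="mix"):
            write_haplotypes(mixed, tmp_path / "x.tsv")


class TestFixtures:
    def test_lineage_sizes_match_publication(self, table4):
        assert {l: len(table4.haplotypes(l)) for l in "ABDG"} == {
            "A": 10, "B": 12, "D": 8, "G": 11,
        }

    def test_lineage_a_first_row(self, table4):
        first = table4.haplotypes("A")[0]
        assert first.repeats == (10, 20, 10, 13, 7, 16, 15)
        assert first.source_family == "Fam 10"

    def test_fam33_alternate_allele_kept_as_annotation(self, table4):
        fam33 = [h for h in table4.haplotypes("G") if h.source_family == "Fam 33"]
        assert len(fam33) == 1
        assert fam33[0].repeats[4] == 7  # primary value used in computation
        assert ("AAAC_alternate", "5") in fam33[0].annotations

    def test_fam1_listed_under_both_lineages(self, table4):
        rows = [r for r in table4.rows if r.family == "Fam 1"]
        assert sorted(r.lineage for r in rows) == ["A", "D"]
        assert len({r.row_id for r in rows}) == 2  # no deduplication

    def test_table1_shape_and_counts(self, table1):
        assert len(table1.labels) == 13
        assert sum(table1.n_families.values()) == 51
        assert table1.n_families["B"] == 12
        assert len(table1.joseph) == 20

    def test_table2_published_genotype_counts(self):
        table2 = load_fixture("table2")
        row = next(g for g in table2 if g.rs_id == "rs56268847" and g.group == "MJD")
        assert (row.n_hom_ref, row.n_het, row.n_hom_alt) == (46, 60, 3)
        assert row.n == 109

    def test_table3_row_count(self):
        assert len(load_fixture("table3")) == 22

    def test_unknown_fixture_rejected(self):
        with pytest.raises(KeyError, match="unknown fixture"):
            load_fixture("table9")
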