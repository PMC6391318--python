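import pytest

from mjdhap.families import GenotypeTable, Individual, Pedigree
from mjdhap.markers import MarkerDef, MarkerKind, MarkerPanel, default_panel


def make_snp_panel(specs):
    """Build a small SNP panel from (marker_id, offset_kb, alleles) tuples."""
    markers = tuple(
        MarkerDef(mid, None, MarkerKind.SNP, off, frozenset(alleles))
        for mid, off, alleles in sorted(specs, key=lambda s: s[1])
    )
    return MarkerPanel(markers, sum(1 for m in markers if m.offset_kb < 0))


def make_trio(fam="f1", child_expansion=0, father_expansion=0, mother_expansion=0):
    ped = Pedigree(fam)
    ped.add(Individual("dad", fam, sex="male", expansion_count=father_expansion))
    ped.add(Individual("mum", fam, sex="female", expansion_count=mother_expansion))
    ped.add(
        Individual(
            "kid", fam, father_id="dad", mother_id="mum",
            expansion_count=child_expansion,
        )
    )
    ped.validate()
    return ped


def fill_genotypes(panel, assignments):
    """assignments: {individual: {marker: (a, b) or None}} -> GenotypeTable."""
    table = GenotypeTable(panel)
    for iid, cells in assignments.items():
        for mid, pair in cells.items():
            table.set(iid, mid, pair)
    return table


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def table1():
    from mjdhap.fixtures import load_fixture

    return load_fixture("table1")


@pytest.fixture(scope="session")
def table4():
    from mjdhap.fixtures import load_fixture

    return load_fixture("table4")


@pytest.fixture
def two_snp_panel():
    return make_snp_panel([("s1", -1.0, "AG"), ("s2", 1.0, "TC")])
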