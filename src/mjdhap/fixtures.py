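"""Packaged transcriptions of the study's published data tables.

Four tables ship with the package as plain TSV:

* table1 — the 13 disease-associated 20-SNP haplotypes (columns A–M)
  with family counts, next to the Joseph reference lineage;
* table2 — genotype counts for four SNPs in patients and controls, with
  the published HWE / association p-values kept as annotations;
* table3 — six-SNP haplotype frequencies in control and disease
  chromosomes with the published δ and p columns;
* table4 — the 7-locus STR haplotypes of the families carrying the four
  major SNP lineages (A, B, D, G), with the published age estimates.

Known quirks of the source are preserved verbatim rather than
reconciled: "Fam 1" appears under both lineages A and D (distinct row
ids, no deduplication), and Fam 33's (AAAC)n entry "7 (5)" is stored as
primary value 7 with the 5 kept as an annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .haplotypes import StrHaplotype
from .stats import GenotypeCounts

__all__ = [
    "Table1",
    "Table4",
    "Table4Row",
    "load_fixture",
    "LINEAGE_SIZES",
]

#: published per-lineage family counts for the STR table
LINEAGE_SIZES = {"A": 10, "B": 12, "D": 8, "G": 11}


def _fixture_path(name: str):
    return resources.files("mjdhap") / "fixtures" / f"{name}.tsv"


@dataclass(frozen=True)
class Table1:
    """Disease SNP haplotypes (A–M) vs the Joseph reference."""

    snp_order: Tuple[str, ...]
    joseph: Tuple[str, ...]
    labels: Tuple[str, ...]
    n_families: Dict[str, int]
    haplotypes: Dict[str, Tuple[str, ...]]  # label -> 20-allele vector

    def joseph_allele(self, rs_id: str) -> str:
        return self.joseph[self.snp_order.index(rs_id)]


@dataclass(frozen=True)
class Table4Row:
    lineage: str
    row_id: str
    family: str
    haplotype: StrHaplotype


@dataclass(frozen=True)
class Table4:
    rows: Tuple[Table4Row, ...]
    printed_ages: Dict[str, Tuple[float, float]]  # lineage -> (mean, ±)

    def haplotypes(self, lineage: str) -> List[StrHaplotype]:
        if lineage not in LINEAGE_SIZES:
            raise KeyError(f"unknown lineage {lineage!r}")
        return [r.haplotype for r in self.rows if r.lineage == lineage]

    @property
    def lineages(self) -> Tuple[str, ...]:
        return tuple(sorted({r.lineage for r in self.rows}))


def _load_table1() -> Table1:
    with resources.as_file(_fixture_path("table1")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    labels = tuple(df.columns[2:])
    counts_row = df[df["rs_id"] == "n_families"].iloc[0]
    n_families = {lab: int(counts_row[lab]) for lab in labels}
    body = df[df["rs_id"] != "n_families"]
    snp_order = tuple(body["rs_id"])
    joseph = tuple(body["joseph"])
    haplotypes = {lab: tuple(body[lab]) for lab in labels}
    assert len(labels) == 13, "Table 1 must have 13 haplotype columns"
    assert len(snp_order) == 20
    return Table1(snp_order, joseph, labels, n_families, haplotypes)


def _load_table2() -> List[GenotypeCounts]:
    with resources.as_file(_fixture_path("table2")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    out: List[GenotypeCounts] = []
    for _, row in df.iterrows():
        out.append(
            GenotypeCounts(
                rs_id=row["rs_id"],
                group=row["group"],
                ref_allele=row["ref_allele"],
                alt_allele=row["alt_allele"],
                n_hom_ref=int(row["n_hom_ref"]),
                n_het=int(row["n_het"]),
                n_hom_alt=int(row["n_hom_alt"]),
                printed={
                    "hwe_p": row["hwe_p_printed"],
                    "ref_count": row["ref_count_printed"],
                    "ref_freq": row["ref_freq_printed"],
                    "alt_count": row["alt_count_printed"],
                    "alt_freq": row["alt_freq_printed"],
                    "allele_p": row["allele_p_printed"],
                },
            )
        )
    return out


def _load_table3() -> pd.DataFrame:
    with resources.as_file(_fixture_path("table3")) as path:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"haplotype": str, "delta_printed": str, "p_printed": str},
        )
    df["freq_control"] = df["freq_control"].astype(float)
    df["freq_mjd"] = df["freq_mjd"].astype(float)
    assert len(df) == 22, "Table 3 must have 22 haplotype rows"
    return df


def _load_table4() -> Table4:
    with resources.as_file(_fixture_path("table4")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    rows: List[Table4Row] = []
    ages: Dict[str, Tuple[float, float]] = {}
    for _, row in df.iterrows():
        repeats = tuple(
            int(row[c]) for c in ("TAT_223", "GT_199", "ATA_194", "AC_21", "AAAC", "GT", "AC_190")
        )
        annotations: Tuple[Tuple[str, str], ...] = ()
        if row["AAAC_note"] != ".":
            annotations = (("AAAC_alternate", row["AAAC_note"]),)
        rows.append(
            Table4Row(
                lineage=row["lineage"],
                row_id=row["row_id"],
                family=row["family"],
                haplotype=StrHaplotype(
                    repeats=repeats,
                    disease_flag=True,
                    source_family=row["family"],
                    annotations=annotations,
                ),
            )
        )
        ages[row["lineage"]] = (
            float(row["age_mean_printed"]),
            float(row["age_pm_printed"]),
        )
    table = Table4(tuple(rows), ages)
    for lineage, size in LINEAGE_SIZES.items():
        got = len(table.haplotypes(lineage))
        assert got == size, f"lineage {lineage}: expected {size} rows, got {got}"
    return table


_LOADERS = {
    "table1": _load_table1,
    "table2": _load_table2,
    "table3": _load_table3,
    "table4": _load_table4,
}


def load_fixture(name: str):
    """Return the packaged transcription of one published table."""
    try:
        loader = _LOADERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {sorted(_LOADERS)}"
        ) from None
    return loader()
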