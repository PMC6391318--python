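"""Marker panel: the SNPs and STRs flanking the ATXN3 (CAG)n repeat.

The panel is an ordered physical map.  Offsets are kilobases from the
(CAG)n anchor; negative offsets are upstream (centromeric side in the
default panel).  The anchor itself is not a genotyped marker — it is the
expanded CAG repeat whose linked alleles define the disease haplotype —
but phasing can represent it as a biallelic pseudo-marker (see
:meth:`MarkerPanel.with_expansion`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "MarkerKind",
    "MarkerDef",
    "MarkerPanel",
    "ManifestError",
    "load_marker_manifest",
    "default_panel",
    "EXPANSION_MARKER_ID",
    "EXPANSION_ALLELE",
    "NORMAL_ALLELE",
    "STR_LOCI",
    "CORE6_RS_IDS",
]

VALID_BASES = frozenset("ACGT")

#: STR loci in physical (= Table-layout) order; repeat-count vectors over
#: these seven loci are the unit of the founder-dating analysis.
STR_LOCI = ("TAT_223", "GT_199", "ATA_194", "AC_21", "AAAC", "GT", "AC_190")

#: The six "core" SNPs whose haplotype defines the two ancestral MJD
#: lineages (Joseph = T-T-A-C-A-C, Machado = G-T-G-G-C-A in this order).
CORE6_RS_IDS = (
    "rs12590497",
    "rs16999141",
    "rs1048755",
    "rs12895357",
    "rs7158733",
    "rs3092822",
)

EXPANSION_MARKER_ID = "CAG_expansion"
EXPANSION_ALLELE = "E"  # expanded (>51 CAG repeats)
NORMAL_ALLELE = "N"


class MarkerKind(str, Enum):
    SNP = "SNP"
    STR = "STR"


class ManifestError(ValueError):
    """Raised for malformed marker manifests."""


@dataclass(frozen=True)
class MarkerDef:
    """A single marker: a SNP (base alleles) or an STR (repeat counts)."""

    marker_id: str
    rs_id: Optional[str]
    kind: MarkerKind
    offset_kb: float
    allele_domain: Optional[frozenset] = None  # None for STR = any int >= 1

    def __post_init__(self):
        if self.kind is MarkerKind.SNP:
            if not self.allele_domain:
                raise ManifestError(f"SNP {self.marker_id} needs an allele domain")
            # the expansion pseudo-marker uses symbolic E/N alleles
            if self.marker_id != EXPANSION_MARKER_ID:
                bad = set(self.allele_domain) - VALID_BASES
                if bad:
                    raise ManifestError(
                        f"SNP {self.marker_id} has non-base alleles {sorted(bad)}"
                    )

    def allele_ok(self, allele: Union[str, int]) -> bool:
        if self.kind is MarkerKind.STR:
            return isinstance(allele, int) and allele >= 1
        return allele in self.allele_domain

    def parse_allele(self, token: str) -> Union[str, int]:
        """Parse one allele token from a genotype file cell."""
        if self.kind is MarkerKind.STR:
            try:
                value = int(token)
            except ValueError:
                raise ManifestError(
                    f"allele {token!r} at STR {self.marker_id} is not an integer"
                ) from None
            if value < 1:
                raise ManifestError(
                    f"allele {value} at STR {self.marker_id} must be >= 1"
                )
            return value
        if token not in self.allele_domain:
            raise ManifestError(
                f"allele {token!r} outside domain {sorted(self.allele_domain)} "
                f"of {self.marker_id}"
            )
        return token


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered marker catalogue with the (CAG)n anchor position.

    ``anchor_index`` is the number of markers physically upstream of the
    repeat: the anchor sits between ``markers[anchor_index - 1]`` and
    ``markers[anchor_index]``.
    """

    markers: tuple
    anchor_index: int

    def __post_init__(self):
        ids = [m.marker_id for m in self.markers]
        if len(ids) != len(set(ids)):
            raise ManifestError("duplicate marker_id in panel")
        offs = [m.offset_kb for m in self.markers]
        if offs != sorted(offs):
            raise ManifestError("panel markers are not in physical order")

    def __len__(self):
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def marker_ids(self) -> tuple:
        return tuple(m.marker_id for m in self.markers)

    def snps(self) -> tuple:
        return tuple(m for m in self.markers if m.kind is MarkerKind.SNP)

    def strs(self) -> tuple:
        return tuple(m for m in self.markers if m.kind is MarkerKind.STR)

    def get(self, marker_id: str) -> MarkerDef:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def __contains__(self, marker_id: str) -> bool:
        return any(m.marker_id == marker_id for m in self.markers)

    def subset(self, marker_ids: Iterable[str]) -> "MarkerPanel":
        """Panel restricted to the given markers (panel order preserved)."""
        wanted = set(marker_ids)
        kept = tuple(m for m in self.markers if m.marker_id in wanted)
        anchor = sum(1 for m in kept if m.offset_kb < 0)
        return MarkerPanel(kept, anchor)

    def with_expansion(self) -> "MarkerPanel":
        """Panel with the expansion modeled as a biallelic pseudo-marker.

        Placed at offset 0, i.e. exactly at the anchor, so "in phase with
        the expansion" becomes an ordinary phase query on this marker.
        """
        if EXPANSION_MARKER_ID in self:
            return self
        pseudo = MarkerDef(
            EXPANSION_MARKER_ID,
            None,
            MarkerKind.SNP,
            0.0,
            frozenset({EXPANSION_ALLELE, NORMAL_ALLELE}),
        )
        markers = (
            self.markers[: self.anchor_index]
            + (pseudo,)
            + self.markers[self.anchor_index :]
        )
        return MarkerPanel(markers, self.anchor_index)


def _parse_domain(token: str, kind: MarkerKind, marker_id: str):
    if kind is MarkerKind.STR:
        if token not in ("1+", "."):
            raise ManifestError(f"STR {marker_id}: unexpected domain {token!r}")
        return None
    alleles = frozenset(a.strip() for a in token.split(",") if a.strip())
    if not alleles:
        raise ManifestError(f"SNP {marker_id}: empty allele domain")
    return alleles


def load_marker_manifest(path: Union[str, Path]) -> MarkerPanel:
    """Read a tab-separated marker manifest into an ordered panel.

    Columns: marker_id, rs_id, kind, offset_kb, domain.  Markers are
    sorted by offset; the anchor index is the count of negative offsets.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["marker_id", "rs_id", "kind", "offset_kb", "domain"]
        if header != expected:
            raise ManifestError(f"bad manifest header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ManifestError(f"{path.name}:{lineno}: expected 5 columns")
            marker_id, rs_id, kind_s, offset_s, domain_s = parts
            try:
                kind = MarkerKind(kind_s)
            except ValueError:
                raise ManifestError(
                    f"{path.name}:{lineno}: unknown marker kind {kind_s!r}"
                ) from None
            try:
                offset = float(offset_s)
            except ValueError:
                raise ManifestError(
                    f"{path.name}:{lineno}: unparseable offset {offset_s!r}"
                ) from None
            rows.append(
                MarkerDef(
                    marker_id,
                    None if rs_id == "." else rs_id,
                    kind,
                    offset,
                    _parse_domain(domain_s, kind, marker_id),
                )
            )
    ids = [m.marker_id for m in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ManifestError(f"duplicate marker_id(s): {sorted(dupes)}")
    rows.sort(key=lambda m: m.offset_kb)
    anchor = sum(1 for m in rows if m.offset_kb < 0)
    return MarkerPanel(tuple(rows), anchor)


def default_panel() -> MarkerPanel:
    """The shipped 27-marker panel (20 SNPs + 7 STRs) around ATXN3."""
    ref = resources.files("mjdhap") / "fixtures" / "marker_manifest.tsv"
    with resources.as_file(ref) as path:
        return load_marker_manifest(path)
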