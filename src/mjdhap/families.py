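"""Pedigrees and unphased genotype tables — the pipeline's raw input.

Pedigree files follow the standard 6-column PED layout (family,
individual, father, mother, sex, affection) with an optional seventh
column giving the number of expanded CAG alleles carried (0, 1, or 2;
a patient homozygous for the expansion has 2).  Genotype tables are
tab-separated matrices: rows are individuals, columns markers, cells
``a/b`` (unordered) or ``.`` for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from .markers import MarkerPanel

__all__ = [
    "Sex",
    "Affection",
    "Carrier",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "GenotypeError",
    "GenotypeTable",
    "load_pedigree",
    "load_genotypes",
    "write_pedigree",
    "write_genotypes",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Carrier(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class PedigreeError(ValueError):
    pass


class GenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    expansion_count: Optional[int] = None  # None = unknown

    def __post_init__(self):
        # accept plain strings for the enum fields
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "affected", Affection(self.affected))
        if self.expansion_count is not None and self.expansion_count not in (0, 1, 2):
            raise PedigreeError(
                f"{self.individual_id}: expansion_count must be 0, 1 or 2"
            )

    @property
    def expansion_carrier(self) -> Carrier:
        if self.expansion_count is None:
            return Carrier.UNKNOWN
        return Carrier.YES if self.expansion_count >= 1 else Carrier.NO


@dataclass
class Pedigree:
    """One family: individuals keyed by id, with referential integrity."""

    family_id: str
    individuals: Dict[str, Individual] = field(default_factory=dict)

    def add(self, ind: Individual) -> None:
        if ind.individual_id in self.individuals:
            raise PedigreeError(f"duplicate individual {ind.individual_id}")
        self.individuals[ind.individual_id] = ind

    def __len__(self):
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[individual_id]

    def parents_of(self, individual_id: str) -> Tuple[Optional[Individual], Optional[Individual]]:
        ind = self.individuals[individual_id]
        father = self.individuals.get(ind.father_id) if ind.father_id else None
        mother = self.individuals.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def children_of(self, individual_id: str) -> List[Individual]:
        return [
            i
            for i in self.individuals.values()
            if individual_id in (i.father_id, i.mother_id)
        ]

    def founders(self) -> List[Individual]:
        return [
            i
            for i in self.individuals.values()
            if i.father_id is None and i.mother_id is None
        ]

    def carriers(self) -> List[Individual]:
        return [i for i in self.individuals.values() if i.expansion_carrier is Carrier.YES]

    def n_generations(self) -> int:
        depth: Dict[str, int] = {}

        def d(iid: str) -> int:
            if iid in depth:
                return depth[iid]
            ind = self.individuals[iid]
            parents = [p for p in (ind.father_id, ind.mother_id) if p in self.individuals]
            depth[iid] = 1 + (max(d(p) for p in parents) if parents else 0)
            return depth[iid]

        return max((d(i) for i in self.individuals), default=0)

    def validate(self, study_mode: bool = False) -> None:
        """Check referential integrity and acyclicity.

        ``study_mode`` additionally enforces the cohort's inclusion
        criteria: at least two generations and at least four members.
        """
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.individuals:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {pid!r} of "
                        f"{ind.individual_id} is not defined"
                    )
        # cycle check: iterative DFS over parent links
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {iid: WHITE for iid in self.individuals}

        def visit(start: str) -> None:
            stack = [(start, iter(self._parent_ids(start)))]
            color[start] = GRAY
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if color[p] == GRAY:
                        raise PedigreeError(
                            f"family {self.family_id}: cyclic parentage through {p!r}"
                        )
                    if color[p] == WHITE:
                        color[p] = GRAY
                        stack.append((p, iter(self._parent_ids(p))))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

        for iid in self.individuals:
            if color[iid] == WHITE:
                visit(iid)
        if study_mode:
            if len(self) < 4:
                raise PedigreeError(
                    f"family {self.family_id}: fewer than 4 members"
                )
            if self.n_generations() < 2:
                raise PedigreeError(
                    f"family {self.family_id}: fewer than 2 generations"
                )

    def _parent_ids(self, iid: str) -> List[str]:
        ind = self.individuals[iid]
        return [p for p in (ind.father_id, ind.mother_id) if p in self.individuals]


_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_AFF = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN,
        "-9": Affection.UNKNOWN}


def load_pedigree(path: Union[str, Path], study_mode: bool = False) -> List[Pedigree]:
    """Load a PED-like file into one :class:`Pedigree` per family."""
    path = Path(path)
    peds: Dict[str, Pedigree] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (6, 7):
                raise PedigreeError(f"{path.name}:{lineno}: expected 6 or 7 columns")
            fam, iid, fid, mid, sex_s, aff_s = parts[:6]
            exp: Optional[int] = None
            if len(parts) == 7 and parts[6] != ".":
                try:
                    exp = int(parts[6])
                except ValueError:
                    raise PedigreeError(
                        f"{path.name}:{lineno}: bad expansion_count {parts[6]!r}"
                    ) from None
            if iid in (fid, mid):
                raise PedigreeError(
                    f"{path.name}:{lineno}: {iid} listed as its own parent"
                )
            ind = Individual(
                individual_id=iid,
                family_id=fam,
                father_id=None if fid in ("0", ".") else fid,
                mother_id=None if mid in ("0", ".") else mid,
                sex=_SEX.get(sex_s, Sex.UNKNOWN),
                affected=_AFF.get(aff_s, Affection.UNKNOWN),
                expansion_count=exp,
            )
            peds.setdefault(fam, Pedigree(fam)).add(ind)
    for ped in peds.values():
        ped.validate(study_mode=study_mode)
    return list(peds.values())


Allele = Union[str, int]
GenotypePair = Tuple[Allele, Allele]


@dataclass
class GenotypeTable:
    """Unordered allele pairs per (individual, marker); missing is explicit."""

    panel: MarkerPanel
    entries: Dict[Tuple[str, str], Optional[GenotypePair]] = field(default_factory=dict)

    def set(self, individual_id: str, marker_id: str,
            pair: Optional[GenotypePair]) -> None:
        marker = self.panel.get(marker_id)
        if pair is not None:
            for allele in pair:
                if not marker.allele_ok(allele):
                    raise GenotypeError(
                        f"{individual_id}@{marker_id}: allele {allele!r} "
                        f"outside marker domain"
                    )
            pair = tuple(sorted(pair, key=str))  # unordered canonical form
        self.entries[(individual_id, marker_id)] = pair

    def get(self, individual_id: str, marker_id: str) -> Optional[GenotypePair]:
        return self.entries.get((individual_id, marker_id))

    def individuals(self) -> List[str]:
        seen: Dict[str, None] = {}
        for iid, _ in self.entries:
            seen.setdefault(iid)
        return list(seen)

    def markers_typed(self) -> List[str]:
        seen: Dict[str, None] = {}
        for _, mid in self.entries:
            seen.setdefault(mid)
        return list(seen)


def load_genotypes(path: Union[str, Path], panel: MarkerPanel) -> GenotypeTable:
    """Read a genotype TSV (rows = individuals, columns = markers)."""
    path = Path(path)
    table = GenotypeTable(panel)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] not in ("individual_id", "id"):
            raise GenotypeError(f"{path.name}: first header column must be individual_id")
        marker_ids = header[1:]
        for mid in marker_ids:
            if mid not in panel:
                raise GenotypeError(f"{path.name}: unknown marker column {mid!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeError(f"{path.name}:{lineno}: ragged row")
            iid = parts[0]
            for mid, cell in zip(marker_ids, parts[1:]):
                cell = cell.strip()
                if cell in (".", ""):
                    table.set(iid, mid, None)
                    continue
                if "/" not in cell:
                    raise GenotypeError(
                        f"{path.name}:{lineno}: cell {cell!r} is not 'a/b' or '.'"
                    )
                a_s, b_s = cell.split("/", 1)
                marker = panel.get(mid)
                try:
                    pair = (marker.parse_allele(a_s), marker.parse_allele(b_s))
                except Exception as exc:
                    raise GenotypeError(f"{path.name}:{lineno}: {exc}") from None
                table.set(iid, mid, pair)
    return table


_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_OUT = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}


def write_pedigree(pedigrees, path: Union[str, Path]) -> None:
    """Write pedigrees in the 7-column PED-like dialect read back by
    :func:`load_pedigree`."""
    path = Path(path)
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
    with path.open("w") as fh:
        for ped in pedigrees:
            for ind in ped:
                exp = "." if ind.expansion_count is None else str(ind.expansion_count)
                fh.write(
                    f"{ind.family_id} {ind.individual_id} "
                    f"{ind.father_id or '0'} {ind.mother_id or '0'} "
                    f"{_SEX_OUT[ind.sex]} {_AFF_OUT[ind.affected]} {exp}\n"
                )


def write_genotypes(table: GenotypeTable, path: Union[str, Path]) -> None:
    """Write a genotype table in the TSV dialect read by :func:`load_genotypes`."""
    path = Path(path)
    marker_ids = [m for m in table.panel.marker_ids if m in set(table.markers_typed())]
    with path.open("w") as fh:
        fh.write("individual_id\t" + "\t".join(marker_ids) + "\n")
        for iid in table.individuals():
            cells = []
            for mid in marker_ids:
                g = table.get(iid, mid)
                cells.append("." if g is None else f"{g[0]}/{g[1]}")
            fh.write(iid + "\t" + "\t".join(cells) + "\n")
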