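"""Phased haplotype containers and their TSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple, Union

from .markers import STR_LOCI

__all__ = [
    "SnpHaplotype",
    "StrHaplotype",
    "HaplotypeError",
    "write_haplotypes",
    "read_snp_haplotypes",
    "read_str_haplotypes",
]


class HaplotypeError(ValueError):
    pass


@dataclass(frozen=True)
class SnpHaplotype:
    """Phased allele vector over a SNP panel.

    ``disease_flag`` marks the haplotype as in phase with the CAG
    expansion.  ``inference`` records how phase was obtained.
    """

    alleles: Tuple[str, ...]
    disease_flag: bool = False
    source_family: str = ""
    inference: str = "fixture"  # segregation | em | fixture

    def __post_init__(self):
        if not self.alleles:
            raise HaplotypeError("empty SNP haplotype")

    def __len__(self):
        return len(self.alleles)


@dataclass(frozen=True)
class StrHaplotype:
    """Repeat-count vector over the seven flanking STR loci."""

    repeats: Tuple[int, ...]
    disease_flag: bool = False
    source_family: str = ""
    annotations: Tuple[Tuple[str, str], ...] = ()  # e.g. alternate allele notes

    def __post_init__(self):
        if len(self.repeats) != len(STR_LOCI):
            raise HaplotypeError(
                f"STR haplotype must cover {len(STR_LOCI)} loci, got {len(self.repeats)}"
            )
        if any((not isinstance(r, int)) or r < 1 for r in self.repeats):
            raise HaplotypeError("STR repeat counts must be integers >= 1")

    def __len__(self):
        return len(self.repeats)


def write_haplotypes(
    haps: Sequence[Union[SnpHaplotype, StrHaplotype]], path: Union[str, Path]
) -> None:
    """Write haplotypes as TSV; round-trips through the matching reader."""
    if not haps:
        raise HaplotypeError("refusing to write an empty haplotype list")
    kinds = {type(h) for h in haps}
    if len(kinds) > 1:
        raise HaplotypeError("cannot mix SNP and STR haplotypes in one file")
    lengths = {len(h) for h in haps}
    if len(lengths) > 1:
        raise HaplotypeError("haplotypes of differing length (mixed panels?)")
    path = Path(path)
    is_str = isinstance(haps[0], StrHaplotype)
    with path.open("w") as fh:
        if is_str:
            fh.write("family\tdisease_flag\t" + "\t".join(STR_LOCI) + "\n")
            for h in haps:
                fh.write(
                    f"{h.source_family}\t{int(h.disease_flag)}\t"
                    + "\t".join(str(r) for r in h.repeats)
                    + "\n"
                )
        else:
            cols = [f"snp{i+1}" for i in range(len(haps[0]))]
            fh.write("family\tdisease_flag\tinference\t" + "\t".join(cols) + "\n")
            for h in haps:
                fh.write(
                    f"{h.source_family}\t{int(h.disease_flag)}\t{h.inference}\t"
                    + "\t".join(h.alleles)
                    + "\n"
                )


def read_str_haplotypes(path: Union[str, Path]) -> List[StrHaplotype]:
    path = Path(path)
    out: List[StrHaplotype] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["family", "disease_flag"] or tuple(header[2:]) != STR_LOCI:
            raise HaplotypeError(f"{path.name}: not an STR haplotype file")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                StrHaplotype(
                    repeats=tuple(int(x) for x in parts[2:]),
                    disease_flag=bool(int(parts[1])),
                    source_family=parts[0],
                )
            )
    return out


def read_snp_haplotypes(path: Union[str, Path]) -> List[SnpHaplotype]:
    path = Path(path)
    out: List[SnpHaplotype] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["family", "disease_flag", "inference"]:
            raise HaplotypeError(f"{path.name}: not a SNP haplotype file")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                SnpHaplotype(
                    alleles=tuple(parts[3:]),
                    disease_flag=bool(int(parts[1])),
                    source_family=parts[0],
                    inference=parts[2],
                )
            )
    return out
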