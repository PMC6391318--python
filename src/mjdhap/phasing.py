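"""Haplotype phasing by Mendelian segregation, with an EM estimator.

Segregation phasing fixes an allele's parental origin wherever
transmission forces it: a homozygous child, a homozygous parent, or a
child allele traceable to exactly one parent.  Everything else is
flagged ambiguous, never guessed.  The CAG expansion is modeled as a
biallelic pseudo-marker (E/N) at the anchor, derived from each
individual's expansion count, so "in phase with the expansion" is an
ordinary phase query rather than special-cased logic.

For unrelated individuals an expectation-maximization estimator of
population haplotype frequencies provides statistical phase (the
study-design stand-in for coalescent-prior Gibbs samplers).  Phased
pairs whose posterior does not exceed the retention threshold (strict
inequality, default 0.6) are excluded from downstream haplotype lists.

Mendelian inconsistencies abort the family's phasing with a located
report — curated clinical pedigrees are assumed, so no error-correction
heuristics are attempted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .families import Carrier, GenotypeTable, Pedigree
from .haplotypes import SnpHaplotype, StrHaplotype
from .markers import (
    EXPANSION_ALLELE,
    EXPANSION_MARKER_ID,
    MarkerPanel,
    NORMAL_ALLELE,
)

__all__ = [
    "PhasingConfig",
    "PhasedPair",
    "MendelianError",
    "PhasingError",
    "InconsistentSegregationError",
    "SegregationResult",
    "phase_by_segregation",
    "FamilyDiseaseHaplotypes",
    "disease_haplotype_for_family",
    "EMResult",
    "em_haplotype_frequencies",
]


class PhasingError(ValueError):
    pass


class InconsistentSegregationError(PhasingError):
    """Carriers of one family disagree on the co-segregating haplotype."""


@dataclass(frozen=True)
class PhasingConfig:
    posterior_threshold: float = 0.6
    em_max_iterations: int = 1000
    em_tolerance: float = 1e-8
    seed: int = 0
    max_pairs_per_individual: int = 65536

    def __post_init__(self):
        if not (0.0 < self.posterior_threshold <= 1.0):
            raise PhasingError("posterior_threshold must lie in (0, 1]")
        if self.em_tolerance <= 0:
            raise PhasingError("em_tolerance must be positive")


@dataclass(frozen=True)
class MendelianError:
    individual_id: str
    marker_id: str
    detail: str


@dataclass
class PhasedPair:
    """Phase of one individual: haplotype_a / haplotype_b allele vectors.

    For segregation-phased children, side "a" is paternal and "b"
    maternal.  Unresolved markers hold ``None``.  ``disease_side``
    records which side carries the expansion ("both" only for an
    expansion homozygote, "none" for non-carriers).
    """

    individual_id: str
    haplotype_a: Tuple
    haplotype_b: Tuple
    posterior: float
    method: str  # segregation | em
    disease_side: str = "unknown"  # a | b | both | none | unknown
    ambiguous_markers: Tuple[str, ...] = ()
    family_id: str = ""


@dataclass
class SegregationResult:
    pairs: Dict[str, PhasedPair]
    errors: List[MendelianError]
    panel: MarkerPanel  # working panel (includes the expansion pseudo-marker)


def _expansion_genotype(ind) -> Optional[Tuple[str, str]]:
    if ind.expansion_count is None:
        return None
    return {
        0: (NORMAL_ALLELE, NORMAL_ALLELE),
        1: (EXPANSION_ALLELE, NORMAL_ALLELE),
        2: (EXPANSION_ALLELE, EXPANSION_ALLELE),
    }[ind.expansion_count]


def phase_by_segregation(
    pedigree: Pedigree,
    genotypes: GenotypeTable,
    panel: MarkerPanel,
    include_expansion: bool = True,
) -> SegregationResult:
    """Resolve phase per family member wherever transmission forces it."""
    work = panel.with_expansion() if include_expansion else panel
    marker_ids = work.marker_ids

    def geno(ind, marker_id):
        if marker_id == EXPANSION_MARKER_ID:
            return _expansion_genotype(ind)
        return genotypes.get(ind.individual_id, marker_id)

    pairs: Dict[str, PhasedPair] = {}
    errors: List[MendelianError] = []

    # pass 1: children (anyone with a parent in the pedigree)
    for ind in pedigree:
        father, mother = pedigree.parents_of(ind.individual_id)
        if father is None and mother is None:
            continue
        hap_a: List = []
        hap_b: List = []
        ambiguous: List[str] = []
        for mid in marker_ids:
            g = geno(ind, mid)
            if g is None:
                hap_a.append(None)
                hap_b.append(None)
                continue
            a, b = g
            fg = geno(father, mid) if father else None
            mg = geno(mother, mid) if mother else None
            if a == b:
                ok_f = fg is None or a in fg
                ok_m = mg is None or a in mg
                if not (ok_f and ok_m):
                    errors.append(
                        MendelianError(
                            ind.individual_id, mid,
                            f"homozygous {a}/{a} but allele absent from a parent",
                        )
                    )
                    hap_a.append(None)
                    hap_b.append(None)
                    continue
                hap_a.append(a)
                hap_b.append(a)
                continue
            opt_ab = (fg is None or a in fg) and (mg is None or b in mg)
            opt_ba = (fg is None or b in fg) and (mg is None or a in mg)
            if opt_ab and not opt_ba:
                hap_a.append(a)
                hap_b.append(b)
            elif opt_ba and not opt_ab:
                hap_a.append(b)
                hap_b.append(a)
            elif not opt_ab and not opt_ba:
                errors.append(
                    MendelianError(
                        ind.individual_id, mid,
                        f"alleles {a}/{b} incompatible with parental genotypes",
                    )
                )
                hap_a.append(None)
                hap_b.append(None)
            else:
                ambiguous.append(mid)
                hap_a.append(None)
                hap_b.append(None)
        pairs[ind.individual_id] = PhasedPair(
            individual_id=ind.individual_id,
            haplotype_a=tuple(hap_a),
            haplotype_b=tuple(hap_b),
            posterior=1.0,
            method="segregation",
            disease_side=_disease_side(ind, hap_a, hap_b, marker_ids),
            ambiguous_markers=tuple(ambiguous),
            family_id=pedigree.family_id,
        )

    # pass 2: founders, anchored through transmissions to phased children
    for ind in pedigree:
        if ind.individual_id in pairs:
            continue
        hap_a: List = [None] * len(marker_ids)  # side "a" = disease side
        hap_b: List = [None] * len(marker_ids)
        ambiguous: List[str] = []
        children = pedigree.children_of(ind.individual_id)
        # disease-side alleles: what this founder transmitted to a child
        # who received the expansion from them
        donor_side_alleles: Dict[str, Set] = {}
        if ind.expansion_carrier is Carrier.YES:
            for child in children:
                cp = pairs.get(child.individual_id)
                if cp is None:
                    continue
                side = 0 if child.father_id == ind.individual_id else 1
                child_hap = cp.haplotype_a if side == 0 else cp.haplotype_b
                k_exp = marker_ids.index(EXPANSION_MARKER_ID) if EXPANSION_MARKER_ID in marker_ids else None
                if k_exp is None or child_hap[k_exp] != EXPANSION_ALLELE:
                    continue
                for mid, allele in zip(marker_ids, child_hap):
                    if allele is not None:
                        donor_side_alleles.setdefault(mid, set()).add(allele)
        for k, mid in enumerate(marker_ids):
            g = geno(ind, mid)
            if g is None:
                continue
            a, b = g
            if a == b:
                hap_a[k] = a
                hap_b[k] = a
                continue
            transmitted = donor_side_alleles.get(mid)
            if transmitted and len(transmitted) == 1:
                t = next(iter(transmitted))
                if t in (a, b):
                    hap_a[k] = t
                    hap_b[k] = b if t == a else a
                    continue
                errors.append(
                    MendelianError(
                        ind.individual_id, mid,
                        f"transmitted allele {t!r} absent from genotype {a}/{b}",
                    )
                )
                continue
            ambiguous.append(mid)
        pairs[ind.individual_id] = PhasedPair(
            individual_id=ind.individual_id,
            haplotype_a=tuple(hap_a),
            haplotype_b=tuple(hap_b),
            posterior=1.0,
            method="segregation",
            disease_side=_disease_side(ind, hap_a, hap_b, marker_ids),
            ambiguous_markers=tuple(ambiguous),
            family_id=pedigree.family_id,
        )
    return SegregationResult(pairs, errors, work)


def _disease_side(ind, hap_a, hap_b, marker_ids) -> str:
    if ind.expansion_count == 2:
        return "both"
    if ind.expansion_count == 0:
        return "none"
    if EXPANSION_MARKER_ID not in marker_ids:
        return "unknown"
    k = marker_ids.index(EXPANSION_MARKER_ID)
    if hap_a[k] == EXPANSION_ALLELE:
        return "a"
    if hap_b[k] == EXPANSION_ALLELE:
        return "b"
    return "unknown"


@dataclass
class FamilyDiseaseHaplotypes:
    """Disease haplotype(s) co-transmitted with the expansion in a family."""

    family_id: str
    snp_haplotypes: List[SnpHaplotype]
    str_haplotypes: List[StrHaplotype]
    full_vectors: List[Tuple]  # over the non-pseudo markers of the panel
    warnings: List[str] = field(default_factory=list)


def _merge_vectors(vectors: Sequence[Tuple], marker_ids, family_id) -> Tuple:
    merged: List = [None] * len(marker_ids)
    for vec in vectors:
        for k, allele in enumerate(vec):
            if allele is None:
                continue
            if merged[k] is None:
                merged[k] = allele
            elif merged[k] != allele:
                raise InconsistentSegregationError(
                    f"family {family_id}: carriers disagree at {marker_ids[k]} "
                    f"({merged[k]!r} vs {allele!r}); possible recombination — "
                    "family excluded"
                )
    return tuple(merged)


def disease_haplotype_for_family(
    result: SegregationResult, pedigree: Pedigree
) -> FamilyDiseaseHaplotypes:
    """Extract the haplotype(s) segregating with the expansion.

    All single-copy carriers must agree at jointly resolved markers;
    disagreement (intra-family recombination or genotyping error)
    raises :class:`InconsistentSegregationError`.  A family with an
    expansion homozygote yields two disease haplotypes: the patient's
    paternal and maternal sides, each merged with the matching parent's
    transmitted haplotype.
    """
    marker_ids = result.panel.marker_ids
    warnings: List[str] = []

    def side_vec(pair: PhasedPair, side: str) -> Tuple:
        return pair.haplotype_a if side == "a" else pair.haplotype_b

    carriers = pedigree.carriers()
    if not any(c.individual_id in result.pairs for c in carriers):
        raise PhasingError(f"family {pedigree.family_id}: no phased carrier")

    homozygotes = [c for c in carriers if c.expansion_count == 2]
    vectors: List[Tuple]
    if homozygotes:
        patient = homozygotes[0]
        pair = result.pairs[patient.individual_id]
        father, mother = pedigree.parents_of(patient.individual_id)
        sides = []
        for side, parent in (("a", father), ("b", mother)):
            group = [side_vec(pair, side)]
            if parent is not None and parent.expansion_count == 1:
                ppair = result.pairs.get(parent.individual_id)
                if ppair is not None and ppair.disease_side in ("a", "b"):
                    group.append(side_vec(ppair, ppair.disease_side))
            sides.append(_merge_vectors(group, marker_ids, pedigree.family_id))
        vectors = sides
        if len(homozygotes) > 1:
            warnings.append("multiple expansion homozygotes; using the first")
    else:
        group = []
        for c in carriers:
            pair = result.pairs.get(c.individual_id)
            if pair is None:
                continue
            if pair.disease_side not in ("a", "b"):
                warnings.append(
                    f"{c.individual_id}: disease phase unresolved, skipped"
                )
                continue
            group.append(side_vec(pair, pair.disease_side))
        if not group:
            raise PhasingError(
                f"family {pedigree.family_id}: no carrier with resolved "
                "disease phase"
            )
        vectors = [_merge_vectors(group, marker_ids, pedigree.family_id)]

    snp_ids = [m.marker_id for m in result.panel.snps()
               if m.marker_id != EXPANSION_MARKER_ID]
    str_ids = [m.marker_id for m in result.panel.strs()]
    keep_ids = [m.marker_id for m in result.panel
                if m.marker_id != EXPANSION_MARKER_ID]
    snp_haps: List[SnpHaplotype] = []
    str_haps: List[StrHaplotype] = []
    full: List[Tuple] = []
    for vec in vectors:
        by_id = dict(zip(marker_ids, vec))
        full.append(tuple(by_id[m] for m in keep_ids))
        snp_vec = tuple(by_id[m] for m in snp_ids)
        if snp_ids and all(a is not None for a in snp_vec):
            snp_haps.append(
                SnpHaplotype(snp_vec, disease_flag=True,
                             source_family=pedigree.family_id,
                             inference="segregation")
            )
        elif snp_ids:
            warnings.append("SNP disease haplotype incomplete")
        str_vec = tuple(by_id[m] for m in str_ids)
        if len(str_ids) == 7 and all(r is not None for r in str_vec):
            str_haps.append(
                StrHaplotype(str_vec, disease_flag=True,
                             source_family=pedigree.family_id)
            )
        elif str_ids:
            warnings.append("STR disease haplotype incomplete")
    return FamilyDiseaseHaplotypes(
        pedigree.family_id, snp_haps, str_haps, full, warnings
    )


# ---------------------------------------------------------------------------
# EM haplotype-frequency estimation for unrelated individuals


@dataclass
class EMResult:
    frequencies: Dict[Tuple, float]
    pairs: Dict[str, List[Tuple[Tuple, Tuple, float]]]  # iid -> (h1, h2, post)
    retained: Dict[str, Optional[Tuple[Tuple, Tuple, float]]]
    log_likelihoods: List[float]
    n_iterations: int
    converged: bool


def _marker_options(g, candidates) -> List[Tuple]:
    if g is None:
        return [(x, y) for x in candidates for y in candidates]
    a, b = g
    if a == b:
        return [(a, a)]
    return [(a, b), (b, a)]


def em_haplotype_frequencies(
    genotypes: GenotypeTable,
    panel: MarkerPanel,
    config: PhasingConfig = PhasingConfig(),
    individual_ids: Optional[Sequence[str]] = None,
) -> EMResult:
    """EM estimate of haplotype frequencies from unphased genotypes.

    Individuals are assumed unrelated; pair weights use Hardy-Weinberg
    priors (2 f_i f_j for heterozygous pairs).  Missing genotypes are
    marginalized over the alleles observed at that marker.  The
    algorithm is deterministic: equal initial frequencies over all
    observation-compatible haplotypes, no random restarts.
    """
    marker_ids = [m for m in panel.marker_ids if m in genotypes.markers_typed()]
    if not marker_ids:
        raise PhasingError("no typed markers")
    iids = list(individual_ids) if individual_ids else genotypes.individuals()
    if not iids:
        raise PhasingError("no individuals")

    observed_alleles: Dict[str, Set] = {m: set() for m in marker_ids}
    for iid in iids:
        for m in marker_ids:
            g = genotypes.get(iid, m)
            if g is not None:
                observed_alleles[m].update(g)
    for m in marker_ids:
        if not observed_alleles[m]:
            marker = panel.get(m)
            if marker.allele_domain is None:
                raise PhasingError(f"marker {m}: no observed alleles to impute from")
            observed_alleles[m] = set(marker.allele_domain)

    # enumerate compatible unordered haplotype pairs per individual
    person_pairs: Dict[str, List[Tuple[Tuple, Tuple]]] = {}
    for iid in iids:
        options = [
            _marker_options(genotypes.get(iid, m), sorted(observed_alleles[m], key=str))
            for m in marker_ids
        ]
        n_comb = math.prod(len(o) for o in options)
        if n_comb > config.max_pairs_per_individual:
            raise PhasingError(
                f"{iid}: {n_comb} compatible completions exceed the cap; "
                "too much missingness/heterozygosity for exhaustive EM"
            )
        seen = set()
        pairs = []
        for combo in itertools.product(*options):
            h1 = tuple(x for x, _ in combo)
            h2 = tuple(y for _, y in combo)
            key = (h1, h2) if h1 <= h2 else (h2, h1)
            if key not in seen:
                seen.add(key)
                pairs.append(key)
        if not pairs:
            raise PhasingError(f"{iid}: no compatible haplotype pair")
        person_pairs[iid] = pairs

    universe = sorted({h for prs in person_pairs.values() for pair in prs for h in pair})
    freq = {h: 1.0 / len(universe) for h in universe}

    def pair_weight(h1, h2):
        w = freq[h1] * freq[h2]
        return 2.0 * w if h1 != h2 else w

    n = len(iids)
    logliks: List[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, config.em_max_iterations + 1):
        counts = {h: 0.0 for h in universe}
        ll = 0.0
        for iid in iids:
            weights = [pair_weight(h1, h2) for h1, h2 in person_pairs[iid]]
            total = sum(weights)
            if total <= 0.0:
                raise PhasingError(f"{iid}: zero likelihood (corrupt data)")
            ll += math.log(total)
            for (h1, h2), w in zip(person_pairs[iid], weights):
                post = w / total
                counts[h1] += post
                counts[h2] += post
        freq = {h: c / (2.0 * n) for h, c in counts.items()}
        logliks.append(ll)
        if len(logliks) >= 2 and abs(logliks[-1] - logliks[-2]) < config.em_tolerance:
            converged = True
            break

    pairs_out: Dict[str, List[Tuple[Tuple, Tuple, float]]] = {}
    retained: Dict[str, Optional[Tuple[Tuple, Tuple, float]]] = {}
    for iid in iids:
        weights = [pair_weight(h1, h2) for h1, h2 in person_pairs[iid]]
        total = sum(weights)
        scored = sorted(
            (
                (h1, h2, w / total)
                for (h1, h2), w in zip(person_pairs[iid], weights)
            ),
            key=lambda x: -x[2],
        )
        pairs_out[iid] = scored
        best = scored[0]
        # strict inequality: posteriors <= threshold are not retained
        retained[iid] = best if best[2] > config.posterior_threshold else None
    return EMResult(freq, pairs_out, retained, logliks, iteration, converged)
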