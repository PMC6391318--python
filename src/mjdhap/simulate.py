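"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* a star-genealogy founder simulator — n chromosomes descend
  independently from one founder STR haplotype for t generations; per
  generation each locus mutates with probability mu by +-1 repeat
  (equal probability, reflecting floor at one repeat), and with
  probability c a recombination replaces the segment downstream of a
  uniformly chosen inter-locus breakpoint with a draw from a background
  haplotype pool.  The star genealogy is exactly the model under which
  lambda = epsilon * t holds, which makes parameter-recovery
  experiments well-posed.
* a nuclear-family generator for phasing tests — founders draw
  haplotype pairs from a pool, children inherit one haplotype per
  parent without intra-panel recombination, genotypes are emitted
  unphased and the phased truth is retained.

Random-stream discipline: one ``numpy`` Generator per call, seeded from
the caller's seed; within a generation, mutation draws precede
recombination draws.  All repeat arithmetic is integer, so runs are
bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dating import RateModel, per_generation_change, mean_steps
from .families import Affection, GenotypeTable, Individual, Pedigree, Sex
from .haplotypes import StrHaplotype
from .markers import MarkerPanel
from .network import DistanceMode, modal_haplotype

__all__ = [
    "SimulationParams",
    "SimTruth",
    "SimulationError",
    "simulate_founder_sample",
    "FamilySpec",
    "FamilyTruth",
    "simulate_family",
    "recovery_experiment",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationParams:
    founder: Tuple[int, ...]
    n_chromosomes: int
    t_generations: int
    model: RateModel = RateModel()
    background_pool: Tuple[Tuple[Tuple[int, ...], float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1:
            raise SimulationError("n_chromosomes must be >= 1")
        if self.t_generations < 0:
            raise SimulationError("t_generations must be >= 0")
        if self.model.c > 0 and not self.background_pool:
            raise SimulationError("recombination (c > 0) needs a background pool")
        if self.background_pool:
            total = sum(f for _, f in self.background_pool)
            if abs(total - 1.0) > 1e-9:
                raise SimulationError("background pool frequencies must sum to 1")


@dataclass(frozen=True)
class SimTruth:
    """Realized history per chromosome, for model-level checks."""

    params: SimulationParams
    changed_generations: np.ndarray  # generations with >= 1 mutation or recomb
    n_mutation_events: np.ndarray
    n_recombination_events: np.ndarray


def simulate_founder_sample(
    params: SimulationParams,
) -> Tuple[List[StrHaplotype], SimTruth]:
    """Evolve n independent chromosomes from the founder for t generations."""
    rng = np.random.default_rng(params.seed)
    n = params.n_chromosomes
    founder = np.asarray(params.founder, dtype=np.int64)
    n_loci = founder.size
    model = params.model
    state = np.tile(founder, (n, 1))
    changed = np.zeros(n, dtype=np.int64)
    n_mut = np.zeros(n, dtype=np.int64)
    n_rec = np.zeros(n, dtype=np.int64)

    pool_haps = None
    pool_freqs = None
    if params.background_pool:
        pool_haps = np.asarray([h for h, _ in params.background_pool], dtype=np.int64)
        pool_freqs = np.asarray([f for _, f in params.background_pool])

    for _ in range(params.t_generations):
        mut = rng.random((n, n_loci)) < model.mu_per_locus
        if mut.any():
            steps = rng.integers(0, 2, size=(n, n_loci)) * 2 - 1
            state = np.where(mut, np.maximum(state + steps, 1), state)
        gen_changed = mut.any(axis=1)
        n_mut += mut.sum(axis=1)
        if model.c > 0:
            rec = rng.random(n) < model.c
            if rec.any():
                idx = np.flatnonzero(rec)
                breakpoints = rng.integers(1, n_loci, size=idx.size)
                donors = rng.choice(len(pool_haps), size=idx.size, p=pool_freqs)
                for j, bp, dn in zip(idx, breakpoints, donors):
                    state[j, bp:] = pool_haps[dn, bp:]
                gen_changed = gen_changed | rec
                n_rec += rec.astype(np.int64)
        changed += gen_changed

    haps = [
        StrHaplotype(tuple(int(x) for x in row), disease_flag=True,
                     source_family=f"sim{i}")
        for i, row in enumerate(state)
    ] if n_loci == 7 else [tuple(int(x) for x in row) for row in state]
    return haps, SimTruth(params, changed, n_mut, n_rec)


# ---------------------------------------------------------------------------
# nuclear families for phasing tests


@dataclass(frozen=True)
class FamilySpec:
    """Shape of a simulated family: couples and sibship sizes.

    ``n_generations`` >= 2; in each generation beyond the second, the
    first child of the previous sibship marries an unrelated founder
    spouse and has ``n_children`` children.
    """

    n_generations: int = 2
    n_children: int = 2

    def __post_init__(self):
        if self.n_generations < 2 or self.n_children < 1:
            raise SimulationError("need >= 2 generations and >= 1 child")


@dataclass
class FamilyTruth:
    """Phased truth: per individual, (paternal, maternal) haplotype and
    which sides carry the expansion."""

    haplotypes: Dict[str, Tuple[Tuple, Tuple]]
    disease_sides: Dict[str, Tuple[bool, bool]]


def simulate_family(
    pool: Sequence[Tuple[Tuple, float]],
    panel: MarkerPanel,
    spec: FamilySpec = FamilySpec(),
    seed: int = 0,
    disease_haplotype: Optional[Tuple] = None,
    family_id: str = "simfam",
) -> Tuple[Pedigree, GenotypeTable, FamilyTruth]:
    """Simulate one family and its unphased genotype table.

    ``pool`` holds (allele vector over panel markers, frequency) pairs.
    If ``disease_haplotype`` is given, the first founder father carries
    exactly one copy of it (replacing one pool draw), so the expansion
    pseudo-marker co-segregates with it by construction.
    """
    if not pool:
        raise SimulationError("empty haplotype pool")
    freqs = np.asarray([f for _, f in pool])
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise SimulationError("pool frequencies must sum to 1")
    haps = [tuple(h) for h, _ in pool]
    for h in haps:
        if len(h) != len(panel):
            raise SimulationError("pool haplotype length != panel size")
    rng = np.random.default_rng(seed)

    ped = Pedigree(family_id)
    truth = FamilyTruth({}, {})
    counter = [0]

    def draw() -> Tuple:
        return haps[rng.choice(len(haps), p=freqs)]

    def add(iid, father, mother, sex, pat, mat, pat_d, mat_d):
        exp = int(pat_d) + int(mat_d)
        ped.add(
            Individual(
                individual_id=iid,
                family_id=family_id,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affected=Affection.AFFECTED if exp else Affection.UNAFFECTED,
                expansion_count=exp,
            )
        )
        truth.haplotypes[iid] = (pat, mat)
        truth.disease_sides[iid] = (pat_d, mat_d)

    def new_id(prefix):
        counter[0] += 1
        return f"{prefix}{counter[0]}"

    def make_couple_and_descend(gen: int, father_id=None, father_state=None):
        """Create a couple (using ``father_state`` if the father already
        exists from the previous sibship) and their children."""
        if father_id is None:
            fid = new_id("F")
            pat, mat = draw(), draw()
            pat_d = mat_d = False
            if gen == 2 and disease_haplotype is not None:
                pat, pat_d = tuple(disease_haplotype), True
            add(fid, None, None, Sex.MALE, pat, mat, pat_d, mat_d)
            father_state = (pat, mat, pat_d, mat_d)
        else:
            fid = father_id
        mid = new_id("M")
        add(mid, None, None, Sex.FEMALE, draw(), draw(), False, False)
        mother_state = truth.haplotypes[mid] + truth.disease_sides[mid]

        children = []
        for _ in range(spec.n_children):
            cid = new_id("C")
            side_f = int(rng.integers(0, 2))
            side_m = int(rng.integers(0, 2))
            f_hap = father_state[side_f]
            f_dis = father_state[2 + side_f]
            m_hap = mother_state[side_m]
            m_dis = mother_state[2 + side_m]
            sex = Sex.MALE if rng.integers(0, 2) else Sex.FEMALE
            add(cid, fid, mid, sex, f_hap, m_hap, f_dis, m_dis)
            children.append(cid)
        if gen < spec.n_generations:
            heir = children[0]
            heir_state = truth.haplotypes[heir] + truth.disease_sides[heir]
            make_couple_and_descend(gen + 1, father_id=heir, father_state=heir_state)

    make_couple_and_descend(2)
    ped.validate()

    table = GenotypeTable(panel)
    for iid, (pat, mat) in truth.haplotypes.items():
        for k, marker in enumerate(panel):
            table.set(iid, marker.marker_id, (pat[k], mat[k]))
    return ped, table, truth


# ---------------------------------------------------------------------------
# parameter-recovery experiment


def recovery_experiment(
    t_values: Sequence[int],
    n_chromosomes: int = 10,
    n_reps: int = 200,
    model: RateModel = RateModel(),
    mode: DistanceMode = DistanceMode.LOCUS_COUNT,
    founder: Tuple[int, ...] = (10, 20, 10, 13, 7, 16, 15),
    seed: int = 0,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Simulate -> infer-ancestor -> lambda_hat -> t_hat, many times.

    Returns one row per true t with the median estimate, its relative
    deviation from truth (``central_rel_error`` = |median(t_hat) - t|/t),
    the per-replicate median absolute relative error, the median signed
    relative error, and — when ``n_boot`` > 0 — the coverage of the
    bootstrap age +- 2 SE interval.
    """
    eps = per_generation_change(model)
    if eps == 0.0:
        raise SimulationError("epsilon = 0: t is unidentifiable")
    ss = np.random.SeedSequence(seed)
    rows = []
    for t, child_ss in zip(t_values, ss.spawn(len(t_values))):
        rep_seeds = child_ss.generate_state(2 * n_reps) % (2**31)
        t_hats = np.empty(n_reps)
        covered = np.zeros(n_reps, dtype=bool)
        for r in range(n_reps):
            params = SimulationParams(
                founder=founder,
                n_chromosomes=n_chromosomes,
                t_generations=int(t),
                model=model,
                seed=int(rep_seeds[2 * r]),
            )
            haps, _ = simulate_founder_sample(params)
            anc = modal_haplotype(haps).haplotype
            lam = mean_steps(haps, anc, mode)
            t_hats[r] = lam / eps
            if n_boot:
                se = _bootstrap_age_se(
                    haps, eps, model.generation_years, mode, n_boot,
                    int(rep_seeds[2 * r + 1]),
                )
                age_hat = t_hats[r] * model.generation_years
                true_age = t * model.generation_years
                covered[r] = abs(age_hat - true_age) <= 2 * se
        rel = (t_hats - t) / t if t > 0 else np.zeros_like(t_hats)
        median_t = float(np.median(t_hats))
        rows.append(
            {
                "true_t": t,
                "median_t_hat": median_t,
                "central_rel_error": abs(median_t - t) / t if t > 0 else abs(median_t),
                "median_abs_rel_error": float(np.median(np.abs(rel))),
                "median_signed_rel_error": float(np.median(rel)),
                "coverage_2se": float(covered.mean()) if n_boot else np.nan,
                "n_reps": n_reps,
                "n_chromosomes": n_chromosomes,
            }
        )
    return pd.DataFrame(rows)


def _bootstrap_age_se(haps, eps, gen_years, mode, n_boot, seed) -> float:
    rng = np.random.default_rng(seed)
    n = len(haps)
    ages = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = [haps[i] for i in idx]
        anc = modal_haplotype(sample).haplotype
        ages[b] = mean_steps(sample, anc, mode) / eps * gen_years
    return float(ages.std(ddof=1))
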