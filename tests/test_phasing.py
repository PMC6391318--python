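"""Segregation phasing, disease-haplotype extraction, and EM."""

import math

import pytest

from conftest import fill_genotypes, make_snp_panel, make_trio
from mjdhap.families import Individual, Pedigree
from mjdhap.fixtures import load_fixture
from mjdhap.markers import EXPANSION_MARKER_ID, default_panel
from mjdhap.phasing import (
    InconsistentSegregationError,
    PhasingConfig,
    PhasingError,
    disease_haplotype_for_family,
    em_haplotype_frequencies,
    phase_by_segregation,
)
from mjdhap.simulate import FamilySpec, simulate_family


def snp_subpanel():
    p = default_panel()
    return p.subset([m.marker_id for m in p.snps()])


class TestSegregation:
    def test_homozygous_parent_forces_child_phase(self):
        panel = make_snp_panel([("s1", -1.0, "AG")])
        ped = make_trio()
        table = fill_genotypes(
            panel,
            {"dad": {"s1": ("A", "A")}, "mum": {"s1": ("A", "G")},
             "kid": {"s1": ("A", "G")}},
        )
        result = phase_by_segregation(ped, table, panel)
        pair = result.pairs["kid"]
        k = result.panel.marker_ids.index("s1")
        assert pair.haplotype_a[k] == "A"  # paternal
        assert pair.haplotype_b[k] == "G"  # maternal
        assert pair.posterior == 1.0
        assert pair.ambiguous_markers == ()
        assert not result.errors

    def test_double_heterozygous_trio_stays_ambiguous(self):
        panel = make_snp_panel([("s1", -1.0, "AG"), ("s2", 1.0, "TC")])
        ped = make_trio()
        het = {"s1": ("A", "G"), "s2": ("T", "C")}
        table = fill_genotypes(panel, {"dad": het, "mum": het, "kid": het})
        result = phase_by_segregation(ped, table, panel)
        assert set(result.pairs["kid"].ambiguous_markers) == {"s1", "s2"}
        assert not result.errors

    def test_mendelian_inconsistency_is_reported_not_dropped(self):
        panel = make_snp_panel([("s1", -1.0, "AG")])
        ped = make_trio()
        table = fill_genotypes(
            panel,
            {"dad": {"s1": ("A", "A")}, "mum": {"s1": ("A", "A")},
             "kid": {"s1": ("A", "G")}},
        )
        result = phase_by_segregation(ped, table, panel)
        assert len(result.errors) == 1
        err = result.errors[0]
        assert err.individual_id == "kid" and err.marker_id == "s1"

    def test_missing_genotype_skips_marker(self):
        panel = make_snp_panel([("s1", -1.0, "AG")])
        ped = make_trio()
        table = fill_genotypes(
            panel,
            {"dad": {"s1": ("A", "A")}, "mum": {"s1": ("A", "G")},
             "kid": {"s1": None}},
        )
        result = phase_by_segregation(ped, table, panel)
        k = result.panel.marker_ids.index("s1")
        assert result.pairs["kid"].haplotype_a[k] is None
        assert not result.errors

    def test_expansion_homozygote_flagged_on_both_sides(self):
        panel = make_snp_panel([("s1", -1.0, "AG")])
        fam = "f9"
        ped = Pedigree(fam)
        ped.add(Individual("dad", fam, sex="male", expansion_count=1))
        ped.add(Individual("mum", fam, sex="female", expansion_count=1))
        ped.add(Individual("patient", fam, father_id="dad", mother_id="mum",
                           affected="affected", expansion_count=2))
        ped.add(Individual("sister", fam, father_id="dad", mother_id="mum",
                           expansion_count=0))
        ped.validate()
        table = fill_genotypes(
            panel,
            {"dad": {"s1": ("A", "A")}, "mum": {"s1": ("G", "G")},
             "patient": {"s1": ("A", "G")}, "sister": {"s1": ("A", "G")}},
        )
        result = phase_by_segregation(ped, table, panel)
        assert result.pairs["patient"].disease_side == "both"
        fam_haps = disease_haplotype_for_family(result, ped)
        # one disease haplotype per parental expansion
        assert len(fam_haps.snp_haplotypes) == 2
        alleles = sorted(h.alleles for h in fam_haps.snp_haplotypes)
        assert alleles == [("A",), ("G",)]

    def test_unanimous_carriers_yield_family_disease_haplotype(self):
        panel = snp_subpanel()
        t1 = load_fixture("table1")
        disease = t1.haplotypes["B"]
        pool = [(t1.joseph, 0.6), (t1.haplotypes["G"], 0.4)]
        ped, table, truth = simulate_family(
            pool, panel, FamilySpec(3, 3), seed=11, disease_haplotype=disease
        )
        result = phase_by_segregation(ped, table, panel)
        assert not result.errors
        fam = disease_haplotype_for_family(result, ped)
        (vec,) = fam.full_vectors
        for got, want in zip(vec, disease):
            if got is not None:
                assert got == want

    def test_disagreeing_carriers_raise_inconsistency(self):
        panel = make_snp_panel([("s1", -1.0, "AG")])
        fam = "fx"
        ped = Pedigree(fam)
        ped.add(Individual("dad", fam, sex="male", expansion_count=1))
        ped.add(Individual("mum", fam, sex="female", expansion_count=0))
        ped.add(Individual("sib1", fam, father_id="dad", mother_id="mum",
                           expansion_count=1))
        ped.add(Individual("sib2", fam, father_id="dad", mother_id="mum",
                           expansion_count=1))
        ped.validate()
        table = fill_genotypes(
            panel,
            {"dad": {"s1": ("A", "G")}, "mum": {"s1": ("A", "A")},
             "sib1": {"s1": ("A", "G")}, "sib2": {"s1": ("A", "A")}},
        )
        result = phase_by_segregation(ped, table, panel)
        with pytest.raises(InconsistentSegregationError, match="disagree"):
            disease_haplotype_for_family(result, ped)

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_recovers_truth_at_informative_markers(self, seed):
        """Simulated phase, dropped and re-inferred, matches the truth at
        every marker segregation can resolve (and is never wrong)."""
        panel = snp_subpanel()
        t1 = load_fixture("table1")
        pool = [
            (t1.joseph, 0.4),
            (t1.haplotypes["B"], 0.3),
            (t1.haplotypes["M"], 0.3),
        ]
        ped, table, truth = simulate_family(
            pool, panel, FamilySpec(3, 2), seed=seed,
            disease_haplotype=t1.haplotypes["B"],
        )
        result = phase_by_segregation(ped, table, panel)
        assert not result.errors
        work_ids = result.panel.marker_ids
        src_index = {m: i for i, m in enumerate(panel.marker_ids)}
        n_checked = 0
        for iid, pair in result.pairs.items():
            father, mother = ped.parents_of(iid)
            if father is None and mother is None:
                continue  # founders are anchored differently
            pat_truth, mat_truth = truth.haplotypes[iid]
            for k, mid in enumerate(work_ids):
                if mid == EXPANSION_MARKER_ID:
                    continue
                if pair.haplotype_a[k] is not None:
                    assert pair.haplotype_a[k] == pat_truth[src_index[mid]]
                    n_checked += 1
                if pair.haplotype_b[k] is not None:
                    assert pair.haplotype_b[k] == mat_truth[src_index[mid]]
        assert n_checked > 0


class TestEM:
    def test_single_heterozygous_site_is_unambiguous(self, two_snp_panel):
        table = fill_genotypes(
            two_snp_panel, {"p1": {"s1": ("A", "G"), "s2": ("T", "T")}}
        )
        res = em_haplotype_frequencies(table, two_snp_panel)
        best = res.retained["p1"]
        assert best is not None
        assert best[2] == pytest.approx(1.0)

    def test_fully_homozygous_data_reproduces_proportions(self, two_snp_panel):
        table = fill_genotypes(
            two_snp_panel,
            {
                "p1": {"s1": ("A", "A"), "s2": ("T", "T")},
                "p2": {"s1": ("A", "A"), "s2": ("T", "T")},
                "p3": {"s1": ("G", "G"), "s2": ("C", "C")},
            },
        )
        res = em_haplotype_frequencies(table, two_snp_panel)
        assert res.frequencies[("A", "T")] == pytest.approx(2 / 3)
        assert res.frequencies[("G", "C")] == pytest.approx(1 / 3)

    def test_two_snp_worked_example_reaches_analytic_fixed_point(self, two_snp_panel):
        """4x AA/TT + 2x AG/TC: the double heterozygotes resolve to the
        A-T / G-C pairing; fixed point f(AT) = 10/12, f(GC) = 2/12."""
        assignments = {}
        for i in range(4):
            assignments[f"hom{i}"] = {"s1": ("A", "A"), "s2": ("T", "T")}
        for i in range(2):
            assignments[f"het{i}"] = {"s1": ("A", "G"), "s2": ("T", "C")}
        table = fill_genotypes(two_snp_panel, assignments)
        config = PhasingConfig(em_tolerance=1e-12)
        res = em_haplotype_frequencies(table, two_snp_panel, config)
        assert res.converged
        assert res.frequencies[("A", "T")] == pytest.approx(10 / 12, abs=1e-5)
        assert res.frequencies[("G", "C")] == pytest.approx(2 / 12, abs=1e-5)
        assert res.frequencies.get(("A", "C"), 0.0) == pytest.approx(0.0, abs=1e-5)
        best = res.retained["het0"]
        assert best is not None  # posterior > 0.6 so the pair is kept
        assert {best[0], best[1]} == {("A", "T"), ("G", "C")}
        assert best[2] > 0.999

    def test_log_likelihood_is_monotone(self, two_snp_panel):
        assignments = {
            "a": {"s1": ("A", "G"), "s2": ("T", "C")},
            "b": {"s1": ("A", "A"), "s2": ("T", "C")},
            "c": {"s1": ("A", "G"), "s2": ("C", "C")},
            "d": {"s1": ("G", "G"), "s2": ("T", "T")},
        }
        table = fill_genotypes(two_snp_panel, assignments)
        res = em_haplotype_frequencies(table, two_snp_panel)
        diffs = [b - a for a, b in zip(res.log_likelihoods, res.log_likelihoods[1:])]
        assert all(d >= -1e-9 for d in diffs)

    def test_missing_genotypes_are_marginalized(self, two_snp_panel):
        table = fill_genotypes(
            two_snp_panel,
            {
                "p1": {"s1": ("A", "A"), "s2": ("T", "T")},
                "p2": {"s1": ("A", "A"), "s2": None},
            },
        )
        res = em_haplotype_frequencies(table, two_snp_panel)
        # p2's completion is pulled toward the observed T allele
        assert res.frequencies[("A", "T")] > 0.7

    def test_low_posterior_pairs_are_not_retained(self, two_snp_panel):
        # a lone double heterozygote: both pairings at posterior 0.5
        table = fill_genotypes(
            two_snp_panel, {"p1": {"s1": ("A", "G"), "s2": ("T", "C")}}
        )
        res = em_haplotype_frequencies(table, two_snp_panel)
        assert res.retained["p1"] is None

    def test_no_individuals_rejected(self, two_snp_panel):
        from mjdhap.families import GenotypeTable

        with pytest.raises(PhasingError):
            em_haplotype_frequencies(GenotypeTable(two_snp_panel), two_snp_panel)
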