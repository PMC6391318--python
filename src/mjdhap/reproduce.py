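"""One-call reproduction of the study's in-table numbers.

Every quantity is recomputed from the packaged fixtures and labeled:

* ``reproduced`` — matches the published value at its printed precision;
* ``approximated`` — the published analysis choice is underdetermined
  (e.g. the exact HWE convention, the dating constants) and our
  documented convention lands near but not on the printed value;
* ``not_reproducible`` — internally inconsistent in the source or
  outside the published interval under every convention we expose;
  flagged, never forced.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

from . import stats as st
from .dating import RateModel, ages_table, date_all_lineages
from .fixtures import load_fixture
from .lineage import tabulate_table1
from .network import DistanceMode

__all__ = ["run_reproduce"]

ABSTRACT_AGE_RANGE = (8000.0, 17000.0)


def _delta_status(computed: float, printed: str) -> str:
    if printed in (".", ""):
        return "not_compared"
    if f"{computed:.3f}" == f"{float(printed):.3f}":
        return "reproduced"
    if computed < 0 <= float(printed):
        # published value has the sign lost (Fd < Fc row)
        return "not_reproducible"
    return "approximated"


def run_reproduce(
    model: Optional[RateModel] = None,
    mode: DistanceMode = DistanceMode.LOCUS_COUNT,
    n_boot: int = 1000,
    seed: int = 1,
    out_dir: Optional[Path] = None,
) -> Dict:
    """Recompute the published tables; return a labeled report dict."""
    model = model or RateModel()
    report: Dict = {"config": {
        "mu_per_locus": model.mu_per_locus,
        "c": model.c,
        "generation_years": model.generation_years,
        "distance_mode": str(DistanceMode(mode).value),
        "n_boot": n_boot,
        "seed": seed,
    }}

    # --- lineage tabulation (table 1) -------------------------------------
    summary = tabulate_table1()
    n_g = summary.families_with("rs56268847", "G")
    report["lineages"] = {
        "n_distinct_disease_haplotypes": {
            "value": summary.n_distinct_haplotypes,
            "published": 13,
            "status": "reproduced" if summary.n_distinct_haplotypes == 13 else "not_reproducible",
        },
        "families_with_G_at_rs56268847": {
            "value": n_g,
            "published": 28,
            "status": "reproduced" if n_g == 28 else "not_reproducible",
        },
        "freq_G_of_stated_families": {
            "value": round(n_g / 50.0, 2),
            "published": 0.56,
            "status": "reproduced" if round(n_g / 50.0, 2) == 0.56 else "not_reproducible",
        },
        "family_assignments": {
            "value": summary.n_family_assignments,
            "published": 50,
            "status": "approximated",
            "note": "per-column n's sum to 51 (one family listed under two "
                    "lineages); the text states 50 families",
        },
    }

    # --- genotype/allele statistics (table 2) ------------------------------
    table2 = load_fixture("table2")
    t2_rows: List[Dict] = []
    by_rs: Dict[str, Dict[str, st.GenotypeCounts]] = {}
    for g in table2:
        by_rs.setdefault(g.rs_id, {})[g.group] = g
        ac = st.allele_counts(g)
        counts_match = (
            str(ac.ref) == g.printed["ref_count"]
            and str(ac.alt) == g.printed["alt_count"]
        )
        freqs_match = (
            f"{ac.freq_ref:.2f}" == g.printed["ref_freq"]
            and f"{ac.freq_alt:.2f}" == g.printed["alt_freq"]
        )
        hwe_x2 = st.hwe_test(g, "chi_square_gof")
        hwe_ex = st.hwe_test(g, "exact")
        t2_rows.append({
            "rs_id": g.rs_id,
            "group": g.group,
            "allele_counts": {
                "value": [ac.ref, ac.alt],
                "published": [int(g.printed["ref_count"]), int(g.printed["alt_count"])],
                "status": "reproduced" if counts_match and freqs_match else "not_reproducible",
            },
            "hwe": {
                "chi_square_p": hwe_x2.p_value,
                "exact_p": hwe_ex.p_value,
                "published_p": g.printed["hwe_p"],
                "status": "approximated",
                "note": "published HWE convention unstated; both of our "
                        "documented conventions reported",
            },
        })
    for rs, groups in by_rs.items():
        if {"MJD", "control"} <= set(groups):
            case = st.allele_counts(groups["MJD"])
            ctrl = st.allele_counts(groups["control"])
            res = st.allele_chi_square((case.ref, case.alt), (ctrl.ref, ctrl.alt))
            published = groups["MJD"].printed["allele_p"]
            ok = published == "<0.001" and res.p_value < 0.001
            t2_rows.append({
                "rs_id": rs,
                "group": "MJD vs control",
                "allele_chi_square": {
                    "value": res.p_value,
                    "published": published,
                    "status": "reproduced" if ok else "approximated",
                },
            })
    report["table2"] = t2_rows

    # --- six-SNP haplotypes and delta (table 3) -----------------------------
    table3 = load_fixture("table3")
    t3_rows: List[Dict] = []
    for _, row in table3.iterrows():
        fc, fd = row["freq_control"], row["freq_mjd"]
        if fc >= 1.0:
            continue
        delta = st.delta_statistic(fd, fc).delta
        entry = {
            "haplotype": row["haplotype"],
            "delta": {
                "value": round(delta, 3),
                "published": row["delta_printed"],
                "status": _delta_status(delta, row["delta_printed"]),
            },
        }
        if entry["delta"]["status"] == "not_reproducible":
            entry["delta"]["note"] = (
                "formula gives a negative value where the table prints a "
                "positive one (Fd < Fc); reported signed, not forced"
            )
        t3_rows.append(entry)
    n_mjd = int((table3["freq_mjd"] > 0).sum())
    n_ctrl = int((table3["freq_control"] > 0).sum())
    report["table3"] = {
        "rows": t3_rows,
        "distinct_mjd_haplotypes": {
            "value": n_mjd, "published": 7,
            "status": "reproduced" if n_mjd == 7 else "not_reproducible",
        },
        "distinct_control_haplotypes": {
            "value": n_ctrl, "published": 21,
            "status": "reproduced" if n_ctrl == 21 else "not_reproducible",
        },
    }

    # --- founder ages (table 4) ---------------------------------------------
    table4 = load_fixture("table4")
    estimates = date_all_lineages(table4, model, mode, n_boot=n_boot, seed=seed)
    ages_df = ages_table(estimates, table4.printed_ages)
    lo, hi = ABSTRACT_AGE_RANGE
    ages = {est.lineage: est.age_years for est in estimates}
    t4 = {"lineages": {}}
    for _, row in ages_df.iterrows():
        within = bool(row["within_published_interval"])
        t4["lineages"][row["lineage"]] = {
            "age_years": row["age_years"],
            "se_years": row["se_years"],
            "lambda": row["lambda"],
            "epsilon": row["epsilon"],
            "ancestor": row["ancestor"],
            "ties": row["ties"],
            "published": f"{row['published_age']:.0f} ± {row['published_pm']:.0f}",
            "within_published_interval": within,
            "status": "approximated" if within else "not_reproducible",
        }
        if not within:
            t4["lineages"][row["lineage"]]["note"] = (
                "outside the published mean ± spread under the documented "
                "defaults; the published step-counting convention is unstated"
            )
    t4["all_within_abstract_range"] = {
        "value": bool(all(lo <= a <= hi for a in ages.values())),
        "published_range_years": [lo, hi],
        "status": "reproduced" if all(lo <= a <= hi for a in ages.values())
        else "not_reproducible",
    }
    report["table4"] = t4

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "reproduce_report.json").write_text(
            json.dumps(report, indent=2, default=str)
        )
        ages_df.to_csv(out_dir / "founder_ages.tsv", sep="\t", index=False)
    return report
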