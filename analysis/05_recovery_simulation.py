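#!/usr/bin/env python
"""Validate the dating estimator on simulated star genealogies.

Simulates founder samples at known ages (t = 100, 300, 500 generations,
n = 10 chromosomes, 200 replicates each), reruns the full
ancestor-inference -> lambda -> t pipeline, and tabulates the accuracy
of the estimate and the coverage of the bootstrap ±2 SE interval.
Also verifies the generative identity E[changed generations] =
epsilon * t at n = 2000.  Writes results/recovery.tsv.
"""

import math
from pathlib import Path

from mjdhap.dating import RateModel, per_generation_change
from mjdhap.simulate import (
    SimulationParams,
    recovery_experiment,
    simulate_founder_sample,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    df = recovery_experiment(
        [100, 300, 500], n_chromosomes=10, n_reps=200, seed=2024, n_boot=200
    )
    df.to_csv(OUT / "recovery.tsv", sep="\t", index=False)
    for _, row in df.iterrows():
        print(f"true t = {row.true_t:>3.0f}: median t_hat = "
              f"{row.median_t_hat:6.1f} ({row.central_rel_error:.1%} off), "
              f"median |rel err| = {row.median_abs_rel_error:.1%}, "
              f"2SE coverage = {row.coverage_2se:.0%}.")
    print("The downward drift of t_hat at larger t is the locus-count "
          "saturation bias (a locus counts once however often it mutated); "
          "at t = 100 the per-replicate error floor reflects the small "
          "expected number of changes (~4 per 10-chromosome sample), not "
          "estimator quality.")

    model = RateModel()
    eps = per_generation_change(model)
    t, n = 300, 2000
    _, truth = simulate_founder_sample(
        SimulationParams((10, 20, 10, 13, 7, 16, 15), n, t, model, seed=77)
    )
    mean = truth.changed_generations.mean()
    se = math.sqrt(t * eps * (1 - eps) / n)
    print(f"Generative check at n = {n}, t = {t}: mean changed generations "
          f"{mean:.3f} vs epsilon*t = {eps * t:.3f} "
          f"({abs(mean - eps * t) / se:.1f} Monte-Carlo SEs apart).")


if __name__ == "__main__":
    main()
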