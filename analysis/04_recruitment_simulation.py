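"""Monte-Carlo comparison of recruitment-date distributions.

Using the estimated per-zone seasonal profiles, simulates 100 recruitment
schedules of 61 test patients under (a) a Poisson(6.5) commencement-month
distribution clamped to the 15-month intervention window and (b) a discrete
uniform distribution over the same window, and compares the resulting peak
synchronized deviations.  An evenly spread recruitment should attenuate the
residual seasonal confound more than the Poisson-concentrated one.
Writes recruitment_sim.csv (per replicate) and recruitment_summary.csv.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from seasonsync import compare_distributions, run_recruitment_simulation
from seasonsync.io_cli import read_patients

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 61
N_REPS = 100
WINDOW = 15
LAMBDA = 6.5

_spec = importlib.util.spec_from_file_location(
    "sync_step", Path(__file__).with_name("03_synchronized_profile.py"))
_sync_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_sync_step)


def main() -> None:
    profiles = _sync_step.load_profiles()
    patients = read_patients(RESULTS / "patients.csv")
    test_zone_counts: dict = {}
    for p in patients:
        if p.group == "test":
            test_zone_counts[p.zone] = test_zone_counts.get(p.zone, 0) + 1
    n_test = sum(test_zone_counts.values())

    poisson = run_recruitment_simulation(
        profiles, test_zone_counts, "poisson", {"lam": LAMBDA, "window": WINDOW},
        n_reps=N_REPS, seed=SEED, label="poisson(6.5)")
    uniform = run_recruitment_simulation(
        profiles, test_zone_counts, "uniform", {"window": WINDOW},
        n_reps=N_REPS, seed=SEED, label="uniform(15)")
    cmp = compare_distributions(uniform, poisson)

    pd.DataFrame(
        dict(replicate=range(1, N_REPS + 1),
             poisson_peak_pct=poisson.peaks,
             uniform_peak_pct=uniform.peaks)
    ).to_csv(RESULTS / "recruitment_sim.csv", index=False)
    pd.DataFrame(
        [dict(distribution=r.label, n_patients=n_test, n_reps=r.n_reps,
              mean_peak_pct=round(r.mean_peak, 2), sd_peak_pct=round(r.sd_peak, 2))
         for r in (poisson, uniform)]
    ).to_csv(RESULTS / "recruitment_summary.csv", index=False)

    print(f"{n_test} test patients, {N_REPS} replicates per distribution")
    print(f"poisson(6.5) clamped to {WINDOW} months: "
          f"mean peak {poisson.mean_peak:.2f}% (SD {poisson.sd_peak:.2f}%)")
    print(f"uniform over {WINDOW} months:           "
          f"mean peak {uniform.mean_peak:.2f}% (SD {uniform.sd_peak:.2f}%)")
    print(f"uniform smaller in {cmp.n_a_smaller}/{N_REPS} paired replicates "
          f"(t = {cmp.t_statistic:.2f}, p = {cmp.p_value:.2g})")


if __name__ == "__main__":
    main()
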