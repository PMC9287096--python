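"""Generate the study cohort: ~15,000 adults with deprivation-graded risk
factors, >10 years of proportional-hazards follow-up, coded event records
and 6% missing deprivation scores. Writes cohort.csv / events.csv plus the
generative ground truth to scratch/cohort/ (large, regenerable files)."""

from pathlib import Path

import deprisk as d
from deprisk.deprivation import simd_groups

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SEED = 1


def main() -> None:
    cfg = d.default_config().replace(seed=SEED)
    sim = d.simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    sim.cohort.to_csv(OUT / "cohort.csv", index=False)
    sim.events.to_csv(OUT / "events.csv", index=False)
    sim.truth.to_csv(OUT / "truth.csv", index=False)

    c, t = sim.cohort, sim.truth
    g = simd_groups(c["simd"])
    print(f"cohort: n={len(c)}, {100 * (c['sex'] == 'F').mean():.1f}% female, "
          f"median age {t['age'].median():.0f}")
    for grp, label in ((1, "most deprived"), (2, "middle"), (3, "least deprived")):
        m = g == grp
        print(f"  group {grp} ({label}): n={int(m.sum())} "
              f"({100 * m.mean():.0f}%), smoking {100 * t['smoker'][m].mean():.1f}%, "
              f"diabetes {100 * t['diabetes'][m].mean():.1f}%")
    print(f"  missing SIMD: {int(c['simd'].isna().sum())} "
          f"({100 * c['simd'].isna().mean():.0f}%)")
    print(f"10-year composite event fraction: {100 * sim.event_fraction_by(10):.2f}%")
    print(f"events file: {len(sim.events)} coded records -> {OUT}")


if __name__ == "__main__":
    main()
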