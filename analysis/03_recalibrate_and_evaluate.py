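"""Recalibrate each score's 10-year baseline survival to the whole cohort
(per sex, never within a deprivation stratum) and report calibration and
discrimination stratified by deprivation group: observed vs predicted risk,
P/O ratio, Z test, C-statistic, decile curves. Writes results/validation/."""

from pathlib import Path

from deprisk.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
OUT = ROOT / "results" / "validation"


def main() -> None:
    result = run_pipeline(
        RunConfig(
            cohort_path=str(COHORT / "cohort.csv"),
            events_path=str(COHORT / "events.csv"),
            models=("assign", "score2", "pce"),
            recalibrate=True,
            refit=False,
            output_dir=str(OUT),
            seed=1,
        )
    )
    for name, res in result["models"].items():
        recal = res.recalibration
        print(f"\n{name}: S0(10) updated "
              + ", ".join(f"{s} {recal.original_s0[s]:.4f} -> {recal.updated_s0[s]:.4f}"
                          for s in ("female", "male")))
        print("  stratum                  n  events  observed  predicted   P/O      p")
        for sname, s in res.recalibrated_report.strata.items():
            if s.observed is None:
                continue
            print(f"  {sname:22s} {s.n:5d} {s.n_events:6d}   "
                  f"{100 * s.observed:5.2f}%    {100 * s.predicted:5.2f}%  "
                  f"{s.ratio:5.2f}  {s.p:.3f}{' *' if s.significant else ''}")
    print(f"\nreports and decile tables -> {OUT}")


if __name__ == "__main__":
    main()
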