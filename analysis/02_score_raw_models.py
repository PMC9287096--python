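"""Score the cohort with the published (non-recalibrated) ASSIGN, SCORE2 and
PCE equations against their own endpoints and report raw calibration: none of
the scores is expected to fit a contemporary cohort before recalibration
(ASSIGN's 1980s baseline overpredicts roughly two-fold). Writes raw reports
to results/raw_scores/."""

from pathlib import Path

from deprisk.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
OUT = ROOT / "results" / "raw_scores"


def main() -> None:
    result = run_pipeline(
        RunConfig(
            cohort_path=str(COHORT / "cohort.csv"),
            events_path=str(COHORT / "events.csv"),
            models=("assign", "score2", "pce"),
            recalibrate=False,
            refit=False,
            output_dir=str(OUT),
            seed=1,
        )
    )
    print("raw (non-recalibrated) calibration, whole cohort:")
    for name, res in result["models"].items():
        s = res.raw_report.strata["all"]
        print(f"  {name:7s} observed {100 * s.observed:5.2f}%  "
              f"predicted {100 * s.predicted:5.2f}%  "
              f"P/O ratio {s.ratio:5.2f}  C={s.c_statistic:.3f}  "
              f"({res.n_flagged} unscorable)")
    print(f"reports -> {OUT}")


if __name__ == "__main__":
    main()
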