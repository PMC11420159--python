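#!/usr/bin/env python
"""Nap report: per-stage relative band power and correlations.

Consumes the nap EDFs and hypnogram from 01_simulate_sessions.py, runs the
per-stage relative-spectral-power comparison between devices (permutation
mean-difference tests per band under BH-FDR) and the per-stage 10-s-window
correlations against scalp T7-T8, and writes tables to results/nap/.
"""

from pathlib import Path

from earqc.plots import plot_stage_correlations
from earqc.reports import run_nap_report

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
OUT = ROOT / "results" / "nap"


def main() -> None:
    report = run_nap_report(
        inear=SESSIONS / "nap_inear.edf",
        scalp=SESSIONS / "nap_scalp.edf",
        hypnogram=ROOT / "results" / "nap_hypnogram.csv",
        n_perm=1600,
        seed=7,
        out_dir=OUT,
    )
    print(report.tables["rms_summary"].to_string(index=False))
    print(report.tables["rsp_by_stage"].to_string(index=False))
    sig = report.tables["rsp_band_tests"].query("q_significant")
    print(f"{len(sig)} stage/band RSP differences significant after FDR")
    stage = report.tables["stage_correlations"]
    print(stage.to_string(index=False))
    print("not observed:", report.metadata["stages_not_observed"],
          "| untested:", report.metadata["stages_untested"])

    figdir = OUT / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    plot_stage_correlations(stage, "in-ear vs scalp T7-T8 by stage").savefig(
        figdir / "stage_correlations.png", dpi=120
    )
    print(f"tables in {OUT}, figure in {figdir}")


if __name__ == "__main__":
    main()
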