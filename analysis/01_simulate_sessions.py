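#!/usr/bin/env python
"""Generate the two synthetic study sessions and export them as EDF.

Writes one alpha-test session (10 alternating 30-s EC/EO trials, 250 Hz
in-ear + 2000 Hz scalp, shared triggers, 0.25 s clock offset, 20 ppm drift)
and one 1-h nap with its hypnogram.  EDFs and ground-truth sidecars go to
scratch/sessions/ (binary, regenerable); the schedule and hypnogram CSVs go
to results/.
"""

from pathlib import Path

from earqc.io import write_edf, write_json
from earqc.simulate import SimConfig, generate_alpha_test, generate_nap, write_sidecar

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"
SEED = 20240101


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    alpha_cfg = SimConfig(protocol="alpha_test", seed=SEED)
    alpha = generate_alpha_test(alpha_cfg)
    write_edf(OUT / "alpha_inear.edf", alpha.inear)
    write_edf(OUT / "alpha_scalp.edf", alpha.scalp)
    write_sidecar(OUT / "alpha_ground_truth.json", alpha.ground_truth, alpha_cfg)
    write_json(RESULTS / "alpha_schedule.json", {"schedule": alpha.schedule})
    print(
        f"alpha session: {alpha.inear.duration_s:.0f} s, "
        f"{len(alpha.scalp.labels)} scalp channels, "
        f"{len(alpha.ground_truth['artifact_intervals'])} injected artifacts"
    )

    nap_cfg = SimConfig(protocol="nap", nap_len_s=3600, seed=SEED + 1)
    nap = generate_nap(nap_cfg)
    write_edf(OUT / "nap_inear.edf", nap.inear)
    write_edf(OUT / "nap_scalp.edf", nap.scalp)
    write_sidecar(OUT / "nap_ground_truth.json", nap.ground_truth, nap_cfg)
    nap.hypnogram.to_csv(RESULTS / "nap_hypnogram.csv")
    counts = {
        st: nap.hypnogram.stages.count(st)
        for st in nap.hypnogram.observed_stages()
    }
    print(f"nap session: {nap.hypnogram.n_epochs} epochs, stages {counts}")


if __name__ == "__main__":
    main()
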