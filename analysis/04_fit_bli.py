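#!/usr/bin/env python
"""Fit the 1:1 Langmuir model to the synthetic BLI trace set and compare
the recovered kinetic constants with the generating truth."""

import json
from pathlib import Path

from survbind import bli, io
from survbind.sampling import SamplerConfig
from survbind.synthetic import GroundTruth

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    traces = io.read_bli_csv(ROOT / "data" / "bli_traces.csv")
    truth = GroundTruth.from_json(ROOT / "data" / "bli_truth.json")
    posterior = bli.fit_bli(traces, SamplerConfig(steps=500, burn=1000, seed=SEED, thin=5))
    summary = bli.summarize_bli(posterior, conc_unit="nM")
    io.write_posterior(
        posterior, ROOT / "bli_posterior.csv", ROOT / "bli_summary.json",
        {"summary": summary, "truth": truth.params},
    )
    print(json.dumps(summary, indent=1))
    kd_true_nM = truth.params["KD_app"] * 1e9
    print(f"truth KD_app {kd_true_nM:g} nM, k_off {truth.params['k_off']:g}/s; "
          f"recovered {summary['KD_app']['mean']:.2f} nM, "
          f"{summary['k_off_per_s']['mean']:.2e}/s")


if __name__ == "__main__":
    main()
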