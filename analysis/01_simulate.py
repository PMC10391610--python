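#!/usr/bin/env python
"""Generate the four synthetic study datasets with ground-truth sidecars.

Writes under results/data/: a 16-capillary MST dilution series (truth
Kd = 2000 nM), a 4-concentration BLI trace set (truth KD_app = 10 nM,
k_off = 1e-3/s), a 10-point NMR titration (truth cpc ~ 2.1 uM), and a
tiled peptide array (~5000 15-mers, hidden composition rule, ~40%
interacting, 10% label noise).
"""

from pathlib import Path

from survbind import io, synthetic

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    caps, gt = synthetic.gen_mst(seed=SEED)
    io.write_mst_csv(caps, OUT / "mst_traces.csv")
    gt.to_json(OUT / "mst_truth.json")
    print(f"MST: {len(caps)} capillaries, truth Kd = {gt.params['Kd']} nM")

    traces, gt = synthetic.gen_bli(seed=SEED)
    io.write_bli_csv(traces, OUT / "bli_traces.csv")
    gt.to_json(OUT / "bli_truth.json")
    print(f"BLI: {len(traces)} traces, truth KD_app = {gt.params['KD_app'] * 1e9:g} nM")

    series, gt = synthetic.gen_nmr(seed=SEED)
    io.write_nmr_series(series, OUT / "nmr_series.csv")
    gt.to_json(OUT / "nmr_truth.json")
    print(f"NMR: {series.conc.size} points, truth cpc = "
          f"{10 ** gt.params['log10_cpc'] * 1e3:.2f} uM")

    proteins, peptides, measurements, gt = synthetic.gen_peptide_array(
        label_noise=0.10, seed=SEED
    )
    io.write_fasta(sorted(proteins.items()), OUT / "proteins.fasta")
    io.write_array_table(peptides, measurements, OUT / "array.tsv")
    gt.meta.to_json(OUT / "array_truth.json")
    n_int = sum(gt.true_labels.values())
    print(f"array: {len(peptides)} peptides from {len(proteins)} proteins, "
          f"{n_int} interacting ({100 * n_int / len(peptides):.1f}%)")


if __name__ == "__main__":
    main()
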