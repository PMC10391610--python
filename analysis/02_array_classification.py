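#!/usr/bin/env python
"""Classify the synthetic peptide array by atom composition.

Labels the duplicate intensities, featurizes, Ward-clusters, trains the
perceptron classifier under three schemes (random half split; every-third
peptide to remove sequence overlap; weak interactions excluded), and
summarizes composition uniqueness and the composition-probability
combinatorics.  Writes reports under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from survbind import io
from survbind.atom_types import default_atom_type_map
from survbind.peptide_array import (
    ClassifierConfig,
    Label,
    SplitScheme,
    composition_uniqueness,
    featurize,
    label_measurements,
    mean_composition_probability,
    sequence_identity_probability,
    split_dataset,
    train_and_evaluate,
    ward_cluster,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"


def run_scheme(name, ids, feat, y, tiling_index, fi_floor=0.0, mean_fi=None,
               hidden_units=100):
    keep = ids
    if fi_floor > 0:
        keep = [i for i in ids if not (y[i] and mean_fi[i] < fi_floor)]
    scheme = "every_third" if name.startswith("every_third") else "half_random"
    train, test = split_dataset(keep, SplitScheme(scheme, SEED), tiling_index)
    report = train_and_evaluate(
        np.array([feat[i] for i in train]), np.array([y[i] for i in train]),
        np.array([feat[i] for i in test]), np.array([y[i] for i in test]),
        ClassifierConfig(seed=SEED, fi_floor=fi_floor, hidden_units=hidden_units),
    )
    print(f"{name}: n_train={len(train)} n_test={len(test)} "
          f"balanced_acc={report.balanced_accuracy:.3f} "
          f"precision={ {k: round(v, 2) for k, v in report.precision.items()} }")
    return {
        "confusion": report.confusion.tolist(),
        "precision": report.precision,
        "recall": report.recall,
        "balanced_accuracy": report.balanced_accuracy,
        "n_train": len(train),
        "n_test": len(test),
    }


def main() -> None:
    peptides, measurements = io.read_array_table(DATA / "array.tsv")
    labels = label_measurements(measurements)
    mean_fi = {m.peptide_id: m.mean for m in measurements}
    amap = default_atom_type_map()
    X = featurize(peptides, amap)
    feat = {p.id: X[i] for i, p in enumerate(peptides)}

    tiling_index, counter = {}, {}
    for p in peptides:
        tiling_index[p.id] = counter.get(p.protein_id, 0)
        counter[p.protein_id] = tiling_index[p.id] + 1

    ids = [p.id for p in peptides if labels[p.id] is not Label.EXCLUDED]
    y = {i: labels[i] is Label.INTERACTING for i in ids}
    frac = np.mean([y[i] for i in ids])
    print(f"{len(ids)} labeled peptides, {frac:.1%} interacting")

    # hierarchical structure of the composition space (first 500 peptides)
    Z = ward_cluster(X[:500])
    io.write_table(
        pd.DataFrame(Z, columns=["left", "right", "height", "size"]),
        ROOT / "array_ward_linkage.csv",
    )

    reports = {
        "half_random": run_scheme("half_random", ids, feat, y, tiling_index),
        "every_third": run_scheme("every_third", ids, feat, y, tiling_index),
        "half_random_fi_floor_100": run_scheme(
            "half_random_fi100", ids, feat, y, tiling_index,
            fi_floor=100.0, mean_fi=mean_fi,
        ),
        "half_random_9_hidden_units": run_scheme(
            "half_random_9units", ids, feat, y, tiling_index, hidden_units=9
        ),
    }

    n_shared = composition_uniqueness(peptides)
    print(f"{n_shared} peptides share an amino-acid composition with another")
    reports["composition"] = {
        "n_peptides_sharing_composition": n_shared,
        "fraction_interacting": float(frac),
        "p_specific_sequence_20_15": sequence_identity_probability(20, 15),
        "p_mean_composition_20_15": mean_composition_probability(20, 15),
        "p_mean_composition_20_5": mean_composition_probability(20, 5),
    }
    (ROOT / "array_classification.json").write_text(json.dumps(reports, indent=1))
    print(f"wrote {ROOT / 'array_classification.json'}")


if __name__ == "__main__":
    main()
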