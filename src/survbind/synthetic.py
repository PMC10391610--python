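"""Ground-truth-tagged synthetic data for every pipeline stage.

Each generator is a deterministic function of (truth, design, seed), calls
the *same* mean functions the fitting modules use (so a zero-noise dataset
equals the model mean pointwise), and returns a :class:`GroundTruth` record
that serializes the exact generating parameters.

Default designs mirror the study conditions: a 16-capillary MST dilution
series (97 nM labeled constant, unlabeled two-fold series from 23.2 nM to
761 uM), a 4-concentration BLI ladder {3.7, 11.1, 33.3, 100} nM with 600 s
association / 1200 s dissociation, a 10-point log-spaced NMR titration with
<= 5% noise, and a peptide array of 15-mers (10-residue overlap) in which a
hidden composition rule makes about 40% of peptides interacting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import bli, mst, nmr
from .atom_types import AtomTypeMap, default_atom_type_map
from .peptide_array import ArrayMeasurement, Peptide, featurize, tile_protein

# ---------------------------------------------------------------------------
# ground truth record


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating parameters of one synthetic dataset."""

    model: str
    params: dict
    design: dict
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        text = json.dumps(_clean(asdict(self)), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return GroundTruth(**data)


# ---------------------------------------------------------------------------
# MST


@dataclass(frozen=True)
class MSTParameters:
    """Generating parameters; scalars broadcast over capillaries.

    The default exponential rates sit in the bulk of the model's
    LogNormal(0, 1) rate priors; a much slower nu2 would be locally
    indistinguishable from the free linear drift over the 25 s heating
    window and would leave the amplitude curve (hence Kd) unidentified.
    """

    Kd: float = 2000.0  # nM
    U: float = 0.15
    B: float = 0.45
    epsilon: float = 0.005
    R: float = 0.7
    nu0: float = 0.001  # 1/s
    nu1: float = 2.0  # 1/s, fast (T-jump-like) process
    nu2: float = 0.4  # 1/s, slow (thermophoretic) process


def default_mst_concentrations(
    labeled_nM: float = 97.0, top_unlabeled_nM: float = 761e3, n: int = 16
) -> np.ndarray:
    """Total chain concentrations of the two-fold dilution design (nM)."""
    unlabeled = top_unlabeled_nM / 2.0 ** np.arange(n)[::-1]
    return unlabeled + labeled_nM


def gen_mst(
    truth: MSTParameters = MSTParameters(),
    concentrations: np.ndarray | None = None,
    t_start: float = -5.0,
    t_end: float = 25.0,
    dt: float = 0.5,
    seed: int = 0,
) -> tuple[list[mst.MSTCapillary], GroundTruth]:
    """Simulate an MST dilution series on the grid [t_start, t_end] step dt."""
    if concentrations is None:
        concentrations = default_mst_concentrations()
    concentrations = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    times = np.arange(t_start, t_end + dt / 2, dt)
    capillaries = []
    for i, c in enumerate(concentrations, start=1):
        alpha = mst.degree_of_association(c, truth.Kd)
        a_total = truth.U + (truth.B - truth.U) * alpha
        mean = mst.progress_mean(
            times, truth.nu0, truth.nu1, truth.nu2, truth.R, a_total
        )
        y = mean + truth.epsilon * rng.standard_normal(times.size)
        capillaries.append(
            mst.MSTCapillary(index=i, c_total=float(c), times=times, fluorescence=y)
        )
    gt = GroundTruth(
        model="mst",
        params=asdict(truth),
        design={
            "c_total_nM": concentrations,
            "t_start_s": t_start,
            "t_end_s": t_end,
            "dt_s": dt,
        },
        seed=seed,
    )
    return capillaries, gt


# ---------------------------------------------------------------------------
# BLI


@dataclass(frozen=True)
class BLIParameters:
    KD_app: float = 10e-9  # M
    k_off: float = 1e-3  # 1/s
    A: float = 1.0
    epsilon: float = 0.005


def gen_bli(
    truth: BLIParameters = BLIParameters(),
    concs_nM: tuple[float, ...] = (3.7, 11.1, 33.3, 100.0),
    assoc_span: float = 600.0,
    dissoc_span: float = 1200.0,
    rate_hz: float = 1.0,
    seed: int = 0,
) -> tuple[list[bli.BLITrace], GroundTruth]:
    """Simulate association/dissociation traces for a concentration ladder.

    The dissociation phase starts at the *noise-free* association endpoint,
    so the empirical-Bayes delta0 prior is tested honestly (the fit still
    treats delta0 as unknown).
    """
    rng = np.random.default_rng(seed)
    k_on = truth.k_off / truth.KD_app
    dt = 1.0 / rate_hz
    t_assoc = np.arange(0.0, assoc_span + dt / 2, dt)
    t_dissoc = np.arange(0.0, dissoc_span + dt / 2, dt)
    traces = []
    for c_nM in concs_nM:
        c = c_nM * 1e-9
        mean_a = bli.association_mean(t_assoc, c, truth.KD_app, k_on, truth.k_off, truth.A)
        delta0 = bli.association_mean(
            assoc_span, c, truth.KD_app, k_on, truth.k_off, truth.A
        )
        mean_d = bli.dissociation_mean(t_dissoc, delta0, truth.k_off)
        traces.append(
            bli.BLITrace(
                trace_id=f"{c_nM:g}nM",
                conc=c,
                t_assoc=t_assoc,
                y_assoc=mean_a + truth.epsilon * rng.standard_normal(t_assoc.size),
                t_dissoc=t_dissoc,
                y_dissoc=mean_d + truth.epsilon * rng.standard_normal(t_dissoc.size),
            )
        )
    gt = GroundTruth(
        model="bli",
        params=asdict(truth),
        design={
            "concs_nM": list(concs_nM),
            "assoc_span_s": assoc_span,
            "dissoc_span_s": dissoc_span,
            "rate_hz": rate_hz,
        },
        seed=seed,
    )
    return traces, gt


# ---------------------------------------------------------------------------
# NMR


@dataclass(frozen=True)
class CPCParameters:
    """Logistic truth; the default decays from 1 at low c to b at high c
    (k < 0), emulating the loss of free-protein signal with added peptide."""

    log10_cpc: float = -2.68  # cpc ~ 2.1 uM in dimensionless (mM) units
    k: float = -5.0
    L: float = 0.6
    b: float = 0.4
    epsilon: float = 0.02


def default_nmr_concentrations(
    low_uM: float = 0.1, high_uM: float = 3000.0, n: int = 10
) -> np.ndarray:
    """Log-spaced titration grid, dimensionless (c / 1 mM)."""
    return np.geomspace(low_uM * 1e-3, high_uM * 1e-3, n)


def gen_nmr(
    truth: CPCParameters = CPCParameters(),
    conc: np.ndarray | None = None,
    seed: int = 0,
    peptide_id: str = "synthetic",
) -> tuple[nmr.NMRTitrationSeries, GroundTruth]:
    """Simulate a normalized-intensity titration series."""
    if conc is None:
        conc = default_nmr_concentrations()
    conc = np.asarray(conc, dtype=float)
    rng = np.random.default_rng(seed)
    mean = nmr.logistic_mean(conc, truth.log10_cpc, truth.k, truth.L, truth.b)
    series = nmr.NMRTitrationSeries(
        peptide_id, conc, mean + truth.epsilon * rng.standard_normal(conc.size)
    )
    gt = GroundTruth(
        model="nmr_cpc",
        params=asdict(truth),
        design={"conc_mM": conc},
        seed=seed,
    )
    return series, gt


# ---------------------------------------------------------------------------
# peptide array

# Swiss-Prot-like amino-acid background frequencies (percent); natural
# sequences are compositionally biased, unlike a uniform alphabet.
AA_FREQUENCIES = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

FI_MAX = 64193.0  # 16-bit scanner ceiling


@dataclass(frozen=True)
class ArrayGroundTruth:
    """Array-specific truth: hidden rule and per-peptide labels."""

    rule_weights: np.ndarray
    rule_threshold: float
    rule_labels: dict[str, bool]  # noiseless hidden-rule labels
    true_labels: dict[str, bool]  # after label noise; drive the intensities
    meta: GroundTruth = field(default=None)  # type: ignore[assignment]


def random_protein(rng: np.random.Generator, length: int) -> str:
    letters = list(AA_FREQUENCIES)
    p = np.array([AA_FREQUENCIES[a] for a in letters])
    return "".join(rng.choice(letters, size=length, p=p / p.sum()))


def gen_peptide_array(
    n_proteins: int = 60,
    length_range: tuple[int, int] = (200, 700),
    atom_map: AtomTypeMap | None = None,
    interacting_fraction: float = 0.40,
    label_noise: float = 0.0,
    duplicate_cv: float = 0.10,
    intensity_median: float = 1500.0,
    intensity_sigma: float = 1.0,
    hidden_rule_seed: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[Peptide], list[ArrayMeasurement], ArrayGroundTruth]:
    """Simulate a tiled peptide array with a hidden composition rule.

    Random protein-like sequences are tiled into 15-mers (10-overlap); a
    linear rule over standardized atom-composition features, thresholded at
    the (1 - interacting_fraction) score quantile, assigns the hidden label
    (the steep limit of a logistic interaction probability).  ``label_noise``
    flips that fraction of labels before intensities are drawn; interacting
    peptides get log-normal intensities truncated at the 16-bit scanner
    maximum, and duplicates are perturbed with relative noise
    ``duplicate_cv``.
    """
    if length_range[0] < 15:
        raise ValueError("protein lengths must be >= 15")
    if atom_map is None:
        atom_map = default_atom_type_map()
    rng = np.random.default_rng(seed)
    rule_rng = np.random.default_rng(
        seed if hidden_rule_seed is None else hidden_rule_seed
    )

    proteins: dict[str, str] = {}
    peptides: list[Peptide] = []
    for i in range(n_proteins):
        pid = f"prot{i + 1:03d}"
        seq = random_protein(rng, int(rng.integers(length_range[0], length_range[1] + 1)))
        proteins[pid] = seq
        peptides.extend(tile_protein(seq, protein_id=pid))

    features = featurize(peptides, atom_map).astype(float)
    mu = features.mean(axis=0)
    sd = np.where(features.std(axis=0) > 0, features.std(axis=0), 1.0)
    weights = rule_rng.standard_normal(features.shape[1])
    scores = (features - mu) / sd @ weights
    threshold = float(np.quantile(scores, 1.0 - interacting_fraction))
    rule_labels = scores > threshold

    flips = rng.random(len(peptides)) < label_noise
    true_labels = rule_labels ^ flips

    measurements: list[ArrayMeasurement] = []
    for pep, interacting in zip(peptides, true_labels):
        if interacting:
            fi = min(
                float(
                    np.exp(
                        np.log(intensity_median)
                        + intensity_sigma * rng.standard_normal()
                    )
                ),
                FI_MAX,
            )
        else:
            fi = 0.0
        reps = np.clip(
            fi * (1.0 + duplicate_cv * rng.standard_normal(2)), 0.0, FI_MAX
        )
        measurements.append(
            ArrayMeasurement(pep.id, float(reps[0]), float(reps[1]))
        )

    meta = GroundTruth(
        model="peptide_array",
        params={
            "interacting_fraction": interacting_fraction,
            "label_noise": label_noise,
            "duplicate_cv": duplicate_cv,
            "intensity_median": intensity_median,
            "intensity_sigma": intensity_sigma,
        },
        design={
            "n_proteins": n_proteins,
            "length_range": list(length_range),
            "n_peptides": len(peptides),
        },
        seed=seed,
    )
    gt = ArrayGroundTruth(
        rule_weights=weights,
        rule_threshold=threshold,
        rule_labels={p.id: bool(l) for p, l in zip(peptides, rule_labels)},
        true_labels={p.id: bool(l) for p, l in zip(peptides, true_labels)},
        meta=meta,
    )
    return proteins, peptides, measurements, gt
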