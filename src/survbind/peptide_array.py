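"""Peptide-microarray analysis: tiling, featurization, labeling, clustering,
classification and composition combinatorics.

The array design tiles each protein into 15-mers with a 10-residue overlap.
Duplicate fluorescence measurements are reduced to binary interaction labels
(zero mean intensity, or duplicates disagreeing by more than 40% relative
variation, mean non-interacting).  Peptides are represented by their
heavy-atom composition (see :mod:`survbind.atom_types`) and a multi-layer
perceptron is trained to predict the label from composition alone.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import balanced_accuracy_score
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .atom_types import STANDARD_RESIDUES, AtomTypeMap

WINDOW = 15
OVERLAP = 10


class Label(str, Enum):
    INTERACTING = "interacting"
    NON_INTERACTING = "non_interacting"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class Peptide:
    """One tiled array element.

    ``start`` is the 1-based position of the first *natural* residue in the
    parent protein; ``filler_mask`` flags synthetic filler positions (a
    contiguous prefix and/or suffix), which are not part of the natural
    sequence.
    """

    id: str
    protein_id: str
    start: int
    sequence: str
    filler_mask: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.filler_mask is None:
            object.__setattr__(self, "filler_mask", (False,) * len(self.sequence))
        if len(self.filler_mask) != len(self.sequence):
            raise ValueError("filler_mask length must match sequence length")
        if self.start < 1:
            raise ValueError("start must be >= 1")

    @property
    def natural_sequence(self) -> str:
        return "".join(
            r for r, f in zip(self.sequence, self.filler_mask) if not f
        )

    @property
    def natural_positions(self) -> range:
        n = sum(not f for f in self.filler_mask)
        return range(self.start, self.start + n)


@dataclass(frozen=True)
class ArrayMeasurement:
    """Duplicate fluorescence intensities for one peptide (16-bit scale)."""

    peptide_id: str
    fi_rep1: float
    fi_rep2: float

    def __post_init__(self) -> None:
        for v in (self.fi_rep1, self.fi_rep2):
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.peptide_id}: intensities must be finite and >= 0"
                )

    @property
    def mean(self) -> float:
        return 0.5 * (self.fi_rep1 + self.fi_rep2)


@dataclass(frozen=True)
class ClassificationReport:
    """2x2 confusion counts (rows true, cols predicted; class order
    [non_interacting, interacting]) plus derived per-class metrics."""

    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    balanced_accuracy: float


@dataclass(frozen=True)
class SplitScheme:
    scheme: str = "half_random"  # or "every_third"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("half_random", "every_third"):
            raise ValueError(f"unknown split scheme {self.scheme!r}")


@dataclass(frozen=True)
class ClassifierConfig:
    hidden_units: int = 100
    feature_standardization: bool = True
    seed: int = 0
    fi_floor: float = 0.0
    max_epochs: int = 200

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


# ---------------------------------------------------------------------------
# tiling


def _validate_sequence(sequence: str, context: str = "sequence") -> str:
    sequence = sequence.upper()
    for i, ch in enumerate(sequence, start=1):
        if ch not in STANDARD_RESIDUES:
            raise ValueError(
                f"{context}: non-standard residue {ch!r} at position {i}"
            )
    return sequence


def tile_protein(
    sequence: str,
    protein_id: str = "protein",
    window: int = WINDOW,
    overlap: int = OVERLAP,
    mode: str = "anchor_cterm",
    filler_residue: str = "G",
) -> list[Peptide]:
    """Tile a protein into overlapping window-length peptides.

    Consecutive tiles share exactly ``overlap`` natural residues.  When the
    sequence length does not fit the stride, the terminal tile is either
    right-anchored at the C-terminus (``anchor_cterm``, so it overlaps its
    predecessor by more than ``overlap``) or padded with ``filler_residue``
    and flagged in ``filler_mask`` (``filler`` mode).  Every natural residue
    is covered by at least one tile.
    """
    if mode not in ("anchor_cterm", "filler"):
        raise ValueError(f"unknown tiling mode {mode!r}")
    if not 0 <= overlap < window:
        raise ValueError("require 0 <= overlap < window")
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    sequence = _validate_sequence(sequence, protein_id)

    step = window - overlap
    L = len(sequence)
    peptides: list[Peptide] = []

    if L <= window:
        starts: list[int] = [1]
    else:
        starts = list(range(1, L - window + 2, step))
        last_end = starts[-1] + window - 1
        if last_end < L:
            if mode == "anchor_cterm":
                starts.append(L - window + 1)
            else:
                starts.append(starts[-1] + step)

    for s in starts:
        chunk = sequence[s - 1 : s - 1 + window]
        pad = window - len(chunk)
        mask = (False,) * len(chunk) + (True,) * pad
        peptides.append(
            Peptide(
                id=f"{protein_id}_{s}",
                protein_id=protein_id,
                start=s,
                sequence=chunk + filler_residue * pad,
                filler_mask=mask,
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# featurization


def featurize(peptides: list[Peptide], amap: AtomTypeMap) -> np.ndarray:
    """Atom-composition matrix: one row per peptide, columns = categories.

    Each row is the sum of the per-residue atom-count vectors of the
    peptide's residues (filler included: the filler is physically present on
    the chip).  Additive and order-free by construction.
    """
    if not peptides:
        return np.zeros((0, len(amap.categories)), dtype=int)
    return np.stack([amap.as_matrix(p.sequence).sum(axis=0) for p in peptides])


# ---------------------------------------------------------------------------
# labeling


def label_measurements(
    measurements: list[ArrayMeasurement],
    exclusion_ids: set[str] = frozenset(),
    rel_var_threshold: float = 0.40,
) -> dict[str, Label]:
    """Assign interaction labels from duplicate intensities.

    excluded if the id is on the exclusion list (e.g. His-rich peptides
    cross-reacting with the anti-His antibody); non-interacting if the
    duplicate mean is zero or the duplicates differ by more than
    ``rel_var_threshold`` relative to their mean; interacting otherwise.
    """
    labels: dict[str, Label] = {}
    for m in measurements:
        if m.peptide_id in exclusion_ids:
            labels[m.peptide_id] = Label.EXCLUDED
            continue
        mean = m.mean
        if mean == 0:
            labels[m.peptide_id] = Label.NON_INTERACTING
        elif abs(m.fi_rep1 - m.fi_rep2) / mean > rel_var_threshold:
            labels[m.peptide_id] = Label.NON_INTERACTING
        else:
            labels[m.peptide_id] = Label.INTERACTING
    return labels


def propose_his_exclusions(peptides: list[Peptide], min_his: int = 5) -> set[str]:
    """Flag peptides with >= ``min_his`` histidines as candidate exclusions
    (His-rich peptides bind the anti-His detection antibody)."""
    return {p.id for p in peptides if p.sequence.count("H") >= min_his}


# ---------------------------------------------------------------------------
# clustering


def ward_cluster(features: np.ndarray) -> np.ndarray:
    """Ward hierarchical clustering on Euclidean distances.

    Returns the standard 4-column merge table (left, right, height, size)
    with n-1 rows for n observations.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need at least two observations to cluster")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain missing/non-finite values")
    return linkage(features, method="ward", metric="euclidean")


# ---------------------------------------------------------------------------
# train/test splitting


def split_dataset(
    peptide_ids: list[str],
    scheme: SplitScheme,
    tiling_index: dict[str, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Partition labeled peptides into train and test sets.

    ``half_random``: a seeded permutation split into halves differing in size
    by at most one.  ``every_third``: retain only every third peptide of each
    protein's tiling order (removing all sequence overlap between retained
    15-mers, since 3 tiles x 5-residue step spans the full window), then split
    the retained set in half.  ``tiling_index`` maps peptide id to its 0-based
    index within its protein's tiling order and is required for
    ``every_third``.
    """
    ids = list(peptide_ids)
    if len(ids) < 2:
        raise ValueError("need at least two peptides to split")
    if scheme.scheme == "every_third":
        if tiling_index is None:
            raise ValueError("every_third requires tiling_index")
        ids = [i for i in ids if tiling_index[i] % 3 == 0]
        if len(ids) < 2:
            raise ValueError("fewer than two peptides retained by every_third")
    rng = np.random.default_rng(scheme.seed)
    perm = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    train = [ids[i] for i in sorted(perm[:half])]
    test = [ids[i] for i in sorted(perm[half:])]
    return train, test


# ---------------------------------------------------------------------------
# classification


def precision_recall(
    confusion: np.ndarray, decimals: int | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-class precision and recall from a 2x2 confusion matrix.

    Rows are true classes, columns predicted, class order
    [non_interacting, interacting].  A class with zero predicted (precision)
    or zero true (recall) members yields NaN with a warning rather than 0.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2):
        raise ValueError("confusion matrix must be 2x2")
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be non-negative")
    if confusion.sum() == 0:
        raise ValueError("confusion matrix is empty")
    classes = [Label.NON_INTERACTING.value, Label.INTERACTING.value]
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    for k, cls in enumerate(classes):
        pred = confusion[:, k].sum()
        true = confusion[k, :].sum()
        if pred == 0:
            warnings.warn(f"precision undefined for {cls}: no predictions")
            precision[cls] = math.nan
        else:
            precision[cls] = float(confusion[k, k] / pred)
        if true == 0:
            warnings.warn(f"recall undefined for {cls}: no true members")
            recall[cls] = math.nan
        else:
            recall[cls] = float(confusion[k, k] / true)
    if decimals is not None:
        precision = {c: round(v, decimals) for c, v in precision.items()}
        recall = {c: round(v, decimals) for c, v in recall.items()}
    return precision, recall


def train_and_evaluate(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> ClassificationReport:
    """Train the composition classifier and evaluate on held-out peptides.

    Labels are booleans (True = interacting).  Features are standardized with
    training-set mean/scale only.  The classifier is a single-hidden-layer
    perceptron (rectified units, adaptive-moment gradient training, fixed
    seed).
    """
    y_train = np.asarray(train_labels, dtype=bool)
    y_test = np.asarray(test_labels, dtype=bool)
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            "training set contains a single class; both interacting and "
            "non-interacting examples are required"
        )
    X_train = np.asarray(train_features, dtype=float)
    X_test = np.asarray(test_features, dtype=float)
    if config.feature_standardization:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)
    clf = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        max_iter=config.max_epochs,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # max_iter cap is intentional
        clf.fit(X_train, y_train)
    y_pred = clf.predict(X_test)

    confusion = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_test.astype(int), y_pred.astype(int)):
        confusion[t, p] += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall = precision_recall(confusion)
    return ClassificationReport(
        confusion=confusion,
        precision=precision,
        recall=recall,
        balanced_accuracy=float(balanced_accuracy_score(y_test, y_pred)),
    )


# ---------------------------------------------------------------------------
# composition combinatorics


def residue_composition(peptide: Peptide | str) -> tuple[int, ...]:
    """20-dimensional residue-count vector (alphabetical residue order)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    counts = Counter(seq)
    return tuple(counts.get(r, 0) for r in sorted(STANDARD_RESIDUES))


def composition_uniqueness(peptides: list[Peptide]) -> int:
    """Number of peptides that share their amino-acid composition with at
    least one other peptide on the array."""
    comps = Counter(residue_composition(p) for p in peptides)
    return sum(1 for p in peptides if comps[residue_composition(p)] > 1)


def sequence_identity_probability(alphabet: int = 20, length: int = WINDOW) -> float:
    """Probability of one specific sequence under a uniform residue model."""
    if alphabet < 1 or length < 1:
        raise ValueError("alphabet and length must be >= 1")
    return float(alphabet) ** (-length)


def composition_count(alphabet: int, length: int) -> int:
    """Number of distinct residue multisets: combination with repetition,
    C(alphabet + length - 1, length)."""
    return math.comb(alphabet + length - 1, length)


def mean_composition_probability(alphabet: int = 20, length: int = WINDOW) -> float:
    """Average probability of a signature composition, approximated as the
    reciprocal of the combination-with-repetition count."""
    if alphabet < 1 or length < 1:
        raise ValueError("alphabet and length must be >= 1")
    return 1.0 / composition_count(alphabet, length)
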