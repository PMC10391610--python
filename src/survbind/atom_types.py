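"""Atom-type taxonomy used to featurize peptides by heavy-atom composition.

Each of the 20 standard residues is described by the number of heavy atoms
it contributes to a fixed list of chemical categories.  Summing these
per-residue vectors over a peptide yields its atom-composition feature
vector, the input of the interaction classifier.

The default taxonomy distinguishes the four backbone atoms (N, CA, C', O)
and ten side-chain categories (aliphatic/aromatic/carboxamide carbons,
amide/basic/aromatic nitrogens, hydroxyl/amide/carboxylate oxygens and
sulfur).  Any alternative table — e.g. one transcribed from a published
supplementary file — can be loaded from YAML/JSON with
:func:`load_atom_type_map`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: side-chain categories; backbone categories are appended below
_SIDECHAIN_CATEGORIES = [
    "aliphatic_C",
    "aromatic_C",
    "carboxamide_C",  # sp2 carbon of amide, carboxylate and guanidinium groups
    "amide_N",
    "basic_N",
    "aromatic_N",
    "hydroxyl_O",
    "amide_O",
    "carboxylate_O",
    "sulfur",
]
_BACKBONE_CATEGORIES = ["backbone_N", "backbone_CA", "backbone_C", "backbone_O"]

DEFAULT_CATEGORIES = _SIDECHAIN_CATEGORIES + _BACKBONE_CATEGORIES

# side-chain heavy atoms per residue: {category: count}; backbone added uniformly
_SIDECHAINS: dict[str, dict[str, int]] = {
    "G": {},
    "A": {"aliphatic_C": 1},
    "V": {"aliphatic_C": 3},
    "L": {"aliphatic_C": 4},
    "I": {"aliphatic_C": 4},
    "P": {"aliphatic_C": 3},
    "F": {"aliphatic_C": 1, "aromatic_C": 6},
    "W": {"aliphatic_C": 1, "aromatic_C": 8, "aromatic_N": 1},
    "Y": {"aliphatic_C": 1, "aromatic_C": 6, "hydroxyl_O": 1},
    "S": {"aliphatic_C": 1, "hydroxyl_O": 1},
    "T": {"aliphatic_C": 2, "hydroxyl_O": 1},
    "C": {"aliphatic_C": 1, "sulfur": 1},
    "M": {"aliphatic_C": 3, "sulfur": 1},
    "N": {"aliphatic_C": 1, "carboxamide_C": 1, "amide_N": 1, "amide_O": 1},
    "Q": {"aliphatic_C": 2, "carboxamide_C": 1, "amide_N": 1, "amide_O": 1},
    "D": {"aliphatic_C": 1, "carboxamide_C": 1, "carboxylate_O": 2},
    "E": {"aliphatic_C": 2, "carboxamide_C": 1, "carboxylate_O": 2},
    "K": {"aliphatic_C": 4, "basic_N": 1},
    "R": {"aliphatic_C": 3, "carboxamide_C": 1, "basic_N": 3},
    "H": {"aliphatic_C": 1, "aromatic_C": 3, "aromatic_N": 2},
}


@dataclass(frozen=True)
class AtomTypeMap:
    """Mapping residue -> integer atom counts over a fixed category list."""

    categories: tuple[str, ...]
    counts: dict[str, np.ndarray]  # residue -> vector over categories

    def __post_init__(self) -> None:
        n = len(self.categories)
        missing = sorted(set(STANDARD_RESIDUES) - set(self.counts))
        if missing:
            raise ValueError(f"atom-type map is missing residues: {''.join(missing)}")
        for res, vec in self.counts.items():
            if vec.shape != (n,):
                raise ValueError(
                    f"residue {res!r}: count vector has length {vec.shape[0]}, "
                    f"expected {n}"
                )
            if np.any(vec < 0):
                raise ValueError(f"residue {res!r}: negative atom counts")

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(sorted(self.counts))

    def vector(self, residue: str) -> np.ndarray:
        try:
            return self.counts[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} not in atom-type map") from None

    def as_matrix(self, residues: str) -> np.ndarray:
        """Stack per-residue vectors for a residue string (rows in order)."""
        return np.stack([self.vector(r) for r in residues])

    def to_dict(self) -> dict:
        return {
            res: {
                cat: int(c)
                for cat, c in zip(self.categories, vec)
                if c  # sparse representation
            }
            for res, vec in sorted(self.counts.items())
        }


def default_atom_type_map() -> AtomTypeMap:
    """Default heavy-atom taxonomy over the 20 standard residues."""
    counts = {}
    for res in STANDARD_RESIDUES:
        vec = np.zeros(len(DEFAULT_CATEGORIES), dtype=int)
        for cat, c in _SIDECHAINS[res].items():
            vec[DEFAULT_CATEGORIES.index(cat)] = c
        for cat in _BACKBONE_CATEGORIES:
            vec[DEFAULT_CATEGORIES.index(cat)] = 1
        counts[res] = vec
    return AtomTypeMap(tuple(DEFAULT_CATEGORIES), counts)


def load_atom_type_map(path: str | Path) -> AtomTypeMap:
    """Load a residue -> {category: count} table from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or not data:
        raise ValueError(f"{path}: expected a residue -> counts mapping")
    categories = sorted({cat for entry in data.values() for cat in entry})
    counts = {}
    for res, entry in data.items():
        vec = np.zeros(len(categories), dtype=int)
        for cat, c in entry.items():
            vec[categories.index(cat)] = int(c)
        counts[str(res).upper()] = vec
    return AtomTypeMap(tuple(categories), counts)


def save_atom_type_map(amap: AtomTypeMap, path: str | Path) -> None:
    path = Path(path)
    data = amap.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data))
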