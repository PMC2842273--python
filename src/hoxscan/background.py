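"""Background residue composition and RANDOM control-class generation.

The control (CTL) class of every classifier version is anchored by
randomly generated sequences. Drawing them from the composition of the
actual training alignments (rather than a uniform alphabet) puts the
null class in a realistic region of profile-score space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import AA_INDEX, AMINO_ACIDS, SequenceRecord

#: BLOSUM62-style average protein composition; the default proto-consensus
#: sampling distribution for the synthetic generator.
BLOSUM62_BACKGROUND = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "Q": 0.034, "E": 0.054, "G": 0.074, "H": 0.026, "I": 0.068,
    "L": 0.099, "K": 0.058, "M": 0.025, "F": 0.047, "P": 0.039,
    "S": 0.057, "T": 0.051, "W": 0.013, "Y": 0.032, "V": 0.073,
}


@dataclass(frozen=True)
class Composition:
    """A probability distribution over the 20 amino acids."""

    frequencies: np.ndarray  # AMINO_ACIDS order

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.shape != (20,):
            raise ValueError("composition must cover exactly the 20 amino acids")
        if np.any(f < 0):
            raise ValueError("composition frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("composition frequencies must sum to 1")
        object.__setattr__(self, "frequencies", f)

    def frequency(self, residue: str) -> float:
        return float(self.frequencies[AA_INDEX[residue]])

    def as_dict(self) -> dict[str, float]:
        return {a: float(self.frequencies[i]) for i, a in enumerate(AMINO_ACIDS)}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, freqs: dict[str, float]) -> "Composition":
        f = np.array([freqs[a] for a in AMINO_ACIDS], dtype=float)
        return cls(f / f.sum())

    @classmethod
    def uniform(cls) -> "Composition":
        return cls(np.full(20, 1.0 / 20.0))

    @classmethod
    def blosum62(cls) -> "Composition":
        return cls.from_dict(BLOSUM62_BACKGROUND)


def estimate_composition(seqs: Sequence[SequenceRecord]) -> Composition:
    """Maximum-likelihood residue frequencies over all sequences ('X' excluded)."""
    if not seqs:
        raise ValueError("cannot estimate composition from an empty sequence set")
    counts = np.zeros(20)
    for s in seqs:
        for c in s.residues:
            i = AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no standard residues found in input sequences")
    return Composition(counts / total)


def generate_random_sequences(
    n: int,
    length: int = 60,
    composition: Composition | None = None,
    seed: int = 0,
    id_prefix: str = "RANDOM",
) -> list[SequenceRecord]:
    """Draw ``n`` i.i.d. random sequences from a residue composition.

    Sequences get ids ``RANDOM_0001`` onward and are fully reproducible
    from the seed.
    """
    if n < 1 or length < 1:
        raise ValueError("need n >= 1 and length >= 1")
    if composition is None:
        composition = Composition.blosum62()
    f = composition.frequencies
    if f.sum() <= 0 or np.all(f == 0):
        raise ValueError("degenerate composition: no probability mass")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))
    draws = rng.choice(20, size=(n, length), p=f)
    return [
        SequenceRecord(
            id=f"{id_prefix}_{i + 1:04d}",
            residues="".join(alphabet[draws[i]]),
        )
        for i in range(n)
    ]
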