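"""Synthetic homology families with controlled divergence.

The generator emulates the structure of the real classification task:
a handful of closely related homology groups (think ANT/CENT/POST and
the ParaHox groups GSX/XLOX/CDX), each a cloud of mutated copies of a
group consensus, plus random background decoys for the CTL class and,
optionally, a "HOMEO-like" decoy family standing in for non-Hox
homeodomain proteins: related to every group (it shares the
proto-consensus) yet belonging to none, and only modestly more diverged
than genuine group members — which is precisely why such sequences are
needed in the control class of non-relaxed classifier versions. All group consensuses descend from a
single seeded proto-consensus (an in-silico ProtoHox), so between-group
identity is tunable the way real paralogous groups are related.

Every draw is reproducible from the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .background import Composition, generate_random_sequences
from .seqio import AMINO_ACIDS, Alignment, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_GROUP_LABELS = ("ANT", "CENT", "POST", "GSX", "XLOX", "CDX")
HOMEO_LABEL = "HOMEO"
CTL_LABEL = "CTL"


@dataclass
class FamilySpec:
    """Parameters of one synthetic family set.

    ``groups`` maps each homology-group label to its consensus sequence
    (all the same length, default 60 — the homeodomain). Members are
    per-site mutated copies of the consensus; ``n_background`` adds
    random decoys labelled CTL. ``homeo_consensus`` (optional) defines a
    seventh decoy family of non-group homeodomain-like sequences for
    non-relaxed training; its members mutate at ``homeo_divergence``,
    slightly above the group rate so they resemble the groups without
    belonging to any.
    """

    groups: list[tuple[str, str]]
    n_per_group: int = 20
    substitution_rate: float = 0.15
    indel_rate: float = 0.01
    n_background: int = 100
    seed: int = 0
    composition: Composition = field(default_factory=Composition.blosum62)
    homeo_consensus: Optional[str] = None
    n_homeo: int = 0
    homeo_divergence: float = 0.20

    def __post_init__(self) -> None:
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        lengths = {len(c) for _, c in self.groups}
        if len(lengths) > 1:
            raise ValueError("group consensus sequences must have equal length")
        for rate in (self.substitution_rate, self.indel_rate, self.homeo_divergence):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if self.n_per_group < 1:
            raise ValueError("need n_per_group >= 1")


@dataclass
class FamilySet:
    """Output of :func:`make_family_set`."""

    records: list[SequenceRecord]          # members + homeo + background, in order
    labels: dict[str, str]                 # seq_id -> group label or CTL
    alignments: dict[str, Alignment]       # per-group ungapped training alignments
    spec: FamilySpec

    @property
    def group_labels(self) -> list[str]:
        return [g for g, _ in self.spec.groups]

    def background_ids(self) -> list[str]:
        return [r.id for r in self.records if r.id.startswith("RANDOM_")]

    def homeo_ids(self) -> list[str]:
        return [r.id for r in self.records if r.id.startswith(f"{HOMEO_LABEL}_")]


def _substitute(residues: str, rate: float, composition: Composition,
                rng: np.random.Generator) -> str:
    """Per-site substitution to a *different* residue drawn from composition."""
    if rate == 0.0:
        return residues
    out = list(residues)
    freqs = composition.frequencies
    alphabet = AMINO_ACIDS
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        orig = out[i]
        probs = freqs.copy()
        j = alphabet.find(orig)
        if j >= 0:
            probs[j] = 0.0
        total = probs.sum()
        if total <= 0:
            continue  # degenerate composition concentrated on the original
        out[i] = alphabet[rng.choice(20, p=probs / total)]
    return "".join(out)


def _apply_indels(residues: str, rate: float, composition: Composition,
                  rng: np.random.Generator) -> str:
    if rate == 0.0:
        return residues
    out = []
    freqs = composition.frequencies
    for c in residues:
        r = rng.random()
        if r < rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(AMINO_ACIDS[rng.choice(20, p=freqs)])
        out.append(c)
    if not out:
        out.append(residues[0])
    return "".join(out)


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float = 0.0,
    composition: Optional[Composition] = None,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate a sequence site-wise: substitutions first, then indels.

    Each site is substituted independently with probability
    ``substitution_rate`` (to a residue other than the original, drawn
    from the composition); indels are applied per-site with probability
    ``indel_rate`` (deletion or insertion with equal odds).
    """
    for rate in (substitution_rate, indel_rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("rates must be in [0, 1)")
    if composition is None:
        composition = Composition.blosum62()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mutated = _substitute(seq, substitution_rate, composition, rng)
    result = _apply_indels(mutated, indel_rate, composition, rng)
    if len(result) != len(seq):
        logger.debug("indels changed length %d -> %d", len(seq), len(result))
    return result


def _random_consensus(length: int, composition: Composition,
                      rng: np.random.Generator) -> str:
    draws = rng.choice(20, size=length, p=composition.frequencies)
    return "".join(AMINO_ACIDS[i] for i in draws)


def default_family_spec(
    seed: int = 0,
    n_groups: int = 6,
    length: int = 60,
    consensus_identity: float = 0.70,
    n_per_group: int = 20,
    substitution_rate: float = 0.15,
    indel_rate: float = 0.01,
    n_background: int = 100,
    n_homeo: int = 0,
    homeo_divergence: float = 0.20,
) -> FamilySpec:
    """Build the default 6-group spec from a seeded proto-consensus.

    All group consensuses are independent mutants of one proto sequence;
    with per-consensus divergence ``q`` the expected pairwise consensus
    identity is roughly ``(1 - q)^2``, so ``q = 1 - sqrt(identity)``.
    """
    if n_groups > len(DEFAULT_GROUP_LABELS):
        labels = list(DEFAULT_GROUP_LABELS) + [
            f"GRP{i}" for i in range(n_groups - len(DEFAULT_GROUP_LABELS))
        ]
    else:
        labels = list(DEFAULT_GROUP_LABELS[:n_groups])
    composition = Composition.blosum62()
    rng = np.random.default_rng(seed)
    proto = _random_consensus(length, composition, rng)
    q = 1.0 - float(np.sqrt(consensus_identity))
    groups = [
        (label, mutate_sequence(proto, q, 0.0, composition, rng))
        for label in labels
    ]
    homeo = mutate_sequence(proto, q, 0.0, composition, rng)
    return FamilySpec(
        groups=groups,
        n_per_group=n_per_group,
        substitution_rate=substitution_rate,
        indel_rate=indel_rate,
        n_background=n_background,
        seed=seed,
        composition=composition,
        homeo_consensus=homeo,
        n_homeo=n_homeo,
        homeo_divergence=homeo_divergence,
    )


def sample_group_members(
    consensus: str,
    n: int,
    substitution_rate: float,
    indel_rate: float,
    composition: Composition,
    rng: np.random.Generator,
    id_prefix: str,
) -> tuple[list[SequenceRecord], Alignment]:
    """Mutated copies of a consensus plus their ungapped true alignment.

    Substitution-only copies form the alignment rows (all the same
    length); indels are applied afterwards to produce the released,
    unaligned sequences.
    """
    records, rows = [], []
    for i in range(n):
        aligned = _substitute(consensus, substitution_rate, composition, rng)
        released = _apply_indels(aligned, indel_rate, composition, rng)
        seq_id = f"{id_prefix}_{i + 1:03d}"
        rows.append((seq_id, aligned))
        records.append(SequenceRecord(id=seq_id, residues=released))
    return records, Alignment.from_pairs(rows)


def make_family_set(spec: FamilySpec) -> FamilySet:
    """Generate the labelled sequence set and per-group training alignments."""
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    alignments: dict[str, Alignment] = {}
    for label, consensus in spec.groups:
        members, aln = sample_group_members(
            consensus, spec.n_per_group, spec.substitution_rate, spec.indel_rate,
            spec.composition, rng, id_prefix=label,
        )
        records.extend(members)
        alignments[label] = aln
        for m in members:
            labels[m.id] = label
    if spec.n_homeo > 0:
        if spec.homeo_consensus is None:
            raise ValueError("n_homeo > 0 requires a homeo_consensus")
        homeo, _ = sample_group_members(
            spec.homeo_consensus, spec.n_homeo, spec.homeo_divergence,
            spec.indel_rate, spec.composition, rng, id_prefix=HOMEO_LABEL,
        )
        records.extend(homeo)
        for m in homeo:
            labels[m.id] = CTL_LABEL
    if spec.n_background > 0:
        decoy_seed = int(rng.integers(2**31))
        decoys = generate_random_sequences(
            spec.n_background, length=len(spec.groups[0][1]),
            composition=spec.composition, seed=decoy_seed,
        )
        records.extend(decoys)
        for d in decoys:
            labels[d.id] = CTL_LABEL
    return FamilySet(records=records, labels=labels, alignments=alignments, spec=spec)


def sample_homeo_decoys(spec: FamilySpec, n: int, seed: int) -> list[SequenceRecord]:
    """Fresh held-out HOMEO-like decoys from the spec's homeo consensus."""
    if spec.homeo_consensus is None:
        raise ValueError("spec has no homeo consensus")
    rng = np.random.default_rng(seed)
    records, _ = sample_group_members(
        spec.homeo_consensus, n, spec.homeo_divergence, spec.indel_rate,
        spec.composition, rng, id_prefix=f"{HOMEO_LABEL}HELD",
    )
    return records
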