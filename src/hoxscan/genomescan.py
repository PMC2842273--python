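"""End-to-end classifier versions and proteome screening.

A *version* bundles everything needed to classify proteins: one
generalised profile per homology group, a trained discriminant, and a
candidate-filter threshold. Versions differ in their CTL training
composition — "relaxed" versions train the control class on random
sequences only (so divergent homeobox proteins can be forced into Hox
groups, useful for studying ParaHox/cnidarian genes), non-relaxed
versions add non-Hox homeodomain decoys so every non-Hox sequence is
returned as CTL.

Screening a proteome: candidates are first filtered by best profile
score (a profile-score analogue of an InterPro homeobox-domain filter),
then scored, classified, and — when gene coordinates are available —
reported as per-scaffold cluster layouts with transcription orientation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .background import Composition, estimate_composition, generate_random_sequences
from .discriminant import (
    CTL,
    DiscriminantModel,
    LabelledScores,
    Prediction,
    make_priors,
    predict,
    select_variables,
    train_discriminant,
)
from .profile import (
    GeneralisedProfile,
    ScoreTable,
    SubstitutionMatrix,
    build_profile,
    load_profiles,
    save_profiles,
    score_table,
)
from .seqio import Alignment, GeneCoordinate, SequenceRecord, read_alignment, read_fasta

logger = logging.getLogger(__name__)

RANDOM_ONLY = "random_only"
RANDOM_PLUS_HOMEO = "random_plus_homeo"


@dataclass
class VersionConfig:
    """Recipe for one classifier version.

    ``alignments`` maps homology-group labels to their training
    alignments. ``ctl_composition`` selects the control-class recipe:
    ``random_only`` (a relaxed version) or ``random_plus_homeo``
    (requires ``homeo_records``). The CTL prior defaults to the
    conservative 0.90, the rest spread equally over the groups.
    """

    name: str
    alignments: dict[str, Alignment]
    ctl_composition: str = RANDOM_PLUS_HOMEO
    homeo_records: Optional[list[SequenceRecord]] = None
    n_random: Optional[int] = None
    random_length: int = 60
    ctl_prior: float = 0.90
    priors: Optional[dict[str, float]] = None
    mode: str = "local"
    selection: bool = False
    pseudocount_weight: float = 1.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    max_gap_fraction: float = 0.5
    threshold_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.ctl_composition not in {RANDOM_ONLY, RANDOM_PLUS_HOMEO}:
            raise ValueError(f"unknown ctl_composition {self.ctl_composition!r}")
        if self.ctl_composition == RANDOM_PLUS_HOMEO and not self.homeo_records:
            raise ValueError("random_plus_homeo requires homeo_records")
        if not self.alignments:
            raise ValueError("version needs at least one group alignment")

    @property
    def relaxed(self) -> bool:
        return self.ctl_composition == RANDOM_ONLY

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VersionConfig":
        """Load a config whose alignment/homeo entries are file paths."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        alignments = {
            g: read_alignment(base / p) for g, p in raw.pop("alignments").items()
        }
        homeo = raw.pop("homeo_fasta", None)
        homeo_records = read_fasta(base / homeo) if homeo else None
        return cls(alignments=alignments, homeo_records=homeo_records, **raw)


@dataclass
class VersionBundle:
    """A trained version: profiles + discriminant + candidate threshold."""

    name: str
    profiles: list[GeneralisedProfile]
    model: DiscriminantModel
    threshold: float
    manifest: dict = field(default_factory=dict)

    @property
    def groups(self) -> list[str]:
        return [p.group for p in self.profiles]

    def score(self, seqs: Sequence[SequenceRecord], mode: str = "local") -> ScoreTable:
        return score_table(self.profiles, seqs, mode=mode)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_profiles(self.profiles, directory / "profiles.json")
        self.model.to_json(directory / "model.json")
        manifest = dict(self.manifest)
        manifest.update({"name": self.name, "threshold": self.threshold})
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "VersionBundle":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        return cls(
            name=manifest["name"],
            profiles=load_profiles(directory / "profiles.json"),
            model=DiscriminantModel.from_json(directory / "model.json"),
            threshold=float(manifest["threshold"]),
            manifest=manifest,
        )


def _alignment_hash(alignments: dict[str, Alignment]) -> str:
    h = hashlib.sha256()
    for group in sorted(alignments):
        h.update(group.encode())
        for row in alignments[group].rows:
            h.update(row.id.encode())
            h.update(row.residues.encode())
    return h.hexdigest()


def build_version(config: VersionConfig, seed: int = 0,
                  matrix: Optional[SubstitutionMatrix] = None) -> VersionBundle:
    """Train a classifier version from group alignments.

    Pipeline: build one profile per group; pool the ungapped alignment
    rows as the labelled Hox training set; generate RANDOM control
    sequences from the training composition (plus HOMEO decoys for
    non-relaxed versions); score everything; train the discriminant
    (with greedy variable selection if enabled); record the candidate
    threshold as the ``threshold_quantile`` of the RANDOM best-score
    null distribution. Deterministic given (config, seed).
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    groups = sorted(config.alignments)
    profiles = []
    for g in groups:
        try:
            profiles.append(
                build_profile(
                    config.alignments[g], matrix=matrix,
                    pseudocount_weight=config.pseudocount_weight,
                    gap_open=config.gap_open, gap_extend=config.gap_extend,
                    group=g, max_gap_fraction=config.max_gap_fraction,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"profile construction failed for group {g!r}") from exc

    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for g in groups:
        for rec in config.alignments[g].ungapped_records():
            rid = f"{g}:{rec.id}"
            records.append(SequenceRecord(id=rid, residues=rec.residues))
            labels[rid] = g

    composition = estimate_composition(records)
    max_class = max(sum(1 for v in labels.values() if v == g) for g in groups)
    n_random = config.n_random if config.n_random else max(200, 2 * max_class)
    rng = np.random.default_rng(seed)
    random_seed = int(rng.integers(2**31))
    randoms = generate_random_sequences(
        n_random, length=config.random_length, composition=composition,
        seed=random_seed,
    )
    records.extend(randoms)
    for r in randoms:
        labels[r.id] = CTL
    if not config.relaxed:
        for i, rec in enumerate(config.homeo_records):
            rid = f"HOMEO:{rec.id}"
            records.append(SequenceRecord(id=rid, residues=rec.residues))
            labels[rid] = CTL

    try:
        table = score_table(profiles, records, mode=config.mode)
    except Exception as exc:
        raise RuntimeError("training-set scoring failed") from exc

    data = LabelledScores(table=table, labels=labels)
    priors = config.priors if config.priors else make_priors(data.classes,
                                                             config.ctl_prior)
    selected = (
        select_variables(data, priors=priors, shrinkage="auto")
        if config.selection else groups
    )
    try:
        model = train_discriminant(data, priors=priors, shrinkage="auto",
                                   selected=selected)
    except Exception as exc:
        raise RuntimeError("discriminant training failed") from exc

    random_ids = [r.id for r in randoms]
    null_best = table.data.loc[random_ids].max(axis=1).to_numpy()
    threshold = float(np.quantile(null_best, config.threshold_quantile))

    manifest = {
        "package_version": _pkg_version,
        "seed": seed,
        "random_seed": random_seed,
        "n_random": n_random,
        "ctl_composition": config.ctl_composition,
        "ctl_prior": config.ctl_prior,
        "mode": config.mode,
        "matrix": matrix.name,
        "alignments_sha256": _alignment_hash(config.alignments),
        "selected_profiles": selected,
        "threshold_quantile": config.threshold_quantile,
    }
    return VersionBundle(
        name=config.name, profiles=profiles, model=model,
        threshold=threshold, manifest=manifest,
    )


def filter_homeodomain_candidates(
    proteins: Sequence[SequenceRecord],
    profiles: Sequence[GeneralisedProfile],
    min_best_score: float,
    mode: str = "local",
) -> list[SequenceRecord]:
    """Keep proteins whose best score over all profiles reaches the threshold.

    This is the screening analogue of requiring a homeobox-domain match
    before classification; with threshold 0 every protein passes.
    """
    if min_best_score < 0:
        raise ValueError("min_best_score must be >= 0")
    if min_best_score == 0:
        return list(proteins)
    table = score_table(profiles, proteins, mode=mode)
    best = table.data.max(axis=1)
    return [p for p in proteins if best[p.id] >= min_best_score]


@dataclass(frozen=True)
class LayoutEntry:
    seq_id: str
    predicted: str
    start: int
    end: int
    strand: str
    gap_to_previous: Optional[int]


@dataclass
class ClusterLayout:
    """Per-scaffold ordered layout of predicted (non-CTL) genes."""

    scaffolds: dict[str, list[LayoutEntry]]

    def to_text(self) -> str:
        lines = []
        for scaffold in sorted(self.scaffolds):
            lines.append(f"scaffold {scaffold}:")
            for e in self.scaffolds[scaffold]:
                gap = "" if e.gap_to_previous is None else f"  (+{e.gap_to_previous} bp)"
                arrow = "->" if e.strand == "+" else "<-"
                lines.append(
                    f"  {e.start:>10}..{e.end:<10} {arrow} {e.seq_id}"
                    f" [{e.predicted}]{gap}"
                )
        return "\n".join(lines)

    def to_gff3(self, path: str | Path, source: str = "hoxscan") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for scaffold in sorted(self.scaffolds):
                for e in self.scaffolds[scaffold]:
                    attrs = f"ID={e.seq_id};homology_group={e.predicted}"
                    fh.write(
                        f"{scaffold}\t{source}\tgene\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\t{attrs}\n"
                    )


def scan_proteome(
    proteins: Sequence[SequenceRecord],
    bundle: VersionBundle,
    coords: Optional[Sequence[GeneCoordinate]] = None,
    mode: str = "local",
) -> tuple[list[Prediction], Optional[ClusterLayout]]:
    """Screen a proteome: filter candidates, classify, lay out clusters.

    Returns predictions for candidate proteins (sorted by sequence id, so
    the result is independent of input order) and, when coordinates are
    given, a per-scaffold layout of the non-CTL predictions in coordinate
    order with inter-gene distances and strand.
    """
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in proteome")
    candidates = filter_homeodomain_candidates(
        proteins, bundle.profiles, bundle.threshold, mode=mode
    )
    if not candidates:
        return [], (ClusterLayout(scaffolds={}) if coords is not None else None)
    candidates = sorted(candidates, key=lambda p: p.id)
    table = bundle.score(candidates, mode=mode)
    predictions = predict(bundle.model, table)
    layout = None
    if coords is not None:
        coord_map = {c.seq_id: c for c in coords}
        scaffolds: dict[str, list] = {}
        for p in predictions:
            if p.predicted == CTL:
                continue
            c = coord_map.get(p.seq_id)
            if c is None:
                logger.warning(
                    "no coordinates for predicted gene %s; excluded from layout",
                    p.seq_id,
                )
                continue
            scaffolds.setdefault(c.scaffold, []).append((c, p))
        out: dict[str, list[LayoutEntry]] = {}
        for scaffold, entries in scaffolds.items():
            entries.sort(key=lambda cp: (cp[0].start, cp[0].seq_id))
            rows = []
            prev_end = None
            for c, p in entries:
                gap = None if prev_end is None else max(c.start - prev_end, 0)
                rows.append(
                    LayoutEntry(
                        seq_id=p.seq_id, predicted=p.predicted,
                        start=c.start, end=c.end, strand=c.strand,
                        gap_to_previous=gap,
                    )
                )
                prev_end = c.end
            out[scaffold] = rows
        layout = ClusterLayout(scaffolds=out)
    return predictions, layout
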