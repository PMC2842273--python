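"""Sequence, alignment, coordinate and table I/O in standard text formats.

Proteins and homeodomain alignments come in as (aligned) FASTA, gene
coordinates as GFF3 or BED, and score tables / predictions go out as TSV.
Internally coordinates are 0-based half-open regardless of the input
convention (GFF3 is 1-based inclusive, BED is already half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, in the column order used by
#: every score matrix in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence.

    Residues are upper-case; 'X' (and other IUPAC ambiguity letters) are
    tolerated and treated as unknown downstream. Gap characters are a
    hard error: aligned rows belong in :class:`Alignment`.
    """

    id: str
    residues: str
    description: str = ""
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if GAP in self.residues or "." in self.residues:
            raise ValueError(
                f"gap character in unaligned input (record {self.id!r})"
            )
        if not self.residues.isupper() or not self.residues.isalpha():
            raise ValueError(
                f"record {self.id!r}: residues must be upper-case letters"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRow:
    """One row of a multiple alignment; '-' marks gap columns."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("aligned row requires a non-empty id")
        if not self.residues:
            raise ValueError(f"empty alignment row {self.id!r}")

    def ungapped(self) -> SequenceRecord:
        return SequenceRecord(
            id=self.id,
            residues=self.residues.replace(GAP, ""),
            description=self.description,
        )


@dataclass(frozen=True)
class Alignment:
    """A multiple protein alignment with equal-width rows."""

    rows: tuple[AlignedRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment requires at least one row")
        object.__setattr__(self, "rows", tuple(self.rows))
        w = len(self.rows[0].residues)
        for row in self.rows:
            if len(row.residues) != w:
                raise ValueError(
                    f"ragged alignment: row {row.id!r} has width "
                    f"{len(row.residues)}, expected {w}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")

    @property
    def width(self) -> int:
        return len(self.rows[0].residues)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def column(self, i: int) -> str:
        return "".join(r.residues[i] for r in self.rows)

    def ungapped_records(self) -> list[SequenceRecord]:
        return [r.ungapped() for r in self.rows]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        return cls(tuple(AlignedRow(i, s) for i, s in pairs))


@dataclass(frozen=True)
class GeneCoordinate:
    """Genomic location of a gene model, 0-based half-open internally."""

    seq_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"coordinate {self.seq_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"coordinate {self.seq_id!r}: strand must be + or -")


def _clean_residues(raw: str, record_id: str) -> str:
    seq = str(raw).upper()
    if seq.endswith("*"):
        seq = seq.rstrip("*")
    if "*" in seq:
        logger.warning("record %s: internal '*' stop characters stripped", record_id)
        seq = seq.replace("*", "")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped protein sequences from a FASTA file.

    Lower-case residues are upper-cased; trailing/internal ``*`` stops are
    stripped (with a warning for internal ones). Gap characters, duplicate
    ids and empty entries raise ``ValueError`` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_residues(str(rec.seq), rec.id)
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        if GAP in seq or "." in seq:
            raise ValueError(
                f"gap character in unaligned input (record {rec.id!r} in {path})"
            )
        records.append(
            SequenceRecord(id=rec.id, residues=seq, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file ('-' gaps) into an :class:`Alignment`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(".", GAP)
        rows.append(AlignedRow(id=rec.id, residues=seq, description=rec.description))
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    return Alignment(tuple(rows))


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in alignment.rows
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_gff3(path: str | Path, feature_types: Sequence[str] = ("gene",)) -> list[GeneCoordinate]:
    """Read gene coordinates from GFF3 (1-based inclusive on disk).

    The feature ``ID`` attribute (falling back to ``Name``) keys each
    coordinate to a protein id.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    coords = []
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            seq_id = feat.attributes.get("ID", feat.attributes.get("Name", [feat.id]))[0]
            coords.append(
                GeneCoordinate(
                    seq_id=seq_id,
                    scaffold=feat.seqid,
                    start=feat.start - 1,  # to 0-based half-open
                    end=feat.end,
                    strand=feat.strand,
                )
            )
    return coords


def read_bed(path: str | Path) -> list[GeneCoordinate]:
    """Read BED (0-based half-open natively): chrom, start, end, name[, score, strand]."""
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"BED file {path} needs at least 4 columns (name required)")
    coords = []
    for _, row in df.iterrows():
        strand = str(row[5]) if df.shape[1] > 5 else "+"
        coords.append(
            GeneCoordinate(
                seq_id=str(row[3]),
                scaffold=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=strand,
            )
        )
    return coords


def write_predictions(predictions: Sequence, path: str | Path) -> None:
    """Write predictions as TSV: seq_id, predicted_class, one posterior per class.

    Posteriors are printed with 8 decimals; rows keep input order.
    """
    if not predictions:
        raise ValueError("no predictions to write")
    classes = list(predictions[0].posteriors.keys())
    with open(path, "w") as fh:
        fh.write("seq_id\tpredicted_class\t" + "\t".join(classes) + "\n")
        for p in predictions:
            if list(p.posteriors.keys()) != classes:
                raise ValueError("inconsistent class sets across predictions")
            vals = "\t".join(f"{p.posteriors[c]:.8f}" for c in classes)
            fh.write(f"{p.seq_id}\t{p.predicted}\t{vals}\n")


def read_predictions(path: str | Path) -> list:
    """Round-trip reader for :func:`write_predictions` output."""
    from .discriminant import Prediction

    path = Path(path)
    preds = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        classes = header[2:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            posteriors = {c: float(v) for c, v in zip(classes, parts[2:])}
            preds.append(
                Prediction(seq_id=parts[0], predicted=parts[1], posteriors=posteriors)
            )
    return preds


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (seq_id, class) TSV with header into a dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            seq_id, label = line.rstrip("\n").split("\t")[:2]
            labels[seq_id] = label
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tclass\n")
        for seq_id, label in labels.items():
            fh.write(f"{seq_id}\t{label}\n")
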