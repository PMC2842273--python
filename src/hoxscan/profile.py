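"""Generalised profiles: construction from group alignments and DP scoring.

A generalised profile is a position-specific scoring matrix over the 20
amino acids built from a multiple alignment of one homology group. Column
frequencies are extrapolated through a substitution matrix, so every
position assigns a finite score to every residue — including residues
never observed in the training column (e.g. a G-only column still scores
A better than W under BLOSUM62, because G→A substitutions are less
penalised than G→W). Queries are scored by affine-gap dynamic programming,
either locally (Smith–Waterman style, for full-length proteins) or
semiglobally (profile fully aligned, query ends free).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import AA_INDEX, AMINO_ACIDS, GAP, Alignment, SequenceRecord

logger = logging.getLogger(__name__)

_NEG = -1e30


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 20x20 residue substitution scores (AMINO_ACIDS order)."""

    scores: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.allclose(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(self, "scores", s)

    def score(self, a: str, b: str) -> float:
        return float(self.scores[AA_INDEX[a], AA_INDEX[b]])

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        s = np.empty((20, 20))
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                s[i, j] = m[a, b]
        return cls(scores=s, name="BLOSUM62")

    @classmethod
    def identity(cls, match: float = 1.0, mismatch: float = 0.0) -> "SubstitutionMatrix":
        s = np.full((20, 20), float(mismatch))
        np.fill_diagonal(s, float(match))
        return cls(scores=s, name="identity")


@dataclass
class GeneralisedProfile:
    """Per-position 20-residue score matrix plus affine gap penalties."""

    group: str
    match_scores: np.ndarray  # length x 20
    gap_open: float = 11.0
    gap_extend: float = 1.0
    n_training: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.match_scores, dtype=float)
        if m.ndim != 2 or m.shape[1] != 20 or m.shape[0] < 1:
            raise ValueError("match_scores must be (length >= 1) x 20")
        if not np.all(np.isfinite(m)):
            raise ValueError("match_scores must be finite for all 20 residues")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            # the affine convention: opening a gap costs at least extending
            # one; below this the per-run cost model is not well defined
            raise ValueError("gap_open must be >= gap_extend")
        self.match_scores = m

    @property
    def length(self) -> int:
        return int(self.match_scores.shape[0])

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "length": self.length,
            "alphabet": AMINO_ACIDS,
            "match_scores": [[round(float(v), 10) for v in row] for row in self.match_scores],
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "n_training": self.n_training,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneralisedProfile":
        return cls(
            group=d["group"],
            match_scores=np.asarray(d["match_scores"], dtype=float),
            gap_open=float(d["gap_open"]),
            gap_extend=float(d["gap_extend"]),
            n_training=int(d.get("n_training", 0)),
            provenance=d.get("provenance", {}),
        )


@dataclass(frozen=True)
class ProfileScore:
    """Best alignment score of one profile against one query."""

    seq_id: str
    group: str
    score: float
    start: int  # matched query segment, 0-based half-open
    end: int


def save_profiles(profiles: Sequence[GeneralisedProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_profiles(path: str | Path) -> list[GeneralisedProfile]:
    with open(path) as fh:
        return [GeneralisedProfile.from_dict(d) for d in json.load(fh)]


def extract_match_columns(alignment: Alignment, max_gap_fraction: float) -> Alignment:
    """Drop alignment columns whose gap fraction exceeds the threshold."""
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    keep = []
    n = alignment.n_rows
    for i in range(alignment.width):
        gaps = alignment.column(i).count(GAP)
        if gaps / n <= max_gap_fraction:
            keep.append(i)
    if not keep:
        raise ValueError("no match columns remain after gap filtering")
    rows = [
        (r.id, "".join(r.residues[i] for i in keep)) for r in alignment.rows
    ]
    return Alignment.from_pairs(rows)


def build_profile(
    alignment: Alignment,
    matrix: Optional[SubstitutionMatrix] = None,
    pseudocount_weight: float = 1.0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    group: str = "",
    max_gap_fraction: float = 0.5,
    background: Optional[np.ndarray] = None,
) -> GeneralisedProfile:
    """Build a generalised profile by substitution-matrix extrapolation.

    For each match position ``i`` and residue ``a``::

        match_scores[i][a] = sum_b f(b, i) * S(a, b)

    where ``f(b, i)`` are gap-excluded observed frequencies at column ``i``
    smoothed with ``pseudocount_weight`` pseudo-observations of the
    background composition, and ``S`` is the substitution matrix (default
    BLOSUM62). Unknown residues ('X' etc.) are excluded from the counts
    and logged. Columns that are entirely gaps raise an error.
    """
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be non-negative")
    matched = extract_match_columns(alignment, max_gap_fraction)
    L = matched.width
    counts = np.zeros((L, 20))
    n_unknown = 0
    for i in range(L):
        col = matched.column(i)
        for c in col:
            if c == GAP:
                continue
            j = AA_INDEX.get(c)
            if j is None:
                n_unknown += 1
                continue
            counts[i, j] += 1
    if n_unknown:
        logger.info(
            "profile %s: %d unknown residues treated as 'X' (no score contribution)",
            group, n_unknown,
        )
    col_totals = counts.sum(axis=1)
    if np.any(col_totals == 0):
        bad = int(np.argmax(col_totals == 0))
        raise ValueError(f"column {bad} has no observed residues (all gaps/unknown)")
    if background is None:
        background = counts.sum(axis=0)
        background = background / background.sum()
    background = np.asarray(background, dtype=float)
    w = float(pseudocount_weight)
    freqs = (counts + w * background[None, :]) / (col_totals[:, None] + w)
    match_scores = freqs @ matrix.scores
    return GeneralisedProfile(
        group=group,
        match_scores=match_scores,
        gap_open=gap_open,
        gap_extend=gap_extend,
        n_training=matched.n_rows,
        provenance={
            "matrix": matrix.name,
            "pseudocount_weight": w,
            "max_gap_fraction": max_gap_fraction,
        },
    )


def _query_indices(residues: str) -> np.ndarray:
    """Map residues to alphabet indices; unknown residues get -1 (score 0)."""
    return np.array([AA_INDEX.get(c, -1) for c in residues], dtype=np.int64)


def _tie_min(v1: np.ndarray, v2: np.ndarray, s1: np.ndarray, s2: np.ndarray):
    """Elementwise max of v1, v2 carrying start positions; ties take min start."""
    v = np.maximum(v1, v2)
    s = np.where(v1 > v2, s1, np.where(v2 > v1, s2, np.minimum(s1, s2)))
    return v, s


def _dp_align(
    S: np.ndarray, gap_open: float, gap_extend: float, local: bool
) -> tuple[float, int, int]:
    """Affine-gap DP of a profile (rows) against a query (columns).

    Returns (score, query_start, query_end). Local mode floors cell scores
    at zero and reports the maximal-scoring segment with deterministic
    tie-breaking (earliest start, then shortest segment). Semiglobal mode
    aligns the full profile with free query overhangs.

    Row-wise vectorisation: gaps that consume profile positions (state F)
    depend only on the previous row; gaps that consume query residues
    (state E) are resolved within a row with a running-maximum transform
    of the affine penalty. Assumes the affine convention
    ``gap_open >= gap_extend`` (enforced on profiles), under which each
    maximal gap run costs ``open + extend * (len - 1)``.
    """
    L, m = S.shape
    go, ge = float(gap_open), float(gap_extend)
    j_idx = np.arange(m + 1, dtype=np.int64)

    Hprev = np.zeros(m + 1)
    sHprev = j_idx.copy()
    Fprev = np.full(m + 1, _NEG)
    sFprev = j_idx.copy()

    best = 0.0 if local else _NEG
    best_start, best_end = 0, 0

    for i in range(L):
        F, sF = _tie_min(Hprev - go, Fprev - ge, sHprev, sFprev)
        # D: cells reached by a diagonal step or a profile-consuming gap
        diag = Hprev[:m] + S[i]
        D, sD = _tie_min(diag, F[1:], sHprev[:m], sF[1:])
        if local:
            D = np.maximum(D, 0.0)
            sD = np.where(D == 0.0, j_idx[1:], sD)
        # E: gaps consuming query residues, affine, resolved by running max
        E = np.full(m + 1, _NEG)
        sE = j_idx.copy()
        if m >= 2:
            A = D + ge * j_idx[1:]
            cummax = np.maximum.accumulate(A)
            prev = np.concatenate(([_NEG], cummax[:-1]))
            kpos = np.where(A > prev, j_idx[1:], 0)
            kpos = np.maximum.accumulate(kpos)  # earliest k attaining the max
            E[2:] = cummax[:-1] - go - ge * (j_idx[2:] - 1)
            sE[2:] = sD[kpos[:-1] - 1]
        H = np.empty(m + 1)
        sH = np.empty(m + 1, dtype=np.int64)
        if local:
            H[0], sH[0] = 0.0, 0
        else:
            H[0], sH[0] = F[0], sF[0]
        H[1:], sH[1:] = _tie_min(D, E[1:], sD, sE[1:])
        if local:
            zero = H == 0.0
            sH[zero] = j_idx[zero]

        if local or i == L - 1:
            rowmax = float(H.max())
            if rowmax >= best:
                cells = np.flatnonzero(H == rowmax)
                starts = sH[cells]
                order = np.lexsort((cells, starts))
                j = int(cells[order[0]])
                st = int(starts[order[0]])
                cand = (rowmax, st, j)
                cur = (best, best_start, best_end)
                if rowmax > best or (st, j) < (best_start, best_end) or cur[0] == _NEG:
                    best, best_start, best_end = cand

        Hprev, sHprev, Fprev, sFprev = H, sH, F, sF

    if local and best <= 0.0:
        return 0.0, 0, 0
    return best, best_start, best_end


def score_sequence(
    profile: GeneralisedProfile, seq: SequenceRecord, mode: str = "local"
) -> ProfileScore:
    """Score one query against one profile by affine-gap DP.

    Local mode returns the best positive-scoring segment (score 0, empty
    segment if none); semiglobal mode aligns the whole profile against the
    query with free leading/trailing query residues.
    """
    if mode not in {"local", "semiglobal"}:
        raise ValueError(f"unknown scoring mode {mode!r}")
    if len(seq) < 10:
        logger.debug("query %s is shorter than 10 residues", seq.id)
    qidx = _query_indices(seq.residues)
    S = np.zeros((profile.length, len(qidx)))
    known = qidx >= 0
    if known.any():
        S[:, known] = profile.match_scores[:, qidx[known]]
    score, start, end = _dp_align(
        S, profile.gap_open, profile.gap_extend, local=(mode == "local")
    )
    return ProfileScore(
        seq_id=seq.id, group=profile.group, score=float(score), start=start, end=end
    )


@dataclass
class ScoreTable:
    """Sequences x profiles matrix of alignment scores.

    One row per query (the per-sequence "vector of scores"), one column
    per homology-group profile; no missing cells.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("score table has missing cells")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sequence ids in score table")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate group labels in score table")
        self.data = self.data.astype(float)

    @property
    def seq_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> list[str]:
        return list(self.data.columns)

    def vector(self, seq_id: str, selected: Optional[Sequence[str]] = None) -> np.ndarray:
        cols = list(selected) if selected is not None else self.groups
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise KeyError(f"score table missing profiles: {missing}")
        return self.data.loc[seq_id, cols].to_numpy(dtype=float)

    def matrix(self, selected: Optional[Sequence[str]] = None) -> np.ndarray:
        cols = list(selected) if selected is not None else self.groups
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise KeyError(f"score table missing profiles: {missing}")
        return self.data[cols].to_numpy(dtype=float)

    def subset_rows(self, seq_ids: Sequence[str]) -> "ScoreTable":
        return ScoreTable(self.data.loc[list(seq_ids)].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "seq_id"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


def score_table(
    profiles: Sequence[GeneralisedProfile],
    seqs: Sequence[SequenceRecord],
    mode: str = "local",
) -> ScoreTable:
    """Score every sequence against every profile into a complete table."""
    if not profiles or not seqs:
        raise ValueError("need at least one profile and one sequence")
    groups = [p.group for p in profiles]
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group labels among profiles")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids among queries")
    values = np.empty((len(seqs), len(profiles)))
    for j, p in enumerate(profiles):
        for i, s in enumerate(seqs):
            values[i, j] = score_sequence(p, s, mode=mode).score
    return ScoreTable(pd.DataFrame(values, index=ids, columns=groups))
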