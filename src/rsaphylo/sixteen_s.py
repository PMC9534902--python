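"""16S rRNA gene pairwise distances.

Sequences are aligned globally (Needleman-Wunsch with affine gap
penalties, Gotoh recursion) and the distance between two aligned
sequences is the fraction of differing columns, where a run of
consecutive gap columns can count as a single difference ("onegap", the
mothur pairwise.seqs default), every gap column separately ("eachgap"),
or gap columns can be ignored ("nogaps").  A genome pair's distance is
the mean over all cross pairs of their 16S gene copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .distance import DistanceMatrix

VALID_CHARS = set("ACGTN")
DISTANCE_RULES = ("onegap", "eachgap", "nogaps")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme; defaults mirror mothur pairwise.seqs defaults.

    A gap run of length L scores gap_open + (L-1)*gap_extend.  'N' is
    scored as a mismatch against everything, including another 'N'.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    distance_rule: str = "onegap"
    count_ends: bool = True

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise AlignmentError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("gap penalties must be <= 0")
        if self.distance_rule not in DISTANCE_RULES:
            raise AlignmentError(f"distance_rule must be one of {DISTANCE_RULES}")

    def pair_score(self, a: str, b: str) -> float:
        if a == b and a != "N":
            return self.match
        return self.mismatch


def _check_seq(s: str, name: str) -> str:
    s = s.upper()
    if not s:
        raise AlignmentError(f"{name}: empty sequence")
    bad = set(s) - VALID_CHARS
    if bad:
        raise AlignmentError(f"{name}: invalid characters {sorted(bad)}")
    return s


def needleman_wunsch(
    s1: str, s2: str, scoring: AlignmentScoring | None = None
) -> tuple[str, str, float]:
    """Optimal global alignment under affine gaps (Gotoh).

    Returns (aligned_s1, aligned_s2, score).  Traceback ties prefer
    diagonal, then up (gap in s2), then left (gap in s1), so the output
    is deterministic.
    """
    scoring = scoring or AlignmentScoring()
    s1 = _check_seq(s1, "s1")
    s2 = _check_seq(s2, "s2")
    n, m = len(s1), len(s2)
    NEG = -np.inf
    go, ge = scoring.gap_open, scoring.gap_extend

    M = np.full((n + 1, m + 1), NEG)   # ends in (mis)match
    X = np.full((n + 1, m + 1), NEG)   # ends with gap in s2 (consumes s1; "up")
    Y = np.full((n + 1, m + 1), NEG)   # ends with gap in s1 (consumes s2; "left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge

    # row-vectorized fill; Y's within-row recursion is a running max:
    # Y[i,j] = ge*(j-1) + max_{j'<=j-1}( max(M,X)[i,j'] + go - ge*j' ),
    # with the Y[0,:] boundary folded in via the previous Y value.
    s2_arr = np.frombuffer(s2.encode(), dtype="S1")
    jidx = np.arange(1, m + 1, dtype=float)
    for i in range(1, n + 1):
        ci = s1[i - 1]
        sub = np.where(
            (s2_arr == ci.encode()) & (s2_arr != b"N"), scoring.match, scoring.mismatch
        )
        M[i, 1:] = np.maximum.reduce(
            [M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]]
        ) + sub
        X[i, 1:] = np.maximum.reduce(
            [M[i - 1, 1:] + go, X[i - 1, 1:] + ge, Y[i - 1, 1:] + go]
        )
        X[i, 0] = go + (i - 1) * ge
        base = np.maximum(M[i, :-1], X[i, :-1]) + go - ge * (jidx - 1.0)
        Y[i, 1:] = np.maximum.accumulate(base) + ge * (jidx - 1.0)

    # traceback: state priority M (diagonal) > X (up) > Y (left)
    i, j = n, m
    best = max(M[i, j], X[i, j], Y[i, j])
    state = "M" if M[i, j] == best else ("X" if X[i, j] == best else "Y")
    a1, a2 = [], []
    while i > 0 or j > 0:
        if state == "M":
            sub = scoring.pair_score(s1[i - 1], s2[j - 1])
            prev = M[i, j] - sub
            for prev_state, val in (("M", M[i - 1, j - 1]),
                                    ("X", X[i - 1, j - 1]),
                                    ("Y", Y[i - 1, j - 1])):
                if np.isclose(val, prev):
                    break
            a1.append(s1[i - 1])
            a2.append(s2[j - 1])
            i -= 1
            j -= 1
            state = prev_state
        elif state == "X":
            cur = X[i, j]
            for prev_state, val in (("M", M[i - 1, j] + go),
                                    ("X", X[i - 1, j] + ge),
                                    ("Y", Y[i - 1, j] + go)):
                if np.isclose(val, cur):
                    break
            a1.append(s1[i - 1])
            a2.append("-")
            i -= 1
            state = prev_state
        else:
            cur = Y[i, j]
            for prev_state, val in (("M", M[i, j - 1] + go),
                                    ("X", X[i, j - 1] + go),
                                    ("Y", Y[i, j - 1] + ge)):
                if np.isclose(val, cur):
                    break
            a1.append("-")
            a2.append(s2[j - 1])
            j -= 1
            state = prev_state
    return "".join(reversed(a1)), "".join(reversed(a2)), float(best)


def alignment_score(a1: str, a2: str, scoring: AlignmentScoring | None = None) -> float:
    """Score of an already-aligned pair under the same gap convention."""
    scoring = scoring or AlignmentScoring()
    if len(a1) != len(a2):
        raise AlignmentError("aligned sequences differ in length")
    score = 0.0
    in_gap1 = in_gap2 = False
    for c1, c2 in zip(a1, a2):
        if c1 == "-":
            score += scoring.gap_extend if in_gap1 else scoring.gap_open
            in_gap1, in_gap2 = True, False
        elif c2 == "-":
            score += scoring.gap_extend if in_gap2 else scoring.gap_open
            in_gap1, in_gap2 = False, True
        else:
            score += scoring.pair_score(c1, c2)
            in_gap1 = in_gap2 = False
    return score


def seq_distance(a1: str, a2: str, scoring: AlignmentScoring | None = None) -> float:
    """Distance in [0,1] between two aligned sequences.

    Columns where both sequences have a base are counted, with a
    difference when the bases differ (or either is N).  Gap-column runs
    count per distance_rule; count_ends=False excludes terminal gap runs
    from both counts.
    """
    scoring = scoring or AlignmentScoring()
    if len(a1) != len(a2):
        raise AlignmentError("aligned sequences differ in length")
    L = len(a1)
    gap_col = [(a1[k] == "-") != (a2[k] == "-") for k in range(L)]
    if any(a1[k] == "-" and a2[k] == "-" for k in range(L)):
        raise AlignmentError("column with gaps in both sequences")

    start, end = 0, L
    if not scoring.count_ends:
        while start < L and gap_col[start]:
            start += 1
        while end > start and gap_col[end - 1]:
            end -= 1

    counted = 0
    diffs = 0
    k = start
    while k < end:
        if gap_col[k]:
            run_len = 0
            while k < end and gap_col[k]:
                run_len += 1
                k += 1
            if scoring.distance_rule == "onegap":
                counted += 1
                diffs += 1
            elif scoring.distance_rule == "eachgap":
                counted += run_len
                diffs += run_len
            # nogaps: run ignored
        else:
            counted += 1
            if a1[k] != a2[k] or a1[k] == "N":
                diffs += 1
            k += 1
    if counted == 0:
        return 0.0
    return diffs / counted


def pairwise_16s_distance(
    s1: str, s2: str, scoring: AlignmentScoring | None = None
) -> float:
    """Align two unaligned gene copies and return their distance."""
    a1, a2, _ = needleman_wunsch(s1, s2, scoring)
    return seq_distance(a1, a2, scoring)


def genome_pair_distance(
    a: Sequence[str], b: Sequence[str], scoring: AlignmentScoring | None = None
) -> float:
    """Mean pairwise distance over all cross pairs of 16S gene copies."""
    if not a or not b:
        raise AlignmentError("both genomes need at least one 16S sequence")
    dists = [pairwise_16s_distance(x, y, scoring) for x in a for y in b]
    return float(np.mean(dists))


def build_16s_matrix(
    genes: Mapping[str, Sequence[str]], scoring: AlignmentScoring | None = None
) -> tuple[DistanceMatrix, list[str]]:
    """Genome-level 16S distance matrix; genomes without sequences dropped.

    The matrix is accepted as-is for average-linkage clustering; the
    triangle inequality is not enforced.
    """
    kept = [g for g, seqs in genes.items() if seqs]
    dropped = [g for g in genes if g not in kept]
    if len(kept) < 2:
        raise AlignmentError("need at least 2 genomes with 16S sequences")
    n = len(kept)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = genome_pair_distance(
                genes[kept[i]], genes[kept[j]], scoring
            )
    return DistanceMatrix(kept, d), dropped


def read_16s_fasta(path: str | Path, separator: str = "|") -> dict[str, list[str]]:
    """Read a 16S FASTA with headers `>genomeID|copyN` into a GeneSet."""
    genes: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id.split(separator)[0]
        genes.setdefault(gid, []).append(_check_seq(str(rec.seq), rec.id))
    if not genes:
        raise AlignmentError(f"{path}: no sequences found")
    return genes


def write_16s_fasta(
    genes: Mapping[str, Sequence[str]], path: str | Path, separator: str = "|"
) -> None:
    with open(path, "w") as fh:
        for gid, seqs in genes.items():
            for k, s in enumerate(seqs, start=1):
                fh.write(f">{gid}{separator}{k}\n{s}\n")
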