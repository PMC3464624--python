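"""Pairwise global alignment and percent-difference utilities.

Two aligners are provided behind one interface:

* ``"edit"`` — unit-cost global (Needleman-Wunsch) alignment via edlib;
  very fast, used for all-pairs clone comparisons.
* ``"affine"`` — score-based global alignment (match +1, mismatch -1,
  gap open -5, gap extend -1) via Bio.Align; used where the shape of
  indel blocks matters (intron location).

Percent difference is the proportion of differing positions among
comparable columns: positions where either sequence has a gap or ``N``
are excluded from numerator and denominator.
"""

from __future__ import annotations

import re

import edlib
import numpy as np
from Bio import Align

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

AFFINE_MATCH = 1
AFFINE_MISMATCH = -1
AFFINE_OPEN = -5
AFFINE_EXTEND = -1


def _affine_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = AFFINE_MATCH
    al.mismatch_score = AFFINE_MISMATCH
    al.open_gap_score = AFFINE_OPEN
    al.extend_gap_score = AFFINE_EXTEND
    return al


def align_pair(a: str, b: str, method: str = "edit") -> tuple[str, str]:
    """Globally align two sequences; returns the two gapped strings."""
    a, b = a.upper(), b.upper()
    if method == "edit":
        res = edlib.align(a, b, mode="NW", task="path")
        ga, gb = [], []
        ia = ib = 0
        for num, op in _CIGAR_RE.findall(res["cigar"]):
            num = int(num)
            if op in "=XM":
                ga.append(a[ia:ia + num]); gb.append(b[ib:ib + num])
                ia += num; ib += num
            elif op == "I":  # insertion in query (a) relative to target (b)
                ga.append(a[ia:ia + num]); gb.append("-" * num)
                ia += num
            elif op == "D":
                ga.append("-" * num); gb.append(b[ib:ib + num])
                ib += num
        return "".join(ga), "".join(gb)
    if method == "affine":
        aln = _affine_aligner().align(a, b)[0]
        sa, sb = str(aln[0]), str(aln[1])
        return sa, sb
    raise ValueError(f"unknown alignment method {method!r}")


def percent_difference(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing positions among comparable aligned columns."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a = np.frombuffer(aligned_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(aligned_b.upper().encode(), dtype=np.uint8)
    bad = np.frombuffer(b"-N", dtype=np.uint8)
    mask = ~(np.isin(a, bad) | np.isin(b, bad))
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable (non-gap, non-N) columns")
    return float((a[mask] != b[mask]).sum() / n)


def pairwise_difference(a: str, b: str, method: str = "edit") -> float:
    """Percent difference between two sequences, aligning internally.

    Equal-length inputs are compared column-by-column without alignment
    (they are treated as already aligned); unequal lengths are globally
    aligned first.
    """
    a, b = a.upper(), b.upper()
    if len(a) == len(b):
        return percent_difference(a, b)
    if method == "edit" and "N" not in a and "N" not in b:
        # fast path: mismatch/match counts straight from the edlib cigar
        res = edlib.align(a, b, mode="NW", task="path")
        matches = mismatches = 0
        for num, op in _CIGAR_RE.findall(res["cigar"]):
            if op == "=":
                matches += int(num)
            elif op == "X":
                mismatches += int(num)
        comparable = matches + mismatches
        if comparable == 0:
            raise ValueError("no comparable (non-gap) columns")
        return mismatches / comparable
    return percent_difference(*align_pair(a, b, method=method))
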