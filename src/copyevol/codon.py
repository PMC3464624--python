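"""Codon-level machinery shared by the simulator and the selection models.

Implements the standard genetic code bookkeeping, F3x4 equilibrium codon
frequencies, the Goldman-Yang (GY94) codon rate matrix, and the
Nei-Gojobori (NG86) pairwise dN/dS estimator with Jukes-Cantor correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

NUCLEOTIDES = "TCAG"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_CODON_TABLE = {}
_BASES_BY_POS = "TTTT" "CCCC" "AAAA" "GGGG"
_AA = (
    "FFLLSSSSYY**CC*W"  # TTT..TGG
    "LLLLPPPPHHQQRRRR"  # CTT..CGG
    "IIIMTTTTNNKKSSRR"  # ATT..AGG
    "VVVVAAAADDEEGGGG"  # GTT..GGG
)
for _i, (_n1, _n2, _n3) in enumerate(itertools.product(NUCLEOTIDES, repeat=3)):
    _CODON_TABLE[_n1 + _n2 + _n3] = _AA[_i]

STOP_CODONS = tuple(sorted(c for c, a in _CODON_TABLE.items() if a == "*"))
SENSE_CODONS = tuple(sorted(c for c, a in _CODON_TABLE.items() if a != "*"))
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = np.array([_CODON_TABLE[c] for c in SENSE_CODONS])

#: codon x position -> nucleotide index (into NUCLEOTIDES)
CODON_NT = np.array(
    [[NT_INDEX[c[p]] for p in range(3)] for c in SENSE_CODONS], dtype=np.int8
)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon ('*' for stop)."""
    return _CODON_TABLE[codon.upper().replace("U", "T")]


@lru_cache(maxsize=None)
def _pair_structure():
    """Classify all single-nucleotide codon-pair changes.

    Returns boolean (61, 61) arrays: single_nt (exactly one position differs),
    transition (that difference is a transition), synonymous.
    """
    diff = (CODON_NT[:, None, :] != CODON_NT[None, :, :])
    ndiff = diff.sum(axis=2)
    single = ndiff == 1
    # position of the single difference (undefined elsewhere)
    pos = np.argmax(diff, axis=2)
    # transition pairs among T,C,A,G indices: (T,C)=(0,1), (A,G)=(2,3)
    transition = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    synonymous = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    ts_pairs = {(0, 1), (1, 0), (2, 3), (3, 2)}
    for i in range(N_SENSE):
        for j in range(N_SENSE):
            if not single[i, j]:
                continue
            p = pos[i, j]
            transition[i, j] = (CODON_NT[i, p], CODON_NT[j, p]) in ts_pairs
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return single, transition, synonymous


def f3x4_frequencies(sequences) -> np.ndarray:
    """Equilibrium codon frequencies from position-specific base frequencies.

    ``sequences`` is an iterable of coding nucleotide strings (lengths
    divisible by 3).  Returns a length-61 vector over SENSE_CODONS that sums
    to 1.  Ambiguous characters are ignored in the base counts.
    """
    counts = np.zeros((3, 4))
    for seq in sequences:
        s = seq.upper().replace("U", "T")
        if len(s) % 3:
            raise ValueError("coding sequence length must be divisible by 3")
        for p in range(3):
            for ch in s[p::3]:
                if ch in NT_INDEX:
                    counts[p, NT_INDEX[ch]] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases found")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    pi = np.ones(N_SENSE)
    for p in range(3):
        pi *= pos_freq[p, CODON_NT[:, p]]
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate base composition: all sense codons have zero frequency")
    return pi / total


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 instantaneous rate matrix, scaled to one expected substitution
    per codon per unit time at the stationary distribution ``pi``.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for codon pairs
    differing at exactly one position; 0 otherwise.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_SENSE,) or abs(pi.sum() - 1) > 1e-9 or (pi < 0).any():
        raise ValueError("pi must be a 61-vector of frequencies summing to 1")
    single, transition, synonymous = _pair_structure()
    Q = np.where(single, pi[None, :], 0.0)
    Q = Q * np.where(transition, kappa, 1.0) * np.where(synonymous, 1.0, omega)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise ValueError("rate matrix has zero total rate; check parameters")
    return Q / rate


class ReversibleTransition:
    """Eigendecomposition of a reversible rate matrix for fast P(t).

    Uses the pi^(1/2)-symmetrized form so a symmetric eigensolver applies.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        # guard zero frequencies for the similarity transform
        safe = np.maximum(pi, 1e-300)
        sq = np.sqrt(safe)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2.0
        self._evals, self._U = np.linalg.eigh(B)
        # P(t) = D^-1/2 U e^{L t} U^T D^1/2 with D = diag(pi)
        self._sq = sq

    def probability_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        expl = np.exp(self._evals * t)
        M = (self._U * expl[None, :]) @ self._U.T
        P = (M / self._sq[:, None]) * self._sq[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS
# ---------------------------------------------------------------------------

@dataclass
class NG86Result:
    """Nei-Gojobori (1986) pairwise estimates with Jukes-Cantor correction."""

    dn: float
    ds: float
    omega: float  # nan when undefined (dS == 0 or correction out of range)
    undefined: bool
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


@lru_cache(maxsize=None)
def _ng86_tables():
    """Per-codon site counts and per-pair pathway-averaged difference counts.

    Sites: each codon position contributes ``(# synonymous non-stop changes)
    / (# non-stop changes)`` synonymous sites, remainder nonsynonymous.
    Differences: averaged over all orderings of the differing positions,
    excluding pathways that pass through stop codons.
    """
    syn_sites = np.zeros(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        for p in range(3):
            syn = tot = 0
            for n in NUCLEOTIDES:
                if n == codon[p]:
                    continue
                alt = codon[:p] + n + codon[p + 1:]
                if _CODON_TABLE[alt] == "*":
                    continue
                tot += 1
                if _CODON_TABLE[alt] == _CODON_TABLE[codon]:
                    syn += 1
            if tot:
                syn_sites[i] += syn / tot

    syn_d = np.zeros((N_SENSE, N_SENSE))
    nonsyn_d = np.zeros((N_SENSE, N_SENSE))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            positions = [p for p in range(3) if ci[p] != cj[p]]
            paths = []
            for order in itertools.permutations(positions):
                cur = ci
                s = n = 0
                ok = True
                for p in order:
                    nxt = cur[:p] + cj[p] + cur[p + 1:]
                    if _CODON_TABLE[nxt] == "*":
                        ok = False
                        break
                    if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                if ok:
                    paths.append((s, n))
            if not paths:  # all pathways blocked by stops; count all as nonsyn
                paths = [(0, len(positions))]
            syn_d[i, j] = np.mean([p[0] for p in paths])
            nonsyn_d[i, j] = np.mean([p[1] for p in paths])
    return syn_sites, syn_d, nonsyn_d


def codon_indices(seq: str) -> np.ndarray:
    """Sense-codon indices for a coding sequence; -1 for ambiguous/stop codons."""
    s = seq.upper().replace("U", "T")
    if len(s) % 3:
        raise ValueError("sequence length must be divisible by 3")
    out = np.full(len(s) // 3, -1, dtype=np.int64)
    for k in range(len(out)):
        out[k] = CODON_INDEX.get(s[3 * k: 3 * k + 3], -1)
    return out


def _jukes_cantor(p: float):
    if p >= 0.75:
        return np.nan
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_counts(a_idx: np.ndarray, b_idx: np.ndarray):
    """Raw NG86 site and difference counts for two codon-index vectors.

    Codon positions where either index is -1 (ambiguity/stop) are skipped.
    Returns (syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs).
    """
    syn_sites, syn_d, nonsyn_d = _ng86_tables()
    mask = (a_idx >= 0) & (b_idx >= 0)
    ai, bi = a_idx[mask], b_idx[mask]
    if ai.size == 0:
        raise ValueError("no comparable codons")
    S = (syn_sites[ai].sum() + syn_sites[bi].sum()) / 2.0
    N = 3.0 * ai.size - S
    sd = syn_d[ai, bi].sum()
    nd = nonsyn_d[ai, bi].sum()
    return S, N, sd, nd


def ng86_pairwise(a: str, b: str) -> NG86Result:
    """NG86 dN, dS and their ratio for two aligned coding sequences."""
    ai, bi = codon_indices(a), codon_indices(b)
    if ai.size != bi.size:
        raise ValueError("sequences must have equal length")
    S, N, sd, nd = ng86_counts(ai, bi)
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    undefined = bool(np.isnan(ds) or np.isnan(dn) or ds == 0)
    omega = np.nan if undefined else dn / ds
    return NG86Result(
        dn=float(dn), ds=float(ds), omega=float(omega), undefined=undefined,
        syn_sites=float(S), nonsyn_sites=float(N),
        syn_diffs=float(sd), nonsyn_diffs=float(nd),
    )
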