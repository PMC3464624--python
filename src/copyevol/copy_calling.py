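"""Collapse cloned sequences into copies; richness and saturation curves.

Cloned PCR products carry polymerase errors, so distinct clones of the same
underlying gene copy differ by a small number of substitutions.  Clones are
therefore collapsed into copies by single-linkage clustering at a percent
difference threshold derived from the expected PCR error (two clones belong
to the same copy when they are less than ``threshold`` different), and each
cluster is reported as a majority-rule consensus.  Copy richness is then
estimated with the abundance-based Chao1 estimator, and saturation
(accumulation) curves measure whether the library was sequenced deeply
enough to find all copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .alignment import pairwise_difference

_VALID = set("ACGTN")


@dataclass
class CloneLibrary:
    """Raw sequenced clones for one sample."""

    sample_id: str
    records: list  # list of (clone_id, sequence)

    def __post_init__(self):
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("clone ids must be unique")
        for cid, seq in self.records:
            if not seq:
                raise ValueError(f"clone {cid!r} has empty sequence")
            extra = set(seq.upper()) - _VALID
            if extra:
                raise ValueError(f"clone {cid!r} has invalid characters {extra}")

    def __len__(self):
        return len(self.records)


@dataclass
class Copy:
    copy_id: str
    consensus: str
    members: list
    count: int


@dataclass
class CopySet:
    """Collapsed consensus copies with member counts."""

    sample_id: str
    copies: list  # list of Copy

    @property
    def member_counts(self) -> list:
        return [c.count for c in self.copies]

    def __len__(self):
        return len(self.copies)


@dataclass
class RichnessEstimate:
    observed_richness: int
    chao1: float
    chao1_se: float
    f1: int
    f2: int


@dataclass
class AccumulationCurve:
    k: np.ndarray            # clones sampled
    mean: np.ndarray         # mean distinct copies after k clones
    lo: np.ndarray           # 5th percentile
    hi: np.ndarray           # 95th percentile
    n_orderings: int
    seed: int


def expected_pcr_error(cycles: int, per_cycle_per_base_error: float) -> float:
    """Expected per-base error after ``cycles`` rounds of PCR.

    Linear accumulation: each cycle adds ``per_cycle_per_base_error``
    errors per base, so 35 cycles of a 1/9000 polymerase give 35/9000.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    if not 0 <= per_cycle_per_base_error <= 1:
        raise ValueError("error rate must be in [0, 1]")
    return cycles * per_cycle_per_base_error


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _consensus(seqs: list) -> str:
    """Majority-rule consensus; ties break to the alphabetically first base.

    Members of equal length are stacked column-wise.  With mixed lengths the
    minority-length members are pairwise-aligned onto the modal-length frame
    first (rare; only happens if clones with different indel structure were
    linked).
    """
    lengths = [len(s) for s in seqs]
    modal = max(sorted(set(lengths)), key=lengths.count)
    frame = sorted(s for s in seqs if len(s) == modal)
    others = [s for s in seqs if len(s) != modal]
    if others:
        from .alignment import align_pair
        ref = frame[0]
        projected = []
        for s in others:
            ga, gb = align_pair(ref, s)
            proj = "".join(cb for ca, cb in zip(ga, gb) if ca != "-")
            projected.append(proj.replace("-", "N"))
        frame = frame + projected
    mat = np.vstack([_seq_array(s) for s in frame])
    out = np.empty(mat.shape[1], dtype=np.uint8)
    # vote among A,C,G,T (N excluded unless column is all N)
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    counts = np.stack([(mat == b).sum(axis=0) for b in letters])
    best = counts.max(axis=0)
    # alphabetically first base among the tied maxima
    out = letters[np.argmax(counts == best[None, :], axis=0)]
    out[best == 0] = ord("N")
    return out.tobytes().decode()


def _distance_matrix(seqs: list, method: str = "edit") -> np.ndarray:
    """Condensed-style square matrix of pairwise percent differences.

    Equal-length groups are compared with vectorized column counts; pairs of
    unequal length go through global alignment.
    """
    n = len(seqs)
    D = np.zeros((n, n))
    by_len: dict[int, list] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for idxs in by_len.values():
        if len(idxs) < 2:
            continue
        mat = np.vstack([_seq_array(seqs[i]) for i in idxs])
        isn = mat == ord("N")
        for a in range(len(idxs)):
            diff = (mat[a + 1:] != mat[a][None, :])
            ok = ~(isn[a + 1:] | isn[a][None, :])
            denom = ok.sum(axis=1)
            if (denom == 0).any():
                raise ValueError("no comparable columns in a clone pair")
            d = (diff & ok).sum(axis=1) / denom
            for off, val in enumerate(d):
                i, j = idxs[a], idxs[a + 1 + off]
                D[i, j] = D[j, i] = val
    # unequal-length pairs
    lens = sorted(by_len)
    for a in range(len(lens)):
        for b in range(a + 1, len(lens)):
            for i in by_len[lens[a]]:
                for j in by_len[lens[b]]:
                    d = pairwise_difference(seqs[i], seqs[j], method=method)
                    D[i, j] = D[j, i] = d
    return D


def collapse_clones(library: CloneLibrary, threshold: float = 0.01,
                    method: str = "edit") -> CopySet:
    """Single-linkage collapse of clones at a percent-difference threshold.

    Two clones with ``pairwise_difference < threshold`` are linked; connected
    components form copies and each copy is reported as a majority-rule
    consensus of its members.  Output is independent of input order.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    ids = [r[0] for r in library.records]
    seqs = [r[1].upper() for r in library.records]
    n = len(seqs)
    if n == 0:
        return CopySet(sample_id=library.sample_id, copies=[])
    D = _distance_matrix(seqs, method=method)
    link = (D < threshold)
    np.fill_diagonal(link, True)
    ii, jj = np.nonzero(link)
    g = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, comp = connected_components(g, directed=False)
    clusters: dict[int, list] = {}
    for i, c in enumerate(comp):
        clusters.setdefault(c, []).append(i)
    built = []
    for members in clusters.values():
        cons = _consensus([seqs[i] for i in members])
        mids = sorted(ids[i] for i in members)
        built.append((cons, mids))
    # deterministic ordering: by descending member count, then consensus
    built.sort(key=lambda x: (-len(x[1]), x[0]))
    copies = [
        Copy(copy_id=f"{library.sample_id}_copy{k + 1:02d}", consensus=cons,
             members=mids, count=len(mids))
        for k, (cons, mids) in enumerate(built)
    ]
    return CopySet(sample_id=library.sample_id, copies=copies)


def refine_copyset(copyset: CopySet, library: CloneLibrary,
                   threshold: float = 0.01, method: str = "edit") -> CopySet:
    """Consensus-membership re-collapse of a copy set.

    Pairwise single linkage between clones is fragile exactly at the PCR
    error scale: two clones of the same copy sit at roughly twice the
    per-clone error from each other, so sparsely sampled copies can shatter
    into singletons even though every clone is well within the threshold of
    the copy's majority-rule consensus.  This step applies the same <
    ``threshold`` rule clone-to-consensus: two copies are merged when every
    member clone of the union lies within the threshold of the union's
    majority consensus (errors vote each other out, so the union consensus
    of a shattered copy is clean, while a union of genuinely distinct
    copies leaves every clone roughly half the copy distance plus its own
    errors away and is rejected).  Merges repeat to a fixpoint, closest
    consensus pairs first, so the result is stable under a further pass.
    """
    seq_of = dict(library.records)
    members = [list(c.members) for c in copyset.copies]
    consensi = [c.consensus for c in copyset.copies]

    def acceptable(i: int, j: int):
        pooled = members[i] + members[j]
        cons = _consensus([seq_of[m] for m in pooled])
        if all(pairwise_difference(seq_of[m], cons, method=method) < threshold
               for m in pooled):
            return cons
        return None

    while len(members) > 1:
        n = len(members)
        candidates = sorted(
            (pairwise_difference(consensi[i], consensi[j], method=method), i, j)
            for i in range(n) for j in range(i + 1, n)
        )
        merged = False
        for dist, i, j in candidates:
            if dist >= 2 * threshold:
                break
            cons = acceptable(i, j)
            if cons is not None:
                members[i] = members[i] + members[j]
                consensi[i] = cons
                del members[j], consensi[j]
                merged = True
                break
        if not merged:
            break
    built = sorted(
        ((cons, sorted(mids)) for cons, mids in zip(consensi, members)),
        key=lambda x: (-len(x[1]), x[0]))
    copies = [
        Copy(copy_id=f"{copyset.sample_id}_copy{k + 1:02d}", consensus=cons,
             members=mids, count=len(mids))
        for k, (cons, mids) in enumerate(built)
    ]
    return CopySet(sample_id=copyset.sample_id, copies=copies)


def chao1(member_counts: list) -> RichnessEstimate:
    """Abundance-based Chao1 richness estimate with classical variance.

    With doubletons present: S_chao1 = S_obs + f1^2 / (2 f2); otherwise the
    bias-corrected form S_obs + f1 (f1 - 1) / 2 is used.  The standard error
    follows the classical Chao (1987) variance for the corresponding case and
    is 0 when there are no singletons.
    """
    counts = list(member_counts)
    if not counts:
        raise ValueError("member_counts is empty")
    if any(c < 1 for c in counts):
        raise ValueError("member counts must be >= 1")
    s_obs = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if f1 == 0:
        return RichnessEstimate(s_obs, float(s_obs), 0.0, f1, f2)
    if f2 > 0:
        est = s_obs + f1 ** 2 / (2 * f2)
        r = f1 / f2
        var = f2 * (r ** 2 / 2 + r ** 3 + r ** 4 / 4)
    else:
        est = s_obs + f1 * (f1 - 1) / 2
        var = (f1 * (f1 - 1) / 2 + f1 * (2 * f1 - 1) ** 2 / 4
               - f1 ** 4 / (4 * est))
    return RichnessEstimate(s_obs, float(est), float(np.sqrt(max(var, 0.0))),
                            f1, f2)


def accumulation_curve(assignments: list, n_orderings: int = 100,
                       seed: int = 0) -> AccumulationCurve:
    """Mean and 5-95 percentile band of distinct copies vs clones sampled.

    ``assignments`` maps each clone (by position) to its copy; random
    orderings of the clones are drawn and distinct copies counted in every
    prefix.
    """
    if n_orderings < 1:
        raise ValueError("n_orderings must be >= 1")
    codes = np.unique(np.asarray(assignments), return_inverse=True)[1]
    n = codes.size
    rng = np.random.default_rng(seed)
    curves = np.empty((n_orderings, n), dtype=np.int64)
    for o in range(n_orderings):
        order = rng.permutation(n)
        seen = np.zeros(codes.max() + 1, dtype=bool)
        c = 0
        for k, idx in enumerate(order):
            if not seen[codes[idx]]:
                seen[codes[idx]] = True
                c += 1
            curves[o, k] = c
    return AccumulationCurve(
        k=np.arange(1, n + 1),
        mean=curves.mean(axis=0),
        lo=np.percentile(curves, 5, axis=0),
        hi=np.percentile(curves, 95, axis=0),
        n_orderings=n_orderings,
        seed=seed,
    )
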