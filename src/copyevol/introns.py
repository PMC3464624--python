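"""Intron location, the copy x intron-site matrix, and class assignment.

Genomic copies are compared against an intron-free coding reference by
global affine-gap alignment; maximal insertions in the genomic sequence are
reported as introns with their splice motifs.  Observed insertion points are
merged into a canonical site catalogue (nearby points sharing a donor motif
are one site), every copy gets a presence/absence vector over the catalogue,
and copies are grouped into pattern variants (identical vectors) and major
classes (variants within a small Hamming radius, capturing single intron
gains/losses inside a class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from Bio import Align

#: accepted 5' splice motifs, checked against the start of the intron
DONOR_MOTIFS = ("GGT", "GT")
ACCEPTOR_MOTIF = "AG"


def _intron_aligner() -> Align.PairwiseAligner:
    """Spliced-comparison scoring: expensive gap opens and cheap extensions
    keep each intron as one contiguous insertion even against a divergent
    reference (a split gap must beat a whole intron by chance matches)."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -12
    al.extend_gap_score = -0.5
    return al


@dataclass
class IntronObservation:
    """One intron in one genomic copy.

    ``site`` is the insertion point in reference CDS coordinates (0-based,
    half-open: the intron is inserted before reference position ``site``);
    ``genomic_start``/``genomic_end`` delimit the intron in the genomic
    sequence; ``flagged`` marks introns without canonical GT..AG (or GGT)
    boundaries.
    """

    site: int
    length: int
    donor: str      # first 3 bases
    acceptor: str   # last 2 bases
    genomic_start: int
    genomic_end: int
    flagged: bool


@dataclass
class ClassAssignment:
    """copy id -> (major class id, pattern variant id), plus the patterns."""

    classes: dict          # copy_id -> int (1-based)
    variants: dict         # copy_id -> int (1-based)
    class_patterns: dict   # class id -> list of variant patterns (tuples)

    @property
    def n_classes(self) -> int:
        return len(set(self.classes.values()))

    @property
    def n_variants(self) -> int:
        return len({v for v in self.variants.values()})

    def to_frame(self) -> pd.DataFrame:
        rows = [{"copy_id": cid, "class": self.classes[cid],
                 "variant": self.variants[cid]} for cid in sorted(self.classes)]
        return pd.DataFrame(rows)


def _shifts(window: int):
    """0, +1, -1, +2, -2, ... up to +/-window."""
    yield 0
    for d in range(1, window + 1):
        yield d
        yield -d


def _motif_ok(intron: str) -> bool:
    return (any(intron.startswith(m) for m in DONOR_MOTIFS)
            and intron.endswith(ACCEPTOR_MOTIF))


def locate_introns(genomic: str, reference_cds: str,
                   min_identity: float = 0.5, min_intron: int = 4,
                   refine_window: int = 15) -> list:
    """Locate introns in a genomic copy against an intron-free reference.

    Global affine alignment; maximal insertions in the genomic sequence are
    introns.  Insertion boundaries are slid within cost-neutral shifts to
    match GT..AG (or GGT 5') splice motifs where possible; insertions that
    still lack the motif are reported flagged, not dropped.
    """
    genomic = genomic.upper()
    reference_cds = reference_cds.upper()
    if len(genomic) < 0.8 * len(reference_cds):
        raise ValueError("genomic sequence shorter than 80% of the reference; "
                         "wrong gene or truncated clone")
    aln = _intron_aligner().align(reference_cds, genomic)[0]
    ref_blocks, gen_blocks = aln.aligned
    # exonic identity check over aligned blocks
    matches = compared = 0
    for (r0, r1), (g0, g1) in zip(ref_blocks, gen_blocks):
        a = np.frombuffer(reference_cds[r0:r1].encode(), dtype=np.uint8)
        b = np.frombuffer(genomic[g0:g1].encode(), dtype=np.uint8)
        matches += int((a == b).sum())
        compared += len(a)
    if compared == 0 or matches / compared < min_identity:
        raise ValueError("alignment identity below "
                         f"{min_identity:.0%} on exonic columns; wrong gene?")
    observations = []
    for k in range(len(ref_blocks) - 1):
        r_gap = int(ref_blocks[k + 1][0] - ref_blocks[k][1])
        g0, g1 = int(gen_blocks[k][1]), int(gen_blocks[k + 1][0])
        g_len = g1 - g0
        if g_len - r_gap < min_intron:
            continue  # small or reference-side gap: exonic indel, not intron
        # in a mixed gap (reference bases skipped alongside the insertion)
        # the skipped exon bases sit adjacent to their aligned neighbours,
        # so the net insertion is anchored after them
        start = g0 + r_gap
        end = g1
        best_delta = None
        # prefer the strong (GGT) donor at any shift over a bare GT donor,
        # then the smallest shift within each tier
        for donor in DONOR_MOTIFS:
            for delta in _shifts(refine_window):
                s, e = start + delta, end + delta
                if s < 0 or e > len(genomic):
                    continue
                intron = genomic[s:e]
                if intron.startswith(donor) and intron.endswith(ACCEPTOR_MOTIF):
                    best_delta = delta
                    break
            if best_delta is not None:
                break
        if best_delta is not None:
            start += best_delta
            end += best_delta
        intron = genomic[start:end]
        # the reference-side insertion point moves with the exonic flank
        site = int(ref_blocks[k + 1][0] + (start - (g0 + r_gap)))
        observations.append(IntronObservation(
            site=site, length=len(intron), donor=intron[:3],
            acceptor=intron[-2:], genomic_start=start, genomic_end=end,
            flagged=not _motif_ok(intron)))
    return observations


def canonicalize_sites(observations_by_copy: dict, merge_window: int = 6):
    """Merge observed insertion points into a canonical site catalogue.

    Sites within ``merge_window`` bases of each other are merged when they
    share a donor motif (canonical position = median); two nearby sites with
    *different canonical donors* stay distinct (a putative translocation,
    not the same site).  Observations flagged for lacking a canonical
    splice motif are treated as noisy boundary calls: they merge into a
    nearby canonical site regardless of their donor string.  Returns
    (catalogue, patterns): catalogue is a list of (position, donor) and
    patterns maps copy id to a 0/1 vector over the catalogue.
    """
    if merge_window < 0:
        raise ValueError("merge_window must be >= 0")
    entries = []  # (position, donor, flagged, copy_id)
    for cid, obs in observations_by_copy.items():
        for o in obs:
            entries.append((o.site, o.donor, o.flagged, cid))
    if not entries:
        return [], {cid: np.zeros(0, dtype=np.int8)
                    for cid in observations_by_copy}
    entries.sort(key=lambda e: (e[0], e[2], e[1]))
    # single-linkage chains within the window; donors must agree unless one
    # side is a flagged (noisy) observation
    groups = []  # [positions], donor or None, any_canonical
    assigned = [-1] * len(entries)
    for i, (pos, donor, flagged, _) in enumerate(entries):
        placed = False
        for gi in range(len(groups) - 1, -1, -1):
            gpos, gdonor, _ = groups[gi]
            if pos - gpos[-1] > merge_window:
                continue
            if pos - gpos[0] > 4 * merge_window:
                continue
            if flagged or gdonor is None or gdonor == donor:
                gpos.append(pos)
                if gdonor is None and not flagged:
                    groups[gi] = (gpos, donor, True)
                assigned[i] = gi
                placed = True
                break
        if not placed:
            groups.append(([pos], None if flagged else donor, not flagged))
            assigned[i] = len(groups) - 1
    # support-weighted curation: a site seen in a single copy that sits just
    # beyond the merge window of a well-supported site is a noisy boundary
    # call, not a new site; absorb it into the supported site
    target = list(range(len(groups)))
    for gi, (gpos, gdonor, _) in enumerate(groups):
        if len(gpos) != 1:
            continue
        med = np.median(gpos)
        best = None
        for gj, (hpos, hdonor, _) in enumerate(groups):
            if gj == gi or len(hpos) < 3:
                continue
            d = abs(np.median(hpos) - med)
            if d <= 2 * merge_window and (best is None or d < best[0]):
                best = (d, gj)
        if best is not None:
            target[gi] = best[1]
    canon = [(int(np.median(groups[target[gi]][0])),
              groups[target[gi]][1] if groups[target[gi]][1] else "?")
             for gi in range(len(groups))]
    catalogue = sorted(set(canon))
    remap = [catalogue.index(c) for c in canon]
    patterns = {cid: np.zeros(len(catalogue), dtype=np.int8)
                for cid in observations_by_copy}
    for (pos, donor, flagged, cid), gi in zip(entries, assigned):
        patterns[cid][remap[gi]] = 1
    return catalogue, patterns


def assign_classes(patterns: dict, merge_radius: int = 1) -> ClassAssignment:
    """Group intron patterns into variants and major classes.

    Variants are the distinct 0/1 vectors; major classes are connected
    components of the graph joining variants whose Hamming distance is at
    most ``merge_radius`` (single intron gains/losses by default).  Class
    ids are ordered by descending member count, ties by lexicographically
    smallest pattern.
    """
    if not patterns:
        raise ValueError("no patterns supplied")
    ids = sorted(patterns)
    mat = np.vstack([patterns[c] for c in ids])
    variants, inverse = np.unique(mat, axis=0, return_inverse=True)
    nv = variants.shape[0]
    dist = (variants[:, None, :] != variants[None, :, :]).sum(axis=2)
    link = dist <= merge_radius
    g = coo_matrix(link.astype(int))
    _, comp = connected_components(g, directed=False)
    member_count = np.bincount(inverse, minlength=nv)
    class_sizes = {}
    class_minpat = {}
    for v in range(nv):
        c = comp[v]
        class_sizes[c] = class_sizes.get(c, 0) + int(member_count[v])
        pat = tuple(int(x) for x in variants[v])
        if c not in class_minpat or pat < class_minpat[c]:
            class_minpat[c] = pat
    ordered = sorted(class_sizes, key=lambda c: (-class_sizes[c],
                                                 class_minpat[c]))
    class_id = {c: k + 1 for k, c in enumerate(ordered)}
    # variant ids: within ordering by descending count then pattern
    variant_order = sorted(
        range(nv), key=lambda v: (class_id[comp[v]], -member_count[v],
                                  tuple(int(x) for x in variants[v])))
    variant_id = {v: k + 1 for k, v in enumerate(variant_order)}
    classes = {cid: class_id[comp[inverse[k]]] for k, cid in enumerate(ids)}
    var_ids = {cid: variant_id[inverse[k]] for k, cid in enumerate(ids)}
    class_patterns = {}
    for v in range(nv):
        class_patterns.setdefault(class_id[comp[v]], []).append(
            tuple(int(x) for x in variants[v]))
    return ClassAssignment(classes=classes, variants=var_ids,
                           class_patterns=class_patterns)


def splice(genomic: str, observations: list) -> str:
    """Remove intron segments from a genomic copy, restoring the CDS."""
    segments = sorted((o.genomic_start, o.genomic_end) for o in observations)
    for (a0, a1), (b0, b1) in zip(segments, segments[1:]):
        if b0 < a1:
            raise ValueError("overlapping intron observations")
    out = []
    prev = 0
    for s, e in segments:
        out.append(genomic[prev:s])
        prev = e
    out.append(genomic[prev:])
    result = "".join(out)
    if not result:
        raise ValueError("splicing removed the entire sequence")
    return result


def pattern_matrix(patterns: dict, catalogue: list) -> pd.DataFrame:
    """Copies x sites 0/1 DataFrame with catalogue positions as columns."""
    cols = [f"site_{pos}_{donor}" for pos, donor in catalogue]
    return pd.DataFrame(
        {c: patterns[c] for c in sorted(patterns)}, index=cols
    ).T.astype(int)
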