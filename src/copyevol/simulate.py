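"""Synthetic gene families, clone libraries and codon alignments.

The generator emulates the statistical structure of a multi-copy gene
family surveyed by cloning PCR products from several species:

* each species carries a fixed set of divergent copy types (default 8),
  each present as a pair of near-identical sequences (<1.5% divergent,
  as expected for copies homogenized by gene conversion);
* copy types group into intron classes (default 5) sharing intron
  presence/absence patterns over a 17-site catalogue, with single-intron
  pattern variants inside some classes (8 patterns in total);
* coding sequence evolves under a GY94 codon process with separate
  dN/dS ratios on within-class and between-class branches, plus a
  constrained block (near-zero omega, emulating an invariant functional
  site) and a divergent block (neutral between classes, emulating the
  codon set flagged by branch-site analysis);
* clone libraries resample copies with Dirichlet-multinomial abundances
  and add per-base PCR substitution errors accumulated over 35 cycles.

Every random quantity flows from a single integer seed, and a
:class:`TruthRecord` ties each generated copy to its species, class,
copy type, pair partner, intron pattern and clean coding sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codon as cd
from .copy_calling import CloneLibrary
from .trees import LabeledTree

WITHIN = "within"
BETWEEN = "between"

#: canonical intron presence/absence base patterns for the default
#: 17-site / 5-class catalogue (pairwise Hamming distance >= 6; together
#: the classes cover every site)
_CANONICAL_PATTERNS = np.array([
    [1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 0],
    [1, 1, 0, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 0, 0],
    [0, 0, 0, 0, 1, 1, 0, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0],
    [0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 0, 0, 1, 1, 0, 0, 1],
], dtype=np.int8)
#: one copy type per class (round-robin order) toggles this site off,
#: producing the single-intron "variant" patterns
_CANONICAL_VARIANT_SITES = {0: 6, 1: 10, 2: 14}


@dataclass
class FamilySimConfig:
    """Study conditions for one simulated gene family."""

    n_species: int = 4
    n_classes: int = 5
    copy_types_per_species: int = 8
    pair_divergence: float = 0.015
    between_type_divergence: float = 0.12
    between_class_divergence: float = 0.30
    species_divergence: float = 0.04
    intron_site_count: int = 17
    intron_length_range: tuple = (42, 70)
    long_intron_lengths: dict = field(default_factory=lambda: {2: (107, 131), 12: (166, 295)})
    loss_probability: float = 0.0
    n_codons: int = 480
    kappa: float = 2.0
    omega_within: float = 0.015
    omega_between: float = 0.074
    divergent_block: tuple = (300, 330)
    divergent_omega_between: float = 1.0
    constrained_block: tuple = (139, 162)
    constrained_omega: float = 0.001
    seed: int = 0

    def __post_init__(self):
        for name in ("pair_divergence", "between_type_divergence",
                     "between_class_divergence", "species_divergence",
                     "loss_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_classes > self.copy_types_per_species:
            raise ValueError("n_classes must be <= copy_types_per_species")
        if min(self.intron_length_range) < 4:
            raise ValueError("intron lengths must be >= 4")
        for rng_ in self.long_intron_lengths.values():
            if min(rng_) < 4:
                raise ValueError("intron lengths must be >= 4")
        if self.between_type_divergence <= 0.10:
            warnings.warn("between_type_divergence <= 0.10: copy types may "
                          "not be separable from similar pairs", stacklevel=2)


@dataclass
class CloneSimConfig:
    """Clone-library sampling and PCR error conditions."""

    clones_per_sample: int = 135
    abundance_concentration: float = 40.0
    per_base_error: float = 35.0 / 9000.0
    seed: int = 0

    def __post_init__(self):
        if self.clones_per_sample < 1:
            raise ValueError("clones_per_sample must be >= 1")
        if not 0 <= self.per_base_error <= 0.05:
            raise ValueError("per_base_error must be in [0, 0.05]")
        if self.abundance_concentration <= 0:
            raise ValueError("abundance_concentration must be > 0")


@dataclass
class CodonSimConfig:
    """GY94 branch-class simulation conditions."""

    n_codons: int = 500
    kappa: float = 2.0
    omega_by_branch_class: dict = field(
        default_factory=lambda: {WITHIN: 0.015, BETWEEN: 0.074})
    codon_frequencies: np.ndarray | None = None
    site_classes: list | None = None  # [(proportion, omega_by_branch_class)]
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.codon_frequencies is not None:
            pi = np.asarray(self.codon_frequencies, dtype=float)
            if pi.shape != (cd.N_SENSE,):
                raise ValueError("codon_frequencies must have length 61 "
                                 "(stop codons excluded)")
            if abs(pi.sum() - 1) > 1e-9:
                raise ValueError("codon_frequencies must sum to 1")
            self.codon_frequencies = pi
        if self.site_classes is not None:
            total = sum(p for p, _ in self.site_classes)
            if abs(total - 1) > 1e-9:
                raise ValueError("site class proportions must sum to 1")


@dataclass
class CopyTruth:
    copy_id: str
    species: str
    class_label: int
    type_label: int
    partner_id: str | None
    pattern: tuple
    cds: str
    genomic: str


@dataclass
class TruthRecord:
    """Ground truth for every generated copy."""

    copies: dict            # copy_id -> CopyTruth
    catalogue: list         # intron insertion points, CDS coordinates
    root_cds: str
    divergent_sites: list   # codon indices (0-based)
    constrained_sites: list
    seed: int

    def copies_of(self, species: str) -> dict:
        return {cid: t for cid, t in self.copies.items() if t.species == species}

    @property
    def species(self) -> list:
        return sorted({t.species for t in self.copies.values()})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"copy_id": t.copy_id, "species": t.species, "class": t.class_label,
             "copy_type": t.type_label, "partner": t.partner_id or "",
             "pattern": "".join(map(str, t.pattern))}
            for t in self.copies.values()
        ]
        return pd.DataFrame(rows).sort_values("copy_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GY94 simulation on a labeled tree
# ---------------------------------------------------------------------------

class _TransitionCache:
    def __init__(self, kappa: float, pi: np.ndarray):
        self.kappa = kappa
        self.pi = pi
        self._eig: dict[float, cd.ReversibleTransition] = {}
        self._P: dict[tuple, np.ndarray] = {}

    def matrix(self, omega: float, t: float) -> np.ndarray:
        key = (omega, t)
        if key not in self._P:
            if omega not in self._eig:
                Q = cd.gy94_rate_matrix(self.kappa, omega, self.pi)
                self._eig[omega] = cd.ReversibleTransition(Q, self.pi)
            self._P[key] = self._eig[omega].probability_matrix(t)
        return self._P[key]


def _evolve_states(tree: LabeledTree, cache: _TransitionCache,
                   omega_of_label, n_sites: int, rng) -> dict:
    """Simulate codon states site-i.i.d. down the tree; returns leaf states."""
    pi = cache.pi
    states = {tree.root: rng.choice(cd.N_SENSE, size=n_sites, p=pi)}
    order = tree.postorder()[::-1]  # preorder
    for idx in order:
        if idx == tree.root:
            continue
        node = tree.nodes[idx]
        parent_states = states[node.parent]
        omega = omega_of_label(node.label)
        if node.length == 0:
            states[idx] = parent_states.copy()
        else:
            P = cache.matrix(omega, node.length)
            cum = np.cumsum(P, axis=1)
            r = rng.random(n_sites)
            rows = cum[parent_states]
            states[idx] = (r[:, None] > rows).sum(axis=1).astype(np.int64)
    return {tree.nodes[i].name: states[i] for i in tree.leaves}


def simulate_codon_alignment(tree: LabeledTree, config: CodonSimConfig) -> dict:
    """Simulate a codon alignment under GY94 with branch-class omegas.

    Sites evolve i.i.d.; with ``site_classes`` set, sites are partitioned
    into contiguous blocks with their own omega-by-branch-class maps (the
    mixture used by branch-site analyses).  Returns ``{taxon: codon string}``.
    """
    labels = tree.branch_labels
    if config.site_classes is None:
        maps = [config.omega_by_branch_class]
    else:
        maps = [m for _, m in config.site_classes]
    for m in maps:
        missing = labels - set(m)
        if missing:
            raise ValueError(f"branch labels {sorted(missing)} missing from "
                             "omega_by_branch_class")
    rng = np.random.default_rng(config.seed)
    pi = (config.codon_frequencies if config.codon_frequencies is not None
          else np.full(cd.N_SENSE, 1.0 / cd.N_SENSE))
    cache = _TransitionCache(config.kappa, pi)

    if config.site_classes is None:
        blocks = [(config.n_codons, config.omega_by_branch_class)]
    else:
        sizes = [int(round(p * config.n_codons)) for p, _ in config.site_classes]
        sizes[-1] = config.n_codons - sum(sizes[:-1])
        blocks = [(s, m) for s, (_, m) in zip(sizes, config.site_classes)]

    parts: dict[str, list] = {name: [] for name in tree.leaf_names}
    for size, omega_map in blocks:
        if size <= 0:
            continue
        leaf_states = _evolve_states(
            tree, cache, lambda lab, m=omega_map: m[lab], size, rng)
        for name, st in leaf_states.items():
            parts[name].append(st)
    out = {}
    for name, chunks in parts.items():
        idx = np.concatenate(chunks)
        out[name] = "".join(cd.SENSE_CODONS[i] for i in idx)
    return out


# ---------------------------------------------------------------------------
# Gene family simulation
# ---------------------------------------------------------------------------

_NTS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, rate: float, rng, protect: tuple = (0, 0)) -> str:
    """iid substitutions at ``rate`` per base; first/last ``protect`` bases kept."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lo, hi = protect[0], len(arr) - protect[1]
    if hi <= lo:
        return seq
    hits = np.nonzero(rng.random(hi - lo) < rate)[0] + lo
    for pos in hits:
        choices = _NTS[_NTS != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def _random_intron(length: int, rng) -> str:
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length - 5))
    return "GGT" + body + "AG"


def _class_patterns(n_sites: int, n_classes: int, n_types: int, rng):
    """Base pattern per class plus per-type patterns (with variants).

    Returns (type_class: list of class index per type, type_patterns:
    (n_types, n_sites) int8).  For the canonical 17-site / 5-class catalogue
    a fixed design is used; otherwise patterns are sampled with pairwise
    Hamming distance >= 6 and full site coverage.
    """
    if n_sites == 17 and n_classes == 5:
        base = _CANONICAL_PATTERNS.copy()
        variant_sites = dict(_CANONICAL_VARIANT_SITES)
    else:
        for _ in range(2000):
            base = (rng.random((n_classes, n_sites)) < 0.45).astype(np.int8)
            dist = (base[:, None, :] != base[None, :, :]).sum(axis=2)
            np.fill_diagonal(dist, n_sites)
            if dist.min() >= 6 and base.max(axis=0).min() == 1 \
                    and base.sum(axis=1).min() >= 2:
                break
        else:
            raise ValueError("could not construct class patterns; "
                             "increase intron_site_count")
        variant_sites = {}
        for c in range(n_classes):
            present = np.nonzero(base[c])[0]
            variant_sites[c] = int(rng.choice(present))

    type_class = [t % n_classes for t in range(n_types)]
    type_patterns = np.zeros((n_types, n_sites), dtype=np.int8)
    seen_in_class: dict[int, int] = {}
    for t, c in enumerate(type_class):
        pat = base[c].copy()
        occurrence = seen_in_class.get(c, 0)
        if occurrence == 1 and c in variant_sites:
            pat[variant_sites[c]] = 0  # single-intron loss variant
        seen_in_class[c] = occurrence + 1
        type_patterns[t] = pat
    return type_class, type_patterns


def _family_tree(cfg: FamilySimConfig, type_class: list) -> LabeledTree:
    """Copy genealogy: classes -> copy types -> species -> similar pairs.

    Branch lengths are in expected substitutions per codon, chosen so that
    pairwise nucleotide divergences approximate the configured targets
    (a codon substitution is ~1/3 of a nucleotide substitution per site).
    """
    l_pair = 1.5 * cfg.pair_divergence
    l_sp = max(1.5 * cfg.species_divergence - l_pair, 0.0)
    l_type = max(1.5 * cfg.between_type_divergence - l_sp - l_pair, 1e-6)
    l_class = max(1.5 * cfg.between_class_divergence
                  - l_type - l_sp - l_pair, 1e-6)
    tree = LabeledTree()
    root = tree.add_node(name="root")
    class_nodes = {}
    for c in sorted(set(type_class)):
        class_nodes[c] = tree.add_node(parent=root, length=l_class, label=BETWEEN)
    for t, c in enumerate(type_class):
        tnode = tree.add_node(parent=class_nodes[c], length=l_type, label=WITHIN)
        for s in range(cfg.n_species):
            snode = tree.add_node(parent=tnode, length=l_sp, label=WITHIN)
            for member in "ab":
                tree.add_node(name=f"sp{s + 1}_type{t + 1}{member}",
                              parent=snode, length=l_pair, label=WITHIN)
    return tree


def _intron_length(site_ordinal: int, cfg: FamilySimConfig, rng) -> int:
    lo, hi = cfg.long_intron_lengths.get(site_ordinal, cfg.intron_length_range)
    return int(rng.integers(lo, hi + 1))


def simulate_family(config: FamilySimConfig, collapse_threshold: float = 0.01):
    """Simulate a gene family; returns (copies, truth, tree).

    ``copies`` maps copy id to its genomic (intron-containing) sequence.
    The returned tree covers all copies, with ``within``/``between`` branch
    class labels, and the truth record carries everything downstream stages
    are tested against.
    """
    cfg = config
    if cfg.pair_divergence < collapse_threshold:
        warnings.warn(
            f"pair_divergence={cfg.pair_divergence} is below the collapse "
            f"threshold {collapse_threshold}; similar pairs will merge into "
            "one copy downstream", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.intron_site_count
    L = 3 * cfg.n_codons

    type_class, type_patterns = _class_patterns(
        n_sites, cfg.n_classes, cfg.copy_types_per_species, rng)
    tree = _family_tree(cfg, type_class)

    # coding sequence evolution with three site categories
    d0, d1 = cfg.divergent_block
    c0, c1 = cfg.constrained_block
    categories = np.zeros(cfg.n_codons, dtype=np.int8)
    categories[d0:d1] = 1
    categories[c0:c1] = 2
    omega_maps = [
        {WITHIN: cfg.omega_within, BETWEEN: cfg.omega_between},
        {WITHIN: 0.013, BETWEEN: cfg.divergent_omega_between},
        {WITHIN: cfg.constrained_omega, BETWEEN: cfg.constrained_omega},
    ]
    pi = np.full(cd.N_SENSE, 1.0 / cd.N_SENSE)
    cache = _TransitionCache(cfg.kappa, pi)
    root_states = np.empty(cfg.n_codons, dtype=np.int64)
    leaf_states = {name: np.empty(cfg.n_codons, dtype=np.int64)
                   for name in tree.leaf_names}
    for cat, omega_map in enumerate(omega_maps):
        sel = np.nonzero(categories == cat)[0]
        if sel.size == 0:
            continue
        # root draw + evolution for this category
        states = {tree.root: rng.choice(cd.N_SENSE, size=sel.size, p=pi)}
        for idx in tree.postorder()[::-1]:
            if idx == tree.root:
                continue
            node = tree.nodes[idx]
            omega = omega_map[node.label]
            if node.length == 0:
                states[idx] = states[node.parent].copy()
            else:
                P = cache.matrix(omega, node.length)
                cum = np.cumsum(P, axis=1)
                r = rng.random(sel.size)
                states[idx] = (r[:, None] > cum[states[node.parent]]).sum(axis=1)
        root_states[sel] = states[tree.root]
        for li in tree.leaves:
            leaf_states[tree.nodes[li].name][sel] = states[li]
    root_cds = "".join(cd.SENSE_CODONS[i] for i in root_states)

    # intron site catalogue: insertion points in CDS coordinates
    positions = []
    attempts = 0
    while len(positions) < n_sites:
        p = int(rng.integers(45, L - 45))
        if all(abs(p - q) >= 30 for q in positions):
            positions.append(p)
        attempts += 1
        if attempts > 100000:
            raise ValueError("could not place intron sites; sequence too short")
    catalogue = sorted(positions)

    # intron sequences: family base per site, then hierarchical substitutions
    base_introns = {}
    for ordinal, site in enumerate(catalogue, start=1):
        base_introns[site] = _random_intron(_intron_length(ordinal, cfg, rng), rng)
    class_introns = {
        c: {s: _mutate(seq, 0.08, rng, protect=(3, 2))
            for s, seq in base_introns.items()}
        for c in sorted(set(type_class))
    }
    type_introns = {
        t: {s: _mutate(seq, 0.04, rng, protect=(3, 2))
            for s, seq in class_introns[type_class[t]].items()}
        for t in range(cfg.copy_types_per_species)
    }

    copies: dict[str, str] = {}
    truth_copies: dict[str, CopyTruth] = {}
    lost: set = set()
    for s in range(cfg.n_species):
        species = f"sp{s + 1}"
        for t in range(cfg.copy_types_per_species):
            if rng.random() < cfg.loss_probability:
                lost.add((species, t))
                continue
            sp_introns = {site: _mutate(seq, cfg.species_divergence / 2, rng,
                                        protect=(3, 2))
                          for site, seq in type_introns[t].items()}
            pattern = type_patterns[t]
            ids = [f"{species}_type{t + 1}a", f"{species}_type{t + 1}b"]
            for member, cid in zip("ab", ids):
                cds = "".join(cd.SENSE_CODONS[i] for i in leaf_states[cid])
                member_introns = {
                    site: _mutate(seq, cfg.pair_divergence / 2, rng,
                                  protect=(3, 2))
                    for site, seq in sp_introns.items()}
                genomic = _assemble_genomic(cds, catalogue, pattern,
                                            member_introns)
                partner = ids[1] if member == "a" else ids[0]
                copies[cid] = genomic
                truth_copies[cid] = CopyTruth(
                    copy_id=cid, species=species,
                    class_label=type_class[t] + 1, type_label=t + 1,
                    partner_id=partner, pattern=tuple(int(x) for x in pattern),
                    cds=cds, genomic=genomic)

    # prune lost copies from the tree
    if lost:
        tree = _prune_leaves(tree, set(copies))

    truth = TruthRecord(
        copies=truth_copies, catalogue=catalogue, root_cds=root_cds,
        divergent_sites=list(range(d0, d1)),
        constrained_sites=list(range(c0, c1)), seed=cfg.seed)
    return copies, truth, tree


def _assemble_genomic(cds: str, catalogue: list, pattern: np.ndarray,
                      introns: dict) -> str:
    parts = []
    prev = 0
    for site, present in zip(catalogue, pattern):
        parts.append(cds[prev:site])
        if present:
            parts.append(introns[site])
        prev = site
    parts.append(cds[prev:])
    return "".join(parts)


def _prune_leaves(tree: LabeledTree, keep: set) -> LabeledTree:
    """Drop leaves not in ``keep``; suppress resulting unary internals."""
    # build child lists on a copy, then rebuild recursively
    out = LabeledTree()

    def build(idx: int, parent_out: int, acc_len: float, label: str):
        node = tree.nodes[idx]
        children = [c for c in node.children if _has_kept_leaf(tree, c, keep)]
        if tree.is_leaf(idx):
            out.add_node(name=node.name, parent=parent_out,
                         length=acc_len + node.length, label=label or node.label)
            return
        if parent_out == -1:
            me = out.add_node(name=node.name)
        elif len(children) == 1:
            # unary: merge this branch into the child's
            build(children[0], parent_out, acc_len + node.length,
                  label or node.label)
            return
        else:
            me = out.add_node(name=node.name, parent=parent_out,
                              length=acc_len + node.length,
                              label=label or node.label)
        for c in children:
            build(c, me, 0.0, "")

    build(tree.root, -1, 0.0, "")
    return out


def _has_kept_leaf(tree: LabeledTree, idx: int, keep: set) -> bool:
    if tree.is_leaf(idx):
        return tree.nodes[idx].name in keep
    return any(_has_kept_leaf(tree, c, keep) for c in tree.nodes[idx].children)


def branch_class_tree(n_classes: int = 3, types_per_class: int = 2,
                      within_length: float = 0.2,
                      between_length: float = 0.3) -> LabeledTree:
    """Small labeled tree for branch-class recovery studies.

    ``n_classes`` clades hang off the root on ``between``-labeled internal
    branches; each clade carries ``types_per_class`` tips on ``within``
    branches.  Branch lengths are expected substitutions per codon.
    """
    tree = LabeledTree()
    root = tree.add_node(name="root")
    for c in range(n_classes):
        anc = tree.add_node(parent=root, length=between_length, label=BETWEEN)
        for t in range(types_per_class):
            tree.add_node(name=f"c{c + 1}t{t + 1}", parent=anc,
                          length=within_length, label=WITHIN)
    return tree


# ---------------------------------------------------------------------------
# Clone libraries
# ---------------------------------------------------------------------------

def simulate_clone_library(copies: dict, config: CloneSimConfig,
                           sample_id: str = "sample"):
    """Sample a clone library from one sample's copies.

    Copy abundances are drawn once from a symmetric Dirichlet, clone counts
    from a multinomial, and each clone is its source copy with independent
    per-base substitution errors (no indels).  Returns (CloneLibrary,
    {clone_id: copy_id}).
    """
    if not copies:
        raise ValueError("need at least one copy")
    rng = np.random.default_rng(config.seed)
    ids = sorted(copies)
    k = len(ids)
    probs = rng.dirichlet(np.full(k, config.abundance_concentration))
    counts = rng.multinomial(config.clones_per_sample, probs)
    records = []
    mapping = {}
    i = 0
    for cid, n in zip(ids, counts):
        for _ in range(n):
            i += 1
            clone_id = f"{sample_id}_clone{i:03d}"
            seq = _mutate(copies[cid], config.per_base_error, rng)
            records.append((clone_id, seq))
            mapping[clone_id] = cid
    return CloneLibrary(sample_id=sample_id, records=records), mapping


def simulate_clone_libraries(copies: dict, truth: TruthRecord,
                             config: CloneSimConfig):
    """One clone library per species; seeds derived from ``config.seed``."""
    libraries = {}
    mappings = {}
    seeds = np.random.SeedSequence(config.seed).spawn(len(truth.species))
    for sub, species in zip(seeds, truth.species):
        sp_copies = {cid: t.genomic
                     for cid, t in truth.copies.items() if t.species == species}
        sub_cfg = CloneSimConfig(
            clones_per_sample=config.clones_per_sample,
            abundance_concentration=config.abundance_concentration,
            per_base_error=config.per_base_error,
            seed=int(sub.generate_state(1)[0] % (2 ** 31)))
        lib, mp = simulate_clone_library(sp_copies, sub_cfg, sample_id=species)
        libraries[species] = lib
        mappings.update(mp)
    return libraries, mappings


# ---------------------------------------------------------------------------
# Synthetic structural/functional region annotation
# ---------------------------------------------------------------------------

def simulate_region_annotation(truth: TruthRecord, n_codons: int | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Protein-coordinate region annotation consistent with the truth.

    Functional regions (GTP contacts, nonexchangeable site, beta-interface,
    C-terminal helices) cover ~25-30% of the protein and avoid the divergent
    codon block, emulating divergence kept out of functionally critical
    regions; structural regions (helices/sheets) are placed independently of
    the divergence pattern.  Coordinates are 1-based inclusive.
    """
    rng = np.random.default_rng(seed)
    n = n_codons or (len(truth.root_cds) // 3)
    div = set(truth.divergent_sites)
    rows = []
    # structural: alternating helix/sheet segments with gaps
    pos = 1
    toggle = 0
    while pos < n - 10:
        seg = int(rng.integers(8, 18))
        gap = int(rng.integers(4, 12))
        subtype = "alpha helix" if toggle % 2 == 0 else "beta sheet"
        rows.append({"start": pos, "end": min(pos + seg - 1, n),
                     "category": "structural", "subtype": subtype})
        pos += seg + gap
        toggle += 1
    # functional: constrained block plus fixed-subtype intervals avoiding
    # divergent codons
    c_sites = truth.constrained_sites
    rows.append({"start": min(c_sites) + 1, "end": max(c_sites) + 1,
                 "category": "functional", "subtype": "nonexchangeable site"})
    subtypes = ["beta-interface", "GTP-ribose", "GTP-nucleotide",
                "GTP-phosphate", "C-terminal H11/H12"]
    placed = 0
    attempts = 0
    while placed < len(subtypes) and attempts < 10000:
        attempts += 1
        seg = int(rng.integers(12, 30))
        start = int(rng.integers(0, n - seg))
        interval = set(range(start, start + seg))
        if interval & div:
            continue
        if interval & set(c_sites):
            continue
        rows.append({"start": start + 1, "end": start + seg,
                     "category": "functional", "subtype": subtypes[placed]})
        placed += 1
    return pd.DataFrame(rows)
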