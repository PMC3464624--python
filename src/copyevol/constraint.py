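"""Site-level physicochemical constraint scores and permutation tests.

A simplified multivariate physicochemical impact score is computed per
alignment column: six residue property scales (Kyte-Doolittle hydropathy,
Grantham polarity, net charge, Zamyatnin residue volume, Chou-Fasman helix
and sheet propensities), each z-normalized over the 20 residues, are
summarized per column by a (weighted) mean and variance; the impact of a
candidate residue is its squared, variance-scaled distance from the column
profile summed over properties, and a site's score is the mean impact over
all 20 candidate residues.  Conserved columns therefore score high (any
substitution is a large perturbation); columns already occupied by diverse
residues score low.

The score table feeds two randomization tests mirroring the usual analysis
of divergently evolving codons: a permutation test of the mean score at a
focal site set against random draws from a background, and a Monte Carlo
test of the concentration of focal sites in annotated structural or
functional regions.  Both report two-tailed p-values with the +1
small-sample correction, so the minimum attainable p is 2/(n+1), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Grantham (1974) polarity
_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}
#: net side-chain charge at neutral pH (His partially protonated)
_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})
#: Zamyatnin (1972) residue volume, A^3
_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
#: Chou-Fasman helix propensity P(alpha)
_HELIX = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70, "Q": 1.11,
    "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08, "L": 1.21, "K": 1.16,
    "M": 1.45, "F": 1.13, "P": 0.57, "S": 0.77, "T": 0.83, "W": 1.08,
    "Y": 0.69, "V": 1.06,
}
#: Chou-Fasman sheet propensity P(beta)
_SHEET = {
    "A": 0.83, "R": 0.93, "N": 0.89, "D": 0.54, "C": 1.19, "Q": 1.10,
    "E": 0.37, "G": 0.75, "H": 0.87, "I": 1.60, "L": 1.30, "K": 0.74,
    "M": 1.05, "F": 1.38, "P": 0.55, "S": 0.75, "T": 1.19, "W": 1.37,
    "Y": 1.47, "V": 1.70,
}

PROPERTY_SCALES = {
    "hydropathy": kd,
    "polarity": _POLARITY,
    "charge": _CHARGE,
    "volume": _VOLUME,
    "helix_propensity": _HELIX,
    "sheet_propensity": _SHEET,
}

REGION_CATEGORIES = ("structural", "functional")
REGION_SUBTYPES = (
    "alpha helix", "beta sheet", "beta-interface", "GTP-ribose",
    "GTP-nucleotide", "GTP-phosphate", "nonexchangeable site",
    "C-terminal H11/H12",
)


def _scale_matrix() -> np.ndarray:
    """(n_properties, 20) z-normalized scale values."""
    rows = []
    for table in PROPERTY_SCALES.values():
        v = np.array([table[a] for a in AMINO_ACIDS], dtype=float)
        rows.append((v - v.mean()) / v.std())
    return np.vstack(rows)


@dataclass
class SiteScoreTable:
    """Per-column impact scores over a protein alignment."""

    scores: np.ndarray        # NaN where the column was skipped (gappy)
    polymorphic: np.ndarray   # bool per column
    n_residues: np.ndarray    # distinct residues observed per column
    missing: np.ndarray       # bool, True for skipped columns

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": np.arange(self.scores.size),
            "score": self.scores,
            "polymorphic": self.polymorphic,
            "n_residues": self.n_residues,
            "missing": self.missing,
        })

    @property
    def polymorphic_sites(self) -> np.ndarray:
        return np.nonzero(self.polymorphic & ~self.missing)[0]

    @property
    def valid_sites(self) -> np.ndarray:
        return np.nonzero(~self.missing)[0]


def mapp_scores(alignment: dict, weights: dict | None = None,
                max_gap_fraction: float = 0.5,
                variance_floor_percentile: float = 5.0,
                min_variance: float = 0.05) -> SiteScoreTable:
    """Physicochemical impact score per alignment column.

    ``alignment`` maps sequence name to an aligned protein string.
    ``weights`` optionally assigns per-sequence weights (uniform by
    default).  Columns with more than ``max_gap_fraction`` gaps are skipped
    and reported missing.  Per-property column variances are floored at the
    given percentile of all column variances (and at ``min_variance``) so
    invariant columns remain finite.
    """
    names = sorted(alignment)
    if len(names) < 3:
        raise ValueError("need at least 3 sequences")
    L = {len(alignment[n]) for n in names}
    if len(L) != 1:
        raise ValueError("aligned sequences must have equal length")
    (ncol,) = L
    w = np.array([1.0 if weights is None else weights[n] for n in names])
    w = w / w.sum()
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    S = _scale_matrix()  # (P, 20)
    nprop = S.shape[0]

    res = np.full((len(names), ncol), -1, dtype=np.int16)
    for r, n in enumerate(names):
        for c, ch in enumerate(alignment[n].upper()):
            res[r, c] = aa_index.get(ch, -1)
    ok = res >= 0
    gap_frac = 1.0 - ok.mean(axis=0)
    missing = gap_frac > max_gap_fraction

    # weighted mean and variance of each property per column
    means = np.zeros((nprop, ncol))
    variances = np.zeros((nprop, ncol))
    wcol = np.where(ok, w[:, None], 0.0)
    wsum = wcol.sum(axis=0)
    wsafe = np.where(wsum > 0, wsum, 1.0)
    for p in range(nprop):
        vals = np.where(ok, S[p][np.clip(res, 0, None)], 0.0)
        m = (wcol * vals).sum(axis=0) / wsafe
        v = (wcol * (vals - m[None, :]) ** 2).sum(axis=0) / wsafe
        means[p] = m
        variances[p] = v
    valid = ~missing
    floor = np.maximum(
        np.percentile(variances[:, valid], variance_floor_percentile, axis=1)
        if valid.any() else np.zeros(nprop),
        min_variance,
    )
    vfl = np.maximum(variances, floor[:, None])

    # impact of each candidate residue, averaged over the 20 residues
    # (S[p,a] - m[p,c])^2 / v[p,c], summed over properties
    diff = S[:, :, None] - means[:, None, :]          # (P, 20, C)
    impact = (diff ** 2 / vfl[:, None, :]).sum(axis=0)  # (20, C)
    scores = impact.mean(axis=0)
    scores[missing] = np.nan

    n_res = np.array([
        len(set(res[ok[:, c], c].tolist())) if ok[:, c].any() else 0
        for c in range(ncol)
    ])
    return SiteScoreTable(
        scores=scores, polymorphic=(n_res > 1) & ~missing,
        n_residues=n_res, missing=missing,
    )


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    p: float
    n_replicates: int
    n_focal: int
    seed: int


def _draws_without_replacement(rng, n_items: int, k: int, reps: int,
                               chunk: int = 20000) -> np.ndarray:
    """(reps, k) index draws without replacement, chunked for memory."""
    out = np.empty((reps, k), dtype=np.int64)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        r = rng.random((m, n_items))
        out[done:done + m] = np.argpartition(r, k - 1, axis=1)[:, :k]
        done += m
    return out


def _two_tailed_p(null: np.ndarray, observed: float) -> float:
    n = null.size
    eps = 1e-9 * max(1.0, abs(observed))  # guard float summation noise
    ge = (1 + int((null >= observed - eps).sum())) / (n + 1)
    le = (1 + int((null <= observed + eps).sum())) / (n + 1)
    return min(1.0, 2.0 * min(ge, le))


def permutation_test(scores: SiteScoreTable | np.ndarray, focal,
                     background="all", n: int = 10000,
                     seed: int = 0) -> PermutationResult:
    """Two-tailed permutation test of the mean score at focal sites.

    ``background`` is ``"all"`` (all scored sites), ``"polymorphic"``
    (polymorphic sites only) or an explicit index array; ``n`` replicates
    draw ``|focal|`` sites without replacement from the background.  The
    +1 correction bounds p away from 0 (a zero-exceedance outcome reports
    p = 2/(n+1), an upper bound, not p = 0).
    """
    if isinstance(scores, SiteScoreTable):
        values = scores.scores
        if background == "all":
            bg = scores.valid_sites
        elif background == "polymorphic":
            bg = scores.polymorphic_sites
        else:
            bg = np.asarray(background, dtype=int)
    else:
        values = np.asarray(scores, dtype=float)
        bg = (np.nonzero(~np.isnan(values))[0] if isinstance(background, str)
              else np.asarray(background, dtype=int))
    focal = np.asarray(sorted(set(int(i) for i in focal)), dtype=int)
    if focal.size == 0:
        raise ValueError("focal set is empty")
    if bg.size < focal.size:
        raise ValueError("background smaller than the focal set")
    observed = float(np.nanmean(values[focal]))
    rng = np.random.default_rng(seed)
    draws = _draws_without_replacement(rng, bg.size, focal.size, n)
    null = values[bg[draws]].mean(axis=1)
    return PermutationResult(
        observed=observed, null_mean=float(null.mean()),
        p=_two_tailed_p(null, observed), n_replicates=n,
        n_focal=int(focal.size), seed=seed,
    )


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    p: float
    n_replicates: int
    seed: int


def read_regions_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_regions(df)


def validate_regions(df: pd.DataFrame) -> pd.DataFrame:
    required = {"start", "end", "category", "subtype"}
    if not required <= set(df.columns):
        raise ValueError(f"region table needs columns {sorted(required)}")
    if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
        raise ValueError("regions must satisfy 1 <= start <= end")
    bad = set(df["category"]) - set(REGION_CATEGORIES)
    if bad:
        raise ValueError(f"unknown region categories {sorted(bad)}")
    return df


def region_sites(regions: pd.DataFrame, category: str) -> np.ndarray:
    """0-based site indices covered by a category (1-based inclusive input)."""
    sel = regions[regions["category"] == category]
    sites: set = set()
    for _, row in sel.iterrows():
        sites.update(range(int(row["start"]) - 1, int(row["end"])))
    return np.array(sorted(sites), dtype=int)


def region_enrichment(focal, regions: pd.DataFrame, universe: int,
                      category: str = "functional", n: int = 10000,
                      seed: int = 0) -> EnrichmentResult:
    """Monte Carlo two-tailed test of focal-site concentration in a region
    category; replicates draw |focal| positions uniformly without
    replacement from the universe of sites."""
    focal = np.asarray(sorted(set(int(i) for i in focal)), dtype=int)
    if universe < focal.size:
        raise ValueError("universe smaller than focal set")
    member = np.zeros(universe, dtype=bool)
    cat_sites = region_sites(validate_regions(regions), category)
    member[cat_sites[cat_sites < universe]] = True
    observed = int(member[focal].sum())
    rng = np.random.default_rng(seed)
    draws = _draws_without_replacement(rng, universe, focal.size, n)
    null = member[draws].sum(axis=1)
    expected = focal.size * member.mean()
    return EnrichmentResult(
        category=category, observed=observed, expected=float(expected),
        p=_two_tailed_p(null, observed), n_replicates=n, seed=seed,
    )


def region_conservation(alignment: dict, interval: tuple) -> float:
    """Fraction of columns in ``interval`` (1-based inclusive protein
    coordinates) with a single observed residue across sequences."""
    names = sorted(alignment)
    start, end = interval
    L = len(alignment[names[0]])
    if not (1 <= start <= end <= L):
        raise ValueError("interval outside the alignment")
    conserved = 0
    for c in range(start - 1, end):
        residues = {alignment[n][c].upper() for n in names}
        residues -= {"-", ".", "X"}
        if len(residues) <= 1:
            conserved += 1
    return conserved / (end - start + 1)
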