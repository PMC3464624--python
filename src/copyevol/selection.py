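"""Codon selection analyses: branch-class and branch-site GY94 models,
sliding-window NG86 dN/dS, and a base-composition homogeneity diagnostic.

The likelihood machinery is a Felsenstein pruning implementation over the
61 sense codons with per-branch-class rate matrices.  Model fitting follows
the usual practice for these models: maximize over kappa and the class
omegas with branch lengths taken from the tree (optionally re-optimized
once under the one-ratio model and then fixed), with multiple omega starts.
AIC is reported with k counted as the number of free omega parameters, the
convention matching the branch-class model tables this package reproduces;
``k_convention="all-free"`` counts every optimized parameter instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.optimize import minimize
from scipy.spatial.distance import squareform

from . import codon as cd
from .trees import LabeledTree

_SCALE_THRESHOLD = 1e-250


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

class CodonAlignment:
    """Aligned coding sequences indexed over the 61 sense codons.

    Codons containing ambiguity characters or stops are treated as missing
    data (partial likelihood 1 over all states) and the affected columns are
    recorded in ``flagged_columns``.
    """

    def __init__(self, sequences: dict):
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned (equal length)")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length must be divisible by 3")
        self.names = sorted(sequences)
        self.n_codons = length // 3
        self.matrix = np.vstack([cd.codon_indices(sequences[n]) for n in self.names])
        self.flagged_columns = sorted(
            int(c) for c in np.nonzero((self.matrix < 0).any(axis=0))[0])

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from .io import read_fasta
        return cls(read_fasta(path))

    def subset(self, names) -> "CodonAlignment":
        out = object.__new__(CodonAlignment)
        keep = [self.names.index(n) for n in names]
        out.names = [self.names[i] for i in keep]
        out.n_codons = self.n_codons
        out.matrix = self.matrix[keep]
        out.flagged_columns = sorted(
            int(c) for c in np.nonzero((out.matrix < 0).any(axis=0))[0])
        return out

    def to_dict(self) -> dict:
        return {
            n: "".join(cd.SENSE_CODONS[i] if i >= 0 else "NNN"
                       for i in self.matrix[k])
            for k, n in enumerate(self.names)
        }

    def f3x4(self) -> np.ndarray:
        seqs = [
            "".join(cd.SENSE_CODONS[i] for i in row if i >= 0)
            for row in self.matrix
        ]
        return cd.f3x4_frequencies(seqs)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

class GY94Likelihood:
    """Felsenstein pruning for GY94 with branch-class omegas on one dataset."""

    def __init__(self, alignment: CodonAlignment, tree: LabeledTree):
        tree.validate()
        names = set(alignment.names)
        tips = set(tree.leaf_names)
        if names != tips:
            raise ValueError(f"alignment/tree taxa mismatch: "
                             f"{sorted(names ^ tips)[:5]}")
        self.aln = alignment
        self.tree = tree
        patterns, inverse, counts = np.unique(
            alignment.matrix.T, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns.T  # (n_taxa, n_patterns)
        self.pattern_of_column = inverse
        self.counts = counts.astype(float)
        self.n_patterns = self.patterns.shape[1]
        row = {n: i for i, n in enumerate(alignment.names)}
        self.tip_rows = {
            idx: row[tree.nodes[idx].name] for idx in tree.leaves}
        self.postorder = tree.postorder()

    def _transition_matrices(self, kappa, omega_by_label, pi, lengths):
        eig: dict[float, cd.ReversibleTransition] = {}
        P = {}
        for idx in self.postorder:
            if idx == self.tree.root:
                continue
            node = self.tree.nodes[idx]
            if node.label not in omega_by_label:
                raise ValueError(f"no omega for branch label {node.label!r}")
            omega = float(omega_by_label[node.label])
            if omega not in eig:
                Q = cd.gy94_rate_matrix(kappa, omega, pi)
                eig[omega] = cd.ReversibleTransition(Q, pi)
            t = lengths[idx] if lengths is not None else node.length
            P[idx] = eig[omega].probability_matrix(t)
        return P

    def pattern_likelihoods(self, kappa, omega_by_label, pi, lengths=None):
        """Per-pattern column likelihoods and the per-pattern log scaling."""
        if len(self.tree.nodes) == 1:  # single-taxon degenerate case
            obs = self.patterns[self.tip_rows[self.tree.root]]
            like = np.where(obs >= 0, pi[np.clip(obs, 0, None)], 1.0)
            return like, np.zeros(self.n_patterns)
        P = self._transition_matrices(kappa, omega_by_label, pi, lengths)
        partial = {}
        logscale = np.zeros(self.n_patterns)
        for idx in self.postorder:
            node = self.tree.nodes[idx]
            if self.tree.is_leaf(idx):
                continue
            acc = np.ones((cd.N_SENSE, self.n_patterns))
            for child in node.children:
                if self.tree.is_leaf(child):
                    obs = self.patterns[self.tip_rows[child]]
                    M = np.where(obs[None, :] >= 0,
                                 P[child][:, np.clip(obs, 0, None)], 1.0)
                else:
                    M = P[child] @ partial.pop(child)
                acc *= M
            mx = acc.max(axis=0)
            small = mx < _SCALE_THRESHOLD
            if small.any():
                safe = np.where(small & (mx > 0), mx, 1.0)
                acc /= safe[None, :]
                logscale += np.log(safe)
            partial[idx] = acc
        root = partial[self.tree.root]
        like = pi @ root
        return like, logscale

    def loglik(self, kappa, omega_by_label, pi, lengths=None) -> float:
        like, logscale = self.pattern_likelihoods(kappa, omega_by_label, pi,
                                                  lengths)
        if (like <= 0).any() or not np.isfinite(like).all():
            bad = int(np.nonzero((like <= 0) | ~np.isfinite(like))[0][0])
            cols = np.nonzero(self.pattern_of_column == bad)[0]
            raise FloatingPointError(
                f"non-finite likelihood at alignment column(s) {cols[:5]}")
        return float(self.counts @ (np.log(like) + logscale))


def gy94_loglik(alignment, tree: LabeledTree, kappa: float,
                omega_by_label: dict, pi=None, lengths=None) -> float:
    """Log-likelihood of a codon alignment under GY94 with class omegas.

    ``alignment`` may be a CodonAlignment or a dict of coding sequences;
    ``pi`` defaults to F3x4 frequencies estimated from the alignment.
    """
    if not isinstance(alignment, CodonAlignment):
        alignment = CodonAlignment(alignment)
    if pi is None:
        pi = alignment.f3x4()
    return GY94Likelihood(alignment, tree).loglik(kappa, omega_by_label, pi,
                                                  lengths)


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    model: str
    lnl: float
    k: int
    estimates: dict
    se: dict
    converged: bool
    n_starts: int
    details: dict = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.lnl


@dataclass
class SiteClassPosterior:
    """Naive empirical Bayes site-class posteriors for the branch-site model."""

    posteriors: pd.DataFrame  # columns p0, p1, p2a, p2b indexed by codon
    threshold: float
    flagged: list  # codon indices with P(2a) + P(2b) > threshold


def _resolve_groups(scheme, labels: set) -> dict:
    """Map branch labels to omega-group names for a class scheme."""
    if isinstance(scheme, dict):
        missing = labels - set(scheme)
        if missing:
            raise ValueError(f"scheme missing labels {sorted(missing)}")
        return dict(scheme)
    if scheme == "one-ratio":
        return {lab: "omega" for lab in labels}
    if scheme == "by-label":
        return {lab: f"omega_{lab}" for lab in labels}
    raise ValueError(f"unknown scheme {scheme!r}; use 'one-ratio', 'by-label' "
                     "or an explicit label->group mapping")


def _numerical_se(fun, x: np.ndarray, rel_step: float = 1e-4):
    """Standard errors from the inverse observed information of ``fun``
    (a log-likelihood) at ``x`` via central-difference Hessian."""
    n = x.size
    h = np.maximum(np.abs(x) * rel_step, 1e-8)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[[i, j]] += [h[i], -h[j]]
                xmp[[i, j]] += [-h[i], h[j]]
                xmm[[i, j]] += [-h[i], -h[j]]
                H[i, j] = H[j, i] = (
                    fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        d = np.diag(cov)
        return np.where(d > 0, np.sqrt(np.clip(d, 0, None)), np.nan)
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def optimize_branch_lengths(alignment, tree: LabeledTree, pi=None,
                            kappa0: float = 2.0, omega0: float = 0.1):
    """Re-optimize branch lengths jointly with kappa/omega under the
    one-ratio model; returns (new_tree, kappa_hat, omega_hat, lnl)."""
    if not isinstance(alignment, CodonAlignment):
        alignment = CodonAlignment(alignment)
    if pi is None:
        pi = alignment.f3x4()
    engine = GY94Likelihood(alignment, tree)
    branch_idx = [i for i in engine.postorder if i != tree.root]
    x0 = np.concatenate([
        [np.log(kappa0), np.log(omega0)],
        np.log(np.maximum([tree.nodes[i].length for i in branch_idx], 1e-4)),
    ])

    def neg(x):
        kappa = np.exp(x[0])
        omega = {lab: np.exp(x[1]) for lab in tree.branch_labels}
        lengths = dict(zip(branch_idx, np.exp(x[2:])))
        try:
            return -engine.loglik(kappa, omega, pi, lengths)
        except FloatingPointError:
            return 1e12

    res = minimize(neg, x0, method="L-BFGS-B",
                   bounds=[(-4, 4), (-12, 3)] + [(-11, 2)] * len(branch_idx),
                   options={"maxiter": 500, "ftol": 1e-10})
    new_tree = tree.copy()
    new_tree.set_lengths(dict(zip(branch_idx, np.exp(res.x[2:]))))
    return new_tree, float(np.exp(res.x[0])), float(np.exp(res.x[1])), float(-res.fun)


def fit_branch_class_model(alignment, tree: LabeledTree, scheme="by-label",
                           pi=None, starts=(0.05, 0.5, 1.5),
                           optimize_lengths: bool = False,
                           compute_se: bool = True,
                           k_convention: str = "omega-only") -> ModelFit:
    """Maximum-likelihood fit of a GY94 branch-class model.

    ``scheme`` assigns one free omega per branch-label group: ``"one-ratio"``
    pools all branches; ``"by-label"`` gives each distinct branch label its
    own ratio (the within/between and within1/rest/between models when the
    tree carries those labels); a dict maps labels to named groups
    explicitly.
    """
    if not isinstance(alignment, CodonAlignment):
        alignment = CodonAlignment(alignment)
    if pi is None:
        pi = alignment.f3x4()
    if optimize_lengths:
        tree, _, _, _ = optimize_branch_lengths(alignment, tree, pi=pi)
    groups = _resolve_groups(scheme, tree.branch_labels)
    group_names = sorted(set(groups.values()))
    engine = GY94Likelihood(alignment, tree)

    def unpack(x):
        kappa = np.exp(x[0])
        omegas = dict(zip(group_names, np.exp(x[1:])))
        omega_by_label = {lab: omegas[g] for lab, g in groups.items()}
        return kappa, omegas, omega_by_label

    def neg(x):
        kappa, _, omega_by_label = unpack(x)
        try:
            return -engine.loglik(kappa, omega_by_label, pi)
        except FloatingPointError:
            return 1e12

    best = None
    for w0 in starts:
        x0 = np.concatenate([[np.log(2.0)], np.full(len(group_names), np.log(w0))])
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(-4, 4)] + [(-12, 3)] * len(group_names),
                       options={"maxiter": 300, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    kappa, omegas, _ = unpack(best.x)
    estimates = {"kappa": kappa, **omegas}
    se = {name: np.nan for name in estimates}
    if compute_se:
        natural = np.concatenate([[kappa], [omegas[g] for g in group_names]])

        def ll_natural(v):
            omega_by_label = {lab: v[1 + group_names.index(g)]
                              for lab, g in groups.items()}
            try:
                return engine.loglik(v[0], omega_by_label, pi)
            except FloatingPointError:
                return -1e12

        ses = _numerical_se(ll_natural, natural)
        se = dict(zip(["kappa"] + group_names, ses))
    k = (len(group_names) if k_convention == "omega-only"
         else 1 + len(group_names))
    model_name = scheme if isinstance(scheme, str) else "custom-classes"
    return ModelFit(
        model=f"branch-class:{model_name}", lnl=float(-best.fun), k=k,
        estimates=estimates, se=se, converged=bool(best.success),
        n_starts=len(starts),
        details={"groups": groups, "k_convention": k_convention,
                 "n_evals": int(best.nfev)},
    )


def fit_branch_site_model(alignment, tree: LabeledTree,
                          foreground_labels=("between",), pi=None,
                          starts=((0.7, 0.1), (0.5, 0.3)),
                          threshold: float = 0.95,
                          compute_se: bool = False,
                          k_convention: str = "all-free"):
    """Branch-site model A fit with naive empirical Bayes site posteriors.

    Site classes: 0 (omega0 everywhere), 1 (neutral everywhere), 2a
    (omega0 background, omega2 foreground) and 2b (neutral background,
    omega2 foreground), with proportions (p0, p1, p2a, p2b) parameterized
    as in model A.  Returns (ModelFit, SiteClassPosterior); codons with
    P(2a) + P(2b) above ``threshold`` form the flagged divergent set.
    """
    if not isinstance(alignment, CodonAlignment):
        alignment = CodonAlignment(alignment)
    if pi is None:
        pi = alignment.f3x4()
    fg = set(foreground_labels)
    labels = tree.branch_labels
    if not fg or not fg <= labels:
        raise ValueError("foreground labels must be a non-empty subset of "
                         f"tree labels {sorted(labels)}")
    if fg == labels:
        raise ValueError("foreground must be a proper subset of branches")
    engine = GY94Likelihood(alignment, tree)

    def class_maps(omega0, omega2):
        def mk(bg, fgv):
            return {lab: (fgv if lab in fg else bg) for lab in labels}
        return [mk(omega0, omega0), mk(1.0, 1.0), mk(omega0, omega2),
                mk(1.0, omega2)]

    def proportions(a, b):
        ea, eb = np.exp(a), np.exp(b)
        norm = ea + eb + 1.0
        p0, p1 = ea / norm, eb / norm
        p2 = 1.0 / norm
        denom = p0 + p1
        return np.array([p0, p1, p2 * p0 / denom, p2 * p1 / denom])

    def components(x):
        kappa = np.exp(x[0])
        a, b = x[1], x[2]
        omega0 = 1.0 / (1.0 + np.exp(-x[3]))  # in (0, 1)
        omega2 = 1.0 + np.exp(x[4])           # >= 1
        props = proportions(a, b)
        per_class = []
        for omega_map in class_maps(omega0, omega2):
            like, logscale = engine.pattern_likelihoods(kappa, omega_map, pi)
            per_class.append((like, logscale))
        return kappa, omega0, omega2, props, per_class

    def neg(x):
        try:
            _, _, _, props, per_class = components(x)
        except FloatingPointError:
            return 1e12
        base = per_class[0][1]
        mix = np.zeros_like(per_class[0][0])
        for (like, logscale), p in zip(per_class, props):
            mix += p * like * np.exp(logscale - base)
        if (mix <= 0).any() or not np.isfinite(mix).all():
            return 1e12
        return -float(engine.counts @ (np.log(mix) + base))

    best = None
    for p0_init, w0_init in starts:
        x0 = np.array([np.log(2.0),
                       np.log(p0_init / (1 - p0_init - 0.05)),
                       np.log(0.05 / (1 - p0_init - 0.05)),
                       np.log(w0_init / (1 - w0_init)),
                       np.log(0.5)])
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(-4, 4), (-12, 12), (-12, 12), (-14, 14),
                               (-15, 5)],
                       options={"maxiter": 400, "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    kappa, omega0, omega2, props, per_class = components(best.x)
    estimates = {
        "kappa": float(kappa), "omega0": float(omega0), "omega2": float(omega2),
        "p0": float(props[0]), "p1": float(props[1]),
        "p2a": float(props[2]), "p2b": float(props[3]),
        "p2": float(props[2] + props[3]),
    }
    # naive empirical Bayes posteriors at the MLE
    base = per_class[0][1]
    weighted = np.vstack([
        p * like * np.exp(logscale - base)
        for (like, logscale), p in zip(per_class, props)
    ])
    post = weighted / weighted.sum(axis=0, keepdims=True)
    per_column = post[:, engine.pattern_of_column].T
    posteriors = pd.DataFrame(per_column, columns=["p0", "p1", "p2a", "p2b"])
    posteriors.index.name = "codon"
    elevated = per_column[:, 2] + per_column[:, 3]
    flagged = sorted(int(i) for i in np.nonzero(elevated > threshold)[0])
    k = 5 if k_convention == "all-free" else 4
    fit = ModelFit(
        model="branch-site:modelA", lnl=float(-best.fun), k=k,
        estimates=estimates, se={name: np.nan for name in estimates},
        converged=bool(best.success), n_starts=len(starts),
        details={"foreground": sorted(fg), "n_evals": int(best.nfev)},
    )
    if compute_se:
        def ll_natural(v):
            x = np.array([np.log(v[0]), best.x[1], best.x[2],
                          np.log(v[1] / (1 - v[1])), np.log(max(v[2] - 1, 1e-12))])
            return -neg(x)
        ses = _numerical_se(ll_natural, np.array([kappa, omega0, omega2]))
        fit.se.update(dict(zip(["kappa", "omega0", "omega2"], ses)))
    return fit, SiteClassPosterior(posteriors=posteriors, threshold=threshold,
                                   flagged=flagged)


def split_within_label(tree: LabeledTree, focal_leaves, within_label="within",
                       new_label="within1") -> LabeledTree:
    """Relabel within-class branches whose descendant leaves all belong to
    ``focal_leaves`` (e.g. class-1 copies), enabling three-ratio fits."""
    focal = set(focal_leaves)
    out = tree.copy()

    def leafset(idx):
        if out.is_leaf(idx):
            return {out.nodes[idx].name}
        return set().union(*(leafset(c) for c in out.nodes[idx].children))

    for i, node in enumerate(out.nodes):
        if i == out.root or node.label != within_label:
            continue
        if leafset(i) <= focal:
            node.label = new_label
    return out


def compare_models(fits: list) -> pd.DataFrame:
    """Rank model fits by AIC (ascending); ties break to fewer parameters."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = [{"model": f.model, "lnl": f.lnl, "k": f.k, "aic": f.aic}
            for f in fits]
    df = pd.DataFrame(rows).sort_values(["aic", "k"]).reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# Sliding-window NG86
# ---------------------------------------------------------------------------

def sliding_window_dnds(alignment, groups: dict, window: int = 15,
                        step: int = 5) -> pd.DataFrame:
    """Windowed between-group mean NG86 dN and dS.

    ``groups`` maps taxon name to a group label (e.g. intron class); all
    pairs spanning two different groups contribute.  Windows with dS = 0
    are flagged undefined (ratio NaN).
    """
    if window < 3 or step < 1:
        raise ValueError("window must be >= 3 and step >= 1")
    if not isinstance(alignment, CodonAlignment):
        alignment = CodonAlignment(alignment)
    syn_sites, syn_d, nonsyn_d = cd._ng86_tables()
    pairs = [
        (i, j)
        for i in range(len(alignment.names))
        for j in range(i + 1, len(alignment.names))
        if groups.get(alignment.names[i]) != groups.get(alignment.names[j])
    ]
    if not pairs:
        raise ValueError("no between-group pairs")
    n = alignment.n_codons
    starts = list(range(0, max(n - window, 0) + 1, step))
    rows = []
    # per-pair per-codon contributions
    contrib = []
    for i, j in pairs:
        ai, bi = alignment.matrix[i], alignment.matrix[j]
        ok = (ai >= 0) & (bi >= 0)
        S = np.where(ok, (syn_sites[np.clip(ai, 0, None)] +
                          syn_sites[np.clip(bi, 0, None)]) / 2, 0.0)
        N = np.where(ok, 3.0 - S, 0.0)
        sd = np.where(ok, syn_d[np.clip(ai, 0, None), np.clip(bi, 0, None)], 0.0)
        nd = np.where(ok, nonsyn_d[np.clip(ai, 0, None), np.clip(bi, 0, None)], 0.0)
        contrib.append((S, N, sd, nd))
    for w0 in starts:
        w1 = w0 + window
        dns, dss = [], []
        for S, N, sd, nd in contrib:
            Ssum, Nsum = S[w0:w1].sum(), N[w0:w1].sum()
            if Ssum <= 0 or Nsum <= 0:
                continue
            ps, pn = sd[w0:w1].sum() / Ssum, nd[w0:w1].sum() / Nsum
            ds, dn = cd._jukes_cantor(ps), cd._jukes_cantor(pn)
            if not (np.isnan(ds) or np.isnan(dn)):
                dss.append(ds)
                dns.append(dn)
        mean_dn = float(np.mean(dns)) if dns else np.nan
        mean_ds = float(np.mean(dss)) if dss else np.nan
        undefined = (not dss) or mean_ds == 0
        rows.append({
            "start_codon": w0, "end_codon": w1, "mean_dn": mean_dn,
            "mean_ds": mean_ds,
            "dnds": (np.nan if undefined else mean_dn / mean_ds),
            "undefined": undefined,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Base-composition homogeneity
# ---------------------------------------------------------------------------

def _composition_statistic(seq_arrays) -> float:
    counts = np.vstack([
        [(a == ord(b)).sum() for b in "ACGT"] for a in seq_arrays
    ]).astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    pooled = counts.sum(axis=0) / counts.sum()
    expected = totals * pooled[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _hky_matrix(kappa: float, pi4: np.ndarray) -> np.ndarray:
    Q = np.tile(pi4, (4, 1))
    # order A, C, G, T: transitions are A<->G (0,2) and C<->T (1,3)
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi4 * np.diag(Q)).sum()
    return Q / rate


def composition_chisq(sequences: dict, n_sim: int = 1000, seed: int = 0,
                      kappa: float = 2.0):
    """Chi-squared test of base-composition homogeneity across sequences.

    The statistic sums (observed - expected)^2 / expected over sequences and
    bases, with expectations from the pooled composition (gaps and N
    excluded).  The null distribution is simulated under a homogeneous HKY
    process on an average-linkage guide tree built from Jukes-Cantor
    distances, and p carries the +1 Monte Carlo correction.
    """
    names = sorted(sequences)
    if len(names) < 2:
        raise ValueError("need at least two sequences")
    arrays = [np.frombuffer(sequences[n].upper().encode(), dtype=np.uint8)
              for n in names]
    keep = [a[np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8))]
            for a in arrays]
    observed = _composition_statistic(keep)

    # guide tree from JC distances (pairwise deletion on aligned columns)
    n = len(names)
    L = min(len(a) for a in arrays)
    code = {ord(c): k for k, c in enumerate("ACGT")}
    mat = np.full((n, L), -1, dtype=np.int8)
    for i, a in enumerate(arrays):
        for b, k in code.items():
            mat[i, (a[:L] == b)] = k
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] >= 0) & (mat[j] >= 0)
            p = (mat[i][ok] != mat[j][ok]).mean() if ok.any() else 0.0
            p = min(p, 0.70)
            dist[i, j] = dist[j, i] = -0.75 * np.log(1 - 4 * p / 3)
    Z = linkage(squareform(dist, checks=False), method="average")
    root, _ = to_tree(Z, rd=True)

    pooled = np.array([(np.concatenate(keep) == ord(b)).sum() for b in "ACGT"],
                      dtype=float)
    pi4 = pooled / pooled.sum()
    eig = cd.ReversibleTransition(_hky_matrix(kappa, pi4), pi4)
    rng = np.random.default_rng(seed)
    lengths = [len(a) for a in keep]

    def simulate_once():
        seqs = {}

        def walk(node, state, height):
            t = max(height - node.dist, 0.0)
            if t > 0:
                P = eig.probability_matrix(t)
                cum = np.cumsum(P, axis=1)
                r = rng.random(state.size)
                state = (r[:, None] > cum[state]).sum(axis=1)
            if node.is_leaf():
                seqs[node.id] = state
            else:
                walk(node.left, state, node.dist)
                walk(node.right, state, node.dist)

        root_state = rng.choice(4, size=max(lengths), p=pi4)
        walk(root, root_state, root.dist)
        return [
            np.frombuffer(b"ACGT", dtype=np.uint8)[seqs[i][:lengths[i]]]
            for i in range(n)
        ]

    exceed = 0
    for _ in range(n_sim):
        sim = simulate_once()
        if _composition_statistic(sim) >= observed:
            exceed += 1
    p = (exceed + 1) / (n_sim + 1)
    return observed, float(p)
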