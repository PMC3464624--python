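"""Predicted protein chemistry: GRAVY, isoelectric point, instability index,
and tests of whether intron classes are predictable from these indices.

The three indices follow the standard ProtParam definitions: GRAVY is the
mean Kyte-Doolittle hydropathy; pI is the pH where the Henderson-
Hasselbalch net charge (Bjellqvist pKa set) crosses zero; the instability
index is the length-normalized sum of Guruprasad dipeptide weights (DIWV),
with < 40 predicted stable.  Scale tables are taken from Biopython's
published ProtParam data.  Class predictability is assessed with linear
discriminant analysis (resubstitution and leave-one-out accuracy) and
per-index one-way ANOVA with Tukey HSD pairwise contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqUtils.IsoelectricPoint import negative_pKs, positive_pKs, pKcterminal, pKnterminal
from Bio.SeqUtils.ProtParamData import DIWV, kd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, cross_val_predict
from sklearn.preprocessing import StandardScaler

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
STABILITY_THRESHOLD = 40.0


@dataclass
class ChemProfile:
    copy_id: str
    gravy: float
    isoelectric_point: float
    instability_index: float

    @property
    def stable(self) -> bool:
        return self.instability_index < STABILITY_THRESHOLD


def _clean(protein: str, context: str) -> str:
    protein = protein.upper().replace("*", "")
    if not protein:
        raise ValueError(f"{context}: empty protein sequence")
    unknown = set(protein) - STANDARD_RESIDUES
    if unknown:
        warnings.warn(f"{context}: skipping non-standard residues "
                      f"{sorted(unknown)}", stacklevel=3)
    return protein


def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value.

    Positive values indicate a hydrophobic protein.  Non-standard residues
    are skipped (with a warning).
    """
    protein = _clean(protein, "gravy")
    vals = [kd[r] for r in protein if r in STANDARD_RESIDUES]
    if not vals:
        raise ValueError("no standard residues")
    return float(np.mean(vals))


def _net_charge(counts: dict, nterm: str, cterm: str, ph: float) -> float:
    pos = sum(
        n / (1.0 + 10.0 ** (ph - pk))
        for res, pk in positive_pKs.items()
        for n in [counts.get(res, 0)]
    )
    pos += 1.0 / (1.0 + 10.0 ** (ph - pKnterminal.get(nterm, 7.5)))
    neg = sum(
        n / (1.0 + 10.0 ** (pk - ph))
        for res, pk in negative_pKs.items()
        for n in [counts.get(res, 0)]
    )
    neg += 1.0 / (1.0 + 10.0 ** (pKcterminal.get(cterm, 3.55) - ph))
    return pos - neg


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH of zero net charge under the Henderson-Hasselbalch model.

    Charged groups: N-terminus, H, K, R (positive); C-terminus, D, E, C, Y
    (negative), with the Bjellqvist pKa set.  Solved by bisection on
    [0, 14] to ``tol`` pH units.
    """
    protein = _clean(protein, "isoelectric_point")
    kept = [r for r in protein if r in STANDARD_RESIDUES]
    counts = {r: kept.count(r) for r in set(kept)}
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _net_charge(counts, kept[0], kept[-1], mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(protein: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights.

    Values below 40 predict a stable protein.  Non-standard residues break
    the dipeptide chain (their dipeptides contribute nothing).
    """
    protein = _clean(protein, "instability_index")
    if len(protein) < 2:
        raise ValueError("need at least two residues")
    total = 0.0
    for a, b in zip(protein, protein[1:]):
        if a in STANDARD_RESIDUES and b in STANDARD_RESIDUES:
            total += DIWV[a][b]
    return float(10.0 * total / len(protein))


def chem_profile(copy_id: str, protein: str) -> ChemProfile:
    return ChemProfile(
        copy_id=copy_id, gravy=gravy(protein),
        isoelectric_point=isoelectric_point(protein),
        instability_index=instability_index(protein),
    )


def profiles_frame(profiles: list) -> pd.DataFrame:
    return pd.DataFrame([
        {"copy_id": p.copy_id, "gravy": p.gravy,
         "isoelectric_point": p.isoelectric_point,
         "instability_index": p.instability_index, "stable": p.stable}
        for p in profiles
    ])


@dataclass
class DiscriminantReport:
    class_accuracy: dict        # class -> resubstitution accuracy
    loo_class_accuracy: dict    # class -> leave-one-out accuracy
    confusion: pd.DataFrame     # rows true class, columns predicted
    projection: pd.DataFrame    # discriminant coordinates per copy


_FEATURES = ["gravy", "isoelectric_point", "instability_index"]


def _feature_matrix(profiles) -> tuple:
    if isinstance(profiles, pd.DataFrame):
        X = profiles[_FEATURES].to_numpy(dtype=float)
        ids = list(profiles["copy_id"]) if "copy_id" in profiles else list(profiles.index)
    else:
        X = np.array([[p.gravy, p.isoelectric_point, p.instability_index]
                      for p in profiles], dtype=float)
        ids = [p.copy_id for p in profiles]
    return X, ids


def discriminant_classify(profiles, labels) -> DiscriminantReport:
    """Linear discriminant analysis of chemistry profiles against classes.

    Features are standardized; per-class correct-identification rates are
    reported both by resubstitution (the paper-comparable number) and
    leave-one-out cross-validation.
    """
    X, ids = _feature_matrix(profiles)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 members each")
    Xs = StandardScaler().fit_transform(X)
    # guard a singular pooled within-class covariance
    resid = np.vstack([Xs[y == c] - Xs[y == c].mean(axis=0) for c in classes])
    pooled = resid.T @ resid / max(len(y) - len(classes), 1)
    if np.linalg.cond(pooled) > 1e10:
        raise ValueError(
            "pooled within-class covariance is singular; add jitter to the "
            "features or drop a collinear feature")
    lda = LinearDiscriminantAnalysis()
    lda.fit(Xs, y)
    pred = lda.predict(Xs)
    loo_pred = cross_val_predict(LinearDiscriminantAnalysis(), Xs, y,
                                 cv=LeaveOneOut())
    conf = pd.crosstab(pd.Series(y, name="true"),
                       pd.Series(pred, name="predicted"))
    conf = conf.reindex(index=classes, columns=classes, fill_value=0)
    acc = {c: float((pred[y == c] == c).mean()) for c in classes}
    loo = {c: float((loo_pred[y == c] == c).mean()) for c in classes}
    proj = pd.DataFrame(lda.transform(Xs), index=ids,
                        columns=[f"LD{i + 1}" for i in range(lda.transform(Xs).shape[1])])
    return DiscriminantReport(class_accuracy=acc, loo_class_accuracy=loo,
                              confusion=conf, projection=proj)


def class_contrasts(profiles, labels) -> pd.DataFrame:
    """One-way ANOVA F and Tukey HSD adjusted p per chemistry index.

    Returns a tidy frame with one row per (index, class pair), carrying the
    global F statistic/p and the pairwise Tukey p.
    """
    X, _ = _feature_matrix(profiles)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2 or min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 classes with >= 2 members each")
    rows = []
    for f_idx, feature in enumerate(_FEATURES):
        samples = [X[y == c, f_idx] for c in classes]
        F, p_global = stats.f_oneway(*samples)
        tk = stats.tukey_hsd(*samples)
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                rows.append({
                    "index": feature, "class_a": classes[i],
                    "class_b": classes[j], "anova_F": float(F),
                    "anova_p": float(p_global),
                    "tukey_p": float(tk.pvalue[i, j]),
                })
    return pd.DataFrame(rows)
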