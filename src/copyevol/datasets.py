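"""Access to the deposited alpha tubulin clone sequences (GenBank).

The cloned bdelloid alpha tubulin copies were deposited as GenBank
accessions JX193018-JX193069, with the intron-free monogonont cDNA
BJ999223.1 as coding reference.  These helpers fetch the records via
NCBI Entrez (network required) and rerun the intron-classing plus
protein-chemistry discriminant analysis on them.
"""

from __future__ import annotations

import numpy as np

DEPOSITED_RANGE = ("JX193018", "JX193069")
REFERENCE_CDNA = "BJ999223.1"


def deposited_accessions() -> list:
    """The full JX193018-JX193069 accession list."""
    prefix = DEPOSITED_RANGE[0][:2]
    lo = int(DEPOSITED_RANGE[0][2:])
    hi = int(DEPOSITED_RANGE[1][2:])
    return [f"{prefix}{i}" for i in range(lo, hi + 1)]


def fetch_genbank(accessions, email: str = "copyevol@example.org",
                  timeout: float = 30.0) -> dict:
    """Fetch nucleotide FASTA records from NCBI; returns {accession: seq}."""
    from Bio import Entrez, SeqIO

    Entrez.email = email
    handle = Entrez.efetch(db="nucleotide", id=",".join(accessions),
                           rettype="fasta", retmode="text")
    out = {}
    for rec in SeqIO.parse(handle, "fasta"):
        out[rec.id.split(".")[0]] = str(rec.seq).upper()
    handle.close()
    return out


def deposited_discriminant_analysis(copies: dict, reference_cds: str):
    """Intron classes + chemistry LDA on deposited genomic copies.

    Returns (assignment, report): the intron ClassAssignment and the
    DiscriminantReport of the three chemistry indices against classes
    (classes with fewer than 2 members are excluded from the LDA).
    """
    from .chemistry import chem_profile, discriminant_classify, profiles_frame
    from .codon import translate_codon
    from .introns import assign_classes, canonicalize_sites, locate_introns, splice

    obs = {}
    spliced = {}
    for cid, seq in copies.items():
        o = locate_introns(seq, reference_cds)
        obs[cid] = o
        spliced[cid] = splice(seq, o)
    _, patterns = canonicalize_sites(obs)
    assignment = assign_classes(patterns)
    profs = []
    labels = []
    for cid, cds in sorted(spliced.items()):
        usable = cds[: 3 * (len(cds) // 3)]
        aa = "".join(translate_codon(usable[i:i + 3])
                     for i in range(0, len(usable), 3))
        aa = aa.rstrip("*").replace("*", "X")
        profs.append(chem_profile(cid, aa))
        labels.append(assignment.classes[cid])
    labels = np.asarray(labels)
    keep_classes = {c for c in set(labels.tolist())
                    if (labels == c).sum() >= 2}
    mask = np.array([l in keep_classes for l in labels])
    frame = profiles_frame([p for p, m in zip(profs, mask) if m])
    report = discriminant_classify(frame, labels[mask])
    return assignment, report
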