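"""End-to-end orchestration: simulate -> collapse -> introns -> chemistry ->
constraint -> selection -> report.

The pipeline is a pure function of its configuration (including every
seed): rerunning with the same config reproduces the same report.  Each
stage writes its artifacts under the output directory and contributes to a
single consolidated :class:`RunReport`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io
from .chemistry import chem_profile, discriminant_classify, profiles_frame
from .constraint import (mapp_scores, permutation_test, region_enrichment,
                         region_conservation)
from .copy_calling import accumulation_curve, chao1, collapse_clones, refine_copyset
from .introns import assign_classes, canonicalize_sites, locate_introns, pattern_matrix, splice
from .selection import CodonAlignment, compare_models, fit_branch_class_model
from .simulate import (CloneSimConfig, FamilySimConfig,
                       simulate_clone_libraries, simulate_family,
                       simulate_region_annotation)
from .trees import LabeledTree


@dataclass
class PipelineConfig:
    """All stage parameters for one run; everything random is seeded."""

    outdir: str = "copyevol_run"
    seed: int = 0
    family: FamilySimConfig = field(default_factory=FamilySimConfig)
    clones: CloneSimConfig = field(default_factory=CloneSimConfig)
    collapse_threshold: float = 0.01
    accumulation_orderings: int = 200
    merge_window: int = 6
    merge_radius: int = 1
    permutation_replicates: int = 10000
    run_selection: bool = True
    selection_max_taxa: int = 40
    stages: tuple = ("simulate", "collapse", "introns", "chem", "constraint",
                     "selection")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["family"]["intron_length_range"] = list(self.family.intron_length_range)
        d["family"]["long_intron_lengths"] = {
            int(k): list(v) for k, v in self.family.long_intron_lengths.items()}
        for key in ("divergent_block", "constrained_block"):
            d["family"][key] = list(d["family"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        fam = dict(d.pop("family", {}))
        if "intron_length_range" in fam:
            fam["intron_length_range"] = tuple(fam["intron_length_range"])
        if "long_intron_lengths" in fam:
            fam["long_intron_lengths"] = {
                int(k): tuple(v) for k, v in fam["long_intron_lengths"].items()}
        for key in ("divergent_block", "constrained_block"):
            if key in fam:
                fam[key] = tuple(fam[key])
        cl = dict(d.pop("clones", {}))
        stages = tuple(d.pop("stages", cls.stages))
        return cls(family=FamilySimConfig(**fam), clones=CloneSimConfig(**cl),
                   stages=stages, **d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.load_yaml(path))

    def save(self, path):
        io.dump_yaml(self.to_dict(), path)


@dataclass
class RunReport:
    """Consolidated per-run results; every number traces to a stage file."""

    samples: pd.DataFrame | None = None          # copy counts + Chao1
    class_table: pd.DataFrame | None = None      # copy -> class/variant
    n_classes: int | None = None
    n_patterns: int | None = None
    catalogue_size: int | None = None
    chemistry: pd.DataFrame | None = None
    discriminant_accuracy: dict | None = None
    constraint_tests: dict | None = None
    conservation: dict | None = None
    model_table: pd.DataFrame | None = None
    preferred_model: str | None = None
    truth_summary: dict | None = None
    provenance: dict | None = None

    def to_json_dict(self) -> dict:
        def df(x):
            return None if x is None else json.loads(x.to_json(orient="records"))
        return {
            "samples": df(self.samples),
            "class_table": df(self.class_table),
            "n_classes": self.n_classes,
            "n_patterns": self.n_patterns,
            "catalogue_size": self.catalogue_size,
            "chemistry": df(self.chemistry),
            "discriminant_accuracy": self.discriminant_accuracy,
            "constraint_tests": self.constraint_tests,
            "conservation": self.conservation,
            "model_table": df(self.model_table),
            "preferred_model": self.preferred_model,
            "truth_summary": self.truth_summary,
            "provenance": self.provenance,
        }


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def match_copies_to_truth(copyset, clone_map: dict) -> dict:
    """Map each consensus copy to the truth copy most of its clones came from."""
    out = {}
    for c in copyset.copies:
        sources = [clone_map[m] for m in c.members if m in clone_map]
        if sources:
            vals, counts = np.unique(sources, return_counts=True)
            out[c.copy_id] = str(vals[np.argmax(counts)])
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the configured stages in dependency order and write artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    report = RunReport()
    stages = set(config.stages)
    seedseq = np.random.SeedSequence(config.seed)
    sub = {name: int(s.generate_state(1)[0] % (2 ** 31))
           for name, s in zip(
               ("family", "clones", "curve", "regions", "perm", "enrich"),
               seedseq.spawn(6))}

    # ----- simulate ------------------------------------------------------
    try:
        family_cfg = FamilySimConfig(**{**asdict(config.family),
                                        "seed": sub["family"]})
        family_cfg.long_intron_lengths = dict(config.family.long_intron_lengths)
        copies, truth, tree = simulate_family(
            family_cfg, collapse_threshold=config.collapse_threshold)
        clone_cfg = CloneSimConfig(
            clones_per_sample=config.clones.clones_per_sample,
            abundance_concentration=config.clones.abundance_concentration,
            per_base_error=config.clones.per_base_error, seed=sub["clones"])
        libraries, clone_map = simulate_clone_libraries(copies, truth, clone_cfg)
        io.write_fasta(copies, out / "copies_true.fasta")
        io.write_fasta({"reference": truth.root_cds}, out / "reference_cds.fasta")
        io.write_tsv(truth.to_frame(), out / "truth.tsv")
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        for species, lib in libraries.items():
            io.write_fasta(dict(lib.records), out / f"clones_{species}.fasta")
        report.truth_summary = {
            "n_species": len(truth.species),
            "true_copies_per_species": {
                sp: len(truth.copies_of(sp)) for sp in truth.species},
            "n_true_patterns": len({t.pattern for t in truth.copies.values()}),
            "n_true_classes": len({t.class_label for t in truth.copies.values()}),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e
    if "simulate" not in stages:
        # simulate is the root stage of the synthetic pipeline; nothing else
        # can run without it
        return _finish(report, config, out)

    # ----- collapse -------------------------------------------------------
    copysets = {}
    consensus_truth = {}
    if "collapse" in stages:
        try:
            rows = []
            for species, lib in sorted(libraries.items()):
                cs = collapse_clones(lib, threshold=config.collapse_threshold)
                cs = refine_copyset(cs, lib,
                                    threshold=config.collapse_threshold)
                copysets[species] = cs
                io.write_copyset_fasta(cs, out / f"copies_{species}.fasta")
                rich = chao1(cs.member_counts)
                assignment = {}
                for c in cs.copies:
                    for m in c.members:
                        assignment[m] = c.copy_id
                curve = accumulation_curve(
                    [assignment[cid] for cid, _ in lib.records],
                    n_orderings=config.accumulation_orderings,
                    seed=sub["curve"])
                io.write_tsv(pd.DataFrame({
                    "clones": curve.k, "mean": curve.mean,
                    "p5": curve.lo, "p95": curve.hi}),
                    out / f"accumulation_{species}.tsv")
                rows.append({
                    "sample": species, "clones": len(lib),
                    "observed_copies": rich.observed_richness,
                    "true_copies": len(truth.copies_of(species)),
                    "chao1": rich.chao1, "chao1_se": rich.chao1_se,
                    "f1": rich.f1, "f2": rich.f2,
                })
                consensus_truth.update(match_copies_to_truth(cs, clone_map))
            report.samples = pd.DataFrame(rows)
            io.write_tsv(report.samples, out / "richness.tsv")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("collapse", e) from e

    # ----- introns --------------------------------------------------------
    spliced = {}
    class_assignment = None
    if "introns" in stages and copysets:
        try:
            obs_by_copy = {}
            seq_by_copy = {}
            for species, cs in sorted(copysets.items()):
                for c in cs.copies:
                    obs_by_copy[c.copy_id] = locate_introns(
                        c.consensus, truth.root_cds)
                    seq_by_copy[c.copy_id] = c.consensus
            catalogue, patterns = canonicalize_sites(
                obs_by_copy, merge_window=config.merge_window)
            class_assignment = assign_classes(
                patterns, merge_radius=config.merge_radius)
            for cid, obs in obs_by_copy.items():
                spliced[cid] = splice(seq_by_copy[cid], obs)
            io.write_tsv(pattern_matrix(patterns, catalogue).reset_index(
                names="copy_id"), out / "pattern_matrix.tsv")
            report.class_table = class_assignment.to_frame()
            io.write_tsv(report.class_table, out / "classes.tsv")
            report.n_classes = class_assignment.n_classes
            report.n_patterns = class_assignment.n_variants
            report.catalogue_size = len(catalogue)
            io.write_fasta(spliced, out / "spliced_cds.fasta")
        except Exception as e:  # noqa: BLE001
            raise StageError("introns", e) from e

    # ----- chemistry ------------------------------------------------------
    proteins = {}
    if spliced:
        from .codon import translate_codon
        for cid, cds in spliced.items():
            if len(cds) % 3 == 0:
                aa = "".join(translate_codon(cds[i:i + 3])
                             for i in range(0, len(cds), 3))
                proteins[cid] = aa.rstrip("*").replace("*", "X")
    if "chem" in stages and proteins and class_assignment:
        try:
            profs = [chem_profile(cid, seq)
                     for cid, seq in sorted(proteins.items())]
            report.chemistry = profiles_frame(profs)
            io.write_tsv(report.chemistry, out / "chemistry.tsv")
            labels = [class_assignment.classes[p.copy_id] for p in profs]
            counts = pd.Series(labels).value_counts()
            if len(counts) >= 2 and counts.min() >= 2:
                rep = discriminant_classify(report.chemistry, labels)
                report.discriminant_accuracy = {
                    "resubstitution": {str(k): v
                                       for k, v in rep.class_accuracy.items()},
                    "leave_one_out": {str(k): v
                                      for k, v in rep.loo_class_accuracy.items()},
                }
                io.write_tsv(rep.confusion.reset_index(),
                             out / "discriminant_confusion.tsv")
        except Exception as e:  # noqa: BLE001
            raise StageError("chem", e) from e

    # ----- constraint -----------------------------------------------------
    if "constraint" in stages and proteins:
        try:
            lens = [len(p) for p in proteins.values()]
            modal = max(set(lens), key=lens.count)
            aligned = {c: p for c, p in proteins.items() if len(p) == modal}
            table = mapp_scores(aligned)
            io.write_tsv(table.to_frame(), out / "site_scores.tsv")
            n_prot = table.scores.size
            focal = [s for s in truth.divergent_sites if s < n_prot]
            perm = permutation_test(table, focal, background="all",
                                    n=config.permutation_replicates,
                                    seed=sub["perm"])
            perm_poly = permutation_test(table, focal, background="polymorphic",
                                         n=config.permutation_replicates,
                                         seed=sub["perm"] + 1)
            regions = simulate_region_annotation(truth, n_codons=n_prot,
                                                 seed=sub["regions"])
            io.write_tsv(regions, out / "regions.tsv")
            func = region_enrichment(focal, regions, universe=n_prot,
                                     category="functional",
                                     n=config.permutation_replicates,
                                     seed=sub["enrich"])
            struct = region_enrichment(focal, regions, universe=n_prot,
                                       category="structural",
                                       n=config.permutation_replicates,
                                       seed=sub["enrich"] + 1)
            report.constraint_tests = {
                "divergent_vs_all_p": perm.p,
                "divergent_vs_all_observed": perm.observed,
                "divergent_vs_all_null_mean": perm.null_mean,
                "divergent_vs_polymorphic_p": perm_poly.p,
                "functional_region_observed": func.observed,
                "functional_region_expected": func.expected,
                "functional_region_p": func.p,
                "structural_region_observed": struct.observed,
                "structural_region_p": struct.p,
            }
            c_lo = min(truth.constrained_sites) + 1
            c_hi = min(max(truth.constrained_sites) + 1, n_prot)
            report.conservation = {
                "constrained_block": region_conservation(aligned, (c_lo, c_hi)),
                "whole_protein": region_conservation(aligned, (1, n_prot)),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("constraint", e) from e

    # ----- selection ------------------------------------------------------
    if "selection" in stages and config.run_selection and spliced:
        try:
            matched = {cid: consensus_truth.get(cid) for cid in spliced}
            usable = {cid: t for cid, t in matched.items() if t is not None}
            tips = set(tree.leaf_names)
            keep = {cid: t for cid, t in usable.items() if t in tips}
            # relabel alignment onto truth tree tip names (1:1 where possible)
            seen = {}
            seqs = {}
            for cid, t in sorted(keep.items()):
                if t not in seen and len(spliced[cid]) % 3 == 0:
                    seen[t] = cid
                    seqs[t] = spliced[cid]
            if len(seqs) > config.selection_max_taxa:
                names = sorted(seqs)[:config.selection_max_taxa]
                seqs = {n: seqs[n] for n in names}
            pruned = _prune_to(tree, set(seqs))
            aln = CodonAlignment(seqs)
            fits = [
                fit_branch_class_model(aln, pruned, scheme="one-ratio",
                                       compute_se=False),
                fit_branch_class_model(aln, pruned, scheme="by-label",
                                       compute_se=False),
            ]
            table = compare_models(fits)
            report.model_table = table
            report.preferred_model = table.iloc[0]["model"]
            io.write_tsv(table, out / "model_comparison.tsv")
            ests = pd.DataFrame([
                {"model": f.model, **{k: v for k, v in f.estimates.items()}}
                for f in fits
            ])
            io.write_tsv(ests, out / "model_estimates.tsv")
        except Exception as e:  # noqa: BLE001
            raise StageError("selection", e) from e

    return _finish(report, config, out)


def _prune_to(tree: LabeledTree, keep: set) -> LabeledTree:
    from .simulate import _prune_leaves
    return _prune_leaves(tree, keep)


def _finish(report: RunReport, config: PipelineConfig, out: Path) -> RunReport:
    cfg = config.to_dict()
    hashed = {k: v for k, v in cfg.items() if k != "outdir"}
    digest = hashlib.sha256(
        json.dumps(hashed, sort_keys=True).encode()).hexdigest()[:16]
    report.provenance = {
        "config": cfg, "config_hash": digest, "version": __version__,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, default=float)
    return report
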