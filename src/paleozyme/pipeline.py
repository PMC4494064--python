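"""End-to-end pipeline orchestration on synthetic data.

``run_pipeline`` wires the stages together: simulate a dated species tree
and gene families with known truth, reconcile each family's gene tree
against the species tree (after weak-branch rearrangement), date the
species tree from a relaxed-clock phylogram by penalized likelihood, and
join everything into a per-branch report (ages, per-family duplication /
loss / copy-number columns and a compact annotation string).

Every artifact is written with a manifest (parameters, seeds, content
hashes); a rerun with the same configuration is bit-identical.  All
randomness flows from one master seed through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chronos, reconcile, synthetic_data
from .treecore import Tree, write_newick


class PipelineError(RuntimeError):
    pass


@dataclass
class FamilySpec:
    name: str
    dup_rate: float  # per lineage per Ma
    loss_rate: float  # per lineage per Ma


@dataclass
class PipelineConfig:
    """Configuration of a synthetic end-to-end run."""

    seed: int = 0
    n_taxa: int = 10
    root_age: float = 800.0
    birth_rate: float = 1.0
    families: list[FamilySpec] = field(
        default_factory=lambda: [
            FamilySpec("GH28", 0.002, 0.002),
            FamilySpec("PL1", 0.002, 0.002),
            FamilySpec("CE8", 0.002, 0.002),
        ]
    )
    support_threshold: float = 70.0
    support_jitter: float = 0.0  # probability an internal edge gets support < 100
    mean_rate: float = 0.001  # substitutions / site / Ma
    sigma: float = 0.2  # lognormal sd of log branch rates
    smoothing: float | None = None  # None -> cross-validate
    lambda_grid: list[float] = field(
        default_factory=lambda: list(chronos.DEFAULT_LAMBDA_GRID)
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        fams = raw.pop("families", None)
        cfg = cls(**raw)
        if fams is not None:
            cfg.families = [FamilySpec(**f) for f in fams]
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineResult:
    species_tree: Tree
    truths: dict  # family -> GeneFamilyTruth
    reconciliations: dict  # family -> ReconciliationResult
    chronogram: chronos.Chronogram
    branch_report: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # -- stage 1: simulate ---------------------------------------------------
    seed_sp = _stage_seed(config.seed, 1)
    species = synthetic_data.sim_species_tree(
        config.n_taxa, config.birth_rate, config.root_age, seed=seed_sp
    )
    truths = {}
    gene_trees = {}
    for k, fam in enumerate(config.families):
        seed_fam = _stage_seed(config.seed, 100 + k)
        truth = synthetic_data.sim_gene_family(
            species, fam.dup_rate, fam.loss_rate, seed=seed_fam, family_id=fam.name
        )
        gtree = truth.gene_tree.copy()
        rng = np.random.default_rng(_stage_seed(config.seed, 200 + k))
        for node in gtree.postorder():
            if node.parent is not None and not node.is_leaf():
                node.support = (
                    float(rng.uniform(30.0, 100.0))
                    if rng.random() < config.support_jitter
                    else 100.0
                )
        truths[fam.name] = truth
        gene_trees[fam.name] = gtree
    seed_ph = _stage_seed(config.seed, 2)
    phylogram = synthetic_data.sim_relaxed_phylogram(
        species, config.mean_rate, config.sigma, seed=seed_ph
    )
    sim_outputs = {"species_tree.nwk": write_newick(species)}
    for name, gtree in gene_trees.items():
        sim_outputs[f"gene_tree_{name}.nwk"] = gtree.write_newick()
    sim_outputs["phylogram.nwk"] = phylogram.tree.write_newick()
    _write_stage(outdir, manifest, "simulate", seed_sp, sim_outputs)

    # -- stage 2: reconcile --------------------------------------------------
    reconciliations = {}
    recon_outputs = {}
    for name, gtree in gene_trees.items():
        leafmap = reconcile.leafmap_from_prefix(gtree)
        _, result = reconcile.rearrange_weak(
            gtree, species, leafmap, config.support_threshold
        )
        reconciliations[name] = result
        recon_outputs[f"branches_{name}.tsv"] = result.branch_table(
            include_terminal=True
        ).to_csv(sep="\t", index=False)
    _write_stage(outdir, manifest, "reconcile", None, recon_outputs)

    # -- stage 3: date -------------------------------------------------------
    cals = [chronos.Calibration(clade="root", kind="fixed", age=config.root_age)]
    if config.smoothing is None:
        cv_table, lam = chronos.cross_validate(
            phylogram.tree, cals, config.lambda_grid
        )
        date_extra = {"cv_table.tsv": cv_table.to_csv(sep="\t", index=False)}
    else:
        lam = config.smoothing
        date_extra = {}
    chrono = chronos.fit_chronogram(phylogram.tree, cals, lam)
    chrono_tree = chrono.tree.copy()
    date_outputs = {
        "chronogram.nwk": chrono_tree.write_newick(include=("length",)),
        "ages.tsv": chrono.table().to_csv(sep="\t", index=False),
        **date_extra,
    }
    _write_stage(outdir, manifest, "date", _stage_seed(config.seed, 3), date_outputs)

    # -- stage 4: report -----------------------------------------------------
    report = build_branch_report(species, reconciliations, chrono)
    _write_stage(
        outdir,
        manifest,
        "report",
        None,
        {"branch_report.tsv": report.to_csv(sep="\t", index=False)},
    )

    manifest["thresholds"] = {
        "support_threshold": config.support_threshold,
        "smoothing": lam,
    }
    manifest_text = json.dumps(manifest, indent=2, sort_keys=True)
    (outdir / "manifest.json").write_text(manifest_text)
    return PipelineResult(
        species_tree=species,
        truths=truths,
        reconciliations=reconciliations,
        chronogram=chrono,
        branch_report=report,
        manifest=manifest,
    )


def _write_stage(outdir: Path, manifest: dict, stage: str, seed, outputs: dict) -> None:
    entry = {"seed": seed, "outputs": {}}
    for filename, text in outputs.items():
        path = outdir / filename
        path.write_text(text if text.endswith("\n") else text + "\n")
        entry["outputs"][filename] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()
    manifest["stages"][stage] = entry


def build_branch_report(
    species: Tree,
    reconciliations: dict,
    chronogram: chronos.Chronogram,
    averaged: dict | None = None,
) -> pd.DataFrame:
    """One row per species branch: age interval from the chronogram plus
    per-family duplication/loss/copy columns and the compact annotation
    (``GH28:D3`` style; ``D<rearranged>/D<bootstrap>`` when bootstrap
    averages are supplied)."""
    sets = species.leaf_sets()
    rows = []
    for node in species.postorder():
        clade = frozenset(sets[node.id])
        parent_clade = (
            frozenset(sets[node.parent.id]) if node.parent is not None else None
        )
        row = {
            "clade": "|".join(sorted(clade)),
            "terminal": node.is_leaf(),
            "parent_age": chronogram.ages[parent_clade]
            if parent_clade is not None
            else float("nan"),
            "child_age": chronogram.ages[clade] if not node.is_leaf() else 0.0,
        }
        notes = []
        for fam, result in sorted(reconciliations.items()):
            d = result.duplications[node.id]
            l = result.losses[node.id]
            row[f"{fam}_dups"] = d
            row[f"{fam}_losses"] = l
            row[f"{fam}_copies"] = result.exiting[node.id]
            note = None
            if d > 0 and not node.is_leaf():
                note = f"{fam}:D{d}"
            if averaged is not None and fam in averaged:
                bd = averaged[fam].mean_duplications[node.id]
                if bd > 0 and not node.is_leaf():
                    note = f"{fam}:D{d}/D{bd:.2f}"
            if note:
                notes.append(note)
        row["annotation"] = ";".join(notes)
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame, fmt: str, path) -> None:
    """Serialise a branch report as TSV or JSON (records), value-preserving
    across a JSON -> TSV -> JSON round trip."""
    path = Path(path)
    if fmt == "tsv":
        report.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(report.to_dict(orient="records"), indent=2))
    else:
        raise PipelineError(f"unknown report format {fmt!r}")


def load_report(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path, sep="\t")
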