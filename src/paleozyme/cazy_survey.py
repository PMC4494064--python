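"""Enzyme-family copy-number survey.

Turns homology hit tables (family, genome, protein, e-value, functional
domain flag) into per-genome, per-family copy-number matrices under two
filters: an inclusive e-value cutoff (default 1e-5) and removal of hits
without the predicted functional domain.  A catalog of the 20 surveyed
carbohydrate-active enzyme families (glycoside hydrolases, polysaccharide
lyases, carbohydrate esterases), nine of them pectin-specific, ships as
package data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

HIT_COLUMNS = ["family", "genome", "protein", "evalue", "domain_ok"]

DEFAULT_E_MAX = 1e-5


class CazySurveyError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyCatalog:
    """Enzyme family -> (class, pectin-specific flag)."""

    classes: dict  # family -> "GH" | "PL" | "CE"
    pectin_specific: frozenset

    @property
    def families(self) -> list[str]:
        return list(self.classes)

    def __contains__(self, family: str) -> bool:
        return family in self.classes


def default_catalog() -> FamilyCatalog:
    """The 20-family survey catalog shipped with the package."""
    raw = json.loads(
        resources.files("paleozyme").joinpath("data/family_catalog.json").read_text()
    )
    classes = {fam: info["class"] for fam, info in raw["families"].items()}
    pectin = frozenset(
        fam for fam, info in raw["families"].items() if info["pectin_specific"]
    )
    return FamilyCatalog(classes=classes, pectin_specific=pectin)


def load_catalog(path) -> FamilyCatalog:
    raw = json.loads(open(path).read())
    classes = {fam: info["class"] for fam, info in raw["families"].items()}
    pectin = frozenset(
        fam for fam, info in raw["families"].items() if info["pectin_specific"]
    )
    return FamilyCatalog(classes=classes, pectin_specific=pectin)


def _check_hits(hits: pd.DataFrame) -> None:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise CazySurveyError(f"hit table lacks columns: {missing}")
    if len(hits) and (hits["evalue"] < 0).any():
        raise CazySurveyError("e-values must be non-negative")


def filter_hits(
    hits: pd.DataFrame,
    e_max: float = DEFAULT_E_MAX,
    require_domain: bool = True,
) -> pd.DataFrame:
    """Screen hits at an inclusive e-value cutoff and (optionally) require
    the predicted functional domain; duplicate (family, genome, protein)
    rows collapse to the best e-value."""
    if e_max <= 0:
        raise CazySurveyError("e_max must be positive")
    _check_hits(hits)
    if hits.empty:
        return hits.copy()
    out = hits[hits["evalue"] <= e_max]
    if require_domain:
        out = out[out["domain_ok"].astype(bool)]
    out = (
        out.sort_values("evalue")
        .drop_duplicates(subset=["family", "genome", "protein"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    return out


@dataclass
class CopyMatrix:
    """Genomes x families table of filtered copy counts, plus the proteins
    assigned to more than one family (kept once per family, but flagged)."""

    matrix: pd.DataFrame
    multi_family: pd.DataFrame

    def __getitem__(self, key):
        return self.matrix[key]


def copy_number_matrix(
    hits: pd.DataFrame, catalog: FamilyCatalog, genomes: list[str]
) -> CopyMatrix:
    """Count distinct filtered proteins per (genome, family).

    Genomes without hits get explicit zero rows; families absent from the
    hits get zero columns.  A protein hitting several families counts once
    in each and appears in the multi-assignment report.
    """
    _check_hits(hits)
    unknown_fams = set(hits["family"]) - set(catalog.families)
    if unknown_fams:
        raise CazySurveyError(f"families not in catalog: {sorted(unknown_fams)}")
    unknown_gen = set(hits["genome"]) - set(genomes)
    if unknown_gen:
        raise CazySurveyError(f"genomes not in genome list: {sorted(unknown_gen)}")

    dedup = hits.drop_duplicates(subset=["family", "genome", "protein"])
    counts = (
        dedup.groupby(["genome", "family"])["protein"].nunique().unstack(fill_value=0)
    )
    matrix = counts.reindex(index=genomes, columns=catalog.families, fill_value=0)
    matrix = matrix.fillna(0).astype(int)
    matrix.index.name = "genome"

    fam_per_protein = dedup.groupby(["genome", "protein"])["family"].nunique()
    multi = fam_per_protein[fam_per_protein > 1].reset_index()
    multi.columns = ["genome", "protein", "n_families"]
    return CopyMatrix(matrix=matrix, multi_family=multi)


def summarize_families(matrix: CopyMatrix | pd.DataFrame, catalog: FamilyCatalog) -> pd.DataFrame:
    """Per-genome summary: pectin-specific copy total, number of
    pectin-specific families present, and the full presence/absence vector
    (``has_<family>`` columns)."""
    m = matrix.matrix if isinstance(matrix, CopyMatrix) else matrix
    pectin_cols = [f for f in m.columns if f in catalog.pectin_specific]
    out = pd.DataFrame(index=m.index)
    out["pectin_copy_total"] = m[pectin_cols].sum(axis=1)
    out["pectin_families_present"] = (m[pectin_cols] > 0).sum(axis=1)
    out["families_present"] = (m > 0).sum(axis=1)
    for fam in m.columns:
        out[f"has_{fam}"] = (m[fam] > 0).astype(int)
    return out.reset_index()


def read_hit_table(path) -> pd.DataFrame:
    hits = pd.read_csv(path, sep="\t")
    _check_hits(hits)
    return hits


def write_copy_matrix(matrix: CopyMatrix, path) -> None:
    matrix.matrix.to_csv(path, sep="\t")
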