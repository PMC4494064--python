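"""Single-copy ortholog filtering and supermatrix construction.

Implements the filter chain applied to ortholog cluster tables before
phylogenomic analysis: the single-copy filter (at most one protein per
genome, minimum genome occupancy, redundant clusters removed), the
reciprocal-best-hit (RBH) vetting against a pairwise similarity-score table,
the concatenation of per-gene alignments into a partitioned supermatrix, and
Dayhoff six-group recoding of amino-acid alignments.

Cluster tables are pandas DataFrames with columns ``cluster, genome,
protein``; score tables have columns ``query, subject, score``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .treecore import GAP, MISSING, Alignment, AlignmentError

CLUSTER_COLUMNS = ["cluster", "genome", "protein"]
SCORE_COLUMNS = ["query", "subject", "score"]

#: Dayhoff six-group recoding of the 20 amino acids.  Group order:
#: {AGPST}=0, {DENQ}=1, {HKR}=2, {ILMV}=3, {FWY}=4, {C}=5.
DAYHOFF_GROUPS: dict[str, str] = {
    **{aa: "0" for aa in "AGPST"},
    **{aa: "1" for aa in "DENQ"},
    **{aa: "2" for aa in "HKR"},
    **{aa: "3" for aa in "ILMV"},
    **{aa: "4" for aa in "FWY"},
    "C": "5",
}

#: ambiguity codes mapped to missing rather than rejected
_AMBIGUOUS = set("BZJXU*")


class OrthologError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise OrthologError(f"{what} table lacks columns: {missing}")


def filter_single_copy(
    clusters: pd.DataFrame, n_genomes: int, min_occupancy: float = 0.5
) -> pd.DataFrame:
    """Retain single-copy clusters with sufficient genome occupancy.

    A cluster is kept when it has at most one protein per genome and covers
    at least ``min_occupancy`` of the ``n_genomes`` genomes (inclusive
    boundary).  Redundant clusters -- identical ``(genome, protein)``
    membership -- are collapsed to the one with the smallest cluster id.
    """
    if n_genomes < 1:
        raise OrthologError("n_genomes must be >= 1")
    if not (0.0 < min_occupancy <= 1.0):
        raise OrthologError("min_occupancy must lie in (0, 1]")
    if clusters.empty:
        return clusters.copy()
    _check_columns(clusters, CLUSTER_COLUMNS, "cluster")

    keep_ids = []
    memberships: dict[frozenset, str] = {}
    for cid, grp in sorted(clusters.groupby("cluster"), key=lambda kv: str(kv[0])):
        if grp["genome"].value_counts().max() > 1:
            continue  # paralogs: more than one protein in some genome
        if grp["genome"].nunique() / n_genomes < min_occupancy:
            continue
        membership = frozenset(zip(grp["genome"], grp["protein"]))
        if membership in memberships:
            continue  # redundant cluster, first id retained
        memberships[membership] = cid
        keep_ids.append(cid)
    return clusters[clusters["cluster"].isin(keep_ids)].reset_index(drop=True)


@dataclass
class RBHResult:
    """Outcome of RBH vetting: the kept clusters plus a per-cluster report
    with status ``kept | rejected | unevaluable``."""

    kept: pd.DataFrame
    report: pd.DataFrame


def rbh_filter(
    clusters: pd.DataFrame,
    scores: pd.DataFrame,
    protein_genomes: dict[str, str] | None = None,
) -> RBHResult:
    """Keep clusters whose members are mutual best hits.

    For every member ``p`` and every other genome ``g`` represented in the
    cluster, ``p``'s best-scoring hit among proteins of ``g`` (over the whole
    score table) must be the cluster's own member from ``g`` -- uniquely, so
    a tied best score with an outside protein rejects the cluster.  Clusters
    for which some required ``(protein, genome)`` comparison has no scored
    pair are reported as ``unevaluable`` and not kept.

    ``protein_genomes`` maps protein ids to genomes; by default it is derived
    from the cluster table itself.
    """
    _check_columns(clusters, CLUSTER_COLUMNS, "cluster")
    _check_columns(scores, SCORE_COLUMNS, "score")
    if protein_genomes is None:
        protein_genomes = dict(zip(clusters["protein"], clusters["genome"]))

    # best hit of each query within each subject genome: score and whether
    # the top score is attained by a unique subject
    sc = scores.copy()
    sc = sc[sc["query"] != sc["subject"]]
    sc["subject_genome"] = sc["subject"].map(protein_genomes)
    sc = sc.dropna(subset=["subject_genome"])
    best: dict[tuple[str, str], tuple[float, set[str]]] = {}
    for q, sg, subj, score in zip(
        sc["query"], sc["subject_genome"], sc["subject"], sc["score"]
    ):
        if not math.isfinite(score):
            raise OrthologError(f"non-finite score for pair ({q}, {subj})")
        key = (q, sg)
        if key not in best or score > best[key][0]:
            best[key] = (score, {subj})
        elif score == best[key][0]:
            best[key][1].add(subj)

    statuses = []
    for cid, grp in sorted(clusters.groupby("cluster"), key=lambda kv: str(kv[0])):
        members = dict(zip(grp["genome"], grp["protein"]))
        status = "kept"
        for g_p, p in members.items():
            for g_q, q in members.items():
                if g_p == g_q:
                    continue
                entry = best.get((p, g_q))
                if entry is None:
                    status = "unevaluable"
                    break
                top_score, top_subjects = entry
                if top_subjects != {q}:
                    status = "rejected"
                    break
            if status != "kept":
                break
        statuses.append((cid, status))

    report = pd.DataFrame(statuses, columns=["cluster", "status"])
    kept_ids = set(report.loc[report["status"] == "kept", "cluster"])
    kept = clusters[clusters["cluster"].isin(kept_ids)].reset_index(drop=True)
    return RBHResult(kept=kept, report=report)


def protein_genome_map(clusters: pd.DataFrame) -> dict[str, str]:
    """Protein -> genome mapping over a (full, unfiltered) cluster table."""
    _check_columns(clusters, CLUSTER_COLUMNS, "cluster")
    return dict(zip(clusters["protein"], clusters["genome"]))


def filter_chain(
    clusters: pd.DataFrame,
    scores: pd.DataFrame,
    n_genomes: int,
    min_occupancy: float = 0.5,
) -> RBHResult:
    """Full cluster filter chain: single-copy/occupancy first, then RBH
    vetting (with the protein->genome map taken from the *unfiltered*
    table, so redirected best hits remain resolvable)."""
    genome_map = protein_genome_map(clusters)
    single = filter_single_copy(clusters, n_genomes, min_occupancy)
    return rbh_filter(single, scores, protein_genomes=genome_map)


@dataclass
class Supermatrix:
    """Concatenated alignment with its partition table and per-taxon
    occupancy (fraction of genes present)."""

    alignment: Alignment
    occupancy: dict[str, float] = field(default_factory=dict)

    @property
    def partitions(self) -> list[tuple[str, int, int]]:
        return self.alignment.partitions or []


def concat_supermatrix(
    alignments: list[tuple[str, Alignment]], taxon_universe: list[str]
) -> Supermatrix:
    """Concatenate per-gene alignments over a fixed taxon universe.

    Genes are sorted by name (canonical order, so the result is invariant to
    input order); taxa missing from a gene are filled with the missing symbol
    ``?`` over that partition.  Occupancy is the fraction of genes in which
    each taxon is present.
    """
    if not alignments:
        raise OrthologError("no gene alignments supplied")
    names = [name for name, _ in alignments]
    if len(set(names)) != len(names):
        raise OrthologError("duplicate gene names in input")
    ordered = sorted(alignments, key=lambda kv: kv[0])

    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxon_universe}
    present: dict[str, int] = {t: 0 for t in taxon_universe}
    offset = 0
    for name, aln in ordered:
        extra = set(aln.taxa) - set(taxon_universe)
        if extra:
            raise OrthologError(f"gene {name!r} has taxa outside the universe: {sorted(extra)}")
        width = aln.n_sites
        for t in taxon_universe:
            if t in aln.sequences:
                chunks[t].append(aln.sequences[t])
                present[t] += 1
            else:
                chunks[t].append(MISSING * width)
        parts.append((name, offset, offset + width))
        offset += width

    seqs = {t: "".join(chunks[t]) for t in taxon_universe}
    occupancy = {t: present[t] / len(ordered) for t in taxon_universe}
    return Supermatrix(Alignment(seqs, partitions=parts), occupancy=occupancy)


def dayhoff_recode(alignment: Alignment) -> Alignment:
    """Collapse a 20-state amino-acid alignment to six Dayhoff groups.

    Gaps (``-``) and missing (``?``) pass through unchanged; ambiguity codes
    (B, Z, J, X, U, ``*``) become missing.  Any other symbol is an error.
    """
    recoded = {}
    for taxon, seq in alignment.sequences.items():
        out = []
        for ch in seq.upper():
            if ch in DAYHOFF_GROUPS:
                out.append(DAYHOFF_GROUPS[ch])
            elif ch == GAP:
                out.append(GAP)
            elif ch == MISSING or ch in _AMBIGUOUS:
                out.append(MISSING)
            else:
                raise OrthologError(
                    f"unknown residue symbol {ch!r} in sequence {taxon!r}"
                )
        recoded[taxon] = "".join(out)
    return Alignment(recoded, alignment.partitions, alphabet="dayhoff6")


def occupancy_table(matrix: Supermatrix) -> pd.DataFrame:
    """Per-taxon occupancy report (the species-tree sidebar statistic)."""
    return pd.DataFrame(
        {"taxon": list(matrix.occupancy), "occupancy": list(matrix.occupancy.values())}
    )
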