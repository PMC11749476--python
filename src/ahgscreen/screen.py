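"""Candidate classification, secretome filtering and cross-species ranking.

Affinity profiles from direction-stratified seeded walks are aggregated to
one score per (species, direction, gene). A gene is a candidate aging hub
gene if its score reaches the affinity threshold (default 1e-4, inclusive)
in at least one run; candidates are categorized by whether they pass only
under up-seeded runs (up_specific), only under down-seeded runs
(down_specific), or both (shared). Candidates encoding secreted proteins
are then ranked per species by their best-direction score, and the final
hub-gene set is the intersection of every species' top-k ranked list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import normalize_symbol
from .rwr import AffinityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "DIRECTIONS",
    "CATEGORIES",
    "ScreenParams",
    "ScreenResult",
    "read_deg_table",
    "aggregate_scores",
    "classify_candidates",
    "filter_secretory",
    "rank_top_k",
    "cross_species_overlap",
    "secretory_fraction",
    "run_screen",
    "write_screen_result",
    "write_ahg_set",
]

DIRECTIONS = ("up", "down")
CATEGORIES = ("up_specific", "down_specific", "shared", "none")

_DEG_COLUMNS = ["species", "tissue", "cell_type", "gene", "direction"]


@dataclass(frozen=True)
class ScreenParams:
    """Screening thresholds.

    affinity_threshold
        Minimum steady-state affinity score for candidacy; the comparison is
        inclusive (score >= threshold). Default 1e-4.
    top_k
        Number of secreted candidates kept per species before intersecting
        across species. Default 50.
    aggregation
        How per-context scores collapse to one score per (species,
        direction): "mean" or "max".
    """

    affinity_threshold: float = 1e-4
    top_k: int = 50
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.affinity_threshold <= 0:
            raise ValueError("affinity_threshold must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.aggregation not in ("mean", "max"):
            raise ValueError(f"aggregation must be 'mean' or 'max', got {self.aggregation!r}")


@dataclass(frozen=True)
class ScreenResult:
    """Accumulating result of the screening stages.

    scores
        Long table (species, direction, gene, score) after aggregation.
    per_species
        One row per (gene, species): up_score, down_score (NaN where the
        gene never appeared in that stratum), ranking_score =
        max(up, down), and per-species candidacy.
    category
        Global per-gene category over the union candidate universe.
    secreted / ranks / ahgs / ahg_avg_score
        Filled in by the later stages; None until then.
    """

    scores: pd.DataFrame
    per_species: pd.DataFrame
    category: pd.Series
    threshold: float
    secreted: pd.Series | None = None
    ranks: dict[str, tuple[str, ...]] | None = None
    ahgs: tuple[str, ...] | None = None
    ahg_avg_score: pd.Series | None = None

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.per_species["species"].unique()))

    @property
    def candidates(self) -> tuple[str, ...]:
        return tuple(self.category.index[self.category != "none"])

    def category_counts(self) -> dict[str, int]:
        counts = self.category.value_counts().to_dict()
        return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG table TSV with header columns
    ``species tissue cell_type gene direction [effect]``.

    Gene symbols are upper-cased; exact duplicate records are dropped with a
    warning (the table invariant forbids them).
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _DEG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    table["gene"] = table["gene"].map(normalize_symbol)
    bad = ~table["direction"].isin(DIRECTIONS)
    if bad.any():
        raise ValueError(
            f"invalid direction values: {sorted(table.loc[bad, 'direction'].unique())}"
        )
    if "effect" in table.columns:
        table["effect"] = pd.to_numeric(table["effect"])
    n_before = len(table)
    table = table.drop_duplicates(subset=_DEG_COLUMNS, keep="first").reset_index(drop=True)
    if len(table) < n_before:
        logger.warning("dropped %d duplicate DEG records", n_before - len(table))
    return table


def map_deg_genes(table: pd.DataFrame, mapping: Mapping[str, str]) -> pd.DataFrame:
    """Translate DEG gene symbols through an ortholog map (identity for unmapped)."""
    out = table.copy()
    out["gene"] = out["gene"].map(lambda g: normalize_symbol(mapping.get(g, g)))
    return out.drop_duplicates(subset=_DEG_COLUMNS, keep="first").reset_index(drop=True)


def aggregate_scores(
    profiles: Sequence[AffinityProfile], aggregation: str = "mean"
) -> pd.DataFrame:
    """Collapse per-context profiles to one score per (species, direction, gene).

    Genes absent from a context's propagation component contribute nothing
    to the aggregate (they are not zero-padded), so a gene's mean is over
    the contexts in which it could receive mass.
    """
    if not profiles:
        raise ValueError("no affinity profiles to aggregate")
    if aggregation not in ("mean", "max"):
        raise ValueError(f"aggregation must be 'mean' or 'max', got {aggregation!r}")
    parts = []
    for prof in profiles:
        part = prof.scores.rename("score").rename_axis("gene").reset_index()
        part["species"] = prof.species
        part["direction"] = prof.direction
        parts.append(part)
    long = pd.concat(parts, ignore_index=True)
    agg = (
        long.groupby(["species", "direction", "gene"], sort=True)["score"]
        .agg(aggregation)
        .reset_index()
    )
    return agg


def _per_species_table(scores: pd.DataFrame, threshold: float) -> pd.DataFrame:
    wide = scores.pivot_table(
        index=["gene", "species"], columns="direction", values="score", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    for d in DIRECTIONS:
        if d not in wide.columns:
            wide[d] = np.nan
    wide = wide.rename(columns={"up": "up_score", "down": "down_score"})
    wide["ranking_score"] = wide[["up_score", "down_score"]].max(axis=1)
    wide["candidate"] = (wide["up_score"] >= threshold) | (wide["down_score"] >= threshold)
    return wide.sort_values(["gene", "species"]).reset_index(drop=True)[
        ["gene", "species", "up_score", "down_score", "ranking_score", "candidate"]
    ]


def classify_candidates(scores: pd.DataFrame, threshold: float) -> ScreenResult:
    """Assign each scored gene a candidate category.

    A gene passes in direction d when score(species, d, gene) >= threshold
    for ANY species (union semantics, so the three category counts
    partition one global candidate set). Genes passing in neither
    direction get category "none".
    """
    if scores.empty:
        raise ValueError("empty score table")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    passing = scores[scores["score"] >= threshold]
    up_pass = set(passing.loc[passing["direction"] == "up", "gene"])
    down_pass = set(passing.loc[passing["direction"] == "down", "gene"])
    genes = sorted(scores["gene"].unique())

    def cat(g: str) -> str:
        u, d = g in up_pass, g in down_pass
        if u and d:
            return "shared"
        if u:
            return "up_specific"
        if d:
            return "down_specific"
        return "none"

    category = pd.Series([cat(g) for g in genes], index=genes, name="category")
    n_cand = int((category != "none").sum())
    if n_cand == 0:
        logger.warning("no gene passed the affinity threshold %g", threshold)
    logger.info(
        "classified %d candidates (threshold %g): %s",
        n_cand,
        threshold,
        {k: v for k, v in category.value_counts().items() if k != "none"},
    )
    return ScreenResult(
        scores=scores,
        per_species=_per_species_table(scores, threshold),
        category=category,
        threshold=threshold,
    )


def filter_secretory(result: ScreenResult, secretome: Iterable[str]) -> ScreenResult:
    """Flag candidates that encode secreted proteins.

    Non-secreted candidates stay in the result (and in category counts) but
    are excluded from ranking. An empty secretome is an input error; a
    secretome disjoint from the candidates is legal but leaves nothing to
    rank, which is logged.
    """
    secretome_set = {normalize_symbol(g) for g in secretome}
    if not secretome_set:
        raise ValueError("secretome gene set is empty")
    secreted = pd.Series(
        [g in secretome_set for g in result.category.index],
        index=result.category.index,
        name="secreted",
    )
    rankable = int((secreted & (result.category != "none")).sum())
    if rankable == 0:
        logger.warning("secretome is disjoint from the candidate set; nothing to rank")
    return replace(result, secreted=secreted)


def rank_top_k(result: ScreenResult, k: int) -> ScreenResult:
    """Rank each species' secreted candidates and keep the top k.

    Sort key: best-direction aggregated score descending, ties broken by
    gene symbol ascending — deterministic and stable under any input
    permutation. A gene is rankable in a species only if it passes the
    threshold in that species and is secreted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if result.secreted is None:
        raise ValueError("secretome flags not set; call filter_secretory first")
    ranks: dict[str, tuple[str, ...]] = {}
    for species in result.species:
        block = result.per_species[
            (result.per_species["species"] == species)
            & result.per_species["candidate"]
            & result.per_species["gene"].map(result.secreted)
        ]
        ordered = block.sort_values(
            ["ranking_score", "gene"], ascending=[False, True], kind="mergesort"
        )
        ranks[species] = tuple(ordered["gene"].head(k))
    return replace(result, ranks=ranks)


def cross_species_overlap(result: ScreenResult) -> ScreenResult:
    """Intersect the per-species top-k lists into the final hub-gene set.

    Requires at least two species. Each final gene also gets a
    cross-species average score: the mean over species of its
    best-direction aggregated score.
    """
    if result.ranks is None:
        raise ValueError("per-species rankings not computed; call rank_top_k first")
    if len(result.ranks) < 2:
        raise ValueError(
            f"cross-species overlap needs >= 2 species, got {len(result.ranks)}"
        )
    lists = [set(genes) for genes in result.ranks.values()]
    ahgs = tuple(sorted(set.intersection(*lists)))
    if not ahgs:
        logger.info("top-%s lists are disjoint across species; no hub gene survives", "k")
    by_gene = result.per_species[result.per_species["gene"].isin(ahgs)]
    avg = by_gene.groupby("gene")["ranking_score"].mean().reindex(list(ahgs))
    avg.name = "cross_species_avg_score"
    return replace(result, ahgs=ahgs, ahg_avg_score=avg)


def secretory_fraction(result: ScreenResult) -> pd.Series:
    """Per-species fraction of candidates that encode secreted proteins.

    Species with zero candidates report NaN (the fraction is undefined).
    """
    if result.secreted is None:
        raise ValueError("secretome flags not set; call filter_secretory first")
    out = {}
    for species in result.species:
        block = result.per_species[result.per_species["species"] == species]
        cand = block[block["candidate"]]
        if cand.empty:
            out[species] = np.nan
            continue
        out[species] = float(cand["gene"].map(result.secreted).mean())
    return pd.Series(out, name="secretory_fraction")


def run_screen(
    profiles: Sequence[AffinityProfile],
    secretome: Iterable[str],
    params: ScreenParams = ScreenParams(),
) -> ScreenResult:
    """Full screen: aggregate, classify, flag secretome, rank, intersect."""
    scores = aggregate_scores(profiles, params.aggregation)
    result = classify_candidates(scores, params.affinity_threshold)
    result = filter_secretory(result, secretome)
    result = rank_top_k(result, params.top_k)
    result = cross_species_overlap(result)
    return result


def _fmt(x: float) -> str:
    return "NA" if pd.isna(x) else f"{x:.6e}"


def write_screen_result(result: ScreenResult, path: str | Path) -> None:
    """Write the per-(gene, species) screen table as TSV.

    Row order and float formatting are fixed so identical inputs produce
    byte-identical files.
    """
    secreted = result.secreted if result.secreted is not None else pd.Series(dtype=bool)
    rank_of: dict[tuple[str, str], int] = {}
    if result.ranks is not None:
        for species, genes in result.ranks.items():
            for i, g in enumerate(genes, start=1):
                rank_of[(g, species)] = i
    ahgs = set(result.ahgs or ())
    avg = result.ahg_avg_score if result.ahg_avg_score is not None else pd.Series(dtype=float)
    with Path(path).open("w") as fh:
        fh.write(
            "gene\tcategory\tspecies\tup_score\tdown_score\tsecreted\trank\t"
            "is_ahg\tcross_species_avg_score\n"
        )
        table = result.per_species.sort_values(["gene", "species"])
        for row in table.itertuples(index=False):
            g = row.gene
            fh.write(
                "\t".join(
                    [
                        g,
                        result.category.get(g, "none"),
                        row.species,
                        _fmt(row.up_score),
                        _fmt(row.down_score),
                        str(bool(secreted.get(g, False))).lower(),
                        str(rank_of.get((g, row.species), "NA")),
                        str(g in ahgs).lower(),
                        _fmt(avg.get(g, np.nan)),
                    ]
                )
                + "\n"
            )


def write_ahg_set(result: ScreenResult, path: str | Path) -> None:
    """Write the final intersected gene list, one symbol per line."""
    if result.ahgs is None:
        raise ValueError("final hub-gene set not computed")
    with Path(path).open("w") as fh:
        for g in result.ahgs:
            fh.write(g + "\n")
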