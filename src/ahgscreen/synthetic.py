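"""Synthetic fixtures with planted ground truth.

Real inputs to the screen — a PPI database snapshot, tens of thousands of
direction-labelled aging DEG calls from single-cell atlases, and a secreted-
protein annotation — are not redistributable, so this module generates
structurally similar stand-ins with a known answer:

* one scale-free (preferential-attachment) network per species over a
  shared gene-symbol universe, emulating heavy-tailed PPI degree
  distributions and symbol-based orthology;
* a set of planted hub genes, present and secreted in every species, whose
  connectivity is boosted above the bulk of the degree distribution;
* per-(species, tissue, cell type) DEG sets whose genes are drawn
  preferentially from the planted hubs' network neighborhoods — encoding
  the screen's premise that aging hub genes are network-central to aging
  DEGs without necessarily being DEGs themselves;
* a secretome covering a small fraction of genes (~6% by default, within
  the 3-9% regime typical of secreted-protein annotations) plus the hubs.

Every output is a pure function of the configuration, including its RNG
seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .network import PPINetwork, write_edge_list

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "generate_network",
    "plant_hubs",
    "generate_deg_table",
    "generate_secretome",
    "generate_fixture",
    "toy_config",
]

_DEFAULT_SPECIES = ("HUMAN", "MACAQUE", "MOUSE", "RAT")


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic study.

    n_genes
        Genes per species; all species share the symbol universe
        G000001..G{n} so symbol intersection plays the role of orthology.
    n_species, n_tissues, n_cell_types
        Context grid: every species contributes n_tissues x n_cell_types
        contexts, each with an up- and a down-regulated DEG set.
    degs_per_context
        DEG calls per context per direction.
    n_planted_hubs
        Ground-truth hub genes (default 7), shared across species and
        always secreted.
    hub_extra_degree
        Extra random edges attached to each hub per species, lifting hubs
        into the upper tail of the degree distribution.
    hub_seed_bias
        Probability that a DEG is drawn from the union of planted-hub
        neighborhoods rather than uniformly; 0 gives the null regime with
        no planted signal.
    secretome_fraction
        Fraction of the gene universe sampled into the secretome (hubs are
        added on top).
    attach_m
        Preferential-attachment parameter (edges per new node).
    rng_seed
        Master seed; every stream below is derived from it.
    """

    n_genes: int = 300
    n_species: int = 4
    n_tissues: int = 2
    n_cell_types: int = 2
    degs_per_context: int = 30
    n_planted_hubs: int = 7
    hub_extra_degree: int = 16
    hub_seed_bias: float = 0.85
    secretome_fraction: float = 0.06
    attach_m: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_species": self.n_species,
            "n_tissues": self.n_tissues,
            "n_cell_types": self.n_cell_types,
            "degs_per_context": self.degs_per_context,
            "attach_m": self.attach_m,
        }
        bad = [k for k, v in counts.items() if v < 1]
        if bad:
            raise ValueError(f"counts must be >= 1: {bad}")
        if self.n_planted_hubs < 0 or self.n_planted_hubs > self.n_genes:
            raise ValueError("n_planted_hubs must be in [0, n_genes]")
        if not 0.0 <= self.hub_seed_bias <= 1.0:
            raise ValueError("hub_seed_bias must be in [0, 1]")
        if not 0.0 < self.secretome_fraction < 1.0:
            raise ValueError("secretome_fraction must be in (0, 1)")
        if self.attach_m >= self.n_genes:
            raise ValueError("attach_m must be smaller than n_genes")

    @property
    def species_names(self) -> tuple[str, ...]:
        names = list(_DEFAULT_SPECIES[: self.n_species])
        names += [f"SP{i:02d}" for i in range(len(names) + 1, self.n_species + 1)]
        return tuple(names)


@dataclass(frozen=True)
class FixtureBundle:
    """Generated inputs plus the planted truth."""

    config: FixtureConfig
    networks: dict[str, PPINetwork]
    deg_table: pd.DataFrame
    secretome: tuple[str, ...]
    ortholog_map: dict[str, str]
    hubs: tuple[str, ...]


def _gene_labels(n_genes: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n_genes + 1)]


def generate_network(n_genes: int, attach_m: int, rng_seed: int) -> PPINetwork:
    """Connected preferential-attachment graph with G000001.. labels.

    The growth starts from a complete graph on ``attach_m`` nodes and adds
    each remaining node with ``attach_m`` degree-proportional edges, so the
    edge count is attach_m * (n_genes - attach_m) + C(attach_m, 2) and the
    degree distribution is heavy-tailed like real PPI networks.
    """
    if not n_genes > attach_m >= 1:
        raise ValueError(f"need n_genes > attach_m >= 1, got {n_genes}, {attach_m}")
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    initial = nx.complete_graph(attach_m) if attach_m >= 2 else None
    g = nx.barabasi_albert_graph(
        n_genes, attach_m, seed=int(rng_seed), initial_graph=initial
    )
    labels = _gene_labels(n_genes)
    g = nx.relabel_nodes(g, {i: labels[i] for i in g.nodes})
    return PPINetwork.from_edges(((a, b, 1.0) for a, b in g.edges), nodes=labels)


def plant_hubs(
    net: PPINetwork,
    n_hubs: int,
    extra_degree: int,
    rng_seed: int,
    hub_genes: tuple[str, ...] | None = None,
) -> tuple[PPINetwork, tuple[str, ...]]:
    """Boost the connectivity of designated hub genes.

    Each hub gains ``extra_degree`` new random edges. Targets are drawn
    from a shared random pool of about ``3 * extra_degree`` genes, so the
    planted hubs acquire overlapping neighborhoods the way hub proteins in
    real PPI networks share partners within complexes and pathways. If
    ``hub_genes`` is omitted they are drawn uniformly; the caller passes an
    explicit set to share hub symbols across species. Returns the
    augmented network and the hub tuple.
    """
    nodes = net.nodes
    if n_hubs > len(nodes):
        raise ValueError("more hubs requested than genes in the network")
    rng = np.random.default_rng(rng_seed)
    if hub_genes is None:
        hub_genes = tuple(
            sorted(str(g) for g in rng.choice(nodes, size=n_hubs, replace=False))
        )
    elif len(hub_genes) != n_hubs:
        raise ValueError("hub_genes length does not match n_hubs")
    if n_hubs == 0:
        return net, ()
    g = net.graph.copy()
    non_hubs = sorted(set(nodes) - set(hub_genes))
    pool_size = min(3 * extra_degree, len(non_hubs))
    pool = sorted(str(x) for x in rng.choice(non_hubs, size=pool_size, replace=False))
    for hub in hub_genes:
        if hub not in g:
            raise ValueError(f"hub gene {hub} is not in the network")
        candidates = sorted(set(pool) - set(g.neighbors(hub)))
        if extra_degree > len(candidates):
            raise ValueError(
                f"hub {hub}: cannot add {extra_degree} edges, only "
                f"{len(candidates)} eligible target genes remain"
            )
        for target in rng.choice(candidates, size=extra_degree, replace=False):
            g.add_edge(hub, str(target), weight=1.0)
    return PPINetwork(g), tuple(hub_genes)


def generate_deg_table(
    networks: dict[str, PPINetwork],
    hubs: tuple[str, ...],
    cfg: FixtureConfig,
    rng_seed: int,
) -> pd.DataFrame:
    """Direction-stratified DEG calls biased toward hub neighborhoods.

    Per (species, tissue, cell_type, direction) the configured number of
    genes is drawn without replacement: each draw comes from the union of
    the planted hubs' neighbors with probability ``hub_seed_bias``, else
    uniformly from all genes (so hubs themselves can be sampled). Up and
    down sets within a context are disjoint.
    """
    rng = np.random.default_rng(rng_seed)
    records = []
    for species in sorted(networks):
        net = networks[species]
        genes = np.array(net.nodes)
        if 2 * cfg.degs_per_context > len(genes):
            raise ValueError(
                f"{species}: {cfg.degs_per_context} DEGs per direction exceed "
                f"the {len(genes)}-gene universe"
            )
        # closed neighborhoods: hubs are legitimate DEGs themselves
        neighborhood = sorted(
            set(hubs).union(*(net.neighbors(h) for h in hubs)) if hubs else set()
        )
        neighborhood = np.array(neighborhood)
        for t in range(1, cfg.n_tissues + 1):
            for c in range(1, cfg.n_cell_types + 1):
                taken: set[str] = set()
                for direction in ("up", "down"):
                    chosen: list[str] = []
                    while len(chosen) < cfg.degs_per_context:
                        use_bias = (
                            len(neighborhood) > 0
                            and rng.random() < cfg.hub_seed_bias
                        )
                        pool = neighborhood if use_bias else genes
                        g = str(rng.choice(pool))
                        if g in taken:
                            continue
                        taken.add(g)
                        chosen.append(g)
                    for g in chosen:
                        records.append(
                            (species, f"TISSUE{t:02d}", f"CELL{c:02d}", g, direction)
                        )
    return pd.DataFrame(
        records, columns=["species", "tissue", "cell_type", "gene", "direction"]
    )


def generate_secretome(
    genes: tuple[str, ...],
    fraction: float,
    must_include: tuple[str, ...],
    rng_seed: int,
) -> tuple[str, ...]:
    """Sample round(fraction * n) genes and union in ``must_include``."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    missing = sorted(set(must_include) - set(genes))
    if missing:
        raise ValueError(f"must_include genes absent from the universe: {missing}")
    rng = np.random.default_rng(rng_seed)
    k = round(fraction * len(genes))
    sampled = set(rng.choice(sorted(genes), size=k, replace=False))
    return tuple(sorted(sampled | set(must_include)))


def _child_seeds(master: int, n: int) -> list[int]:
    """Independent reproducible substream seeds below 2**31."""
    ss = np.random.SeedSequence(int(master))
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def generate_fixture(
    cfg: FixtureConfig, out_dir: str | Path | None = None
) -> FixtureBundle:
    """Generate the full bundle and optionally write it to disk.

    Files written: one ``ppi_<species>.tsv`` edge list per species,
    ``deg_table.tsv``, ``secretome.txt``, ``ortholog_map.tsv`` (identity,
    since the universe is shared), ``truth.txt`` with the planted hubs, and
    ``fixture_config.yaml`` recording the configuration used.
    """
    seeds = _child_seeds(cfg.rng_seed, 3 + 2 * cfg.n_species)
    hub_pick_seed, deg_seed, secretome_seed, *per_species = seeds

    universe = tuple(_gene_labels(cfg.n_genes))
    hub_rng = np.random.default_rng(hub_pick_seed)
    hubs = tuple(
        sorted(str(g) for g in hub_rng.choice(universe, size=cfg.n_planted_hubs, replace=False))
    ) if cfg.n_planted_hubs else ()

    networks: dict[str, PPINetwork] = {}
    for i, species in enumerate(cfg.species_names):
        net_seed, plant_seed = per_species[2 * i], per_species[2 * i + 1]
        net = generate_network(cfg.n_genes, cfg.attach_m, net_seed)
        net, _ = plant_hubs(
            net, cfg.n_planted_hubs, cfg.hub_extra_degree, plant_seed, hub_genes=hubs
        )
        networks[species] = net

    deg_table = generate_deg_table(networks, hubs, cfg, deg_seed)
    secretome = generate_secretome(
        universe, cfg.secretome_fraction, hubs, secretome_seed
    )
    ortholog_map = {g: g for g in universe}
    bundle = FixtureBundle(
        config=cfg,
        networks=networks,
        deg_table=deg_table,
        secretome=secretome,
        ortholog_map=ortholog_map,
        hubs=hubs,
    )
    if out_dir is not None:
        write_fixture(bundle, out_dir)
    return bundle


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in the TSV/TXT dialects the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for species, net in bundle.networks.items():
        p = out / f"ppi_{species.lower()}.tsv"
        write_edge_list(net, p)
        paths[f"network_{species}"] = p
    p = out / "deg_table.tsv"
    bundle.deg_table.to_csv(p, sep="\t", index=False)
    paths["deg_table"] = p
    p = out / "secretome.txt"
    p.write_text("".join(g + "\n" for g in bundle.secretome))
    paths["secretome"] = p
    p = out / "ortholog_map.tsv"
    with p.open("w") as fh:
        for src in sorted(bundle.ortholog_map):
            fh.write(f"{src}\t{bundle.ortholog_map[src]}\n")
    paths["ortholog_map"] = p
    p = out / "truth.txt"
    p.write_text("".join(g + "\n" for g in bundle.hubs))
    paths["truth"] = p
    p = out / "fixture_config.yaml"
    p.write_text(yaml.safe_dump(dataclasses.asdict(bundle.config), sort_keys=True))
    paths["config"] = p
    logger.info("fixture written to %s (%d files)", out, len(paths))
    return paths


#: Per-species top-k used with the toy preset. At 300 genes the secretome
#: holds ~25 candidates, so a cut below the pool size is what makes the
#: ranking stage discriminative at this scale (the default 50 matches
#: genome-scale inputs where the secreted candidate pool is far larger).
TOY_TOP_K = 12


def toy_config(rng_seed: int = 0) -> FixtureConfig:
    """Desk-scale preset: 4 species x 2 tissues x 2 cell types, 300 genes.

    Runs the whole pipeline end-to-end in seconds while keeping the planted
    signal recoverable but not trivial. Pair it with ``TOY_TOP_K`` for the
    ranking stage.
    """
    return FixtureConfig(rng_seed=rng_seed)
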