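"""Ground-truthed synthetic inputs for every pipeline stage.

Real inputs to this kind of analysis are deposited gene trees, homology hit
tables, and draft assemblies; none are needed to exercise the pipeline.  The
generators here emit the exact file formats the other modules read, together
with truth records, so classifier recovery, filter arithmetic, and gate
accuracy are all checkable against known answers.

Determinism contract: the same seed yields byte-identical output on any
platform.  Random number streams are per-component (topology, supports,
branch lengths) so changing one knob does not perturb unrelated draws.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .pathway_model import (
    GenomeGeneSet,
    PathwayGraph,
    Reaction,
    default_genomes,
    default_pathways,
)
from .phylo import AnnotatedTree, TaxonMap, parse_newick
from .screening import FilterConfig, GeneEvidence, HomologyHit

__all__ = [
    "SimConfig",
    "TruthRecord",
    "QUERY_GROUP",
    "GROUP_DOMAINS",
    "simulate_gene_tree",
    "simulate_hits",
    "closed_form_survivor_count",
    "simulate_contigs",
    "scenario_matrix",
]

QUERY_GROUP = "Trypanosomatidae"

#: taxonomic domain of each simulated group
GROUP_DOMAINS = {
    QUERY_GROUP: "Eukaryota",
    "Opisthokonta": "Eukaryota",
    "Viridiplantae": "Eukaryota",
    "Stramenopiles": "Eukaryota",
    "Apicomplexa": "Eukaryota",
    "Firmicutes": "Bacteria",
    "Bacteroidetes": "Bacteria",
    "Actinobacteria": "Bacteria",
    "Acidobacteria": "Bacteria",
    "Cyanobacteria": "Bacteria",
    "Alphaproteobacteria": "Bacteria",
    "Betaproteobacteria": "Bacteria",
    "Gammaproteobacteria": "Bacteria",
    "Deltaproteobacteria": "Bacteria",
}

_DEFAULT_GROUPS = {
    "Opisthokonta": 6,
    "Viridiplantae": 5,
    "Firmicutes": 7,
    "Bacteroidetes": 6,
    "Gammaproteobacteria": 6,
    "Actinobacteria": 5,
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the gene-tree simulator.

    ``decisive_support`` is the BSV written on the edge enclosing the grafted
    query clade; all other internal edges draw from ``support_noise``
    (inclusive integer range).
    """

    seed: int = 0
    n_query_leaves: int = 4
    group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_GROUPS))
    implant_transfer: bool = False
    donor_group: str | None = None
    decisive_support: int = 100
    support_noise: tuple[int, int] = (60, 100)
    branch_length_scale: float = 0.1
    break_query_clade: bool = False

    def __post_init__(self) -> None:
        if self.implant_transfer:
            if self.donor_group is None or self.donor_group not in self.group_sizes:
                raise ValueError("implant_transfer requires donor_group in group_sizes")


@dataclass
class TruthRecord:
    gene_id: str
    transferred: bool
    donor: str | None
    query_clade_intact: bool = True
    decisive_bsv: int | None = None
    contaminant: bool = False


class _Node:
    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label=None, children=None, length=0.0, support=None):
        self.label = label
        self.children = children or []
        self.length = length
        self.support = support

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        sup = "" if self.support is None else str(self.support)
        return f"({inner}){sup}:{self.length:.6f}"


def _rng(seed: int, stream: str) -> random.Random:
    return random.Random(f"{seed}:{stream}")


def _leaf(label: str, lrng: random.Random, scale: float) -> _Node:
    return _Node(label=label, length=lrng.expovariate(1.0 / scale))


def _join_all(nodes: list[_Node], trng, srng, lrng, scale, lo, hi) -> _Node:
    """Random sequential binary joins; supports from Uniform{lo..hi}."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i = trng.randrange(len(nodes))
        a = nodes.pop(i)
        j = trng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(
            _Node(
                children=[a, b],
                length=lrng.expovariate(1.0 / scale),
                support=srng.randint(lo, hi),
            )
        )
    return nodes[0]


def simulate_gene_tree(
    cfg: SimConfig,
) -> tuple[AnnotatedTree, TaxonMap, TruthRecord]:
    """Backbone tree with group-coherent clades, optionally with the query
    clade pruned from Eukaryota and regrafted inside the donor group.

    The edge enclosing the graft carries ``decisive_support``; the same seed
    yields byte-identical Newick.
    """
    total = cfg.n_query_leaves + sum(cfg.group_sizes.values())
    if total < 6:
        raise ValueError("need at least 6 leaves in total")
    for g in cfg.group_sizes:
        if g not in GROUP_DOMAINS:
            raise ValueError(f"unknown group {g}")
    domains = {GROUP_DOMAINS[g] for g in cfg.group_sizes}
    if domains != {"Eukaryota", "Bacteria"}:
        raise ValueError("group_sizes must cover a bacterial and a eukaryotic background")
    if cfg.implant_transfer and cfg.group_sizes[cfg.donor_group] < 2:
        raise ValueError("donor clade needs at least 2 leaves")

    trng = _rng(cfg.seed, "topology")
    srng = _rng(cfg.seed, "supports")
    lrng = _rng(cfg.seed, "lengths")
    scale = cfg.branch_length_scale
    lo, hi = cfg.support_noise

    taxa: TaxonMap = {}
    query_labels = [f"{QUERY_GROUP}_q{i + 1}" for i in range(cfg.n_query_leaves)]
    for lbl in query_labels:
        taxa[lbl] = ("Eukaryota", QUERY_GROUP)

    def group_subtree(group: str, labels: list[str]) -> _Node:
        leaves = [_leaf(l, lrng, scale) for l in labels]
        if len(leaves) == 1:
            return leaves[0]
        # group-internal supports kept high so every group is a firm clade
        return _join_all(leaves, trng, srng, lrng, scale, max(lo, 90), hi)

    euk_parts: list[_Node] = []
    bact_parts: list[_Node] = []
    donor_labels_all: dict[str, list[str]] = {}
    for group, n in sorted(cfg.group_sizes.items()):
        labels = [f"{group}_{i + 1}" for i in range(n)]
        donor_labels_all[group] = labels
        for l in labels:
            taxa[l] = (GROUP_DOMAINS[group], group)
        if group == cfg.donor_group and cfg.implant_transfer:
            continue  # built below, around the graft
        node = group_subtree(group, labels)
        (euk_parts if GROUP_DOMAINS[group] == "Eukaryota" else bact_parts).append(node)

    if cfg.break_query_clade and cfg.n_query_leaves >= 2:
        half = cfg.n_query_leaves // 2
        q_main, q_stray = query_labels[:half], query_labels[half:]
    else:
        q_main, q_stray = query_labels, []
    query_sub = group_subtree(QUERY_GROUP, q_main)

    truth = TruthRecord(
        gene_id=f"sim{cfg.seed}",
        transferred=cfg.implant_transfer,
        donor=cfg.donor_group if cfg.implant_transfer else None,
        query_clade_intact=not (cfg.break_query_clade and q_stray),
        decisive_bsv=cfg.decisive_support if cfg.implant_transfer else None,
    )

    if cfg.implant_transfer:
        labels = donor_labels_all[cfg.donor_group]
        k = trng.randint(1, len(labels) - 1)
        sister, rest = labels[:k], labels[k:]
        grafted = _Node(
            children=[query_sub, group_subtree(cfg.donor_group, sister)],
            length=lrng.expovariate(1.0 / scale),
            support=cfg.decisive_support,
        )
        donor_clade = _Node(
            children=[grafted, group_subtree(cfg.donor_group, rest)],
            length=lrng.expovariate(1.0 / scale),
            support=srng.randint(lo, hi),
        )
        bact_parts.append(donor_clade)
    else:
        euk_parts.append(query_sub)
    if q_stray:
        euk_parts.append(group_subtree(QUERY_GROUP, q_stray))

    euk = _join_all(euk_parts, trng, srng, lrng, scale, lo, hi)
    bact = _join_all(bact_parts, trng, srng, lrng, scale, lo, hi)
    root = _Node(children=[euk, bact], support=srng.randint(lo, hi))
    newick = root.newick() + ";"
    tree = parse_newick(newick)
    tree.source_newick = newick  # byte-identical for identical SimConfig
    return tree, taxa, truth


# ---------------------------------------------------------------------------
# Homology hit tables
# ---------------------------------------------------------------------------

def simulate_hits(
    seed: int,
    n_species: int = 50,
    n_genera: int = 10,
    n_good_species: int = 30,
    hits_per_species: int = 2,
    query_length: int = 400,
) -> list[HomologyHit]:
    """Hit table with a controlled pass/fail structure.

    Species ``i`` belongs to genus ``i % n_genera``.  The first
    ``n_good_species`` species each carry exactly one hit passing every
    per-hit rule (significant, complete, covering >= 75% of the query);
    every other hit fails at least one rule, alternating failure modes.
    The survivor count of the default filter is therefore
    :func:`closed_form_survivor_count`, exactly.
    """
    if n_genera > n_species:
        raise ValueError("n_genera must be <= n_species")
    rng = _rng(seed, "hits")
    hits: list[HomologyHit] = []
    for i in range(n_species):
        species = f"species_{i:04d}"
        genus = f"genus_{i % n_genera:03d}"
        for k in range(hits_per_species):
            good = i < n_good_species and k == 0
            if good:
                ev = 10 ** rng.uniform(-80, -20)
                q_start, q_end = 1, rng.randint(
                    int(0.80 * query_length), query_length
                )
                complete = True
            else:
                mode = (i + k) % 3
                if mode == 0:  # insignificant
                    ev = 10 ** rng.uniform(-8, -1)
                    q_start, q_end, complete = 1, query_length, True
                elif mode == 1:  # short alignment
                    ev = 10 ** rng.uniform(-80, -20)
                    q_start, q_end = 1, int(0.5 * query_length)
                    complete = True
                else:  # partial subject sequence
                    ev = 10 ** rng.uniform(-80, -20)
                    q_start, q_end, complete = 1, query_length, False
            hits.append(
                HomologyHit(
                    query_id="query",
                    subject_id=f"s{i:04d}_{k}",
                    subject_species=species,
                    subject_genus=genus,
                    evalue=ev,
                    bitscore=round(rng.uniform(100, 900), 1),
                    q_start=q_start,
                    q_end=q_end,
                    subject_complete=complete,
                    query_length=query_length,
                )
            )
    rng.shuffle(hits)
    return hits


def closed_form_survivor_count(
    n_species: int,
    n_genera: int,
    n_good_species: int,
    cfg: FilterConfig = FilterConfig(),
) -> int:
    """Exact survivor count for :func:`simulate_hits` output under ``cfg``."""
    passing = min(n_good_species, cfg.max_hits)  # one passing hit per species
    if passing <= cfg.genus_dedup_threshold:
        return passing
    # genera are assigned round-robin, so the first `passing` species cover
    # min(passing, n_genera) distinct genera
    return min(passing, n_genera)


# ---------------------------------------------------------------------------
# Contig evidence with planted contaminants
# ---------------------------------------------------------------------------

def simulate_contigs(
    seed: int,
    n_genes: int = 100,
    contaminant_fraction: float = 0.0,
) -> tuple[list[GeneEvidence], list[TruthRecord]]:
    """Contig evidence tables with planted contaminants.

    Legitimate genes emulate the long same-orientation gene stretches of
    trypanosomatid contigs and pass at least three criteria; contaminants
    (short isolated contigs, low coverage, divergent GC, no congruence) pass
    at most one.
    """
    if not 0 <= contaminant_fraction <= 1:
        raise ValueError("contaminant_fraction must be in [0, 1]")
    rng = _rng(seed, "contigs")
    n_cont = round(n_genes * contaminant_fraction)
    flags = [True] * n_cont + [False] * (n_genes - n_cont)
    rng.shuffle(flags)
    gc_mean, gc_sd, cov_median = 0.52, 0.02, 20.0
    evidence: list[GeneEvidence] = []
    truth: list[TruthRecord] = []
    for i, is_cont in enumerate(flags):
        gid = f"gene_{i:04d}"
        if not is_cont:
            ev = GeneEvidence(
                gene_id=gid,
                contig_id=f"contig_{i:04d}",
                neighbor_orientations=["+"] * rng.randint(4, 8),
                neighbor_trypanosomatid_hits=rng.randint(7, 10),
                neighbor_total=10,
                gene_gc=gc_mean + rng.uniform(-1.5, 1.5) * gc_sd,
                genome_gene_gc_mean=gc_mean,
                genome_gene_gc_sd=gc_sd,
                gene_coverage=cov_median * rng.uniform(0.9, 1.4),
                genome_gene_coverage_median=cov_median,
                congruent=True,
            )
        else:
            # at most one criterion may pass: a minority of contaminants keep
            # a typical GC, none keeps context, coverage, or congruence
            gc_ok = rng.random() < 0.3
            ev = GeneEvidence(
                gene_id=gid,
                contig_id=f"short_{i:04d}",
                neighbor_orientations=[rng.choice("+-") for _ in range(2)],
                neighbor_trypanosomatid_hits=rng.randint(0, 2),
                neighbor_total=10,
                gene_gc=(
                    gc_mean + rng.uniform(-1.0, 1.0) * gc_sd
                    if gc_ok
                    else gc_mean + rng.choice([-1, 1]) * rng.uniform(3.5, 6.0) * gc_sd
                ),
                genome_gene_gc_mean=gc_mean,
                genome_gene_gc_sd=gc_sd,
                gene_coverage=cov_median * rng.uniform(0.1, 0.5),
                genome_gene_coverage_median=cov_median,
                congruent=False,
            )
        evidence.append(ev)
        truth.append(
            TruthRecord(
                gene_id=gid, transferred=False, donor=None, contaminant=is_cont
            )
        )
    return evidence, truth


# ---------------------------------------------------------------------------
# Pathway scenarios
# ---------------------------------------------------------------------------

def _tiny_pathway() -> PathwayGraph:
    return PathwayGraph(
        id="toy3",
        metabolites=frozenset({"a", "b", "c", "aa"}),
        reactions=(
            Reaction("r1", frozenset({"a"}), frozenset({"b"}), frozenset({"1.1.1.1"}), "toy3"),
            Reaction("r2", frozenset({"b"}), frozenset({"c"}), frozenset({"2.2.2.2"}), "toy3"),
            Reaction("r3", frozenset({"c"}), frozenset({"aa"}), frozenset({"3.3.3.3"}), "toy3"),
        ),
        seeds=frozenset({"a"}),
        targets=frozenset({"aa"}),
    )


def scenario_matrix(scenario: str) -> tuple[list[PathwayGraph], list[GenomeGeneSet]]:
    """Deterministic pathway/genome fixtures by name.

    ``paper_fig9`` is the shipped study matrix; ``all_host`` / ``all_symbiont``
    put every enzyme in one compartment of a toy pathway; ``random_small``
    scatters the toy pathway's enzymes over host and symbiont with a fixed
    seed.
    """
    if scenario == "paper_fig9":
        return default_pathways(), default_genomes()
    toy = _tiny_pathway()
    if scenario == "all_host":
        return [toy], [
            GenomeGeneSet("host_all", "SHT", set(toy.ecs), partner="sym_none"),
            GenomeGeneSet("sym_none", "TPE", set(), partner="host_all"),
        ]
    if scenario == "all_symbiont":
        return [toy], [
            GenomeGeneSet("host_none", "SHT", set(), partner="sym_all"),
            GenomeGeneSet("sym_all", "TPE", set(toy.ecs), partner="host_none"),
        ]
    if scenario == "random_small":
        rng = _rng(20130909, "scenario")  # fixed: fixture emission
        genomes: list[GenomeGeneSet] = []
        for i in range(4):
            host_ecs = {ec for ec in sorted(toy.ecs) if rng.random() < 0.5}
            sym_ecs = {ec for ec in sorted(toy.ecs) if rng.random() < 0.5}
            genomes.append(
                GenomeGeneSet(f"host_{i}", "SHT", host_ecs, partner=f"sym_{i}")
            )
            genomes.append(
                GenomeGeneSet(f"sym_{i}", "TPE", sym_ecs, partner=f"host_{i}")
            )
        return [toy], genomes
    raise ValueError(
        f"unknown scenario {scenario!r}; available: "
        "paper_fig9, random_small, all_host, all_symbiont"
    )
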