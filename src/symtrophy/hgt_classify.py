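"""Sister-group classification of gene trees: HGT, native, or undetermined.

A nuclear gene of a trypanosomatid is called horizontally transferred when
the query leaves form a clade whose smallest well-supported enclosing clade
is dominated by bacterial sequences; it is native when that clade is
dominated by eukaryotes.  Support classes follow the bootstrap conventions
of the underlying study design: strong for BSV >= 80, moderate for
50 <= BSV < 80 (both bounds configurable), unsupported otherwise.

The classifier operates purely on the unrooted topology, the edge supports,
and a leaf-to-taxonomy map, so its output is invariant under re-rooting and
leaf reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylo import AnnotatedTree, TaxonMap, adjacency

__all__ = [
    "ClassifierConfig",
    "HGTCall",
    "classify",
    "support_class",
    "tally_calls",
    "detect_cotransfer",
    "call_from_affiliation",
    "load_affiliation_table",
    "calls_tsv",
]


@dataclass(frozen=True)
class ClassifierConfig:
    strong_bsv: int = 80
    moderate_bsv: int = 50
    #: fraction of leaves that must share a domain/group to name it
    donor_majority: float = 0.75
    #: maximum number of enclosing clades examined (None = unlimited)
    max_walk: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.moderate_bsv <= self.strong_bsv <= 100:
            raise ValueError("need 0 <= moderate_bsv <= strong_bsv <= 100")
        if not 0.5 < self.donor_majority <= 1:
            raise ValueError("donor_majority must be in (0.5, 1]")


@dataclass
class HGTCall:
    gene_id: str
    query_monophyletic: bool
    call: str  # HGT | native_eukaryotic | undetermined
    donor: str | None = None  # group name or "mixed:<groups>"
    support_class: str = "unsupported"  # strong | moderate | unsupported
    decisive_bsv: int | None = None
    #: group -> leaf count of the decisive clade's non-query leaves
    composition: dict = field(default_factory=dict)
    #: per-clade sub-calls for non-monophyletic queries
    subcalls: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.call == "HGT":
            assert self.donor is not None
            assert self.support_class in {"strong", "moderate"}
        if self.call == "native_eukaryotic":
            assert self.donor is None


def support_class(bsv: int | None, cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """strong / moderate / unsupported for a bootstrap support value.

    The moderate band is closed below and open above ([50, 80) by default),
    so the two classes are disjoint and exhaustive; absent support is
    unsupported.
    """
    if bsv is None:
        return "unsupported"
    if not 0 <= bsv <= 100:
        raise ValueError(f"BSV {bsv} outside [0, 100]")
    if bsv >= cfg.strong_bsv:
        return "strong"
    if bsv >= cfg.moderate_bsv:
        return "moderate"
    return "unsupported"


# ---------------------------------------------------------------------------
# Tree-walk classification
# ---------------------------------------------------------------------------

def _classify_clade(
    adj,
    taxa: TaxonMap,
    query: frozenset[str],
    cfg: ClassifierConfig,
    gene_id: str,
) -> HGTCall:
    """Classify one monophyletic query clade by walking enclosing clades."""
    # locate the query edge: the edge whose one side is exactly `query`
    query_edge = None
    for e in adj.edge_support:
        a, b = tuple(e)
        if adj.side_leaves(b, a) == query:
            query_edge = (b, a)  # walk from a outward
            break
        if adj.side_leaves(a, b) == query:
            query_edge = (a, b)
            break
    if query_edge is None and len(query) == 1:
        # pendant edge of a single leaf
        leaf_id = next(k for k, v in adj.leaf_label.items() if v in query)
        other = adj.neighbors[leaf_id][0]
        query_edge = (other, leaf_id)
    if query_edge is None:
        raise ValueError("query clade not found on tree")

    # Walk outward: at each node crossed, continue along the edge leading to
    # the largest remaining subtree; the recorded enclosing clade is the
    # query-side (complement) of that edge, which grows monotonically.
    inner, outer = query_edge[1], query_edge[0]
    decisive_bsv: int | None = None
    decisive_clade: frozenset[str] | None = None
    steps = 0
    while True:
        candidates = [w for w in adj.neighbors[outer] if w != inner]
        if not candidates:
            break
        # far-side leaf sets of each candidate edge
        far = {w: adj.side_leaves(outer, w) for w in candidates}
        # continue toward the largest subtree (ties: lexicographic smallest
        # leaf label, for determinism)
        nxt = max(candidates, key=lambda w: (len(far[w]), min(far[w])))
        sup = adj.edge_support[frozenset({outer, nxt})]
        enclosing = adj.side_leaves(nxt, outer)  # query-side of that edge
        steps += 1
        if sup is not None and sup >= cfg.moderate_bsv:
            decisive_bsv = sup
            decisive_clade = enclosing
            break
        if cfg.max_walk is not None and steps >= cfg.max_walk:
            break
        if len(far[nxt]) <= 1:
            break
        inner, outer = outer, nxt

    if decisive_clade is None:
        return HGTCall(
            gene_id=gene_id,
            query_monophyletic=True,
            call="undetermined",
            support_class="unsupported",
        )

    sclass = support_class(decisive_bsv, cfg)
    non_query = decisive_clade - query
    comp: dict[str, int] = {}
    n_bact = n_euk = 0
    for leaf in non_query:
        domain, group = taxa[leaf]
        comp[group] = comp.get(group, 0) + 1
        if domain == "Bacteria":
            n_bact += 1
        elif domain == "Eukaryota":
            n_euk += 1
    total = len(non_query)

    call = "undetermined"
    donor: str | None = None
    if total and n_bact / total >= cfg.donor_majority:
        call = "HGT"
        bact_groups = {
            g: c for g, c in comp.items()
            if any(taxa[l] == ("Bacteria", g) for l in non_query)
        }
        best = sorted(bact_groups.items(), key=lambda kv: (-kv[1], kv[0]))
        top_count = best[0][1]
        tied = [g for g, c in best if c == top_count]
        if len(tied) == 1 and top_count / n_bact >= cfg.donor_majority:
            donor = tied[0]
        else:  # no single dominant group, or tie: conservative
            donor = "mixed:" + ",".join(sorted(bact_groups))
    elif total and n_euk / total >= cfg.donor_majority:
        call = "native_eukaryotic"
    if sclass == "unsupported":
        call = "undetermined"
        donor = None
    if call == "native_eukaryotic":
        donor = None
    return HGTCall(
        gene_id=gene_id,
        query_monophyletic=True,
        call=call,
        donor=donor,
        support_class=sclass,
        decisive_bsv=decisive_bsv,
        composition=comp,
    )


def _maximal_query_clades(adj, query: frozenset[str]) -> list[frozenset[str]]:
    """Maximal sets of query leaves separable from everything else by one
    edge (computed on the unrooted adjacency graph)."""
    leaf_ids = {k for k, v in adj.leaf_label.items() if v in query}
    clades: list[frozenset[str]] = []
    for e in adj.edge_support:
        for a, b in (tuple(e), tuple(e)[::-1]):
            side = adj.side_leaves(a, b)
            if side and side <= query:
                clades.append(side)
    for lid in leaf_ids:  # single leaves are always clades
        clades.append(frozenset({adj.leaf_label[lid]}))
    # keep maximal ones
    maximal = [
        c for c in set(clades) if not any(c < d for d in clades)
    ]
    return sorted(maximal, key=lambda c: (-len(c), min(c)))


def classify(
    tree: AnnotatedTree,
    taxa: TaxonMap,
    query: frozenset[str] | set[str],
    cfg: ClassifierConfig = ClassifierConfig(),
    gene_id: str = "",
) -> HGTCall:
    """Classify one gene tree as HGT / native_eukaryotic / undetermined.

    Query leaves (the trypanosomatid sequences) must all map to Eukaryota.
    For a non-monophyletic query, each maximal query-only clade is classified
    separately; the overall call is undetermined unless the sub-calls agree.
    """
    query = frozenset(query)
    leaves = tree.leaf_set()
    if not query or not query <= leaves:
        raise ValueError("query leaves must be a non-empty subset of the tree")
    if query == leaves:
        raise ValueError("query equals the whole tree")
    missing = [l for l in leaves if l not in taxa]
    if missing:
        raise ValueError(f"taxa map does not cover leaves: {missing[:3]}")
    for l in query:
        if taxa[l][0] != "Eukaryota":
            raise ValueError(f"query leaf {l} is not mapped to Eukaryota")

    adj = adjacency(tree)
    clades = _maximal_query_clades(adj, query)
    if len(clades) == 1 and clades[0] == query:
        return _classify_clade(adj, taxa, query, cfg, gene_id)

    subcalls = [
        _classify_clade(adj, taxa, c, cfg, f"{gene_id}[{i}]")
        for i, c in enumerate(clades)
    ]
    agree = len({(s.call, s.donor) for s in subcalls}) == 1
    if agree and subcalls[0].call != "undetermined":
        first = subcalls[0]
        merged_comp: dict[str, int] = {}
        for s in subcalls:
            for g, c in s.composition.items():
                merged_comp[g] = merged_comp.get(g, 0) + c
        bsvs = [s.decisive_bsv for s in subcalls if s.decisive_bsv is not None]
        bsv = min(bsvs) if bsvs else None
        return HGTCall(
            gene_id=gene_id,
            query_monophyletic=False,
            call=first.call,
            donor=first.donor,
            support_class=support_class(bsv, cfg),
            decisive_bsv=bsv,
            composition=merged_comp,
            subcalls=subcalls,
        )
    return HGTCall(
        gene_id=gene_id,
        query_monophyletic=False,
        call="undetermined",
        subcalls=subcalls,
    )


# ---------------------------------------------------------------------------
# Tally and co-transfer
# ---------------------------------------------------------------------------

def tally_calls(calls: list[HGTCall]) -> dict:
    """Summary counts: total, HGT, native, undetermined, per-donor.

    Donors of the form "mixed:<...>" are pooled under "mixed".
    """
    ids = [c.gene_id for c in calls]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene_id in call list")
    per_donor: dict[str, int] = {}
    n_hgt = n_native = n_und = 0
    for c in calls:
        if c.call == "HGT":
            n_hgt += 1
            key = "mixed" if (c.donor or "").startswith("mixed") else c.donor
            per_donor[key] = per_donor.get(key, 0) + 1
        elif c.call == "native_eukaryotic":
            n_native += 1
        else:
            n_und += 1
    return {
        "n_total": len(calls),
        "n_hgt": n_hgt,
        "n_native": n_native,
        "n_undetermined": n_und,
        "per_donor_counts": per_donor,
    }


def detect_cotransfer(
    calls: list[HGTCall],
    gene_locations: dict[str, tuple[str, int]],
) -> list[tuple[str, str]]:
    """Pairs of HGT-called genes with the same donor group, on the same
    contig, at adjacent ordinal positions (tandem co-transfer candidates)."""
    hgt = [c for c in calls if c.call == "HGT" and c.gene_id in gene_locations]
    pairs: list[tuple[str, str]] = []
    for i in range(len(hgt)):
        for j in range(i + 1, len(hgt)):
            a, b = hgt[i], hgt[j]
            if a.donor != b.donor:
                continue
            ca, pa = gene_locations[a.gene_id]
            cb, pb = gene_locations[b.gene_id]
            if ca == cb and abs(pa - pb) == 1:
                pairs.append(tuple(sorted((a.gene_id, b.gene_id))))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Affiliation-table route (summary-level inputs)
# ---------------------------------------------------------------------------

def call_from_affiliation(
    gene_id: str,
    domain: str,
    donor_group: str | None,
    bsv: int | None,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> HGTCall:
    """Apply the support/affiliation rule to one row of a per-gene summary
    table (sister-group domain, donor group, BSV of the decisive clade)."""
    sclass = support_class(bsv, cfg)
    if sclass == "unsupported" or domain not in {"Bacteria", "Eukaryota"}:
        return HGTCall(gene_id, True, "undetermined", None, "unsupported", bsv)
    if domain == "Bacteria":
        return HGTCall(gene_id, True, "HGT", donor_group or "mixed:unassigned",
                       sclass, bsv)
    return HGTCall(gene_id, True, "native_eukaryotic", None, sclass, bsv)


def load_affiliation_table(
    text: str, cfg: ClassifierConfig = ClassifierConfig()
) -> list[HGTCall]:
    """Read a per-gene affiliation/BSV TSV and classify each row.

    Expected columns: gene_id, ec, pathway, domain, donor_group, bsv, note.
    """
    calls: list[HGTCall] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells
            continue
        row = dict(zip(header, cells))
        bsv = int(row["bsv"]) if row.get("bsv", "").strip() else None
        calls.append(
            call_from_affiliation(
                row["gene_id"],
                row["domain"],
                row.get("donor_group") or None,
                bsv,
                cfg,
            )
        )
    return calls


def calls_tsv(calls: list[HGTCall]) -> str:
    """Per-gene call table (TSV)."""
    lines = ["gene_id\tmonophyletic\tcall\tdonor\tsupport_class\tdecisive_bsv"]
    for c in calls:
        lines.append(
            "\t".join(
                [
                    c.gene_id,
                    str(c.query_monophyletic).lower(),
                    c.call,
                    c.donor or "",
                    c.support_class,
                    "" if c.decisive_bsv is None else str(c.decisive_bsv),
                ]
            )
        )
    return "\n".join(lines) + "\n"
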