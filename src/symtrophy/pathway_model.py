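"""Amino acid biosynthesis pathways as reaction graphs over EC presence/absence.

The model captures what the genome content of a trypanosomatid host (SHT or
RT), of its proteobacterial endosymbiont (TPE), or of the host+symbiont union
can synthesize.  A pathway is a set of reactions; a reaction fires when all of
its substrate metabolites are available and the genome carries at least one of
its catalyst EC numbers.  Reachability is the fixed point of firing reactions
starting from the pathway's seed metabolites.

Compartments:
    SHT  symbiont-harboring trypanosomatid (host nucleus)
    RT   regular trypanosomatid (no symbiont)
    TPE  trypanosomatid proteobacterial endosymbiont

The union semantics assume free metabolite exchange between host cytoplasm
and symbiont, which is the premise of the complementation argument: a
"chimeric" route draws successive enzymes from both genomes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ECNumber",
    "Reaction",
    "PathwayGraph",
    "GenomeGeneSet",
    "SynthesisVerdict",
    "PathwayParseError",
    "PathwayValidationError",
    "PairingError",
    "normalize_ec",
    "load_pathways",
    "default_pathways",
    "reachable",
    "synthesis_verdict",
    "autotrophy_matrix",
    "load_presence_matrix",
    "load_organism_table",
    "default_genomes",
    "DAP_PATHWAY_ECS",
]

# EC numbers: 3 or 4 dot-separated fields; partial classes ("4.1.3.-") and
# subunit suffixes ("4.2.1.20a") are legal.  A trailing "?" marks a reaction
# whose gene is unknown in all organisms and is excluded from genomic
# evaluation (it can never match a genome's gene set).
_EC_RE = re.compile(r"^\d+\.(?:\d+|-)\.(?:\d+|-)(?:\.(?:\d+|-)[a-z]?)?[a-z]?\??$")

ECNumber = str

#: The nine enzymes of the bacterial-type DAP route from L-aspartate to lysine.
DAP_PATHWAY_ECS = frozenset(
    {
        "2.7.2.4",
        "1.2.1.11",
        "4.2.1.52",
        "1.3.1.26",
        "2.3.1.117",
        "2.6.1.17",
        "3.5.1.18",
        "5.1.1.7",
        "4.1.1.20",
    }
)


class PathwayParseError(ValueError):
    """Malformed pathway-definition document."""


class PathwayValidationError(ValueError):
    """Structurally valid document violating a pathway invariant."""


class PairingError(ValueError):
    """Inconsistent SHT/TPE host-symbiont pairing."""


def normalize_ec(value: str) -> ECNumber:
    """Trim and validate an EC identifier (string comparison semantics)."""
    v = value.strip()
    if not _EC_RE.match(v):
        raise ValueError(f"not an EC number: {value!r}")
    return v


@dataclass(frozen=True)
class Reaction:
    """One arrow of a pathway figure.

    All substrates are required (AND); any one catalyst suffices (OR).
    Catalysts carrying the unknown-gene flag ("?" suffix) never match a
    genome and only document the biochemical step.
    """

    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    catalysts: frozenset[ECNumber]
    pathway_id: str = ""

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise PathwayValidationError(
                f"reaction {self.id}: substrates and products must be non-empty"
            )
        if self.substrates & self.products:
            raise PathwayValidationError(
                f"reaction {self.id}: substrates and products overlap"
            )
        if not self.catalysts:
            raise PathwayValidationError(f"reaction {self.id}: no catalysts")

    def can_fire(self, available: frozenset[str] | set[str], genes: set[ECNumber]) -> bool:
        if not self.substrates <= set(available):
            return False
        return any(c in genes for c in self.catalysts if not c.endswith("?"))


@dataclass(frozen=True)
class PathwayGraph:
    """Metabolites and EC-catalyzed reactions of one biosynthesis pathway."""

    id: str
    metabolites: frozenset[str]
    reactions: tuple[Reaction, ...]
    seeds: frozenset[str]
    targets: frozenset[str]

    def __post_init__(self) -> None:
        for r in self.reactions:
            for m in r.substrates | r.products:
                if m not in self.metabolites:
                    raise PathwayValidationError(
                        f"pathway {self.id}, reaction {r.id}: "
                        f"undeclared metabolite {m!r}"
                    )
        if not self.seeds <= self.metabolites:
            raise PathwayValidationError(f"pathway {self.id}: seeds not declared")
        if not self.targets <= self.metabolites:
            raise PathwayValidationError(f"pathway {self.id}: targets not declared")
        if self.seeds & self.targets:
            raise PathwayValidationError(f"pathway {self.id}: seeds overlap targets")

    @property
    def ecs(self) -> frozenset[ECNumber]:
        out: set[ECNumber] = set()
        for r in self.reactions:
            out |= {c for c in r.catalysts if not c.endswith("?")}
        return frozenset(out)


@dataclass
class GenomeGeneSet:
    """An organism's compartment kind and its set of EC numbers.

    SHT hosts are paired with their TPE symbiont via ``partner`` (reciprocal);
    RT organisms have no partner.
    """

    organism: str
    kind: str  # SHT | RT | TPE
    genes: set[ECNumber]
    partner: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"SHT", "RT", "TPE"}:
            raise ValueError(f"{self.organism}: unknown kind {self.kind!r}")
        if self.kind == "RT" and self.partner is not None:
            raise PairingError(f"RT organism {self.organism} cannot have a partner")


@dataclass
class SynthesisVerdict:
    """Who can make a target: the host alone, the symbiont alone, only the
    union of both genomes, or nobody."""

    organism: str
    target: str
    producible_by: str  # host_alone | symbiont_alone | union_only | neither
    used_reactions: dict[str, list[str]] = field(default_factory=dict)
    missing_steps: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pathway-definition document
#
# Sections:   [pathway <id>]
# Directives: metabolites: a, b, c     (repeatable)
#             seeds: a, b
#             targets: x
# Reactions:  <reaction_id>: subst + subst -> prod + prod | EC, EC, ...
# ---------------------------------------------------------------------------

def load_pathways(config_text: str) -> list[PathwayGraph]:
    """Parse a pathway-definition document into :class:`PathwayGraph` objects.

    Raises :class:`PathwayParseError` for malformed lines (naming the
    offending reaction) and :class:`PathwayValidationError` for dangling
    metabolite ids.
    """
    pathways: list[PathwayGraph] = []
    cur_id: str | None = None
    metabolites: set[str] = set()
    seeds: set[str] = set()
    targets: set[str] = set()
    reactions: list[Reaction] = []

    def flush() -> None:
        nonlocal metabolites, seeds, targets, reactions
        if cur_id is None:
            return
        pathways.append(
            PathwayGraph(
                id=cur_id,
                metabolites=frozenset(metabolites),
                reactions=tuple(reactions),
                seeds=frozenset(seeds),
                targets=frozenset(targets),
            )
        )
        metabolites, seeds, targets, reactions = set(), set(), set(), []

    for lineno, raw in enumerate(config_text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            m = re.match(r"^\[pathway\s+([\w.-]+)\]$", line)
            if not m:
                raise PathwayParseError(f"line {lineno}: bad section header {line!r}")
            flush()
            cur_id = m.group(1)
            continue
        if cur_id is None:
            raise PathwayParseError(f"line {lineno}: content before any [pathway] section")
        key, _, rest = line.partition(":")
        key = key.strip()
        rest = rest.strip()
        if key in {"metabolites", "seeds", "targets"}:
            # semicolon-separated: metabolite ids may contain commas
            # ("2,3-dihydrodipicolinate")
            ids = [x.strip() for x in rest.split(";") if x.strip()]
            if key == "metabolites":
                metabolites.update(ids)
            elif key == "seeds":
                seeds.update(ids)
                metabolites.update(ids)
            else:
                targets.update(ids)
                metabolites.update(ids)
            continue
        # reaction line
        if "->" not in rest or "|" not in rest:
            raise PathwayParseError(
                f"line {lineno}: reaction {key!r} must look like "
                f"'id: a + b -> c | EC,EC'"
            )
        lhs, _, tail = rest.partition("->")
        prods_part, _, ec_part = tail.partition("|")
        substrates = frozenset(x.strip() for x in lhs.split("+") if x.strip())
        products = frozenset(x.strip() for x in prods_part.split("+") if x.strip())
        try:
            catalysts = frozenset(normalize_ec(c) for c in ec_part.split(",") if c.strip())
        except ValueError as e:
            raise PathwayParseError(f"line {lineno}: reaction {key!r}: {e}") from e
        if not catalysts:
            raise PathwayParseError(f"line {lineno}: reaction {key!r}: no catalysts")
        reactions.append(
            Reaction(
                id=key,
                substrates=substrates,
                products=products,
                catalysts=catalysts,
                pathway_id=cur_id,
            )
        )
    flush()
    return pathways


def _read_data(name: str) -> str:
    return (resources.files("symtrophy") / "data" / name).read_text()


def default_pathways() -> list[PathwayGraph]:
    """The shipped pathway set: lysine (DAP), methionine/cysteine, threonine,
    branched-chain amino acids, aromatic amino acids, histidine,
    arginine/ornithine/polyamines, and the methionine salvage cycle."""
    return load_pathways(_read_data("pathways.txt"))


# ---------------------------------------------------------------------------
# Reachability
# ---------------------------------------------------------------------------

def reachable(
    pathway: PathwayGraph,
    genes: Iterable[ECNumber],
    extra_seeds: Iterable[str] = (),
) -> set[str]:
    """Fixed point of reaction firing from seeds ∪ extra_seeds.

    A reaction fires iff all substrates are available and at least one of its
    catalysts is in ``genes``.  Deterministic regardless of reaction order;
    an empty gene set legally returns just the seeds.
    """
    extra = set(extra_seeds)
    if not extra <= pathway.metabolites:
        bad = sorted(extra - pathway.metabolites)
        raise PathwayValidationError(
            f"pathway {pathway.id}: extra seeds not declared: {bad}"
        )
    gene_set = set(genes)
    avail = set(pathway.seeds) | extra
    changed = True
    while changed:
        changed = False
        for r in pathway.reactions:
            if r.products <= avail:
                continue
            if r.can_fire(avail, gene_set):
                avail |= r.products
                changed = True
    return avail


def _fired_reactions(pathway: PathwayGraph, genes: set[ECNumber]) -> list[Reaction]:
    avail = set(pathway.seeds)
    fired: list[Reaction] = []
    fired_ids: set[str] = set()
    changed = True
    while changed:
        changed = False
        for r in pathway.reactions:
            if r.id in fired_ids:
                continue
            if r.can_fire(avail, genes):
                avail |= r.products
                fired.append(r)
                fired_ids.add(r.id)
                changed = True
    return fired


def synthesis_verdict(
    pathway: PathwayGraph,
    host: GenomeGeneSet,
    symbiont: GenomeGeneSet | None,
    target: str,
) -> SynthesisVerdict:
    """Classify who can synthesize ``target``.

    Precedence host_alone > symbiont_alone > union_only: chimeric routes are
    only reported when genuinely required.  In the union run each fired
    reaction is attributed to the compartment(s) whose genome carries one of
    its catalysts.
    """
    if target not in pathway.targets:
        raise ValueError(f"{target!r} is not a target of pathway {pathway.id}")
    if symbiont is not None:
        if host.kind == "RT":
            raise PairingError(f"RT organism {host.organism} has no symbiont")
        if host.partner != symbiont.organism or symbiont.partner != host.organism:
            raise PairingError(
                f"{symbiont.organism} is not the partner of {host.organism}"
            )

    host_ok = target in reachable(pathway, host.genes)
    sym_genes = symbiont.genes if symbiont is not None else set()
    sym_ok = symbiont is not None and target in reachable(pathway, sym_genes)
    union_genes = set(host.genes) | set(sym_genes)
    union_ok = target in reachable(pathway, union_genes)

    if host_ok:
        producible = "host_alone"
    elif sym_ok:
        producible = "symbiont_alone"
    elif union_ok:
        producible = "union_only"
    else:
        producible = "neither"

    used: dict[str, list[str]] = {}
    missing: list[str] = []
    if producible != "neither":
        for r in _fired_reactions(pathway, union_genes):
            live = {c for c in r.catalysts if not c.endswith("?")}
            if live & set(host.genes):
                used.setdefault("host", []).append(r.id)
            if live & set(sym_genes):
                used.setdefault("symbiont", []).append(r.id)
    fired_ids = {r.id for r in _fired_reactions(pathway, union_genes)}
    missing = [r.id for r in pathway.reactions if r.id not in fired_ids]
    return SynthesisVerdict(
        organism=host.organism,
        target=target,
        producible_by=producible,
        used_reactions=used,
        missing_steps=missing,
    )


def autotrophy_matrix(
    pathways: Sequence[PathwayGraph],
    genomes: Sequence[GenomeGeneSet],
) -> dict[str, dict[str, str]]:
    """One verdict per (host organism, pathway target).

    SHT hosts are evaluated with their paired TPE; RT organisms host-alone.
    Returns {organism: {target: producible_by}}.
    """
    names = [g.organism for g in genomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate organism names")
    by_name = {g.organism: g for g in genomes}
    # a target claimed by several pathways (e.g. methionine, made de novo and
    # by the salvage cycle) is reported per pathway
    target_owners: dict[str, int] = {}
    for pw in pathways:
        for t in pw.targets:
            target_owners[t] = target_owners.get(t, 0) + 1
    # validate reciprocal pairings
    for g in genomes:
        if g.kind == "SHT":
            if g.partner is None or g.partner not in by_name:
                raise PairingError(f"SHT {g.organism} has unresolved partner")
            p = by_name[g.partner]
            if p.kind != "TPE" or p.partner != g.organism:
                raise PairingError(f"{g.organism}/{g.partner}: pairing not reciprocal")
    out: dict[str, dict[str, str]] = {}
    for g in genomes:
        if g.kind == "TPE":
            continue
        sym = by_name[g.partner] if g.kind == "SHT" else None
        row: dict[str, str] = {}
        for pw in pathways:
            for target in sorted(pw.targets):
                v = synthesis_verdict(pw, g, sym, target)
                key = target if target_owners[target] == 1 else f"{target}({pw.id})"
                row[key] = v.producible_by
        out[g.organism] = row
    return out


def matrix_to_tsv(matrix: Mapping[str, Mapping[str, str]]) -> str:
    """Serialize an autotrophy matrix as TSV (rows = organisms)."""
    targets = sorted({t for row in matrix.values() for t in row})
    lines = ["organism\t" + "\t".join(targets)]
    for org in sorted(matrix):
        lines.append(org + "\t" + "\t".join(matrix[org].get(t, "") for t in targets))
    return "\n".join(lines) + "\n"


def matrix_to_json(matrix: Mapping[str, Mapping[str, str]]) -> str:
    return json.dumps({k: dict(v) for k, v in matrix.items()}, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Shipped presence matrix
# ---------------------------------------------------------------------------

def load_presence_matrix(text: str) -> dict[str, set[ECNumber]]:
    """Parse an EC-by-organism 0/1 TSV into {organism: set of ECs}."""
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    organisms = header[1:]
    out: dict[str, set[ECNumber]] = {o: set() for o in organisms}
    for line in lines[1:]:
        cells = line.rstrip("\n").split("\t")
        ec = normalize_ec(cells[0])
        for org, cell in zip(organisms, cells[1:]):
            if cell.strip() == "1":
                out[org].add(ec)
    return out


def load_organism_table(text: str) -> list[tuple[str, str, str | None]]:
    """Parse the organism/kind/partner TSV companion of a presence matrix."""
    rows: list[tuple[str, str, str | None]] = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("organism\t"):
            continue
        org, kind, partner = (line.rstrip("\n").split("\t") + [""])[:3]
        rows.append((org, kind, partner or None))
    return rows


def default_genomes() -> list[GenomeGeneSet]:
    """Genome gene sets transcribed from the study's compartment annotations:
    five SHT/TPE pairs plus the two regular trypanosomatids."""
    presence = load_presence_matrix(_read_data("presence_fig9.tsv"))
    table = load_organism_table(_read_data("organisms_fig9.tsv"))
    return [
        GenomeGeneSet(organism=org, kind=kind, genes=presence.get(org, set()), partner=partner)
        for org, kind, partner in table
    ]
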