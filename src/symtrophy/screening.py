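"""Ortholog-collection filtering and the contamination-evidence gate.

Two independent quality screens precede any phylogenetic conclusion:

* :func:`filter_hits` reduces a homology search hit table to one
  representative per species (per genus for very large collections),
  keeping only significant, complete, well-covered matches.

* :func:`evaluate_gate` decides whether a gene assembled from a draft
  genome is a legitimate nuclear gene rather than a contaminant, from four
  evidence criteria — genomic context, sequencing coverage, GC content, and
  phylogenetic congruence — accepting the gene when at least two pass.
  The numeric surrogates for the qualitative criteria are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "HomologyHit",
    "FilterConfig",
    "GeneEvidence",
    "GateThresholds",
    "GateResult",
    "filter_hits",
    "evaluate_gate",
    "parse_hits_tsv",
    "hits_tsv",
    "gate_results_tsv",
]


@dataclass(frozen=True)
class HomologyHit:
    """One row of a tabular homology search (outfmt-6-like, with added
    species / genus / completeness columns)."""

    query_id: str
    subject_id: str
    subject_species: str
    subject_genus: str
    evalue: float
    bitscore: float
    q_start: int
    q_end: int
    subject_complete: bool
    query_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end <= self.query_length):
            raise ValueError(
                f"hit {self.subject_id}: bad coordinates "
                f"{self.q_start}-{self.q_end}/{self.query_length}"
            )
        if self.evalue <= 0:
            raise ValueError(f"hit {self.subject_id}: evalue must be > 0")

    @property
    def query_coverage(self) -> float:
        return (self.q_end - self.q_start + 1) / self.query_length


@dataclass(frozen=True)
class FilterConfig:
    evalue_max: float = 1e-10
    max_hits: int = 10_000
    min_query_cov: float = 0.75
    #: above this many surviving sequences, dedup per genus instead of species
    genus_dedup_threshold: int = 1500

    def __post_init__(self) -> None:
        if not 0 < self.min_query_cov <= 1:
            raise ValueError("min_query_cov must be in (0, 1]")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


def _hit_rank(h: HomologyHit) -> tuple:
    # ascending evalue, then descending bitscore, then subject id
    return (h.evalue, -h.bitscore, h.subject_id)


def filter_hits(hits: list[HomologyHit], cfg: FilterConfig = FilterConfig()) -> list[HomologyHit]:
    """Apply the five collection rules in order.

    (1) significance, (2) completeness + >= min_query_cov coverage of the
    query, (3) cap at max_hits best by e-value, (4) best hit per subject
    species, (5) if still above genus_dedup_threshold, best per genus.
    Deterministic tie-breaking (e-value, bitscore, subject id) makes the
    operation idempotent.
    """
    kept = [h for h in hits if h.evalue <= cfg.evalue_max]
    kept = [
        h for h in kept
        if h.subject_complete and h.query_coverage >= cfg.min_query_cov
    ]
    kept = sorted(kept, key=_hit_rank)[: cfg.max_hits]
    by_species: dict[str, HomologyHit] = {}
    for h in kept:  # already rank-sorted: first seen per species is best
        by_species.setdefault(h.subject_species, h)
    survivors = sorted(by_species.values(), key=_hit_rank)
    if len(survivors) > cfg.genus_dedup_threshold:
        by_genus: dict[str, HomologyHit] = {}
        for h in survivors:
            by_genus.setdefault(h.subject_genus, h)
        survivors = sorted(by_genus.values(), key=_hit_rank)
    return survivors


# ---------------------------------------------------------------------------
# Contamination gate
# ---------------------------------------------------------------------------

@dataclass
class GeneEvidence:
    """Per-gene contig evidence used by the contamination gate."""

    gene_id: str
    contig_id: str
    #: strands ('+'/'-') of the flanking genes, in contig order
    neighbor_orientations: list[str]
    neighbor_trypanosomatid_hits: int
    neighbor_total: int
    gene_gc: float
    genome_gene_gc_mean: float
    genome_gene_gc_sd: float
    gene_coverage: float
    genome_gene_coverage_median: float
    congruent: bool | None = None  # None = no tree available

    def __post_init__(self) -> None:
        for name in ("gene_gc", "genome_gene_gc_mean", "genome_gene_gc_sd"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{self.gene_id}: {name}={v} outside [0, 1]")
        if self.gene_coverage < 0 or self.genome_gene_coverage_median < 0:
            raise ValueError(f"{self.gene_id}: negative coverage")


@dataclass(frozen=True)
class GateThresholds:
    """Numeric surrogates for the qualitative evidence criteria."""

    min_same_strand_run: int = 3
    min_trypanosomatid_neighbor_frac: float = 0.5
    min_coverage_frac_of_median: float = 0.75
    max_gc_sd: float = 2.0
    min_criteria: int = 2


@dataclass
class GateResult:
    gene_id: str
    criteria: dict  # {context, coverage, gc, congruence} -> bool or None
    n_pass: int
    accepted: bool


def _longest_run(strands: list[str]) -> int:
    best = run = 0
    prev: str | None = None
    for s in strands:
        run = run + 1 if s == prev else 1
        prev = s
        best = max(best, run)
    return best


def evaluate_gate(
    ev: GeneEvidence, thresholds: GateThresholds = GateThresholds()
) -> GateResult:
    """Score the four criteria and accept iff at least ``min_criteria`` pass.

    Absent criteria (e.g. no gene tree, so congruence unknown) count as not
    passed — never as failed-with-prejudice, but they cannot help a gene in.
    """
    t = thresholds
    context = (
        _longest_run(ev.neighbor_orientations) >= t.min_same_strand_run
        and ev.neighbor_total > 0
        and ev.neighbor_trypanosomatid_hits / ev.neighbor_total
        >= t.min_trypanosomatid_neighbor_frac
    )
    coverage = (
        ev.gene_coverage
        >= t.min_coverage_frac_of_median * ev.genome_gene_coverage_median
    )
    gc = abs(ev.gene_gc - ev.genome_gene_gc_mean) <= t.max_gc_sd * ev.genome_gene_gc_sd
    congruence = ev.congruent if ev.congruent is None else bool(ev.congruent)
    criteria = {
        "context": context,
        "coverage": coverage,
        "gc": gc,
        "congruence": congruence,
    }
    n_pass = sum(1 for v in criteria.values() if v is True)
    return GateResult(
        gene_id=ev.gene_id,
        criteria=criteria,
        n_pass=n_pass,
        accepted=n_pass >= t.min_criteria,
    )


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

_HIT_COLS = [
    "query_id", "subject_id", "subject_species", "subject_genus", "evalue",
    "bitscore", "q_start", "q_end", "subject_complete", "query_length",
]


def hits_tsv(hits: list[HomologyHit]) -> str:
    lines = ["\t".join(_HIT_COLS)]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query_id, h.subject_id, h.subject_species, h.subject_genus,
                    f"{h.evalue:.3g}", f"{h.bitscore:.1f}", str(h.q_start),
                    str(h.q_end), "1" if h.subject_complete else "0",
                    str(h.query_length),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def parse_hits_tsv(text: str) -> list[HomologyHit]:
    hits: list[HomologyHit] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells
            continue
        row = dict(zip(header, cells))
        hits.append(
            HomologyHit(
                query_id=row["query_id"],
                subject_id=row["subject_id"],
                subject_species=row["subject_species"],
                subject_genus=row["subject_genus"],
                evalue=float(row["evalue"]),
                bitscore=float(row["bitscore"]),
                q_start=int(row["q_start"]),
                q_end=int(row["q_end"]),
                subject_complete=row["subject_complete"] == "1",
                query_length=int(row["query_length"]),
            )
        )
    return hits


def gate_results_tsv(results: list[GateResult]) -> str:
    lines = ["gene_id\tcontext\tcoverage\tgc\tcongruence\tn_pass\taccepted"]
    for r in results:
        def cell(v):
            return "" if v is None else ("1" if v else "0")
        lines.append(
            "\t".join(
                [
                    r.gene_id,
                    cell(r.criteria["context"]),
                    cell(r.criteria["coverage"]),
                    cell(r.criteria["gc"]),
                    cell(r.criteria["congruence"]),
                    str(r.n_pass),
                    "1" if r.accepted else "0",
                ]
            )
        )
    return "\n".join(lines) + "\n"
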