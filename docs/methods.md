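# Methods

## Pathway model

Each amino acid pathway is a directed hypergraph: reactions with substrate
sets (all required), product sets, and catalyst sets of EC numbers (any one
suffices).  Alternative enzymes for the same step — e.g. aminoacylase
(EC:3.5.1.14) or acetylornithine deacetylase (EC:3.5.1.16) for
N-acetylornithine → ornithine — are listed as alternative catalysts of one
reaction.  `reachable(pathway, genes, extra_seeds)` computes the fixed point
of reaction firing from the pathway's seed metabolites; because firing is
monotone, the fixed point is unique and independent of reaction order, and
reachability is monotone in the gene set (tested against exhaustive
enumeration of firing subsets on small graphs).

Seed metabolites are the pathway entry compounds of the source figures
(L-aspartate, pyruvate, glutamate, L-serine, glycine, PRPP, erythrose
4-phosphate, phosphoenolpyruvate, carbamoyl phosphate, S-adenosyl-
methionine).  Currency metabolites (ATP, CoA, NAD(P)H, H2O, glutamine as an
amino donor) are omitted from substrate sets, as figures conventionally do.
Shared precursors — aspartate 4-semialdehyde, homoserine, threonine,
S-adenosyl-methionine, putrescine — carry identical ids across pathway
sections so multi-pathway reasoning composes; the reactions producing them
are repeated in every pathway that consumes them.

`synthesis_verdict` evaluates a target for the host genes alone, the
symbiont genes alone, and their union, and reports with precedence
`host_alone > symbiont_alone > union_only > neither`, so a chimeric
("union_only") verdict is issued only when genuinely required.  Union
semantics assume free metabolite exchange between host cytoplasm and
symbiont — the implicit premise of any complementation argument; transport
is not modeled.  In the union run, each fired reaction is attributed to
every compartment whose genome carries one of its catalysts (ties recorded
on both sides).

Modeling choices on specific steps:

* **Tryptophan synthase.**  The alpha/beta subunit pair (4.2.1.20a/b) is
  modeled as two sequential reactions — indoleglycerol phosphate → indole
  (alpha) and indole + serine → tryptophan (beta) — which both enforces the
  both-subunits requirement for the full route and exposes the beta-only
  indole condensation that hosts carrying just the beta subunit can run.
* **Histidinol-phosphate phosphatase.**  The canonical EC:3.1.3.15 is absent
  from the endosymbiont genomes; following the hypothesis that their
  IMPase-family genes fill this gap, the shipped matrix records a candidate
  activity `3.1.3.15c` for the endosymbionts and the reaction accepts either
  catalyst.  Without this assumption histidine would be unreachable for
  every organism, contradicting both the nutritional picture and the
  pathway-overview figure this matrix transcribes.
* **Citrulline hydrolase (EC:3.5.1.20).**  Biochemically demonstrated but
  without a known gene in any organism; shipped with an unknown-gene flag
  ("?" suffix) that removes it from genomic evaluation while keeping the
  step documented.
* **HisF cyclase / amidotransferase pair.**  Collapsed to a single reaction
  catalyzed by 4.1.3.-; both members are endosymbiont-exclusive in the
  data, so the collapse cannot change any verdict.
* **Threonine aldolase (EC:4.1.2.5)** is included as a full alternative
  route to threonine; organisms carrying it are threonine-autotrophic from
  glycine regardless of the aspartate chain.
* **Methionine and cysteine** have interconversion routes and a salvage
  cycle whose entry points are nutritional (serine, S-adenosyl-methionine)
  rather than strictly biosynthetic, so their verdicts are reported per
  entry metabolite: the de-novo pathway and the salvage cycle appear as
  separate columns (`methionine(met_cys)`, `methionine(met_salvage)`)
  instead of being merged into one flag.

## Shipped presence matrix

`data/presence_fig9.tsv` transcribes the compartment annotations of the
study's pathway figures and results text into an EC × organism 0/1 matrix
over five SHT/TPE pairs and two RT genomes.  Organisms of the same
compartment class share a profile except where the text distinguishes them
(e.g. ornithine decarboxylase present in *Angomonas* but not *Strigomonas*;
diaminopimelate epimerase and the eukaryotic ornithine carbamoyltransferase
in *H. muscarum* only; threonine aldolase in *C. acanthocephali* but not
*H. muscarum*).  It is a working transcription, not a deposited dataset.

## HGT classifier

Trees are treated as unrooted throughout; no outgroup or rooting rule is
assumed, and all answers are functions of the split set, so they are
invariant under re-rooting and Newick rotation (tested).  Missing edge
supports are treated as 0 for threshold purposes and reported as absent.

Given the query (trypanosomatid) leaves:

1. Test query monophyly (single-edge separability).  Non-monophyletic
   queries are split into maximal query-only clades, each classified
   separately; the overall call is undetermined unless the sub-calls agree.
   Genes with two orthologs of independent history are therefore analyzed
   as two query sets.
2. From the query edge, walk outward, at each node continuing along the
   edge toward the largest remaining subtree (ties broken by smallest leaf
   label).  Each crossed edge bounds a successively larger clade containing
   the query.
3. The decisive clade is the smallest enclosing clade whose edge support
   reaches `moderate_bsv` (default 50).  The decisive support is read on the
   enclosing-clade edge, matching how sister-group supports are quoted.
4. The non-query leaves of the decisive clade are tallied by taxonomy: if a
   fraction ≥ `donor_majority` (default 0.75) is bacterial the call is HGT,
   with the donor named when a single bacterial group reaches the same
   majority among bacterial leaves (ties and scattered compositions yield
   `mixed:<groups>`); a eukaryotic majority yields native; otherwise
   undetermined.
5. Support class: strong iff BSV ≥ 80, moderate iff 50 ≤ BSV < 80 (lower
   bound inclusive, upper exclusive, so the classes are disjoint and
   exhaustive); no decisive edge ⇒ unsupported ⇒ undetermined.

The `donor_majority` fraction is an explicit, reproducible surrogate for
the by-eye composition judgments such analyses traditionally make; it is
config-exposed, as are both BSV thresholds.

`data/gene_calls_39.tsv` applies this rule at the summary level: one row
per nuclear gene with the sister-group domain, donor group, and decisive
BSV as stated in the published results prose.  The file is a
**reconstruction** — the authoritative per-gene table is supplementary
material not redistributed here.  Rows whose support the text calls "low"
carry an empty BSV (trees in that study display only values ≥ 50);
BSV values not printed in the text (mostly native genes) are reconstructed
placeholders ≥ 50 flagged `bsv reconstructed`, which affect no call because
the affiliation rule only needs them to clear the moderate threshold.

## Screening

`filter_hits` applies, in order: e-value ≤ 1e-10; subject complete and
aligned over ≥ 75% of the query; cap at 10,000 best by e-value; best hit
per subject species; and, when more than 1,500 sequences remain, best per
genus.  Tie-breaking (e-value, then bitscore, then subject id) is fixed for
determinism, which also makes the operation idempotent.

The contamination gate scores four criteria: genomic context (a run of ≥ 3
same-strand neighbors and ≥ 50% of neighbors matching trypanosomatids),
coverage (≥ 0.75 × the genome's median per-gene coverage), GC (within 2 SD
of the genome mean), and phylogenetic congruence (query taxa monophyletic
in the gene's tree).  A gene is accepted when ≥ 2 criteria pass; an
unevaluable criterion counts as not passed.  The numeric thresholds are
declared surrogates for qualitative published criteria and are all
config-exposed (`GateThresholds`).

## Synthetic data

The gene-tree simulator builds a backbone with one firmly supported clade
per taxonomic group under a eukaryote and a bacterial stem.  A transfer is
implanted by growing the query clade inside the donor group's clade; the
edge enclosing the graft carries the configured decisive support, while
other internal edges draw from Uniform{60..100} (group-internal edges from
Uniform{90..100}).  Supports are simulated directly — tree inference and
bootstrap resampling are out of scope — so the simulator probes the
classification rule, not phylogenetic estimation: recovery statistics on
simulated trees say nothing about alignment quality, model misspecification,
or rogue taxa in real data.  Defaults: 4 query leaves and six background
groups of 5–7 leaves (~33 leaves), exponential branch lengths with mean
0.1.  Same seed ⇒ byte-identical Newick; topology, supports, and lengths
use separate random streams so one knob never perturbs another's draws.

The hit-table generator gives the first `n_good_species` species exactly
one hit passing every per-hit rule and makes all other hits fail one rule
(alternating insignificance, short alignment, incomplete subject), so the
filter's survivor count has an exact closed form.  The contig generator
draws legitimate genes to pass 3–4 gate criteria and contaminants to pass
at most one (a minority keep a typical GC), modeling the short, isolated,
low-coverage contigs contaminants occupy in draft assemblies.

## Numerical and interface notes

* The "patristic distance" summary quoted in percent for ortholog
  alignments is implemented as the gap-excluded pairwise p-distance
  (per-pair deletion); branch-length path distances cannot be percentages.
  The maximum/median are taken over all pairs, median of an even count
  being the mean of the central pair.  Pairs with no comparable columns
  are excluded with a warning.
* EC numbers are compared as trimmed strings; partial classes ("4.1.3.-")
  and subunit suffixes ("4.2.1.20a") are legal.
* Bootstrap values are integers in [0, 100]; values parsed from internal
  node labels outside that range are rejected.
* Problem sizes in the test suite (200 classifier replicates, 500
  round-trip trees, 500-gene gate mixtures, ≤ 6-reaction oracle graphs)
  were chosen so the full suite runs in seconds while the binomial noise
  on the 95% recovery bounds stays well below the margin the generator's
  construction guarantees.

## Known limitations

* Presence/absence of an EC says nothing about expression or activity;
  verdicts are genomic capability, not demonstrated flux.
* The union model ignores transport and compartment stoichiometry.
* The classifier is sister-group-based; it does not perform
  reconciliation against a species tree and cannot date transfers or
  distinguish a single ancient transfer followed by losses from repeated
  independent transfers.
* The shipped matrix and 39-gene table are transcriptions/reconstructions
  of published statements, with the reconstruction points flagged in the
  files themselves.
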