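# symtrophy

Tools for studying how an obligate bacterial endosymbiont completes the
essential amino acid metabolism of its trypanosomatid host, and how much of
the host's own contribution was acquired by horizontal gene transfer (HGT)
from bacteria.

Symbiont-harboring trypanosomatids (SHT; genera *Angomonas* and
*Strigomonas*) grow in defined media that starve their symbiont-free
relatives (RT), because each carries a single betaproteobacterial
endosymbiont (TPE, *Ca.* Kinetoplastibacterium spp.) whose reduced genome
retains the biosynthetic enzymes the host lacks.  `symtrophy` makes the two
computable claims behind that picture reproducible:

1. **Pathway complementation.**  Given an EC-number presence/absence matrix
   per genome and the amino acid pathways as reaction graphs, which amino
   acids can the host alone, the symbiont alone, or only the host+symbiont
   union synthesize?  A reaction fires when all substrates are available and
   any one of its catalyst ECs is encoded; reachability is the fixed point
   from the pathway's seed metabolites.
2. **HGT classification.**  Given a bootstrapped gene tree and a
   leaf-to-taxonomy map, is the trypanosomatid clade's smallest
   well-supported enclosing clade bacterial (HGT, with a named donor group),
   eukaryotic (native), or neither (undetermined)?  Support classes follow
   bootstrap conventions: strong for BSV ≥ 80, moderate for 50 ≤ BSV < 80.

Around these sit the screening steps any such analysis needs — homology-hit
filtering (significance, completeness, ≥ 75% query coverage, one sequence
per species or genus) and a 2-of-4 contamination-evidence gate (genomic
context, sequencing coverage, GC content, phylogenetic congruence) — plus a
synthetic-data module that generates ground-truthed gene trees, hit tables,
and contig evidence so the whole pipeline is testable without any downloads.

## Worked example

Which amino acids can *Angomonas deanei* make, and who contributes the
enzymes?

```python
from symtrophy import pathway_model as pm

pathways = pm.default_pathways()          # Figures' reaction graphs
genomes = pm.default_genomes()            # shipped EC presence matrix
by = {g.organism: g for g in genomes}

arg = next(p for p in pathways if p.id == "arg_orn")
v = pm.synthesis_verdict(arg, by["A_deanei"], by["K_crithidii"], "arginine")
print(v.producible_by)
print(sorted(v.used_reactions["host"]))
print(sorted(v.used_reactions["symbiont"]))
```

```
union_only
['arg11', 'arg13', 'arg14', 'arg15', 'arg5', 'arg7', 'arg8', 'arg9']
['arg1', 'arg12', 'arg2', 'arg3', 'arg4', 'arg5', 'arg6']
```

Arginine is a chimeric product: the symbiont supplies the glutamate route to
ornithine (`arg1`–`arg4`) and the ornithine carbamoyltransferase step
(`arg6`, EC:2.1.3.3), while the host nucleus encodes the deacetylase and the
citrulline→arginine arm (`arg7`–`arg9`) — so neither genome closes the urea
cycle alone (`union_only`).  The listing also attributes the polyamine
branch reactions that fire alongside (`arg11`–`arg15`).

The HGT side, from the shell:

```sh
symtrophy classify --affiliation-table builtin:39 --out out/
```

```
{"n_hgt": 18, "n_native": 18, "n_total": 39, "n_undetermined": 3, ...}
```

Of the 39 nuclear genes involved in essential amino acid biosynthesis, 18
classify as horizontally transferred from bacteria (Firmicutes,
Bacteroidetes, and Gammaproteobacteria each account for at least three),
18 as native eukaryotic genes, and 3 stay undetermined for lack of
bootstrap support.

Other subcommands: `pathways` (autotrophy table), `filter` (hit filtering),
`gate` (contamination gate), `simulate` (ground-truthed gene trees),
`report` (tally + autotrophy bundle).  All thresholds are exposed as flags;
the effective configuration is echoed into each output directory.

## Layout

- `src/symtrophy/pathway_model.py` — reaction graphs, reachability, verdicts
- `src/symtrophy/phylo.py` — Newick I/O, bipartitions, monophyly, p-distances
- `src/symtrophy/hgt_classify.py` — sister-group walk, support classes, tallies
- `src/symtrophy/screening.py` — hit filters and the contamination gate
- `src/symtrophy/synthetic_data.py` — ground-truthed generators
- `src/symtrophy/data/` — shipped pathway definitions, presence matrix, and
  the 39-gene affiliation table (a reconstruction from published results
  text; see `docs/methods.md`)

See `docs/methods.md` for the model, its assumptions, and its limitations.
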