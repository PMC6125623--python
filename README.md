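# gemcarve

Top-down reconstruction of genome-scale metabolic models. Starting from a
curated, simulation-ready **universal model**, gemcarve scores every
reaction with gene-homology evidence and *carves* an organism-specific
model with a MILP that maximizes evidence while enforcing network
connectivity (every retained reaction must carry flux in a single
steady-state certificate). On top of that it provides score-weighted
gap-filling against growth media, ensemble generation with phenotype
voting, microbial community merging with a shared extracellular pool, and
the usual simulation toolbox (FBA/FVA, phenotype arrays, gene
essentiality, confusion metrics).

Everything is testable offline: a fixtures module generates toy universes,
synthetic alignments and cross-feeding species pairs with known ground
truth.

## Library quick start

```python
from gemcarve import carve, fba, score_pipeline
from gemcarve.fixtures import make_toy6

universe, scores, media = make_toy6()
solution = carve(universe, scores)     # MILP subnetwork selection
model = solution.model                 # pruned organism model
print(fba(model, medium=media["A10"]).growth)
```

Key modules (under `src/gemcarve/`):

| module        | contents |
|---------------|----------|
| `core`        | `Model`/`Reaction`/`Metabolite`, GPR parsing (DNF), media, stoichiometric matrix |
| `io`          | SBML Level 3 + FBC v2, legacy COBRA-dialect SBML, native JSON dialect |
| `tables`      | TSV readers: media, thermodynamics, concentrations, biomass, constraints, gene scores |
| `curation`    | mass balance, ΔG-based reversibility, blocked/dead-end pruning, energy-cycle detection, biomass templates |
| `scoring`     | BLAST outfmt-6 parsing, GPR score algebra, median-1 normalization |
| `carving`     | the carve MILP, soft/hard constraints, model pruning |
| `gapfilling`  | score-weighted minimal extension per medium |
| `ensemble`    | randomized-weight ensembles, Jaccard distances, threshold voting |
| `community`   | model merging, minimal media, MIP (metabolic interaction potential) |
| `phenotyping` | FBA/FVA, phenotype arrays, free diffusion, essentiality, metrics |
| `fixtures`    | deterministic synthetic universes and alignments |

## CLI

```bash
# carve an organism model from a universe + evidence
gemcarve carve --universe universe.xml --alignment hits.tsv \
    --output organism.xml --dialect fbc2

# use precomputed gene scores, gap-fill against media, fixed seed
gemcarve carve --universe universe.xml --gene-scores genes.tsv \
    --media media.tsv --seed 1 --output organism.xml

# ensembles (writes the union SBML + a presence-matrix TSV)
gemcarve carve --universe universe.xml --gene-scores genes.tsv \
    --ensemble 50 --seed 7 --output ensemble.xml

# gap-fill an existing model
gemcarve gapfill --model organism.xml --universe universe.xml \
    --media media.tsv --output filled.xml

# merge species models into a community, report the MIP score
gemcarve merge sp1.xml sp2.xml --mip --output community.xml --json

# write synthetic fixtures
gemcarve fixtures --name toy6 --outdir fixtures/
```

Media, constraint and score tables are plain TSV; see
`src/gemcarve/tables.py` for the column contracts. Model files can be
SBML (FBC2 or legacy COBRA dialect) or the package's JSON dialect
(`--dialect json`), which serializes the in-memory model directly and is
the format of choice for hand-written test inputs.

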