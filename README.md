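# phyloscape

Continental-scale spatial phylogenetics for gridded species assemblages.

Herbarium-style point records tell us *where* species occur; a dated
phylogeny tells us *how much evolutionary history* they carry. `phyloscape`
combines the two: it aggregates occurrence records into grid-cell
assemblages, builds and dates supertrees from taxonomic backbones, and maps
where evolutionary history is concentrated, where it is geographically
restricted, and whether co-occurring species are more or less related than
chance expects. It is written for biogeographers and community
phylogeneticists analysing floras (or faunas) at regional to continental
extents.

## What it computes

For every grid cell with species set $C$ on a dated tree:

- **Species richness** $S = |C|$.
- **Faith's phylogenetic diversity**
  $\mathrm{PD} = \sum_{b \in T(C)} \ell_b$, the branch lengths of the
  minimal subtree $T(C)$ spanning $C$ (root path included by default).
- **Rosauer's phylogenetic endemism**
  $\mathrm{PE} = \sum_{b \in T(C)} \ell_b / R_b$, where the branch range
  $R_b$ counts the grid cells holding at least one descendant of $b$ —
  evolutionary history down-weighted by how widespread it is. Over all
  cells PE sums to the total tree length.
- **Weighted endemism** $\mathrm{WE} = \sum_{s \in C} 1/r_s$ with $r_s$ the
  number of cells occupied by species $s$.
- **Phylogenetic structure**: mean pairwise patristic distance (MPD) and
  mean nearest-taxon distance (MNTD), standardized against a
  richness-preserving null model into the net relatedness index
  $\mathrm{NRI} = -(\mathrm{MPD}_{obs} - \overline{\mathrm{MPD}}_{null}) /
  \mathrm{sd}(\mathrm{MPD}_{null})$ and the analogous NTI. Null
  assemblages are uniform $S$-subsets of a species pool — either
  *continental* (all analyzed species) or *regional* (species of the
  cell's region) — drawn without re-using a combination, with a default
  budget of 4999 draws, optional early stopping, and one shared null per
  (pool, richness) class. Positive NRI means phylogenetic clustering,
  negative means evenness (overdispersion).

Tree preparation follows the classic supertree workflow: species are
grafted onto a genus/family-labelled backbone (genera assumed
monophyletic), and node ages are interpolated from a landmark table of
crown ages, evenly spacing undated nodes between dated ones to produce an
ultrametric tree.

A synthetic-landscape generator (`phyloscape.simulate`) produces ultrametric
trees, niche optima evolved with tunable phylogenetic signal along two
orthogonal environmental gradients, and occurrence tables under contrasting
assembly scenarios (environmental filtering, distant-lineage refugia,
neutral), so the entire pipeline is testable with no external data.

## Worked example

```python
import phyloscape as ps

# a 12 x 12 landscape of 10 km cells, 120 species, with a refugial block
# holding distantly related lineages
cfg = ps.ScenarioConfig(n_species=120, n_cells_x=12, n_cells_y=12,
                        refugia=[(1, 4, 8, 11)], seed=42)
tree, optima, occ = ps.simulate_scenario(cfg, "refugia")

grid = ps.filter_min_richness(ps.grid_occurrences(occ, cfg.cell_size), 5)
model = ps.PhyloStructureModel(grid, tree, ps.NullModelConfig(max_iter=999, seed=0))
res = model.fit()
print(res.summary())
```

```
Phylogenetic structure analysis
==============================================
cells: 144   species: 120   pool: continental
null draws: max 999, window 100, mode literal
----------------------------------------------
    S: median    29.0000   range [6.0000, 65.0000]
   PD: median  1046.7605   range [386.7477, 1559.7578]
   PE: median    15.3801   range [4.7018, 38.7700]
   WE: median     0.8000   range [0.1500, 1.6250]
  MPD: median   146.6716   range [123.8848, 158.8879]
 MNTD: median    39.4325   range [22.7409, 110.6159]
  NRI: median     0.0128   range [-1.1745, 3.2555]
  NTI: median     0.7526   range [-3.4288, 2.5632]
----------------------------------------------
           neutral: 109
    clustered_weak: 19
         even_weak: 12
     clustered_sig: 4
----------------------------------------------
null stop reasons: max_iterations=50
richness-PD Pearson r = 0.960
```

Reading the output: richness and PD are tightly correlated (r = 0.96), PE
ranges almost tenfold across cells (the refugial block concentrates
restricted branch length), and most cells are neutral while the refugial
cells fall on the evenness side (negative NRI) — co-occurring lineages
there are *less* related than random draws from the continental pool.
`res.cell_metrics` holds the full per-cell table and `res.null_audit` the
per-richness-class null distributions (draw counts, moments, stop reasons).

The same pipeline runs from the shell on delimited text files:

```bash
phyloscape simulate --out fixture --scenario refugia --seed 7
phyloscape grid     --occurrences fixture/occurrences.csv --cell-size 10000 --out grid.csv
phyloscape nri      --grid grid.csv --tree fixture/tree.nwk --out nri.csv --seed 3
phyloscape sorensen --grid grid.csv --out sorensen.csv
```

plus `graft` (attach species to a labelled backbone), `date` (landmark age
interpolation) and `metrics` (diversity metrics without null models). Each
command writes a `.manifest.json` recording arguments, seed and stop
reasons; identical seed and config reproduce outputs byte for byte.

## Layout

| module | contents |
| --- | --- |
| `phyloscape.tree` | Newick I/O, pruning, patristic matrices |
| `phyloscape.grafting` | taxonomy tables, genus/family grafting |
| `phyloscape.dating` | landmark (bladj-style) age interpolation |
| `phyloscape.gridding` | occurrence binning, aggregation, regional pools |
| `phyloscape.metrics` | PD, PE, WE, MPD, MNTD, Sorensen dissimilarity |
| `phyloscape.null_models` | null draws, convergence, NRI/NTI, classes |
| `phyloscape.simulate` | synthetic trees, niches, assembly scenarios |
| `phyloscape.model` | `PhyloStructureModel` / `...Results` facade |
| `phyloscape.cli` | `phyloscape` command-line pipeline |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
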