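# Methods

This note records the modelling choices behind `phyloscape`: the indices and
their conventions, the null model, the landmark dating rule, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would otherwise have to reverse-engineer.

## Gridding

Occurrence records (species, x, y in a projected planar CRS, meters) are
binned into half-open square cells: a point at $(x, y)$ falls in cell
$(\lfloor (x-x_0)/s \rfloor, \lfloor (y-y_0)/s \rfloor)$ for cell size $s$
and origin $(x_0, y_0)$ (default origin (0, 0); grids are alignment-free
otherwise). Presence is binary; duplicates collapse. Records with
non-finite coordinates are dropped and counted, never silently ignored.
Re-aggregation by an integer factor unions the species sets of child cells
(the usual 10 km → 50 km workflow is `aggregate_cells(grid, 5)`).

Retention uses a *strict* threshold: `filter_min_richness(grid, 5)` keeps
cells with **more than** 5 species. This mirrors the common practice of
dropping sparse cells so isolated records in marginal habitat do not
populate the map; raising the threshold disproportionately removes
species-poor temperate cells, so 5 is the default, not higher.

Region labels belong to cells, not species: a species occurring in two
regions is a member of both regional pools. When records carry region
labels, a cell takes the majority label of its records; aggregated cells
take the majority label of their children. Ties break to the
lexicographically smallest label — an arbitrary but deterministic rule.

Geographic-to-projected coordinate transformation is deliberately out of
scope; square-kilometre cells presuppose a metric projection, and choosing
one is a pre-processing decision.

## Supertree preparation

**Grafting.** Species absent from a backbone tree are attached as new tips
under the internal node labelled with their genus, falling back to their
family node, assuming genus monophyly. Multiple attachments at one node
form polytomies. Species with neither node present are reported as
unplaced and skipped with a warning — grafting is an incremental curation
workflow and should not hard-fail midway. Only internal node labels are
valid graft points; a genus appearing only as a tip cannot receive
children without silently changing the backbone's tip set. Grafted tips
carry no branch length until dating; undated trees are rejected by the
metrics layer, because approximate branch lengths carry real signal that
topology-only (all-equal) lengths would discard.

**Landmark dating.** An age table fixes crown ages (Myr) for labelled
clades; the root must be fixed and tips are implicitly age 0. Dated nodes
are processed oldest first. For a dated node of age $t_A$ whose descendant
chain ends at a dated anchor of age $t_D$ with $m$ undated nodes between,
the $k$-th intervening node receives $t_A - k\,(t_A - t_D)/(m+1)$ — even
spacing. Once dated, a node is never revised; newly dated nodes anchor
their own side branches in turn. Branch lengths are recomputed as age
differences, so the output is exactly ultrametric.

One choice was genuinely open: which dated node below a chain serves as its
lower anchor. Taking the *nearest* dated descendant can date a node younger
than an older landmark on a side branch, which produces negative branch
lengths (we observed this on random topologies). `phyloscape` instead
anchors each chain on the **oldest** dated node in the subtree (ties →
fewest intervening edges, then label). Because every node interpolated on
the chain is then older than every dated node beneath it, age monotonicity
— hence non-negative branch lengths — is guaranteed, while the even-spacing
formula and oldest-first, never-revise processing are unchanged. Fully
landmarked trees and simple chains are unaffected by this choice.

## Diversity indices

* **PD** is root-inclusive by default: the spanning subtree includes the
  path from the species set's MRCA to the root, which makes single-species
  PD well defined (the tip-to-root path) and matches the convention of the
  standard community-phylogenetics tools (verified against picante's
  `pd(..., include.root = TRUE)` in the test suite). An
  `include_root=False` flag drops the shared root path.
* **PE** uses the same spanning-subtree convention, dividing each branch
  length by its range $R_b$ (cells with ≥ 1 descendant). Ranges are
  computed *relative to the analyzed grid only* — no correction for
  distribution outside the study extent, so PE is endemism within the
  analysis window by construction. With every branch occupied somewhere,
  $\sum_{cells} \mathrm{PE}$ equals the total tree length exactly; this
  conservation identity is a standing test.
* **WE** is the species-level analogue; $\sum_{cells} \mathrm{WE}$ equals
  the species count.
* **MPD / MNTD** use presence-weighted (unweighted) distinct pairs — grid
  presences carry no abundances. Cells with one species get PD/PE/WE but
  *missing* (not zero) MPD/MNTD/NRI/NTI; the default richness filter
  removes such cells anyway.
* **Sorensen dissimilarity** between regional floras,
  $1 - 2|A \cap B|/(|A|+|B|)$, supports region-level comparison and
  ordination done elsewhere.

## Null model and standardization

Null assemblages preserve cell richness $S$ and draw uniformly from the
species pool — continental (all species on the analyzed grid) or regional
(species in cells of the cell's region). One null distribution is computed
per (pool, richness) class and shared by all matching cells; MPD and MNTD
are scored on the same draw sequence so both indices are audited together.

Draws never re-use a combination: when $\binom{N}{S}$ fits inside the
iteration budget the full combination set is enumerated and shuffled
(stop reason `combinations_exhausted`); otherwise subsets are
rejection-sampled against a canonical-key hash set (memory-capped at
5 × 10⁶ keys with an explicit error). Defaults: 4999 draws, early stopping
considered only after 500 draws over a window of the last 100 scores.

The window criterion ships in two modes. The **literal** rule — stop when
min/max of the window is below 0.005 — is the rule as usually printed, but
for positive scores of similar magnitude the ratio sits near 1 and the rule
effectively never fires; it is nonetheless the default, implemented
faithfully rather than silently "corrected". The **relative_range** mode
reads the same numbers as a stability test (1 − min/max < 0.005) and does
fire when the window is flat. The mode used is recorded in the run
manifest; we never substitute one for the other.

Standardization uses the sample (n−1) SD:
$\mathrm{NRI} = -(\mathrm{MPD}_{obs} - \mu_{null})/\sigma_{null}$, so
clustering is positive. When $\sigma_{null} = 0$ (e.g. a cell holding the
whole pool, a single possible draw) the score is undefined: the cell is
flagged `neutral_degenerate` rather than divided by zero. Classification
uses two configurable thresholds, weak = 1.0 and significant = 1.96 |z|;
the source analyses do not print their cutoffs, so these conventional
normal quantiles are defaults, not claims. No multiple-testing correction
is applied across cells (deliberately, matching standard practice for
these maps).

Per-class RNG streams derive from the master seed via
`numpy.random.SeedSequence([seed, pool_index, S])`, so results are
independent of cell iteration order and bit-reproducible; identical seed
and config give byte-identical output tables.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes:

* **Tree** — pure-birth (Yule), rescaled to root age 100; the simulator's
  clock is run one further exponential waiting interval past the last
  speciation so no terminal branch has zero length. Extinction is omitted:
  it changes tree shape but adds nothing to what the pipeline tests.
* **Gradients** — moisture rising along x, temperature along y, both
  linear on [0, 1]: the two orthogonal continental axes (wet–dry,
  tropical–temperate) reduced to their simplest form.
* **Niches** — per-species optima are a mixture
  `signal · BM + (1 − signal) · iid uniform`, with the Brownian component
  rescaled to [0, 1]; signal 0 severs trait–phylogeny association, signal 1
  is pure conservatism.
* **Scenarios** —
  `filtering`: a species occupies cells within a tolerance of its optima
  on both axes (default tolerance 0.16, set so that median cell richness
  ≈ 20 at the default 20 × 20 grid with 200 species — large enough for
  stable pairwise metrics, small enough for fast nulls);
  `neutral`: each species occupies 40 cells uniformly at random — by
  species exchangeability, cell composition given richness is a uniform
  pool draw, which is what makes this scenario a calibration standard;
  `refugia`: background species occupy contiguous ranges (the 40 cells
  nearest a random centre) that exclude the refugial blocks, while the
  `refugium_lineage_count` (default 12) most distant lineages (greedy
  max–min on patristic distance) live only in those blocks. Refugia are
  thus floristically distinct islands holding distant-lineage mixtures —
  the configuration that produces evenness, concentrated PE, and regional
  pools that genuinely differ from the continental one.
* **Regions** — axis-aligned blocks covering the grid exactly once
  (default: west/east halves). All randomness flows from one master seed
  through named `SeedSequence` streams.

What the generator does **not** emulate: real geography and coastlines,
spatially autocorrelated sampling effort, taxonomic error, non-monophyletic
genera, abundance structure, or range sizes spanning orders of magnitude.
Passing tests therefore demonstrate that the pipeline's mathematics and
statistics behave as specified under controlled conditions — not that any
particular empirical map is correct.

Two behaviours of the refugia scenario are worth knowing. First, the
strength of refugial evenness varies with tree shape across seeds (Yule
trees concentrate divergences near the root, so "maximally distant" is only
moderately more distant than average); conclusions should average over
replicate landscapes, as the acceptance script does. Second, regional-pool
attenuation of the refugial signal — the analogue of an isolated region's
evenness weakening under its own pool — emerges only when regional floras
genuinely differ; on small grids where typical ranges span most of the
landscape, regional and continental pools nearly coincide and the contrast
disappears into noise.

## Problem sizes used in tests

Unit tests run on hand-checkable 3-tip examples and random trees of 4–15
tips against brute-force enumeration oracles (explicit path sums, edge-wise
subtree membership, full combination enumeration). Statistical checks use a
20 × 20 / 200-species neutral landscape (400 cells, 999 draws per richness
class) for calibration, twenty replicate 12 × 12 / 120-species landscapes
for scenario recovery, and six replicate default-size landscapes for
regional-pool attenuation — sizes chosen as the smallest at which the
respective effects are stably measurable. An R cross-check validates
patristic distances, PD and MPD against ape/picante on a 12-tip tree.

## Known limitations

* Grafting requires a single genus and family per species; reconciling
  conflicting source taxonomies is upstream curation, not handled here.
* The landmark set must be age-consistent (each landmark younger than its
  nearest landmark ancestor); inconsistent tables are rejected, not
  repaired.
* PE offers no cross-boundary range correction: endemism is relative to
  the analysis extent by design.
* The null model is the uniform richness-preserving draw only; swap-based
  and frequency-weighted nulls are out of scope.
* NTI is computed and reported but the classification column follows NRI,
  matching the emphasis on deep phylogenetic structure.
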