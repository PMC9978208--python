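# Methods

## Protocol overview

The package biases template-based structure prediction toward a requested
conformational state by controlling the two inputs a template-aware
predictor sees: which template structures it is given, and how much
evolutionary signal survives in the MSA. Per model, a *recipe* combines one
MSA variant with one template set and a derived seed; an ensemble is a list
of recipes dispatched to a predictor behind a uniform contract
(`(query, msa, templates, recycles, seed) → (coords, pLDDT, pTM)`).

## Template selection

Templates are `TemplateRecord`s: a PDB chain with either a GPCR activation
state (`Active`, `Inactive`, `Intermediate`, `G protein`, `Arrestin`) or a
KLIFS-style kinase feature block (`dfg` ∈ {in, out, out-like}, `ac_helix` ∈
{in, out}, `salt_bridge` ∈ {yes, no}, `a_loop` ∈ {in, out}), plus the
template-search `rank_score` and percent `seq_identity`. Filtering rules:

- GPCR mode keeps records whose state matches the query; a query for
  `Active` additionally accepts `G protein` and `Arrestin` complexes
  (configurable, on by default), since transducer-bound receptors are in
  active-like conformations.
- Kinase mode conjoins the three feature criteria; `all` disables one.
- Same-subfamily templates are excluded by default in GPCR mode (to avoid
  templating a receptor on its own close homolog's known structure) and
  kept in kinase mode.
- Optional floors on `rank_score` and `seq_identity` (both default 0)
  expose the "sequence similarity filter" of the randomized-pool protocol
  without guessing an undocumented cutoff.

Selection is top-k in rank order — ranking preserves the upstream template
search's order via `rank_score` rather than re-sorting by raw identity,
because published top-4 lists are not monotonic in identity; ties break by
`(pdb_id, chain_id)` for determinism — or a uniform random draw of k
survivors per model. Randomized draws use a counter-based seed
`(query.seed, draw_index)` so each model's draw is independent and
reproducible in any order.

Defaults (resolved configuration, GPCR mode): k = 4 templates, 8 cluster +
16 extra MSA rows, 50 models, 0 recycles, subfamily exclusion on. Kinase
mode: k = 20, subfamily exclusion off. The earlier template-free variant of
the protocol (16 cluster + 32 extra rows, no templates) is expressible
through the same configuration surface.

## MSA interventions

A3M rows are kept verbatim (uppercase/`-` = match columns, lowercase =
insertions); all operations preserve the query row exactly.

- **Shallow subsampling**: uniform random choice of `n_clusters` rows
  (query forced first) and `n_extra` disjoint rows from the remainder. No
  k-means-style clustering is attempted: the two counts handed to the
  predictor are the contract, the draw is seeded. The "extra" block is
  returned unanchored (it does not contain the query), so the two blocks
  are disjoint.
- **noMSA**: every non-query row receives gap characters at the match
  columns covered by at least one selected template's footprint (the set of
  query positions the template models); other columns are untouched. The
  operation is idempotent.
- **SPEACH-style masking**: one alignment variant per placement of a masked
  window of `w` consecutive match columns (default w = 10). The stride
  defaults to w (non-overlapping windows) with the final window
  right-aligned so the union of windows covers every column; the stride is
  exposed for overlapping sweeps. Masking uses gap characters; a predictor
  adapter may re-encode masked columns as unknown-residue tokens if its
  input format prefers that.

Inside `run_ensemble`, exactly `n_models` recipes are dispatched in every
mode; SPEACH mode cycles the window variants over model indices, so a full
sweep is obtained by setting `n_models` to (a multiple of) the variant
count.

## The mock predictor

The packaged predictor is a deterministic geometric consensus builder, not
a neural network. It exists to make the selection/evaluation logic testable
offline, under the premise the protocol rests on: the predicted ensemble
follows the conformation of the supplied templates.

1. Template chains are loaded (Cα only) and mutually superposed onto the
   first template over shared residue numbers (closed-form Kabsch).
2. Each query residue covered by ≥1 template gets the mean of the aligned
   template coordinates; the per-residue spread sd_i (root-mean-square
   deviation of contributors from the mean) is recorded.
3. Seeded Gaussian noise of σ Å (default 0.5) is added to all coordinates.
4. Uncovered stretches are extended as an ideal α-helix (1.5 Å rise,
   100°/residue) continuing from the nearest modelled flank — a neutral,
   finite placeholder, flagged by low confidence.
5. Confidence: pLDDT_i = 100·exp(−sd_i / 2 Å) on covered residues, 30 on
   uncovered ones; pTM is the mean of the same agreement term (0.3 where
   uncovered), clipped to [0, 1]. Both are monotone in inter-template
   agreement; the exponential form and the 2 Å scale are package choices,
   not calibrated probabilities.

Residue matching throughout (mock predictor and metrics) is by residue
number; fixtures and templates share query numbering, which makes the
mapping exact. Unmatched residues are excluded and counted. A real
predictor adapter registers under `register_predictor` and receives the
same recipes.

## Unfolded-model filter

"Unfolded" is operationalized (no published criterion exists) as mean
pLDDT < 40 or radius of gyration > 2.5 × the globular expectation
Rg ≈ 2.2·N^0.38 Å. Both thresholds are configuration. A fully extended
chain (Rg = d·√((N²−1)/12) with d = 3.8 Å) exceeds the ceiling for any
realistic N, while rigid toy bundles pass with a wide margin. Failed or
discarded models stay in the run manifest with a status, never silently
dropped.

## Evaluation metrics

- **Kabsch superposition**: closed-form SVD solution with the determinant
  correction guaranteeing a proper rotation; inputs with fewer than 3
  common residues or collinear selections (second singular value ≤ 1e-8 of
  the first) are rejected.
- **TM-RMSD**: superpose on the union of `TM*` segments, score there. Loop
  residues are scored **in the TM frame** by default — the loop number then
  measures loop placement relative to the helical bundle rather than
  internal loop geometry; `loop_frame="independent"` gives the alternative.
  Global RMSD superposes on all matched residues.
- **pTM–RMSD correlation**: Spearman rank correlation with average-rank
  ties (scipy); fewer than 3 finite pairs is an error, zero variance yields
  NaN flagged with a warning, never 0.
- **Kinase classification**: a model is superposed on the kinase *core*
  (all residues outside the DFG/ac_helix/a_loop motifs) onto each labelled
  exemplar of a reference library; each feature takes the label of the
  exemplar with the smallest motif Cα-RMSD (a_loop uses DFG + a_loop
  residues). The margin (gap to the nearest differently-labelled exemplar)
  is reported; exact ties go to the lower-index exemplar with a warning.
  This classifier is a documented stand-in: labels for *predicted* models
  are not provided by the annotation databases, which label experimental
  structures only.

## Synthetic fixtures

- **Toy GPCR**: seven ideal α-helices (2.3 Å radius, 1.5 Å rise,
  100°/residue) standing antiparallel on a 14 Å circle, joined by straight
  4-residue connectors; 205 residues by default. "Activation" is a rigid
  radial displacement of TM6 (default 4 Å), so the no-fit RMSD over TM6
  between the two states equals the displacement exactly — the ground
  truth every metric test is anchored to.
- **Toy kinase**: a 98-residue two-helix core with an aC-helix (14
  residues), DFG (3) and activation loop (11). The DFG flip relocates DFG +
  a_loop rigidly by 6 Å; the aC-helix shift is 5 Å; all four (a_loop, ac_H)
  combinations are generated.
- **Annotation fixtures**: template chains are per-record noisy copies
  (σ = 0.3 Å) of the matching state's conformer, with reproducible rank
  scores and identities; benchmark fixtures reproduce published top-4
  template lists (ids, chains, identities, rank order) with synthetic toy
  coordinates standing in for the real chains. A 12-template GPCR pool per
  state and a 12-chain kinase pool spanning all feature combinations are
  the default study conditions; toy MSAs use 64 rows (GPCR) / 32 rows
  (kinase) at 50% identity.

What the fixtures deliberately lack: side chains, realistic loop
geometry, sequence–structure coupling, template gaps/insertions, and any
learned component in the predictor. Passing tests therefore demonstrate
that the *protocol logic* — filtering, randomization, MSA bookkeeping,
superposition, classification, seeding — is correct and that template
choice controls the mock ensemble's conformation; they do not measure how
strongly a real network's predictions can be steered, which requires GPU
inference on real targets and is outside this package's scope.

## Problem sizes and numerical choices

Tests and the acceptance script run ensembles of 20–50 models over the
205-residue toy receptor and 98-residue toy kinase; selection-uniformity
checks use 10,000 seeded draws against the exact uniform law (chi-square,
p > 0.01), and the Kabsch implementation is verified against a rotation-
grid + simplex brute-force oracle to 1e-3 Å and against an independent
Wahba solver to 1e-9 Å. All seeds are derived with `numpy` `SeedSequence`
from `(run_seed, model_index)` counters and kept below 2^31. PDB output
carries 3-decimal coordinates, so file round-trips are exact only to
~5·10⁻⁴ Å; tests compare at 1e-3 Å where files are involved.

## Known limitations

- The remote GPCRdb/KLIFS clients map a minimal subset of the public
  schemas onto `TemplateRecord` and document their own state mapping
  (e.g. which payload fields produce `Intermediate` or complex states);
  they are exercised only through injected transports.
- Loop RMSD in the TM frame and the nearest-exemplar kinase classifier are
  reasonable but not unique conventions; both are switchable/replaceable.
- The mock predictor ignores MSA *content* (only its provenance and counts
  flow into recipes); consequences of MSA weakening on a learned predictor
  cannot be observed at mock scale.
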