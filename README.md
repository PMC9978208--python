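# statebias

Conformational-state-biased template selection, MSA manipulation and
ensemble evaluation for protein structure prediction.

## The problem

Template-based predictors such as AlphaFold2 typically return one
conformation per target — usually the one best supported by the
evolutionary signal in the MSA — even when the biology of interest lives in
another state. G-protein-coupled receptors (GPCRs) switch between inactive
and active conformations (the hallmark being an outward swing of
transmembrane helix 6), and protein kinases toggle their DFG motif,
activation loop (a_loop) and aC-helix (ac_H) between "in" and "out"
arrangements. Structural biologists and drug designers often need models of
a *specific* state: the active receptor for agonist design, the DFG-out
kinase for type-II inhibitors.

`statebias` implements a protocol for steering an ensemble of predicted
models toward a user-defined state:

1. **Annotation-driven template filtering** — templates are drawn from an
   annotated store (GPCRdb-style activation states `Active`, `Inactive`,
   `Intermediate`, `G protein`, `Arrestin`; KLIFS-style kinase features
   `DFG`, `ac_helix`, `salt_bridge` with values `in`/`out`/`out-like`/`all`)
   and filtered to those matching the query. A request for `Active` also
   accepts transducer-bound complexes; same-subfamily templates can be
   excluded to avoid self-templating.
2. **Ranking and selection** — the top *k* survivors by the upstream
   template-search rank (k = 4 for GPCRs, 20 for kinases by default), or a
   *randomized* uniform draw of *k* survivors per model to widen the sampled
   structural space.
3. **MSA weakening** — the alignment is thinned so templates can win:
   shallow subsampling (8 cluster + 16 extra sequences by default), removal
   of all non-query rows over template-covered columns (noMSA), or
   SPEACH-style sliding-window masking (window of 10 columns).
4. **Ensemble generation** — per-model recipes (MSA variant × template set
   × seeds) are dispatched to a pluggable predictor. The packaged predictor
   is a deterministic mock that builds each model as the superposed
   per-residue consensus of its templates plus seeded noise; a real
   AlphaFold2/ColabFold adapter can be registered behind the same contract.
5. **Filtering and evaluation** — unfolded models (low mean pLDDT or radius
   of gyration far above the globular expectation Rg ≈ 2.2·N^0.38 Å) are
   discarded; ensembles are scored as Cα TM-RMSD (RMSD over the
   transmembrane helices after Kabsch superposition on those helices), loop
   RMSD in the TM frame, global RMSD, Spearman correlation between pTM and
   RMSD, and — for kinases — nearest-exemplar classification of the
   a_loop/ac_H conformation.

Everything runs offline: a synthetic fixture generator produces annotated
template pools, toy GPCR/kinase conformer pairs with exactly known state
displacements, segment maps and toy A3M alignments.

## Worked example

`examples/03_biased_ensembles.py` builds a 24-template annotated pool over
a toy seven-helix receptor whose active and inactive reference conformers
differ by a rigid 4 Å outward displacement of TM6, then generates one
ensemble biased toward each state and scores both against the *active*
reference:

```
query state=Active  : 20 models kept, median TM-RMSD to Active ref = 0.90 A, best = 0.84 A (model 4)
query state=Inactive: 20 models kept, median TM-RMSD to Active ref = 1.66 A, best = 1.60 A (model 9)
```

The Active-biased ensemble sits ~0.8 Å closer to the active reference than
the Inactive-biased one — the selected templates, not the MSA, decide which
conformation the ensemble occupies. `examples/05_kinase_features.py` shows
the kinase analogue:

```
templates DFG=all/ac_H=all -> a_loop=in/ac_H=in: 3, a_loop=in/ac_H=out: 12, a_loop=out/ac_H=in: 3, a_loop=out/ac_H=out: 2
templates DFG=in /ac_H=in  -> a_loop=in/ac_H=in: 20
templates DFG=in /ac_H=out -> a_loop=in/ac_H=out: 20
templates DFG=out/ac_H=all -> a_loop=out/ac_H=in: 6, a_loop=out/ac_H=out: 14
```

DFG=in template pools yield only a_loop=in models, while the DFG=out pool
enriches a_loop=out — the ensemble inherits the structural features of its
templates.

The same pipeline is scriptable from the shell:

```bash
statebias fixtures --out fx --n-active 12 --n-inactive 12 --seed 1
statebias run --query-fasta fx/query.a3m --msa fx/query.a3m \
    --annotations fx/annotations.tsv --mode gpcr --state Active \
    --num-models 20 --seed 1 --out run_active
statebias evaluate --reference fx/state_A.pdb --segments fx/segments.json \
    --models run_active --out eval_active
```

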