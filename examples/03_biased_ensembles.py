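"""End-to-end state biasing: Active vs Inactive GPCR ensembles.

Generates two 20-model ensembles with the mock (template-consensus)
predictor, one biased toward each activation state, and scores both against
the Active reference conformer. The state the templates carry should pull
the ensemble toward the matching reference.
"""

import tempfile
from pathlib import Path

import statebias as sb

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp)
    tsv = sb.make_annotation_fixture(out, n_active=12, n_inactive=12, seed=1)
    records = sb.load_annotations(sb.AnnotationSource("fixture", str(tsv)))
    active_ref = sb.read_structure(out / "state_A.pdb")
    segments = sb.SegmentMap.from_json(out / "segments.json")
    seq = records[0].sequence
    msa = sb.make_toy_msa(len(seq), depth=64, seed=1)

    for state in ("Active", "Inactive"):
        cfg = sb.resolve_config(
            {"gpcr_state": state, "num_models": 20, "seed": 1}, mode="gpcr"
        )
        models, _ = sb.run_ensemble(seq, msa, records, cfg)
        survivors = sb.discard_unfolded(models, cfg.plddt_floor, cfg.rg_ceiling)
        table, best = sb.ensemble_summary(survivors, active_ref, segments)
        print(f"query state={state:8s}: {len(survivors)} models kept, "
              f"median TM-RMSD to Active ref = {table['tm_rmsd'].median():.2f} A, "
              f"best = {table['tm_rmsd'].min():.2f} A (model {best})")

# The Active-biased ensemble sits closer to the Active reference than the
# Inactive-biased one; the gap between the two medians is the bias signal
# (the references themselves differ by a 4 A rigid TM6 displacement).
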