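"""The three MSA interventions: shallow subsampling, noMSA, SPEACH masking.

Each weakens the evolutionary signal in a different way so that templates
can steer the prediction: fewer rows (shallow), gaps over template-covered
columns (noMSA), or a sliding masked window (SPEACH-style variants).
"""

import statebias as sb

msa = sb.make_toy_msa(query_length=60, depth=200, seed=0)
print(f"raw MSA: {msa.depth} rows x {msa.query_length} columns")

clusters, extras = sb.subsample(msa, sb.SubsampleSpec(n_clusters=8, n_extra=16,
                                                      seed=0))
print(f"shallow subsample: {clusters.depth} cluster rows (query first) "
      f"+ {extras.depth} extra rows")

nomsa = sb.remove_msa_over_templates(msa, covered_columns=range(10, 41))
gapped = sum(row[9:40].count("-") for row in nomsa.rows[1:])
print(f"noMSA over columns 10-40: {gapped} cells gapped, query untouched")

variants = sb.speach_mask_variants(msa, window=10)
starts = [v.params["start"] for v in variants]
print(f"SPEACH window=10: {len(variants)} variants, windows start at {starts}")

# The counts (8+16 rows, window of 10) are the shallow-MSA settings the
# ensemble driver uses by default; every variant keeps the query row intact.
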