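"""Refine a marker set for an unusual lineage and derive auxiliary markers.

Markers that are rare and phylogenetically clustered mislead completeness
estimates; they are detected against the genome tree and excluded.
Auxiliary single-copy markers are then derived by comparing each
candidate's single-copy occurrence count with the count predicted from
genome quality.
"""

from phylocurate import (
    GenomeQuality, derive_auxiliary_markers, exclude_constrained_markers,
)
from phylocurate.synthetic import simulate_marker_matrix

matrix, tree, truth = simulate_marker_matrix(
    n_genomes=60, n_markers=200, frac_single_copy=0.5,
    clade_restricted_frac=0.25, seed=11)

excluded = exclude_constrained_markers(matrix, tree,
                                       freq_threshold=0.10, dist_quantile=0.25)
planted_clade = set(truth.params["clade_restricted_markers"])
print(f"{len(excluded)} markers excluded as phylogenetically constrained; "
      f"{len(set(excluded) & planted_clade)} of them are planted "
      f"clade-restricted markers (of {len(planted_clade)})")

qualities = {g: GenomeQuality(g, c, truth.params["contamination"][g])
             for g, c in truth.params["completeness"].items()}
derived = derive_auxiliary_markers(matrix, qualities)
planted_single = set(truth.params["single_copy_markers"])
tp = len(set(derived) & planted_single)
print(f"{len(derived)} auxiliary single-copy markers derived; "
      f"{tp}/{len(planted_single)} planted single-copy markers recovered, "
      f"{len(derived) - tp} false positives")

# A marker is accepted when its observed single-copy count across genomes
# sits inside the 95% band around the sum of per-genome
# (completeness - contamination) — multi-copy and clade-restricted markers
# fall far outside that band.
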