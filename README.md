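# phylocurate

Curation toolkit for candidate bacterial phyla known only from draft
genomes (MAGs and SAGs).  When a lineage has never been cultivated, every
step of describing it — deciding which genomes are good, how many species
they represent, what to call them, how big their cells are and whether they
are active in situ — rests on a handful of quantitative procedures.
`phylocurate` implements those procedures as a tested, importable library:

* **Genome quality** — completeness/contamination from single-copy marker
  copy counts; detection of phylogenetically constrained markers that
  depress completeness of unusual lineages; derivation of auxiliary
  lineage-specific single-copy markers; MIMAG-style quality tiers;
  giant-ORF (> 20 kb) flagging.
* **Genome size** — `Size_est = (Size_obs − Size_obs × contamination) /
  completeness`, quantile placement against a reference collection, and
  ANOVA + Tukey HSD group comparison.
* **Species delineation** — single-linkage clustering at 95% average
  nucleotide identity (ANI), representative selection, a desk-scale
  fragment-based ANI, and FastANI table ingestion.
* **Rank consistency** — reciprocal-best-hit average amino acid identity
  (AAI) between proteomes and intra- vs inter-genus consistency audits.
* **Nomenclature** — screening proposed taxon names against large catalogs
  by exact match and bounded Damerau-Levenshtein distance (D ≤ 2), with two
  sound prefilters and a band-limited dynamic program.
* **Ecology** — cell-size intervals from serial-filtration retention
  patterns, filter-fraction abundance shifts, and quantitative
  stable-isotope probing (qSIP) statistics: atom-fraction-excess (AFE)
  utilization calls and predator-vs-community percent differences.
* **Synthetic data** — seeded generators that plant ground truth for every
  stage (marker matrices, ANI blocks, ortholog proteomes, name catalogs,
  filtration patterns, AFE tables), so the whole pipeline is testable
  without external downloads.

## Worked example

```python
import pandas as pd
from phylocurate import (MarkerSet, recompute_quality, assign_quality_tier,
                         estimate_genome_size, single_linkage_species,
                         screen_names, NameCatalog)
from phylocurate.synthetic import simulate_marker_matrix, simulate_ani_matrix

# genome quality from a marker copy-count matrix (genomes x markers)
matrix, tree, truth = simulate_marker_matrix(
    n_genomes=30, n_markers=300, frac_single_copy=1.0,
    clade_restricted_frac=0.0, seed=7)
ms = MarkerSet(list(matrix.columns))
q = recompute_quality(matrix.loc["g0000"], ms)
q.has_5S = q.has_16S = q.has_23S = True; q.trna_count = 20
print(q.completeness, q.contamination, assign_quality_tier(q))
# 0.9633 0.04 high
print(estimate_genome_size(2_100_000, 0.9, 0.05))
# 2216666.67  -> a 2.1 Mb assembly at 90% completeness, 5% contamination
#                implies a ~2.22 Mb complete genome

# species at 95% ANI
ani, truth = simulate_ani_matrix(n_species=5, genomes_per_species=3, seed=19)
clusters = single_linkage_species(ani, threshold=95.0)
print(len(clusters))
# 5  -> the planted species partition, recovered exactly

# name screening
catalog = NameCatalog(["Omnitrophus", "Velamenicoccus"], "reference")
(report,) = screen_names(["Omnitrophas"], catalog, D=2)
print(report.matches)
# [('omnitrophus', 'reference', 1, 'near')]  -> one edit away: confusable
```

The `examples/` directory holds one short narrative script per capability
(`genome_quality.py`, `marker_refinement.py`, `species_delineation.py`,
`aai_ranks.py`, `name_screening.py`, `cell_size_and_qsip.py`); each builds
a small input, runs the method and explains the printed numbers.

File-based inputs (marker-count TSV, FastANI tables, Newick trees, FASTA,
GFF3, filtration and AFE tables, name catalogs) go through
`phylocurate.io`.

## Scope

Sequencing, assembly, binning, HMM searches, reference-database
classification and tree inference are out of scope: marker counts, ANI
tables, proteomes, trees and AFE values are consumed as inputs.  The
fragment ANI is a labelled desk-scale surrogate, not a FastANI
reimplementation.  See `docs/methods.md` for models, defaults, numerical
choices and limitations.
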