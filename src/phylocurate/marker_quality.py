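"""Lineage-aware genome quality estimation from single-copy marker genes.

Draft genomes recovered without cultivation (MAGs and SAGs) are scored by
the fraction of expected single-copy marker genes present (completeness)
and duplicated (contamination).  General bacterial marker sets can be
misleading for unusual lineages: some markers are systematically absent
from a whole phylum, or confined to one clade within it, and depress the
completeness of perfectly good genomes.  This module provides

* set-fraction completeness/contamination from a marker copy-count row;
* detection of phylogenetically constrained markers (infrequently present
  and concentrated on a short patch of the tree) to exclude from the set;
* derivation of auxiliary lineage-specific single-copy markers, accepting a
  candidate when its single-copy occurrence count across representative
  genomes sits inside the 95% confidence band predicted from those genomes'
  completeness - contamination;
* complete-genome size estimation
  ``size_est = (size_obs - size_obs * contamination) / completeness``
  and its quantile placement against a reference collection;
* MIMAG-style quality tiers (high / medium / low / discard);
* giant-ORF flagging (> 20 kb by default) and one-way ANOVA + Tukey HSD
  group comparison of genome sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerSet",
    "GenomeQuality",
    "GenomeRecord",
    "recompute_quality",
    "exclude_constrained_markers",
    "derive_auxiliary_markers",
    "estimate_genome_size",
    "assign_quality_tier",
    "find_giant_orfs",
    "size_quantile",
    "group_compare",
    "GroupComparison",
]


@dataclass
class MarkerSet:
    """A set of candidate single-copy marker genes, minus refinements.

    ``provenance`` labels where the set came from, e.g. "general-bacterial"
    or "auxiliary-derived".
    """

    marker_ids: list
    excluded_ids: list = field(default_factory=list)
    provenance: str = "general-bacterial"

    def __post_init__(self):
        if not self.marker_ids:
            raise ValueError("marker_ids must be non-empty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        extra = set(self.excluded_ids) - set(self.marker_ids)
        if extra:
            raise ValueError(f"excluded ids not in marker set: {sorted(extra)}")

    @property
    def effective(self) -> list:
        """Marker ids after exclusion, in original order."""
        excl = set(self.excluded_ids)
        return [m for m in self.marker_ids if m not in excl]


@dataclass
class GenomeQuality:
    genome_id: str
    completeness: float
    contamination: float
    has_5S: bool = False
    has_16S: bool = False
    has_23S: bool = False
    trna_count: int = 0
    tier: str | None = None


@dataclass
class GenomeRecord:
    genome_id: str
    size_obs: int
    size_est: float | None = None
    group_label: str = ""
    quantile: float | None = None

    def __post_init__(self):
        if self.size_obs <= 0:
            raise ValueError("size_obs must be positive")


def recompute_quality(counts_row, marker_set: MarkerSet) -> GenomeQuality:
    """Set-fraction completeness and contamination for one genome.

    completeness = fraction of non-excluded markers present (count >= 1);
    contamination = mean excess copies, sum(max(0, count - 1)) / n_markers.
    ``counts_row`` is a mapping or Series of per-marker copy counts covering
    every non-excluded marker.
    """
    markers = marker_set.effective
    if not markers:
        raise ValueError("effective marker set is empty")
    missing = [m for m in markers if m not in counts_row]
    if missing:
        raise ValueError(f"counts_row missing markers: {missing[:5]}")
    counts = np.asarray([counts_row[m] for m in markers], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative marker counts")
    gid = counts_row.name if isinstance(counts_row, pd.Series) else ""
    return GenomeQuality(
        genome_id=str(gid),
        completeness=float((counts >= 1).mean()),
        contamination=float(np.maximum(counts - 1, 0).sum() / len(markers)),
    )


def _patristic_matrix(tree, genome_ids):
    """Dense patristic (path-length) distance matrix over genome_ids."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [g for g in genome_ids if g not in taxa]
    if missing:
        raise ValueError(f"genome(s) not found as tree tips: {missing}")
    n = len(genome_ids)
    dmat = np.zeros((n, n))
    for i, gi in enumerate(genome_ids):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[gi], taxa[genome_ids[j]])
            dmat[i, j] = dmat[j, i] = d
    return dmat


def exclude_constrained_markers(matrix: pd.DataFrame, tree,
                                freq_threshold: float = 0.10,
                                dist_quantile: float = 0.25) -> list:
    """Markers whose presence is phylogenetically constrained.

    A marker is excluded when it is infrequently present (presence frequency
    below ``freq_threshold``) *and* the genomes bearing it are unusually
    close on the tree: their mean pairwise patristic distance falls below
    the ``dist_quantile`` quantile of that statistic over all markers with
    at least two bearers.  Markers present in <= 1 genome are excluded
    unconditionally.

    ``matrix`` is genomes x markers (integer copy counts); ``tree`` a
    dendropy tree whose tip labels cover the matrix genomes.
    """
    if not (0 < freq_threshold < 1 and 0 < dist_quantile < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    genome_ids = list(matrix.index)
    dmat = _patristic_matrix(tree, genome_ids)
    presence = matrix.to_numpy() >= 1
    n_genomes = len(genome_ids)

    mean_dist = {}
    for k, marker in enumerate(matrix.columns):
        bearers = np.nonzero(presence[:, k])[0]
        if len(bearers) >= 2:
            sub = dmat[np.ix_(bearers, bearers)]
            iu = np.triu_indices(len(bearers), k=1)
            mean_dist[marker] = float(sub[iu].mean())

    excluded = []
    cutoff = np.quantile(list(mean_dist.values()), dist_quantile) if mean_dist else np.inf
    for k, marker in enumerate(matrix.columns):
        n_bearers = int(presence[:, k].sum())
        if n_bearers <= 1:
            excluded.append(marker)
            continue
        freq = n_bearers / n_genomes
        if freq < freq_threshold and mean_dist[marker] < cutoff:
            excluded.append(marker)
    return excluded


def derive_auxiliary_markers(matrix: pd.DataFrame, qualities,
                             z: float = 1.96,
                             occurrence: str = "single_copy",
                             continuity_correction: bool = True) -> list:
    """Auxiliary single-copy markers from a candidate copy-count matrix.

    For each candidate marker the observed occurrence count across the
    representative genomes is compared with the count predicted from genome
    quality: a genome of completeness c and contamination k is expected to
    carry a true single-copy gene in exactly one copy with probability
    p = c - k.  The marker is accepted when its observed count lies within
    z * sigma of mu = sum(p_g), with sigma from the sum of independent
    Bernoulli(p_g) variances (sigma = 0 degenerates to exact equality).
    Because the observed count is discrete, the normal-approximation band
    includes a half-count continuity correction by default (without it the
    band's real coverage falls below its nominal 95%).

    ``occurrence`` selects the observed statistic: ``"single_copy"``
    (default) counts genomes bearing exactly one copy, matching the p = c - k
    prediction; ``"presence"`` counts genomes with >= 1 copy.

    ``qualities`` maps genome_id -> GenomeQuality (or is a list of them)
    and must cover every genome in ``matrix``.  Returns a sorted list.
    """
    if matrix.shape[0] == 0:
        raise ValueError("empty genome set")
    if not isinstance(qualities, dict):
        qualities = {q.genome_id: q for q in qualities}
    missing = [g for g in matrix.index if g not in qualities]
    if missing:
        raise ValueError(f"qualities missing for genomes: {missing[:5]}")
    p = np.array([qualities[g].completeness - qualities[g].contamination
                  for g in matrix.index])
    if (p < 0).any() or (p > 1).any():
        warnings.warn("completeness - contamination outside [0, 1]; clipping")
        p = np.clip(p, 0.0, 1.0)
    mu = p.sum()
    sigma = float(np.sqrt((p * (1 - p)).sum()))
    counts = matrix.to_numpy()
    if occurrence == "single_copy":
        obs = (counts == 1).sum(axis=0)
    elif occurrence == "presence":
        obs = (counts >= 1).sum(axis=0)
    else:
        raise ValueError(f"unknown occurrence mode {occurrence!r}")
    if sigma == 0.0:
        accept = np.isclose(obs, mu)
    else:
        half = z * sigma + (0.5 if continuity_correction else 0.0)
        accept = np.abs(obs - mu) <= half
    return sorted(str(m) for m in matrix.columns[accept])


def estimate_genome_size(size_obs: float, completeness: float,
                         contamination: float) -> float:
    """Complete-genome size: (size_obs - size_obs * contamination) / completeness."""
    if size_obs <= 0:
        raise ValueError("size_obs must be positive")
    if not 0 < completeness <= 1:
        raise ValueError("completeness must lie in (0, 1]")
    if not 0 <= contamination < 1:
        raise ValueError("contamination must lie in [0, 1)")
    return (size_obs - size_obs * contamination) / completeness


def assign_quality_tier(q: GenomeQuality) -> str:
    """MIMAG-style tier from completeness, contamination and RNA inventory.

    Evaluated in order: discard when completeness < 10% or contamination
    > 10%; high when > 90% complete, < 5% contaminated, with 5S/16S/23S
    rRNAs and >= 18 tRNAs; medium when > 50% complete and < 10%
    contaminated; low when 10-50% complete and < 5% contaminated; anything
    left over is discarded with a warning.
    """
    c, k = q.completeness, q.contamination
    if c < 0.10 or k > 0.10:
        return "discard"
    if c > 0.90 and k < 0.05 and q.has_5S and q.has_16S and q.has_23S \
            and q.trna_count >= 18:
        return "high"
    if c > 0.50 and k < 0.10:
        return "medium"
    if 0.10 <= c <= 0.50 and k < 0.05:
        return "low"
    warnings.warn(
        f"genome {q.genome_id!r} (completeness {c:.2f}, contamination {k:.2f}) "
        "matches no tier rule; discarding"
    )
    return "discard"


def find_giant_orfs(orfs: pd.DataFrame, min_len_nt: int = 20000) -> pd.DataFrame:
    """ORFs strictly longer than ``min_len_nt``, sorted by length descending.

    ``orfs`` needs a ``length_nt`` column (see ``io.read_orf_gff3`` /
    ``io.orf_table_from_protein_fasta``).  Giant ORFs (> 20 kb) are a
    hallmark of putative predatory/parasitic lineages.
    """
    if orfs.empty:
        return orfs.copy()
    giant = orfs[orfs["length_nt"] > min_len_nt]
    return giant.sort_values("length_nt", ascending=False).reset_index(drop=True)


def size_quantile(size_est: float, reference_sizes) -> float:
    """Mid-rank quantile of ``size_est`` within a reference size collection.

    (number strictly smaller + half the ties) / n.
    """
    reference_sizes = np.asarray(list(reference_sizes), dtype=float)
    if reference_sizes.size == 0:
        raise ValueError("reference_sizes must be non-empty")
    return float(stats.percentileofscore(reference_sizes, size_est, kind="mean") / 100.0)


@dataclass
class GroupComparison:
    """One-way ANOVA F test plus Tukey-HSD pairwise table."""

    f_stat: float
    p_value: float
    table: pd.DataFrame  # group_a, group_b, diff, p_adj
    degenerate: bool = False


def group_compare(values, group_labels) -> GroupComparison:
    """Compare group means: one-way ANOVA followed by Tukey's HSD.

    Degenerate inputs are flagged: if every value is identical the F
    statistic is undefined (reported as NaN, all pairwise p = 1); if
    within-group variance is zero but means differ, F is infinite and
    differing pairs get p = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    names = sorted(pd.unique(labels).tolist())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == g] for g in names]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two values per group")

    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    means = {g: grp.mean() for g, grp in zip(names, groups)}

    within_var = sum(((g - g.mean()) ** 2).sum() for g in groups)
    between_var = sum(len(g) * (g.mean() - values.mean()) ** 2 for g in groups)

    if within_var == 0.0:
        rows = [(a, b, means[a] - means[b], 1.0 if means[a] == means[b] else 0.0)
                for a, b in pairs]
        table = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p_adj"])
        if between_var == 0.0:
            return GroupComparison(np.nan, 1.0, table, degenerate=True)
        return GroupComparison(np.inf, 0.0, table, degenerate=True)

    f_stat, p_value = stats.f_oneway(*groups)
    if between_var == 0.0:  # identical group means with real spread
        f_stat, p_value = 0.0, 1.0
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append((names[i], names[j], means[names[i]] - means[names[j]],
                         float(res.pvalue[i, j])))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p_adj"])
    return GroupComparison(float(f_stat), float(p_value), table)
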