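"""Species delineation from average nucleotide identity (ANI).

Genomes sharing >= 95% ANI are conventionally the same species.  Species
are taken as single-linkage clusters at that threshold — i.e. connected
components of the graph with an edge wherever the (symmetrized) ANI of a
pair reaches the threshold — and each cluster is represented by its most
complete genome.

``compute_ani`` is a desk-scale fragment-mapping surrogate for FastANI:
the query genome is cut into fixed-length fragments, each fragment is
aligned to the reference (both strands, end-free in the reference via
edlib's infix mode, so the whole fragment is always covered), and ANI is
the mean identity of the fragments that map at >= ``min_identity``.
Precomputed FastANI tables are the primary input path
(``io.read_fastani`` / ``ani_matrix_from_pairs``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .marker_quality import GenomeQuality, assign_quality_tier

__all__ = [
    "ANIResult",
    "SpeciesCluster",
    "compute_ani",
    "ani_matrix_from_pairs",
    "symmetrize_ani",
    "single_linkage_species",
    "select_representative",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class ANIResult:
    ani: float | None  # percent, None when no fragment maps
    n_mapped: int
    n_fragments: int


@dataclass
class SpeciesCluster:
    cluster_id: int
    members: list
    representative: str | None = None


def compute_ani(genome_a, genome_b, fragment_len: int = 1000,
                min_identity: float = 0.7) -> ANIResult:
    """Directed fragment-based ANI of genome_a against genome_b (percent).

    Genomes are sequences of contig strings (a bare string is one contig).
    Each full-length fragment of ``genome_a`` is aligned end-free to every
    contig of ``genome_b`` on both strands; a fragment maps when its best
    identity (1 - edits / fragment length) reaches ``min_identity``.  With
    infix alignment the fragment is covered end to end by construction.
    Returns mean mapped identity, or ``ani=None`` when nothing maps.
    """
    contigs_a = [genome_a] if isinstance(genome_a, str) else list(genome_a)
    contigs_b = [genome_b] if isinstance(genome_b, str) else list(genome_b)
    if not any(contigs_a) or not any(contigs_b):
        raise ValueError("both genomes must be non-empty")

    fragments = []
    for contig in contigs_a:
        for s in range(0, len(contig) - fragment_len + 1, fragment_len):
            fragments.append(contig[s: s + fragment_len])
        if len(contig) < fragment_len:
            fragments.append(contig)

    identities = []
    n_mapped = 0
    for frag in fragments:
        best = None
        for target in contigs_b:
            for query in (frag, _revcomp(frag)):
                d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
                if d >= 0 and (best is None or d < best):
                    best = d
        if best is None:
            continue
        ident = 1.0 - best / len(frag)
        if ident >= min_identity:
            identities.append(ident)
            n_mapped += 1
    ani = 100.0 * float(np.mean(identities)) if identities else None
    return ANIResult(ani=ani, n_mapped=n_mapped, n_fragments=len(fragments))


def ani_matrix_from_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Square (possibly directed) ANI matrix from long-form query/reference rows.

    ``pairs`` needs columns query, reference, ani (e.g. from
    ``io.read_fastani``).  Missing pairs stay NaN; the diagonal is 100.
    """
    genomes = sorted(set(pairs["query"]) | set(pairs["reference"]))
    mat = pd.DataFrame(np.nan, index=genomes, columns=genomes)
    for _, row in pairs.iterrows():
        mat.loc[row["query"], row["reference"]] = row["ani"]
    np.fill_diagonal(mat.values, 100.0)
    return mat


def symmetrize_ani(ani: pd.DataFrame) -> pd.DataFrame:
    """Mean of the two directions; a missing direction uses the available one."""
    a = ani.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        sym = np.nanmean(np.stack([a, a.T]), axis=0)
    return pd.DataFrame(sym, index=ani.index, columns=ani.columns)


def single_linkage_species(ani: pd.DataFrame, threshold: float = 95.0) -> list:
    """Single-linkage species clusters at an ANI threshold (default 95%).

    Clusters are the connected components of the graph with an edge where
    symmetrized ANI >= threshold (missing values form no edge).  Clusters
    are ordered by their smallest member id; members are sorted.
    """
    if list(ani.index) != list(ani.columns):
        raise ValueError("ANI matrix must be square with matching labels")
    sym = symmetrize_ani(ani).to_numpy()
    adj = np.nan_to_num(sym, nan=-np.inf) >= threshold
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    genomes = np.asarray(ani.index)
    comps = [sorted(genomes[labels == c].tolist()) for c in range(n_comp)]
    comps.sort(key=lambda members: members[0])
    return [SpeciesCluster(cluster_id=i, members=m) for i, m in enumerate(comps)]


def select_representative(members, qualities, sizes=None) -> str:
    """The cluster representative: its most complete genome.

    Ties break by lower contamination, then larger observed size, then
    lexicographic genome id.  When any member reaches the high or medium
    quality tier, only those members are considered.

    ``qualities`` maps genome_id -> GenomeQuality; ``sizes`` optionally maps
    genome_id -> observed assembly size (bp) for the tie-break.
    """
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    if not isinstance(qualities, dict):
        qualities = {q.genome_id: q for q in qualities}
    missing = [g for g in members if g not in qualities]
    if missing:
        raise ValueError(f"quality unknown for members: {missing}")
    sizes = sizes or {}

    def tier(g):
        q = qualities[g]
        return q.tier if q.tier is not None else assign_quality_tier(q)

    pool = [g for g in members if tier(g) in ("high", "medium")] or members
    return min(pool, key=lambda g: (-qualities[g].completeness,
                                    qualities[g].contamination,
                                    -sizes.get(g, 0), g))
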