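"""Average amino acid identity (AAI) between proteomes, enveomics-style.

AAI is the mean percent identity over reciprocal-best-hit (RBH) protein
pairs between two genomes, computed from all-vs-all local alignments
(BLOSUM62, affine gaps mirroring blastp defaults: open 11, extend 1).
A pair is an RBH when each protein is the other's best hit and the
alignment passes identity, coverage-of-the-shorter-sequence, and length
filters.  Intra- versus inter-genus AAI distributions within each family
flag rank assignments that need attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "Proteome",
    "AAIResult",
    "compute_aai",
    "rank_consistency_report",
]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYXBZ*")


@dataclass
class Proteome:
    """Predicted protein sequences of one genome."""

    genome_id: str
    sequences: list  # (protein_id, amino-acid string)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError(f"proteome {self.genome_id!r} is empty")
        for pid, seq in self.sequences:
            bad = set(seq.upper()) - _VALID_AA
            if bad:
                raise ValueError(f"protein {pid!r} has invalid residues {sorted(bad)}")


@dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    aai: float | None  # percent; None when no RBH pair passes the filters
    n_rbh: int
    filters: dict = field(default_factory=dict)


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


def _aln_columns(aligner, sa, sb) -> int:
    c = aligner.align(sa, sb)[0].counts()
    return c.gaps + c.identities + c.mismatches


def _best_hits(score, seqs_self, seqs_other, ids_other, aligner, axis):
    """Best-hit index along ``axis``; ties break by longest alignment, then
    lexicographic protein id."""
    best = []
    scores = score if axis == 1 else score.T
    for i, row in enumerate(scores):
        top = row.max()
        cand = np.nonzero(row == top)[0]
        if len(cand) > 1:
            cand = sorted(
                cand,
                key=lambda j: (-_aln_columns(aligner, seqs_self[i], seqs_other[j]),
                               ids_other[j]),
            )
        best.append(int(cand[0]))
    return np.array(best)


def compute_aai(a: Proteome, b: Proteome, min_identity: float = 20.0,
                min_coverage: float = 0.5, min_aln_len: int = 0) -> AAIResult:
    """AAI of two proteomes over reciprocal best hits.

    ``min_identity`` is percent identity over alignment columns;
    ``min_coverage`` is the aligned fraction of the shorter sequence;
    ``min_aln_len`` a minimum alignment length in columns.  Symmetric by
    construction: swapping the proteomes yields the same value.
    """
    aligner = _aligner()
    seqs_a = [s.upper() for _, s in a.sequences]
    seqs_b = [s.upper() for _, s in b.sequences]
    ids_a = [pid for pid, _ in a.sequences]
    ids_b = [pid for pid, _ in b.sequences]

    score = np.empty((len(seqs_a), len(seqs_b)))
    for i, sa in enumerate(seqs_a):
        for j, sb in enumerate(seqs_b):
            score[i, j] = aligner.score(sa, sb)

    best_ab = _best_hits(score, seqs_a, seqs_b, ids_b, aligner, axis=1)
    best_ba = _best_hits(score, seqs_b, seqs_a, ids_a, aligner, axis=0)

    identities = []
    for i, j in enumerate(best_ab):
        if best_ba[j] != i:
            continue
        if score[i, j] <= 0:  # no positive-scoring local alignment exists
            continue
        aln = aligner.align(seqs_a[i], seqs_b[j])[0]
        c = aln.counts()
        ident = c.identities
        columns = c.gaps + c.identities + c.mismatches
        if columns == 0:
            continue
        pct_identity = 100.0 * ident / columns
        shorter = min(len(seqs_a[i]), len(seqs_b[j]))
        aligned_res = min(sum(e - s for s, e in aln.aligned[0]),
                          sum(e - s for s, e in aln.aligned[1]))
        coverage = aligned_res / shorter
        if (pct_identity >= min_identity and coverage >= min_coverage
                and columns >= min_aln_len):
            identities.append(pct_identity)

    filters = {"min_identity": min_identity, "min_coverage": min_coverage,
               "min_aln_len": min_aln_len}
    if not identities:
        return AAIResult(a.genome_id, b.genome_id, None, 0, filters)
    return AAIResult(a.genome_id, b.genome_id, float(np.mean(identities)),
                     len(identities), filters)


def rank_consistency_report(aai: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Intra- versus inter-genus AAI consistency within each family.

    ``aai`` is a square matrix over species representatives; ``taxonomy``
    has columns genome_id, genus, family.  For each family the
    min/median/max of intra-genus and inter-genus AAI are reported, and a
    genus is flagged when any of its intra-genus values falls below any
    inter-genus value of the same family (overlap violation).  Families
    with a single representative are reported as not evaluable.  Report
    only — no renaming is performed.
    """
    tax = taxonomy.set_index("genome_id")
    rows = []
    for family, members in tax.groupby("family").groups.items():
        members = sorted(members)
        if len(members) < 2:
            rows.append({"family": family, "n_genomes": len(members),
                         "evaluable": False, "flagged_genera": []})
            continue
        intra, inter = {}, []
        for i, g1 in enumerate(members):
            for g2 in members[i + 1:]:
                val = aai.loc[g1, g2]
                if pd.isna(val):
                    continue
                if tax.loc[g1, "genus"] == tax.loc[g2, "genus"]:
                    intra.setdefault(tax.loc[g1, "genus"], []).append(float(val))
                else:
                    inter.append(float(val))
        flagged = sorted(genus for genus, vals in intra.items()
                         if inter and min(vals) < max(inter))
        intra_all = [v for vals in intra.values() for v in vals]
        rows.append({
            "family": family,
            "n_genomes": len(members),
            "evaluable": True,
            "intra_min": min(intra_all) if intra_all else np.nan,
            "intra_median": float(np.median(intra_all)) if intra_all else np.nan,
            "intra_max": max(intra_all) if intra_all else np.nan,
            "inter_min": min(inter) if inter else np.nan,
            "inter_median": float(np.median(inter)) if inter else np.nan,
            "inter_max": max(inter) if inter else np.nan,
            "flagged_genera": flagged,
        })
    return pd.DataFrame(rows)
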