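"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator takes an explicit integer seed (one shared RNG protocol, no
global state), returns the dataset in the exact in-memory form the
consuming module expects, and a :class:`SyntheticTruth` sidecar recording
the planted parameters.  Regeneration with the same seed is byte-identical,
and truth objects round-trip through JSON.

The generators emulate the *study conditions* of a phylum-curation
campaign: marker copy-count matrices over draft genomes of varying
completeness/contamination, block-structured ANI matrices with planted
species, ortholog proteome pairs at controlled identity, Latin-like name
catalogs with planted near-duplicates at known edit distances, serial
filtration retention patterns from true cell sizes, and qSIP AFE replicate
tables with planted guild effects.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .aai import Proteome
from .ecology import AFE_COLUMNS, FiltrationObservation
from .nomenclature import NameCatalog, dl_distance

__all__ = [
    "SyntheticTruth",
    "simulate_marker_matrix",
    "simulate_ani_matrix",
    "simulate_proteome_pair",
    "simulate_name_catalog",
    "simulate_filtration",
    "simulate_qsip",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticTruth:
    """Planted parameters of one synthetic scenario, JSON-serializable."""

    scenario: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not serializable: {type(o)}")
        text = json.dumps({"scenario": self.scenario, "seed": self.seed,
                           "params": self.params},
                          sort_keys=True, indent=2, default=_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SyntheticTruth":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(**payload)


# ---------------------------------------------------------------------------
# marker matrices
# ---------------------------------------------------------------------------

def _random_tree(genome_ids, seed) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace(genome_ids)
    return dendropy.simulate.treesim.pure_kingman_tree(
        taxon_namespace=ns, pop_size=1.0, rng=random.Random(seed))


def _clades(tree, lo_frac=0.10, hi_frac=0.50):
    """Tip-label sets of internal nodes whose size falls in [lo, hi] of tips."""
    n = len(tree.taxon_namespace)
    clades = []
    for node in tree.preorder_internal_node_iter():
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        if lo_frac * n <= len(tips) <= hi_frac * n:
            clades.append(sorted(tips))
    return clades


def simulate_marker_matrix(n_genomes: int = 100, n_markers: int = 500,
                           frac_single_copy: float = 0.5,
                           completeness_range=(0.5, 1.0),
                           contamination_range=(0.0, 0.1),
                           clade_restricted_frac: float = 0.25,
                           seed: int = 0):
    """Marker copy-count matrix with planted quality and marker classes.

    Per-genome completeness c and contamination k are drawn uniformly from
    the stated ranges.  A planted single-copy marker occurs in a genome as
    two copies with probability k, one copy with probability c - k, else
    absent — so presence has probability c, expected excess copies equal k,
    and single-copy occurrence has probability exactly c - k.
    Clade-restricted markers follow the same process but only inside one
    randomly chosen clade (10-50% of tips) of a random coalescent tree;
    the remaining markers are multi-copy (2 + Poisson(0.5) copies, present
    in ~95% of genomes).  Observed assembly sizes are generated as
    size_true * c / (1 - k), so the size estimator is exact given the
    planted quality.

    Returns ``(matrix, tree, truth)``: genomes x markers DataFrame, a
    dendropy tree over the genomes, and the planted truth.
    """
    if n_genomes < 1 or n_markers < 1:
        raise ValueError("need at least one genome and one marker")
    for frac in (frac_single_copy, clade_restricted_frac):
        if not 0 <= frac <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genome_ids = [f"g{i:04d}" for i in range(n_genomes)]
    marker_ids = [f"M{i:04d}" for i in range(n_markers)]
    tree = _random_tree(genome_ids, seed=int(rng.integers(2**31 - 1)))

    c = rng.uniform(*completeness_range, n_genomes)
    k = rng.uniform(*contamination_range, n_genomes)
    k = np.minimum(k, c)  # contamination never exceeds presence probability

    n_single = round(frac_single_copy * n_markers)
    n_clade = round(clade_restricted_frac * n_markers)
    n_clade = min(n_clade, n_markers - n_single)
    classes = (["single_copy"] * n_single + ["clade_restricted"] * n_clade
               + ["multi_copy"] * (n_markers - n_single - n_clade))

    clades = _clades(tree) or [genome_ids]
    counts = np.zeros((n_genomes, n_markers), dtype=int)
    clade_assignment = {}
    for m, cls in enumerate(classes):
        if cls == "single_copy":
            u = rng.random(n_genomes)
            counts[:, m] = np.where(u < k, 2, np.where(u < c, 1, 0))
        elif cls == "clade_restricted":
            members = clades[rng.integers(len(clades))]
            clade_assignment[marker_ids[m]] = members
            in_clade = np.isin(genome_ids, members)
            u = rng.random(n_genomes)
            counts[:, m] = np.where(in_clade, np.where(u < k, 2,
                                    np.where(u < c, 1, 0)), 0)
        else:
            present = rng.random(n_genomes) < 0.95
            counts[:, m] = np.where(present, 2 + rng.poisson(0.5, n_genomes), 0)

    size_true = rng.uniform(0.9e6, 3.2e6, n_genomes)
    size_obs = size_true * c / (1 - k)

    matrix = pd.DataFrame(counts, index=genome_ids, columns=marker_ids)
    truth = SyntheticTruth(
        scenario="marker_matrix", seed=seed,
        params={
            "completeness": dict(zip(genome_ids, c)),
            "contamination": dict(zip(genome_ids, k)),
            "single_copy_markers": [m for m, cl in zip(marker_ids, classes)
                                    if cl == "single_copy"],
            "clade_restricted_markers": [m for m, cl in zip(marker_ids, classes)
                                         if cl == "clade_restricted"],
            "multi_copy_markers": [m for m, cl in zip(marker_ids, classes)
                                   if cl == "multi_copy"],
            "clade_members": clade_assignment,
            "size_true": dict(zip(genome_ids, size_true)),
            "size_obs": dict(zip(genome_ids, size_obs)),
        })
    return matrix, tree, truth


# ---------------------------------------------------------------------------
# ANI matrices
# ---------------------------------------------------------------------------

def simulate_ani_matrix(n_species: int = 10, genomes_per_species: int = 3,
                        within_mean: float = 98.0, between_mean: float = 80.0,
                        sd: float = 0.5, seed: int = 0):
    """Block-structured symmetric ANI matrix with a planted species partition.

    Within-species pairs draw from Normal(within_mean, sd) and
    between-species pairs from Normal(between_mean, sd) (clipped to
    [0, 100], diagonal 100).  With the two distributions separated from the
    95% threshold by several sd the planted partition is recovered exactly
    by single-linkage clustering.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(genomes_per_species):
        sizes = [int(genomes_per_species)] * n_species
    else:
        sizes = [int(s) for s in genomes_per_species]
    genome_ids, species_of = [], {}
    for s, size in enumerate(sizes):
        for i in range(size):
            gid = f"s{s:03d}_g{i:02d}"
            genome_ids.append(gid)
            species_of[gid] = s
    n = len(genome_ids)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        mat[i, i] = 100.0
        for j in range(i + 1, n):
            mu = within_mean if species_of[genome_ids[i]] == species_of[genome_ids[j]] \
                else between_mean
            v = float(np.clip(rng.normal(mu, sd), 0.0, 100.0))
            mat[i, j] = mat[j, i] = v
    ani = pd.DataFrame(mat, index=genome_ids, columns=genome_ids)
    partition = {}
    for gid, s in species_of.items():
        partition.setdefault(s, []).append(gid)
    truth = SyntheticTruth(
        scenario="ani_matrix", seed=seed,
        params={"partition": [sorted(v) for _, v in sorted(partition.items())],
                "within_mean": within_mean, "between_mean": between_mean,
                "sd": sd})
    return ani, truth


# ---------------------------------------------------------------------------
# proteome pairs
# ---------------------------------------------------------------------------

def simulate_proteome_pair(n_orthologs: int = 50, target_identity: float = 80.0,
                           length_range=(150, 300), seed: int = 0):
    """Two proteomes related by one-to-one orthologs at a target identity.

    Each ortholog pair is a random protein and a copy with independent
    per-site substitution (to a different residue) at rate
    1 - target_identity/100, gap-free.  The realized per-pair identities
    are recorded in the truth.
    """
    if n_orthologs < 1:
        raise ValueError("need at least one ortholog")
    if not 0 < target_identity <= 100:
        raise ValueError("target_identity must lie in (0, 100]")
    rng = np.random.default_rng(seed)
    sub_rate = 1.0 - target_identity / 100.0
    seqs_a, seqs_b, realized = [], [], []
    aa = np.array(list(AMINO_ACIDS))
    for o in range(n_orthologs):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        s = aa[rng.integers(0, len(aa), length)]
        t = s.copy()
        hit = rng.random(length) < sub_rate
        for pos in np.nonzero(hit)[0]:
            choices = [x for x in AMINO_ACIDS if x != s[pos]]
            t[pos] = choices[rng.integers(len(choices))]
        seqs_a.append((f"o{o:04d}_a", "".join(s)))
        seqs_b.append((f"o{o:04d}_b", "".join(t)))
        realized.append(100.0 * (1 - hit.mean()))
    truth = SyntheticTruth(
        scenario="proteome_pair", seed=seed,
        params={"target_identity": target_identity,
                "realized_identity": realized,
                "n_orthologs": n_orthologs})
    return (Proteome("genomeA", seqs_a), Proteome("genomeB", seqs_b), truth)


# ---------------------------------------------------------------------------
# name catalogs
# ---------------------------------------------------------------------------

_CONSONANTS = "bcdfghlmnprstvz"
_VOWELS = "aeiou"
_SUFFIXES = ["us", "a", "um", "is", "ella", "icus", "ium", "ensis", "ix", "ans"]


def _latin_name(rng) -> str:
    n_syll = int(rng.integers(2, 5))
    parts = []
    for _ in range(n_syll):
        parts.append(_CONSONANTS[rng.integers(len(_CONSONANTS))])
        parts.append(_VOWELS[rng.integers(len(_VOWELS))])
    return "".join(parts) + _SUFFIXES[rng.integers(len(_SUFFIXES))]


def _apply_edits(name: str, d: int, rng) -> str:
    letters = string.ascii_lowercase
    s = list(name)
    for _ in range(d):
        op = rng.integers(4)
        if op == 0 and len(s) > 1:          # deletion
            del s[int(rng.integers(len(s)))]
        elif op == 1:                       # insertion
            s.insert(int(rng.integers(len(s) + 1)),
                     letters[rng.integers(26)])
        elif op == 2:                       # substitution
            pos = int(rng.integers(len(s)))
            repl = letters[rng.integers(26)]
            s[pos] = repl
        else:                               # adjacent transposition
            if len(s) >= 2:
                pos = int(rng.integers(len(s) - 1))
                s[pos], s[pos + 1] = s[pos + 1], s[pos]
    return "".join(s)


def simulate_name_catalog(n_names: int = 10000, planted=None, seed: int = 0,
                          max_tries: int = 200):
    """Latin-like name catalog with proposed names at known edit distances.

    ``planted`` maps edit distance -> number of proposed names to plant at
    exactly that OSA distance from their nearest catalog entry (default
    ``{1: 25, 2: 25, 3: 50}``).  Each planted proposal is built by editing
    a random catalog name and is verified with the full-DP oracle: its
    distance to the source equals d and no other catalog entry is closer.

    Returns ``(catalog, proposed, truth)`` where ``proposed`` is a list of
    ``(name, true_distance, source_name)`` tuples.
    """
    planted = {1: 25, 2: 25, 3: 50} if planted is None else dict(planted)
    rng = np.random.default_rng(seed)
    names, seen = [], set()
    while len(names) < n_names:
        name = _latin_name(rng)
        if name not in seen:
            seen.add(name)
            names.append(name)
    catalog = NameCatalog(names, "synthetic-catalog")

    max_d = max(planted) if planted else 0
    proposed = []
    for d, count in sorted(planted.items()):
        for _ in range(count):
            for _try in range(max_tries):
                source = names[int(rng.integers(n_names))]
                cand = _apply_edits(source, d, rng)
                if not cand or cand in seen:
                    continue
                if dl_distance(source, cand) != d:
                    continue
                # oracle check: no catalog entry closer than (or tied below) d
                nearest = min(dl_distance(cand, other)
                              for other in names
                              if abs(len(other) - len(cand)) <= max_d + 1) \
                    if d <= max_d else d
                if nearest == d:
                    proposed.append((cand, d, source))
                    break
            else:
                raise RuntimeError(f"could not plant a distance-{d} neighbor")
    truth = SyntheticTruth(
        scenario="name_catalog", seed=seed,
        params={"n_names": n_names,
                "planted": [{"name": n, "distance": d, "source": s}
                            for n, d, s in proposed]})
    return catalog, proposed, truth


# ---------------------------------------------------------------------------
# filtration
# ---------------------------------------------------------------------------

def simulate_filtration(n_taxa: int = 500, true_size_range=(0.05, 1.5),
                        pore_sizes=(1.0, 0.45, 0.2), retention_noise: float = 0.0,
                        seed: int = 0):
    """Serial-filtration retention patterns from planted true cell sizes.

    Noiseless mode retains each taxon exactly on the largest pore not
    exceeding its true size (cells smaller than every pore pass through the
    whole train); noisy mode then flips each retention flag independently
    with probability ``retention_noise``.
    """
    rng = np.random.default_rng(seed)
    pores = tuple(float(p) for p in pore_sizes)
    sizes = rng.uniform(*true_size_range, n_taxa)
    observations = []
    for t, size in enumerate(sizes):
        capture = max((p for p in pores if p <= size), default=None)
        retained = [p == capture for p in pores]
        if retention_noise > 0:
            flips = rng.random(len(pores)) < retention_noise
            retained = [r ^ f for r, f in zip(retained, flips)]
        observations.append(FiltrationObservation(
            taxon_id=f"t{t:04d}", pore_sizes=pores, retained=tuple(retained)))
    truth = SyntheticTruth(
        scenario="filtration", seed=seed,
        params={"true_sizes": {o.taxon_id: float(s)
                               for o, s in zip(observations, sizes)},
                "pore_sizes": list(pores),
                "retention_noise": retention_noise})
    return observations, truth


# ---------------------------------------------------------------------------
# qSIP
# ---------------------------------------------------------------------------

def simulate_qsip(n_samples: int = 114, n_replicates: int = 3,
                  guild_counts=None, effect_multipliers=None,
                  baseline_afe: float = 0.05, noise_sigma: float = 0.3,
                  isotope: str = "18O", seed: int = 0):
    """AFE replicate table with planted per-guild activity effects.

    Every sample draws a lognormal baseline AFE; a taxon's true AFE is the
    sample baseline times its guild multiplier, and replicates add
    multiplicative lognormal noise (sigma = ``noise_sigma``).
    ``guild_counts`` defaults to 2 focal, 3 predatory and 20 non-predatory
    taxa; ``effect_multipliers`` defaults to 2.0 / 2.0 / 1.0 respectively.

    Returns ``(table, truth)`` with ``table`` in AFE long form
    (taxon_id, sample_id, replicate, isotope, afe, guild).
    """
    guild_counts = guild_counts or {"focal": 2, "predatory": 3,
                                    "non_predatory": 20}
    effect_multipliers = effect_multipliers or {"focal": 2.0, "predatory": 2.0,
                                                "non_predatory": 1.0}
    rng = np.random.default_rng(seed)
    taxa = []
    for guild, count in sorted(guild_counts.items()):
        for i in range(count):
            taxa.append((f"{guild}_{i:02d}", guild))
    baselines = baseline_afe * rng.lognormal(0.0, 0.5, n_samples)
    rows = []
    for s in range(n_samples):
        sample_id = f"S{s:03d}"
        for taxon_id, guild in taxa:
            true_afe = baselines[s] * effect_multipliers[guild]
            for r in range(n_replicates):
                afe = true_afe * rng.lognormal(0.0, noise_sigma)
                rows.append((taxon_id, sample_id, r, isotope, afe, guild))
    table = pd.DataFrame(rows, columns=AFE_COLUMNS)
    truth = SyntheticTruth(
        scenario="qsip", seed=seed,
        params={"guild_counts": guild_counts,
                "effect_multipliers": effect_multipliers,
                "baseline_afe": baseline_afe, "noise_sigma": noise_sigma,
                "baselines": {f"S{s:03d}": float(b)
                              for s, b in enumerate(baselines)},
                "n_replicates": n_replicates})
    return table, truth
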