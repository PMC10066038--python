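"""Taxon-name collision screening.

Proposing many new taxon names at once risks colliding with the >450,000
genus names already registered across nomenclatural catalogs (Catalogue of
Life, NCBI taxonomy, IRMNG, the Candidatus list).  This module screens
proposed names by exact lookup and then by bounded Damerau-Levenshtein (DL)
distance: two names within an edit distance of 2 are considered confusable.

Screening a proposal against a whole catalog with a full DL dynamic program
is wasteful, because almost all catalog names are obviously far away.  Two
sound lower bounds prune the candidate list before any DP runs:

1. *length prefilter* — every insertion/deletion is one edit, so names whose
   lengths differ by more than ``D`` cannot be within distance ``D``;
2. *character-set prefilter* — every character of ``a`` absent from ``b``
   must be removed or substituted, so more than ``D`` exclusive characters
   also rules the pair out.

Survivors are resolved by a band-limited DP that computes the exact distance
whenever it is <= ``D``.

The DL variant implemented as primary is optimal string alignment (OSA):
an adjacent transposition costs one edit but no substring is edited twice.
The unrestricted Damerau-Levenshtein distance is available via
``variant="dl"``; the two can differ when distances reach 2 or more
(e.g. "ca" -> "abc" is 2 under unrestricted DL but 3 under OSA).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "normalize_name",
    "dl_distance",
    "length_prefilter",
    "charset_prefilter",
    "bounded_dl",
    "NameCatalog",
    "CollisionReport",
    "screen_names",
]

# Latin ligatures / special letters that NFKD decomposition does not expand.
LIGATURE_TABLE = {
    "æ": "ae",   # ae ligature
    "œ": "oe",   # oe ligature
    "ß": "ss",   # sharp s
    "ø": "o",    # o with stroke
    "ł": "l",    # l with stroke
    "đ": "d",    # d with stroke
    "ð": "d",    # eth
    "þ": "th",   # thorn
    "ı": "i",    # dotless i
}


def normalize_name(raw: str) -> str:
    """Case-fold, strip whitespace, expand ligatures and drop diacritics.

    Deterministic and idempotent; raises ``ValueError`` if nothing is left.
    """
    s = raw.strip().casefold()
    for lig, repl in LIGATURE_TABLE.items():
        s = s.replace(lig, repl)
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    if not s:
        raise ValueError(f"name {raw!r} is empty after normalization")
    return s


# ---------------------------------------------------------------------------
# distance kernels
# ---------------------------------------------------------------------------

def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("utf-32-le"), dtype=np.int32).copy()


@njit(cache=False)
def _osa_kernel(a, b):  # pragma: no cover - exercised via dl_distance
    la = a.shape[0]
    lb = b.shape[0]
    if la == 0:
        return lb
    if lb == 0:
        return la
    d = np.empty((la + 1, lb + 1), np.int64)
    for i in range(la + 1):
        d[i, 0] = i
    for j in range(lb + 1):
        d[0, j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            v = d[i - 1, j - 1] + cost
            if d[i - 1, j] + 1 < v:
                v = d[i - 1, j] + 1
            if d[i, j - 1] + 1 < v:
                v = d[i, j - 1] + 1
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                if d[i - 2, j - 2] + 1 < v:
                    v = d[i - 2, j - 2] + 1
            d[i, j] = v
    return d[la, lb]


@njit(cache=False)
def _dl_kernel(a, b):  # pragma: no cover
    # Lowrance-Wagner unrestricted Damerau-Levenshtein. Symbols must be
    # pre-mapped to the range [0, n_symbols); a/b are small int arrays.
    la = a.shape[0]
    lb = b.shape[0]
    if la == 0:
        return lb
    if lb == 0:
        return la
    nsym = 0
    for i in range(la):
        if a[i] + 1 > nsym:
            nsym = a[i] + 1
    for j in range(lb):
        if b[j] + 1 > nsym:
            nsym = b[j] + 1
    inf = la + lb
    d = np.empty((la + 2, lb + 2), np.int64)
    d[0, 0] = inf
    for i in range(la + 1):
        d[i + 1, 1] = i
        d[i + 1, 0] = inf
    for j in range(lb + 1):
        d[1, j + 1] = j
        d[0, j + 1] = inf
    da = np.zeros(nsym, np.int64)
    for i in range(1, la + 1):
        db = 0
        for j in range(1, lb + 1):
            k = da[b[j - 1]]
            l = db
            if a[i - 1] == b[j - 1]:
                cost = 0
                db = j
            else:
                cost = 1
            v = d[i, j] + cost                      # substitution / match
            if d[i, j + 1] + 1 < v:                 # deletion
                v = d[i, j + 1] + 1
            if d[i + 1, j] + 1 < v:                 # insertion
                v = d[i + 1, j] + 1
            t = d[k, l] + (i - k - 1) + 1 + (j - l - 1)  # transposition
            if t < v:
                v = t
            d[i + 1, j + 1] = v
        da[a[i - 1]] = i
    return d[la + 1, lb + 1]


@njit(cache=False)
def _osa_banded_kernel(a, b, D):  # pragma: no cover
    # Exact OSA distance when <= D, else D + 1. Cells with |i - j| > D
    # cannot lie on a path of cost <= D, so the DP is restricted to the band.
    la = a.shape[0]
    lb = b.shape[0]
    if la - lb > D or lb - la > D:
        return D + 1
    if la == 0:
        return lb
    if lb == 0:
        return la
    big = D + 1
    d = np.full((la + 1, lb + 1), big, np.int64)
    for i in range(min(la, D) + 1):
        d[i, 0] = i
    for j in range(min(lb, D) + 1):
        d[0, j] = j
    for i in range(1, la + 1):
        jlo = i - D if i - D > 1 else 1
        jhi = i + D if i + D < lb else lb
        rowmin = big
        for j in range(jlo, jhi + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            v = d[i - 1, j - 1] + cost
            if d[i - 1, j] + 1 < v:
                v = d[i - 1, j] + 1
            if d[i, j - 1] + 1 < v:
                v = d[i, j - 1] + 1
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                if d[i - 2, j - 2] + 1 < v:
                    v = d[i - 2, j - 2] + 1
            if v > big:
                v = big
            d[i, j] = v
            if v < rowmin:
                rowmin = v
        if rowmin > D:
            return D + 1
    return d[la, lb] if d[la, lb] <= D else D + 1


@njit(cache=False)
def _batch_banded_kernel(q, qlen, cat, catlen, idx, D, out):  # pragma: no cover
    for r in range(idx.shape[0]):
        i = idx[r]
        out[r] = _osa_banded_kernel(q[:qlen], cat[i, : catlen[i]], D)


def dl_distance(a: str, b: str, variant: str = "osa") -> int:
    """Damerau-Levenshtein distance between two (normalized) strings.

    ``variant="osa"`` (default) is the optimal-string-alignment restriction;
    ``variant="dl"`` is the unrestricted Lowrance-Wagner distance.
    """
    ea, eb = _encode(a), _encode(b)
    if variant == "osa":
        return int(_osa_kernel(ea, eb))
    if variant == "dl":
        # remap code points to a compact symbol range for the da[] table
        symbols, mapped = np.unique(np.concatenate([ea, eb]), return_inverse=True)
        return int(_dl_kernel(mapped[: len(ea)].astype(np.int32),
                              mapped[len(ea):].astype(np.int32)))
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# prefilters and the bounded distance
# ---------------------------------------------------------------------------

def length_prefilter(a: str, b: str, D: int) -> bool:
    """True iff the pair survives the length criterion |len(a)-len(b)| <= D."""
    return abs(len(a) - len(b)) <= D


def charset_prefilter(a: str, b: str, D: int, symmetric: bool = False) -> bool:
    """True iff the pair survives the exclusive-character criterion.

    Each character of ``a`` absent from ``b`` forces at least one edit, so
    more than ``D`` such characters proves distance > D.  The symmetric mode
    additionally applies the same (equally valid) bound in the b-vs-a
    direction.
    """
    sa, sb = set(a), set(b)
    if len(sa - sb) > D:
        return False
    if symmetric and len(sb - sa) > D:
        return False
    return True


def bounded_dl(a: str, b: str, D: int, symmetric_charset: bool = False):
    """OSA distance if it is <= ``D``, else ``None`` (the ">D" sentinel).

    Applies the two prefilters first; survivors are resolved by the
    band-limited DP, which returns the exact distance whenever it is <= D.
    """
    if not length_prefilter(a, b, D):
        return None
    if not charset_prefilter(a, b, D, symmetric=symmetric_charset):
        return None
    dist = int(_osa_banded_kernel(_encode(a), _encode(b), D))
    return dist if dist <= D else None


# ---------------------------------------------------------------------------
# catalogs and screening
# ---------------------------------------------------------------------------

def _char_mask(s: str) -> int:
    # 63-bit character membership mask. Hash collisions (ord % 63) can only
    # undercount exclusive characters, so the vectorized prefilter built on
    # these masks remains a sound lower bound; for plain a-z names it is exact.
    m = 0
    for c in s:
        m |= 1 << (ord(c) % 63)
    return m


class NameCatalog:
    """Normalized reference taxon names with a prebuilt screening index.

    Parameters
    ----------
    names : iterable of raw name strings
    sources : matching source tags, or a single tag applied to every name
    """

    def __init__(self, names, sources="catalog"):
        names = list(names)
        if isinstance(sources, str):
            sources = [sources] * len(names)
        sources = list(sources)
        if len(sources) != len(names):
            raise ValueError("names and sources lengths differ")
        self.entries = list(zip(names, sources))
        self.normalized = [normalize_name(n) for n in names]
        self.sources = sources
        self._exact: dict[str, list[int]] = {}
        for i, n in enumerate(self.normalized):
            self._exact.setdefault(n, []).append(i)
        self._lengths = np.array([len(n) for n in self.normalized], dtype=np.int64)
        self._masks = np.array([_char_mask(n) for n in self.normalized], dtype=np.uint64)
        maxlen = int(self._lengths.max()) if len(names) else 0
        self._padded = np.zeros((len(names), maxlen), dtype=np.int32)
        for i, n in enumerate(self.normalized):
            self._padded[i, : len(n)] = _encode(n)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CollisionReport:
    """Exact and near matches of one proposed name against a catalog."""

    proposed: str
    matches: list[tuple[str, str, int, str]] = field(default_factory=list)
    # (catalog name, source, distance, "exact" | "near")
    D: int = 2
    n_catalog: int = 0
    n_prefilter_pass: int = 0  # candidates that reached the banded DP

    @property
    def has_collision(self) -> bool:
        return bool(self.matches)


def screen_names(proposed, catalog: NameCatalog, D: int = 2,
                 symmetric_charset: bool = False) -> list[CollisionReport]:
    """Screen proposed names: exact hash lookups, then bounded DL near matches.

    Near matches are names at OSA distance 1..D.  The per-candidate
    prefilters run vectorized over the whole catalog (length difference and
    a bitmask lower bound on exclusive characters); only survivors reach the
    banded DP.  Reports are sorted by distance, then source, then name.
    """
    if len(catalog) == 0:
        return [CollisionReport(proposed=p, D=D) for p in proposed]
    reports = []
    for raw in proposed:
        p = normalize_name(raw)
        rep = CollisionReport(proposed=raw, D=D, n_catalog=len(catalog))
        for i in catalog._exact.get(p, []):
            rep.matches.append((catalog.normalized[i], catalog.sources[i], 0, "exact"))
        pmask = np.uint64(_char_mask(p))
        cand = np.abs(catalog._lengths - len(p)) <= D
        excl = np.bitwise_count(pmask & ~catalog._masks)
        cand &= excl <= D
        if symmetric_charset:
            cand &= np.bitwise_count(catalog._masks & ~pmask) <= D
        idx = np.nonzero(cand)[0]
        rep.n_prefilter_pass = int(idx.size)
        if idx.size:
            q = np.zeros(max(len(p), 1), dtype=np.int32)
            q[: len(p)] = _encode(p)
            out = np.empty(idx.size, dtype=np.int64)
            _batch_banded_kernel(q, len(p), catalog._padded, catalog._lengths,
                                 idx, D, out)
            for r, i in enumerate(idx):
                if 1 <= out[r] <= D:
                    rep.matches.append(
                        (catalog.normalized[i], catalog.sources[i], int(out[r]), "near")
                    )
        rep.matches.sort(key=lambda m: (m[2], m[1], m[0]))
        reports.append(rep)
    return reports
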