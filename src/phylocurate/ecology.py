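"""Cell-size inference from serial filtration and qSIP activity statistics.

Serial filtration pushes a water sample through successively smaller pore
sizes (e.g. 1.0 -> 0.45 -> 0.2 um).  A taxon detected on a filter is at
least as large as that pore and smaller than any upstream pore it passed,
so the retention pattern bounds the cell size.  Retention on
non-contiguous filters (caught on 1.0 um and 0.2 um but absent from
0.45 um) is flagged: it may indicate aggregates rather than single cells.

Quantitative stable-isotope probing (qSIP) estimates each taxon's atom
fraction excess (AFE) — the excess heavy-isotope content of its DNA after
incubation with a labelled substrate.  A taxon is called a substrate
utilizer when both tails of the 95% confidence interval of its replicate
AFE values lie above zero.  Putative predators are compared against the
community by the percent difference between a focal taxon's AFE and the
aggregate AFE of all non-predatory taxa from the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .marker_quality import GroupComparison, group_compare

__all__ = [
    "FiltrationObservation",
    "SizeInterval",
    "infer_size_interval",
    "abundance_shift",
    "aggregate_by_taxon",
    "UtilizationCall",
    "afe_utilization",
    "PercentDifferenceSummary",
    "afe_percent_difference",
    "guild_activity_compare",
]

AFE_COLUMNS = ["taxon_id", "sample_id", "replicate", "isotope", "afe", "guild"]


@dataclass
class FiltrationObservation:
    """Retention pattern of one taxon across a serial filter train."""

    taxon_id: str
    pore_sizes: tuple  # um, strictly decreasing along the flow path
    retained: tuple    # bool per filter
    rel_abundance: tuple | None = None
    serial: bool = True

    def __post_init__(self):
        pores = tuple(float(p) for p in self.pore_sizes)
        if len(pores) == 0:
            raise ValueError("at least one filter is required")
        if any(b <= a for a, b in zip(pores[1:], pores[:-1])):
            raise ValueError("pore sizes must be strictly decreasing")
        if len(self.retained) != len(pores):
            raise ValueError("retained flags must match pore_sizes")
        if self.rel_abundance is not None and len(self.rel_abundance) != len(pores):
            raise ValueError("rel_abundance must match pore_sizes")
        self.pore_sizes = pores
        self.retained = tuple(bool(r) for r in self.retained)


@dataclass
class SizeInterval:
    """Estimated cell-size range [lower, upper) in um; upper=None is open."""

    lower: float
    upper: float | None
    flag: str  # consistent | non_contiguous | all_passed

    def __post_init__(self):
        if self.upper is not None and not self.lower < self.upper:
            raise ValueError("lower must be < upper")

    def contains(self, size: float) -> bool:
        return size >= self.lower and (self.upper is None or size < self.upper)


def infer_size_interval(obs: FiltrationObservation) -> SizeInterval:
    """Cell-size interval implied by a serial-filtration retention pattern.

    Retaining pores R: lower bound = min(R); upper bound = the smallest
    non-retaining pore larger than max(R) (open if every larger pore
    retained).  Empty R means the organism passed everything:
    [0, smallest pore) with flag ``all_passed``.  A retention run broken by
    a non-retaining filter in its middle is flagged ``non_contiguous``
    (single cells cannot be caught above and below a pore they passed;
    aggregates can).
    """
    if not obs.serial:
        raise ValueError("size inference requires a serial filter train")
    pores = obs.pore_sizes
    retaining = [p for p, r in zip(pores, obs.retained) if r]
    if not retaining:
        return SizeInterval(lower=0.0, upper=min(pores), flag="all_passed")
    lower = min(retaining)
    larger_non_retaining = [p for p, r in zip(pores, obs.retained)
                            if not r and p > max(retaining)]
    upper = min(larger_non_retaining) if larger_non_retaining else None
    inside = [r for p, r in zip(pores, obs.retained)
              if min(retaining) <= p <= max(retaining)]
    flag = "consistent" if all(inside) else "non_contiguous"
    return SizeInterval(lower=lower, upper=upper, flag=flag)


def abundance_shift(rel_abund_045: float, rel_abund_02: float) -> str:
    """Direction of the relative-abundance change from the 0.45 um to the
    0.2 um filter fraction: ``increase`` / ``decrease`` / ``equal``
    (strict comparisons).  An increase indicates cells enriched in the
    smallest size fraction."""
    for v in (rel_abund_045, rel_abund_02):
        if not 0.0 <= v <= 1.0:
            raise ValueError("relative abundances must lie in [0, 1]")
    if rel_abund_02 > rel_abund_045:
        return "increase"
    if rel_abund_02 < rel_abund_045:
        return "decrease"
    return "equal"


def aggregate_by_taxon(table: pd.DataFrame, taxonomy: pd.DataFrame,
                       rank: str) -> pd.DataFrame:
    """Sum sequence-variant abundances to a taxonomic rank, per filter.

    ``table`` has columns taxon_id, filter_id, abundance; ``taxonomy`` maps
    taxon_id to rank columns (rows missing from it pool as "unclassified").
    Abundances are summed within rank groups and re-normalized to fractions
    within each filter.  Returns long form: rank, filter_id, abundance.
    """
    mapping = taxonomy.set_index("taxon_id")[rank] if rank in taxonomy.columns \
        else pd.Series(dtype=object)
    groups = table["taxon_id"].map(mapping).fillna("unclassified")
    out = (table.assign(**{rank: groups})
           .groupby([rank, "filter_id"], as_index=False)["abundance"].sum())
    totals = out.groupby("filter_id")["abundance"].transform("sum")
    out["abundance"] = np.where(totals > 0, out["abundance"] / totals, 0.0)
    return out


@dataclass
class UtilizationCall:
    ci_low: float | None
    ci_high: float | None
    utilized: bool | None
    evaluable: bool = True
    method: str = "t"


def afe_utilization(values, n_boot: int = 1000, seed=None,
                    method: str = "t") -> UtilizationCall:
    """Substrate-utilization call from replicate AFE values.

    The taxon is called a utilizer when both tails of the 95% confidence
    interval of the replicate AFE values exceed zero, i.e. ``ci_low > 0``.

    ``method="t"`` (default) uses the Student-t interval of the mean; with
    few replicates it is the only taxon-local construction whose
    false-positive rate under an AFE = 0 null stays near the nominal 2.5%.
    ``method="bootstrap"`` uses a seeded percentile bootstrap of the mean
    (``n_boot`` resamples); note that with n replicates an all-positive
    sample (probability 2^-n under a symmetric null) always yields an
    all-positive bootstrap distribution, so its small-n false-positive rate
    is bounded below by 2^-n.  Fewer than two replicates are not evaluable.
    """
    values = np.asarray(list(values), dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("AFE values must be finite")
    if len(values) < 2:
        return UtilizationCall(None, None, None, evaluable=False, method=method)
    if method == "t":
        mean = values.mean()
        half = stats.t.ppf(0.975, len(values) - 1) * stats.sem(values, ddof=1)
        if np.isnan(half):  # zero spread
            half = 0.0
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(values, size=(n_boot, len(values)), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
    else:
        raise ValueError(f"unknown method {method!r}")
    return UtilizationCall(float(lo), float(hi), bool(lo > 0), method=method)


@dataclass
class PercentDifferenceSummary:
    """Per-sample percent differences of a focal taxon's AFE vs the
    non-predatory community, with distribution summary."""

    per_sample: pd.Series
    median: float
    q1: float
    q3: float
    ci_low: float
    ci_high: float
    excluded_samples: list = field(default_factory=list)
    np_aggregate: str = "mean"


def _validate_afe_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in AFE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"AFE table missing columns: {missing}")
    if not np.isfinite(table["afe"].to_numpy(dtype=float)).all():
        raise ValueError("AFE values must be finite")
    return table


def afe_percent_difference(focal, table: pd.DataFrame,
                           np_aggregate: str = "mean",
                           n_boot: int = 1000, seed=None) -> PercentDifferenceSummary:
    """Percent difference of a focal taxon's AFE vs non-predatory taxa.

    ``focal`` maps sample_id -> the focal taxon's AFE in that sample;
    ``table`` is an AFE table (columns taxon_id, sample_id, replicate,
    isotope, afe, guild).  Per sample:
    ``100 * (AFE_P - AFE_NP) / AFE_NP`` where AFE_NP aggregates (mean or
    median) the replicate-mean AFE of every non-predatory taxon in that
    sample.  Samples whose NP aggregate is <= 0 are excluded and reported.
    The summary gives the median, inner quartiles and a seeded
    percentile-bootstrap 95% CI of the median of the per-sample
    distribution.
    """
    _validate_afe_table(table)
    if np_aggregate not in ("mean", "median"):
        raise ValueError("np_aggregate must be 'mean' or 'median'")
    focal = pd.Series(dict(focal)) if not isinstance(focal, pd.Series) else focal
    np_taxon_means = (table[table["guild"] == "non_predatory"]
                      .groupby(["sample_id", "taxon_id"])["afe"].mean())

    values, excluded = {}, []
    for sample, afe_p in focal.items():
        per_taxon = np_taxon_means.loc[sample] if sample in np_taxon_means.index.get_level_values(0) else None
        if per_taxon is None or len(per_taxon) == 0:
            raise ValueError(f"sample {sample!r} has no non-predatory taxa")
        afe_np = float(getattr(per_taxon, np_aggregate)())
        if afe_np <= 0:
            excluded.append(sample)
            continue
        values[sample] = 100.0 * (afe_p - afe_np) / afe_np
    per_sample = pd.Series(values, dtype=float)
    if per_sample.empty:
        raise ValueError("no sample with a positive non-predatory AFE aggregate")

    rng = np.random.default_rng(seed)
    arr = per_sample.to_numpy()
    boot_medians = np.median(
        rng.choice(arr, size=(n_boot, len(arr)), replace=True), axis=1)
    lo, hi = np.percentile(boot_medians, [2.5, 97.5])
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return PercentDifferenceSummary(
        per_sample=per_sample, median=float(med), q1=float(q1), q3=float(q3),
        ci_low=float(lo), ci_high=float(hi),
        excluded_samples=excluded, np_aggregate=np_aggregate)


def guild_activity_compare(table: pd.DataFrame) -> GroupComparison:
    """ANOVA + Tukey HSD of per-taxon mean AFE between guilds."""
    _validate_afe_table(table)
    per_taxon = table.groupby(["guild", "taxon_id"])["afe"].mean().reset_index()
    return group_compare(per_taxon["afe"].to_numpy(), per_taxon["guild"].to_numpy())
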