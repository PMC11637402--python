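"""Diversity and differentiation estimators for simulated haplotypes.

All estimators operate on a :class:`SiteFrequencyTable` — per-site,
per-deme allele counts — and use unordered distinct-pair counting
(sample-size corrected), so a site's diversity is the probability that
two haplotypes drawn without replacement differ at that site.  The
ordering ``pi_S <= pi_T <= pi_B`` holds for the underlying allele
frequencies; the unbiased estimators may invert it by at most their
correction terms (order ``1/n`` per deme), which vanishes at the sample
sizes the simulator produces.

``F_ST`` follows Hudson (``1 - pi_S / pi_B``) as a ratio of averages
across sites, after discarding sites whose pooled minor-allele
frequency is below a threshold (default 0.05); ``G_ST`` is the
total-diversity analogue ``1 - pi_S / pi_T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteFrequencyTable",
    "ReplicateSummary",
    "site_frequency_table",
    "pi_within",
    "pi_between",
    "pi_total",
    "minor_allele_frequency",
    "hudson_fst",
    "gst",
    "summarize_table",
    "summarize_replicates",
]


@dataclass
class SiteFrequencyTable:
    """Per-site allele counts split by deme.

    ``counts[s]`` is a ``(d, a_s)`` integer array for site ``s``
    (``a_s`` = number of distinct alleles observed at the site); every
    deme row sums to ``2 * N_local`` haplotypes.
    """

    counts: list[np.ndarray]
    n_per_deme: int

    def __post_init__(self) -> None:
        for s, c in enumerate(self.counts):
            if c.ndim != 2:
                raise ValueError(f"site {s}: counts must be 2-D (deme x allele)")
            if not np.all(c.sum(axis=1) == self.n_per_deme):
                raise ValueError(
                    f"site {s}: deme counts must each sum to {self.n_per_deme}")

    @property
    def n_sites(self) -> int:
        return len(self.counts)

    @property
    def d(self) -> int:
        return self.counts[0].shape[0] if self.counts else 0


def site_frequency_table(labels: np.ndarray, d: int) -> SiteFrequencyTable:
    """Build a table from an ``(H, L)`` matrix of per-haplotype allele
    labels, with haplotypes stored deme-contiguously."""
    H, L = labels.shape
    if H % d:
        raise ValueError("haplotype count not divisible by deme count")
    n = H // d
    deme_of = np.repeat(np.arange(d), n)
    counts = []
    for s in range(L):
        _, inv = np.unique(labels[:, s], return_inverse=True)
        a = inv.max() + 1
        c = np.zeros((d, a), dtype=np.int64)
        np.add.at(c, (deme_of, inv), 1)
        counts.append(c)
    return SiteFrequencyTable(counts=counts, n_per_deme=n)


# ---------------------------------------------------------------------------
# Per-site diversity components
# ---------------------------------------------------------------------------

def _pi_within_site(c: np.ndarray, n: int) -> float:
    """Mean over demes of P(two haplotypes drawn without replacement
    within the deme differ)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes per deme")
    same = (c * (c - 1)).sum(axis=1) / (n * (n - 1))
    return float(np.mean(1.0 - same))


def _pi_between_site(c: np.ndarray, n: int) -> float:
    """Mean over unordered deme pairs of P(two cross-deme haplotypes
    differ)."""
    d = c.shape[0]
    if d < 2:
        raise ValueError("pi_between requires at least 2 demes")
    tot = c.sum(axis=0).astype(float)
    # sum over pairs j<k of sum_a c_j c_k = (tot^2 - sum_j c_j^2) / 2
    cross_same = float(((tot ** 2).sum() - (c.astype(float) ** 2).sum()) / 2.0)
    n_pairs = d * (d - 1) / 2.0
    return 1.0 - cross_same / (n_pairs * n * n)


def _pi_total_site(c: np.ndarray, n: int) -> float:
    """P(two haplotypes drawn without replacement from the pooled
    metapopulation differ)."""
    tot = c.sum(axis=0)
    n_tot = int(tot.sum())
    same = (tot * (tot - 1)).sum() / (n_tot * (n_tot - 1))
    return float(1.0 - same)


def _maf_site(c: np.ndarray) -> float:
    tot = c.sum(axis=0)
    return float(1.0 - tot.max() / tot.sum())


# ---------------------------------------------------------------------------
# Table-level estimators
# ---------------------------------------------------------------------------

def pi_within(table: SiteFrequencyTable) -> float:
    """pi_S: per-site diversity within demes, averaged over sites and demes."""
    n = table.n_per_deme
    return float(np.mean([_pi_within_site(c, n) for c in table.counts]))


def pi_between(table: SiteFrequencyTable) -> float:
    """pi_B: per-site diversity between haplotypes from different demes."""
    n = table.n_per_deme
    return float(np.mean([_pi_between_site(c, n) for c in table.counts]))


def pi_total(table: SiteFrequencyTable) -> float:
    """pi_T: per-site diversity of the pooled metapopulation."""
    n = table.n_per_deme
    return float(np.mean([_pi_total_site(c, n) for c in table.counts]))


def minor_allele_frequency(table: SiteFrequencyTable) -> np.ndarray:
    """Pooled minor-allele frequency per site (1 - max allele frequency,
    which handles multi-allelic sites)."""
    return np.array([_maf_site(c) for c in table.counts])


def _passing(table: SiteFrequencyTable, maf_threshold: float) -> list[np.ndarray]:
    if maf_threshold <= 0.0:
        return table.counts
    maf = minor_allele_frequency(table)
    return [c for c, f in zip(table.counts, maf) if f >= maf_threshold]


def hudson_fst(table: SiteFrequencyTable, maf_threshold: float = 0.05) -> float:
    """Hudson's F_ST = 1 - mean(pi_S) / mean(pi_B) over sites passing
    the pooled-MAF filter (ratio of averages).  Returns ``nan`` when no
    site passes (undefined, deliberately not zero)."""
    keep = _passing(table, maf_threshold)
    if not keep:
        return math.nan
    n = table.n_per_deme
    ps = np.mean([_pi_within_site(c, n) for c in keep])
    pb = np.mean([_pi_between_site(c, n) for c in keep])
    if pb == 0.0:
        return math.nan
    return float(1.0 - ps / pb)


def gst(table: SiteFrequencyTable, maf_threshold: float = 0.0) -> float:
    """G_ST = 1 - mean(pi_S) / mean(pi_T); unfiltered by default."""
    keep = _passing(table, maf_threshold)
    if not keep:
        return math.nan
    n = table.n_per_deme
    ps = np.mean([_pi_within_site(c, n) for c in keep])
    pt = np.mean([_pi_total_site(c, n) for c in keep])
    if pt == 0.0:
        return math.nan
    return float(1.0 - ps / pt)


# ---------------------------------------------------------------------------
# Replicate summaries
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSummary:
    """Summary statistics of one simulated replicate.

    ``pi_*`` are unfiltered per-site averages; ``F_ST`` and ``G_ST``
    are computed on sites passing the MAF filter used at construction.
    """

    pi_S: float
    pi_B: float
    pi_T: float
    F_ST: float
    G_ST: float
    n_sites_passing: int
    replicate: int = -1
    fixed_deleterious: int = 0


def summarize_table(table: SiteFrequencyTable,
                    maf_threshold: float = 0.05) -> ReplicateSummary:
    """All summary statistics for one replicate's frequency table."""
    d = table.d
    ps = pi_within(table)
    pt = pi_total(table)
    if d >= 2:
        pb = pi_between(table)
        f = hudson_fst(table, maf_threshold)
        g = gst(table, maf_threshold)
    else:
        pb, f, g = pt, math.nan, math.nan
    return ReplicateSummary(
        pi_S=ps, pi_B=pb, pi_T=pt, F_ST=f, G_ST=g,
        n_sites_passing=len(_passing(table, maf_threshold)),
    )


def summarize_replicates(
    summaries: list[ReplicateSummary],
    ci: tuple[float, float] = (2.5, 97.5),
) -> dict[str, dict[str, float]]:
    """Cross-replicate means and percentile confidence intervals.

    Replicates whose statistic is undefined (``nan``, e.g. no site
    passed the MAF filter) are dropped for that statistic.
    """
    out: dict[str, dict[str, float]] = {}
    for stat in ("pi_S", "pi_B", "pi_T", "F_ST", "G_ST"):
        vals = np.array([getattr(s, stat) for s in summaries], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[stat] = {"mean": math.nan, "ci_low": math.nan,
                         "ci_high": math.nan, "n": 0}
            continue
        lo, hi = np.percentile(vals, ci)
        out[stat] = {"mean": float(vals.mean()), "ci_low": float(lo),
                     "ci_high": float(hi), "n": int(vals.size)}
    return out
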