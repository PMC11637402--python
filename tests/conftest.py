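"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bgsisland import IslandParams, SelectionSegment


@pytest.fixture
def study_segment() -> SelectionSegment:
    """The selected region used throughout the study design:
    700 sites, U = 7e-3, strong selection (N_local * t = 7.5)."""
    return SelectionSegment(t=0.015, mu_del=1e-5, L=700, M=0.0)


@pytest.fixture
def study_island() -> IslandParams:
    return IslandParams(d=10, N_local=500, m=0.009)


# ---------------------------------------------------------------------------
# Exhaustive pairwise-difference oracle for the diversity estimators
# ---------------------------------------------------------------------------

def pairwise_oracle(labels: np.ndarray, d: int) -> dict[str, float]:
    """Diversity statistics by exhaustive enumeration of haplotype pairs.

    ``labels`` is (H, L) with haplotypes deme-contiguous.  Per site,
    diversity is the fraction of differing pairs among the relevant
    pairs (within-deme pairs averaged over demes for pi_S, cross-deme
    pairs averaged over deme pairs for pi_B, all pooled pairs for
    pi_T); statistics average over sites.  Completely independent of
    the count-based implementation.
    """
    H, L = labels.shape
    n = H // d
    deme_of = np.repeat(np.arange(d), n)
    pi_s_sites, pi_b_sites, pi_t_sites = [], [], []
    for s in range(L):
        col = labels[:, s]
        per_deme = []
        for dd in range(d):
            pairs = list(itertools.combinations(np.nonzero(deme_of == dd)[0], 2))
            per_deme.append(np.mean([col[i] != col[j] for i, j in pairs]))
        pi_s_sites.append(np.mean(per_deme))
        if d >= 2:
            per_pair = []
            for d1, d2 in itertools.combinations(range(d), 2):
                diffs = [col[i] != col[j]
                         for i in np.nonzero(deme_of == d1)[0]
                         for j in np.nonzero(deme_of == d2)[0]]
                per_pair.append(np.mean(diffs))
            pi_b_sites.append(np.mean(per_pair))
        pairs = list(itertools.combinations(range(H), 2))
        pi_t_sites.append(np.mean([col[i] != col[j] for i, j in pairs]))
    out = {"pi_S": float(np.mean(pi_s_sites)),
           "pi_T": float(np.mean(pi_t_sites))}
    if d >= 2:
        out["pi_B"] = float(np.mean(pi_b_sites))
    return out


def oracle_fst(labels: np.ndarray, d: int, maf_threshold: float = 0.05):
    """Hudson F_ST and G_ST by exhaustive enumeration (ratio of
    averages over MAF-passing sites)."""
    H, L = labels.shape
    keep = []
    for s in range(L):
        _, counts = np.unique(labels[:, s], return_counts=True)
        if 1.0 - counts.max() / H >= maf_threshold:
            keep.append(s)
    if not keep:
        return np.nan, np.nan
    o = pairwise_oracle(labels[:, keep], d)
    return 1.0 - o["pi_S"] / o["pi_B"], 1.0 - o["pi_S"] / o["pi_T"]
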