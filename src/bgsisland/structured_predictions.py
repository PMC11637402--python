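"""Metapopulation-level predictions: F_ST, G_ST, global N_e and diversity.

Builds on the local BGS solution to predict differentiation and
diversity for the whole island model.  Differentiation follows the
Hudson definition ``F_ST = 1 - pi_S / pi_B`` and its total-diversity
analogue ``G_ST = 1 - pi_S / pi_T``.  The finite-island equilibrium
formulas used here assume reproduction (drift) happens first, then
migration, then measurement, and retain terms of order m^2::

    F_ST = 1 / (1 + (d-1) d (4 - 2m) N_local B_local m / (d(1-m) - 1)^2)
    G_ST = 1 / (1 +   d^2   (4 - 2m) N_local B_local m / (d(1-m) - 1)^2)

Background selection enters purely through the rescaled local size
``B_local * N_local``.  Total diversity uses the structure-inflated
global effective size ``N_e,global = N_global / (1 - G_ST)`` and a
global BGS factor ``B_global``, with the saturating infinite-alleles
form ``pi_T = theta / (1 + theta)``, ``theta = 4 N_e,global B_global mu``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .bgs_theory import (
    BGSLocalResult,
    IslandParams,
    NeutralRegion,
    SelectionSegment,
    heterozygosity_B,
    solve_local_equilibrium,
)

__all__ = [
    "MetapopPrediction",
    "predict_fst",
    "predict_gst",
    "predict_fst_two_island_haploid",
    "global_effective_size",
    "predict_pi",
]


@dataclass
class MetapopPrediction:
    """Predicted metapopulation quantities under background selection.

    ``pi_B_pred`` is derived from ``pi_S`` and Hudson's ``F_ST``
    (``pi_B = pi_S / (1 - F_ST)``); an equivalent route through
    ``pi_T`` and ``G_ST`` gives the same number because both ratios
    come from the same local rescaling.
    """

    F_ST_pred: float
    G_ST_pred: float
    N_e_global: float
    B_global: float
    pi_T_pred: float
    pi_S_pred: float
    pi_B_pred: float
    pi_T_neutral: float
    pi_S_neutral: float
    F_ST_neutral: float
    G_ST_neutral: float
    N_e_global_neutral: float
    B_local: float
    B_local_het: float
    local: BGSLocalResult | None = None


def _fst_denominator_term(island: IslandParams, B_local: float) -> float:
    d, m = island.d, island.m
    core = d * (1.0 - m) - 1.0
    if core <= 0:
        raise ValueError("d(1-m) - 1 must be positive for the equilibrium formula")
    return (4.0 - 2.0 * m) * island.N_local * B_local * m / core ** 2


def predict_fst(island: IslandParams, B_local: float) -> float:
    """Equilibrium Hudson F_ST in a finite island model under BGS.

    Requires ``d >= 2`` and ``m > 0`` (without migration there is no
    migration-drift equilibrium).  Decreasing in both ``m`` and the
    rescaled local size ``N_local * B_local``; as ``m -> 0`` it tends to
    the familiar ``1 / (4 N_e m d/(d-1) + 1)``.
    """
    if island.d < 2:
        raise ValueError("F_ST prediction requires d >= 2")
    if island.m <= 0:
        raise ValueError("F_ST prediction requires m > 0")
    if not (0.0 < B_local <= 1.0):
        raise ValueError(f"B_local must be in (0, 1], got {B_local}")
    return 1.0 / (1.0 + (island.d - 1) * island.d * _fst_denominator_term(island, B_local))


def predict_gst(island: IslandParams, B_local: float) -> float:
    """Equilibrium G_ST (``1 - pi_S/pi_T``) in a finite island model.

    Same preconditions as :func:`predict_fst`; always <= the Hudson
    F_ST for the same inputs because ``pi_T <= pi_B``.
    """
    if island.d < 2:
        raise ValueError("G_ST prediction requires d >= 2")
    if island.m <= 0:
        raise ValueError("G_ST prediction requires m > 0")
    if not (0.0 < B_local <= 1.0):
        raise ValueError(f"B_local must be in (0, 1], got {B_local}")
    return 1.0 / (1.0 + island.d ** 2 * _fst_denominator_term(island, B_local))


def predict_fst_two_island_haploid(N_local: float, B: float, m: float) -> float:
    """Classic two-island haploid approximation ``F_ST = 1/(4 B N m + 1)``."""
    if N_local <= 0 or B <= 0 or m <= 0:
        raise ValueError("N_local, B and m must be positive")
    return 1.0 / (4.0 * B * N_local * m + 1.0)


def global_effective_size(island: IslandParams, G_ST: float) -> float:
    """Global effective size of the metapopulation, ``N_global / (1 - G_ST)``.

    Population structure stretches coalescence times for lineages in
    different demes, inflating the effective size of the metapopulation
    above its census size; equals ``N_global`` when ``G_ST = 0``.
    """
    if not (0.0 <= G_ST < 1.0):
        raise ValueError(f"G_ST must be in [0, 1), got {G_ST}")
    return island.N_global / (1.0 - G_ST)


def _saturating_pi(N_e: float, mu: float) -> float:
    theta = 4.0 * N_e * mu
    return theta / (1.0 + theta)


def _global_B(N_e_global: float, segments: Sequence[SelectionSegment],
              tau_horizon_factor: float = 10.0) -> float:
    """Global BGS factor: the metapopulation treated as one panmictic
    unit of size ``N_e,global`` (heterozygosity variant, interference
    rescaling on)."""
    pan = IslandParams(d=1, N_local=N_e_global, m=0.0)
    solved = solve_local_equilibrium(pan, segments, apply_migration_effect=False,
                                     interference_rescale=True)
    _, B_het = heterozygosity_B(pan, segments, solved,
                                apply_migration_effect=False,
                                tau_horizon_factor=tau_horizon_factor)
    return B_het


def predict_pi(
    island: IslandParams,
    segments: Sequence[SelectionSegment],
    neutral: NeutralRegion,
    tau_horizon_factor: float = 10.0,
) -> MetapopPrediction:
    """Full prediction pipeline for diversity and differentiation.

    Solves the local BGS model (migration effect and interference
    rescaling on, heterozygosity variant), predicts ``G_ST``/``F_ST``
    from the rescaled local size, inflates to ``N_e,global``, computes
    the global BGS factor at that size, and finally the saturating
    diversity ``pi_T = theta/(1+theta)``.  ``pi_S = pi_T (1 - G_ST)``
    and ``pi_B = pi_S / (1 - F_ST)``.  Neutral baselines repeat the
    pipeline with ``B = 1``.

    With ``d == 1`` (panmictic) differentiation is zero by definition
    and only the diversity quantities are meaningful.
    """
    mu = neutral.mu_neutral
    solved = solve_local_equilibrium(island, segments,
                                     apply_migration_effect=True,
                                     interference_rescale=True)
    N_eH, B_het = heterozygosity_B(island, segments, solved,
                                   apply_migration_effect=True,
                                   tau_horizon_factor=tau_horizon_factor)
    solved.N_eH_local, solved.B_local_het = N_eH, B_het

    if island.d == 1:
        F = G = F0 = G0 = 0.0
        N_eg = N_eg0 = island.N_global
    else:
        F = predict_fst(island, B_het)
        G = predict_gst(island, B_het)
        F0 = predict_fst(island, 1.0)
        G0 = predict_gst(island, 1.0)
        N_eg = global_effective_size(island, G)
        N_eg0 = global_effective_size(island, G0)

    B_global = _global_B(N_eg, segments, tau_horizon_factor)
    pi_T = _saturating_pi(N_eg * B_global, mu)
    pi_S = pi_T * (1.0 - G)
    pi_B = pi_S / (1.0 - F) if F < 1.0 else float("nan")
    pi_T0 = _saturating_pi(N_eg0, mu)
    pi_S0 = pi_T0 * (1.0 - G0)

    return MetapopPrediction(
        F_ST_pred=F, G_ST_pred=G, N_e_global=N_eg, B_global=B_global,
        pi_T_pred=pi_T, pi_S_pred=pi_S, pi_B_pred=pi_B,
        pi_T_neutral=pi_T0, pi_S_neutral=pi_S0,
        F_ST_neutral=F0, G_ST_neutral=G0, N_e_global_neutral=N_eg0,
        B_local=solved.B_local, B_local_het=B_het, local=solved,
    )
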