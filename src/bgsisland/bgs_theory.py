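"""Background-selection theory for a single subpopulation of an island model.

The strength of background selection (BGS) is summarised by
``B = N_e / N_e0``, the factor by which purifying selection at linked
sites shrinks the effective population size experienced by a neutral
locus.  Two families of predictions are implemented here:

* the classic deterministic mutation-selection-balance formulas
  (:func:`classic_B_site_sum`, :func:`classic_B_region`), valid for
  strongly selected deleterious alleles, and
* a quantitative-genetic model that remains valid under weak selection
  (the interference regime), in which a neutral lineage's excess
  variance in reproductive success is ``V_A * Q^2`` — the additive
  fitness variance of linked selected sites times a "linkage inflation
  factor" summing the lineage's cross-generation association with
  deleterious backgrounds.  In a subpopulation exchanging migrants at
  rate ``m`` the association is also broken by emigration, which enters
  as a ``(1 - m)`` factor per generation inside ``Q^2`` (the "migration
  effect": migration weakens local BGS).

The weak-selection model couples two unknowns — the local
fitness-effective size ``N_f,local = B_local * N_local`` and the
fixation rate ``R`` of deleterious alleles — and is solved to a fixed
point by :func:`solve_local_equilibrium`.  A heterozygosity-effective
size ``N_eH`` (the size relevant to equilibrium diversity, lying
between ``N_f`` and ``N``) is obtained by :func:`heterozygosity_B`.

Unit conventions
----------------
``U`` on a :class:`SelectionSegment` is the *gametic* deleterious
mutation rate of the segment (``mu_del * L``, per haploid genome per
generation).  The diploid genomic rate is ``2 U``.  The additive fitness
variance at mutation-selection balance is ``V_A = 2 U t`` (diploid
rate times the heterozygous effect), reduced to ``V_A = (2U - 2R) t``
when fixation removes variance; the fixation rate from the diffusion
result, ``R = 4 N_f U t / (exp(4 N_f t) - 1)``, uses the gametic rate
and tends to ``U`` (the neutral substitution rate) as ``t -> 0``, so
``V_A`` tends to zero smoothly in the neutral limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "IslandParams",
    "SelectionSegment",
    "NeutralRegion",
    "SegmentDiagnostics",
    "BGSLocalResult",
    "classic_B_site_sum",
    "classic_B_region",
    "decay_factor_Z",
    "q_infinity_sq_point",
    "q_infinity_sq_region",
    "fixation_rate",
    "solve_local_equilibrium",
    "heterozygosity_B",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandParams:
    """Demographic structure of a finite island model.

    Parameters
    ----------
    d
        Number of demes (>= 1).
    N_local
        Diploid individuals per deme.
    m
        Total immigrant fraction per deme per generation, in [0, 1).
        A single deme (``d == 1``) forces ``m == 0``.
    """

    d: int
    N_local: float
    m: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"deme count d must be >= 1, got {self.d}")
        if self.N_local <= 0:
            raise ValueError(f"N_local must be positive, got {self.N_local}")
        if not (0.0 <= self.m < 1.0):
            raise ValueError(f"migration rate m must be in [0, 1), got {self.m}")
        if self.d == 1 and self.m != 0.0:
            raise ValueError("a single deme (d=1) requires m=0")

    @property
    def N_global(self) -> float:
        """Total diploid size of the metapopulation, d * N_local."""
        return self.d * self.N_local


@dataclass(frozen=True)
class SelectionSegment:
    """A contiguous region of sites under purifying selection.

    ``t`` is the selection coefficient against heterozygotes (fitness of
    a heterozygote is ``1 - t``; effects multiply across allele copies),
    ``mu_del`` the per-base-pair deleterious mutation rate per gamete,
    ``L`` the number of selected sites and ``M`` the segment's map
    length in Morgans.  ``U = mu_del * L`` is the gametic deleterious
    mutation rate of the whole segment.
    """

    t: float
    mu_del: float
    L: int
    M: float = 0.0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"t must be >= 0, got {self.t}")
        if self.mu_del < 0:
            raise ValueError(f"mu_del must be >= 0, got {self.mu_del}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if self.M < 0:
            raise ValueError(f"M must be >= 0, got {self.M}")

    @property
    def U(self) -> float:
        """Gametic deleterious mutation rate of the segment (mu_del * L)."""
        return self.mu_del * self.L


@dataclass(frozen=True)
class NeutralRegion:
    """The focal neutral region: per-bp gametic mutation rate and length."""

    mu_neutral: float
    L_neutral: int

    def __post_init__(self) -> None:
        if self.mu_neutral < 0:
            raise ValueError("mu_neutral must be >= 0")
        if self.L_neutral < 1:
            raise ValueError("L_neutral must be >= 1")


@dataclass(frozen=True)
class SegmentDiagnostics:
    """Per-segment quantities at the solved equilibrium.

    ``Z`` is the per-generation decay factor of the fitness-variance
    association (``1 - V_M / V_A``), ``V_A`` the segment's additive
    fitness variance, ``V_M ~= 2 U t^2`` the mutational variance,
    ``Q_inf_sq`` the asymptotic region-averaged linkage inflation
    factor and ``R`` the segment's deleterious fixation rate.
    ``clamped`` flags segments whose ``V_A`` or ``Z`` hit the physical
    bounds (fully drift-dominated).
    """

    Z: float
    V_A: float
    V_M: float
    Q_inf_sq: float
    R: float
    clamped: bool = False


@dataclass
class BGSLocalResult:
    """Solved local BGS quantities for one subpopulation."""

    B_local: float
    N_f_local: float
    R: float
    N_eH_local: float | None = None
    B_local_het: float | None = None
    diagnostics: list[SegmentDiagnostics] = field(default_factory=list)
    converged: bool = True
    iterations: int = 0


class ConvergenceError(RuntimeError):
    """Raised when the coupled (N_f, R) solver fails; carries last iterate."""

    def __init__(self, message: str, last_B: float, last_R: float):
        super().__init__(message)
        self.last_B = last_B
        self.last_R = last_R


# ---------------------------------------------------------------------------
# Classic deterministic formulas (background selection regime)
# ---------------------------------------------------------------------------

def classic_B_site_sum(
    mu: Sequence[float] | np.ndarray,
    t: Sequence[float] | np.ndarray,
    r: Sequence[float] | np.ndarray,
) -> float:
    """Deterministic B from a per-site sum, ``exp[-sum mu_i t_i / (r_i + t_i)^2]``.

    ``mu_i``, ``t_i`` and ``r_i`` are the deleterious mutation rate,
    heterozygous selection coefficient and recombination fraction to the
    focal neutral site for each selected site.  Requires ``t_i > 0``
    everywhere (the deterministic formula has no meaning without
    selection).
    """
    mu = np.asarray(mu, dtype=float)
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    if mu.size == 0:
        return 1.0
    if np.any(t <= 0):
        raise ValueError("classic_B_site_sum requires t > 0 at every site")
    if np.any(r < 0) or np.any(mu < 0):
        raise ValueError("mu and r must be non-negative")
    return float(np.exp(-np.sum(mu * t / (r + t) ** 2)))


def classic_B_region(U: float, t: float, M: float) -> float:
    """Deterministic B for a region: ``exp[-2U / (2t + M)]``.

    Continuous-region limit of the site sum for a neutral site embedded
    in the centre of a selected region of total map length ``M`` Morgans
    with gametic deleterious rate ``U`` and uniform heterozygous effect
    ``t``.
    """
    if U < 0:
        raise ValueError("U must be >= 0")
    if U == 0:
        return 1.0
    denom = 2.0 * t + M
    if denom <= 0:
        raise ValueError("classic_B_region requires 2t + M > 0 when U > 0")
    return math.exp(-2.0 * U / denom)


# ---------------------------------------------------------------------------
# Quantitative-genetic model building blocks
# ---------------------------------------------------------------------------

def decay_factor_Z(U: float, t: float, R: float) -> tuple[float, bool]:
    """Per-generation decay factor ``Z = 1 - U t / (U - 2R)`` of the
    fitness-variance association, clamped to ``[0, 1)``.

    ``U`` here is the mutation rate on the same scale as the variance
    ratio ``V_M / V_A = U t / (U - 2R)`` (callers solving the diploid
    system pass the diploid genomic rate).  With ``R = 0`` this is the
    strong-selection limit ``Z = 1 - t``.  When fixation has consumed
    the additive variance (``U - 2R <= U t``) the association decays
    instantly: returns ``(0.0, True)`` with the clamp flag set.
    """
    if U <= 0:
        raise ValueError("decay_factor_Z requires U > 0")
    if R == 0:
        z = 1.0 - t
        return (z, False) if z > 0 else (0.0, True)
    denom = U - 2.0 * R
    if denom <= 0 or denom <= U * t:
        return 0.0, True
    z = 1.0 - U * t / denom
    if z >= 1.0:  # t == 0: no decay through selection
        return math.nextafter(1.0, 0.0), False
    return z, False


def q_infinity_sq_point(r: float, Z: float, m: float) -> float:
    """Asymptotic linkage inflation factor at recombination fraction ``r``.

    The association of a neutral lineage with a deleterious background
    decays per generation by selection (``Z``), recombination
    (``1 - r``) and emigration (``1 - m``); summing the autocorrelation
    ``C(tau) = [Z (1-r)(1-m)]^tau`` over all generations and squaring
    gives ``Q^2 = [1 / (1 - Z(1-r)(1-m))]^2 >= 1``.
    """
    a = Z * (1.0 - r) * (1.0 - m)
    if a < 0:
        raise ValueError("Z(1-r)(1-m) must be >= 0")
    if a >= 1.0:
        raise ValueError(f"geometric sum diverges: Z(1-r)(1-m) = {a} >= 1")
    return (1.0 / (1.0 - a)) ** 2


def q_infinity_sq_region(M: float, Z: float, m: float) -> float:
    """Region-averaged asymptotic ``Q^2`` for a segment of map length ``M``.

    Average of :func:`q_infinity_sq_point` over ``r in [0, M/2]`` (the
    neutral site sits at the centre of the segment, so the relevant
    recombination fractions run from 0 to half the map length)::

        (2/M) * int_0^{M/2} dr / (1 - a + a r)^2
            = 1 / [(1 - a) * (1 - a + a M / 2)],   a = Z (1 - m).

    Reduces to the point value at ``M = 0``.
    """
    if M < 0:
        raise ValueError("M must be >= 0")
    a = Z * (1.0 - m)
    if a < 0:
        raise ValueError("Z(1-m) must be >= 0")
    if a >= 1.0:
        raise ValueError(f"Z(1-m) = {a} >= 1: Q^2 diverges")
    if M == 0.0:
        return q_infinity_sq_point(0.0, Z, m)
    return 1.0 / ((1.0 - a) * (1.0 - a + a * M / 2.0))


def fixation_rate(N_f: float, U: float, t: float) -> float:
    """Per-generation fixation rate of deleterious alleles.

    Diffusion result ``R = 4 N_f U t / (exp(4 N_f t) - 1)``: the influx
    of new deleterious mutations (``2 N_f`` gametic genomes times the
    gametic rate ``U``) times the fixation probability of a semidominant
    deleterious allele.  Continuous at ``t = 0`` where ``R -> U`` (the
    neutral substitution rate) and vanishing as ``N_f t -> infinity``.
    """
    if N_f <= 0:
        raise ValueError("N_f must be > 0")
    if U < 0 or t < 0:
        raise ValueError("U and t must be >= 0")
    x = 4.0 * N_f * t
    if x < 1e-8:
        # x / (e^x - 1) = 1 - x/2 + O(x^2)
        return U * (1.0 - 0.5 * x)
    # x e^{-x} / (1 - e^{-x}) is overflow-safe for large x
    return U * x * math.exp(-x) / (-math.expm1(-x))


# ---------------------------------------------------------------------------
# Coupled local equilibrium
# ---------------------------------------------------------------------------

def _evaluate_B(
    B: float,
    segments: Sequence[SelectionSegment],
    N_local: float,
    m_eff: float,
    interference_rescale: bool,
) -> tuple[float, list[SegmentDiagnostics]]:
    """One evaluation of the model: given a trial B, recompute R per
    segment at the (optionally rescaled) population size and return the
    implied B together with per-segment diagnostics."""
    theta = 0.0
    diags: list[SegmentDiagnostics] = []
    for seg in segments:
        U = seg.U
        if U == 0.0 or seg.t == 0.0:
            diags.append(SegmentDiagnostics(Z=0.0, V_A=0.0, V_M=0.0,
                                            Q_inf_sq=1.0, R=U if seg.t == 0 else 0.0))
            continue
        N_fix = B * N_local if interference_rescale else N_local
        R = fixation_rate(N_fix, U, seg.t)
        U_dip = 2.0 * U
        V_M = U_dip * seg.t ** 2
        V_A = (U_dip - 2.0 * R) * seg.t
        clamped = False
        if V_A <= 0.0:
            V_A = 0.0
            clamped = True
        Z, z_clamped = decay_factor_Z(U_dip, seg.t, R)
        clamped = clamped or z_clamped
        Q2 = q_infinity_sq_region(seg.M, Z, m_eff)
        theta += V_A * Q2 / 2.0
        diags.append(SegmentDiagnostics(Z=Z, V_A=V_A, V_M=V_M, Q_inf_sq=Q2,
                                        R=R, clamped=clamped))
    return math.exp(-theta), diags


def solve_local_equilibrium(
    island: IslandParams,
    segments: Sequence[SelectionSegment],
    apply_migration_effect: bool = True,
    interference_rescale: bool = True,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> BGSLocalResult:
    """Solve the coupled (N_f,local, R) system for one subpopulation.

    The fitness-effective size satisfies
    ``N_f = N_local * exp[-sum_i V_A,i Q_i^2 / 2]`` with
    ``V_A = (2U - 2R) t`` and the region-averaged ``Q^2`` carrying the
    ``(1 - m)`` migration factor, while ``R`` is the fixation rate
    evaluated at the effective size of the selected sites themselves.
    With ``interference_rescale`` the selected sites are taken to
    experience the same BGS as the neutral site (their effective size is
    the rescaled ``B_local * N_local``), closing the system into a fixed
    point on ``B_local``; without it, ``R`` is evaluated once at the
    census size ``N_local``.  ``apply_migration_effect=False`` drops the
    ``(1 - m)`` factors (panmictic behaviour, for comparison).

    Damped fixed-point iteration, falling back to a bracketed root solve
    if oscillating; raises :class:`ConvergenceError` on failure.
    """
    m_eff = island.m if apply_migration_effect else 0.0

    if all(seg.U == 0.0 or seg.t == 0.0 for seg in segments):
        B, diags = _evaluate_B(1.0, segments, island.N_local, m_eff, False)
        return BGSLocalResult(B_local=1.0, N_f_local=float(island.N_local),
                              R=sum(d.R for d in diags), diagnostics=diags,
                              converged=True, iterations=0)

    if not interference_rescale:
        B, diags = _evaluate_B(1.0, segments, island.N_local, m_eff, False)
        return BGSLocalResult(B_local=B, N_f_local=B * island.N_local,
                              R=sum(d.R for d in diags), diagnostics=diags,
                              converged=True, iterations=1)

    B = 1.0
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        B_model, _ = _evaluate_B(B, segments, island.N_local, m_eff, True)
        B_next = B + damping * (B_model - B)
        if abs(B_next - B) <= tol * max(B_next, 1e-300):
            B = B_next
            converged = True
            break
        B = B_next

    if not converged:
        # fall back to a bracketed root solve on f(B) = B - model(B)
        def f(b: float) -> float:
            return b - _evaluate_B(b, segments, island.N_local, m_eff, True)[0]

        try:
            B = optimize.brentq(f, 1e-12, 1.0, xtol=1e-14, rtol=8.9e-16)
            converged = True
        except ValueError as exc:  # pragma: no cover - defensive
            _, diags = _evaluate_B(B, segments, island.N_local, m_eff, True)
            raise ConvergenceError(
                f"local BGS solver did not converge after {max_iter} iterations",
                last_B=B, last_R=sum(d.R for d in diags)) from exc

    B_final, diags = _evaluate_B(B, segments, island.N_local, m_eff, True)
    return BGSLocalResult(B_local=B_final, N_f_local=B_final * island.N_local,
                          R=sum(d.R for d in diags), diagnostics=diags,
                          converged=converged, iterations=iterations)


# ---------------------------------------------------------------------------
# Heterozygosity-effective size
# ---------------------------------------------------------------------------

def _q_sq_tau_region(M: float, Z: float, m: float, tau: np.ndarray,
                     n_nodes: int = 64) -> np.ndarray:
    """Time-dependent region-averaged linkage factor ``Q^2(tau)``.

    ``Q^2(tau, r) = [(1 - a^tau) / (1 - a)]^2`` with
    ``a = Z (1-r)(1-m)``, averaged over ``r in [0, M/2]`` with
    Gauss-Legendre quadrature (a single node at ``r = 0`` when
    ``M == 0``).  Returns an array over ``tau``.
    """
    if M == 0.0:
        r_nodes = np.array([0.0])
        weights = np.array([1.0])
    else:
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        r_nodes = 0.5 * (x + 1.0) * (M / 2.0)
        weights = w / 2.0  # normalised average over [0, M/2]
    a = Z * (1.0 - r_nodes) * (1.0 - m)  # (nodes,)
    a = np.clip(a, 0.0, 1.0 - 1e-15)
    with np.errstate(divide="ignore"):
        log_a = np.where(a > 0, np.log(a), -np.inf)
    pow_a = np.exp(tau[:, None] * log_a[None, :])  # (tau, nodes)
    q = ((1.0 - pow_a) / (1.0 - a[None, :])) ** 2
    return q @ weights


def heterozygosity_B(
    island: IslandParams,
    segments: Sequence[SelectionSegment],
    solved: BGSLocalResult,
    apply_migration_effect: bool = True,
    tau_horizon_factor: float = 10.0,
) -> tuple[float, float]:
    """Heterozygosity-effective size ``N_eH,local`` and ``B_local_het``.

    Neutral alleles segregating at equilibrium arose at different times
    in the past, so they have accumulated different amounts of the
    cross-generation association that drives BGS; the asymptotic
    ``Q^2`` overstates the effect for young alleles.  Using the
    time-dependent factor, a neutral allele that arose ``tau``
    generations ago experienced effective size
    ``N_f(tau) = N_local * exp[-sum_i V_A,i Q_i^2(tau) / 2]``.
    Equilibrium diversity is proportional to the expected lifetime of a
    lineage, giving

        ``B_het = (1 / 2N_local) * sum_tau prod_{i<tau} (1 - 1/(2 N_f(i)))``

    (the running product is the probability a lineage survives drift
    for ``tau`` generations; the empty product at ``tau = 0`` is 1).
    The sum is truncated at ``tau_horizon_factor * N_local`` generations
    and the geometric tail is added analytically at the asymptotic
    ``N_f``, which makes the neutral limit exactly 1.

    Returns ``(N_eH_local, B_local_het)``; ``B_local <= B_het <= 1``.
    """
    N = float(island.N_local)
    m_eff = island.m if apply_migration_effect else 0.0
    T = max(2, int(round(tau_horizon_factor * N)))
    tau = np.arange(T, dtype=float)

    theta_tau = np.zeros(T)
    for seg, diag in zip(segments, solved.diagnostics):
        if diag.V_A <= 0.0 or diag.Z <= 0.0:
            continue
        q2 = _q_sq_tau_region(seg.M, diag.Z, m_eff, tau)
        theta_tau += diag.V_A * q2 / 2.0
    N_f_tau = N * np.exp(-theta_tau)

    # survival probability through generations 0 .. tau-1
    log_surv = np.log1p(-1.0 / (2.0 * np.maximum(N_f_tau, 0.50001)))
    cum = np.concatenate(([0.0], np.cumsum(log_surv)))  # P(tau), tau = 0..T
    P = np.exp(cum)
    N_f_inf = max(solved.N_f_local, 0.50001)
    total = P[:-1].sum() + P[-1] * 2.0 * N_f_inf  # analytic geometric tail
    B_het = float(total / (2.0 * N))
    B_het = min(B_het, 1.0)
    return B_het * N, B_het
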