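"""Forward-time diploid Wright-Fisher island-model simulator with BGS.

Replicates the study design used throughout this package's theory at a
configurable scale: ``d`` demes of ``N_local`` diploids, a central
block of neutral sites flanked on both sides by selected sites, fitness
multiplicative across deleterious allele copies (``w = (1-t)^k``),
non-overlapping generations with the event order

    reproduction (selection + recombination + mutation)  ->  migration

which matters: the equilibrium F_ST formula in
:mod:`bgsisland.structured_predictions` assumes drift happens before
migration each generation.

Representation.  The neutral block is internally non-recombining, so a
haplotype's entire neutral sequence is inherited as a unit.  Each
distinct neutral sequence lives as one row of a per-replicate "pool"
array and haplotypes carry integer ids into it; reproduction copies ids
(cheap) and only a neutral mutation materialises a new row.  Selected
sites are explicit biallelic 0/1 matrices.  Replicates are advanced in
lock-step inside one set of numpy arrays, which is what makes the
replicate counts used for confidence intervals affordable.

Neutral mutations follow an infinite-alleles model per site (every
event creates a novel allele label), matching the saturating diversity
expectation ``pi = theta / (1 + theta)``.  Deleterious mutation is
irreversible; events landing on an already-mutant site are no-ops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bgs_theory import IslandParams
from .popgen_stats import ReplicateSummary, site_frequency_table, summarize_table

__all__ = [
    "GenomeLayout",
    "SimConfig",
    "PopulationState",
    "fitness",
    "run_replicates",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Genome architecture: [flank A][neutral block][flank B].

    ``L_selected`` selected sites are split evenly between the two
    flanks; ``M`` is the total map length (Morgans) spanning the
    selected region, with the neutral block sitting — indivisible — at
    the map's midpoint.
    """

    L_neutral: int
    L_selected: int
    M: float = 0.0

    def __post_init__(self) -> None:
        if self.L_neutral < 1:
            raise ValueError("L_neutral must be >= 1")
        if self.L_selected < 0 or self.L_selected % 2:
            raise ValueError("L_selected must be even and >= 0")
        if self.M < 0:
            raise ValueError("M must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to run a batch of replicates."""

    island: IslandParams
    layout: GenomeLayout
    t: float
    U: float
    mu_neutral: float
    generations: int
    replicates: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.t < 0 or self.U < 0 or self.mu_neutral < 0:
            raise ValueError("rates must be non-negative")
        if self.U > 0 and self.layout.L_selected == 0:
            raise ValueError("U > 0 requires selected sites in the layout")

    @property
    def mu_del_per_site(self) -> float:
        """Per-selected-site deleterious mutation rate, U / L_selected."""
        if self.layout.L_selected == 0:
            return 0.0
        return self.U / self.layout.L_selected


def fitness(k: np.ndarray | int, t: float) -> np.ndarray | float:
    """Multiplicative fitness ``w = (1 - t)^k`` for ``k`` deleterious
    allele copies carried by an individual (both haplotypes)."""
    return (1.0 - t) ** np.asarray(k)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

class PopulationState:
    """Mutable state of a batch of replicate metapopulations.

    Haplotypes are indexed ``0 .. d*2N-1``; haplotypes ``2j`` and
    ``2j+1`` belong to diploid individual ``j``, and individuals are
    stored deme-contiguously (deme ``i`` owns individuals
    ``i*N .. (i+1)*N - 1``).  Census sizes are constant by construction.
    """

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        d, N = config.island.d, int(config.island.N_local)
        R = config.replicates
        self.R, self.d, self.N = R, d, N
        self.H = d * 2 * N  # haplotypes per replicate
        L_sel = config.layout.L_selected
        self.sel = np.zeros((R, self.H, L_sel), dtype=np.uint8)
        # neutral pool: rows are distinct neutral-block sequences
        self._cap = max(2 * self.H, 1024)
        self.pool = np.zeros((R, self._cap, config.layout.L_neutral),
                             dtype=np.int32)
        self._pool_used = np.ones(R, dtype=np.int64)  # row 0 = ancestral
        self.neu_id = np.zeros((R, self.H), dtype=np.int64)
        self._next_label = np.ones(R, dtype=np.int64)
        self.generation = 0
        # map positions of selected sites: flank A on [0, M/2),
        # flank B on (M/2, M]; neutral block at M/2 exactly.
        M = config.layout.M
        half = L_sel // 2
        if L_sel:
            self.sel_pos = np.empty(L_sel)
            self.sel_pos[:half] = np.linspace(0.0, M / 2, half, endpoint=False)
            self.sel_pos[half:] = M - self.sel_pos[:half][::-1]
        else:
            self.sel_pos = np.empty(0)
        self.neutral_pos = M / 2

    # -- neutral pool plumbing ---------------------------------------------

    def _ensure_capacity(self, needed: np.ndarray) -> None:
        if np.all(self._pool_used + needed <= self._cap):
            return
        self._compact_pool()
        max_need = int((self._pool_used + needed).max())
        if max_need > self._cap:
            new_cap = max(2 * self._cap, max_need)
            pool = np.zeros((self.R, new_cap, self.pool.shape[2]), np.int32)
            pool[:, : self._cap] = self.pool
            self.pool = pool
            self._cap = new_cap

    def _compact_pool(self) -> None:
        """Garbage-collect pool rows not referenced by any live haplotype."""
        for r in range(self.R):
            live, inverse = np.unique(self.neu_id[r], return_inverse=True)
            self.pool[r, : live.size] = self.pool[r, live]
            self.neu_id[r] = inverse
            self._pool_used[r] = live.size

    def neutral_matrix(self, r: int) -> np.ndarray:
        """Materialise the (H, L_neutral) allele-label matrix of replicate r."""
        return self.pool[r, self.neu_id[r]]

    # -- per-generation events ---------------------------------------------

    def step(self) -> None:
        """Advance one generation: reproduce, then migrate."""
        self.reproduce()
        self.migrate()
        self.generation += 1

    def reproduce(self) -> None:
        """Wright-Fisher reproduction within each deme.

        Each offspring draws two parents (with replacement, selfing
        allowed) with probability proportional to fitness within its
        natal deme; each parent transmits one recombinant gamete; de
        novo deleterious and neutral mutations are added per gamete.
        """
        cfg, rng = self.cfg, self.rng
        R, d, N, H = self.R, self.d, self.N, self.H
        L_sel = cfg.layout.L_selected

        # --- parent sampling: (R, d, N, 2) individual indices within deme
        if cfg.t > 0.0 and L_sel:
            k = (self.sel.reshape(R, d, N, 2, L_sel).sum(axis=(3, 4))
                 .astype(np.int64))  # (R, d, N) deleterious copies per indiv
            logw = k * np.log1p(-cfg.t)
            w = np.exp(logw - logw.max(axis=2, keepdims=True))
            cdf = np.cumsum(w, axis=2)
            tot = cdf[:, :, -1:]
            u = rng.random((R, d, 2 * N)) * tot
            parents = np.empty((R, d, 2 * N), dtype=np.int64)
            for rr in range(R):  # searchsorted per (replicate, deme)
                for dd in range(d):
                    parents[rr, dd] = np.searchsorted(cdf[rr, dd], u[rr, dd],
                                                      side="right")
            np.clip(parents, 0, N - 1, out=parents)
        else:
            parents = rng.integers(0, N, size=(R, d, 2 * N))
        parents = parents.reshape(R, d, N, 2)
        # global individual index, then haplotype base index
        deme_off = (np.arange(d) * N)[None, :, None, None]
        par_ind = parents + deme_off  # (R, d, N, 2) in 0..d*N-1

        # --- gametes: which parental haplotype contributes the neutral
        # block, and the recombinant selected flanks
        start = rng.integers(0, 2, size=(R, d, N, 2))  # starting haplotype
        par_hap = 2 * par_ind + start  # haplotype carrying the map origin

        if cfg.layout.M > 0.0 and L_sel:
            n_co = rng.poisson(cfg.layout.M, size=(R, d, N, 2))
        else:
            n_co = np.zeros((R, d, N, 2), dtype=np.int64)

        # offspring arrays
        flat_hap = par_hap.reshape(R, -1)  # (R, 2*d*N) = (R, H)
        new_neu = np.take_along_axis(self.neu_id, flat_hap, axis=1)
        if L_sel:
            rep_idx = np.arange(R)[:, None]
            new_sel = self.sel[rep_idx, flat_hap]  # (R, H, L_sel)
        else:
            new_sel = self.sel

        # crossovers are rare: handle gametes with n_co >= 1 individually
        co_flat = n_co.reshape(R, -1)
        if co_flat.any():
            reps, gams = np.nonzero(co_flat)
            for rr, g in zip(reps, gams):
                c = co_flat[rr, g]
                pos = np.sort(rng.random(c) * cfg.layout.M)
                h0 = flat_hap[rr, g]
                h1 = h0 ^ 1
                # phase along the map: 0 before first crossover
                phase_at = np.searchsorted(pos, self.sel_pos, side="left") % 2
                sites_from_other = phase_at.astype(bool)
                gam = self.sel[rr, h0].copy()
                gam[sites_from_other] = self.sel[rr, h1, sites_from_other]
                new_sel[rr, g] = gam
                if np.searchsorted(pos, self.neutral_pos, side="left") % 2:
                    new_neu[rr, g] = self.neu_id[rr, h1]

        self.sel = np.ascontiguousarray(new_sel)
        self.neu_id = new_neu

        # --- de novo deleterious mutations, Poisson(U) per gamete
        if cfg.U > 0.0 and L_sel:
            n_mut = rng.poisson(cfg.U, size=(R, H))
            tot = int(n_mut.sum())
            if tot:
                rep_i = np.repeat(np.arange(R * H) // H, n_mut.ravel())
                hap_i = np.repeat(np.arange(R * H) % H, n_mut.ravel())
                site_i = rng.integers(0, L_sel, size=tot)
                self.sel[rep_i, hap_i, site_i] = 1  # no-op if already mutant

        # --- de novo neutral mutations, Poisson(mu * L_neutral) per gamete
        lam = cfg.mu_neutral * cfg.layout.L_neutral
        if lam > 0.0:
            n_mut = rng.poisson(lam, size=(R, H))
            per_rep = n_mut.sum(axis=1)
            if per_rep.any():
                self._ensure_capacity(per_rep)
                for r in np.nonzero(per_rep)[0]:
                    haps = np.repeat(np.arange(H), n_mut[r])
                    for h in haps:
                        row = self._pool_used[r]
                        self.pool[r, row] = self.pool[r, self.neu_id[r, h]]
                        site = rng.integers(0, cfg.layout.L_neutral)
                        self.pool[r, row, site] = self._next_label[r]
                        self._next_label[r] += 1
                        self.neu_id[r, h] = row
                        self._pool_used[r] += 1

    def migrate(self) -> None:
        """Exchange individuals between demes by a random permutation.

        Each individual is marked as a migrant with probability
        ``m * d / (d - 1)`` and the marked individuals are randomly
        permuted across the vacated slots metapopulation-wide.  A
        migrant's destination deme is then uniform over all ``d`` demes
        (it may land back home with probability ~``1/d``), so the
        probability of actually changing deme is ``m`` and every other
        deme is reached with probability ``m / (d - 1)``.  Because the
        exchange is a permutation, deme sizes and metapopulation allele
        counts are exactly conserved.
        """
        m, d, N, R = self.cfg.island.m, self.d, self.N, self.R
        if m == 0.0 or d < 2:
            return
        rng = self.rng
        p_mark = min(1.0, m * d / (d - 1))
        L_sel = self.cfg.layout.L_selected
        marks = rng.random((R, d * N)) < p_mark
        neu2 = self.neu_id.reshape(R, d * N, 2)
        sel2 = (self.sel.reshape(R, d * N, 2 * L_sel) if L_sel else None)
        for r in range(R):
            idx = np.nonzero(marks[r])[0]
            if idx.size < 2:
                continue
            dest = rng.permutation(idx)
            neu2[r, idx] = neu2[r, dest]
            if sel2 is not None:
                sel2[r, idx] = sel2[r, dest]

    # -- bookkeeping ---------------------------------------------------------

    def fixed_deleterious_count(self, r: int) -> int:
        """Selected sites fixed for the deleterious allele in replicate r."""
        if self.cfg.layout.L_selected == 0:
            return 0
        return int((self.sel[r].min(axis=0) == 1).sum())


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_replicates(config: SimConfig, progress: bool = False,
                   maf_threshold: float = 0.05) -> list[ReplicateSummary]:
    """Run the configured burn-in for all replicates and summarise.

    Replicates advance in lock-step from a single generator seeded with
    ``master_seed``, so results are deterministic given the seed and the
    full configuration (including the replicate count).  Each replicate
    is summarised at the final generation via the estimators in
    :mod:`bgsisland.popgen_stats`.
    """
    rng = np.random.default_rng(config.master_seed)
    state = PopulationState(config, rng)
    report_every = max(1, config.generations // 20)
    for g in range(config.generations):
        state.step()
        if progress and (g + 1) % report_every == 0:
            print(f"  generation {g + 1}/{config.generations}", flush=True)

    out: list[ReplicateSummary] = []
    for r in range(config.replicates):
        table = site_frequency_table(state.neutral_matrix(r),
                                     config.island.d)
        summ = summarize_table(table, maf_threshold=maf_threshold)
        summ.replicate = r
        summ.fixed_deleterious = state.fixed_deleterious_count(r)
        out.append(summ)
    return out
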