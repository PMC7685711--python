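"""Titer-scaled susceptible-infected evolutionary simulator.

A discrete-generation SI model of a DNA virus in a host population of
fixed size N.  Each infected host carries a viral genotype over K
ordered focal loci; titer multiplies up through a decreasing series of
gains but only along the maximal prefix of consecutive derived alleles
(an out-of-order mutation confers nothing until its predecessors
arrive).  Infection pressure and the per-variant mutation rate scale
with titer, so each titer-raising mutation raises the supply of the
next — the chain-reaction that lets the full high-titer genotype evolve
recurrently and quickly.  Removal scales as titer**a with a < 1 by
default so higher titer buys a net transmission advantage.

Genotypes are tracked as counts over the 2**K genotype classes, which
reproduces the individual-level law exactly while staying cheap at
N = 10**6.  Recombination pairs infected hosts at random and swaps
genotype suffixes at each adjacent-locus interval with a fixed
probability that deliberately does not scale with titer.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams", "SimState", "SimResult", "titer_of_genotype",
    "si_deterministic", "step_generation", "run_replicates",
    "summarize_wait_times", "estimate_selection_coefficient",
    "time_to_frequency", "joint_mutation_probability",
]


@dataclass(frozen=True)
class SimParams:
    """All rates and the epistatic gain structure of the simulator.

    ``gains`` are multiplicative titer increases for mutations 1..K in
    order; ``mu_variant`` is the per-variant per-generation rate at
    titer 1 (multiplied by the host's current titer); ``recomb_rate`` is
    the suffix-swap probability per adjacent-locus interval per sampled
    pair per generation.  ``virulence_exponent`` a sets removal
    probability gamma0 * titer**a; a = 1 makes transmission and removal
    scale identically (titer-neutral fitness), a < 1 gives higher-titer
    genotypes a net advantage.
    """

    n_hosts: int = 1_000_000
    beta0: float = 0.1
    gamma0: float = 0.1
    virulence_exponent: float = 0.5
    mu_variant: float = 3.3e-7
    n_loci: int = 5
    gains: tuple[float, ...] = (10.0, 3.0, 2.0, 1.5, 1.25)
    t0: float = 1.0
    recomb_rate: float = 0.02
    init_infected_freq: float = 0.10
    max_generations: int = 100_000
    n_replicates: int = 1000
    fixation_threshold: float = 0.99
    establishment_rule: str = "drift_barrier"   # or "absolute"
    establishment_count: float = 1.0            # used when rule == "absolute"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_hosts < 1:
            raise ValueError("n_hosts must be >= 1")
        if len(self.gains) != self.n_loci:
            raise ValueError("gains must have length n_loci")
        if any(g <= 1 for g in self.gains):
            raise ValueError("gains must all be > 1")
        if any(b >= a for a, b in zip(self.gains, self.gains[1:])):
            raise ValueError("gains must be strictly decreasing")
        for name in ("mu_variant", "recomb_rate", "init_infected_freq",
                     "fixation_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.beta0 < 0 or self.gamma0 < 0:
            raise ValueError("beta0 and gamma0 must be >= 0")
        if self.establishment_rule not in ("drift_barrier", "absolute"):
            raise ValueError("establishment_rule must be drift_barrier or absolute")

    @classmethod
    def from_dict(cls, d) -> "SimParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimParams keys: {sorted(unknown)}")
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**d)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}


def titer_of_genotype(g, params: SimParams) -> float:
    """Titer of a binary genotype: gains multiply along the maximal
    prefix of consecutive derived alleles starting at locus 1."""
    t = params.t0
    for allele, gain in zip(g, params.gains):
        if not allele:
            break
        t *= gain
    return t


def si_deterministic(beta: float, gamma: float, i0: float, n_steps: int
                     ) -> np.ndarray:
    """Discrete susceptible-infected recursion on proportions.

    I' = I + S·I·beta − I·gamma with S = 1 − I, clipped to [0, 1];
    converges to I* = max(0, 1 − gamma/beta).  Returns an
    (n_steps + 1, 2) array of (S, I).
    """
    if beta < 0 or gamma < 0:
        raise ValueError("beta and gamma must be >= 0")
    if not 0.0 < i0 < 1.0:
        raise ValueError("i0 must be in (0, 1)")
    out = np.empty((n_steps + 1, 2))
    i = i0
    out[0] = (1 - i, i)
    for t in range(1, n_steps + 1):
        s = 1.0 - i
        i = min(1.0, max(0.0, i + s * i * beta - i * gamma))
        out[t] = (1.0 - i, i)
    return out


# ---------------------------------------------------------------------------
# genotype-class state

def _prefix_length(g: int, K: int) -> int:
    m = 0
    while m < K and (g >> m) & 1:
        m += 1
    return m


class _ClassTables:
    """Precomputed per-genotype-class quantities for one parameter set."""

    def __init__(self, params: SimParams):
        K = params.n_loci
        n = 1 << K
        self.K = K
        self.n_classes = n
        self.full = n - 1
        self.titer = np.empty(n)
        self.open_loci = []
        for g in range(n):
            m = _prefix_length(g, K)
            t = params.t0
            for k in range(m):
                t *= params.gains[k]
            self.titer[g] = t
            self.open_loci.append(np.array([k for k in range(K) if not (g >> k) & 1],
                                           dtype=np.int64))
        a = params.virulence_exponent
        self.p_death = np.minimum(1.0, params.gamma0 * self.titer**a)
        self.p_mut = np.minimum(1.0, params.mu_variant * self.titer)
        # carrier membership matrix: class x locus
        self.member = np.array([[(g >> k) & 1 for k in range(K)] for g in range(n)],
                               dtype=np.int64)
        # establishment context: mutation k counts only in genotypes carrying
        # the complete prefix 1..k, where its selective advantage s_k applies
        # (an out-of-order mutation is neutral and cannot escape drift)
        self.prefix_member = np.array(
            [[1 if _prefix_length(g, K) >= k + 1 else 0 for k in range(K)]
             for g in range(n)], dtype=np.int64)
        # consecutive-prefix titers and establishment thresholds
        prefix_titer = [params.t0]
        for gain in params.gains:
            prefix_titer.append(prefix_titer[-1] * gain)
        self.prefix_titer = np.array(prefix_titer)
        s = (self.prefix_titer[1:] / self.prefix_titer[:-1]) ** (1.0 - a) - 1.0
        self.selection = s
        if params.establishment_rule == "absolute":
            self.establish_threshold = np.full(K, float(params.establishment_count))
        else:
            with np.errstate(divide="ignore"):
                self.establish_threshold = np.where(s > 0, 1.0 / (2.0 * s), np.inf)
        # recombination crossover patterns: for pattern P over K-1 intervals,
        # child takes partner's allele at locus k iff an odd number of the
        # intervals < k are active
        n_pat = 1 << (K - 1) if K > 1 else 1
        masks = np.zeros(n_pat, dtype=np.int64)
        for pat in range(n_pat):
            take_b = 0
            odd = 0
            for k in range(K):
                if k > 0 and (pat >> (k - 1)) & 1:
                    odd ^= 1
                if odd:
                    take_b |= 1 << k
            masks[pat] = take_b
        self.pattern_mask = masks
        r = params.recomb_rate
        if K > 1 and 0 < r:
            n_swaps = np.array([bin(p).count("1") for p in range(n_pat)])
            pat_prob = r**n_swaps * (1 - r) ** (K - 1 - n_swaps)
            self.p_any_swap = float(1.0 - (1.0 - r) ** (K - 1))
            active = np.arange(n_pat) != 0
            self.active_patterns = np.flatnonzero(active)
            self.active_pattern_prob = pat_prob[active] / pat_prob[active].sum()
        else:
            self.p_any_swap = 0.0
            self.active_patterns = np.array([], dtype=np.int64)
            self.active_pattern_prob = np.array([])


def _recombine_pair(a: int, b: int, pattern_mask: int) -> tuple[int, int]:
    """Apply one crossover pattern to an ordered genotype pair."""
    a2 = (a & ~pattern_mask) | (b & pattern_mask)
    b2 = (b & ~pattern_mask) | (a & pattern_mask)
    return a2, b2


@dataclass
class SimState:
    """Counts per genotype class plus event bookkeeping for one replicate."""

    generation: int
    susceptible: int
    infected: np.ndarray                  # int64 counts, length 2**K
    t_first: np.ndarray                   # per-locus, NaN until seen
    t_establish: np.ndarray
    t_fix: np.ndarray
    cum_mutations: np.ndarray             # cumulative mutation events per locus
    cum_new_infections: np.ndarray = None  # cumulative per class
    cum_deaths: np.ndarray = None          # cumulative per class
    full_first_by: str | None = None      # "mutation" or "recombination"

    @classmethod
    def initial(cls, params: SimParams, tables: _ClassTables) -> "SimState":
        I = np.zeros(tables.n_classes, dtype=np.int64)
        I[0] = int(round(params.init_infected_freq * params.n_hosts))
        K = params.n_loci
        nan = np.full(K, np.nan)
        return cls(generation=0, susceptible=params.n_hosts - I[0], infected=I,
                   t_first=nan.copy(), t_establish=nan.copy(), t_fix=nan.copy(),
                   cum_mutations=np.zeros(K, dtype=np.int64),
                   cum_new_infections=np.zeros(tables.n_classes, dtype=np.int64),
                   cum_deaths=np.zeros(tables.n_classes, dtype=np.int64))

    def total_infected(self) -> int:
        return int(self.infected.sum())

    def all_fixed(self) -> bool:
        return bool(np.all(np.isfinite(self.t_fix)))


def _record_events(state: SimState, tables: _ClassTables,
                   fixation_threshold: float) -> None:
    carriers = state.infected @ tables.member
    prefix_carriers = state.infected @ tables.prefix_member
    total = state.infected.sum()
    g = state.generation
    for k in range(tables.K):
        if carriers[k] > 0 and not np.isfinite(state.t_first[k]):
            state.t_first[k] = g
        if prefix_carriers[k] >= tables.establish_threshold[k] and \
                not np.isfinite(state.t_establish[k]):
            state.t_establish[k] = g
        if total > 0 and carriers[k] / total >= fixation_threshold and \
                not np.isfinite(state.t_fix[k]):
            state.t_fix[k] = g


def step_generation(state: SimState, params: SimParams,
                    rng: np.random.Generator,
                    tables: _ClassTables | None = None) -> SimState:
    """Advance one generation in place (and return the state).

    Order of events: (i) new infections — one binomial draw on the total
    force of infection, allocated to source classes by their
    titer-weighted share; (ii) removals per class at gamma0·T**a, dead
    hosts returning to the susceptible pool; (iii) titer-scaled mutation
    at each underived locus (out of order allowed, no back-mutation);
    (iv) recombination via random pairing and per-interval suffix swaps;
    (v) first-appearance / establishment / fixation recording.
    """
    if tables is None:
        tables = _ClassTables(params)
    N = params.n_hosts
    I = state.infected
    S = state.susceptible

    # (i) + (ii) infection and removal from the generation-start state
    weights = tables.titer * I
    lam = params.beta0 * weights.sum() / N
    if lam > 1.0:
        logger.debug("generation %d: force of infection %.3f clipped to 1",
                     state.generation, lam)
    n_new = rng.binomial(S, min(1.0, lam)) if S > 0 and lam > 0 else 0
    new_by_class = np.zeros_like(I)
    if n_new > 0:
        new_by_class = rng.multinomial(n_new, weights / weights.sum())
    deaths = rng.binomial(I, tables.p_death)
    I += new_by_class - deaths
    state.cum_new_infections += new_by_class
    state.cum_deaths += deaths

    # (iii) mutation
    was_full_empty = I[tables.full] == 0
    occupied = np.flatnonzero(I)
    for gcls in occupied:
        pm = tables.p_mut[gcls]
        open_k = tables.open_loci[gcls]
        if pm <= 0.0 or len(open_k) == 0:
            continue
        avail = I[gcls]
        counts = rng.binomial(avail, pm, size=len(open_k))
        if counts.sum() > avail:        # vanishingly rare; keep counts feasible
            excess = counts.sum() - avail
            for idx in np.argsort(counts)[::-1]:
                take = min(excess, counts[idx])
                counts[idx] -= take
                excess -= take
                if excess == 0:
                    break
        for k, c in zip(open_k, counts):
            if c > 0:
                I[gcls] -= c
                I[gcls | (1 << k)] += c
                state.cum_mutations[k] += c
    if was_full_empty and I[tables.full] > 0 and state.full_first_by is None:
        state.full_first_by = "mutation"

    # (iv) recombination
    if tables.p_any_swap > 0.0:
        total = int(I.sum())
        occupied = np.flatnonzero(I)
        if total >= 2 and len(occupied) >= 2:
            n_pairs = total // 2
            n_active = rng.binomial(n_pairs, tables.p_any_swap)
            if n_active > 0:
                was_full_empty = I[tables.full] == 0
                f = I[occupied] / total
                joint = np.outer(f, f).ravel()
                cell_counts = rng.multinomial(n_active, joint / joint.sum())
                m = len(occupied)
                usage = np.zeros(m, dtype=np.int64)
                cells = []
                for idx in np.flatnonzero(cell_counts):
                    ai, bi = divmod(idx, m)
                    if occupied[ai] == occupied[bi]:
                        continue  # identical genotypes: swap is a no-op
                    c = cell_counts[idx]
                    cells.append((ai, bi, c))
                    usage[ai] += c
                    usage[bi] += c
                # repair the with-replacement approximation if a class is
                # oversubscribed (only matters for near-empty classes)
                over = usage - I[occupied]
                if np.any(over > 0):
                    for ci in range(len(cells)):
                        ai, bi, c = cells[ci]
                        while c > 0 and (over[ai] > 0 or over[bi] > 0):
                            c -= 1
                            over[ai] -= 1
                            over[bi] -= 1
                        cells[ci] = (ai, bi, c)
                for ai, bi, c in cells:
                    if c <= 0:
                        continue
                    a, b = int(occupied[ai]), int(occupied[bi])
                    pat_counts = rng.multinomial(c, tables.active_pattern_prob)
                    for pat_i in np.flatnonzero(pat_counts):
                        pc = pat_counts[pat_i]
                        mask = int(tables.pattern_mask[tables.active_patterns[pat_i]])
                        a2, b2 = _recombine_pair(a, b, mask)
                        I[a] -= pc
                        I[b] -= pc
                        I[a2] += pc
                        I[b2] += pc
                if was_full_empty and I[tables.full] > 0 and state.full_first_by is None:
                    state.full_first_by = "recombination"

    state.susceptible = N - int(I.sum())
    state.generation += 1
    _record_events(state, tables, params.fixation_threshold)
    return state


@dataclass
class SimResult:
    """Event times (generations; NaN = censored) for one replicate."""

    t_first: np.ndarray
    t_establish: np.ndarray
    t_fix: np.ndarray
    recombination_assembled: bool
    final_infected_frequency: float
    final_type_freqs: np.ndarray
    n_generations: int


def _run_one(params: SimParams, tables: _ClassTables,
             rng: np.random.Generator) -> SimResult:
    state = SimState.initial(params, tables)
    _record_events(state, tables, params.fixation_threshold)
    while state.generation < params.max_generations:
        step_generation(state, params, rng, tables)
        if state.all_fixed():
            break
        if state.total_infected() == 0:
            break
    total = state.total_infected()
    freqs = state.infected / total if total > 0 else np.zeros_like(state.infected, dtype=float)
    return SimResult(
        t_first=state.t_first.copy(),
        t_establish=state.t_establish.copy(),
        t_fix=state.t_fix.copy(),
        recombination_assembled=state.full_first_by == "recombination",
        final_infected_frequency=total / params.n_hosts,
        final_type_freqs=freqs,
        n_generations=state.generation,
    )


def run_replicates(params: SimParams, n_replicates: int | None = None,
                   seed: int | None = None) -> tuple[list[SimResult], dict]:
    """Independent replicates with derived per-replicate seeds.

    The summary reports, per mutation index, mean and standard deviation
    of inter-establishment wait times, the fraction of replicates whose
    first mutation establishes within 1000 generations, the maximum
    generation at which all K mutations have fixed, and the number of
    replicates where recombination first assembled the full genotype.
    """
    if n_replicates is None:
        n_replicates = params.n_replicates
    if seed is None:
        seed = params.seed
    tables = _ClassTables(params)
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    results = [_run_one(params, tables, np.random.default_rng(s)) for s in seeds]

    waits = summarize_wait_times(results)
    est1 = np.array([r.t_establish[0] for r in results])
    frac_1000 = float(np.mean(np.nan_to_num(est1, nan=np.inf) <= 1000))
    fix_all = np.array([np.max(r.t_fix) for r in results])
    n_censored = int(np.sum(~np.isfinite(fix_all)))
    max_fix = float(np.nanmax(fix_all)) if np.isfinite(fix_all).any() else float("nan")
    summary = {
        "n_replicates": n_replicates,
        "frac_establish_first_within_1000": frac_1000,
        "max_full_fixation_generation": max_fix,
        "n_replicates_not_fixed": n_censored,
        "n_recombination_assembled": int(sum(r.recombination_assembled for r in results)),
        "wait_times": waits,
    }
    return results, summary


def summarize_wait_times(results: list[SimResult], min_uncensored: int = 30
                         ) -> pd.DataFrame:
    """Per-mutation-index mean and sd of inter-establishment waits.

    wait_k = t_establish(k) − t_establish(k−1) with t_establish(0) = 0;
    indices with fewer than ``min_uncensored`` replicates contributing
    are flagged insufficient.  Columns note whether means and sds
    decrease monotonically over fully-supported indices.
    """
    K = len(results[0].t_establish)
    est = np.vstack([r.t_establish for r in results])
    prev = np.column_stack([np.zeros(len(results)), est[:, :-1]])
    waits = est - prev
    rows = []
    for k in range(K):
        ok = np.isfinite(waits[:, k])
        n = int(ok.sum())
        rows.append({
            "mutation_index": k + 1,
            "n_uncensored": n,
            "mean_wait": float(waits[ok, k].mean()) if n else float("nan"),
            "sd_wait": float(waits[ok, k].std(ddof=1)) if n > 1 else float("nan"),
            "insufficient": n < min_uncensored,
        })
    out = pd.DataFrame(rows)
    means = out.loc[~out["insufficient"], "mean_wait"].to_numpy()
    sds = out.loc[~out["insufficient"], "sd_wait"].to_numpy()
    out.attrs["means_strictly_decreasing"] = bool(
        len(means) >= 2 and np.all(np.diff(means) < 0))
    out.attrs["sds_strictly_decreasing"] = bool(
        len(sds) >= 2 and np.all(np.diff(sds) < 0))
    return out


# ---------------------------------------------------------------------------
# closed-form selection arithmetic

def estimate_selection_coefficient(p0: float, p1: float, t: float) -> float:
    """s solving p1 = p0·(1+s)**t (exponential growth of a frequency)."""
    if not 0.0 < p0 <= 1.0:
        raise ValueError("p0 must be in (0, 1]")
    if not 0.0 < p1 <= 1.0:
        raise ValueError("p1 must be in (0, 1]")
    if t <= 0:
        raise ValueError("t must be > 0")
    return (p1 / p0) ** (1.0 / t) - 1.0


def time_to_frequency(p0: float, p1: float, s: float,
                      generations_per_year: float = 5.0) -> tuple[float, float]:
    """Generations (and years) for a frequency to grow from p0 to p1 at
    selection coefficient s: t = ln(p1/p0)/ln(1+s)."""
    if s <= -1.0:
        raise ValueError("s must be > -1")
    if not 0.0 < p0 <= 1.0 or not 0.0 < p1 <= 1.0:
        raise ValueError("frequencies must be in (0, 1]")
    if p1 == p0:
        return 0.0, 0.0
    if s == 0.0:
        raise ValueError("s = 0 cannot change the frequency")
    t = math.log(p1 / p0) / math.log1p(s)
    return t, t / generations_per_year


def joint_mutation_probability(mu_variant: float | None = None, K: int = 5,
                               base_rate: float = 1e-6) -> float:
    """Probability that all K variant mutations arise in one generation.

    With the default per-site rate of 1e-6 and a 1/3 chance of the
    correct nucleotide, the per-variant rate is 3.33e-7 and the joint
    probability for K = 5 is 4.12e-33.
    """
    if mu_variant is None:
        mu_variant = base_rate / 3.0
    if not 0.0 < mu_variant < 1.0:
        raise ValueError("mu_variant must be in (0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    return mu_variant**K
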