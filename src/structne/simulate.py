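"""Forward-in-time diploid Wright-Fisher simulator.

Discrete non-overlapping generations, random mating without selfing,
recombination on a uniform genetic map, neutral infinite-sites mutation,
backward migration between demes, scheduled demographic events, and the
mechanics of a large chromosomal inversion: crossovers falling inside the
inverted interval are discarded in inversion heterozygotes, and carriers
experience frequency-dependent fitness ``1 - (q - 0.5) * s`` that balances
the inversion near frequency 0.5.

Two representations are used.  The population state
(:class:`MetapopState`) stores all haplotypes of the metapopulation as a
dense 0/1 matrix over the currently segregating positions, which lets a
whole generation of meioses be produced with vectorized numpy operations.
The op-level API (:func:`make_gamete` on sparse :class:`Haplotype` /
:class:`Individual` objects) exposes a single meiosis for inspection and
testing; both paths implement the same crossover model.

Backward migration: each offspring first chooses the deme its parents come
from (with probability ``m`` a different deme), then two distinct parents
within that deme with probability proportional to fitness.  This matches the
Wright-Fisher metapopulation convention of keeping deme sizes exact every
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GenomeConfig, ScenarioConfig


class SimulationError(RuntimeError):
    pass


class InversionLost(SimulationError):
    """The segregating inversion was lost; the replicate should be retried."""


# ---------------------------------------------------------------------------
# Op-level (sparse) types
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    """One gamete: sorted derived-allele positions plus inversion orientation."""

    mutations: np.ndarray
    carries_inversion: bool = False

    def __post_init__(self):
        self.mutations = np.asarray(self.mutations, dtype=np.int64)
        if self.mutations.size and np.any(np.diff(self.mutations) <= 0):
            raise ValueError("mutation positions must be unique and sorted")


@dataclass
class Individual:
    haplotype_a: Haplotype
    haplotype_b: Haplotype
    deme_id: int = 0
    fitness: float = 1.0

    def __post_init__(self):
        if self.fitness <= 0:
            raise ValueError("fitness must be > 0")


@dataclass
class MetapopState:
    """The evolving metapopulation.

    ``haplotypes`` is a ``(2 * n_individuals, S)`` 0/1 matrix over the
    ``S`` currently segregating ``positions``; individual ``i`` owns rows
    ``2i`` and ``2i + 1``.  Demes occupy contiguous individual blocks in the
    order of ``deme_sizes``.  ``diagnostics`` carries per-generation counters
    (e.g. realized crossovers inside the inversion in heterozygote meioses).
    """

    positions: np.ndarray
    haplotypes: np.ndarray
    inv_flags: np.ndarray
    deme_sizes: tuple
    generation_index: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_individuals(self) -> int:
        return sum(self.deme_sizes)

    def deme_of_individuals(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.deme_sizes)), self.deme_sizes)

    def inversion_frequency(self, deme: int | None = None) -> float:
        """Current inversion frequency q (per deme or metapopulation-wide)."""
        if deme is None:
            return float(self.inv_flags.mean()) if self.inv_flags.size else 0.0
        offs = np.concatenate(([0], np.cumsum(self.deme_sizes)))
        lo, hi = 2 * offs[deme], 2 * offs[deme + 1]
        return float(self.inv_flags[lo:hi].mean())


def initial_state(scenario: ScenarioConfig) -> MetapopState:
    n = sum(scenario.deme_sizes)
    return MetapopState(
        positions=np.empty(0, dtype=np.int64),
        haplotypes=np.zeros((2 * n, 0), dtype=np.uint8),
        inv_flags=np.zeros(2 * n, dtype=bool),
        deme_sizes=tuple(scenario.deme_sizes),
        generation_index=0,
    )


# ---------------------------------------------------------------------------
# Inversion fitness
# ---------------------------------------------------------------------------

def inversion_fitness(q: float, coefficient: float = 0.2) -> float:
    """Fitness multiplier of inversion carriers at inversion frequency ``q``.

    ``w(q) = 1 - (q - 0.5) * coefficient``: neutral at q = 0.5, advantageous
    below, deleterious above -- a balancing, frequency-dependent scheme.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"inversion frequency q={q} outside [0, 1]")
    return 1.0 - (q - 0.5) * coefficient


# ---------------------------------------------------------------------------
# Single meiosis (op-level)
# ---------------------------------------------------------------------------

def _draw_crossovers(rng, genome: GenomeConfig, size=None):
    """Poisson crossover counts for one (or ``size``) meioses."""
    return rng.poisson(genome.map_length_morgans, size=size)

def _suppress_in_interval(xpos: np.ndarray, interval) -> np.ndarray:
    """Discard crossover positions inside the inverted interval."""
    start, end = interval
    return xpos[(xpos < start) | (xpos >= end)]


def make_gamete(parent: Individual, genome: GenomeConfig,
                inversion_interval=None, rng=None, return_crossovers=False):
    """One meiosis: recombine the parent's haplotypes and add new mutations.

    Crossover positions are uniform on the sequence with a Poisson total
    (mean = map length in Morgans); alleles at positions >= a crossover point
    switch parental haplotype.  If the parent is heterozygous for the
    inversion, crossovers inside ``inversion_interval`` are discarded.  New
    mutations arise at Poisson(L * mu) uniform positions under infinite
    sites (collisions resampled).  The gamete carries the inversion flag of
    the haplotype contributing the interval midpoint.
    """
    rng = np.random.default_rng() if rng is None else rng
    L = genome.sequence_length_bp
    ha, hb = parent.haplotype_a, parent.haplotype_b

    n_x = int(_draw_crossovers(rng, genome))
    xpos = np.sort(rng.integers(1, L, size=n_x))
    het = (inversion_interval is not None
           and ha.carries_inversion != hb.carries_inversion)
    if het:
        xpos = _suppress_in_interval(xpos, inversion_interval)

    first = int(rng.integers(2))  # which haplotype contributes position 0
    sources = (ha, hb) if first == 0 else (hb, ha)
    bounds = np.concatenate(([0], xpos, [L]))
    segs = []
    for k in range(len(bounds) - 1):
        src = sources[k % 2].mutations
        lo = np.searchsorted(src, bounds[k], side="left")
        hi = np.searchsorted(src, bounds[k + 1], side="left")
        segs.append(src[lo:hi])
    mut = np.concatenate(segs) if segs else np.empty(0, dtype=np.int64)

    n_new = rng.poisson(L * genome.mutation_rate)
    if n_new:
        existing = set(mut.tolist())
        new = []
        while len(new) < n_new:
            p = int(rng.integers(0, L))
            if p not in existing:
                existing.add(p)
                new.append(p)
        mut = np.sort(np.concatenate([mut, np.array(new, dtype=np.int64)]))

    if inversion_interval is not None:
        mid = (inversion_interval[0] + inversion_interval[1]) // 2
        n_before = int(np.searchsorted(xpos, mid, side="right"))
        flag = sources[n_before % 2].carries_inversion
    else:
        flag = False

    gamete = Haplotype(mut, carries_inversion=bool(flag))
    if return_crossovers:
        return gamete, xpos
    return gamete


# ---------------------------------------------------------------------------
# Migration
# ---------------------------------------------------------------------------

def migration_active(scenario: ScenarioConfig, offspring_generation_bp: int) -> bool:
    """Pulsed migration: active only in offspring generations divisible by
    the migration period (period 1 = every generation)."""
    if scenario.migration_rate == 0.0:
        return False
    return offspring_generation_bp % scenario.migration_period == 0


def parent_deme_probabilities(deme_id: int, scenario: ScenarioConfig) -> np.ndarray:
    """Distribution of the parental deme for an offspring born in ``deme_id``."""
    n = len(scenario.deme_sizes)
    m = scenario.migration_rate
    p = np.zeros(n)
    if scenario.family == "source_sink":
        # deme 0 is the source and never receives migrants
        if deme_id == 0:
            p[0] = 1.0
        else:
            p[deme_id] = 1.0 - m
            p[0] += m
    else:
        p[deme_id] = 1.0 - m
        if n > 1:
            others = [d for d in range(n) if d != deme_id]
            p[others] = m / (n - 1)
        else:
            p[deme_id] = 1.0
    return p


def choose_parent_deme(deme_id: int, scenario: ScenarioConfig,
                       generation_bp: int, rng) -> int:
    """Backward-migration draw of one offspring's parental deme."""
    if not migration_active(scenario, generation_bp):
        return deme_id
    p = parent_deme_probabilities(deme_id, scenario)
    return int(rng.choice(len(p), p=p))


# ---------------------------------------------------------------------------
# One generation, vectorized
# ---------------------------------------------------------------------------

def _deme_fitness_weights(state: MetapopState, scenario: ScenarioConfig):
    """Per-individual sampling weights; uniform unless the inversion segregates."""
    if scenario.inversion is None or not state.inv_flags.any():
        return None
    coef = scenario.inversion.selection_coefficient
    flags = state.inv_flags
    carrier = flags[0::2] | flags[1::2]
    weights = np.ones(state.n_individuals)
    offs = np.concatenate(([0], np.cumsum(state.deme_sizes)))
    for d in range(len(state.deme_sizes)):
        lo, hi = offs[d], offs[d + 1]
        q = float(flags[2 * lo:2 * hi].mean())
        w = inversion_fitness(q, coef)
        weights[lo:hi][carrier[lo:hi]] = max(w, 1e-9)
    return weights


def _sample_parent_pairs(parent_demes, state, weights, rng):
    """Two distinct parents per offspring, chosen within each parental deme
    with probability proportional to fitness."""
    n_off = parent_demes.size
    p1 = np.empty(n_off, dtype=np.int64)
    p2 = np.empty(n_off, dtype=np.int64)
    offs = np.concatenate(([0], np.cumsum(state.deme_sizes)))
    for d in np.unique(parent_demes):
        sel = np.flatnonzero(parent_demes == d)
        lo, hi = offs[d], offs[d + 1]
        size = hi - lo
        if size < 2:
            raise SimulationError(f"deme {d} has fewer than 2 individuals")
        if weights is None:
            a = rng.integers(lo, hi, size=sel.size)
            b = rng.integers(lo, hi, size=sel.size)
            clash = a == b
            while clash.any():
                b[clash] = rng.integers(lo, hi, size=int(clash.sum()))
                clash = a == b
        else:
            w = weights[lo:hi]
            prob = w / w.sum()
            a = lo + rng.choice(size, size=sel.size, p=prob)
            b = lo + rng.choice(size, size=sel.size, p=prob)
            clash = a == b
            while clash.any():
                b[clash] = lo + rng.choice(size, size=int(clash.sum()), p=prob)
                clash = a == b
        p1[sel], p2[sel] = a, b
    return p1, p2


def _offspring_parent_demes(state, scenario, events_now, offspring_sizes, g_off, rng):
    """Parental-deme index for every offspring, honouring events and migration."""
    deme_of_off = np.repeat(np.arange(len(offspring_sizes)), offspring_sizes)
    split = next((e for e in events_now if e.kind == "split"), None)
    admix = next((e for e in events_now if e.kind == "admix"), None)
    if split is not None:
        return np.zeros(deme_of_off.size, dtype=np.int64)
    if admix is not None:
        return rng.integers(0, len(state.deme_sizes), size=deme_of_off.size)
    if not migration_active(scenario, g_off):
        return deme_of_off.astype(np.int64)
    out = deme_of_off.astype(np.int64).copy()
    for d in range(len(offspring_sizes)):
        sel = np.flatnonzero(deme_of_off == d)
        if sel.size == 0:
            continue
        p = parent_deme_probabilities(d, scenario)
        out[sel] = rng.choice(len(p), size=sel.size, p=p)
    return out


def advance_generation(state: MetapopState, scenario: ScenarioConfig, rng,
                       prune: bool = True) -> MetapopState:
    """Produce the next generation of the whole metapopulation.

    Applies any demographic event scheduled at the parents' generation,
    draws parental demes (migration), parent pairs (fitness-weighted,
    no selfing), one recombinant gamete per parent, new mutations, and —
    unless ``prune`` is disabled to track individual alleles to fixation —
    drops sites that are no longer segregating (which never alters any
    genotype contrast).
    """
    genome = scenario.genome
    L = genome.sequence_length_bp
    g_parent = scenario.total_generations - state.generation_index
    g_off = g_parent - 1
    events_now = [e for e in scenario.events if e.time == g_parent]

    # introduce_inversion modifies the parent state before reproduction
    for e in events_now:
        if e.kind == "introduce_inversion":
            state = introduce_inversion(state, scenario,
                                        copies=e.params.get("copies", 1),
                                        deme=e.params.get("deme", 0), rng=rng)

    # offspring deme structure
    sizes = list(state.deme_sizes)
    split = next((e for e in events_now if e.kind == "split"), None)
    admix = next((e for e in events_now if e.kind == "admix"), None)
    if split is not None:
        if len(sizes) != 1:
            raise SimulationError("split requires a single ancestral deme")
        sizes = list(split.params["daughter_sizes"])
    elif admix is not None:
        sizes = [admix.params["size"]]
    for e in events_now:
        if e.kind == "resize":
            sizes[e.params["deme"]] = e.params["size"]
    if any(s < 2 for s in sizes):
        raise SimulationError("an event left a deme with fewer than 2 individuals")
    offspring_sizes = tuple(sizes)
    n_off = sum(offspring_sizes)

    parent_demes = _offspring_parent_demes(state, scenario, events_now,
                                           offspring_sizes, g_off, rng)
    weights = _deme_fitness_weights(state, scenario)
    p1, p2 = _sample_parent_pairs(parent_demes, state, weights, rng)

    # one gamete per parent: gametes 2k (from p1) and 2k+1 (from p2)
    parents = np.empty(2 * n_off, dtype=np.int64)
    parents[0::2], parents[1::2] = p1, p2
    n_gam = parents.size

    kx = _draw_crossovers(rng, genome, size=n_gam)
    gidx = np.repeat(np.arange(n_gam), kx)
    xpos = rng.integers(1, L, size=int(kx.sum()))

    inv = scenario.inversion
    inv_active = inv is not None and state.inv_flags.any()
    n_suppressed_hits = 0
    if inv_active and xpos.size:
        het_parent = state.inv_flags[2 * parents] != state.inv_flags[2 * parents + 1]
        inside = (xpos >= inv.start_bp) & (xpos < inv.end_bp)
        drop = inside & het_parent[gidx]
        gidx, xpos = gidx[~drop], xpos[~drop]
        # diagnostics: realized crossovers inside the interval in het meioses
        n_suppressed_hits = int((((xpos >= inv.start_bp) & (xpos < inv.end_bp))
                                 & het_parent[gidx]).sum())

    start = rng.integers(0, 2, size=n_gam).astype(np.uint8)
    H = state.haplotypes
    S = state.positions.size

    # parity of crossover count left of each site decides the source haplotype
    G = np.empty((n_gam, S), dtype=np.uint8)
    rows_even = 2 * parents + start          # contributes where parity is even
    rows_odd = 2 * parents + (1 - start)
    if xpos.size == 0:
        G[:] = H[rows_even]
        cross_count_mid = np.zeros(n_gam, dtype=np.int64)
    else:
        order = np.argsort(gidx, kind="stable")
        gidx_s, xpos_s = gidx[order], xpos[order]
        counts = np.bincount(gidx_s, minlength=n_gam)
        has_x = counts > 0
        G[~has_x] = H[rows_even[~has_x]]
        sub = np.flatnonzero(has_x)
        if sub.size:
            # crossover insertion points into the segregating-site grid
            col = np.searchsorted(state.positions, xpos_s, side="left")
            step = np.zeros((sub.size, S + 1), dtype=np.uint8)
            row_of = np.full(n_gam, -1)
            row_of[sub] = np.arange(sub.size)
            np.add.at(step, (row_of[gidx_s].astype(np.int64), col), 1)
            parity = np.cumsum(step[:, :-1], axis=1) & 1
            Ge = H[rows_even[sub]]
            Go = H[rows_odd[sub]]
            G[sub] = np.where(parity == 0, Ge, Go)
        if inv is not None:
            mid = (inv.start_bp + inv.end_bp) // 2
            cross_count_mid = np.zeros(n_gam, dtype=np.int64)
            np.add.at(cross_count_mid, gidx, (xpos <= mid).astype(np.int64))
        else:
            cross_count_mid = np.zeros(n_gam, dtype=np.int64)

    # inversion flag travels with the haplotype contributing the midpoint
    if inv is not None:
        src = np.where(cross_count_mid % 2 == 0, rows_even, rows_odd)
        new_flags = state.inv_flags[src]
    else:
        new_flags = np.zeros(n_gam, dtype=bool)

    # new mutations (infinite sites: collisions with segregating positions
    # or other new mutations are resampled)
    n_new = int(rng.poisson(n_gam * L * genome.mutation_rate))
    if n_new:
        existing = set(state.positions.tolist())
        new_pos = []
        while len(new_pos) < n_new:
            p = int(rng.integers(0, L))
            if p not in existing:
                existing.add(p)
                new_pos.append(p)
        new_pos = np.array(new_pos, dtype=np.int64)
        owners = rng.integers(0, n_gam, size=n_new)
        new_cols = np.zeros((n_gam, n_new), dtype=np.uint8)
        new_cols[owners, np.arange(n_new)] = 1
        positions = np.concatenate([state.positions, new_pos])
        G = np.concatenate([G, new_cols], axis=1)
        order = np.argsort(positions)
        positions = positions[order]
        G = G[:, order]
    else:
        positions = state.positions

    # prune fixed and lost sites
    if prune and positions.size:
        colsum = G.sum(axis=0, dtype=np.int64)
        keep = (colsum > 0) & (colsum < n_gam)
        if not keep.all():
            positions = positions[keep]
            G = G[:, keep]

    return MetapopState(
        positions=positions,
        haplotypes=np.ascontiguousarray(G),
        inv_flags=new_flags,
        deme_sizes=offspring_sizes,
        generation_index=state.generation_index + 1,
        diagnostics={"n_crossovers_in_inversion_het": n_suppressed_hits},
    )


def introduce_inversion(state: MetapopState, scenario: ScenarioConfig,
                        copies: int = 1, deme: int = 0, rng=None) -> MetapopState:
    """Flag ``copies`` uniformly chosen haplotypes of ``deme`` as inverted."""
    rng = np.random.default_rng() if rng is None else rng
    offs = np.concatenate(([0], np.cumsum(state.deme_sizes)))
    lo, hi = 2 * offs[deme], 2 * offs[deme + 1]
    flags = state.inv_flags.copy()
    chosen = rng.choice(hi - lo, size=min(copies, hi - lo), replace=False)
    flags[lo + chosen] = True
    return MetapopState(state.positions, state.haplotypes, flags,
                        state.deme_sizes, state.generation_index,
                        dict(state.diagnostics))


# ---------------------------------------------------------------------------
# Full scenario
# ---------------------------------------------------------------------------

def run_chromosome(scenario: ScenarioConfig, seed_seq) -> MetapopState:
    """Run one replicate chromosome from an empty state to generation 0.

    Raises :class:`InversionLost` if a segregating inversion is lost (the
    caller retries with a fresh stream).
    """
    rng = np.random.default_rng(seed_seq)
    state = initial_state(scenario)
    inv = scenario.inversion
    inv_introduced = False
    if inv is not None and inv.target_mode == "balanced":
        state = introduce_inversion(state, scenario, copies=inv.initial_copies,
                                    deme=0, rng=rng)
        inv_introduced = True
    recent_low_time = (inv.introduce_time
                       if inv is not None and inv.target_mode == "recent_low" else None)

    for _ in range(scenario.total_generations):
        g_parent = scenario.total_generations - state.generation_index
        if recent_low_time is not None and g_parent == recent_low_time:
            state = introduce_inversion(state, scenario, copies=inv.initial_copies,
                                        deme=0, rng=rng)
            inv_introduced = True
        state = advance_generation(state, scenario, rng)
        if inv_introduced and not state.inv_flags.any():
            raise InversionLost(
                f"inversion lost at generation index {state.generation_index}")
    return state


def run_scenario(scenario: ScenarioConfig, max_retries: int = 500) -> list:
    """Run all replicate chromosomes of a scenario.

    Chromosome replicates use independent, deterministically derived random
    streams (``SeedSequence(scenario.seed).spawn``), so results are exactly
    reproducible given the scenario seed.  Replicates that lose a segregating
    inversion are retried with a fresh derived stream.
    """
    master = np.random.SeedSequence(scenario.seed)
    chrom_seqs = master.spawn(scenario.genome.n_chromosomes)
    states = []
    for cs in chrom_seqs:
        for _attempt in range(max_retries):
            try:
                states.append(run_chromosome(scenario, cs.spawn(1)[0]))
                break
            except InversionLost:
                continue
        else:
            raise SimulationError(
                f"inversion lost in all {max_retries} retries of one chromosome")
    return states
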