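"""Historical Ne estimation from distance-binned linkage disequilibrium.

The estimator is a moment method built on the classical relation between
expected squared correlation of allelic states and effective size: for
unphased diploid data under random mating,

    E[r^2(c)]  ~=  1 / (alpha + 4 N c)  +  1 / n,

with ``c`` the recombination distance in Morgans, ``alpha = 2`` for unphased
data, and ``1/n`` the sampling inflation for ``n`` diploids.  LD at distance
``c`` predominantly reflects drift about ``t = 1 / (2 c)`` generations ago,
so inverting the relation bin by bin over a grid of distances yields a
trajectory of historical Ne against generations before present:

    Ne_hat(c) = (1 / r2_adj - alpha) / (4 c),   t(c) = 1 / (2 c),

where ``r2_adj`` is the bin mean composite r^2 minus ``1/n``.  With the
default distance range 0.001-0.05 Morgan the trajectory spans roughly 10 to
500 generations before present.

r^2 is the squared Pearson correlation of genotype dosages (composite LD),
valid without phase information.  Only pairs on the same chromosome are
used; chromosomes are pooled by pair-count-weighted averaging per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NeVkReference
from .genotypes import GenotypeMatrix


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunables of the LD binning and inversion step.

    ``c_min``/``c_max`` bound the genetic distances used (Morgans);
    ``n_bins`` log-spaced bins cover the range; each bin keeps at most
    ``max_pairs_per_bin`` SNP pairs (uniform seeded subsample).  ``alpha`` is
    the constant in the Sved-type denominator (2 for unphased random-mating
    data); ``sample_correction`` subtracts ``1/n`` from bin means.
    """

    c_min: float = 0.001
    c_max: float = 0.05
    n_bins: int = 30
    max_pairs_per_bin: int = 100_000
    alpha: float = 2.0
    sample_correction: bool = True
    seed: int = 0
    split_halves: bool = False

    def __post_init__(self):
        if not (0 < self.c_min < self.c_max <= 0.5):
            raise EstimationError("need 0 < c_min < c_max <= 0.5")
        if self.n_bins < 3:
            raise EstimationError("need at least 3 bins")

    def bin_edges(self) -> np.ndarray:
        return np.geomspace(self.c_min, self.c_max, self.n_bins + 1)

    def bin_mids(self) -> np.ndarray:
        e = self.bin_edges()
        return np.sqrt(e[:-1] * e[1:])


@dataclass
class LDBin:
    """One genetic-distance bin of SNP pairs."""

    c_mid: float
    mean_r2: float
    pair_count: int
    t_mapped: float


@dataclass
class NeTrajectory:
    """Estimated historical Ne against generations before present."""

    t: np.ndarray
    c_mid: np.ndarray
    pair_count: np.ndarray
    mean_r2: np.ndarray
    r2_adj: np.ndarray
    ne_hat: np.ndarray
    reference: NeVkReference | None = None
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t": self.t, "c_mid": self.c_mid, "pair_count": self.pair_count,
            "mean_r2": self.mean_r2, "r2_adj": self.r2_adj, "Ne_hat": self.ne_hat,
        })
        if self.reference is not None:
            df["expected_NeVk"] = [self.reference.value_at(t) for t in self.t]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    def ne_in_window(self, t_lo: float, t_hi: float) -> float:
        """Median Ne_hat over bins mapped to ``t_lo <= t <= t_hi``."""
        sel = (self.t >= t_lo) & (self.t <= t_hi)
        if not sel.any():
            return float("nan")
        return float(np.median(self.ne_hat[sel]))


# ---------------------------------------------------------------------------
# Pairwise r^2
# ---------------------------------------------------------------------------

def dosage_r2(x, y) -> float:
    """Squared Pearson correlation of two dosage vectors (composite r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise EstimationError("need two equal-length vectors of length >= 3")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        raise EstimationError("r^2 undefined for a constant dosage vector")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pair_r2(X: np.ndarray, I: np.ndarray, J: np.ndarray,
             chunk: int = 100_000) -> np.ndarray:
    """Vectorized composite r^2 for SNP-index pairs (I, J) of matrix X."""
    n = X.shape[0]
    Xc = X.astype(np.float64)
    Xc -= Xc.mean(axis=0)
    sd = Xc.std(axis=0)
    out = np.empty(I.size, dtype=np.float64)
    for s in range(0, I.size, chunk):
        i, j = I[s:s + chunk], J[s:s + chunk]
        cov = np.einsum("ni,ni->i", Xc[:, i], Xc[:, j], dtype=np.float64) / n
        out[s:s + chunk] = (cov / (sd[i] * sd[j])) ** 2
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def _bins_for_chromosome(dosages, gpos, cfg: EstimatorConfig, rng):
    """Pair enumeration, r^2 and binning for one chromosome's SNPs."""
    S = gpos.size
    edges = cfg.bin_edges()
    mids = cfg.bin_mids()
    sums = np.zeros(cfg.n_bins)
    counts = np.zeros(cfg.n_bins, dtype=np.int64)
    if S >= 2:
        lo = np.searchsorted(gpos, gpos + cfg.c_min, side="left")
        hi = np.searchsorted(gpos, gpos + cfg.c_max, side="right")
        n_per = hi - lo
        total = int(n_per.sum())
        if total:
            I = np.repeat(np.arange(S), n_per)
            starts = np.concatenate(([0], np.cumsum(n_per)))[:-1]
            J = np.arange(total) - np.repeat(starts, n_per) + np.repeat(lo, n_per)
            d = gpos[J] - gpos[I]
            b = np.clip(np.digitize(d, edges) - 1, 0, cfg.n_bins - 1)
            keep_I, keep_J, keep_b = [], [], []
            for k in range(cfg.n_bins):
                sel = np.flatnonzero(b == k)
                if sel.size > cfg.max_pairs_per_bin:
                    sel = rng.choice(sel, size=cfg.max_pairs_per_bin, replace=False)
                keep_I.append(I[sel]); keep_J.append(J[sel])
                keep_b.append(np.full(sel.size, k, dtype=np.int64))
            I = np.concatenate(keep_I); J = np.concatenate(keep_J)
            b = np.concatenate(keep_b)
            if I.size:
                r2 = _pair_r2(dosages, I, J)
                sums = np.bincount(b, weights=r2, minlength=cfg.n_bins)
                counts = np.bincount(b, minlength=cfg.n_bins)
    return [LDBin(c_mid=float(mids[k]),
                  mean_r2=float(sums[k] / counts[k]) if counts[k] else float("nan"),
                  pair_count=int(counts[k]),
                  t_mapped=bin_to_time(float(mids[k])))
            for k in range(cfg.n_bins)]


def bin_pairs_by_distance(gm: GenotypeMatrix, cfg: EstimatorConfig,
                          rng=None) -> list:
    """Distance-binned mean r^2 pooled over chromosomes.

    Only intra-chromosome pairs with genetic distance in
    ``[c_min, c_max]`` enter; each log-spaced bin is capped at
    ``max_pairs_per_bin`` pairs per chromosome (seeded subsample), and
    chromosomes are pooled by pair-count-weighted averaging.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    per_chrom = bin_pairs_per_chromosome(gm, cfg, rng)
    pooled = pool_chromosomes(per_chrom)
    if all(b.pair_count == 0 for b in pooled):
        raise EstimationError(
            "no SNP pairs fall in the configured distance range on any chromosome")
    return pooled


def bin_pairs_per_chromosome(gm: GenotypeMatrix, cfg: EstimatorConfig,
                             rng=None) -> list:
    """Per-chromosome bin lists (same grid), for pooling or split-half use."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    out = []
    for c in np.unique(gm.chromosomes):
        sel = gm.chromosomes == c
        out.append(_bins_for_chromosome(gm.dosages[:, sel],
                                        gm.genetic_positions[sel], cfg, rng))
    return out


def pool_chromosomes(bin_lists) -> list:
    """Pair-count-weighted pooling of per-chromosome bins on one grid."""
    if not bin_lists:
        raise EstimationError("no chromosomes to pool")
    grid = [b.c_mid for b in bin_lists[0]]
    for bl in bin_lists[1:]:
        if [b.c_mid for b in bl] != grid:
            raise EstimationError("chromosome bin grids differ; cannot pool")
    pooled = []
    for k, c_mid in enumerate(grid):
        n = sum(bl[k].pair_count for bl in bin_lists)
        if n:
            s = sum(bl[k].mean_r2 * bl[k].pair_count
                    for bl in bin_lists if bl[k].pair_count)
            mean = s / n
        else:
            mean = float("nan")
        pooled.append(LDBin(c_mid, mean, n, bin_to_time(c_mid)))
    return pooled


def bin_to_time(c_mid: float) -> float:
    """Historical generation probed by LD at distance ``c_mid``: t = 1/(2c)."""
    if not (0 < c_mid <= 0.5):
        raise EstimationError("c must be in (0, 0.5]")
    return 1.0 / (2.0 * c_mid)


# ---------------------------------------------------------------------------
# Inversion to Ne
# ---------------------------------------------------------------------------

def estimate_ne_curve(bins, n_individuals: int, cfg: EstimatorConfig,
                      reference: NeVkReference | None = None,
                      metadata: dict | None = None) -> NeTrajectory:
    """Invert binned r^2 into an Ne(t) trajectory.

    Bins whose corrected r^2 falls outside ``(0, 1/alpha)`` are dropped (the
    closed form has no positive solution there); the count of dropped bins
    is recorded in the trajectory metadata.
    """
    if not bins:
        raise EstimationError("no bins supplied")
    correction = 1.0 / n_individuals if cfg.sample_correction else 0.0
    rows = []
    n_dropped = 0
    r2_adj_all = []
    for b in bins:
        if b.pair_count == 0 or not np.isfinite(b.mean_r2):
            continue
        r2_adj = b.mean_r2 - correction
        r2_adj_all.append(r2_adj)
        if r2_adj <= 0 or r2_adj >= 1.0 / cfg.alpha:
            n_dropped += 1
            continue
        ne = (1.0 / r2_adj - cfg.alpha) / (4.0 * b.c_mid)
        rows.append((b.t_mapped, b.c_mid, b.pair_count, b.mean_r2, r2_adj, ne))
    if not rows:
        lohi = (f"[{min(r2_adj_all):.4g}, {max(r2_adj_all):.4g}]"
                if r2_adj_all else "(none)")
        raise EstimationError(
            f"every bin was dropped; adjusted r^2 range {lohi} has no bin in "
            f"(0, {1.0 / cfg.alpha:.3g})")
    rows.sort(key=lambda r: r[0])
    t, c_mid, pc, mr2, r2a, ne = (np.array(v) for v in zip(*rows))
    meta = dict(metadata or {})
    meta.update(n_individuals=n_individuals, n_bins_dropped=n_dropped,
                alpha=cfg.alpha, c_min=cfg.c_min, c_max=cfg.c_max)
    return NeTrajectory(t, c_mid, pc.astype(np.int64), mr2, r2a, ne,
                        reference=reference, metadata=meta)


def estimate_ne(gm: GenotypeMatrix, cfg: EstimatorConfig | None = None,
                reference: NeVkReference | None = None) -> NeTrajectory:
    """End-to-end: bin pairs, pool chromosomes, invert to Ne(t).

    With ``cfg.split_halves`` the chromosomes are pooled in two halves, a
    trajectory estimated from each, and the two Ne curves averaged (the bin
    grid is shared, so averaging is per bin).
    """
    cfg = cfg or EstimatorConfig()
    rng = np.random.default_rng(cfg.seed)
    per_chrom = bin_pairs_per_chromosome(gm, cfg, rng)
    n = gm.n_individuals
    if cfg.split_halves and len(per_chrom) >= 2:
        h = len(per_chrom) // 2
        traj_a = estimate_ne_curve(pool_chromosomes(per_chrom[:h]), n, cfg, reference)
        traj_b = estimate_ne_curve(pool_chromosomes(per_chrom[h:]), n, cfg, reference)
        df = (traj_a.to_frame().merge(traj_b.to_frame(), on=["t", "c_mid"],
                                      suffixes=("_a", "_b")))
        if df.empty:
            raise EstimationError("split halves share no usable bins")
        ne = (df["Ne_hat_a"] + df["Ne_hat_b"]) / 2
        return NeTrajectory(
            df["t"].to_numpy(), df["c_mid"].to_numpy(),
            (df["pair_count_a"] + df["pair_count_b"]).to_numpy(),
            ((df["mean_r2_a"] * df["pair_count_a"]
              + df["mean_r2_b"] * df["pair_count_b"])
             / (df["pair_count_a"] + df["pair_count_b"])).to_numpy(),
            ((df["r2_adj_a"] + df["r2_adj_b"]) / 2).to_numpy(),
            ne.to_numpy(), reference=reference,
            metadata={"split_halves": True, "n_individuals": n})
    pooled = pool_chromosomes(per_chrom)
    if all(b.pair_count == 0 for b in pooled):
        raise EstimationError(
            "no SNP pairs fall in the configured distance range on any chromosome")
    return estimate_ne_curve(pooled, n, cfg, reference)
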