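"""Richness-preserving null models and NRI/NTI standardization.

Observed MPD/MNTD values are compared against null assemblages of the same
richness S drawn uniformly, without replacement of whole combinations, from a
species pool — either the continental pool (all species in the analyzed set)
or the pool of the region holding the cell. One null distribution is built
per (pool, S) combination and shared by every cell of that richness in that
pool.

Draw sequence stopping, in order of precedence per draw:

* ``combinations_exhausted`` — all C(N, S) distinct subsets have been used;
* ``converged`` — after at least ``min_iter_before_stop`` draws, the window
  criterion over the last ``window`` MPD scores fires (see
  :func:`convergence_check`);
* ``max_iterations`` — the iteration budget (default 4999) is spent.

Standardized effect sizes use the sample (n-1) standard deviation:

    NRI = -(MPD_obs - mean_null) / sd_null       (NTI likewise from MNTD)

so positive values mean the assemblage is phylogenetically clustered
(observed distances smaller than the null) and negative values even
(overdispersed). Cells are classified by |z| against a weak and a significant
threshold (defaults 1.0 and 1.96).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .gridding import AssemblageGrid, continental_pool, regional_pools
from .metrics import compute_cell_metrics
from .tree import patristic_matrix, tip_labels

__all__ = [
    "NullModelConfig",
    "NullDistribution",
    "draw_null_assemblages",
    "convergence_check",
    "standardize",
    "classify",
    "run_nri_analysis",
]

CLASSES = ("clustered_sig", "clustered_weak", "neutral", "even_weak", "even_sig")

# dedup set size above which we refuse to track non-reuse exactly
_COMBINATION_CAP = 5_000_000


@dataclass(frozen=True)
class NullModelConfig:
    """Tunables for the null-model run (defaults follow common practice:
    4999 iterations, early stopping checked after 500 with a 100-score
    window and tolerance 0.005)."""

    pool_kind: str = "continental"  # or "regional"
    max_iter: int = 4999
    min_iter_before_stop: int = 500
    window: int = 100
    tolerance: float = 0.005
    convergence_mode: str = "literal"  # or "relative_range"
    sig_threshold: float = 1.96
    weak_threshold: float = 1.0
    include_root: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.pool_kind not in ("continental", "regional"):
            raise ValueError(f"pool_kind must be continental|regional, got {self.pool_kind!r}")
        if self.convergence_mode not in ("literal", "relative_range"):
            raise ValueError(f"unknown convergence_mode {self.convergence_mode!r}")
        if not (0 < self.weak_threshold < self.sig_threshold):
            raise ValueError("need 0 < weak_threshold < sig_threshold")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class NullDistribution:
    """Audit record of one null distribution (one pool x richness class)."""

    pool_label: str
    pool_size: int
    S: int
    n_draws: int
    mpd_mean: float
    mpd_sd: float
    mntd_mean: float
    mntd_sd: float
    stop_reason: str  # max_iterations | converged | combinations_exhausted | degenerate
    seed: int
    degenerate: bool = False


class _DrawSequence:
    """Iterator over distinct uniform S-subsets of a pool.

    Non-reuse is exact: when C(N, S) fits in the iteration budget the full
    combination set is enumerated and shuffled; otherwise subsets are sampled
    with rejection against a hash set of canonical keys (collisions are
    vanishingly rare in that regime). ``stop_reason`` is set when iteration
    ends without an external break.
    """

    def __init__(self, pool: Sequence[str], S: int, max_iter: int, rng: np.random.Generator):
        self.pool = sorted(pool)
        N = len(self.pool)
        if S > N:
            raise ValueError(f"richness S={S} exceeds pool size {N}")
        if S < 1:
            raise ValueError("S must be >= 1")
        self.S = S
        self.max_iter = max_iter
        self.rng = rng
        self.total = comb(N, S)
        self.stop_reason: str | None = None
        self.n_drawn = 0

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        N = len(self.pool)
        if self.S == N:
            self.n_drawn = 1
            yield tuple(self.pool)
            self.stop_reason = "degenerate"
            return
        if self.total <= self.max_iter:
            combos = list(itertools.combinations(range(N), self.S))
            self.rng.shuffle(combos)
            for c in combos:
                self.n_drawn += 1
                yield tuple(self.pool[i] for i in c)
            self.stop_reason = "combinations_exhausted"
            return
        seen: set[tuple[int, ...]] = set()
        while self.n_drawn < self.max_iter:
            idx = tuple(sorted(self.rng.choice(N, size=self.S, replace=False).tolist()))
            if idx in seen:
                continue
            if len(seen) >= _COMBINATION_CAP:
                raise MemoryError(
                    f"combination tracking exceeded {_COMBINATION_CAP} keys; "
                    "reduce max_iter or pool size")
            seen.add(idx)
            self.n_drawn += 1
            yield tuple(self.pool[i] for i in idx)
        self.stop_reason = "max_iterations"


def draw_null_assemblages(pool: Sequence[str] | frozenset[str], S: int,
                          max_iter: int, seed: int) -> list[frozenset[str]]:
    """Distinct uniform S-subsets of ``pool`` (materialized; see _DrawSequence).

    Ends at ``max_iter`` draws or when all C(N, S) combinations are used.
    The same seed reproduces the same sequence. S = |pool| yields the single
    degenerate draw.
    """
    seq = _DrawSequence(list(pool), S, max_iter, np.random.default_rng(seed))
    draws = [frozenset(d) for d in seq]
    draws_stop_reason = seq.stop_reason
    draw_null_assemblages.last_stop_reason = draws_stop_reason  # introspection hook
    return draws


def convergence_check(scores: Sequence[float], mode: str = "literal",
                      tolerance: float = 0.005, window: int = 100) -> bool:
    """Early-stopping criterion on the trailing window of null scores.

    ``literal`` mode: min/max of the last ``window`` scores < tolerance —
    the rule as usually printed, which for similar positive scores (ratio
    near 1) effectively never fires. ``relative_range`` mode reads it as a
    stability test: 1 - min/max < tolerance, i.e. the window's scores agree
    to within the tolerance fraction. The caller enforces the minimum
    iteration count; this function only inspects values.
    """
    if len(scores) < window:
        return False
    tail = np.asarray(scores[-window:], dtype=float)
    mx = tail.max()
    if mx <= 0:
        return False
    ratio = tail.min() / mx
    if mode == "literal":
        return bool(ratio < tolerance)
    if mode == "relative_range":
        return bool((1.0 - ratio) < tolerance)
    raise ValueError(f"unknown convergence mode {mode!r}")


def standardize(obs: float, null_mean: float, null_sd: float) -> float:
    """Negated z-score: -(obs - mean)/sd. NaN when sd is 0 (degenerate)."""
    if null_sd == 0 or not np.isfinite(null_sd):
        return float("nan")
    return -(obs - null_mean) / null_sd


def classify(z: float, sig_threshold: float = 1.96, weak_threshold: float = 1.0) -> str:
    """Map a standardized score to a significance class.

    |z| >= sig -> significant, weak <= |z| < sig -> weak, else neutral;
    the sign separates clustering (positive) from evenness (negative).
    NaN (degenerate null) classifies as neutral.
    """
    if not (0 < weak_threshold < sig_threshold):
        raise ValueError("need 0 < weak_threshold < sig_threshold")
    if not np.isfinite(z):
        return "neutral"
    if abs(z) >= sig_threshold:
        return "clustered_sig" if z > 0 else "even_sig"
    if abs(z) >= weak_threshold:
        return "clustered_weak" if z > 0 else "even_weak"
    return "neutral"


def _null_distribution(pool_label: str, pool: frozenset[str], S: int,
                       dist: pd.DataFrame, config: NullModelConfig,
                       seed: int) -> NullDistribution:
    """Build the shared null for one (pool, S): draw, score, stop, summarize.

    Convergence is monitored on the MPD score stream; MNTD shares the same
    draws so both indices come from a single audited sequence.
    """
    labels = sorted(pool)
    pos = {l: i for i, l in enumerate(labels)}
    D = dist.loc[labels, labels].to_numpy()
    rng = np.random.default_rng(seed)
    seq = _DrawSequence(labels, S, config.max_iter, rng)
    iu = np.triu_indices(S, k=1)
    mpd_scores: list[float] = []
    mntd_scores: list[float] = []
    stop_reason = None
    for draw in seq:
        idx = np.fromiter((pos[s] for s in draw), dtype=np.intp, count=S)
        sub = D[np.ix_(idx, idx)]
        mpd_scores.append(float(sub[iu].mean()))
        sub2 = sub.copy()
        np.fill_diagonal(sub2, np.inf)
        mntd_scores.append(float(sub2.min(axis=1).mean()))
        if (len(mpd_scores) >= config.min_iter_before_stop
                and convergence_check(mpd_scores, config.convergence_mode,
                                      config.tolerance, config.window)):
            stop_reason = "converged"
            break
    if stop_reason is None:
        stop_reason = seq.stop_reason
    n = len(mpd_scores)
    degenerate = stop_reason == "degenerate" or n < 2
    ddof = 1 if n >= 2 else 0
    return NullDistribution(
        pool_label=pool_label,
        pool_size=len(labels),
        S=S,
        n_draws=n,
        mpd_mean=float(np.mean(mpd_scores)),
        mpd_sd=float(np.std(mpd_scores, ddof=ddof)) if n >= 2 else 0.0,
        mntd_mean=float(np.mean(mntd_scores)),
        mntd_sd=float(np.std(mntd_scores, ddof=ddof)) if n >= 2 else 0.0,
        stop_reason=stop_reason,
        seed=seed,
        degenerate=degenerate,
    )


def run_nri_analysis(grid: AssemblageGrid, tree, config: NullModelConfig | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full phylogenetic-structure analysis of a grid against a dated tree.

    Returns ``(metrics, nulls)``: the per-cell metrics table with NRI, NTI
    and significance class filled in, and the null-distribution audit table
    (one row per pool x richness class with draw counts, running moments,
    stop reason and seed).

    Null distributions are computed once per (pool, S) and shared by all
    cells of that richness in that pool. Pool membership: ``continental``
    uses every species on the grid; ``regional`` uses the species occurring
    in cells of the cell's region (region labels are then required).
    Per-class RNG streams are derived from ``config.seed`` so results are
    reproducible and independent of cell iteration order.
    """
    config = config or NullModelConfig()
    missing = sorted(grid.species - set(tip_labels(tree)))
    if missing:
        raise KeyError(f"grid species absent from tree: {missing}")

    metrics = compute_cell_metrics(grid, tree, include_root=config.include_root)
    dist = patristic_matrix(tree)

    if config.pool_kind == "continental":
        pools = {"continental": continental_pool(grid)}
        pool_for_cell = {c: "continental" for c in grid.cells}
    else:
        if not grid.has_regions:
            raise ValueError("regional pools requested but grid has no region labels")
        pools = regional_pools(grid)
        pool_for_cell = {c: grid.region_of[c] for c in grid.cells}

    pool_index = {label: k for k, label in enumerate(sorted(pools))}
    needed = sorted({(pool_for_cell[c], len(sp)) for c, sp in grid.cells.items()
                     if len(sp) >= 2})
    nulls: dict[tuple[str, int], NullDistribution] = {}
    for pool_label, S in needed:
        pool = pools[pool_label]
        if S > len(pool):  # cannot happen for well-formed pools
            raise ValueError(f"cell richness {S} exceeds pool {pool_label!r} size {len(pool)}")
        child_seed = int(
            np.random.SeedSequence([config.seed, pool_index[pool_label], S])
            .generate_state(1)[0] % (2**31)
        )
        nulls[(pool_label, S)] = _null_distribution(
            pool_label, pool, S, dist, config, child_seed)

    nri_col, nti_col, cls_col = [], [], []
    for row in metrics.itertuples(index=False):
        cell = (row.cell_i, row.cell_j)
        S = row.S
        if S < 2:
            nri_col.append(np.nan)
            nti_col.append(np.nan)
            cls_col.append("")
            continue
        nd = nulls[(pool_for_cell[cell], S)]
        if nd.degenerate:
            nri_col.append(np.nan)
            nti_col.append(np.nan)
            cls_col.append("neutral_degenerate")
            continue
        nri = standardize(row.MPD, nd.mpd_mean, nd.mpd_sd)
        nti = standardize(row.MNTD, nd.mntd_mean, nd.mntd_sd)
        nri_col.append(nri)
        nti_col.append(nti)
        if np.isfinite(nri):
            cls_col.append(classify(nri, config.sig_threshold, config.weak_threshold))
        else:
            cls_col.append("neutral_degenerate")
    metrics["NRI"] = nri_col
    metrics["NTI"] = nti_col
    metrics["class"] = cls_col

    audit = pd.DataFrame(
        [{
            "pool": nd.pool_label, "pool_size": nd.pool_size, "S": nd.S,
            "metric": m, "n_draws": nd.n_draws,
            "null_mean": nd.mpd_mean if m == "MPD" else nd.mntd_mean,
            "null_sd": nd.mpd_sd if m == "MPD" else nd.mntd_sd,
            "stop_reason": nd.stop_reason, "seed": nd.seed,
            "degenerate": nd.degenerate,
        }
            for nd in (nulls[k] for k in sorted(nulls))
            for m in ("MPD", "MNTD")],
        columns=["pool", "pool_size", "S", "metric", "n_draws", "null_mean",
                 "null_sd", "stop_reason", "seed", "degenerate"],
    )
    return metrics, audit
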