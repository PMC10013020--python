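"""Surrogate data engines for the uncoupled null hypothesis.

Four methods, all seeded and bit-reproducible:

* ``local_permutation`` — replaces the source blocks of the at-event joint
  history embeddings with source blocks observed at *random time points*
  whose target blocks are close (max norm), realizing the null "present of
  the target independent of the source history given the target history"
  while keeping the target/source-history relation.  Under that null the
  conditional distribution of the source history given the target history is
  identical at events and at random times, so the donors are an exact null
  draw.  Operates on embedding matrices; no surrogate event series exists.
  (A plain within-set permutation, :func:`local_permutation`, is also
  provided; as a surrogate engine it is ineffective because the source-block
  *marginal* at target events already carries the event-locking signature of
  coupling, which a permutation preserves.)
* ``shuffle`` — random permutation of the inter-event intervals, preserving
  their distribution but destroying all serial and cross correlation.
* ``iaaft`` — iterative amplitude-adjusted Fourier transform on the interval
  series, preserving both the amplitude distribution and (approximately) the
  power spectrum.
* ``jodi`` — autocorrelation-preserving permutation of the intervals: seeded
  greedy pairwise-swap descent from a random shuffle, minimizing the summed
  squared lag-1..5 autocorrelation discrepancy with the original.

``surrogate_mir_values`` wires these into M surrogate MIR estimates used for
the cMIR correction and the 95th-percentile significance test.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from ._seeds import spawn_rng
from .events import (
    EmbeddingSet,
    EventSeries,
    IntervalSeries,
    embed_at_times,
    events_from_intervals,
    intervals,
    sample_random_times,
)
from .estimators import (
    EstimatorConfig,
    _jitter_matrix,
    _surrogate_joint_update,
    _ter_parts,
    ter,
)


def _donor_pool(
    target: EventSeries, source: EventSeries, cfg: EstimatorConfig, tag: int
) -> np.ndarray:
    """Fresh random-time joint embeddings used as source-block donors.

    Kept disjoint from the estimation reference set: sharing rows between the
    surrogate event matrix and the reference set would contaminate the
    neighbor searches with exact duplicates.
    """
    n = cfg.n_u
    if n is None:
        from .events import embed_at_events

        n = embed_at_events(target, source, cfg.l)[0].n
    u = sample_random_times(target, source, cfg.l, n, spawn_rng(cfg.seed, tag, 7))
    joint, _ = embed_at_times(target, source, cfg.l, u)
    return _jitter_matrix(
        joint.samples, spawn_rng(cfg.seed, tag, 8), cfg.jitter_scale
    )

__all__ = [
    "SurrogateConfig",
    "local_permutation",
    "surrogate_shuffle",
    "surrogate_iaaft",
    "surrogate_jodi",
    "surrogate_mir_values",
]

_INTERVAL_METHODS = ("shuffle", "iaaft", "jodi")


@dataclass(frozen=True)
class SurrogateConfig:
    """Surrogate engine selector and parameters.

    method : one of {"local_permutation", "shuffle", "iaaft", "jodi"}.
    M : number of surrogate pairs (default 100).
    n_perm_neighbors : local-permutation neighborhood size (donor rows
        eligible per event row).  Default 30, matched to the estimator's
        neighbor count k: coupling structure finer than the kNN smoothing
        scale is invisible to the estimator, so tighter conditioning only
        starves the donor pool.
    max_iter : iteration cap for the IAAFT loop / JODI swap sweeps.
    apply_to : which process interval-based methods surrogate: "source"
        (default; each TER direction gets its own source surrogated) or
        "both" (one independent surrogate per process, MIR on the pair).
    """

    method: str = "local_permutation"
    M: int = 100
    seed: int | None = None
    n_perm_neighbors: int = 30
    max_iter: int = 100
    apply_to: str = "source"

    def __post_init__(self) -> None:
        if self.method not in ("local_permutation",) + _INTERVAL_METHODS:
            raise ValueError(f"unknown surrogate method {self.method!r}")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.n_perm_neighbors < 1:
            raise ValueError("n_perm_neighbors must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.apply_to not in ("source", "both"):
            raise ValueError("apply_to must be 'source' or 'both'")


# ---------------------------------------------------------------------------
# local permutation


def _neighbor_permutation(
    target_block: np.ndarray, n_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    """Bijective assignment i -> pi(i), pi(i) != i, preferring target-space kNN.

    Being a permutation, it preserves the source-block multiset exactly.  Rows
    whose nearest neighbors are all taken fall back to a random free row (rare
    for n_neighbors ~ 10 at a few hundred rows).
    """
    n = target_block.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_perm_neighbors+1={n_neighbors + 1} rows")
    tree = cKDTree(target_block)
    _, nbr = tree.query(target_block, k=n_neighbors + 1, p=np.inf)
    assign = np.full(n, -1, dtype=int)
    used = np.zeros(n, dtype=bool)
    for i in rng.permutation(n):
        cand = nbr[i][(nbr[i] != i) & ~used[nbr[i]]]
        if cand.size:
            j = int(rng.choice(cand))
        else:
            free = np.flatnonzero(~used)
            free = free[free != i]
            if free.size == 0:
                j = i  # forced self-assignment, fixed below
            else:
                j = int(rng.choice(free))
        assign[i] = j
        used[j] = True
    # repair the (at most one) forced self-assignment by a swap
    for i in np.flatnonzero(assign == np.arange(n)):
        choices = np.flatnonzero(assign != i)
        choices = choices[choices != i]
        j = int(rng.choice(choices))
        assign[i], assign[j] = assign[j], assign[i]
    return assign


def local_permutation(
    joint: EmbeddingSet,
    l: int | None = None,
    n_perm_neighbors: int = 10,
    seed: int | np.random.Generator | None = None,
) -> EmbeddingSet:
    """Locally permute the source blocks of a joint embedding set.

    Each row's source block (last l columns) is replaced by the source block
    of a row drawn from its ``n_perm_neighbors`` nearest rows in target-block
    (first l columns) max-norm distance, via a seeded self-avoiding bijection.
    Target blocks are unchanged and the source-block multiset is preserved.
    """
    if joint.scope != "joint":
        raise ValueError("local_permutation requires a joint-scope embedding set")
    l = l if l is not None else joint.l
    if l != joint.l:
        raise ValueError("l does not match the embedding set")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 0)
    perm = _neighbor_permutation(joint.samples[:, :l], n_perm_neighbors, rng)
    out = joint.samples.copy()
    out[:, l:] = joint.samples[perm, l:]
    return replace(joint, samples=out)


# ---------------------------------------------------------------------------
# interval-series surrogates


def surrogate_shuffle(
    iv: IntervalSeries, seed: int | np.random.Generator | None = None
) -> IntervalSeries:
    """Seeded uniform permutation of the intervals."""
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 0)
    return replace(iv, intervals=rng.permutation(iv.intervals))


def surrogate_iaaft(
    iv: IntervalSeries,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 100,
) -> IntervalSeries:
    """Iterative amplitude-adjusted Fourier transform surrogate.

    Alternates imposing the original Fourier amplitude spectrum with
    rank-ordering back to the original amplitudes, starting from a random
    shuffle; stops when the rank ordering no longer changes or after
    ``max_iter`` iterations.  The output's sorted amplitudes equal the
    original's exactly.
    """
    x = iv.intervals
    n = x.size
    if n < 8:
        raise ValueError("IAAFT needs at least 8 intervals")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 0)
    sorted_x = np.sort(x)
    target_amp = np.abs(np.fft.rfft(x))
    s = rng.permutation(x)
    prev_rank = None
    for _ in range(max_iter):
        spec = np.fft.rfft(s)
        phases = np.angle(spec)
        s = np.fft.irfft(target_amp * np.exp(1j * phases), n)
        rank = np.argsort(np.argsort(s, kind="stable"), kind="stable")
        s = sorted_x[rank]
        if prev_rank is not None and np.array_equal(rank, prev_rank):
            break
        prev_rank = rank
    return replace(iv, intervals=s)


def _lagged_sums(z: np.ndarray, lags: np.ndarray) -> np.ndarray:
    return np.array([float(np.dot(z[:-lag], z[lag:])) for lag in lags])


def surrogate_jodi(
    iv: IntervalSeries,
    seed: int | np.random.Generator | None = None,
    max_iter: int = 100,
    n_lags: int = 5,
    tol: float = 1e-4,
) -> IntervalSeries:
    """Autocorrelation-preserving permutation of the intervals.

    Starts from a random shuffle (so cross-coupling with any partner series is
    destroyed) and greedily applies pairwise swaps that reduce the summed
    squared discrepancy of the lag-1..``n_lags`` autocorrelations from the
    original's, stopping at ``tol`` or after ``max_iter`` sweeps of n proposals.
    The output is a permutation, so the amplitude multiset is preserved
    exactly.
    """
    x = iv.intervals
    n = x.size
    if n < 8:
        raise ValueError("needs at least 8 intervals")
    rng = seed if isinstance(seed, np.random.Generator) else spawn_rng(seed, 0)
    lags = np.arange(1, n_lags + 1)
    z0 = x - x.mean()
    denom = float(np.dot(z0, z0))
    if denom == 0:
        return replace(iv, intervals=rng.permutation(x))
    target = _lagged_sums(z0, lags) / denom

    s = rng.permutation(x)
    z = s - s.mean()
    c = _lagged_sums(z, lags)

    def objective(csums: np.ndarray) -> float:
        return float(np.sum((csums / denom - target) ** 2))

    obj = objective(c)
    for _ in range(max_iter):
        if obj < tol:
            break
        for _ in range(n):
            a, b = rng.integers(0, n, size=2)
            if a == b or z[a] == z[b]:
                continue
            c_new = c.copy()
            for li, lag in enumerate(lags):
                pairs = set()
                for idx in (a, b):
                    if idx - lag >= 0:
                        pairs.add((idx - lag, idx))
                    if idx + lag < n:
                        pairs.add((idx, idx + lag))
                old = sum(z[i] * z[j] for i, j in pairs)
                za, zb = z[a], z[b]
                z[a], z[b] = zb, za
                new = sum(z[i] * z[j] for i, j in pairs)
                z[a], z[b] = za, zb
                c_new[li] += new - old
            obj_new = objective(c_new)
            if obj_new < obj:
                z[a], z[b] = z[b], z[a]
                s[a], s[b] = s[b], s[a]
                c = c_new
                obj = obj_new
    return replace(iv, intervals=s)


_SURROGATE_FNS = {
    "shuffle": lambda iv, rng, scfg: surrogate_shuffle(iv, rng),
    "iaaft": lambda iv, rng, scfg: surrogate_iaaft(iv, rng, max_iter=scfg.max_iter),
    "jodi": lambda iv, rng, scfg: surrogate_jodi(iv, rng, max_iter=scfg.max_iter),
}


# ---------------------------------------------------------------------------
# surrogate MIR distribution


def surrogate_mir_values(
    x: EventSeries,
    y: EventSeries,
    cfg: EstimatorConfig | None = None,
    scfg: SurrogateConfig | None = None,
) -> np.ndarray:
    """M surrogate MIR values under the configured null engine (nats/s).

    For interval-based engines each surrogate pair is rebuilt from surrogated
    interval series (by default the source process of each TER direction) and
    the MIR re-estimated.  For ``local_permutation`` no surrogate event series
    exists: each surrogate MIR is the sum of the two directed TERs recomputed
    after replacing, independently per direction, each at-event joint row's
    source block with one drawn (with replacement) from its
    ``n_perm_neighbors`` nearest rows -- in target-block max-norm distance --
    of a dedicated pool of random-time embeddings, disjoint from the
    estimation reference set.  The random-time reference set and the
    target-only entropy terms are unchanged by construction and re-used.
    """
    cfg = cfg or EstimatorConfig()
    scfg = scfg or SurrogateConfig()
    vals = np.empty(scfg.M)

    if scfg.method == "local_permutation":
        parts = (_ter_parts(x, y, cfg, tag=0), _ter_parts(y, x, cfg, tag=1))
        donors = (
            _donor_pool(x, y, cfg, tag=0),
            _donor_pool(y, x, cfg, tag=1),
        )
        neighborhoods = []
        for p, dpool in zip(parts, donors):
            n_nb = min(scfg.n_perm_neighbors, dpool.shape[0])
            _, nbr = cKDTree(dpool[:, : p.l]).query(
                p.J_ev[:, : p.l], k=n_nb, p=np.inf
            )
            neighborhoods.append(np.atleast_2d(nbr))
        for m in range(scfg.M):
            total = 0.0
            for d_i, (p, dpool, nbr) in enumerate(
                zip(parts, donors, neighborhoods)
            ):
                rng = spawn_rng(scfg.seed, 2, m, d_i)
                pick = nbr[
                    np.arange(nbr.shape[0]),
                    rng.integers(0, nbr.shape[1], size=nbr.shape[0]),
                ]
                J_perm = p.J_ev.copy()
                J_perm[:, p.l :] = dpool[pick, p.l :]
                total += _surrogate_joint_update(p, J_perm)
            vals[m] = total
        return vals

    fn = _SURROGATE_FNS[scfg.method]
    x_iv, y_iv = intervals(x), intervals(y)
    for m in range(scfg.M):
        y_s = events_from_intervals(fn(y_iv, spawn_rng(scfg.seed, 2, m, 0), scfg))
        x_s = events_from_intervals(fn(x_iv, spawn_rng(scfg.seed, 2, m, 1), scfg))
        if scfg.apply_to == "source":
            # each direction tests decoupling of its own source process
            t_yx = ter(x, source=y_s, cfg=cfg, _tag=0)
            t_xy = ter(y, source=x_s, cfg=cfg, _tag=1)
        else:
            t_yx = ter(x_s, source=y_s, cfg=cfg, _tag=0)
            t_xy = ter(y_s, source=x_s, cfg=cfg, _tag=1)
        vals[m] = t_yx.value + t_xy.value
    return vals
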