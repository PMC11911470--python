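"""Preranked weighted Kolmogorov–Smirnov gene-set enrichment with permutation nulls.

The enrichment score (ES) of a member set S in a ranked universe of N items
with statistics s_i (sorted descending) is the extremum of the running sum

    P_hit(i)  = sum_{j in S, j <= i} |s_j|^q / sum_{j in S} |s_j|^q
    P_miss(i) = #(non-members <= i) / (N - |S|)

with weight exponent q (default 1).  Under ``score_type="pos"`` — appropriate
for non-negative statistics such as -log10 p — only the positive extremum is
taken and the permutation p-value is one-sided upward.  Under
``score_type="std"`` the signed extremum of larger magnitude is used, with
sign-stratified null normalization, which suits signed rankings such as
log-fold-changes.

The null distribution permutes set membership: random same-size sets drawn
without replacement from the universe (the only exchangeable unit for
preranked input).  p = (b + 1)/(n + 1) where b counts null ES at least as
extreme as the observed one.  When the estimate hits the resolution floor
(b = 0) and ``eps == 0``, the number of permutations escalates tenfold up to
``n_perm_max``.  Null ES distributions depend only on set size, so they are
cached and shared across same-size sets within one call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import InputError

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Identifiers with aligned real statistics, sorted descending."""

    items: list[str]
    stats: np.ndarray
    score_type: str = "pos"  # pos | std

    @classmethod
    def from_stats(cls, items: Iterable[str], stats: Iterable[float],
                   score_type: str = "pos") -> "RankedList":
        """Build a ranked list, sorting descending (ties by identifier)."""
        items = [str(i) for i in items]
        stats = np.asarray(list(stats), dtype=float)
        if len(items) != len(stats):
            raise InputError("items and stats differ in length")
        if len(set(items)) != len(items):
            raise InputError("duplicate identifiers in ranked list")
        if score_type not in ("pos", "std"):
            raise InputError(f"unknown score_type: {score_type}")
        if score_type == "pos" and np.any(stats < 0):
            raise InputError("score_type 'pos' requires non-negative statistics")
        order = sorted(range(len(items)), key=lambda i: (-stats[i], items[i]))
        return cls([items[i] for i in order], stats[order], score_type)

    def __len__(self) -> int:
        return len(self.items)

    def index(self) -> dict[str, int]:
        return {item: i for i, item in enumerate(self.items)}


@dataclass
class GseaParams:
    """Tuning knobs for the permutation GSEA."""

    weight_exponent: float = 1.0
    n_perm: int = 1000
    n_perm_max: int = 100_000
    eps: float = 0.0  # 0 = adaptive permutation escalation at the floor
    min_size: int = 1
    max_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_perm > self.n_perm_max:
            raise InputError("n_perm exceeds n_perm_max")
        if self.weight_exponent < 0 or self.min_size < 1:
            raise InputError("invalid GSEA parameters")


@dataclass(slots=True)
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p: float
    effective_size: int
    n_perm: int = 0


def _batch_es(positions: np.ndarray, weights: np.ndarray, n: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative running-sum extrema for batches of member sets.

    ``positions``: (R, m) sorted 0-based ranks of the members of R sets.
    The running sum rises only at member positions and falls linearly in
    between, so the maximum is attained immediately after a hit and the
    minimum immediately before a hit (or at the final zero).
    """
    r, m = positions.shape
    if m >= n:
        raise InputError("member set must be a proper subset of the universe")
    w = weights[positions]
    cw = np.cumsum(w, axis=1)
    denom = cw[:, -1].copy()
    zero = denom <= 0
    if np.any(zero):
        # all member weights zero: fall back to uniform hit increments
        cw[zero] = np.arange(1, m + 1, dtype=float)
        denom[zero] = m
    hit = cw / denom[:, None]
    k = np.arange(1, m + 1, dtype=float)
    inv_miss = 1.0 / (n - m)
    dev_after = hit - (positions + 1 - k) * inv_miss
    es_pos = dev_after.max(axis=1)
    hit_before = np.empty_like(hit)
    hit_before[:, 0] = 0.0
    hit_before[:, 1:] = hit[:, :-1]
    dev_before = hit_before - (positions - (k - 1)) * inv_miss
    es_neg = np.minimum(dev_before.min(axis=1), 0.0)
    return es_pos, es_neg


def enrichment_score(ranked: RankedList, members: Iterable[str],
                     weight_exponent: float = 1.0) -> float:
    """Observed ES of ``members`` in ``ranked`` (positive extremum for 'pos',
    larger-magnitude signed extremum for 'std'; ties favor positive)."""
    idx = ranked.index()
    pos = sorted(idx[m] for m in set(members) if m in idx)
    n = len(ranked)
    if len(pos) == 0 or len(pos) == n:
        raise InputError("degenerate set: empty intersection or full universe")
    w = np.abs(ranked.stats) ** weight_exponent
    ep, en = _batch_es(np.asarray([pos]), w, n)
    if ranked.score_type == "pos":
        return float(ep[0])
    return float(ep[0]) if ep[0] >= -en[0] else float(en[0])


class _NullCache:
    """Seeded, size-keyed cache of permutation-null ES draws for one ranking."""

    def __init__(self, weights: np.ndarray, n: int, seed: int, score_type: str):
        self.w = weights
        self.n = n
        self.seed = seed
        self.score_type = score_type
        self._store: dict[tuple[int, int], np.ndarray] = {}

    def null_es(self, m: int, n_perm: int) -> np.ndarray:
        key = (m, n_perm)
        if key not in self._store:
            rng = np.random.default_rng(
                np.random.SeedSequence(self.seed, spawn_key=(m, n_perm)))
            out = np.empty(n_perm)
            chunk = max(1, int(4_000_000 // max(self.n, 1)))
            for start in range(0, n_perm, chunk):
                stop = min(start + chunk, n_perm)
                u = rng.random((stop - start, self.n))
                pos = np.argpartition(u, m - 1, axis=1)[:, :m] if m < self.n \
                    else np.tile(np.arange(self.n), (stop - start, 1))
                pos.sort(axis=1)
                ep, en = _batch_es(pos, self.w, self.n)
                if self.score_type == "pos":
                    out[start:stop] = ep
                else:
                    out[start:stop] = np.where(ep >= -en, ep, en)
            self._store[key] = out
        return self._store[key]


def _one_set(obs_es: float, m: int, cache: _NullCache, params: GseaParams
             ) -> tuple[float, float, int]:
    """(p, nes, n_perm_used) with adaptive escalation at the resolution floor."""
    n_perm = params.n_perm
    while True:
        null = cache.null_es(m, n_perm)
        if cache.score_type == "pos" or obs_es >= 0:
            side = null[null >= 0]
            b = int(np.count_nonzero(side >= obs_es))
            denom_null = side[side > 0]
            nes = obs_es / denom_null.mean() if denom_null.size else float("nan")
            p = (b + 1) / (side.size + 1)
        else:
            side = null[null < 0]
            b = int(np.count_nonzero(side <= obs_es))
            nes = obs_es / np.abs(side).mean() if side.size else float("nan")
            p = (b + 1) / (side.size + 1)
        if b == 0 and params.eps == 0 and n_perm < params.n_perm_max:
            n_perm = min(n_perm * 10, params.n_perm_max)
            continue
        return p, float(nes), n_perm


def gsea_preranked(ranked: RankedList, sets: Mapping[str, set] | "object",
                   params: GseaParams | None = None) -> list[EnrichmentResult]:
    """Permutation GSEA of every set against one ranked list.

    ``sets`` is a mapping set_id -> member identifiers (a
    :class:`npscreen.prioritize.SetCollection` is accepted).  Sets whose
    effective size (intersection with the ranked universe) falls outside
    ``[min_size, max_size]``, or which cover the whole universe, are skipped
    with a log entry.  Results come back sorted by set_id.
    """
    if params is None:
        params = GseaParams()
    members_map = getattr(sets, "members", sets)
    n = len(ranked)
    if n < 2:
        raise InputError("ranked universe must contain at least 2 items")
    idx = ranked.index()
    w = np.abs(ranked.stats) ** params.weight_exponent
    cache = _NullCache(w, n, params.seed, ranked.score_type)
    results: list[EnrichmentResult] = []
    for set_id in sorted(members_map):
        pos = sorted(idx[m] for m in members_map[set_id] if m in idx)
        m = len(pos)
        if m == 0 or m == n:
            logger.info("set %s skipped: degenerate (effective size %d of %d)",
                        set_id, m, n)
            continue
        if m < params.min_size or (params.max_size is not None and m > params.max_size):
            logger.info("set %s skipped: effective size %d outside bounds", set_id, m)
            continue
        ep, en = _batch_es(np.asarray([pos]), w, n)
        if ranked.score_type == "pos":
            obs = float(ep[0])
        else:
            obs = float(ep[0]) if ep[0] >= -en[0] else float(en[0])
        p, nes, used = _one_set(obs, m, cache, params)
        results.append(EnrichmentResult(set_id=set_id, es=obs, nes=nes, p=p,
                                        effective_size=m, n_perm=used))
    return results


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT signature file (set id, description, members...)."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0].strip():
                continue
            out[parts[0].strip()] = {p.strip() for p in parts[2:] if p.strip()}
    if not out:
        raise InputError(f"no sets parsed from GMT file: {path}")
    return out
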