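"""Consensus ranking of natural products and screening of herbal ingredients.

Per-analysis NP enrichment p-values (one GSEA per QTL x GWAS dataset pair)
are pooled with Stouffer's method, Z = sum_i Phi^{-1}(1 - p_i) / sqrt(k),
meta-p = 1 - Phi(Z); the -log10 meta-p values form the NP ranking on which a
second preranked GSEA scores each herb (set of NPs).  Herb p-values are
Bonferroni- and BH-adjusted over the herbs actually tested; candidates are
selected at Bonferroni-adjusted p < 0.05 (strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import P_CEILING, P_FLOOR, InputError, neglog10
from .gsea import EnrichmentResult, GseaParams, RankedList, gsea_preranked

logger = logging.getLogger(__name__)

HERB_TABLE_COLUMNS = ["INGREDIENT", "NES", "P_VALUE", "P_FDR", "P_BONFERRONI",
                      "N_NP_TARGETS", "SELECTED"]


@dataclass
class SetCollection:
    """Two-layer membership maps: NP -> target genes, or herb -> NPs."""

    layer: str  # np_to_gene | herb_to_np
    members: dict[str, set]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(slots=True)
class ConsensusNpRank:
    np_id: str
    per_analysis_p: dict
    z_sum: float
    meta_p: float
    rank_stat: float


@dataclass(slots=True)
class HerbResult:
    herb_id: str
    nes: float
    p: float
    p_fdr: float
    p_bonferroni: float
    n_np_targets: int
    selected: bool


def read_relationships(path, layer: str) -> SetCollection:
    """Parse a two-column relationship export (SET_ID, MEMBER_ID per line).

    Duplicate pairs are deduplicated; rows with an empty field are dropped
    with a warning.  The first two columns are used whatever their header.
    """
    if layer not in ("np_to_gene", "herb_to_np"):
        raise InputError(f"unknown layer: {layer}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty relationship file: {path}")
    if df.shape[1] < 2 or len(df) == 0:
        raise InputError(f"relationship file needs two columns and data rows: {path}")
    sets: dict[str, set] = {}
    n_rows = n_bad = 0
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        n_rows += 1
        a = "" if pd.isna(a) else str(a).strip()
        b = "" if pd.isna(b) else str(b).strip()
        if not a or not b:
            n_bad += 1
            continue
        sets.setdefault(a, set()).add(b)
    if n_bad:
        logger.warning("read_relationships(%s): dropped %d/%d malformed rows",
                       path, n_bad, n_rows)
    logger.info("read_relationships(%s): %d sets, %d memberships", path,
                len(sets), sum(len(s) for s in sets.values()))
    return SetCollection(layer=layer, members=sets)


def stouffer_combine(p_values: Sequence[float]) -> tuple[float, float]:
    """Equal-weight Stouffer combination of one-sided p-values.

    Small p maps to a large positive z (z_i = Phi^{-1}(1 - p_i));
    Z = sum z_i / sqrt(k); meta-p = 1 - Phi(Z).  Boundary p-values are
    clamped to (floor, 1 - 1e-16) before the quantile transform.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InputError("stouffer_combine needs at least one p-value")
    if np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    if np.any(p <= 0) or np.any(p >= 1):
        logger.info("stouffer_combine: clamped %d boundary p-value(s)",
                    int(np.sum((p <= 0) | (p >= 1))))
    p = np.clip(p, P_FLOOR, P_CEILING)
    z = stats.norm.isf(p)
    z_sum = float(z.sum() / math.sqrt(p.size))
    meta_p = float(stats.norm.sf(z_sum))
    return z_sum, float(np.clip(meta_p, P_FLOOR, P_CEILING))


def consensus_np_records(per_analysis: Mapping[str, Sequence[EnrichmentResult]]
                         ) -> list[ConsensusNpRank]:
    """Per-NP Stouffer consensus over all analyses in which the NP was tested."""
    if len(per_analysis) == 0:
        raise InputError("no analyses provided")
    pooled: dict[str, dict] = {}
    for pair_id in sorted(per_analysis):
        for res in per_analysis[pair_id]:
            pooled.setdefault(res.set_id, {})[pair_id] = res.p
    out = []
    for np_id in sorted(pooled):
        ps = pooled[np_id]
        z, meta = stouffer_combine([ps[k] for k in sorted(ps)])
        out.append(ConsensusNpRank(np_id=np_id, per_analysis_p=ps, z_sum=z,
                                   meta_p=meta,
                                   rank_stat=float(neglog10(meta))))
    return out


def consensus_np_ranking(per_analysis: Mapping[str, Sequence[EnrichmentResult]]
                         ) -> RankedList:
    """NPs ranked by descending -log10 of the Stouffer meta-p."""
    recs = consensus_np_records(per_analysis)
    return RankedList.from_stats([r.np_id for r in recs],
                                 [r.rank_stat for r in recs], score_type="pos")


def adjust_pvalues(p: Sequence[float], method: str) -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini–Hochberg step-up adjustment.

    Input order is preserved; BH enforces monotonicity from the largest p
    downward.
    """
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(q, 1.0)
        return out
    raise InputError(f"unknown adjustment method: {method}")


def prioritize_herbs(np_rank: RankedList, herb_sets: SetCollection | Mapping[str, set],
                     params: GseaParams | None = None) -> list[HerbResult]:
    """Second-level GSEA of herbs (NP sets) on the consensus NP ranking.

    Bonferroni m = number of herbs actually tested (post size-filter); BH FDR
    is reported alongside.  Rows are sorted by p ascending (ties by
    descending NES, then herb id); ``selected`` is the strict Bonferroni
    criterion p_bonferroni < 0.05.
    """
    if len(np_rank) == 0:
        raise InputError("empty NP universe")
    results = gsea_preranked(np_rank, herb_sets, params)
    if not results:
        return []
    p = [r.p for r in results]
    p_bonf = adjust_pvalues(p, "bonferroni")
    p_fdr = adjust_pvalues(p, "bh")
    rows = [HerbResult(herb_id=r.set_id, nes=r.nes, p=r.p,
                       p_fdr=float(f), p_bonferroni=float(b),
                       n_np_targets=r.effective_size,
                       selected=bool(b < 0.05))
            for r, f, b in zip(results, p_fdr, p_bonf)]
    rows.sort(key=lambda h: (h.p, -h.nes, h.herb_id))
    logger.info("prioritize_herbs: %d herbs tested (Bonferroni m=%d), %d selected",
                len(rows), len(rows), sum(h.selected for h in rows))
    return rows


def herb_table(rows: Sequence[HerbResult]) -> pd.DataFrame:
    """Candidate table mirroring the published screening output columns."""
    return pd.DataFrame({
        "INGREDIENT": [h.herb_id for h in rows],
        "NES": [h.nes for h in rows],
        "P_VALUE": [h.p for h in rows],
        "P_FDR": [h.p_fdr for h in rows],
        "P_BONFERRONI": [h.p_bonferroni for h in rows],
        "N_NP_TARGETS": [h.n_np_targets for h in rows],
        "SELECTED": [h.selected for h in rows],
    })


def compare_scores_by_label(scores: Sequence[float], labels: Sequence[bool]
                            ) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of scores between two label groups.

    Exact null distribution when min(n1, n0) <= 10 and there are no ties;
    normal approximation with tie correction otherwise.  Returns the rank sum
    of the True group and the two-sided p-value.
    """
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=bool)
    g1, g0 = scores[labels], scores[~labels]
    if g1.size == 0 or g0.size == 0:
        raise InputError("both label groups must be non-empty")
    has_ties = np.unique(scores).size < scores.size
    method = "exact" if (min(g1.size, g0.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g0, alternative="two-sided", method=method)
    rank_sum = float(res.statistic + g1.size * (g1.size + 1) / 2.0)
    return rank_sum, float(res.pvalue)
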