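"""Summary-data-based Mendelian randomization (SMR) gene-disease statistics.

For a gene instrumented by its top cis-QTL SNP, the SMR Wald-ratio estimate of
the causal effect of the gene's molecular level (exposure x) on the trait
(outcome y) is

    b_SMR = b_y / b_x

and the associated test statistic, with z_x = b_x/se_x and z_y = b_y/se_y, is

    T_SMR = z_x^2 * z_y^2 / (z_x^2 + z_y^2)   ~  chi-square, 1 df.

T_SMR is bounded above by min(z_x^2, z_y^2) and approaches the smaller
marginal chi-square as the other association becomes arbitrarily strong.  The
gene ranking statistic downstream is -log10(p_SMR), with the p-value floored
at 1e-300 to keep the statistic finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from ._util import P_FLOOR, neglog10
from .sumstats import (InstrumentSet, LdTable, VariantAssoc, find_proxy_with_id,
                       harmonize, variants_from_frame)

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class GeneAssociation:
    """Per-gene SMR result for one QTL x GWAS dataset pair."""

    gene_id: str
    dataset_pair_id: str
    top_snp: str
    b_smr: float
    t_smr: float
    p_smr: float
    rank_stat: float


def smr_statistic(b_x: float, se_x: float, b_y: float, se_y: float
                  ) -> tuple[float, float, float]:
    """(b_SMR, T_SMR, p_SMR) from exposure and outcome effect estimates.

    Raises ``ValueError`` when b_x == 0 (undefined Wald ratio); callers flag
    and skip the gene.
    """
    if se_x <= 0 or se_y <= 0:
        raise ValueError("standard errors must be positive")
    if b_x == 0:
        raise ValueError("b_x is zero: SMR ratio undefined")
    z_x = b_x / se_x
    z_y = b_y / se_y
    zx2, zy2 = z_x * z_x, z_y * z_y
    b_smr = b_y / b_x
    t_smr = zx2 * zy2 / (zx2 + zy2)
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    return b_smr, t_smr, max(p_smr, P_FLOOR)  # keep p in (0, 1] under underflow


def gene_association(instruments: InstrumentSet,
                     outcome: Mapping[str, VariantAssoc] | pd.DataFrame,
                     ld: LdTable | None = None,
                     dataset_pair_id: str = "",
                     *,
                     proxies: bool = False,
                     proxy_min_r2: float = 0.8,
                     palindrome_eaf_window: float = 0.08,
                     min_p_over_instruments: bool = False
                     ) -> GeneAssociation | None:
    """SMR association for one gene against an outcome GWAS.

    Instruments are tried in order of exposure p-value (ties by snp_id): the
    top SNP is looked up in the outcome (optionally through an LD proxy),
    harmonized, and fed to :func:`smr_statistic`; if it cannot be used the
    next-best instrument is tried, so genes are not silently lost.  With
    ``min_p_over_instruments`` every usable instrument is evaluated and the
    smallest SMR p-value is kept.
    """
    if isinstance(outcome, pd.DataFrame):
        outcome = {v.snp_id: v for v in variants_from_frame(outcome)}
    order = sorted(instruments.variants, key=lambda v: (v.p, v.snp_id))
    best: GeneAssociation | None = None
    for exp in order:
        out = outcome.get(exp.snp_id)
        proxy_of = None
        if out is None and proxies and ld is not None:
            found = find_proxy_with_id(exp.snp_id, outcome, ld, proxy_min_r2)
            if found is not None:
                out, proxy_of = found
        if out is None:
            continue
        pair = harmonize(exp, out, palindrome_eaf_window, proxy_of=proxy_of)
        if pair.dropped:
            continue
        if pair.exposure.beta == 0:
            logger.info("gene %s: top SNP %s has b_x = 0, skipped",
                        instruments.gene_id, exp.snp_id)
            continue
        b, t, p = smr_statistic(pair.exposure.beta, pair.exposure.se,
                                pair.outcome.beta, pair.outcome.se)
        assoc = GeneAssociation(
            gene_id=instruments.gene_id, dataset_pair_id=dataset_pair_id,
            top_snp=exp.snp_id, b_smr=b, t_smr=t, p_smr=p,
            rank_stat=float(neglog10(p)))
        if not min_p_over_instruments:
            return assoc
        if best is None or (assoc.p_smr, assoc.gene_id) < (best.p_smr, best.gene_id):
            best = assoc
    return best


def rank_genes(assocs: Sequence[GeneAssociation]):
    """Genes ordered by descending -log10 p_SMR (ties by gene_id).

    Returns a :class:`npscreen.gsea.RankedList` with non-negative scores.
    """
    from .gsea import RankedList

    seen = set()
    for a in assocs:
        if a.gene_id in seen:
            raise ValueError(f"duplicate gene in ranking: {a.gene_id}")
        seen.add(a.gene_id)
    return RankedList.from_stats([a.gene_id for a in assocs],
                                 [a.rank_stat for a in assocs],
                                 score_type="pos")


def associations_to_frame(assocs: Sequence[GeneAssociation]) -> pd.DataFrame:
    """Gene-ranking table in the on-disk dialect (descending rank_stat)."""
    rows = sorted(assocs, key=lambda a: (-a.rank_stat, a.gene_id))
    return pd.DataFrame({
        "GENE": [a.gene_id for a in rows],
        "TOP_SNP": [a.top_snp for a in rows],
        "B_SMR": [a.b_smr for a in rows],
        "T_SMR": [a.t_smr for a in rows],
        "P_SMR": [a.p_smr for a in rows],
        "RANK_STAT": [a.rank_stat for a in rows],
    })
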