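"""Reading, filtering, LD-clumping and harmonizing GWAS/QTL summary statistics.

Exposure (QTL) and outcome (GWAS) associations travel as :class:`VariantAssoc`
records.  The canonical on-disk dialect is a tab-separated table with header
columns ``SNP CHR POS EA OA EAF BETA SE P [FDR] [N] [GENE]``; alternate headers
are remapped through a schema dictionary.  Harmonization follows the standard
two-sample MR conventions: allele swaps flip the sign of the outcome effect,
strand complements are resolved for unambiguous SNVs, and palindromic (A/T,
G/C) variants are aligned by effect-allele frequency or dropped when the
frequency is uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import ConfigurationError, InputError

logger = logging.getLogger(__name__)

# canonical header -> internal field name
CANONICAL_COLUMNS = {
    "SNP": "snp_id",
    "CHR": "chrom",
    "POS": "pos",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "p",
    "FDR": "fdr",
    "N": "n",
    "GENE": "gene_id",
}

REQUIRED_FIELDS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "p")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(slots=True)
class VariantAssoc:
    """One SNP's association record from a GWAS or QTL summary-stats table."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    p: float
    fdr: float | None = None
    n: float | None = None


@dataclass(slots=True)
class InstrumentSet:
    """Genetic instruments (significant QTL SNPs) for one gene."""

    gene_id: str
    variants: list[VariantAssoc]
    dataset_id: str = ""


@dataclass(slots=True)
class HarmonizedPair:
    """Exposure/outcome records aligned to a common effect allele."""

    snp_id: str
    exposure: VariantAssoc
    outcome: VariantAssoc
    action_taken: str  # none | swap_flip | strand_complement | dropped_palindrome | dropped_mismatch
    proxy_of: str | None = None

    @property
    def dropped(self) -> bool:
        return self.action_taken.startswith("dropped")


class LdTable:
    """Pairwise LD r² lookup with optional allele-phase information.

    Symmetric on lookup; absent pairs are r² = 0.  Phase info, when present,
    maps alleles of one SNP onto the in-phase alleles of the other
    (``a1:b1,a2:b2`` in the ``PHASED_ALLELES`` column, alleles of SNP_A before
    the colon).
    """

    def __init__(self, records: Iterable[tuple] = ()):
        self._r2: dict[tuple[str, str], float] = {}
        self._phase: dict[tuple[str, str], dict[str, str]] = {}
        self._partners: dict[str, set[str]] = {}
        for rec in records:
            a, b, r2 = rec[0], rec[1], float(rec[2])
            phase = rec[3] if len(rec) > 3 else None
            if not 0.0 <= r2 <= 1.0:
                raise InputError(f"r2 out of [0,1] for pair {a},{b}: {r2}")
            self._r2[(a, b)] = r2
            self._r2[(b, a)] = r2
            self._partners.setdefault(a, set()).add(b)
            self._partners.setdefault(b, set()).add(a)
            if phase and isinstance(phase, str) and phase.strip():
                fwd, rev = {}, {}
                for pair in phase.split(","):
                    x, y = pair.split(":")
                    fwd[x.strip()] = y.strip()
                    rev[y.strip()] = x.strip()
                self._phase[(a, b)] = fwd
                self._phase[(b, a)] = rev

    @classmethod
    def read(cls, path) -> "LdTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("SNP_A", "SNP_B", "R2"):
            if col not in df.columns:
                raise ConfigurationError(f"LD table missing column {col!r}")
        recs = []
        for row in df.itertuples(index=False):
            phase = getattr(row, "PHASED_ALLELES", None)
            if phase is not None and (not isinstance(phase, str)):
                phase = None
            recs.append((row.SNP_A, row.SNP_B, float(row.R2), phase))
        return cls(recs)

    def r2(self, a: str, b: str) -> float:
        return self._r2.get((a, b), 0.0)

    def partners(self, snp: str) -> set[str]:
        return self._partners.get(snp, set())

    def phase_map(self, a: str, b: str) -> dict[str, str] | None:
        """Alleles of ``b`` keyed to the in-phase alleles of ``a``... (b→a)."""
        m = self._phase.get((a, b))
        if m is None:
            return None
        return {v: k for k, v in m.items()}


def read_sumstats(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a summary-statistics table into canonical typed columns.

    ``schema`` maps file column names onto canonical header names (e.g.
    ``{"rsid": "SNP", "effect_allele": "EA"}``).  Rows violating the record
    invariants (se <= 0, p outside (0,1], identical alleles, EAF outside
    [0,1]) are dropped and counted in the log.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty summary-statistics file: {path}")
    if df.shape[1] == 1 and df.shape[0] == 0:
        raise InputError(f"empty summary-statistics file: {path}")
    return canonicalize(df, schema, source=str(path))


def canonicalize(df: pd.DataFrame, schema: Mapping[str, str] | None = None,
                 source: str = "<memory>") -> pd.DataFrame:
    """Canonicalize an in-memory dialect table (see :func:`read_sumstats`)."""
    path = source
    df = df.copy()
    if schema:
        df = df.rename(columns=dict(schema))
    known = {c: CANONICAL_COLUMNS[c] for c in df.columns if c in CANONICAL_COLUMNS}
    df = df.rename(columns=known)
    missing = [f for f in REQUIRED_FIELDS if f not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; provide a schema mapping"
        )
    if len(df) == 0:
        raise InputError(f"no data rows in summary-statistics file: {path}")

    for col in ("pos",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "p", "fdr", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    for col in ("snp_id", "chrom", "effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()

    n0 = len(df)
    ok = (
        df["se"].gt(0)
        & df["p"].gt(0)
        & df["p"].le(1)
        & df["beta"].notna()
        & df["pos"].notna()
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | (df["eaf"].ge(0) & df["eaf"].le(1)))
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.info("read_sumstats(%s): dropped %d/%d invalid rows", path, dropped, n0)
    df = df.loc[ok].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df.attrs["n_dropped"] = dropped
    return df


def variants_from_frame(df: pd.DataFrame) -> list[VariantAssoc]:
    """Materialize canonical-frame rows as :class:`VariantAssoc` records."""
    out = []
    for r in df.itertuples(index=False):
        out.append(VariantAssoc(
            snp_id=r.snp_id, chrom=str(r.chrom), pos=int(r.pos),
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=None if pd.isna(r.eaf) else float(r.eaf),
            beta=float(r.beta), se=float(r.se), p=float(r.p),
            fdr=None if pd.isna(r.fdr) else float(r.fdr),
            n=None if pd.isna(r.n) else float(r.n),
        ))
    return out


def select_instruments(qtl: pd.DataFrame, fdr_threshold: float = 0.05,
                       dataset_id: str = "") -> list[InstrumentSet]:
    """Per-gene significant QTL SNPs at ``fdr < fdr_threshold``.

    If the table carries no FDR column, Benjamini–Hochberg is applied across
    the entire table first.  Genes with no surviving variant are omitted.
    """
    if not 0.0 < fdr_threshold < 1.0:
        raise ConfigurationError(f"fdr_threshold must be in (0,1): {fdr_threshold}")
    if "gene_id" not in qtl.columns:
        raise ConfigurationError("QTL table lacks a GENE column")
    df = qtl
    if "fdr" not in df.columns or df["fdr"].isna().all():
        df = df.copy()
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    keep = df.loc[df["fdr"] < fdr_threshold]
    out = []
    for gene, grp in keep.groupby("gene_id", sort=True):
        out.append(InstrumentSet(gene_id=str(gene),
                                 variants=variants_from_frame(grp),
                                 dataset_id=dataset_id))
    return out


def ld_clump(variants: Sequence[VariantAssoc], ld: LdTable | None,
             r2_threshold: float = 0.001, window_kb: int = 10_000) -> list[VariantAssoc]:
    """Greedy LD clumping: keep the most significant SNP of each LD clump.

    Sort ascending by p (ties by snp_id); repeatedly retain the best remaining
    SNP and discard remaining SNPs with r² >= threshold within ``window_kb``
    of it.  Pairs absent from the LD table, on different chromosomes, or
    farther apart than the window count as r² = 0.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ConfigurationError(f"r2_threshold must be in (0,1]: {r2_threshold}")
    if ld is None:
        ld = LdTable()
    pending = sorted(variants, key=lambda v: (v.p, v.snp_id))
    kept: list[VariantAssoc] = []
    win = window_kb * 1000
    while pending:
        best = pending.pop(0)
        kept.append(best)
        survivors = []
        for v in pending:
            if v.chrom == best.chrom and abs(v.pos - best.pos) <= win \
                    and ld.r2(best.snp_id, v.snp_id) >= r2_threshold:
                continue
            survivors.append(v)
        pending = survivors
    return kept


def _is_snv(a: str, b: str) -> bool:
    return len(a) == 1 and len(b) == 1 and a in _COMPLEMENT and b in _COMPLEMENT


def _is_palindromic(a: str, b: str) -> bool:
    return _is_snv(a, b) and {a, b} in _PALINDROMIC_PAIRS


def _flip(v: VariantAssoc) -> VariantAssoc:
    return replace(v, effect_allele=v.other_allele, other_allele=v.effect_allele,
                   beta=-v.beta, eaf=None if v.eaf is None else 1.0 - v.eaf)


def _complement(v: VariantAssoc) -> VariantAssoc:
    return replace(v, effect_allele=_COMPLEMENT[v.effect_allele],
                   other_allele=_COMPLEMENT[v.other_allele])


def harmonize(exposure: VariantAssoc, outcome: VariantAssoc,
              palindrome_eaf_window: float = 0.08,
              proxy_of: str | None = None) -> HarmonizedPair:
    """Align an outcome record to the exposure's effect/other alleles.

    Swapped alleles negate the outcome beta (and reflect EAF); strand
    complements are applied for unambiguous SNVs.  Palindromic variants carry
    no strand information in their alleles, so they are aligned by comparing
    effect-allele frequencies: both EAFs must fall outside the ambiguity
    window ``0.5 ± palindrome_eaf_window``, otherwise the pair is dropped.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(
            f"harmonize called on different SNPs: {exposure.snp_id} vs {outcome.snp_id}")
    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    o = outcome

    def _pair(action, out):
        return HarmonizedPair(exposure.snp_id, exposure, out, action, proxy_of)

    if _is_palindromic(e_ea, e_oa):
        if not _is_snv(o.effect_allele, o.other_allele) or \
                {o.effect_allele, o.other_allele} != {e_ea, e_oa}:
            return _pair("dropped_mismatch", o)
        if exposure.eaf is None or o.eaf is None:
            return _pair("dropped_palindrome", o)
        w = palindrome_eaf_window
        if abs(exposure.eaf - 0.5) <= w or abs(o.eaf - 0.5) <= w:
            return _pair("dropped_palindrome", o)
        # textual orientation is meaningless for palindromes: frequency decides
        f = o.eaf if o.effect_allele == e_ea else 1.0 - o.eaf
        b = o.beta if o.effect_allele == e_ea else -o.beta
        if (f - 0.5) * (exposure.eaf - 0.5) < 0:
            f, b = 1.0 - f, -b
        if (o.effect_allele, o.other_allele, o.beta) == (e_ea, e_oa, b):
            return _pair("none", o)
        aligned = replace(o, effect_allele=e_ea, other_allele=e_oa, beta=b, eaf=f)
        return _pair("swap_flip", aligned)

    if (o.effect_allele, o.other_allele) == (e_ea, e_oa):
        return _pair("none", o)
    if (o.effect_allele, o.other_allele) == (e_oa, e_ea):
        return _pair("swap_flip", _flip(o))
    # strand complement only defined for single-nucleotide alleles
    if _is_snv(o.effect_allele, o.other_allele) and _is_snv(e_ea, e_oa):
        oc = _complement(o)
        if (oc.effect_allele, oc.other_allele) == (e_ea, e_oa):
            return _pair("strand_complement", oc)
        if (oc.effect_allele, oc.other_allele) == (e_oa, e_ea):
            return _pair("strand_complement", _flip(oc))
    return _pair("dropped_mismatch", o)


def find_proxy(snp_id: str, outcome: Mapping[str, VariantAssoc] | pd.DataFrame,
               ld: LdTable, min_r2: float = 0.8) -> VariantAssoc | None:
    """Best LD proxy for ``snp_id`` among outcome SNPs (r² >= ``min_r2``).

    Ties on r² break lexicographically by snp_id.  The returned record is
    re-keyed to the query SNP, with alleles re-phased through the LD table's
    phase info when available (kept as-is otherwise, assuming shared coding).
    """
    found = find_proxy_with_id(snp_id, outcome, ld, min_r2)
    return None if found is None else found[0]


def find_proxy_with_id(snp_id: str, outcome: Mapping[str, VariantAssoc] | pd.DataFrame,
                       ld: LdTable, min_r2: float = 0.8
                       ) -> tuple[VariantAssoc, str] | None:
    """:func:`find_proxy`, additionally returning the proxy's own rsID."""
    if not 0.0 < min_r2 <= 1.0:
        raise ConfigurationError(f"min_r2 must be in (0,1]: {min_r2}")
    if isinstance(outcome, pd.DataFrame):
        outcome = {v.snp_id: v for v in variants_from_frame(outcome)}
    best: tuple[float, str] | None = None
    for cand in ld.partners(snp_id):
        if cand not in outcome:
            continue
        r2 = ld.r2(snp_id, cand)
        if r2 < min_r2:
            continue
        key = (-r2, cand)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    proxy_id = best[1]
    rec = outcome[proxy_id]
    phase = ld.phase_map(snp_id, proxy_id)  # proxy allele -> query allele
    if phase and rec.effect_allele in phase and rec.other_allele in phase:
        rec = replace(rec, effect_allele=phase[rec.effect_allele],
                      other_allele=phase[rec.other_allele])
    return replace(rec, snp_id=snp_id), proxy_id
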