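"""Configuration-driven end-to-end runner.

Stages, per QTL x GWAS dataset pair: instrument selection (FDR filter) →
LD clumping → harmonization → SMR gene ranking → NP-level preranked GSEA;
then Stouffer consensus over pairs → herb-level GSEA → multiple-testing
adjustment → candidate table.  Every intermediate table is written so each
stage is inspectable, and re-running with the same config and seed
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import ConfigurationError, InputError, derived_seed
from .gsea import GseaParams, gsea_preranked
from .prioritize import (consensus_np_records, herb_table, prioritize_herbs,
                         read_relationships)
from .smr import associations_to_frame, gene_association, rank_genes
from .sumstats import LdTable, ld_clump, read_sumstats, select_instruments, \
    variants_from_frame

logger = logging.getLogger(__name__)

TABLE_FLOAT_FMT = "%.10g"


@dataclass
class DatasetRef:
    id: str
    path: str
    schema: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    qtl_datasets: list[DatasetRef]
    gwas_datasets: list[DatasetRef]
    np_to_gene_path: str
    herb_to_np_path: str
    out_dir: str = "results"
    ld_path: str | None = None
    instrument_fdr_threshold: float = 0.05
    clump_r2_threshold: float = 0.001
    clump_window_kb: int = 10_000
    proxies_enabled: bool = False
    proxy_min_r2: float = 0.8
    palindrome_eaf_window: float = 0.08
    min_p_over_instruments: bool = False
    gsea_np: GseaParams = field(default_factory=GseaParams)
    gsea_herb: GseaParams = field(default_factory=GseaParams)
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration; relative paths resolve to the file's dir."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config is not a mapping: {path}")
    base = path.parent

    def _resolve(p):
        return None if p is None else str((base / p).resolve()) \
            if not Path(p).is_absolute() else str(p)

    def _datasets(key):
        out = []
        for d in raw.get(key, []) or []:
            out.append(DatasetRef(id=str(d["id"]), path=_resolve(d["path"]),
                                  schema=dict(d.get("schema") or {})))
        return out

    def _gsea(key):
        g = dict(raw.get(key) or {})
        g.setdefault("seed", int(raw.get("seed", 0)))
        return GseaParams(**{k: v for k, v in g.items()
                             if k in {f.name for f in dataclasses.fields(GseaParams)}})

    clump = dict(raw.get("clump") or {})
    proxies = dict(raw.get("proxies") or {})
    return RunConfig(
        qtl_datasets=_datasets("qtl_datasets"),
        gwas_datasets=_datasets("gwas_datasets"),
        np_to_gene_path=_resolve(raw.get("np_to_gene_path")),
        herb_to_np_path=_resolve(raw.get("herb_to_np_path")),
        out_dir=str(base / raw.get("out_dir", "results")),
        ld_path=_resolve(raw.get("ld_path")),
        instrument_fdr_threshold=float(raw.get("instrument_fdr_threshold", 0.05)),
        clump_r2_threshold=float(clump.get("r2_threshold", 0.001)),
        clump_window_kb=int(clump.get("window_kb", 10_000)),
        proxies_enabled=bool(proxies.get("enabled", False)),
        proxy_min_r2=float(proxies.get("min_r2", 0.8)),
        palindrome_eaf_window=float(raw.get("palindrome_eaf_window", 0.08)),
        min_p_over_instruments=bool(raw.get("min_p_over_instruments", False)),
        gsea_np=_gsea("gsea_np"),
        gsea_herb=_gsea("gsea_herb"),
        seed=int(raw.get("seed", 0)),
    )


def validate_config(config: RunConfig) -> list[str]:
    """Collect configuration findings; an empty list means runnable."""
    findings: list[str] = []
    if not config.qtl_datasets:
        findings.append("qtl_datasets: at least one QTL dataset is required")
    if not config.gwas_datasets:
        findings.append("gwas_datasets: at least one GWAS dataset is required")
    for ref in list(config.qtl_datasets) + list(config.gwas_datasets):
        if not ref.path or not Path(ref.path).exists():
            findings.append(f"dataset {ref.id}: file not found: {ref.path}")
    for key in ("np_to_gene_path", "herb_to_np_path"):
        p = getattr(config, key)
        if not p:
            findings.append(f"{key}: missing")
        elif not Path(p).exists():
            findings.append(f"{key}: file not found: {p}")
    if config.ld_path is not None and not Path(config.ld_path).exists():
        findings.append(f"ld_path: file not found: {config.ld_path}")
    if not 0.0 < config.instrument_fdr_threshold < 1.0:
        findings.append("instrument_fdr_threshold: must lie in (0, 1)")
    if not 0.0 < config.clump_r2_threshold <= 1.0:
        findings.append("clump.r2_threshold: must lie in (0, 1]")
    if not 0.0 < config.proxy_min_r2 <= 1.0:
        findings.append("proxies.min_r2: must lie in (0, 1]")
    if not 0.0 <= config.palindrome_eaf_window < 0.5:
        findings.append("palindrome_eaf_window: must lie in [0, 0.5)")
    return findings


def _setup_run_logger(out_dir: Path) -> tuple[logging.Logger, logging.Handler]:
    run_logger = logging.getLogger("npscreen.run")
    run_logger.setLevel(logging.INFO)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s\t%(message)s"))
    run_logger.addHandler(handler)
    return run_logger, handler


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute all stages; returns a map of output names to file paths."""
    findings = validate_config(config)
    if findings:
        raise ConfigurationError("; ".join(findings))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log, handler = _setup_run_logger(out_dir)
    t0 = time.time()
    outputs: dict[str, str] = {"run_log": str(out_dir / "run.log")}
    try:
        log.info("[config] npscreen %s seed=%d", __version__, config.seed)
        for f in dataclasses.fields(RunConfig):
            log.info("[config] %s = %r", f.name, getattr(config, f.name))

        ld = LdTable.read(config.ld_path) if config.ld_path else LdTable()
        np_sets = read_relationships(config.np_to_gene_path, "np_to_gene")
        herb_sets = read_relationships(config.herb_to_np_path, "herb_to_np")
        log.info("[input] %d NP sets, %d herb sets", len(np_sets), len(herb_sets))

        qtl_frames = {d.id: read_sumstats(d.path, d.schema or None)
                      for d in config.qtl_datasets}
        gwas_frames = {d.id: read_sumstats(d.path, d.schema or None)
                       for d in config.gwas_datasets}

        per_pair_np: dict[str, list] = {}
        for qd in config.qtl_datasets:
            instruments = select_instruments(
                qtl_frames[qd.id], config.instrument_fdr_threshold, dataset_id=qd.id)
            instruments = [
                dataclasses.replace(
                    iset,
                    variants=ld_clump(iset.variants, ld, config.clump_r2_threshold,
                                      config.clump_window_kb))
                for iset in instruments]
            log.info("[smr] %s: %d genes with instruments after FDR filter + clumping",
                     qd.id, len(instruments))
            for gd in config.gwas_datasets:
                pair_id = f"{qd.id}__{gd.id}"
                outcome = {v.snp_id: v
                           for v in variants_from_frame(gwas_frames[gd.id])}
                assocs = []
                for iset in instruments:
                    a = gene_association(
                        iset, outcome, ld, dataset_pair_id=pair_id,
                        proxies=config.proxies_enabled,
                        proxy_min_r2=config.proxy_min_r2,
                        palindrome_eaf_window=config.palindrome_eaf_window,
                        min_p_over_instruments=config.min_p_over_instruments)
                    if a is not None:
                        assocs.append(a)
                if not assocs:
                    raise InputError(f"[smr] {pair_id}: no usable gene association")
                gene_path = out_dir / f"genes_{pair_id}.tsv"
                associations_to_frame(assocs).to_csv(
                    gene_path, sep="\t", index=False, float_format=TABLE_FLOAT_FMT)
                outputs[f"genes_{pair_id}"] = str(gene_path)
                log.info("[smr] %s: %d gene associations", pair_id, len(assocs))

                ranked = rank_genes(assocs)
                params = dataclasses.replace(
                    config.gsea_np, seed=derived_seed(config.seed, "gsea_np", pair_id))
                np_res = gsea_preranked(ranked, np_sets, params)
                if not np_res:
                    raise InputError(f"[gsea-np] {pair_id}: empty NP enrichment")
                np_path = out_dir / f"np_{pair_id}.tsv"
                pd.DataFrame({
                    "NP": [r.set_id for r in np_res],
                    "ES": [r.es for r in np_res],
                    "NES": [r.nes for r in np_res],
                    "P_VALUE": [r.p for r in np_res],
                    "EFFECTIVE_SIZE": [r.effective_size for r in np_res],
                    "N_PERM": [r.n_perm for r in np_res],
                }).to_csv(np_path, sep="\t", index=False, float_format=TABLE_FLOAT_FMT)
                outputs[f"np_{pair_id}"] = str(np_path)
                per_pair_np[pair_id] = np_res
                log.info("[gsea-np] %s: %d NPs tested", pair_id, len(np_res))

        recs = consensus_np_records(per_pair_np)
        cons_path = out_dir / "np_consensus.tsv"
        pd.DataFrame({
            "NP": [r.np_id for r in sorted(recs, key=lambda r: (-r.rank_stat, r.np_id))],
            "Z_SUM": [r.z_sum for r in sorted(recs, key=lambda r: (-r.rank_stat, r.np_id))],
            "META_P": [r.meta_p for r in sorted(recs, key=lambda r: (-r.rank_stat, r.np_id))],
            "RANK_STAT": [r.rank_stat for r in sorted(recs, key=lambda r: (-r.rank_stat, r.np_id))],
            "N_ANALYSES": [len(r.per_analysis_p) for r in sorted(recs, key=lambda r: (-r.rank_stat, r.np_id))],
        }).to_csv(cons_path, sep="\t", index=False, float_format=TABLE_FLOAT_FMT)
        outputs["np_consensus"] = str(cons_path)
        log.info("[consensus] %d NPs pooled over %d analyses", len(recs),
                 len(per_pair_np))

        from .gsea import RankedList
        np_rank = RankedList.from_stats([r.np_id for r in recs],
                                        [r.rank_stat for r in recs], "pos")
        herb_params = dataclasses.replace(
            config.gsea_herb, seed=derived_seed(config.seed, "gsea_herb"))
        herbs = prioritize_herbs(np_rank, herb_sets, herb_params)
        if not herbs:
            raise InputError("[gsea-herb] no herb could be tested")
        herb_path = out_dir / "herbs.tsv"
        herb_table(herbs).to_csv(herb_path, sep="\t", index=False,
                                 float_format=TABLE_FLOAT_FMT)
        outputs["herbs"] = str(herb_path)
        log.info("[gsea-herb] %d herbs tested, %d selected (Bonferroni p < 0.05)",
                 len(herbs), sum(h.selected for h in herbs))
        log.info("[done] %.1f s", time.time() - t0)
        return outputs
    finally:
        log.removeHandler(handler)
        handler.close()
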