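"""Seeded synthetic GWAS/QTL summary statistics and herb–NP–gene networks.

The generator emulates the statistical structure the pipeline assumes:

* every gene carries a handful of cis-QTL instrument SNPs with strong
  exposure associations (|z_x| centred on ``qtl_z_scale``);
* for causal genes the outcome effect of each instrument is
  ``gene_effect`` times its true exposure effect, for null genes zero, with
  per-dataset sampling noise from the standard GWAS standard-error model
  ``se = 1/sqrt(2 n maf (1 - maf))``;
* effective NPs draw a fixed fraction of their targets from causal genes;
  planted herbs draw a fixed fraction of their NPs from effective NPs; the
  background draws uniformly.

Outputs are written in exactly the delimited dialects the pipeline reads, and
identical seeds produce byte-identical files.  Allele pairs are drawn from
the non-palindromic SNV combinations only, so harmonization never discards
generated records for strand ambiguity (the palindrome policy is exercised by
dedicated tests instead).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import P_FLOOR, InputError

SUMSTATS_FLOAT_FMT = "%.10g"

# ordered (EA, OA) pairs excluding palindromic A/T and C/G combinations
_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT"
                 if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})]


@dataclass
class BenchmarkSpec:
    """Study conditions of the synthetic benchmark (defaults = signal setting)."""

    n_genes: int = 500
    n_causal: int = 50
    n_snps_per_gene: int = 3
    qtl_z_scale: float = 8.0
    gene_effect: float = 0.5  # outcome effect per unit exposure, causal genes
    n_qtl_datasets: int = 2
    n_gwas_datasets: int = 2
    n_nps: int = 200
    n_effective_nps: int = 40
    targets_per_np: int = 20
    causal_target_fraction: float = 0.6
    n_herbs: int = 200
    n_planted_herbs: int = 20
    nps_per_herb: int = 30
    effective_np_fraction: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    qtl_n: int = 31684       # eQTL-cohort scale
    gwas_n: int = 487511     # large case-control GWAS scale
    ld_mode: str = "independent"  # independent | block
    block_r2: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_genes:
            raise InputError("n_causal exceeds n_genes")
        if self.n_effective_nps > self.n_nps:
            raise InputError("n_effective_nps exceeds n_nps")
        if self.n_planted_herbs > self.n_herbs:
            raise InputError("n_planted_herbs exceeds n_herbs")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InputError("maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.causal_target_fraction <= 1.0:
            raise InputError("causal_target_fraction must lie in [0,1]")


@dataclass
class TruthLabels:
    """Planted ground truth of one benchmark realization."""

    causal_genes: set = field(default_factory=set)
    effective_nps: set = field(default_factory=set)
    planted_herbs: set = field(default_factory=set)


def _gene_ids(spec):
    width = len(str(spec.n_genes))
    return [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]


def _two_sided_p(z):
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)


def simulate_sumstats(spec: BenchmarkSpec
                      ) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], TruthLabels]:
    """QTL exposure tables, GWAS outcome tables and the causal-gene truth.

    A latent per-SNP true exposure effect is drawn once; each QTL dataset
    observes it with its own sampling noise, and each GWAS dataset observes
    ``gene_effect x`` the latent effect (causal genes only) with independent
    noise — the two-sample structure SMR assumes.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_truth, ss_variants = root.spawn(2)
    rng_truth = np.random.default_rng(ss_truth)
    rng_var = np.random.default_rng(ss_variants)

    genes = _gene_ids(spec)
    causal = set(rng_truth.choice(genes, size=spec.n_causal, replace=False))

    n_snp = spec.n_genes * spec.n_snps_per_gene
    snp_gene = np.repeat(np.arange(spec.n_genes), spec.n_snps_per_gene)
    snp_ids = [f"rs{g + 1:05d}{k}" for g in range(spec.n_genes)
               for k in range(1, spec.n_snps_per_gene + 1)]
    chrom = (snp_gene % 22) + 1
    pos = 1_000_000 * (snp_gene // 22 + 1) + (np.arange(n_snp) % spec.n_snps_per_gene) * 5_000
    maf = rng_var.uniform(*spec.maf_range, size=n_snp)
    pair_idx = rng_var.integers(0, len(_ALLELE_PAIRS), size=n_snp)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    se_ref = 1.0 / np.sqrt(2.0 * spec.qtl_n * maf * (1.0 - maf))
    z_true = np.abs(rng_var.normal(spec.qtl_z_scale, 1.0, size=n_snp))
    sign = rng_var.choice([-1.0, 1.0], size=n_snp)
    beta_x_true = sign * z_true * se_ref
    delta = np.array([spec.gene_effect if genes[g] in causal else 0.0
                      for g in snp_gene])
    beta_y_true = delta * beta_x_true

    base = pd.DataFrame({
        "SNP": snp_ids, "CHR": chrom.astype(str), "POS": pos,
        "EA": ea, "OA": oa, "EAF": maf,
    })

    qtl_tables: dict[str, pd.DataFrame] = {}
    for d in range(1, spec.n_qtl_datasets + 1):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1, d)))
        n_d = int(spec.qtl_n * rng.uniform(0.7, 1.3))
        se_x = 1.0 / np.sqrt(2.0 * n_d * maf * (1.0 - maf))
        b_x = beta_x_true + rng.normal(0.0, se_x)
        p = _two_sided_p(b_x / se_x)
        df = base.copy()
        df["BETA"] = b_x
        df["SE"] = se_x
        df["P"] = p
        df["FDR"] = multipletests(p, method="fdr_bh")[1]
        df["N"] = n_d
        df["GENE"] = [genes[g] for g in snp_gene]
        qtl_tables[f"qtl_{d}"] = df

    gwas_tables: dict[str, pd.DataFrame] = {}
    for d in range(1, spec.n_gwas_datasets + 1):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2, d)))
        n_d = int(spec.gwas_n * rng.uniform(0.7, 1.3))
        se_y = 1.0 / np.sqrt(2.0 * n_d * maf * (1.0 - maf))
        b_y = beta_y_true + rng.normal(0.0, se_y)
        p = _two_sided_p(b_y / se_y)
        df = base.copy()
        df["BETA"] = b_y
        df["SE"] = se_y
        df["P"] = p
        df["N"] = n_d
        # present a random subset with swapped allele orientation, so the
        # harmonization stage does real work on every run
        swap = rng.random(n_snp) < 0.3
        df.loc[swap, ["EA", "OA"]] = df.loc[swap, ["OA", "EA"]].to_numpy()
        df.loc[swap, "BETA"] = -df.loc[swap, "BETA"]
        df.loc[swap, "EAF"] = 1.0 - df.loc[swap, "EAF"]
        gwas_tables[f"gwas_{d}"] = df

    truth = TruthLabels(causal_genes=causal)
    return qtl_tables, gwas_tables, truth


def simulate_networks(spec: BenchmarkSpec, truth: TruthLabels
                      ) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """NP→gene and herb→NP relationship tables with planted effective sets."""
    genes = _gene_ids(spec)
    if spec.targets_per_np > spec.n_genes or spec.nps_per_herb > spec.n_nps:
        raise InputError("requested set sizes exceed the identifier pools")
    n_causal_targets = math.ceil(spec.causal_target_fraction * spec.targets_per_np)
    if n_causal_targets > len(truth.causal_genes):
        raise InputError("causal-target demand exceeds the causal-gene pool")
    n_eff_nps = math.ceil(spec.effective_np_fraction * spec.nps_per_herb)
    if n_eff_nps > spec.n_effective_nps:
        raise InputError("effective-NP demand exceeds the effective-NP pool")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(3,)))
    np_ids = [f"NP{i:04d}" for i in range(1, spec.n_nps + 1)]
    herb_ids = [f"HB{i:04d}" for i in range(1, spec.n_herbs + 1)]
    effective = set(rng.choice(np_ids, size=spec.n_effective_nps, replace=False))
    planted = set(rng.choice(herb_ids, size=spec.n_planted_herbs, replace=False))
    causal_list = sorted(truth.causal_genes)
    noncausal = [g for g in genes if g not in truth.causal_genes]
    effective_list = sorted(effective)
    background_nps = [n for n in np_ids if n not in effective]

    np_rows = []
    for np_id in np_ids:
        if np_id in effective:
            chosen = list(rng.choice(causal_list, size=n_causal_targets, replace=False))
            rest = spec.targets_per_np - n_causal_targets
            pool = [g for g in genes if g not in set(chosen)]
            chosen += list(rng.choice(pool, size=rest, replace=False))
        else:
            chosen = list(rng.choice(genes, size=spec.targets_per_np, replace=False))
        np_rows += [(np_id, g) for g in chosen]
    np_to_gene = pd.DataFrame(np_rows, columns=["NP", "GENE"])

    herb_rows = []
    for herb in herb_ids:
        if herb in planted:
            chosen = list(rng.choice(effective_list, size=n_eff_nps, replace=False))
            rest = spec.nps_per_herb - n_eff_nps
            pool = [n for n in np_ids if n not in set(chosen)]
            chosen += list(rng.choice(pool, size=rest, replace=False))
        else:
            chosen = list(rng.choice(np_ids, size=spec.nps_per_herb, replace=False))
        herb_rows += [(herb, n) for n in chosen]
    herb_to_np = pd.DataFrame(herb_rows, columns=["HERB", "NP"])

    out_truth = TruthLabels(causal_genes=set(truth.causal_genes),
                            effective_nps=effective, planted_herbs=planted)
    return np_to_gene, herb_to_np, out_truth


def _ld_table(spec: BenchmarkSpec) -> pd.DataFrame:
    """LD export: empty under independent SNPs, within-gene blocks otherwise."""
    rows = []
    if spec.ld_mode == "block" and spec.n_snps_per_gene > 1:
        for g in range(spec.n_genes):
            ids = [f"rs{g + 1:05d}{k}" for k in range(1, spec.n_snps_per_gene + 1)]
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    rows.append((ids[i], ids[j], spec.block_r2))
    return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def make_benchmark(spec: BenchmarkSpec, out_dir) -> dict[str, str]:
    """Write a complete, self-contained pipeline input bundle.

    Emits sumstats, relationship and LD files, a runnable ``config.yaml``, a
    ``truth.tsv`` label file, and a ``manifest.txt`` of file SHA-256 hashes.
    Identical specs (including seed) produce identical hashes.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format=SUMSTATS_FLOAT_FMT)
        written.append(path)
        return path

    try:
        qtl_tables, gwas_tables, truth0 = simulate_sumstats(spec)
        np_to_gene, herb_to_np, truth = simulate_networks(spec, truth0)
        for name, df in qtl_tables.items():
            _write(df, f"{name}.tsv")
        for name, df in gwas_tables.items():
            _write(df, f"{name}.tsv")
        _write(_ld_table(spec), "ld.tsv")
        _write(np_to_gene, "np_to_gene.tsv")
        _write(herb_to_np, "herb_to_np.tsv")
        truth_df = pd.DataFrame(
            [("causal_gene", g) for g in sorted(truth.causal_genes)]
            + [("effective_np", n) for n in sorted(truth.effective_nps)]
            + [("planted_herb", h) for h in sorted(truth.planted_herbs)],
            columns=["CATEGORY", "ID"])
        _write(truth_df, "truth.tsv")

        config = {
            "seed": spec.seed,
            "out_dir": "results",
            "qtl_datasets": [{"id": k, "path": f"{k}.tsv"} for k in sorted(qtl_tables)],
            "gwas_datasets": [{"id": k, "path": f"{k}.tsv"} for k in sorted(gwas_tables)],
            "ld_path": "ld.tsv",
            "np_to_gene_path": "np_to_gene.tsv",
            "herb_to_np_path": "herb_to_np.tsv",
            "instrument_fdr_threshold": 0.05,
            "clump": {"r2_threshold": 0.001, "window_kb": 10000},
            "proxies": {"enabled": False, "min_r2": 0.8},
            "palindrome_eaf_window": 0.08,
            "gsea_np": {"n_perm": 1000, "n_perm_max": 100000,
                        "weight_exponent": 1.0, "eps": 0.0, "min_size": 1},
            "gsea_herb": {"n_perm": 1000, "n_perm_max": 100000,
                          "weight_exponent": 1.0, "eps": 0.0, "min_size": 1},
        }
        cfg_path = out / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(config, sort_keys=True))
        written.append(cfg_path)

        manifest = {p.name: _sha256(p) for p in sorted(written)}
        man_path = out / "manifest.txt"
        man_path.write_text("".join(f"{k}\t{v}\n" for k, v in manifest.items()))
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def benchmark_run(spec: BenchmarkSpec, workdir, n_perm: int | None = None,
                  n_perm_max: int | None = None):
    """Generate a benchmark, run the full pipeline on it, and load the results.

    Returns ``(herb_table_frame, truth_labels, outputs)``.  ``n_perm`` /
    ``n_perm_max`` override both GSEA levels (handy for scaling permutation
    work to the problem size).
    """
    import yaml

    from .pipeline import load_config, run_pipeline

    out = Path(workdir)
    make_benchmark(spec, out)
    if n_perm is not None or n_perm_max is not None:
        cfg = yaml.safe_load((out / "config.yaml").read_text())
        for key in ("gsea_np", "gsea_herb"):
            if n_perm is not None:
                cfg[key]["n_perm"] = int(n_perm)
            if n_perm_max is not None:
                cfg[key]["n_perm_max"] = int(n_perm_max)
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    outputs = run_pipeline(load_config(out / "config.yaml"))
    herbs = pd.read_csv(outputs["herbs"], sep="\t")
    truth_df = pd.read_csv(out / "truth.tsv", sep="\t")
    truth = TruthLabels(
        causal_genes=set(truth_df.loc[truth_df.CATEGORY == "causal_gene", "ID"]),
        effective_nps=set(truth_df.loc[truth_df.CATEGORY == "effective_np", "ID"]),
        planted_herbs=set(truth_df.loc[truth_df.CATEGORY == "planted_herb", "ID"]))
    return herbs, truth, outputs


def recovery_metrics(herb_rows, truth: TruthLabels) -> dict[str, float]:
    """Rank-based recovery of planted herbs from a screening table.

    AUC is the probability that a planted herb outranks a background herb
    (ranks taken from the table's row order, best first); median rank is the
    median 1-based position of the planted herbs.  Accepts a list of
    :class:`npscreen.prioritize.HerbResult` or a herb table frame.
    """
    if isinstance(herb_rows, pd.DataFrame):
        ids = list(herb_rows["INGREDIENT"])
    else:
        ids = [h.herb_id for h in herb_rows]
    ranks = {h: i + 1 for i, h in enumerate(ids)}
    planted = [ranks[h] for h in truth.planted_herbs if h in ranks]
    background = [r for h, r in ranks.items() if h not in truth.planted_herbs]
    if not planted or not background:
        raise InputError("need planted and background herbs in the table")
    p = np.asarray(planted, dtype=float)
    b = np.asarray(background, dtype=float)
    wins = (p[:, None] < b[None, :]).sum() + 0.5 * (p[:, None] == b[None, :]).sum()
    return {"auc": float(wins / (p.size * b.size)),
            "median_planted_rank": float(np.median(p)),
            "n_planted": float(p.size)}
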