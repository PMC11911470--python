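import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from npscreen._util import ConfigurationError, InputError
from npscreen.sumstats import (LdTable, VariantAssoc, find_proxy, harmonize,
                               ld_clump, read_sumstats, select_instruments,
                               variants_from_frame)


def _va(snp="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.2, beta=0.1,
        se=0.02, p=1e-4, **kw):
    return VariantAssoc(snp_id=snp, chrom=chrom, pos=pos, effect_allele=ea,
                        other_allele=oa, eaf=eaf, beta=beta, se=se, p=p, **kw)


class TestReadSumstats:
    def test_parses_canonical_header(self, write_tsv, sumstats_rows):
        df = read_sumstats(write_tsv(sumstats_rows))
        assert len(df) == 3
        assert list(df["snp_id"]) == ["rs1", "rs2", "rs3"]
        assert df["beta"].dtype == float and df["pos"].dtype == np.int64

    def test_invalid_rows_dropped_and_counted(self, write_tsv, sumstats_rows):
        bad = sumstats_rows.copy()
        bad.loc[1, "SE"] = 0.0
        df = read_sumstats(write_tsv(bad))
        assert len(df) == 2 and df.attrs["n_dropped"] == 1

    def test_schema_remapping_matches_canonical(self, write_tsv, sumstats_rows):
        renamed = sumstats_rows.rename(columns={"SNP": "rsid", "EA": "A1", "OA": "A2"})
        df1 = read_sumstats(write_tsv(sumstats_rows, "a.tsv"))
        df2 = read_sumstats(write_tsv(renamed, "b.tsv"),
                            schema={"rsid": "SNP", "A1": "EA", "A2": "OA"})
        pd.testing.assert_frame_equal(df1, df2)

    def test_missing_column_is_configuration_error(self, write_tsv, sumstats_rows):
        with pytest.raises(ConfigurationError):
            read_sumstats(write_tsv(sumstats_rows.drop(columns=["BETA"])))

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(InputError):
            read_sumstats(path)


class TestSelectInstruments:
    def _qtl(self, genes, fdrs, ps=None):
        n = len(genes)
        df = pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(n)], "chrom": "1",
            "pos": np.arange(n) * 1000 + 1, "effect_allele": "A",
            "other_allele": "G", "eaf": 0.2, "beta": 0.1, "se": 0.02,
            "p": ps if ps is not None else [1e-6] * n,
            "fdr": fdrs, "n": 1000.0, "gene_id": genes,
        })
        return df

    def test_fdr_filter_per_gene(self):
        out = select_instruments(self._qtl(["G1", "G1"], [0.01, 0.2]), 0.05)
        assert len(out) == 1 and len(out[0].variants) == 1
        assert out[0].variants[0].fdr == 0.01

    def test_bh_applied_when_fdr_missing(self):
        df = self._qtl(["G1"] * 4, [np.nan] * 4, ps=[0.01, 0.02, 0.03, 0.04])
        out = select_instruments(df, 0.05)
        # BH over (0.01..0.04) adjusts every p to 0.04 < 0.05
        assert len(out) == 1 and len(out[0].variants) == 4

    def test_all_above_threshold_gives_empty_list(self):
        assert select_instruments(self._qtl(["G1", "G2"], [0.5, 0.9]), 0.05) == []

    def test_existing_fdr_column_never_recomputed(self):
        a = self._qtl(["G1", "G2"], [0.01, 0.01], ps=[0.9, 0.9])
        b = self._qtl(["G1", "G2"], [0.01, 0.01], ps=[1e-9, 1e-9])
        va = [v.snp_id for s in select_instruments(a, 0.05) for v in s.variants]
        vb = [v.snp_id for s in select_instruments(b, 0.05) for v in s.variants]
        assert va == vb


class TestLdClump:
    def test_hand_worked_greedy_example(self):
        vs = [_va("s1", pos=1000, p=1e-8), _va("s2", pos=2000, p=1e-6),
              _va("s3", pos=3000, p=1e-4)]
        ld = LdTable([("s1", "s2", 0.5), ("s1", "s3", 0.01), ("s2", "s3", 0.01)])
        kept = ld_clump(vs, ld, r2_threshold=0.1, window_kb=10_000)
        assert [v.snp_id for v in kept] == ["s1", "s3"]

    def test_no_ld_records_retains_all(self):
        vs = [_va(f"s{i}", pos=i * 1000 + 1, p=10 ** -i) for i in range(1, 4)]
        assert len(ld_clump(vs, LdTable(), 0.001)) == 3

    def test_perfect_ld_keeps_single_best(self):
        vs = [_va(f"s{i}", pos=i * 1000 + 1, p=10 ** -i) for i in range(1, 4)]
        ld = LdTable([("s1", "s2", 1.0), ("s1", "s3", 1.0), ("s2", "s3", 1.0)])
        kept = ld_clump(vs, ld, 0.5)
        assert [v.snp_id for v in kept] == ["s3"]  # smallest p

    def test_window_limits_ld_reach(self):
        vs = [_va("s1", pos=1_000, p=1e-8), _va("s2", pos=20_000_000, p=1e-6)]
        ld = LdTable([("s1", "s2", 0.99)])
        assert len(ld_clump(vs, ld, 0.1, window_kb=10_000)) == 2

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            ld_clump([], LdTable(), r2_threshold=0.0)

    def test_clumped_set_mutually_sub_threshold_and_keeps_min_p(self):
        rng = np.random.default_rng(7)
        n = 20
        vs = [_va(f"s{i:02d}", pos=i * 2000 + 1, p=float(rng.random()))
              for i in range(n)]
        recs = [(f"s{i:02d}", f"s{j:02d}", float(rng.random()))
                for i in range(n) for j in range(i + 1, n)]
        ld = LdTable(recs)
        kept = ld_clump(vs, ld, 0.3)
        ids = [v.snp_id for v in kept]
        assert min(vs, key=lambda v: (v.p, v.snp_id)).snp_id in ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert ld.r2(a, b) < 0.3


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        e = _va(ea="A", oa="G", beta=0.2)
        o = _va(ea="G", oa="A", beta=0.1, eaf=0.8)
        h = harmonize(e, o)
        assert h.action_taken == "swap_flip"
        assert h.outcome.effect_allele == "A" and h.outcome.beta == -0.1
        assert h.outcome.eaf == pytest.approx(0.2)

    def test_identical_orientation_untouched(self):
        e, o = _va(beta=0.2), _va(beta=0.1)
        h = harmonize(e, o)
        assert h.action_taken == "none" and h.outcome.beta == 0.1

    def test_strand_complement_resolved(self):
        e = _va(ea="A", oa="G", beta=0.2)
        o = _va(ea="T", oa="C", beta=0.1)
        h = harmonize(e, o)
        assert h.action_taken == "strand_complement"
        assert (h.outcome.effect_allele, h.outcome.other_allele) == ("A", "G")
        assert h.outcome.beta == 0.1

    def test_ambiguous_palindrome_dropped(self):
        e = _va(ea="A", oa="T", eaf=0.2)
        o = _va(ea="A", oa="T", eaf=0.50)
        h = harmonize(e, o, palindrome_eaf_window=0.08)
        assert h.action_taken == "dropped_palindrome" and h.dropped

    def test_palindrome_resolved_by_frequency(self):
        e = _va(ea="A", oa="T", eaf=0.2, beta=0.2)
        o = _va(ea="A", oa="T", eaf=0.8, beta=0.1)  # opposite frequency side
        h = harmonize(e, o, palindrome_eaf_window=0.08)
        assert h.action_taken == "swap_flip"
        assert h.outcome.beta == -0.1 and h.outcome.eaf == pytest.approx(0.2)

    def test_palindrome_missing_eaf_dropped(self):
        h = harmonize(_va(ea="A", oa="T", eaf=None), _va(ea="A", oa="T", eaf=0.2))
        assert h.action_taken == "dropped_palindrome"

    def test_irreconcilable_alleles_dropped(self):
        h = harmonize(_va(ea="A", oa="G"), _va(ea="A", oa="C"))
        assert h.action_taken == "dropped_mismatch"

    def test_indels_compared_as_strings_only(self):
        e = _va(ea="AT", oa="A")
        assert harmonize(e, _va(ea="A", oa="AT")).action_taken == "swap_flip"
        # complement never attempted for non-SNV alleles
        assert harmonize(e, _va(ea="TA", oa="T")).action_taken == "dropped_mismatch"

    def test_different_snp_is_contract_violation(self):
        with pytest.raises(ValueError):
            harmonize(_va("rs1"), _va("rs2"))


_alleles = hst.sampled_from(["A", "C", "G", "T"])


@given(
    ea=_alleles, oa=_alleles,
    orientation=hst.sampled_from(["same", "swap", "comp", "comp_swap"]),
    e_eaf=hst.floats(0.01, 0.99), o_eaf=hst.floats(0.01, 0.99),
    beta=hst.floats(-1, 1, allow_nan=False),
)
@settings(max_examples=300, derandomize=True)
def test_harmonize_idempotent_and_double_flip_invariant(ea, oa, orientation,
                                                        e_eaf, o_eaf, beta):
    """Re-harmonizing an aligned pair is a no-op, and presenting the outcome
    with swapped alleles + negated beta yields the same aligned effect."""
    if ea == oa:
        return
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    e = _va(ea=ea, oa=oa, eaf=e_eaf, beta=0.2)
    o_ea, o_oa, o_beta, o_f = ea, oa, beta, o_eaf
    if orientation in ("swap", "comp_swap"):
        o_ea, o_oa, o_beta, o_f = o_oa, o_ea, -o_beta, 1 - o_f
    if orientation in ("comp", "comp_swap"):
        o_ea, o_oa = comp[o_ea], comp[o_oa]
    o = _va(ea=o_ea, oa=o_oa, eaf=o_f, beta=o_beta)

    h = harmonize(e, o)
    if not h.dropped:
        h2 = harmonize(e, h.outcome)
        assert h2.action_taken == "none"
        assert h2.outcome == h.outcome

    flipped = dataclasses.replace(o, effect_allele=o.other_allele,
                                  other_allele=o.effect_allele,
                                  beta=-o.beta, eaf=1 - o.eaf)
    hf = harmonize(e, flipped)
    assert hf.dropped == h.dropped
    if not h.dropped:
        assert hf.outcome.beta == pytest.approx(h.outcome.beta)
        assert hf.outcome.effect_allele == h.outcome.effect_allele


class TestFindProxy:
    def _outcome(self, *snps):
        return {v.snp_id: v for v in snps}

    def test_single_candidate_returned_rekeyed(self):
        out = self._outcome(_va("rsP", ea="C", oa="T", beta=0.3))
        ld = LdTable([("rsQ", "rsP", 0.9, "A:C,G:T")])
        v = find_proxy("rsQ", out, ld, 0.8)
        assert v.snp_id == "rsQ"
        # re-phased onto the query SNP's alleles
        assert (v.effect_allele, v.other_allele) == ("A", "G")

    def test_below_threshold_gives_none(self):
        out = self._outcome(_va("rsP"))
        ld = LdTable([("rsQ", "rsP", 0.7)])
        assert find_proxy("rsQ", out, ld, 0.8) is None

    def test_tie_breaks_lexicographically(self):
        out = self._outcome(_va("rsB"), _va("rsA"))
        ld = LdTable([("rsQ", "rsB", 0.9), ("rsQ", "rsA", 0.9)])
        v = find_proxy("rsQ", out, ld, 0.8)
        assert v.snp_id == "rsQ"  # rekeyed; chosen proxy is rsA
        ld2 = LdTable([("rsQ", "rsB", 0.9), ("rsQ", "rsA", 0.9)])
        from npscreen.sumstats import find_proxy_with_id
        assert find_proxy_with_id("rsQ", out, ld2, 0.8)[1] == "rsA"


def test_variants_roundtrip_from_frame(write_tsv, sumstats_rows):
    df = read_sumstats(write_tsv(sumstats_rows))
    vs = variants_from_frame(df)
    assert [v.snp_id for v in vs] == ["rs1", "rs2", "rs3"]
    assert vs[1].beta == -0.2 and vs[1].fdr is None
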