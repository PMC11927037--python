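"""Summary-statistics I/O, QC, allele harmonization and LD clumping."""

import numpy as np
import pandas as pd
import pytest

from mrcascade.sumstats import (
    EmptyInputError,
    LDMatrix,
    NoInstrumentsError,
    SumStats,
    SumStatsFormatError,
    clump,
    harmonize,
    read_sumstats,
    write_sumstats,
)


def _ss(rows, trait_id="t", trait_type="eqtl_gene", symbol=""):
    return SumStats(trait_id, trait_type, pd.DataFrame(rows), symbol)


ROW = dict(chr="1", pos=1000, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, p=1e-6, n=500)


class TestReadWrite:
    def test_well_formed_file_reads_clean(self, sumstats_tsv):
        ss, tally = read_sumstats(sumstats_tsv, trait_id="x")
        assert len(ss) == 3
        assert all(v == 0 for v in tally.values())

    def test_invariant_violations_are_dropped_and_tallied(self, tmp_path):
        df = pd.DataFrame(
            [
                {"snp": "rs1", **ROW},
                {"snp": "rs2", **{**ROW, "se": 0.0}},          # bad SE
                {"snp": "rs3", **{**ROW, "p": 0.0}},            # p outside (0,1]
                {"snp": "rs4", **{**ROW, "ea": "A", "oa": "A"}},  # ea == oa
                {"snp": "rs1", **ROW},                           # duplicate id
            ]
        )
        path = tmp_path / "dirty.tsv"
        df.to_csv(path, sep="\t", index=False)
        ss, tally = read_sumstats(path)
        assert len(ss) == 1
        assert tally == {"bad_se": 1, "bad_p": 1, "bad_alleles": 1, "bad_n": 0, "dup": 1}

    def test_missing_mandatory_column_raises(self, tmp_path):
        path = tmp_path / "nocol.tsv"
        pd.DataFrame({"snp": ["rs1"], "beta": [0.1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(SumStatsFormatError):
            read_sumstats(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.tsv"
        pd.DataFrame(columns=["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(EmptyInputError):
            read_sumstats(path)

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "mapped.tsv"
        pd.DataFrame([{"rsid": "rs1", **{k: v for k, v in ROW.items()}}]).rename(
            columns={}
        ).to_csv(path, sep="\t", index=False)
        ss, _ = read_sumstats(path, column_map={"snp": "rsid"})
        assert ss.table.loc[0, "snp"] == "rs1"

    def test_round_trip_is_field_identical(self, sumstats_tsv, tmp_path):
        ss, _ = read_sumstats(sumstats_tsv)
        out = tmp_path / "rt.tsv"
        write_sumstats(ss, out)
        ss2, tally = read_sumstats(out)
        pd.testing.assert_frame_equal(ss.table, ss2.table)
        assert all(v == 0 for v in tally.values())


class TestHarmonize:
    def _pair(self, exp_alleles=("A", "G"), out_alleles=("A", "G"), out_beta=0.5, out_eaf=0.3, exp_eaf=0.3):
        exp = _ss([{"snp": "rs1", **{**ROW, "ea": exp_alleles[0], "oa": exp_alleles[1], "eaf": exp_eaf}}])
        out = _ss(
            [{"snp": "rs1", **{**ROW, "ea": out_alleles[0], "oa": out_alleles[1], "beta": out_beta, "eaf": out_eaf}}],
            trait_type="outcome",
        )
        return exp, out

    def test_identical_coding_unchanged(self):
        exp, out = self._pair()
        pairs = harmonize(exp, out)
        assert pairs.table.loc[0, "beta_out"] == 0.5
        assert pairs.table.loc[0, "action"] == "kept"

    def test_swapped_alleles_flip_beta(self):
        exp, out = self._pair(out_alleles=("G", "A"))
        pairs = harmonize(exp, out)
        assert pairs.table.loc[0, "beta_out"] == -0.5
        assert pairs.table.loc[0, "action"] == "flipped"

    def test_palindromic_half_frequency_dropped(self):
        exp = _ss([{"snp": "rs1", **{**ROW, "ea": "A", "oa": "T", "eaf": 0.5}},
                   {"snp": "rs2", **{**ROW, "pos": 2000}}])
        out = _ss([{"snp": "rs1", **{**ROW, "ea": "A", "oa": "T", "eaf": 0.5}},
                   {"snp": "rs2", **{**ROW, "pos": 2000}}], trait_type="outcome")
        pairs = harmonize(exp, out)
        assert list(pairs.table["snp"]) == ["rs2"]

    def test_palindromic_missing_eaf_dropped_nonpalindromic_kept(self):
        exp = _ss([{"snp": "rs1", **{**ROW, "ea": "C", "oa": "G", "eaf": np.nan}},
                   {"snp": "rs2", **{**ROW, "pos": 2000, "eaf": np.nan}}])
        out = _ss([{"snp": "rs1", **{**ROW, "ea": "C", "oa": "G", "eaf": np.nan}},
                   {"snp": "rs2", **{**ROW, "pos": 2000, "eaf": np.nan}}], trait_type="outcome")
        pairs = harmonize(exp, out)
        assert list(pairs.table["snp"]) == ["rs2"]

    def test_empty_intersection_raises(self):
        exp = _ss([{"snp": "rs1", **ROW}])
        out = _ss([{"snp": "rs9", **ROW}], trait_type="outcome")
        with pytest.raises(NoInstrumentsError):
            harmonize(exp, out)

    def test_double_flip_is_involutive(self, rng):
        """Flipping outcome alleles twice returns the original pairs."""
        n = 12
        base = [
            {"snp": f"rs{i}", "chr": "1", "pos": 1000 + i, "ea": "A", "oa": "G",
             "eaf": float(rng.uniform(0.05, 0.95)), "beta": float(rng.normal()),
             "se": 0.02, "p": 1e-6, "n": 500}
            for i in range(n)
        ]
        exp = _ss(base)
        out_rows = [dict(r) for r in base]
        out = _ss(out_rows, trait_type="outcome")
        once = harmonize(exp, out)
        flipped = [
            {**r, "ea": r["oa"], "oa": r["ea"], "beta": -r["beta"], "eaf": 1 - r["eaf"]}
            for r in out_rows
        ]
        twice_src = [
            {**r, "ea": r["oa"], "oa": r["ea"], "beta": -r["beta"], "eaf": 1 - r["eaf"]}
            for r in flipped
        ]
        twice = harmonize(exp, _ss(twice_src, trait_type="outcome"))
        pd.testing.assert_frame_equal(once.table, twice.table)


def brute_force_clump_check(ss, ld, kept, p_thresh, window_kb, r2_thresh):
    """Independent pairwise-constraint audit of a clumped set.

    Valid: no two retained SNPs conflict (same chromosome, within the window,
    r² at or above the ceiling).  Maximal w.r.t. the greedy p-ordering: every
    discarded candidate conflicts with some retained SNP that precedes it in
    (p, snp id) order.
    """
    tab = ss.table.set_index("snp")
    cand = tab[tab["p"] < p_thresh]
    kept_set = set(kept)

    def conflict(s1, s2):
        return (
            tab.loc[s1, "chr"] == tab.loc[s2, "chr"]
            and abs(tab.loc[s1, "pos"] - tab.loc[s2, "pos"]) <= window_kb * 1000
            and ld.r2(s1, s2) >= r2_thresh
        )

    for s1 in kept:
        for s2 in kept:
            if s1 < s2:
                assert not conflict(s1, s2), f"retained pair {s1},{s2} conflicts"
    order = sorted(cand.index, key=lambda s: (cand.loc[s, "p"], s))
    for s in cand.index:
        if s in kept_set:
            continue
        earlier = [k for k in kept_set if (tab.loc[k, "p"], k) < (tab.loc[s, "p"], s)]
        assert any(conflict(s, k) for k in earlier), f"discarded {s} conflicts with no retained SNP"


class TestClump:
    def _locus(self, rng, n_snps):
        pos = np.sort(rng.choice(np.arange(1, 4_000_000, 1000), size=n_snps, replace=False))
        A = rng.normal(size=(n_snps, max(2, n_snps // 2)))
        c = A @ A.T
        d = np.sqrt(np.diag(c))
        r = c / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        snps = [f"rs{i:03d}" for i in range(n_snps)]
        p = 10.0 ** rng.uniform(-12, -4, n_snps)
        rows = [
            {"snp": snps[i], "chr": "1", "pos": int(pos[i]), "ea": "A", "oa": "G",
             "eaf": 0.3, "beta": 0.1, "se": 0.02, "p": float(p[i]), "n": 100}
            for i in range(n_snps)
        ]
        return _ss(rows), LDMatrix(snps, r)

    def test_single_significant_snp_kept(self):
        ss = _ss([{"snp": "rs1", **{**ROW, "p": 1e-9}}])
        ld = LDMatrix(["rs1"], np.eye(1))
        assert clump(ss, ld) == ["rs1"]

    def test_stronger_snp_dominates_linked_neighbour(self):
        ss = _ss([
            {"snp": "rs1", **{**ROW, "p": 1e-9, "pos": 1000}},
            {"snp": "rs2", **{**ROW, "p": 1e-8, "pos": 6000}},
        ])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]]))
        assert clump(ss, ld) == ["rs1"]

    def test_no_candidate_below_threshold_returns_empty(self):
        ss = _ss([{"snp": "rs1", **{**ROW, "p": 1e-3}}])
        assert clump(ss, LDMatrix(["rs1"], np.eye(1))) == []

    @pytest.mark.parametrize("r2_thresh,window_kb", [(0.001, 10_000), (0.2, 500), (0.5, 2000)])
    def test_matches_pairwise_constraint_oracle(self, rng, r2_thresh, window_kb):
        """Greedy selection is valid and maximal on random loci of up to 25 SNPs."""
        for rep in range(60):
            n = int(rng.integers(2, 26))
            ss, ld = self._locus(rng, n)
            kept = clump(ss, ld, p_thresh=1e-4, window_kb=window_kb, r2_thresh=r2_thresh)
            assert kept
            brute_force_clump_check(ss, ld, kept, 1e-4, window_kb, r2_thresh)
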