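import itertools
import math

import numpy as np
import pandas as pd
import pytest

from intronhet.evolution import (
    OrthologAlignmentPair,
    SaturationError,
    divergence_table,
    group_permutation_test,
    group_rate_summary,
    intron_p_distance,
    ks_filter,
    nei_gojobori_rates,
    screen_orthologs,
    structure_conservation,
)

# ---------------------------------------------------------------------------
# Independent oracle: explicit pathway enumeration over Biopython translation
# ---------------------------------------------------------------------------

from Bio.Seq import Seq


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_sites(codon):
    syn = 0.0
    for pos in range(3):
        s = v = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _aa(alt) == "*":
                continue
            v += 1
            if _aa(alt) == _aa(codon):
                s += 1
        if v:
            syn += s / v
    return syn, 3 - syn


def oracle_pair(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur, s, n, ok = c1, 0, 0, True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*" and step < len(order) - 1:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            paths.append((s, n))
    if not paths:
        for order in itertools.permutations(positions):
            cur, s, n = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _aa(nxt) == _aa(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n))
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_nei_gojobori(seq1, seq2):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if any(b not in "ACGT" for b in c1 + c2) or _aa(c1) == "*" or _aa(c2) == "*":
            continue
        s1, n1 = oracle_sites(c1)
        s2, n2 = oracle_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = oracle_pair(c1, c2)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N
    jc = lambda p: 0.0 if p == 0 else -0.75 * math.log(1 - 4 * p / 3)  # noqa: E731
    return jc(pN), jc(pS)


SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if _aa(a + b + c) != "*"
]


def random_codon_pair_sequences(rng, n_codons):
    c1, c2 = [], []
    for _ in range(n_codons):
        base = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        if rng.random() < 0.6:
            other = base
        else:
            other = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
        c1.append(base)
        c2.append(other)
    return "".join(c1), "".join(c2)


class TestNeiGojobori:
    def test_identical_sequences_have_zero_rates(self):
        seq = "ATGGCTAAATTTGGG"
        assert nei_gojobori_rates(seq, seq) == (0.0, 0.0)

    def test_leucine_tta_ttg_is_purely_synonymous(self):
        # TTA -> TTG is Leu -> Leu: the only difference is synonymous, so
        # K_A must be 0 and K_S positive (identical flanking codons keep
        # the synonymous proportion below the correction's 3/4 bound)
        ka, ks = nei_gojobori_rates("GGGTTAGGG", "GGGTTGGGG")
        assert ka == 0.0
        assert ks > 0.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_pathway_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq1, seq2 = random_codon_pair_sequences(rng, 30)
        try:
            got = nei_gojobori_rates(seq1, seq2)
        except SaturationError:
            with pytest.raises(ValueError):
                oracle_nei_gojobori(seq1, seq2)
            return
        expected = oracle_nei_gojobori(seq1, seq2)
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)

    def test_symmetric_in_the_two_sequences(self):
        rng = np.random.default_rng(100)
        seq1, seq2 = random_codon_pair_sequences(rng, 40)
        try:
            fwd = nei_gojobori_rates(seq1, seq2)
            rev = nei_gojobori_rates(seq2, seq1)
        except SaturationError:
            return
        assert fwd[0] == pytest.approx(rev[0], abs=1e-12)
        assert fwd[1] == pytest.approx(rev[1], abs=1e-12)

    def test_site_counts_sum_to_three_per_codon(self):
        from intronhet.evolution import codon_site_counts

        for codon in SENSE_CODONS:
            s, n = codon_site_counts(codon)
            assert s + n == pytest.approx(3.0, abs=1e-9)

    def test_gapped_codons_are_skipped(self):
        ka, ks = nei_gojobori_rates("GGG---TTAGGG", "GGGGCGTTGGGG")
        assert (ka, ks) == nei_gojobori_rates("GGGTTAGGG", "GGGTTGGGG")

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            nei_gojobori_rates("ATG", "ATGGCG")


class TestKsFilter:
    def frame(self, ks_values):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(ks_values))],
                "K_A": 0.01, "K_S": ks_values, "ka_ks": np.nan,
                "mean_K_I": np.nan, "n_introns": 0,
            }
        )

    def test_ks_above_threshold_discarded(self):
        out = ks_filter(self.frame([0.15, 0.05]))
        assert out["K_S"].tolist() == [0.05]

    def test_boundary_value_retained(self):
        out = ks_filter(self.frame([0.1]))
        assert len(out) == 1


class TestIntronPDistance:
    def test_identical_introns(self):
        assert intron_p_distance("ACGT", "ACGT", [False] * 4) == 0.0

    def test_differences_confined_to_masked_columns_are_ignored(self):
        assert intron_p_distance("ACGT", "TTGT", [True, True, False, False]) == 0.0

    def test_two_differences_over_hundred_columns(self):
        s1 = "A" * 100
        s2 = "C" * 2 + "A" * 98
        assert intron_p_distance(s1, s2, [False] * 100) == pytest.approx(0.02)

    def test_gap_columns_excluded_from_denominator(self):
        assert intron_p_distance("AC-T", "ACGT", [False] * 4) == 0.0

    def test_all_masked_raises(self):
        with pytest.raises(ValueError):
            intron_p_distance("ACGT", "ACGT", [True] * 4)


class TestScreening:
    def make_pair(self, gene_id, match_fraction):
        n = 100
        n_match = int(round(match_fraction * n))
        states1 = "E" * n
        states2 = "E" * n_match + "I" * (n - n_match)
        return OrthologAlignmentPair(gene_id, "ATG", "ATG", (), states1, states2)

    def test_multi_candidate_queries_discarded(self):
        hits = pd.DataFrame(
            {"query": ["q1", "q2", "q2"], "candidate": ["c1", "c2", "c3"]}
        )
        alignments = {"q1": self.make_pair("q1", 0.9)}
        retained = screen_orthologs(hits, alignments)
        assert [p.gene_id for p in retained] == ["q1"]

    @pytest.mark.parametrize("fraction,kept", [(0.85, True), (0.70, False), (0.80, True)])
    def test_structure_conservation_threshold(self, fraction, kept):
        hits = pd.DataFrame({"query": ["q1"], "candidate": ["c1"]})
        retained = screen_orthologs(hits, {"q1": self.make_pair("q1", fraction)})
        assert (len(retained) == 1) is kept

    def test_missing_alignment_raises(self):
        hits = pd.DataFrame({"query": ["q1"], "candidate": ["c1"]})
        with pytest.raises(KeyError):
            screen_orthologs(hits, {})

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_matches_naive_column_comparison(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        s1 = "".join(rng.choice(["E", "I"], size=n))
        s2 = "".join(rng.choice(["E", "I"], size=n))
        pair = OrthologAlignmentPair("g", "", "", (), s1, s2)
        naive = sum(a == b for a, b in zip(s1, s2)) / n
        assert structure_conservation(pair) == pytest.approx(naive)


class TestGroupSummary:
    def test_ratio_of_means_arithmetic(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b"], "K_A": [0.02, 0.04], "K_S": [0.05, 0.05],
                "ka_ks": [0.4, 0.8], "mean_K_I": [0.01, 0.03], "n_introns": 1,
            }
        )
        out = group_rate_summary(df, {"a": "x", "b": "x"})
        assert out.loc[0, "ka_ks"] == pytest.approx(0.6)
        assert out.loc[0, "n"] == 2
        assert out.loc[0, "mean_K_I"] == pytest.approx(0.02)

    def test_zero_divergence_group_reports_nan(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a"], "K_A": [0.0], "K_S": [0.0], "ka_ks": [np.nan],
                "mean_K_I": [0.0], "n_introns": 1,
            }
        )
        out = group_rate_summary(df, {"a": "x"})
        assert np.isnan(out.loc[0, "ka_ks"])

    def test_unlabeled_gene_raises(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a"], "K_A": [0.01], "K_S": [0.05], "ka_ks": [0.2],
                "mean_K_I": [0.0], "n_introns": 1,
            }
        )
        with pytest.raises(ValueError):
            group_rate_summary(df, {})


class TestGroupPermutation:
    def test_identical_multisets_give_large_p(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        res = group_permutation_test(vals, vals, n_perm=400, seed=0)
        assert res.observed == pytest.approx(0.0)
        assert res.p_value >= 0.5

    def test_three_vs_three_matches_exhaustive_enumeration(self):
        a = [1.0, 2.0, 3.0]
        b = [4.0, 5.0, 7.0]
        pooled = a + b
        observed = np.mean(a) - np.mean(b)
        stats = []
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            stats.append(np.mean(ga) - np.mean(gb))
        exact = sum(s <= observed for s in stats) / len(stats)
        res = group_permutation_test(a, b, n_perm=20_000, seed=1, alternative="less")
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_value - exact) < 4 * se + 2e-3

    def test_null_calibration_roughly_uniform(self):
        from scipy import stats as st

        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(100):
            a = rng.normal(size=12)
            b = rng.normal(size=12)
            pvals.append(
                group_permutation_test(a, b, n_perm=200, seed=rep).p_value
            )
        assert st.kstest(pvals, "uniform").pvalue > 0.01


class TestDivergenceTable:
    def test_table_contains_expected_columns_and_values(self):
        pair = OrthologAlignmentPair(
            "g1", "GGGTTAGGG", "GGGTTGGGG",
            ((("A" * 50), ("A" * 48 + "CC"), np.zeros(50, dtype=bool)),),
        )
        df = divergence_table([pair])
        assert df.loc[0, "K_A"] == 0.0
        assert df.loc[0, "K_S"] > 0
        assert df.loc[0, "mean_K_I"] == pytest.approx(0.04)
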