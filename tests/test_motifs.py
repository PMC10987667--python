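"""Motif grammar, matching, enrichment statistics and sub-motif discovery."""

from __future__ import annotations

import numpy as np
import pytest

from phoswave.motifs import (
    AMINO_ACIDS,
    MotifGrammarError,
    SiteWindow,
    builtin_kinase_motifs,
    discover_submotif,
    fisher_family_pvalues,
    fisher_test,
    match_site,
    match_table,
    motif_enrichment,
    parse_motif,
    residue_logo,
    scan_protein_sequence,
    significance_stars,
)

from _oracles import fisher_two_sided_enum, motif_regex

EXTENDED_PATTERNS = ("[DEN]x[ST]*F", "[DEN]x[ST]*G", "[DEN]x[ST]*[FG]",
                     "[DEN]x[ST]*[LIMYF]", "S[ST]*P")


def window_from_center(text: str, center: int = 0, half: int = 15) -> SiteWindow:
    """Embed a short fragment into a full window with ``text[center]`` as
    the phospho-acceptor; remaining positions are alanine."""
    left = "A" * (half - center)
    right = "A" * (half - (len(text) - 1 - center))
    return SiteWindow(left + text + right)


class TestParseMotif:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("[ST]*Px[KR]", {0: set("ST"), 1: {"P"}, 3: set("KR")}),
            ("RPx[ST]*", {-3: {"R"}, -2: {"P"}, 0: set("ST")}),
            ("[DEN]x[ST]*", {-2: set("DEN"), 0: set("ST")}),
            ("[LM]xx[ST]*x[STVILMFYW][YIFM]",
             {-3: set("LM"), 0: set("ST"), 2: set("STVILMFYW"),
              3: set("YIFM")}),
        ],
    )
    def test_offsets_and_sets(self, text, expected):
        pattern = parse_motif(text)
        assert {o: set(r) for o, r in pattern.constraints.items()} == expected

    @pytest.mark.parametrize("bad", ["[ST]P", "[ST]*P*", "[]*P", "[ST]*-",
                                     "x*P", "[st]*P"])
    def test_grammar_errors(self, bad):
        with pytest.raises(MotifGrammarError):
            parse_motif(bad)

    def test_builtin_table_has_twelve_kinases(self):
        patterns = builtin_kinase_motifs()
        assert len(patterns) == 12
        assert len({p.name for p in patterns}) == 12


class TestMatchSite:
    def test_strict_cdk_site(self):
        # e.g. an S*PxK site on a spindle-pole protein
        w = window_from_center("SPAK")
        assert match_site(w, parse_motif("[ST]*Px[KR]"))

    def test_polo_site_with_n_minus_two(self):
        # NxS* matches the Polo consensus [DEN]x[ST]*
        w = window_from_center("NAS", center=2)  # N at -2, S centre
        assert w.center == "S"
        assert match_site(w, parse_motif("[DEN]x[ST]*"))

    def test_tyrosine_never_matches_st_star(self):
        w = window_from_center("YP")
        assert w.center == "Y"
        assert not match_site(w, parse_motif("[ST]*P"))

    def test_padding_at_constrained_offset_fails(self):
        seq = "_" * 14 + "NSP" + "A" * 14  # -2 offset lands on padding
        w = SiteWindow(seq)
        assert w.center == "S"
        assert not match_site(w, parse_motif("[DEN]x[ST]*"))

    def test_matches_regex_oracle_on_random_windows(self, rng):
        """Exact agreement with an independent regex matcher on the full
        17-pattern set over random windows (scaled-up in acceptance)."""
        patterns = [(p, motif_regex(p.pattern_text))
                    for p in builtin_kinase_motifs()]
        patterns += [(parse_motif(t), motif_regex(t))
                     for t in EXTENDED_PATTERNS]
        alphabet = np.array(list(AMINO_ACIDS + "_"))
        for _ in range(500):
            seq = "".join(rng.choice(alphabet, size=31))
            w = SiteWindow(seq)
            for pattern, regex in patterns:
                assert match_site(w, pattern) == bool(regex.match(seq))

    def test_match_table_shape(self):
        wins = {"s1": window_from_center("SPAK"),
                "s2": window_from_center("NAS", center=2)}
        t = match_table(wins, builtin_kinase_motifs())
        assert t.shape == (2, 12)
        assert t.loc["s1", "Cdc28 strict"]
        assert t.loc["s2", "Cdc5"]


class TestFisher:
    def test_matches_enumeration_oracle(self, rng):
        for _ in range(150):
            N = int(rng.integers(1, 61))
            a = int(rng.integers(0, N + 1))
            b = int(rng.integers(0, N - a + 1))
            c = int(rng.integers(0, N - a - b + 1))
            d = N - a - b - c
            _, p = fisher_test(a, b, c, d)
            assert p == pytest.approx(fisher_two_sided_enum(a, b, c, d),
                                      abs=1e-9)

    def test_family_values_match_per_table(self, rng):
        for _ in range(30):
            N = int(rng.integers(2, 61))
            r1 = int(rng.integers(0, N + 1))
            c1 = int(rng.integers(0, N + 1))
            fam = fisher_family_pvalues(N, r1, c1)
            for i, a in enumerate(range(max(0, r1 + c1 - N),
                                        min(r1, c1) + 1)):
                b, c = r1 - a, c1 - a
                d = (N - r1) - c
                assert fam[i] == pytest.approx(fisher_test(a, b, c, d)[1],
                                               abs=1e-12)

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.5) == ""


class TestMotifEnrichment:
    def _matches(self, n_match_in_group, n_group, n_match_bg, n_bg):
        import pandas as pd
        ids = [f"g{i}" for i in range(n_group)] + [
            f"b{i}" for i in range(n_bg - n_group)]
        flags = ([True] * n_match_in_group
                 + [False] * (n_group - n_match_in_group)
                 + [True] * (n_match_bg - n_match_in_group)
                 + [False] * ((n_bg - n_group)
                              - (n_match_bg - n_match_in_group)))
        return pd.DataFrame({"m": flags}, index=ids)

    def test_enriched_group_and_oracle_p(self):
        m = self._matches(20, 20, 50, 100)
        res = motif_enrichment({"grp": [f"g{i}" for i in range(20)]},
                               background=list(m.index), matches=m)
        row = res.iloc[0]
        assert row["direction"] == "enriched"
        assert row["p_value"] == pytest.approx(
            fisher_two_sided_enum(20, 0, 50, 50), abs=1e-9)

    def test_null_composition_not_significant(self):
        m = self._matches(10, 20, 50, 100)
        res = motif_enrichment({"grp": [f"g{i}" for i in range(20)]},
                               background=list(m.index), matches=m)
        assert res.iloc[0]["odds_ratio"] == pytest.approx(1.0)
        assert res.iloc[0]["p_value"] > 0.05

    def test_depleted_group(self):
        m = self._matches(0, 20, 50, 100)
        res = motif_enrichment({"grp": [f"g{i}" for i in range(20)]},
                               background=list(m.index), matches=m)
        assert res.iloc[0]["direction"] == "depleted"

    def test_rest_mode_uses_disjoint_background(self):
        m = self._matches(20, 20, 50, 100)
        res = motif_enrichment({"grp": [f"g{i}" for i in range(20)]},
                               background=list(m.index), matches=m,
                               mode="rest")
        row = res.iloc[0]
        assert (row["n_bg_match"], row["n_bg_nonmatch"]) == (30, 50)

    def test_empty_group_rejected(self):
        m = self._matches(5, 10, 20, 40)
        with pytest.raises(ValueError):
            motif_enrichment({"grp": []}, background=list(m.index),
                             matches=m)


class TestResidueLogo:
    def test_extreme_foreground_enrichment_flagged(self, rng):
        fg = [window_from_center("SF") for _ in range(30)]
        alphabet = np.array(list(AMINO_ACIDS))
        bg = [SiteWindow("".join(rng.choice(alphabet, 15)) + "S"
                         + "".join(rng.choice(alphabet, 15)))
              for _ in range(200)]
        logo = residue_logo(fg, bg)
        cell = logo[(logo["offset"] == 1) & (logo["residue"] == "F")]
        assert cell.iloc[0]["significant"]
        assert cell.iloc[0]["pct_difference"] > 50

    def test_identical_sets_have_no_significant_cells(self, rng):
        alphabet = np.array(list(AMINO_ACIDS))
        wins = [SiteWindow("".join(rng.choice(alphabet, 15)) + "S"
                           + "".join(rng.choice(alphabet, 15)))
                for _ in range(40)]
        logo = residue_logo(wins, wins)
        assert not logo["significant"].any()
        assert (logo["pct_difference"].abs() < 1e-12).all()

    def test_antisymmetric_under_swap(self, rng):
        alphabet = np.array(list(AMINO_ACIDS))
        mk = lambda n: [SiteWindow("".join(rng.choice(alphabet, 15)) + "T"
                                   + "".join(rng.choice(alphabet, 15)))
                        for _ in range(n)]
        fg, bg = mk(25), mk(35)
        ab = residue_logo(fg, bg).set_index(["offset", "residue"])
        ba = residue_logo(bg, fg).set_index(["offset", "residue"])
        joined = ab.join(ba, lsuffix="_ab", rsuffix="_ba", how="inner")
        assert np.allclose(joined["pct_difference_ab"],
                           -joined["pct_difference_ba"])
        assert np.allclose(joined["p_value_ab"], joined["p_value_ba"])

    def test_per_offset_fg_percents_sum_to_100(self, rng):
        alphabet = np.array(list(AMINO_ACIDS))
        fg = [SiteWindow("".join(rng.choice(alphabet, 15)) + "S"
                         + "".join(rng.choice(alphabet, 15)))
              for _ in range(30)]
        logo = residue_logo(fg, fg)
        sums = logo.groupby("offset")["fg_pct"].sum()
        assert np.allclose(sums, 100.0)

    def test_small_count_p_matches_enumeration(self):
        fg = [window_from_center("SF") for _ in range(8)] + [
            window_from_center("SA") for _ in range(2)]
        bg = [window_from_center("SF") for _ in range(5)] + [
            window_from_center("SA") for _ in range(35)]
        logo = residue_logo(fg, bg)
        cell = logo[(logo["offset"] == 1) & (logo["residue"] == "F")]
        assert cell.iloc[0]["p_value"] == pytest.approx(
            fisher_two_sided_enum(8, 2, 5, 35), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residue_logo([SiteWindow("ASA")], [SiteWindow("AASAA")])


class TestDiscoverSubmotif:
    def _polo_windows(self, plus1: str, n: int):
        return [window_from_center("NAS" + plus1, center=2) for _ in range(n)]

    def test_planted_phenylalanine_recovered(self):
        fg = self._polo_windows("F", 30) + self._polo_windows("A", 20)
        bg = self._polo_windows("F", 5) + self._polo_windows("A", 45)
        base = parse_motif("[DEN]x[ST]*")
        res = discover_submotif(base, 1, fg, bg)
        assert res.iloc[0]["residue"] == "F"
        assert res.iloc[0]["p_value"] == pytest.approx(
            fisher_two_sided_enum(30, 20, 5, 45), abs=1e-9)

    def test_equal_distributions_yield_nothing(self):
        wins = self._polo_windows("F", 10) + self._polo_windows("G", 10)
        res = discover_submotif(parse_motif("[DEN]x[ST]*"), 1, wins, wins)
        assert res.empty

    def test_two_enriched_residues_ranked_by_p(self):
        fg = (self._polo_windows("F", 30) + self._polo_windows("G", 15)
              + self._polo_windows("A", 5))
        bg = (self._polo_windows("F", 3) + self._polo_windows("G", 3)
              + self._polo_windows("A", 44))
        res = discover_submotif(parse_motif("[DEN]x[ST]*"), 1, fg, bg)
        assert list(res["residue"]) == ["F", "G"]
        assert res["p_value"].is_monotonic_increasing

    def test_constrained_offset_rejected(self):
        with pytest.raises(ValueError):
            discover_submotif(parse_motif("[DEN]x[ST]*"), -2,
                              self._polo_windows("F", 5),
                              self._polo_windows("F", 5))


class TestScanProteinSequence:
    @pytest.mark.parametrize(
        "seq,positions",
        [("STSTP", [3]), ("TTTTP", []), ("SSPSTP", [1, 4]),
         ("SSPSSP", [1, 4]), ("ASTP", [2])],
    )
    def test_known_fragments(self, seq, positions):
        assert scan_protein_sequence(seq) == positions

    def test_agrees_with_brute_force(self, rng):
        alphabet = np.array(list(AMINO_ACIDS))
        for _ in range(50):
            seq = "".join(rng.choice(alphabet, size=60))
            brute = [i + 1 for i in range(58)
                     if seq[i] == "S" and seq[i + 1] in "ST"
                     and seq[i + 2] == "P"]
            assert scan_protein_sequence(seq) == brute

    def test_star_rejected(self):
        with pytest.raises(MotifGrammarError):
            scan_protein_sequence("ASTPA", "S[ST]*P")
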