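"""Consensus and PSSM promoter scanning against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from nrfomics import motifs, simulate


def oracle_consensus_hits(seq, pattern_str, alphabet, strands="both"):
    """Brute-force: test per-position set membership on every window."""
    allowed = [set(alphabet[l]) for l in pattern_str]
    W = len(pattern_str)
    L = len(seq)
    hits = []
    for i in range(L - W + 1):
        win = seq[i:i + W]
        if all(b in a for b, a in zip(win, allowed)):
            hits.append((i - L, "+"))
        if strands == "both":
            rc = motifs.reverse_complement(win)
            if all(b in a for b, a in zip(rc, allowed)):
                hits.append((i - L, "-"))
    return sorted(hits)


def oracle_pssm_scores(seq, probs, background, eps):
    """Score every window with weights recomputed from first principles."""
    W = probs.shape[1]
    L = len(seq)
    out = {}
    for i in range(L - W + 1):
        win = seq[i:i + W]
        if "N" in win:
            continue
        s = 0.0
        for j, b in enumerate(win):
            f = probs["ACGT".index(b), j]
            s += math.log((f + eps) / ((1 + 4 * eps) * background[b]))
        out[i - L] = s
    return out


class TestConsensusScan:
    def test_direct_expansion_hit(self):
        pat = motifs.make_pattern("RTGABNNNGCA", alphabet="legacy")
        hits = motifs.consensus_scan({"g": "TTTGTGAGAAAGCATTT"}, pat, strands="plus")
        assert len(hits) == 1
        assert hits.iloc[0]["matched"] == "GTGAGAAAGCA"

    def test_alphabet_switch_changes_r(self):
        # A at the R position: excluded by R=G/C, allowed by IUPAC R=A/G
        seq = {"g": "TTATGAGAAAGCATT"}
        legacy = motifs.make_pattern("RTGABNNNGCA", alphabet="legacy")
        iupac = motifs.make_pattern("RTGABNNNGCA", alphabet="iupac")
        assert len(motifs.consensus_scan(seq, legacy, strands="plus")) == 0
        assert len(motifs.consensus_scan(seq, iupac, strands="plus")) == 1

    def test_planted_motif_found_at_offset(self):
        promoters, truth = simulate.simulate_promoters(
            n_genes=1, length=500,
            planted=[simulate.PromoterTruth("gene000", "GTGAGAAAGCA", -100, "+")],
            seed=5)
        pat = motifs.make_pattern("RTGABNNNGCA", alphabet="legacy")
        hits = motifs.consensus_scan(promoters, pat, strands="plus")
        assert -100 in set(hits["start"])

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        """Scanner hit multisets equal the window-enumeration oracle on 100
        seeded random 500-mers."""
        pat = motifs.make_pattern("RTGABNNNGCA", alphabet="legacy")
        rng = np.random.default_rng(99)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=500,
                                     p=[0.26, 0.24, 0.24, 0.26]))
            hits = motifs.consensus_scan({"g": seq}, pat, strands="both")
            got = sorted(zip(hits["start"], hits["strand"]))
            assert got == oracle_consensus_hits(seq, "RTGABNNNGCA",
                                                motifs.LEGACY_ARE_ALPHABET)

    def test_n_in_sequence_never_matches(self):
        pat = motifs.make_pattern("N", alphabet="legacy")
        hits = motifs.consensus_scan({"g": "ANA"}, pat, strands="plus")
        assert len(hits) == 2  # the two A windows; the N window is not a hit

    def test_strand_symmetry(self):
        promoters, _ = simulate.simulate_promoters(n_genes=3, length=300, seed=8)
        pat = motifs.make_pattern("RTGABNNNGCA", alphabet="legacy")
        fwd = motifs.consensus_scan(promoters, pat, strands="both")
        rc = {g: motifs.reverse_complement(s) for g, s in promoters.items()}
        rev = motifs.consensus_scan(rc, pat, strands="both")
        W = len(pat)
        for gene, seq in promoters.items():
            L = len(seq)
            # window starting at offset s maps to offset -W - L - s on the
            # reverse complement; strands swap, the multiset is preserved
            a = sorted(-W - L - s for s in fwd.loc[fwd.gene == gene, "start"])
            b = sorted(rev.loc[rev.gene == gene, "start"])
            assert a == b


class TestBackground:
    def test_counting(self):
        assert motifs.background_frequencies({"g": "AATT"}) == {
            "A": 0.5, "T": 0.5, "C": 0.0, "G": 0.0}
        bg = motifs.background_frequencies({"g": "ACGT"})
        assert all(v == 0.25 for v in bg.values())

    def test_recovers_generator_composition(self):
        promoters, _ = simulate.simulate_promoters(
            n_genes=40, length=2000,
            base_composition={"A": 0.26, "T": 0.26, "C": 0.24, "G": 0.24}, seed=2)
        bg = motifs.background_frequencies(promoters)
        assert bg["A"] == pytest.approx(0.26, abs=0.01)
        assert bg["C"] == pytest.approx(0.24, abs=0.01)
        assert sum(bg.values()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            motifs.background_frequencies({"g": "NNNN"})


class TestPssm:
    def test_null_matrix_zero_weights(self):
        probs = np.tile([[0.26], [0.24], [0.24], [0.26]], (1, 5))
        m = motifs.ProbabilityMatrix(probs)
        pssm = motifs.build_pssm(m, background=motifs.MOUSE_PROMOTER_BACKGROUND,
                                 pseudocount=0.0)
        np.testing.assert_allclose(pssm.weights, 0.0, atol=1e-12)

    def test_hand_computed_weight(self):
        # f(A,1)=0.7 against uniform background, eps=0: ln(0.7/0.25)=ln(2.8)
        probs = np.array([[0.7, 0.1], [0.1, 0.1], [0.1, 0.7], [0.1, 0.1]])
        m = motifs.ProbabilityMatrix(probs)
        uniform = {b: 0.25 for b in "ACGT"}
        pssm = motifs.build_pssm(m, background=uniform, pseudocount=0.0)
        assert pssm.weights[0, 0] == pytest.approx(math.log(2.8))
        assert pssm.weights[2, 1] == pytest.approx(math.log(2.8))

    def test_zero_cell_requires_pseudocount(self):
        probs = np.array([[1.0], [0.0], [0.0], [0.0]])
        m = motifs.ProbabilityMatrix(probs)
        uniform = {b: 0.25 for b in "ACGT"}
        with pytest.raises(ValueError, match="pseudocount"):
            motifs.build_pssm(m, background=uniform, pseudocount=0.0)
        pssm = motifs.build_pssm(m, background=uniform, pseudocount=0.001)
        assert np.isfinite(pssm.weights).all()

    def test_expected_score_under_background_nonpositive(self, rng):
        # Jensen: E_p[ln(f/p)] = -KL(p || f) <= 0 per column
        for _ in range(20):
            raw = rng.random((4, 6)) + 0.05
            probs = raw / raw.sum(axis=0)
            m = motifs.ProbabilityMatrix(probs)
            bg_raw = rng.random(4) + 0.2
            bg = dict(zip("ACGT", bg_raw / bg_raw.sum()))
            pssm = motifs.build_pssm(m, background=bg, pseudocount=0.0)
            p = np.array([bg[b] for b in "ACGT"])[:, None]
            assert float((pssm.weights * p).sum()) <= 1e-9

    def test_matrix_roundtrip(self, tmp_path, rng):
        raw = rng.random((4, 7)) + 0.1
        m = motifs.ProbabilityMatrix(raw / raw.sum(axis=0))
        path = tmp_path / "matrix.txt"
        motifs.write_probability_matrix(m, path)
        again = motifs.read_probability_matrix(path)
        np.testing.assert_allclose(m.probs, again.probs, atol=1e-6)


class TestPssmScan:
    def _informative_matrix(self, word):
        probs = np.full((4, len(word)), 0.04)
        for i, b in enumerate(word):
            probs["ACGT".index(b), i] = 0.88
        return motifs.ProbabilityMatrix(probs)

    def test_zero_weight_matrix_no_hits(self):
        probs = np.tile([[0.26], [0.24], [0.24], [0.26]], (1, 4))
        pssm = motifs.build_pssm(motifs.ProbabilityMatrix(probs),
                                 background=motifs.MOUSE_PROMOTER_BACKGROUND,
                                 pseudocount=0.0)
        hits, summary = motifs.pssm_scan({"g": "ACGTACGTACGT"}, pssm, threshold=1.0)
        assert len(hits) == 0
        assert summary.iloc[0]["n_matches"] == 0

    def test_argmax_word_is_best_hit(self):
        word = "TGACTCAGCA"
        promoters, _ = simulate.simulate_promoters(
            n_genes=1, length=400,
            planted=[simulate.PromoterTruth("gene000", word, -250, "+")], seed=3)
        pssm = motifs.build_pssm(self._informative_matrix(word),
                                 background={b: 0.25 for b in "ACGT"})
        _, summary = motifs.pssm_scan(promoters, pssm, threshold=1.0, strands="plus")
        assert summary.iloc[0]["best_start"] == -250
        assert word in summary.iloc[0]["best_site"].upper()

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        """Per-gene counts and maxima equal the window-by-window oracle on
        100 seeded random 500-mers."""
        raw = rng.random((4, 11)) + 0.05
        probs = raw / raw.sum(axis=0)
        bg = {"A": 0.26, "T": 0.26, "C": 0.24, "G": 0.24}
        eps = 0.001
        pssm = motifs.build_pssm(motifs.ProbabilityMatrix(probs),
                                 background=bg, pseudocount=eps)
        for rep in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            hits, summary = motifs.pssm_scan({"g": seq}, pssm, threshold=1.0,
                                             strands="plus")
            oracle = oracle_pssm_scores(seq, probs, bg, eps)
            expected = {pos: s for pos, s in oracle.items() if s > 1.0}
            assert len(hits) == len(expected)
            got = dict(zip(hits["start"], hits["score"]))
            for pos, s in expected.items():
                assert got[pos] == pytest.approx(s, abs=1e-9)
            if expected:
                assert summary.iloc[0]["highest_score"] == pytest.approx(
                    max(expected.values()), abs=1e-9)

    def test_window_with_n_skipped(self):
        probs = np.full((4, 3), 0.25)
        pssm = motifs.build_pssm(motifs.ProbabilityMatrix(probs),
                                 background={b: 0.25 for b in "ACGT"})
        hits, summary = motifs.pssm_scan({"g": "ACNGT"}, pssm, threshold=-1.0,
                                         strands="plus")
        # windows ACN, CNG, NGT all contain N: no scoreable window
        assert summary.iloc[0]["n_matches"] == 0

    def test_short_promoter_zero_windows(self):
        probs = np.full((4, 8), 0.25)
        pssm = motifs.build_pssm(motifs.ProbabilityMatrix(probs),
                                 background={b: 0.25 for b in "ACGT"})
        _, summary = motifs.pssm_scan({"g": "ACGT"}, pssm, threshold=0.0)
        assert summary.iloc[0]["n_matches"] == 0

    def test_both_strands_superset_of_plus(self):
        promoters, _ = simulate.simulate_promoters(n_genes=5, length=300, seed=6)
        raw = np.random.default_rng(1).random((4, 9)) + 0.05
        pssm = motifs.build_pssm(
            motifs.ProbabilityMatrix(raw / raw.sum(axis=0)),
            background={b: 0.25 for b in "ACGT"})
        plus, _ = motifs.pssm_scan(promoters, pssm, strands="plus")
        both, _ = motifs.pssm_scan(promoters, pssm, strands="both")
        assert len(both) >= len(plus)


class TestPanel:
    def test_single_gene_group_and_means(self):
        tbl = pd.DataFrame({
            "gene": ["g1", "g2"],
            "consensus_count": [1, 3],
            "n_matches": [10, 14],
            "highest_score": [4.0, 6.0],
            "mean_score": [2.0, 3.0],
        })
        out = motifs.panel_summary(tbl, {"solo": ["g1"], "pair": ["g1", "g2"]})
        solo = out.set_index("group").loc["solo"]
        pair = out.set_index("group").loc["pair"]
        assert solo["consensus_count"] == 1
        assert pair["consensus_count"] == 2.0
        assert pair["highest_score"] == 5.0

    def test_empty_group_warns_and_omitted(self):
        tbl = pd.DataFrame({"gene": ["g1"], "consensus_count": [1]})
        with pytest.warns(UserWarning, match="empty"):
            out = motifs.panel_summary(tbl, {"ok": ["g1"], "none": ["zz"]})
        assert list(out["group"]) == ["ok"]


class TestPromoterIO:
    def test_roundtrip_and_case(self, tmp_path):
        promoters, _ = simulate.simulate_promoters(n_genes=3, length=120, seed=4)
        path = tmp_path / "p.fasta"
        motifs.write_promoters(promoters, path)
        again = motifs.read_promoters(path)
        assert again == promoters
        lower = path.read_text().replace("ACG", "acg")
        (tmp_path / "lower.fasta").write_text(lower)
        assert motifs.read_promoters(tmp_path / "lower.fasta") == promoters

    def test_duplicate_ids_rejected(self, tmp_path):
        (tmp_path / "dup.fasta").write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            motifs.read_promoters(tmp_path / "dup.fasta")
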