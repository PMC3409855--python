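"""PWM parsing, mat_sim scoring, window extraction, scanning, TF activity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortisurv.tfbs import (
    PWM,
    PromoterRecord,
    ScanGrid,
    build_count_table,
    extract_window,
    mat_sim,
    parse_transfac,
    pwm_from_consensus,
    pwm_from_counts,
    scan_count,
    tf_activity,
    write_transfac,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# TRANSFAC parsing


def test_parse_single_position_counts_normalised():
    text = "NA  TOY\nXX\nP0 A C G T\n01 10 0 0 0 A\n02 5 5 5 5 N\n//\n"
    (pwm,) = parse_transfac(text)
    assert pwm.name == "TOY"
    np.testing.assert_allclose(pwm.freqs[0], [1, 0, 0, 0])
    np.testing.assert_allclose(pwm.freqs[1], [0.25] * 4)


def test_parse_malformed_row_reports_line_number():
    text = "NA  BAD\nP0 A C G T\n01 1 2 3\n//\n"
    with pytest.raises(ValueError, match="line 3"):
        parse_transfac(text)


def test_write_parse_round_trip():
    pwms = [
        pwm_from_consensus("M1", "GGGACTTTCC"),
        pwm_from_counts("M2", [[3, 1, 1, 1], [1, 1, 1, 9], [2, 2, 3, 3]]),
    ]
    back = parse_transfac(write_transfac(pwms))
    assert [p.name for p in back] == ["M1", "M2"]
    for a, b in zip(pwms, back):
        np.testing.assert_allclose(a.freqs, b.freqs, atol=1e-15)


def test_pwm_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        PWM("bad", np.array([[0.5, 0.5, 0.5, 0.5]]))
    with pytest.raises(ValueError, match="zero total"):
        pwm_from_counts("bad", [[0, 0, 0, 0]])


# ---------------------------------------------------------------------------
# mat_sim


def test_consensus_scores_one():
    pwm = pwm_from_consensus("M", "GGGACTTTCC")
    assert mat_sim(pwm, "GGGACTTTCC") == pytest.approx(1.0)


def test_uniform_matrix_degenerate_scores_one():
    pwm = PWM("U", np.full((4, 4), 0.25))
    assert pwm.degenerate
    assert mat_sim(pwm, "ACGT") == 1.0


def test_two_position_hand_computation():
    # only the informative first position contributes: score = 0.1/0.7
    pwm = PWM("H", np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]]))
    assert mat_sim(pwm, "CA") == pytest.approx(0.1 / 0.7, abs=1e-12)
    assert mat_sim(pwm, "AA") == pytest.approx(1.0)


def test_wrong_length_rejected():
    pwm = pwm_from_consensus("M", "ACGT")
    with pytest.raises(ValueError, match="length"):
        mat_sim(pwm, "ACG")


def test_ambiguous_base_policies():
    pwm = pwm_from_consensus("M", "AAAA", p_match=0.97)
    expect = mat_sim(pwm, "AANA")
    assert 0 <= expect < 1
    assert np.isnan(mat_sim(pwm, "AANA", ambiguous="skip"))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(4, 12))
def test_mat_sim_bounds_random_matrices(seed, L):
    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.full(4, 0.7), size=L)
    pwm = PWM("R", f)
    seq = "".join(rng.choice(list("ACGT"), L))
    s = mat_sim(pwm, seq)
    assert 0.0 <= s <= 1.0 + 1e-12
    assert mat_sim(pwm, pwm.consensus) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# windows


def _record(seq="A" * 1200, tss=1000):
    return PromoterRecord("G1", seq, tss)


def test_window_lengths():
    rec = _record()
    assert len(extract_window(rec, 300, 200)) == 500
    assert len(extract_window(rec, 1000, 200)) == 1200
    assert extract_window(rec, 0, 0) == ""


def test_window_nesting_suffix_alignment(rng):
    seq = "".join(rng.choice(list("ACGT"), 1200))
    rec = PromoterRecord("G", seq, 1000)
    big = extract_window(rec, 1000, 200)
    small = extract_window(rec, 300, 200)
    assert big.endswith(small)


def test_window_truncation_warns():
    rec = PromoterRecord("G", "ACGT" * 50, 100)
    with pytest.warns(UserWarning, match="truncated"):
        w = extract_window(rec, 300, 200)
    assert len(w) == 200  # 100 upstream available + 100 downstream


# ---------------------------------------------------------------------------
# scanning


def test_scan_empty_and_short_sequences():
    pwm = pwm_from_consensus("M", "GGGACTTTCC")
    assert scan_count(pwm, "", 0.8) == 0
    assert scan_count(pwm, "ACGT", 0.8) == 0


def test_scan_finds_planted_consensus(rng):
    pwm = pwm_from_consensus("M", "GGGACTTTCC")
    bg = list(rng.choice(list("ACGT"), 500))
    for pos in (17, 200, 404):
        bg[pos : pos + 10] = list("GGGACTTTCC")
    seq = "".join(bg)
    assert scan_count(pwm, seq, 0.95) >= 3


def test_scan_counts_monotone_in_stringency(rng):
    pwm = pwm_from_consensus("M", "GGGACTTTCC")
    seq = "".join(rng.choice(list("ACGT"), 2000))
    counts = [scan_count(pwm, seq, s) for s in (0.80, 0.90, 0.95)]
    assert counts[0] >= counts[1] >= counts[2]


def test_scan_strand_symmetry(rng):
    pwm = pwm_from_consensus("M", "GGGACTTTCC")
    seq = "".join(rng.choice(list("ACGT"), 800))
    rc = seq.translate(REVCOMP)[::-1]
    for s in (0.80, 0.90, 0.95):
        assert scan_count(pwm, seq, s) == scan_count(pwm, rc, s)


def test_scan_matches_per_offset_rescoring_oracle(rng):
    pwm = PWM("R", rng.dirichlet(np.full(4, 0.5), size=6))
    seq = "".join(rng.choice(list("ACGT"), 300))
    rc = seq.translate(REVCOMP)[::-1]
    for sg in (0.8, 0.9):
        brute = 0
        for strand in (seq, rc):
            for i in range(len(strand) - 5):
                if mat_sim(pwm, strand[i : i + 6]) >= sg:
                    brute += 1
        assert scan_count(pwm, seq, sg) == brute


def test_scan_rejects_bad_stringency():
    pwm = pwm_from_consensus("M", "ACGT")
    with pytest.raises(ValueError):
        scan_count(pwm, "ACGTACGT", 0.0)


# ---------------------------------------------------------------------------
# count table and activity


def test_count_table_has_nine_entries_per_gene_motif(rng):
    rec = PromoterRecord("G1", "".join(rng.choice(list("ACGT"), 1200)), 1000)
    pwm = pwm_from_consensus("M", "GGGACTTTCC")
    table = build_count_table([rec], [pwm])
    assert len(table) == 9
    assert set(zip(table.upstream, table.stringency)) == set(ScanGrid().combinations)


def test_count_table_window_and_stringency_monotonicity(rng):
    recs = [
        PromoterRecord(f"G{i}", "".join(rng.choice(list("ACGT"), 1200)), 1000)
        for i in range(10)
    ]
    pwm = pwm_from_consensus("M", "GGGACTTTCC", p_match=0.7)  # soft: plenty of hits
    table = build_count_table(recs, [pwm])
    piv = table.pivot_table(index="gene", columns=["upstream", "stringency"],
                            values="count")
    for up in (300, 600, 1000):
        assert (piv[(up, 0.80)] >= piv[(up, 0.90)]).all()
        assert (piv[(up, 0.90)] >= piv[(up, 0.95)]).all()
    for sg in (0.80, 0.90, 0.95):
        assert (piv[(1000, sg)] >= piv[(600, sg)]).all()
        assert (piv[(600, sg)] >= piv[(300, sg)]).all()


def test_doubling_planted_sites_doubles_counts():
    cons = "GGGACTTTCC"
    pwm = pwm_from_consensus("M", cons)
    pad = "ACGTACGTACGTACGTACGT"
    one = pad * 10 + cons + pad * 10  # single site
    two = pad * 4 + cons + pad * 2 + cons + pad * 4
    r1 = PromoterRecord("G1", one.ljust(500, "A")[:500], 300)
    r2 = PromoterRecord("G2", two.ljust(500, "A")[:500], 300)
    t = build_count_table([r1, r2], [pwm], ScanGrid(upstreams=(300,), downstream=200,
                                                    stringencies=(0.95,)))
    c = t.set_index("gene")["count"]
    assert c["G2"] == 2 * c["G1"] == 2


def test_tf_activity_equal_densities_fold_near_one(rng):
    genes = [f"G{i}" for i in range(60)]
    rows = [(g, "M", u, s, rng.poisson(2)) for g in genes
            for u in (300, 600, 1000) for s in (0.8, 0.9, 0.95)]
    table = pd.DataFrame(rows, columns=["gene", "motif", "upstream", "stringency",
                                        "count"])
    res = tf_activity(table, genes[:20], genes[20:])
    assert res.loc["M", "mean_fold"] == pytest.approx(1.0, abs=0.35)
    assert res.loc["M", "p"] > 0.01


def test_tf_activity_swap_inverts_folds(rng):
    genes = [f"G{i}" for i in range(40)]
    rows = [(g, "M", u, s, rng.poisson(3 if g < "G020" else 1.5))
            for g in genes for u in (300, 600, 1000) for s in (0.8, 0.9, 0.95)]
    table = pd.DataFrame(rows, columns=["gene", "motif", "upstream", "stringency",
                                        "count"])
    a = tf_activity(table, genes[:20], genes[20:])
    b = tf_activity(table, genes[20:], genes[:20])
    np.testing.assert_allclose(np.array(a.loc["M", "folds"]),
                               1 / np.array(b.loc["M", "folds"]), rtol=1e-12)


def test_tf_activity_permutation_null_centred_at_one(rng):
    genes = [f"G{i:03d}" for i in range(80)]
    rows = [(g, "M", u, s, rng.poisson(2)) for g in genes
            for u in (300, 600, 1000) for s in (0.8, 0.9, 0.95)]
    table = pd.DataFrame(rows, columns=["gene", "motif", "upstream", "stringency",
                                        "count"])
    folds = []
    for _ in range(50):
        perm = list(rng.permutation(genes))
        folds.append(tf_activity(table, perm[:20], perm[20:]).loc["M", "mean_fold"])
    assert np.mean(folds) == pytest.approx(1.0, abs=0.05)


def test_tf_activity_input_validation(rng):
    table = pd.DataFrame({"gene": ["A"], "motif": ["M"], "upstream": [300],
                          "stringency": [0.8], "count": [1]})
    with pytest.raises(ValueError, match="nonempty"):
        tf_activity(table, [], ["A"])
    with pytest.raises(ValueError, match="disjoint"):
        tf_activity(table, ["A"], ["A"])


def test_tf_activity_all_zero_combination_stays_finite():
    rows = [(g, "M", u, s, 0) for g in ("A", "B", "C", "D")
            for u in (300,) for s in (0.8, 0.9)]
    table = pd.DataFrame(rows, columns=["gene", "motif", "upstream", "stringency",
                                        "count"])
    res = tf_activity(table, ["A", "B"], ["C", "D"])
    assert np.isfinite(res.loc["M", "mean_fold"])
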