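import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fsatool import (
    Alignment,
    PSSM,
    information_content,
    pssm_from_alignment,
    read_psiblast_pssm,
    write_psiblast_pssm,
)
from fsatool.alignment import AA_ORDER
from fsatool.errors import PssmFormatError, PssmParseError, UndefinedColumnError

LETTERS = "  ".join(AA_ORDER)


def _fixture_row(pos, res, logodds, pct, info, weight):
    return (
        f"{pos:5d} {res}  "
        + " ".join(str(v) for v in logodds)
        + "  "
        + " ".join(str(v) for v in pct)
        + f"  {info} {weight}"
    )


def _pct(**kw):
    row = [0] * 20
    for aa, v in kw.items():
        row[AA_ORDER.index(aa)] = v
    return row


#: Hand-written 3-position fixture in the psiblast ASCII dialect.
FIXTURE_PCT = [
    _pct(A=100),
    _pct(D=50, E=50),
    _pct(K=25, R=25, S=30, G=20),
]
FIXTURE_LOGODDS = [
    _pct(A=7, R=-3),
    _pct(D=5, E=4, A=-2),
    _pct(K=3, R=2, S=2, G=1),
]
FIXTURE_INFO = [4.32, 3.32, 2.03]


def write_fixture(path):
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + LETTERS + "   " + LETTERS,
    ]
    for i, res in enumerate("ADK"):
        lines.append(
            _fixture_row(
                i + 1, res, FIXTURE_LOGODDS[i], FIXTURE_PCT[i], FIXTURE_INFO[i], "1.00"
            )
        )
    lines += ["", "                      K         Lambda"]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestPsiblastReader:
    def test_fixture_cells_read_exactly(self, tmp_path):
        pssm = read_psiblast_pssm(write_fixture(tmp_path / "f.pssm"))
        assert pssm.query == "ADK"
        assert pssm.length == 3
        np.testing.assert_array_equal(pssm.freq, np.array(FIXTURE_PCT) / 100.0)
        np.testing.assert_array_equal(pssm.logodds, np.array(FIXTURE_LOGODDS, float))
        np.testing.assert_array_equal(pssm.info, FIXTURE_INFO)

    def test_pure_column_gives_unit_frequency(self, tmp_path):
        pssm = read_psiblast_pssm(write_fixture(tmp_path / "f.pssm"))
        assert pssm.freq[0, AA_ORDER.index("A")] == 1.0
        assert pssm.freq[0].sum() == 1.0

    def test_truncated_after_header_is_format_error(self, tmp_path):
        f = tmp_path / "trunc.pssm"
        f.write_text("\nheader text\n            " + LETTERS + "   " + LETTERS + "\n")
        with pytest.raises(PssmFormatError, match="truncated"):
            read_psiblast_pssm(f)

    def test_missing_percentage_block_is_format_error(self, tmp_path):
        f = tmp_path / "short.pssm"
        f.write_text(
            "\n            "
            + LETTERS
            + "   "
            + LETTERS
            + "\n    1 A  "
            + " ".join(["0"] * 20)
            + "\n"
        )
        with pytest.raises(PssmFormatError, match="percentage"):
            read_psiblast_pssm(f)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        f = tmp_path / "bad.pssm"
        row = _fixture_row(1, "A", _pct(A=7), _pct(A=100), "oops", "1.0")
        f.write_text("\n            " + LETTERS + "   " + LETTERS + "\n" + row + "\n")
        with pytest.raises(PssmParseError, match=r":3:"):
            read_psiblast_pssm(f)

    def test_rounded_down_percentages_are_renormalized(self, tmp_path):
        f = tmp_path / "r.pssm"
        pct = _pct(D=33, E=33, A=33)  # sums to 99, as psiblast rounding produces
        row = _fixture_row(1, "D", _pct(D=1), pct, "1.0", "1.0")
        body = "\n            " + LETTERS + "   " + LETTERS + "\n"
        f.write_text(body + "\n".join(_fixture_row(i + 1, "D", _pct(D=1), pct, "1.0", "1.0") for i in range(2)) + "\n")
        pssm = read_psiblast_pssm(f)
        assert pssm.freq[0].sum() == pytest.approx(1.0, abs=1e-12)
        assert pssm.metadata["renormalized_rows"] == [1, 2]

    def test_roundtrip_is_bit_exact_for_fixture(self, tmp_path):
        first = read_psiblast_pssm(write_fixture(tmp_path / "f.pssm"))
        write_psiblast_pssm(first, tmp_path / "g.pssm")
        second = read_psiblast_pssm(tmp_path / "g.pssm")
        np.testing.assert_array_equal(first.freq, second.freq)
        np.testing.assert_array_equal(first.logodds, second.logodds)
        np.testing.assert_array_equal(first.info, second.info)
        assert first.query == second.query


class TestPssmFromAlignment:
    def test_pure_column_zero_pseudocount(self):
        aln = Alignment.from_records([("s%d" % i, "A") for i in range(4)])
        pssm = pssm_from_alignment(aln, pseudocount=0.0)
        assert pssm.freq[0, AA_ORDER.index("A")] == 1.0
        assert pssm.info[0] == pytest.approx(math.log2(20), abs=1e-12)

    def test_uniform_column_has_zero_information(self):
        aln = Alignment.from_records([(f"s{i}", aa) for i, aa in enumerate(AA_ORDER)])
        pssm = pssm_from_alignment(aln, pseudocount=0.0)
        assert pssm.info[0] == pytest.approx(0.0, abs=1e-12)

    def test_toy_column_matches_manual_calculation(self):
        # 3 x D, 2 x E, pseudocount 1, uniform background
        aln = Alignment.from_records([("a", "D"), ("b", "D"), ("c", "D"), ("d", "E"), ("e", "E")])
        pssm = pssm_from_alignment(aln, pseudocount=1.0)
        # manual: p(D) = (3 + 1/20) / 6, p(E) = (2 + 1/20) / 6, others (1/20)/6
        pD, pE, pOther = 3.05 / 6, 2.05 / 6, 0.05 / 6
        assert pssm.freq[0, AA_ORDER.index("D")] == pytest.approx(pD, abs=1e-12)
        assert pssm.freq[0, AA_ORDER.index("E")] == pytest.approx(pE, abs=1e-12)
        assert pssm.freq[0, AA_ORDER.index("A")] == pytest.approx(pOther, abs=1e-12)
        ent = -(pD * math.log2(pD) + pE * math.log2(pE) + 18 * pOther * math.log2(pOther))
        assert pssm.info[0] == pytest.approx(math.log2(20) - ent, abs=1e-12)
        # log-odds in bits against the uniform background
        assert pssm.logodds[0, AA_ORDER.index("D")] == pytest.approx(
            math.log2(pD / 0.05), abs=1e-12
        )

    def test_reference_gap_columns_dropped(self):
        aln = Alignment.from_records([("ref", "M-K"), ("s1", "MAK"), ("s2", "MAK")])
        pssm = pssm_from_alignment(aln)
        assert pssm.query == "MK"
        assert pssm.length == 2

    def test_column_without_usable_characters_rejected(self):
        aln = Alignment.from_records([("ref", "MXK"), ("s1", "M-K"), ("s2", "MXK")])
        with pytest.raises(UndefinedColumnError, match="2"):
            pssm_from_alignment(aln)

    def test_low_coverage_columns_flagged_but_computed(self):
        aln = Alignment.from_records(
            [("ref", "MK"), ("s1", "M-"), ("s2", "M-"), ("s3", "M-"), ("s4", "MK")]
        )
        pssm = pssm_from_alignment(aln)
        assert pssm.metadata["low_coverage_positions"] == [2]
        assert pssm.length == 2

    @given(
        st.lists(
            st.text(alphabet=AA_ORDER, min_size=6, max_size=6),
            min_size=2,
            max_size=8,
        ),
        st.floats(min_value=0.01, max_value=5.0),
    )
    def test_frequency_rows_sum_to_one(self, seqs, pseudocount):
        aln = Alignment.from_records([(f"s{i}", s) for i, s in enumerate(seqs)])
        pssm = pssm_from_alignment(aln, pseudocount=pseudocount)
        np.testing.assert_allclose(pssm.freq.sum(axis=1), 1.0, atol=1e-9)

    def test_information_non_increasing_toward_uniform(self):
        rng = np.random.default_rng(7)
        p = rng.dirichlet(np.full(20, 0.3))
        u = np.full(20, 1 / 20)
        infos = [
            information_content((1 - t) * p + t * u) for t in np.linspace(0, 1, 11)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(infos, infos[1:]))

    def test_random_pssm_roundtrips_through_writer(self, tmp_path):
        rng = np.random.default_rng(3)
        freq = rng.dirichlet(np.ones(20), size=5)
        pssm = PSSM(
            query="MKVLR",
            freq=freq,
            logodds=np.log2(freq / 0.05),
            info=np.asarray(information_content(freq)),
        )
        write_psiblast_pssm(pssm, tmp_path / "w.pssm", fmt="%.17g")
        back = read_psiblast_pssm(tmp_path / "w.pssm")
        # percent scaling costs at most one rounding step per cell
        np.testing.assert_allclose(back.freq, pssm.freq, rtol=1e-15, atol=0)
        np.testing.assert_array_equal(back.info, pssm.info)
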