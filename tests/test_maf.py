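"""MAF grammar: parsing, canonical serialization, block validation."""

import pytest
from hypothesis import given, settings, strategies as st

from mafco.maf import (
    ELine, ILine, MSAB, MafFile, MafFormatError, QLine, SLine,
    parse_maf, serialize_maf, validate_msab,
)
from mafco.synth import GenParams, generate_maf

SIMPLE = "a score=23\ns hg18.chr1 100 8 + 247249719 ACGT--ACGT\n"


def test_parse_single_block_fields():
    maf = parse_maf(SIMPLE)
    assert len(maf.blocks) == 1
    block = maf.blocks[0]
    assert block.a_line_text == " score=23"
    row = block.rows[0]
    assert (row.source, row.start, row.size, row.strand, row.src_size) == (
        "hg18.chr1", 100, 8, "+", 247249719
    )
    assert row.text == "ACGT--ACGT"
    assert row.size == sum(c != "-" for c in row.text)


def test_parse_empty_input():
    maf = parse_maf("")
    assert maf.blocks == [] and maf.header_lines == []


def test_header_only_file_round_trips():
    text = "##maf version=1\n"
    maf = parse_maf(text)
    assert maf.header_lines == ["##maf version=1"]
    assert serialize_maf(maf) == text


def test_serialize_s_line_format():
    row = SLine("hg18.chr1", 100, 8, "+", 247249719, "ACGT--ACGT")
    maf = MafFile(blocks=[MSAB(a_line_text=" score=23", rows=[row],
                               inter_block_blank_lines=0)])
    assert serialize_maf(maf) == SIMPLE


@pytest.mark.parametrize("bad, match", [
    ("x foo\n", "unknown line type"),
    ("a score=1\nq hg18.chr1 999\n", "no preceding 's'"),
    ("a score=1\ni hg18.chr1 C 0 C 0\n", "no preceding 's'"),
    ("a s=1\ns a.b 0 2 + 10 AC\ns c.d 0 3 + 10 ACG\n", "column count"),
    ("a s=1\ns a.b 0 2 + 10 AC\nq other.src 99\n", "does not match"),
    ("a s=1\ns a.b 0 2 + 10 AC\nq a.b 999\n", "length"),
    ("a s=1\ns a.b 0 2 * 10 AC\n", "strand"),
    ("a s=1\ns a.b 0 2 + 10 AXC\n", "invalid alignment"),
    ("a s=1\ns a.b 0 2 + 10 AC\n\ns c.d 0 2 + 9 GG\n", "outside of a block"),
])
def test_parse_errors_carry_line_numbers(bad, match):
    with pytest.raises(MafFormatError, match=match):
        parse_maf(bad)


def test_parse_error_reports_offending_line():
    with pytest.raises(MafFormatError) as err:
        parse_maf("a score=1\ns a.b 0 2 + 10 AC\nx oops\n")
    assert err.value.line_number == 3


def test_padded_input_is_normalized_and_flagged():
    padded = "a score=23\ns hg18.chr1   100 8 + 247249719 ACGT--ACGT\n"
    maf = parse_maf(padded)
    assert maf.was_normalized
    assert serialize_maf(maf) == SIMPLE  # canonical form, not the input


def test_blank_line_separators_are_counted():
    text = "##maf version=1\n\na s=1\ns a.b 0 2 + 10 AC\n\n\na s=2\ns a.b 2 2 + 10 GG\n\n"
    maf = parse_maf(text)
    assert [b.inter_block_blank_lines for b in maf.blocks] == [1, 2]
    assert maf.trailing_blank_lines == 1
    assert serialize_maf(maf) == text


def test_q_and_i_attach_to_preceding_s_line():
    text = (
        "a score=1\n"
        "s hg18.chr1 0 4 + 100 ACGT\n"
        "s mm9.chr2 5 3 + 200 AC-T\n"
        "q mm9.chr2 99-9\n"
        "i mm9.chr2 C 0 I 42\n"
        "e rn4.chr3 7 11 + 300 I\n"
    )
    maf = parse_maf(text)
    block = maf.blocks[0]
    assert block.rows[0].q_line is None and block.rows[0].i_line is None
    assert block.rows[1].q_line.values == "99-9"
    assert block.rows[1].i_line == ILine("C", 0, "I", 42)
    assert block.e_lines == [ELine("rn4.chr3", 7, 11, "+", 300, "I")]
    assert serialize_maf(maf) == text


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("profile_kwargs", [
    dict(include_q=False, include_i=False, include_e=False),
    dict(include_q=True, include_i=True, include_e=True),
    dict(include_q=False, include_i=True, include_e=True, p_short_block=0.4),
])
def test_round_trip_on_generated_files(seed, profile_kwargs):
    maf = generate_maf(GenParams(seed=seed, n_blocks=20, **profile_kwargs))
    text = serialize_maf(maf)
    reparsed = parse_maf(text)
    assert not reparsed.was_normalized
    assert serialize_maf(reparsed) == text


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), n_blocks=st.integers(0, 12))
def test_round_trip_property_over_generator_space(seed, n_blocks):
    maf = generate_maf(GenParams(seed=seed, n_blocks=n_blocks))
    text = serialize_maf(maf)
    assert serialize_maf(parse_maf(text)) == text


# --- validate_msab: one positive and one negative case per rule ---

def _block(**kwargs):
    defaults = dict(source="hg18.chr1", start=0, size=4, strand="+",
                    src_size=100, text="AC-GT")
    defaults.update(kwargs)
    defaults["size"] = kwargs.get("size", len(defaults["text"]) -
                                  defaults["text"].count("-"))
    return MSAB(a_line_text=" score=0", rows=[SLine(**defaults)])


def test_validate_accepts_consistent_block():
    assert validate_msab(_block(text="AC-GT")) == []


def test_validate_flags_size_mismatch():
    diags = validate_msab(_block(text="AC-GT", size=5))
    assert any("size field" in d for d in diags)


def test_validate_flags_column_count_mismatch():
    block = _block(text="AC-GT")
    block.rows.append(SLine("mm9.chr1", 0, 3, "+", 50, "ACG"))
    assert any("column count" in d for d in validate_msab(block))


def test_validate_q_gap_replication():
    good = _block(text="AC-GT")
    good.rows.append(SLine("mm9.chr1", 0, 4, "+", 50, "AC-GT",
                           q_line=QLine("99-99")))
    assert validate_msab(good) == []
    bad = _block(text="AC-GT")
    bad.rows.append(SLine("mm9.chr1", 0, 4, "+", 50, "AC-GT",
                          q_line=QLine("999-9")))
    assert any("gap mismatch" in d for d in validate_msab(bad))


def test_validate_rejects_q_on_reference_row():
    block = _block(text="AC-GT")
    block.rows[0].q_line = QLine("99-99")
    assert any("reference" in d for d in validate_msab(block))


def test_validate_status_alphabets():
    block = _block(text="AC-GT")
    block.rows[0].i_line = ILine("C", 0, "Q", 1)
    assert any("right status" in d for d in validate_msab(block))
    block2 = _block(text="AC-GT")
    block2.e_lines.append(ELine("rn4.chr1", 0, 5, "+", 10, "n"))
    assert any("invalid status" in d for d in validate_msab(block2))


def test_validate_alignment_alphabet():
    block = _block(text="AC-GT")
    block.rows[0].text = "AC-GU"
    assert any("invalid alignment characters" in d for d in validate_msab(block))
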