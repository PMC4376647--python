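"""Line codecs: stream decomposition, header prediction, block round trips."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from mafco.codecs import (
    CodecConfig, GobDecoder, GobEncoder, SourceState, StreamBundle,
    merge_row, predict_start, split_row,
)
from mafco.maf import ELine, ILine, MSAB, QLine, SLine
from mafco.synth import GenParams, generate_maf

ALPHABET = "AaCcGgTtNn-"


# --- three-stream decomposition (the symbol mapping table) ---

@pytest.mark.parametrize("char, main, extra, case", [
    ("A", 0, None, 0), ("a", 0, None, 1),
    ("C", 1, 0, 0), ("c", 1, 0, 1),
    ("G", 2, None, 0), ("g", 2, None, 1),
    ("T", 3, None, 0), ("t", 3, None, 1),
    ("N", 1, 1, 0), ("n", 1, 1, 1),
    ("-", 4, None, None),
])
def test_symbol_mapping_table(char, main, extra, case):
    b = split_row(char)
    assert b.main == [main]
    assert b.extra == ([extra] if extra is not None else [])
    assert b.case == ([case] if case is not None else [])


def test_split_worked_example():
    b = split_row("AcN-g")
    assert b.main == [0, 1, 1, 4, 2]
    assert b.extra == [0, 1]
    assert b.case == [0, 1, 0, 1]
    assert merge_row(b) == "AcN-g"


def test_merge_examples():
    assert merge_row(StreamBundle([4, 4, 4], [], [])) == "---"
    assert merge_row(StreamBundle([1], [1], [0])) == "N"


def test_split_rejects_foreign_characters():
    with pytest.raises(ValueError):
        split_row("ACGU")


def test_merge_rejects_inconsistent_streams():
    from mafco.coder import CoderIntegrityError
    with pytest.raises(CoderIntegrityError):
        merge_row(StreamBundle([1], [], [0]))  # missing extra bit
    with pytest.raises(CoderIntegrityError):
        merge_row(StreamBundle([0], [], [0, 1]))  # surplus case bit


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.text(alphabet=ALPHABET, max_size=80))
def test_merge_inverts_split(text):
    bundle = split_row(text)
    assert len(bundle.case) == sum(c != "-" for c in text)
    assert len(bundle.extra) == sum(m == 1 for m in bundle.main)
    assert merge_row(bundle) == text


# --- start-offset prediction ---

def _state(last_start=None, last_size=None):
    s = SourceState(0, "x.chr1", 1000)
    s.last_start, s.last_size = last_start, last_size
    return s


def test_contiguous_start_predicts_offset_zero():
    assert predict_start(_state(100, 20), 120) == ("offset", 0)


def test_forward_jump_predicts_positive_offset():
    assert predict_start(_state(100, 20), 150) == ("offset", 30)


def test_negative_offset_falls_back_to_absolute():
    assert predict_start(_state(100, 20), 115) == ("absolute", 115)


def test_no_prior_state_is_absolute():
    assert predict_start(_state(), 7) == ("absolute", 7)
    assert predict_start(None, 7) == ("absolute", 7)


# --- block-level round trips through one GOB ---

def _roundtrip(blocks, config=None):
    enc = GobEncoder(config)
    for b in blocks:
        enc.encode_block(b)
    data = enc.finish()
    dec = GobDecoder(data, config)
    return [dec.decode_block() for _ in blocks], data


def _sblock(text_rows, blank=1, **extra):
    rows = []
    for i, (src, start, text) in enumerate(text_rows):
        rows.append(SLine(src, start, len(text) - text.count("-"),
                          "+", 1000 + i, text))
    return MSAB(a_line_text=" score=1.0", rows=rows,
                inter_block_blank_lines=blank, **extra)


def test_single_row_block_round_trips():
    blocks = [_sblock([("hg18.chr1", 5, "ACGT")])]
    out, _ = _roundtrip(blocks)
    assert out == blocks


def test_all_line_types_round_trip():
    b = _sblock([("hg18.chr1", 0, "AC-GTn"), ("mm9.chrX", 9, "acN--T")])
    b.rows[1].q_line = QLine("99F--8")
    b.rows[1].i_line = ILine("N", 0, "I", 42)
    b.e_lines.append(ELine("rn4.chr2", 77, 5, "-", 4242, "I"))
    out, _ = _roundtrip([b])
    assert out == [b]


def test_pure_e_block_round_trips():
    b = MSAB(a_line_text=" score=0", inter_block_blank_lines=2)
    b.e_lines.append(ELine("rn4.chr2", 77, 5, "+", 4242, "C"))
    out, _ = _roundtrip([b])
    assert out == [b]


def test_size_field_is_recomputed_not_transmitted():
    """A corrupted size cannot be encoded: the encoder refuses it."""
    b = _sblock([("hg18.chr1", 5, "AC-GT")])
    b.rows[0].size = 5  # text has 4 non-gaps
    with pytest.raises(ValueError, match="non-gap"):
        GobEncoder().encode_block(b)


def test_repeat_source_transmits_no_name_bytes():
    name = "averyveryverylongspeciesname.chromosome_42"
    first = _sblock([(name, 0, "ACGT" * 6)])
    repeat = _sblock([(name, 24, "ACGT" * 6)])
    enc1 = GobEncoder()
    enc1.encode_block(first)
    after_first = enc1.enc.bytes_so_far
    enc1.encode_block(repeat)
    second_cost = enc1.enc.bytes_so_far - after_first
    # the repeat block codes id + offset + strand + image, but no name string:
    # far fewer bytes than the name alone would need
    assert second_cost < len(name) // 2
    out, _ = _roundtrip([first, repeat])
    assert out == [first, repeat]


def test_strand_sequence_round_trips():
    blocks = []
    for i, strand in enumerate("-+-"):
        b = _sblock([("hg18.chr1", 10 * i, "ACGT")])
        b.rows[0].strand = strand
        b.rows[0].start = 100 - 10 * i  # also exercises absolute fallback
        blocks.append(b)
    out, _ = _roundtrip(blocks)
    assert [b.rows[0].strand for b in out] == ["-", "+", "-"]
    assert out == blocks


def test_q_gaps_are_skipped_and_reconstructed():
    b = _sblock([("hg18.chr1", 0, "ACAGT"), ("mm9.chr1", 0, "AC-GT")])
    b.rows[1].q_line = QLine("99-9F")
    out, _ = _roundtrip([b])
    assert out[0].rows[1].q_line.values == "99-9F"


def test_reference_row_q_line_is_refused():
    b = _sblock([("hg18.chr1", 0, "ACGT"), ("mm9.chr1", 0, "ACGT")])
    b.rows[0].q_line = QLine("9999")
    with pytest.raises(ValueError, match="reference"):
        GobEncoder().encode_block(b)


def test_skewed_quality_stream_codes_far_below_uniform():
    """A corpus with ~92% '9' qualities costs well under log2(12) bits per
    quality character once the model adapts."""
    import math
    params = GenParams(seed=17, n_blocks=120, include_i=False, include_e=False)
    maf = generate_maf(params)
    with_q = GobEncoder()
    without_q = GobEncoder()
    stripped = []
    for b in maf.blocks:
        with_q.encode_block(b)
        from copy import deepcopy
        s = deepcopy(b)
        for r in s.rows:
            r.q_line = None
        without_q.encode_block(s)
        stripped.append(s)
    n_q_chars = sum(
        sum(c != "-" for c in r.q_line.values)
        for b in maf.blocks for r in b.rows if r.q_line
    )
    assert n_q_chars > 10_000
    delta_bits = (len(with_q.finish()) - len(without_q.finish())) * 8
    bits_per_char = delta_bits / n_q_chars  # includes presence-bit overhead
    assert bits_per_char < math.log2(12) / 2


def test_block_without_q_costs_one_presence_symbol():
    b = _sblock([("hg18.chr1", 0, "ACGT"), ("mm9.chr1", 0, "ACGT")])
    enc = GobEncoder()
    enc.encode_block(b)
    # the q-presence model saw exactly one event (the block-level 0 bit)
    assert sum(enc.m.q_block.c) == 1
    assert sum(enc.m.q_line.c) == 0


def test_i_first_occurrence_transmits_all_four_fields():
    b = _sblock([("hg18.chr1", 0, "ACGT"), ("mm9.chr1", 0, "ACGT")])
    b.rows[1].i_line = ILine("N", 0, "C", 7)
    enc = GobEncoder()
    enc.encode_block(b)
    # four status/count fields, no irregularity bits yet
    assert sum(enc.m.i_irr_status.c) == 0
    assert sum(enc.m.i_irr_count.c) == 0
    out, _ = _roundtrip([b])
    assert out == [b]


def test_i_count_irregularity_is_independent_of_status():
    """left_count != previous right_count with matching status sets exactly
    the count irregularity bit."""
    b1 = _sblock([("hg18.chr1", 0, "ACGT"), ("mm9.chr1", 0, "ACGT")])
    b1.rows[1].i_line = ILine("N", 0, "C", 7)
    b2 = _sblock([("hg18.chr1", 4, "ACGT"), ("mm9.chr1", 4, "ACGT")])
    b2.rows[1].i_line = ILine("C", 99, "C", 0)  # status regular, count not
    enc = GobEncoder()
    enc.encode_block(b1)
    enc.encode_block(b2)
    assert enc.m.i_irr_status.c[:2] == [1, 0]  # one regular-status event
    assert enc.m.i_irr_count.c[:2] == [0, 1]   # one irregular-count event
    out, _ = _roundtrip([b1, b2])
    assert out == [b1, b2]


def test_i_regular_chain_transmits_no_left_fields():
    blocks = []
    start = 0
    for k in range(30):
        b = _sblock([("hg18.chr1", start, "ACGT"), ("mm9.chr1", start, "ACGT")])
        right = 5 * k
        left = 5 * (k - 1) if k else 0
        b.rows[1].i_line = ILine("I" if k else "N", left, "I", right)
        blocks.append(b)
        start += 4
    enc = GobEncoder()
    for b in blocks:
        enc.encode_block(b)
    # 29 regular events on each irregularity stream, zero irregular ones
    assert enc.m.i_irr_status.c[1::2] == [0] * (len(enc.m.i_irr_status.c) // 2)
    out, _ = _roundtrip(blocks)
    assert out == blocks


def test_e_status_chain_and_irregularity():
    blocks = []
    for k in range(10):
        b = MSAB(a_line_text=" score=0", inter_block_blank_lines=1)
        status = "I" if k != 5 else "C"  # one irregularity at block 5
        b.e_lines.append(ELine("rn4.chr2", 100, 50, "+", 999, status))
        blocks.append(b)
    enc = GobEncoder()
    for b in blocks:
        enc.encode_block(b)
    irregular_events = sum(enc.m.e_irr_e.c[1::2])
    assert irregular_events == 2  # I->C and C->I transitions
    out, _ = _roundtrip(blocks)
    assert out == blocks


def test_e_for_unseen_source_sends_full_header():
    b = MSAB(a_line_text=" score=0", inter_block_blank_lines=1)
    b.e_lines.append(ELine("brandnew.chr9", 1234, 56, "+", 777777, "M"))
    out, _ = _roundtrip([b])
    assert out == [b]


def test_vertical_redundancy_is_exploited():
    """A block whose third row repeats the first compresses smaller than
    three unrelated rows under the same fresh models."""
    rng = random.Random(0)
    base = "".join(rng.choice("ACGT") for _ in range(400))
    other = "".join(rng.choice("ACGT") for _ in range(400))
    third_same = _sblock([("a.c1", 0, base), ("b.c1", 0, other), ("c.c1", 0, base)])
    third_diff = _sblock([("a.c1", 0, base), ("b.c1", 0, other),
                          ("c.c1", 0, "".join(rng.choice("ACGT") for _ in range(400)))])
    _, data_same = _roundtrip([third_same])
    _, data_diff = _roundtrip([third_diff])
    assert len(data_same) < len(data_diff)


def test_all_gap_image_codes_far_below_uniform():
    import math
    enc = GobEncoder()
    before = enc.enc.bytes_so_far
    enc._encode_image(["-" * 20] * 20)
    image_bits = (enc.enc.bytes_so_far - before + 8) * 8  # +slack for buffering
    uniform_bits = 20 * 20 * math.log2(5)
    assert image_bits < uniform_bits / 3


def test_integer_coding_round_trips():
    rng = random.Random(4)
    values = [0, 247249719] + [rng.randrange(10 ** 12) for _ in range(200)]
    enc = GobEncoder()
    for v in values:
        enc._encode_int(v)
    dec = GobDecoder(enc.finish())
    assert [dec._decode_int() for _ in values] == values


def test_negative_integer_rejected():
    with pytest.raises(ValueError):
        GobEncoder()._encode_int(-1)


def test_encoder_decoder_states_mirror_after_every_block():
    """Model count digests agree between encoder and decoder block by block."""
    maf = generate_maf(GenParams(seed=42, n_blocks=12))
    enc = GobEncoder()
    for b in maf.blocks:
        enc.encode_block(b)
    data = enc.finish()
    dec = GobDecoder(data)

    def digest(bank):
        import hashlib
        h = hashlib.sha256()
        h.update(repr(sorted(bank.main_counts.items())).encode())
        for name in ("extra", "case", "start_flag", "strand", "q_block",
                     "q_line", "i_block", "i_line", "i_irr_status",
                     "i_irr_count", "e_irr_e", "e_irr_i"):
            h.update(repr(getattr(bank, name).c).encode())
        for name in ("q_vals", "i_status", "e_status"):
            h.update(repr(sorted(getattr(bank, name).model.counts.items())).encode())
        return h.hexdigest()

    enc2 = GobEncoder()
    for b in maf.blocks:
        enc2.encode_block(b)
        decoded = dec.decode_block()
        assert decoded == b
        assert digest(enc2.m) == digest(dec.m)


def test_offset_mode_dominates_on_contiguous_corpora():
    """>=95% of start fields ride the offset stream at zero when the
    generator emits contiguous blocks."""
    maf = generate_maf(GenParams(seed=9, n_blocks=300, contiguity_rate=1.0,
                                 include_e=False))
    from mafco.codecs import predict_start as ps
    states = {}
    n_offset0 = n_total = 0
    for block in maf.blocks:
        updates = []
        for row in block.rows:
            st = states.get(row.source)
            if st is not None:
                mode, value = ps(st, row.start)
                n_total += 1
                n_offset0 += (mode == "offset" and value == 0)
            else:
                states[row.source] = st = _state()
            updates.append((st, row.start, row.size))
        for st, start, size in updates:
            st.last_start, st.last_size = start, size
    assert n_total > 500
    assert n_offset0 / n_total >= 0.95


def test_config_is_validated():
    with pytest.raises(ValueError):
        CodecConfig(alpha=0)
    with pytest.raises(ValueError):
        CodecConfig(order_strand=-1)
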