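"""Codec: text <-> bit grids, addressing, scramble/descramble, spacing."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ddckit.codec import (
    MessageGrid,
    PlainMessage,
    apply_spacing,
    assign_address,
    decode_grids,
    decode_text,
    descramble,
    encode_message,
    encode_text,
    get_scheme,
    render_ciphertext,
    scramble,
)
from ddckit.errors import CapacityError, EncodingError, StateError

A5 = get_scheme("a5")

# strategy for encodable messages: 1-4 words of 1-5 uppercase letters
words_st = st.lists(
    st.text(alphabet=st.sampled_from("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), min_size=1, max_size=5),
    min_size=1,
    max_size=4,
)
messages_st = words_st.map(" ".join)


class TestEncode:
    def test_one_grid_per_word(self):
        grids = encode_text("DNA NANO TECH", A5)
        assert len(grids) == 3
        assert all(not g.scrambled for g in grids)
        assert all(g.address_bits.sum() == 0 for g in grids)

    def test_empty_message_gives_no_grids(self):
        assert encode_text("", A5) == []

    def test_unencodable_character_raises(self):
        with pytest.raises(EncodingError, match="'7'"):
            encode_text("DNA7", A5)

    def test_word_too_long_names_the_word(self):
        with pytest.raises(CapacityError, match="TOOLONGW"):
            encode_text("TOOLONGW", A5)

    def test_every_alphabet_character_round_trips(self):
        # exhaustive brute-force round-trip oracle over the full alphabet
        for ch in A5.alphabet_map:
            if ch == " ":
                continue
            out = decode_text(encode_text(ch, A5), A5)
            assert out.text == ch

    def test_ascii8_round_trips_mixed_case_word(self):
        ascii8 = get_scheme("ascii8")
        grids = encode_text("DnaNano", ascii8)
        assert len(grids) > 1  # word spans carriers at 3 chars each
        grids = [assign_address(g, i, ascii8) for i, g in enumerate(grids)]
        assert decode_text(grids, ascii8).text == "DnaNano"


class TestSpacing:
    def test_two_char_word_gets_blank_middle_column(self):
        (grid,) = encode_text("AB", A5)
        assert grid.message_bits[:, 1].sum() == 0
        assert grid.message_bits[:, 0].any() and grid.message_bits[:, 2].any()

    def test_dna_has_blank_between_character_columns(self):
        (grid,) = encode_text("DNA", A5)
        # characters at columns 0, 2, 4; blanks at 1 and 3
        assert grid.message_bits[:, 1].sum() == 0
        assert grid.message_bits[:, 3].sum() == 0

    @given(word=st.text(alphabet=st.sampled_from("ABCXYZ"), min_size=2, max_size=2))
    def test_spacing_conserves_bit_count(self, word):
        # conservation checked by direct counting against the dense layout
        dense = encode_text(word, get_scheme("ascii8"))  # no-spacing scheme unused here
        (grid,) = encode_text(word, A5)
        codes = [A5.alphabet_map[c] for c in word]
        expected = sum(bin(c).count("1") for c in codes)
        assert int(grid.message_bits.sum()) == expected

    def test_overlong_word_drops_spacing_but_encodes(self, caplog):
        (grid,) = encode_text("NANO", A5)  # 4 chars need 7 columns for spacing
        assert grid.message_bits[:, :4].any(axis=0).all()

    def test_strict_spacing_raises_on_insufficient_columns(self):
        grid = MessageGrid(np.zeros((5, 5)), np.zeros((1, 5)), n_chars=4)
        grid.message_bits[0, :4] = 1
        with pytest.raises(CapacityError):
            apply_spacing(grid, A5, strict=True)


class TestAddress:
    def test_index_zero_is_all_zeros(self):
        (g,) = encode_text("A", A5)
        assert assign_address(g, 0, A5).address_bits.sum() == 0

    def test_index_five_is_00101(self):
        (g,) = encode_text("A", A5)
        assert assign_address(g, 5, A5).address_bits.tolist() == [[0, 0, 1, 0, 1]]

    def test_all_32_indices_read_back(self):
        (g,) = encode_text("A", A5)
        for i in range(32):
            assert assign_address(g, i, A5).word_index == i

    def test_out_of_range_index_raises(self):
        (g,) = encode_text("A", A5)
        with pytest.raises(CapacityError):
            assign_address(g, 32, A5)

    def test_address_capacity_is_32(self):
        assert A5.address_capacity == 32


def _random_grid(rng, word_index=None):
    g = MessageGrid(rng.integers(0, 2, (5, 5)), np.zeros((1, 5)))
    return assign_address(g, word_index if word_index is not None else int(rng.integers(0, 32)))


class TestScramble:
    def test_word_zero_leaves_column_zero_unchanged(self):
        rng = np.random.default_rng(3)
        g = _random_grid(rng, word_index=0)
        s = scramble(g)
        assert np.array_equal(s.message_bits[:, 0], g.message_bits[:, 0])

    def test_scramble_descramble_is_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            g = _random_grid(rng)
            assert descramble(scramble(g)).same_bits(g)

    def test_scramble_conserves_bit_count(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            g = _random_grid(rng)
            assert scramble(g).message_bits.sum() == g.message_bits.sum()

    def test_double_scramble_raises(self):
        g = scramble(_random_grid(np.random.default_rng(6)))
        with pytest.raises(StateError):
            scramble(g)

    def test_descramble_of_unscrambled_raises(self):
        with pytest.raises(StateError):
            descramble(_random_grid(np.random.default_rng(7)))

    def test_all_zero_grid_is_fixed_point_for_any_address(self):
        for i in range(32):
            g = assign_address(MessageGrid(np.zeros((5, 5)), np.zeros((1, 5))), i)
            assert scramble(g).message_bits.sum() == 0

    def test_composition_is_identity_permutation_for_all_addresses(self):
        # brute force over the address space with explicit permutation matrices
        for w in range(32):
            perm = np.zeros((25, 25), dtype=int)
            for src in range(25):
                # single-1 grid marking position src
                single = (np.arange(25) == src).reshape(5, 5).astype(np.uint8)
                g = assign_address(MessageGrid(single, np.zeros((1, 5))), w)
                dst = int(np.flatnonzero(scramble(g).message_bits.ravel())[0])
                perm[dst, src] = 1
            inv = np.zeros_like(perm)
            for src in range(25):
                g = assign_address(
                    MessageGrid((np.arange(25) == src).reshape(5, 5).astype(np.uint8),
                                np.zeros((1, 5))), w)
                g.scrambled = True
                dst = int(np.flatnonzero(descramble(g).message_bits.ravel())[0])
                inv[dst, src] = 1
            assert np.array_equal(inv @ perm, np.eye(25, dtype=int))

    def test_descramble_depends_only_on_address_and_shape(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b = _random_grid(rng, 9), _random_grid(rng, 9)
            sa, sb = scramble(a), scramble(b)
            # apply the inverse derived from a's address to b's content: must
            # equal b's own descramble since addresses match
            sb_clone = sb.copy()
            sb_clone.address_bits = sa.address_bits.copy()
            assert descramble(sb_clone).same_bits(descramble(sb))

    def test_ciphertext_differs_from_plaintext(self):
        grids = encode_message("DNA NANO TECH", A5)
        cipher = " ".join(render_ciphertext(g, A5) for g in grids)
        assert cipher != "DNA NANO TECH"


class TestDecode:
    def test_full_phrase_round_trip(self):
        assert decode_grids(encode_message("DNA NANO TECH", A5), A5).text == "DNA NANO TECH"

    def test_all_zero_grids_decode_to_empty_string(self):
        zeros = [MessageGrid(np.zeros((5, 5)), np.zeros((1, 5)))]
        assert decode_text(zeros, A5).text == ""

    def test_decode_requires_descrambled_grids(self):
        grids = encode_message("DNA", A5)
        with pytest.raises(StateError):
            decode_text(grids, A5)

    def test_unknown_codes_degrade_to_fallback_glyph(self):
        bits = np.zeros((5, 5), dtype=np.uint8)
        bits[:, 0] = [1, 1, 0, 1, 1]  # code 27: outside the A-Z alphabet
        g = MessageGrid(bits, np.zeros((1, 5)))
        assert decode_text([g], A5).text == "?"

    @given(text=messages_st)
    def test_pipeline_round_trip_random_messages(self, text):
        assert decode_grids(encode_message(text, A5), A5).text == text
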