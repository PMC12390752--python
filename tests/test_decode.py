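"""Decoder: conformation calls, bit assignment, message recovery."""

import numpy as np
import pytest

from ddckit.carrier import IC, OFF, ON, UC, site_xy, marker_xy
from ddckit.codec import encode_message, get_scheme
from ddckit.decode import (
    assign_spots,
    classify_conformation,
    decode_message,
    find_spots,
    read_ciphertext,
)
from ddckit.errors import StateError
from ddckit.simulate import ReadoutParams, SpotField, render_raster, simulate_structure

A5 = get_scheme("a5")

NOISELESS = ReadoutParams(p_user=1.0, p_ic=0.0, q=1.0, fp_rate=0.0, loc_sigma_nm=0.0)


def _noiseless_field(design, grid, key, conf_params=NOISELESS, seed=0):
    return simulate_structure(design, grid, key, conf_params, np.random.default_rng(seed))


@pytest.fixture(scope="module")
def dna_grid():
    return encode_message("DNA")[0]


class TestClassify:
    def test_noiseless_on_geometry_classifies_on(self, ddc1, keys, dna_grid):
        field = _noiseless_field(ddc1, dna_grid, keys[1])
        assert classify_conformation(field, ddc1).category == ON

    def test_noiseless_off_geometry_classifies_off(self, ddc1, dna_grid):
        params = ReadoutParams(p_spont=0.0, p_ic=0.0, q=1.0, loc_sigma_nm=0.0)
        field = _noiseless_field(ddc1, dna_grid, None, params)
        assert field.truth.category == OFF
        assert classify_conformation(field, ddc1).category == OFF

    def test_empty_field_is_uncertain(self, ddc1):
        assert classify_conformation(SpotField(np.empty((0, 2))), ddc1).category == UC

    def test_stalled_intermediate_classifies_ic(self, ddc1, keys, dna_grid):
        params = ReadoutParams(p_user=0.5, p_admin=0.5, p_spont=0.1, p_ic=0.2, q=1.0, loc_sigma_nm=0.0)
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(40):
            f = simulate_structure(ddc1, dna_grid, keys[1], params, rng)
            if f.truth.category == IC:
                hits += 1
                assert classify_conformation(f, ddc1).category == IC
        assert hits > 0

    def test_accuracy_degrades_monotonically_with_noise(self, ddc1, keys, dna_grid):
        accs = []
        for sigma in (0.3, 1.5, 2.8):
            params = ReadoutParams(loc_sigma_nm=sigma)
            rng = np.random.default_rng(44)
            ok = total = 0
            for _ in range(300):
                f = simulate_structure(ddc1, dna_grid, keys[1], params, rng)
                total += 1
                ok += classify_conformation(f, ddc1).category == f.truth.category
            accs.append(ok / total)
        assert accs[0] >= accs[1] >= accs[2]


class TestAssign:
    def test_noiseless_bits_equal_the_grid(self, ddc1, keys, dna_grid):
        field = _noiseless_field(ddc1, dna_grid, keys[1])
        res = assign_spots(field, ddc1, ON)
        truth = np.vstack([dna_grid.address_bits, dna_grid.message_bits])
        assert np.array_equal(res.bits, truth)
        assert res.n_noise == 0 and res.marker_hits == 2

    def test_single_site_dropout_calls_zero_there_only(self, ddc1, keys, dna_grid):
        field = _noiseless_field(ddc1, dna_grid, keys[1])
        truth = np.vstack([dna_grid.address_bits, dna_grid.message_bits])
        # remove the spot of one known biotin site
        r, c = map(int, np.argwhere(truth)[0])
        x, y = site_xy(ddc1, r - 1, c, ON)
        keep = ~np.all(np.isclose(field.xy, [x, y]), axis=1)
        res = assign_spots(SpotField(field.xy[keep]), ddc1, ON)
        expected = truth.copy()
        expected[r, c] = 0
        assert np.array_equal(res.bits, expected)

    def test_assignment_requires_pure_conformation(self, ddc1, dna_grid, keys):
        field = _noiseless_field(ddc1, dna_grid, keys[1])
        with pytest.raises(StateError):
            assign_spots(field, ddc1, IC)

    def test_matches_exhaustive_nearest_site_oracle(self, ddc1):
        # brute-force oracle: per spot, scan every site with plain loops,
        # tie-breaking toward the lower (row, col) index
        rng = np.random.default_rng(7)
        sites = [(r, c) for r in range(-1, 5) for c in range(5)]
        positions = {rc: site_xy(ddc1, rc[0], rc[1], ON) for rc in sites}
        positions_m = {("marker", i): marker_xy(ddc1, i, ON) for i in range(2)}
        all_sites = {**positions, **positions_m}
        ordered = sites + [("marker", 0), ("marker", 1)]
        for _ in range(30):
            n_spots = rng.integers(1, 9)
            chosen = rng.choice(len(ordered), size=n_spots, replace=False)
            xy = np.array([all_sites[ordered[i]] for i in chosen]) + rng.normal(
                0, 0.4, (n_spots, 2)
            )
            res = assign_spots(SpotField(xy), ddc1, ON)
            expected = np.zeros((6, 5), dtype=np.uint8)
            tol = 0.35 * 6.0
            for sx, sy in xy:
                best, best_d = None, np.inf
                for rc in ordered:
                    px, py = all_sites[rc]
                    d = np.hypot(sx - px, sy - py)
                    if d < best_d - 1e-9:
                        best, best_d = rc, d
                if best_d <= tol and best[0] != "marker":
                    expected[best[0] + 1, best[1]] = 1
            assert np.array_equal(res.bits, expected)


class TestDecodeMessage:
    def test_noiseless_matched_key_recovers_word_with_corrinfo(self, ddc1, keys, dna_grid):
        field = _noiseless_field(ddc1, dna_grid, keys[1])
        call = decode_message(field, ddc1, A5, truth=dna_grid)
        assert call.category == ON
        assert call.decoded_text == "DNA"
        assert call.corrinfo is True

    def test_off_conformation_never_decodes(self, ddc1, dna_grid):
        params = ReadoutParams(p_spont=0.0, p_ic=0.0, q=1.0, loc_sigma_nm=0.0)
        field = _noiseless_field(ddc1, dna_grid, None, params)
        call = decode_message(field, ddc1, A5, truth=dna_grid)
        assert call.category == OFF
        assert call.decoded_text is None
        assert call.corrinfo is False

    def test_locked_carrier_reads_as_ciphertext(self, ddc1, dna_grid):
        params = ReadoutParams(p_spont=0.0, p_ic=0.0, q=1.0, loc_sigma_nm=0.0)
        field = _noiseless_field(ddc1, dna_grid, None, params)
        cipher = read_ciphertext(field, ddc1, A5)
        assert cipher is not None and cipher != "DNA"

    def test_corrinfo_implies_on_category(self, ddc1, keys, dna_grid):
        params = ReadoutParams(loc_sigma_nm=0.5)
        rng = np.random.default_rng(9)
        for _ in range(200):
            f = simulate_structure(ddc1, dna_grid, keys[1], params, rng)
            call = decode_message(f, ddc1, A5, truth=dna_grid)
            if call.corrinfo:
                assert call.category == ON

    def test_decoded_corrinfo_tally_equals_simulator_tally(self, ddc1, keys, dna_grid):
        # cross-module consistency: at low localisation noise the decoder
        # reproduces the simulator's own CorrInfo labels structure by structure
        params = ReadoutParams(loc_sigma_nm=0.25)
        rng = np.random.default_rng(10)
        for _ in range(400):
            f = simulate_structure(ddc1, dna_grid, keys[1], params, rng)
            call = decode_message(f, ddc1, A5, truth=dna_grid)
            assert bool(call.corrinfo) == f.truth.corrinfo


class TestRasterPath:
    def test_peak_finder_recovers_noiseless_spot_positions(self, ddc1, keys, dna_grid):
        field = _noiseless_field(ddc1, dna_grid, keys[1])
        pixel = 1.0
        image, origin = render_raster(field, pixel_nm=pixel, psf_sigma_nm=2.0)
        found = find_spots(image, origin, pixel, min_intensity_rel=0.3)
        assert found.n_spots == field.n_spots
        # every true spot recovered within one pixel
        for xy in field.xy:
            d = np.min(np.linalg.norm(found.xy - xy, axis=1))
            assert d <= pixel
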