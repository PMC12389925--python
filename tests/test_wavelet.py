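"""Windowed DWT engine: counts, trimming, scaleogram algebra, inversion."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from eegdenoise.wavelet import (
    Window,
    build_scaleogram,
    collapse_scaleogram,
    decompose_window,
    denormalize_scaleogram,
    max_level,
    normalize_scaleogram,
    reconstruct,
    LevelCoeffs,
)


# --- independent filter-bank oracle -----------------------------------------
# One level of the periodized orthogonal DWT is a circular correlation with the
# decomposition filters followed by downsampling by 2; for a filter of length L
# the output is aligned as c[k] = sum_n f[n] x[(2k + L/2 - n) mod N].  The
# multi-level oracle recurses on the approximation.

def _dwt_level_oracle(x, wavelet):
    w = pywt.Wavelet(wavelet)
    lo, hi = np.array(w.dec_lo), np.array(w.dec_hi)
    L = len(lo)
    N = x.size
    idx = (2 * np.arange(N // 2)[:, None] + L // 2 - np.arange(L)[None, :]) % N
    return x[idx] @ lo, x[idx] @ hi


def _wavedec_oracle(x, wavelet, level):
    details = []
    approx = x
    for _ in range(level):
        approx, d = _dwt_level_oracle(approx, wavelet)
        details.append(d)
    return approx, details


def _padded_input(current, previous, n):
    conc = np.concatenate([previous, current])
    return pywt.pad(conc, (0, n), mode="smooth")


# --- decomposition -----------------------------------------------------------

@pytest.mark.parametrize("wavelet", ["db4", "sym4"])
def test_level_counts_and_shapes(wavelet, rng):
    """A 1024-sample window yields n/2**m coefficients per level and an 8x512 scaleogram."""
    w = Window(rng.standard_normal(1024), 0, 1024.0)
    coeffs = decompose_window(w, None, wavelet)
    assert coeffs.n_levels == 7  # floor(log2(1024 / 7))
    for m in range(1, 8):
        assert coeffs.details[m - 1].size == 1024 >> m
    assert coeffs.approximation.size == 8
    scal = build_scaleogram(coeffs)
    assert scal.matrix.shape == (8, 512)


def test_zero_window_gives_zero_coefficients():
    w = Window(np.zeros(256), 0, 256.0)
    coeffs = decompose_window(w, Window(np.zeros(256), -1, 256.0), "db4")
    for d in coeffs.details:
        assert np.all(d == 0)
    assert np.all(coeffs.approximation == 0)


def test_impulse_matches_filter_bank_oracle(rng):
    """Trimmed coefficients of an impulse agree with direct convolve-and-downsample."""
    n = 1024
    cur = np.zeros(n)
    cur[512] = 1.0
    prev = rng.standard_normal(n) * 0.0
    w = Window(cur, 1, 1024.0)
    coeffs = decompose_window(w, Window(prev, 0, 1024.0), "db4")
    padded = _padded_input(cur, prev, n)
    _, details_oracle = _wavedec_oracle(padded, "db4", coeffs.n_levels)
    for m in range(1, coeffs.n_levels + 1):
        expect = details_oracle[m - 1][n >> m : (2 * n) >> m]
        np.testing.assert_allclose(coeffs.details[m - 1], expect, atol=1e-10)
        # energy concentrated at time centres near the impulse (sample n + 512)
        centres = (np.arange(n >> m) + (n >> m)) * (1 << m)
        support = pywt.Wavelet("db4").dec_len * (1 << m)
        far = np.abs(centres - (n + 512)) > support
        assert np.all(np.abs(coeffs.details[m - 1][far]) < 1e-12)


def test_random_window_matches_oracle(rng):
    cur = rng.standard_normal(512)
    prev = rng.standard_normal(512)
    coeffs = decompose_window(Window(cur, 1, 512.0), Window(prev, 0, 512.0), "sym4")
    padded = _padded_input(cur, prev, 512)
    approx_o, details_o = _wavedec_oracle(padded, "sym4", coeffs.n_levels)
    n = 512
    for m in range(1, coeffs.n_levels + 1):
        np.testing.assert_allclose(
            coeffs.details[m - 1], details_o[m - 1][n >> m : (2 * n) >> m], atol=1e-9
        )
    M = coeffs.n_levels
    np.testing.assert_allclose(coeffs.approximation, approx_o[n >> M : (2 * n) >> M], atol=1e-9)


def test_rejects_bad_inputs(rng):
    with pytest.raises(ValueError, match="wavelet"):
        decompose_window(Window(rng.standard_normal(256)), None, "nosuchwave")
    # 136 is not a multiple of 2**M for db4 (M = floor(log2(136/7)) = 4)
    with pytest.raises(ValueError, match="multiple"):
        decompose_window(Window(rng.standard_normal(136)), None, "db4")
    with pytest.raises(ValueError):
        decompose_window(
            Window(rng.standard_normal(256)), Window(rng.standard_normal(128)), "db4"
        )


def test_linearity(rng):
    x = rng.standard_normal(256)
    y = rng.standard_normal(256)
    a, b = 2.5, -1.25
    cx = decompose_window(Window(x), None, "db4")
    cy = decompose_window(Window(y), None, "db4")
    cz = decompose_window(Window(a * x + b * y), None, "db4")
    for m in range(cz.n_levels):
        np.testing.assert_allclose(
            cz.details[m], a * cx.details[m] + b * cy.details[m], atol=1e-9
        )


def test_left_edge_robustness(rng):
    """Shallow-level coefficients away from the left edge ignore the previous window."""
    n = 1024
    cur = rng.standard_normal(n)
    prev_a = rng.standard_normal(n)
    prev_b = rng.standard_normal(n) * 5.0
    ca = decompose_window(Window(cur, 1), Window(prev_a, 0), "db4")
    cb = decompose_window(Window(cur, 1), Window(prev_b, 0), "db4")
    L = pywt.Wavelet("db4").dec_len
    for m in range(1, 5):  # shallow levels, support << n
        support_coeffs = L  # support in units of level-m coefficients
        da, db = ca.details[m - 1], cb.details[m - 1]
        np.testing.assert_allclose(da[support_coeffs:], db[support_coeffs:], atol=1e-10)


# --- scaleogram algebra ------------------------------------------------------

def test_replication_rule():
    """Level-2 coefficients [a, b] spread to [a, a, b, b] on a k=4 time axis."""
    coeffs = LevelCoeffs(
        details=[np.array([1.0, 2.0, 3.0, 4.0]), np.array([10.0, 20.0])],
        approximation=np.array([5.0, 6.0]),
        wavelet_name="db4",
    )
    scal = build_scaleogram(coeffs)
    np.testing.assert_array_equal(scal.matrix[1], [10.0, 10.0, 20.0, 20.0])
    np.testing.assert_array_equal(scal.matrix[2], [5.0, 5.0, 6.0, 6.0])


def test_build_rejects_inconsistent_levels():
    bad = LevelCoeffs(
        details=[np.arange(4.0), np.arange(3.0)],  # level 2 should hold 2
        approximation=np.arange(3.0),
        wavelet_name="db4",
    )
    with pytest.raises(ValueError, match="level 2"):
        build_scaleogram(bad)


def test_normalization_scales_and_inverts():
    coeffs = LevelCoeffs(
        details=[np.full(8, 8.0), np.full(4, 8.0), np.full(2, 8.0)],
        approximation=np.full(2, 8.0),
        wavelet_name="db4",
    )
    scal = build_scaleogram(coeffs)
    norm = normalize_scaleogram(scal)
    assert norm.normalized
    assert norm.matrix[0, 0] == 4.0  # level 1: 8 / 2
    assert norm.matrix[2, 0] == 1.0  # level 3: 8 / 8
    assert norm.matrix[3, 0] == 1.0  # approximation: 8 / 2**3
    with pytest.raises(ValueError, match="already"):
        normalize_scaleogram(norm)
    back = denormalize_scaleogram(norm)
    np.testing.assert_array_equal(back.matrix, scal.matrix)


def test_collapse_round_trip_and_guard(rng):
    w = Window(rng.standard_normal(512), 3, 512.0)
    coeffs = decompose_window(w, None, "db4")
    scal = build_scaleogram(coeffs)
    with pytest.raises(ValueError, match="normalized"):
        collapse_scaleogram(normalize_scaleogram(scal), coeffs.conc_context)
    back = collapse_scaleogram(scal, coeffs.conc_context)
    for m in range(coeffs.n_levels):
        np.testing.assert_array_equal(back.details[m], coeffs.details[m])
    for a, b in zip(back.conc_context.coeff_arrays, coeffs.conc_context.coeff_arrays):
        np.testing.assert_array_equal(a, b)


def test_collapse_single_column_edit_touches_one_coeff_per_level(rng):
    """Mitigating the group-leading column changes exactly one context coefficient per level."""
    w = Window(rng.standard_normal(512), 0, 512.0)
    coeffs = decompose_window(w, None, "db4")
    scal = build_scaleogram(coeffs)
    edited = scal.matrix.copy()
    edited[:, 0] *= 0.5  # column 0 leads every replication group
    from eegdenoise.wavelet import Scaleogram

    back = collapse_scaleogram(Scaleogram(edited, scal.n_levels), coeffs.conc_context)
    for a, b in zip(back.conc_context.coeff_arrays, coeffs.conc_context.coeff_arrays):
        diff = np.flatnonzero(a != b)
        assert diff.size <= 1  # zero only if that coefficient was already 0


# --- reconstruction ----------------------------------------------------------

@pytest.mark.parametrize("wavelet", ["db4", "sym4"])
def test_round_trip_reconstruction(wavelet, rng):
    cur = Window(rng.standard_normal(1024), 1, 1024.0)
    prev = Window(rng.standard_normal(1024), 0, 1024.0)
    coeffs = decompose_window(cur, prev, wavelet)
    out = reconstruct(coeffs)
    rms = np.sqrt(np.mean(cur.samples**2))
    assert np.abs(out.samples - cur.samples).max() < 1e-8 * rms


def test_zeroed_coefficients_give_zero_output(rng):
    coeffs = decompose_window(Window(rng.standard_normal(256)), None, "db4")
    for arr in coeffs.conc_context.coeff_arrays:
        arr[:] = 0.0
    out = reconstruct(coeffs)
    np.testing.assert_array_equal(out.samples, np.zeros(256))


def test_single_coefficient_edit_is_local(rng):
    """Halving one level-1 coefficient perturbs only samples inside its support."""
    n = 512
    cur = Window(rng.standard_normal(n), 1, 512.0)
    prev = Window(rng.standard_normal(n), 0, 512.0)
    coeffs = decompose_window(cur, prev, "db4")
    base = reconstruct(coeffs).samples
    j = (n >> 1) + 100  # level-1 coefficient index inside the current window
    ctx = coeffs.conc_context
    ctx.coeff_arrays[-1][j] *= 0.5
    edited = reconstruct(coeffs).samples
    diff = np.abs(edited - base)
    centre = j * 2 - n  # sample position within the current window
    L = pywt.Wavelet("db4").rec_len
    far = np.abs(np.arange(n) - centre) > 2 * (L + 2)
    assert np.all(diff[far] < 1e-14)
    assert diff.max() > 0


def test_reconstruct_requires_context():
    orphan = LevelCoeffs([np.zeros(4)], np.zeros(4), "db4", None)
    with pytest.raises(ValueError, match="context"):
        reconstruct(orphan)


@settings(max_examples=20, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    wavelet=st.sampled_from(["db4", "sym4", "db2"]),
    with_prev=st.booleans(),
)
def test_perfect_reconstruction_property(seed, wavelet, with_prev):
    rng = np.random.default_rng(seed)
    cur = Window(rng.standard_normal(256) * 10, 1, 256.0)
    prev = Window(rng.standard_normal(256) * 10, 0, 256.0) if with_prev else None
    out = reconstruct(decompose_window(cur, prev, wavelet))
    rms = np.sqrt(np.mean(cur.samples**2))
    assert np.abs(out.samples - cur.samples).max() < 1e-8 * rms


def test_max_level_rule():
    assert max_level(1024, "db4") == 7  # filter length 8
    assert max_level(256, "db1") == 8  # Haar, filter length 2
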