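"""EMD sifting, ensemble variants, IMF selection and reconstruction."""

import numpy as np
import pytest

from eegsift import (
    DecompositionConfig,
    IMFSet,
    ImfSelection,
    ceemd,
    eemd,
    emd,
    envelope_mean,
    find_extrema,
    reconstruct,
    select_imfs,
    sift_imf,
)
from eegsift.errors import MonotoneRemainder, NoInformativeIMFs, ValidationError
from eegsift.signal_metrics import pearson_pr


class TestFindExtrema:
    @pytest.mark.parametrize(
        "x,maxima,minima",
        [
            ([0, 1, 0, -1, 0], [1], [3]),
            ([1, 2, 3, 4], [], []),
            ([0, 1, 1, 0], [1], []),                  # plateau floor-midpoint
            ([0, -1, -1, -1, 0], [], [2]),            # 3-plateau -> midpoint
            ([0, 2, 0, 3, 0], [1, 3], [2]),
        ],
    )
    def test_cases(self, x, maxima, minima):
        mx, mn = find_extrema(np.array(x, dtype=float))
        assert mx.tolist() == maxima
        assert mn.tolist() == minima

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            find_extrema(np.array([1.0, 2.0]))


class TestEnvelopeMean:
    def test_pure_sinusoid_mean_near_zero(self):
        t = np.linspace(0, 8, 1024, endpoint=False)
        x = np.sin(2 * np.pi * t)  # 8 full cycles
        m = envelope_mean(x)
        central = m[256:768]
        assert np.abs(central).max() < 0.05  # < 5% of unit amplitude

    def test_offset_sinusoid_mean_near_offset(self):
        t = np.linspace(0, 8, 1024, endpoint=False)
        c = 2.5
        m = envelope_mean(c + np.sin(2 * np.pi * t))
        central = m[256:768]
        assert np.abs(central - c).max() < 0.05

    def test_single_maximum_is_monotone_remainder(self):
        x = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 50)])
        with pytest.raises(MonotoneRemainder):
            envelope_mean(x)


class TestSiftImf:
    def test_imf_plus_remainder_is_input(self, rng):
        x = rng.standard_normal(512)
        res = sift_imf(x)
        np.testing.assert_allclose(res.imf + res.remainder, x, atol=1e-12)

    def test_first_imf_tracks_fast_tone(self):
        t = np.arange(1024) / 1000.0
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 50 * t)
        res = sift_imf(x)
        fast = np.sin(2 * np.pi * 50 * t)
        assert pearson_pr(res.imf, fast) > 0.95

    def test_constant_input_flags_completion(self):
        res = sift_imf(np.full(64, 3.0))
        assert res.monotone
        np.testing.assert_array_equal(res.imf, np.zeros(64))


class TestEmd:
    def test_completeness_random_signals(self, rng):
        for _ in range(10):
            x = rng.standard_normal(512)
            d = emd(x)
            assert np.abs(d.reconstruct_full() - x).max() < 1e-8

    def test_pure_tone_energy_in_first_component(self):
        t = np.arange(512) / 512.0
        x = np.sin(2 * np.pi * 16 * t)
        d = emd(x)
        energies = (d.imfs ** 2).sum(axis=1)
        assert energies[0] / energies.sum() > 0.95

    def test_monotone_ramp_all_zero_imfs(self):
        x = np.linspace(0.0, 5.0, 64)
        d = emd(x)
        np.testing.assert_array_equal(d.imfs, np.zeros_like(d.imfs))
        np.testing.assert_array_equal(d.residual, x)
        assert d.n_natural == 0

    def test_fixed_component_count_with_padding(self, rng):
        x = rng.standard_normal(64)
        d = emd(x, DecompositionConfig(n_imfs=9))
        assert d.imfs.shape == (9, 64)
        assert d.n_natural <= 9

    def test_imf_oscillation_and_frequency_ordering(self, rng):
        """Extrema vs zero-crossings differ by <=1 and zero-crossing count is
        non-increasing with IMF index, each in >=90% of random decompositions."""
        osc_ok = osc_total = 0
        order_ok = order_total = 0
        for _ in range(20):
            x = rng.standard_normal(512)
            d = emd(x)
            zc = []
            for j in range(d.n_natural):
                imf = d.imfs[j]
                mx, mn = find_extrema(imf)
                n_ext = mx.size + mn.size
                n_zc = int(np.sum(np.diff(np.sign(imf)[np.sign(imf) != 0]) != 0))
                zc.append(n_zc)
                if j < d.n_natural - 1:  # non-final natural IMFs
                    osc_total += 1
                    osc_ok += abs(n_ext - n_zc) <= 1
            order_total += max(len(zc) - 1, 0)
            order_ok += sum(a >= b for a, b in zip(zc, zc[1:]))
        assert osc_ok / osc_total >= 0.9
        assert order_ok / order_total >= 0.9


class TestEnsembles:
    def test_eemd_zero_noise_equals_emd(self, rng, fast_decomp_config):
        x = rng.standard_normal(256)
        cfg = DecompositionConfig(noise_ratio=0.0, ensemble_pairs=4)
        d0, d1 = emd(x, cfg), eemd(x, cfg, rng)
        np.testing.assert_array_equal(d0.imfs, d1.imfs)
        np.testing.assert_array_equal(d0.residual, d1.residual)

    def test_ceemd_zero_noise_equals_emd(self, rng):
        x = rng.standard_normal(256)
        cfg = DecompositionConfig(noise_ratio=0.0, ensemble_pairs=4)
        d0, d1 = emd(x, cfg), ceemd(x, cfg, rng)
        np.testing.assert_array_equal(d0.imfs, d1.imfs)

    def test_ensembles_seed_reproducible(self, rng, fast_decomp_config):
        x = rng.standard_normal(256)
        a = ceemd(x, fast_decomp_config, np.random.default_rng(3))
        b = ceemd(x, fast_decomp_config, np.random.default_rng(3))
        np.testing.assert_array_equal(a.imfs, b.imfs)
        np.testing.assert_array_equal(a.residual, b.residual)

    def test_complementary_pair_identity(self, rng):
        x = rng.standard_normal(128)
        n = rng.standard_normal(128)
        np.testing.assert_allclose(((x + n) + (x - n)) / 2, x, atol=1e-12)

    def test_eemd_error_shrinks_with_ensemble_size(self, rng):
        x = rng.standard_normal(256)
        errs = {}
        for m in (5, 50):
            d = eemd(x, DecompositionConfig(ensemble_pairs=m), np.random.default_rng(0))
            errs[m] = np.abs(d.reconstruct_full() - x).max()
        assert errs[50] <= errs[5]

    def test_ceemd_error_not_worse_than_eemd(self, rng):
        """Paired over 10 random signals: CEEMD reconstruction error <= EEMD
        in at least 8 (noise cancels exactly in complementary pairs)."""
        wins = 0
        cfg = DecompositionConfig(ensemble_pairs=4)
        for k in range(10):
            x = np.random.default_rng(100 + k).standard_normal(256)
            ec = np.abs(ceemd(x, cfg, np.random.default_rng(k)).reconstruct_full() - x).max()
            ee = np.abs(eemd(x, cfg, np.random.default_rng(k)).reconstruct_full() - x).max()
            wins += ec <= ee
        assert wins >= 8


class TestSelectionReconstruction:
    def _imfset_from(self, rows, residual=None):
        rows = np.asarray(rows, dtype=float)
        residual = np.zeros(rows.shape[1]) if residual is None else residual
        return IMFSet(imfs=rows, residual=residual, n_natural=rows.shape[0])

    def test_identical_component_selected_with_pr_one(self, rng):
        raw = rng.standard_normal(64)
        s = self._imfset_from([raw, rng.standard_normal(64) * 1e-3])
        sel = select_imfs(s, raw, threshold=0.1)
        assert 1 in sel.selected_indices
        assert sel.correlations[0] == pytest.approx(1.0)

    def test_uncorrelated_imfs_raise(self, rng):
        n = 4096
        raw = rng.standard_normal(n)
        noise_rows = [np.random.default_rng(50 + k).standard_normal(n) for k in range(3)]
        s = self._imfset_from(noise_rows)
        with pytest.raises(NoInformativeIMFs):
            select_imfs(s, raw, threshold=0.1)

    def test_threshold_zero_selects_all_nonnegative(self, rng):
        raw = rng.standard_normal(256)
        s = self._imfset_from([raw, raw * 2.0 + 0.01])
        sel = select_imfs(s, raw, threshold=0.0)
        assert sel.selected_indices == [1, 2]

    def test_select_all_plus_residual_reproduces_emd_input(self, rng):
        x = rng.standard_normal(256)
        d = emd(x)
        sel = ImfSelection(
            selected_indices=list(range(1, d.n_imfs + 1)),
            correlations=np.ones(d.n_imfs),
            threshold=0.0,
        )
        np.testing.assert_allclose(reconstruct(d, sel) + d.residual, x, atol=1e-8)

    def test_empty_selection_forbidden(self):
        with pytest.raises(NoInformativeIMFs):
            ImfSelection(selected_indices=[], correlations=np.zeros(3))

    def test_reconstruction_snr_beats_single_imfs(self):
        """Summing the top-correlated IMFs recovers a clean tone better than
        any single IMF does (synthetic tone + noise)."""
        from eegsift.signal_metrics import snr_db

        rng = np.random.default_rng(8)
        t = np.arange(1024) / 1024.0
        clean = np.sin(2 * np.pi * 20 * t) + 0.5 * np.sin(2 * np.pi * 5 * t)
        x = clean + 0.3 * rng.standard_normal(t.size)
        d = emd(x)
        sel = select_imfs(d, x, threshold=0.1)
        rec = reconstruct(d, sel)
        best_single = max(
            snr_db(clean, d.imfs[j]) for j in range(d.n_natural)
        )
        assert snr_db(clean, rec) > best_single

    def test_dataset_average_selection(self, rng):
        raws = [rng.standard_normal(128) for _ in range(3)]
        sets = [self._imfset_from([r, rng.standard_normal(128)]) for r in raws]
        sel = select_imfs(sets, raws, threshold=0.5)
        assert sel.selected_indices == [1]
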