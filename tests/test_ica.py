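"""Temporal ICA sweep, reference waveform, component selection, reconstruction."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from oeica.datatypes import DynamicSeries, GasProtocol, ValidationError
from oeica.ica import (
    ICARun,
    build_reference,
    extract_masked_matrix,
    rank_components,
    reconstruct_oe,
    run_ica_sweep,
    select_oe_component,
)
from oeica.phantom import generate_phantom, noise_free
from oeica.pipeline import process_echo
from oeica.pse import pse_map


def _make_run(courses: np.ndarray, k: int | None = None, seed: int = 0) -> ICARun:
    """ICARun wrapper around given unit-variance time courses (maps arbitrary)."""
    courses = np.asarray(courses, dtype=float)
    courses = courses / courses.std(axis=1, keepdims=True)
    k = k or courses.shape[0]
    v = 10
    return ICARun(
        k=k, seed=seed, time_courses=courses,
        spatial_maps=np.ones((v, k)), mean=np.zeros(v), converged=True,
    )


class TestReferenceWaveform:
    def test_phase_convention(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        dt = short_protocol.dynamic_interval_s
        i_switch = int(short_protocol.switch_times_s[0] / dt)
        i_peak = i_switch + int(short_protocol.gas_period_s / dt)
        assert ref.values[i_switch] == pytest.approx(-1.0)
        assert ref.values[i_peak] == pytest.approx(1.0)
        assert (ref.values[:i_switch] == -1.0).all()

    def test_periodicity_after_baseline(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        dt = short_protocol.dynamic_interval_s
        i_switch = int(short_protocol.switch_times_s[0] / dt)
        period = int(2 * short_protocol.gas_period_s / dt)
        post = ref.values[i_switch:]
        np.testing.assert_allclose(post[period:], post[: post.size - period], atol=1e-12)

    def test_series_shorter_than_baseline_rejected(self, short_protocol):
        with pytest.raises(ValidationError):
            build_reference(short_protocol, 10)


class TestExtraction:
    def test_roundtrip_restores_masked_voxels(self, rng):
        data = rng.uniform(1, 2, size=(2, 20, 5, 5))
        s = DynamicSeries(data, 1.0)
        mask = np.zeros((2, 5, 5), dtype=bool)
        mask[0, 1:4, 1:4] = True
        mat, coords, removed = extract_masked_matrix(s, mask)
        assert mat.shape == (9, 20) and removed.size == 0
        restored = np.zeros_like(data)
        restored[coords[:, 0], :, coords[:, 1], coords[:, 2]] = mat
        np.testing.assert_array_equal(restored[0, :, 1:4, 1:4], data[0, :, 1:4, 1:4])

    def test_constant_voxel_removed_and_recorded(self, rng):
        data = rng.uniform(1, 2, size=(1, 20, 3, 3))
        data[0, :, 0, 0] = 1.0
        s = DynamicSeries(data, 1.0)
        mask = np.ones((1, 3, 3), dtype=bool)
        mat, coords, removed = extract_masked_matrix(s, mask)
        assert mat.shape == (8, 20)
        assert removed.tolist() == [[0, 0, 0]]

    def test_mask_shape_mismatch_rejected(self, rng):
        s = DynamicSeries(rng.uniform(1, 2, size=(1, 20, 3, 3)), 1.0)
        with pytest.raises(ValidationError):
            extract_masked_matrix(s, np.ones((2, 3, 3), dtype=bool))


class TestSweep:
    def test_recovers_three_known_sources(self, rng):
        """Sinusoid + ramp + square mixture: sources come back up to sign and
        permutation with |Pearson| > 0.99 (exhaustive matching oracle)."""
        from conftest import three_temporal_sources

        sources = three_temporal_sources(180)
        mixing = rng.normal(size=(200, 3))
        x = mixing @ sources + 5.0
        runs = run_ica_sweep(x, 3, 3, seed=0)
        got = runs[0].time_courses
        corr = np.abs(np.corrcoef(sources, got)[:3, 3:])
        # exhaustive permutation matching
        from itertools import permutations

        best = max(sum(corr[i, p[i]] for i in range(3)) for p in permutations(range(3)))
        assert best / 3 > 0.99

    def test_full_rank_factorization_is_exact(self, rng):
        """Rank-2 data with K=2: mean + maps @ courses reproduces the input."""
        t = np.linspace(0, 1, 60)
        sources = np.vstack([np.sin(2 * np.pi * 5 * t), np.sign(np.sin(2 * np.pi * 2 * t))])
        x = rng.normal(size=(50, 2)) @ sources + 3.0
        run = run_ica_sweep(x, 2, 2, seed=1)[0]
        recon = run.mean[:, None] + run.spatial_maps @ run.time_courses
        assert np.linalg.norm(recon - x) / np.linalg.norm(x) < 1e-6

    def test_sweep_contract(self, rng):
        x = rng.normal(size=(40, 50)) + 10
        runs = run_ica_sweep(x, 3, 8, seed=42)
        assert [r.k for r in runs] == list(range(3, 9))
        assert [r.seed for r in runs] == [42 + k for k in range(3, 9)]
        for r in runs:
            np.testing.assert_allclose(r.time_courses.var(axis=1), 1.0, atol=1e-6)

    def test_k_bounds_validated(self, rng):
        x = rng.normal(size=(10, 30))
        with pytest.raises(ValidationError, match="k_max"):
            run_ica_sweep(x, 2, 11, seed=0)
        with pytest.raises(ValidationError):
            run_ica_sweep(x, 1, 5, seed=0)


class TestSelection:
    def test_exact_reference_component_wins_with_rho_one(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        noise = np.random.default_rng(0).normal(size=(2, ref.values.size))
        run = _make_run(np.vstack([ref.values, noise]))
        comp = select_oe_component([run], ref)
        assert comp.index == 0
        # unit-variance scaling can flip ranks of near-tied cosine samples,
        # so exact rho = 1 holds only to ~1e-4
        assert comp.rho == pytest.approx(1.0, abs=1e-4)
        assert not comp.below_threshold

    def test_tie_broken_toward_smaller_k(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        noise = np.random.default_rng(1).normal(size=ref.values.size)
        small = _make_run(np.vstack([noise, ref.values]), k=2, seed=5)
        large = _make_run(np.vstack([noise, ref.values, noise[::-1]]), k=3, seed=6)
        comp = select_oe_component([small, large], ref)
        assert comp.k == 2 and comp.index == 1

    def test_pure_noise_rarely_reaches_threshold(self, short_protocol):
        """Null calibration of the 0.4 magnitude threshold: the best of 22
        i.i.d. Gaussian courses at T = 180 stays below 0.4 almost always."""
        protocol = GasProtocol(baseline_s=45.0, gas_period_s=90.0, n_cycles=1,
                               dynamic_interval_s=1.5)
        t = 180
        ref = build_reference(protocol, t)
        r = np.random.default_rng(11)
        below = 0
        reps = 200
        for _ in range(reps):
            run = _make_run(r.normal(size=(22, t)))
            rank_components([run], ref)
            if np.abs(run.rho).max() < 0.4:
                below += 1
        assert below / reps > 0.95

    def test_below_threshold_triggers_resweep(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        r = np.random.default_rng(2)
        bad = _make_run(r.normal(size=(3, ref.values.size)))
        seeds_used = []

        def resweep(seed):
            seeds_used.append(seed)
            return [_make_run(np.vstack([ref.values, r.normal(size=ref.values.size)]), seed=seed)]

        comp = select_oe_component([bad], ref, seed=7, resweep=resweep)
        assert seeds_used == [10007]
        assert comp.retries == 1
        assert comp.rho == pytest.approx(1.0, abs=1e-4)

    def test_exhausted_retries_flagged_not_raised(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        r = np.random.default_rng(3)
        bad = [_make_run(r.normal(size=(3, ref.values.size)))]
        comp = select_oe_component(
            bad, ref, max_retries=2, seed=0,
            resweep=lambda s: [_make_run(r.normal(size=(3, ref.values.size)))],
        )
        assert comp.below_threshold
        assert comp.retries == 2

    def test_negative_correlation_sign_oriented(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        run = _make_run(np.vstack([-ref.values,
                                   np.random.default_rng(4).normal(size=ref.values.size)]))
        comp = select_oe_component([run], ref)
        assert comp.rho == pytest.approx(1.0, abs=1e-4)
        assert spearmanr(comp.time_course, ref.values).statistic == pytest.approx(1.0, abs=1e-4)

    def test_reference_length_mismatch_rejected(self, short_protocol):
        ref = build_reference(short_protocol, short_protocol.n_dynamics)
        run = _make_run(np.random.default_rng(5).normal(size=(2, ref.values.size + 1)))
        with pytest.raises(ValidationError):
            select_oe_component([run], ref)


@pytest.fixture(scope="module")
def selected(small_phantom, small_config):
    series, masks, _ = small_phantom
    mat, coords, _ = extract_masked_matrix(series[0], masks.thoracic)
    runs = run_ica_sweep(mat, 4, 8, seed=0)
    ref = build_reference(small_config.protocol, series[0].n_dynamics)
    comp = select_oe_component(runs, ref)
    return series[0], coords, comp


class TestReconstruction:
    def test_joint_sign_flip_is_invariant(self, selected):
        series, coords, comp = selected
        flipped = replace(comp, time_course=-comp.time_course, spatial_map=-comp.spatial_map)
        a = reconstruct_oe(series, coords, comp)
        b = reconstruct_oe(series, coords, flipped)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_scale_gauge_leaves_pse_unchanged(self, selected, small_config):
        """(c * course, map / c) is the same factorisation: PSE maps agree."""
        series, coords, comp = selected
        base_map, _ = pse_map(reconstruct_oe(series, coords, comp), small_config.protocol)
        for c in (-1.0, 0.1, 10.0):
            gauged = replace(
                comp, time_course=c * comp.time_course, spatial_map=comp.spatial_map / c
            )
            m, _ = pse_map(reconstruct_oe(series, coords, gauged), small_config.protocol)
            np.testing.assert_allclose(m, base_map, atol=1e-9)

    def test_zero_map_reconstructs_temporal_mean(self, selected):
        series, coords, comp = selected
        zeroed = replace(comp, spatial_map=np.zeros_like(comp.spatial_map))
        recon = reconstruct_oe(series, coords, zeroed)
        mean = series.data.mean(axis=1)
        np.testing.assert_allclose(recon.data, np.repeat(mean[:, None], series.n_dynamics, 1))

    def test_clean_single_source_reconstruction_matches_input(self, clean_config):
        """One true source, no confounds: K=2 reconstruction reproduces the
        masked input to < 1% relative RMS.  A trace of noise keeps the
        factorisation non-degenerate (pure rank-1 data has no second
        whitened direction)."""
        series, masks, _ = generate_phantom(replace(clean_config, sigma=1e-3))
        s = series[0]
        mat, coords, _ = extract_masked_matrix(s, masks.thoracic)
        runs = run_ica_sweep(mat, 2, 2, seed=0)
        ref = build_reference(clean_config.protocol, s.n_dynamics)
        comp = select_oe_component(runs, ref)
        recon = reconstruct_oe(s, coords, comp)
        diff = (recon.data - s.data)[masks.thoracic[:, None].repeat(s.n_dynamics, 1)]
        rel = np.sqrt(np.mean(diff**2)) / np.sqrt(np.mean(s.data[masks.thoracic[:, None].repeat(s.n_dynamics, 1)] ** 2))
        assert rel < 0.01

    def test_dimension_mismatch_rejected(self, selected):
        series, coords, comp = selected
        with pytest.raises(ValidationError):
            reconstruct_oe(series, coords[:-1], comp)


class TestPipelineInvariants:
    def test_selection_deterministic_for_fixed_seed(self, small_phantom, small_config):
        series, masks, _ = small_phantom
        res = [
            process_echo(series[0], masks, small_config.protocol, k_min=4, k_max=6, seed=9)
            for _ in range(2)
        ]
        assert res[0].component.k == res[1].component.k
        assert res[0].component.index == res[1].component.index
        np.testing.assert_array_equal(res[0].component.time_course, res[1].component.time_course)
        np.testing.assert_array_equal(res[0].pse_map_ica, res[1].pse_map_ica)

    def test_echo_one_processing_ignores_echo_two(self, small_config):
        """Corrupting echo 2 must not change anything computed for echo 1."""
        series, masks, _ = generate_phantom(small_config)
        first = process_echo(series[0], masks, small_config.protocol, k_min=4, k_max=6, seed=1)
        series2, masks2, _ = generate_phantom(small_config)
        series2[1].data[:] = 0.0  # corrupt the other echo
        second = process_echo(series2[0], masks2, small_config.protocol, k_min=4, k_max=6, seed=1)
        np.testing.assert_array_equal(first.pse_map_ica, second.pse_map_ica)

    def test_fastica_agrees_with_rotation_search_oracle(self, rng):
        """On a 2-source problem the FastICA unmixing matches an exhaustive
        rotation search over the whitened 2-D subspace (Amari index < 0.1)."""
        t = np.linspace(0, 1, 60)
        sources = np.vstack(
            [np.sign(np.sin(2 * np.pi * 4 * t)), np.sin(2 * np.pi * 9 * t)]
        )
        x = rng.normal(size=(40, 2)) @ sources + 2.0
        run = run_ica_sweep(x, 2, 2, seed=0)[0]

        # oracle: whiten the temporal data, grid-search the rotation angle
        # maximising total non-Gaussianity (|excess kurtosis|)
        xt = x.T - x.T.mean(axis=0)
        u, sv, _ = np.linalg.svd(xt, full_matrices=False)
        z = u[:, :2] * np.sqrt(xt.shape[0])  # whitened (T, 2)
        best_angle, best_score = 0.0, -np.inf
        for ang in np.linspace(0, np.pi / 2, 2001):
            c, s = np.cos(ang), np.sin(ang)
            y = z @ np.array([[c, -s], [s, c]])
            k4 = ((y**4).mean(axis=0) / (y**2).mean(axis=0) ** 2) - 3
            score = np.abs(k4).sum()
            if score > best_score:
                best_score, best_angle = score, ang
        c, s = np.cos(best_angle), np.sin(best_angle)
        oracle = (z @ np.array([[c, -s], [s, c]])).T  # (2, T)

        # performance matrix between the two solutions
        corr = np.corrcoef(np.vstack([run.time_courses, oracle]))[:2, 2:]
        p = np.abs(corr)
        amari = 0.0
        for i in range(2):
            amari += p[i].sum() / p[i].max() - 1
            amari += p[:, i].sum() / p[:, i].max() - 1
        amari /= 2 * 2 * (2 - 1)
        assert amari < 0.1
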