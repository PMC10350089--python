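import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from musicflow import (
    AUTOFLUORESCENCE_ID,
    EventTable,
    ReferenceSpectrum,
    build_reference_matrix,
    compare_single_vs_triple,
    diagonal_dominance,
    gate_positive,
    normalize_abundances,
    percent_positive_unmixed,
    specificity_matrix,
    unmix_events,
)
from musicflow.gating import GateResult
from musicflow.simulate import (
    NoiseModel,
    PopulationSpec,
    make_autofluorescence_endmember,
    make_endmember,
    simulate_event_table,
)


def grid_search_nnls(R, y, n_points=9, n_refine=14):
    """Independent brute-force oracle: exhaustive grid over the non-negative
    orthant, refined around the incumbent until the step stabilizes."""
    k = R.shape[1]
    col_norms = np.linalg.norm(R, axis=0)
    hi = np.full(k, 2.0 * np.linalg.norm(y) / col_norms.min() + 1e-9)
    lo = np.zeros(k)
    best_x, best_obj = None, np.inf
    for _ in range(n_refine):
        axes = [np.linspace(lo[j], hi[j], n_points) for j in range(k)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
        resid = mesh @ R.T - y
        objs = np.einsum("ij,ij->i", resid, resid)
        i = int(np.argmin(objs))
        if objs[i] < best_obj:
            best_obj, best_x = objs[i], mesh[i]
        span = (hi - lo) / (n_points - 1)
        lo = np.maximum(best_x - span, 0.0)
        hi = best_x + span
    return best_x, np.sqrt(best_obj)


def _refs_from_endmembers(endmembers, af):
    panel = af.panel
    spectra = [
        ReferenceSpectrum(e.probe_id, e.spectrum, panel) for e in endmembers
    ]
    return build_reference_matrix(
        spectra, ReferenceSpectrum(AUTOFLUORESCENCE_ID, af.spectrum, panel)
    )


@pytest.fixture
def refs(trio):
    endmembers, af = trio
    return _refs_from_endmembers(endmembers, af)


class TestUnmixEvents:
    def test_exact_member(self, full_panel, trio, refs):
        endmembers, af = trio
        y = 3.0 * endmembers[0].spectrum
        table = EventTable(full_panel, y[None, :])
        res = unmix_events(table, refs)
        np.testing.assert_allclose(res.abundances[0], [3.0, 0, 0, 0], atol=1e-10)
        assert res.residual_norm[0] == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_mixture_exact_and_matches_oracle(self, full_panel, trio, refs):
        endmembers, af = trio
        R = np.column_stack(
            [endmembers[0].spectrum, endmembers[1].spectrum, af.spectrum]
        )
        y = 2.0 * R[:, 0] + 1.0 * R[:, 1] + 0.5 * R[:, 2]
        small_refs = _refs_from_endmembers(endmembers[:2], af)
        res = unmix_events(EventTable(full_panel, y[None, :]), small_refs)
        np.testing.assert_allclose(res.abundances[0], [2.0, 1.0, 0.5], atol=1e-8)
        x_oracle, obj_oracle = grid_search_nnls(R, y)
        np.testing.assert_allclose(x_oracle, [2.0, 1.0, 0.5], atol=1e-3)

    def test_pathological_negative_event(self, full_panel, trio, refs):
        endmembers, af = trio
        y = -endmembers[0].spectrum
        res = unmix_events(EventTable(full_panel, y[None, :]), refs)
        np.testing.assert_array_equal(res.abundances[0], 0.0)
        assert res.residual_norm[0] == pytest.approx(np.linalg.norm(y))

    def test_panel_mismatch(self, panel, trio, refs):
        with pytest.raises(ValueError, match="panel"):
            unmix_events(EventTable(panel, np.ones((1, panel.n_channels))), refs)

    @given(
        events=arrays(
            np.float64, (5, 22),
            elements=st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
        )
    )
    def test_non_negativity_property(self, events):
        from musicflow import default_panel
        from musicflow.simulate import make_endmember as mk

        panel = default_panel()
        a = mk("A", 2, panel)
        b = mk("B", 14, panel)
        af = make_autofluorescence_endmember(panel)
        refs = _refs_from_endmembers([a, b], af)
        res = unmix_events(EventTable(panel, events), refs)
        assert np.all(res.abundances >= 0)

    def test_scale_equivariance(self, full_panel, trio, refs, rng):
        y = rng.normal(10, 5, size=(4, full_panel.n_channels))
        res1 = unmix_events(EventTable(full_panel, y), refs)
        res2 = unmix_events(EventTable(full_panel, 3.5 * y), refs)
        np.testing.assert_allclose(res2.abundances, 3.5 * res1.abundances,
                                   rtol=1e-8, atol=1e-9)

    def test_oracle_equivalence_random_problems(self, rng):
        """NNLS objective matches the refined grid-search oracle on random
        3-endmember problems."""
        from musicflow import ChannelPanel

        panel = ChannelPanel(tuple(f"C{i}" for i in range(6)))
        for _ in range(10):
            R = rng.random((6, 3)) + 0.05
            y = rng.normal(0, 2, size=6)
            spectra = [
                ReferenceSpectrum(f"p{j}", R[:, j] / R[:, j].max(), panel)
                for j in range(2)
            ]
            refs = build_reference_matrix(
                spectra, ReferenceSpectrum(AUTOFLUORESCENCE_ID, R[:, 2] / R[:, 2].max(), panel)
            )
            res = unmix_events(EventTable(panel, y[None, :]), refs)
            _, obj_oracle = grid_search_nnls(refs.matrix, y)
            assert res.residual_norm[0] <= obj_oracle + 1e-6 * max(1.0, obj_oracle)
            assert obj_oracle <= res.residual_norm[0] + 1e-6 * max(1.0, res.residual_norm[0])

    def test_collinear_columns_warn(self, full_panel, trio):
        endmembers, af = trio
        a = endmembers[0]
        dup = ReferenceSpectrum("dup", a.spectrum, full_panel)
        orig = ReferenceSpectrum(a.probe_id, a.spectrum, full_panel)
        refs = build_reference_matrix(
            [orig, dup], ReferenceSpectrum(AUTOFLUORESCENCE_ID, af.spectrum, full_panel)
        )
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            unmix_events(EventTable(full_panel, np.ones((1, full_panel.n_channels))), refs)


class TestNormalizeAbundances:
    def _noiseless_single(self, trio, n=200, seed=0):
        endmembers, af = trio
        pop = PopulationSpec(
            n_events=n, fraction_positive={"Atto488": 1.0},
            abundance_cv=0.5, autofluorescence_level=0.0, noise=NoiseModel(0.0, 0.0),
        )
        return simulate_event_table(endmembers, af, pop, "single:Atto488",
                                    np.random.default_rng(seed))

    def test_identical_positives_normalize_to_one(self, full_panel, trio, refs):
        endmembers, af = trio
        y = np.tile(5.0 * endmembers[0].spectrum, (20, 1))
        table = EventTable(full_panel, y)
        um = unmix_events(table, refs)
        gate = GateResult(0.0, np.ones(20, dtype=bool), "B2")
        norm = normalize_abundances(table, um, gate, "Atto488", refs)
        np.testing.assert_allclose(norm.normalized_intensity, 1.0)
        np.testing.assert_allclose(norm.normalized_unmixed, 1.0)

    def test_noiseless_correlation_is_one(self, trio, refs):
        table, _ = self._noiseless_single(trio)
        um = unmix_events(table, refs)
        gate = GateResult(0.0, np.ones(table.n_events, dtype=bool), "B2")
        norm = normalize_abundances(table, um, gate, "Atto488", refs)
        r = np.corrcoef(norm.normalized_intensity, norm.normalized_unmixed)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            norm.normalized_intensity, norm.normalized_unmixed, rtol=1e-8
        )

    def test_doubling_leaves_normalization_unchanged(self, trio, refs):
        table, _ = self._noiseless_single(trio)
        gate = GateResult(0.0, np.ones(table.n_events, dtype=bool), "B2")
        um1 = unmix_events(table, refs)
        n1 = normalize_abundances(table, um1, gate, "Atto488", refs)
        doubled = EventTable(table.panel, 2.0 * table.intensities)
        um2 = unmix_events(doubled, refs)
        n2 = normalize_abundances(doubled, um2, gate, "Atto488", refs)
        np.testing.assert_allclose(n1.normalized_intensity, n2.normalized_intensity)
        np.testing.assert_allclose(n1.normalized_unmixed, n2.normalized_unmixed,
                                   rtol=1e-8)

    def test_zero_median_rejected(self, full_panel, trio, refs):
        table = EventTable(full_panel, np.zeros((10, full_panel.n_channels)))
        um = unmix_events(table, refs)
        gate = GateResult(0.0, np.ones(10, dtype=bool), "B2")
        with pytest.raises(ValueError, match="median"):
            normalize_abundances(table, um, gate, "Atto488", refs)


class TestSpecificityMatrix:
    def _simulate_panel(self, trio, noise, seed=21, n=2000):
        endmembers, af = trio
        rng = np.random.default_rng(seed)
        singles = []
        for em in endmembers:
            pop = PopulationSpec(
                n_events=n, fraction_positive={em.probe_id: 0.4}, noise=noise
            )
            t, _ = simulate_event_table(endmembers, af, pop,
                                        f"single:{em.probe_id}", rng)
            singles.append((t, em.probe_id))
        unstained, _ = simulate_event_table(
            endmembers, af, PopulationSpec(n_events=n, noise=noise), "unstained", rng
        )
        return singles, unstained

    def test_noiseless_identity(self, trio, refs):
        singles, unstained = self._simulate_panel(trio, NoiseModel(0.0, 0.0))
        m = specificity_matrix(singles, refs, unstained)
        np.testing.assert_allclose(np.diag(m.to_numpy()), 1.0, atol=1e-9)
        off = m.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-9)

    def test_noisy_diagonal_dominance(self, trio, refs):
        singles, unstained = self._simulate_panel(trio, NoiseModel(0.25, 10.0))
        m = specificity_matrix(singles, refs, unstained)
        assert diagonal_dominance(m) > 0

    def test_missing_single_sample(self, trio, refs):
        singles, unstained = self._simulate_panel(trio, NoiseModel(0.0, 0.0))
        with pytest.raises(ValueError, match="missing singly-stained"):
            specificity_matrix(singles[:2], refs, unstained)


class TestPercentPositiveUnmixed:
    def test_half_above_zero_background(self, full_panel, trio, refs):
        endmembers, af = trio
        stained = np.vstack([
            10.0 * np.tile(endmembers[0].spectrum, (10, 1)),
            np.zeros((10, full_panel.n_channels)),
        ])
        un = np.zeros((50, full_panel.n_channels))
        um = unmix_events(EventTable(full_panel, stained), refs)
        um_u = unmix_events(EventTable(full_panel, un), refs)
        assert percent_positive_unmixed(um, "Atto488", um_u) == pytest.approx(50.0)

    def test_intensity_and_unmixed_gates_agree_noiseless(self, trio, refs):
        endmembers, af = trio
        pop = PopulationSpec(
            n_events=2000, fraction_positive={"Atto488": 0.3},
            autofluorescence_level=5.0, noise=NoiseModel(0.0, 0.0),
        )
        rng = np.random.default_rng(3)
        stained, _ = simulate_event_table(endmembers, af, pop, "single:Atto488", rng)
        unstained, _ = simulate_event_table(
            endmembers, af,
            PopulationSpec(n_events=2000, autofluorescence_level=5.0,
                           noise=NoiseModel(0.0, 0.0)),
            "unstained", rng,
        )
        gate = gate_positive(stained, unstained, channel="B2")
        um = unmix_events(stained, refs)
        um_u = unmix_events(unstained, refs)
        pct_unmixed = percent_positive_unmixed(um, "Atto488", um_u)
        assert pct_unmixed == pytest.approx(gate.percent_positive, abs=0.5)

    def test_tandem_unmixed_positivity_biased_low(self, trio, refs):
        """A tandem endmember that is an exact convex combination of its
        parents is not identifiable against them per event: noise splits part
        of its unmixed signal onto the parent columns, so the unmixed
        positivity of the tandem probe undercounts while the intensity gate
        does not. (The analogous single- vs multi-stain discrepancy appears
        in real tandem-stained samples.)"""
        endmembers, af = trio
        pop = PopulationSpec(
            n_events=4000, fraction_positive={"Atto488_647": 0.5},
            noise=NoiseModel(0.25, 10.0),
        )
        rng = np.random.default_rng(6)
        stained, truth = simulate_event_table(
            endmembers, af, pop, "single:Atto488_647", rng
        )
        unstained, _ = simulate_event_table(
            endmembers, af, PopulationSpec(n_events=4000, noise=NoiseModel(0.25, 10.0)),
            "unstained", rng,
        )
        emp = 100 * float(np.mean(truth[:, 2] > 0))
        # references estimated from the data (as the pipeline does), so the
        # tandem column is only approximately collinear with its parents
        from musicflow import (
            build_autofluorescence_reference,
            build_reference_matrix,
            build_reference_spectrum,
        )

        gate = gate_positive(stained, unstained, channel="B2")
        ref_c = build_reference_spectrum(stained, gate, "Atto488_647")
        refs_est = build_reference_matrix(
            [refs.spectra[0], refs.spectra[1], ref_c], refs.spectra[-1]
        )
        um = unmix_events(stained, refs_est)
        um_u = unmix_events(unstained, refs_est)
        pct = percent_positive_unmixed(um, "Atto488_647", um_u)
        gate_pct = gate_positive(
            stained, unstained, channel="peak_channel",
            reference=refs_est.column("Atto488_647"),
        ).percent_positive
        assert gate_pct == pytest.approx(emp, abs=1.0)  # intensity route unbiased
        ci = 2.576 * np.sqrt(emp / 100 * (1 - emp / 100) / 4000) * 100
        assert pct < emp - ci  # unmixed route systematically undercounts
        # the lost signal reappears as spurious parent-dye positivity
        parent_pct = max(
            percent_positive_unmixed(um, "Atto488", um_u),
            percent_positive_unmixed(um, "Atto647", um_u),
        )
        assert parent_pct > 5.0

    def test_unknown_endmember(self, full_panel, trio, refs):
        um = unmix_events(
            EventTable(full_panel, np.ones((2, full_panel.n_channels))), refs
        )
        with pytest.raises(KeyError):
            percent_positive_unmixed(um, "nope", um)


class TestCompareSingleVsTriple:
    def test_identical_triplicates(self):
        df = compare_single_vs_triple({"A": [10, 10, 10]}, {"A": [10, 10, 10]})
        assert df.loc["A", "difference"] == 0.0
        assert df.loc["A", "p_value"] == 1.0

    def test_separated_means_significant(self):
        df = compare_single_vs_triple(
            {"A": [10.0, 10.01, 9.99]}, {"A": [20.0, 20.02, 19.98]}
        )
        assert df.loc["A", "p_value"] < 0.05
        assert df.loc["A", "difference"] == pytest.approx(10.0, abs=0.1)

    def test_too_few_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_single_vs_triple({"A": [10.0]}, {"A": [10.0, 11.0]})

    def test_type_i_error_calibrated(self):
        """Under the null (same generator, different seeds) the Welch test
        rejects at ≈ the nominal 5% rate."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(30.0, 2.0, size=3)
            b = rng.normal(30.0, 2.0, size=3)
            df = compare_single_vs_triple({"A": list(a)}, {"A": list(b)})
            rejections += df.loc["A", "p_value"] < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 0.025
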