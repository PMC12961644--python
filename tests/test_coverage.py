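"""Coverage metrics: worked bin arithmetic, neuron-coverage corner cases,
and incremental / from-scratch equivalence for every strategy."""

import numpy as np
import pytest

from stimfuzz.constraints import (
    RETINAL_LIMITS,
    Constraint,
    ElectrodeArraySpec,
    StimulationVector,
)
from stimfuzz.coverage import (
    METRIC_IDS,
    BinningSpec,
    IKMICCoverage,
    IDivApproxCoverage,
    ProfiledRanges,
    RandomProjector,
    TestObservation,
    VOKMOCCoverage,
    VOKMVPCoverage,
    VOKMVPVCoverage,
    VOVCCCoverage,
    bin_index,
    make_metric,
    preprocess_ranges,
)
from stimfuzz.mutation import ImageInput, random_image
from stimfuzz.testbed import MLPEncoder, ToyRetinalEncoder, default_seed_images

from conftest import random_stim

ONE = ElectrodeArraySpec(n_electrodes=1)


def obs_with_proportions(props_by_constraint, n_electrodes=1, image=None):
    """Build a TestObservation with hand-set proportions."""
    stim = StimulationVector.from_arrays(
        [20.0] * n_electrodes,
        [1.0] * n_electrodes,
        [1.0] * n_electrodes,
        ElectrodeArraySpec(n_electrodes=n_electrodes),
    )
    image = image or ImageInput(np.zeros((2, 2)), input_id="obs")
    props = {
        Constraint.PI: np.zeros(n_electrodes),
        Constraint.CD: np.zeros(n_electrodes),
        Constraint.IC: np.array([0.0]),
        Constraint.AE: np.array([0.0]),
    }
    props.update(props_by_constraint)
    return TestObservation(image=image, stim=stim, proportions=props)


class TestBinIndex:
    @pytest.mark.parametrize(
        "value,K,lo,hi,expected",
        [
            (0.1, 5, 0.0, 1.25, 0),
            (0.6, 5, 0.0, 1.25, 2),
            (1.1, 5, 0.0, 1.25, 4),
            (9.0, 5, 0.0, 1.25, 4),    # above max -> outermost bin
            (-1.0, 5, 0.0, 1.25, 0),   # below min -> outermost bin
            (1.25, 5, 0.0, 1.25, 4),   # value exactly at hi -> top bin
            (1.0, 4, 0.0, 8.0, 0),
            (3.0, 4, 0.0, 8.0, 1),
            (7.0, 4, 0.0, 8.0, 3),
        ],
    )
    def test_edges_and_clamps(self, value, K, lo, hi, expected):
        assert bin_index(value, K, lo, hi) == expected


class TestVOKMVP:
    def test_worked_example(self):
        """1 aggregate proportion stream, K=5 over [0, 1.25], values
        {0.1, 0.6, 1.1} cover bins {0, 2, 4} -> 3 of 5 bins."""
        state = VOKMVPCoverage(1, BinningSpec(K=5, range_lo=0.0, range_hi=1.25))
        for v in (0.1, 0.6, 1.1):
            state.observe(
                obs_with_proportions({Constraint.IC: np.array([v])})
            )
        # count only the IC cells to mirror the single-constraint example
        ic_cells = {c for c in state.covered if c[0] == "IC"}
        assert len(ic_cells) / state.binning.K == pytest.approx(0.6)

    def test_out_of_range_clamps(self):
        state = VOKMVPCoverage(1, BinningSpec(K=5, range_lo=0.0, range_hi=1.25))
        state.observe(obs_with_proportions({Constraint.IC: np.array([9.0])}))
        assert ("IC", 4) in state.covered

    def test_empty_state_is_zero(self):
        state = VOKMVPCoverage(4, BinningSpec(K=5))
        assert state.coverage == 0.0

    def test_total_counts_both_scopes(self):
        # K·|V_A| + K·|V_E|·|I| with 2 aggregate and 2 electrode-wise types
        state = VOKMVPCoverage(10, BinningSpec(K=7))
        assert state.total == 7 * 2 + 7 * 2 * 10

    def test_missing_proportion_rejected(self):
        state = VOKMVPCoverage(1, BinningSpec(K=5))
        obs = obs_with_proportions({})
        del obs.proportions[Constraint.AE]
        with pytest.raises(ValueError):
            state.observe(obs)


class TestVOKMVPV:
    def test_safe_proportions_contribute_nothing(self):
        state = VOKMVPVCoverage(1, BinningSpec(K=5, range_lo=0.0, range_hi=2.0))
        for v in (0.2, 0.8, 1.0):
            state.observe(obs_with_proportions({Constraint.IC: np.array([v])}))
        assert state.coverage == 0.0

    def test_violating_region_support(self):
        # support [1, 2], K=5: proportion 1.1 falls in bin 0
        state = VOKMVPVCoverage(1, BinningSpec(K=5, range_lo=0.0, range_hi=2.0))
        state.observe(obs_with_proportions({Constraint.IC: np.array([1.1])}))
        assert ("IC", 0) in state.covered
        state.observe(obs_with_proportions({Constraint.IC: np.array([3.0])}))
        assert ("IC", 4) in state.covered  # clamp carries over

    def test_subset_of_vokmvp_on_violating_region(self, rng):
        """Cells VO-KMVP-V covers are never more numerous than the
        violating-region cells VO-KMVP covers at the same bin width."""
        spec = ElectrodeArraySpec(n_electrodes=3)
        full = VOKMVPCoverage(3, BinningSpec(K=10, range_lo=1.0, range_hi=2.0))
        vonly = VOKMVPVCoverage(3, BinningSpec(K=10, range_lo=1.0, range_hi=2.0))
        for _ in range(100):
            stim = random_stim(rng, spec)
            obs = TestObservation.from_test(
                ImageInput(np.zeros((2, 2)), input_id="x"), stim, RETINAL_LIMITS
            )
            full.observe(obs)
            vonly.observe(obs)
        assert len(vonly.covered) <= len(full.covered)


class TestVOKMOC:
    def test_worked_example(self):
        """One output dimension, profiled range [0, 8], K=4: values
        {1, 3, 7} cover bins {0, 1, 3} -> Cov = 0.75."""
        ranges = ProfiledRanges(output_lo=np.array([0.0]), output_hi=np.array([8.0]))
        state = VOKMOCCoverage(ranges, K=4)
        spec = ElectrodeArraySpec(
            n_electrodes=1, params_per_electrode=1,
            shared_frequency=20.0, shared_pulse_duration=1.0,
        )
        for v in (1.0, 3.0, 7.0):
            stim = StimulationVector.amplitudes_only([v], spec)
            obs = TestObservation.from_test(
                ImageInput(np.zeros((2, 2)), input_id="x"), stim, RETINAL_LIMITS
            )
            state.observe(obs)
        assert state.coverage == pytest.approx(0.75)

    def test_identical_tests_saturate_at_one_bin_per_dim(self):
        ranges = ProfiledRanges(
            output_lo=np.zeros(3), output_hi=np.full(3, 10.0)
        )
        state = VOKMOCCoverage(ranges, K=5)
        spec = ElectrodeArraySpec(
            n_electrodes=3, params_per_electrode=1,
            shared_frequency=20.0, shared_pulse_duration=1.0,
        )
        for _ in range(4):
            stim = StimulationVector.amplitudes_only([1.0, 2.0, 3.0], spec)
            obs = TestObservation.from_test(
                ImageInput(np.zeros((2, 2)), input_id="x"), stim, RETINAL_LIMITS
            )
            state.observe(obs)
        assert state.coverage == pytest.approx(1.0 / 5)

    def test_requires_ranges(self):
        with pytest.raises(ValueError):
            VOKMOCCoverage(ProfiledRanges(), K=4)


class TestVOVCC:
    def test_counting(self):
        state = VOVCCCoverage()
        assert state.coverage == 0.0
        state.observe(obs_with_proportions({Constraint.PI: np.array([1.5])}))
        assert state.coverage == pytest.approx(0.25)
        # saturates at 1 when all four types have been violated
        state.observe(
            obs_with_proportions(
                {
                    Constraint.CD: np.array([1.5]),
                    Constraint.IC: np.array([1.5]),
                    Constraint.AE: np.array([1.5]),
                }
            )
        )
        assert state.coverage == 1.0
        state.observe(obs_with_proportions({Constraint.PI: np.array([1.9])}))
        assert state.coverage == 1.0


class TestIKMIC:
    def test_single_image_covers_one_bin_per_pixel(self):
        state = IKMICCoverage((4, 4), K=10)
        img = ImageInput(np.zeros((4, 4)), input_id="black")
        state.observe(TestObservation(img, _dummy_stim(), _zero_props()))
        assert state.coverage == pytest.approx(0.1)
        # same image again: idempotent
        state.observe(TestObservation(img, _dummy_stim(), _zero_props()))
        assert state.coverage == pytest.approx(0.1)
        white = ImageInput(np.ones((4, 4)), input_id="white")
        state.observe(TestObservation(white, _dummy_stim(), _zero_props()))
        assert state.coverage == pytest.approx(0.2)

    def test_shape_mismatch_rejected(self):
        state = IKMICCoverage((4, 4), K=10)
        img = ImageInput(np.zeros((3, 3)), input_id="small")
        with pytest.raises(ValueError):
            state.observe(TestObservation(img, _dummy_stim(), _zero_props()))


class TestIDivApprox:
    def test_identity_projector_reduces_to_pixel_binning(self):
        proj = lambda img: img.pixels.ravel()
        ranges = ProfiledRanges(feature_lo=np.array([0.0]), feature_hi=np.array([1.0]))
        state = IDivApproxCoverage(proj, ranges, K=10)
        kmic = IKMICCoverage((1, 1), K=10)
        for v in (0.0, 0.55, 0.99):
            img = ImageInput(np.array([[v]]), input_id=f"px{v}")
            obs = TestObservation(img, _dummy_stim(), _zero_props())
            state.observe(obs)
            kmic.observe(obs)
        assert state.coverage == kmic.coverage

    def test_identical_images_saturate(self):
        proj = RandomProjector((4, 4), n_features=8)
        img = ImageInput(np.full((4, 4), 0.3), input_id="x")
        feats = proj(img)
        ranges = ProfiledRanges(feature_lo=feats - 1.0, feature_hi=feats + 1.0)
        state = IDivApproxCoverage(proj, ranges, K=5)
        for _ in range(3):
            state.observe(TestObservation(img, _dummy_stim(), _zero_props()))
        assert state.coverage == pytest.approx(1.0 / 5)


def _dummy_stim():
    return StimulationVector.from_arrays([20.0], [1.0], [1.0], ONE)


def _zero_props():
    return {
        Constraint.PI: np.zeros(1),
        Constraint.CD: np.zeros(1),
        Constraint.IC: np.array([0.0]),
        Constraint.AE: np.array([0.0]),
    }


class TestNeuronMetrics:
    def _obs(self, activations):
        img = ImageInput(np.zeros((2, 2)), input_id="x")
        return TestObservation(img, _dummy_stim(), _zero_props(),
                               activations=activations)

    def test_single_neuron_snac_and_nbc(self):
        ranges = ProfiledRanges(
            neuron_lo=[np.array([0.0])], neuron_hi=[np.array([1.0])]
        )
        snac = make_metric("N-SNAC", n_electrodes=1, image_shape=(2, 2),
                           ranges=ranges)
        nbc = make_metric("N-NBC", n_electrodes=1, image_shape=(2, 2),
                          ranges=ranges)
        obs = self._obs([np.array([1.5])])
        snac.observe(obs)
        nbc.observe(obs)
        assert snac.coverage == 1.0
        assert nbc.coverage == 0.5  # only the above-high corner

    def test_nc_zero_when_nothing_exceeds_threshold(self):
        nc = make_metric("N-NC", n_electrodes=1, image_shape=(2, 2),
                         layer_sizes=[3])
        # constant activations scale to zeros: nothing crosses t = 0.75
        nc.observe(self._obs([np.array([0.5, 0.5, 0.5])]))
        assert nc.coverage == 0.0

    def test_tknc_covers_argmax_only(self):
        tknc = make_metric("N-TKNC", n_electrodes=1, image_shape=(2, 2),
                           layer_sizes=[2], tknc_k=1)
        tknc.observe(self._obs([np.array([0.1, 0.9])]))
        assert tknc.covered == {(0, 1)}
        tknc.observe(self._obs([np.array([0.8, 0.2])]))
        assert tknc.coverage == 1.0

    def test_kmnc_ignores_out_of_range(self):
        ranges = ProfiledRanges(
            neuron_lo=[np.array([0.0])], neuron_hi=[np.array([1.0])]
        )
        kmnc = make_metric("N-KMNC", n_electrodes=1, image_shape=(2, 2),
                           ranges=ranges, kmnc_k=10)
        kmnc.observe(self._obs([np.array([2.0])]))
        assert kmnc.coverage == 0.0
        kmnc.observe(self._obs([np.array([0.55])]))
        assert kmnc.covered == {(0, 0, 5)}

    def test_black_box_encoder_rejected(self):
        nc = make_metric("N-NC", n_electrodes=1, image_shape=(2, 2),
                         layer_sizes=[2])
        with pytest.raises(ValueError):
            nc.observe(TestObservation(
                ImageInput(np.zeros((2, 2)), input_id="x"),
                _dummy_stim(), _zero_props(), activations=None,
            ))


class TestPreprocessRanges:
    def test_min_max_and_permutation_invariance(self, rng):
        class Enc:
            array_spec = ElectrodeArraySpec(
                n_electrodes=1, params_per_electrode=1,
                shared_frequency=20.0, shared_pulse_duration=1.0,
            )
            def encode(self, img):
                return StimulationVector.amplitudes_only(
                    [float(img.pixels.sum())], self.array_spec
                )

        imgs = [
            ImageInput(np.full((1, 1), v), input_id=f"i{v}")
            for v in (0.1, 0.3, 0.7)
        ]
        r1 = preprocess_ranges(imgs, Enc())
        r2 = preprocess_ranges(imgs[::-1], Enc())
        np.testing.assert_array_equal(r1.output_lo, r2.output_lo)
        assert r1.output_lo[0] == pytest.approx(0.1)
        assert r1.output_hi[0] == pytest.approx(0.7)

    def test_constant_encoder_degenerate_range(self):
        class Enc:
            array_spec = ElectrodeArraySpec(
                n_electrodes=1, params_per_electrode=1,
                shared_frequency=20.0, shared_pulse_duration=1.0,
            )
            def encode(self, img):
                return StimulationVector.amplitudes_only([2.0], self.array_spec)

        imgs = [ImageInput(np.zeros((1, 1)), input_id="a")]
        r = preprocess_ranges(imgs, Enc())
        assert r.output_lo[0] == r.output_hi[0] == 2.0

    def test_empty_profiling_set_rejected(self):
        with pytest.raises(ValueError):
            preprocess_ranges([], object())


class TestTwoPhaseGain:
    def test_peek_does_not_mutate(self):
        state = VOVCCCoverage()
        obs = obs_with_proportions({Constraint.PI: np.array([1.5])})
        new = state.peek(obs)
        assert new and state.coverage == 0.0
        state.commit(new)
        assert state.coverage == 0.25

    def test_gain_semantics(self):
        state = VOVCCCoverage()
        obs = obs_with_proportions({Constraint.PI: np.array([1.5])})
        assert state.gain(obs)
        state.observe(obs)
        assert not state.gain(obs)  # already covered

    def test_bn_never_gains_ba_always_gains(self):
        bn = make_metric("B-N", n_electrodes=1, image_shape=(2, 2))
        ba = make_metric("B-A", n_electrodes=1, image_shape=(2, 2))
        for i in range(3):
            obs = obs_with_proportions({}, image=ImageInput(
                np.zeros((2, 2)), input_id=f"t{i}"))
            assert not bn.gain(obs)
            assert ba.gain(obs)
            bn.observe(obs)
            ba.observe(obs)


N_TESTS = 200


@pytest.fixture(scope="module")
def observations():
    enc = MLPEncoder(image_shape=(12, 12), hidden=16, weight_seed=7)
    rng = np.random.default_rng(123)
    obs = []
    for i in range(N_TESTS):
        img = random_image(12, 12, rng, input_id=f"r{i}")
        stim, acts = enc.encode_with_activations(img)
        obs.append(TestObservation.from_test(img, stim, RETINAL_LIMITS,
                                             activations=acts))
    return obs


@pytest.fixture(scope="module")
def profiled():
    enc = MLPEncoder(image_shape=(12, 12), hidden=16, weight_seed=7)
    rng = np.random.default_rng(9)
    imgs = [random_image(12, 12, rng, input_id=f"p{i}") for i in range(30)]
    return preprocess_ranges(imgs, enc, projector=RandomProjector((12, 12)))


class TestIncrementalEqualsFromScratch:
    """For every strategy the incremental state after N random tests
    equals a from-scratch recomputation over the full test list, the Cov
    value is in [0,1] and nondecreasing, and the final value is invariant
    to test order."""

    def _fresh(self, metric_id, profiled):
        return make_metric(
            metric_id,
            n_electrodes=225,
            image_shape=(12, 12),
            binning=BinningSpec(K=20, range_lo=0.0, range_hi=2.0),
            ranges=profiled,
            layer_sizes=(16, 16),
            projector=RandomProjector((12, 12)),
            kmnc_k=50,
        )

    @pytest.mark.parametrize("metric_id", METRIC_IDS)
    def test_equivalence_monotonicity_order_invariance(
        self, metric_id, observations, profiled
    ):
        inc = self._fresh(metric_id, profiled)
        trace = []
        for obs in observations:
            inc.observe(obs)
            trace.append(inc.coverage)
        # monotone in [0, 1]
        assert all(0.0 <= c <= 1.0 for c in trace)
        assert all(a <= b + 1e-15 for a, b in zip(trace, trace[1:]))
        # from-scratch equality on covered-cell sets
        scratch = self._fresh(metric_id, profiled)
        all_cells = set()
        for obs in observations:
            all_cells |= scratch.cells(obs)
        assert inc.covered == all_cells
        # order invariance of the final value
        perm = self._fresh(metric_id, profiled)
        order = np.random.default_rng(5).permutation(len(observations))
        for j in order:
            perm.observe(observations[j])
        assert perm.covered == inc.covered
        assert perm.coverage == inc.coverage
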