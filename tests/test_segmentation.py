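"""Selection seeding, spreading (vs a brute-force BFS oracle), and transfer."""

import numpy as np
import pytest

from uncrowding.field import init_field, step_field
from uncrowding.params import GeometrySpec, ModelParams
from uncrowding.segmentation import (
    MASK_SUPPORT_THRESHOLD,
    SegmentationState,
    SelectionSignal,
    init_state,
    place_selection_signals,
    seed_and_spread,
    step_segmentation,
    transfer_contours,
)
from uncrowding.stimuli import StimulusFrame, make_flankers, make_vernier, rasterize

# ---------------------------------------------------------------------------
# independent oracle: budgeted BFS over the contour graph, pure python


def oracle_spread_step(mask, act, driven, params):
    """Reference implementation of one spread step on sets of pixels.

    Mirrors the documented rule: decay, then a fast sweep (launched from
    masked pixels on or adjacent to strongly driven contours, growing only
    across such contours) and a slow crawl of ``spread_slow_px`` rings
    across any living contour.
    """
    h, w = mask.shape
    m = mask * np.exp(-params.dt_ms / params.tau_selection_ms)
    support = {(r, c) for r in range(h) for c in range(w) if m[r, c] > MASK_SUPPORT_THRESHOLD}
    if not support:
        return m
    alive = {(r, c) for r in range(h) for c in range(w) if act[r, c] > params.spread_threshold}
    fresh = {
        (r, c)
        for r in range(h)
        for c in range(w)
        if act[r, c] >= params.spread_fast_threshold or driven[r, c]
    }

    def neighbours(px):
        r, c = px
        return {
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if 0 <= r + dr < h and 0 <= c + dc < w
        }

    # fast-phase sources: selected pixels on or next to a driven contour
    b = {p for p in support if (neighbours(p) | {p}) & fresh}
    new = set()
    for _ in range(params.spread_fast_px - params.spread_slow_px):
        if not b:
            break
        cand = set()
        for p in b:
            cand |= neighbours(p)
        cand = (cand - b) & alive & fresh
        if not cand:
            break
        b |= cand
        new |= cand
    support = support | new
    for _ in range(params.spread_slow_px):
        cand = set()
        for p in support:
            cand |= neighbours(p)
        cand = (cand - support) & alive
        if not cand:
            break
        support |= cand
        new |= cand
    out = m.copy()
    for r, c in new:
        out[r, c] = 1.0
    return out


def random_contour_map(rng, h, w, n_strokes=6):
    """Random 1-px strokes of mixed strength on an empty canvas."""
    act = np.zeros((h, w))
    for _ in range(n_strokes):
        r, c = rng.integers(0, h), rng.integers(0, w)
        dr, dc = rng.choice([-1, 0, 1]), rng.choice([-1, 0, 1])
        if dr == dc == 0:
            dc = 1
        strength = rng.choice([0.3, 0.6, 0.9, 1.0])
        for _ in range(rng.integers(3, max(h, w))):
            if not (0 <= r < h and 0 <= c < w):
                break
            act[r, c] = strength
            r, c = r + dr, c + dc
    return act


def make_state_from(act, mask, time_ms=100):
    h, w = act.shape
    f = init_field((h, w))
    f.activity[0, 0] = act
    f.time_ms = time_ms
    return SegmentationState(field=f, selected_mask=mask.copy(), signals=[])


class TestSpreadOracle:
    def test_matches_bfs_oracle_on_random_toy_maps(self):
        """Acceptance-grade check: morphological spreading equals the
        pure-python budgeted BFS on dozens of random contour maps."""
        params = ModelParams(spread_fast_px=9, spread_slow_px=3)
        rng = np.random.default_rng(99)
        for trial in range(60):
            h, w = int(rng.integers(12, 64)), int(rng.integers(12, 64))
            act = random_contour_map(rng, h, w)
            mask = np.zeros((h, w))
            occupied = np.argwhere(act > 0)
            if len(occupied) == 0:
                continue
            for idx in rng.choice(len(occupied), size=min(4, len(occupied)), replace=False):
                r, c = occupied[idx]
                mask[r, c] = 1.0
            driven = (rng.random((h, w)) < 0.2) & (act > 0)
            raster = np.zeros((4, h, w))
            raster[0] = driven.astype(float)
            state = make_state_from(act, mask)
            state = seed_and_spread(state, params, input_raster=raster)
            expected = oracle_spread_step(mask, act, driven, params)
            assert np.allclose(state.selected_mask, expected), f"trial {trial}"

    def test_toy_cross_grows_as_plain_bfs_ball(self):
        """With unit speeds the mask after k steps is the BFS ball of radius
        k on a cross-shaped contour."""
        params = ModelParams(spread_fast_px=1, spread_slow_px=1)
        act = np.zeros((7, 7))
        act[3, :] = 1.0
        act[:, 3] = 1.0
        mask = np.zeros((7, 7))
        mask[3, 3] = 1.0
        state = make_state_from(act, mask)
        for k in range(1, 4):
            state = seed_and_spread(state, params)
            reached = state.selected_mask > 0.1
            for r in range(7):
                for c in range(7):
                    dist = max(abs(r - 3), abs(c - 3))
                    if act[r, c] > 0:
                        assert reached[r, c] == (dist <= k), (k, r, c)
                    else:
                        assert not reached[r, c]

    def test_isolated_seed_with_no_contour_neighbours_never_grows(self):
        params = ModelParams()
        act = np.zeros((9, 9))
        act[4, 4] = 1.0
        mask = np.zeros((9, 9))
        mask[4, 4] = 1.0
        state = make_state_from(act, mask)
        for _ in range(5):
            state = seed_and_spread(state, params)
        # the lone seeded pixel decays but nothing else is ever reached
        assert (state.selected_mask > 0).sum() <= 1
        assert state.selected_mask[4, 4] == state.selected_mask.max()

    def test_disconnected_component_never_selected(self):
        params = ModelParams()
        act = np.zeros((9, 20))
        act[4, 0:6] = 1.0
        act[4, 10:16] = 1.0  # gap of 4 px
        mask = np.zeros((9, 20))
        mask[4, 2] = 1.0
        state = make_state_from(act, mask)
        for _ in range(10):
            state = seed_and_spread(state, params)
        assert (state.selected_mask[4, 10:16] > 0).sum() == 0


class TestSignals:
    def test_one_signal_per_side_symmetric_without_jitter(self, geometry, rng):
        p = ModelParams(seed_jitter_arcmin=0.0)
        sigs = place_selection_signals("Cubes", p, rng, geometry)
        assert len(sigs) == 2
        xs = sorted(s.center_x for s in sigs)
        assert xs[0] == -xs[1]
        assert all(s.center_y == 0.0 for s in sigs)

    def test_lines_signals_sit_on_the_flanking_lines(self, geometry, rng):
        p = ModelParams(seed_jitter_arcmin=0.0)
        sigs = place_selection_signals("Lines", p, rng, geometry)
        assert sorted(abs(s.center_x) for s in sigs) == [23.0, 23.0]
        # a 30' radius seed centered there overlaps the vernier zone
        assert all(abs(s.center_x) - s.radius < 4.0 for s in sigs)

    def test_unflanked_yields_no_signals(self, params, rng):
        assert place_selection_signals(None, params, rng) == []
        assert place_selection_signals("unflanked", params, rng) == []

    def test_equal_seeds_identical_placements(self, params, geometry):
        a = place_selection_signals("Cubes", params, np.random.default_rng(5), geometry)
        b = place_selection_signals("Cubes", params, np.random.default_rng(5), geometry)
        assert [(s.center_x, s.center_y) for s in a] == [(s.center_x, s.center_y) for s in b]

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            SelectionSignal(0, 0, radius=0.0)


class TestTransfer:
    def test_full_transfer_moves_everything(self):
        p = ModelParams(transfer_rate=1.0)
        state = init_state((5, 5))
        state.field.activity[0, :, 2, 2] = 0.8
        state.selected_mask[2, 2] = 1.0
        state = transfer_contours(state, p)
        assert state.field.activity[0, :, 2, 2] == pytest.approx(0.0)
        assert state.field.activity[1, :, 2, 2] == pytest.approx(0.8)

    def test_per_pixel_conservation_at_transfer_instant(self, rng):
        p = ModelParams()
        state = init_state((6, 6))
        state.field.activity[:] = rng.random(state.field.activity.shape) * 0.8
        state.selected_mask[:] = rng.random((6, 6))
        before = state.field.activity.sum(axis=0)
        state = transfer_contours(state, p)
        after = state.field.activity.sum(axis=0)
        assert np.allclose(before, after, atol=1e-12)

    def test_miss_property_layer1_stays_zero_for_whole_trial(self, geometry):
        # seed circles that never intersect any contour: Layer 1 silent
        p = ModelParams(seed_jitter_arcmin=0.0)
        frame = StimulusFrame(
            segments=tuple(make_vernier(240.0, geometry)), label="vernier",
            vernier_offset=240.0, contains_vernier=True,
        )
        raster = rasterize(frame, p.px_per_arcmin, p.canvas_x_arcmin, p.canvas_y_arcmin)
        sigs = [SelectionSignal(150.0, 0.0, 30.0), SelectionSignal(-150.0, 0.0, 30.0)]
        state = init_state(p.raster_shape, sigs)
        for i in range(10):
            state = step_segmentation(state, raster if i < 1 else None, p)
        assert state.field.activity[1].sum() == 0.0
        assert state.selected_mask.sum() == 0.0

    def test_flankers_isolated_from_vernier_after_160ms_cubes(self, geometry):
        """After eight steps of a sustained Cubes display, the flanker
        contours have largely moved to Layer 1 while the vernier stays in
        Layer 0."""
        p = ModelParams(seed_jitter_arcmin=0.0)
        vern = make_vernier(240.0, geometry)
        flank = make_flankers("Cubes", geometry)
        frame = StimulusFrame(
            segments=tuple(vern + flank), label="t",
            vernier_offset=240.0, contains_vernier=True,
        )
        raster = rasterize(frame, p.px_per_arcmin, p.canvas_x_arcmin, p.canvas_y_arcmin)
        vern_only = rasterize(
            StimulusFrame(segments=tuple(vern), label="v", vernier_offset=240.0, contains_vernier=True),
            p.px_per_arcmin, p.canvas_x_arcmin, p.canvas_y_arcmin,
        ).astype(bool)
        flank_only = raster.astype(bool) & ~vern_only
        rng = np.random.default_rng(0)
        sigs = place_selection_signals("Cubes", p, rng, geometry)
        state = init_state(p.raster_shape, sigs)
        for _ in range(8):  # 160 ms
            state = step_segmentation(state, raster, p)
        a = state.field.activity
        flank_l1_share = a[1][flank_only].sum() / (a[0][flank_only].sum() + a[1][flank_only].sum())
        vern_l0_share = a[0][vern_only].sum() / (a[0][vern_only].sum() + a[1][vern_only].sum())
        assert flank_l1_share >= 0.8
        assert vern_l0_share >= 0.8


class TestComposition:
    def test_step_equals_manual_substeps(self, geometry):
        p = ModelParams(seed_jitter_arcmin=0.0)
        frame = StimulusFrame(
            segments=tuple(make_vernier(240.0, geometry) + make_flankers("Cubes", geometry)),
            label="t", vernier_offset=240.0, contains_vernier=True,
        )
        raster = rasterize(frame, p.px_per_arcmin, p.canvas_x_arcmin, p.canvas_y_arcmin)
        sigs = place_selection_signals("Cubes", p, np.random.default_rng(3), geometry)
        s1 = init_state(p.raster_shape, sigs)
        s2 = init_state(p.raster_shape, list(sigs))
        from uncrowding.segmentation import ROUTING_THRESHOLD

        for i in range(6):
            inp = raster if i < 1 else None
            s1 = step_segmentation(s1, inp, p)
            # manual decomposition
            if inp is None:
                s2.field = step_field(s2.field, None, p)
                s2 = seed_and_spread(s2, p, None)
                s2 = transfer_contours(s2, p)
            else:
                routed = (s2.selected_mask > ROUTING_THRESHOLD)[None, :, :]
                s2.field = step_field(s2.field, inp * ~routed, p)
                s2 = seed_and_spread(s2, p, inp)
                s2 = transfer_contours(s2, p)
                s2.field.activity[1] = np.minimum(1.0, s2.field.activity[1] + inp * routed)
            assert np.allclose(s1.field.activity, s2.field.activity)
            assert np.allclose(s1.selected_mask, s2.selected_mask)

    def test_mirrored_stimulus_and_seeds_give_mirrored_state(self, geometry):
        p = ModelParams(seed_jitter_arcmin=0.0)

        def run(offset_sign):
            frame = StimulusFrame(
                segments=tuple(make_vernier(offset_sign * 240.0, geometry) + make_flankers("Cubes", geometry)),
                label="t", vernier_offset=offset_sign * 240.0, contains_vernier=True,
            )
            raster = rasterize(frame, p.px_per_arcmin, p.canvas_x_arcmin, p.canvas_y_arcmin)
            sigs = place_selection_signals("Cubes", p, np.random.default_rng(0), geometry)
            state = init_state(p.raster_shape, sigs)
            for _ in range(8):
                state = step_segmentation(state, raster, p)
            return state

        plus, minus = run(+1), run(-1)
        # mirror about the vertical midline swaps the two diagonal channels
        mirrored = minus.field.activity[:, [0, 1, 3, 2], :, ::-1]
        assert np.allclose(plus.field.activity, mirrored)
        assert np.allclose(plus.selected_mask, minus.selected_mask[:, ::-1])

    def test_blank_input_with_empty_mask_is_pure_decay(self, params):
        state = init_state((8, 8))
        state.field.activity[0, 0, 3, 3] = 1.0
        state = step_segmentation(state, None, params)
        assert state.field.activity[0, 0, 3, 3] == pytest.approx(np.exp(-20 / params.tau_contour_ms))
        assert state.selected_mask.sum() == 0.0
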