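"""Spot detection and Crocker–Grier-style linking."""

import itertools

import numpy as np
import pytest

from dxtrack import SpotObservation, TrackingParams, detect_spots, \
    link_spots, subtract_background, tracks_to_table


def render_spot(shape, x, y, sigma=1.5, amplitude=1000.0, background=0.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return background + amplitude * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2)
    )


def obs_at(frame, positions):
    return [SpotObservation(frame=frame, x=float(x), y=float(y), intensity=1.0)
            for x, y in positions]


class TestBackground:
    def test_constant_image_removed_entirely(self):
        img = np.full((64, 64), 7.0)
        assert np.all(subtract_background(img, 5) == 0)

    def test_all_zero_image_stays_zero(self):
        assert np.all(subtract_background(np.zeros((64, 64)), 5) == 0)

    def test_delta_spike_preserved(self):
        # one hot pixel cannot move a 15x15 window median
        img = np.full((64, 64), 20.0)
        img[30, 30] += 500.0
        out = subtract_background(img, 5)
        assert out[30, 30] == pytest.approx(500.0, rel=0.05)
        assert np.count_nonzero(out) <= 5

    def test_integer_and_float_paths_agree_in_interior(self):
        rng = np.random.default_rng(1234)
        img = rng.poisson(20, size=(64, 64)).astype(np.uint16)
        a = subtract_background(img, 3)
        b = subtract_background(img.astype(float), 3)
        assert np.allclose(a[10:-10, 10:-10], b[10:-10, 10:-10])

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="smaller than"):
            subtract_background(np.zeros((10, 10)), 5)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros(100), 5)


class TestDetection:
    params = TrackingParams(detection_threshold=50.0, min_spot_diameter=5)

    def test_blank_image_gives_no_spots(self):
        assert detect_spots(np.zeros((64, 64)), self.params) == []

    def test_subpixel_centroid_accuracy(self):
        img = render_spot((64, 64), x=40.3, y=17.8)
        rng = np.random.default_rng(1234)
        noisy = rng.poisson(img + 50.0).astype(float)  # SNR ~ 20 at peak
        corrected = subtract_background(noisy, 5)
        spots = detect_spots(corrected, self.params)
        assert len(spots) == 1
        assert spots[0].x == pytest.approx(40.3, abs=0.1)
        assert spots[0].y == pytest.approx(17.8, abs=0.1)

    def test_two_well_separated_spots(self):
        img = render_spot((96, 96), 20.0, 20.0) + render_spot((96, 96), 70.0, 70.0)
        spots = detect_spots(img, self.params)
        assert len(spots) == 2

    def test_intensity_positive_and_frame_recorded(self):
        img = render_spot((64, 64), 30.0, 30.0)
        spots = detect_spots(img, self.params, frame=7)
        assert spots[0].frame == 7
        assert spots[0].intensity > 0


def brute_force_links(prev, curr, r_max):
    """Exhaustive min-cost assignment between two frames.

    Over all injective matchings whose pairs are within r_max, prefer more
    matches, then the lowest total squared displacement.
    """
    best = (0, 0.0, ())
    n, m = len(prev), len(curr)
    for k in range(min(n, m), -1, -1):
        found = None
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = ((prev[i].x - curr[j].x) ** 2
                          + (prev[i].y - curr[j].y) ** 2)
                    if d2 > r_max**2:
                        ok = False
                        break
                    cost += d2
                if ok and (found is None or cost < found[0]):
                    found = (cost, tuple(zip(rows, cols)))
        if found is not None:
            return set(found[1])
    return set()


class TestLinking:
    def test_stationary_spot_single_track(self):
        frames = [obs_at(f, [(10.0, 10.0)]) for f in range(10)]
        tracks = link_spots(frames, TrackingParams(search_radius=3.0))
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_jump_beyond_search_radius_splits_track(self):
        pos = [(10.0, 10.0)] * 5 + [(40.0, 40.0)] * 5
        frames = [obs_at(f, [p]) for f, p in enumerate(pos)]
        tracks = link_spots(frames, TrackingParams(search_radius=3.0))
        assert sorted(len(t) for t in tracks) == [5, 5]

    def test_matches_exhaustive_assignment_oracle(self):
        rng = np.random.default_rng(1234)
        params = TrackingParams(search_radius=4.0, min_track_length=2)
        for trial in range(20):
            n_spots = rng.integers(2, 6)
            pos = rng.uniform(10, 90, size=(n_spots, 2))
            frames = []
            for f in range(6):
                pos = pos + rng.normal(0, 1.0, size=pos.shape)
                frames.append(obs_at(f, pos))
            tracks = link_spots(frames, params)
            # collect implementation links per frame pair
            impl = {f: set() for f in range(5)}
            for tr in tracks:
                for a, b in zip(tr[:-1], tr[1:]):
                    ia = frames[a.frame].index(a)
                    ib = frames[b.frame].index(b)
                    impl[a.frame].add((ia, ib))
            for f in range(5):
                oracle = brute_force_links(frames[f], frames[f + 1],
                                           params.search_radius)
                assert impl[f] == oracle, f"trial {trial} frame {f}"

    def test_observation_conservation(self):
        rng = np.random.default_rng(1234)
        frames = [
            obs_at(f, rng.uniform(0, 100, size=(4, 2))) for f in range(8)
        ]
        params = TrackingParams(search_radius=5.0, min_track_length=2)
        tracks = link_spots(frames, params)
        n_linked = sum(len(t) for t in tracks)
        total = sum(len(g) for g in frames)
        assert n_linked <= total
        # every observation appears in at most one track
        seen = set()
        for t in tracks:
            for o in t:
                key = (o.frame, o.x, o.y)
                assert key not in seen
                seen.add(key)

    def test_memory_bridges_single_frame_gap(self):
        frames = [obs_at(0, [(10.0, 10.0)]), [], obs_at(2, [(10.5, 10.0)])]
        no_mem = link_spots(frames, TrackingParams(search_radius=3.0,
                                                   memory=0))
        with_mem = link_spots(frames, TrackingParams(search_radius=3.0,
                                                     memory=1))
        assert no_mem == []  # both fragments shorter than min_track_length
        assert len(with_mem) == 1 and len(with_mem[0]) == 2

    def test_determinism(self):
        rng = np.random.default_rng(1234)
        frames = [
            obs_at(f, rng.uniform(0, 50, size=(5, 2))) for f in range(6)
        ]
        params = TrackingParams(search_radius=6.0)
        t1 = link_spots(frames, params)
        t2 = link_spots(frames, params)
        assert tracks_to_table(t1).equals(tracks_to_table(t2))

    def test_unordered_frames_rejected(self):
        frames = [obs_at(3, [(1.0, 1.0)]), obs_at(1, [(1.0, 1.0)])]
        with pytest.raises(ValueError, match="ordered by frame"):
            link_spots(frames, TrackingParams(search_radius=3.0))

    def test_min_track_length_filter(self):
        frames = [obs_at(0, [(10.0, 10.0)])]
        assert link_spots(frames, TrackingParams(search_radius=3.0)) == []


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TrackingParams(search_radius=0.0)
        with pytest.raises(ValueError):
            TrackingParams(memory=-1)
        with pytest.raises(ValueError):
            TrackingParams(min_track_length=1)
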