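import numpy as np
import pytest

from flysin.interaction import (InteractionCriteria, InteractionEvent, build_network,
                                detect_events, events_to_frame, pairwise_state,
                                write_edge_list)
from flysin.trajectory_io import FlyTrack


def _static_tracks(positions, headings, n_frames):
    """Stationary flies: positions [(x, y)...], headings [rad...]."""
    frames = np.arange(n_frames)
    return [
        FlyTrack(i, frames, np.full(n_frames, float(x)), np.full(n_frames, float(y)),
                 np.full(n_frames, float(h)))
        for i, ((x, y), h) in enumerate(zip(positions, headings))
    ]


class TestPairwiseState:
    def test_within_distance_facing_directly(self, criteria):
        tracks = _static_tracks([(0, 0), (4.9, 0)], [0.0, np.pi], 1)
        s = pairwise_state(tracks, criteria, 0)
        assert s[0, 1] and s[1, 0]

    def test_beyond_distance_false_regardless_of_angle(self, criteria):
        tracks = _static_tracks([(0, 0), (5.1, 0)], [0.0, np.pi], 1)
        s = pairwise_state(tracks, criteria, 0)
        assert not s[0, 1] and not s[1, 0]

    def test_distance_boundary_inclusive(self, criteria):
        tracks = _static_tracks([(0, 0), (5.0, 0)], [0.0, np.pi], 1)
        assert pairwise_state(tracks, criteria, 0)[0, 1]

    @pytest.mark.parametrize("offset_deg,expected", [(79.0, True), (81.0, False), (100.0, False)])
    def test_field_of_view_half_cone(self, criteria, offset_deg, expected):
        # target 3 mm away at offset_deg off the actor's heading (+x); cone is +/-80
        a = np.deg2rad(offset_deg)
        tracks = _static_tracks([(0, 0), (3 * np.cos(a), 3 * np.sin(a))], [0.0, np.pi], 1)
        assert bool(pairwise_state(tracks, criteria, 0)[0, 1]) is expected

    def test_directionality(self, criteria):
        # actor faces away from target; target faces actor
        tracks = _static_tracks([(0, 0), (3, 0)], [np.pi, np.pi], 1)
        s = pairwise_state(tracks, criteria, 0)
        assert not s[0, 1] and s[1, 0]

    def test_missing_fly_gives_false(self, criteria):
        t0 = FlyTrack(0, np.array([0]), np.array([0.0]), np.array([0.0]), np.array([0.0]))
        t1 = FlyTrack(1, np.array([1]), np.array([1.0]), np.array([0.0]), np.array([np.pi]))
        s = pairwise_state([t0, t1], criteria, 1)
        assert not s[0, 1]


class TestDetectEvents:
    def _two_fly_run(self, n_true, n_frames=40):
        """Face-to-face 4 mm apart for the first n_true frames, then far apart."""
        frames = np.arange(n_frames)
        x1 = np.where(frames < n_true, 4.0, 30.0)
        t0 = FlyTrack(0, frames, np.zeros(n_frames), np.zeros(n_frames), np.zeros(n_frames))
        t1 = FlyTrack(1, frames, x1, np.zeros(n_frames), np.full(n_frames, np.pi))
        return [t0, t1]

    def test_18_frames_at_30hz_kept(self, criteria):
        events = detect_events(self._two_fly_run(18), criteria, 30.0)
        mine = [e for e in events if e.actor_fly == 0]
        assert len(mine) == 1
        assert mine[0].duration_s == pytest.approx(0.6)
        assert (mine[0].start_frame, mine[0].end_frame) == (0, 17)

    def test_17_frames_at_30hz_dropped(self, criteria):
        events = detect_events(self._two_fly_run(17), criteria, 30.0)
        assert events == []

    def test_two_separated_runs_give_two_events(self, criteria):
        # hand-built: frames 0-19 close (20 frames), 20-39 far, 40-64 close (25)
        n = 65
        frames = np.arange(n)
        x1 = np.where((frames < 20) | (frames >= 40), 4.0, 30.0)
        t0 = FlyTrack(0, frames, np.zeros(n), np.zeros(n), np.zeros(n))
        t1 = FlyTrack(1, frames, x1, np.zeros(n), np.full(n, np.pi))
        events = [e for e in detect_events([t0, t1], criteria, 30.0) if e.actor_fly == 0]
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 19), (40, 64)]
        assert [e.duration_s for e in events] == pytest.approx([20 / 30, 25 / 30])

    def test_gap_breaks_run(self, criteria):
        tracks = self._two_fly_run(40, n_frames=40)
        # remove frame 20 from fly 1: two 20-frame runs instead of one 40-frame run
        t1 = tracks[1]
        keep = t1.frames != 20
        tracks[1] = FlyTrack(1, t1.frames[keep], t1.x[keep], t1.y[keep], t1.heading[keep])
        events = [e for e in detect_events(tracks, criteria, 30.0) if e.actor_fly == 0]
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 19), (21, 39)]

    def test_symmetric_tracks_symmetric_events(self, criteria):
        events = detect_events(self._two_fly_run(25), criteria, 30.0)
        fwd = [e for e in events if e.actor_fly == 0]
        rev = [e for e in events if e.actor_fly == 1]
        assert len(fwd) == len(rev) == 1
        assert fwd[0].duration_s == rev[0].duration_s
        assert (fwd[0].start_frame, fwd[0].end_frame) == (rev[0].start_frame, rev[0].end_frame)

    @pytest.mark.parametrize("loosen", ["distance", "angle"])
    def test_loosening_criteria_never_loses_events(self, loosen):
        rng = np.random.default_rng(42)
        n = 300
        frames = np.arange(n)
        tracks = []
        for i in range(4):
            steps = rng.normal(0, 0.8, size=(n, 2))
            xy = np.cumsum(steps, axis=0)
            tracks.append(FlyTrack(i, frames, xy[:, 0], xy[:, 1],
                                   rng.uniform(-np.pi, np.pi, n)))
        tight = InteractionCriteria()
        if loosen == "distance":
            loose = InteractionCriteria(max_distance_body_lengths=4.0)
        else:
            loose = InteractionCriteria(max_facing_angle_deg=300.0)
        n_tight = len(detect_events(tracks, tight, 30.0))
        n_loose = len(detect_events(tracks, loose, 30.0))
        assert n_loose >= n_tight


class TestBuildNetwork:
    def test_zero_events_keeps_isolates(self):
        g = build_network([], 12)
        assert g.number_of_nodes() == 12 and g.number_of_edges() == 0

    def test_counts_and_durations_aggregate(self):
        events = [InteractionEvent(0, 1, s, s + 29, 1.0) for s in (0, 100, 200)]
        g = build_network(events, 3)
        assert g[0][1]["count"] == 3
        assert g[0][1]["duration_s"] == pytest.approx(3.0)
        assert not g.has_edge(1, 0)

    def test_adjacency_matches_manual_tally(self, criteria):
        # hand-built trajectory: flies 0,1 face-to-face for 20 frames; fly 2 far away
        n = 30
        frames = np.arange(n)
        x1 = np.where(frames < 20, 4.0, 30.0)
        tracks = [
            FlyTrack(0, frames, np.zeros(n), np.zeros(n), np.zeros(n)),
            FlyTrack(1, frames, x1, np.zeros(n), np.full(n, np.pi)),
            FlyTrack(2, frames, np.full(n, -25.0), np.full(n, 10.0), np.zeros(n)),
        ]
        events = detect_events(tracks, criteria, 30.0)
        g = build_network(events, 3)
        assert set(g.edges) == {(0, 1), (1, 0)}
        assert g[0][1]["count"] == g[1][0]["count"] == 1
        assert g[0][1]["duration_s"] == pytest.approx(20 / 30)

    def test_event_id_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_network([InteractionEvent(0, 5, 0, 10, 0.6)], 3)


def test_event_and_edge_tables_round_numbers(tmp_path, criteria):
    events = [InteractionEvent(0, 1, 0, 17, 0.6), InteractionEvent(1, 0, 5, 40, 1.2)]
    df = events_to_frame(events)
    assert list(df.columns) == ["actor", "target", "start_frame", "end_frame", "duration_s"]
    assert len(df) == 2
    g = build_network(events, 4)
    out = tmp_path / "edges.csv"
    write_edge_list(g, out)
    assert out.read_text().startswith("actor,target,count,duration_s")


def test_criteria_validation():
    with pytest.raises(ValueError):
        InteractionCriteria(min_duration_s=0)
    with pytest.raises(ValueError):
        InteractionCriteria(max_facing_angle_deg=400)
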