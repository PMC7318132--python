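"""Near-attack-conformation classification and accessibility profiles."""

from __future__ import annotations

import numpy as np
import pytest

from p450nac.geometry import pairwise_distance, three_point_angle
from p450nac.nac_profiler import (
    AccessibilityProfile,
    CatalyticCenter,
    NacCriterion,
    SiteDefinition,
    SiteMap,
    SiteStats,
    access_time_series,
    accessibility_profile,
    classify_frame,
    evaluate_hydrogen,
    load_site_map,
    read_profile_json,
    stereo_summary,
)
from p450nac.structure_io import write_profile_json

from conftest import OXO_POS, hydrogen_index, make_trajectory

OXO_Z = OXO_POS[2]


# ---------------------------------------------------------------------------
# evaluate_hydrogen


@pytest.mark.parametrize(
    "h_pos, accessible, d_expected, theta_expected",
    [
        # collinear above the oxo, inside the window
        ((0.0, 0.0, OXO_Z + 2.5), True, 2.5, 180.0),
        # distance beyond the ceiling
        ((0.0, 0.0, OXO_Z + 3.6), False, 3.6, 180.0),
        # inclusive distance bounds
        ((0.0, 0.0, OXO_Z + 2.0), True, 2.0, 180.0),
        ((0.0, 0.0, OXO_Z + 3.5), True, 3.5, 180.0),
    ],
)
def test_evaluate_hydrogen_boundaries(center, h_pos, accessible, d_expected,
                                      theta_expected):
    traj = make_trajectory([{"H1": h_pos}])
    got_access, d, theta = evaluate_hydrogen(
        traj.frames[0], hydrogen_index(traj, "H1"), center
    )
    assert d == pytest.approx(d_expected, abs=1e-9)
    assert theta == pytest.approx(theta_expected, abs=1e-7)
    assert got_access is accessible


def test_angle_threshold_is_strict(center):
    """An angle exactly at theta_min is not accessible ('above' is strict,
    unlike the inclusive distance bounds)."""
    # H at 2.5 Å from the oxo, ~120° from the oxo→Fe axis
    traj = make_trajectory(
        [{"H1": (2.5 * np.sqrt(3) / 2, 0.0, OXO_Z + 1.25)}]
    )
    h = hydrogen_index(traj, "H1")
    _, d, theta = evaluate_hydrogen(traj.frames[0], h, center)
    assert d == pytest.approx(2.5, abs=1e-9)
    assert theta == pytest.approx(120.0, abs=1e-7)
    # pin the threshold to the exactly-computed angle: strict ⇒ inaccessible
    at_boundary = NacCriterion(theta_min=theta)
    assert evaluate_hydrogen(traj.frames[0], h, center, at_boundary)[0] is False
    just_below = NacCriterion(theta_min=theta - 1e-9)
    assert evaluate_hydrogen(traj.frames[0], h, center, just_below)[0] is True


def test_evaluate_hydrogen_degenerate(center):
    traj = make_trajectory([{"H1": OXO_POS}])
    with pytest.raises(ValueError):
        evaluate_hydrogen(traj.frames[0], 2, center)


# ---------------------------------------------------------------------------
# classify_frame


def test_methyl_site_single_event_best_hydrogen(center):
    """Two of three methyl hydrogens accessible → one event, smaller H–oxo."""
    traj = make_trajectory(
        [{
            "H19A": (0.0, 0.0, OXO_Z + 2.8),
            "H19B": (0.0, 0.2, OXO_Z + 2.4),
            "H19C": (0.0, 0.0, OXO_Z + 6.0),
        }]
    )
    site_map = SiteMap({"19": SiteDefinition(
        tuple(hydrogen_index(traj, n) for n in ("H19A", "H19B", "H19C")),
        "methyl",
    )})
    events = classify_frame(traj.frames[0], site_map, center)
    assert len(events) == 1
    assert events[0].best_hydrogen == hydrogen_index(traj, "H19B")
    assert events[0].h_oxo < 2.5


def test_two_sites_two_events(two_site_fixture):
    traj, site_map, center = two_site_fixture
    events = classify_frame(traj.frames[2], site_map, center, frame_index=2)
    assert sorted(e.site for e in events) == ["A", "B"]


def test_no_accessible_hydrogen_empty(two_site_fixture):
    traj, site_map, center = two_site_fixture
    assert classify_frame(traj.frames[3], site_map, center) == []


def test_classify_matches_brute_force_oracle(center):
    """On random frames, classification agrees with a literal per-hydrogen
    re-evaluation of the distance window and angle threshold."""
    rng = np.random.default_rng(1234)
    criterion = NacCriterion()
    n_frames = 300
    names = ["HA", "HB", "HC", "HD", "HE"]
    site_of = {"HA": "s1", "HB": "s1", "HC": "s2", "HD": "s3", "HE": "s3"}
    for _ in range(n_frames):
        positions = {
            n: tuple(np.array(OXO_POS) + rng.uniform(-4.5, 4.5, 3))
            for n in names
        }
        traj = make_trajectory([positions])
        idx = {n: hydrogen_index(traj, n) for n in names}
        site_map = SiteMap({
            "s1": SiteDefinition((idx["HA"], idx["HB"])),
            "s2": SiteDefinition((idx["HC"],)),
            "s3": SiteDefinition((idx["HD"], idx["HE"])),
        })
        frame = traj.frames[0]
        # brute force: which sites have any hydrogen inside the criterion?
        expected_sites = set()
        for n in names:
            d = pairwise_distance(frame[idx[n]], frame[1])
            theta = three_point_angle(frame[idx[n]], frame[1], frame[0])
            if criterion.d_min <= d <= criterion.d_max and theta > criterion.theta_min:
                expected_sites.add(site_of[n])
        events = classify_frame(frame, site_map, center, criterion)
        assert {e.site for e in events} == expected_sites


def test_events_invariant_under_rigid_transform(two_site_fixture):
    """Rotating + translating every atom of a frame leaves events unchanged."""
    traj, site_map, center = two_site_fixture
    rng = np.random.default_rng(99)
    from scipy.spatial.transform import Rotation

    rotation = Rotation.random(rng=rng).as_matrix()
    translation = rng.uniform(-20, 20, 3)
    for f in range(traj.n_frames):
        before = classify_frame(traj.frames[f], site_map, center)
        moved = traj.frames[f] @ rotation.T + translation
        after = classify_frame(moved, site_map, center)
        assert [(e.site, e.best_hydrogen) for e in after] == [
            (e.site, e.best_hydrogen) for e in before
        ]
        for b, a in zip(before, after):
            assert a.h_oxo == pytest.approx(b.h_oxo, abs=1e-9)
            assert a.h_oxo_fe == pytest.approx(b.h_oxo_fe, abs=1e-7)


# ---------------------------------------------------------------------------
# accessibility_profile / access_time_series


def test_profile_hand_enumeration(two_site_fixture):
    """f1,f2 access {A}; f3 {A,B}; f4 none → A 75 %, B 25 % (events denom)."""
    traj, site_map, center = two_site_fixture
    profile = accessibility_profile(traj, site_map, center)
    assert profile.event_count("A") == 3
    assert profile.event_count("B") == 1
    assert profile.percentage("A") == pytest.approx(75.0)
    assert profile.percentage("B") == pytest.approx(25.0)
    assert profile.total_events == 4
    assert profile.total_frames == 4
    assert profile.frames_with_access == 3


def test_profile_frames_denominator(two_site_fixture):
    """Frames denominator: 3 frames with access → A 100 %, B 33.3 %."""
    traj, site_map, center = two_site_fixture
    profile = accessibility_profile(traj, site_map, center, denominator="frames")
    assert profile.percentage("A") == pytest.approx(100.0)
    assert profile.percentage("B") == pytest.approx(100.0 / 3)


def test_profile_all_zero_when_nothing_accessible(center):
    traj = make_trajectory([{"H1": (0.0, 0.0, OXO_Z + 8.0)}] * 3)
    site_map = SiteMap({"X": SiteDefinition((hydrogen_index(traj, "H1"),))})
    profile = accessibility_profile(traj, site_map, center)
    assert profile.total_events == 0
    assert profile.percentage("X") == 0.0


def test_time_series_matches_profile(two_site_fixture):
    traj, site_map, center = two_site_fixture
    records = access_time_series(traj, site_map, center)
    assert [r.accessed_sites for r in records] == [
        frozenset({"A"}), frozenset({"A"}), frozenset({"A", "B"}), frozenset(),
    ]
    profile = accessibility_profile(traj, site_map, center)
    counts = {"A": 0, "B": 0}
    for rec in records:
        for event in rec.events:
            counts[event.site] += 1
    assert counts == {
        label: profile.event_count(label) for label in ("A", "B")
    }


def test_skip_frames_trims_leading(two_site_fixture):
    traj, site_map, center = two_site_fixture
    profile = accessibility_profile(traj, site_map, center, skip_frames=2)
    assert profile.total_frames == 2
    assert profile.event_count("A") == 1
    assert profile.event_count("B") == 1


def test_criterion_widening_monotonicity(two_site_fixture):
    """Lower d_min / higher d_max / lower theta_min never lose events."""
    traj, site_map, center = two_site_fixture
    base = NacCriterion()
    counts_base = {
        label: accessibility_profile(traj, site_map, center, base).event_count(label)
        for label in site_map.sites
    }
    for wider in (
        base.widened(d_min=1.0),
        base.widened(d_max=7.0),
        base.widened(theta_min=90.0),
        NacCriterion(1.0, 7.0, 90.0),
    ):
        counts = {
            label: accessibility_profile(traj, site_map, center, wider)
            .event_count(label)
            for label in site_map.sites
        }
        assert all(counts[l] >= counts_base[l] for l in counts_base)


# ---------------------------------------------------------------------------
# stereo_summary


def test_stereo_summary_arithmetic():
    site_map = SiteMap({
        "2β": SiteDefinition((0,), "beta"),
        "2α": SiteDefinition((1,), "alpha"),
        "19": SiteDefinition((2,), "methyl"),
    })
    profile = AccessibilityProfile(
        per_site={
            "2β": SiteStats(2, 50.0),
            "2α": SiteStats(1, 25.0),
            "19": SiteStats(1, 25.0),
        },
        total_events=4, total_frames=4, frames_with_access=4,
    )
    summary = stereo_summary(profile, site_map)
    assert summary == pytest.approx(
        {"beta": 50.0, "alpha": 25.0, "methyl": 25.0, "other": 0.0}
    )


def test_stereo_summary_label_mismatch():
    site_map = SiteMap({"A": SiteDefinition((0,), "beta")})
    profile = AccessibilityProfile(
        per_site={"Z": SiteStats(1, 100.0)},
        total_events=1, total_frames=1, frames_with_access=1,
    )
    with pytest.raises(ValueError):
        stereo_summary(profile, site_map)


# ---------------------------------------------------------------------------
# site map file + profile JSON round trip


def test_load_site_map_resolves_selectors(tmp_path, center):
    traj = make_trajectory(
        [{"H6B": (0, 0, OXO_Z + 2.5), "H19A": (0, 0, OXO_Z + 6.0)}]
    )
    path = tmp_path / "sites.yaml"
    path.write_text(
        '"6β": {hydrogens: [{atom_name: H6B}], class: beta}\n'
        '"19": {hydrogens: [H19A], class: methyl}\n',
        encoding="utf-8",
    )
    site_map = load_site_map(path, traj)
    assert set(site_map.sites) == {"6β", "19"}
    assert site_map.sites["6β"].stereo_class == "beta"
    events = classify_frame(traj.frames[0], site_map, center)
    assert [e.site for e in events] == ["6β"]


def test_site_map_rejects_shared_hydrogen():
    with pytest.raises(ValueError):
        SiteMap({
            "A": SiteDefinition((2,)),
            "B": SiteDefinition((2, 3)),
        })


def test_profile_json_round_trip(tmp_path, two_site_fixture):
    traj, site_map, center = two_site_fixture
    profile = accessibility_profile(traj, site_map, center)
    path = tmp_path / "profile.json"
    write_profile_json(profile, path, site_map)
    back = read_profile_json(path)
    assert back.per_site == profile.per_site
    assert back.total_events == profile.total_events
    assert back.denominator == profile.denominator
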