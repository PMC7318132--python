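"""Near-attack-conformation classification and per-site accessibility profiles.

The reactive species of a P450, Compound I, abstracts a substrate hydrogen
via its iron-oxo moiety.  A trajectory frame puts a candidate site of
metabolism (SOM) in a near-attack conformation (NAC) when one of the site's
hydrogens lies within a distance window of the oxo atom and the
hydrogen–oxo–iron angle exceeds a threshold.  The default criterion is an
H–oxo distance of 2.0–3.5 Å (inclusive) and an H–oxo–Fe angle strictly above
120°, the geometry characteristic of the hydrogen-atom-transfer transition
species.

The accessibility profile counts, per site, the frames in which the site is
in a NAC, and expresses each count as a percentage of all access events
("events" denominator, the default — percentages then sum to 100) or of all
frames with at least one access ("frames" denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .geometry import pairwise_distance, three_point_angle
from .structure_io import AtomSelector, Trajectory, resolve_selector

logger = logging.getLogger("p450nac")

__all__ = [
    "STEREO_CLASSES",
    "CatalyticCenter",
    "SiteDefinition",
    "SiteMap",
    "NacCriterion",
    "SiteAccessEvent",
    "SiteStats",
    "AccessibilityProfile",
    "FrameRecord",
    "load_site_map",
    "evaluate_hydrogen",
    "classify_frame",
    "accessibility_profile",
    "access_time_series",
    "stereo_summary",
    "read_profile_json",
]

STEREO_CLASSES = ("alpha", "beta", "methyl", "other")

# Plausible Fe–oxo bond length window (Å); outside it the "catalytic center"
# is probably misselected, but profiling proceeds with a warning.
_FE_OXO_RANGE = (1.4, 2.2)


@dataclass(frozen=True)
class NacCriterion:
    """Geometric definition of a near-attack conformation.

    Distance bounds are inclusive ("in the range of"); the angle bound is
    strict ("above").
    """

    d_min: float = 2.0
    d_max: float = 3.5
    theta_min: float = 120.0

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max):
            raise ValueError("criterion requires 0 < d_min < d_max")
        if not (0 < self.theta_min < 180):
            raise ValueError("criterion requires 0 < theta_min < 180")

    def widened(self, *, d_min=None, d_max=None, theta_min=None) -> "NacCriterion":
        return NacCriterion(
            d_min=self.d_min if d_min is None else d_min,
            d_max=self.d_max if d_max is None else d_max,
            theta_min=self.theta_min if theta_min is None else theta_min,
        )


@dataclass(frozen=True)
class CatalyticCenter:
    """Topology indices of the Compound I iron and oxo atoms."""

    fe_index: int
    oxo_index: int

    def __post_init__(self) -> None:
        if self.fe_index == self.oxo_index:
            raise ValueError("fe_index and oxo_index must differ")

    def check_geometry(self, trajectory: Trajectory) -> None:
        """Warn (never fail) if the Fe–oxo distance looks non-physical."""
        fe = trajectory.frames[:, self.fe_index]
        oxo = trajectory.frames[:, self.oxo_index]
        dists = np.linalg.norm(fe - oxo, axis=1)
        bad = (dists <= _FE_OXO_RANGE[0]) | (dists >= _FE_OXO_RANGE[1])
        if bad.any():
            logger.warning(
                "Fe-oxo distance outside (%.1f, %.1f) A in %d/%d frames "
                "(min %.2f, max %.2f); check the Fe/oxo selectors",
                *_FE_OXO_RANGE, int(bad.sum()), len(dists),
                float(dists.min()), float(dists.max()),
            )


@dataclass(frozen=True)
class SiteDefinition:
    """Candidate abstractable hydrogens of one SOM plus its stereo class.

    Stereo-distinct hydrogens on the same carbon (6α vs 6β) are separate
    sites; a methyl site (18, 19) owns its three equivalent hydrogens.
    """

    hydrogens: tuple[int, ...]
    stereo_class: str = "other"

    def __post_init__(self) -> None:
        if not self.hydrogens:
            raise ValueError("a site needs at least one hydrogen index")
        if self.stereo_class not in STEREO_CLASSES:
            raise ValueError(
                f"stereo_class must be one of {STEREO_CLASSES}, "
                f"got {self.stereo_class!r}"
            )


@dataclass(frozen=True)
class SiteMap:
    """Mapping from site label (e.g. "6β", "19") to its hydrogen atoms."""

    sites: Mapping[str, SiteDefinition]

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for label, site in self.sites.items():
            for h in site.hydrogens:
                if h in seen:
                    raise ValueError(
                        f"hydrogen index {h} assigned to both "
                        f"{seen[h]!r} and {label!r}"
                    )
                seen[h] = label

    def validate_indices(self, trajectory: Trajectory) -> None:
        n = trajectory.n_atoms
        for label, site in self.sites.items():
            for h in site.hydrogens:
                if not 0 <= h < n:
                    raise ValueError(
                        f"site {label!r}: hydrogen index {h} out of range for "
                        f"{n}-atom topology"
                    )


def load_site_map(path: str | Path, trajectory: Trajectory) -> SiteMap:
    """Read a site-map file (YAML/JSON) and resolve its selectors.

    Expected structure::

        "6β": {hydrogens: [{atom_name: H6B}], class: beta}
        "19": {hydrogens: [{atom_name: H19A}, {atom_name: H19B}], class: methyl}

    Selector entries may also be bare strings, shorthand for the atom name.
    """
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: site map must be a non-empty mapping")
    sites: dict[str, SiteDefinition] = {}
    for label, entry in raw.items():
        if not isinstance(entry, dict) or "hydrogens" not in entry:
            raise ValueError(f"{path}: site {label!r} needs a 'hydrogens' list")
        indices = []
        for sel in entry["hydrogens"]:
            if isinstance(sel, str):
                selector = AtomSelector(atom_name=sel)
            else:
                selector = AtomSelector(
                    atom_name=sel["atom_name"],
                    chain_id=sel.get("chain_id"),
                    residue_id=sel.get("residue_id"),
                    residue_name=sel.get("residue_name"),
                )
            indices.append(resolve_selector(trajectory, selector))
        stereo = entry.get("class", "other")
        sites[str(label)] = SiteDefinition(tuple(indices), stereo)
    return SiteMap(sites)


@dataclass(frozen=True)
class SiteAccessEvent:
    """One site accessing the oxo moiety in one frame."""

    frame_index: int
    site: str
    best_hydrogen: int
    h_oxo: float
    h_oxo_fe: float


@dataclass(frozen=True)
class SiteStats:
    event_count: int
    percentage: float


@dataclass
class AccessibilityProfile:
    """Per-site access-event counts and percentages over an ensemble."""

    per_site: dict[str, SiteStats]
    total_events: int
    total_frames: int
    frames_with_access: int
    denominator: str = "events"

    def percentage(self, site: str) -> float:
        return self.per_site[site].percentage

    def event_count(self, site: str) -> int:
        return self.per_site[site].event_count


@dataclass(frozen=True)
class FrameRecord:
    """Per-frame record of the access time series."""

    frame_index: int
    events: tuple[SiteAccessEvent, ...]

    @property
    def accessed_sites(self) -> frozenset[str]:
        return frozenset(e.site for e in self.events)


# ---------------------------------------------------------------------------
# Classification


def evaluate_hydrogen(
    frame: np.ndarray,
    h_index: int,
    center: CatalyticCenter,
    criterion: NacCriterion = NacCriterion(),
) -> tuple[bool, float, float]:
    """Evaluate one hydrogen of one frame against the NAC criterion.

    Returns ``(accessible, h_oxo distance Å, h_oxo_fe angle °)``.
    """
    h = frame[h_index]
    oxo = frame[center.oxo_index]
    fe = frame[center.fe_index]
    h_oxo = pairwise_distance(h, oxo)
    h_oxo_fe = three_point_angle(h, oxo, fe)
    accessible = (
        criterion.d_min <= h_oxo <= criterion.d_max
        and h_oxo_fe > criterion.theta_min
    )
    return accessible, h_oxo, h_oxo_fe


def classify_frame(
    frame: np.ndarray,
    site_map: SiteMap,
    center: CatalyticCenter,
    criterion: NacCriterion = NacCriterion(),
    frame_index: int = 0,
) -> list[SiteAccessEvent]:
    """All site-access events of a single frame.

    A site is accessed iff at least one of its hydrogens satisfies the
    criterion (at most one event per site per frame, so the three equivalent
    hydrogens of a methyl site are never triple-counted).  The event records
    the accessible hydrogen with the smallest H–oxo distance, ties broken by
    the lowest atom index.  Distinct sites may each yield an event in the
    same frame.
    """
    events: list[SiteAccessEvent] = []
    for label, site in site_map.sites.items():
        best: tuple[float, int, float] | None = None  # (h_oxo, h_index, angle)
        for h_index in site.hydrogens:
            accessible, h_oxo, h_oxo_fe = evaluate_hydrogen(
                frame, h_index, center, criterion
            )
            if accessible and (best is None or (h_oxo, h_index) < best[:2]):
                best = (h_oxo, h_index, h_oxo_fe)
        if best is not None:
            events.append(
                SiteAccessEvent(
                    frame_index=frame_index,
                    site=label,
                    best_hydrogen=best[1],
                    h_oxo=best[0],
                    h_oxo_fe=best[2],
                )
            )
    return events


def access_time_series(
    trajectory: Trajectory,
    site_map: SiteMap,
    center: CatalyticCenter,
    criterion: NacCriterion = NacCriterion(),
    skip_frames: int = 0,
) -> list[FrameRecord]:
    """Frame-by-frame access records, in trajectory order.

    ``skip_frames`` drops the leading N frames (an equilibration trim).
    Aggregating the records reproduces :func:`accessibility_profile` counts
    exactly.
    """
    if skip_frames < 0:
        raise ValueError("skip_frames must be >= 0")
    site_map.validate_indices(trajectory)
    center.check_geometry(trajectory)
    records = []
    for f in range(skip_frames, trajectory.n_frames):
        events = classify_frame(
            trajectory.frames[f], site_map, center, criterion, frame_index=f
        )
        records.append(FrameRecord(frame_index=f, events=tuple(events)))
    return records


def profile_from_records(
    records: Sequence[FrameRecord],
    site_labels: Iterable[str],
    total_frames: int,
    denominator: str = "events",
) -> AccessibilityProfile:
    """Aggregate frame records into an accessibility profile."""
    if denominator not in ("events", "frames"):
        raise ValueError("denominator must be 'events' or 'frames'")
    counts = {label: 0 for label in site_labels}
    frames_with_access = 0
    for rec in records:
        if rec.events:
            frames_with_access += 1
        for event in rec.events:
            counts[event.site] += 1
    total_events = sum(counts.values())
    if denominator == "events":
        denom = total_events
    else:
        denom = frames_with_access
    if denom == 0:
        logger.warning("no access events in %d frames; all percentages zero",
                       total_frames)
        per_site = {label: SiteStats(0, 0.0) for label in counts}
    else:
        per_site = {
            label: SiteStats(count, 100.0 * count / denom)
            for label, count in counts.items()
        }
    return AccessibilityProfile(
        per_site=per_site,
        total_events=total_events,
        total_frames=total_frames,
        frames_with_access=frames_with_access,
        denominator=denominator,
    )


def accessibility_profile(
    trajectory: Trajectory,
    site_map: SiteMap,
    center: CatalyticCenter,
    criterion: NacCriterion = NacCriterion(),
    denominator: str = "events",
    skip_frames: int = 0,
) -> AccessibilityProfile:
    """Per-site accessibility percentages over a trajectory.

    With the default "events" denominator the percentage of a site is its
    access-event count divided by the total number of (frame, site) access
    events, so a frame exposing two sites contributes two to the denominator
    and percentages always sum to 100.  The "frames" denominator divides by
    the number of frames with at least one access instead (percentages may
    then exceed 100 in total).
    """
    records = access_time_series(
        trajectory, site_map, center, criterion, skip_frames=skip_frames
    )
    return profile_from_records(
        records,
        site_map.sites.keys(),
        total_frames=len(records),
        denominator=denominator,
    )


def read_profile_json(path: str | Path) -> AccessibilityProfile:
    """Read back a profile serialized by structure_io.write_profile_json."""
    import json

    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    per_site = {
        label: SiteStats(int(entry["event_count"]), float(entry["percentage"]))
        for label, entry in payload["per_site"].items()
    }
    return AccessibilityProfile(
        per_site=per_site,
        total_events=int(payload["total_events"]),
        total_frames=int(payload["total_frames"]),
        frames_with_access=int(payload["frames_with_access"]),
        denominator=payload.get("denominator", "events"),
    )


def stereo_summary(
    profile: AccessibilityProfile, site_map: SiteMap
) -> dict[str, float]:
    """Percentage of total access events per stereochemical class.

    Quantifies observations such as scaffold flips exposing a small
    proportion of α-face sites.
    """
    unknown = set(profile.per_site) - set(site_map.sites)
    if unknown:
        raise ValueError(
            f"profile sites missing from the site map: {sorted(unknown)}"
        )
    summary = {cls: 0.0 for cls in STEREO_CLASSES}
    for label, stats in profile.per_site.items():
        summary[site_map.sites[label].stereo_class] += stats.percentage
    return summary
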