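"""Synthetic active-site trajectories with known accessibility ground truth.

The generator emulates the statistical structure of an MD trajectory of a
P450 active site: in each frame the candidate sites of metabolism compete
stochastically for exposure to the Compound I oxo moiety.  One site is
"hit" per frame (drawn from a categorical distribution with per-site
probabilities p_s and background probability 1 − Σp_s); one of the hit
site's hydrogens is placed in a geometry that satisfies the near-attack
criterion by construction, all other hydrogens in geometries that violate
it.  The closed-form ground truth — per-site percentage 100·p_s/Σp_t and
access fraction Σp_s — makes end-to-end parameter-recovery tests possible.

This is NOT molecular dynamics: hydrogens are placed independently per
frame with no bonded geometry, no substrate rigid-body motion and no
protein.  The generator exercises the profiling statistics, not the
physics.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .nac_profiler import (
    CatalyticCenter,
    NacCriterion,
    SiteDefinition,
    SiteMap,
)
from .structure_io import (
    AtomRecord,
    Trajectory,
    atomic_write_text,
    write_multimodel_pdb,
)

logger = logging.getLogger("p450nac")

__all__ = [
    "SyntheticSiteSpec",
    "SyntheticSpec",
    "GroundTruth",
    "example_spec",
    "load_synthetic_spec",
    "build_toy_topology",
    "simulate_trajectory",
    "expected_profile",
    "write_outputs",
]

_FE_OXO_BOND = 1.62  # Å, ferryl Fe=O bond length used for the toy center


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """One competing site: hit probability, stereo class, hydrogen count."""

    probability: float
    stereo_class: str = "other"
    n_hydrogens: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("site probability must be in [0, 1]")
        if not 1 <= self.n_hydrogens <= 3:
            raise ValueError("a site carries 1-3 hydrogens")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full specification of a synthetic trajectory.

    Hit geometry is drawn inside the criterion window (distance uniform in
    ``hit_d``, angle uniform in ``hit_theta``, azimuth isotropic); miss
    geometry is an isotropic direction at a distance in ``miss_d``, beyond
    the criterion's distance ceiling.  ``coaccess`` optionally names a pair
    of sites hit jointly with a stated probability, producing the
    co-accessible frames needed to distinguish the events and frames
    percentage denominators.
    """

    sites: Mapping[str, SyntheticSiteSpec]
    n_frames: int = 10_000
    seed: int = 0
    hit_d: tuple[float, float] = (2.1, 3.4)
    hit_theta: tuple[float, float] = (125.0, 175.0)
    miss_d: tuple[float, float] = (4.5, 6.5)
    coaccess: tuple[str, str, float] | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("spec needs at least one site")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        total = self.total_hit_probability
        if total > 1.0 + 1e-12:
            raise ValueError(f"site probabilities sum to {total} > 1")
        if not (self.hit_d[0] < self.hit_d[1]):
            raise ValueError("hit_d window must be increasing")
        if self.miss_d[0] < 4.0:
            raise ValueError("miss distances must be >= 4.0 A")
        if self.coaccess is not None:
            a, b, prob = self.coaccess
            if a == b or a not in self.sites or b not in self.sites:
                raise ValueError("coaccess must name two distinct known sites")
            if not 0.0 <= prob <= 1.0:
                raise ValueError("coaccess probability must be in [0, 1]")

    @property
    def coaccess_probability(self) -> float:
        return self.coaccess[2] if self.coaccess is not None else 0.0

    @property
    def total_hit_probability(self) -> float:
        return sum(s.probability for s in self.sites.values()) + \
            self.coaccess_probability

    def check_within_criterion(self, criterion: NacCriterion) -> None:
        if not (criterion.d_min <= self.hit_d[0] and
                self.hit_d[1] <= criterion.d_max):
            raise ValueError("hit distance window must lie inside the criterion")
        if not self.hit_theta[0] > criterion.theta_min:
            raise ValueError("hit angles must lie above the criterion threshold")
        if self.miss_d[0] <= criterion.d_max:
            raise ValueError("miss distances must exceed the criterion ceiling")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations for a synthetic spec."""

    expected_percentages: dict[str, float]  # events-denominator percentages
    expected_access_fraction: float         # fraction of frames with >=1 access

    def __post_init__(self) -> None:
        total = sum(self.expected_percentages.values())
        if total > 0 and abs(total - 100.0) > 1e-9:
            raise ValueError(f"expected percentages sum to {total}, not 100")


def example_spec(n_frames: int = 10_000, seed: int = 42) -> SyntheticSpec:
    """The reference two-site competition: an angular methyl site drawing
    45 % of frames against a β-face site drawing 5 %, background 50 % —
    truth percentages 90/10, mirroring methyl-site dominance over a β site."""
    return SyntheticSpec(
        sites={
            "19": SyntheticSiteSpec(0.45, "methyl", 3),
            "6β": SyntheticSiteSpec(0.05, "beta", 1),
        },
        n_frames=n_frames,
        seed=seed,
    )


def load_synthetic_spec(path: str | Path) -> SyntheticSpec:
    """Read a spec from YAML/JSON.

    Structure::

        sites:
          "19": {probability: 0.45, class: methyl, n_hydrogens: 3}
          "6β": {probability: 0.05, class: beta}
        n_frames: 10000
        seed: 42
        coaccess: {site_a: "19", site_b: "6β", probability: 0.1}   # optional
    """
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "sites" not in raw:
        raise ValueError(f"{path}: spec must be a mapping with a 'sites' key")
    sites = {}
    for label, entry in raw["sites"].items():
        sites[str(label)] = SyntheticSiteSpec(
            probability=float(entry["probability"]),
            stereo_class=entry.get("class", "other"),
            n_hydrogens=int(entry.get("n_hydrogens", 1)),
        )
    kwargs: dict = {}
    for key in ("n_frames", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in ("hit_d", "hit_theta", "miss_d"):
        if key in raw:
            kwargs[key] = tuple(float(v) for v in raw[key])
    if "coaccess" in raw and raw["coaccess"] is not None:
        co = raw["coaccess"]
        kwargs["coaccess"] = (
            str(co["site_a"]), str(co["site_b"]), float(co["probability"])
        )
    unknown = set(raw) - {"sites", "n_frames", "seed", "hit_d", "hit_theta",
                          "miss_d", "coaccess"}
    if unknown:
        raise ValueError(f"{path}: unknown spec key(s): {sorted(unknown)}")
    return SyntheticSpec(sites=sites, **kwargs)


# ---------------------------------------------------------------------------
# Topology


def build_toy_topology(
    spec: SyntheticSpec,
) -> tuple[Trajectory, SiteMap, CatalyticCenter]:
    """Minimal Compound I + substrate topology.

    Iron at the origin, oxo at (0, 0, 1.62) Å; one dummy substrate carbon
    per site plus its hydrogens, all initially at miss geometry.  Atom names
    are unique so every selector resolves unambiguously, and the returned
    single-frame trajectory round-trips through multi-model PDB.
    """
    records: list[AtomRecord] = []
    serial = 1
    records.append(AtomRecord(serial, "FE", "HEM", 1, "A", "FE", (0.0, 0.0, 0.0)))
    serial += 1
    records.append(
        AtomRecord(serial, "OXO", "HEM", 1, "A", "O", (0.0, 0.0, _FE_OXO_BOND))
    )
    serial += 1

    site_defs: dict[str, SiteDefinition] = {}
    hydrogen_names: dict[str, list[str]] = {}
    suffixes = "ABC"
    for i, (label, site) in enumerate(spec.sites.items(), start=1):
        # dummy carbons sit on a ring of radius 6 A around the oxo, well
        # outside the criterion window
        phi = 2 * math.pi * (i - 1) / max(len(spec.sites), 1)
        carbon = (6.0 * math.cos(phi), 6.0 * math.sin(phi), _FE_OXO_BOND)
        records.append(AtomRecord(serial, f"C{i}", "LIG", 2, "A", "C", carbon))
        serial += 1
        indices = []
        names = []
        for j in range(site.n_hydrogens):
            name = f"H{i}{suffixes[j]}"
            pos = (carbon[0], carbon[1], carbon[2] + 1.1 * (j + 1))
            records.append(AtomRecord(serial, name, "LIG", 2, "A", "H", pos))
            indices.append(serial - 1)  # 0-based index == serial - 1
            names.append(name)
            serial += 1
        site_defs[label] = SiteDefinition(tuple(indices), site.stereo_class)
        hydrogen_names[label] = names

    frames = np.array([[r.position for r in records]], dtype=float)
    trajectory = Trajectory(topology=records, frames=frames)
    site_map = SiteMap(site_defs)
    center = CatalyticCenter(fe_index=0, oxo_index=1)
    trajectory._site_hydrogen_names = hydrogen_names  # for sitemap emission
    return trajectory, site_map, center


# ---------------------------------------------------------------------------
# Simulation


def _hit_position(oxo, axis_to_fe, d, theta_deg, phi, out=None):
    """Point at distance d from oxo whose angle to the oxo→Fe axis is theta."""
    theta = math.radians(theta_deg)
    # orthonormal frame around the oxo->Fe axis
    u = axis_to_fe
    e1 = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(e1, u)) > 0.9:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 = e1 - np.dot(e1, u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    direction = (
        math.cos(theta) * u
        + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2)
    )
    return oxo + d * direction


def _isotropic_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    while norm < 1e-12:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
    return v / norm


def simulate_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Draw a stochastic trajectory realizing the spec's site competition.

    Per frame, in a fixed documented order from a single seeded generator:
    (1) one uniform draw selects the frame category (co-access pair, a
    single site, or background); (2) for each hit site, one integer draw
    picks the exposed hydrogen and three draws place it (distance, angle,
    azimuth); (3) every remaining site hydrogen gets a miss geometry
    (distance draw + isotropic direction), in topology order.  The output is
    bit-identical for identical spec + seed.
    """
    spec.check_within_criterion(NacCriterion())
    base, site_map, center = build_toy_topology(spec)
    rng = np.random.default_rng(spec.seed)

    oxo = base.frames[0, center.oxo_index]
    fe = base.frames[0, center.fe_index]
    axis = (fe - oxo) / np.linalg.norm(fe - oxo)

    labels = list(spec.sites)
    probs = np.array([spec.sites[s].probability for s in labels])
    cum = np.cumsum(probs)
    c = spec.coaccess_probability

    frames = np.repeat(base.frames, spec.n_frames, axis=0)
    for f in range(spec.n_frames):
        u = rng.random()
        if c > 0 and u < c:
            hit_sites = [spec.coaccess[0], spec.coaccess[1]]
        else:
            u -= c
            k = int(np.searchsorted(cum, u, side="right"))
            hit_sites = [labels[k]] if k < len(labels) else []
        hit_hydrogens: dict[str, int] = {}
        for label in hit_sites:
            indices = site_map.sites[label].hydrogens
            chosen = indices[int(rng.integers(len(indices)))]
            d = rng.uniform(*spec.hit_d)
            theta = rng.uniform(*spec.hit_theta)
            phi = rng.uniform(0.0, 2 * math.pi)
            frames[f, chosen] = _hit_position(oxo, axis, d, theta, phi)
            hit_hydrogens[label] = chosen
        for label in labels:
            for h in site_map.sites[label].hydrogens:
                if hit_hydrogens.get(label) == h:
                    continue
                d = rng.uniform(*spec.miss_d)
                frames[f, h] = oxo + d * _isotropic_unit(rng)

    return Trajectory(topology=base.topology, frames=frames)


def expected_profile(spec: SyntheticSpec) -> GroundTruth:
    """Closed-form expectations under the events denominator.

    Per frame, site s yields an event with probability p_s plus the
    co-access probability when s belongs to the co-access pair; the expected
    percentage is the event probability over the summed event probabilities.
    """
    c = spec.coaccess_probability
    pair = set(spec.coaccess[:2]) if spec.coaccess is not None else set()
    event_prob = {
        label: site.probability + (c if label in pair else 0.0)
        for label, site in spec.sites.items()
    }
    total = sum(event_prob.values())
    if total == 0:
        logger.warning("all site probabilities are zero; truth is all-zero")
        percentages = {label: 0.0 for label in event_prob}
        return GroundTruth(percentages, 0.0)
    percentages = {label: 100.0 * p / total for label, p in event_prob.items()}
    access_fraction = sum(s.probability for s in spec.sites.values()) + c
    return GroundTruth(percentages, access_fraction)


# ---------------------------------------------------------------------------
# Emission


def write_outputs(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit trajectory.pdb, sitemap.yaml and truth.json for a spec.

    All three are directly consumable by the profiling pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trajectory = simulate_trajectory(spec)
    base, site_map, _center = build_toy_topology(spec)
    truth = expected_profile(spec)

    pdb_path = outdir / "trajectory.pdb"
    write_multimodel_pdb(trajectory, pdb_path)

    sitemap_payload = {
        label: {
            "hydrogens": [{"atom_name": n} for n in base._site_hydrogen_names[label]],
            "class": spec.sites[label].stereo_class,
        }
        for label in spec.sites
    }
    sitemap_path = outdir / "sitemap.yaml"
    atomic_write_text(
        sitemap_path,
        yaml.safe_dump(sitemap_payload, allow_unicode=True, sort_keys=False),
    )

    truth_path = outdir / "truth.json"
    atomic_write_text(
        truth_path,
        json.dumps(
            {
                "expected_percentages": truth.expected_percentages,
                "expected_access_fraction": truth.expected_access_fraction,
                "n_frames": spec.n_frames,
                "seed": spec.seed,
            },
            ensure_ascii=False,
            indent=2,
        ) + "\n",
    )
    return {"trajectory": pdb_path, "sitemap": sitemap_path, "truth": truth_path}
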