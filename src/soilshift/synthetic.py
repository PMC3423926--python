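"""Synthetic soil-community generator.

Emulates a two-soil phenanthrene-spiking microcosm study at the data level:
two soils x {control, spiked} x 3 replicate samples, sequenced to uneven
depths, with thousands of species-level OTUs following a long-tailed
(lognormal) abundance law.  Pollution responders are planted explicitly —
dominant genera rising to ~20% relative abundance in spiked soils, plus a
set of moderately abundant OTUs driven to zero ("diminished") — and the
generator returns the ground truth so every downstream statistic can be
checked against what was planted.

A companion generator emits DGGE-like lane-intensity profiles (Gaussian
band peaks over a gel gradient) with the same treatment structure, for the
fingerprint-comparison code path.

All randomness flows from one integer seed through named
``numpy.random.Generator`` streams; there is no global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .otu_report import RANKS, UNCLASSIFIED, OtuTable, SampleGroups

# -- specification -------------------------------------------------------------


@dataclass(frozen=True)
class EnrichedEffect:
    """One planted responder: a single OTU (with its own classified genus)
    raised in the spiked groups.

    Either ``target`` (absolute relative abundance in the spiked community,
    e.g. 0.20) or ``fold`` (> 1 multiplier on the control abundance) must be
    given.  ``soils`` = None plants the responder in every soil.
    """

    label: str
    target: float | None = None
    fold: float | None = None
    soils: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if (self.target is None) == (self.fold is None):
            raise ValueError(f"effect {self.label!r}: give exactly one of target/fold")
        if self.target is not None and not 0 < self.target < 1:
            raise ValueError(f"effect {self.label!r}: target must be in (0,1)")
        if self.fold is not None and self.fold <= 1:
            raise ValueError(f"effect {self.label!r}: fold must be > 1")


@dataclass(frozen=True)
class DiminishedEffect:
    """Planted decliners: `n` moderately abundant OTUs per scoped soil whose
    spiked-group probability is set exactly to zero (mode ``absent``) or
    multiplied by ``factor`` in (0, 1) (mode ``reduced``)."""

    n: int = 10
    mode: str = "absent"
    factor: float | None = None
    control_abundance: float = 0.01
    soils: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("absent", "reduced"):
            raise ValueError("mode must be 'absent' or 'reduced'")
        if self.mode == "reduced" and not (self.factor and 0 < self.factor < 1):
            raise ValueError("reduced mode needs factor in (0,1)")


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the simulated study.

    Defaults mirror the target scenario, a day-63 two-soil pyrosequencing
    design:
    12 samples (2 soils x control/spiked x 3 replicates), group mean +- sd
    sequencing depths of 3272+-640 (Cambisol control), 1695+-2079 (Cambisol
    spiked), 4420+-562 (Luvisol control) and 1964+-1869 (Luvisol spiked)
    truncated at a floor of 200 reads, ~2000 species-level OTUs with a
    lognormal abundance law, about 40% of OTUs unclassified at genus level,
    a 30% between-soil composition divergence, and Dirichlet-multinomial
    replicate overdispersion with concentration 100 (which reproduces
    between-replicate standard deviations of a few percent for a ~20%
    responder, a realistic replicate scatter for such designs).
    """

    n_otus: int = 2000
    n_phyla: int = 15
    n_classes: int = 30
    n_orders: int = 60
    n_families: int = 120
    n_genera: int = 250
    unclassified_genus_frac: float = 0.4
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 1.5
    soil_divergence: float = 0.3
    dirichlet_concentration: float | None = 100.0
    soils: tuple[str, ...] = ("Cambisol", "Luvisol")
    n_replicates: int = 3
    depth_by_group: tuple[tuple[str, str, float, float], ...] = (
        ("Cambisol", "control", 3272.0, 640.0),
        ("Cambisol", "spiked", 1695.0, 2079.0),
        ("Luvisol", "control", 4420.0, 562.0),
        ("Luvisol", "spiked", 1964.0, 1869.0),
    )
    depth_default: tuple[float, float] = (2500.0, 800.0)
    depth_floor: int = 200
    enriched: tuple[EnrichedEffect, ...] = ()
    diminished: tuple[DiminishedEffect, ...] = ()
    # DGGE gel model
    dgge_positions: int = 200
    dgge_bands: int = 25
    dgge_shared_band_frac: float = 0.6
    dgge_band_width: float = 2.0
    dgge_effect_fold: float = 5.0
    dgge_noise: float = 0.05

    @classmethod
    def study_emulation(cls, **overrides) -> "CommunitySpec":
        """Conditions of the emulated spiking study: two common responders
        (a dominant one raised to ~20% relative abundance and a secondary
        one to ~5%, the Sphingomonas/Polaromonas pattern) and ten
        moderately abundant OTUs absent from both spiked soils."""
        base = dict(
            enriched=(
                EnrichedEffect("responder_dominant", target=0.20),
                EnrichedEffect("responder_secondary", target=0.05),
            ),
            diminished=(DiminishedEffect(n=10, mode="absent"),),
        )
        base.update(overrides)
        return cls(**base)

    def depth_law(self, soil: str, treatment: str) -> tuple[float, float]:
        for s, t, mean, sd in self.depth_by_group:
            if s == soil and t == treatment:
                return mean, sd
        return self.depth_default


@dataclass
class GroundTruth:
    """What was planted: responders, decliners and the true per-sample
    proportion vectors."""

    enriched: list[dict]
    diminished: dict[str, list[str]]
    true_profiles: pd.DataFrame = field(repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "enriched": self.enriched,
            "diminished": self.diminished,
            "true_profiles": {
                s: self.true_profiles[s].round(10).to_dict()
                for s in self.true_profiles.columns
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Named substream of the run seed (taxonomy=0, profiles=1, reads=2, gel=3)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


# -- sample design -------------------------------------------------------------


def design(spec: CommunitySpec) -> SampleGroups:
    """Sample metadata for the simulated study (ids like T63CA1: soil
    initial + A(control)/P(spiked) + replicate)."""
    rows = []
    for soil in spec.soils:
        for treatment, code in (("control", "A"), ("spiked", "P")):
            for rep in range(1, spec.n_replicates + 1):
                sid = f"T63{soil[0].upper()}{code}{rep}"
                rows.append((sid, soil, treatment, rep))
    frame = pd.DataFrame(rows, columns=["sample_id", "soil", "treatment", "replicate"])
    return SampleGroups(frame.set_index("sample_id"))


# -- taxonomy ------------------------------------------------------------------


def generate_taxonomy(spec: CommunitySpec, seed: int) -> pd.DataFrame:
    """Random but internally consistent six-rank lineages for ``n_otus`` OTUs.

    The rank hierarchy is a tree: each genus maps to exactly one family,
    each family to one order, and so on.  A fraction of OTUs is truncated to
    ``unclassified`` at genus level, mimicking reads that cannot be reliably
    classified that deep.
    """
    rng = _rng(seed, 0)
    phyla = [f"Phylum{i:02d}" for i in range(1, spec.n_phyla + 1)]
    classes = [f"Class{i:02d}" for i in range(1, spec.n_classes + 1)]
    orders = [f"Order{i:02d}" for i in range(1, spec.n_orders + 1)]
    families = [f"Family{i:03d}" for i in range(1, spec.n_families + 1)]
    genera = [f"Genus{i:03d}" for i in range(1, spec.n_genera + 1)]

    def parents(children: list[str], parent_pool: list[str]) -> dict[str, str]:
        # every parent used at least once, remainder assigned at random
        picks = list(parent_pool) + list(
            rng.choice(parent_pool, size=max(0, len(children) - len(parent_pool)))
        )
        rng.shuffle(picks)
        return dict(zip(children, picks))

    class_parent = parents(classes, phyla)
    order_parent = parents(orders, classes)
    family_parent = parents(families, orders)
    genus_parent = parents(genera, families)

    otu_ids = [f"OTU{i:05d}" for i in range(1, spec.n_otus + 1)]
    if spec.n_otus >= spec.n_genera:
        # every genus realized at least once, remainder at random
        otu_genus = np.array(
            genera + list(rng.choice(genera, size=spec.n_otus - spec.n_genera))
        )
        rng.shuffle(otu_genus)
    else:
        otu_genus = rng.choice(genera, size=spec.n_otus)
    unclassified = rng.random(spec.n_otus) < spec.unclassified_genus_frac
    rows = []
    for g, uncl in zip(otu_genus, unclassified):
        fam = genus_parent[g]
        order = family_parent[fam]
        cls = order_parent[order]
        phy = class_parent[cls]
        rows.append(["Bacteria", phy, cls, order, fam, UNCLASSIFIED if uncl else g])
    return pd.DataFrame(rows, index=otu_ids, columns=list(RANKS))


# -- true community profiles ---------------------------------------------------


def generate_true_profiles(
    spec: CommunitySpec, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """True per-sample OTU proportion vectors plus the planted ground truth.

    Control profiles per soil are a lognormal base community with a fraction
    ``soil_divergence`` of OTU abundances independently redrawn per soil.
    Spiked profiles start from the soil's control profile, zero (or shrink)
    the planted decliners, pin each planted responder at its target share
    (or multiply by its fold), and renormalize the remaining mass.
    """
    rng = _rng(seed, 1)
    groups = design(spec)
    lineages = generate_taxonomy(spec, seed)
    otu_ids = list(lineages.index)
    n = spec.n_otus

    base = rng.lognormal(spec.abundance_meanlog, spec.abundance_sdlog, size=n)

    # choose planted OTUs once, shared across soils; responders need a
    # classified genus, all planted OTUs are distinct
    classified = np.flatnonzero((lineages["genus"] != UNCLASSIFIED).to_numpy())
    taken: set[int] = set()
    enriched_truth: list[dict] = []
    enriched_idx: dict[str, int] = {}
    for eff in spec.enriched:
        pool = np.array([i for i in classified if i not in taken])
        # prefer a genus not shared with other OTUs so the genus-level signal
        # is carried by the responder alone when possible
        genus_counts = lineages["genus"].value_counts()
        singles = [i for i in pool if genus_counts[lineages["genus"].iloc[i]] == 1]
        i = int(rng.choice(singles if singles else pool))
        taken.add(i)
        enriched_idx[eff.label] = i
        enriched_truth.append(
            {
                "label": eff.label,
                "otu_id": otu_ids[i],
                "genus": str(lineages["genus"].iloc[i]),
                "soils": list(eff.soils) if eff.soils else list(spec.soils),
                "target": eff.target,
                "fold": eff.fold,
            }
        )

    diminished_idx: dict[str, list[int]] = {soil: [] for soil in spec.soils}
    for dim in spec.diminished:
        scoped = list(dim.soils) if dim.soils else list(spec.soils)
        pool = np.array([i for i in range(n) if i not in taken])
        chosen = rng.choice(pool, size=dim.n, replace=False)
        taken.update(int(i) for i in chosen)
        for soil in scoped:
            diminished_idx[soil].extend(int(i) for i in chosen)

    controls: dict[str, np.ndarray] = {}
    for soil in spec.soils:
        prof = base.copy()
        k = int(round(spec.soil_divergence * n))
        if k:
            idx = rng.choice(n, size=k, replace=False)
            prof[idx] = rng.lognormal(spec.abundance_meanlog, spec.abundance_sdlog, size=k)
        prof = prof / prof.sum()
        # plant decliners at a fixed, moderately high control share so the
        # "times the average detected OTU" rules have something to find
        pinned: dict[int, float] = {}
        for dim in spec.diminished:
            scoped = list(dim.soils) if dim.soils else list(spec.soils)
            if soil not in scoped:
                continue
            for i in diminished_idx[soil]:
                pinned[i] = dim.control_abundance
        if pinned:
            free = np.ones(n, dtype=bool)
            free[list(pinned)] = False
            pin_total = sum(pinned.values())
            prof[~free] = 0.0
            prof[free] *= (1.0 - pin_total) / prof[free].sum()
            for i, v in pinned.items():
                prof[i] = v
        controls[soil] = prof

    spiked: dict[str, np.ndarray] = {}
    for soil in spec.soils:
        prof = controls[soil].copy()
        for dim in spec.diminished:
            scoped = list(dim.soils) if dim.soils else list(spec.soils)
            if soil not in scoped:
                continue
            for i in diminished_idx[soil]:
                prof[i] = 0.0 if dim.mode == "absent" else prof[i] * dim.factor
        pinned = {}
        for eff in spec.enriched:
            scoped = list(eff.soils) if eff.soils else list(spec.soils)
            if soil not in scoped:
                continue
            i = enriched_idx[eff.label]
            if eff.target is not None:
                pinned[i] = eff.target
            else:
                prof[i] *= eff.fold
        if pinned:
            free = np.ones(n, dtype=bool)
            free[list(pinned)] = False
            pin_total = sum(pinned.values())
            prof[~free] = 0.0
            prof[free] *= (1.0 - pin_total) / prof[free].sum()
            for i, v in pinned.items():
                prof[i] = v
        else:
            prof = prof / prof.sum()
        spiked[soil] = prof

    cols = {}
    for sid in groups.sample_ids:
        soil = str(groups.frame.loc[sid, "soil"])
        treatment = str(groups.frame.loc[sid, "treatment"])
        cols[sid] = controls[soil] if treatment == "control" else spiked[soil]
    profiles = pd.DataFrame(cols, index=otu_ids)

    truth = GroundTruth(
        enriched=enriched_truth,
        diminished={s: [otu_ids[i] for i in idx] for s, idx in diminished_idx.items()},
        true_profiles=profiles,
    )
    return profiles, truth


# -- read sampling -------------------------------------------------------------


def _truncated_normal_depth(
    rng: np.random.Generator, mean: float, sd: float, floor: int
) -> int:
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if d >= floor:
            return int(round(d))
    return floor


def sample_reads(
    profiles: pd.DataFrame, spec: CommunitySpec, seed: int
) -> OtuTable:
    """Draw read counts: per sample, a truncated-normal depth and a
    multinomial draw on a Dirichlet-perturbed copy of the true profile
    (concentration ``dirichlet_concentration``; None = exact multinomial).

    Structural zeros in the true profile stay exactly zero.  OTUs observed
    in no sample are dropped, as in a real OTU report.
    """
    rng = _rng(seed, 2)
    groups = design(spec)
    counts = {}
    for sid in profiles.columns:
        soil = str(groups.frame.loc[sid, "soil"])
        treatment = str(groups.frame.loc[sid, "treatment"])
        mean, sd = spec.depth_law(soil, treatment)
        depth = _truncated_normal_depth(rng, mean, sd, spec.depth_floor)
        p = profiles[sid].to_numpy()
        if spec.dirichlet_concentration is not None:
            q = np.zeros_like(p)
            nz = p > 0
            g = rng.gamma(spec.dirichlet_concentration * p[nz])
            total = g.sum()
            q[nz] = g / total if total > 0 else p[nz]
        else:
            q = p
        counts[sid] = rng.multinomial(depth, q / q.sum())
    table = pd.DataFrame(counts, index=profiles.index)
    detected = table.sum(axis=1) > 0
    lineages = generate_taxonomy(spec, seed)
    return OtuTable(table.loc[detected], lineages.loc[detected])


# -- DGGE lane profiles --------------------------------------------------------


def generate_dgge_profiles(spec: CommunitySpec, seed: int) -> pd.DataFrame:
    """Lane-intensity matrix (gel position x lane) emulating a DGGE gel.

    Each soil community is a set of Gaussian band peaks (positions shared
    across soils for ``dgge_shared_band_frac`` of bands); spiking multiplies
    one band per planted responder by ``dgge_effect_fold`` in the scoped
    soils.  Additive Gaussian noise with sd ``dgge_noise`` x the mean band
    height is applied per lane and clipped at zero; with ``dgge_noise = 0``
    replicate lanes are identical.
    """
    rng = _rng(seed, 3)
    groups = design(spec)
    pos = np.arange(spec.dgge_positions, dtype=float)

    n_shared = int(round(spec.dgge_shared_band_frac * spec.dgge_bands))
    shared_pos = rng.uniform(5, spec.dgge_positions - 5, size=n_shared)
    shared_int = rng.lognormal(0.0, 0.8, size=n_shared)

    def lane_profile(centers, heights):
        z = (pos[:, None] - centers[None, :]) / spec.dgge_band_width
        return (heights[None, :] * np.exp(-0.5 * z**2)).sum(axis=1)

    soil_bands: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    responder_band: dict[str, np.ndarray] = {}
    for soil in spec.soils:
        n_own = spec.dgge_bands - n_shared
        centers = np.concatenate(
            [shared_pos, rng.uniform(5, spec.dgge_positions - 5, size=n_own)]
        )
        heights = np.concatenate([shared_int, rng.lognormal(0.0, 0.8, size=n_own)])
        soil_bands[soil] = (centers, heights)
        responder_band[soil] = rng.choice(
            spec.dgge_bands, size=min(len(spec.enriched), spec.dgge_bands), replace=False
        )

    lanes = {}
    mean_height = float(np.mean(shared_int)) if n_shared else 1.0
    for sid in groups.sample_ids:
        soil = str(groups.frame.loc[sid, "soil"])
        treatment = str(groups.frame.loc[sid, "treatment"])
        centers, heights = soil_bands[soil]
        heights = heights.copy()
        if treatment == "spiked":
            for b, eff in zip(responder_band[soil], spec.enriched):
                scoped = list(eff.soils) if eff.soils else list(spec.soils)
                if soil in scoped:
                    heights[b] *= spec.dgge_effect_fold
        profile = lane_profile(centers, heights)
        if spec.dgge_noise > 0:
            profile = profile + rng.normal(0.0, spec.dgge_noise * mean_height, size=len(pos))
        lanes[sid] = np.clip(profile, 0.0, None)
    return pd.DataFrame(lanes, index=pd.Index(pos, name="position"))


# -- convenience bundle --------------------------------------------------------


@dataclass
class SimulatedDataset:
    table: OtuTable
    groups: SampleGroups
    dgge: pd.DataFrame
    truth: GroundTruth
    spec: CommunitySpec
    seed: int


def simulate_dataset(spec: CommunitySpec, seed: int) -> SimulatedDataset:
    """Full simulated study: OTU report, metadata, gel profiles, ground truth."""
    profiles, truth = generate_true_profiles(spec, seed)
    table = sample_reads(profiles, spec, seed)
    dgge = generate_dgge_profiles(spec, seed)
    return SimulatedDataset(table, design(spec), dgge, truth, spec, seed)
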