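"""Synthetic worlds with known ground truth: an ultrametric phylogeny,
Brownian-evolving cochlear geometry, linked audiograms and ABR variants.

The generative family is a conical-exponential spiral,

    x(s) = r(s) cos(2 pi T s),  y(s) = r(s) sin(2 pi T s),  z(s) = H s,
    r(s) = r0 exp(-k s),        s in [0, 1],

with an undulation u sin(2 pi T s) added to z over the basal turn
(s <= 1/T; one full sine period, so the curve stays continuous).  Four
interpretable parameters (turns T, basal radius r0, decay k, height H)
span the observed range from flat/wide "primate-like" to tall, tightly
coiled "tower" cochleae, and every downstream metric has a closed-form or
quadrature truth.  The bony tube has radius rho0 (1 - c s), so the
cross-section area at station s is pi rho0^2 (1 - c s)^2; the oval window
is a planar ellipse.

Hearing is tied to morphology through a linear linkage on
(log10 CL, NT, log10 OWA, log10 CW): each response (log2 LFC, log2 HFC,
SPL1) is intercept + slopes . (predictors - reference) + Gaussian noise.
Audiogram threshold curves are lower envelopes of one (V) or two (W)
parabolas in (log2 f, dB) anchored to cross the 60 dB SPL criterion at
the true cut-offs.

All randomness flows from one root seed through a fixed
numpy.random.SeedSequence spawn order (tree, trait evolution, traits
table, one stream per specimen render, one per audiogram), so a world is
bit-identical under regeneration from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy.integrate import quad

from . import geometry
from .io_formats import (
    AudiogramRecord,
    LandmarkFile,
    Phylogeny,
    write_audiogram_table,
    write_landmark_file,
    write_newick,
    write_trait_table,
)

CUTOFF_DB = 60.0


@dataclass
class MorphoArchetype:
    """Generative cochlea parameters (lengths in mm)."""

    name: str
    turns: float          # T, > 1
    basal_radius: float   # r0
    radius_decay: float   # k, r(s) = r0 exp(-k s)
    height: float         # H
    tube_radius0: float   # rho0
    tube_taper: float     # c in [0, 1)
    undulation: float     # u, basal-turn z amplitude

    def __post_init__(self):
        if self.turns <= 1:
            raise ValueError("turns must exceed 1")
        if min(self.basal_radius, self.height, self.tube_radius0) <= 0:
            raise ValueError("r0, H, rho0 must be positive")
        if not (0 <= self.tube_taper < 1):
            raise ValueError("tube taper must lie in [0, 1)")


@dataclass
class LinkageModel:
    """Linear map from true morphology to audiometric truth.

    Responses: log2 LFC (kHz), log2 HFC (kHz), SPL1 (dB SPL).  Predictors
    (log10 CL, NT, log10 OWA, log10 CW) enter centered at ``reference``.
    """

    intercepts: dict[str, float]
    slopes: dict[str, dict[str, float]]  # response -> predictor -> slope
    residual_sd: dict[str, float]
    reference: dict[str, float]

    def __post_init__(self):
        if any(sd < 0 for sd in self.residual_sd.values()):
            raise ValueError("residual s.d. must be >= 0")

    def predict(self, predictors: dict[str, float], rng: np.random.Generator
                ) -> dict[str, float]:
        out = {}
        for resp, icpt in self.intercepts.items():
            v = icpt
            for pred, slope in self.slopes.get(resp, {}).items():
                v += slope * (predictors[pred] - self.reference.get(pred, 0.0))
            v += rng.normal(0.0, self.residual_sd.get(resp, 0.0))
            out[resp] = v
        return {
            "LFC": 2.0 ** out["log2_lfc"],
            "HFC": 2.0 ** out["log2_hfc"],
            "SPL1": out["spl1"],
        }


def default_linkage() -> LinkageModel:
    """Effect directions follow the study system: longer, more tightly
    coiled cochleae lower the low-frequency limit; larger oval windows and
    more coiling lower the high-frequency limit; wider basal turns improve
    1 kHz sensitivity."""
    return LinkageModel(
        intercepts={"log2_lfc": math.log2(0.25),
                    "log2_hfc": math.log2(40.0),
                    "spl1": 32.0},
        slopes={
            "log2_lfc": {"log10_cl": -4.0, "nt": -0.8},
            "log2_hfc": {"log10_owa": -1.2, "nt": -0.3},
            "spl1": {"log10_cw": -60.0, "nt": -4.0},
        },
        residual_sd={"log2_lfc": 0.25, "log2_hfc": 0.25, "spl1": 2.5},
        reference={"log10_cl": math.log10(19.0), "nt": 2.5,
                   "log10_owa": math.log10(1.1), "log10_cw": math.log10(3.6)},
    )


# ----------------------------------------------------------------- trees


def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0, root_age: float = 75.0
) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree, depth rescaled to ``root_age`` (Myr).

    The root splits at time 0; thereafter lineages split after exponential
    waits with total rate (k * birth_rate), the splitting lineage chosen
    uniformly.  A final exponential wait past the n-th split keeps every
    terminal branch strictly positive; all branch lengths are then scaled
    so the tip depth equals ``root_age``.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth_times = {id(root): 0.0}
    active = []
    for _ in range(2):
        child = root.new_child()
        birth_times[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        parent = active.pop(int(rng.integers(k)))
        parent.edge.length = t - birth_times[id(parent)]
        for _ in range(2):
            child = parent.new_child()
            birth_times[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (n_tips * birth_rate))
    factor = root_age / t_end
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node in active:
            node.edge.length = (t_end - birth_times[id(node)]) * factor
        else:
            node.edge.length *= factor
    width = len(str(n_tips))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"sp{i:0{width}d}")
    return Phylogeny(tree)


# --------------------------------------------------------- trait evolution

#: fields evolving multiplicatively (BM on log scale enforces positivity)
LOG_SCALE_FIELDS = ("basal_radius", "height", "tube_radius0")
#: fields evolving additively, with a hard lower clip
NATURAL_SCALE_FIELDS = {"turns": 1.05, "undulation": 0.0, "radius_decay": 0.05,
                        "tube_taper": 0.0}


def evolve_traits(
    phy: Phylogeny,
    root_archetype: MorphoArchetype,
    bm_rates: dict[str, float],
    group_shifts: dict[str, dict[str, float]] | None = None,
    clades: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> dict[str, MorphoArchetype]:
    """Evolve each archetype field as Brownian motion along the tree.

    r0, H and rho0 evolve on the log scale (positivity); T, k, c and u
    evolve additively with a lower clip.  ``group_shifts`` adds a fixed
    offset on the evolving scale at the stem of the named clade (defined
    by ``clades[name]`` tip labels); a shift naming an unknown clade is an
    error.
    """
    group_shifts = group_shifts or {}
    clades = clades or {}
    for name in group_shifts:
        if name not in clades:
            raise ValueError(f"shift on unknown clade {name!r}")
    if any(r < 0 for r in bm_rates.values()):
        raise ValueError("BM rates must be >= 0")
    shift_nodes: dict[int, dict[str, float]] = {}
    for name, shifts in group_shifts.items():
        tips = clades[name]
        mrca = phy.tree.mrca(taxon_labels=tips)
        if mrca is None:
            raise ValueError(f"clade {name!r} tips not found in tree")
        shift_nodes.setdefault(id(mrca), {})
        for fld, val in shifts.items():
            shift_nodes[id(mrca)][fld] = shift_nodes[id(mrca)].get(fld, 0.0) + val

    rng = np.random.default_rng(seed)
    fields_ = list(LOG_SCALE_FIELDS) + list(NATURAL_SCALE_FIELDS)
    root_vals = {}
    for fld in fields_:
        v = getattr(root_archetype, fld)
        root_vals[fld] = math.log(v) if fld in LOG_SCALE_FIELDS else v

    node_vals: dict[int, dict[str, float]] = {}
    tip_vals: dict[str, dict[str, float]] = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            vals = dict(root_vals)
        else:
            parent = node_vals[id(node.parent_node)]
            bl = node.edge.length
            vals = {}
            for fld in fields_:
                rate = bm_rates.get(fld, 0.0)
                incr = rng.normal(0.0, math.sqrt(rate * bl)) if rate > 0 else 0.0
                vals[fld] = parent[fld] + incr
        for fld, sh in shift_nodes.get(id(node), {}).items():
            vals[fld] += sh
        node_vals[id(node)] = vals
        if node.is_leaf():
            tip_vals[node.taxon.label] = vals

    out = {}
    for sp in phy.tip_labels:
        vals = tip_vals[sp]
        kwargs = {}
        for fld in fields_:
            v = vals[fld]
            if fld in LOG_SCALE_FIELDS:
                v = math.exp(v)
            else:
                v = max(v, NATURAL_SCALE_FIELDS[fld])
            kwargs[fld] = v
        kwargs["tube_taper"] = min(kwargs["tube_taper"], 0.95)
        out[sp] = MorphoArchetype(name=sp, **kwargs)
    return out


# ------------------------------------------------------------- rendering


def _spiral_point(arch: MorphoArchetype, s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, float)
    theta = 2.0 * np.pi * arch.turns * s
    r = arch.basal_radius * np.exp(-arch.radius_decay * s)
    z = arch.height * s
    basal = s <= 1.0 / arch.turns
    z = z + np.where(basal, arch.undulation * np.sin(2.0 * np.pi * arch.turns * s), 0.0)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def analytic_arc_length(arch: MorphoArchetype) -> float:
    """Arc length of the noiseless spiral by adaptive quadrature."""
    T, r0, k, H, u = (arch.turns, arch.basal_radius, arch.radius_decay,
                      arch.height, arch.undulation)

    def speed(s):
        r = r0 * math.exp(-k * s)
        dr = -k * r
        dtheta = 2.0 * math.pi * T
        dz = H
        if s <= 1.0 / T:
            dz += u * 2.0 * math.pi * T * math.cos(2.0 * math.pi * T * s)
        return math.sqrt(dr * dr + (r * dtheta) ** 2 + dz * dz)

    sb = 1.0 / T
    a1, _ = quad(speed, 0.0, sb, limit=200)
    a2, _ = quad(speed, sb, 1.0, limit=200)
    return a1 + a2


def analytic_width(arch: MorphoArchetype, n: int = 2000) -> float:
    """Max pairwise planar distance within the basal turn (dense truth)."""
    s = np.linspace(0.0, 1.0 / arch.turns, n)
    r = arch.basal_radius * np.exp(-arch.radius_decay * s)
    th = 2.0 * np.pi * arch.turns * s
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    from scipy.spatial.distance import pdist
    return float(pdist(pts).max())


def tube_area(arch: MorphoArchetype, s) -> np.ndarray:
    """Cross-section area pi (rho0 (1 - c s))^2 at arc fraction s."""
    s = np.asarray(s, float)
    return np.pi * (arch.tube_radius0 * (1.0 - arch.tube_taper * s)) ** 2


def oval_window_semi_axes(arch: MorphoArchetype) -> tuple[float, float]:
    return 1.2 * arch.tube_radius0, 0.8 * arch.tube_radius0


def render_cochlea(
    arch: MorphoArchetype,
    n_raw_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_stations: int = 130,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One specimen's measured geometry.

    Returns ``(curve, rw_landmarks, station_areas, ow_outline)`` where
    ``curve`` is the raw digitized polyline from the second round-window
    landmark (s = 0) to the apex (s = 1), ``rw_landmarks`` the two
    round-window anchor points (LM1 above the tube, LM2 = curve start),
    ``station_areas`` the tube cross-section areas at the ``n_stations``
    configuration stations (equal arc-length fractions), and
    ``ow_outline`` a noisy planar ellipse near the round window.
    I.i.d. Gaussian coordinate noise of sd ``noise_sd`` mm is added to
    every digitized point.
    """
    if n_raw_points < 20:
        raise ValueError("n_raw_points must be >= 20")
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n_raw_points)
    curve = _spiral_point(arch, s)
    lm2 = curve[0].copy()
    lm1 = lm2 + np.array([0.0, 0.0, 1.6 * arch.tube_radius0])
    if noise_sd > 0:
        curve = curve + rng.normal(0.0, noise_sd, curve.shape)
        lm1 = lm1 + rng.normal(0.0, noise_sd, 3)
        curve[0] = lm2  # LM2 is the shared anchor; keep identical
    rw = np.vstack([lm1, lm2])
    station_s = np.linspace(0.0, 1.0, n_stations - 1)  # LM2..apex stations
    station_areas = np.concatenate([[tube_area(arch, 0.0)],
                                    tube_area(arch, station_s)])
    a, b = oval_window_semi_axes(arch)
    t = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    ow = np.column_stack([
        lm2[0] + a * np.cos(t),
        lm2[1] + 0.0 * t,
        lm2[2] + 0.8 * arch.tube_radius0 + b * np.sin(t),
    ])
    if noise_sd > 0:
        ow = ow + rng.normal(0.0, 0.2 * noise_sd, ow.shape)
    return curve, rw, station_areas, ow


# ------------------------------------------------------------ audiograms


def default_frequency_grid() -> np.ndarray:
    """Half-octave ladder 0.063-64 kHz, the span literature audiograms use."""
    return 0.0625 * 2.0 ** (0.5 * np.arange(21))


def generate_audiogram(
    species: str,
    lfc_true: float,
    hfc_true: float,
    spl1_true: float | None = None,
    shape: str = "V",
    frequency_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    peak_sensitivity: float = 15.0,
    w_depth_offset: float = 5.0,
    w_cf_fractions: tuple[float, float] = (0.30, 0.72),
) -> tuple[AudiogramRecord, dict[str, float]]:
    """Threshold curve crossing 60 dB SPL at the true cut-offs.

    V: one parabola in (log2 f, dB) with vertex midway between the
    cut-offs; if ``spl1_true`` is given the vertex depth is solved so the
    curve passes through (1 kHz, SPL1).  W: the lower envelope of two
    parabolas with vertices at ``w_cf_fractions`` of the log2 span, the
    high-frequency dip ``w_depth_offset`` dB deeper.  Returns the sampled
    record (grid restricted to where the envelope is informative) and the
    truth dict (LFC, HFC, CF1, CF2, PS, SPL1).
    """
    if not (lfc_true < 1.0 < hfc_true):
        raise ValueError(f"need LFC < 1 kHz < HFC, got {lfc_true}, {hfc_true}")
    grid = default_frequency_grid() if frequency_grid is None else np.asarray(frequency_grid, float)
    xl, xh = math.log2(lfc_true), math.log2(hfc_true)
    rng = np.random.default_rng(seed)

    if shape == "V":
        xv = 0.5 * (xl + xh)
        half = xh - xv
        if spl1_true is not None:
            w = (xv / half) ** 2  # weight of the criterion at 1 kHz (x=0)
            if w >= 1.0:
                raise ValueError("1 kHz outside the cut-off span; cannot anchor SPL1")
            ps = (spl1_true - CUTOFF_DB * w) / (1.0 - w)
        else:
            ps = peak_sensitivity
        if not (0.0 < ps < CUTOFF_DB - 2.0):
            raise ValueError(f"infeasible anchoring: vertex depth {ps:.1f} dB")
        a = (CUTOFF_DB - ps) / half**2

        def envelope(x):
            return ps + a * (x - xv) ** 2

        cf1 = cf2 = 2.0 ** xv
        ps_true = ps
    elif shape == "W":
        xc1 = xl + w_cf_fractions[0] * (xh - xl)
        xc2 = xl + w_cf_fractions[1] * (xh - xl)
        d2 = peak_sensitivity
        d1 = peak_sensitivity + w_depth_offset
        if not (0.0 < d2 < CUTOFF_DB - 2.0 and 0.0 < d1 < CUTOFF_DB - 2.0):
            raise ValueError("infeasible W anchoring")
        a1 = (CUTOFF_DB - d1) / (xc1 - xl) ** 2
        a2 = (CUTOFF_DB - d2) / (xh - xc2) ** 2

        def envelope(x):
            x = np.asarray(x, float)
            return np.minimum(d1 + a1 * (x - xc1) ** 2, d2 + a2 * (x - xc2) ** 2)

        cf1, cf2 = 2.0 ** xc1, 2.0 ** xc2
        ps_true = min(d1, d2)
    else:
        raise ValueError("shape must be 'V' or 'W'")

    x = np.log2(grid)
    thr = np.asarray(envelope(x), float)
    # keep the informative part of the grid: thresholds below ~75 dB SPL
    keep = thr <= CUTOFF_DB + 15.0
    if keep.sum() < 3:
        raise ValueError("frequency grid too coarse for the cut-off span")
    f_used = grid[keep]
    thr = thr[keep]
    if noise_sd > 0:
        thr = thr + rng.normal(0.0, noise_sd, thr.shape)
    rec = AudiogramRecord(species=species, method="BA-S",
                          frequencies_khz=f_used, thresholds_db=thr)
    truth = {
        "LFC": lfc_true, "HFC": hfc_true, "CF1": cf1, "CF2": cf2,
        "PS": ps_true, "SPL1": float(envelope(0.0)),
    }
    return rec, truth


def default_abr_offset(f_khz: float) -> float:
    """Positive ABR-behavioral offset, larger below 2 kHz (9-18 dB)."""
    return 9.0 + 9.0 * float(np.clip(math.log2(4.0 / f_khz) / 2.0, 0.0, 1.0))


def make_abr_variant(
    audiogram: AudiogramRecord,
    offset_profile: Callable[[float], float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AudiogramRecord:
    """ABR thresholds = behavioral + positive frequency-dependent offset."""
    profile = default_abr_offset if offset_profile is None else offset_profile
    rng = np.random.default_rng(seed)
    offs = np.array([profile(f) for f in audiogram.frequencies_khz])
    thr = audiogram.thresholds_db + offs
    if noise_sd > 0:
        thr = thr + rng.normal(0.0, noise_sd, thr.shape)
    return AudiogramRecord(species=audiogram.species, method="ABR",
                           frequencies_khz=audiogram.frequencies_khz.copy(),
                           thresholds_db=thr)


# ----------------------------------------------------------------- world


def default_root_archetype() -> MorphoArchetype:
    return MorphoArchetype(
        name="root", turns=2.5, basal_radius=1.5, radius_decay=0.4,
        height=3.5, tube_radius0=0.55, tube_taper=0.45, undulation=0.12,
    )


def default_bm_rates() -> dict[str, float]:
    # per-Myr rates sized so tip s.d. over a 75 Myr tree is ~0.4 turns,
    # ~15% in r0/rho0, ~20% in H
    return {
        "turns": 0.002,
        "basal_radius": 3.0e-4,
        "height": 5.0e-4,
        "tube_radius0": 2.0e-4,
        "radius_decay": 1.0e-5,
        "undulation": 2.0e-5,
        "tube_taper": 0.0,
    }


def default_group_shifts() -> dict[str, dict[str, float]]:
    # tower clade: more turns, taller; wide clade: enlarged basal turn
    return {
        "SH": {"turns": 0.9, "height": 0.30},
        "Primates": {"basal_radius": 0.22, "turns": -0.25},
    }


@dataclass
class WorldConfig:
    """Study conditions for a synthetic world (defaults emulate the
    sample: 33 species, mode 2 specimens, time-calibrated tree)."""

    n_species: int = 33
    specimens_per_species: int = 2
    root_age: float = 75.0
    birth_rate: float = 1.0
    left_side_fraction: float = 0.3
    n_raw_points: int = 200
    landmark_noise_sd: float = 0.01   # mm, digitization noise
    audiogram_noise_sd: float = 1.0   # dB
    w_shape_fraction: float = 0.3
    n_abr_only: int = 4
    n_reference: int = 2
    root_archetype: MorphoArchetype = field(default_factory=default_root_archetype)
    bm_rates: dict = field(default_factory=default_bm_rates)
    group_shifts: dict = field(default_factory=default_group_shifts)
    linkage: LinkageModel = field(default_factory=default_linkage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorldConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, val in raw.items():
            if key == "root_archetype":
                kwargs[key] = MorphoArchetype(**val)
            elif key == "linkage":
                kwargs[key] = LinkageModel(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class Specimen:
    specimen_id: str
    species: str
    side: str
    cochlea: LandmarkFile
    oval_window: LandmarkFile
    station_areas: np.ndarray


@dataclass
class SyntheticWorld:
    config: WorldConfig
    seed: int
    phylogeny: Phylogeny
    archetypes: dict[str, MorphoArchetype]
    groups: dict[str, str]            # species -> group label
    specimens: list[Specimen]
    audiograms: list[AudiogramRecord]  # the "published" records
    behavioral: dict[str, AudiogramRecord]  # exactly one per species
    traits: pd.DataFrame
    truth: pd.DataFrame               # per-species ground truth
    reference_species: list[str]
    abr_offset_profile: Callable[[float], float]


def _assign_groups(phy: Phylogeny) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Deterministic clade-based group labels: the two root subtrees are
    the wide ('Primates'-like) and coiled sides; the coiled side splits
    again into 'Myomorpha' and 'SH' (sciuromorph + hystricomorph pooled)."""
    groups: dict[str, str] = {}
    clades: dict[str, list[str]] = {}

    def tips_of(node):
        return sorted(lf.taxon.label for lf in node.leaf_iter())

    def split(labels):
        """Child subtrees of the MRCA of ``labels``, smallest first."""
        if len(labels) < 2:
            return [labels]
        node = phy.tree.mrca(taxon_labels=labels)
        subs = sorted((tips_of(ch) for ch in node.child_nodes()), key=len)
        return [s for s in subs if s] or [labels]

    sides = sorted(
        (tips_of(ch) for ch in phy.tree.seed_node.child_nodes()), key=len)
    small, large = sides[0], sides[-1]
    if len(small) >= 3:
        clades["Primates"] = small
        remaining = large
    else:
        for sp in small:
            groups[sp] = "other"
        subs = split(large)
        clades["Primates"] = subs[0]
        remaining = subs[-1] if len(subs) > 1 else []
    for sp in clades["Primates"]:
        groups[sp] = "Primates"
    subs = split(remaining) if remaining else []
    if len(subs) >= 2:
        clades["SH"] = subs[0]
        clades["Myomorpha"] = subs[-1]
        for sp in subs[0]:
            groups[sp] = "SH"
        for sp in subs[-1]:
            groups[sp] = "Myomorpha"
    else:
        for sp in remaining:
            groups[sp] = "Myomorpha"
        if remaining:
            clades["Myomorpha"] = list(remaining)
    return groups, clades


def generate_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Compose tree, trait evolution, renders, audiograms and traits."""
    cfg = config or WorldConfig()
    ss = np.random.SeedSequence(seed)
    n_streams = 4 + cfg.n_species * (cfg.specimens_per_species + 2)
    children = ss.spawn(n_streams)
    it = iter(children)
    seed_of = lambda: int(next(it).generate_state(1)[0] & 0x7FFFFFFF)

    tree_seed = seed_of()
    evo_seed = seed_of()
    trait_seed = seed_of()
    choice_seed = seed_of()

    phy = simulate_tree(cfg.n_species, cfg.birth_rate, tree_seed, cfg.root_age)
    groups, clades = _assign_groups(phy)
    shifts = {k: v for k, v in cfg.group_shifts.items() if k in clades}
    archetypes = evolve_traits(phy, cfg.root_archetype, cfg.bm_rates,
                               shifts, clades, evo_seed)

    rng_choice = np.random.default_rng(choice_seed)
    species = phy.tip_labels
    n_w = int(round(cfg.w_shape_fraction * len(species)))
    w_species = set(rng_choice.choice(species, size=n_w, replace=False))
    # reference species get both behavioral and ABR; abr-only species are
    # published as ABR records alone
    pool = [sp for sp in species]
    picks = rng_choice.choice(pool, size=cfg.n_reference + cfg.n_abr_only,
                              replace=False)
    reference = sorted(str(s) for s in picks[: cfg.n_reference])
    abr_only = sorted(str(s) for s in picks[cfg.n_reference:])

    rng_traits = np.random.default_rng(trait_seed)

    specimens: list[Specimen] = []
    audiograms: list[AudiogramRecord] = []
    behavioral: dict[str, AudiogramRecord] = {}
    truth_rows = []
    trait_rows = []
    for sp in species:
        arch = archetypes[sp]
        cl = analytic_arc_length(arch)
        cw = analytic_width(arch)
        a, b = oval_window_semi_axes(arch)
        owa = math.pi * a * b
        preds = {
            "log10_cl": math.log10(cl), "nt": arch.turns,
            "log10_owa": math.log10(owa), "log10_cw": math.log10(cw),
        }
        for j in range(cfg.specimens_per_species):
            rseed = seed_of()
            curve, rw, areas, ow = render_cochlea(
                arch, cfg.n_raw_points, cfg.landmark_noise_sd, rseed
            )
            side = "left" if (rng_choice.random() < cfg.left_side_fraction) else "right"
            pts = np.vstack([rw[0], curve])  # LM1, LM2, ..., apex
            ow_pts = ow
            if side == "left":
                pts = geometry.mirror_configuration(pts)
                ow_pts = geometry.mirror_configuration(ow_pts)
            sid = f"{sp}_{j + 1}"
            specimens.append(Specimen(
                specimen_id=sid, species=sp, side=side,
                cochlea=LandmarkFile(sid, sp, side, "cochlea_curve", pts),
                oval_window=LandmarkFile(sid, sp, side, "oval_window", ow_pts),
                station_areas=areas,
            ))
        link_seed = seed_of()
        aud_seed = seed_of()
        rng_link = np.random.default_rng(link_seed)
        resp = cfg.linkage.predict(preds, rng_link)
        shape = "W" if sp in w_species else "V"
        rec, aud_truth = generate_audiogram(
            sp, resp["LFC"], resp["HFC"],
            spl1_true=resp["SPL1"] if shape == "V" else None,
            shape=shape, noise_sd=cfg.audiogram_noise_sd, seed=aud_seed,
        )
        behavioral[sp] = rec
        if sp in abr_only:
            audiograms.append(make_abr_variant(rec, seed=aud_seed))
        else:
            audiograms.append(rec)
            if sp in reference:
                audiograms.append(make_abr_variant(rec, seed=aud_seed))
        mass = 10.0 ** (2.3 + 2.2 * (math.log10(cl) - math.log10(19.0))
                        + rng_traits.normal(0.0, 0.12))
        iad = 18.0 * (mass / 200.0) ** 0.33 * math.exp(rng_traits.normal(0.0, 0.08))
        trait_rows.append({"species": sp, "body_mass_g": mass,
                           "interaural_mm": iad, "group": groups[sp]})
        truth_rows.append({
            "species": sp, "group": groups[sp], "shape": shape,
            "turns": arch.turns, "basal_radius": arch.basal_radius,
            "radius_decay": arch.radius_decay, "height": arch.height,
            "tube_radius0": arch.tube_radius0, "tube_taper": arch.tube_taper,
            "undulation": arch.undulation,
            "CL": cl, "CW": cw, "OWA": owa, "NT": arch.turns,
            "ACS": float(np.mean(tube_area(arch, np.array([0.2, 0.4, 0.6, 0.8, 1.0])))),
            "CSR": float(tube_area(arch, 0.2) / tube_area(arch, 1.0)),
            **{f"true_{k}": v for k, v in aud_truth.items()},
        })
    traits = pd.DataFrame(trait_rows).set_index("species").sort_index()
    truth = pd.DataFrame(truth_rows).set_index("species").sort_index()
    return SyntheticWorld(cfg, seed, phy, archetypes, groups, specimens,
                          audiograms, behavioral, traits, truth, reference,
                          default_abr_offset)


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Materialise a world as plain-text files (landmark dialect, Newick,
    CSV, TSV); deterministic, so equal (config, seed) gives equal bytes."""
    outdir = Path(outdir)
    (outdir / "landmarks").mkdir(parents=True, exist_ok=True)
    write_newick(world.phylogeny, outdir / "tree.nwk")
    for spm in world.specimens:
        (outdir / "landmarks" / f"{spm.specimen_id}_cochlea.lmk").write_text(
            write_landmark_file(spm.cochlea))
        (outdir / "landmarks" / f"{spm.specimen_id}_oval_window.lmk").write_text(
            write_landmark_file(spm.oval_window))
    write_audiogram_table(world.audiograms, outdir / "audiograms.csv")
    write_trait_table(world.traits, outdir / "traits.csv")
    area_rows = []
    for spm in sorted(world.specimens, key=lambda s: s.specimen_id):
        for i, a in enumerate(spm.station_areas):
            area_rows.append((spm.specimen_id, i, a))
    pd.DataFrame(area_rows, columns=["specimen_id", "station", "area_mm2"]) \
        .to_csv(outdir / "station_areas.csv", index=False)
    world.truth.to_csv(outdir / "truth.tsv", sep="\t", lineterminator="\n")
    snap = world.config.snapshot()
    snap["seed"] = world.seed
    snap["reference_species"] = world.reference_species
    (outdir / "config.yaml").write_text(yaml.safe_dump(snap, sort_keys=True))
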