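"""Synthetic landscapes, den placements and choice-set data with known truth.

Everything downstream is tested by recovery: the generator places dens under
a known proximity-based selection model and draws matched choice sets under a
known conditional-logit model, so the analysis stages can be checked against
the parameters that generated the data.

The landscape is a labelled Voronoi tessellation of random seed points
clipped to a rectangular extent: patches are assigned to land-cover classes
greedily by area so realized class fractions track the configured target
proportions.  Roads are random chords across the extent.

Den placement weights location ``z`` by ``exp(sum_f coef_f * (-d_f(z)/1000))``
where ``d_f`` is the nearest distance (m) to feature ``f`` — a positive
coefficient (per km) attracts dens toward the feature, zero coefficients give
uniform placement.

Choice sets mimic a matched use/availability design: one used site plus
``m`` available sites, covariates drawn independently (Poisson burrow and
shrub counts, visibility uniform on the 0-15 pole range, a near-separating
categorical substrate), and the used row drawn by a conditional logit on the
true betas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPoint, box
from shapely.ops import voronoi_diagram

from .geospatial import (
    FEATURES,
    LAND_COVER_CLASSES,
    GeometryError,
    LandscapeMap,
    nearest_distances,
)

SUBSTRATE_LEVELS: tuple[str, ...] = ("earthen_bund", "boulder_pile", "other")

#: covariate columns of a choice-set table, in canonical order
CHOICE_COLUMNS = ("set_id", "used", "rodent_burrows", "visibility", "shrub_count", "substrate", "x", "y")


class ConfigurationError(ValueError):
    pass


@dataclass
class LandscapeConfig:
    """Configuration of the synthetic land-cover mosaic."""

    extent_m: tuple[float, float] = (10_000.0, 10_000.0)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            # fractions follow the study region's reported land-cover mix:
            # a short-grassland-dominated mosaic with plantation, cropland,
            # fallow and ploughed land, and a small built-up remainder.
            "grassland": 0.25,
            "plantation": 0.22,
            "agricultural": 0.24,
            "fallow": 0.12,
            "ploughed": 0.10,
            "built_up": 0.07,
        }
    )
    n_patches: int = 400
    n_roads: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.extent_m
        if not (w > 0 and h > 0):
            raise ConfigurationError(f"extent must be strictly positive, got {self.extent_m}")
        for cls, p in self.class_proportions.items():
            if cls not in LAND_COVER_CLASSES:
                raise ConfigurationError(f"unknown land-cover class {cls!r}")
            if p < 0:
                raise ConfigurationError(f"negative proportion for {cls!r}: {p}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class proportions must sum to 1, got {total}")
        n_active = sum(1 for p in self.class_proportions.values() if p > 0)
        if self.n_patches < n_active:
            raise ConfigurationError(
                f"n_patches={self.n_patches} < {n_active} classes with non-zero proportion"
            )


@dataclass
class SelectionTruth:
    """Ground-truth selection parameters for both analysis scales.

    ``den_proximity_coefs`` are log-weights per km on negative distance to
    each feature (positive = attraction).  ``choice_betas`` are the true
    conditional-logit coefficients on raw covariate scales; interaction terms
    use ``"a:b"`` keys.  ``substrate_effect`` is a per-level log-odds offset
    added to a row's utility.
    """

    den_proximity_coefs: dict[str, float] = field(default_factory=dict)
    choice_betas: dict[str, float] = field(default_factory=dict)
    substrate_effect: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, d in (
            ("den_proximity_coefs", self.den_proximity_coefs),
            ("choice_betas", self.choice_betas),
            ("substrate_effect", self.substrate_effect),
        ):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ConfigurationError(f"non-finite coefficient {name}[{k!r}] = {v}")
        for f in self.den_proximity_coefs:
            if f not in FEATURES:
                raise ConfigurationError(f"unknown den-proximity feature {f!r}")
        for s in self.substrate_effect:
            if s not in SUBSTRATE_LEVELS:
                raise ConfigurationError(f"unknown substrate level {s!r}")


def default_truth() -> SelectionTruth:
    """Truth emulating the study's findings: strong grassland selection and
    mild road attraction at the home-range scale; burrow and visibility
    effects (positive, interaction negligible) plus a near-separating
    preference for artificial substrates at the den-area scale."""
    return SelectionTruth(
        den_proximity_coefs={"grassland": 12.0, "roads": 1.5},
        choice_betas={"rodent_burrows": 1.2, "visibility": 0.33, "shrub_count": 0.04},
        substrate_effect={"earthen_bund": 5.76, "boulder_pile": 5.33, "other": 0.0},
    )


def null_truth() -> SelectionTruth:
    """All-zero truth: uniform den placement, uniform choice."""
    return SelectionTruth()


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def generate_landscape(config: LandscapeConfig) -> LandscapeMap:
    """Generate a labelled Voronoi mosaic plus road chords.

    The polygon layers partition the extent exactly (cells are clipped to the
    extent rectangle); greedy largest-deficit labelling keeps realized class
    areal fractions close to the configured proportions.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.extent_m
    extent = box(0.0, 0.0, w, h)

    if config.n_patches == 1:
        patches = [extent]
    else:
        pts = np.column_stack([rng.random(config.n_patches) * w, rng.random(config.n_patches) * h])
        cells = voronoi_diagram(MultiPoint(pts), envelope=extent)
        patches = []
        for cell in cells.geoms:
            clipped = cell.intersection(extent)
            if clipped.is_empty:
                continue
            if clipped.geom_type == "Polygon":
                patches.append(clipped)
            else:  # rare MultiPolygon sliver from clipping
                patches.extend(g for g in clipped.geoms if g.geom_type == "Polygon")

    # Greedy labelling by remaining target-area deficit, largest patches first.
    total_area = extent.area
    deficit = {c: p * total_area for c, p in config.class_proportions.items() if p > 0}
    layers: dict[str, list] = {c: [] for c in deficit}
    for patch in sorted(patches, key=lambda g: -g.area):
        cls = max(deficit, key=deficit.get)
        layers[cls].append(patch)
        deficit[cls] -= patch.area

    roads = [_random_chord(rng, w, h) for _ in range(config.n_roads)]
    return LandscapeMap(class_layers=layers, roads=roads)


def _random_chord(rng: np.random.Generator, w: float, h: float) -> LineString:
    """A random chord: segment between two points on distinct rectangle edges."""
    while True:
        e1, e2 = rng.integers(0, 4, size=2)
        if e1 != e2:
            break
    return LineString([_edge_point(rng, e1, w, h), _edge_point(rng, e2, w, h)])


def _edge_point(rng: np.random.Generator, edge: int, w: float, h: float) -> tuple[float, float]:
    t = rng.random()
    if edge == 0:
        return (t * w, 0.0)
    if edge == 1:
        return (t * w, h)
    if edge == 2:
        return (0.0, t * h)
    return (w, t * h)


# ---------------------------------------------------------------------------
# Den placement
# ---------------------------------------------------------------------------

def place_dens(
    landscape: LandscapeMap,
    truth: SelectionTruth,
    n_dens: int,
    seed: int,
    margin_m: float = 0.0,
    n_candidates: int = 20_000,
) -> pd.DataFrame:
    """Sample den locations under the proximity-based selection model.

    Importance sampling: ``n_candidates`` locations are drawn uniformly over
    the extent (inset by ``margin_m`` on every side, so e.g. an 800 m buffer
    around each den stays inside the mapped area), then ``n_dens`` dens are
    drawn with probability proportional to
    ``exp(sum_f coef_f * (-d_f/1000))``.  All-zero coefficients give exactly
    uniform placement.  Returns a DataFrame with x, y columns.
    """
    if landscape.is_empty():
        raise GeometryError("cannot place dens on an empty landscape")
    if n_dens < 0:
        raise ConfigurationError(f"n_dens must be >= 0, got {n_dens}")
    if n_dens == 0:
        return pd.DataFrame({"x": [], "y": []})
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = shapely.total_bounds(
        [p for polys in landscape.class_layers.values() for p in polys]
    )
    minx, miny, maxx, maxy = minx + margin_m, miny + margin_m, maxx - margin_m, maxy - margin_m
    if not (maxx > minx and maxy > miny):
        raise ConfigurationError("margin_m leaves no sampling area")
    cand = np.column_stack(
        [rng.uniform(minx, maxx, n_candidates), rng.uniform(miny, maxy, n_candidates)]
    )
    active = {f: c for f, c in truth.den_proximity_coefs.items() if c != 0.0}
    if active:
        logw = np.zeros(n_candidates)
        for feat, coef in active.items():
            logw -= coef * nearest_distances(cand, landscape, feat) / 1000.0
        logw -= logw.max()
        p = np.exp(logw)
        p /= p.sum()
        idx = rng.choice(n_candidates, size=n_dens, replace=True, p=p)
    else:
        idx = rng.choice(n_candidates, size=n_dens, replace=True)
    return pd.DataFrame({"x": cand[idx, 0], "y": cand[idx, 1]})


# ---------------------------------------------------------------------------
# Choice-set generation
# ---------------------------------------------------------------------------

def generate_choice_data(
    n_sets: int,
    m_available: int,
    truth: SelectionTruth,
    seed: int,
    burrow_mean: float = 3.0,
    shrub_mean: float = 2.0,
    substrate_probs: tuple[float, float, float] = (0.05, 0.03, 0.92),
    spacing_m: float = 300.0,
) -> pd.DataFrame:
    """Simulate matched choice sets: 1 used + ``m_available`` rows per set.

    Covariates per candidate row: rodent-burrow count ~ Poisson(burrow_mean),
    visibility ~ Uniform(0, 15), shrub count ~ Poisson(shrub_mean).  The used
    row is drawn with probability exp(u_j)/sum_k exp(u_k) where u is the
    linear predictor under ``truth.choice_betas`` (interaction keys ``"a:b"``
    are products of the raw covariates).

    Substrate is a descriptive covariate (it is never fitted downstream —
    it exists to exercise the separation detector and the proportion
    summaries): available rows draw it from the availability distribution
    ``substrate_probs`` over ``(earthen_bund, boulder_pile, other)``, while
    the used row draws from probabilities proportional to
    ``substrate_probs * exp(substrate_effect)`` — a discrete choice over
    substrate availability, so ``truth.substrate_effect`` keeps its
    log-odds-of-selection meaning.  With the defaults this yields
    near-complete separation between used and available substrates.

    With ``m_available == 4`` the candidate positions are one centre point
    plus four points ``spacing_m`` away in the cardinal directions (the
    matched-availability field design); otherwise random bearings are used.
    Returns a tidy DataFrame with columns ``CHOICE_COLUMNS``.
    """
    if n_sets < 1 or m_available < 1:
        raise ConfigurationError("n_sets and m_available must be >= 1")
    rng = np.random.default_rng(seed)
    n_rows = m_available + 1
    avail_p = np.asarray(substrate_probs, dtype=float)
    if abs(avail_p.sum() - 1.0) > 1e-9 or np.any(avail_p < 0):
        raise ConfigurationError(f"substrate_probs must be a probability vector, got {substrate_probs}")
    used_p = avail_p * np.exp([truth.substrate_effect.get(s, 0.0) for s in SUBSTRATE_LEVELS])
    used_p = used_p / used_p.sum()
    rows = []
    for s in range(n_sets):
        burrows = rng.poisson(burrow_mean, n_rows).astype(float)
        vis = rng.uniform(0.0, 15.0, n_rows)
        shrubs = rng.poisson(shrub_mean, n_rows).astype(float)
        cov = {"rodent_burrows": burrows, "visibility": vis, "shrub_count": shrubs}
        util = np.zeros(n_rows)
        for term, beta in truth.choice_betas.items():
            vals = np.ones(n_rows)
            for part in term.split(":"):
                if part not in cov:
                    raise ConfigurationError(f"unknown covariate {part!r} in choice_betas")
                vals = vals * cov[part]
            util += beta * vals
        util -= util.max()
        p = np.exp(util)
        p /= p.sum()
        used_idx = rng.choice(n_rows, p=p)
        substrate = rng.choice(SUBSTRATE_LEVELS, size=n_rows, p=avail_p)
        substrate[used_idx] = rng.choice(SUBSTRATE_LEVELS, p=used_p)

        cx, cy = rng.uniform(0, 10_000, 2)
        if m_available == 4:
            offsets = [(0.0, 0.0), (0.0, spacing_m), (spacing_m, 0.0), (0.0, -spacing_m), (-spacing_m, 0.0)]
        else:
            ang = rng.uniform(0, 2 * math.pi, n_rows - 1)
            offsets = [(0.0, 0.0)] + [
                (spacing_m * math.cos(a), spacing_m * math.sin(a)) for a in ang
            ]
        for j in range(n_rows):
            rows.append(
                {
                    "set_id": s,
                    "used": int(j == used_idx),
                    "rodent_burrows": burrows[j],
                    "visibility": vis[j],
                    "shrub_count": shrubs[j],
                    "substrate": substrate[j],
                    "x": cx + offsets[j][0],
                    "y": cy + offsets[j][1],
                }
            )
    return pd.DataFrame(rows, columns=list(CHOICE_COLUMNS))


def write_choice_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_choice_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CHOICE_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise ConfigurationError(f"choice CSV missing columns: {sorted(missing)}")
    return df
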