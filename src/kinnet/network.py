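"""Microtubule network geometry.

Microtubules (MTs) are modeled as static straight segments of 12000 nm with a
discrete lattice of 8-nm motor binding sites, laid out in a rectangular 2-D
region (12100 x 7000 nm by default).  All MTs share the same polarity: the
minus end sits in the left part of the region, the plus end points right, so
plus-end-directed motors transport cargo along +x.

Two layout families are provided:

* **NRS** (non-radial structure): near-axial MTs whose minus ends are spread
  over the whole region, so track crossings are distributed everywhere.
* **QRS** (quasi-radial structure): MTs fan out from a small core disc at the
  left-center of the region, so crossings concentrate in the core and the
  line density decays roughly like 1/r with distance from it.

Pairwise segment crossings are computed exactly and mapped to the nearest
lattice site on each MT; motors stepping across a crossing site may switch
tracks (handled by the engine).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

MT_LENGTH = 12000.0  # nm
LATTICE_SPACING = 8.0  # nm
N_SITES = int(MT_LENGTH / LATTICE_SPACING)  # 1500
GEOM_TOL = 1e-6  # nm, tolerance for intersection tests

_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class RegionGeometry:
    """Rectangular transport region; x is the transport axis."""

    length: float = 12100.0  # nm
    width: float = 7000.0  # nm


@dataclass(frozen=True)
class Microtubule:
    """A directed 2-D segment with an 8-nm lattice, minus -> plus."""

    id: int
    minus_end: np.ndarray  # shape (2,), nm
    unit_vector: np.ndarray  # shape (2,), unit norm, minus -> plus
    n_sites: int = N_SITES
    lattice_spacing: float = LATTICE_SPACING

    @property
    def length(self) -> float:
        return self.n_sites * self.lattice_spacing

    @property
    def plus_end(self) -> np.ndarray:
        return self.minus_end + self.length * self.unit_vector


@dataclass(frozen=True)
class Crossing:
    """Geometric intersection of two MTs, mapped to a lattice site on each."""

    mt_a: int
    site_a: int
    mt_b: int
    site_b: int
    point: np.ndarray  # shape (2,), nm


@dataclass
class Network:
    mts: list[Microtubule]
    crossings: list[Crossing]
    structure_tag: str  # "NRS" | "QRS"
    region: RegionGeometry
    seed: int
    # site-indexed crossing lookup: {(mt_id, site): [(other_mt, other_site), ...]}
    _crossing_map: dict[tuple[int, int], list[tuple[int, int]]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self._crossing_map:
            self._crossing_map = _build_crossing_map(self.crossings)

    @property
    def n_mts(self) -> int:
        return len(self.mts)

    def branches_at(self, mt_id: int, site: int) -> list[tuple[int, int]]:
        """MTs (with their mapped site) reachable from a crossing site."""
        return self._crossing_map.get((mt_id, site), [])


def _build_crossing_map(
    crossings: list[Crossing],
) -> dict[tuple[int, int], list[tuple[int, int]]]:
    cmap: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for c in crossings:
        cmap.setdefault((c.mt_a, c.site_a), []).append((c.mt_b, c.site_b))
        cmap.setdefault((c.mt_b, c.site_b), []).append((c.mt_a, c.site_a))
    return cmap


def site_position(mt: Microtubule, site: int) -> np.ndarray:
    """Position of lattice site ``site`` (r_i = i * 8 nm along the MT axis)."""
    if not 0 <= site < mt.n_sites:
        raise IndexError(f"site {site} out of range [0, {mt.n_sites})")
    return mt.minus_end + site * mt.lattice_spacing * mt.unit_vector


def _mt_from_angle(mt_id: int, minus_end: np.ndarray, theta: float) -> Microtubule:
    u = np.array([np.cos(theta), np.sin(theta)])
    return Microtubule(id=mt_id, minus_end=np.asarray(minus_end, dtype=float), unit_vector=u)


def _inside(region: RegionGeometry, p: np.ndarray) -> bool:
    return (
        -GEOM_TOL <= p[0] <= region.length + GEOM_TOL
        and -GEOM_TOL <= p[1] <= region.width + GEOM_TOL
    )


def generate_nrs(
    n_mts: int, region: RegionGeometry | None = None, seed: int = 0
) -> Network:
    """Generate a non-radial network of near-axial MTs.

    Minus-end x ~ U[0, length - 12000*cos(theta)], y ~ U[0, width], orientation
    theta ~ U[-15 deg, +15 deg]; draws whose plus end leaves the region are
    rejected and resampled (bounded attempts), which spreads crossings over the
    whole region.
    """
    if n_mts < 1:
        raise ValueError("n_mts must be >= 1")
    region = region or RegionGeometry()
    rng = np.random.default_rng(seed)
    mts: list[Microtubule] = []
    for i in range(n_mts):
        for _ in range(_MAX_ATTEMPTS):
            theta = rng.uniform(np.deg2rad(-15.0), np.deg2rad(15.0))
            x_max = region.length - MT_LENGTH * np.cos(theta)
            if x_max < 0:
                continue
            minus = np.array([rng.uniform(0.0, x_max), rng.uniform(0.0, region.width)])
            mt = _mt_from_angle(i, minus, theta)
            if _inside(region, mt.minus_end) and _inside(region, mt.plus_end):
                mts.append(mt)
                break
        else:
            raise RuntimeError(
                "NRS sampling failed: region cannot accommodate the draw"
            )
    return Network(mts, compute_crossings(mts), "NRS", region, seed)


QRS_CORE_RADIUS = 300.0  # nm
QRS_CORE_CENTER_X = 150.0  # nm


def generate_qrs(
    n_mts: int, region: RegionGeometry | None = None, seed: int = 0
) -> Network:
    """Generate a quasi-radial network fanning from a core disc.

    Minus ends are uniform in a disc of radius 300 nm centered at
    (150, width/2); theta ~ U[-16 deg, +16 deg] so the plus ends span the
    region width.  Draws leaving the region are resampled.  Crossings
    concentrate near the core and line density decays ~1/r outward.
    """
    if n_mts < 1:
        raise ValueError("n_mts must be >= 1")
    region = region or RegionGeometry()
    rng = np.random.default_rng(seed)
    center = np.array([QRS_CORE_CENTER_X, region.width / 2.0])
    mts: list[Microtubule] = []
    for i in range(n_mts):
        for _ in range(_MAX_ATTEMPTS):
            # uniform in the core disc
            r = QRS_CORE_RADIUS * np.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * np.pi)
            minus = center + r * np.array([np.cos(phi), np.sin(phi)])
            theta = rng.uniform(np.deg2rad(-16.0), np.deg2rad(16.0))
            mt = _mt_from_angle(i, minus, theta)
            if _inside(region, mt.minus_end) and _inside(region, mt.plus_end):
                mts.append(mt)
                break
        else:
            raise RuntimeError(
                "QRS sampling failed: region cannot accommodate the draw"
            )
    return Network(mts, compute_crossings(mts), "QRS", region, seed)


def compute_crossings(mts: list[Microtubule]) -> list[Crossing]:
    """Exact pairwise segment intersections mapped to nearest lattice sites.

    Collinear overlapping segments register no crossing (measure zero under
    continuous sampling); a warning is emitted if one is encountered.
    """
    n = len(mts)
    if n < 2:
        return []
    p = np.array([mt.minus_end for mt in mts])  # (n, 2)
    d = np.array([mt.unit_vector * mt.length for mt in mts])  # (n, 2) full extent
    crossings: list[Crossing] = []
    ia, ib = np.triu_indices(n, k=1)
    # solve p_a + t*d_a = p_b + s*d_b for each pair
    denom = d[ia, 0] * d[ib, 1] - d[ia, 1] * d[ib, 0]
    dp = p[ib] - p[ia]
    parallel = np.abs(denom) < GEOM_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dp[:, 0] * d[ib, 1] - dp[:, 1] * d[ib, 0]) / denom
        s = (dp[:, 0] * d[ia, 1] - dp[:, 1] * d[ia, 0]) / denom
    hit = (~parallel) & (t >= 0) & (t <= 1) & (s >= 0) & (s <= 1)
    # collinear overlap check for the parallel pairs (warn only)
    if np.any(parallel):
        cross_dp = dp[:, 0] * d[ia, 1] - dp[:, 1] * d[ia, 0]
        if np.any(parallel & (np.abs(cross_dp) < GEOM_TOL)):
            warnings.warn(
                "collinear overlapping microtubules: no crossing registered",
                stacklevel=2,
            )
    for k in np.nonzero(hit)[0]:
        a, b = int(ia[k]), int(ib[k])
        point = p[a] + t[k] * d[a]
        site_a = _nearest_site(mts[a], t[k])
        site_b = _nearest_site(mts[b], s[k])
        crossings.append(Crossing(mts[a].id, site_a, mts[b].id, site_b, point))
    return crossings


def _nearest_site(mt: Microtubule, t_frac: float) -> int:
    """Nearest lattice site to the fractional position t along the MT.

    Ties (exactly halfway between sites) round down for determinism.
    """
    x = t_frac * mt.length / mt.lattice_spacing  # in units of sites
    lo = int(np.floor(x))
    site = lo if (x - lo) <= 0.5 else lo + 1
    return int(np.clip(site, 0, mt.n_sites - 1))


def mts_within_reach(
    network: Network, point: np.ndarray, reach: float
) -> list[tuple[int, int, float]]:
    """MTs whose minimum distance to ``point`` is <= ``reach``.

    Returns ``(mt_id, nearest_site, distance)`` sorted by distance; the
    nearest site is the lattice site closest to the orthogonal projection of
    the point onto the segment (clamped to the MT ends).
    """
    if reach <= 0:
        raise ValueError("reach must be > 0")
    point = np.asarray(point, dtype=float)
    out: list[tuple[int, int, float]] = []
    for mt in network.mts:
        rel = point - mt.minus_end
        proj = float(rel @ mt.unit_vector)
        proj = min(max(proj, 0.0), mt.length)
        nearest = mt.minus_end + proj * mt.unit_vector
        dist = float(np.linalg.norm(point - nearest))
        if dist <= reach:
            site = _nearest_site(mt, proj / mt.length)
            out.append((mt.id, site, dist))
    out.sort(key=lambda r: (r[2], r[0]))
    return out


# ---------------------------------------------------------------------------
# plain-text serialization


def save_network(network: Network, mts_path: str, crossings_path: str) -> None:
    """Write the MT table and the crossings table as whitespace-delimited text."""
    with open(mts_path, "w") as fh:
        fh.write("# id x_minus y_minus x_plus y_plus\n")
        for mt in network.mts:
            plus = mt.plus_end
            fh.write(
                f"{mt.id} {mt.minus_end[0]:.6f} {mt.minus_end[1]:.6f} "
                f"{plus[0]:.6f} {plus[1]:.6f}\n"
            )
    with open(crossings_path, "w") as fh:
        fh.write("# mt_a site_a mt_b site_b x y\n")
        for c in network.crossings:
            fh.write(
                f"{c.mt_a} {c.site_a} {c.mt_b} {c.site_b} "
                f"{c.point[0]:.6f} {c.point[1]:.6f}\n"
            )


def load_network(
    mts_path: str,
    crossings_path: str,
    structure_tag: str = "NRS",
    region: RegionGeometry | None = None,
) -> Network:
    region = region or RegionGeometry()
    mts: list[Microtubule] = []
    for line in open(mts_path):
        if line.startswith("#") or not line.strip():
            continue
        mt_id, xm, ym, xp, yp = line.split()
        minus = np.array([float(xm), float(ym)])
        plus = np.array([float(xp), float(yp)])
        vec = plus - minus
        length = float(np.linalg.norm(vec))
        mts.append(
            Microtubule(
                id=int(mt_id),
                minus_end=minus,
                unit_vector=vec / length,
                n_sites=int(round(length / LATTICE_SPACING)),
            )
        )
    crossings: list[Crossing] = []
    for line in open(crossings_path):
        if line.startswith("#") or not line.strip():
            continue
        a, sa, b, sb, x, y = line.split()
        crossings.append(
            Crossing(int(a), int(sa), int(b), int(sb), np.array([float(x), float(y)]))
        )
    return Network(mts, crossings, structure_tag, region, seed=-1)
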