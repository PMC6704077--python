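"""Synthetic head model, 10-10 electrode layout, and FEM-like field generator.

The analysis pipeline only ever consumes per-node scalars, so a finite
element solve is not required to exercise it.  This module provides a
phenomenological stand-in with the qualitative behaviour real tDCS field
simulations exhibit:

* the field peaks on the cortex just under the anode,
* it spreads along the scalp path from anode to cathode (the cathode
  position steers where the current "leaks"),
* it is strictly linear in the injected current, and
* smaller electrode pads give a sharper, higher peak.

The head is a sphere of radius ``head_radius``; cortical nodes sit on an
outer spherical shell (with a smaller inner shell standing in for sublobar
structures) and carry deterministic (hemisphere, lobe, gyrus) labels from a
fixed angular partition, so atlas lookups need no external database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    AtlasLabelTable,
    FieldVector,
    MscopeError,
    NodeCloud,
    SPACE_TALAIRACH,
)

DEFAULT_HEAD_RADIUS = 85.0  # mm, adult scalp sphere
DEFAULT_CURRENT_MA = 2.0    # the conventional tDCS intensity

# ---------------------------------------------------------------------------
# montage specifications (X_Y_L_B names)
# ---------------------------------------------------------------------------

#: short tokens used in montage names -> canonical electrode-site labels
_CATHODE_ALIASES = {
    "CZ": "CZ",
    "SO": "SO_contra",
    "MAXILLA": "maxilla_contra",
    "NECK": "neck_nape",
}
_ALIAS_BY_SITE = {
    "SO_contra": "SO",
    "maxilla_contra": "Maxilla",
    "neck_nape": "Neck",
}


@dataclass(frozen=True)
class MontageSpec:
    """One anode-cathode configuration: sites, pad size (cm) and current (mA).

    ``size_l`` is the inferior-superior pad dimension and ``size_b`` the
    anterior-posterior one; their product is the pad area in cm^2.
    """

    anode_label: str
    cathode_label: str
    size_l: float = 5.0
    size_b: float = 5.0
    current: float = DEFAULT_CURRENT_MA

    def __post_init__(self) -> None:
        if self.current <= 0:
            raise MscopeError("current must be positive")
        if self.size_l <= 0 or self.size_b <= 0:
            raise MscopeError("electrode dimensions must be positive")
        if self.anode_label == self.cathode_label:
            raise MscopeError("anode and cathode must differ")

    @property
    def area(self) -> float:
        """Pad area in cm^2."""
        return self.size_l * self.size_b

    @property
    def name(self) -> str:
        """The X_Y_L_B name of this montage."""
        def num(v: float) -> str:
            return str(int(v)) if float(v).is_integer() else str(v)
        cat = _ALIAS_BY_SITE.get(self.cathode_label, self.cathode_label)
        return f"{self.anode_label}_{cat}_{num(self.size_l)}_{num(self.size_b)}"


def parse_montage_name(name: str, current: float = DEFAULT_CURRENT_MA,
                       known_sites: set[str] | None = None) -> MontageSpec:
    """Parse an ``ANODE_CATHODE_L_B`` montage name, e.g. ``CP5_CZ_5_5``.

    The current defaults to 2 mA.  Cathode short forms SO / Maxilla / Neck
    map to the canonical extracephalic-or-contralateral site labels.
    """
    parts = name.split("_")
    if len(parts) != 4:
        raise MscopeError(f"malformed montage name {name!r} "
                          "(expected ANODE_CATHODE_L_B)")
    anode, cathode_tok, l_tok, b_tok = parts
    if not re.fullmatch(r"\d+(\.\d+)?", l_tok) or \
            not re.fullmatch(r"\d+(\.\d+)?", b_tok):
        raise MscopeError(f"malformed electrode size in {name!r}")
    cathode = _CATHODE_ALIASES.get(cathode_tok.upper(), cathode_tok)
    sites = known_sites if known_sites is not None else set(_SITE_ANGLES)
    if anode not in sites:
        raise MscopeError(f"unknown anode label {anode!r}")
    if cathode not in sites:
        raise MscopeError(f"unknown cathode label {cathode_tok!r}")
    return MontageSpec(anode_label=anode, cathode_label=cathode,
                       size_l=float(l_tok), size_b=float(b_tok),
                       current=current)


def enumerate_paper_montages(size_l: float = 5.0, size_b: float = 5.0,
                             current: float = DEFAULT_CURRENT_MA
                             ) -> list[MontageSpec]:
    """The 10 montages of the reading-pathway study.

    Five dorsal-pathway montages (anode CP5) and five ventral-pathway
    montages (anode TP7), each against the cathodes CZ, contralateral SO,
    contralateral maxilla, nape of the neck, and the contralateral
    homologous site (CP6 / TP8).
    """
    out = []
    for anode, homologous in (("CP5", "CP6"), ("TP7", "TP8")):
        for cathode in ("CZ", "SO_contra", "maxilla_contra", "neck_nape",
                        homologous):
            out.append(MontageSpec(anode, cathode, size_l, size_b, current))
    return out


# ---------------------------------------------------------------------------
# 10-10 electrode layout on a sphere
# ---------------------------------------------------------------------------

# (inclination from vertex, azimuth from anterior; degrees).  Positive
# azimuth rotates toward the left (odd-numbered) side; the proportional
# 10-10 system puts 18 deg between neighbouring rows.  Extracephalic sites
# have inclination > 90 deg, i.e. below the equator of the sphere.
_SITE_ANGLES: dict[str, tuple[float, float]] = {
    "CZ": (0.0, 0.0),
    "C3": (36.0, 90.0), "C4": (36.0, -90.0),
    "C5": (54.0, 90.0), "C6": (54.0, -90.0),
    "CP5": (54.0, 108.0), "CP6": (54.0, -108.0),
    "P3": (36.0, 126.0), "P4": (36.0, -126.0),
    "T7": (72.0, 90.0), "T8": (72.0, -90.0),
    "TP7": (72.0, 108.0), "TP8": (72.0, -108.0),
    "P7": (72.0, 126.0), "P8": (72.0, -126.0),
    "O1": (72.0, 162.0), "O2": (72.0, -162.0),
    "SO_contra": (81.0, -18.0),
    # extracephalic stand-ins (no neck geometry exists on a sphere)
    "maxilla_contra": (108.0, -30.0),
    "neck_nape": (130.0, 180.0),
}

EXTRACEPHALIC_SITES = frozenset({"maxilla_contra", "neck_nape"})


def _direction(theta_deg: float, phi_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    ph = np.deg2rad(phi_deg)
    return np.array([-np.sin(th) * np.sin(ph),
                     np.sin(th) * np.cos(ph),
                     np.cos(th)])


@dataclass
class ElectrodeLayout:
    """Electrode-site label -> 3D scalp coordinate (mm), on a sphere."""

    positions: dict[str, np.ndarray]
    head_radius: float

    def __getitem__(self, site: str) -> np.ndarray:
        try:
            return self.positions[site]
        except KeyError:
            raise MscopeError(f"electrode site {site!r} absent from layout")

    def __contains__(self, site: str) -> bool:
        return site in self.positions

    def with_site(self, site: str, coord: np.ndarray) -> "ElectrodeLayout":
        pos = dict(self.positions)
        pos[site] = np.asarray(coord, dtype=float)
        return ElectrodeLayout(positions=pos, head_radius=self.head_radius)


def layout_electrodes(head_radius: float = DEFAULT_HEAD_RADIUS
                      ) -> ElectrodeLayout:
    """Standard 10-10 sites (plus extracephalic stand-ins) on the scalp
    sphere, from fixed spherical angles; CZ sits at the apex."""
    if head_radius <= 0:
        raise MscopeError("head_radius must be positive")
    positions = {
        site: head_radius * _direction(theta, phi)
        for site, (theta, phi) in _SITE_ANGLES.items()
    }
    return ElectrodeLayout(positions=positions, head_radius=head_radius)


# ---------------------------------------------------------------------------
# synthetic atlas partition
# ---------------------------------------------------------------------------

class SyntheticAtlas:
    """Deterministic angular parcellation of the two-shell node cloud.

    Hemisphere is the sign of x (x = 0 goes left, RAS convention).  The
    outer (cortex) shell is split into a medial limbic band and four
    sectors — frontal (anterior-superior), parietal (posterior-superior),
    temporal (lateral-inferior), occipital (posterior-inferior) — each
    subdivided into named gyri by azimuth / height bands.  Inner-shell
    nodes are sublobar.  The boundaries are expressed on the unit direction
    of each node, so the partition is scale-free and purely geometric.
    """

    #: |x|-direction half-width of the medial limbic band
    LIMBIC_X = 0.22
    #: z-direction boundary between superior (frontal/parietal) and
    #: inferior (temporal/occipital) sectors
    SUPERIOR_Z = 0.45
    #: azimuth (deg from anterior) of the frontal/parietal boundary
    CENTRAL_ALPHA = 85.0
    #: azimuth of the frontal/temporal boundary below SUPERIOR_Z
    ANTERIOR_ALPHA = 45.0
    #: azimuth of the temporal/occipital boundary
    POSTERIOR_ALPHA = 145.0

    def __init__(self, head_radius: float = DEFAULT_HEAD_RADIUS,
                 cortex_fraction: float = 0.78,
                 inner_fraction: float = 0.55):
        self.head_radius = head_radius
        self.cortex_fraction = cortex_fraction
        self.inner_fraction = inner_fraction
        # shell classifier: everything closer to the inner radius is sublobar
        self._shell_split = 0.5 * (cortex_fraction + inner_fraction) \
            * head_radius

    # -- scalar predicates (kept simple so an independent re-implementation
    #    is easy to write against the documented rules) ---------------------

    def label_one(self, coord: np.ndarray) -> tuple[str, str, str]:
        x, y, z = (float(v) for v in coord)
        r = float(np.sqrt(x * x + y * y + z * z))
        hemisphere = "left" if x <= 0 else "right"
        if r < self._shell_split:
            lobe = "sublobar"
            ux = abs(x) / r if r > 0 else 0.0
            if ux > 0.5:
                gyrus = "Insula"
            elif y > 0:
                gyrus = "Caudate"
            else:
                gyrus = "Thalamus"
            return hemisphere, lobe, gyrus
        ux, uy, uz = x / r, y / r, z / r
        ax = abs(ux)
        if ax <= self.LIMBIC_X:
            lobe = "limbic"
            gyrus = "Anterior Cingulate" if uy > 0 else "Posterior Cingulate"
            return hemisphere, lobe, gyrus
        alpha = float(np.degrees(np.arctan2(ax, uy)))  # 0 anterior, 180 post.
        if uz >= self.SUPERIOR_Z:
            if alpha < self.CENTRAL_ALPHA:
                return hemisphere, "frontal", self._frontal_gyrus(alpha)
            return hemisphere, "parietal", self._parietal_gyrus(alpha, ax)
        if alpha <= self.ANTERIOR_ALPHA:
            return hemisphere, "frontal", "Orbital Gyrus"
        if alpha >= self.POSTERIOR_ALPHA:
            gyrus = "Cuneus" if uz >= 0 else "Lingual Gyrus"
            return hemisphere, "occipital", gyrus
        return hemisphere, "temporal", self._temporal_gyrus(uz)

    @staticmethod
    def _frontal_gyrus(alpha: float) -> str:
        if alpha < 30:
            return "Superior Frontal Gyrus"
        if alpha < 55:
            return "Middle Frontal Gyrus"
        if alpha < 65:
            return "Inferior Frontal Gyrus"
        return "Precentral Gyrus"

    @staticmethod
    def _parietal_gyrus(alpha: float, ax: float) -> str:
        if alpha < 95:
            return "Postcentral Gyrus"
        if ax >= 0.55:
            return "Supramarginal Gyrus" if alpha < 125 else "Angular Gyrus"
        if ax >= 0.35:
            return "Inferior Parietal Lobule"
        return "Superior Parietal Lobule"

    @staticmethod
    def _temporal_gyrus(uz: float) -> str:
        if uz >= 0.28:
            return "Superior Temporal Gyrus"
        if uz >= 0.08:
            return "Middle Temporal Gyrus"
        if uz >= -0.12:
            return "Inferior Temporal Gyrus"
        return "Fusiform Gyrus"

    def label(self, coords: np.ndarray) -> pd.DataFrame:
        coords = np.asarray(coords, dtype=float)
        rows = [self.label_one(c) for c in coords]
        return pd.DataFrame(rows, columns=["hemisphere", "lobe", "gyrus"])


# ---------------------------------------------------------------------------
# head model
# ---------------------------------------------------------------------------

def build_head_model(n_nodes: int, seed: int,
                     head_radius: float = DEFAULT_HEAD_RADIUS,
                     cortex_fraction: float = 0.78,
                     inner_fraction: float = 0.55,
                     sublobar_node_fraction: float = 0.10,
                     cap_theta_max_deg: float = 120.0,
                     ) -> tuple[NodeCloud, AtlasLabelTable]:
    """Sample a two-shell hemispheric-cap node cloud and label every node.

    The outer shell (cortex) holds ``1 - sublobar_node_fraction`` of the
    nodes, quasi-uniformly over the spherical cap of half-angle
    ``cap_theta_max_deg`` from the vertex; the rest sit on an inner shell
    labeled sublobar.  Deterministic given ``seed``.
    """
    if n_nodes < 100:
        raise MscopeError("n_nodes must be at least 100")
    rng = np.random.default_rng(seed)
    n_inner = int(round(sublobar_node_fraction * n_nodes))
    n_outer = n_nodes - n_inner
    z_min = np.cos(np.deg2rad(cap_theta_max_deg))

    def cap_points(n: int, radius: float) -> np.ndarray:
        z = rng.uniform(z_min, 1.0, size=n)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
        s = np.sqrt(1.0 - z * z)
        return radius * np.column_stack(
            (s * np.cos(phi), s * np.sin(phi), z))

    outer = cap_points(n_outer, cortex_fraction * head_radius)
    inner = cap_points(n_inner, inner_fraction * head_radius)
    coords = np.vstack((outer, inner))
    cloud = NodeCloud(node_id=np.arange(1, n_nodes + 1), coords=coords,
                      space=SPACE_TALAIRACH)
    atlas = SyntheticAtlas(head_radius=head_radius,
                           cortex_fraction=cortex_fraction,
                           inner_fraction=inner_fraction)
    lab = atlas.label(coords).assign(node_id=cloud.node_id)
    labels = AtlasLabelTable(lab[list(AtlasLabelTable.REQUIRED)])
    if n_nodes >= 2000:
        present = set(labels.categories_present())
        from .io import CATEGORIES
        missing = [c for c in CATEGORIES if c not in present]
        if missing:  # pragma: no cover - guards the partition geometry
            raise MscopeError(f"partition left categories empty: {missing}")
    return cloud, labels


# ---------------------------------------------------------------------------
# field simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Tunable parameters of the phenomenological field model.

    ``sigma0`` is the Gaussian source spread (mm) for the reference
    5x5 cm^2 pad; the spread scales as ``(area/25)**size_spread_exponent``
    and the peak gain as ``(25/area)**peak_gain_exponent``, so smaller pads
    give sharper, higher peaks.  ``leak_fraction`` weighs the anode->cathode
    path term (Gaussian of width ``path_sigma`` around the great-circle
    scalp path, projected to the cortex shell).  ``noise_sd`` adds seeded
    Gaussian noise in field units (0 keeps the model exactly linear in the
    injected current).
    """

    sigma0: float = 35.0
    size_spread_exponent: float = 0.5
    peak_gain_exponent: float = 0.5
    leak_fraction: float = 0.35
    path_sigma: float = 25.0
    noise_sd: float = 0.0
    seed: int = 0
    n_arc_samples: int = 64

    def __post_init__(self) -> None:
        if self.sigma0 <= 0 or self.path_sigma <= 0:
            raise MscopeError("kernel widths must be positive")
        if not 0.0 <= self.leak_fraction <= 1.0:
            raise MscopeError("leak_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise MscopeError("noise_sd must be non-negative")


def _slerp(a: np.ndarray, b: np.ndarray, n: int) -> np.ndarray:
    """Great-circle interpolation between unit vectors ``a`` and ``b``."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    omega = np.arccos(dot)
    t = np.linspace(0.0, 1.0, n)
    if omega < 1e-12:
        return np.outer(np.ones(n), a)
    so = np.sin(omega)
    pts = (np.sin((1 - t) * omega)[:, None] * a +
           np.sin(t * omega)[:, None] * b) / so
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def arc_points(layout: ElectrodeLayout, anode: str, cathode: str,
               shell_radius: float, n: int = 64) -> np.ndarray:
    """The anode->cathode great-circle scalp path, sampled and projected
    radially onto the cortex shell."""
    a = layout[anode] / np.linalg.norm(layout[anode])
    b = layout[cathode] / np.linalg.norm(layout[cathode])
    return shell_radius * _slerp(a, b, n)


def simulate_field(montage: MontageSpec, cloud: NodeCloud,
                   layout: ElectrodeLayout,
                   params: SimulationParams | None = None,
                   seed: int | None = None) -> FieldVector:
    """Per-node scalar field for one montage.

    value_i = (current / 2 mA) * gain(area)
              * [ G_sigma(|x_i - anode_cortex|)
                  + leak_fraction * G_path(dist(x_i, anode->cathode arc)) ]
              + noise,  clipped at 0,

    with Gaussian kernels G(d) = exp(-d^2 / (2 w^2)).  Strictly linear in
    the injected current when ``noise_sd == 0``; deterministic given the
    seed (``seed`` argument overrides ``params.seed``).
    """
    params = params or SimulationParams()
    if montage.anode_label not in layout:
        raise MscopeError(f"anode {montage.anode_label!r} absent from layout")
    if montage.cathode_label not in layout:
        raise MscopeError(
            f"cathode {montage.cathode_label!r} absent from layout")
    radii = np.linalg.norm(cloud.coords, axis=1)
    shell_radius = float(radii.max())

    area = montage.area
    gain = (25.0 / area) ** params.peak_gain_exponent
    sigma = params.sigma0 * (area / 25.0) ** params.size_spread_exponent

    anode_point = shell_radius * layout[montage.anode_label] \
        / np.linalg.norm(layout[montage.anode_label])
    d_anode = np.linalg.norm(cloud.coords - anode_point, axis=1)
    source = np.exp(-0.5 * (d_anode / sigma) ** 2)

    arc = arc_points(layout, montage.anode_label, montage.cathode_label,
                     shell_radius, params.n_arc_samples)
    # min Euclidean distance from each node to the sampled path
    d_arc = np.min(
        np.linalg.norm(cloud.coords[:, None, :] - arc[None, :, :], axis=2),
        axis=1,
    )
    path = np.exp(-0.5 * (d_arc / params.path_sigma) ** 2)

    value = (montage.current / DEFAULT_CURRENT_MA) * gain \
        * (source + params.leak_fraction * path)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed if seed is None else seed)
        value = value + rng.normal(0.0, params.noise_sd, size=value.size)
    value = np.clip(value, 0.0, None)
    return FieldVector(node_id=cloud.node_id.copy(), value=value,
                       kind="MCD", montage_name=montage.name)
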