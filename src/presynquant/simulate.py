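"""Synthetic ground-truth generators for every pipeline stage.

The generators emulate the three kinds of raw data the quantification
pipeline consumes:

* **Axon scenes** — a curvilinear axon ridge imaged at 20 nm/px (the STED
  acquisition pixel size) bearing diffraction-limited puncta in two cluster
  channels, with a controlled centre offset between channel-A and channel-B
  puncta. The axon ridge is rendered into a separate marker plane (the role
  Synaptophysin-1 plays in the experiment) so the cluster channels stay
  clean, mirroring the multi-colour acquisition.
* **pHluorin bouton pairs** — quenched (F0) and depolarized (Fmax) frames
  with per-bouton release fractions r chosen so that
  (Fmax − F0)/Fmax = r exactly in the noise-free limit.
* **Phosphosite tables** — MaxQuant-style site tables with per-replicate
  intensities, protein abundances and localization probabilities, with a
  ground-truth pass/fail flag for the high-confidence filter.

Every generator is fully determined by ``seed`` in its config. Noise is
Poisson on (signal + background) followed by additive Gaussian read noise;
both components can be switched off for exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .imaging import PixelImage, ImageStack

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_axon_scene",
    "generate_phluorin_pair",
    "generate_phosphosite_table",
    "generate_cell_scene",
    "render_gaussians",
    "apply_noise",
]

AXON_CHANNEL = "axon_marker"
CHANNEL_A = "cluster_a"
CHANNEL_B = "cluster_b"


@dataclass
class SimulationConfig:
    """Stated world of the simulator.

    Lengths are in nm. Defaults follow the acquisition (20 nm/px) and a
    realistic distal axon: shaft FWHM 400 nm, effective PSF sigma 80 nm
    (STED-like), puncta peak 300 counts over a 10-count background, shot
    noise at unit gain plus 2-count read noise, 20 puncta per channel and a
    100 nm A→B centre offset (the co-clustering distance the analysis is
    meant to resolve).
    """

    image_shape: tuple[int, int] = (672, 672)
    pixel_size_nm: float = 20.0
    axon_width_nm: float = 400.0  # FWHM of the ridge cross-section
    psf_sigma_nm: float = 80.0
    cluster_amplitude: float = 300.0
    background: float = 10.0
    poisson_gain: float = 1.0  # 0 disables shot noise
    gaussian_sd: float = 2.0  # 0 disables read noise
    n_clusters_per_channel: int = 20
    nn_offset_nm: float = 100.0
    seed: int = 0
    # package extensions
    axon_amplitude: float = 60.0  # ridge peak in the marker plane
    include_marker_channel: bool = True
    min_cluster_spacing_nm: float = 600.0
    cluster_centers_a: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "axon_width_nm", "psf_sigma_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.nn_offset_nm < 0:
            raise ValueError("nn_offset_nm must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generators know that the pipeline must recover."""

    axon_path: np.ndarray | None = None  # (n, 2) physical (x, y) nm
    cluster_centers: dict = field(default_factory=dict)  # channel -> (n, 2) nm
    bouton_truth: pd.DataFrame | None = None
    site_truth: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def _pixel_centers(n: int, pixel_size_nm: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * pixel_size_nm


def render_gaussians(
    shape: tuple[int, int],
    pixel_size_nm: float,
    centers_nm: np.ndarray,
    amplitude: float,
    sigma_nm: float,
) -> np.ndarray:
    """Render isotropic Gaussians (peak = ``amplitude``) sampled at pixel
    centres; the physical coordinate of pixel (i, j) is ((j+0.5)px, (i+0.5)px).
    """
    img = np.zeros(shape, dtype=np.float64)
    centers_nm = np.atleast_2d(np.asarray(centers_nm, dtype=np.float64))
    if centers_nm.size == 0:
        return img
    xs = _pixel_centers(shape[1], pixel_size_nm)
    ys = _pixel_centers(shape[0], pixel_size_nm)
    halo = 6.0 * sigma_nm
    for cx, cy in centers_nm:
        j0, j1 = np.searchsorted(xs, [cx - halo, cx + halo])
        i0, i1 = np.searchsorted(ys, [cy - halo, cy + halo])
        dx = xs[j0:j1] - cx
        dy = ys[i0:i1] - cy
        img[i0:i1, j0:j1] += amplitude * np.outer(
            np.exp(-(dy**2) / (2 * sigma_nm**2)),
            np.exp(-(dx**2) / (2 * sigma_nm**2)),
        )
    return img


def _render_ridge(
    shape: tuple[int, int],
    pixel_size_nm: float,
    path_nm: np.ndarray,
    amplitude: float,
    width_fwhm_nm: float,
) -> np.ndarray:
    """Axon ridge: Gaussian cross-section (FWHM ``width_fwhm_nm``) around the
    path, implemented as distance-to-path via a KD-tree over dense path points.
    """
    from scipy.spatial import cKDTree

    sigma = width_fwhm_nm / 2.3548200450309493
    xs = _pixel_centers(shape[1], pixel_size_nm)
    ys = _pixel_centers(shape[0], pixel_size_nm)
    xx, yy = np.meshgrid(xs, ys)
    tree = cKDTree(path_nm)
    d, _ = tree.query(np.column_stack([xx.ravel(), yy.ravel()]), k=1)
    return amplitude * np.exp(-(d.reshape(shape) ** 2) / (2 * sigma**2))


def apply_noise(img: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise at ``poisson_gain`` counts/e-, then Gaussian read
    noise; either component is skipped when its parameter is 0."""
    out = np.asarray(img, dtype=np.float64)
    if config.poisson_gain > 0:
        out = config.poisson_gain * rng.poisson(
            np.clip(out / config.poisson_gain, 0, None)
        ).astype(np.float64)
    if config.gaussian_sd > 0:
        out = out + rng.normal(0.0, config.gaussian_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# axon scenes
# ---------------------------------------------------------------------------


def _sample_axon_path(
    config: SimulationConfig, rng: np.random.Generator, margin_nm: float
) -> np.ndarray:
    """Smooth, non-self-intersecting path crossing the field left to right.

    The heading performs a bounded random walk (curvature-capped) and is
    clipped to ±60°, which makes the path monotone in x and therefore free of
    self-intersections.
    """
    h, w = config.image_shape
    px = config.pixel_size_nm
    x_max = w * px - margin_nm
    y_min, y_max = margin_nm, h * px - margin_nm
    step = px  # one pixel per step
    x = margin_nm
    y = rng.uniform(y_min + 0.2 * (y_max - y_min), y_max - 0.2 * (y_max - y_min))
    theta = rng.uniform(-0.3, 0.3)
    # curvature cap: radius of curvature >= step / max_dtheta ~ 80 px, gentle
    # enough that the 1.41 um morphological closing cannot fill a bend and
    # far below self-intersection within one PSF
    max_dtheta = 0.012
    pts = [(x, y)]
    while x < x_max:
        theta = np.clip(theta + rng.normal(0, max_dtheta), -np.pi / 3, np.pi / 3)
        # steer back toward the interior near the top/bottom margins
        if y < y_min + 10 * px:
            theta = min(theta + 2 * max_dtheta, np.pi / 3)
        elif y > y_max - 10 * px:
            theta = max(theta - 2 * max_dtheta, -np.pi / 3)
        x += step * np.cos(theta)
        y += step * np.sin(theta)
        pts.append((x, y))
    return np.asarray(pts)


def _sample_spaced_arclengths(
    total: float, n: int, min_spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """n arclength positions in (0, total) with pairwise spacing >= min_spacing."""
    if n * min_spacing >= total:
        raise ValueError("scene overflow: cannot place clusters with requested spacing")
    slack = total - n * min_spacing
    u = np.sort(rng.uniform(0, slack, size=n))
    return u + min_spacing * (np.arange(n) + 0.5)


def generate_axon_scene(config: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Simulate a two-cluster-channel axon scene with known geometry.

    Returns an :class:`ImageStack` whose planes are (optionally) the axon
    marker ridge, cluster channel A and cluster channel B, plus the ground
    truth (path and per-channel centres in nm). Channel-B puncta sit at
    ``nn_offset_nm`` from their channel-A partner in a uniformly random
    direction.
    """
    h, w = config.image_shape
    px = config.pixel_size_nm
    if config.nn_offset_nm >= min(h, w) * px:
        raise ValueError("scene overflow: nn_offset_nm exceeds the field of view")
    rng = np.random.default_rng(config.seed)
    margin = 6 * config.psf_sigma_nm + config.nn_offset_nm + 2 * px
    path = _sample_axon_path(config, rng, margin)

    if config.cluster_centers_a is not None:
        centers_a = np.asarray(config.cluster_centers_a, dtype=np.float64)
    else:
        seg = np.hypot(*np.diff(path, axis=0).T)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        s = _sample_spaced_arclengths(
            arclen[-1], config.n_clusters_per_channel, config.min_cluster_spacing_nm, rng
        )
        centers_a = np.column_stack(
            [np.interp(s, arclen, path[:, 0]), np.interp(s, arclen, path[:, 1])]
        )
    phi = rng.uniform(0, 2 * np.pi, size=len(centers_a))
    centers_b = centers_a + config.nn_offset_nm * np.column_stack([np.cos(phi), np.sin(phi)])

    field_nm = np.array([w * px, h * px])
    for name, c in (("A", centers_a), ("B", centers_b)):
        if len(c) and ((c < 0).any() or (c >= field_nm).any()):
            raise ValueError(f"scene overflow: channel {name} centre outside image")

    img_a = config.background + render_gaussians(
        (h, w), px, centers_a, config.cluster_amplitude, config.psf_sigma_nm
    )
    img_b = config.background + render_gaussians(
        (h, w), px, centers_b, config.cluster_amplitude, config.psf_sigma_nm
    )
    planes = []
    if config.include_marker_channel:
        marker = config.background + _render_ridge(
            (h, w), px, path, config.axon_amplitude, config.axon_width_nm
        )
        planes.append(PixelImage(apply_noise(marker, config, rng), px, AXON_CHANNEL))
    planes.append(PixelImage(apply_noise(img_a, config, rng), px, CHANNEL_A))
    planes.append(PixelImage(apply_noise(img_b, config, rng), px, CHANNEL_B))

    truth = GroundTruth(
        axon_path=path,
        cluster_centers={CHANNEL_A: centers_a, CHANNEL_B: centers_b},
    )
    return ImageStack(planes, metadata={"config": config.to_dict()}), truth


# ---------------------------------------------------------------------------
# pHluorin bouton pairs
# ---------------------------------------------------------------------------


def generate_phluorin_pair(
    config: SimulationConfig,
    n_boutons: int = 50,
    release_fractions: np.ndarray | None = None,
    f0_true: float = 100.0,
    roi_radius_px: int = 5,
    n_planes: int = 1,
    off_plane_factor: float = 0.4,
) -> tuple[ImageStack, ImageStack, np.ndarray, GroundTruth]:
    """Simulate quenched/depolarized frame pairs with known release fractions.

    Boutons are uniform discs on a dark (quenched) background laid out on a
    grid; per bouton, ``Fmax_true = F0_true / (1 - r)`` so the release metric
    (Fmax − F0)/Fmax equals r exactly without noise. Returns
    ``(F0_stack, Fmax_stack, roi_labels, truth)`` where ``roi_labels`` is an
    integer label map (0 = background).
    """
    rng = np.random.default_rng(config.seed)
    if release_fractions is None:
        release_fractions = rng.uniform(0.1, 0.6, size=n_boutons)
    r = np.asarray(release_fractions, dtype=np.float64)
    if (r >= 1).any() or (r < 0).any():
        raise ValueError("release fractions must lie in [0, 1)")
    n_boutons = len(r)

    spacing = 4 * roi_radius_px + 4
    per_row = int(np.ceil(np.sqrt(n_boutons)))
    side = per_row * spacing + spacing
    px = config.pixel_size_nm
    yy, xx = np.mgrid[0:side, 0:side]
    labels = np.zeros((side, side), dtype=np.int64)
    f0_img = np.zeros((side, side))
    fmax_img = np.zeros((side, side))
    f0_vals = np.full(n_boutons, float(f0_true))
    fmax_vals = f0_vals / (1.0 - r)
    for k in range(n_boutons):
        ci = spacing + (k // per_row) * spacing
        cj = spacing + (k % per_row) * spacing
        disc = (yy - ci) ** 2 + (xx - cj) ** 2 <= roi_radius_px**2
        labels[disc] = k + 1
        f0_img[disc] = f0_vals[k]
        fmax_img[disc] = fmax_vals[k]

    def _stack(base: np.ndarray, tag: str) -> ImageStack:
        planes = []
        for z in range(n_planes):
            plane = base if z == 0 else base * off_plane_factor
            planes.append(PixelImage(apply_noise(plane, config, rng), px, f"{tag}_z{z}"))
        return ImageStack(planes)

    truth = GroundTruth(
        bouton_truth=pd.DataFrame(
            {
                "roi": np.arange(1, n_boutons + 1),
                "F0_true": f0_vals,
                "Fmax_true": fmax_vals,
                "release_fraction": r,
            }
        )
    )
    return _stack(f0_img, "F0"), _stack(fmax_img, "Fmax"), labels, truth


# ---------------------------------------------------------------------------
# phosphosite tables
# ---------------------------------------------------------------------------


def generate_phosphosite_table(
    config: SimulationConfig,
    n_sites: int = 200,
    n_replicates: int = 4,
    min_replicates: int = 3,
    min_loc_prob: float = 0.75,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a MaxQuant-style phosphosite table with known filter truth.

    Intensities are log-normal; each site is present (non-missing) in a
    random subset of replicates; localization probabilities come from a
    high/low mixture so both sides of the 0.75 cut are populated. The truth
    flag is computed directly from the generated presence pattern and
    probability — independently of the filtering code under test.
    """
    if n_replicates < 1:
        raise ValueError("replicate count must be >= 1")
    rng = np.random.default_rng(config.seed)
    residues = rng.choice(["S", "T", "Y"], size=n_sites, p=[0.6, 0.3, 0.1])
    positions = np.sort(rng.choice(np.arange(1, 10 * n_sites), size=n_sites, replace=False))
    high = rng.random(n_sites) < 0.5
    loc_prob = np.where(
        high, rng.beta(9, 1.5, size=n_sites), rng.beta(2.5, 2.5, size=n_sites)
    ).round(3)

    n_present = rng.integers(0, n_replicates + 1, size=n_sites)
    present = np.zeros((n_sites, n_replicates), dtype=bool)
    for i, k in enumerate(n_present):
        present[i, rng.choice(n_replicates, size=k, replace=False)] = True

    intensity = 2.0 ** rng.normal(20.0, 1.5, size=(n_sites, n_replicates))
    intensity[~present] = np.nan
    abundance = 2.0 ** rng.normal(25.0, 0.5, size=(n_sites, n_replicates))

    table = pd.DataFrame(
        {
            "protein_id": "PLPPR3",
            "variant": "ICDm",
            "residue": residues,
            "position": positions,
            "localization_prob": loc_prob,
        }
    )
    for rep in range(n_replicates):
        table[f"intensity_rep{rep + 1}"] = intensity[:, rep]
    for rep in range(n_replicates):
        table[f"protein_abundance_rep{rep + 1}"] = abundance[:, rep]

    truth_pass = (n_present >= min_replicates) & (loc_prob > min_loc_prob)
    truth = GroundTruth(
        site_truth=pd.DataFrame(
            {
                "position": positions,
                "residue": residues,
                "n_present": n_present,
                "localization_prob": loc_prob,
                "truth_pass": truth_pass,
            }
        )
    )
    return table, truth


# ---------------------------------------------------------------------------
# filopodia cell scenes
# ---------------------------------------------------------------------------


def generate_cell_scene(
    config: SimulationConfig,
    n_filopodia: int = 12,
    cell_radius_nm: float = 10_000.0,
    interior_intensity: float = 100.0,
    membrane_intensity: float = 0.0,
    filopodium_intensity: float = 250.0,
    min_angular_sep: float = 0.35,
) -> tuple[PixelImage, GroundTruth]:
    """A round cell filled with membrane marker plus n bright filopodial stems.

    The marker fills the cell roughly uniformly (as a farnesylated GFP does
    in projection; an explicit rim can be added via ``membrane_intensity``),
    and filopodium stems are rendered as tight spots crossing the cell
    border, so sampling intensity along the detected outline shows exactly
    ``n_filopodia`` peaks.
    """
    rng = np.random.default_rng(config.seed)
    px = config.pixel_size_nm
    r_px = cell_radius_nm / px
    side = int(np.ceil(2 * r_px + 20))
    c = side / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    rad = np.hypot(yy + 0.5 - c, xx + 0.5 - c)
    img = np.where(rad <= r_px, interior_intensity, 0.0)
    ring = np.exp(-((rad - r_px) ** 2) / (2 * 1.5**2))
    img = img + membrane_intensity * ring

    angles = []
    while len(angles) < n_filopodia:
        a = rng.uniform(0, 2 * np.pi)
        if all(min(abs(a - b), 2 * np.pi - abs(a - b)) > min_angular_sep for b in angles):
            angles.append(a)
    angles = np.asarray(angles)
    # filopodium stems: tight spots (sigma 150 nm, a realistic filopodium
    # width) just outside the cell body so they cross the traced border
    r_spot = r_px + 2.0
    centers = np.column_stack(
        [(c + r_spot * np.cos(angles)) * px, (c + r_spot * np.sin(angles)) * px]
    )
    img = img + render_gaussians((side, side), px, centers, filopodium_intensity, 1.5 * px)
    img = apply_noise(img + config.background, config, rng)
    truth = GroundTruth(extras={"n_filopodia": n_filopodia, "angles": angles, "radius_nm": cell_radius_nm})
    return PixelImage(img, px, "membrane"), truth
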