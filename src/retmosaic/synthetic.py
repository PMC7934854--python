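"""Seeded synthetic data with planted ground truth.

Three generators emulate the raw inputs of a retinal-degeneration rescue
study so every downstream quantification can be benchmarked against known
truth:

* :func:`generate_flatmount` — an en-face confocal flat mount of a retina in
  which every point of fluorescence is a labelled cone nucleus, including a
  bright/dim intensity mixture, touching nuclei, and circumscribed cone-free
  "craters" in the mosaic;
* :func:`generate_em_field` — a scanning-EM field of the RPE apical surface
  tiled into microvilli-covered, process-free, and dead regions with known
  area fractions;
* :func:`generate_de_tables` — a pair of differential-expression tables with
  planted directionally discordant / concordant significant genes and one
  enriched annotation term.

All generators are deterministic for a fixed spec and seed; independent
sub-streams are derived from the seed so that, e.g., changing the number of
nuclei does not perturb the noise field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "FlatMountSpec",
    "FlatMountTruth",
    "EMFieldSpec",
    "DETableSpec",
    "generate_flatmount",
    "generate_em_field",
    "generate_de_tables",
    "sample_craters",
]

# (row, col) 0-based pixel coordinates, origin top-left, everywhere.


@dataclass(frozen=True)
class FlatMountSpec:
    """Parameters of a synthetic cone-mosaic flat mount.

    Defaults emulate a whole flat mount imaged at low magnification: a
    disc-shaped retina ~10^3 px across carrying a few thousand cone nuclei
    rendered as isotropic Gaussian spots (sigma 2.5 px), a 20% dim
    subpopulation at 30% of the bright amplitude, 10% of nuclei touching a
    neighbour, and additive Gaussian plus Poisson shot noise.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    pixel_size_um: float = 1.0
    retina_radius_px: float = 480.0
    onh_center: tuple[float, float] | None = None  # None -> image centre
    n_cones: int = 2000
    dim_fraction: float = 0.2
    bright_amplitude: float = 2000.0
    dim_amplitude: float = 600.0
    nucleus_sigma_px: float = 2.5
    cluster_fraction: float = 0.1
    craters: tuple[tuple[float, float, float], ...] = ()
    background_level: float = 100.0
    noise_sd: float = 10.0
    shot_noise: bool = True
    min_separation_px: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValidationError("image dimensions must be positive")
        if self.pixel_size_um <= 0 or self.retina_radius_px <= 0:
            raise ValidationError("pixel size and retina radius must be positive")
        if self.n_cones < 0:
            raise ValidationError("n_cones must be non-negative")
        for name in ("dim_fraction", "cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.bright_amplitude <= 0 or self.dim_amplitude <= 0:
            raise ValidationError("amplitudes must be positive")
        if self.dim_amplitude >= self.bright_amplitude:
            raise ValidationError("dim_amplitude must be smaller than bright_amplitude")
        if self.nucleus_sigma_px <= 0:
            raise ValidationError("nucleus_sigma_px must be positive")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValidationError("background and noise_sd must be non-negative")
        centre = self.center
        for cr, cc, r in self.craters:
            if r <= 0:
                raise ValidationError("crater radius must be positive")
            d = np.hypot(cr - centre[0], cc - centre[1])
            if d + r > self.retina_radius_px:
                raise ValidationError(
                    f"crater at ({cr:.1f}, {cc:.1f}) radius {r:.1f} extends outside the retina disc"
                )

    @property
    def center(self) -> tuple[float, float]:
        if self.onh_center is not None:
            return self.onh_center
        return ((self.image_height_px - 1) / 2.0, (self.image_width_px - 1) / 2.0)


@dataclass
class FlatMountTruth:
    """A rendered flat mount plus its planted ground truth."""

    image: np.ndarray          # float64, (H, W)
    retina_mask: np.ndarray    # bool, (H, W)
    crater_mask: np.ndarray    # bool, (H, W)
    onh_center: tuple[float, float]
    centroids: np.ndarray      # float64, (n, 2) as (row, col)
    classes: np.ndarray        # array of 'bright' / 'dim'
    spec: FlatMountSpec

    @property
    def n_true(self) -> int:
        return len(self.centroids)

    def truth_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": self.centroids[:, 0] if self.n_true else np.empty(0),
                "col": self.centroids[:, 1] if self.n_true else np.empty(0),
                "class": self.classes,
            }
        )


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def sample_craters(
    spec_or_radius,
    n_craters: int,
    area_fraction: float,
    seed: int = 0,
    min_gap_px: float = 20.0,
    max_attempts: int = 10_000,
) -> tuple[tuple[float, float, float], ...]:
    """Sample non-overlapping crater discs inside the retina disc.

    ``n_craters`` equal-radius discs are drawn whose total area is
    ``area_fraction`` of the retina disc area, placed by rejection sampling
    with pairwise gaps of at least ``min_gap_px``.  Raises after
    ``max_attempts`` rejections.
    """
    if isinstance(spec_or_radius, FlatMountSpec):
        R = spec_or_radius.retina_radius_px
        center = spec_or_radius.center
    else:
        R = float(spec_or_radius)
        center = (0.0, 0.0)
    if n_craters <= 0 or not 0 < area_fraction < 1:
        raise ValidationError("need n_craters >= 1 and area_fraction in (0, 1)")
    r = R * np.sqrt(area_fraction / n_craters)
    rng = np.random.default_rng(seed)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_craters:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError(
                f"could not place {n_craters} craters of radius {r:.1f} in {max_attempts} attempts"
            )
        # uniform over the disc of feasible centres
        u = rng.uniform(0, 1)
        theta = rng.uniform(0, 2 * np.pi)
        rad = (R - r) * np.sqrt(u)
        cand = (center[0] + rad * np.cos(theta), center[1] + rad * np.sin(theta))
        ok = all(
            np.hypot(cand[0] - pr, cand[1] - pc) >= 2 * r + min_gap_px for pr, pc, _ in placed
        )
        if ok:
            placed.append((cand[0], cand[1], r))
    return tuple(placed)


def _place_centroids(spec: FlatMountSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample cone nucleus positions.

    Positions are uniform over the retina disc, excluded from crater discs
    (with a half-pixel margin so rounded coordinates stay off the crater
    mask).  ``cluster_fraction`` of the nuclei are instead attached to an
    already-placed partner at distance in [sigma, 2 sigma].
    """
    n = spec.n_cones
    if n == 0:
        return np.empty((0, 2))
    center = spec.center
    sig = spec.nucleus_sigma_px
    margin = 3.0 * sig  # keep rendered spots inside the retina
    craters = np.asarray(spec.craters, dtype=float).reshape(-1, 3)

    def valid(pt: np.ndarray, placed: np.ndarray, n_placed: int) -> bool:
        if np.hypot(pt[0] - center[0], pt[1] - center[1]) > spec.retina_radius_px - margin:
            return False
        if len(craters) and np.any(
            np.hypot(pt[0] - craters[:, 0], pt[1] - craters[:, 1]) <= craters[:, 2] + 1.0
        ):
            return False
        if spec.min_separation_px > 0 and n_placed:
            d = np.hypot(placed[:n_placed, 0] - pt[0], placed[:n_placed, 1] - pt[1])
            if d.min() < spec.min_separation_px:
                return False
        return True

    n_cluster = int(round(spec.cluster_fraction * n))
    n_single = n - n_cluster
    pts = np.empty((n, 2))
    count = 0
    attempts = 0
    max_attempts = 200 * n + 10_000
    while count < n_single:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError("could not place nuclei; retina too crowded for the spec")
        u = rng.uniform(0, 1)
        theta = rng.uniform(0, 2 * np.pi)
        rad = (spec.retina_radius_px - margin) * np.sqrt(u)
        pt = np.array([center[0] + rad * np.cos(theta), center[1] + rad * np.sin(theta)])
        if valid(pt, pts, count):
            pts[count] = pt
            count += 1
    while count < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError("could not place clustered nuclei")
        partner = pts[rng.integers(0, count)]
        dist = rng.uniform(1.0, 2.0) * sig
        theta = rng.uniform(0, 2 * np.pi)
        pt = partner + dist * np.array([np.cos(theta), np.sin(theta)])
        # clustered nuclei ignore min_separation by construction
        spec_nosep = pt
        if np.hypot(pt[0] - center[0], pt[1] - center[1]) > spec.retina_radius_px - margin:
            continue
        if len(craters) and np.any(
            np.hypot(pt[0] - craters[:, 0], pt[1] - craters[:, 1]) <= craters[:, 2] + 1.0
        ):
            continue
        pts[count] = spec_nosep
        count += 1
    return pts


def _render_spots(
    shape: tuple[int, int],
    centroids: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Accumulate isotropic 2-D Gaussian spots onto a zero image."""
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(4 * sigma))
    for (r, c), a in zip(centroids, amplitudes):
        r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
        c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
        r0, r1 = max(r0, 0), min(r1, shape[0])
        c0, c1 = max(c0, 0), min(c1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1)[:, None] - r
        cc = np.arange(c0, c1)[None, :] - c
        img[r0:r1, c0:c1] += a * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))
    return img


def render_image(
    spec: FlatMountSpec,
    centroids: np.ndarray,
    amplitudes: np.ndarray,
    rng_noise: np.random.Generator | None = None,
) -> np.ndarray:
    """Render nuclei at explicit positions under the spec's imaging model."""
    shape = (spec.image_height_px, spec.image_width_px)
    if rng_noise is None:
        rng_noise = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(3)[2])
    signal = spec.background_level + _render_spots(
        shape, centroids, amplitudes, spec.nucleus_sigma_px
    )
    if spec.shot_noise:
        image = rng_noise.poisson(np.clip(signal, 0, None)).astype(float)
    else:
        image = signal
    if spec.noise_sd > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sd, size=shape)
    return np.clip(image, 0.0, None)


def generate_flatmount(spec: FlatMountSpec) -> FlatMountTruth:
    """Render a flat mount and return it together with its ground truth."""
    spec.validate()
    shape = (spec.image_height_px, spec.image_width_px)
    center = spec.center

    ss = np.random.SeedSequence(spec.seed)
    rng_pos, rng_class, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    retina_mask = _disc_mask(shape, center, spec.retina_radius_px)
    crater_mask = np.zeros(shape, dtype=bool)
    for cr, cc, r in spec.craters:
        crater_mask |= _disc_mask(shape, (cr, cc), r)
    crater_mask &= retina_mask

    centroids = _place_centroids(spec, rng_pos)
    is_dim = rng_class.uniform(size=len(centroids)) < spec.dim_fraction
    classes = np.where(is_dim, "dim", "bright")
    amplitudes = np.where(is_dim, spec.dim_amplitude, spec.bright_amplitude)

    image = render_image(spec, centroids, amplitudes, rng_noise)

    return FlatMountTruth(
        image=image,
        retina_mask=retina_mask,
        crater_mask=crater_mask,
        onh_center=center,
        centroids=centroids,
        classes=classes,
        spec=spec,
    )


def generate_cluster_mosaic(
    spec: FlatMountSpec,
    n_singletons: int = 300,
    kmer_counts: Mapping[int, int] | None = None,
    member_spacing_sigma: tuple[float, float] = (1.4, 2.0),
    singleton_separation_px: float = 10.0,
    cluster_separation_px: float = 28.0,
):
    """A mosaic of isolated nuclei plus planted touching k-mers.

    ``kmer_counts`` maps cluster size k to the number of planted clusters
    (default 50 each of k = 2, 3, 4).  Cluster members form a chain with
    successive spacings uniform in ``member_spacing_sigma`` x sigma, so
    members overlap into one thresholded component.  Clusters keep
    ``cluster_separation_px`` clear of everything else, making per-cluster
    recovery unambiguous.  All nuclei are bright-class.

    Returns ``(truth, clusters)`` where ``clusters`` is a list of (k, 2)
    position arrays, one per planted k-mer.
    """
    spec.validate()
    if kmer_counts is None:
        kmer_counts = {2: 50, 3: 50, 4: 50}
    shape = (spec.image_height_px, spec.image_width_px)
    center = spec.center
    sig = spec.nucleus_sigma_px
    margin = 3.0 * sig + 3.0 * max(member_spacing_sigma) * sig
    ss = np.random.SeedSequence(spec.seed)
    rng_pos, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    def sample_point(max_r: float) -> np.ndarray:
        u = rng_pos.uniform(0, 1)
        theta = rng_pos.uniform(0, 2 * np.pi)
        rad = max_r * np.sqrt(u)
        return np.array([center[0] + rad * np.cos(theta), center[1] + rad * np.sin(theta)])

    anchors: list[np.ndarray] = []
    ks: list[int] = []
    for k, cnt in sorted(kmer_counts.items()):
        ks.extend([k] * cnt)
    attempts = 0
    while len(anchors) < len(ks):
        attempts += 1
        if attempts > 100_000:
            raise ValidationError("could not place clusters; reduce counts or separation")
        pt = sample_point(spec.retina_radius_px - margin)
        if all(np.hypot(*(pt - a)) >= cluster_separation_px for a in anchors):
            anchors.append(pt)

    clusters: list[np.ndarray] = []
    for anchor, k in zip(anchors, ks):
        members = [anchor]
        while len(members) < k:
            step = rng_pos.uniform(*member_spacing_sigma) * sig
            theta = rng_pos.uniform(0, 2 * np.pi)
            cand = members[-1] + step * np.array([np.cos(theta), np.sin(theta)])
            # stay near the anchor so the cluster is one component
            if np.hypot(*(cand - anchor)) > cluster_separation_px / 3:
                continue
            if any(np.hypot(*(cand - m)) < 0.8 * sig for m in members):
                continue
            members.append(cand)
        clusters.append(np.array(members))

    singles: list[np.ndarray] = []
    attempts = 0
    while len(singles) < n_singletons:
        attempts += 1
        if attempts > 200 * n_singletons + 10_000:
            raise ValidationError("could not place singletons; retina too crowded")
        pt = sample_point(spec.retina_radius_px - margin)
        if any(np.hypot(*(pt - a)) < 0.75 * cluster_separation_px for a in anchors):
            continue
        if singles and np.min(np.hypot(*(np.array(singles) - pt).T)) < singleton_separation_px:
            continue
        singles.append(pt)

    centroids = np.vstack([np.array(singles).reshape(-1, 2)] + clusters)
    amplitudes = np.full(len(centroids), spec.bright_amplitude)
    image = render_image(spec, centroids, amplitudes, rng_noise)
    retina_mask = _disc_mask(shape, center, spec.retina_radius_px)
    truth = FlatMountTruth(
        image=image,
        retina_mask=retina_mask,
        crater_mask=np.zeros(shape, dtype=bool),
        onh_center=center,
        centroids=centroids,
        classes=np.array(["bright"] * len(centroids)),
        spec=spec,
    )
    return truth, clusters


# ---------------------------------------------------------------------------
# scanning-EM fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EMFieldSpec:
    """Parameters of a synthetic RPE scanning-EM field.

    The default field area (110 x 102 um^2) matches a 1000x scanning-EM
    photomicrograph of the RPE apical surface.  The field is tiled into
    three region classes: microvilli carpet (bright, high-frequency filament
    texture), no apical processes (smooth dark), and dead/debris (mid-grey
    speckle; in real data these regions are manually traced).
    """

    image_height_px: int = 510
    image_width_px: int = 550
    field_area_um2: float = 110.0 * 102.0
    frac_microvilli: float = 0.6
    frac_none: float = 0.3
    frac_dead: float = 0.1
    filament_density: float = 0.5
    filament_width_px: float = 1.0
    region_scale_px: float = 30.0
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValidationError("image dimensions must be positive")
        if self.field_area_um2 <= 0:
            raise ValidationError("field_area_um2 must be positive")
        fr = (self.frac_microvilli, self.frac_none, self.frac_dead)
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValidationError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError(f"fractions must sum to 1, got {sum(fr)!r}")


def generate_em_field(spec: EMFieldSpec):
    """Generate an EM-like field.

    Returns ``(image, region_masks, true_fractions)`` where ``region_masks``
    is a dict of three disjoint boolean masks tiling the image
    (``microvilli``, ``none``, ``dead``) and ``true_fractions`` the realized
    pixel fractions.  Region geometry comes from thresholding smoothed
    Gaussian random fields at the quantiles matching the requested
    fractions, so realized fractions track requests to pixel resolution.
    """
    from scipy.ndimage import gaussian_filter

    spec.validate()
    shape = (spec.image_height_px, spec.image_width_px)
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_tex, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    g1 = gaussian_filter(rng_geom.normal(size=shape), spec.region_scale_px)
    g2 = gaussian_filter(rng_geom.normal(size=shape), spec.region_scale_px)

    if spec.frac_dead > 0:
        dead = g1 <= np.quantile(g1, spec.frac_dead)
    else:
        dead = np.zeros(shape, dtype=bool)
    rest = ~dead
    if spec.frac_microvilli > 0 and rest.any():
        if spec.frac_none == 0:
            microvilli = rest.copy()
        else:
            # split the remaining pixels by the second field's quantile
            frac_mv_rest = spec.frac_microvilli / (spec.frac_microvilli + spec.frac_none)
            thr = np.quantile(g2[rest], 1.0 - frac_mv_rest)
            microvilli = rest & (g2 > thr)
    else:
        microvilli = np.zeros(shape, dtype=bool)
    none_mask = rest & ~microvilli

    # textures
    image = np.zeros(shape, dtype=float)
    fil = gaussian_filter(
        rng_tex.normal(size=shape), (spec.filament_width_px, 4.0 * spec.filament_width_px)
    )
    fil = fil / (fil.std() + 1e-12)
    image[microvilli] = 190.0 + 35.0 * np.clip(fil[microvilli] * spec.filament_density * 2, -1.5, 1.5)
    smooth = gaussian_filter(rng_tex.normal(size=shape), 3.0)
    image[none_mask] = 40.0 + 8.0 * smooth[none_mask] / (smooth.std() + 1e-12)
    image[dead] = 105.0 + 12.0 * rng_tex.normal(size=int(dead.sum()))
    if spec.noise_sd > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sd, size=shape)
    image = np.clip(image, 0.0, 255.0)

    masks = {"microvilli": microvilli, "none": none_mask, "dead": dead}
    npx = image.size
    true_fractions = {k: float(m.sum()) / npx for k, m in masks.items()}
    return image, masks, true_fractions


# ---------------------------------------------------------------------------
# differential-expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DETableSpec:
    """Parameters of a pair of planted differential-expression tables.

    Table A emulates a treatment-vs-control comparison and table B a
    degeneration time-course comparison over the same gene universe.
    ``n_sig_discordant`` genes are significant in both with opposite
    log2-fold-change signs (the direct-rescue signature), ``n_sig_concordant``
    with the same sign; one annotation term is enriched in the discordant
    set by construction.
    """

    n_genes: int = 5000
    n_sig_discordant: int = 12
    n_sig_concordant: int = 40
    alpha: float = 0.05
    effect_size_mean: float = 1.5
    effect_size_sd: float = 0.5
    n_terms: int = 50
    planted_term_size: int = 30
    frac_sig_single: float = 0.1  # genes significant in exactly one table, per table
    comparison_a: str = "treated_vs_control"
    comparison_b: str = "late_vs_early"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.n_sig_discordant < 0 or self.n_sig_concordant < 0:
            raise ValidationError("planted counts must be non-negative")
        if self.n_sig_discordant + self.n_sig_concordant > self.n_genes:
            raise ValidationError("planted significant genes exceed the gene universe")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.effect_size_sd < 0 or self.effect_size_mean <= 0:
            raise ValidationError("effect-size parameters invalid")
        if self.n_terms < 1 or self.planted_term_size < 1:
            raise ValidationError("need at least one term of positive size")
        if self.planted_term_size > self.n_genes:
            raise ValidationError("planted_term_size exceeds the gene universe")


def _padj(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Log-uniform adjusted p-values in (lo, hi)."""
    return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)


def generate_de_tables(spec: DETableSpec):
    """Generate ``(table_a, table_b, term_map, planted_truth)``.

    Tables are data frames with columns ``gene``, ``log2fc``, ``padj``,
    ``comparison``; ``term_map`` has columns ``gene``, ``term``;
    ``planted_truth`` records the planted gene identifiers and term.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_assign, rng_effect, rng_terms = (np.random.default_rng(s) for s in ss.spawn(3))

    width = max(5, len(str(spec.n_genes)))
    genes = np.array([f"g{i:0{width}d}" for i in range(spec.n_genes)])
    perm = rng_assign.permutation(spec.n_genes)
    n_d, n_c = spec.n_sig_discordant, spec.n_sig_concordant
    idx_disc = perm[:n_d]
    idx_conc = perm[n_d : n_d + n_c]
    idx_rest = perm[n_d + n_c :]

    lfc_a = rng_effect.normal(0.0, 0.3, size=spec.n_genes)
    lfc_b = rng_effect.normal(0.0, 0.3, size=spec.n_genes)
    padj_a = _padj(rng_effect, spec.n_genes, spec.alpha, 1.0 - 1e-9)
    padj_b = _padj(rng_effect, spec.n_genes, spec.alpha, 1.0 - 1e-9)

    def effect(n: int) -> np.ndarray:
        e = np.abs(rng_effect.normal(spec.effect_size_mean, spec.effect_size_sd, size=n))
        return np.clip(e, 0.25, None)

    sign_d = np.where(rng_effect.uniform(size=n_d) < 0.5, 1.0, -1.0)
    lfc_a[idx_disc] = sign_d * effect(n_d)
    lfc_b[idx_disc] = -sign_d * effect(n_d)
    padj_a[idx_disc] = _padj(rng_effect, n_d, 1e-8, spec.alpha * 0.5)
    padj_b[idx_disc] = _padj(rng_effect, n_d, 1e-8, spec.alpha * 0.5)

    sign_c = np.where(rng_effect.uniform(size=n_c) < 0.5, 1.0, -1.0)
    lfc_a[idx_conc] = sign_c * effect(n_c)
    lfc_b[idx_conc] = sign_c * effect(n_c)
    padj_a[idx_conc] = _padj(rng_effect, n_c, 1e-8, spec.alpha * 0.5)
    padj_b[idx_conc] = _padj(rng_effect, n_c, 1e-8, spec.alpha * 0.5)

    # remaining genes: significant in at most one table
    u = rng_effect.uniform(size=len(idx_rest))
    a_only = idx_rest[u < spec.frac_sig_single]
    b_only = idx_rest[(u >= spec.frac_sig_single) & (u < 2 * spec.frac_sig_single)]
    lfc_a[a_only] = np.where(rng_effect.uniform(size=len(a_only)) < 0.5, 1, -1) * effect(len(a_only))
    padj_a[a_only] = _padj(rng_effect, len(a_only), 1e-8, spec.alpha * 0.5)
    lfc_b[b_only] = np.where(rng_effect.uniform(size=len(b_only)) < 0.5, 1, -1) * effect(len(b_only))
    padj_b[b_only] = _padj(rng_effect, len(b_only), 1e-8, spec.alpha * 0.5)

    table_a = pd.DataFrame(
        {"gene": genes, "log2fc": lfc_a, "padj": padj_a, "comparison": spec.comparison_a}
    )
    table_b = pd.DataFrame(
        {"gene": genes, "log2fc": lfc_b, "padj": padj_b, "comparison": spec.comparison_b}
    )

    # annotation terms; term 0 is planted around the discordant set
    rows: list[tuple[str, str]] = []
    planted_term = "T000"
    planted_members = list(genes[idx_disc])
    n_fill = max(0, spec.planted_term_size - len(planted_members))
    if n_fill:
        fill = rng_terms.choice(genes[idx_rest], size=min(n_fill, len(idx_rest)), replace=False)
        planted_members.extend(fill)
    rows.extend((g, planted_term) for g in planted_members)
    for t in range(1, spec.n_terms):
        size = int(rng_terms.integers(10, 61))
        members = rng_terms.choice(genes, size=min(size, spec.n_genes), replace=False)
        rows.extend((g, f"T{t:03d}") for g in members)
    term_map = pd.DataFrame(rows, columns=["gene", "term"])

    planted_truth = {
        "discordant_up_in_a": sorted(genes[idx_disc[sign_d > 0]]),
        "discordant_down_in_a": sorted(genes[idx_disc[sign_d < 0]]),
        "concordant": sorted(genes[idx_conc]),
        "planted_term": planted_term,
        "alpha": spec.alpha,
    }
    return table_a, table_b, term_map, planted_truth
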