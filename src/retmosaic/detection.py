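"""Two-pass cone-nucleus detection in retinal flat mounts.

Cones are counted from the fluorescent nuclear signal in three stages:

1. **Bright pass** — Otsu's threshold (computed over the masked intensity
   histogram) binarizes the nuclear signal; 8-connected components above a
   minimum area become bright-nucleus components.  Components larger than a
   robust single-nucleus area estimate are merged nuclei and are
   *fragmented* into ``round(area / area_1)`` cones.
2. **Bright modelling** — each bright cone is modelled as an isotropic
   Gaussian spot: sub-pixel positions from the Laplacian-of-Gaussian (LoG)
   response (joint least-squares refinement inside merged components),
   amplitudes by fixed-point relaxation against the residual image.  The
   model is subtracted so dim nuclei hiding on the skirts of bright ones
   become visible.
3. **Dim pass** — a scale-normalized LoG blob detector at the nucleus scale
   runs on the residual image; local maxima above the background-response
   threshold and farther than the dedupe radius from every bright call are
   dim-cone calls.

``n_cones`` is the sum of the fragmentation counts plus the surviving dim
calls.  The pipeline is invariant to a positive linear gain of the image:
Otsu's threshold, the normalized LoG response, and every automatic
threshold scale with the image.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import DegenerateHistogramError, InsufficientDataError, ValidationError

__all__ = [
    "DetectionParams",
    "BrightComponent",
    "ConeCall",
    "ConeSet",
    "otsu_threshold",
    "detect_bright",
    "detect_dim",
    "fragment_count",
    "estimate_cone_area",
    "count_cones",
    "log_response",
]

_EIGHT = np.ones((3, 3), dtype=bool)
# full width at half maximum of a Gaussian spot, in sigmas
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))
_DEFAULT_SIGMA = 2.5


@dataclass
class DetectionParams:
    """Tunable knobs of the two-pass detector.

    ``None`` values are resolved from the data: the nucleus scale
    ``log_sigma_px`` from the single-nucleus area estimate together with the
    amplitude/threshold geometry of a thresholded Gaussian spot, the LoG
    response threshold from the background response distribution (mean +
    5 SD outside bright components) on the residual image, and the dedupe
    radius from the nucleus scale.  ``dim_floor_fraction`` ignores dim
    candidates whose implied amplitude is below that fraction of the typical
    bright amplitude — blobs that faint are background structure or model
    residue, not nuclei (planted dim nuclei run ~30% of bright).
    """

    min_component_area_px: int = 4
    log_sigma_px: float | None = None
    log_response_threshold: float | None = None
    dedupe_radius_px: float | None = None
    cone_area_estimate_px: float | Literal["auto"] = "auto"
    n_otsu_bins: int = 256
    dim_floor_fraction: float = 0.15
    max_joint_fit: int = 6  # largest merge size refined by joint fitting
    adjudicate_fragmentation: bool = True  # BIC-select k vs k+1 near the rounding boundary

    def validate(self) -> None:
        if self.min_component_area_px < 1:
            raise ValidationError("min_component_area_px must be >= 1")
        if self.log_sigma_px is not None and self.log_sigma_px <= 0:
            raise ValidationError("log_sigma_px must be positive")
        if self.log_response_threshold is not None and self.log_response_threshold <= 0:
            raise ValidationError("log_response_threshold must be positive")
        if self.dedupe_radius_px is not None and self.dedupe_radius_px < 1:
            raise ValidationError("dedupe_radius_px must be >= 1")
        if self.cone_area_estimate_px != "auto" and (
            not np.isreal(self.cone_area_estimate_px) or self.cone_area_estimate_px <= 0
        ):
            raise ValidationError("cone_area_estimate_px must be positive or 'auto'")
        if not 0.0 <= self.dim_floor_fraction < 1.0:
            raise ValidationError("dim_floor_fraction must lie in [0, 1)")


@dataclass
class BrightComponent:
    """One 8-connected component of the Otsu-binarized bright signal."""

    component_id: int
    area_px: int
    centroid: tuple[float, float]  # intensity-weighted (row, col)
    rows: np.ndarray
    cols: np.ndarray


@dataclass
class ConeCall:
    centroid: tuple[float, float]
    source: Literal["otsu", "log"]
    component_id: int | None = None


@dataclass
class ConeSet:
    """Detected cone calls plus the post-fragmentation total and provenance."""

    calls: list[ConeCall]
    n_cones: int
    params: DetectionParams
    otsu_threshold: float
    log_threshold: float | None
    log_sigma_px: float | None
    cone_area_estimate_px: float | None

    def centroids(self) -> np.ndarray:
        if not self.calls:
            return np.empty((0, 2))
        return np.array([c.centroid for c in self.calls], dtype=float)

    def to_dataframe(self):
        import pandas as pd

        cents = self.centroids()
        return pd.DataFrame(
            {
                "row": cents[:, 0] if len(cents) else np.empty(0),
                "col": cents[:, 1] if len(cents) else np.empty(0),
                "source": [c.source for c in self.calls],
                "component_id": [
                    c.component_id if c.component_id is not None else -1 for c in self.calls
                ],
            }
        )

    def summary(self) -> dict:
        return {
            "n_cones": int(self.n_cones),
            "n_calls": len(self.calls),
            "n_otsu_calls": sum(1 for c in self.calls if c.source == "otsu"),
            "n_log_calls": sum(1 for c in self.calls if c.source == "log"),
            "otsu_threshold": float(self.otsu_threshold),
            "log_threshold": None if self.log_threshold is None else float(self.log_threshold),
            "log_sigma_px": None if self.log_sigma_px is None else float(self.log_sigma_px),
            "cone_area_estimate_px": None
            if self.cone_area_estimate_px is None
            else float(self.cone_area_estimate_px),
            "params": {k: v for k, v in asdict(self.params).items()},
        }


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] < 2 or image.shape[1] < 2:
        raise ValidationError("image must be a 2-D grid of at least 2x2 pixels")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite values")
    return image


def _as_mask(image: np.ndarray, mask) -> np.ndarray:
    if mask is None:
        return np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValidationError("mask shape does not match image")
    return mask


def otsu_threshold(image: np.ndarray, mask: np.ndarray | None = None, nbins: int = 256) -> float:
    """Otsu's threshold over the masked intensity histogram.

    The histogram uses ``nbins`` equal-width bins over the masked intensity
    range; the returned threshold is the bin edge maximizing between-class
    variance, with ties broken toward the lowest candidate.  Foreground is
    ``image > threshold``.
    """
    image = _validate_image(image)
    vals = image[np.asarray(mask, dtype=bool)] if mask is not None else image.ravel()
    if vals.size < 2:
        raise DegenerateHistogramError("mask selects fewer than 2 pixels")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateHistogramError("constant image under mask; no threshold exists")
    hist, edges = np.histogram(vals, bins=nbins, range=(lo, hi))
    hist = hist.astype(float)
    total = hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(hist)
    w1 = total - w0
    s0 = np.cumsum(hist * centers)
    s_all = s0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = s0 / w0
        mu1 = (s_all - s0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf
    # candidate t puts bins [0..t] in background; argmax takes the lowest tie
    t = int(np.argmax(sigma_b[:-1]))
    return float(edges[t + 1])


def detect_bright(
    image: np.ndarray,
    retina_mask: np.ndarray | None,
    params: DetectionParams | None = None,
) -> list[BrightComponent]:
    """Bright pass: Otsu binarization + 8-connected components.

    Components smaller than ``min_component_area_px`` are discarded;
    centroids are intensity-weighted.
    """
    params = params or DetectionParams()
    params.validate()
    image = _validate_image(image)
    mask = _as_mask(image, retina_mask)
    thr = otsu_threshold(image, mask, nbins=params.n_otsu_bins)
    binary = (image > thr) & mask
    labels, n = ndi.label(binary, structure=_EIGHT)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= params.min_component_area_px) + 1
    comps: list[BrightComponent] = []
    if len(keep) == 0:
        return comps
    centroids = ndi.center_of_mass(image, labels, keep)
    objects = ndi.find_objects(labels)
    for new_id, (lab, cent) in enumerate(zip(keep, centroids), start=1):
        sl = objects[lab - 1]
        rr, cc = np.nonzero(labels[sl] == lab)
        comps.append(
            BrightComponent(
                component_id=new_id,
                area_px=int(areas[lab - 1]),
                centroid=(float(cent[0]), float(cent[1])),
                rows=rr + sl[0].start,
                cols=cc + sl[1].start,
            )
        )
    return comps


def fragment_count(component_area_px: float, cone_area_estimate_px: float) -> int:
    """Number of cones in a merged component: ``max(1, round(area / estimate))``.

    Rounding is half-to-even.
    """
    if component_area_px <= 0 or cone_area_estimate_px <= 0:
        raise ValidationError("areas must be positive")
    return max(1, int(np.round(component_area_px / cone_area_estimate_px)))


def estimate_cone_area(bright_components) -> float:
    """Robust single-nucleus area: median of areas within [0.5, 1.5] x median.

    Merged components (doublets and larger) fall outside the window, so the
    estimate is dominated by singletons.  Requires >= 5 components.
    """
    if len(bright_components) and isinstance(bright_components[0], BrightComponent):
        areas = np.array([c.area_px for c in bright_components], dtype=float)
    else:
        areas = np.asarray(bright_components, dtype=float)
    if areas.size < 5:
        raise InsufficientDataError(
            f"need >= 5 components to estimate cone area, got {areas.size}"
        )
    med = float(np.median(areas))
    sel = areas[(areas >= 0.5 * med) & (areas <= 1.5 * med)]
    return float(np.median(sel))


def log_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized negative Laplacian-of-Gaussian response.

    Positive peaks at the centres of bright blobs of scale ~``sigma``.
    """
    return -(sigma**2) * ndi.gaussian_laplace(np.asarray(image, dtype=float), sigma)


# ---------------------------------------------------------------------------
# bright-spot modelling
# ---------------------------------------------------------------------------


def _render_gaussians(
    shape: tuple[int, int], centers: np.ndarray, amps: np.ndarray, sigma: float
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    half = int(np.ceil(5 * sigma))
    for (r, c), a in zip(centers, amps):
        if a == 0:
            continue
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


def _quadratic_subpixel(resp: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """Refine a peak position by a separable quadratic fit on the 3x3 patch."""
    H, W = resp.shape
    if not (1 <= r < H - 1 and 1 <= c < W - 1):
        return float(r), float(c)
    z = resp[r - 1 : r + 2, c - 1 : c + 2]
    dr, drr = (z[2, 1] - z[0, 1]) / 2.0, z[2, 1] - 2 * z[1, 1] + z[0, 1]
    dc, dcc = (z[1, 2] - z[1, 0]) / 2.0, z[1, 2] - 2 * z[1, 1] + z[1, 0]
    off_r = -dr / drr if drr < 0 else 0.0
    off_c = -dc / dcc if dcc < 0 else 0.0
    return r + float(np.clip(off_r, -1, 1)), c + float(np.clip(off_c, -1, 1))


def _initial_positions(
    image: np.ndarray, resp0: np.ndarray, comp: BrightComponent, k: int, sigma: float
) -> list[tuple[float, float]]:
    """Seed ``k`` sub-centroids inside a component.

    Distinct LoG maxima (sub-pixel refined) are used when exactly ``k`` are
    resolvable; otherwise the pixel coordinates are k-means partitioned and
    intensity-weighted per-part centroids returned.
    """
    from skimage.feature import peak_local_max

    pm = np.zeros(image.shape, dtype=bool)
    pm[comp.rows, comp.cols] = True
    peaks = peak_local_max(
        np.where(pm, resp0, -np.inf),
        min_distance=max(1, int(round(sigma))),
        num_peaks=k,
        exclude_border=False,
    )
    if len(peaks) == k:
        return [_quadratic_subpixel(resp0, r, c) for r, c in peaks]
    from scipy.cluster.vq import kmeans2

    coords = np.column_stack([comp.rows, comp.cols]).astype(float)
    w = image[comp.rows, comp.cols]
    try:
        centers, lab = kmeans2(coords, k, minit="++", seed=0)
    except Exception:
        return [comp.centroid] * k
    out: list[tuple[float, float]] = []
    for j in range(k):
        sel = lab == j
        if sel.any():
            out.append(
                (
                    float(np.average(coords[sel, 0], weights=w[sel])),
                    float(np.average(coords[sel, 1], weights=w[sel])),
                )
            )
        else:
            out.append((float(centers[j, 0]), float(centers[j, 1])))
    return out


def _fit_spots(
    image: np.ndarray,
    model: np.ndarray,
    comp: BrightComponent,
    positions: np.ndarray,
    amps0: np.ndarray,
    own: np.ndarray | None,
    sigma: float,
    bg: float,
):
    """Jointly fit k Gaussian spots on the component's local patch.

    The contribution of all *other* spots (``model`` minus this
    component's own rendering ``own``) is held fixed.  Returns
    ``(positions, amplitudes, bic, ok)`` where the BIC uses the patch SSE
    with 3 parameters per spot.
    """
    from scipy.optimize import least_squares

    H, W = image.shape
    k = len(positions)
    pad = int(np.ceil(3 * sigma))
    r0, r1 = max(0, comp.rows.min() - pad), min(H, comp.rows.max() + pad + 1)
    c0, c1 = max(0, comp.cols.min() - pad), min(W, comp.cols.max() + pad + 1)
    if own is None:
        own_patch = _render_gaussians((r1 - r0, c1 - c0), positions - [r0, c0], amps0, sigma)
    else:
        own_patch = own[r0:r1, c0:c1]
    target = image[r0:r1, c0:c1] - (model[r0:r1, c0:c1] - own_patch) - bg
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    x0 = np.concatenate([np.asarray(positions, dtype=float).ravel(), amps0])

    def residual(x):
        m = np.zeros((r1 - r0, c1 - c0))
        for j in range(k):
            pr, pc, a = x[2 * j], x[2 * j + 1], x[2 * k + j]
            m += a * np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2 * sigma**2))
        return (m - target).ravel()

    try:
        sol = least_squares(residual, x0, max_nfev=40)
    except Exception:
        return positions, amps0, np.inf, False
    x = sol.x
    ok = all(
        0 <= x[2 * j] < H and 0 <= x[2 * j + 1] < W and x[2 * k + j] >= 0 for j in range(k)
    )
    n = target.size
    sse = float(np.sum(sol.fun**2))
    bic = n * np.log(max(sse, 1e-12) / n) + 3 * k * np.log(n)
    pts = np.array([[x[2 * j], x[2 * j + 1]] for j in range(k)])
    return pts, x[2 * k :], bic, ok


@dataclass
class _BrightModel:
    calls: np.ndarray          # (n, 2) sub-pixel bright-call positions
    amps: np.ndarray           # fitted spot amplitudes
    comp_ids: np.ndarray       # component id per call
    k_per_comp: list[int]      # fragmentation count per component
    sigma: float
    area_estimate: float | None
    background: float
    amplitude: float           # median singleton amplitude (gain reference)
    model_image: np.ndarray
    footprint: np.ndarray      # bool: pixels belonging to bright components


def _estimate_sigma(
    est: float | None, amp: float | None, thr: float, bg: float, params: DetectionParams
) -> float:
    """Nucleus Gaussian scale from the thresholded-spot geometry.

    A spot of amplitude A binarized at threshold t over background b covers
    pi * 2 sigma^2 * ln(A / (t - b)) pixels; inverting the single-nucleus
    area gives sigma.  Falls back to the area-only estimate (half-maximum
    geometry) and finally to 2.5 px.
    """
    if params.log_sigma_px is not None:
        return params.log_sigma_px
    if est is None:
        return _DEFAULT_SIGMA
    if amp is not None and thr - bg > 0 and amp > 1.05 * (thr - bg):
        return float(np.sqrt(est / (2.0 * np.pi * np.log(amp / (thr - bg)))))
    return float(np.sqrt(est / (2.0 * np.pi * np.log(2.0))))


def _build_bright_model(
    image: np.ndarray,
    mask: np.ndarray,
    components: Sequence[BrightComponent],
    params: DetectionParams,
    thr: float,
) -> _BrightModel:
    if params.cone_area_estimate_px != "auto":
        est: float | None = float(params.cone_area_estimate_px)
    else:
        try:
            est = estimate_cone_area(components)
        except InsufficientDataError:
            est = None

    bmask = np.zeros(image.shape, dtype=bool)
    if components:
        for c in components:
            bmask[c.rows, c.cols] = True
        dist_bright = ndi.distance_transform_edt(~bmask)
    else:
        dist_bright = np.full(image.shape, np.inf)
    far = mask & (dist_bright > _FWHM * _DEFAULT_SIGMA)
    bg = float(np.median(image[far])) if far.any() else float(np.median(image[mask]))

    amp: float | None = None
    if est is not None:
        singles = [c for c in components if 0.5 * est <= c.area_px <= 1.5 * est]
        if singles:
            ci = np.round([c.centroid for c in singles]).astype(int)
            amp = float(np.median(image[ci[:, 0], ci[:, 1]]) - bg)
    sigma = _estimate_sigma(est, amp, thr, bg, params)

    resp0 = log_response(image, sigma)
    shape_clip = np.array(image.shape) - 1
    comp_pts: list[np.ndarray] = []
    comp_amps: list[np.ndarray] = []
    k_per_comp: list[int] = []
    for comp in components:
        k = fragment_count(comp.area_px, est) if est else 1
        k_per_comp.append(k)
        if k == 1:
            vals = resp0[comp.rows, comp.cols]
            j = int(np.argmax(vals))
            pts = np.array([_quadratic_subpixel(resp0, comp.rows[j], comp.cols[j])])
        else:
            pts = np.asarray(_initial_positions(image, resp0, comp, k, sigma))
        ci = np.clip(np.round(pts).astype(int), 0, shape_clip)
        comp_pts.append(pts)
        comp_amps.append(np.clip(image[ci[:, 0], ci[:, 1]] - bg, 0.0, None))

    if not comp_pts or sum(k_per_comp) == 0:
        return _BrightModel(
            np.empty((0, 2)),
            np.empty(0),
            np.empty(0, dtype=int),
            k_per_comp,
            sigma,
            est,
            bg,
            amp if amp is not None else 0.0,
            np.zeros(image.shape),
            bmask,
        )

    model = _render_gaussians(image.shape, np.concatenate(comp_pts), np.concatenate(comp_amps), sigma)

    # joint sub-pixel refinement of merged components
    for i, (comp, k) in enumerate(zip(components, k_per_comp)):
        if 2 <= k <= params.max_joint_fit:
            pts, a, _, ok = _fit_spots(
                image, model, comp, comp_pts[i], comp_amps[i], None, sigma, bg
            )
            if ok:
                comp_pts[i], comp_amps[i] = pts, a

    amp_ref = amp if amp is not None else float(np.median(np.concatenate(comp_amps)))

    def adjudicate(model: np.ndarray, promoted: set[int]) -> None:
        """Promote k -> k+1 where the area ratio sits just below the rounding
        boundary and a (k+1)-spot model is decisively better (BIC margin,
        amplitude floor, spot-separation guards)."""
        for i, (comp, k) in enumerate(zip(components, k_per_comp)):
            ratio = comp.area_px / est
            frac = ratio - np.floor(ratio)
            if i in promoted or not (
                k < params.max_joint_fit and 0.15 <= frac < 0.5 and ratio >= 1.15
            ):
                continue
            pts_k, amps_k, bic_k, ok_k = _fit_spots(
                image, model, comp, comp_pts[i], comp_amps[i], None, sigma, bg
            )
            if ok_k:
                comp_pts[i], comp_amps[i] = pts_k, np.clip(amps_k, 0.0, None)
            # seed the extra spot at the largest unexplained residual pixel
            own = _render_gaussians(image.shape, comp_pts[i], comp_amps[i], sigma)
            res = image - (model - own) - own - bg
            j = int(np.argmax(res[comp.rows, comp.cols]))
            seed_pts = np.vstack([comp_pts[i], [comp.rows[j], comp.cols[j]]])
            seed_amps = np.append(
                comp_amps[i], max(float(res[comp.rows[j], comp.cols[j]]), 1.0)
            )
            pts_a, amps_a, bic_a, ok_a = _fit_spots(
                image, model, comp, seed_pts, seed_amps, own, sigma, bg
            )
            accept = ok_a and amps_a.min() >= 0.15 * amp_ref and bic_a + 20.0 < bic_k
            if accept:
                d = np.sqrt(((pts_a[:, None, :] - pts_a[None, :, :]) ** 2).sum(-1))
                np.fill_diagonal(d, np.inf)
                accept = d.min() >= 1.5
            if accept:
                comp_pts[i], comp_amps[i] = pts_a, np.clip(amps_a, 0.0, None)
                k_per_comp[i] = k + 1
                promoted.add(i)

    def consolidate() -> None:
        """Merge duplicate fits of one nucleus (< ~half a nucleus radius
        apart) and drop sub-floor spots."""
        merge_radius = 0.9
        for i, k in enumerate(k_per_comp):
            if k < 2:
                continue
            pts, a = comp_pts[i], comp_amps[i]
            while len(pts) > 1:
                d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
                np.fill_diagonal(d, np.inf)
                jmin = np.unravel_index(np.argmin(d), d.shape)
                if d[jmin] >= merge_radius:
                    break
                j1, j2 = jmin
                w = a[j1] + a[j2]
                merged = (pts[j1] * a[j1] + pts[j2] * a[j2]) / w if w > 0 else pts[j1]
                pts = np.vstack([np.delete(pts, [j1, j2], axis=0), merged])
                a = np.append(np.delete(a, [j1, j2]), w)
            low = a < 0.15 * amp_ref
            if low.any() and len(pts) - low.sum() >= 1:
                pts, a = pts[~low], a[~low]
            comp_pts[i], comp_amps[i] = pts, a
            k_per_comp[i] = len(pts)

    def relax(model: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fixed-point amplitude relaxation against the smoothed residual."""
        calls = np.concatenate(comp_pts)
        amps = np.concatenate(comp_amps)
        ci = np.clip(np.round(calls).astype(int), 0, shape_clip)
        for _ in range(2):
            model = _render_gaussians(image.shape, calls, amps, sigma)
            sm = ndi.gaussian_filter(image - model - bg, sigma)
            amps = np.clip(amps + 2.0 * sm[ci[:, 0], ci[:, 1]], 0.0, None)
        # write refined amplitudes back into the per-component arrays
        pos = 0
        for i in range(len(comp_amps)):
            comp_amps[i] = amps[pos : pos + len(comp_amps[i])]
            pos += len(comp_amps[i])
        return calls, amps, _render_gaussians(image.shape, calls, amps, sigma)

    if params.adjudicate_fragmentation and est:
        promoted: set[int] = set()
        for _ in range(2):
            adjudicate(model, promoted)
            consolidate()
            calls, amps, model = relax(model)
    else:
        calls, amps, model = relax(model)

    comp_ids = np.concatenate(
        [np.full(len(p), c.component_id, dtype=int) for p, c in zip(comp_pts, components)]
    )

    return _BrightModel(
        calls,
        amps,
        comp_ids,
        k_per_comp,
        sigma,
        est,
        bg,
        amp if amp is not None else (float(np.median(amps)) if len(amps) else 0.0),
        model,
        bmask,
    )


# ---------------------------------------------------------------------------
# dim pass
# ---------------------------------------------------------------------------


def _dim_pass(
    image: np.ndarray,
    mask: np.ndarray,
    bm: _BrightModel,
    params: DetectionParams,
) -> tuple[list[ConeCall], float | None]:
    """LoG blob detection on the bright-subtracted residual."""
    from skimage.feature import peak_local_max
    from scipy.spatial import cKDTree

    sigma = bm.sigma
    dedupe_r = (
        params.dedupe_radius_px if params.dedupe_radius_px is not None else max(1.0, sigma)
    )
    residual = image - bm.model_image
    resp = log_response(residual, sigma)

    thr = params.log_response_threshold
    if thr is None:
        if len(bm.calls):
            seeds = np.zeros(image.shape, dtype=bool)
            ci = np.clip(np.round(bm.calls).astype(int), 0, np.array(image.shape) - 1)
            seeds[ci[:, 0], ci[:, 1]] = True
            dist_calls = ndi.distance_transform_edt(~seeds)
        else:
            dist_calls = np.full(image.shape, np.inf)
        bgr = mask & (dist_calls > 2.0 * _FWHM * sigma)
        if not bgr.any():
            bgr = mask
        bg_vals = resp[bgr]
        thr = float(bg_vals.mean() + 5.0 * bg_vals.std())
        # a real nucleus is at least dim_floor_fraction of a bright one;
        # a matched-scale Gaussian spot of amplitude A peaks at ~A/2 in the
        # normalized LoG response
        floor = params.dim_floor_fraction * bm.amplitude * 0.5
        thr = max(thr, floor)
    if thr <= 0:
        thr = np.finfo(float).tiny

    # candidate dim peaks must lie outside the binarized bright footprint:
    # supra-threshold pixels already belong to components and are counted
    # through fragmentation, so a call there would double-count
    search = mask & ~bm.footprint
    peaks = peak_local_max(
        np.where(search, resp, -np.inf),
        min_distance=max(1, int(round(sigma)) - 1),
        threshold_abs=thr,
        exclude_border=False,
    ).astype(float)
    if len(peaks) and len(bm.calls):
        d, _ = cKDTree(bm.calls).query(peaks)
        peaks = peaks[d > dedupe_r]
    if len(peaks):
        # residues of the bright model scale with the local model intensity;
        # require the implied blob amplitude (2x the matched-scale response)
        # to stand clear of it
        pi = peaks.astype(int)
        local = bm.model_image[pi[:, 0], pi[:, 1]]
        rv = resp[pi[:, 0], pi[:, 1]]
        peaks = peaks[2.0 * rv >= 0.3 * local]
    return (
        [ConeCall(centroid=(float(r), float(c)), source="log") for r, c in peaks],
        float(thr),
    )


def detect_dim(
    image: np.ndarray,
    retina_mask: np.ndarray | None,
    bright_components: Sequence[BrightComponent],
    params: DetectionParams | None = None,
) -> list[ConeCall]:
    """Dim pass: LoG blob detection after bright-spot subtraction.

    Builds the bright-spot model from the supplied components, subtracts
    it, and returns LoG maxima of the residual above the response threshold,
    inside the retina mask, and farther than the dedupe radius from every
    bright call.
    """
    params = params or DetectionParams()
    params.validate()
    image = _validate_image(image)
    mask = _as_mask(image, retina_mask)
    try:
        thr = otsu_threshold(image, mask, nbins=params.n_otsu_bins)
    except DegenerateHistogramError:
        thr = float(image.max())
    bm = _build_bright_model(image, mask, list(bright_components), params, thr)
    calls, _ = _dim_pass(image, mask, bm, params)
    return calls


def count_cones(
    image: np.ndarray,
    retina_mask: np.ndarray | None = None,
    params: DetectionParams | None = None,
) -> ConeSet:
    """Run the full two-pass detector and return the cone calls and count.

    ``n_cones`` is the sum of fragmentation counts over bright components
    plus the number of dim (LoG) calls surviving deduplication.  A blank
    image (no signal above threshold, no LoG peaks) yields ``n_cones == 0``.
    """
    params = params or DetectionParams()
    params.validate()
    image = _validate_image(image)
    mask = _as_mask(image, retina_mask)

    try:
        thr = otsu_threshold(image, mask, nbins=params.n_otsu_bins)
    except DegenerateHistogramError:
        # constant image: nothing to detect
        return ConeSet([], 0, params, float("nan"), None, None, None)
    bright = detect_bright(image, mask, params)
    bm = _build_bright_model(image, mask, bright, params, thr)

    calls: list[ConeCall] = []
    for (r, c), cid in zip(bm.calls, bm.comp_ids):
        calls.append(ConeCall(centroid=(float(r), float(c)), source="otsu", component_id=int(cid)))
    n_cones = int(sum(bm.k_per_comp))

    dim_calls, log_thr = _dim_pass(image, mask, bm, params)
    calls.extend(dim_calls)
    n_cones += len(dim_calls)

    resolved = DetectionParams(
        min_component_area_px=params.min_component_area_px,
        log_sigma_px=bm.sigma,
        log_response_threshold=params.log_response_threshold,
        dedupe_radius_px=params.dedupe_radius_px
        if params.dedupe_radius_px is not None
        else max(1.0, bm.sigma),
        cone_area_estimate_px=params.cone_area_estimate_px,
        n_otsu_bins=params.n_otsu_bins,
        dim_floor_fraction=params.dim_floor_fraction,
        max_joint_fit=params.max_joint_fit,
    )
    return ConeSet(
        calls=calls,
        n_cones=n_cones,
        params=resolved,
        otsu_threshold=thr,
        log_threshold=log_thr,
        log_sigma_px=bm.sigma,
        cone_area_estimate_px=bm.area_estimate,
    )
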