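"""Spot detection and sub-pixel Gaussian localization.

Candidate regions are found by binarizing a normalized cross-correlation
map of each pixel's neighbourhood against a Gaussian template, then each
candidate is refined by least-squares fitting of

    I * exp(-((x - x0)^2 + (y - y0)^2) / (2*sigma^2)) + J

in a small window around the candidate peak.  Trajectories whose average
SNR or Gaussian width fall outside the configured gates are artifacts and
removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .core import Spot, TrackSet, Trajectory

__all__ = ["DetectionConfig", "detect_spots", "filter_artifacts"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Detection and artifact-filter parameters.

    corr_threshold : binarization threshold on the normalized
        cross-correlation with a Gaussian template of ``template_sigma``
        pixels.
    window : half-size (pixels) of the Gaussian-fit window.
    snr_min : trajectories with mean SNR <= snr_min are artifacts.
    sigma_range : trajectories with mean width outside (lo, hi) px are
        artifacts.
    snr_mode : "residual" divides the fitted amplitude by the SD of the
        fit residuals in the window; "background" divides by the SD of
        the image outside candidate regions.
    spot_snr_min : per-spot floor applied at detection time; fits whose
        amplitude does not even reach this many noise SDs are noise
        excursions of the correlation map, not candidates worth keeping
        (much weaker than the trajectory-level ``snr_min`` gate).
    """

    corr_threshold: float = 0.4
    template_sigma: float = 2.0
    window: int = 8
    snr_min: float = 5.0
    sigma_range: tuple[float, float] = (1.0, 4.0)
    snr_mode: str = "residual"
    spot_snr_min: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.corr_threshold < 1:
            raise ValueError("corr_threshold must be in (0, 1)")
        lo, hi = self.sigma_range
        if not lo < hi:
            raise ValueError("sigma_range must be (low, high) with low < high")
        if self.window < 2 * hi:
            raise ValueError("fit window must be >= 2 * sigma_range high")
        if self.snr_mode not in ("residual", "background"):
            raise ValueError("snr_mode must be 'residual' or 'background'")


def _gaussian_template(sigma: float) -> np.ndarray:
    half = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    return np.exp(-(xx**2 + yy**2) / (2 * sigma**2))


def _correlation_map(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Pixelwise normalized cross-correlation with a Gaussian template."""
    tpl = _gaussian_template(sigma)
    tpl = tpl - tpl.mean()
    n = tpl.size
    tpl_norm = np.sqrt((tpl**2).sum())
    img = frame.astype(float)
    box = np.ones_like(tpl)
    local_sum = signal.fftconvolve(img, box[::-1, ::-1], mode="same")
    local_sq = signal.fftconvolve(img**2, box[::-1, ::-1], mode="same")
    num = signal.fftconvolve(img, tpl[::-1, ::-1], mode="same")
    var = np.maximum(local_sq - local_sum**2 / n, 0.0)
    denom = np.sqrt(var) * tpl_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 1e-12, num / denom, 0.0)
    return ncc


def _fit_gaussian(window_img: np.ndarray, x_off: float, y_off: float):
    """Fit I*exp(-((x-x0)^2+(y-y0)^2)/2sigma^2)+J in pixel coordinates."""
    h, w = window_img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    j0 = float(np.percentile(window_img, 20))
    i0 = float(window_img.max() - j0)
    cy, cx = np.unravel_index(np.argmax(window_img), window_img.shape)

    def residual(p):
        amp, x0, y0, sigma, off = p
        model = amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2)) + off
        return (model - window_img).ravel()

    res = optimize.least_squares(
        residual,
        x0=[max(i0, 1e-3), float(cx), float(cy), 2.0, j0],
        bounds=(
            [0.0, -1.0, -1.0, 0.3, -np.inf],
            [np.inf, w + 1.0, h + 1.0, max(h, w), np.inf],
        ),
        max_nfev=400,
    )
    if not res.success:
        return None
    amp, x0, y0, sigma, off = res.x
    resid_sd = float(np.std(res.fun))
    return amp, x0 + x_off, y0 + y_off, sigma, off, resid_sd


def detect_spots(
    frame: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
    pixel_size: float = 0.1,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect and localize fluorescent spots in one image frame.

    Returns sub-pixel spots in µm; candidates whose Gaussian fit fails to
    converge are dropped (and logged), not fatal.  Duplicate fits landing
    within 1 px of a stronger one are merged, keeping the higher SNR.
    """
    from skimage import measure  # local import keeps module load light

    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("detect_spots expects a single 2D frame")
    ncc = _correlation_map(frame, config.template_sigma)
    # boundary zone of the template has invalid local statistics
    border = int(np.ceil(3 * config.template_sigma))
    ncc[:border, :] = 0.0
    ncc[-border:, :] = 0.0
    ncc[:, :border] = 0.0
    ncc[:, -border:] = 0.0
    binary = ncc > config.corr_threshold
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return []
    bg_sd = float(frame[~binary].std()) if (~binary).any() else float(frame.std())

    candidates = []
    for region in measure.regionprops(labels, intensity_image=frame):
        if region.area < 3:
            continue
        ry, rx = region.centroid_weighted if region.area else region.centroid
        candidates.append((int(round(ry)), int(round(rx))))

    half = config.window
    spots: list[Spot] = []
    for cy, cx in candidates:
        y0w = max(cy - half, 0)
        x0w = max(cx - half, 0)
        win = frame[y0w:cy + half + 1, x0w:cx + half + 1]
        if win.shape[0] < 5 or win.shape[1] < 5:
            continue
        fit = _fit_gaussian(win, x0w, y0w)
        if fit is None:
            log.debug("Gaussian fit failed for candidate at (%d, %d)", cx, cy)
            continue
        amp, x_px, y_px, sigma, off, resid_sd = fit
        if sigma < 0.5:  # sub-PSF width: a noise spike, not a particle
            continue
        noise = resid_sd if config.snr_mode == "residual" else bg_sd
        snr = amp / noise if noise > 0 else np.inf
        if snr < config.spot_snr_min:
            continue
        spots.append(
            Spot(
                frame=frame_index,
                x=float(x_px * pixel_size),
                y=float(y_px * pixel_size),
                intensity=float(amp),
                background=float(off),
                sigma=float(sigma),
                snr=float(snr),
            )
        )

    # merge duplicates within 1 px, keep the higher-SNR fit
    spots.sort(key=lambda s: -s.snr)
    kept: list[Spot] = []
    for s in spots:
        if all(
            np.hypot(s.x - o.x, s.y - o.y) > pixel_size for o in kept
        ):
            kept.append(s)
    kept.sort(key=lambda s: (s.x, s.y))
    return kept


def filter_artifacts(
    trackset_or_trajectories, config: DetectionConfig = DetectionConfig()
):
    """Remove artifact trajectories (noise-driven detections).

    Drops trajectories whose mean SNR is <= ``snr_min`` or whose mean
    Gaussian width lies outside ``sigma_range``; survivors are unchanged.
    Idempotent.
    """
    lo, hi = config.sigma_range

    def keep(t: Trajectory) -> bool:
        snr = np.mean(t.snr)
        sig = np.mean(t.sigma)
        return snr > config.snr_min and lo <= sig <= hi

    if isinstance(trackset_or_trajectories, TrackSet):
        kept = [t for t in trackset_or_trajectories if keep(t)]
        return trackset_or_trajectories.with_trajectories(kept)
    return [t for t in trackset_or_trajectories if keep(t)]
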