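"""Synthetic data generators with known ground truth.

Every analysis routine in this package is validated against data whose
answer is known by construction:

* :func:`make_vortex_field` builds velocity fields as superpositions of
  Gaussian-core vortices whose radius of peak tangential speed — the
  quantity the vortex length scale estimator recovers — is a parameter.
* :func:`make_nematic_movie` renders a polarized-fluorescence-style movie
  of a nematic texture (intensity follows the cos^2 law in the director
  angle) advected by a prescribed flow, so optical-flow estimates can be
  compared against the exact displacement field.
* :func:`make_toy_micro_curves` produces smooth, analytically controlled
  strain-rate / crosslinking curves for exercising the scaling layer
  without running stochastic simulations.

Defaults mirror the experimental imaging conditions the analysis chain is
designed for: 2 s frame interval and micrometer-scale pixels.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .flow import VelocityField
from .scaling import MicroCurve

__all__ = [
    "make_vortex_field",
    "make_vortex_movie",
    "make_correlated_field",
    "make_nematic_movie",
    "make_toy_micro_curves",
]


def _gaussian_vortex_uv(
    shape: tuple[int, int],
    center: tuple[float, float],
    core_radius: float,
    peak_speed: float,
    sense: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One Gaussian-core vortex: u_theta(r) = v0 (r/a) exp((1 - (r/a)^2)/2).

    The tangential speed peaks exactly at r = a with value v0; the induced
    vorticity is positive in the core and weakly negative outside, so the
    net circulation decays, keeping superpositions short-ranged.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    ra = r / core_radius
    mag = peak_speed * ra * np.exp((1.0 - ra**2) / 2.0)
    r_safe = np.where(r == 0, 1.0, r)
    # counterclockwise for sense=+1
    ux = sense * mag * (-dy / r_safe)
    uy = sense * mag * (dx / r_safe)
    return ux, uy


def make_vortex_field(
    shape: tuple[int, int] = (128, 128),
    n_vortices: int = 6,
    core_radius: float = 8.0,
    peak_speed: float = 1.0,
    pixel_size: float = 1.0,
    dt: float = 2.0,
    seed: int = 0,
    min_separation: float | None = None,
) -> VelocityField:
    """Superposition of Gaussian-core vortices with random centers and senses.

    ``core_radius`` (pixels) is the ground-truth radius of peak tangential
    speed of each vortex. Centers are rejected closer than
    ``min_separation`` (default ``3 * core_radius``) to each other so the
    individual peaks are not washed out; senses are random and balanced in
    expectation.
    """
    rng = np.random.default_rng(seed)
    if min_separation is None:
        min_separation = 3.0 * core_radius
    h, w = shape
    margin = core_radius
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_vortices:
        attempts += 1
        if attempts > 10000:
            raise ValueError("cannot place vortices: lower n_vortices or separation")
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all(np.hypot(c[0] - a, c[1] - b) >= min_separation for a, b in centers):
            centers.append(c)
    ux = np.zeros(shape)
    uy = np.zeros(shape)
    for c in centers:
        sense = 1 if rng.random() < 0.5 else -1
        a, b = _gaussian_vortex_uv(shape, c, core_radius, peak_speed, sense)
        ux += a
        uy += b
    return VelocityField(ux, uy, pixel_size=pixel_size, dt=dt)


def make_vortex_movie(
    n_frames: int = 10,
    shape: tuple[int, int] = (128, 128),
    n_vortices: int = 6,
    core_radius: float = 8.0,
    peak_speed: float = 1.0,
    pixel_size: float = 1.0,
    dt: float = 2.0,
    seed: int = 0,
) -> list[VelocityField]:
    """Independent vortex fields sharing one ground-truth core radius.

    Each frame draws fresh vortex centers/senses from a seed derived from
    ``seed``, mimicking a movie of an evolving vortex population.
    """
    base = np.random.default_rng(seed)
    seeds = base.integers(0, 2**31 - 1, size=n_frames)
    return [
        make_vortex_field(
            shape=shape,
            n_vortices=n_vortices,
            core_radius=core_radius,
            peak_speed=peak_speed,
            pixel_size=pixel_size,
            dt=dt,
            seed=int(s),
        )
        for s in seeds
    ]


def make_correlated_field(
    shape: tuple[int, int] = (256, 256),
    correlation_length: float = 10.0,
    rms_speed: float = 1.0,
    pixel_size: float = 1.0,
    dt: float = 2.0,
    seed: int = 0,
) -> VelocityField:
    """Gaussian random velocity field with exponential autocorrelation.

    Both components are independent stationary Gaussian fields with
    isotropic correlation ``C(r) = exp(-r / L)`` (``L = correlation_length``
    in pixels), synthesized spectrally: the 2-D power spectrum of the
    exponential correlation is ``S(k) = 2 pi L^2 / (1 + (kL)^2)^(3/2)``.
    By construction the normalized velocity autocorrelation crosses 1/e at
    exactly ``L`` (in physical units, ``L * pixel_size``), making this the
    oracle for the correlation-length estimator. ``L`` should be well below
    the domain size or the periodic synthesis biases the tail.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    ky = np.fft.fftfreq(h) * 2 * np.pi
    kx = np.fft.fftfreq(w) * 2 * np.pi
    k = np.hypot(*np.meshgrid(ky, kx, indexing="ij"))
    L = correlation_length
    power = 2 * np.pi * L**2 / (1 + (k * L) ** 2) ** 1.5
    comps = []
    for _ in range(2):
        noise = rng.standard_normal(shape)
        f = np.real(np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(power)))
        f -= f.mean()
        comps.append(f)
    scale = rms_speed / np.sqrt(np.mean(comps[0] ** 2 + comps[1] ** 2))
    return VelocityField(comps[0] * scale, comps[1] * scale, pixel_size=pixel_size, dt=dt)


def _smooth_random_field(shape, correlation_px, rng) -> np.ndarray:
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, correlation_px, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def make_nematic_movie(
    n_frames: int = 8,
    shape: tuple[int, int] = (128, 128),
    texture_scale: float = 6.0,
    polarizer_angle: float = 0.0,
    base_intensity: float = 200.0,
    contrast: float = 600.0,
    noise_sd: float = 5.0,
    flow: VelocityField | None = None,
    pixel_size: float = 1.0,
    dt: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, VelocityField]:
    """Polarized-microscopy-style movie of an advected nematic texture.

    A spatially smooth director angle field ``theta(x)`` (correlation length
    ``texture_scale`` pixels) is rendered as
    ``I = base + contrast * cos^2(theta - polarizer_angle)`` plus Gaussian
    camera noise, then advected frame to frame by the prescribed ``flow``
    (default: a single counterclockwise Gaussian-core vortex centered in the
    frame) using semi-Lagrangian backtracing with periodic wrapping.

    Returns the float movie (shape ``(n_frames, H, W)``, nonnegative) and
    the ground-truth velocity field in µm/s. Realism limits: the texture is
    frozen in the co-moving frame (no director dynamics, photobleaching, or
    defect creation), and the flow is steady.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if flow is None:
        ux, uy = _gaussian_vortex_uv(
            shape, (h / 2.0, w / 2.0), core_radius=min(h, w) / 4.0, peak_speed=1.5, sense=1
        )
        flow = VelocityField(ux, uy, pixel_size=pixel_size, dt=dt)
    theta = np.pi * (_smooth_random_field(shape, texture_scale, rng) % 1.0)
    clean = base_intensity + contrast * np.cos(theta - polarizer_angle) ** 2

    # displacement per frame in pixels
    dx = flow.ux * dt / pixel_size
    dy = flow.uy * dt / pixel_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    frames = np.empty((n_frames, h, w), dtype=float)
    img = clean
    for i in range(n_frames):
        frames[i] = np.maximum(img + noise_sd * rng.standard_normal(shape), 0.0)
        img = ndimage.map_coordinates(img, [yy - dy, xx - dx], order=3, mode="wrap")
    return frames, flow


def make_toy_micro_curves(
    atp_grid: np.ndarray | None = None,
    eps_max: float = 10.0,
    eps_half: float = 50.0,
    pcl_half: float = 50.0,
) -> MicroCurve:
    """Analytically controlled micro-curves for the scaling layer.

    Strain rate saturates, ``eps = eps_max * atp / (atp + eps_half)``, and
    crosslinking decays, ``Pcl = 1 / (1 + atp / pcl_half)`` — the qualitative
    shapes the stepping model produces, with every derivative available in
    closed form for oracle tests. Default grid: 16 log-spaced points on
    [1, 1000] µM.
    """
    if atp_grid is None:
        atp_grid = np.logspace(0, 3, 16)
    atp = np.asarray(atp_grid, dtype=float)
    eps = eps_max * atp / (atp + eps_half)
    pcl = 1.0 / (1.0 + atp / pcl_half)
    return MicroCurve(atp_grid=atp, epsilon=eps, p_crosslink=pcl)
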