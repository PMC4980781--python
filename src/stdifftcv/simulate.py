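"""Synthetic fluorescence time-lapse sequences with ground-truth masks.

The generator emulates fluorescently labeled nuclei migrating on a 2D
surface: bright, roughly elliptical blobs on a darker background, with
frame-to-frame motion, optional mitosis (one blob splitting into two
diverging daughters), cells entering/leaving the field of view (via
initial positions and velocities), and additive noise.

Blobs are smoothed flat-top ellipses — an ellipse indicator convolved
with a Gaussian point-spread function — so the half-maximum contour (the
ground-truth mask boundary) coincides with the steepest-gradient contour,
as it does for real nuclei of finite physical extent.  Ground-truth masks
are the noiseless per-cell supports above half the cell's amplitude.

When ``target_snr_db`` is set, the cell amplitudes are rescaled so that
the measured SNR (20 log10 of the cell-to-background mean ratio, using
the generated masks) hits the target; the additive noise is zero-mean and
does not move that ratio, so it remains a separate knob (it drives CNR).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_sequence import FrameSequence, ImageFrame, LabelMask

__all__ = ["CellSpec", "SimConfig", "generate_sequence", "standard_fixtures"]


@dataclass(frozen=True)
class CellSpec:
    """One simulated nucleus: initial center, velocity and shape."""

    center: tuple[float, float]  # (row, col) at frame 0
    velocity: tuple[float, float] = (0.0, 0.0)  # px/frame
    radii: tuple[float, float] = (10.0, 10.0)  # ellipse semi-axes (px)
    angle: float = 0.0  # orientation (rad)
    amplitude: float = 180.0  # intensity above background; negative = absorption


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic sequence.

    When ``cells`` is None, ``n_cells`` cells are drawn at random inside
    the frame with speeds equal to ``displacement``.  All randomness is
    driven by ``seed``; identical configs produce bit-identical output.
    """

    shape: tuple[int, int] = (128, 128)
    n_frames: int = 10
    n_cells: int = 2
    cells: tuple[CellSpec, ...] | None = None
    amplitude_mean: float = 180.0
    amplitude_sd: float = 10.0
    background: float = 20.0
    radius_range: tuple[float, float] = (8.0, 14.0)
    displacement: float = 2.0  # px/frame
    psf_sigma: float = 2.0
    mitosis_events: tuple[tuple[int, int], ...] = ()  # (frame, cell index)
    noise_model: str = "gaussian"
    noise_sd: float = 4.0
    target_snr_db: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_cells < 0:
            raise ValueError("counts must be nonnegative (and >= 1 frame)")
        if self.radius_range[0] < 2:
            raise ValueError("cell radii must be >= 2 px")
        if self.radius_range[0] > min(self.shape) or (
            self.cells and any(max(c.radii) > min(self.shape) for c in self.cells)
        ):
            raise ValueError("impossible geometry: radius exceeds frame")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _random_cells(cfg: SimConfig, rng: np.random.Generator) -> list[CellSpec]:
    cells = []
    h, w = cfg.shape
    margin = cfg.radius_range[1] + 2
    for _ in range(cfg.n_cells):
        center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        theta = rng.uniform(0, 2 * np.pi)
        vel = (cfg.displacement * np.sin(theta), cfg.displacement * np.cos(theta))
        radii = tuple(rng.uniform(*cfg.radius_range) for _ in range(2))
        amp = max(1.0, rng.normal(cfg.amplitude_mean, cfg.amplitude_sd))
        cells.append(CellSpec(center=center, velocity=vel, radii=radii,
                              angle=rng.uniform(0, np.pi), amplitude=amp))
    return cells


def _cells_at(cfg: SimConfig, base: list[CellSpec], t: int) -> list[CellSpec]:
    """Cell states at frame t, applying motion and mitosis events."""
    events = {cell_idx: frame for frame, cell_idx in cfg.mitosis_events}
    out: list[CellSpec] = []
    for idx, c in enumerate(base):
        cy = c.center[0] + c.velocity[0] * t
        cx = c.center[1] + c.velocity[1] * t
        t_div = events.get(idx)
        if t_div is not None and t >= t_div:
            # split into two diverging daughters along the minor axis
            dt_div = t - t_div
            sep = 0.7 * min(c.radii) + 1.2 * dt_div
            uy, ux = np.cos(c.angle), -np.sin(c.angle)
            daughter_radii = (c.radii[0] / 1.35, c.radii[1] / 1.35)
            for sgn in (+1.0, -1.0):
                out.append(CellSpec(
                    center=(cy + sgn * sep * uy, cx + sgn * sep * ux),
                    velocity=c.velocity, radii=daughter_radii,
                    angle=c.angle, amplitude=c.amplitude))
        else:
            out.append(CellSpec(center=(cy, cx), velocity=c.velocity,
                                radii=c.radii, angle=c.angle,
                                amplitude=c.amplitude))
    return out


def _render_cell(shape: tuple[int, int], c: CellSpec, psf_sigma: float
                 ) -> np.ndarray:
    """Noiseless contribution of one cell: smoothed flat-top ellipse."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - c.center[0]
    dx = xx - c.center[1]
    ca, sa = np.cos(c.angle), np.sin(c.angle)
    u = (ca * dy + sa * dx) / c.radii[0]
    v = (-sa * dy + ca * dx) / c.radii[1]
    inside = (u * u + v * v) <= 1.0
    if psf_sigma > 0:
        prof = gaussian_filter(inside.astype(np.float64), psf_sigma,
                               mode="constant")
    else:
        prof = inside.astype(np.float64)
    return c.amplitude * prof


def generate_sequence(cfg: SimConfig) -> tuple[FrameSequence, list[LabelMask]]:
    """Render a sequence and its ground-truth instance masks.

    Frames are ``background + sum(cell contributions) + noise`` clipped at
    zero; masks label each pixel with the cell whose noiseless
    contribution is largest among those exceeding half that cell's
    amplitude.
    """
    rng = np.random.default_rng(cfg.seed)
    base = list(cfg.cells) if cfg.cells is not None else _random_cells(cfg, rng)

    contribs: list[list[np.ndarray]] = []  # [t][cell]
    for t in range(cfg.n_frames):
        cells_t = _cells_at(cfg, base, t)
        contribs.append([_render_cell(cfg.shape, c, cfg.psf_sigma)
                         for c in cells_t])
    amplitudes = [
        [c.amplitude for c in _cells_at(cfg, base, t)]
        for t in range(cfg.n_frames)
    ]

    def masks_for(scale: float) -> list[np.ndarray]:
        out = []
        for t in range(cfg.n_frames):
            lab = np.zeros(cfg.shape, dtype=np.int64)
            if contribs[t]:
                stack = np.stack(contribs[t])
                # support = where a cell's (possibly negative) contribution
                # exceeds half its own amplitude in magnitude
                over = np.abs(stack) >= 0.5 * np.abs(
                    np.array(amplitudes[t]))[:, None, None]
                best = np.argmax(np.abs(stack), axis=0)
                any_over = over.any(axis=0)
                # pixel belongs to its strongest contributor if that one is over
                winner_over = over[best, np.arange(cfg.shape[0])[:, None],
                                   np.arange(cfg.shape[1])[None, :]]
                lab[any_over & winner_over] = best[any_over & winner_over] + 1
            out.append(lab)
        return out

    scale = 1.0
    gt = masks_for(scale)
    if cfg.target_snr_db is not None:
        r = 10.0 ** (cfg.target_snr_db / 20.0)
        cell_vals, bg_vals = [], []
        for t in range(cfg.n_frames):
            signal = np.sum(contribs[t], axis=0) if contribs[t] else np.zeros(cfg.shape)
            m = gt[t] > 0
            if m.any():
                cell_vals.append(signal[m])
                bg_vals.append(signal[~m])
        if not cell_vals:
            raise ValueError("target_snr_db requires at least one visible cell")
        a = float(np.concatenate(cell_vals).mean())
        b = float(np.concatenate(bg_vals).mean())
        denom = a - r * b
        if denom <= 0:
            raise ValueError("target SNR unreachable: background signal too strong")
        scale = cfg.background * (r - 1.0) / denom

    frames = []
    for t in range(cfg.n_frames):
        signal = np.sum(contribs[t], axis=0) if contribs[t] else np.zeros(cfg.shape)
        img = cfg.background + scale * signal
        if img.max() >= 2**16:
            raise ValueError("blob intensities exceed the 16-bit range")
        if cfg.noise_model == "gaussian":
            img = img + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
        else:
            img = rng.poisson(np.maximum(img, 0.0)).astype(np.float64)
        frames.append(ImageFrame(pixels=np.maximum(img, 0.0), frame_index=t))

    masks = [LabelMask(labels=lab, frame_index=t) for t, lab in enumerate(gt)]
    return FrameSequence(frames=tuple(frames)), masks


def standard_fixtures() -> dict[str, SimConfig]:
    """Named study conditions used throughout the test suite.

    * ``clean_two_blob`` — two well-separated bright nuclei, high SNR.
    * ``dim_mover`` — a single absorption cell: mean intensity below the
      background level, moving 4 px/frame.  Intensity-driven methods
      (bright-phase Chan-Vese, the plain T(I_ref) threshold) assign it to
      the background; only its spatio-temporal activity reveals it.
    * ``crowded`` — 12 touching nuclei.
    * ``mitosis`` — two nuclei, one dividing mid-sequence.
    """
    clean = SimConfig(
        n_cells=2,
        cells=(
            CellSpec(center=(42.0, 40.0), velocity=(1.5, 1.0),
                     radii=(12.0, 10.0), angle=0.4, amplitude=180.0),
            CellSpec(center=(85.0, 85.0), velocity=(-1.2, 1.2),
                     radii=(10.0, 13.0), angle=-0.7, amplitude=170.0),
        ),
        background=20.0, noise_sd=3.0, seed=42,
    )
    dim = SimConfig(
        n_cells=1,
        cells=(
            CellSpec(center=(88.0, 50.0), velocity=(-2.8, 2.8),
                     radii=(12.0, 11.0), angle=0.3, amplitude=-30.0),
        ),
        background=40.0, noise_sd=2.0, seed=7,
    )
    crowded = SimConfig(
        n_cells=12, cells=None, radius_range=(9.0, 12.0),
        displacement=1.5, amplitude_mean=170.0, amplitude_sd=15.0,
        background=20.0, noise_sd=4.0, seed=11,
    )
    mitosis = SimConfig(
        n_cells=2,
        cells=(
            CellSpec(center=(40.0, 64.0), velocity=(0.8, 0.3),
                     radii=(11.0, 10.0), angle=0.9, amplitude=180.0),
            CellSpec(center=(90.0, 64.0), velocity=(-0.5, 0.6),
                     radii=(10.0, 10.0), angle=0.0, amplitude=175.0),
        ),
        mitosis_events=((5, 0),),
        background=20.0, noise_sd=3.0, seed=5,
    )
    return {"clean_two_blob": clean, "dim_mover": dim,
            "crowded": crowded, "mitosis": mitosis}


def config_metadata(cfg: SimConfig) -> dict:
    """Full config (including seed) as a YAML-serializable dict."""
    d = dataclasses.asdict(cfg)
    return d
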