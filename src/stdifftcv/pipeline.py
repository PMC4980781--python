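"""End-to-end segmentation pipelines: CV, TCV, ST-Diff and ST-Diff-TCV.

Per frame t the ST-Diff path is:

    triplet {t-1, t, t+1}  ->  standardize  ->  spatio-temporal diffusion
    ->  Parzen edge map  ->  watershed  ->  classify/merge  ->  mask

ST-Diff-TCV additionally refines every frame with the Chan-Vese descent:
on frames with index = 0 (mod k) the level set is re-initialized from the
ST-Diff mask (catching mitoses and cells entering the view), on all other
frames it is carried over from the previous frame's converged field.

All level-set refinement runs on standardized frames, so the fixed energy
weights (expressed on the 0-255 scale) apply uniformly across sequences.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .delineation import ClassStats, RegionModel, classify_and_merge, watershed_labels
from .edge_density import edge_index_map
from .io_sequence import FrameSequence, ImageFrame, LabelMask
from .levelset import (
    CVWeights,
    checkerboard_phi,
    cv_evolve,
    mask_from_phi,
    phi_from_mask,
)
from .standardization import learn_model, standardize_window
from .stdiffusion import DiffusionParams, diffuse_triplet

__all__ = ["PipelineConfig", "StandardizationConfig", "ParzenConfig",
           "DelineationConfig", "segment", "segment_cv", "segment_tcv",
           "segment_stdiff", "segment_stdiff_tcv"]

log = logging.getLogger("stdifftcv")

METHODS = ("CV", "TCV", "STDIFF", "STDIFF_TCV")


@dataclass(frozen=True)
class StandardizationConfig:
    n_bins: int = 256
    iref_quantile: float = 0.8
    iref_value: float | None = None
    lmin_mode: str = "window"
    median_filter: int = 0  # optional pre-filter size, 0 = off


@dataclass(frozen=True)
class ParzenConfig:
    parzen_h: float = 8.0
    parzen_window: int = 7


@dataclass(frozen=True)
class DelineationConfig:
    use_likelihoods: bool = True
    estimate_background: bool = True  # intensity stats from the dominant basin
    area_mean: float = 350.0
    area_sd: float = 250.0
    intensity_mean: float = 170.0
    intensity_sd: float = 80.0
    bg_area_mean: float = 0.0
    bg_area_sd: float = 3000.0
    bg_intensity_mean: float = 25.0
    bg_intensity_sd: float = 10.0
    class_priors: tuple[float, float] = (0.9, 0.1)
    h_minima: float = 0.2


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of every stage plus the method selector."""

    method: str = "STDIFF_TCV"
    k_modulo: int = 5
    seed: int = 0
    reinit_on_handoff: bool = True
    init_mode: str = "checkerboard"
    standardization: StandardizationConfig = field(default_factory=StandardizationConfig)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    parzen: ParzenConfig = field(default_factory=ParzenConfig)
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    levelset: CVWeights = field(default_factory=CVWeights)
    reinit_every: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.k_modulo < 1:
            raise ValueError("k_modulo must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        nested = {
            "standardization": StandardizationConfig,
            "diffusion": DiffusionParams,
            "parzen": ParzenConfig,
            "delineation": DelineationConfig,
            "levelset": CVWeights,
        }
        for key, klass in nested.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if key == "delineation" and "class_priors" in sub:
                    sub["class_priors"] = tuple(sub["class_priors"])
                kwargs[key] = klass(**sub)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delineation"]["class_priors"] = list(d["delineation"]["class_priors"])
        return d


def _region_model(cfg: PipelineConfig, t_ref: float,
                  bg_stats: tuple[float, float] | None = None) -> RegionModel:
    """Assemble the region classifier; background intensity statistics may
    be estimated per frame from the dominant watershed basin."""
    d = cfg.delineation
    bg_mean, bg_sd = (bg_stats if bg_stats is not None
                      else (d.bg_intensity_mean, d.bg_intensity_sd))
    return RegionModel(
        T_ref=t_ref,
        use_likelihoods=d.use_likelihoods,
        cell=ClassStats(d.area_mean, d.area_sd, d.intensity_mean, d.intensity_sd),
        background=ClassStats(d.bg_area_mean, d.bg_area_sd, bg_mean, bg_sd),
        priors=tuple(d.class_priors),
    )


def _learn(sequence: FrameSequence, cfg: PipelineConfig):
    sc = cfg.standardization
    if sc.median_filter:
        from scipy.ndimage import median_filter

        sequence = FrameSequence(frames=tuple(
            ImageFrame(pixels=median_filter(f.pixels, size=sc.median_filter),
                       bit_depth=f.bit_depth, frame_index=f.frame_index)
            for f in sequence
        ))
    model = learn_model(sequence, i_ref=sc.iref_value, n_bins=sc.n_bins,
                        iref_quantile=sc.iref_quantile)
    return sequence, model


def _standardized_triplet(sequence, model, cfg, t):
    triplet = sequence.triplet(t)
    std, _ = standardize_window(triplet, model,
                                lmin_mode=cfg.standardization.lmin_mode)
    return std


def _stdiff_frame(sequence, model, cfg: PipelineConfig, t: int) -> LabelMask:
    """ST-Diff on a single frame: standardize, diffuse, edge map, delineate."""
    try:
        std = _standardized_triplet(sequence, model, cfg, t)
        diffused = diffuse_triplet(std, cfg.diffusion)
        emap = edge_index_map(diffused.center, h=cfg.parzen.parzen_h,
                              window=cfg.parzen.parzen_window)
        ws = watershed_labels(emap, h_min=cfg.delineation.h_minima)
        bg_stats = None
        if cfg.delineation.estimate_background:
            areas = np.bincount(ws.labels.ravel())[1:]
            dominant = int(np.argmax(areas)) + 1
            bg_px = std.center.pixels[ws.labels == dominant]
            bg_stats = (float(bg_px.mean()), max(float(bg_px.std()), 1e-3))
        mask = classify_and_merge(ws, std.center,
                                  _region_model(cfg, model.threshold_255,
                                                bg_stats))
        log.info("frame %d: %d watershed regions -> %d instances",
                 t, ws.n_regions, mask.n_instances)
        return LabelMask(labels=mask.labels, frame_index=t)
    except Exception as exc:  # annotate with frame index
        raise type(exc)(f"frame {t}: {exc}") from exc


def segment_stdiff(sequence: FrameSequence, cfg: PipelineConfig) -> list[LabelMask]:
    """Spatio-temporal diffusion segmentation of every frame."""
    sequence, model = _learn(sequence, cfg)
    return [_stdiff_frame(sequence, model, cfg, t) for t in range(len(sequence))]


def _standardized_center_frames(sequence, model, cfg) -> list[np.ndarray]:
    return [
        _standardized_triplet(sequence, model, cfg, t).center.pixels
        for t in range(len(sequence))
    ]


def _cold_phi(shape, cfg: PipelineConfig) -> np.ndarray:
    if cfg.init_mode != "checkerboard":
        raise ValueError(f"unknown init_mode {cfg.init_mode!r}")
    return checkerboard_phi(shape)


def _orient_bright(phi: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Flip phi if the {phi >= 0} phase is the dimmer one.

    The two-phase energy is symmetric under phase exchange (lambda1 =
    lambda2); for fluorescence the cell phase is the brighter, so the
    convention 'phi positive inside cells' is restored after descent.
    """
    fg = phi >= 0
    if fg.any() and (~fg).any() and img[fg].mean() < img[~fg].mean():
        return -phi
    return phi


def segment_cv(sequence: FrameSequence, cfg: PipelineConfig) -> list[LabelMask]:
    """Plain Chan-Vese: every frame evolved from the cold-start field."""
    sequence, model = _learn(sequence, cfg)
    frames = _standardized_center_frames(sequence, model, cfg)
    out = []
    for t, img in enumerate(frames):
        result = cv_evolve(_cold_phi(img.shape, cfg), img, cfg.levelset,
                           reinit_every=cfg.reinit_every)
        out.append(mask_from_phi(_orient_bright(result.phi, img), frame_index=t))
    return out


def segment_tcv(sequence: FrameSequence, cfg: PipelineConfig) -> list[LabelMask]:
    """Temporally linked Chan-Vese: frame n's field warm-starts frame n+1."""
    sequence, model = _learn(sequence, cfg)
    frames = _standardized_center_frames(sequence, model, cfg)
    phi = _cold_phi(frames[0].shape, cfg)
    out = []
    for t, img in enumerate(frames):
        result = cv_evolve(phi, img, cfg.levelset, reinit_every=cfg.reinit_every)
        oriented = _orient_bright(result.phi, img)
        out.append(mask_from_phi(oriented, frame_index=t))
        phi = _carry_phi(oriented, cfg)
    return out


def _carry_phi(phi: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Temporal handoff of the converged field to the next frame.

    The zero level set is carried over unchanged; with
    ``reinit_on_handoff`` the field around it is redistanced (clipped
    signed distance), which undoes the saturation of phi away from the
    contour so the warm-started descent can track moving cells.
    """
    if cfg.reinit_on_handoff:
        return phi_from_mask(phi >= 0, redistance=True)
    return phi


def segment_stdiff_tcv(sequence: FrameSequence, cfg: PipelineConfig) -> list[LabelMask]:
    """Joint method: ST-Diff initialization every k-th frame, CV refinement on all."""
    sequence, model = _learn(sequence, cfg)
    out = []
    phi: np.ndarray | None = None
    for t in range(len(sequence)):
        std = _standardized_triplet(sequence, model, cfg, t)
        img = std.center.pixels
        if phi is None or t % cfg.k_modulo == 0:
            stdiff_mask = _stdiff_frame(sequence, model, cfg, t)
            phi = phi_from_mask(stdiff_mask.binary,
                                redistance=cfg.reinit_on_handoff)
        # no brightness re-orientation here: the ST-Diff seed fixes which
        # phase is "cell", and that must survive for absorption (darker
        # than background) cells the motion path detected
        result = cv_evolve(phi, img, cfg.levelset, reinit_every=cfg.reinit_every)
        out.append(mask_from_phi(result.phi, frame_index=t))
        phi = _carry_phi(result.phi, cfg)
    return out


_DISPATCH = {
    "CV": segment_cv,
    "TCV": segment_tcv,
    "STDIFF": segment_stdiff,
    "STDIFF_TCV": segment_stdiff_tcv,
}


def segment(sequence: FrameSequence, cfg: PipelineConfig) -> list[LabelMask]:
    """Run the configured method over a sequence."""
    log.info("method=%s k_modulo=%d frames=%d shape=%s",
             cfg.method, cfg.k_modulo, len(sequence), sequence.shape)
    return _DISPATCH[cfg.method](sequence, cfg)
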