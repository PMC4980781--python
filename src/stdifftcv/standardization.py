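"""Frame intensity standardization by histogram transformation.

PDE stages are sensitive to intensity-range drift between frames.  This
module learns a global background reference from all frames of a sequence
(training) and then transforms each three-frame window so that its
background matches that reference (testing):

* training: pool all pixels, build the all-frames CDF ``F_AF`` and record
  the cumulative probability ``F_ref = F_AF(I_ref)`` at a reference
  background-threshold intensity ``I_ref``;
* testing: for each window, find ``I_test`` — the intensity whose
  three-frame CDF value is closest to ``F_ref`` — and apply two affine
  maps: ``T1`` anchors ``I_test`` onto ``I_ref`` (exactly so when
  ``L_Min = G_Min``), and ``T2`` rescales onto the fixed [0, 255] range
  using the global sequence extrema.

After standardization all windows share a common background order of
magnitude, so a single conductance / bandwidth / threshold setting works
across the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_sequence import FrameSequence, FrameTriplet, ImageFrame

__all__ = [
    "CDFTable",
    "StandardizationModel",
    "WindowTransform",
    "empirical_cdf",
    "learn_model",
    "find_I_test",
    "standardize_window",
]

DEFAULT_N_BINS = 256
OUTPUT_RANGE = 255.0


@dataclass(frozen=True)
class CDFTable:
    """Empirical CDF over equal-width bins.

    ``cdf[i]`` is the cumulative probability up to and including bin ``i``
    (right-closed bins).
    """

    bin_edges: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        cdf = np.asarray(self.cdf, dtype=np.float64)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "cdf", cdf)
        if len(edges) != len(cdf) + 1:
            raise ValueError("bin_edges must have len(cdf) + 1 entries")
        if np.any(np.diff(cdf) < -1e-12):
            raise ValueError("cdf must be nondecreasing")
        if cdf[0] < -1e-12 or abs(cdf[-1] - 1.0) > 1e-12:
            raise ValueError("cdf must start >= 0 and end at 1")

    @property
    def n_bins(self) -> int:
        return len(self.cdf)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def bin_of(self, value: float) -> int:
        """Index of the right-closed bin containing ``value`` (clipped)."""
        idx = int(np.searchsorted(self.bin_edges[1:-1], value, side="left"))
        return min(max(idx, 0), self.n_bins - 1)

    def at(self, value: float) -> float:
        """CDF evaluated at the bin containing ``value``."""
        return float(self.cdf[self.bin_of(value)])


def empirical_cdf(
    pixels: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    vrange: tuple[float, float] | None = None,
) -> CDFTable:
    """Histogram-based empirical CDF of a pixel collection.

    Out-of-range pixels are clipped into the end bins so total mass is 1.
    """
    px = np.asarray(pixels, dtype=np.float64).ravel()
    if px.size == 0:
        raise ValueError("empty pixel collection")
    if vrange is None:
        vrange = (float(px.min()), float(px.max()))
    lo, hi = map(float, vrange)
    if not hi > lo:
        raise ValueError(f"degenerate range [{lo}, {hi}]")
    counts, edges = np.histogram(np.clip(px, lo, hi), bins=n_bins, range=(lo, hi))
    cdf = np.cumsum(counts, dtype=np.float64) / px.size
    cdf[-1] = 1.0  # guard cumulative rounding
    return CDFTable(bin_edges=edges, cdf=cdf)


@dataclass(frozen=True)
class StandardizationModel:
    """Global reference learned in the training pass.

    Attributes
    ----------
    I_ref : float
        Reference background-threshold intensity (raw units).
    F_ref : float
        ``F_AF(I_ref)`` — cumulative probability at ``I_ref`` in the pooled
        all-frames histogram.
    G_Min, G_Max : float
        Global sequence intensity extrema.
    """

    I_ref: float
    F_ref: float
    G_Min: float
    G_Max: float
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if not self.G_Min <= self.I_ref <= self.G_Max:
            raise ValueError("I_ref outside the global intensity range")
        if not 0.0 <= self.F_ref <= 1.0:
            raise ValueError("F_ref must lie in [0, 1]")

    def t2(self, x):
        """Affine rescale of global range onto [0, 255] (no clipping here)."""
        return OUTPUT_RANGE * (np.asarray(x, dtype=np.float64) - self.G_Min) / (
            self.G_Max - self.G_Min
        )

    @property
    def threshold_255(self) -> float:
        """Standardized reference value ``T(I_ref)`` on the [0, 255] scale.

        The window transform maps the matched intensity ``I_test`` to
        ``T2(I_ref)`` (exactly so when ``L_Min = G_Min``), so this single
        window-independent value serves as the foreground/background
        threshold on every standardized frame.
        """
        return float(self.t2(self.I_ref))


def learn_model(
    sequence: FrameSequence,
    i_ref: float | None = None,
    n_bins: int = DEFAULT_N_BINS,
    iref_quantile: float = 0.8,
) -> StandardizationModel:
    """Training pass: pooled all-frames CDF and reference probability.

    ``i_ref`` may be given explicitly; otherwise it defaults to the bin
    center where the pooled CDF first reaches ``iref_quantile`` — a
    reproducible stand-in for a manually chosen background-tail threshold.
    """
    pooled = np.concatenate([f.pixels.ravel() for f in sequence.frames])
    table = empirical_cdf(pooled, n_bins=n_bins,
                          vrange=(sequence.global_min, sequence.global_max))
    if i_ref is None:
        idx = int(np.searchsorted(table.cdf, iref_quantile, side="left"))
        idx = min(idx, table.n_bins - 1)
        i_ref = float(table.bin_centers[idx])
    else:
        i_ref = float(i_ref)
        if not sequence.global_min <= i_ref <= sequence.global_max:
            raise ValueError(
                f"I_ref={i_ref} outside global range "
                f"[{sequence.global_min}, {sequence.global_max}]"
            )
    return StandardizationModel(
        I_ref=i_ref,
        F_ref=table.at(i_ref),
        G_Min=sequence.global_min,
        G_Max=sequence.global_max,
        n_bins=n_bins,
    )


def find_I_test(window_cdf: CDFTable, f_ref: float) -> float:
    """Intensity whose window CDF value is closest to ``F_ref``.

    Returns the bin-center intensity minimizing ``|F_3F(I) - F_ref|``;
    ties are broken toward the smallest intensity.  The CDF is evaluated
    at mid-bin mass (the cumulative value minus half the bin's own
    mass), so a point-mass bin — where the step crosses ``F_ref`` — is
    matched exactly rather than tied with every other bin.
    """
    if not 0.0 <= f_ref <= 1.0:
        raise ValueError("F_ref must lie in [0, 1]")
    cdf = window_cdf.cdf
    mass = np.diff(np.concatenate([[0.0], cdf]))
    diffs = np.abs((cdf - 0.5 * mass) - f_ref)
    return float(window_cdf.bin_centers[int(np.argmin(diffs))])


@dataclass(frozen=True)
class WindowTransform:
    """The affine pair ``T = T2 ∘ T1`` fitted to one three-frame window."""

    I_test: float
    L_Min: float
    I_ref: float
    G_Min: float
    G_Max: float

    @property
    def slope1(self) -> float:
        return (self.I_ref - self.G_Min) / (self.I_test - self.L_Min)

    def t1(self, x):
        return self.slope1 * (np.asarray(x, dtype=np.float64) - self.G_Min) + self.G_Min

    def t2(self, x):
        return OUTPUT_RANGE * (np.asarray(x, dtype=np.float64) - self.G_Min) / (
            self.G_Max - self.G_Min
        )

    def __call__(self, x) -> np.ndarray:
        return np.clip(self.t2(self.t1(x)), 0.0, OUTPUT_RANGE)


def standardize_window(
    triplet: FrameTriplet,
    model: StandardizationModel,
    lmin_mode: str = "window",
) -> tuple[FrameTriplet, WindowTransform]:
    """Testing pass: match one window's background to the global reference.

    Parameters
    ----------
    lmin_mode : {"window", "global"}
        ``L_Min`` is the minimum intensity over the current window
        (default) or the global minimum ``G_Min``.

    Returns the standardized triplet (float pixels clipped to [0, 255])
    and the fitted transform.
    """
    if lmin_mode not in ("window", "global"):
        raise ValueError(f"unknown lmin_mode {lmin_mode!r}")
    arrays = triplet.arrays()
    window_pixels = np.concatenate([a.ravel() for a in arrays])
    if window_pixels.max() - window_pixels.min() < 1e-12:
        raise ValueError("degenerate window contrast (constant window)")
    window_cdf = empirical_cdf(
        window_pixels, n_bins=model.n_bins, vrange=(model.G_Min, model.G_Max)
    )
    i_test = find_I_test(window_cdf, model.F_ref)
    l_min = float(window_pixels.min()) if lmin_mode == "window" else model.G_Min
    if abs(i_test - l_min) < 1e-12:
        raise ValueError("degenerate window contrast (I_test = L_Min)")
    tr = WindowTransform(
        I_test=i_test, L_Min=l_min,
        I_ref=model.I_ref, G_Min=model.G_Min, G_Max=model.G_Max,
    )
    out = [
        ImageFrame(pixels=tr(a), bit_depth=f.bit_depth, frame_index=f.frame_index)
        for a, f in zip(arrays, (triplet.prev, triplet.center, triplet.next))
    ]
    std = FrameTriplet(
        prev=out[0], center=out[1], next=out[2],
        padded_prev=triplet.padded_prev, padded_next=triplet.padded_next,
    )
    return std, tr
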