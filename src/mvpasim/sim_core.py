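"""Synthetic block-design BOLD data.

This module generates the data on which every analysis in the package
operates: an alternating two-class (A/B) block design, Gaussian "neural"
noise per voxel, optional class-specific activation patterns, convolution
with a hemodynamic response function (HRF), and removal of the initial
volumes of each block where the previous block's response still spills
over.

The pipeline stages are explicit in :class:`LabeledTimeseries.stage`:

``neural`` -> (optional signal injection) -> ``bold`` -> ``bold_trimmed``

A *null* dataset (signal strength ``s = 0``) has, by construction, no
relation between neural activity and class labels; any significant
classification on it is a false positive. That property is what the
higher-level modules exploit to measure type-I error rates of MVPA
significance procedures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import fftconvolve

__all__ = [
    "ConfigurationError",
    "CLASS_A",
    "CLASS_B",
    "ExperimentDesign",
    "HRFSpec",
    "SignalSpec",
    "LabeledTimeseries",
    "build_block_labels",
    "sample_null_neural",
    "make_class_patterns",
    "inject_signal",
    "hrf_kernel",
    "convolve_with_hrf",
    "trim_initial_volumes",
    "simulate_dataset",
    "as_rng",
    "as_seed_sequence",
]

CLASS_A = "A"
CLASS_B = "B"

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


class ConfigurationError(ValueError):
    """A parameter value violates a documented invariant."""


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce an int, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def as_seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    """Coerce an int (or sequence of ints) into a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        raise TypeError("need a reproducible seed, not a live Generator")
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Geometry of a two-class alternating block design.

    Defaults follow the canonical simulated experiment: TR = 2 s, 32 s
    blocks of 16 volumes each, and the first 8 volumes (16 s) of every
    block discarded so that the sluggish haemodynamic response of the
    previous block cannot leak into the retained data.

    Parameters
    ----------
    tr_seconds
        Repetition time: sampling interval between volumes, in seconds.
    block_seconds
        Duration of one block. Must equal ``volumes_per_block * tr_seconds``.
    volumes_per_block
        Number of volumes acquired per block.
    reps_per_class
        How many times each class's block is repeated (5, 10 or 15 give
        160, 320 or 480 acquired volumes).
    trim_volumes
        Volumes removed from the start of every block before analysis.
    """

    tr_seconds: float = 2.0
    block_seconds: float = 32.0
    volumes_per_block: int = 16
    reps_per_class: int = 5
    trim_volumes: int = 8

    #: Number of experimental conditions; the design is strictly two-class.
    n_classes: int = field(default=2, init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        if self.block_seconds <= 0:
            raise ConfigurationError("block_seconds must be positive")
        if self.volumes_per_block < 1:
            raise ConfigurationError("volumes_per_block must be >= 1")
        if self.reps_per_class < 1:
            raise ConfigurationError("reps_per_class must be >= 1")
        if not np.isclose(self.volumes_per_block * self.tr_seconds,
                          self.block_seconds):
            raise ConfigurationError(
                "block_seconds must equal volumes_per_block * tr_seconds "
                f"({self.volumes_per_block} * {self.tr_seconds} != "
                f"{self.block_seconds})")
        if not 0 <= self.trim_volumes < self.volumes_per_block:
            raise ConfigurationError(
                "trim_volumes must satisfy 0 <= trim_volumes < "
                "volumes_per_block")

    @property
    def n_blocks(self) -> int:
        return 2 * self.reps_per_class

    @property
    def total_volumes(self) -> int:
        """Acquired volumes, before trimming."""
        return self.n_blocks * self.volumes_per_block

    @property
    def retained_per_block(self) -> int:
        return self.volumes_per_block - self.trim_volumes

    @property
    def retained_volumes(self) -> int:
        """Volumes left after trimming every block."""
        return self.n_blocks * self.retained_per_block


@dataclass(frozen=True)
class HRFSpec:
    """Haemodynamic response function family and shape.

    The gamma-family impulse response is ``h(t) = (t/w)^a * exp(-(t/w)/b)``
    with shape parameters ``a`` and ``b`` (seconds) and a width scale ``w``
    that stretches the time axis: ``w < 1`` gives a short, fast HRF,
    ``w > 1`` a long, sluggish one. The raw gamma form spans many orders
    of magnitude (``t^8.6``), so the sampled kernel is normalised to unit
    peak; signal strength is then comparable across widths.

    The ``boxcar`` family is a rectangular kernel of duration ``16 * w``
    seconds, a deliberately crude alternative used to check that results
    do not hinge on the gamma shape.

    ``support_seconds`` truncates the sampled kernel; if None it is chosen
    automatically as the point where the normalised gamma kernel falls
    below 1e-4 of its peak, but never less than 32 s.
    """

    family: str = "gamma"
    a: float = 8.6
    b: float = 0.547
    width_scale: float = 1.0
    support_seconds: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("gamma", "boxcar"):
            raise ConfigurationError(
                f"hrf family must be 'gamma' or 'boxcar', got {self.family!r}")
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("HRF parameters a and b must be positive")
        if self.width_scale <= 0:
            raise ConfigurationError("width_scale must be positive")
        if self.support_seconds is not None and self.support_seconds <= 0:
            raise ConfigurationError("support_seconds must be positive")

    @property
    def peak_time_seconds(self) -> float:
        """Continuous-time location of the gamma kernel's maximum, w*a*b."""
        return self.width_scale * self.a * self.b


@dataclass(frozen=True)
class SignalSpec:
    """Class-related signal injected at the neural stage.

    ``s`` is the standard deviation of the per-voxel class activation
    pattern (0 = null data). ``spatial_sigma`` is the standard deviation,
    in voxel units, of a Gaussian filter applied to each pattern along the
    1-D voxel lattice to induce spatial signal correlations (0 = none).

    The filter is a plain (unit-peak) Gaussian kernel, so smoothing pools
    signal from neighbouring voxels and *raises* the per-voxel signal
    variance along with the correlation — a crude model of spatially
    unspecific vasculature spreading one voxel's activation to its
    neighbours. Set ``renormalize=True`` to rescale the smoothed pattern
    back to a per-voxel standard deviation of ``s``, isolating the pure
    correlation effect.
    """

    s: float = 0.0
    spatial_sigma: float = 0.0
    renormalize: bool = False

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ConfigurationError("signal strength s must be >= 0")
        if self.spatial_sigma < 0:
            raise ConfigurationError("spatial_sigma must be >= 0")

    @property
    def is_null(self) -> bool:
        return self.s == 0


@dataclass(frozen=True)
class LabeledTimeseries:
    """A time-points x voxels data matrix with labels and block structure.

    ``data[t, v]`` is the simulated activity of voxel ``v`` at volume
    ``t``; ``labels[t]`` is the class ('A' or 'B') of that volume and
    ``block_ids[t]`` the acquisition block it belongs to. ``stage``
    records where in the simulation pipeline the object sits.
    """

    data: np.ndarray
    labels: np.ndarray
    block_ids: np.ndarray
    stage: str
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels)
        block_ids = np.asarray(self.block_ids, dtype=int)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "block_ids", block_ids)
        if data.ndim != 2:
            raise ValueError("data must be a 2-D time x voxel matrix")
        n = data.shape[0]
        if labels.shape != (n,) or block_ids.shape != (n,):
            raise ValueError("labels and block_ids must match data length")
        if self.stage not in ("neural", "bold", "bold_trimmed"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if n and np.any(np.diff(block_ids) < 0):
            raise ValueError("block_ids must be non-decreasing in time")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def block_list(self) -> np.ndarray:
        """Distinct block ids, in temporal order."""
        return np.unique(self.block_ids)

    def labels_block_constant(self) -> bool:
        """True when every block carries a single class label."""
        for b in self.block_list():
            lab = self.labels[self.block_ids == b]
            if lab.size and np.any(lab != lab[0]):
                return False
        return True

    def with_labels(self, labels: np.ndarray) -> "LabeledTimeseries":
        """Copy with the per-time-point labels replaced (data shared)."""
        return replace(self, labels=np.asarray(labels))


# ---------------------------------------------------------------------------
# Label structure and neural stage
# ---------------------------------------------------------------------------

def build_block_labels(design: ExperimentDesign) -> tuple[np.ndarray, np.ndarray]:
    """Alternating ABAB... block labels for a design.

    Returns
    -------
    labels : ndarray of 'A'/'B', one per acquired volume
    block_ids : ndarray of int, 0 .. 2*reps_per_class - 1
    """
    per_pair = [CLASS_A] * design.volumes_per_block + \
               [CLASS_B] * design.volumes_per_block
    labels = np.array(per_pair * design.reps_per_class)
    block_ids = np.repeat(np.arange(design.n_blocks), design.volumes_per_block)
    return labels, block_ids


def sample_null_neural(design: ExperimentDesign, n_voxels: int,
                       seed: SeedLike) -> LabeledTimeseries:
    """Draw a null neural dataset: iid standard-normal activity.

    Every voxel at every volume is an independent N(0, 1) draw,
    irrespective of the class label — the simulated brain knows nothing
    about the experimental conditions.
    """
    if n_voxels < 1:
        raise ConfigurationError("n_voxels must be >= 1")
    labels, block_ids = build_block_labels(design)
    rng = as_rng(seed)
    data = rng.standard_normal((design.total_volumes, n_voxels))
    return LabeledTimeseries(data=data, labels=labels, block_ids=block_ids,
                             stage="neural", tr_seconds=design.tr_seconds)


def make_class_patterns(n_voxels: int, spec: SignalSpec,
                        seed: SeedLike) -> tuple[np.ndarray, np.ndarray]:
    """Draw one activation pattern per class.

    Each pattern is a vector of iid N(0, s^2) draws over voxels. When
    ``spatial_sigma > 0`` the pattern is convolved with a unit-peak
    Gaussian kernel on the 1-D voxel lattice (truncated at 4 sigma,
    circular boundary). The lag-d autocorrelation of the smoothed
    pattern is exp(-d^2 / (4 sigma^2)) regardless of kernel scaling;
    with ``renormalize=False`` (default) the amplitude is left as the
    convolution produces it, growing with sigma as neighbouring draws
    are pooled.
    """
    if n_voxels < 1:
        raise ConfigurationError("n_voxels must be >= 1")
    rng = as_rng(seed)
    kernel = None
    if spec.spatial_sigma > 0:
        radius = int(np.ceil(4.0 * spec.spatial_sigma))
        x = np.arange(-radius, radius + 1)
        kernel = np.exp(-x ** 2 / (2.0 * spec.spatial_sigma ** 2))
    patterns = []
    for _ in range(2):
        p = rng.normal(0.0, spec.s, size=n_voxels)
        if kernel is not None:
            p = convolve1d(p, kernel, mode="wrap")
            if spec.renormalize and spec.s > 0:
                # restore the per-voxel sd to s; white noise through the
                # kernel has sd s * sqrt(sum k^2)
                p = p / np.sqrt(np.sum(kernel ** 2))
        patterns.append(p)
    return patterns[0], patterns[1]


def inject_signal(neural: LabeledTimeseries,
                  patterns: tuple[np.ndarray, np.ndarray]) -> LabeledTimeseries:
    """Add the class-A pattern to every A volume and the B pattern to every B.

    The noise component is untouched; only a class-dependent constant
    offset per voxel is introduced, so the difference of class means
    converges to ``pattern_A - pattern_B``.
    """
    if neural.stage != "neural":
        raise ValueError("signal must be injected at the neural stage")
    pattern_a = np.asarray(patterns[0], dtype=float)
    pattern_b = np.asarray(patterns[1], dtype=float)
    if pattern_a.shape != (neural.n_voxels,) or \
            pattern_b.shape != (neural.n_voxels,):
        raise ValueError("pattern length must equal the number of voxels")
    data = neural.data.copy()
    data[neural.labels == CLASS_A] += pattern_a
    data[neural.labels == CLASS_B] += pattern_b
    return replace(neural, data=data)


# ---------------------------------------------------------------------------
# BOLD stage: HRF convolution and trimming
# ---------------------------------------------------------------------------

def _gamma_auto_support(spec: HRFSpec) -> float:
    # Where the normalised canonical-time kernel drops below 1e-4 of peak,
    # scaled by w; floor of 32 s keeps the support conservative.
    t = np.arange(0.0, 200.0, 0.005)
    with np.errstate(over="ignore"):
        h = t ** spec.a * np.exp(-t / spec.b)
    h = h / h.max()
    above = np.nonzero(h >= 1e-4)[0]
    cut = t[above[-1]] * spec.width_scale
    return max(32.0, float(cut))


def hrf_kernel(spec: HRFSpec, tr_seconds: float) -> np.ndarray:
    """Sample the HRF at multiples of TR on [0, support], unit peak.

    For the gamma family the kernel is ``(t/w)^a * exp(-(t/w)/b)``; the
    width scale stretches the time axis, moving the peak to ``w*a*b``
    seconds and widening the response proportionally. The sampled kernel
    is divided by its maximum so that its peak is exactly 1.
    """
    if tr_seconds <= 0:
        raise ConfigurationError("tr_seconds must be positive")
    support = spec.support_seconds
    if spec.family == "gamma":
        if support is None:
            support = _gamma_auto_support(spec)
        if support < spec.peak_time_seconds:
            raise ConfigurationError(
                f"support_seconds={support} is shorter than the kernel peak "
                f"time {spec.peak_time_seconds:.3f} s")
        t = np.arange(0.0, support + 1e-9, tr_seconds)
        tw = t / spec.width_scale
        kernel = tw ** spec.a * np.exp(-tw / spec.b)
    else:  # boxcar
        duration = 16.0 * spec.width_scale
        if support is None:
            support = duration
        t = np.arange(0.0, support + 1e-9, tr_seconds)
        kernel = (t < duration).astype(float)
        if not kernel.any():
            raise ConfigurationError(
                "boxcar support/TR too coarse: kernel has no nonzero sample")
    peak = kernel.max()
    if peak <= 0:
        raise ConfigurationError("sampled kernel has no positive sample")
    return kernel / peak


def convolve_with_hrf(neural: LabeledTimeseries,
                      spec: HRFSpec) -> LabeledTimeseries:
    """Causal per-voxel convolution with the sampled HRF kernel.

    Output is truncated to the input length; labels and block structure
    are unchanged. This is the step that introduces temporal
    autocorrelation into the data: after it, nearby volumes share signal
    even when the underlying neural draws were independent.
    """
    if neural.stage != "neural":
        raise ValueError("convolution applies to the neural stage")
    kernel = hrf_kernel(spec, neural.tr_seconds)
    full = fftconvolve(neural.data, kernel[:, None], mode="full", axes=0)
    data = full[: neural.n_timepoints]
    return replace(neural, data=data, stage="bold")


def trim_initial_volumes(bold: LabeledTimeseries,
                         design: ExperimentDesign) -> LabeledTimeseries:
    """Drop the first ``trim_volumes`` volumes of every block.

    Removes the transition period in which the previous block's
    haemodynamic response still dominates, so that retained volumes
    carry (mostly) their own block's response. Class balance is
    preserved because every block loses the same number of volumes.
    """
    if bold.stage != "bold":
        raise ValueError("trimming applies to the bold stage")
    if design.trim_volumes == 0:
        return replace(bold, stage="bold_trimmed")
    keep = np.ones(bold.n_timepoints, dtype=bool)
    # index of each volume within its block
    _, first = np.unique(bold.block_ids, return_index=True)
    counts = np.bincount(np.searchsorted(np.unique(bold.block_ids),
                                         bold.block_ids))
    within = np.arange(bold.n_timepoints) - np.repeat(first, counts)
    keep = within >= design.trim_volumes
    return LabeledTimeseries(data=bold.data[keep], labels=bold.labels[keep],
                             block_ids=bold.block_ids[keep],
                             stage="bold_trimmed", tr_seconds=bold.tr_seconds)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def simulate_dataset(design: ExperimentDesign, n_voxels: int,
                     hrf: HRFSpec = HRFSpec(),
                     signal: SignalSpec = SignalSpec(),
                     seed: SeedLike = 0) -> LabeledTimeseries:
    """Simulate one complete dataset, returning the trimmed BOLD stage.

    Runs: null neural draw -> (signal injection when ``signal.s > 0``)
    -> HRF convolution -> initial-volume trimming. Pure function of
    (parameters, seed): the seed is split deterministically into a noise
    seed and a pattern seed.
    """
    ss = as_seed_sequence(seed)
    noise_ss, pattern_ss = ss.spawn(2)
    neural = sample_null_neural(design, n_voxels, noise_ss)
    if not signal.is_null:
        patterns = make_class_patterns(n_voxels, signal, pattern_ss)
        neural = inject_signal(neural, patterns)
    bold = convolve_with_hrf(neural, hrf)
    return trim_initial_volumes(bold, design)
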