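"""Ground-truthed synthetic inputs for every pipeline stage.

Generators emulate the statistical structure of the study system:

* micrographs with electron-dense sheet-aggregates of known pixel area over a
  noisy background, plus a segmentation-style label mask;
* radially symmetric low-dose selected-area electron diffraction pairs — a
  target and a matched background exposure sharing a smooth scattering
  envelope and vitreous-ice rings at 3.71 Å and 2.15 Å, the target optionally
  carrying a broad mineral band spanning ~2.5–3.2 Å;
* Bernoulli marker-colocalization counts in a 2×2 location × marker design;
* per-condition aggregate-area samples from a log-normal distribution.

Every generator is a pure function of its spec (seed included): the same spec
yields bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import (DEFAULT_NYQUIST_Q, DEFAULT_PIXEL_SIZE_A, ContingencyTable,
                       DiffractionCalibration, DiffractionImage, LabelMask,
                       Micrograph)

__all__ = [
    "MicrographSpec", "DiffractionSpec", "AggregateTruth",
    "MicrographGroundTruth", "DiffractionGroundTruth",
    "gen_aggregate_micrograph", "gen_diffraction_pair",
    "gen_colocalization_counts", "gen_area_groups",
    "diffraction_radial_intensity", "DEFAULT_AREA_GROUPS",
    "PlacementError", "DEFAULT_MINERAL_BAND",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping aggregate placement is impossible."""


@dataclass(frozen=True)
class MicrographSpec:
    """Parameters of a synthetic aggregate micrograph.

    Aggregates are density-positive (bright on dark background); set
    ``invert`` on the measurement side for the opposite polarity. The label
    mask emulates a generous manual segmentation: each aggregate's footprint
    dilated by ``mask_margin_px`` pixels, so the masked region contains both
    aggregate and nearby background (set the margin to 0 for footprint-exact
    masks). Ground truth always records the footprint.
    """

    image_size: int = 512
    pixel_size: float = DEFAULT_PIXEL_SIZE_A  # Å/px
    n_aggregates: int = 5
    aggregate_intensity: float = 100.0
    aggregate_shape: str = "disk"  # disk | ellipse | fibrous
    background_noise_sd: float = 10.0
    poisson_noise: bool = False
    seed: int = 0
    radius_range: tuple[float, float] = (8.0, 20.0)
    mask_margin_px: int = 6
    background_level: float = 0.0
    stripe_period_px: float = 6.0    # fibrous texture wavelength
    stripe_amplitude: float = 0.25   # fraction of aggregate intensity

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.n_aggregates < 0:
            raise ValueError("n_aggregates must be non-negative")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")
        if self.aggregate_shape not in {"disk", "ellipse", "fibrous"}:
            raise ValueError(f"unknown aggregate_shape {self.aggregate_shape!r}")


@dataclass(frozen=True)
class AggregateTruth:
    label: int
    pixel_count: int
    area_nm2: float
    center: tuple[float, float]  # (row, col)
    shape: str


@dataclass(frozen=True)
class MicrographGroundTruth:
    aggregates: tuple[AggregateTruth, ...]
    pixel_size: float

    @property
    def pixel_counts(self) -> np.ndarray:
        return np.array([a.pixel_count for a in self.aggregates])

    @property
    def areas_nm2(self) -> np.ndarray:
        return np.array([a.area_nm2 for a in self.aggregates])


def _footprint(center, ax_r, ax_c, ii, jj):
    """Boolean footprint on index grids ii, jj: pixels whose center satisfies
    the (normalized) ellipse inequality ≤ 1."""
    return ((ii - center[0]) / ax_r) ** 2 + ((jj - center[1]) / ax_c) ** 2 <= 1.0


def gen_aggregate_micrograph(spec: MicrographSpec
                             ) -> tuple[Micrograph, LabelMask, MicrographGroundTruth]:
    """Generate a micrograph, its label mask and the ground truth.

    Aggregates are placed by rejection sampling so their dilated mask regions
    neither overlap nor touch the image border; if placement fails after many
    attempts a :class:`PlacementError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    ii, jj = np.indices((n, n), dtype=float)
    signal = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=np.int64)
    truths = []
    occupied = np.zeros((n, n), dtype=bool)
    max_attempts = 200 * max(1, spec.n_aggregates)
    attempts = 0
    label = 0
    while label < spec.n_aggregates:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {spec.n_aggregates} non-overlapping "
                f"aggregates in a {n}×{n} image after {attempts} attempts")
        attempts += 1
        r_lo, r_hi = spec.radius_range
        ax_r = rng.uniform(r_lo, r_hi)
        if spec.aggregate_shape == "disk":
            ax_c = ax_r
        else:  # ellipse and fibrous use an elongated footprint
            ax_c = ax_r * rng.uniform(1.2, 2.5)
        margin = spec.mask_margin_px
        lim = max(ax_r, ax_c) + margin + 1
        if 2 * lim >= n:
            continue
        center = (rng.uniform(lim, n - 1 - lim), rng.uniform(lim, n - 1 - lim))
        region = _footprint(center, ax_r + margin, ax_c + margin, ii, jj)
        if np.any(occupied & region):
            continue
        label += 1
        foot = _footprint(center, ax_r, ax_c, ii, jj)
        level = np.full(foot.sum(), spec.aggregate_intensity)
        if spec.aggregate_shape == "fibrous":
            phase = rng.uniform(0, 2 * np.pi)
            stripes = np.sin(2 * np.pi * ii[foot] / spec.stripe_period_px + phase)
            level = level * (1.0 + spec.stripe_amplitude * stripes)
        signal[foot] += level
        mask[region] = label
        occupied |= region
        count = int(foot.sum())
        truths.append(AggregateTruth(
            label=label, pixel_count=count,
            area_nm2=count * (spec.pixel_size / 10.0) ** 2,
            center=center, shape=spec.aggregate_shape))

    image = signal + spec.background_level
    if spec.background_noise_sd > 0:
        image = image + rng.normal(0.0, spec.background_noise_sd, size=(n, n))
    if spec.poisson_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    return (Micrograph(values=image, pixel_size=spec.pixel_size),
            LabelMask(labels=mask),
            MicrographGroundTruth(aggregates=tuple(truths),
                                  pixel_size=spec.pixel_size))


# ---------------------------------------------------------------------------
# diffraction

@dataclass(frozen=True)
class DiffractionSpec:
    """Parameters of a synthetic target/background diffraction pair.

    The noise-free pattern is radially symmetric about the true beam center
    (geometric center plus ``center_offset``):

        I(q) = envelope(q) · [1 + Σᵢ ampᵢ·G(q; 1/dᵢ, wᵢ) + band(q)]

    with ``envelope(q) = A·exp(−k·q)`` (A in expected counts/pixel, k in Å)
    and Gaussian rings G of unit peak height and width w (σ, Å⁻¹). Ring and
    band amplitudes are therefore dimensionless fractions of the local
    envelope. Ice rings sit at the vitreous-ice positions 3.71 Å and 2.15 Å;
    the optional mineral band (present in the target only) defaults to a
    broad Gaussian centered at 2.85 Å spanning roughly 2.5–3.2 Å.
    """

    image_size: int = 512
    nyquist_q: float = DEFAULT_NYQUIST_Q  # Å⁻¹ at the edge center
    center_offset: tuple[float, float] = (0.0, 0.0)  # (row, col) px
    background_decay: tuple[float, float] = (1000.0, 8.0)  # (A counts, k Å)
    ice_rings: tuple[tuple[float, float, float], ...] = (
        (3.71, 0.30, 0.015), (2.15, 0.15, 0.025))  # (d Å, amp, width Å⁻¹)
    mineral_band: tuple[float, float, float] | None = None  # (d Å, amp, width)
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.nyquist_q > 0:
            raise ValueError("nyquist_q must be positive")
        for d, amp, w in self.ice_rings:
            if d <= 0 or amp < 0 or w <= 0:
                raise ValueError("ice rings need d>0, amp>=0, width>0")
        if self.mineral_band is not None:
            d, amp, w = self.mineral_band
            if amp < 0 or w <= 0:
                raise ValueError("mineral band needs amp>=0, width>0")
            if d <= 1.0 / self.nyquist_q:
                raise ValueError(
                    f"mineral band at d={d} Å lies beyond the Nyquist "
                    f"frequency {self.nyquist_q} Å⁻¹ and is not representable")


#: Default mineral band: center 2.85 Å, 10% relative amplitude, width chosen
#: so the band spans roughly d = 2.5–3.2 Å.
DEFAULT_MINERAL_BAND = (2.85, 0.10, 0.035)


@dataclass(frozen=True)
class DiffractionGroundTruth:
    center: tuple[float, float]          # true beam center, absolute (row, col)
    center_offset: tuple[float, float]   # offset from the geometric center
    mineral_band: tuple[float, float, float] | None


def diffraction_radial_intensity(spec: DiffractionSpec, q,
                                 include_band: bool = True) -> np.ndarray:
    """Noise-free expected intensity at spatial frequency q (Å⁻¹)."""
    q = np.asarray(q, dtype=float)
    amp, rate = spec.background_decay
    envelope = amp * np.exp(-rate * q)
    rel = np.ones_like(q)
    for d, a, w in spec.ice_rings:
        rel = rel + a * np.exp(-((q - 1.0 / d) ** 2) / (2 * w ** 2))
    if include_band and spec.mineral_band is not None:
        d, a, w = spec.mineral_band
        rel = rel + a * np.exp(-((q - 1.0 / d) ** 2) / (2 * w ** 2))
    return envelope * rel


def gen_diffraction_pair(spec: DiffractionSpec
                         ) -> tuple[DiffractionImage, DiffractionImage,
                                    DiffractionGroundTruth]:
    """Generate a matched (target, background) diffraction exposure pair.

    Both images share the same envelope, ice rings and true beam center; only
    the target carries the mineral band. With Poisson noise enabled the two
    exposures receive independent draws (target first) from one seeded stream.
    """
    n = spec.image_size
    geo = (n - 1) / 2.0
    center = (geo + spec.center_offset[0], geo + spec.center_offset[1])
    ii, jj = np.indices((n, n), dtype=float)
    radius = np.hypot(ii - center[0], jj - center[1])
    q = radius * DiffractionCalibration(spec.nyquist_q, n).q_per_pixel

    target = diffraction_radial_intensity(spec, q, include_band=True)
    background = diffraction_radial_intensity(spec, q, include_band=False)
    if spec.poisson_noise:
        rng = np.random.default_rng(spec.seed)
        target = rng.poisson(np.clip(target, 0, None)).astype(float)
        background = rng.poisson(np.clip(background, 0, None)).astype(float)

    cal = DiffractionCalibration(nyquist_q=spec.nyquist_q, image_size=n)
    truth = DiffractionGroundTruth(center=center,
                                   center_offset=tuple(spec.center_offset),
                                   mineral_band=spec.mineral_band)
    return (DiffractionImage(values=target, calibration=cal),
            DiffractionImage(values=background, calibration=cal), truth)


# ---------------------------------------------------------------------------
# counts and area samples

def gen_colocalization_counts(n_intra: int, n_extra: int, p_intra: float,
                              p_extra: float, seed: int) -> ContingencyTable:
    """Binomial marker-positive counts per location group.

    Draw order is fixed (intracellular first, then extracellular) so a given
    seed always yields the same table.
    """
    if n_intra < 0 or n_extra < 0:
        raise ValueError("group sizes must be non-negative")
    if not (0 <= p_intra <= 1 and 0 <= p_extra <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    intra_pos = int(rng.binomial(n_intra, p_intra)) if n_intra else 0
    extra_pos = int(rng.binomial(n_extra, p_extra)) if n_extra else 0
    return ContingencyTable(a=extra_pos, b=n_extra - extra_pos,
                            c=intra_pos, d=n_intra - intra_pos)


#: Study-condition defaults for per-condition area samples: (condition label,
#: n aggregates measured, median area nm², log-space standard deviation).
DEFAULT_AREA_GROUPS: tuple[tuple[str, int, float, float], ...] = (
    ("1DIV_NB", 107, 99318.0, 0.8),
    ("1DIV_NB_FBS", 100, 88134.0, 0.8),
    ("1DIV_F12_FBS", 94, 66782.0, 0.8),
    ("20DIV_NB", 94, 56475.0, 0.8),
)


def gen_area_groups(group_specs=DEFAULT_AREA_GROUPS, seed: int = 0
                    ) -> pd.DataFrame:
    """Log-normal per-condition area samples.

    ``group_specs`` is a sequence of ``(label, n, median_nm2, log_sd)``;
    samples are ``median·exp(N(0, log_sd²))`` so the distribution median is
    exactly ``median_nm2``. Returns a DataFrame with columns ``condition``
    and ``area_nm2``, groups drawn in order from one seeded stream.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for label, n_samples, median, log_sd in group_specs:
        if n_samples < 1:
            raise ValueError(f"group {label!r}: n must be >= 1")
        if log_sd < 0:
            raise ValueError(f"group {label!r}: log_sd must be >= 0")
        areas = median * np.exp(rng.normal(0.0, log_sd, size=n_samples))
        frames.append(pd.DataFrame({"condition": label, "area_nm2": areas}))
    return pd.concat(frames, ignore_index=True)
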