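"""First-order (histogram) texture features over a 3D tumor mask.

Definitions: with ``N`` values ``x_i``, ``mu = sum(x_i)/N`` and population
central moments ``m_k = sum((x_i - mu)**k)/N``:

* ``mean_value = mu``
* ``variance   = m_2``
* ``skewness   = m_3 / m_2**1.5``
* ``kurtosis   = m_4 / m_2**2 - 3`` (EXCESS kurtosis: 0 for a Gaussian,
  negative for platykurtic, positive for leptokurtic histograms)
* ``entropy    = -sum(p_b * log2(p_b))`` over the configured histogram,
  in bits; empty bins contribute 0.

Zero-variance samples return 0 for skewness/kurtosis with
``degenerate_flag`` set, rather than NaN.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .imaging_io import CTVolume, GeometryError, Mask3D

__all__ = [
    "BinningConfig",
    "TexturePanel",
    "extract_voxels",
    "first_order_features",
    "texture_from_study",
]

RANGE_MODES = ("mask_min_max", "fixed_window", "mu_pm_3sigma")


@dataclasses.dataclass(frozen=True)
class BinningConfig:
    """Histogram dialect for the entropy feature (the moments ignore it)."""

    n_bins: int = 128
    range_mode: str = "mask_min_max"
    window: tuple[float, float] | None = None
    offset: float = 0.0  # optional constant added to mean_value (gray-level dialects)

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.range_mode not in RANGE_MODES:
            raise ValueError(f"range_mode must be one of {RANGE_MODES}, got {self.range_mode!r}")
        if self.range_mode == "fixed_window":
            if self.window is None or not self.window[0] < self.window[1]:
                raise ValueError("fixed_window mode requires window=(lo, hi) with lo < hi")


@dataclasses.dataclass(frozen=True)
class TexturePanel:
    mean_value: float
    variance: float
    skewness: float
    kurtosis: float
    entropy: float
    n_voxels: int
    n_bins: int
    degenerate_flag: bool

    FIELDS = ("mean_value", "variance", "skewness", "kurtosis", "entropy")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS], dtype=float)


def extract_voxels(vol: CTVolume, mask: Mask3D) -> np.ndarray:
    """HU values of all mask-interior voxels, in fixed scan order."""
    if not vol.same_geometry(mask):
        raise GeometryError(
            f"volume and mask geometry differ (shapes {vol.shape} vs {mask.shape}); "
            "masks are never resampled implicitly"
        )
    return np.asarray(vol.voxels, dtype=np.float64)[mask.voxels]


def _histogram_range(sample: np.ndarray, cfg: BinningConfig) -> tuple[float, float]:
    if cfg.range_mode == "fixed_window":
        assert cfg.window is not None
        return cfg.window
    if cfg.range_mode == "mu_pm_3sigma":
        mu = float(sample.mean())
        sd = float(sample.std())
        return mu - 3.0 * sd, mu + 3.0 * sd
    return float(sample.min()), float(sample.max())


def first_order_features(sample: np.ndarray, cfg: BinningConfig | None = None) -> TexturePanel:
    """Compute the five first-order features of an intensity sample."""
    cfg = cfg or BinningConfig()
    x = np.asarray(sample, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("cannot compute first-order features of an empty sample")
    n = x.size
    mu = float(x.mean())
    d = x - mu
    m2 = float(np.mean(d * d))
    degenerate = m2 == 0.0
    if degenerate:
        skew = 0.0
        kurt = 0.0
        entropy = 0.0
    else:
        m3 = float(np.mean(d**3))
        m4 = float(np.mean(d**4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
        lo, hi = _histogram_range(x, cfg)
        if lo == hi:
            entropy = 0.0
        else:
            counts, _ = np.histogram(x, bins=cfg.n_bins, range=(lo, hi))
            total = counts.sum()
            p = counts[counts > 0] / total
            entropy = float(-np.sum(p * np.log2(p))) if total > 0 else 0.0
            entropy = max(entropy, 0.0)
    return TexturePanel(
        mean_value=mu + cfg.offset,
        variance=m2,
        skewness=skew,
        kurtosis=kurt,
        entropy=entropy,
        n_voxels=n,
        n_bins=cfg.n_bins,
        degenerate_flag=degenerate,
    )


def texture_from_study(
    vol: CTVolume,
    mask: Mask3D,
    cfg: BinningConfig | None = None,
    allow_other_phase: bool = False,
) -> TexturePanel:
    """First-order features of the masked tumor on the pancreatic-phase volume."""
    if vol.phase != "pancreatic" and not allow_other_phase:
        raise ValueError(
            f"texture is defined on the pancreatic phase, got {vol.phase!r} "
            "(pass allow_other_phase=True to override)"
        )
    return first_order_features(extract_voxels(vol, mask), cfg)
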