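"""Apparent diffusion coefficient (ADC) mapping from two-b-value DWI.

With a mono-exponential signal model ``S(b) = S(0) * exp(-b * ADC)``, two
diffusion weightings ``b0 < b1`` give the per-pixel estimate

    ADC = -ln(S1 / S0) / (b1 - b0)        [mm^2/s]

Internally everything is carried in mm^2/s; report-facing code rescales to
the conventional 1e-3 mm^2/s unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: multiply an ADC in mm^2/s by this to obtain the conventional reporting
#: unit of 1e-3 mm^2/s (e.g. 0.000888 mm^2/s -> 0.888).
ADC_REPORT_SCALE = 1e3


@dataclass(frozen=True)
class BValuePair:
    """Two co-registered diffusion-weighted images and their b-values."""

    s0_image: np.ndarray
    s1_image: np.ndarray
    b0: float = 50.0
    b1: float = 1000.0

    def __post_init__(self) -> None:
        s0 = np.asarray(self.s0_image, dtype=float)
        s1 = np.asarray(self.s1_image, dtype=float)
        if s0.shape != s1.shape:
            raise ValueError(
                f"image shapes differ: {s0.shape} vs {s1.shape}"
            )
        if not (self.b1 > self.b0 > 0):
            raise ValueError(
                f"require b1 > b0 > 0, got b0={self.b0}, b1={self.b1}"
            )
        object.__setattr__(self, "s0_image", s0)
        object.__setattr__(self, "s1_image", s1)


@dataclass(frozen=True)
class ADCMap:
    """Per-pixel diffusion coefficient (mm^2/s) with a validity mask.

    ``valid_mask`` flags pixels where both intensities were positive and the
    raw estimate was nonnegative; elsewhere ``adc`` holds 0.
    """

    adc: np.ndarray
    valid_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.adc.shape != self.valid_mask.shape:
            raise ValueError("adc and valid_mask shapes differ")


def compute_adc(pair: BValuePair) -> ADCMap:
    """Pixel-by-pixel ADC from a :class:`BValuePair`.

    Pixels with a nonpositive intensity in either image are invalid.  A
    negative raw estimate (signal increase with b, possible under noise) is
    unphysical; it is clamped to 0 and excluded via ``valid_mask`` so it never
    enters region statistics.
    """
    s0, s1 = pair.s0_image, pair.s1_image
    positive = (s0 > 0) & (s1 > 0)
    adc = np.zeros_like(s0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = -np.log(np.where(positive, s1, 1.0) / np.where(positive, s0, 1.0))
    raw /= pair.b1 - pair.b0
    valid = positive & (raw >= 0)
    adc[valid] = raw[valid]
    return ADCMap(adc=adc, valid_mask=valid)
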