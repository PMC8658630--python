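"""Optical and fluidic geometry of the MMI optofluidic sensor.

A multimode-interference (MMI) waveguide of width ``W`` and refractive
index ``n`` crossing the liquid channel at distance ``L`` from its input
facet produces, by the self-imaging effect, an ``N``-spot excitation
pattern with

    N = n * W**2 / (lambda * L)

rounded to the nearest integer. Every particle transit through the
pattern therefore yields an ``N``-peak fluorescence cluster, which is
the signature the streaming detector looks for.

Lengths may be given in any single consistent unit (the relation is a
pure ratio). Helper constructors and the configuration loader use nm
for the wavelength and µm for the waveguide dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MMIDesign",
    "FlowGeometry",
    "mmi_spot_count",
    "mmi_length_for_spots",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def mmi_spot_count(wavelength: float, width: float, length_mmi: float,
                   index: float) -> int:
    """Number of self-imaged excitation spots of an MMI waveguide.

    Evaluates ``N = n * W**2 / (wavelength * L)`` and rounds to the
    nearest integer, ties rounding up. All lengths must share one unit.

    Parameters
    ----------
    wavelength : float
        Excitation wavelength (same length unit as the others).
    width : float
        MMI waveguide width ``W``.
    length_mmi : float
        Distance ``L`` from the MMI input facet to the liquid channel.
    index : float
        Refractive index ``n`` of the waveguide core.

    Returns
    -------
    int
        Spot count ``N >= 1``.
    """
    _require_positive(wavelength=wavelength, width=width,
                      length_mmi=length_mmi, index=index)
    n_exact = index * width ** 2 / (wavelength * length_mmi)
    return max(1, math.floor(n_exact + 0.5))


def mmi_length_for_spots(n_spots: int, wavelength: float, width: float,
                         index: float) -> float:
    """Intersection distance ``L`` that produces ``n_spots`` spots.

    Inverts the self-imaging relation: ``L = n * W**2 / (N * wavelength)``.
    Round-trips exactly through :func:`mmi_spot_count` before rounding.
    """
    if n_spots < 1:
        raise ValueError(f"n_spots must be >= 1, got {n_spots}")
    _require_positive(wavelength=wavelength, width=width, index=index)
    return index * width ** 2 / (n_spots * wavelength)


@dataclass(frozen=True)
class MMIDesign:
    """MMI excitation geometry; spot count must match the stored parameters.

    All lengths in µm except ``wavelength`` in nm (converted internally).
    """

    wavelength: float   # nm
    width: float        # µm
    length_mmi: float   # µm
    index: float
    n_spots: int

    def __post_init__(self) -> None:
        _require_positive(wavelength=self.wavelength, width=self.width,
                          length_mmi=self.length_mmi)
        if self.index < 1:
            raise ValueError("refractive index must be >= 1")
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        predicted = mmi_spot_count(self.wavelength * 1e-3, self.width,
                                   self.length_mmi, self.index)
        if predicted != self.n_spots:
            raise ValueError(
                f"n_spots={self.n_spots} inconsistent with geometry "
                f"(self-imaging relation gives {predicted})")

    @classmethod
    def from_spots(cls, n_spots: int, wavelength_nm: float, width_um: float,
                   index: float) -> "MMIDesign":
        length = mmi_length_for_spots(n_spots, wavelength_nm * 1e-3,
                                      width_um, index)
        return cls(wavelength_nm, width_um, length, index, n_spots)


@dataclass(frozen=True)
class FlowGeometry:
    """Liquid-channel cross-section and the transit length used for velocity.

    ``mmi_width`` doubles as the transit length in the velocity relation
    ``v = W / dt``: the cluster width is interpreted as the time the
    particle spends crossing the full MMI width.
    """

    channel_cross_section: float  # µm²
    mmi_width: float              # µm

    def __post_init__(self) -> None:
        _require_positive(channel_cross_section=self.channel_cross_section,
                          mmi_width=self.mmi_width)
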