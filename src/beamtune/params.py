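"""Beam-model parameter containers.

The commercial TPS model of an MLC-equipped photon beam exposes four tunable
parameters: the effective target spot sizes ``sigma_x`` (crossline, along leaf
travel) and ``sigma_y`` (inline), the dosimetric leaf gap (DLG) that widens
every MLC-defined aperture to account for transmission through rounded leaf
ends, and the inter-leaf/intra-leaf transmission fraction T.  These four
numbers are what the commissioning workflow in this package tunes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

Axis = Literal["crossline", "inline"]
Role = Literal["measured", "calculated"]

SIGMA_RANGE = (0.0, 5.0)
DLG_RANGE = (-1.0, 5.0)
TRANSMISSION_RANGE = (0.0, 0.1)


@dataclass(frozen=True)
class BeamModelParams:
    """The four tunable beam-model parameters.

    Parameters
    ----------
    sigma_x, sigma_y : float
        Effective target spot size (mm) in the crossline / inline direction:
        the width of the Gaussian smoothing applied to the primary-photon
        fluence at the isocenter plane.
    dlg : float
        Dosimetric leaf gap (mm).  Each MLC-defined field edge along the leaf
        travel direction is retracted by ``dlg / 2``.
    transmission : float
        MLC transmission fraction (closed-leaf / open-field dose ratio).
    """

    sigma_x: float = 0.0
    sigma_y: float = 0.0
    dlg: float = 0.0
    transmission: float = 0.0

    def __post_init__(self) -> None:
        if not SIGMA_RANGE[0] <= self.sigma_x <= SIGMA_RANGE[1]:
            raise ValueError(f"sigma_x={self.sigma_x} outside {SIGMA_RANGE} mm")
        if not SIGMA_RANGE[0] <= self.sigma_y <= SIGMA_RANGE[1]:
            raise ValueError(f"sigma_y={self.sigma_y} outside {SIGMA_RANGE} mm")
        if not DLG_RANGE[0] <= self.dlg <= DLG_RANGE[1]:
            raise ValueError(f"dlg={self.dlg} outside {DLG_RANGE} mm")
        if not TRANSMISSION_RANGE[0] <= self.transmission <= TRANSMISSION_RANGE[1]:
            raise ValueError(
                f"transmission={self.transmission} outside {TRANSMISSION_RANGE}"
            )

    def with_(self, **kwargs) -> "BeamModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth driving the synthetic linac + TPS stand-in.

    ``params`` is the physical truth of the "linac"; the tongue-and-groove
    loss coefficients may differ between the "linac" (``tg_loss_measured``)
    and the "TPS" (``tg_loss_calculated``) — sweeping-gap tests are blind to
    the TG effect, so this asymmetry is what makes the aOSG-optimal DLG
    exceed the sweeping-gap DLG.  ``detector_sigma`` is added in quadrature to
    the spot size for measured profiles (finite detector blurring);
    ``noise_cv`` applies multiplicative Gaussian noise to measured signals.
    """

    params: BeamModelParams = field(default_factory=BeamModelParams)
    tg_loss_measured: float = 0.0
    tg_loss_calculated: float = 0.0
    detector_sigma: float = 0.3
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tg_loss_measured", "tg_loss_calculated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.detector_sigma < 0:
            raise ValueError("detector_sigma must be >= 0")
        if not 0.0 <= self.noise_cv <= 0.02:
            raise ValueError(f"noise_cv={self.noise_cv} outside [0, 0.02]")

    def with_(self, **kwargs) -> "SyntheticTruth":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FieldGeometry:
    """Square MLC-defined field geometry for a profile or sweeping delivery.

    ``field_size`` is the side of the square field at isocenter (mm);
    ``sweep_length`` the total leaf travel of a sweeping delivery (mm);
    ``axis`` selects the scan direction (crossline profiles see the
    DLG-widened, sigma_x-blurred MLC edges; inline profiles the sigma_y
    edges).
    """

    field_size: float
    sweep_length: float = 100.0
    axis: Axis = "crossline"

    def __post_init__(self) -> None:
        if self.field_size <= 0:
            raise ValueError("field_size must be > 0")
        if self.sweep_length <= 0:
            raise ValueError("sweep_length must be > 0")
        if self.axis not in ("crossline", "inline"):
            raise ValueError(f"unknown axis {self.axis!r}")
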