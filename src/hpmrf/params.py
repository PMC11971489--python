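"""Parameter records for the two-pool pyruvate/lactate exchange model.

Three frozen dataclasses hold everything the forward model needs besides the
pulse sequence itself:

* :class:`KineticParams` — the kinetic/spectral constants of one fingerprint
  (conversion rate, relaxation times and chemical-shift frequencies of the
  pyruvate and lactate pools).
* :class:`BolusParams` — the gamma-variate bolus input of hyperpolarized
  pyruvate magnetization.
* :class:`FieldConditions` — scanner non-idealities: B1 scale error, bulk B0
  offset and the intravoxel off-resonance distribution (linewidth).

All records serialize to/from plain dicts and YAML so experiment
configurations can live in config files.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass

import yaml

__all__ = [
    "KineticParams",
    "BolusParams",
    "FieldConditions",
    "LACTATE_SHIFT_HZ",
]

#: Lactate-minus-pyruvate chemical shift at 3 T, Hz.
LACTATE_SHIFT_HZ = 392.0


class _Record:
    """Shared dict/YAML round-trip helpers for the parameter dataclasses."""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict):
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str | io.IOBase):
        if hasattr(text, "read"):
            text = text.read()
        return cls.from_dict(yaml.safe_load(text))

    def replace(self, **changes):
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class KineticParams(_Record):
    """Kinetic and spectral constants of a single fingerprint.

    Defaults are the fixed dictionary values used throughout: literature
    relaxation times for [1-13C]pyruvate and [1-13C]lactate at 3 T and the
    392 Hz lactate chemical shift, with pyruvate on resonance.

    Attributes
    ----------
    kPL : float
        Apparent first-order pyruvate-to-lactate conversion rate, 1/s.
    T1_pyr, T1_lac : float
        Longitudinal relaxation times, s.
    T2_pyr, T2_lac : float
        Transverse relaxation times, s.
    omega_pyr, omega_lac : float
        Chemical-shift frequencies, Hz, in the common rotating frame.
    """

    kPL: float = 0.0
    T1_pyr: float = 30.0
    T1_lac: float = 25.0
    T2_pyr: float = 0.5
    T2_lac: float = 1.0
    omega_pyr: float = 0.0
    omega_lac: float = LACTATE_SHIFT_HZ

    def __post_init__(self):
        if self.kPL < 0:
            raise ValueError(f"kPL must be >= 0, got {self.kPL}")
        for name in ("T1_pyr", "T1_lac", "T2_pyr", "T2_lac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class BolusParams(_Record):
    """Gamma-variate bolus input of pyruvate longitudinal magnetization.

    The input rate is ``u(t) ∝ (t - t_arrival)**(shape_alpha - 1) *
    exp(-(t - t_arrival)/beta)`` with the gamma scale ``beta`` chosen so that
    99% of the total input arrives within ``t_duration`` of arrival.

    ``total_input`` sets the overall amplitude and is the unit in which all
    signals are expressed (the relaxation-free total bolus signal); Monte
    Carlo noise standard deviations are defined on this scale.

    Attributes
    ----------
    t_arrival : float
        Bolus arrival time, s, relative to acquisition start (negative means
        the bolus begins before imaging; the default -4 s reflects the
        calibration delay between bolus detection and the first image).
    t_duration : float
        Bolus duration, s: the window containing 99% of the input.
    shape_alpha : float
        Gamma shape parameter (dimensionless).
    total_input : float
        Total delivered magnetization (dimensionless normalization scale).
    """

    t_arrival: float = -4.0
    t_duration: float = 12.0
    shape_alpha: float = 2.0
    total_input: float = 1.0

    def __post_init__(self):
        if self.t_duration <= 0:
            raise ValueError(f"t_duration must be > 0, got {self.t_duration}")
        if self.shape_alpha <= 0:
            raise ValueError(f"shape_alpha must be > 0, got {self.shape_alpha}")


@dataclass(frozen=True)
class FieldConditions(_Record):
    """Field non-idealities applied on top of the kinetic parameters.

    Attributes
    ----------
    b1_scale : float
        Multiplier on every applied flip angle (B1 calibration error).
    b0_offset : float
        Bulk frequency error, Hz, added to both metabolite frequencies.
    linewidth_fwhm : float
        FWHM, Hz, of the intravoxel off-resonance distribution.
    n_isochromats : int
        Number of isochromats sampling that distribution; must be odd so the
        zero-offset isochromat exists.
    linewidth_shape : str
        ``"lorentzian"`` (default) or ``"gaussian"`` intravoxel distribution.
    """

    b1_scale: float = 1.0
    b0_offset: float = 0.0
    linewidth_fwhm: float = 5.0
    n_isochromats: int = 101
    linewidth_shape: str = "lorentzian"

    def __post_init__(self):
        if self.b1_scale <= 0:
            raise ValueError(f"b1_scale must be > 0, got {self.b1_scale}")
        if self.linewidth_fwhm < 0:
            raise ValueError("linewidth_fwhm must be >= 0")
        if self.n_isochromats < 1 or self.n_isochromats % 2 == 0:
            raise ValueError("n_isochromats must be >= 1 and odd")
        if self.linewidth_shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown linewidth_shape {self.linewidth_shape!r}")
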