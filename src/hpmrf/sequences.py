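"""Pulse sequence schedules for interleaved metabolite-specific imaging.

Three experiment designs are provided, all acquiring pyruvate and lactate
volumes in alternating acquisition blocks:

* ``mrf_sigmoid`` — pyruvate 3D bSSFP with a sigmoid (logistic) variable flip
  angle ramping from 5 to 80 degrees over the acquisition, lactate 3D bSSFP
  at a constant 60 degrees.
* ``mrf_constant`` — identical but with a constant 30 degree pyruvate flip.
* ``hybridgre`` — pyruvate 2D spoiled gradient echo at 10 degrees, lactate
  3D bSSFP at 60 degrees (the prior-generation hybrid design).

Every bSSFP block consists of a nonlinear (sin^2) catalyzation ramp into the
steady state, alternating-phase imaging excitations at fixed TR, a mirrored
de-catalyzation ramp back out, and a final half-angle tip-back pulse that
returns magnetization to the longitudinal axis between blocks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "SigmoidParams",
    "AcquisitionBlock",
    "SequenceSchedule",
    "sigmoid_flip",
    "catalyzation_ramp",
    "build_schedule",
    "DESIGN_IDS",
]

DESIGN_IDS = ("hybridgre", "mrf_constant", "mrf_sigmoid")

PYRUVATE = "pyruvate"
LACTATE = "lactate"


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the logistic flip-angle schedule.

    alpha(t) = alpha_min + (alpha_max - alpha_min) / (1 + exp(t_mid - t))

    with ``t`` the elapsed time in seconds since acquisition start. Defaults:
    5 degrees initial, 80 degrees maximum, midpoint at 20 s.
    """

    alpha_min: float = 5.0
    alpha_max: float = 80.0
    t_mid: float = 20.0

    def __post_init__(self):
        if not (self.alpha_max > self.alpha_min >= 0):
            raise ValueError("require alpha_max > alpha_min >= 0")


def sigmoid_flip(t, p: SigmoidParams = SigmoidParams()):
    """Sigmoid flip angle (degrees) at elapsed time ``t`` (seconds).

    Strictly increasing in ``t``; approaches ``alpha_min`` for t << t_mid and
    ``alpha_max`` for t >> t_mid.
    """
    t = np.asarray(t, dtype=float)
    out = p.alpha_min + (p.alpha_max - p.alpha_min) / (1.0 + np.exp(p.t_mid - t))
    return out if out.ndim else float(out)


def catalyzation_ramp(alpha_edge: float, n_cat: int, direction: str = "up") -> np.ndarray:
    """Nonlinear ramp of preparation flip angles into/out of the bSSFP steady state.

    The profile is ``alpha_edge * sin^2(i*pi/(2*n_cat))`` for i = 1..n_cat,
    a monotone ramp from near zero up to the edge angle. ``direction="down"``
    returns the mirrored (descending) sequence.
    """
    if n_cat < 0:
        raise ValueError("n_cat must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    i = np.arange(1, n_cat + 1, dtype=float)
    ramp = alpha_edge * np.sin(i * np.pi / (2 * n_cat)) ** 2 if n_cat else np.empty(0)
    return ramp if direction == "up" else ramp[::-1].copy()


@dataclass(frozen=True)
class AcquisitionBlock:
    """One metabolite-specific acquisition block.

    ``flips``/``phases`` list every RF excitation in the block, in order:
    catalyzation ramp, imaging excitations, de-catalyzation ramp and (for
    balanced blocks) a final tip-back pulse. ``sample_index`` marks the
    excitation whose echo is recorded as the block's complex sample (the
    center-of-k-space excitation under linear encode ordering).
    """

    start_time: float
    target: str
    mode: str  # "balanced" | "spoiled"
    tr: float
    n_exc: int  # total number of excitations = len(flips)
    flips: tuple  # degrees, per excitation
    phases: tuple  # degrees, per excitation
    sample_index: int
    n_cat: int = 0
    t_readout: float | None = None  # spoiled blocks: echo at t_readout/2
    n_slices: int = 1  # spoiled 2D multi-slice blocks: slices per volume

    def __post_init__(self):
        if len(self.flips) != len(self.phases):
            raise ValueError("flips and phases must have equal length")
        if self.n_exc != len(self.flips):
            raise ValueError("n_exc must equal len(flips)")
        if not (0 <= self.sample_index < len(self.flips)):
            raise ValueError("sample_index out of range")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.target not in (PYRUVATE, LACTATE):
            raise ValueError(f"unknown target {self.target!r}")
        if self.mode not in ("balanced", "spoiled"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def duration(self) -> float:
        return self.n_exc * self.tr

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def imaging_slice(self) -> slice:
        """Indices of the imaging (non-preparation) excitations."""
        if self.mode == "spoiled":
            return slice(0, self.n_exc)
        # balanced: cat ramp, imaging, decat ramp, tip-back
        return slice(self.n_cat, self.n_exc - self.n_cat - 1)

    @property
    def sample_time(self) -> float:
        """Time of the recorded echo."""
        te = self.tr / 2 if self.t_readout is None else self.t_readout / 2
        return self.start_time + self.sample_index * self.tr + te

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flips"] = [float(f) for f in self.flips]
        d["phases"] = [float(p) for p in self.phases]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionBlock":
        d = dict(d)
        d["flips"] = tuple(d["flips"])
        d["phases"] = tuple(d["phases"])
        return cls(**d)


@dataclass(frozen=True)
class SequenceSchedule:
    """Ordered, non-overlapping acquisition blocks of one experiment design."""

    blocks: tuple
    design_id: str
    temporal_resolution: float
    total_duration: float

    def __post_init__(self):
        starts = [b.start_time for b in self.blocks]
        if starts != sorted(starts):
            raise ValueError("blocks must be sorted by start_time")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end_time > b.start_time + 1e-12:
                raise ValueError(
                    f"overlapping blocks: block ending {a.end_time:.4f}s vs "
                    f"block starting {b.start_time:.4f}s"
                )

    def blocks_for(self, target: str) -> list:
        return [b for b in self.blocks if b.target == target]

    @property
    def n_samples(self) -> dict:
        return {t: len(self.blocks_for(t)) for t in (PYRUVATE, LACTATE)}

    def sample_times(self, target: str) -> np.ndarray:
        return np.array([b.sample_time for b in self.blocks_for(target)])

    def to_dict(self) -> dict:
        return {
            "design_id": self.design_id,
            "temporal_resolution": self.temporal_resolution,
            "total_duration": self.total_duration,
            "blocks": [b.to_dict() for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SequenceSchedule":
        return cls(
            blocks=tuple(AcquisitionBlock.from_dict(b) for b in d["blocks"]),
            design_id=d["design_id"],
            temporal_resolution=d["temporal_resolution"],
            total_duration=d["total_duration"],
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text) -> "SequenceSchedule":
        if hasattr(text, "read"):
            text = text.read()
        return cls.from_dict(yaml.safe_load(text))


def _alternating_phases(n: int, start: float = 0.0) -> np.ndarray:
    return (start + 180.0 * np.arange(n)) % 360.0


def _bssfp_block(
    start_time: float,
    target: str,
    tr: float,
    imaging_flips: np.ndarray,
    n_cat: int,
) -> AcquisitionBlock:
    """Assemble a balanced block: cat ramp + imaging + decat ramp + tip-back."""
    imaging_flips = np.atleast_1d(np.asarray(imaging_flips, dtype=float))
    up = catalyzation_ramp(float(imaging_flips[0]), n_cat, "up")
    down = catalyzation_ramp(float(imaging_flips[-1]), n_cat, "down")
    flips = np.concatenate([up, imaging_flips, down])
    phases = _alternating_phases(len(flips))
    # tip-back: half the final ramp angle, same phase as the previous pulse,
    # returning the residual steady-state magnetization to the z axis
    tip = flips[-1] / 2 if len(down) else imaging_flips[-1] / 2
    flips = np.append(flips, tip)
    phases = np.append(phases, phases[-1])
    sample_index = n_cat + len(imaging_flips) // 2
    return AcquisitionBlock(
        start_time=start_time,
        target=target,
        mode="balanced",
        tr=tr,
        n_exc=len(flips),
        flips=tuple(flips),
        phases=tuple(phases),
        sample_index=sample_index,
        n_cat=n_cat,
    )


def build_schedule(design_id: str, **overrides) -> SequenceSchedule:
    """Construct one of the three experiment designs.

    Parameters
    ----------
    design_id : str
        ``"mrf_sigmoid"``, ``"mrf_constant"`` or ``"hybridgre"``.
    overrides : dict
        Optional config keys: ``total_duration`` (s, default 60),
        ``temporal_resolution`` (s), ``n_exc`` (total excitations per bSSFP
        block, default 128, including preparation pulses), ``n_cat``
        (ramp length, default 10), ``tr_pyr``, ``tr_lac``,
        ``flip_pyr``, ``flip_lac``, ``sigmoid`` (:class:`SigmoidParams`).

    Notes
    -----
    Each interleave period of length ``temporal_resolution`` holds one
    pyruvate block at the period start and one lactate block at the
    half-period offset. The number of periods is ``round(total_duration /
    temporal_resolution)``: 15 pyruvate + 15 lactate samples for the 4.1 s
    MRF designs over 60 s, 13 each for the 4.6 s hybrid design.
    """
    if design_id not in DESIGN_IDS:
        raise ValueError(f"unknown design_id {design_id!r}; choose from {DESIGN_IDS}")

    total_duration = float(overrides.pop("total_duration", 60.0))
    n_cat = int(overrides.pop("n_cat", 10))
    n_exc = int(overrides.pop("n_exc", 128))
    sig = overrides.pop("sigmoid", SigmoidParams())
    tr_lac = float(overrides.pop("tr_lac", 0.0153))
    flip_lac = float(overrides.pop("flip_lac", 60.0))

    if design_id == "hybridgre":
        dt = float(overrides.pop("temporal_resolution", 4.6))
        tr_pyr = float(overrides.pop("tr_pyr", 1.0))
        flip_pyr = float(overrides.pop("flip_pyr", 10.0))
        t_readout = float(overrides.pop("t_readout", 0.022))
        n_slices = int(overrides.pop("n_slices", 16))  # 33.6 cm slab / 21 mm slices
    else:
        dt = float(overrides.pop("temporal_resolution", 4.1))
        tr_pyr = float(overrides.pop("tr_pyr", 0.0156))
        flip_pyr = float(overrides.pop("flip_pyr", 30.0))
        t_readout = None
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")

    n_imaging = n_exc - 2 * n_cat - 1  # bSSFP: ramps and tip-back count toward n_exc
    if n_imaging < 1:
        raise ValueError("n_exc too small for the requested n_cat")

    n_periods = int(round(total_duration / dt))
    blocks = []
    for i in range(n_periods):
        t0 = i * dt
        # pyruvate block at the period start
        if design_id == "hybridgre":
            blocks.append(
                AcquisitionBlock(
                    start_time=t0,
                    target=PYRUVATE,
                    mode="spoiled",
                    tr=tr_pyr,
                    n_exc=1,
                    flips=(flip_pyr,),
                    phases=(0.0,),
                    sample_index=0,
                    n_cat=0,
                    t_readout=t_readout,
                    n_slices=n_slices,
                )
            )
        else:
            if design_id == "mrf_sigmoid":
                # evaluated per excitation at absolute time since acquisition start
                t_exc = t0 + np.arange(n_cat, n_cat + n_imaging) * tr_pyr
                flips = sigmoid_flip(t_exc, sig)
            else:
                flips = np.full(n_imaging, flip_pyr)
            blocks.append(_bssfp_block(t0, PYRUVATE, tr_pyr, flips, n_cat))
        # lactate block at the half-period offset
        blocks.append(
            _bssfp_block(t0 + dt / 2, LACTATE, tr_lac, np.full(n_imaging, flip_lac), n_cat)
        )
    return SequenceSchedule(
        blocks=tuple(blocks),
        design_id=design_id,
        temporal_resolution=dt,
        total_duration=total_duration,
    )
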