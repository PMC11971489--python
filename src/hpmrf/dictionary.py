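"""Fingerprint dictionary generation over a kPL grid.

A dictionary is the set of all simulated fingerprints used for parameter
estimation: one entry per kPL value on a regular grid (default 0 to 0.1 1/s
in steps of 1e-4, i.e. 1001 entries), with every other model parameter fixed
at its nominal value. Entries are stored unit-L2-normalized for template
matching; the pre-normalization norms are retained so the matched amplitude
can be recovered and so Monte Carlo noise can be added on the raw
(amplitude-true) signal scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .kinetics import simulate_signal_batch
from .params import BolusParams, FieldConditions, KineticParams
from .sequences import SequenceSchedule, build_schedule

__all__ = [
    "DictionarySpec",
    "Dictionary",
    "generate_dictionary",
    "cached_dictionary",
    "default_dictionary",
]


@dataclass(frozen=True)
class DictionarySpec:
    """Grid definition plus fixed nuisance parameters for one dictionary."""

    schedule: SequenceSchedule
    kpl_min: float = 0.0
    kpl_max: float = 0.1
    kpl_res: float = 1e-4
    kin: KineticParams = field(default_factory=KineticParams)
    bolus: BolusParams = field(default_factory=BolusParams)
    cond: FieldConditions = field(default_factory=FieldConditions)
    sample_mode: str = "block_dc"

    def __post_init__(self):
        if self.kpl_min > self.kpl_max:
            raise ValueError("kpl_min must be <= kpl_max")
        if self.kpl_res <= 0:
            raise ValueError("kpl_res must be > 0")

    @property
    def kpl_grid(self) -> np.ndarray:
        n = int(np.floor((self.kpl_max - self.kpl_min) / self.kpl_res + 1e-9)) + 1
        return self.kpl_min + self.kpl_res * np.arange(n)

    def to_json(self) -> str:
        d = {
            "schedule": self.schedule.to_dict(),
            "kpl_min": self.kpl_min,
            "kpl_max": self.kpl_max,
            "kpl_res": self.kpl_res,
            "kin": self.kin.to_dict(),
            "bolus": self.bolus.to_dict(),
            "cond": self.cond.to_dict(),
            "sample_mode": self.sample_mode,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DictionarySpec":
        d = json.loads(text)
        return cls(
            schedule=SequenceSchedule.from_dict(d["schedule"]),
            kpl_min=d["kpl_min"],
            kpl_max=d["kpl_max"],
            kpl_res=d["kpl_res"],
            kin=KineticParams.from_dict(d["kin"]),
            bolus=BolusParams.from_dict(d["bolus"]),
            cond=FieldConditions.from_dict(d["cond"]),
            sample_mode=d.get("sample_mode", "block_dc"),
        )

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class Dictionary:
    """kPL grid plus matrix of unit-norm complex fingerprints.

    ``entries[i]`` is the unit-L2-norm fingerprint at ``kpl_grid[i]``;
    ``raw_norms[i]`` its pre-normalization norm (so ``raw_norms[:, None] *
    entries`` recovers the amplitude-true signals).
    """

    kpl_grid: np.ndarray
    entries: np.ndarray
    raw_norms: np.ndarray
    times: np.ndarray
    n_pyr: int
    n_lac: int
    spec: DictionarySpec

    def __post_init__(self):
        if self.entries.shape[0] != len(self.kpl_grid):
            raise ValueError("entries/grid size mismatch")
        if np.any(np.diff(self.kpl_grid) <= 0):
            raise ValueError("kpl_grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.kpl_grid)

    @property
    def signal_length(self) -> int:
        return self.entries.shape[1]

    def raw_entry(self, i: int) -> np.ndarray:
        """Amplitude-true fingerprint at grid index i."""
        return self.entries[i] * self.raw_norms[i]

    @property
    def raw_entries(self) -> np.ndarray:
        return self.entries * self.raw_norms[:, None]

    def nearest_index(self, kpl: float) -> int:
        return int(np.argmin(np.abs(self.kpl_grid - kpl)))

    # ---- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Write to HDF5: /kpl_grid, /entries_real, /entries_imag, /raw_norms,
        /times, /spec_json."""
        with h5py.File(path, "w") as h:
            h.create_dataset("kpl_grid", data=self.kpl_grid)
            h.create_dataset("entries_real", data=self.entries.real)
            h.create_dataset("entries_imag", data=self.entries.imag)
            h.create_dataset("raw_norms", data=self.raw_norms)
            h.create_dataset("times", data=self.times)
            h.attrs["n_pyr"] = self.n_pyr
            h.attrs["n_lac"] = self.n_lac
            h.create_dataset("spec_json", data=self.spec.to_json())

    @classmethod
    def load(cls, path) -> "Dictionary":
        with h5py.File(path, "r") as h:
            spec = DictionarySpec.from_json(h["spec_json"][()].decode())
            return cls(
                kpl_grid=h["kpl_grid"][:],
                entries=h["entries_real"][:] + 1j * h["entries_imag"][:],
                raw_norms=h["raw_norms"][:],
                times=h["times"][:],
                n_pyr=int(h.attrs["n_pyr"]),
                n_lac=int(h.attrs["n_lac"]),
                spec=spec,
            )


def generate_dictionary(spec: DictionarySpec) -> Dictionary:
    """Simulate one fingerprint per grid value and normalize.

    Deterministic: regenerating from the same spec is bit-identical.
    """
    grid = spec.kpl_grid
    if len(grid) < 1:
        raise ValueError("degenerate kPL grid")
    signals, times, (n_p, n_l) = simulate_signal_batch(
        spec.schedule, spec.kin, spec.bolus, spec.cond,
        sample_mode=spec.sample_mode, kPL=grid,
    )
    norms = np.linalg.norm(signals, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm fingerprint in dictionary")
    return Dictionary(
        kpl_grid=grid,
        entries=signals / norms[:, None],
        raw_norms=norms,
        times=times,
        n_pyr=n_p,
        n_lac=n_l,
        spec=spec,
    )


def cached_dictionary(spec: DictionarySpec, cache_dir) -> Dictionary:
    """Generate (or load from an HDF5 cache keyed by the spec's content hash)."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"dict_{spec.schedule.design_id}_{spec.content_hash()}.h5"
    if path.exists():
        return Dictionary.load(path)
    d = generate_dictionary(spec)
    d.save(path)
    return d


def default_dictionary(design_id: str, **schedule_overrides) -> Dictionary:
    """Convenience: nominal-parameter dictionary for one of the named designs."""
    return generate_dictionary(DictionarySpec(schedule=build_schedule(design_id, **schedule_overrides)))
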