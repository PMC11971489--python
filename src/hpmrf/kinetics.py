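"""Two-pool Bloch-McConnell signal simulation with gamma bolus input.

The model is a one-way exchange system: hyperpolarized pyruvate magnetization
arrives via a gamma-variate bolus into the pyruvate longitudinal pool and
converts to lactate at rate kPL. Exchange acts on all three magnetization
components of each pool (full modified Bloch-McConnell), so transverse
coherences carry exchanged magnetization — essential for balanced SSFP
acquisition blocks. Each pool relaxes (T1 toward zero — hyperpolarized
magnetization is non-renewable), precesses at its chemical shift plus any
bulk B0 error plus a per-isochromat off-resonance drawn from the intravoxel
linewidth distribution, and is excited by ideal spectrally selective RF
(rotations applied to the target metabolite only).

Because the system is linear with piecewise-constant coefficients, evolution
between RF pulses is computed with the exact matrix exponential. The 6x6
system is block lower triangular and decouples into two 2x2 triangular
subsystems (complex transverse, real longitudinal), so all propagator
elements have closed forms and the whole computation is vectorized over
arbitrary parameter batches and isochromats. The inhomogeneous bolus term is
integrated exactly for a piecewise-constant input rate, with 10 ms sub-steps
while the bolus is active.

All signals are expressed in units of the relaxation-free total bolus signal
(``BolusParams.total_input``, default 1), so a noise SD sigma on this scale
is directly comparable across experiment designs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .params import BolusParams, FieldConditions, KineticParams
from .sequences import LACTATE, PYRUVATE, SequenceSchedule

__all__ = [
    "MagnetizationState",
    "Fingerprint",
    "bolus_input_rate",
    "gamma_scale",
    "isochromat_offsets",
    "evolve_free",
    "apply_rf",
    "simulate_fingerprint",
    "simulate_signal_batch",
    "BOLUS_SUBSTEP",
]

#: Sub-step length (s) for the piecewise-constant bolus integration.
BOLUS_SUBSTEP = 0.010

_TWO_PI = 2.0 * np.pi


# --------------------------------------------------------------------------
# bolus input
# --------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _ppf99(shape_alpha: float) -> float:
    return float(stats.gamma.ppf(0.99, shape_alpha))


def gamma_scale(bolus: BolusParams) -> float:
    """Gamma scale parameter beta (s) such that 99% of the input falls
    within ``t_duration`` of arrival."""
    return bolus.t_duration / _ppf99(bolus.shape_alpha)


def bolus_input_rate(t, bolus: BolusParams):
    """Gamma-variate bolus input rate u(t), magnetization per second.

    Zero before ``t_arrival``; integrates to ``total_input`` over all time,
    with at least 99% delivered within ``[t_arrival, t_arrival+t_duration]``.
    """
    t = np.asarray(t, dtype=float)
    beta = gamma_scale(bolus)
    x = (t - bolus.t_arrival) / beta
    a = bolus.shape_alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(
            x > 0,
            bolus.total_input
            * np.exp((a - 1) * np.log(np.maximum(x, 1e-300)) - x)
            / (special.gamma(a) * beta),
            0.0,
        )
    return u if u.ndim else float(u)


def _bolus_rate_batch(t: float, arr, beta, shape_alpha, total):
    """Vectorized bolus rate at scalar time t for per-row bolus parameters."""
    x = (t - arr) / beta
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(
            x > 0,
            total * np.exp((shape_alpha - 1) * np.log(np.maximum(x, 1e-300)) - x)
            / (special.gamma(shape_alpha) * beta),
            0.0,
        )
    return u


# --------------------------------------------------------------------------
# isochromat distribution
# --------------------------------------------------------------------------

def isochromat_offsets(
    linewidth_fwhm, n_isochromats: int, shape: str = "lorentzian"
) -> np.ndarray:
    """Off-resonance offsets (Hz) sampling the intravoxel distribution.

    Equally spaced quantiles of a Lorentzian (default) or Gaussian of the
    given FWHM, truncated at +/- 3 FWHM; each isochromat carries equal
    probability mass. With odd ``n_isochromats`` the central isochromat sits
    exactly at zero offset. ``linewidth_fwhm`` may be an array, in which case
    the result has shape ``(len(linewidth_fwhm), n_isochromats)``.
    """
    lw = np.atleast_1d(np.asarray(linewidth_fwhm, dtype=float))
    n = n_isochromats
    p = (np.arange(n) + 0.5) / n  # equal-mass quantile midpoints
    if shape == "lorentzian":
        dist = stats.cauchy(scale=1.0 / 2.0)  # FWHM 1
    elif shape == "gaussian":
        dist = stats.norm(scale=1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))))
    else:
        raise ValueError(f"unknown linewidth shape {shape!r}")
    lo, hi = dist.cdf(-3.0), dist.cdf(3.0)
    unit = dist.ppf(lo + p * (hi - lo))  # offsets for FWHM 1
    out = lw[:, None] * unit[None, :]
    return out if np.ndim(linewidth_fwhm) else out[0]


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class MagnetizationState:
    """Magnetization of both pools across isochromats.

    ``M`` has shape ``(n_isochromats, 6)`` with columns
    (Mx_pyr, My_pyr, Mz_pyr, Mx_lac, My_lac, Mz_lac), in units of the total
    bolus input.
    """

    M: np.ndarray

    @classmethod
    def zeros(cls, n_isochromats: int = 1) -> "MagnetizationState":
        return cls(np.zeros((n_isochromats, 6)))

    @property
    def n_isochromats(self) -> int:
        return self.M.shape[0]

    # complex-transverse views used by the propagator
    @property
    def m_pyr(self) -> np.ndarray:
        return self.M[:, 0] + 1j * self.M[:, 1]

    @property
    def m_lac(self) -> np.ndarray:
        return self.M[:, 3] + 1j * self.M[:, 4]

    @property
    def mz_pyr(self) -> np.ndarray:
        return self.M[:, 2]

    @property
    def mz_lac(self) -> np.ndarray:
        return self.M[:, 5]

    def copy(self) -> "MagnetizationState":
        return MagnetizationState(self.M.copy())


@dataclass
class Fingerprint:
    """Simulated complex signal time course of one parameter combination.

    ``signal`` concatenates the pyruvate samples followed by the lactate
    samples; ``times`` holds the matching echo timestamps (s).
    """

    signal: np.ndarray
    times: np.ndarray
    n_pyr: int
    n_lac: int
    meta: dict

    def __post_init__(self):
        if len(self.signal) != len(self.times):
            raise ValueError("signal and times must have equal length")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("fingerprint contains non-finite samples")

    @property
    def pyr(self) -> np.ndarray:
        return self.signal[: self.n_pyr]

    @property
    def lac(self) -> np.ndarray:
        return self.signal[self.n_pyr:]

    def to_dataframe(self):
        import pandas as pd

        met = [PYRUVATE] * self.n_pyr + [LACTATE] * self.n_lac
        return pd.DataFrame(
            {
                "time_s": self.times,
                "metabolite": met,
                "real": self.signal.real,
                "imag": self.signal.imag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, path_or_group, name: str = "fingerprint") -> None:
        import h5py

        own = not isinstance(path_or_group, h5py.Group)
        h = h5py.File(path_or_group, "a") if own else path_or_group
        try:
            g = h.require_group(name)
            for key in ("signal", "times"):
                if key in g:
                    del g[key]
            g.create_dataset("signal", data=self.signal)
            g.create_dataset("times", data=self.times)
            g.attrs["n_pyr"] = self.n_pyr
            g.attrs["n_lac"] = self.n_lac
            for k, v in self.meta.items():
                g.attrs[str(k)] = str(v)
        finally:
            if own:
                h.close()


# --------------------------------------------------------------------------
# batched parameter table
# --------------------------------------------------------------------------

_SWEEPABLE = {
    "kPL": "kpl",
    "T1_pyr": "t1p",
    "T1_lac": "t1l",
    "T2_pyr": "t2p",
    "T2_lac": "t2l",
    "omega_pyr": "wp",
    "omega_lac": "wl",
    "t_arrival": "arr",
    "t_duration": "dur",
    "shape_alpha": "shape_alpha",
    "total_input": "total",
    "b1_scale": "b1",
    "b0_offset": "b0",
    "linewidth_fwhm": "lw",
}


class _BatchParams:
    """Broadcast scalar parameter records plus per-field sweeps to (B,) arrays."""

    def __init__(self, kin: KineticParams, bolus: BolusParams, cond: FieldConditions,
                 sweeps: dict):
        base = {
            "kpl": kin.kPL, "t1p": kin.T1_pyr, "t1l": kin.T1_lac,
            "t2p": kin.T2_pyr, "t2l": kin.T2_lac,
            "wp": kin.omega_pyr, "wl": kin.omega_lac,
            "arr": bolus.t_arrival, "dur": bolus.t_duration,
            "shape_alpha": bolus.shape_alpha, "total": bolus.total_input,
            "b1": cond.b1_scale, "b0": cond.b0_offset, "lw": cond.linewidth_fwhm,
        }
        arrays = {}
        for field, short in _SWEEPABLE.items():
            if field in sweeps:
                arrays[short] = np.atleast_1d(np.asarray(sweeps[field], dtype=float))
        unknown = set(sweeps) - set(_SWEEPABLE)
        if unknown:
            raise ValueError(f"unknown sweep fields: {sorted(unknown)}")
        B = 1
        for a in arrays.values():
            if len(a) != 1:
                if B != 1 and len(a) != B:
                    raise ValueError("sweep arrays must have a common length")
                B = len(a)
        self.B = B
        for field, short in _SWEEPABLE.items():
            a = arrays.get(short, np.array([base[short]], dtype=float))
            self.__dict__[short] = np.broadcast_to(a, (B,)).copy()
        self.n_iso = cond.n_isochromats
        self.lw_shape = cond.linewidth_shape
        self.offs = isochromat_offsets(self.lw, self.n_iso, self.lw_shape)
        self.beta = self.dur / np.array([_ppf99(s) for s in self.shape_alpha])


# --------------------------------------------------------------------------
# closed-form propagator
# --------------------------------------------------------------------------

def _safe_div(num, den, fallback):
    small = np.abs(den) < 1e-12
    out = num / np.where(small, 1.0, den)
    return np.where(small, fallback, out)


class _Propagator:
    """Exact free-evolution propagator, cached per interval length.

    The 6x6 Bloch-McConnell generator decouples into a complex transverse
    pair with rates ``lam_p = -1/T2p - kPL - 2*pi*i*f_p`` and
    ``lam_l = -1/T2l - 2*pi*i*f_l`` coupled by kPL, and a real longitudinal
    pair with rates ``mu_p = -1/T1p - kPL`` and ``mu_l = -1/T1l``. Both 2x2
    subsystems are lower triangular, giving elementwise closed forms for the
    matrix exponential and for the bolus (inhomogeneous) integral.
    """

    def __init__(self, bp: _BatchParams):
        self.bp = bp
        fp = bp.wp[:, None] + bp.b0[:, None] + bp.offs  # (B, n_iso)
        fl = bp.wl[:, None] + bp.b0[:, None] + bp.offs
        self.lam_p = -(1.0 / bp.t2p[:, None] + bp.kpl[:, None]) - 1j * _TWO_PI * fp
        self.lam_l = -(1.0 / bp.t2l[:, None]) - 1j * _TWO_PI * fl
        self.mu_p = (-(1.0 / bp.t1p + bp.kpl))[:, None]  # (B, 1)
        self.mu_l = (-(1.0 / bp.t1l))[:, None]
        self.k = bp.kpl[:, None]
        self._cache: dict = {}
        tail = stats.gamma.ppf(1.0 - 1e-12, bp.shape_alpha) * bp.beta
        self._window = (float(np.min(bp.arr)), float(np.max(bp.arr + tail)))

    def coeffs(self, dt: float):
        key = round(dt, 12)
        c = self._cache.get(key)
        if c is None:
            lp, ll, mp, ml, k = self.lam_p, self.lam_l, self.mu_p, self.mu_l, self.k
            Ep, El = np.exp(lp * dt), np.exp(ll * dt)
            Xt = k * _safe_div(Ep - El, lp - ll, dt * Ep)
            Ezp, Ezl = np.exp(mp * dt), np.exp(ml * dt)
            Xz = k * _safe_div(Ezp - Ezl, mp - ml, dt * Ezp)
            gp = _safe_div(np.expm1(mp * dt), mp, dt)
            gl = _safe_div(np.expm1(ml * dt), ml, dt)
            # longitudinal lactate gain from constant-rate inflow over dt
            wl_near = k * _safe_div(dt * Ezp - gp, mp, np.full_like(gp, dt**2 / 2))
            wl = np.where(
                np.abs(mp - ml) < 1e-12, wl_near, k * _safe_div(gp - gl, mp - ml, 0.0)
            )
            c = (Ep, El, Xt, Ezp, Ezl, Xz, gp, wl)
            self._cache[key] = c
        return c

    def step(self, state, dt: float, u):
        """Advance (mp, ml, zp, zl) by dt with constant bolus rate u (B,)."""
        mp_, ml_, zp_, zl_ = state
        Ep, El, Xt, Ezp, Ezl, Xz, gp, wl = self.coeffs(dt)
        u = u[:, None]
        ml_new = Xt * mp_ + El * ml_
        mp_new = Ep * mp_
        zl_new = Xz * zp_ + Ezl * zl_ + u * wl
        zp_new = Ezp * zp_ + u * gp
        return (mp_new, ml_new, zp_new, zl_new)

    def bolus_window(self):
        return self._window

    def evolve(self, state, t0: float, t1: float, track=None):
        """Evolve from t0 to t1, sub-stepping while the bolus is active.

        ``track``: optional 1-element list accumulating delivered input.
        """
        if t1 < t0:
            raise ValueError("dt must be >= 0")
        if t1 == t0:
            return state
        bp = self.bp
        w_lo, w_hi = self.bolus_window()
        edges = [t0, t1]
        for w in (w_lo, w_hi):
            if t0 < w < t1:
                edges.append(w)
        edges = sorted(edges)
        for a, b in zip(edges, edges[1:]):
            mid = 0.5 * (a + b)
            if w_lo <= mid <= w_hi:
                n = max(1, int(np.ceil((b - a) / BOLUS_SUBSTEP)))
                dt = (b - a) / n
                for i in range(n):
                    tm = a + (i + 0.5) * dt
                    u = _bolus_rate_batch(tm, bp.arr, bp.beta, bp.shape_alpha, bp.total)
                    state = self.step(state, dt, u)
                    if track is not None:
                        track[0] = track[0] + u * dt
            else:
                state = self.step(state, b - a, np.zeros(bp.B))
        return state


def _rotate(state, target: str, theta, phi, pool_freq, t: float):
    """Instantaneous RF rotation of the target pool.

    ``theta``/``phi`` in radians, shape (B, 1). The rotation axis phase is
    ramped at the target metabolite's nominal frequency so the pulse is
    resonant with that pool (``phi_eff = phi - 2*pi*f*t``).
    """
    mp_, ml_, zp_, zl_ = state
    phi_eff = phi - _TWO_PI * pool_freq * t
    c = np.exp(-1j * phi_eff)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    if target == PYRUVATE:
        m, z = mp_, zp_
    else:
        m, z = ml_, zl_
    mt = m * c
    a, b = mt.real, mt.imag
    b_new = b * cos_t + z * sin_t
    z_new = z * cos_t - b * sin_t
    m_new = (a + 1j * b_new) * np.conj(c)
    if target == PYRUVATE:
        return (m_new, ml_, z_new, zl_)
    return (mp_, m_new, zp_, z_new)


# --------------------------------------------------------------------------
# public single-state operations
# --------------------------------------------------------------------------

def _bp_single(kin, bolus, cond) -> _BatchParams:
    return _BatchParams(kin, bolus, cond, {})


def _state_to_tuple(state: MagnetizationState):
    return (
        state.m_pyr[None, :].astype(complex),
        state.m_lac[None, :].astype(complex),
        state.mz_pyr[None, :].astype(float),
        state.mz_lac[None, :].astype(float),
    )


def _tuple_to_state(t) -> MagnetizationState:
    mp_, ml_, zp_, zl_ = (a[0] for a in t)
    M = np.column_stack([mp_.real, mp_.imag, zp_, ml_.real, ml_.imag, zl_])
    return MagnetizationState(M)


def evolve_free(
    state: MagnetizationState,
    dt: float,
    kin: KineticParams,
    bolus: BolusParams,
    cond: FieldConditions,
    t0: float = 0.0,
    return_input: bool = False,
):
    """Free evolution (no RF) for ``dt`` seconds starting at absolute time ``t0``.

    Propagates relaxation, off-resonance precession, one-way exchange on all
    components, and gamma-bolus inflow into the pyruvate longitudinal pool,
    using the exact matrix exponential of the piecewise-constant system.

    If ``return_input`` is true, also returns the bolus input delivered over
    the interval (as integrated by the propagator's piecewise-constant rule).
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if state.n_isochromats != cond.n_isochromats:
        raise ValueError("state/cond isochromat count mismatch")
    prop = _Propagator(_bp_single(kin, bolus, cond))
    track = [np.zeros(1)] if return_input else None
    out = prop.evolve(_state_to_tuple(state), t0, t0 + dt, track=track)
    new = _tuple_to_state(out)
    if return_input:
        return new, float(track[0][0])
    return new


def apply_rf(
    state: MagnetizationState,
    flip: float,
    phase: float,
    target: str,
    cond: FieldConditions,
) -> MagnetizationState:
    """Instantaneous rotation of the target pool by ``flip * b1_scale`` degrees
    about the transverse axis at ``phase`` degrees; the other pool is untouched
    (ideal spectral selectivity)."""
    if target not in (PYRUVATE, LACTATE):
        raise ValueError(f"unknown target {target!r}")
    theta = np.array([[np.deg2rad(flip) * cond.b1_scale]])
    phi = np.array([[np.deg2rad(phase)]])
    out = _rotate(_state_to_tuple(state), target, theta, phi, np.zeros((1, 1)), 0.0)
    return _tuple_to_state(out)


# --------------------------------------------------------------------------
# schedule execution
# --------------------------------------------------------------------------

def _run_schedule(schedule: SequenceSchedule, bp: _BatchParams,
                  sample_mode: str = "block_dc"):
    """Execute a schedule for a parameter batch; returns per-target samples.

    ``sample_mode`` selects what the recorded complex sample of each block is:

    * ``"block_dc"`` (default) — the total (k-space center) signal of the
      block's acquisition: the sum over all imaging excitations of the echo
      demodulated by the excitation's RF phase, times ``n_slices`` for 2D
      multi-slice spoiled blocks (one excitation per slice sub-volume).
    * ``"center_echo"`` — the single echo of the block's center-of-k-space
      excitation (``sample_index``).
    """
    if sample_mode not in ("block_dc", "center_echo"):
        raise ValueError(f"unknown sample_mode {sample_mode!r}")
    prop = _Propagator(bp)
    B, n_iso = bp.B, bp.n_iso
    state = (
        np.zeros((B, n_iso), complex), np.zeros((B, n_iso), complex),
        np.zeros((B, n_iso)), np.zeros((B, n_iso)),
    )
    t_cur = min(0.0, float(np.min(bp.arr)))
    samples = {PYRUVATE: [], LACTATE: []}
    times = {PYRUVATE: [], LACTATE: []}
    freq = {PYRUVATE: bp.wp[:, None], LACTATE: bp.wl[:, None]}
    b1 = bp.b1[:, None]
    for blk in schedule.blocks:
        te = blk.tr / 2 if blk.t_readout is None else blk.t_readout / 2
        sl = blk.imaging_slice
        weight = blk.n_slices if (blk.mode == "spoiled" and sample_mode == "block_dc") else 1.0
        acc = np.zeros(B, complex)
        for j in range(blk.n_exc):
            t = blk.start_time + j * blk.tr
            state = prop.evolve(state, t_cur, t)
            t_cur = t
            state = _rotate(
                state, blk.target, np.deg2rad(blk.flips[j]) * b1,
                np.full((B, 1), np.deg2rad(blk.phases[j])), freq[blk.target], t,
            )
            record = (
                sl.start <= j < sl.stop
                if sample_mode == "block_dc"
                else j == blk.sample_index
            )
            if record:
                ts = t + te
                state = prop.evolve(state, t_cur, ts)
                t_cur = ts
                m = state[0] if blk.target == PYRUVATE else state[1]
                demod = np.exp(
                    1j * (_TWO_PI * freq[blk.target][:, 0] * ts - np.deg2rad(blk.phases[j]))
                )
                acc += weight * m.mean(axis=1) * demod
            if blk.mode == "spoiled":
                t_end = t + blk.tr
                state = prop.evolve(state, t_cur, t_end)
                t_cur = t_end
                idx = 0 if blk.target == PYRUVATE else 1
                state = tuple(
                    np.zeros_like(s) if i == idx else s for i, s in enumerate(state)
                )
        samples[blk.target].append(acc)
        times[blk.target].append(blk.sample_time)
    sig_p = np.array(samples[PYRUVATE]).T if samples[PYRUVATE] else np.zeros((B, 0), complex)
    sig_l = np.array(samples[LACTATE]).T if samples[LACTATE] else np.zeros((B, 0), complex)
    return sig_p, sig_l, np.array(times[PYRUVATE]), np.array(times[LACTATE])


def simulate_signal_batch(
    schedule: SequenceSchedule,
    kin: KineticParams = KineticParams(),
    bolus: BolusParams = BolusParams(),
    cond: FieldConditions = FieldConditions(),
    sample_mode: str = "block_dc",
    **sweeps,
):
    """Simulate fingerprints for a batch of parameter values.

    Any field of the three parameter records may be swept by passing an array
    keyword (e.g. ``kPL=np.linspace(0, 0.1, 1001)``); arrays are broadcast to
    a common batch size B. Returns ``(signals, times, (n_pyr, n_lac))`` where
    ``signals`` has shape (B, n_pyr + n_lac), pyruvate samples first.
    """
    bp = _BatchParams(kin, bolus, cond, sweeps)
    sig_p, sig_l, t_p, t_l = _run_schedule(schedule, bp, sample_mode)
    signals = np.concatenate([sig_p, sig_l], axis=1)
    times = np.concatenate([t_p, t_l])
    return signals, times, (sig_p.shape[1], sig_l.shape[1])


def simulate_fingerprint(
    schedule: SequenceSchedule,
    kin: KineticParams = KineticParams(),
    bolus: BolusParams = BolusParams(),
    cond: FieldConditions = FieldConditions(),
    sample_mode: str = "block_dc",
) -> Fingerprint:
    """Simulate the complex signal time course of one parameter combination.

    The magnetization starts from zero before the bolus lead-in; the bolus
    fills the pyruvate longitudinal pool, the schedule's blocks are stepped
    through chronologically, and one complex sample per acquisition block is
    recorded: the isochromat-mean transverse signal of the target metabolite,
    demodulated at its nominal frequency and summed over the block's imaging
    excitations (see :func:`_run_schedule` for the sampling conventions).
    """
    signals, times, (n_p, n_l) = simulate_signal_batch(
        schedule, kin, bolus, cond, sample_mode=sample_mode
    )
    return Fingerprint(
        signal=signals[0],
        times=times,
        n_pyr=n_p,
        n_lac=n_l,
        meta={
            "design_id": schedule.design_id,
            "kin": dataclasses.asdict(kin),
            "bolus": dataclasses.asdict(bolus),
            "cond": dataclasses.asdict(cond),
        },
    )
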