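"""Deterministic generative model: bilinear neuronal dynamics + balloon model.

The neuronal populations of ``n`` regions evolve as

    dz/dt = (A + sum_j u_j B_j) z + C u

with intrinsic coupling ``A`` (Hz), input-dependent modulations ``B_j``
and direct input weights ``C``.  Each region's activity drives a
hemodynamic cascade (vasodilatory signal s, inflow f, venous volume v,
deoxyhemoglobin q — the balloon/Windkessel model)

    ds/dt = z - kappa*s - gamma*(f - 1)
    df/dt = s
    tau * dv/dt = f - v**(1/alpha)
    tau * dq/dt = f*E(f, rho)/rho - v**(1/alpha) * q / v,
    E(f, rho) = 1 - (1 - rho)**(1/f)

and BOLD signal change is read out as

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v)).

Integration is fixed-step RK4 with zero-order-hold inputs; the public
interface reports BOLD in percent of baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExperimentDesign, ROITimeSeries

__all__ = [
    "ConnectivityParams",
    "HemodynamicParams",
    "NeuralHemoState",
    "SimulationDiverged",
    "neuronal_drift",
    "hemodynamic_drift",
    "bold_observation",
    "simulate_timeseries",
    "assert_stable",
]


class SimulationDiverged(RuntimeError):
    """Neuronal activity exceeded the stability bound during integration."""

    def __init__(self, time_s: float, bound: float):
        self.time_s = time_s
        self.bound = bound
        super().__init__(
            f"neuronal activity exceeded |z| = {bound} at t = {time_s:.3f} s; "
            "the parameter set is dynamically unstable"
        )


@dataclass
class ConnectivityParams:
    """A/B/C matrices of the bilinear neuronal model (all rates in Hz).

    ``A`` is the *effective* intrinsic coupling; its diagonal (the
    self-decay) must be strictly negative.  ``B`` stacks one n x n
    modulation matrix per input channel; ``C`` maps inputs onto regions.
    """

    A: np.ndarray  # (n, n)
    B: np.ndarray  # (m, n, n)
    C: np.ndarray  # (n, m)
    region_labels: tuple[str, ...]
    input_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square; got {self.A.shape}")
        if len(self.region_labels) != n:
            raise ValueError("region_labels length must equal A dimension")
        m = len(self.input_labels)
        if self.B.shape != (m, n, n):
            raise ValueError(
                f"B must have shape ({m}, {n}, {n}); got {self.B.shape}"
            )
        if self.C.shape != (n, m):
            raise ValueError(f"C must have shape ({n}, {m}); got {self.C.shape}")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A (self-decay) must be strictly negative")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]


#: classical balloon-model constants; k1/k3 follow the 1.5 T convention
#: k1 = 7*rho, k2 = 2, k3 = 2*rho - 0.2.
_RHO = 0.32
_HEMO_DEFAULTS = dict(
    kappa=0.64, gamma=0.32, tau=2.0, alpha=0.32, rho=_RHO,
    V0=0.04, k1=7.0 * _RHO, k2=2.0, k3=2.0 * _RHO - 0.2,
)


@dataclass
class HemodynamicParams:
    """Balloon-model constants, scalar or one value per region.

    kappa: vasodilatory signal decay rate (1/s); gamma: autoregulatory
    feedback rate (1/s); tau: mean transit time (s); alpha: vessel
    stiffness exponent; rho: resting oxygen extraction fraction; V0:
    resting venous volume fraction; k1..k3: BOLD readout coefficients.
    """

    kappa: float | np.ndarray = _HEMO_DEFAULTS["kappa"]
    gamma: float | np.ndarray = _HEMO_DEFAULTS["gamma"]
    tau: float | np.ndarray = _HEMO_DEFAULTS["tau"]
    alpha: float | np.ndarray = _HEMO_DEFAULTS["alpha"]
    rho: float | np.ndarray = _HEMO_DEFAULTS["rho"]
    V0: float | np.ndarray = _HEMO_DEFAULTS["V0"]
    k1: float | np.ndarray = _HEMO_DEFAULTS["k1"]
    k2: float | np.ndarray = _HEMO_DEFAULTS["k2"]
    k3: float | np.ndarray = _HEMO_DEFAULTS["k3"]

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "V0"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in ("alpha", "rho"):
            val = np.asarray(getattr(self, name))
            if np.any(val <= 0) or np.any(val >= 1):
                raise ValueError(f"{name} must lie strictly between 0 and 1")

    def broadcast(self, n_regions: int) -> dict[str, np.ndarray]:
        """Per-region (n,) float arrays for every constant."""
        out = {}
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "V0", "k1", "k2", "k3"):
            out[name] = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (n_regions,)
            ).copy()
        return out


@dataclass
class NeuralHemoState:
    """Latent state of the coupled system, one entry per region.

    At rest (z = s = 0, f = v = q = 1) all derivatives vanish.
    """

    z: np.ndarray
    s: np.ndarray
    f: np.ndarray
    v: np.ndarray
    q: np.ndarray

    @classmethod
    def rest(cls, n_regions: int) -> "NeuralHemoState":
        return cls(
            z=np.zeros(n_regions), s=np.zeros(n_regions),
            f=np.ones(n_regions), v=np.ones(n_regions), q=np.ones(n_regions),
        )


def neuronal_drift(
    z: np.ndarray, u: np.ndarray, params: ConnectivityParams
) -> np.ndarray:
    """dz/dt = (A + sum_j u_j B_j) z + C u."""
    z = np.asarray(z, dtype=float)
    u = np.asarray(u, dtype=float)
    if z.shape != (params.n_regions,):
        raise ValueError(
            f"z has shape {z.shape}; expected ({params.n_regions},) to match A"
        )
    if u.shape != (params.n_inputs,):
        raise ValueError(
            f"u has shape {u.shape}; expected ({params.n_inputs},) to match C"
        )
    A_eff = params.A + np.tensordot(u, params.B, axes=1)
    return A_eff @ z + params.C @ u


def hemodynamic_drift(
    state: NeuralHemoState, h: HemodynamicParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Balloon-model derivatives (ds, df, dv, dq) for each region."""
    z, s, f, v, q = (np.asarray(x, dtype=float) for x in
                     (state.z, state.s, state.f, state.v, state.q))
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError(
            "f, v and q must stay positive (integration step too large?)"
        )
    hb = h.broadcast(z.shape[0])
    ds = z - hb["kappa"] * s - hb["gamma"] * (f - 1.0)
    df = s
    fv = v ** (1.0 / hb["alpha"])
    dv = (f - fv) / hb["tau"]
    E = 1.0 - (1.0 - hb["rho"]) ** (1.0 / f)
    dq = (f * E / hb["rho"] - fv * q / v) / hb["tau"]
    return ds, df, dv, dq


def bold_observation(
    v: np.ndarray, q: np.ndarray, h: HemodynamicParams
) -> np.ndarray:
    """BOLD signal change as a fraction of baseline."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be positive")
    hb = h.broadcast(v.shape[0] if v.ndim else 1)
    return hb["V0"] * (
        hb["k1"] * (1.0 - q) + hb["k2"] * (1.0 - q / v) + hb["k3"] * (1.0 - v)
    )


def assert_stable(A: np.ndarray) -> None:
    """Raise if the intrinsic coupling matrix is not strictly stable."""
    lmax = np.max(np.real(np.linalg.eigvals(np.asarray(A, dtype=float))))
    if lmax >= 0:
        raise ValueError(
            f"intrinsic coupling A is unstable (max Re eigenvalue {lmax:.4f} >= 0)"
        )


# ---------------------------------------------------------------------------
# batched fixed-step RK4 integrator (the inversion's inner loop)
# ---------------------------------------------------------------------------

def _simulate_batch_numpy(A, B, C, u, hk, hg, ht, ha, hr, steps_per_scan, dt,
                          z_bound):
    """Vectorized reference integrator.

    A: (nb, n, n); B: (nb, m, n, n); C: (nb, n, m); u: (n_scans, m);
    hemodynamic arrays (nb, n).  Returns (v, q) sampled per scan as
    (nb, n_scans, n) arrays and a per-batch divergence time (-1 = ok).
    """
    nb, n = A.shape[0], A.shape[1]
    n_scans, m = u.shape
    vs = np.empty((nb, n_scans, n))
    qs = np.empty((nb, n_scans, n))
    div = np.full(nb, -1.0)
    alive = np.ones(nb, dtype=bool)

    z = np.zeros((nb, n)); s = np.zeros((nb, n))
    f = np.ones((nb, n)); v = np.ones((nb, n)); q = np.ones((nb, n))
    inv_alpha = 1.0 / ha
    one_minus_rho = 1.0 - hr

    def drift(z, s, f, v, q, uvec):
        Aeff = A + np.tensordot(B, uvec, axes=([1], [0])) if m else A
        dz = np.einsum("bij,bj->bi", Aeff, z) + C @ uvec
        ds = z - hk * s - hg * (f - 1.0)
        df = s
        fc = np.maximum(f, 1e-8)
        vc = np.maximum(v, 1e-8)
        fv = vc ** inv_alpha
        dv = (f - fv) / ht
        E = 1.0 - one_minus_rho ** (1.0 / fc)
        dq = (f * E / hr - fv * q / vc) / ht
        return dz, ds, df, dv, dq

    for sc in range(n_scans):
        vs[:, sc, :] = v
        qs[:, sc, :] = q
        if sc == n_scans - 1:
            break
        uvec = u[sc]
        for st in range(steps_per_scan):
            k1 = drift(z, s, f, v, q, uvec)
            k2 = drift(z + 0.5 * dt * k1[0], s + 0.5 * dt * k1[1],
                       f + 0.5 * dt * k1[2], v + 0.5 * dt * k1[3],
                       q + 0.5 * dt * k1[4], uvec)
            k3 = drift(z + 0.5 * dt * k2[0], s + 0.5 * dt * k2[1],
                       f + 0.5 * dt * k2[2], v + 0.5 * dt * k2[3],
                       q + 0.5 * dt * k2[4], uvec)
            k4 = drift(z + dt * k3[0], s + dt * k3[1], f + dt * k3[2],
                       v + dt * k3[3], q + dt * k3[4], uvec)
            c = dt / 6.0
            z = z + c * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            s = s + c * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            f = f + c * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            v = v + c * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            q = q + c * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
            bad = alive & (
                (np.abs(z).max(axis=1) > z_bound)
                | (f.min(axis=1) <= 0) | (v.min(axis=1) <= 0)
                | (q.min(axis=1) <= 0) | ~np.isfinite(z).all(axis=1)
            )
            if np.any(bad):
                t_now = (sc * steps_per_scan + st + 1) * dt
                div[bad] = t_now
                alive &= ~bad
                # freeze diverged members at rest to keep arrays finite
                z[bad] = 0.0; s[bad] = 0.0
                f[bad] = 1.0; v[bad] = 1.0; q[bad] = 1.0
    return vs, qs, div


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True)
    def _simulate_batch_numba(A, B, C, u, hk, hg, ht, ha, hr, steps_per_scan,
                              dt, z_bound):
        nb, n = A.shape[0], A.shape[1]
        n_scans, m = u.shape
        vs = np.empty((nb, n_scans, n))
        qs = np.empty((nb, n_scans, n))
        div = -np.ones(nb)
        zb = np.zeros(n); sb = np.zeros(n)
        fb = np.zeros(n); vb = np.zeros(n); qb = np.zeros(n)
        dz = np.zeros((4, n)); dss = np.zeros((4, n)); dff = np.zeros((4, n))
        dvv = np.zeros((4, n)); dqq = np.zeros((4, n))
        tz = np.zeros(n); ts = np.zeros(n); tf = np.zeros(n)
        tv = np.zeros(n); tq = np.zeros(n)
        for b in range(nb):
            for i in range(n):
                zb[i] = 0.0; sb[i] = 0.0; fb[i] = 1.0; vb[i] = 1.0; qb[i] = 1.0
            dead = False
            for sc in range(n_scans):
                for i in range(n):
                    vs[b, sc, i] = vb[i]
                    qs[b, sc, i] = qb[i]
                if sc == n_scans - 1 or dead:
                    continue
                for st in range(steps_per_scan):
                    for k in range(4):
                        if k == 0:
                            h = 0.0
                        elif k == 3:
                            h = dt
                        else:
                            h = 0.5 * dt
                        src = 0 if k == 0 else k - 1
                        for i in range(n):
                            if k == 0:
                                tz[i] = zb[i]; ts[i] = sb[i]; tf[i] = fb[i]
                                tv[i] = vb[i]; tq[i] = qb[i]
                            else:
                                tz[i] = zb[i] + h * dz[src, i]
                                ts[i] = sb[i] + h * dss[src, i]
                                tf[i] = fb[i] + h * dff[src, i]
                                tv[i] = vb[i] + h * dvv[src, i]
                                tq[i] = qb[i] + h * dqq[src, i]
                        for i in range(n):
                            acc = 0.0
                            for j in range(n):
                                aij = A[b, i, j]
                                for c in range(m):
                                    aij += u[sc, c] * B[b, c, i, j]
                                acc += aij * tz[j]
                            for c in range(m):
                                acc += C[b, i, c] * u[sc, c]
                            dz[k, i] = acc
                            dss[k, i] = (tz[i] - hk[b, i] * ts[i]
                                         - hg[b, i] * (tf[i] - 1.0))
                            dff[k, i] = ts[i]
                            fc = tf[i] if tf[i] > 1e-8 else 1e-8
                            vc = tv[i] if tv[i] > 1e-8 else 1e-8
                            fv = vc ** (1.0 / ha[b, i])
                            dvv[k, i] = (tf[i] - fv) / ht[b, i]
                            E = 1.0 - (1.0 - hr[b, i]) ** (1.0 / fc)
                            dqq[k, i] = (tf[i] * E / hr[b, i]
                                         - fv * tq[i] / vc) / ht[b, i]
                    c6 = dt / 6.0
                    bad = False
                    for i in range(n):
                        zb[i] += c6 * (dz[0, i] + 2 * dz[1, i]
                                       + 2 * dz[2, i] + dz[3, i])
                        sb[i] += c6 * (dss[0, i] + 2 * dss[1, i]
                                       + 2 * dss[2, i] + dss[3, i])
                        fb[i] += c6 * (dff[0, i] + 2 * dff[1, i]
                                       + 2 * dff[2, i] + dff[3, i])
                        vb[i] += c6 * (dvv[0, i] + 2 * dvv[1, i]
                                       + 2 * dvv[2, i] + dvv[3, i])
                        qb[i] += c6 * (dqq[0, i] + 2 * dqq[1, i]
                                       + 2 * dqq[2, i] + dqq[3, i])
                        if (abs(zb[i]) > z_bound or fb[i] <= 0.0
                                or vb[i] <= 0.0 or qb[i] <= 0.0
                                or not np.isfinite(zb[i])):
                            bad = True
                    if bad:
                        div[b] = (sc * steps_per_scan + st + 1) * dt
                        dead = True
                        for i in range(n):
                            zb[i] = 0.0; sb[i] = 0.0
                            fb[i] = 1.0; vb[i] = 1.0; qb[i] = 1.0
                        break
        return vs, qs, div

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _simulate_batch(A, B, C, u, hemo_arrays, steps_per_scan, dt, z_bound,
                    use_numba: bool | None = None):
    """Integrate a batch of parameter sets; returns (v, q, div_time)."""
    nb, n = A.shape[0], A.shape[1]
    hk, hg, ht, ha, hr = (
        np.broadcast_to(hemo_arrays[k], (nb, n)).copy()
        for k in ("kappa", "gamma", "tau", "alpha", "rho")
    )
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    fn = _simulate_batch_numba if (use_numba and _HAVE_NUMBA) else _simulate_batch_numpy
    return fn(
        np.ascontiguousarray(A, dtype=float),
        np.ascontiguousarray(B, dtype=float),
        np.ascontiguousarray(C, dtype=float),
        np.ascontiguousarray(u, dtype=float),
        hk, hg, ht, ha, hr, steps_per_scan, float(dt), float(z_bound),
    )


def simulate_batch_bold(A, B, C, design: ExperimentDesign,
                        h: HemodynamicParams, dt: float | None = None,
                        z_bound: float = 10.0,
                        use_numba: bool | None = None):
    """Batched noiseless BOLD (fraction of baseline), (nb, n_scans, n).

    Returns ``(y, div_time)`` where ``div_time[b] >= 0`` flags a batch
    member whose neuronal activity left the stability bound (its output
    is frozen at rest from that time on).
    """
    if dt is None:
        dt = design.TR / 8.0
    steps = int(round(design.TR / dt))
    if steps < 1 or abs(steps * dt - design.TR) > 1e-9:
        raise ValueError(f"dt = {dt} must divide TR = {design.TR}")
    n = A.shape[1]
    hb = h.broadcast(n)
    vs, qs, div = _simulate_batch(A, B, C, design.u, hb, steps, dt, z_bound,
                                  use_numba)
    V0, k1, k2, k3 = hb["V0"], hb["k1"], hb["k2"], hb["k3"]
    y = V0 * (k1 * (1.0 - qs) + k2 * (1.0 - qs / vs) + k3 * (1.0 - vs))
    return y, div


def simulate_timeseries(
    params: ConnectivityParams,
    h: HemodynamicParams,
    design: ExperimentDesign,
    dt: float | None = None,
    z_bound: float = 10.0,
    check_stability: bool = True,
) -> ROITimeSeries:
    """Integrate the coupled system from rest and sample BOLD at each TR.

    Output is in percent of baseline signal.  Raises
    :class:`SimulationDiverged` if |z| exceeds ``z_bound``.
    """
    if design.n_inputs != params.n_inputs:
        raise ValueError(
            f"design has {design.n_inputs} input channels, model expects "
            f"{params.n_inputs}"
        )
    if check_stability:
        assert_stable(params.A)
    y, div = simulate_batch_bold(
        params.A[None], params.B[None], params.C[None], design, h, dt, z_bound
    )
    if div[0] >= 0:
        raise SimulationDiverged(float(div[0]), z_bound)
    return ROITimeSeries(
        values=100.0 * y[0],
        TR=design.TR,
        region_labels=params.region_labels,
    )
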