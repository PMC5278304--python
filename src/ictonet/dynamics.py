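"""Bistable stochastic node dynamics on a patient network.

Each network node *k* carries a complex state ``z_k`` obeying

    dz_k/dt = (a|z_k|^4 + b|z_k|^2 + lambda + i*omega) z_k
              + beta * coupling_k(z)  +  eta(t)

with ``a < 0 < b`` and ``lambda`` in the bistable window, so the
deterministic node has a stable rest state at the origin and a stable high
amplitude limit cycle (the seizure state), separated by an unstable limit
cycle (the separatrix).  Complex white noise ``eta`` drives occasional
transitions across the separatrix; the coupling term lets connected nodes
pull each other over.

Two readings of the coupling term are supported: ``input_sum`` couples node
*k* to its neighbours' states (``sum_j C[k,j] z_j``, the convention of the
precursor bistable-network models) while ``self_strength`` multiplies the
node's own state by its connectivity strength (``sum_j C[k,j] z_k``).

Integration is fixed-step Euler-Maruyama with step ``dt``; an ensemble
run shares a single noise stream keyed only by ``(seed, M, N)``, so two
ensembles with the same seed on two different connectivity matrices of the
same size see identical noise - common random numbers across virtual
resections for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import FunctionalConnectivity

__all__ = [
    "ModelParams",
    "BasinGeometry",
    "Trajectory",
    "EscapeTimeEnsemble",
    "NotBistableError",
    "basin_geometry",
    "simulate",
    "escape_times_one_realization",
    "escape_time_ensemble",
]

_NOISE_BLOCK = 1024  # steps of noise drawn per RNG call; part of the noise schedule


class NotBistableError(ValueError):
    """Raised when (a, b, lambda) do not admit rest state + stable limit cycle."""


@dataclass
class ModelParams:
    """Constants of the node model and its integrator.

    a, b : real coefficients of the quintic radial nonlinearity (a<0, b>0).
    lam : bistability parameter; the node is bistable for
        -b^2/(4|a|) <= lam < 0 at the default (a, b).
    omega : angular frequency of the intrinsic oscillation, rad per model
        time unit.  Must stay well below 1/dt for the explicit integrator.
    beta : coupling scale multiplying the connectivity matrix.
    noise_mean : complex mean of the noise process (constant drift).
    noise_sd : per-component SD of the noise process; the Euler-Maruyama
        increment is ``noise_mean*dt + noise_sd*sqrt(dt)*(xi1 + i*xi2)``.
    dt : integrator step, model time units.
    coupling_mode : 'input_sum' (neighbour states) or 'self_strength'
        (own state times node strength).
    """

    a: float = -1.0
    b: float = 2.0
    lam: float = -0.75
    omega: float = 2.0
    beta: float = 0.22
    noise_mean: complex = 0.0003 + 0.0j
    noise_sd: float = 0.05
    dt: float = 0.05
    coupling_mode: str = "input_sum"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.coupling_mode not in ("input_sum", "self_strength"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")


@dataclass
class BasinGeometry:
    """Radii of the three nested invariant circles of the deterministic node."""

    r_rest: float
    r_sep: float
    r_lc: float


@dataclass
class Trajectory:
    """Single noise realization of the network; ``z`` is nodes x steps."""

    z: np.ndarray
    t: np.ndarray
    seed: int | None
    params: ModelParams = field(repr=False, default=None)


@dataclass
class EscapeTimeEnsemble:
    """Escape times over M noise realizations; ``tau`` is nodes x M."""

    tau: np.ndarray
    censored: np.ndarray
    t_max: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.tau.shape != self.censored.shape or self.tau.ndim != 2:
            raise ValueError("tau and censored must be matching 2-D arrays")
        if self.tau.size and (self.tau.min() <= 0 or self.tau.max() > self.t_max):
            raise ValueError("escape times must lie in (0, t_max]")
        if self.tau.size and not np.all(self.tau[self.censored] == self.t_max):
            raise ValueError("censored entries must equal t_max")

    @property
    def n_nodes(self) -> int:
        return self.tau.shape[0]

    @property
    def M(self) -> int:
        return self.tau.shape[1]


def basin_geometry(params: ModelParams) -> BasinGeometry:
    """Radii of the separatrix and stable limit cycle.

    Radial reduction of the node equation: dr/dt = r (a r^4 + b r^2 + lam).
    In x = r^2 the nontrivial circles solve a x^2 + b x + lam = 0; with
    a < 0 < b and lam < 0 both roots are positive, the smaller being the
    (unstable) separatrix and the larger the stable limit cycle.
    """
    a, b, lam = params.a, params.b, params.lam
    disc = b * b - 4.0 * a * lam
    if a >= 0 or b <= 0 or lam >= 0 or disc < 0:
        raise NotBistableError(
            f"(a={a}, b={b}, lam={lam}) is not bistable: need a<0, b>0, "
            f"lam<0 and b^2-4*a*lam>=0 (got discriminant {disc:g})"
        )
    sq = np.sqrt(disc)
    roots = sorted(((-b + sq) / (2 * a), (-b - sq) / (2 * a)))
    x_sep, x_lc = roots
    if x_sep < 0:
        raise NotBistableError("no positive separatrix radius; not bistable")
    return BasinGeometry(r_rest=0.0, r_sep=float(np.sqrt(x_sep)),
                         r_lc=float(np.sqrt(x_lc)))


def _as_matrix(C) -> np.ndarray:
    if isinstance(C, FunctionalConnectivity):
        return C.C
    return np.asarray(C, dtype=float)


def _step_factors(params: ModelParams):
    dt = params.dt
    rot = 1.0 + 1j * params.omega * dt
    mdt = complex(params.noise_mean) * dt
    sig = params.noise_sd * np.sqrt(dt)
    return dt, rot, mdt, sig


def _coupling_matvec(z: np.ndarray, Cs: np.ndarray, mode: str) -> np.ndarray:
    """Coupling term for state block ``z`` of shape (M, N)."""
    if mode == "input_sum":
        return z @ Cs          # Cs = dt*beta*C.T; node k gets sum_j C[k,j] z_j
    return z * Cs              # Cs = dt*beta*row-strengths; z_k * sum_j C[k,j]


def _prepare_coupling(C: np.ndarray, params: ModelParams):
    if params.coupling_mode == "input_sum":
        return np.ascontiguousarray(params.dt * params.beta * C.T)
    return params.dt * params.beta * C.sum(axis=1)


def simulate(
    C,
    params: ModelParams,
    z0: np.ndarray,
    T: float,
    seed: int | None = None,
) -> Trajectory:
    """Integrate one noise realization, storing the full trajectory.

    Deterministic given ``(C, params, z0, seed)``.  Raises on numerical
    overflow, naming the first non-finite step.
    """
    Cm = _as_matrix(C)
    z0 = np.asarray(z0, dtype=complex)
    if Cm.shape[0] != Cm.shape[1] or Cm.shape[0] != z0.shape[0]:
        raise ValueError("C must be square and match z0 length")
    if T < params.dt:
        raise ValueError("T must be at least one step dt")
    dt, rot, mdt, sig = _step_factors(params)
    a, b, lam = params.a, params.b, params.lam
    Cs = _prepare_coupling(Cm, params)
    nsteps = int(round(T / dt))
    N = z0.shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty((N, nsteps + 1), dtype=complex)
    out[:, 0] = z0
    z = z0[None, :].copy()
    step = 0
    with np.errstate(over="ignore", invalid="ignore"):
        while step < nsteps:
            nb = min(_NOISE_BLOCK, nsteps - step)
            noise = rng.standard_normal((nb, 1, N, 2))
            cplx = noise.view(complex)[..., 0]
            for i in range(nb):
                az = z.real**2 + z.imag**2
                g = (a * az + b) * az + lam
                z = z * (rot + dt * g) \
                    + _coupling_matvec(z, Cs, params.coupling_mode) \
                    + (mdt + sig * cplx[i])
                step += 1
                if not np.all(np.isfinite(z)):
                    raise FloatingPointError(
                        f"non-finite state at step {step} (t={step * dt:g}); "
                        "reduce dt or omega"
                    )
                out[:, step] = z[0]
    t = np.arange(nsteps + 1) * dt
    return Trajectory(z=out, t=t, seed=seed, params=params)


def escape_times_one_realization(
    traj: Trajectory,
    geom: BasinGeometry,
    t_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First grid time each node's modulus reaches the separatrix radius.

    Returns ``(tau, censored)``; nodes that never cross within ``t_max``
    get ``tau = t_max`` with ``censored`` set.
    """
    r = np.abs(traj.z)
    if np.any(r[:, 0] >= geom.r_sep):
        bad = np.flatnonzero(r[:, 0] >= geom.r_sep)
        raise ValueError(f"nodes {bad.tolist()} start outside the resting basin")
    if t_max is None:
        t_max = float(traj.t[-1])
    inside = traj.t <= t_max
    crossed = r[:, inside] >= geom.r_sep
    first = crossed.argmax(axis=1)
    hit = crossed.any(axis=1)
    tau = np.where(hit, traj.t[first], t_max)
    # argmax returns 0 when never crossed; column 0 is pre-checked inside
    return tau.astype(float), ~hit


def escape_time_ensemble(
    C,
    params: ModelParams,
    M: int,
    t_max: float = 4000.0,
    seed: int | None = None,
    labels: list[str] | None = None,
) -> EscapeTimeEnsemble:
    """Escape times of every node over ``M`` independent noise realizations.

    All nodes start at the rest state z=0.  Integration stops early once
    every node in every realization has escaped.  The noise stream depends
    only on ``(seed, M, N)`` and the fixed block schedule - not on ``C`` -
    which makes runs with the same seed on ablated variants of the same
    network common-random-number paired.
    """
    Cm = _as_matrix(C)
    if isinstance(C, FunctionalConnectivity) and labels is None:
        labels = list(C.labels)
    N = Cm.shape[0]
    if M < 1:
        raise ValueError("M must be at least 1")
    if t_max < params.dt:
        raise ValueError("t_max must be at least one step dt")
    geom = basin_geometry(params)
    rsep2 = geom.r_sep**2
    dt, rot, mdt, sig = _step_factors(params)
    a, b, lam = params.a, params.b, params.lam
    Cs = _prepare_coupling(Cm, params)
    mode = params.coupling_mode
    nsteps = int(round(t_max / dt))
    rng = np.random.default_rng(seed)

    z = np.zeros((M, N), dtype=complex)
    tau = np.full((M, N), float(t_max))
    esc = np.zeros((M, N), dtype=bool)
    step = 0
    buf = np.empty((_NOISE_BLOCK, M, N, 2))
    with np.errstate(over="ignore", invalid="ignore"):
        while step < nsteps and not esc.all():
            nb = min(_NOISE_BLOCK, nsteps - step)
            rng.standard_normal(out=buf)      # fixed schedule, even on tail blocks
            cplx = buf.view(complex)[..., 0]
            for i in range(nb):
                az = z.real**2 + z.imag**2
                g = (a * az + b) * az + lam
                z = z * (rot + dt * g) + _coupling_matvec(z, Cs, mode) \
                    + (mdt + sig * cplx[i])
                step += 1
                az = z.real**2 + z.imag**2
                s = az.sum()
                if not np.isfinite(s):
                    raise FloatingPointError(
                        f"non-finite state at step {step} (t={step * dt:g}); "
                        "reduce dt or omega"
                    )
                new = az >= rsep2
                new &= ~esc
                if new.any():
                    tau[new] = step * dt
                    esc[new] = True
                    if esc.all():
                        break
    return EscapeTimeEnsemble(tau=tau.T.copy(), censored=(~esc).T.copy(),
                              t_max=float(t_max), labels=labels)
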