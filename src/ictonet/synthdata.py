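"""Synthetic recordings, networks and cohorts with known ground truth.

Real interictal ECoG with surgical follow-up cannot ship with the package,
so every pipeline stage is exercised on synthetic data instead:

* ``gen_correlated_recording`` - band-limited Gaussian multichannel signals
  with a prescribed population correlation matrix (Cholesky-style mixing of
  independently filtered noise), the fixture for connectivity estimation.
* ``gen_planted_network`` - a weighted connectivity matrix with a planted
  hyperconnected "focus" community.  Epileptogenicity is induced purely
  through connectivity (the focus block has the dominant coupling
  eigenmode, hence the highest node strength and clustering), mirroring
  the graph-metric correlates of simulated seizure likelihood; no per-node
  parameter heterogeneity is planted by default.
* ``gen_cohort`` - a cohort of planted-focus patients, half of whom
  received a resection covering the focus (ground-truth good outcome) and
  half a size-matched resection that missed it (poor outcome).

Default weights (w_ff=0.9, w_fb=0.05, w_bb=0.08) put the focus community's
coupling eigenmode well above the background's, so with the default model
parameters focus nodes escape at O(10) time units, background nodes at
O(100), and a focus-resected network stays in the resting state for the
whole simulated horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .connectivity import FunctionalConnectivity, Recording
from .dynamics import ModelParams

__all__ = [
    "PlantedNetworkSpec",
    "SyntheticCohortSpec",
    "SyntheticPatient",
    "gen_correlated_recording",
    "gen_planted_network",
    "gen_cohort",
]


@dataclass
class PlantedNetworkSpec:
    """Planted-focus weighted network.

    N nodes, of which ``focus`` form a hyperconnected community: weights
    are w_ff within the focus, w_fb between focus and background and w_bb
    within the background, each perturbed by multiplicative uniform jitter
    of relative amplitude ``jitter`` and clipped to [0, 1].
    """

    N: int = 20
    focus: tuple[int, ...] = (0, 1, 2, 3)
    w_ff: float = 0.9
    w_fb: float = 0.05
    w_bb: float = 0.08
    jitter: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least 2 nodes to form a network")
        if not self.focus or not all(0 <= f < self.N for f in self.focus):
            raise ValueError("focus must be a nonempty subset of range(N)")
        for w in (self.w_ff, self.w_fb, self.w_bb):
            if not 0 <= w <= 1:
                raise ValueError("weights must lie in [0, 1]")
        if self.w_ff <= self.w_bb:
            raise ValueError("focus must be hyperconnected: w_ff > w_bb")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter must lie in [0, 1)")


def gen_planted_network(spec: PlantedNetworkSpec
                        ) -> tuple[FunctionalConnectivity, np.ndarray]:
    """Symmetric rectified zero-diagonal matrix with a planted focus block.

    Returns the connectivity and the ground-truth focus indices.
    """
    rng = np.random.default_rng(spec.seed)
    focus = np.asarray(sorted(set(spec.focus)), dtype=int)
    is_f = np.isin(np.arange(spec.N), focus)
    W = np.full((spec.N, spec.N), spec.w_bb)
    W[is_f, :] = spec.w_fb
    W[:, is_f] = spec.w_fb
    W[np.ix_(is_f, is_f)] = spec.w_ff
    if spec.jitter > 0:
        j = rng.uniform(-spec.jitter, spec.jitter, size=W.shape)
        j = (j + j.T) / 2.0
        W = W * (1.0 + j)
    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return FunctionalConnectivity(C=W), focus


def gen_correlated_recording(
    R: np.ndarray,
    fs: float = 500.0,
    duration: float = 600.0,
    band: tuple[float, float] = (1.0, 70.0),
    seed: int | None = None,
) -> Recording:
    """Band-limited Gaussian channels with population correlation ``R``.

    Independent white-noise channels are band-pass filtered, standardized
    to unit variance and mixed through a symmetric square root of ``R``,
    which preserves the band limit while imposing the target correlation.
    ``R`` must be symmetric positive semidefinite with unit diagonal
    (rank-deficient R, e.g. duplicated channels, is allowed).
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("R must have unit diagonal")
    w, V = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise ValueError(f"R is not positive semidefinite (min eig {w.min():.3g})")
    L = V * np.sqrt(np.clip(w, 0.0, None))
    n = R.shape[0]
    n_samp = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n, n_samp))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return Recording(samples=L @ x, fs=fs)


@dataclass
class SyntheticPatient:
    patient_id: str
    C: FunctionalConnectivity
    focus: np.ndarray
    resected: np.ndarray
    outcome: str                      # ground truth: good iff resected >= focus


@dataclass
class SyntheticCohortSpec:
    """Cohort of planted-focus patients with known resection quality.

    ``frac_covering`` of the patients get a resection containing the whole
    focus (padded with random background nodes up to ``resection_size``)
    and are labelled good; the rest get a size-matched resection drawn
    from the background only (a surgery that missed the epileptogenic
    zone) and are labelled poor.  Simulation sizes (``M``, ``t_max``,
    ``n_rand``) are the desk-scale defaults used by the package's own
    studies.
    """

    n_patients: int = 20
    frac_covering: float = 0.5
    resection_size: int = 4
    network: PlantedNetworkSpec = field(default_factory=PlantedNetworkSpec)
    params: ModelParams = field(default_factory=ModelParams)
    M: int = 200
    t_max: float = 300.0
    n_rand: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.frac_covering <= 1:
            raise ValueError("frac_covering must lie in [0, 1]")
        if self.resection_size > self.network.N:
            raise ValueError("resection size exceeds network size")
        if self.resection_size < len(set(self.network.focus)):
            raise ValueError(
                "resection_size smaller than the focus: no covering "
                "resection is possible")


def gen_cohort(spec: SyntheticCohortSpec) -> list[SyntheticPatient]:
    """Reproducible planted-focus cohort with ground-truth outcome labels."""
    rng = np.random.default_rng(spec.seed)
    n_cov = int(round(spec.frac_covering * spec.n_patients))
    patients = []
    for i in range(spec.n_patients):
        net_spec = PlantedNetworkSpec(
            **{**spec.network.__dict__,
               "seed": int(rng.integers(2**31))})
        C, focus = gen_planted_network(net_spec)
        background = np.setdiff1d(np.arange(net_spec.N), focus)
        if i < n_cov:
            pad = rng.choice(background, size=spec.resection_size - focus.size,
                             replace=False)
            resected = np.sort(np.concatenate([focus, pad]))
            outcome = "good"
        else:
            resected = np.sort(rng.choice(background, size=spec.resection_size,
                                          replace=False))
            outcome = "poor"
        patients.append(SyntheticPatient(
            patient_id=f"S{i + 1:02d}", C=C, focus=focus,
            resected=resected, outcome=outcome))
    return patients
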