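"""Synthetic multi-ROI cohorts from block-structured VAR(1) processes.

The study's fMRI data are not deposited, so validation runs on simulated
cohorts with known directed structure. A cohort is generated from a lag-1
vector autoregression

    x_t = A x_{t-1} + e_t,        e_t ~ N(0, noise_sd^2 I)

whose coefficient matrix ``A`` (``A[j, i]`` = influence of ROI i at t-1 on
ROI j at t) carries the planted truth:

* ``null``     - self-decay only (no directed edges anywhere);
* ``control``  - denser directed coupling within each subsystem plus a sparse
  set of between-subsystem edges (every ordered subsystem pair receives at
  least a couple of planted edges so that every inter-system statistic has
  signal);
* ``ad``       - the control matrix with every coupling incident to a
  default-network ROI (MTL, DM or Core) multiplicatively attenuated,
  mirroring the disease contrast of interest as a one-parameter effect size.

``A`` is rescaled so the spectral radius of |A| stays <= 0.9 (guaranteed
stationarity, with margin for envelope modulation). Slow co-evolution
scenarios multiply selected couplings by a low-frequency gain envelope
(0.005 Hz sinusoid plus smoothed noise, clipped to [0.2, 1.8]) that is either
shared between two edge sets or drawn independently.

Defaults mirror the study's stated conditions: 27 NC + 24 AD subjects,
52 ROIs, 190 timepoints at TR = 2 s. No hemodynamic convolution is applied:
the analysis operates directly on (filtered) series, and a forward model
would only blur parameter-recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import UnstableCouplingError
from .types import DN_NETWORKS, NetworkPartition, SubjectRecord


@dataclass(frozen=True)
class SimulationParams:
    """Stated world of the generator (see module docstring)."""

    self_coupling: float = 0.4
    within_density: float = 0.15
    within_strength: float = 0.4
    between_density: float = 0.08
    between_strength: float = 0.4
    min_between_edges: int = 2
    ad_attenuation: float = 0.5
    noise_sd: float = 1.0
    max_spectral_radius: float = 0.9


@dataclass(frozen=True)
class CouplingSpec:
    """A lag-1 coupling matrix with its innovation scale and scenario label."""

    A: np.ndarray
    noise_sd: float
    label: str

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        rho = spectral_radius(A)
        if not rho < 1.0:
            raise UnstableCouplingError(f"spectral radius {rho:.3f} >= 1 (non-stationary)")
        diag = np.diag(A)
        if np.any(diag < 0) or np.any(diag > 0.95):
            raise UnstableCouplingError("self-decay entries must lie in [0, 0.95]")

    @property
    def n_rois(self) -> int:
        return self.A.shape[0]

    def planted_edges(self) -> list[tuple[int, int]]:
        """Ordered (src, tgt) index pairs with a nonzero off-diagonal coupling."""
        tgt, src = np.nonzero(self.A - np.diag(np.diag(self.A)))
        return list(zip(src.tolist(), tgt.tolist()))


@dataclass(frozen=True)
class ModulationSpec:
    """Time-varying gains applied to sets of directed couplings.

    ``targets[s]`` is a list of (src, tgt) ROI index pairs whose couplings are
    multiplied by ``envelopes[s, t]`` at timepoint t. ``shared`` records
    whether all sets ride the same envelope.
    """

    targets: tuple[tuple[tuple[int, int], ...], ...]
    envelopes: np.ndarray
    shared: bool

    def __post_init__(self) -> None:
        env = np.atleast_2d(np.asarray(self.envelopes, dtype=float))
        if env.shape[0] != len(self.targets):
            raise ValueError("one envelope row per target set required")
        if np.any(env < 0.2 - 1e-12) or np.any(env > 1.8 + 1e-12):
            raise ValueError("envelope gains must lie in [0.2, 1.8]")
        object.__setattr__(self, "envelopes", env)
        object.__setattr__(
            self, "targets", tuple(tuple((int(s), int(t)) for s, t in ts) for ts in self.targets)
        )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def make_envelope(
    T: int,
    tr_seconds: float = 2.0,
    seed=0,
    freq_hz: float = 0.005,
    noise_weight: float = 0.25,
    depth: float = 0.55,
) -> np.ndarray:
    """Low-frequency gain series in [0.2, 1.8] (sinusoid + smoothed noise)."""
    rng = _rng(seed)
    t = np.arange(T) * tr_seconds
    phase = rng.uniform(0.0, 2.0 * np.pi)
    base = 1.0 + depth * np.sin(2.0 * np.pi * freq_hz * t + phase)
    # Gaussian smoothing with sigma ~25 s keeps the noise power below 0.02 Hz.
    raw = rng.normal(size=T)
    smooth = gaussian_filter1d(raw, sigma=max(25.0 / tr_seconds, 1.0), mode="reflect")
    sd = smooth.std()
    if sd > 0:
        base = base + noise_weight * smooth / sd
    return np.clip(base, 0.2, 1.8)


def build_coupling(
    partition: NetworkPartition,
    scenario: str,
    params: SimulationParams | None = None,
    seed=0,
) -> CouplingSpec:
    """Construct the scenario coupling matrix (see module docstring).

    ``ad`` at the same seed is exactly the ``control`` matrix with DN-incident
    off-diagonal couplings multiplied by ``params.ad_attenuation``.
    """
    params = params or SimulationParams()
    if scenario not in ("null", "control", "ad"):
        raise ValueError(f"unknown scenario {scenario!r}")
    R = partition.n_rois
    A = np.eye(R) * params.self_coupling
    if scenario == "null":
        return CouplingSpec(A=A, noise_sd=params.noise_sd, label="null")

    rng = _rng(seed)
    nets = partition.networks
    idx = {n: partition.indices_of(n) for n in nets}
    # Within-subsystem edges.
    for net in nets:
        ii = idx[net]
        pairs = [(int(s), int(t)) for s in ii for t in ii if s != t]
        n_edges = int(round(params.within_density * len(pairs)))
        chosen = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
        for c in chosen:
            s, t = pairs[int(c)]
            A[t, s] = params.within_strength * rng.choice((-1.0, 1.0))
    # Between-subsystem edges: every ordered pair of subsystems gets some.
    for src_net in nets:
        for tgt_net in nets:
            if src_net == tgt_net:
                continue
            pairs = [(int(s), int(t)) for s in idx[src_net] for t in idx[tgt_net]]
            n_edges = max(
                params.min_between_edges, int(round(params.between_density * len(pairs)))
            )
            chosen = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
            for c in chosen:
                s, t = pairs[int(c)]
                A[t, s] = params.between_strength * rng.choice((-1.0, 1.0))
    # Stabilise on the magnitude matrix so that attenuation (which shrinks
    # magnitudes) can never push the radius back above the cap.
    rho = spectral_radius(np.abs(A))
    if not np.isfinite(rho):
        raise UnstableCouplingError("coupling request cannot be stabilised")
    if rho > params.max_spectral_radius:
        A *= params.max_spectral_radius / rho

    if scenario == "ad":
        dn_idx = np.concatenate([idx[n] for n in DN_NETWORKS if n in idx])
        dn = np.zeros(R, dtype=bool)
        dn[dn_idx] = True
        incident = dn[:, None] | dn[None, :]
        np.fill_diagonal(incident, False)
        A = np.where(incident, A * params.ad_attenuation, A)
    return CouplingSpec(A=A, noise_sd=params.noise_sd, label=scenario)


def simulate_subject(
    coupling: CouplingSpec,
    T: int,
    tr_seconds: float = 2.0,
    seed=0,
    modulation: ModulationSpec | None = None,
    burn_in: int = 200,
    subject_id: str = "sim",
    group: str = "NC",
) -> SubjectRecord:
    """Simulate one subject; bit-reproducible for a fixed seed.

    A burn-in of ``burn_in`` samples is discarded so the returned series is
    (approximately) drawn from the stationary distribution. With modulation,
    target couplings are scaled per timepoint; the pre-sample stretch uses the
    envelope's first value.
    """
    if T < 30:
        raise ValueError("T must be >= 30")
    A = coupling.A
    R = coupling.n_rois
    if modulation is not None:
        if modulation.envelopes.shape[1] != T:
            raise ValueError("envelope length must equal the simulated timepoints")
        worst = A.copy()
        for s, ts in enumerate(modulation.targets):
            gmax = float(np.max(modulation.envelopes[s]))
            for src, tgt in ts:
                worst[tgt, src] = A[tgt, src] * gmax
        if spectral_radius(np.abs(worst)) >= 1.0:
            raise UnstableCouplingError("modulated coupling is non-stationary at peak gain")
    rng = _rng(seed)
    noise = rng.normal(0.0, coupling.noise_sd, size=(burn_in + T, R))
    out = np.empty((T, R))
    x = np.zeros(R)
    for step in range(burn_in + T):
        t = step - burn_in
        if modulation is None:
            At = A
        else:
            At = A.copy()
            for s, ts in enumerate(modulation.targets):
                gain = modulation.envelopes[s, max(t, 0)]
                for src, tgt in ts:
                    At[tgt, src] = A[tgt, src] * gain
        x = At @ x + noise[step]
        if t >= 0:
            out[t] = x
    return SubjectRecord(subject_id=subject_id, group=group, data=out, tr_seconds=tr_seconds)


def simulate_cohort(
    partition: NetworkPartition,
    n_nc: int = 27,
    n_ad: int = 24,
    T: int = 190,
    tr_seconds: float = 2.0,
    params: SimulationParams | None = None,
    seed=0,
) -> tuple[list[SubjectRecord], dict]:
    """Two-group cohort: NC from the control coupling, AD from the attenuated one.

    Per-subject seeds are spawned deterministically from the master seed.
    Returns the records plus a ground-truth dict (couplings and planted edges).
    """
    params = params or SimulationParams()
    control = build_coupling(partition, "control", params, seed)
    ad = build_coupling(partition, "ad", params, seed)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_nc + n_ad)
    records: list[SubjectRecord] = []
    for i in range(n_nc):
        records.append(
            simulate_subject(
                control, T, tr_seconds, seed=np.random.default_rng(children[i]),
                subject_id=f"NC{i + 1:02d}", group="NC",
            )
        )
    for i in range(n_ad):
        records.append(
            simulate_subject(
                ad, T, tr_seconds, seed=np.random.default_rng(children[n_nc + i]),
                subject_id=f"AD{i + 1:02d}", group="AD",
            )
        )
    truth = {
        "control": control,
        "ad": ad,
        "planted_edges": control.planted_edges(),
        "params": params,
    }
    return records, truth


def block_edges(coupling: CouplingSpec, partition: NetworkPartition, src_net: str, tgt_net: str) -> list[tuple[int, int]]:
    """Planted edges running from one subsystem into another."""
    src_set = set(partition.indices_of(src_net).tolist())
    tgt_set = set(partition.indices_of(tgt_net).tolist())
    return [(s, t) for s, t in coupling.planted_edges() if s in src_set and t in tgt_set]


def simulate_coevolution_cohort(
    partition: NetworkPartition,
    n_nc: int = 27,
    n_ad: int = 24,
    T: int = 600,
    tr_seconds: float = 2.0,
    params: SimulationParams | None = None,
    seed=0,
    pair_a: tuple[str, str] = ("FPCNA", "Core"),
    pair_b: tuple[str, str] = ("Core", "DAN"),
    target_strength: float = 0.3,
) -> tuple[list[SubjectRecord], dict]:
    """Co-evolution scenario: two inter-system edge sets under slow modulation.

    NC subjects share one envelope across both edge sets (their inter-system
    flows wax and wane together); AD subjects get independent envelopes (no
    planted co-evolution). Both groups use the *control* coupling so that the
    contrast isolates the temporal coordination, not static strength. The
    modulated edges are set to ``target_strength`` after the stability rescale
    so that windowed Granger estimates can resolve the envelope above the
    short-window estimation noise; stationarity at peak envelope gain is
    re-verified at simulation time.
    """
    params = params or SimulationParams()
    control = build_coupling(partition, "control", params, seed)
    targets_a = tuple(block_edges(control, partition, *pair_a))
    targets_b = tuple(block_edges(control, partition, *pair_b))
    if not targets_a or not targets_b:
        raise UnstableCouplingError("no planted edges in the requested subsystem pairs")
    A = control.A.copy()
    target_mask = np.zeros_like(A, dtype=bool)
    for src, tgt in (*targets_a, *targets_b):
        A[tgt, src] = np.sign(A[tgt, src]) * target_strength
        target_mask[tgt, src] = True
    # Leave stationarity headroom for the peak envelope gain (1.8x) by
    # shrinking the background (non-target, off-diagonal) couplings.
    def peak_radius(mat: np.ndarray) -> float:
        worst = mat.copy()
        worst[target_mask] *= 1.8
        return spectral_radius(np.abs(worst))

    if peak_radius(A) >= 0.95:
        background = (~target_mask) & (~np.eye(A.shape[0], dtype=bool))
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            trial = A.copy()
            trial[background] *= mid
            if peak_radius(trial) < 0.95:
                lo = mid
            else:
                hi = mid
        A[background] *= lo
        if peak_radius(A) >= 1.0:
            raise UnstableCouplingError("co-evolution scenario cannot be stabilised")
    control = CouplingSpec(A=A, noise_sd=control.noise_sd, label="coevolution")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * (n_nc + n_ad))
    records: list[SubjectRecord] = []
    truth_env: dict[str, np.ndarray] = {}
    for i in range(n_nc + n_ad):
        group = "NC" if i < n_nc else "AD"
        sid = f"{group}{(i if group == 'NC' else i - n_nc) + 1:02d}"
        env_rng = np.random.default_rng(children[2 * i])
        if group == "NC":
            env = make_envelope(T, tr_seconds, seed=env_rng)
            envelopes = np.vstack([env, env])
            shared = True
        else:
            envelopes = np.vstack(
                [make_envelope(T, tr_seconds, seed=env_rng) for _ in range(2)]
            )
            shared = False
        mod = ModulationSpec(targets=(targets_a, targets_b), envelopes=envelopes, shared=shared)
        records.append(
            simulate_subject(
                control, T, tr_seconds, seed=np.random.default_rng(children[2 * i + 1]),
                modulation=mod, subject_id=sid, group=group,
            )
        )
        truth_env[sid] = envelopes
    truth = {
        "coupling": control,
        "targets": {"pair_a": targets_a, "pair_b": targets_b},
        "pairs": {"pair_a": pair_a, "pair_b": pair_b},
        "envelopes": truth_env,
    }
    return records, truth


def simulate_common_driver_cohort(
    partition: NetworkPartition,
    n: int = 27,
    driver_sd: float = 1.0,
    T: int = 190,
    tr_seconds: float = 2.0,
    seed=0,
    group: str = "NC",
    driven_networks: Sequence[str] = ("Core", "MTL", "DM", "DAN"),
) -> list[SubjectRecord]:
    """Cohort with one FPCNA ROI acting as a common driver of other subsystems.

    Every driven ROI is ``noise + driver_sd * d`` where ``d`` is the driver
    ROI's (unit-variance) series, so any pair of driven ROIs shares a
    correlation of driver_sd^2 / (driver_sd^2 + 1) that vanishes once the
    FPCNA signals are regressed out. ``driver_sd = 0`` removes the driver.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    fp_idx = partition.indices_of("FPCNA")
    if fp_idx.size == 0:
        raise ValueError("partition has no FPCNA ROIs to act as driver")
    driver_col = int(fp_idx[0])
    driven_cols = np.concatenate([partition.indices_of(nw) for nw in driven_networks])
    records = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        data = rng.normal(size=(T, partition.n_rois))
        d = rng.normal(size=T)
        data[:, driver_col] = d
        data[:, driven_cols] += driver_sd * d[:, None]
        records.append(
            SubjectRecord(
                subject_id=f"{group}{i + 1:02d}", group=group, data=data, tr_seconds=tr_seconds
            )
        )
    return records


def save_ground_truth(truth: dict, path: str | Path) -> None:
    """Serialise a ground-truth bundle (couplings, edges, envelopes) as JSON."""

    def convert(obj):
        if isinstance(obj, CouplingSpec):
            return {"A": obj.A.tolist(), "noise_sd": obj.noise_sd, "label": obj.label}
        if isinstance(obj, SimulationParams):
            return obj.__dict__
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    Path(path).write_text(json.dumps(convert(truth), indent=1))
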