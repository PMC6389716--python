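"""Synthetic resting-state cohort with state-switching connectivity.

Generates multi-subject ROI time series whose functional connectivity
reconfigures over time, the signal regime that temporal-variability
statistics are designed to detect.  The model:

* a modular base correlation matrix (``r_within`` inside modules,
  ``r_between`` across modules);
* a small set of connectivity *states*, each the base matrix plus a
  zero-mean low-rank perturbation whose per-node amplitude is larger in
  designated target modules;
* a hidden state sequence with geometric dwell times; within each dwell
  the signal is multivariate normal with the state's correlation,
  temporally smoothed by a unit-variance AR(1) filter;
* a group factor: patients carry a gain > 1 on the target-module
  perturbation amplitude, coupled to a latent severity that also drives an
  observed clinical score (emulating a motor-symptom scale).

Everything is deterministic given the spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    MANIFEST_COLUMNS,
    CohortManifest,
    SubjectTimeSeries,
    write_manifest,
    write_timeseries,
)
from .partition import (
    DEFAULT_TARGET_MODULES,
    NetworkPartition,
    default_partition,
    write_partition,
)

_EIG_FLOOR = 1e-6


class ParameterRangeError(ValueError):
    """Requested amplitudes are incompatible with a valid correlation matrix."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated cohort.

    Defaults mirror the data regime of the motivating study: 200 volumes at
    TR = 2 s over 264 nodes in 13 modules, with patient groups showing
    amplified connectivity reconfiguration in subcortical, sensorimotor,
    visual and cerebellar modules, and a severity score coupled to that
    amplification.
    """

    n_control: int = 40
    n_patient: int = 42
    partition: NetworkPartition = field(default_factory=default_partition)
    n_volumes: int = 200
    tr_seconds: float = 2.0
    n_states: int = 8
    mean_dwell: float = 25.0
    r_within: float = 0.4
    r_between: float = 0.05
    perturb_rank: int = 3
    amp_base: float = 0.08
    amp_target: float = 0.25
    target_modules: tuple[str, ...] = DEFAULT_TARGET_MODULES
    group_gain: float = 1.8
    severity_coupling: float = 0.7
    score_scale: float = 40.0
    ar_phi: float = 0.3
    noise_sd: float = 1.0
    hetero_min: float = 0.05
    hetero_max: float = 0.95
    hetero_rank: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_patient, self.n_volumes, self.n_states, self.perturb_rank) < 1:
            raise ValueError("all counts must be positive")
        if self.n_volumes < 2 * 3:
            raise ValueError("n_volumes must allow at least two windows of the smallest length")
        if not (0 <= self.amp_base <= self.amp_target):
            raise ValueError("need 0 <= amp_base <= amp_target")
        if not (self.r_between < self.r_within < 1):
            raise ValueError("need r_between < r_within < 1")
        if self.group_gain < 1:
            raise ValueError("group_gain must be >= 1")
        if not (0 <= self.severity_coupling <= 1):
            raise ValueError("severity_coupling must be in [0, 1]")
        if not (0 <= self.ar_phi < 1):
            raise ValueError("ar_phi must be in [0, 1)")
        if self.noise_sd <= 0 or self.mean_dwell < 1:
            raise ValueError("noise_sd > 0 and mean_dwell >= 1 required")
        if not (0 <= self.hetero_min <= self.hetero_max < 1) or self.hetero_rank < 1:
            raise ValueError("need 0 <= hetero_min <= hetero_max < 1 and hetero_rank >= 1")
        unknown = set(self.target_modules) - set(self.partition.labels)
        if unknown:
            raise ValueError(f"target_modules not in partition: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return self.partition.n_nodes


@dataclass(frozen=True)
class SimulatedSubject:
    """One simulated subject with its ground truth."""

    series: SubjectTimeSeries
    group: str
    severity: float
    score: float | None
    state_sequence: np.ndarray
    gain: float


@dataclass(frozen=True)
class SimulatedCohort:
    spec: CohortSpec
    subjects: list[SimulatedSubject]
    manifest: CohortManifest


def base_correlation(spec: CohortSpec) -> np.ndarray:
    """Modular block correlation matrix: r_within inside, r_between across."""
    part = spec.partition
    C = np.full((part.n_nodes, part.n_nodes), spec.r_between)
    for m in part.labels:
        pos = part.positions(m)
        C[np.ix_(pos, pos)] = spec.r_within
    np.fill_diagonal(C, 1.0)
    return C


def _node_amplitudes(spec: CohortSpec, subject_gain: float) -> np.ndarray:
    amp = np.full(spec.n_nodes, spec.amp_base)
    for m in spec.target_modules:
        amp[spec.partition.positions(m)] = spec.amp_target * subject_gain
    return amp


def cohort_base_correlation(spec: CohortSpec) -> np.ndarray:
    """Cohort-level stationary correlation: modular blocks plus fixed heterogeneity.

    The block matrix alone gives every within-module pair the same true
    connectivity, so a unit's unfolded connectivity vector would carry no
    persistent entry-level pattern and the variability statistic would see
    pure noise.  Real FC matrices are heterogeneous, subjects largely share
    that heterogeneity, and regions differ in how much stable idiosyncratic
    structure their profiles carry.  This is emulated by a per-node blend

        B = (u u^T) o R + (v v^T) o base,   u_k = sqrt(w_k), v_k = sqrt(1 - w_k),

    where R is a random factor correlation matrix (rank ``hetero_rank``)
    and the stable-structure fractions w_k are drawn Uniform(hetero_min,
    hetero_max), all once per cohort from the spec seed.  Both Schur terms
    are positive semidefinite and the diagonal is exactly 1, so B is a
    valid correlation matrix; nodes with larger w_k have more stable
    (lower-variability) connectivity profiles, giving the cohort a graded
    node-level variability map.
    """
    base = base_correlation(spec)
    if spec.hetero_max == 0:
        return base
    rng = np.random.default_rng([spec.seed, 0x6E6F6465])
    L = rng.standard_normal((spec.n_nodes, spec.hetero_rank))
    G = L @ L.T
    s = 1.0 / np.sqrt(np.diag(G))
    R = G * np.outer(s, s)
    w = rng.uniform(spec.hetero_min, spec.hetero_max, size=spec.n_nodes)
    u = np.sqrt(w)
    v = np.sqrt(1.0 - w)
    B = np.outer(u, u) * R + np.outer(v, v) * base
    np.fill_diagonal(B, 1.0)
    return B


def build_state_covariances(
    spec: CohortSpec, subject_gain: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-state node-by-node correlation matrices for one subject.

    Each state is the cohort's base matrix plus D S D where D =
    diag(per-node amplitude) and S is a zero-mean random symmetric matrix
    of rank ``perturb_rank`` with O(1) entries.  Indefinite results are
    repaired by clipping eigenvalues at a small floor and re-normalizing to
    unit diagonal, which preserves the block structure for the amplitudes
    used here.
    """
    if subject_gain < 1:
        raise ValueError("subject_gain must be >= 1")
    M = spec.n_nodes
    base = cohort_base_correlation(spec)
    amp = _node_amplitudes(spec, subject_gain)
    covs: list[np.ndarray] = []
    for _ in range(spec.n_states):
        V = rng.standard_normal((M, spec.perturb_rank))
        V *= np.sqrt(M) / np.linalg.norm(V, axis=0)
        signs = rng.choice([-1.0, 1.0], size=spec.perturb_rank)
        if np.all(amp == 0):
            covs.append(base.copy())
            continue
        S = (V * signs) @ V.T / np.sqrt(spec.perturb_rank)
        C = base + (amp[:, None] * amp[None, :]) * S
        C = 0.5 * (C + C.T)
        covs.append(_repair_correlation(C))
    return covs


def _repair_correlation(C: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a floor, renormalize to unit diagonal."""
    try:
        np.linalg.cholesky(C)
        d = np.diag(C)
        if np.all(np.abs(d - 1.0) < 1e-12):
            return C
    except np.linalg.LinAlgError:
        pass
    w, Q = np.linalg.eigh(C)
    w = np.clip(w, _EIG_FLOOR, None)
    C = (Q * w) @ Q.T
    d = np.diag(C).copy()
    if np.any(d <= _EIG_FLOOR):
        raise ParameterRangeError(
            "perturbation amplitude too large: clipped matrix has a vanishing diagonal"
        )
    s = 1.0 / np.sqrt(d)
    C = C * np.outer(s, s)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def subject_gain(spec: CohortSpec, group: str, severity: float) -> float:
    """Target-module amplitude multiplier for a subject.

    Controls have gain 1; patients interpolate between the group floor and
    the full group gain according to their latent severity.
    """
    if group == "control":
        return 1.0
    c = spec.severity_coupling
    return 1.0 + (spec.group_gain - 1.0) * (c * severity + (1.0 - c))


def _sample_state_sequence(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    states = np.empty(spec.n_volumes, dtype=int)
    s = int(rng.integers(spec.n_states))
    p_switch = 1.0 / spec.mean_dwell
    for t in range(spec.n_volumes):
        states[t] = s
        if spec.n_states > 1 and rng.random() < p_switch:
            # jump to a different state, uniform over the others
            s = (s + 1 + int(rng.integers(spec.n_states - 1))) % spec.n_states
    return states


def simulate_subject(
    spec: CohortSpec,
    group: str,
    severity: float,
    seed: int,
    subject_id: str | None = None,
) -> SimulatedSubject:
    """Simulate one subject deterministically from (spec, group, severity, seed)."""
    if group not in ("control", "patient"):
        raise ValueError(f"invalid group label: {group!r}")
    if seed is None:
        raise ValueError("a seed is required; subject simulation must be reproducible")
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gain = subject_gain(spec, group, severity)
    covs = build_state_covariances(spec, gain, rng)
    chols = [np.linalg.cholesky(C) for C in covs]
    states = _sample_state_sequence(spec, rng)
    T, M = spec.n_volumes, spec.n_nodes
    raw = rng.standard_normal((T, M))
    y = np.empty_like(raw)
    # apply each state's Cholesky factor over its dwell segments
    boundaries = np.flatnonzero(np.diff(states)) + 1
    for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, T]):
        y[lo:hi] = raw[lo:hi] @ chols[states[lo]].T
    phi, innov = spec.ar_phi, np.sqrt(1.0 - spec.ar_phi**2)
    x = np.empty_like(y)
    x[0] = y[0]
    for t in range(1, T):
        x[t] = phi * x[t - 1] + innov * y[t]
    x *= spec.noise_sd
    score = None
    if group == "patient":
        score = float(
            max(0.0, spec.score_scale * severity + rng.normal(0.0, 0.1 * spec.score_scale))
        )
    series = SubjectTimeSeries(
        subject_id=subject_id or f"{group}-{seed}", data=x, tr_seconds=spec.tr_seconds
    )
    return SimulatedSubject(
        series=series, group=group, severity=float(severity), score=score,
        state_sequence=states, gain=gain,
    )


def simulate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> SimulatedCohort:
    """Simulate the full cohort; optionally write it in the pipeline's input formats.

    When ``out_dir`` is given, writes one time-series TSV per subject under
    ``data/``, plus ``manifest.tsv``, ``partition.tsv`` and a ground-truth
    sidecar ``ground_truth.tsv`` (per-subject gain, severity, state
    sequence) intended for validation only.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_control + spec.n_patient
    seeds = rng.integers(0, 2**31 - 1, size=n_total)
    severities = np.zeros(n_total)
    severities[spec.n_control:] = rng.uniform(0.0, 1.0, size=spec.n_patient)
    ages = np.clip(rng.normal(62.0, 6.5, size=n_total), 45.0, 85.0)
    sexes = rng.choice(["M", "F"], size=n_total)

    subjects: list[SimulatedSubject] = []
    rows = []
    for i in range(n_total):
        group = "control" if i < spec.n_control else "patient"
        sid = f"{'C' if group == 'control' else 'P'}{i + 1:03d}"
        subj = simulate_subject(spec, group, float(severities[i]), int(seeds[i]), subject_id=sid)
        subjects.append(subj)
        hy = None
        if group == "patient":
            hy = float(np.clip(round((1.0 + 2.0 * subj.severity) * 2) / 2, 1.0, 5.0))
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "path": f"data/{sid}.tsv",
                "age": round(float(ages[i]), 1),
                "sex": sexes[i],
                "updrs3": None if subj.score is None else round(subj.score, 1),
                "hy": hy,
            }
        )
    manifest = CohortManifest(table=pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    cohort = SimulatedCohort(spec=spec, subjects=subjects, manifest=manifest)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "data").mkdir(parents=True, exist_ok=True)
    part = cohort.spec.partition
    for subj in cohort.subjects:
        write_timeseries(subj.series, out / "data" / f"{subj.series.subject_id}.tsv", part)
    write_manifest(cohort.manifest, out / "manifest.tsv")
    write_partition(part, out / "partition.tsv")
    gt = pd.DataFrame(
        {
            "subject_id": [s.series.subject_id for s in cohort.subjects],
            "group": [s.group for s in cohort.subjects],
            "severity": [s.severity for s in cohort.subjects],
            "gain": [s.gain for s in cohort.subjects],
            "score": [s.score for s in cohort.subjects],
            "state_sequence": ["".join(map(str, s.state_sequence)) for s in cohort.subjects],
        }
    )
    gt.to_csv(out / "ground_truth.tsv", sep="\t", index=False, float_format="%.6f")
    with open(out / "spec.json", "w") as fh:
        json.dump(_spec_summary(cohort.spec), fh, indent=2, sort_keys=True)
    return out


def _spec_summary(spec: CohortSpec) -> dict:
    d = {
        k: getattr(spec, k)
        for k in (
            "n_control", "n_patient", "n_volumes", "tr_seconds", "n_states",
            "mean_dwell", "r_within", "r_between", "perturb_rank", "amp_base",
            "amp_target", "group_gain", "severity_coupling", "score_scale",
            "ar_phi", "noise_sd", "seed",
        )
    }
    d["target_modules"] = list(spec.target_modules)
    d["n_nodes"] = spec.n_nodes
    d["module_sizes"] = spec.partition.module_sizes()
    return d


def null_spec(spec: CohortSpec) -> CohortSpec:
    """The matched null cohort: no group effect (gain 1 for everyone)."""
    return replace(spec, group_gain=1.0)
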