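"""Temporal variability of dynamic functional connectivity.

The subject's time series is cut into N non-overlapping windows of length
``l`` volumes; within each window the M x M functional connectivity (FC)
matrix is the Pearson correlation of the windowed signals.  For a unit of
interest — a node's connectivity profile, a module's within-block upper
triangle, or a between-module block — the per-window FC values are unfolded
into a vector, and the temporal variability is

    V = 1 - (2 / (N (N - 1))) * sum_{i<j} corr(f_i, f_j),

one minus the mean Pearson correlation between the unit's connectivity
vectors over all window pairs.  V lies in [0, 2]: 0 when the connectivity
pattern is perfectly stable across windows, values above 1 when profiles
anti-correlate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import SubjectTimeSeries
from .partition import NetworkPartition

MIN_WINDOW_LENGTH = 3
DEFAULT_WINDOW_LENGTH = 20
DEFAULT_SWEEP_LENGTHS = tuple(range(10, 21))


class WindowError(ValueError):
    """Invalid windowing request or degenerate window content."""


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping windowing policy: N = floor(T / l) windows, first N*l volumes."""

    length_volumes: int = DEFAULT_WINDOW_LENGTH

    def __post_init__(self) -> None:
        if self.length_volumes < MIN_WINDOW_LENGTH:
            raise WindowError(
                f"window length must be >= {MIN_WINDOW_LENGTH} volumes, got {self.length_volumes}"
            )

    def n_windows(self, n_volumes: int) -> int:
        return n_volumes // self.length_volumes


@dataclass(frozen=True)
class FCWindowStack:
    """Per-window Pearson FC matrices for one subject: (N, M, M), unit diagonal."""

    subject_id: str
    windows: np.ndarray
    window_length: int

    def __post_init__(self) -> None:
        w = np.asarray(self.windows, dtype=float)
        if w.ndim != 3 or w.shape[1] != w.shape[2]:
            raise ValueError("windows must be (N, M, M)")
        if not np.allclose(w, np.swapaxes(w, 1, 2), atol=1e-12):
            raise ValueError("window FC matrices must be symmetric")
        if not np.allclose(np.diagonal(w, axis1=1, axis2=2), 1.0, atol=1e-12):
            raise ValueError("window FC matrices must have unit diagonal")
        object.__setattr__(self, "windows", w)

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.windows.shape[1]


@dataclass(frozen=True)
class VariabilitySet:
    """Per-subject variability: nodal vector plus K x K module-level matrix.

    ``module_matrix`` holds intra-network variability on the diagonal and
    inter-network variability off it (symmetric), indexed by module label.
    """

    subject_id: str
    window_length: int
    nodal: np.ndarray
    module_matrix: pd.DataFrame
    diagnostics: tuple[str, ...] = field(default=())


def segment_windows(series: SubjectTimeSeries, spec: WindowSpec) -> np.ndarray:
    """Cut the series into N contiguous non-overlapping (l, M) blocks.

    Windows are anchored at the first volume; the trailing T - N*l volumes
    are discarded.
    """
    l = spec.length_volumes
    n = spec.n_windows(series.n_volumes)
    if n < 2:
        raise WindowError(
            f"{series.subject_id}: T={series.n_volumes} gives {n} window(s) of length {l}; "
            "variability needs at least 2"
        )
    return series.data[: n * l].reshape(n, l, series.n_nodes)


def window_fc(block: np.ndarray, window_index: int | None = None) -> np.ndarray:
    """Pearson FC of one (l, M) block: symmetric, unit diagonal, in [-1, 1].

    Raw signed correlations are kept: no Fisher transform, no thresholding.
    """
    block = np.asarray(block, dtype=float)
    var = block.var(axis=0)
    dead = np.flatnonzero(var == 0)
    if dead.size:
        where = "" if window_index is None else f" in window {window_index}"
        raise WindowError(f"zero-variance node(s) {(dead + 1).tolist()}{where}")
    C = np.corrcoef(block, rowvar=False)
    C = np.clip(0.5 * (C + C.T), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def fc_window_stack(
    series: SubjectTimeSeries,
    spec: WindowSpec,
    skip_degenerate_windows: bool = False,
    fisher_z: bool = False,
) -> FCWindowStack:
    """Windowed FC stack for one subject.

    Degenerate windows (a node constant within the window) abort by default;
    with ``skip_degenerate_windows`` the whole window is dropped for all
    nodes, keeping windows aligned across units.  ``fisher_z`` applies the
    arctanh transform to off-diagonal entries before profile correlation.
    """
    blocks = segment_windows(series, spec)
    mats, dropped = [], []
    for i, block in enumerate(blocks):
        try:
            mats.append(window_fc(block, window_index=i))
        except WindowError:
            if not skip_degenerate_windows:
                raise
            dropped.append(i)
    if len(mats) < 2:
        raise WindowError(f"{series.subject_id}: fewer than 2 usable windows")
    w = np.stack(mats)
    if fisher_z:
        off = ~np.eye(w.shape[1], dtype=bool)
        w = w.copy()
        w[:, off] = np.arctanh(np.clip(w[:, off], -1 + 1e-12, 1 - 1e-12))
        # keep the unit diagonal convention; diagonal is excluded from all profiles
        w[:, np.eye(w.shape[1], dtype=bool)] = 1.0
    stack = FCWindowStack(
        subject_id=series.subject_id, windows=w, window_length=spec.length_volumes
    )
    if dropped:
        object.__setattr__(stack, "_dropped_windows", tuple(dropped))
    return stack


def _one_minus_mean_pairwise_corr(X: np.ndarray) -> float:
    """1 - mean Pearson correlation over all row pairs of X (N, P)."""
    N = X.shape[0]
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = np.sqrt((Xc**2).mean(axis=1))
    if np.any(sd == 0):
        return np.nan
    Z = Xc / (sd[:, None] * np.sqrt(X.shape[1]))
    R = Z @ Z.T
    return float(1.0 - (R.sum() - np.trace(R)) / (N * (N - 1)))


def nodal_variability(stack: FCWindowStack, node: int) -> float:
    """Temporal variability V_k of one node (0-based storage position).

    The node's per-window connectivity profile is its FC row with the
    self-entry removed; V_k is one minus the mean pairwise profile
    correlation over the N(N-1)/2 window pairs.
    """
    M = stack.n_nodes
    keep = np.arange(M) != node
    X = stack.windows[:, node, keep]
    return _one_minus_mean_pairwise_corr(X)


def nodal_variability_all(stack: FCWindowStack) -> np.ndarray:
    """Vectorized V_k for every node; NaN where a profile is degenerate."""
    w = stack.windows
    N, M, _ = w.shape
    mask = ~np.eye(M, dtype=bool)
    # profiles: (M, N, M-1)
    prof = np.empty((M, N, M - 1))
    for k in range(M):
        prof[k] = w[:, k, mask[k]]
    Xc = prof - prof.mean(axis=2, keepdims=True)
    sd = np.sqrt((Xc**2).mean(axis=2))
    bad = np.any(sd == 0, axis=1)
    sd = np.where(sd == 0, np.nan, sd)
    Z = Xc / (sd[:, :, None] * np.sqrt(M - 1))
    R = Z @ np.swapaxes(Z, 1, 2)
    tr = np.trace(R, axis1=1, axis2=2)
    V = 1.0 - (R.sum(axis=(1, 2)) - tr) / (N * (N - 1))
    V[bad] = np.nan
    return V


def _block_vectors(stack: FCWindowStack, pairs: np.ndarray) -> np.ndarray:
    """Unfold per-window FC values at the given (i, j) pairs: (N, P)."""
    return stack.windows[:, pairs[:, 0], pairs[:, 1]]


def intra_network_variability(
    stack: FCWindowStack, partition: NetworkPartition, module: str
) -> float:
    """Variability of the within-module upper-triangle connectivity vector."""
    pairs = partition.intra_pairs(module)
    if pairs.shape[0] < 3:
        raise WindowError(
            f"module {module!r} has {partition.positions(module).size} nodes; "
            "intra-network variability needs >= 3 within-module pairs"
        )
    return _one_minus_mean_pairwise_corr(_block_vectors(stack, pairs))


def inter_network_variability(
    stack: FCWindowStack, partition: NetworkPartition, module_a: str, module_b: str
) -> float:
    """Variability of the between-module block connectivity vector (symmetric in A, B)."""
    if module_a == module_b:
        raise WindowError("inter-network variability needs two distinct modules; use intra")
    pairs = partition.inter_pairs(module_a, module_b)
    if pairs.shape[0] < 3:
        raise WindowError(f"block {module_a}|{module_b} has fewer than 3 cross pairs")
    return _one_minus_mean_pairwise_corr(_block_vectors(stack, pairs))


def variability_set(
    series: SubjectTimeSeries,
    partition: NetworkPartition,
    spec: WindowSpec | None = None,
    skip_degenerate_windows: bool = False,
    fisher_z: bool = False,
) -> VariabilitySet:
    """Nodal vector plus module-level matrix for one subject (deterministic)."""
    spec = spec or WindowSpec()
    stack = fc_window_stack(
        series, spec, skip_degenerate_windows=skip_degenerate_windows, fisher_z=fisher_z
    )
    nodal = nodal_variability_all(stack)
    diags = [f"nodal V undefined at node position {k}" for k in np.flatnonzero(np.isnan(nodal))]
    labels = partition.labels
    K = len(labels)
    mm = np.full((K, K), np.nan)
    for a in range(K):
        try:
            mm[a, a] = intra_network_variability(stack, partition, labels[a])
        except WindowError as exc:
            diags.append(str(exc))
        for b in range(a + 1, K):
            mm[a, b] = mm[b, a] = inter_network_variability(stack, partition, labels[a], labels[b])
    return VariabilitySet(
        subject_id=series.subject_id,
        window_length=spec.length_volumes,
        nodal=nodal,
        module_matrix=pd.DataFrame(mm, index=list(labels), columns=list(labels)),
        diagnostics=tuple(diags),
    )


def _flat_units(vs: VariabilitySet) -> np.ndarray:
    """All units of a VariabilitySet as one vector: nodal then module upper triangle."""
    mm = vs.module_matrix.to_numpy()
    iu = np.triu_indices(mm.shape[0])
    return np.concatenate([vs.nodal, mm[iu]])


def window_length_sweep(
    series: SubjectTimeSeries,
    partition: NetworkPartition,
    lengths: tuple[int, ...] = DEFAULT_SWEEP_LENGTHS,
    **kwargs,
) -> dict[int, VariabilitySet]:
    """Variability at each window length for one subject."""
    if series.n_volumes < 2 * max(lengths):
        raise WindowError("series too short for the largest sweep length")
    return {
        l: variability_set(series, partition, WindowSpec(l), **kwargs) for l in lengths
    }


def _pairwise_corr_table(
    per_subject: list[dict[int, np.ndarray]], lengths: tuple[int, ...]
) -> pd.DataFrame:
    """Mean-over-subjects correlation between unit vectors at each length pair."""
    K = len(lengths)
    out = np.eye(K)
    for a, b in combinations(range(K), 2):
        rs = []
        for vecs in per_subject:
            x, y = vecs[lengths[a]], vecs[lengths[b]]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() >= 3:
                rs.append(np.corrcoef(x[ok], y[ok])[0, 1])
        out[a, b] = out[b, a] = float(np.mean(rs)) if rs else np.nan
    return pd.DataFrame(out, index=list(lengths), columns=list(lengths))


def cohort_sweep(
    series_list: list[SubjectTimeSeries],
    partition: NetworkPartition,
    lengths: tuple[int, ...] = DEFAULT_SWEEP_LENGTHS,
    **kwargs,
) -> tuple[dict[str, dict[int, VariabilitySet]], pd.DataFrame, pd.DataFrame]:
    """Sweep over a cohort.

    Returns per-subject per-length VariabilitySets, plus two symmetric
    cross-length correlation tables (nodal units; unfolded module-matrix
    units).  Each table entry is the per-subject Pearson correlation over
    units between the two lengths, averaged over subjects.
    """
    sweeps = {
        s.subject_id: window_length_sweep(s, partition, lengths, **kwargs)
        for s in series_list
    }
    nodal_vecs = [{l: vs.nodal for l, vs in sw.items()} for sw in sweeps.values()]
    K = partition.n_modules
    iu = np.triu_indices(K)
    mod_vecs = [
        {l: vs.module_matrix.to_numpy()[iu] for l, vs in sw.items()} for sw in sweeps.values()
    ]
    return (
        sweeps,
        _pairwise_corr_table(nodal_vecs, tuple(lengths)),
        _pairwise_corr_table(mod_vecs, tuple(lengths)),
    )


def average_over_lengths(sets: list[VariabilitySet]) -> VariabilitySet:
    """Elementwise mean variability across window lengths for one subject.

    A unit missing in more than one length propagates as missing; with a
    single missing length the mean of the present values is used.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 window lengths to average")
    sid = sets[0].subject_id
    labels = list(sets[0].module_matrix.index)
    for vs in sets[1:]:
        if vs.subject_id != sid or list(vs.module_matrix.index) != labels:
            raise ValueError("mismatched subjects or partitions across lengths")
        if vs.nodal.shape != sets[0].nodal.shape:
            raise ValueError("mismatched nodal shapes across lengths")

    def _mean(stacked: np.ndarray) -> np.ndarray:
        ok = np.isfinite(stacked)
        n_missing = (~ok).sum(axis=0)
        cnt = np.maximum(ok.sum(axis=0), 1)
        out = np.where(ok, stacked, 0.0).sum(axis=0) / cnt
        out = np.asarray(out, dtype=float)
        out[n_missing > 1] = np.nan
        return out

    nodal = _mean(np.stack([vs.nodal for vs in sets]))
    mm = _mean(np.stack([vs.module_matrix.to_numpy() for vs in sets]))
    return VariabilitySet(
        subject_id=sid,
        window_length=0,  # 0 marks "averaged over lengths"
        nodal=nodal,
        module_matrix=pd.DataFrame(mm, index=labels, columns=labels),
        diagnostics=tuple(d for vs in sets for d in vs.diagnostics),
    )


def variability_long_frame(
    sets: dict[str, VariabilitySet], partition: NetworkPartition
) -> pd.DataFrame:
    """Long-format table: subject_id, level, unit, window_length, value."""
    rows = []
    labels = partition.labels
    for sid, vs in sets.items():
        for pos, v in enumerate(vs.nodal):
            rows.append((sid, "nodal", str(partition.node_index[pos]), vs.window_length, v))
        mm = vs.module_matrix
        for a, la in enumerate(labels):
            rows.append((sid, "intra", la, vs.window_length, mm.iloc[a, a]))
            for b in range(a + 1, len(labels)):
                rows.append((sid, "inter", f"{la}|{labels[b]}", vs.window_length, mm.iloc[a, b]))
    return pd.DataFrame(rows, columns=["subject_id", "level", "unit", "window_length", "value"])
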