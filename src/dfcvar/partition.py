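"""Node-to-module partitions of whole-brain functional networks.

A partition assigns every network node (a brain region of interest whose
mean BOLD signal forms one time-series column) to exactly one functional
module (sensorimotor, default mode, subcortical, ...).  The partition
defines the index sets used by the variability statistics: singleton nodal
sets, within-module upper-triangle pairs, and between-module block pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

UNCERTAIN_LABEL = "Uncertain"

#: Module sizes of the default 264-node / 13-module whole-brain layout.
#: Sizes follow the published consensus assignment of the 264 functional
#: ROIs (the two sensorimotor subsets merged into a single SMN module).
DEFAULT_MODULE_SIZES: dict[str, int] = {
    "SMN": 35,
    "CON": 14,
    "Auditory": 13,
    "DMN": 58,
    "MemoryRetrieval": 5,
    "Visual": 31,
    "FPN": 25,
    "SAN": 18,
    "Subcortical": 13,
    "VAN": 9,
    "DAN": 11,
    "Cerebellum": 4,
    "Uncertain": 28,
}

#: Modules whose connectivity the synthetic cohort perturbs more strongly
#: in patients (the disease-associated systems).
DEFAULT_TARGET_MODULES = ("Subcortical", "SMN", "Visual", "Cerebellum")


class PartitionError(ValueError):
    """Invalid node-to-module assignment or partition file."""


@dataclass(frozen=True)
class NetworkPartition:
    """Assignment of 1-based node indices to named functional modules.

    Nodes are stored sorted by ``node_index``; all positional index sets
    returned by the accessors refer to this sorted order (0-based).
    """

    node_index: np.ndarray
    module_label: np.ndarray
    mni_xyz: np.ndarray | None = None
    reportable_modules: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        idx = np.asarray(self.node_index, dtype=int)
        lab = np.asarray(self.module_label, dtype=object)
        if idx.ndim != 1 or lab.shape != idx.shape:
            raise PartitionError("node_index and module_label must be 1-D and equal length")
        uniq, counts = np.unique(idx, return_counts=True)
        if np.any(counts > 1):
            dup = uniq[counts > 1]
            raise PartitionError(f"duplicate node_index values: {dup.tolist()}")
        if np.any(uniq != np.arange(uniq.min(), uniq.min() + uniq.size)):
            raise PartitionError("node_index values must be contiguous after sorting")
        if any(not str(m).strip() for m in lab):
            raise PartitionError("empty module label")
        order = np.argsort(idx)
        object.__setattr__(self, "node_index", idx[order])
        object.__setattr__(self, "module_label", lab[order])
        if self.mni_xyz is not None:
            xyz = np.asarray(self.mni_xyz, dtype=float)
            if xyz.shape != (idx.size, 3):
                raise PartitionError("mni_xyz must be (n_nodes, 3)")
            object.__setattr__(self, "mni_xyz", xyz[order])
        labels = self.labels
        if len(labels) < 2:
            raise PartitionError("a partition needs at least 2 modules")
        if not self.reportable_modules:
            rep = tuple(m for m in labels if m != UNCERTAIN_LABEL) or labels
            object.__setattr__(self, "reportable_modules", rep)
        else:
            unknown = set(self.reportable_modules) - set(labels)
            if unknown:
                raise PartitionError(f"reportable_modules not in partition: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return int(self.node_index.size)

    @property
    def labels(self) -> tuple[str, ...]:
        """Module labels in order of first appearance along node_index."""
        seen: dict[str, None] = {}
        for m in self.module_label:
            seen.setdefault(str(m))
        return tuple(seen)

    @property
    def n_modules(self) -> int:
        return len(self.labels)

    def positions(self, module: str) -> np.ndarray:
        """0-based storage positions of the nodes in ``module``."""
        pos = np.flatnonzero(self.module_label == module)
        if pos.size == 0:
            raise PartitionError(f"unknown module label: {module!r}")
        return pos

    def module_sizes(self) -> dict[str, int]:
        return {m: int(self.positions(m).size) for m in self.labels}

    def intra_pairs(self, module: str) -> np.ndarray:
        """Unordered within-module node pairs (upper triangle), canonical order."""
        pos = self.positions(module)
        iu = np.triu_indices(pos.size, k=1)
        return np.column_stack([pos[iu[0]], pos[iu[1]]])

    def inter_pairs(self, module_a: str, module_b: str) -> np.ndarray:
        """All cross pairs between two distinct modules, row-major canonical order.

        The order is fixed by the lexicographically smaller label first so the
        unfolding (and hence the variability) is identical for (A, B) and (B, A).
        """
        if module_a == module_b:
            raise PartitionError("inter_pairs requires two distinct modules")
        a, b = sorted((module_a, module_b))
        pa, pb = self.positions(a), self.positions(b)
        return np.column_stack([np.repeat(pa, pb.size), np.tile(pb, pa.size)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"node_index": self.node_index, "module": self.module_label})
        if self.mni_xyz is not None:
            df[["x", "y", "z"]] = self.mni_xyz
        return df


def read_partition(path: str | Path) -> NetworkPartition:
    """Read a partition TSV (columns node_index, module, optional x/y/z)."""
    df = pd.read_csv(path, sep="\t")
    required = {"node_index", "module"}
    missing = required - set(df.columns)
    if missing:
        raise PartitionError(f"partition file {path} missing columns: {sorted(missing)}")
    try:
        idx = df["node_index"].astype(int).to_numpy()
        if not np.array_equal(idx, df["node_index"].to_numpy(dtype=float)):
            raise ValueError
    except (ValueError, TypeError):
        raise PartitionError(f"non-integer node_index in {path}") from None
    xyz = None
    if {"x", "y", "z"} <= set(df.columns):
        xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if df["module"].isna().any():
        raise PartitionError("empty module label")
    return NetworkPartition(node_index=idx, module_label=df["module"].astype(str).to_numpy(dtype=object), mni_xyz=xyz)


def write_partition(partition: NetworkPartition, path: str | Path) -> None:
    partition.to_frame().to_csv(path, sep="\t", index=False)


def make_partition(module_sizes: dict[str, int], first_index: int = 1) -> NetworkPartition:
    """Build a partition with nodes numbered contiguously in module blocks."""
    labels = np.concatenate([np.full(n, m, dtype=object) for m, n in module_sizes.items()])
    idx = np.arange(first_index, first_index + labels.size)
    return NetworkPartition(node_index=idx, module_label=labels)


def default_partition() -> NetworkPartition:
    """The shipped 264-node, 13-module layout.

    This is a synthetic stand-in for the published 264-ROI parcellation: the
    module sizes match the public consensus table but node numbering is a
    plain block layout, since the source assignment table is not
    redistributed here.
    """
    return make_partition(DEFAULT_MODULE_SIZES)


def default_partition_path() -> Path:
    """Path of the shipped synthetic partition TSV."""
    return Path(str(resources.files("dfcvar").joinpath("data/synthetic_power264_partition.tsv")))
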