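"""Orchestration: one call reproduces the full variability analysis on a cohort.

Stages: per-subject variability at the default window length, permutation
group comparison over every unit (node, module, module pair), within-group
intra-vs-inter paired tests, clinical correlation for patients, the
window-length robustness sweep, and cross-length averaging.  All outputs
are plain TSV/JSON; a run is byte-reproducible given the same inputs and
seed (timings go to the log only).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import CohortManifest, read_manifest, read_timeseries
from .partition import UNCERTAIN_LABEL, NetworkPartition, read_partition
from .stats import (
    benjamini_hochberg,
    group_diffs_under_permutation,
    paired_signflip_test,
    permutation_group_test,
    permutation_membership,
    sex_ratio_test,
    spearman_with_outlier_removal,
    two_sample_t,
)
from .variability import (
    DEFAULT_SWEEP_LENGTHS,
    WindowSpec,
    VariabilitySet,
    average_over_lengths,
    cohort_sweep,
    variability_long_frame,
    variability_set,
)

logger = logging.getLogger("dfcvar")

_INCOMPLETE = "INCOMPLETE"


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str = "manifest.tsv"
    partition: str = "partition.tsv"
    out_dir: str = "run"
    window_length: int = 20
    sweep_lengths: tuple[int, ...] = DEFAULT_SWEEP_LENGTHS
    n_perm: int = 10_000
    seed: int = 0
    outlier_sd: float = 3.0
    score_names: tuple[str, ...] = ("updrs3", "hy")
    nodal_threshold: float = 0.005
    network_thresholds: tuple[float, float] = (0.05, 0.005)
    tr_seconds: float = 2.0
    fisher_z: bool = False
    skip_degenerate_windows: bool = False
    fdr: bool = False
    include_uncertain: bool = False
    run_sweep: bool = True

    def __post_init__(self) -> None:
        for p in (self.nodal_threshold, *self.network_thresholds):
            if not (0 < p < 1):
                raise ValueError(f"thresholds must be in (0, 1), got {p}")
        for l in self.sweep_lengths:
            WindowSpec(l)  # raises on invalid length
        WindowSpec(self.window_length)
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


_CONFIG_KEYS = set(PipelineConfig.__dataclass_fields__)


def parse_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from a YAML file plus keyword overrides (overrides win)."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = set(loaded) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        values.update(loaded)
    unknown = set(overrides) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("sweep_lengths", "score_names", "network_thresholds"):
        if key in values and values[key] is not None:
            values[key] = tuple(values[key])
    return PipelineConfig(**values)


def _unit_table(partition: NetworkPartition) -> pd.DataFrame:
    """Catalogue of all analysis units: M nodal, K intra, K(K-1)/2 inter."""
    labels = partition.labels
    rows = [("nodal", str(i)) for i in partition.node_index]
    rows += [("intra", m) for m in labels]
    rows += [
        ("inter", f"{labels[a]}|{labels[b]}")
        for a in range(len(labels))
        for b in range(a + 1, len(labels))
    ]
    return pd.DataFrame(rows, columns=["level", "unit"])


def _unit_values(vs: VariabilitySet, partition: NetworkPartition) -> np.ndarray:
    mm = vs.module_matrix.to_numpy()
    iu_intra = np.diag_indices(mm.shape[0])
    iu_inter = np.triu_indices(mm.shape[0], k=1)
    return np.concatenate([vs.nodal, mm[iu_intra], mm[iu_inter]])


def _group_comparison(
    values: np.ndarray,
    is_patient: np.ndarray,
    units: pd.DataFrame,
    n_perm: int,
    seed: int,
    fdr: bool,
) -> pd.DataFrame:
    """Vectorized label-permutation test over all units at once.

    Units with missing values fall back to a per-unit test on complete
    subjects; the shared permutation stream keeps clean units comparable.
    """
    n_pat = int(is_patient.sum())
    n_ctrl = int((~is_patient).sum())
    X = np.concatenate([values[is_patient], values[~is_patient]])  # patients first
    observed = values[is_patient].mean(axis=0) - values[~is_patient].mean(axis=0)
    rng = np.random.default_rng(seed)
    member = permutation_membership(n_pat + n_ctrl, n_pat, n_perm, rng)
    clean = ~np.isnan(X).any(axis=0)
    diffs = np.full((n_perm, X.shape[1]), np.nan)
    if clean.any():
        diffs[:, clean] = group_diffs_under_permutation(X[:, clean], member)
    p_greater = np.full(X.shape[1], np.nan)
    p_smaller = np.full(X.shape[1], np.nan)
    p_greater[clean] = (np.sum(diffs[:, clean] >= observed[clean], axis=0) + 1) / (n_perm + 1)
    p_smaller[clean] = (np.sum(diffs[:, clean] <= observed[clean], axis=0) + 1) / (n_perm + 1)
    for j in np.flatnonzero(~clean):
        res = permutation_group_test(
            values[~is_patient, j], values[is_patient, j], n_perm=n_perm,
            seed=seed + 1 + j, unit=units["unit"].iloc[j],
        )
        observed[j] = res.observed_diff
        p_greater[j], p_smaller[j] = res.p_greater, res.p_smaller
    out = units.copy()
    with np.errstate(invalid="ignore"):
        out["mean_control"] = np.nanmean(values[~is_patient], axis=0)
        out["mean_patient"] = np.nanmean(values[is_patient], axis=0)
    out["observed_diff"] = observed
    out["p_greater"] = p_greater
    out["p_smaller"] = p_smaller
    out["p_two_sided"] = np.minimum(1.0, 2.0 * np.minimum(p_greater, p_smaller))
    if fdr:
        out["q_fdr"] = benjamini_hochberg(out["p_two_sided"].to_numpy())
    return out


def _flag_significance(df: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    df = df.copy()
    nodal = df["level"] == "nodal"
    p = df["p_two_sided"]
    df["sig_nodal"] = nodal & (p < cfg.nodal_threshold)
    df["sig_network_p05"] = ~nodal & (p < cfg.network_thresholds[0])
    df["sig_network_p005"] = ~nodal & (p < cfg.network_thresholds[1])
    return df


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / _INCOMPLETE
    marker.write_text("run in progress or failed\n")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    try:
        _run_stages(config, out, timings)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    marker.unlink()
    logger.info("run complete in %.1fs", time.time() - t_start)
    return out


def _run_stages(config: PipelineConfig, out: Path, timings: dict[str, float]) -> None:
    t0 = time.time()
    manifest_path = Path(config.manifest)
    partition = read_partition(config.partition)
    manifest = read_manifest(manifest_path)
    series = {}
    for row in manifest.table.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        series[row.subject_id] = read_timeseries(
            p, partition, config.tr_seconds, subject_id=row.subject_id
        )
    timings["load"] = time.time() - t0
    logger.info("loaded %d subjects, %d nodes", len(series), partition.n_nodes)

    # --- per-subject variability at the reporting window length ---
    t0 = time.time()
    wspec = WindowSpec(config.window_length)
    sets = {
        sid: variability_set(
            s, partition, wspec,
            skip_degenerate_windows=config.skip_degenerate_windows,
            fisher_z=config.fisher_z,
        )
        for sid, s in series.items()
    }
    long = variability_long_frame(sets, partition)
    _write_tsv(long, out / "variability.tsv")
    timings["variability"] = time.time() - t0

    # --- group comparison over all units ---
    t0 = time.time()
    units = _unit_table(partition)
    ids = manifest.table["subject_id"].to_numpy()
    is_patient = (manifest.table["group"] == "patient").to_numpy()
    X = np.stack([_unit_values(sets[sid], partition) for sid in ids])
    comparison = _flag_significance(
        _group_comparison(X, is_patient, units, config.n_perm, config.seed, config.fdr),
        config,
    )
    _write_tsv(comparison, out / "group_comparison.tsv")
    timings["group_comparison"] = time.time() - t0

    # --- within-group intra vs mean-inter paired tests ---
    t0 = time.time()
    labels = list(partition.labels)
    rows = []
    for g, mask in (("control", ~is_patient), ("patient", is_patient)):
        g_ids = ids[mask]
        for a, la in enumerate(labels):
            intra = np.array([sets[sid].module_matrix.iloc[a, a] for sid in g_ids])
            others = [b for b in range(len(labels)) if b != a]
            inter = np.array(
                [sets[sid].module_matrix.iloc[a, others].mean() for sid in g_ids]
            )
            if g_ids.size >= 3:
                res = paired_signflip_test(
                    intra, inter, n_perm=config.n_perm, seed=config.seed + 7000 + a, unit=la
                )
                rows.append((g, la, res.observed_diff, res.p_smaller, res.p_greater, g_ids.size, ""))
            else:
                rows.append((g, la, np.nan, np.nan, np.nan, g_ids.size, "fewer than 3 pairs"))
    intra_inter = pd.DataFrame(
        rows,
        columns=["group", "module", "mean_intra_minus_inter", "p_intra_lower",
                 "p_intra_higher", "n_subjects", "note"],
    )
    _write_tsv(intra_inter, out / "intra_vs_inter.tsv")
    timings["intra_vs_inter"] = time.time() - t0

    # --- demographics (age by Welch t, sex by chi-square) ---
    demo_rows = []
    age = pd.to_numeric(manifest.table["age"], errors="coerce").to_numpy()
    if np.isfinite(age[is_patient]).sum() >= 2 and np.isfinite(age[~is_patient]).sum() >= 2:
        t, p = two_sample_t(age[is_patient], age[~is_patient])
        demo_rows.append(
            ("age", float(np.nanmean(age[is_patient])), float(np.nanmean(age[~is_patient])), t, p)
        )
    sex = manifest.table["sex"].astype(str).str.upper().to_numpy()
    table = np.array(
        [
            [(sex[is_patient] == "M").sum(), (sex[is_patient] == "F").sum()],
            [(sex[~is_patient] == "M").sum(), (sex[~is_patient] == "F").sum()],
        ]
    )
    try:
        p_sex = sex_ratio_test(table)
        demo_rows.append(
            ("sex_male_fraction", float(table[0, 0] / table[0].sum()),
             float(table[1, 0] / table[1].sum()), np.nan, p_sex)
        )
    except ValueError:
        logger.info("sex comparison skipped (empty margin)")
    _write_tsv(
        pd.DataFrame(
            demo_rows, columns=["measure", "patient", "control", "statistic", "p"]
        ),
        out / "demographics.tsv",
    )

    # --- clinical correlation (patients with scores) ---
    t0 = time.time()
    clin_rows = []
    pat_table = manifest.table[is_patient]
    for score_name in config.score_names:
        scores = pd.to_numeric(pat_table[score_name], errors="coerce").to_numpy()
        ok = np.isfinite(scores)
        if ok.sum() < 5:
            logger.info("score %s: only %d patients with values; stage skipped", score_name, ok.sum())
            continue
        pat_ids = pat_table["subject_id"].to_numpy()[ok]
        Xp = np.stack([_unit_values(sets[sid], partition) for sid in pat_ids])
        for j, (level, unit) in enumerate(units.itertuples(index=False)):
            try:
                cc = spearman_with_outlier_removal(
                    Xp[:, j], scores[ok], n_sd=config.outlier_sd, unit=unit
                )
            except ValueError:
                continue
            clin_rows.append(
                (score_name, level, unit, cc.rho, cc.p, cc.n_used, cc.n_outliers,
                 cc.rho_with_outliers, cc.p_with_outliers)
            )
    clinical = pd.DataFrame(
        clin_rows,
        columns=["score", "level", "unit", "rho", "p", "n_used", "n_outliers",
                 "rho_with_outliers", "p_with_outliers"],
    )
    _write_tsv(clinical, out / "clinical_correlation.tsv")
    timings["clinical"] = time.time() - t0

    # --- window-length sweep and cross-length averaging ---
    sweep_summary = {}
    if config.run_sweep and len(config.sweep_lengths) >= 2:
        t0 = time.time()
        sweeps, nodal_corr, module_corr = cohort_sweep(
            list(series.values()), partition, tuple(config.sweep_lengths),
            skip_degenerate_windows=config.skip_degenerate_windows,
            fisher_z=config.fisher_z,
        )
        nodal_corr.to_csv(out / "sweep_nodal_correlation.tsv", sep="\t", float_format="%.6g")
        module_corr.to_csv(out / "sweep_module_correlation.tsv", sep="\t", float_format="%.6g")
        averaged = {
            sid: average_over_lengths(list(per_len.values())) for sid, per_len in sweeps.items()
        }
        _write_tsv(
            variability_long_frame(averaged, partition), out / "variability_avg.tsv"
        )
        Xa = np.stack([_unit_values(averaged[sid], partition) for sid in ids])
        comp_avg = _flag_significance(
            _group_comparison(Xa, is_patient, units, config.n_perm, config.seed, config.fdr),
            config,
        )
        _write_tsv(comp_avg, out / "group_comparison_avg.tsv")
        off = ~np.eye(len(config.sweep_lengths), dtype=bool)
        sweep_summary = {
            "lengths": list(config.sweep_lengths),
            "min_nodal_cross_length_corr": float(np.nanmin(nodal_corr.to_numpy()[off])),
            "min_module_cross_length_corr": float(np.nanmin(module_corr.to_numpy()[off])),
        }
        timings["sweep"] = time.time() - t0

    # --- run summary (deterministic: no wall-clock content) ---
    K = partition.n_modules
    summary = {
        "version": __version__,
        "config": _jsonable(asdict(config)),
        "n_subjects": int(len(series)),
        "n_control": int((~is_patient).sum()),
        "n_patient": int(is_patient.sum()),
        "n_nodes": partition.n_nodes,
        "n_modules": K,
        "unit_counts": {
            "nodal": partition.n_nodes,
            "intra": K,
            "inter": K * (K - 1) // 2,
        },
        "diagnostics": sorted({d for vs in sets.values() for d in vs.diagnostics}),
        "significant_units": {
            "nodal": comparison.loc[comparison["sig_nodal"], "unit"].tolist(),
            "network_p05": comparison.loc[comparison["sig_network_p05"], "unit"].tolist(),
            "network_p005": comparison.loc[comparison["sig_network_p005"], "unit"].tolist(),
        },
        "sweep": sweep_summary,
    }
    assert len(units) == partition.n_nodes + K + K * (K - 1) // 2
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    for stage, dt in timings.items():
        logger.info("stage %-18s %.2fs", stage, dt)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def render_report(run_dir: str | Path, include_uncertain: bool = False) -> Path:
    """Human-readable summary tables from a completed run directory."""
    run_dir = Path(run_dir)
    if (run_dir / _INCOMPLETE).exists() or not (run_dir / "run_summary.json").exists():
        raise RuntimeError(
            f"{run_dir} is not a completed run (incomplete marker or missing summary); "
            "check run.log for the failed stage"
        )
    report = run_dir / "report"
    report.mkdir(exist_ok=True)
    comparison = pd.read_csv(run_dir / "group_comparison.tsv", sep="\t")
    long = pd.read_csv(run_dir / "variability.tsv", sep="\t")
    with open(run_dir / "run_summary.json") as fh:
        summary = json.load(fh)

    def _keep(unit_col: pd.Series) -> pd.Series:
        if include_uncertain:
            return pd.Series(True, index=unit_col.index)
        return ~unit_col.astype(str).str.split("|").apply(lambda xs: UNCERTAIN_LABEL in xs)

    # Table of significant nodal units, in the style of a regions table
    nodal = comparison[(comparison["level"] == "nodal") & comparison["sig_nodal"]]
    table = nodal[["unit", "mean_control", "mean_patient", "p_two_sided"]].rename(
        columns={"unit": "node_index", "mean_control": "NC", "mean_patient": "PD"}
    )
    _write_tsv(table, report / "significant_nodes.tsv")

    # K x K group-mean variability matrices
    mods = long[long["level"].isin(["intra", "inter"])]
    manifest = pd.read_csv(Path(summary["config"]["manifest"]), sep="\t")
    group_of = dict(zip(manifest["subject_id"], manifest["group"].str.lower()))
    mods = mods.assign(group=mods["subject_id"].map(group_of))
    labels = [
        m for m in long.loc[long["level"] == "intra", "unit"].unique()
        if include_uncertain or m != UNCERTAIN_LABEL
    ]
    for g, sub in mods.groupby("group"):
        mat = pd.DataFrame(np.nan, index=labels, columns=labels)
        means = sub.groupby(["level", "unit"])["value"].mean()
        for m in labels:
            if ("intra", m) in means.index:
                mat.loc[m, m] = means[("intra", m)]
        for (level, unit), v in means.items():
            if level == "inter":
                a, b = unit.split("|")
                if a in labels and b in labels:
                    mat.loc[a, b] = mat.loc[b, a] = v
        mat.to_csv(report / f"variability_matrix_{g}.tsv", sep="\t", float_format="%.6g")

    # Scatter data for significant clinical correlations
    clinical_path = run_dir / "clinical_correlation.tsv"
    if clinical_path.exists():
        clinical = pd.read_csv(clinical_path, sep="\t")
        if len(clinical):
            sig = clinical[(clinical["p"] < 0.05) & _keep(clinical["unit"])]
            _write_tsv(sig, report / "significant_clinical_correlations.tsv")

    # Module-level comparison restricted to reportable modules
    net = comparison[comparison["level"].isin(["intra", "inter"]) & _keep(comparison["unit"])]
    _write_tsv(net, report / "network_comparison.tsv")
    return report
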