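"""End-to-end orchestration: simulate -> QC -> connect -> metrics -> hubs -> stats.

A :class:`PipelineConfig` fixes every parameter and every seed, so a run is
idempotent: identical config and seeds give byte-identical output tables.
Each stage consumes and produces only the documented text formats (see
:mod:`connectopharm.io`), and every output file records the configuration
hash it was produced under.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cohort import (
    SESSIONS,
    CohortSpec,
    GroundTruth,
    SubjectRecord,
    generate_cohort,
    simulate_motion,
    simulate_timeseries,
)
from .connectivity import (
    BinaryGraph,
    TimeSeriesMatrix,
    coverage_exclude,
    drop_initial_volumes,
    fisher_z,
    highpass_filter,
    local_threshold,
    regress_nuisance,
    wavelet_correlation,
)
from .hubs import HubSet, hub_summary, identify_hubs, split_half
from .metrics import MetricsRecord, compute_metrics
from .motion import exclude_by_motion, rms_displacement
from .stats import (
    COVARIATES,
    DEFAULT_REPORT_METRICS,
    build_study_table,
    covariate_regression,
    disease_effect_report,
    paired_drug_contrast,
    remove_outliers,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "PipelineResult", "preprocess", "subject_graph"]


def _default_densities() -> list[float]:
    return [round(0.01 * i, 2) for i in range(1, 11)]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    output_dir: str = "artifacts"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    wavelet_name: str = "db4"
    scale: int = 3
    densities: list[float] = field(default_factory=_default_densities)
    primary_density: float = 0.06
    hub_k: float = 1.5
    outlier_k: float = 2.0
    split_half_seed: int = 1
    louvain_seed: int = 2
    louvain_restarts: int = 20
    drop_volumes: int = 5
    highpass_hz: float = 0.01
    coverage_min_subjects: int = 10
    alpha: float = 0.05
    motion_qc: bool = True
    nuisance_regression: bool = True
    write_timeseries: bool = False
    write_matrices: bool = False
    write_graphs: bool = True
    make_plots: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        if self.primary_density not in [round(d, 6) for d in self.densities]:
            raise ValueError(
                f"primary_density {self.primary_density} must be in the density schedule"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# per-subject processing


def preprocess(
    ts: TimeSeriesMatrix,
    config: PipelineConfig,
    nuisance: np.ndarray | None = None,
) -> TimeSeriesMatrix:
    """Volume trimming, high-pass filtering and optional nuisance regression."""
    out = drop_initial_volumes(ts, config.drop_volumes)
    out = highpass_filter(out, config.highpass_hz)
    if nuisance is not None and config.nuisance_regression:
        cols = nuisance[config.drop_volumes:, :]
        keep = cols.std(axis=0) > 0
        if keep.any():
            out = regress_nuisance(out, cols[:, keep])
    return out


def subject_graph(
    ts: TimeSeriesMatrix, config: PipelineConfig, density: float | None = None
) -> BinaryGraph:
    """Wavelet correlation -> Fisher z -> local threshold for one subject."""
    assoc = wavelet_correlation(ts, scale=config.scale, wavelet_name=config.wavelet_name)
    z = fisher_z(assoc)
    return local_threshold(z, density or config.primary_density)


# ---------------------------------------------------------------------------
# results container


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: list[SubjectRecord]
    truth: GroundTruth
    motion_qc: pd.DataFrame | None
    excluded_subjects: list[str]
    metrics_table: pd.DataFrame
    hub_set: HubSet
    study_table: pd.DataFrame
    disease_report: pd.DataFrame
    drug_regressions: pd.DataFrame
    output_dir: Path


def _motion_stage(
    records: list[SubjectRecord], config: PipelineConfig, outdir: Path | None
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate motion, compute RMS displacement, apply the exclusion rules."""
    spec = config.cohort
    meta = {"config_hash": config.config_hash}
    per_record: dict[tuple[str, str], float] = {}
    for rec in records:
        trace = simulate_motion(rec, spec)
        per_record[(rec.subject_id, rec.session)] = rms_displacement(trace)
        if outdir is not None:
            mdir = outdir / "motion"
            mdir.mkdir(exist_ok=True)
            cio.write_motion(trace, mdir / f"{rec.subject_id}_{rec.session}.tsv", meta)

    by_subject: dict[str, list[float]] = {}
    for (sid, _), v in per_record.items():
        by_subject.setdefault(sid, []).append(v)
    values = {sid: float(np.mean(v)) for sid, v in by_subject.items()}

    paired: dict[str, float] = {}
    for sid in values:
        pl = per_record.get((sid, "placebo"))
        if pl is None:
            continue
        diffs = [
            abs(pl - per_record[(sid, drug)])
            for drug in ("atomoxetine", "citalopram")
            if (sid, drug) in per_record
        ]
        if diffs:
            paired[sid] = max(diffs)

    flags = exclude_by_motion(values, paired or None, k=config.outlier_k)
    flags.index.name = "subject_id"
    excluded = sorted(flags.index[flags.exclude])
    if excluded:
        logger.info("motion QC excluded %d subject(s): %s", len(excluded), excluded)
    return flags.reset_index(), excluded


def _drug_regression_table(
    study: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Difference-score regressions of each metric on each covariate, per drug."""
    rows = []
    for drug in ("atomoxetine", "citalopram"):
        drug_rows = study[(study.session == drug) & (study.group == "patient")]
        for metric in DEFAULT_REPORT_METRICS:
            try:
                delta = paired_drug_contrast(study, metric, drug)
            except ValueError:
                continue
            if len(delta) >= 3:
                delta, removed = remove_outliers(delta, k=config.outlier_k)
            else:
                removed = []
            cov_frame = (
                drug_rows[drug_rows.metric == metric]
                .set_index("subject_id")[list(COVARIATES)]
            )
            for cov in COVARIATES:
                x = cov_frame[cov].reindex(delta.index)
                try:
                    res = covariate_regression(delta, x, alpha=config.alpha)
                except ValueError:
                    continue
                rows.append(
                    {
                        "drug": drug,
                        "metric": metric,
                        "covariate": cov,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "r_squared": res.r_squared,
                        "p": res.p,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n": res.n,
                        "n_outliers_removed": len(removed),
                    }
                )
    return pd.DataFrame(rows)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _plots(study: pd.DataFrame, regressions: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pdir = outdir / "plots"
    pdir.mkdir(exist_ok=True)
    top = regressions.nsmallest(min(4, len(regressions)), "p")
    for _, row in top.iterrows():
        delta = paired_drug_contrast(study, row.metric, row.drug)
        cov = (
            study[(study.session == row.drug) & (study.metric == row.metric)]
            .set_index("subject_id")[row.covariate]
            .reindex(delta.index)
        )
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(cov, delta, s=18)
        ax.set_xlabel(row.covariate)
        ax.set_ylabel(f"Δ {row.metric} ({row.drug} - placebo)")
        ax.set_title(f"slope={row.slope:.3g}, p={row.p:.3g}")
        fig.tight_layout()
        fig.savefig(pdir / f"{row.drug}_{row.metric}_{row.covariate}.png", dpi=100)
        plt.close(fig)


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write the artifact directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    meta = {"config_hash": h}
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("connectopharm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        config.to_yaml(outdir / "config.yaml")
        (outdir / "config_hash.txt").write_text(h + "\n")

        # -- simulate --------------------------------------------------
        logger.info("stage simulate: generating cohort (seed=%d)", config.cohort.seed)
        records, truth = generate_cohort(config.cohort)
        cio.write_subjects(records, outdir / "subjects.tsv", meta)
        truth_payload = {
            "config_hash": h,
            "module_assignment": truth.module_assignment.tolist(),
            "hub_nodes": truth.hub_nodes.tolist(),
            "injected": {
                f"{sid}/{session}": fac for (sid, session), fac in truth.injected.items()
            },
        }
        (outdir / "truth.yaml").write_text(yaml.safe_dump(truth_payload, sort_keys=False))

        # -- motion QC -------------------------------------------------
        motion_table, excluded = (None, [])
        if config.motion_qc:
            logger.info("stage qc: motion screening")
            motion_table, excluded = _motion_stage(records, config, outdir)
            _write_table(motion_table, outdir / "motion_qc.tsv", h)
        kept = [r for r in records if r.subject_id not in excluded]

        # -- connect + metrics ----------------------------------------
        logger.info("stage connect: %d record(s)", len(kept))
        processed: dict[tuple[str, str], TimeSeriesMatrix] = {}
        for rec in kept:
            try:
                ts = simulate_timeseries(rec, truth, config.cohort)
                nuis = None
                if config.motion_qc and config.nuisance_regression:
                    trace = simulate_motion(rec, config.cohort)
                    params = np.hstack([trace.translations, trace.rotations])
                    nuis = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
                processed[(rec.subject_id, rec.session)] = preprocess(ts, config, nuis)
            except Exception as err:
                raise RuntimeError(
                    f"stage connect failed for subject {rec.subject_id} "
                    f"session {rec.session}: {err}"
                ) from err

        validity = np.array(
            [ts.values.std(axis=1) > 0 for ts in processed.values()], dtype=bool
        )
        keep_nodes = coverage_exclude(validity, config.coverage_min_subjects)
        keep_idx = np.asarray(keep_nodes, dtype=int)
        if len(keep_idx) < config.cohort.n_nodes:
            logger.info(
                "coverage screening dropped %d node(s)",
                config.cohort.n_nodes - len(keep_idx),
            )

        if config.write_timeseries:
            tdir = outdir / "timeseries"
            tdir.mkdir(exist_ok=True)
        graphs_by_density: dict[float, dict[tuple[str, str], BinaryGraph]] = {
            d: {} for d in config.densities
        }
        for (sid, session), ts in processed.items():
            sub = TimeSeriesMatrix(
                ts.values[keep_idx],
                ts.tr_seconds,
                [ts.node_labels[i] for i in keep_idx],
            )
            if config.write_timeseries:
                cio.write_timeseries(sub, tdir / f"{sid}_{session}.tsv", meta)
            try:
                assoc = wavelet_correlation(sub, config.scale, config.wavelet_name)
                z = fisher_z(assoc)
            except Exception as err:
                raise RuntimeError(
                    f"stage connect failed for subject {sid} session {session}: {err}"
                ) from err
            if config.write_matrices:
                zdir = outdir / "zmatrices"
                zdir.mkdir(exist_ok=True)
                cio.write_association(z, zdir / f"{sid}_{session}.tsv", meta)
            for d in config.densities:
                graphs_by_density[d][(sid, session)] = local_threshold(z, d)
            if config.write_graphs:
                gdir = outdir / "graphs"
                gdir.mkdir(exist_ok=True)
                g6 = graphs_by_density[config.primary_density][(sid, session)]
                pct = int(round(config.primary_density * 100))
                cio.write_graph(g6, gdir / f"{sid}_{session}_d{pct:02d}.tsv", meta)

        logger.info("stage metrics: %d graphs", sum(len(v) for v in graphs_by_density.values()))
        metric_records: dict[tuple[str, str, float], MetricsRecord] = {}
        group_of = {r.subject_id: r.group for r in kept}
        for d in config.densities:
            for (sid, session), g in graphs_by_density[d].items():
                metric_records[(sid, session, d)] = compute_metrics(
                    g,
                    sid,
                    session,
                    n_restarts=config.louvain_restarts,
                    seed=config.louvain_seed,
                    density=d,
                )

        # -- hubs ------------------------------------------------------
        control_ids = sorted({sid for sid, g in group_of.items() if g == "control"})
        definition, evaluation = split_half(control_ids, seed=config.split_half_seed)
        logger.info(
            "stage hubs: split %d controls into %d definition / %d evaluation",
            len(control_ids),
            len(definition),
            len(evaluation),
        )
        def_graphs = {
            sid: graphs_by_density[config.primary_density][(sid, "none")]
            for sid in definition
        }
        hub_set = identify_hubs(def_graphs, k=config.hub_k, evaluation_cohort=evaluation)
        logger.info("stage hubs: %d hub node(s), threshold %.3f", hub_set.n_hubs, hub_set.threshold)
        some_graph = next(iter(def_graphs.values()))
        hub_meta = dict(
            meta,
            split_half_seed=config.split_half_seed,
            primary_density=config.primary_density,
        )
        cio.write_hubset(hub_set, outdir / "hubs.yaml", some_graph.node_labels, hub_meta)
        for rec in metric_records.values():
            hub_summary(rec, hub_set)

        metrics_table = pd.DataFrame(
            [metric_records[key].to_row() for key in sorted(metric_records)]
        )
        _write_table(metrics_table, outdir / "metrics.tsv", h)

        # -- stats -----------------------------------------------------
        logger.info("stage stats")
        primary_rows = [
            metric_records[key].to_row()
            for key in sorted(metric_records)
            if key[2] == config.primary_density
        ]
        study = build_study_table(kept, primary_rows)
        eval_set = set(evaluation)
        ctrl_rows = study[study.group == "control"]
        disease = disease_effect_report(
            controls_eval=ctrl_rows[ctrl_rows.subject_id.isin(eval_set)],
            patients_placebo=study[(study.group == "patient") & (study.session == "placebo")],
            controls_all=ctrl_rows,
            outlier_k=config.outlier_k,
        )
        regressions = _drug_regression_table(study, config)

        sdir = outdir / "stats"
        sdir.mkdir(exist_ok=True)
        _write_table(study, sdir / "study_table.tsv", h)
        _write_table(disease, sdir / "disease_report.tsv", h)
        _write_table(regressions, sdir / "drug_regressions.tsv", h)
        _write_report(disease, regressions, config, sdir / "report.txt")
        if config.make_plots and not regressions.empty:
            _plots(study, regressions, outdir)

        return PipelineResult(
            config=config,
            records=records,
            truth=truth,
            motion_qc=motion_table,
            excluded_subjects=excluded,
            metrics_table=metrics_table,
            hub_set=hub_set,
            study_table=study,
            disease_report=disease,
            drug_regressions=regressions,
            output_dir=outdir,
        )
    finally:
        root.removeHandler(handler)
        handler.close()


def _write_report(
    disease: pd.DataFrame,
    regressions: pd.DataFrame,
    config: PipelineConfig,
    path: Path,
) -> None:
    lines = [
        f"# config_hash={config.config_hash}",
        "",
        "Disease effect (patients on placebo vs controls), primary density "
        f"{config.primary_density:.0%}:",
    ]
    for _, r in disease.iterrows():
        star = " *" if r.p < config.alpha else ""
        lines.append(
            f"  {r.metric:<22} t={r.t:+7.3f}  p={r.p:.4f}{star}  ({r.direction}, "
            f"controls: {r.control_source}, n={r.n_controls}+{r.n_patients})"
        )
    lines.append("")
    lines.append(
        f"Drug effects (difference-score regressions, alpha={config.alpha}), "
        f"significant slopes only:"
    )
    if regressions.empty:
        lines.append("  (no regressions computed)")
    else:
        sig = regressions[regressions.p < config.alpha]
        if sig.empty:
            lines.append("  (none)")
        for _, r in sig.iterrows():
            lines.append(
                f"  {r.drug:<12} d{r.metric} ~ {r.covariate:<24} "
                f"slope={r.slope:+.4g}  r2={r.r_squared:.3f}  p={r.p:.4f}  n={r.n}"
            )
    lines.append("")
    lines.append("A correction for multiple comparisons was not applied "
                 "(network measures are not independent).")
    Path(path).write_text("\n".join(lines) + "\n")
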