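"""Monte-Carlo experiments on the synthetic cohort.

These are the package's calibration and validation studies: null
calibration of the wavelet correlation, recovery of planted hubs, type-I
error of the full pipeline-to-regression chain, sign recovery of injected
drug effects, and detection of planted motion outliers.  Each experiment is
a plain function returning a small dict of summary numbers, so the same
code backs the test suite and reproducibility scripts.

Cohort sizes are arguments with study-scale defaults; the reduced sizes
used by the heavier experiments (fewer nodes and controls per cohort) are
chosen so a full experiment runs in minutes on one core while keeping the
module/hub geometry of the full design (module size just below the mean
degree at the primary density, 5% hub nodes).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import (
    CohortSpec,
    generate_cohort,
    simulate_motion,
    simulate_timeseries,
)
from .connectivity import effective_df, wavelet_correlation, TimeSeriesMatrix
from .hubs import hub_summary, identify_hubs, split_half
from .metrics import (
    MetricsRecord,
    _geodesics,
    clustering_coefficient,
    degree,
    eigen_centrality,
)
from .motion import exclude_by_motion, rms_displacement
from .pipeline import PipelineConfig, preprocess, subject_graph
from .stats import build_study_table, covariate_regression, paired_drug_contrast

__all__ = [
    "null_correlation_calibration",
    "hub_recovery",
    "cohort_regressions",
    "type1_error",
    "drug_effect_recovery",
    "motion_outlier_detection",
]


def null_correlation_calibration(
    n_replicates: int = 1000,
    n_volumes: int = 140,
    scale: int = 3,
    wavelet_name: str = "db4",
    seed: int = 0,
) -> dict:
    """Wavelet correlation of independent white-noise pairs against the
    1% two-sided null bound ``2.58 / sqrt(effective_df)``.

    Returns the fraction of replicates inside the bound (nominally >= 0.99)
    and the empirical null SD of r.
    """
    rng = np.random.default_rng(seed)
    bound = 2.58 / np.sqrt(effective_df(n_volumes, scale, wavelet_name))
    rs = np.empty(n_replicates)
    for i in range(n_replicates):
        ts = TimeSeriesMatrix(rng.standard_normal((2, n_volumes)), tr_seconds=2.0)
        rs[i] = wavelet_correlation(ts, scale, wavelet_name).values[0, 1]
    return {
        "fraction_within_bound": float((np.abs(rs) < bound).mean()),
        "bound": float(bound),
        "null_sd": float(rs.std()),
        "n_replicates": n_replicates,
    }


def _spec_with(base: CohortSpec | None, **overrides) -> CohortSpec:
    if base is None:
        return CohortSpec(**overrides)
    return dataclasses.replace(base, **overrides)


def hub_recovery(
    n_seeds: int = 20,
    spec: CohortSpec | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> dict:
    """Sensitivity and false-discovery rate of split-half hub identification
    against the generator's planted hub set, averaged over seeds.

    Each seed draws a fresh cohort, builds the definition-half control
    graphs at the primary density and applies the 1.5-SD degree rule.
    """
    sens, fdr = [], []
    for s in range(n_seeds):
        sp = _spec_with(spec, seed=seed + s)
        cfg = config or PipelineConfig(cohort=sp)
        records, truth = generate_cohort(sp)
        by_key = {(r.subject_id, r.session): r for r in records}
        controls = sorted({r.subject_id for r in records if r.group == "control"})
        definition, evaluation = split_half(controls, seed=seed + s)
        graphs = {}
        for sid in definition:
            ts = preprocess(simulate_timeseries(by_key[(sid, "none")], truth, sp), cfg)
            graphs[sid] = subject_graph(ts, cfg)
        hub_set = identify_hubs(graphs, k=cfg.hub_k, evaluation_cohort=evaluation)
        true = set(truth.hub_nodes.tolist())
        found = set(hub_set.hub_nodes.tolist())
        sens.append(len(true & found) / len(true))
        fdr.append(len(found - true) / max(1, len(found)))
    return {
        "sensitivity": float(np.mean(sens)),
        "false_discovery_rate": float(np.mean(fdr)),
        "n_seeds": n_seeds,
    }


#: metrics used by the regression experiments (modularity omitted: the
#: Louvain restarts dominate runtime and add nothing to these properties)
_FAST_METRICS = ("clustering", "path_length", "hub_degree", "hub_eigen_centrality")


def cohort_regressions(
    spec: CohortSpec,
    config: PipelineConfig | None = None,
    metrics: tuple[str, ...] = _FAST_METRICS,
    covariates: dict[str, tuple[str, ...]] | None = None,
    split_seed: int | None = None,
):
    """Run one cohort through the pipeline and return the difference-score
    regression results.

    ``covariates`` maps drug -> covariate columns; default uses plasma
    concentration and disease severity for the noradrenergic drug, severity
    and dopaminergic dose for the serotonergic drug.  Yields tuples
    ``(drug, metric, covariate, RegressionResult)``.
    """
    cfg = config or PipelineConfig(cohort=spec)
    covariates = covariates or {
        "atomoxetine": ("plasma_ng_ml", "updrs_iii"),
        "citalopram": ("updrs_iii", "led_mg_day"),
    }
    records, truth = generate_cohort(spec)
    by_key = {(r.subject_id, r.session): r for r in records}
    controls = sorted({r.subject_id for r in records if r.group == "control"})
    definition, evaluation = split_half(
        controls, seed=spec.seed if split_seed is None else split_seed
    )
    graphs = {}
    rows = []
    for r in records:
        ts = preprocess(simulate_timeseries(r, truth, spec), cfg)
        g = subject_graph(ts, cfg)
        if r.group == "control" and r.subject_id in definition:
            graphs[r.subject_id] = g
        # modularity and betweenness are skipped: neither is in
        # _FAST_METRICS and together they dominate runtime; path length and
        # closeness share one all-pairs BFS
        d = _geodesics(g, "cohort_regressions")
        iu = np.triu_indices(g.n_nodes, 1)
        rows.append(
            (
                r,
                MetricsRecord(
                    r.subject_id,
                    r.session,
                    g.density,
                    float(d[iu].mean()),
                    clustering_coefficient(g),
                    0.0,
                    degree(g),
                    np.zeros(g.n_nodes),
                    (g.n_nodes - 1) / d.sum(axis=1),
                    eigen_centrality(g),
                ),
            )
        )
    hub_set = identify_hubs(graphs, k=cfg.hub_k, evaluation_cohort=evaluation)
    metric_rows = []
    for r, rec in rows:
        hub_summary(rec, hub_set)
        metric_rows.append(rec.to_row())
    study = build_study_table([r for r, _ in rows], metric_rows)

    results = []
    for drug, covs in covariates.items():
        for metric in metrics:
            delta = paired_drug_contrast(study, metric, drug)
            frame = study[(study.session == drug) & (study.metric == metric)].set_index(
                "subject_id"
            )
            for cov in covs:
                x = frame[cov].reindex(delta.index)
                results.append((drug, metric, cov, covariate_regression(delta, x)))
    return results


def type1_error(
    n_cohorts: int = 63,
    alpha: float = 0.05,
    seed: int = 0,
    n_nodes: int = 60,
    n_controls: int = 12,
    n_patients: int = 30,
) -> dict:
    """Rejection rate of the pipeline-to-regression chain on null cohorts.

    Cohorts carry the modular/hub structure but no injected disease or drug
    effects, so every drug-by-covariate slope is null; the fraction of
    regressions with p < alpha estimates the chain's type-I error
    (nominally alpha).
    """
    n_reject = n_total = 0
    for c in range(n_cohorts):
        spec = CohortSpec(
            seed=seed + c,
            n_nodes=n_nodes,
            n_controls=n_controls,
            n_patients=n_patients,
            drug_effect_atomoxetine=0.0,
            drug_effect_citalopram=0.0,
            disease_effect=0.0,
        )
        for _, _, _, res in cohort_regressions(spec):
            n_total += 1
            n_reject += res.p < alpha
    return {
        "rejection_rate": n_reject / n_total,
        "n_regressions": n_total,
        "alpha": alpha,
    }


def drug_effect_recovery(
    n_seeds: int = 50,
    seed: int = 0,
    n_nodes: int = 60,
    n_controls: int = 12,
    n_patients: int = 30,
    spec: CohortSpec | None = None,
) -> dict:
    """Sign recovery of the injected drug effects across seeds.

    Checks that the slope of d(hub eigenvector centrality) on plasma
    concentration is positive under the noradrenergic effect, and the slope
    of d(clustering) on disease severity is negative under the
    severity-pivoted serotonergic effect.
    """
    atx_pos = cit_neg = 0
    for s in range(n_seeds):
        sp = _spec_with(
            spec,
            seed=seed + s,
            n_nodes=n_nodes,
            n_controls=n_controls,
            n_patients=n_patients,
        )
        results = {
            (drug, metric, cov): res
            for drug, metric, cov, res in cohort_regressions(sp)
        }
        atx_pos += results[("atomoxetine", "hub_eigen_centrality", "plasma_ng_ml")].slope > 0
        cit_neg += results[("citalopram", "clustering", "updrs_iii")].slope < 0
    return {
        "atomoxetine_positive_fraction": atx_pos / n_seeds,
        "citalopram_negative_fraction": cit_neg / n_seeds,
        "n_seeds": n_seeds,
    }


def motion_outlier_detection(
    n_seeds: int = 100,
    n_subjects: int = 10,
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> dict:
    """Fraction of seeds in which a planted high-motion subject is excluded.

    One subject per cohort is simulated with the outlier flag; exclusion
    uses the one-sided mean + 2 SD rule on RMS displacement.
    """
    detected = 0
    for s in range(n_seeds):
        sp = _spec_with(spec, seed=seed + s, n_controls=n_subjects, n_patients=1)
        records, _ = generate_cohort(sp)
        controls = [r for r in records if r.group == "control"]
        values = {}
        for i, rec in enumerate(controls):
            trace = simulate_motion(rec, sp, outlier=(i == 0))
            values[rec.subject_id] = rms_displacement(trace)
        flags = exclude_by_motion(values)
        detected += bool(flags.loc[controls[0].subject_id, "exclude"])
    return {"detection_rate": detected / n_seeds, "n_seeds": n_seeds}
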