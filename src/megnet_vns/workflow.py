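"""End-to-end pipeline orchestration.

Stages: simulate -> PLV connectivity -> cost-thresholded graph measures ->
heritability / reliability / group statistics / classification.  A single
master seed is expanded into per-stage child seeds through a fixed
``numpy.random.SeedSequence`` splitting scheme, so each stage is
independently re-runnable yet the whole pipeline is reproducible; the
provenance record holds the config and every derived seed.

Heritability runs on simulated twin traits from the pedigree spec: the
signal generator controls phase coupling per *group*, not per *genotype*, so
genetic structure enters through the trait simulator rather than the time
series.  All other stages consume the graph features of the simulated
cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import BANDS, all_band_plv_matrices
from .groupstats import bootstrap_two_way_anova, controls_vs_group_test, fdr_adjust
from .heritability import build_kinship, estimate_h2
from .netmeasures import DEFAULT_COST, MEASURES, subject_features
from .reliability import icc_two_way
from .synthcohort import (
    Cohort,
    CohortSpec,
    PATIENT_GROUPS,
    PedigreeSpec,
    generate_cohort,
    generate_twin_traits,
)
from .vnsclassify import balanced_repeated_cv, select_features

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "cohort_features",
    "features_to_wide",
    "heritability_table",
    "reliability_table",
    "groupstats_table",
    "stage_seeds",
]


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    pedigree: PedigreeSpec = field(default_factory=PedigreeSpec)
    epoch_len_s: float = 3.0
    cost: float = DEFAULT_COST
    n_restarts: int = 100
    n_boot: int = 10_000
    n_reps: int = 1000
    n_controls_drawn: int = 14
    k_folds: int = 10
    feature_sets: tuple[str, ...] = ("theta", "alpha", "beta", "all")
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_restarts", "n_boot", "n_reps", "k_folds", "n_controls_drawn"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch length must be positive")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds (< 2**31) from one master seed."""
    names = ["cohort", "graph", "pedigree", "stats", "classify"]
    state = np.random.SeedSequence(master_seed).generate_state(len(names))
    return {n: int(s & 0x7FFFFFFF) for n, s in zip(names, state)}


def cohort_features(
    cohort: Cohort,
    epoch_len_s: float = 3.0,
    cost: float = DEFAULT_COST,
    n_restarts: int = 100,
    seed: int = 0,
    bands: list[str] | None = None,
) -> pd.DataFrame:
    """Connectivity + graph stage: tidy per-run feature table.

    Columns: subject_id, group, band, run, modularity, transitivity, cpl,
    cost_used.
    """
    bands = list(BANDS) if bands is None else bands
    rows = []
    for row in cohort.manifest.itertuples():
        sid = row.subject_id
        per_band_runs: dict[str, list[np.ndarray]] = {b: [] for b in bands}
        for run in cohort.runs[sid]:
            mats = all_band_plv_matrices(
                run, bands=bands, epoch_len_s=epoch_len_s,
                bin_centers=cohort.spec.bin_centers,
            )
            for b in bands:
                per_band_runs[b].append(mats[b].matrix)
        for b in bands:
            feats = subject_features(
                per_band_runs[b], cost=cost, subject_id=sid, band=b,
                n_restarts=n_restarts, seed=seed,
            )
            for r in range(len(per_band_runs[b])):
                rows.append(
                    dict(
                        subject_id=sid,
                        group=row.group,
                        band=b,
                        run=r,
                        modularity=feats.per_run["modularity"][r],
                        transitivity=feats.per_run["transitivity"][r],
                        cpl=feats.per_run["cpl"][r],
                        cost_used=cost,
                    )
                )
    return pd.DataFrame(rows)


def features_to_wide(per_run: pd.DataFrame) -> pd.DataFrame:
    """Run-averaged wide table: one row per subject, columns <measure>_<band>."""
    avg = (
        per_run.groupby(["subject_id", "group", "band"])[list(MEASURES)]
        .mean()
        .reset_index()
    )
    wide = avg.pivot(index=["subject_id", "group"], columns="band", values=list(MEASURES))
    wide.columns = [f"{m}_{b}" for m, b in wide.columns]
    return wide.reset_index().set_index("subject_id")


def heritability_table(pedigree_spec: PedigreeSpec, seed: int,
                       bands: tuple[str, ...] = ("theta", "alpha", "beta")) -> pd.DataFrame:
    """Estimate h2 for one simulated twin trait per measure x band."""
    rows = []
    j = 0
    for measure in MEASURES:
        for band in bands:
            twins = generate_twin_traits(replace(pedigree_spec, seed=seed + j))
            kin = build_kinship(twins.pedigree)
            fit = estimate_h2(
                twins.traits.to_numpy(),
                twins.covariates["age"].to_numpy(),
                twins.covariates["sex"].to_numpy(),
                kin,
            )
            rows.append(
                dict(
                    measure=measure,
                    band=band,
                    h2=fit.h2,
                    p_value=fit.p_value,
                    covariate_variance_explained_pct=100 * fit.covariate_variance_explained,
                    significant=fit.p_value < 0.01,
                )
            )
            j += 1
    return pd.DataFrame(rows)


def reliability_table(per_run: pd.DataFrame) -> pd.DataFrame:
    """ICC per measure x band for controls and for pooled patients."""
    rows = []
    groups = {
        "controls": per_run.group == "control",
        "patients": per_run.group.isin(PATIENT_GROUPS),
    }
    for gname, mask in groups.items():
        sub = per_run[mask]
        if sub.empty:
            continue
        for band in sub.band.unique():
            for measure in MEASURES:
                table = (
                    sub[sub.band == band]
                    .pivot(index="subject_id", columns="run", values=measure)
                    .dropna()
                )
                res = icc_two_way(table.to_numpy())
                rows.append(
                    dict(group=gname, measure=measure, band=band,
                         icc=res.icc, rating=res.rating)
                )
    return pd.DataFrame(rows)


def groupstats_table(
    wide: pd.DataFrame,
    manifest: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap two-way ANOVA (response x sedation) on patients plus
    control-vs-group rank tests, FDR-corrected across the nine features."""
    sed = manifest.set_index("subject_id")["sedation"]
    wide = wide.join(sed)
    patients = wide[wide.group.isin(PATIENT_GROUPS)]
    controls = wide[wide.group == "control"]
    feature_cols = [c for c in wide.columns if any(c.startswith(m) for m in MEASURES)]

    rows = []
    rng = np.random.default_rng(seed)
    for colname in feature_cols:
        res = bootstrap_two_way_anova(
            patients[colname].to_numpy(),
            (patients.group == "responder").to_numpy(),
            patients.sedation.to_numpy(),
            n_boot=n_boot,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        row = dict(
            feature=colname,
            p_response=res["p_a"],
            p_sedation=res["p_b"],
        )
        for g, label in (("responder", "responders"), ("non-responder", "non_responders")):
            gv = wide.loc[wide.group == g, colname]
            row[f"mean_{label}"] = gv.mean()
            row[f"sd_{label}"] = gv.std()
        row["mean_controls"] = controls[colname].mean()
        row["sd_controls"] = controls[colname].std()
        if len(controls):
            for g, label in (("responder", "responders"), ("non-responder", "non_responders")):
                row[f"p_controls_vs_{label}"] = controls_vs_group_test(
                    controls[colname].to_numpy(),
                    wide.loc[wide.group == g, colname].to_numpy(),
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    adj = fdr_adjust(out["p_response"].to_numpy())
    out["p_response_fdr"] = adj["p_fdr"].to_numpy()
    out["bh_critical"] = adj["bh_critical"].to_numpy()
    out["significant_response"] = adj["significant"].to_numpy()
    if "p_controls_vs_responders" in out:
        cv = np.concatenate(
            [out["p_controls_vs_responders"], out["p_controls_vs_non_responders"]]
        )
        cv_adj = fdr_adjust(cv)["p_fdr"].to_numpy()
        half = len(out)
        out["p_controls_vs_responders_fdr"] = cv_adj[:half]
        out["p_controls_vs_non_responders_fdr"] = cv_adj[half:]
    return out


@dataclass
class PipelineResult:
    config: PipelineConfig
    seeds: dict[str, int]
    manifest: pd.DataFrame
    features_per_run: pd.DataFrame
    features_wide: pd.DataFrame
    heritability: pd.DataFrame
    reliability: pd.DataFrame
    groupstats: pd.DataFrame
    classifier_reports: dict[str, object]
    provenance: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage from a single config; idempotent for a fixed seed."""
    seeds = stage_seeds(config.master_seed)

    cohort = generate_cohort(replace(config.cohort, seed=seeds["cohort"]))
    per_run = cohort_features(
        cohort,
        epoch_len_s=config.epoch_len_s,
        cost=config.cost,
        n_restarts=config.n_restarts,
        seed=seeds["graph"],
    )
    wide = features_to_wide(per_run)

    h2_table = heritability_table(config.pedigree, seed=seeds["pedigree"])
    icc_table = reliability_table(per_run)
    stats_table = groupstats_table(
        wide, cohort.manifest, n_boot=config.n_boot, seed=seeds["stats"]
    )

    labels = (
        wide["group"]
        .map({"non-responder": "NR", "responder": "R", "control": "C"})
        .to_numpy()
    )
    reports = {}
    rng = np.random.default_rng(seeds["classify"])
    for fs in config.feature_sets:
        x, names = select_features(wide, bands=fs)
        reports[fs] = balanced_repeated_cv(
            x,
            labels,
            n_reps=config.n_reps,
            n_controls_drawn=config.n_controls_drawn,
            k=config.k_folds,
            seed=int(rng.integers(0, 2**31 - 1)),
            feature_names=names,
        )

    provenance = dict(
        package_version=__version__,
        master_seed=config.master_seed,
        stage_seeds=seeds,
        config=_config_dict(config),
    )
    result = PipelineResult(
        config=config,
        seeds=seeds,
        manifest=cohort.manifest,
        features_per_run=per_run,
        features_wide=wide,
        heritability=h2_table,
        reliability=icc_table,
        groupstats=stats_table,
        classifier_reports=reports,
        provenance=provenance,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _config_dict(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return convert(config)


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "manifest": result.manifest,
        "features_per_run": result.features_per_run,
        "features_avg": result.features_wide.reset_index(),
        "heritability": result.heritability,
        "reliability": result.reliability,
        "groupstats": result.groupstats,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        (out / f"{name}.md").write_text(df.to_markdown(index=False))
    for fs, rep in result.classifier_reports.items():
        rep.per_class.to_csv(out / f"classifier_{fs}.tsv", sep="\t")
        payload = dict(
            feature_set=fs,
            feature_names=rep.feature_names,
            confusion=rep.confusion.tolist(),
            overall_accuracy=rep.overall_accuracy,
            n_repetitions=rep.n_repetitions,
            per_class=json.loads(rep.per_class.to_json(orient="index")),
        )
        (out / f"classifier_{fs}.json").write_text(json.dumps(payload, indent=2))
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
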