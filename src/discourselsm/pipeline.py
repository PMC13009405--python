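"""End-to-end orchestration: score -> validate -> IRT -> regression ->
lesion suite, from a single config, with a manifest for byte-identical
re-runs.

The report bundle mirrors the structure of a discourse lesion-mapping
study: cohort summary, behavioural validation (checklist score vs CIU
correlation, severity correlations, subtype t-test), IRT fits with model
comparison and M2, the psycholinguistic regression, voxel-wise and
disconnection sparse-CCA maps with cross-validated significance, tract
partial correlations, and the predictive validity comparison.  All
randomness flows from config seeds; reports carry n, seed and package
version so a re-run with the same manifest is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import irt as irtmod
from . import lesionmap as lmap
from . import stats as st
from . import synthdata as sdata
from . import transcripts as tmod

log = logging.getLogger("discourselsm")

__all__ = ["RunConfig", "run_pipeline", "validation_report", "score_cohort"]


@dataclass
class RunConfig:
    simulate: dict | None = None          # SimulationConfig fields
    transcripts_dir: str | None = None
    checklist_path: str | None = None
    masks_dir: str | None = None
    atlas_path: str | None = None
    streamlines_path: str | None = None
    behaviour_path: str | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0
    irt_models: tuple = ("1PL", "2PL", "3PL")
    sparseness: float = -0.3
    folds: int = 4
    coverage_min_fraction: float = 0.10
    disconnection_threshold: float = 0.5
    subtype_groups: tuple = ("anomic", "broca")
    run_lesion_stages: bool = True

    def __post_init__(self):
        real = any([self.transcripts_dir, self.checklist_path, self.masks_dir,
                    self.behaviour_path])
        if self.simulate is not None and real:
            raise ValueError("config must use either a simulate block or real inputs, not both")
        if self.simulate is None and not real:
            raise ValueError("config needs a simulate block or input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        for key in ("transcripts_dir", "checklist_path", "masks_dir", "atlas_path",
                    "streamlines_path", "behaviour_path"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: {val} does not exist")
        return cfg


def score_cohort(transcripts, checklist) -> pd.DataFrame:
    """Score every transcript; returns one row per participant with
    CWF, CIU and word counts."""
    rows = []
    for tr in transcripts:
        res = tmod.score_cwf(tr, checklist)
        rows.append({
            "participant_id": tr.participant_id,
            "CWF": res.total,
            "CIU": tmod.count_cius(tr),
            "word_count": tmod.word_count(tr),
        })
    return pd.DataFrame(rows)


def validation_report(scores: pd.DataFrame,
                      subtype_groups=("anomic", "broca")) -> dict:
    """Behavioural validation: r(CWF, CIU) two-tailed, severity
    correlations when a severity column is present, and the pooled
    t-test between two named subtype groups when present."""
    need = {"CWF", "CIU"}
    complete = scores.dropna(subset=[c for c in ("CWF", "CIU") if c in scores])
    if not need <= set(scores.columns) or len(complete) < 3:
        raise ValueError("need at least 3 complete rows with CWF and CIU columns")
    out = {}
    r = st.pearson(complete["CWF"], complete["CIU"])
    out["r_cwf_ciu"] = {"r": r.r, "p": r.p, "n": r.n, "tails": r.tails}
    if "severity" in scores.columns:
        sub = scores.dropna(subset=["severity"])
        for col in ("CWF", "CIU"):
            rs = st.pearson(sub["severity"], sub[col])
            out[f"r_severity_{col.lower()}"] = {"r": rs.r, "p": rs.p, "n": rs.n}
    if "aphasia_type" in scores.columns and subtype_groups:
        ga, gb = subtype_groups
        a = scores.loc[scores["aphasia_type"] == ga]
        b = scores.loc[scores["aphasia_type"] == gb]
        if len(a) >= 2 and len(b) >= 2:
            out["subtype_t_tests"] = {}
            for col in ("CWF", "CIU"):
                t, df, p = st.pooled_t_test(a[col], b[col])
                out["subtype_t_tests"][col] = {
                    "groups": [ga, gb], "n": [len(a), len(b)],
                    "t": t, "df": df, "p": p,
                }
    return out


def _irt_stage(scores_results, checklist, models, seed) -> dict:
    matrix = tmod.response_matrix(scores_results, checklist, for_irt=True)
    out = {"n_items_retained": len(matrix.items),
           "dropped_items": list(matrix.dropped_items)}
    if len(matrix.items) < 2:
        out["skipped"] = "fewer than 2 informative items"
        return out
    fits = {}
    for model in models:
        fit = irtmod.fit_irt(matrix, model)
        fits[model] = fit
        out[model] = {
            "log_likelihood": fit.log_likelihood,
            "n_params": fit.n_params,
            "converged": fit.converged,
        }
    if "1PL" in fits:
        for other in ("2PL", "3PL"):
            if other in fits:
                cmp_ = irtmod.compare_models(fits["1PL"], fits[other])
                out[f"lrt_1PL_vs_{other}"] = {"chi2": cmp_.chi2, "df": cmp_.df, "p": cmp_.p}
        m2 = irtmod.m2_statistic(fits["1PL"], matrix, seed=seed)
        out["m2_1PL"] = {"statistic": m2.statistic, "df": m2.df, "p": m2.p}
        items_df, persons_df = irtmod.item_person_map(fits["1PL"])
        out["wright_map"] = {
            "items": items_df.to_dict("records"),
            "person_bins": persons_df.to_dict("records"),
        }
    out["_matrix"] = matrix
    out["_fits"] = fits
    return out


def _lesion_stage(cohort, scores, cfg: RunConfig, seed: int) -> dict:
    out = {}
    lesions = cohort.lesions
    n = len(lesions)
    sizes = lesions.lesion_size_cc
    cwf = scores["CWF"].to_numpy(float)
    ciu = scores["CIU"].to_numpy(float)
    cwf_res = lmap.regress_out(cwf, sizes)
    ciu_res = lmap.regress_out(ciu, sizes)

    vox = lmap.voxel_coverage_filter(lesions, cfg.coverage_min_fraction)
    out["coverage"] = {"n_voxels": int(vox.size), "n_subjects": n}
    shape = lesions.grid_shape

    X = lmap.lesion_matrix(lesions, vox)
    lsm = {}
    for name, y in (("CWF", cwf_res), ("CIU", ciu_res)):
        r = lmap.sparse_cca_lsm(X, y, cfg.sparseness, cfg.folds, seed=seed,
                                voxels=vox, grid_shape=shape)
        entry = {"cv_correlation": r.cv_correlation, "p": r.p,
                 "n_displayed": len(r.displayed_voxels)}
        labels = lmap.label_weights(r, cohort.tract_atlas)
        entry["regions"] = labels.to_dict("records")
        lsm[name] = entry
    out["lesion_lsm"] = lsm

    # disconnection LSM on binarized disconnection maps
    disc_rows = []
    for vol in lesions.volumes:
        _, binary = lmap.disconnection_map(vol, cohort.streamlines,
                                           cfg.disconnection_threshold)
        disc_rows.append(binary.ravel())
    D = np.asarray(disc_rows, float)
    dcounts = D.sum(axis=0)
    dvox = np.flatnonzero(dcounts / n >= cfg.coverage_min_fraction - 1e-12)
    disc = {}
    if dvox.size:
        Xd = D[:, dvox]
        for name, y in (("CWF", cwf_res), ("CIU", ciu_res)):
            r = lmap.sparse_cca_lsm(Xd, y, cfg.sparseness, cfg.folds, seed=seed,
                                    voxels=dvox, grid_shape=shape)
            disc[name] = {"cv_correlation": r.cv_correlation, "p": r.p,
                          "n_displayed": len(r.displayed_voxels)}
    out["disconnection_lsm"] = {"n_voxels": int(dvox.size), "results": disc}

    # tract partial correlations (one-tailed negative, as hypothesized)
    tract_loads = {name: np.empty(n) for name in cohort.tract_atlas.tracts}
    for i, vol in enumerate(lesions.volumes):
        pct = lmap.tract_lesion_percentage(vol, cohort.tract_atlas)
        for name, v in pct.items():
            tract_loads[name][i] = v
    tracts = {}
    for name, load in sorted(tract_loads.items()):
        row = {}
        for col, y in (("CWF", cwf), ("CIU", ciu)):
            try:
                pc = st.partial_correlation(load, y, sizes, alternative="less",
                                            names=("lesion_size_cc",))
                row[col] = {"r": pc.r, "p": pc.p, "df": pc.df}
            except st.UndefinedStatisticError:
                row[col] = {"r": None, "p": None, "df": None}
        tracts[name] = row
    out["tract_partial_correlations"] = tracts

    pv = lmap.pvc(X, cwf_res, ciu_res, cfg.sparseness, cfg.folds, seed=seed)
    out["pvc"] = {"aic_single": pv.aic_single, "aic_two": pv.aic_two,
                  "aic_difference": pv.aic_difference, "verdict": pv.verdict}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write the report bundle,
    behaviour table and manifest to ``config.out_dir``.

    Stage failures abort with the stage name; outputs written so far are
    preserved.  The returned dict is the full report bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed, "stages": []}
    stage = "load-inputs"
    try:
        if config.simulate is not None:
            sim_cfg = sdata.SimulationConfig(**{**config.simulate, "seed": config.seed})
            cohort = sdata.generate_cohort(sim_cfg)
            checklist = cohort.checklist
            transcripts = cohort.transcripts
            extra = pd.DataFrame({
                "participant_id": [t.participant_id for t in transcripts],
                "aphasia_type": list(cohort.aphasia_type),
                "severity": cohort.severity,
            })
        else:
            cohort = None
            checklist = tmod.read_checklist(config.checklist_path)
            tdir = Path(config.transcripts_dir)
            transcripts = [tmod.read_transcript_tsv(p) for p in sorted(tdir.glob("*.tsv"))]
            extra = None
            if config.behaviour_path:
                extra = pd.read_csv(config.behaviour_path, sep="\t")

        stage = "score"
        scores = score_cohort(transcripts, checklist)
        if extra is not None:
            scores = scores.merge(extra, on="participant_id", how="left")
        scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)
        report["cohort_summary"] = {
            "n": len(scores),
            "mean_CWF": float(scores["CWF"].mean()) if len(scores) else None,
            "mean_CIU": float(scores["CIU"].mean()) if len(scores) else None,
            "mean_words": float(scores["word_count"].mean()) if len(scores) else None,
        }
        report["stages"].append(stage)

        stage = "validate"
        if len(scores) >= 3:
            report["validation"] = validation_report(scores, config.subtype_groups)
        else:
            report["validation"] = {"skipped": "fewer than 3 participants"}
        report["stages"].append(stage)

        stage = "irt"
        if len(scores) >= 2 and len(checklist) >= 2:
            results = [tmod.score_cwf(t, checklist) for t in transcripts]
            irt_out = _irt_stage(results, checklist, config.irt_models, config.seed)
            irt_out.pop("_matrix", None)
            irt_out.pop("_fits", None)
            report["irt_summary"] = irt_out
        else:
            report["irt_summary"] = {"skipped": "cohort too small"}
        report["stages"].append(stage)

        stage = "regression"
        if len(checklist) >= 6 and len(scores) > 0:
            results = [tmod.score_cwf(t, checklist) for t in transcripts]
            totals = np.zeros(len(checklist))
            for res in results:
                for j, it in enumerate(checklist.items):
                    totals[j] += res.per_item_counts.get(it.item_id, 0)
            reg = st.psycholinguistic_regression(totals, checklist)
            report["regression_summary"] = {
                "r_squared": reg.r_squared, "f_stat": reg.f_stat, "f_p": reg.f_p,
                "coefficients": {k: {"estimate": v[0], "se": v[1], "t": v[2], "p": v[3]}
                                 for k, v in reg.coefficients.items()},
            }
        else:
            report["regression_summary"] = {"skipped": "needs >= 6 items"}
        report["stages"].append(stage)

        stage = "lesion-suite"
        has_lesions = (cohort is not None and len(cohort.lesions) >= 8
                       and config.run_lesion_stages)
        if has_lesions:
            report["lesion_summary"] = _lesion_stage(cohort, scores, config, config.seed)
        else:
            log.warning("lesion stages skipped (no lesion inputs or disabled)")
            report["lesion_summary"] = {"skipped": "no lesion inputs"}
        report["stages"].append(stage)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    bundle_json = json.dumps(report, indent=1, sort_keys=True, default=_jsonable)
    (out_dir / "report.json").write_text(bundle_json + "\n")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "report_sha256": hashlib.sha256(bundle_json.encode()).hexdigest(),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_jsonable) + "\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set, frozenset)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
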