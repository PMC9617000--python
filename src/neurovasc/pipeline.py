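"""End-to-end cohort run: generate -> quantify per subject -> cohort stats.

``run_all`` executes the whole chain on a synthetic cohort and writes a
reproducible run directory:

    resolved_config.yaml   every parameter made explicit
    truth.csv              per-subject ground truth + cognition/health
    subjects.csv           per-subject estimates with QC status
    attrition.csv          exclusion ledger
    stats.csv              robust correlation table with FDR
    recovery.csv           truth-vs-estimate report per quantity
    run.log                per-stage log (timestamp-free, deterministic)
    manifest.json          sha256 checksum of every output

A single run seed fans out to per-subject, per-modality child seeds
(CRC32 of "seed|subject|modality"), so runs are deterministic end to end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asl, breath_hold as bh, cohort_stats, flow_oximetry as fo, mrs
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "run_all", "analyze_cohort"]


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    smoothing_fwhm: float = 5.0
    highpass_cutoff: float = 90.0
    z_threshold: float = 3.1
    top_percentile: float = 90.0
    hrf_mean: float = 6.0
    hrf_sd: float = 3.0
    max_response: float = 400.0
    calibration: fo.OximetryCalibration = field(default_factory=fo.OximetryCalibration)
    stats_predictors: list[str] = field(
        default_factory=lambda: ["est_dcbf_visact", "est_dbold_visact", "est_dcbf_bh"]
    )
    stats_outcomes: list[str] = field(
        default_factory=lambda: ["ist_2000r", "ace", "tmt_b", "sdmt"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        calib = fo.OximetryCalibration(**raw.pop("calibration", {}))
        return cls(cohort=cohort, calibration=calib, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["cognition_couplings"] = [
            list(t) for t in d["cohort"]["cognition_couplings"]
        ]
        return d


def _subject_physiology(cohort: SyntheticCohort, i: int, calib) -> dict:
    """Resting chain for one subject: vessel flows -> gCBF; phase -> SvO2;
    Fick -> gCMRO2.  Brain volume enters from the truth table (structural
    segmentation is out of scope)."""
    row = cohort.truth.iloc[i]
    vmap = cohort.velocity_map(i)
    flows = [fo.vessel_flow(vmap, name) for name in vmap.rois]
    gcbf = fo.total_gcbf(flows, brain_volume=row["brain_volume"])
    pair = cohort.sbo_phase_maps(i, calib)
    dphi = fo.susceptibility_phase(pair)
    svo2 = fo.svo2_from_phase(dphi, pair.delta_te, pair.field_strength, calib)
    svo2 = min(svo2, row["sao2"])
    gcmro2 = fo.cmro2_fick(row["hgb"], gcbf, row["sao2"], svo2)
    return {"est_gcbf": gcbf, "est_svo2": svo2, "est_gcmro2": gcmro2}


def _subject_mrs(cohort: SyntheticCohort, i: int) -> dict:
    s_rest, s_stim = cohort.spectra(i)
    f_rest = mrs.fit_spectrum(s_rest)
    f_stim = mrs.fit_spectrum(s_stim)
    dlac_pct, dlac_abs = mrs.lactate_change(f_rest, f_stim)
    return {
        "est_lactate_rest": f_rest.lactate,
        "est_naa": f_rest.naa,
        "est_dlac_pct": dlac_pct,
        "est_dlac_abs": dlac_abs,
    }


def analyze_cohort(cohort: SyntheticCohort, config: RunConfig, log=None) -> pd.DataFrame:
    """Run every per-subject quantification stage; returns the estimates
    table (one row per subject) merged with cognition/health columns."""

    def say(msg):
        if log is not None:
            log.append(msg)

    n = len(cohort)
    rows = []
    bh_series = []
    for i in range(n):
        rec: dict = {"subject": i}
        try:
            series = cohort.pcasl_series(i)
            res = asl.analyze_subject(
                series,
                smoothing_fwhm=config.smoothing_fwhm,
                highpass_cutoff=config.highpass_cutoff,
                z_threshold=config.z_threshold,
                top_percentile=config.top_percentile,
                hrf_mean=config.hrf_mean,
                hrf_sd=config.hrf_sd,
                max_response=config.max_response,
            )
            included, reason = asl.qc_filter(res, config.max_response)
            rec.update(
                est_dcbf_visact=res.delta_cbf,
                est_dbold_visact=res.delta_bold,
                asl_qc=reason,
                asl_included=included,
                cluster_size=res.cluster_size,
            )
        except Exception as exc:  # pragma: no cover - stage failure path
            raise RuntimeError(f"ASL stage failed for subject {i}: {exc}") from exc
        rec.update(_subject_physiology(cohort, i, config.calibration))
        rec.update(_subject_mrs(cohort, i))
        bh_series.append(cohort.breath_hold_series(i))
        rows.append(rec)
        say(f"subject {i}: asl={rec['asl_qc']} dcbf={rec['est_dcbf_visact']}")

    # Two-pass breath-hold analysis: cohort-mean regressors, then per-subject GLMs.
    pct_flow, pct_avo2, pct_cm = [], [], []
    for s in bh_series:
        avo2, cmro2 = bh.derive_series(s)
        pct_flow.append(bh.percent_change_series(s.flow, s.times, s.paradigm))
        pct_avo2.append(bh.percent_change_series(avo2, s.times, s.paradigm))
        pct_cm.append(bh.percent_change_series(cmro2, s.times, s.paradigm))
    reg_flow = bh.build_population_regressor(pct_flow)
    reg_avo2 = bh.build_population_regressor(pct_avo2)
    reg_cm = bh.build_population_regressor(pct_cm)
    for rec, s in zip(rows, bh_series):
        r = bh.fit_breath_hold_glm(s, reg_flow, reg_avo2, reg_cm)
        rec.update(
            est_dcbf_bh=r.dcbf_bh, est_davo2_bh=r.davo2_bh, est_dcmro2_bh=r.dcmro2_bh
        )
    say("breath-hold stage complete")
    est = pd.DataFrame(rows)
    return est.merge(cohort.truth, on="subject")


_RECOVERY_PAIRS = [
    ("true_dcbf_visact", "est_dcbf_visact"),
    ("true_dbold_visact", "est_dbold_visact"),
    ("true_dcbf_bh", "est_dcbf_bh"),
    ("true_dcmro2_bh", "est_dcmro2_bh"),
    ("true_gcbf", "est_gcbf"),
    ("true_svo2", "est_svo2"),
    ("lactate_rest", "est_lactate_rest"),
    ("naa", "est_naa"),
]


def _recovery_report(table: pd.DataFrame) -> pd.DataFrame:
    recs = []
    for truth_col, est_col in _RECOVERY_PAIRS:
        sub = table[[truth_col, est_col]].dropna()
        err = sub[est_col] - sub[truth_col]
        recs.append(
            {
                "quantity": est_col.replace("est_", ""),
                "n": len(sub),
                "bias": err.mean(),
                "rmse": np.sqrt((err**2).mean()),
                "max_abs_error": err.abs().max(),
            }
        )
    return pd.DataFrame(recs)


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full chain and write the run directory (see module docs)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    cohort = generate_cohort(config.cohort)
    cohort.truth.to_csv(out / "truth.csv", index=False)
    log.append(f"generated cohort of {len(cohort)} subjects")

    table = analyze_cohort(cohort, config, log=log)
    table.to_csv(out / "subjects.csv", index=False)

    reasons = table.loc[~table["asl_included"], "asl_qc"].value_counts().to_dict()
    ledger = cohort_stats.attrition_accounting(len(table), reasons)
    pd.DataFrame(
        [{"reason": k, "excluded": v} for k, v in ledger.exclusions.items()]
        + [{"reason": "completed", "excluded": ledger.completed}]
    ).to_csv(out / "attrition.csv", index=False)
    log.append(f"attrition: {ledger.exclusions} -> completed {ledger.completed}")

    included = table[table["asl_included"]]
    if len(included) >= 3:
        stats = cohort_stats.correlation_table(
            included, config.stats_predictors, config.stats_outcomes
        )
        log.append(f"stats on {len(included)} included subjects")
    else:
        stats = pd.DataFrame(
            columns=["predictor", "outcome", "beta", "r_squared", "p", "p_fdr",
                     "significant", "n_used"]
        )
        log.append("stats skipped: fewer than 3 included subjects")
    stats.to_csv(out / "stats.csv", index=False)

    _recovery_report(table).to_csv(out / "recovery.csv", index=False)

    (out / "run.log").write_text("\n".join(log) + "\n")
    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = {
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            "bytes": p.stat().st_size,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
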