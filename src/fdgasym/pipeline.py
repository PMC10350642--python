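"""End-to-end pipeline: simulate -> quantify -> asymmetry -> agreement.

``run_pipeline`` executes the whole chain for one seeded cohort and
writes, under the output directory:

* ``volumes/``          NIfTI SUV and label volumes (optional)
* ``cohort.csv``        per-patient scan metadata (sidecar)
* ``suvmeans.csv``      per-patient, per-timepoint regional SUVmeans
* ``ai_per_patient.csv`` AI1/AI2/dAI and bands per patient
* ``summary.csv`` / ``summary.json``  Table-style stratified statistics
* ``ratings.csv`` / ``kappa.json``    synthetic observer ratings + kappa
* ``manifest.json``     config hash, seed, package versions

The run is idempotent for a fixed seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry_stats import (
    ai_records_from_suvmeans,
    cohen_kappa,
    ratings_contingency,
    simulate_observers,
    summarize_cohort,
)
from .config import PipelineConfig, load_config
from .phantom import simulate_cohort
from .roi_quant import paired_suvmeans

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


def cohort_sidecar(sims) -> pd.DataFrame:
    rows = []
    for sim in sims:
        r = sim.record
        rows.append(
            dict(
                patient_id=r.patient_id, weight_kg=r.weight_kg, dose_MBq=r.dose_MBq,
                t_early_min=r.t_early, t_delayed_min=r.t_delayed, ez_label=r.ez_label,
                ez_side=r.ez_side, mri_status=r.mri_status, seed=r.seed,
            )
        )
    return pd.DataFrame(rows)


def quantify_cohort(sims) -> pd.DataFrame:
    """Per-patient EZ/contralateral SUVmeans at both time points."""
    rows = []
    for sim in sims:
        r = sim.record
        try:
            early = paired_suvmeans(sim.suv_early, sim.labels, r.ez_label, "early")
            delayed = paired_suvmeans(sim.suv_delayed, sim.labels, r.ez_label, "delayed")
        except (KeyError, ValueError) as exc:
            raise RuntimeError(f"quantify stage failed for patient {r.patient_id}: {exc}") from exc
        rows.append(
            dict(
                patient_id=r.patient_id,
                mri_status=r.mri_status,
                suv_ez_early=early.ez_suvmean,
                suv_contra_early=early.contra_suvmean,
                suv_ez_delayed=delayed.ez_suvmean,
                suv_contra_delayed=delayed.contra_suvmean,
            )
        )
    return pd.DataFrame(rows)


def ai_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                patient_id=r.patient_id, mri_status=r.mri_status,
                suv_ez_early=r.suv_ez_early, suv_contra_early=r.suv_contra_early,
                suv_ez_delayed=r.suv_ez_delayed, suv_contra_delayed=r.suv_contra_delayed,
                AI1=r.ai1, AI2=r.ai2, dAI=r.dai, band1=r.band1, band2=r.band2,
            )
            for r in records
        ]
    )


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.describe(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def summary_dict(summary) -> dict:
    out = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "n_increased": summary.n_increased,
        "n_decreased": summary.n_decreased,
        "n_unchanged": summary.n_unchanged,
        "pct_increased": summary.pct_increased(),
        "pct_decreased": summary.pct_decreased(),
        "strata": {},
    }
    for name, s in summary.strata.items():
        out["strata"][name] = {
            "n": s.n, "AI1_mean": s.ai1_mean, "AI1_sd": s.ai1_sd,
            "AI2_mean": s.ai2_mean, "AI2_sd": s.ai2_sd,
            "dAI_mean": s.dai_mean, "dAI_sd": s.dai_sd,
            "t": s.t, "df": s.df, "p": s.p, "note": s.note,
        }
    return out


def run_pipeline(
    config_path=None,
    seed: int = 0,
    outdir="results/run",
    save_volumes: bool = True,
) -> Path:
    """Run the full synthetic dual-time-point study; returns the output dir."""
    config = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: n=%d seed=%d", config.cohort.n, seed)
    sims = simulate_cohort(config.cohort, seed)

    if save_volumes:
        voldir = outdir / "volumes"
        voldir.mkdir(exist_ok=True)
        sims[0].labels.save(voldir / "labels.nii.gz")
        for sim in sims:
            sim.suv_early.save(voldir / f"{sim.record.patient_id}_early.nii.gz")
            sim.suv_delayed.save(voldir / f"{sim.record.patient_id}_delayed.nii.gz")

    cohort_sidecar(sims).to_csv(outdir / "cohort.csv", index=False)

    logger.info("stage quantify")
    suv_df = quantify_cohort(sims)
    suv_df.to_csv(outdir / "suvmeans.csv", index=False)

    logger.info("stage summarize")
    records = ai_records_from_suvmeans(suv_df)
    ai_table(records).to_csv(outdir / "ai_per_patient.csv", index=False)
    summary = summarize_cohort(records)
    summary.to_frame().to_csv(outdir / "summary.csv", index=False)
    (outdir / "summary.json").write_text(json.dumps(summary_dict(summary), indent=2))

    logger.info("stage kappa")
    pairs = simulate_observers(
        records, config.observers.noise_sd, config.observers.same_threshold, seed=seed + 777
    )
    pd.DataFrame([dict(patient_id=p.patient_id, obs1=p.obs1, obs2=p.obs2) for p in pairs]).to_csv(
        outdir / "ratings.csv", index=False
    )
    table = ratings_contingency(pairs)
    try:
        kappa = cohen_kappa(table)
        payload = {
            "kappa": kappa.kappa, "p_observed": kappa.p_observed,
            "p_expected": kappa.p_expected, "band": kappa.band,
        }
    except ZeroDivisionError:
        # all mass in one category: chance agreement is 1, kappa undefined
        payload = {"kappa": None, "p_observed": 1.0, "p_expected": 1.0,
                   "band": "undefined (single rating category)"}
        logger.warning("kappa undefined: all ratings fell in a single category")
    payload["contingency"] = table.tolist()
    payload["band_convention"] = "half-open [lo, hi); 'very good' closed at 1.00"
    (outdir / "kappa.json").write_text(json.dumps(payload, indent=2))

    manifest = {
        "package": "fdgasym",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "config": config.describe(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", outdir)
    return outdir
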