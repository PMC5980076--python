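"""CSV/YAML contracts and the staged analysis pipeline.

The on-disk contract is deliberately plain: the survival register is a
CSV with columns ``subject_id, t1, t2, delta`` plus covariates (ages
recorded in months, as in national-survey exports, are converted to years
on read); activity tracks are either wide (one row per subject, 10,080
count columns) or long (``subject_id, minute_index, count``) CSV; run
configuration is a flat YAML file.  Every output table starts with a
``# config_hash=...`` comment so results can be traced to the exact
configuration, and each pipeline run serializes its configuration and a
stage-by-stage log into the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .activity import ActivityTrack, TransitionMatrixFeaturizer, filter_track
from .bioage import PCAAge, RidgeAge
from .evaluate import cox_ph_test, detrend_standardize, stratify_km
from .gompertz import GompertzPH
from .perturbation import compute_weights, effect_closed_form, transform_targets

__all__ = [
    "RunConfig",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "pipeline_run",
]

logger = logging.getLogger(__name__)

REQUIRED_COHORT_COLUMNS = ("subject_id", "t1", "t2", "delta")
_YESNO = {"yes": 1, "no": 0, "y": 1, "n": 0, "true": 1, "false": 0}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run, serializable to flat YAML."""

    seed: int = 0
    n_subjects: int = 2000
    simulate: bool = True          # otherwise ingest cohort/track CSVs
    cohort_path: str | None = None
    tracks_path: str | None = None
    stages: list = field(default_factory=lambda: [
        "simulate", "featurize", "fit-bioage", "fit-gompertz",
        "linearize", "evaluate"])
    zero_order_covariates: list = field(default_factory=lambda: ["gender"])
    hra_covariates: list = field(default_factory=lambda: [
        "gender", "smoking", "diabetes", "hypertension"])
    fix_gamma: float | None = None
    l2_penalty: float = 0.0
    ridge_penalties: list | None = None
    out_dir: str = "locoage_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# readers / writers


def read_cohort_csv(path, months_columns=()) -> pd.DataFrame:
    """Read a survival register.

    ``months_columns`` flags age columns recorded in months (they are
    divided by 12).  Categorical yes/no covariates are mapped to 1/0.
    Rows with missing survival fields or ``t2 < t1`` are rejected with a
    logged count.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    for col in months_columns:
        df[col] = df[col].astype(float) / 12.0
    for col in df.columns:
        if df[col].dtype == object and col != "subject_id":
            mapped = df[col].astype(str).str.strip().str.lower().map(_YESNO)
            if mapped.notna().all():
                df[col] = mapped.astype(int)

    n0 = len(df)
    df = df.dropna(subset=["t1", "t2", "delta"])
    n_missing = n0 - len(df)
    bad_order = df["t2"] < df["t1"]
    n_bad = int(bad_order.sum())
    df = df[~bad_order].reset_index(drop=True)
    if n_missing or n_bad:
        logger.warning("rejected %d rows with missing survival fields and "
                       "%d with t2 < t1", n_missing, n_bad)
    df["delta"] = df["delta"].astype(int)
    return df


def write_cohort_csv(df: pd.DataFrame, path, config_hash: str | None = None):
    _write_table(df, path, config_hash)


def _write_table(df: pd.DataFrame, path, config_hash: str | None = None):
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_tracks_csv(path) -> list:
    """Read activity tracks from wide or long CSV (auto-detected)."""
    df = pd.read_csv(path, comment="#")
    if "subject_id" not in df.columns:
        raise ValueError("tracks CSV must have a subject_id column")
    tracks = []
    if {"minute_index", "count"} <= set(df.columns):   # long format
        if df.duplicated(["subject_id", "minute_index"]).any():
            raise ValueError("duplicate (subject_id, minute_index) rows")
        for sid, sub in df.groupby("subject_id", sort=False):
            sub = sub.sort_values("minute_index")
            counts = sub["count"].to_numpy()
            _check_counts(counts, sid)
            tracks.append(ActivityTrack(subject_id=str(sid), counts=counts))
    else:                                              # wide format
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject_id: {sorted(set(dupes))}")
        value_cols = [c for c in df.columns if c != "subject_id"]
        for _, row in df.iterrows():
            counts = row[value_cols].to_numpy(dtype=float)
            _check_counts(counts, row["subject_id"])
            tracks.append(ActivityTrack(subject_id=str(row["subject_id"]),
                                        counts=counts.astype(np.int64)))
    return tracks


def _check_counts(counts, sid):
    if np.any(pd.isna(counts)):
        raise ValueError(f"missing counts for subject {sid}")
    if np.any(np.asarray(counts) < 0):
        raise ValueError(f"negative activity counts for subject {sid}")


def write_tracks_csv(tracks, path, config_hash: str | None = None):
    """Write tracks in wide format (one row per subject)."""
    n = len(tracks[0].counts)
    data = {"subject_id": [t.subject_id for t in tracks]}
    mat = np.vstack([t.counts for t in tracks])
    df = pd.DataFrame(mat, columns=[f"m{i}" for i in range(n)])
    df.insert(0, "subject_id", data["subject_id"])
    _write_table(df, path, config_hash)


# ---------------------------------------------------------------------------
# pipeline


def pipeline_run(config: RunConfig, out_dir=None) -> Path:
    """Execute the staged pipeline and write all tables to ``out_dir``.

    Stage order: simulate|ingest -> featurize -> fit-bioage ->
    fit-gompertz -> linearize -> evaluate.  Any stage failure raises with
    the stage name in the message.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    config.to_yaml(out / "config.yaml")

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: "
                                           "%(message)s"))
    root = logging.getLogger("locoage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    state: dict = {}
    try:
        logger.info("config hash %s, seed %d", h, config.seed)
        for stage in config.stages:
            logger.info("stage %s", stage)
            try:
                _STAGES[stage](config, state, out, h)
            except Exception as exc:
                raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def _get_cohort(config, state, out):
    if "cohort" not in state:
        path = config.cohort_path or out / "cohort.csv"
        state["cohort"] = read_cohort_csv(path)
    return state["cohort"]


def _get_descriptors(config, state, out):
    # allows the featurize stage to be toggled off when a precomputed
    # descriptor table is supplied in the output directory
    if "descriptors" not in state:
        state["descriptors"] = pd.read_csv(out / "descriptors.csv",
                                           comment="#")
    return state["descriptors"]


def _stage_simulate(config: RunConfig, state, out, h):
    if config.simulate:
        sim = synthetic.SimConfig(n_subjects=config.n_subjects,
                                  seed=config.seed)
        cohort = synthetic.generate_cohort(sim)
        rng = np.random.default_rng(config.seed + 1)
        tracks = synthetic.generate_activity_tracks(
            cohort["t1"].to_numpy(), cohort["frailty"].to_numpy(),
            sim.activity_params, rng=rng,
            subject_ids=cohort["subject_id"].tolist())
    else:
        cohort = read_cohort_csv(config.cohort_path)
        tracks = read_tracks_csv(config.tracks_path)
    state["cohort"], state["tracks"] = cohort, tracks
    write_cohort_csv(cohort, out / "cohort.csv", h)
    logger.info("cohort: %d subjects, %d deaths", len(cohort),
                int(cohort["delta"].sum()))


def _stage_featurize(config: RunConfig, state, out, h):
    cohort, tracks = _get_cohort(config, state, out), state["tracks"]
    age = dict(zip(cohort["subject_id"], cohort["t1"]))
    reports = [filter_track(t, age[t.subject_id]) for t in tracks]
    passed = [t for t, r in zip(tracks, reports) if r.passed]
    logger.info("filter: %d of %d tracks pass", len(passed), len(tracks))
    pd.DataFrame([dataclasses.asdict(r) for r in reports]).pipe(
        _write_table, out / "filter_reports.csv", h)

    feat = TransitionMatrixFeaturizer().fit(passed)
    D, extras = feat.describe(passed)
    desc = pd.DataFrame(D, columns=[f"tm{i}" for i in range(D.shape[1])])
    desc.insert(0, "subject_id", extras["subject_id"])
    desc["mean_daily_activity"] = extras["mean_daily_activity"]
    desc["neg_log_activity"] = extras["neg_log_activity"]
    state["descriptors"] = desc
    _write_table(desc, out / "descriptors.csv", h)


def _stage_fit_bioage(config: RunConfig, state, out, h):
    desc = _get_descriptors(config, state, out)
    cohort = _get_cohort(config, state, out).set_index("subject_id")
    ages = cohort.loc[desc["subject_id"], "t1"].to_numpy()
    D = desc[[c for c in desc.columns if c.startswith("tm")]].to_numpy()
    pca = PCAAge().fit(D, ages)
    ridge = RidgeAge(alphas=config.ridge_penalties,
                     random_state=config.seed).fit(D, ages)
    state["bioage_models"] = {"pca": pca, "ridge": ridge}
    pred = pd.DataFrame({
        "subject_id": desc["subject_id"],
        "age": ages,
        "pca_age": pca.predict(D),
        "ridge_age": ridge.predict(D),
    })
    state["bioage"] = pred
    _write_table(pred, out / "bioage.csv", h)


def _stage_fit_gompertz(config: RunConfig, state, out, h):
    cohort = _get_cohort(config, state, out)
    est = GompertzPH(l2_penalty=config.l2_penalty,
                     fix_Gamma=config.fix_gamma)
    est.fit(cohort, covariate_cols=config.zero_order_covariates)
    state["gompertz"] = est.fit_
    payload = {
        "M0": est.M0_, "Gamma": est.Gamma_,
        "beta": est.beta_.to_dict(),
        "neg_log_likelihood": est.fit_.neg_log_likelihood,
        "n_events": est.fit_.n_events,
        "converged": est.fit_.converged,
        "config_hash": h,
    }
    (out / "gompertz_fit.json").write_text(json.dumps(payload, indent=2))
    logger.info("zero-order fit: M0=%.3g Gamma=%.4f", est.M0_, est.Gamma_)


def _stage_linearize(config: RunConfig, state, out, h):
    cohort = _get_cohort(config, state, out)
    desc = _get_descriptors(config, state, out)
    lin = compute_weights(cohort, state["gompertz"],
                          covariate_cols=config.zero_order_covariates)
    kept = cohort.loc[lin.keep, "subject_id"].reset_index(drop=True)
    table = pd.DataFrame({"subject_id": kept, "rho": lin.rho, "R": lin.R,
                          "R_int": transform_targets(lin.R)})
    state["linearized"] = (lin, table)
    _write_table(table, out / "linearized_targets.csv", h)

    # first-order effect of the aggregate activity covariate
    merged = table.merge(desc[["subject_id", "neg_log_activity"]],
                         on="subject_id", how="inner")
    if len(merged) == len(table):
        xi = (merged["neg_log_activity"] -
              merged["neg_log_activity"].mean())
        xi = (xi / xi.std()).to_numpy()
        eff = effect_closed_form(lin, xi, ["neg_log_activity"])
        _write_table(pd.DataFrame({
            "feature": eff.feature_names, "beta_xi": eff.beta_xi,
            "sigma": eff.sigma, "z": eff.z, "p": eff.p_value,
        }), out / "perturbation_effects.csv", h)


def _stage_evaluate(config: RunConfig, state, out, h):
    cohort = _get_cohort(config, state, out).set_index("subject_id")
    pred = state["bioage"]
    sub = cohort.loc[pred["subject_id"]]
    rows = []
    for model in ("pca", "ridge"):
        bioage = pred[f"{model}_age"].to_numpy()
        km = stratify_km(sub.reset_index(), bioage,
                         pred["age"].to_numpy(),
                         sub["gender"].to_numpy())
        for label, curve in km.curves.items():
            _write_table(curve, out / f"km_{model}_{label}.csv", h)
        adj = sub[config.hra_covariates].reset_index(drop=True)
        score = km.acceleration
        score = (score - score.mean()) / score.std()
        rep = cox_ph_test(sub.reset_index(), score, detrend_standardize(
            adj, protect=()), name=f"{model}_acceleration")
        rows.append({
            "model": model, "hazard_ratio": rep.hazard_ratio,
            "ci_low": rep.ci95[0], "ci_high": rep.ci95[1],
            "p_value": rep.p_value, "years_equivalent": rep.years_equivalent,
            "km_logrank_p": km.logrank_p,
        })
    summary = pd.DataFrame(rows)
    _write_table(summary, out / "effects.csv", h)
    (out / "summary.json").write_text(json.dumps({
        "config_hash": h, "seed": config.seed,
        "effects": rows,
    }, indent=2))


_STAGES = {
    "simulate": _stage_simulate,
    "featurize": _stage_featurize,
    "fit-bioage": _stage_fit_bioage,
    "fit-gompertz": _stage_fit_gompertz,
    "linearize": _stage_linearize,
    "evaluate": _stage_evaluate,
}
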