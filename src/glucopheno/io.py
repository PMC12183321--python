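"""Readers, writers and the end-to-end analysis pipeline.

Cohort bundles are directories of long-format CSVs (the layout
``generate_cohort`` writes): a glucose table
(participant_id, source, test_id, time_min, glucose_mg_dl), an analyte
table (participant_id, test_type, analyte, time_min, value), a covariate
table (one row per participant, including the measured SSPG) and an
optional manifest.  ``run_pipeline`` chains simulation, metabolic-index
computation, deviance subphenotyping, curve features, the reduced
representation, the classifier benchmark and the CGM concordance report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinetics as kin
from .cgm import (
    average_home_tests,
    concordance_report,
    intraindividual_cv,
    resample_to_canonical,
)
from .classify import (
    CURVE_COLUMNS,
    CVProtocol,
    benchmark_feature_sets,
    default_feature_sets,
)
from .curves import CANONICAL_GRID, AnalyteSeries, GlucoseCurve
from .features import CurveFeaturizer, FEATURE_NAMES, extract_features, impute_curve
from .indices import (
    Thresholds,
    classify_measures,
    body_fat_percent,
    disposition_index,
    hepatic_ir_index,
    incretin_effect,
    surrogate_markers,
)
from .reduced import ReducedRepresentation
from .simulate import SimulationConfig, SyntheticCohort, generate_cohort
from .subphenotype import assign_dominance, deviance_scores, summarize_dominance

logger = logging.getLogger(__name__)

GLUCOSE_COLUMNS = ("participant_id", "source", "test_id", "time_min",
                   "glucose_mg_dl")
ANALYTE_COLUMNS = ("participant_id", "test_type", "analyte", "time_min",
                   "value")


@dataclass
class CohortBundle:
    """In-memory cohort: long tables plus typed accessors."""

    glucose: pd.DataFrame
    analytes: pd.DataFrame
    covariates: pd.DataFrame
    manifest: dict | None = None
    rejected_rows: int = 0

    def glucose_curve(self, participant_id: str, source: str = "plasma",
                      test_id: str | None = None) -> GlucoseCurve:
        sel = self.glucose[
            (self.glucose["participant_id"] == participant_id)
            & (self.glucose["source"] == source)
        ]
        if test_id is not None:
            sel = sel[sel["test_id"] == test_id]
        else:
            test_id = sel["test_id"].iloc[0]
            sel = sel[sel["test_id"] == test_id]
        sel = sel.sort_values("time_min")
        return GlucoseCurve(
            participant_id, source, str(test_id),
            sel["time_min"].to_numpy(), sel["glucose_mg_dl"].to_numpy(),
        )

    def analyte_series(self, participant_id: str, test_type: str,
                       analyte: str) -> AnalyteSeries:
        sel = self.analytes[
            (self.analytes["participant_id"] == participant_id)
            & (self.analytes["test_type"] == test_type)
            & (self.analytes["analyte"] == analyte)
        ].sort_values("time_min")
        if sel.empty:
            raise LookupError(
                f"no {analyte} {test_type} series for {participant_id}"
            )
        return AnalyteSeries(
            participant_id, test_type, analyte,
            sel["time_min"].to_numpy(), sel["value"].to_numpy(),
        )

    @property
    def participant_ids(self) -> list[str]:
        return list(self.covariates.index)


def _validated(df: pd.DataFrame, required: tuple, value_col: str,
               path: str) -> tuple[pd.DataFrame, int]:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    n0 = len(df)
    numeric = pd.to_numeric(df[value_col], errors="coerce")
    tmin = pd.to_numeric(df["time_min"], errors="coerce")
    bad = numeric.isna() | tmin.isna() | (numeric < 0)
    for idx in df.index[bad]:
        logger.warning("%s: rejecting row %d (unparseable or negative)",
                       path, idx + 2)  # +2: header + 1-based
    df = df[~bad].copy()
    df[value_col] = numeric[~bad]
    df["time_min"] = tmin[~bad]
    return df, int(bad.sum())


def read_cohort_bundle(path) -> CohortBundle:
    """Load a cohort directory; invalid rows are logged and skipped."""
    p = Path(path)
    if not p.is_dir():
        raise FileNotFoundError(f"cohort bundle directory not found: {p}")
    glucose = pd.read_csv(p / "glucose.csv")
    analytes = pd.read_csv(p / "analytes.csv")
    covariates = pd.read_csv(p / "covariates.csv", index_col="participant_id")
    glucose, rej_g = _validated(glucose, GLUCOSE_COLUMNS, "glucose_mg_dl",
                                str(p / "glucose.csv"))
    analytes, rej_a = _validated(analytes, ANALYTE_COLUMNS, "value",
                                 str(p / "analytes.csv"))
    manifest = None
    mpath = p / "manifest.yaml"
    if mpath.exists():
        with open(mpath) as fh:
            manifest = yaml.safe_load(fh)
    return CohortBundle(glucose, analytes, covariates, manifest,
                        rejected_rows=rej_g + rej_a)


def bundle_from_cohort(cohort: SyntheticCohort) -> CohortBundle:
    """Wrap an in-memory simulation result as a bundle (no disk round trip)."""
    cov = cohort.covariates
    return CohortBundle(cohort.glucose, cohort.analytes, cov,
                        manifest={"seed": cohort.config.seed})


def compute_metabolic_profiles(
    bundle: CohortBundle,
    thresholds: Thresholds = Thresholds(),
    error_cv: float = 5.0,
) -> pd.DataFrame:
    """Per-participant metabolic measures, surrogates and class labels.

    For each participant: insulin secretion by C-peptide deconvolution
    (population kinetics chosen by clinical class), disposition index,
    incretin effect from the OGTT/IIGI C-peptide pair, hepatic IR index
    from the OGTT insulin AUC, Deurenberg body fat, HDL and BMI, plus
    HOMA-IR/HOMA-B/Matsuda, followed by threshold classification.
    """
    rows = []
    for pid in bundle.participant_ids:
        cov = bundle.covariates.loc[pid]
        try:
            plasma = impute_curve(bundle.glucose_curve(pid, "plasma"))
            g120 = float(
                plasma.values[np.isclose(plasma.times, 120.0)][0]
            )
            k_class = kin.assign_kinetic_class(
                cov["fpg"], g120, cov["hba1c"], cov["bmi"]
            )
            params = kin.parameters_for(
                k_class, cov.get("weight_kg", 75.0), cov.get("height_m", 1.7)
            )
            cpep_ogtt = bundle.analyte_series(pid, "OGTT", "cpeptide")
            cpep_iigi = bundle.analyte_series(pid, "IIGI", "cpeptide")
            insulin = bundle.analyte_series(pid, "OGTT", "insulin")

            isr = kin.deconvolve_insulin_secretion(
                cpep_ogtt, params, error_cv=error_cv,
                weight_kg=cov.get("weight_kg", 75.0),
            )
            sspg = float(cov["sspg"])
            di = disposition_index(isr, sspg)
            ie = incretin_effect(cpep_ogtt, cpep_iigi)
            bf = body_fat_percent(cov["bmi"], cov["age"], int(cov["sex"]))
            hep = hepatic_ir_index(
                insulin.auc(0, 180), bf, cov["hdl"], cov["bmi"]
            )
            homa_ir, homa_b, matsuda = surrogate_markers(
                cov["fpg"], cov["fasting_insulin"],
                _glucose_as_series(plasma), insulin,
            )
            gip_2h = _analyte_at(bundle, pid, "GIP", 120.0)
            glp1_2h = _analyte_at(bundle, pid, "GLP1", 120.0)
        except (LookupError, ValueError) as exc:
            logger.warning("profile for %s incomplete: %s", pid, exc)
            continue
        profile = dict(
            participant_id=pid, sspg=sspg, di=di, ie_pct=ie,
            hepatic_ir=hep, bf_pct=bf, homa_ir=homa_ir, homa_b=homa_b,
            matsuda=matsuda, gip_2h=gip_2h, glp1_2h=glp1_2h,
            kinetic_class=k_class,
        )
        for c in ("age", "sex", "bmi", "ethnicity", "family_history",
                  "hba1c", "fpg", "fasting_insulin", "hdl", "prs"):
            if c in cov.index:
                profile[c] = cov[c]
        profile.update(classify_measures(profile, thresholds))
        rows.append(profile)
    return pd.DataFrame(rows).set_index("participant_id")


def _glucose_as_series(curve: GlucoseCurve) -> AnalyteSeries:
    post = curve.times >= 0
    return AnalyteSeries(curve.participant_id, "OGTT", "glucose",
                         curve.times[post], curve.values[post])


def _analyte_at(bundle, pid, analyte, t) -> float:
    try:
        s = bundle.analyte_series(pid, "OGTT", analyte)
    except LookupError:
        return float("nan")
    idx = np.isclose(s.times, t)
    return float(s.values[idx][0]) if idx.any() else float("nan")


def curve_matrix(bundle: CohortBundle, source: str = "plasma",
                 average_home: bool = False) -> pd.DataFrame:
    """Wide (n, 16) matrix of canonical curves, imputed, one row per id.

    For ``source='cgm_home'`` with ``average_home`` the two home tests are
    resampled to the canonical grid and averaged.
    """
    rows = {}
    for pid in bundle.participant_ids:
        try:
            if source == "cgm_home" and average_home:
                tests = sorted(
                    bundle.glucose[
                        (bundle.glucose["participant_id"] == pid)
                        & (bundle.glucose["source"] == "cgm_home")
                    ]["test_id"].unique()
                )
                curves = [
                    resample_to_canonical(
                        bundle.glucose_curve(pid, "cgm_home", t)
                    )
                    for t in tests
                ]
                curve = average_home_tests(curves)
            else:
                curve = bundle.glucose_curve(pid, source)
                if not curve.is_canonical:
                    curve = resample_to_canonical(curve)
            rows[pid] = impute_curve(curve).values
        except (LookupError, ValueError, IndexError) as exc:
            logger.warning("curve for %s (%s) unavailable: %s", pid, source, exc)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(CURVE_COLUMNS)
    )


def build_analysis_table(bundle: CohortBundle,
                         profiles: pd.DataFrame,
                         source: str = "plasma",
                         average_home: bool = False) -> pd.DataFrame:
    """Classification-ready table: labels + covariate features + curves.

    Joins the profile table (labels, surrogates, demographics) with the
    wide curve matrix and the 14 engineered features.
    """
    curves = curve_matrix(bundle, source, average_home)
    feats = pd.DataFrame(
        CurveFeaturizer().fit(curves.to_numpy()).transform(curves.to_numpy()),
        index=curves.index, columns=list(FEATURE_NAMES),
    )
    return profiles.join(curves, how="inner").join(feats, how="inner")


@dataclass
class PipelineConfig:
    """Configuration of ``run_pipeline`` (mirrors the YAML config file)."""

    outdir: str = "results"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    protocol: CVProtocol = field(default_factory=CVProtocol)
    delta: float = 0.5
    feature_sets: list | None = None
    phenotypes: list | None = None
    benchmark: bool = True
    input_bundle: str | None = None  # read instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "outdir" in raw:
            cfg.outdir = raw["outdir"]
        if "input_bundle" in raw:
            cfg.input_bundle = raw["input_bundle"]
        if "simulation" in raw:
            cfg.simulation = SimulationConfig(**raw["simulation"])
        if "thresholds" in raw:
            cfg.thresholds = Thresholds(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["thresholds"].items()
            })
        if "protocol" in raw:
            cfg.protocol = CVProtocol(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["protocol"].items()
            })
        for k in ("delta", "benchmark", "feature_sets", "phenotypes"):
            if k in raw:
                setattr(cfg, k, raw[k])
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "seed": config.simulation.seed,
            "n": config.simulation.n_participants,
            "delta": config.delta,
            "protocol": config.protocol.__dict__,
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write result tables.

    Stages: simulate (or read) -> metabolic indices -> deviance
    subphenotypes -> curve features + reduced representation ->
    classifier benchmark (optional) -> CGM concordance.  Each artefact is
    stamped with the config hash and seed; deterministic stages are
    bit-identical across reruns of the same config.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": _config_hash(config),
             "seed": config.simulation.seed}
    written: dict[str, str] = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("simulate")
        if config.input_bundle:
            bundle = read_cohort_bundle(config.input_bundle)
        else:
            paths = generate_cohort(config.simulation, out / "cohort")
            bundle = read_cohort_bundle(out / "cohort")
            written.update(paths)

        _stage("indices")
        profiles = compute_metabolic_profiles(bundle, config.thresholds)
        _write(profiles, out / "profiles.csv", written)

        _stage("subphenotype")
        z = deviance_scores(profiles)
        assignments = z.apply(
            lambda row: assign_dominance(row, config.delta), axis=1
        )
        z_out = z.copy()
        z_out["assignment"] = [str(a) for a in assignments]
        _write(z_out, out / "deviance_scores.csv", written)
        summary = summarize_dominance(list(assignments))
        with open(out / "dominance_summary.json", "w") as fh:
            json.dump({**stamp, **_jsonable(summary)}, fh, indent=2)
        written["dominance_summary"] = str(out / "dominance_summary.json")

        _stage("features")
        table = build_analysis_table(bundle, profiles)
        _write(table[list(FEATURE_NAMES)], out / "curve_features.csv", written)

        _stage("reduce")
        rep = ReducedRepresentation().fit(
            table[list(CURVE_COLUMNS)].to_numpy()
        )
        scores = rep.transform(table[list(CURVE_COLUMNS)].to_numpy())
        red = pd.DataFrame(scores, index=table.index, columns=["PC1", "PC2"])
        _write(red, out / "reduced_representation.csv", written)

        benchmark_table = None
        if config.benchmark:
            _stage("benchmark")
            fsets = (default_feature_sets(config.feature_sets)
                     if config.feature_sets else None)
            benchmark_table = benchmark_feature_sets(
                table, config.phenotypes, fsets, config.protocol
            )
            _write(benchmark_table.reset_index(drop=True),
                   out / "benchmark.csv", written, index=False)

        _stage("cgm-concordance")
        cgm_report = _cgm_stage(bundle, out, written)
    except Exception as exc:
        raise RuntimeError(f"pipeline halted: {exc}") from exc

    return {
        "stamp": stamp,
        "paths": written,
        "profiles": profiles,
        "deviances": z_out,
        "dominance": summary,
        "benchmark": benchmark_table,
        "cgm": cgm_report,
    }


def _cgm_stage(bundle, out, written):
    pairs_home, repeats = {}, {}
    pairs_clinic = {}
    for pid in bundle.participant_ids:
        try:
            h1 = resample_to_canonical(bundle.glucose_curve(pid, "cgm_home", "home1"))
            h2 = resample_to_canonical(bundle.glucose_curve(pid, "cgm_home", "home2"))
            plasma = impute_curve(bundle.glucose_curve(pid, "plasma"))
            clinic = resample_to_canonical(
                bundle.glucose_curve(pid, "cgm_clinic", "clinic")
            )
            pairs_home[pid] = (h1, h2)
            pairs_clinic[pid] = (plasma, clinic)
            repeats[pid] = [h1, h2]
        except (LookupError, ValueError, IndexError):
            continue
    if not pairs_home:
        return None
    home = concordance_report(pairs_home)
    clinic = concordance_report(pairs_clinic)
    cvs = [intraindividual_cv(r)[1] for r in repeats.values()]
    report = {
        "home1_vs_home2": home.attrs["summary"],
        "plasma_vs_clinic_cgm": clinic.attrs["summary"],
        "mean_intraindividual_cv_pct": float(np.mean(cvs)),
    }
    with open(out / "cgm_concordance.json", "w") as fh:
        json.dump(report, fh, indent=2)
    written["cgm_concordance"] = str(out / "cgm_concordance.json")
    return report


def _write(df: pd.DataFrame, path: Path, written: dict, index: bool = True):
    df.to_csv(path, float_format="%.10g", index=index)
    written[path.stem] = str(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
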