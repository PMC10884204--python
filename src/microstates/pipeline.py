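"""End-to-end orchestration: simulate -> cluster -> fit -> stats -> reliability.

A run is driven by a :class:`RunConfig` (typically loaded from YAML).  The
global seed expands into per-stage and per-subject seeds through a fixed
``SeedSequence`` spawn scheme (stage order: cohort, clustering, so results
for one subject do not depend on cohort size downstream of its own seed).

Condition key: session x clustering method x fitting procedure.  The first
(session, method) grand-mean set serves as the normative reference all other
grand means are sorted against, so labels are comparable across conditions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characteristics import compute_stats, stats_to_row
from .clustering import (TemplateSet, aahc, modified_kmeans, save_template_set,
                         sort_against_reference, two_level_grand_mean)
from .errors import ConfigError, MicrostatesError
from .fitting import gm_fitting, ind_fitting
from .maps import Recording, _ref, find_gfp_peaks, gfp_curve
from .montages import standard_1020_montage
from .reliability import corr_diff_ztest, reliability_report
from .simulate import CohortData, CohortDesign, make_templates, simulate_cohort

__all__ = ["RunConfig", "ConditionKey", "validate_config", "run_pipeline",
           "cluster_recording"]


@dataclass(frozen=True)
class ConditionKey:
    """One analysis condition of a full retest design.

    The canonical design crosses two recording days, a pre and a post
    measure per day, two clustering procedures and two fitting procedures —
    16 conditions in total (see :meth:`all_conditions`).
    """

    day: str  # "one" | "two"
    measure: str  # "pre" | "post"
    clustering: str  # "kmeans" | "aahc"
    fitting: str  # "gm" | "ind"

    _VALID = {"day": ("one", "two"), "measure": ("pre", "post"),
              "clustering": ("kmeans", "aahc"), "fitting": ("gm", "ind")}

    def __post_init__(self):
        for name, allowed in self._VALID.items():
            if getattr(self, name) not in allowed:
                raise ConfigError([f"{name} must be one of {allowed}, "
                                   f"got {getattr(self, name)!r}"])

    def __str__(self) -> str:
        return f"day-{self.day}/{self.measure}/{self.clustering}/{self.fitting}"

    @classmethod
    def all_conditions(cls) -> list["ConditionKey"]:
        return [cls(d, m, c, f)
                for d in cls._VALID["day"] for m in cls._VALID["measure"]
                for c in cls._VALID["clustering"] for f in cls._VALID["fitting"]]

logger = logging.getLogger("microstates")

_COHORT_KEYS = {
    "n_subjects", "n_sessions", "duration_s", "srate", "mean_duration_ms",
    "gamma_shape", "between_subject_sd_ms", "within_subject_sd_ms", "snr",
    "oscillation_hz", "template_jitter_r", "amplitude",
}
_ANALYSIS_DEFAULTS = {
    "K": 5,
    "clustering_methods": ["kmeans"],
    "fitting_procedures": ["gm"],
    "n_restarts": 10,
    "min_peak_distance_ms": 0.0,
    "window_ms": 20.0,
    "penalty": 1.0,
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    seed: int
    out_dir: str
    cohort: CohortDesign
    K: int = 5
    clustering_methods: tuple[str, ...] = ("kmeans",)
    fitting_procedures: tuple[str, ...] = ("gm",)
    n_restarts: int = 10
    min_peak_distance_ms: float = 0.0
    window_ms: float = 20.0
    penalty: float = 1.0


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a config mapping or YAML file.

    All problems are collected and reported together in a
    :class:`ConfigError`; unknown keys are errors, never silently ignored.
    """
    if isinstance(source, (str, Path)):
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except OSError as exc:
            raise ConfigError([f"cannot read config file: {exc}"]) from exc
        except yaml.YAMLError as exc:
            raise ConfigError([f"config is not valid YAML: {exc}"]) from exc
    else:
        raw = dict(source)
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    known_top = {"seed", "out_dir", "cohort", "analysis"}
    for key in raw:
        if key not in known_top:
            problems.append(f"unknown key: {key}")
    if "seed" not in raw:
        problems.append("missing required field: seed")
    elif not isinstance(raw["seed"], int):
        problems.append("seed must be an integer")
    out_dir = raw.get("out_dir", "run_output")

    cohort_raw = raw.get("cohort", {}) or {}
    for key in cohort_raw:
        if key not in _COHORT_KEYS:
            problems.append(f"unknown cohort key: {key}")
    analysis_raw = raw.get("analysis", {}) or {}
    for key in analysis_raw:
        if key not in _ANALYSIS_DEFAULTS:
            problems.append(f"unknown analysis key: {key}")
    analysis = {**_ANALYSIS_DEFAULTS, **{k: v for k, v in analysis_raw.items()
                                         if k in _ANALYSIS_DEFAULTS}}
    if not (2 <= int(analysis["K"]) <= 12):
        problems.append(f"K must be in 2..12, got {analysis['K']}")
    for m in analysis["clustering_methods"]:
        if m not in ("kmeans", "aahc"):
            problems.append(f"unknown clustering method: {m}")
    for f in analysis["fitting_procedures"]:
        if f not in ("gm", "ind"):
            problems.append(f"unknown fitting procedure: {f}")

    cohort = None
    if not problems or all("cohort" not in p for p in problems):
        try:
            cohort = CohortDesign(
                **{k: v for k, v in cohort_raw.items() if k in _COHORT_KEYS},
                K=int(analysis["K"]),
                seed=raw.get("seed", 0) if isinstance(raw.get("seed", 0), int) else 0,
            )
        except (MicrostatesError, TypeError, ValueError) as exc:
            problems.append(f"invalid cohort design: {exc}")
    if problems:
        raise ConfigError(problems)
    return RunConfig(
        seed=int(raw["seed"]),
        out_dir=str(out_dir),
        cohort=cohort,
        K=int(analysis["K"]),
        clustering_methods=tuple(analysis["clustering_methods"]),
        fitting_procedures=tuple(analysis["fitting_procedures"]),
        n_restarts=int(analysis["n_restarts"]),
        min_peak_distance_ms=float(analysis["min_peak_distance_ms"]),
        window_ms=float(analysis["window_ms"]),
        penalty=float(analysis["penalty"]),
    )


def cluster_recording(
    rec: Recording,
    K: int,
    method: str = "kmeans",
    n_restarts: int = 10,
    min_peak_distance_ms: float = 0.0,
    seed=None,
) -> TemplateSet:
    """Mean individual maps of one recording: cluster its GFP-peak maps."""
    peaks = find_gfp_peaks(gfp_curve(rec), min_distance_ms=min_peak_distance_ms,
                           srate=rec.srate)
    X = _ref(rec.data[:, peaks]).T
    if method == "kmeans":
        res = modified_kmeans(X, K, n_restarts=n_restarts, seed=seed, montage=rec.montage)
    elif method == "aahc":
        res = aahc(X, K, montage=rec.montage)
    else:
        raise ConfigError([f"unknown clustering method: {method}"])
    return TemplateSet(res.templates.maps, rec.montage, res.templates.labels,
                       level="individual-mean", gev=res.gev)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute a full run; returns the run directory.

    Outputs: grand-mean template sets per condition, wide stats CSVs, long
    reliability CSVs, method-comparison z-tests, a provenance manifest and a
    log.  Deterministic for a fixed config.  On stage failure the completed
    outputs remain and ``manifest.json`` carries the error status.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    cfg_text = yaml.safe_dump({
        "seed": config.seed, "out_dir": str(out), "K": config.K,
        "clustering_methods": list(config.clustering_methods),
        "fitting_procedures": list(config.fitting_procedures),
        "n_restarts": config.n_restarts,
        "min_peak_distance_ms": config.min_peak_distance_ms,
        "window_ms": config.window_ms, "penalty": config.penalty,
        "cohort": asdict(config.cohort),
    }, sort_keys=True)
    (out / "config_used.yaml").write_text(cfg_text)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "stages": {},
        "status": "running",
    }

    def _stage_done(name: str, t0: float):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), "status": "ok"}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_cluster = root.spawn(2)
    try:
        # --- simulate -----------------------------------------------------
        t0 = time.time()
        logger.info("simulate: %s", asdict(config.cohort))
        montage = standard_1020_montage()
        templates = make_templates(montage, K=config.K, seed=_seed_int(ss_cohort))
        cohort = simulate_cohort(templates, config.cohort, seed=_seed_int(ss_cohort) + 1)
        sessions = sorted({r.session_id for r in cohort.recordings})
        _stage_done("simulate", t0)

        # --- individual + grand-mean clustering ---------------------------
        t0 = time.time()
        subj_seeds = ss_cluster.spawn(len(cohort.recordings))
        grand: dict[tuple[str, str], TemplateSet] = {}
        indiv: dict[tuple[str, str, str], TemplateSet] = {}  # (subject, session, method)
        for method in config.clustering_methods:
            for sess in sessions:
                sets = []
                for rec, ss in zip(cohort.recordings, subj_seeds):
                    if rec.session_id != sess:
                        continue
                    ts = cluster_recording(
                        rec, config.K, method=method, n_restarts=config.n_restarts,
                        min_peak_distance_ms=config.min_peak_distance_ms,
                        seed=_seed_int(ss),
                    )
                    indiv[(rec.subject_id, sess, method)] = ts
                    sets.append(ts)
                gm, _ = two_level_grand_mean(
                    sets, K=config.K, method="kmeans",
                    n_restarts=config.n_restarts, seed=_seed_int(ss_cluster),
                )
                grand[(sess, method)] = gm
        reference = grand[(sessions[0], config.clustering_methods[0])]
        (out / "templates").mkdir(exist_ok=True)
        for (sess, method), gm in grand.items():
            gm_sorted = sort_against_reference(gm, reference)
            grand[(sess, method)] = gm_sorted
            save_template_set(gm_sorted, out / "templates" / f"grand_{sess}_{method}")
        logger.info("clustering: K=%d methods=%s restarts=%d",
                    config.K, config.clustering_methods, config.n_restarts)
        _stage_done("cluster", t0)

        # --- fitting + characteristics ------------------------------------
        t0 = time.time()
        (out / "stats").mkdir(exist_ok=True)
        tables: dict[tuple[str, str, str], pd.DataFrame] = {}
        for method in config.clustering_methods:
            for proc in config.fitting_procedures:
                for sess in sessions:
                    rows = []
                    for rec in cohort.recordings:
                        if rec.session_id != sess:
                            continue
                        gm = grand[(sess, method)]
                        if proc == "gm":
                            seq = gm_fitting(rec, gm,
                                             min_peak_distance_ms=config.min_peak_distance_ms,
                                             window_ms=config.window_ms,
                                             penalty=config.penalty)
                        else:
                            seq = ind_fitting(rec, indiv[(rec.subject_id, sess, method)], gm,
                                              min_peak_distance_ms=config.min_peak_distance_ms,
                                              window_ms=config.window_ms,
                                              penalty=config.penalty)
                        st = compute_stats(rec, seq)
                        rows.append(stats_to_row(st, subject=rec.subject_id,
                                                 session=sess, method=method, fitting=proc))
                    table = pd.DataFrame(rows)
                    tables[(sess, method, proc)] = table
                    table.to_csv(out / "stats" / f"stats_{sess}_{method}_{proc}.csv",
                                 index=False)
        logger.info("fitting: window_ms=%s penalty=%s procedures=%s",
                    config.window_ms, config.penalty, config.fitting_procedures)
        _stage_done("fit", t0)

        # --- reliability ---------------------------------------------------
        t0 = time.time()
        (out / "reliability").mkdir(exist_ok=True)
        family_avg: dict[tuple[str, str], pd.DataFrame] = {}
        if len(sessions) >= 2:
            s1, s2 = sessions[0], sessions[1]
            for method in config.clustering_methods:
                for proc in config.fitting_procedures:
                    rep = reliability_report(tables[(s1, method, proc)],
                                             tables[(s2, method, proc)])
                    rep.to_csv(out / "reliability" / f"reliability_{method}_{proc}.csv",
                               index=False)
                    family_avg[(method, proc)] = rep
            comps = []
            n_sub = config.cohort.n_subjects
            conds = list(family_avg)
            for i, c1 in enumerate(conds):
                for c2 in conds[i + 1:]:
                    a, b = family_avg[c1], family_avg[c2]
                    for fam_row in a[a["characteristic"].str.startswith("average_")].itertuples():
                        r1 = fam_row.icc
                        sel = b[b["characteristic"] == fam_row.characteristic]
                        if len(sel) == 0 or np.isnan(r1) or np.isnan(sel.iloc[0]["icc"]):
                            continue
                        r2 = float(sel.iloc[0]["icc"])
                        z, p1, p2 = corr_diff_ztest(r1, n_sub, r2, n_sub)
                        comps.append({"family": fam_row.characteristic,
                                      "condition_1": "/".join(c1), "condition_2": "/".join(c2),
                                      "icc_1": r1, "icc_2": r2, "z": z,
                                      "p_one_sided": p1, "p_two_sided": p2})
            pd.DataFrame(comps).to_csv(out / "reliability" / "method_comparisons.csv",
                                       index=False)
        _stage_done("reliability", t0)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "error"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.removeHandler(handler)
        handler.close()
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.removeHandler(handler)
    handler.close()
    return out
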