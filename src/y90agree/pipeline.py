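"""End-to-end orchestration: simulate -> dose -> extract -> agree -> classify.

Two entry modes:

* ``table`` — draw a multi-observer cohort directly from the log-normal
  cohort model (fast; exercises the statistics core alone);
* ``phantom`` — build one digital phantom per treatment, perturb the true
  masks once per observer, compute the local-deposition dose and extract
  the dosimetric quantities voxel-wise.

Either way the result is a complete-block observer table, which is run
through the full agreement battery (summaries, pairwise + three-way ICC,
pairwise CV, Bland-Altman, RDC with bootstrap CI, normality-gated location
tests) and the dose-target concordance rules, and serialized as a
self-describing JSON report plus a flat per-quantity CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import ReadingsMatrix, bland_altman, compare_readers, icc, pairwise_cv, rdc
from .cohort import (
    COLUMN_BY_QUANTITY,
    TABLE_COLUMNS,
    CohortModel,
    observer_labels,
    simulate_cohort,
    treatment_labels,
    write_observer_table,
)
from .concordance import DEFAULT_RULES, ThresholdRule, discordance_fraction
from .phantom import (
    Ellipsoid,
    PerturbationSpec,
    PhantomGeometry,
    build_phantom,
    extract_measurements,
    local_deposition_dose,
    perturb_mask,
    save_volume,
)

__all__ = [
    "RunConfig",
    "TableSchemaError",
    "IncompleteBlockError",
    "PositivityError",
    "ConsistencyError",
    "read_observer_table",
    "analyze_table",
    "run_pipeline",
    "write_report",
    "read_report",
    "report_summary_frame",
]

log = logging.getLogger("y90agree")

UNITS = {"TV": "ml", "TLV": "ml", "THLV": "ml", "TD": "Gy", "THLD": "Gy"}

#: Tolerance (ml) for the THLV = TLV - TV consistency check on file input;
#: absorbs rounding of exported volumes.
THLV_TOLERANCE_ML = 0.5


class TableSchemaError(ValueError):
    """The CSV does not carry the documented columns."""


class IncompleteBlockError(ValueError):
    """Some (treatment, observer) cell is missing or duplicated."""


class PositivityError(ValueError):
    """Volumes must be positive and doses non-negative."""


class ConsistencyError(ValueError):
    """THLV does not equal TLV - TV within tolerance."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def _default_phantom_params() -> dict:
    return {
        "grid_shape": [44, 54, 64],
        "voxel_size_mm": [4.0, 4.0, 4.0],
        # liver ellipsoid semi-axes (z, y, x) in mm, jittered +/-10% per case
        "liver_semi_axes_mm": [60.0, 75.0, 90.0],
        "liver_jitter": 0.10,
        # tumor radius sampled log-uniformly in this range (mm)
        "tumor_radius_range_mm": [15.0, 40.0],
        # a second lesion with this probability (multifocal disease)
        "second_tumor_prob": 0.24,
        "uptake_ratio_mean": 4.0,
        "uptake_ratio_log_sd": 0.4,
        "activity_mean_gbq": 1.98,
        "activity_sd_gbq": 1.23,
        "activity_min_gbq": 0.3,
        # seeded log-normal activity texture (microsphere clustering)
        "heterogeneity_sigma": 0.25,
        "blur_fwhm_mm": None,
        # per-observer systematic contouring tendencies plus per-case jitter
        "tumor_margins_voxels": [0, 1, -1],
        "tumor_margin_sd": 0.4,
        "tumor_flip_prob": 0.25,
        "liver_margins_voxels": [0, 0, 0],
        "liver_margin_sd": 0.18,
        "liver_flip_prob": 0.05,
    }


@dataclass
class RunConfig:
    mode: str = "table"  # "table" | "phantom"
    n_treatments: int = 25
    n_observers: int = 3
    seed: int = 0
    quantities: tuple[str, ...] = ("TLV", "THLD", "TV", "TD")
    #: per-quantity overrides of the log-scale observer-error SD (table mode)
    sigma_within: dict | None = None
    n_bootstrap: int = 2000
    alpha: float = 0.05
    bonferroni: bool = False
    rules: tuple[ThresholdRule, ...] = DEFAULT_RULES
    phantom: dict = field(default_factory=_default_phantom_params)
    save_volumes: bool = False

    def validate(self) -> None:
        if self.mode not in ("table", "phantom"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_treatments < 2 or self.n_observers < 2:
            raise ValueError("need >= 2 treatments and >= 2 observers")
        unknown = set(self.quantities) - set(UNITS)
        if unknown:
            raise ValueError(f"unknown quantities: {sorted(unknown)}")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        for r in self.rules:
            r.validate()
        if self.mode == "phantom":
            margins_t = self.phantom["tumor_margins_voxels"]
            margins_l = self.phantom["liver_margins_voxels"]
            if len(margins_t) != self.n_observers or len(margins_l) != self.n_observers:
                raise ValueError(
                    "phantom margins lists must have one entry per observer"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quantities"] = list(self.quantities)
        d["rules"] = [dataclasses.asdict(r) for r in self.rules]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "rules" in d:
            d["rules"] = tuple(
                r if isinstance(r, ThresholdRule) else ThresholdRule(**r)
                for r in d["rules"]
            )
        if "quantities" in d:
            d["quantities"] = tuple(d["quantities"])
        phantom = _default_phantom_params()
        phantom.update(d.get("phantom") or {})
        d["phantom"] = phantom
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Table input with validation
# ---------------------------------------------------------------------------


def validate_observer_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise TableSchemaError(f"missing columns: {sorted(missing)}")
    treatments = table["treatment_id"].unique()
    observers = table["observer_id"].unique()
    counts = table.groupby(["treatment_id", "observer_id"]).size()
    if (counts != 1).any() or len(counts) != len(treatments) * len(observers):
        bad = counts[counts != 1]
        raise IncompleteBlockError(
            "incomplete block design: expected exactly one row per "
            f"(treatment, observer); offending cells: {list(bad.index[:5])!r}"
            if len(bad)
            else "incomplete block design: missing (treatment, observer) rows"
        )
    for col in ("TV_ml", "TLV_ml", "THLV_ml"):
        if (table[col] <= 0).any():
            row = table.index[table[col] <= 0][0]
            raise PositivityError(f"non-positive {col} at row {row}")
    for col in ("TD_Gy", "THLD_Gy"):
        if (table[col] < 0).any():
            row = table.index[table[col] < 0][0]
            raise PositivityError(f"negative {col} at row {row}")
    if (table["TV_ml"] >= table["TLV_ml"]).any():
        row = table.index[table["TV_ml"] >= table["TLV_ml"]][0]
        raise PositivityError(f"TV >= TLV at row {row}")
    resid = (table["TLV_ml"] - table["TV_ml"] - table["THLV_ml"]).abs()
    if (resid > THLV_TOLERANCE_ML).any():
        row = table.index[resid > THLV_TOLERANCE_ML][0]
        raise ConsistencyError(
            f"THLV_ml != TLV_ml - TV_ml beyond {THLV_TOLERANCE_ML} ml at row {row}"
        )
    return table


def read_observer_table(path) -> pd.DataFrame:
    """Read and validate a long-format observer CSV."""
    table = pd.read_csv(path)
    validate_observer_table(table)
    n_t = table["treatment_id"].nunique()
    n_o = table["observer_id"].nunique()
    log.info("read %s: %d treatments x %d observers", path, n_t, n_o)
    return table


# ---------------------------------------------------------------------------
# Phantom-mode cohort
# ---------------------------------------------------------------------------


def _sample_geometry(p: dict, rng: np.random.Generator) -> PhantomGeometry:
    shape = tuple(int(s) for s in p["grid_shape"])
    voxel = tuple(float(v) for v in p["voxel_size_mm"])
    center = tuple((s * v) / 2.0 for s, v in zip(shape, voxel))
    jitter = p["liver_jitter"]
    semi = tuple(
        float(a) * rng.uniform(1.0 - jitter, 1.0 + jitter)
        for a in p["liver_semi_axes_mm"]
    )
    liver = Ellipsoid(center, semi)

    n_tumors = 2 if rng.random() < p["second_tumor_prob"] else 1
    lo, hi = p["tumor_radius_range_mm"]
    tumors = []
    for _ in range(n_tumors):
        for _attempt in range(50):
            radius = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            u = rng.uniform(0.0, 0.6)
            tcenter = tuple(
                c + u * a * d for c, a, d in zip(center, semi, direction)
            )
            # conservative containment check before rasterizing: ellipsoidal
            # distance of the center plus the worst-case radius term
            ellip_dist = float(
                np.sqrt(sum(((tc - c) / a) ** 2 for tc, c, a in zip(tcenter, center, semi)))
            )
            if ellip_dist + radius / min(semi) <= 0.90:
                tumors.append(Ellipsoid(tcenter, (radius, radius, radius)))
                break
        else:
            raise RuntimeError("could not place a tumor inside the liver")
    return PhantomGeometry(shape, liver, tuple(tumors), voxel)


def simulate_phantom_table(config: RunConfig, output_dir: Path | None = None) -> pd.DataFrame:
    """Per-treatment phantoms read by perturbed observer segmentations."""
    p = config.phantom
    obs = observer_labels(config.n_observers)
    t_labels = treatment_labels(config.n_treatments)
    children = np.random.SeedSequence(config.seed).spawn(config.n_treatments)
    rows = []
    for i, (t_label, child) in enumerate(zip(t_labels, children)):
        rng = np.random.default_rng(child)
        geometry = _sample_geometry(p, rng)
        activity = max(
            p["activity_min_gbq"],
            rng.normal(p["activity_mean_gbq"], p["activity_sd_gbq"]),
        )
        ratio = float(
            p["uptake_ratio_mean"]
            * np.exp(rng.normal(0.0, p["uptake_ratio_log_sd"]) - p["uptake_ratio_log_sd"] ** 2 / 2)
        )
        phantom = build_phantom(
            geometry,
            total_activity_gbq=activity,
            tumor_to_liver_uptake_ratio=ratio,
            seed=int(rng.integers(2**31)),
            blur_fwhm_mm=p["blur_fwhm_mm"],
            heterogeneity_sigma=p["heterogeneity_sigma"],
        )
        dose = local_deposition_dose(phantom)
        if output_dir is not None and config.save_volumes:
            save_volume(phantom.activity, phantom.voxel_size_mm, output_dir / f"{t_label}_activity.nii.gz")
            save_volume(dose, phantom.voxel_size_mm, output_dir / f"{t_label}_dose.nii.gz")
        true_tumors = phantom.tumor_masks
        for j, o in enumerate(obs):
            liver_spec = PerturbationSpec(
                float(p["liver_margins_voxels"][j])
                + rng.normal(0.0, p["liver_margin_sd"]),
                float(p["liver_flip_prob"]),
            )
            tumor_spec = PerturbationSpec(
                float(p["tumor_margins_voxels"][j])
                + rng.normal(0.0, p["tumor_margin_sd"]),
                float(p["tumor_flip_prob"]),
            )
            liver_obs = perturb_mask(
                phantom.liver_mask, liver_spec, seed=int(rng.integers(2**31))
            )
            tumors_obs = [
                perturb_mask(
                    tm, tumor_spec, seed=int(rng.integers(2**31)), clip_to=liver_obs
                )
                for tm in true_tumors
            ]
            m = extract_measurements(phantom, dose, liver_obs, tumors_obs, o)
            rows.append(
                {
                    "treatment_id": t_label,
                    "observer_id": o,
                    "TV_ml": m.TV,
                    "TLV_ml": m.TLV,
                    "THLV_ml": m.THLV,
                    "TD_Gy": m.TD,
                    "THLD_Gy": m.THLD,
                }
            )
        log.debug("phantom %s done (%d/%d)", t_label, i + 1, config.n_treatments)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}"


def analyze_table(
    table: pd.DataFrame,
    quantities=("TLV", "THLD", "TV", "TD"),
    rules=DEFAULT_RULES,
    n_bootstrap: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> dict:
    """Run the full agreement battery on a validated observer table."""
    validate_observer_table(table)
    report_q = {}
    for qi, q in enumerate(quantities):
        matrix = ReadingsMatrix.from_table(table, q, units=UNITS[q])
        labels = matrix.observer_labels
        summary = {}
        for o in labels:
            col = matrix.column(o)
            summary[o] = {
                "mean": float(np.mean(col)),
                "sd": float(np.std(col, ddof=1)),
                "median": float(np.median(col)),
                "min": float(np.min(col)),
                "max": float(np.max(col)),
            }
        pairs = list(itertools.combinations(labels, 2))
        icc_block = {
            _pair_key(*pr): icc(matrix.subset(pr), alpha=alpha) for pr in pairs
        }
        icc_block["|".join(labels)] = icc(matrix, alpha=alpha)
        cv_block = {
            _pair_key(a, b): pairwise_cv(matrix.column(a), matrix.column(b))
            for a, b in pairs
        }
        ba_block = {
            _pair_key(a, b): bland_altman(matrix.column(a), matrix.column(b))
            for a, b in pairs
        }
        rdc_res = rdc(matrix, n_bootstrap=n_bootstrap, seed=seed + qi)
        comparison = compare_readers(matrix, alpha=alpha)
        if bonferroni:
            n_pairs = len(pairs)
            adjusted = tuple(
                dataclasses.replace(
                    pt,
                    p_value=None
                    if pt.p_value is None
                    else min(1.0, pt.p_value * n_pairs),
                )
                for pt in comparison.pairwise
            )
            comparison = dataclasses.replace(comparison, pairwise=adjusted)
        report_q[q] = {
            "units": UNITS[q],
            "summary": summary,
            "icc": icc_block,
            "cv_percent": cv_block,
            "bland_altman": ba_block,
            "rdc": rdc_res,
            "comparison": comparison,
        }
    conc = {}
    for rule in rules:
        res = discordance_fraction(table, rule)
        conc[rule.label] = {
            "rule": rule,
            "units": "Gy",
            "n_treatments": res.n_treatments,
            "n_discordant": res.n_discordant,
            "fraction_discordant": res.fraction_discordant,
            "classifications": res.classifications,
        }
    return _jsonable({"quantities": report_q, "concordance": conc})


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, output_dir=None) -> dict:
    """Execute an end-to-end run and return the agreement report.

    Deterministic given the config (which includes the seed); when
    ``output_dir`` is given, writes the cohort CSV, the JSON report and a
    flat per-quantity summary CSV there.
    """
    config.validate()
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage 1: cohort (%s mode, n=%d, k=%d, seed=%d)",
             config.mode, config.n_treatments, config.n_observers, config.seed)
    try:
        if config.mode == "table":
            model = CohortModel.default(
                n_treatments=config.n_treatments,
                n_observers=config.n_observers,
                seed=config.seed,
                sigma_within=config.sigma_within,
            )
            table = simulate_cohort(model)
        else:
            table = simulate_phantom_table(config, output_dir=out)
    except Exception as exc:  # annotate with the stage name
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc
    if out is not None:
        write_observer_table(table, out / "cohort.csv")

    log.info("stage 2: agreement battery on %d quantities", len(config.quantities))
    try:
        body = analyze_table(
            table,
            quantities=config.quantities,
            rules=config.rules,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            alpha=config.alpha,
            bonferroni=config.bonferroni,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'analysis' failed: {exc}") from exc

    report = {
        "provenance": {
            "config": config.to_dict(),
            "config_sha256": config.sha256(),
            "seed": config.seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        **body,
    }
    if out is not None:
        write_report(report, out / "report.json")
        report_summary_frame(report).to_csv(out / "summary.csv", index=False)
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def report_summary_frame(report: dict) -> pd.DataFrame:
    """Flat per-quantity table: pairwise + all-observer ICC (with CI) and
    pairwise CV, one row per quantity and pairing."""
    rows = []
    for q, block in report["quantities"].items():
        n_obs = len(block["summary"])
        for pairing, res in block["icc"].items():
            all_observers = len(pairing.split("|")) == n_obs
            rows.append(
                {
                    "quantity": q,
                    "units": block["units"],
                    "pairing": pairing,
                    "icc": res["estimate"],
                    "icc_ci_low": res["ci_low"],
                    "icc_ci_high": res["ci_high"],
                    "cv_percent": block["cv_percent"].get(pairing),
                    "rdc": block["rdc"]["estimate"] if all_observers else None,
                }
            )
    return pd.DataFrame(rows)
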