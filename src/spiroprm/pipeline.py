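"""End-to-end orchestration: simulate -> derive -> PRM -> ULN -> tables.

Stages hand off through plain files (CSV / JSON / NIfTI) inside the run
directory so any stage can be inspected or re-run; a manifest records
the configuration, seed and an aggregate hash so a run is reproducible
byte-for-byte.  Per-stage randomness is derived deterministically from
the single master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import normative, prm, simulate, spirometry, stats

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)

GROUP_ORDER = ("discordant", "smoker_normal", "neversmoker_normal")

TABLE2_CONTINUOUS = (
    ("fev1_pct_pred", "FEV1 % predicted"),
    ("fef2575_pct_pred", "FEF25-75 % predicted"),
    ("sixmwd_m", "6-minute walk distance (m)"),
    ("sgrq_total", "SGRQ total score"),
    ("cat_score", "CAT score"),
    ("fev1_slope_ml_per_year", "FEV1 change (ml/year)"),
    ("exacerbations_year1", "Exacerbations (#/year)"),
)
TABLE2_BINARY = (
    ("medication_use", "Inhaled corticosteroid or bronchodilator use"),
    ("chronic_bronchitis", "Chronic bronchitis"),
    ("dyspnea_mod_severe", "mMRC dyspnea score >= 2"),
)
TABLE3_CONTINUOUS = (
    ("pct_emphysema", "Emphysema (%)"),
    ("pct_fsad", "Functional small airways disease (%)"),
    ("pi10", "Airway wall thickening (Pi10)"),
)
TABLE3_BINARY = (
    ("emph_present", "Emphysema present > ULN"),
    ("fsad_present", "fSAD present > ULN"),
    ("either_present", "Either emphysema or fSAD present"),
    ("both_present", "Both emphysema and fSAD present"),
)
ADJUST_COVARIATES = ("age", "sex", "race", "pack_years", "current_smoker")


@dataclass
class RunConfig:
    """Validated settings for one pipeline run."""

    outdir: str = "spiroprm_run"
    seed: int = 0
    simulate: bool = True
    calibration_file: str | None = None
    size_factor: float = 1.0
    tau: float = 0.95
    threshold_rules: tuple[str, ...] = ("fixed_0.70", "lln")
    #: "realize" renders paired volumes and runs PRM; "true" uses the
    #: generator's fractions directly; "none" skips the CT stages
    ct_mode: str = "realize"
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    save_volumes: bool = False
    normal_fev1_rule: str = "lln"
    group4_mode: str | None = None
    #: "reference_bed" fits the ULN models on a synthetic healthy bed with
    #: known quantiles; "cohort_neversmokers" fits on the cohort's group 3
    normative_training: str = "reference_bed"
    normative_training_n: int = 1500
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.tau < 1):
            raise ValueError("tau must lie in (0, 1)")
        if self.ct_mode not in ("realize", "true", "none"):
            raise ValueError(f"unknown ct_mode {self.ct_mode!r}")
        if self.normative_training not in ("reference_bed", "cohort_neversmokers"):
            raise ValueError(f"unknown normative_training {self.normative_training!r}")
        for rule in self.threshold_rules:
            if rule not in stats.THRESHOLD_RULES:
                raise ValueError(f"unknown threshold rule {rule!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        for f in ("threshold_rules", "volume_shape"):
            setattr(cfg, f, tuple(getattr(cfg, f)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["threshold_rules"] = list(self.threshold_rules)
        d["volume_shape"] = list(self.volume_shape)
        return d


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame]
    accuracy: dict
    manifest: dict
    outdir: Path
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return np.random.SeedSequence([master, int.from_bytes(digest[:4], "big")])


def _comparison_frame(rows: list[stats.ComparisonRow], order=GROUP_ORDER) -> pd.DataFrame:
    recs = []
    for row in rows:
        rec: dict = {"outcome": row.outcome_name, "kind": row.kind}
        for g in row.group_order:
            if row.kind == "continuous":
                m, s = row.group_summary[g]
                rec[f"{g}_mean"] = m
                rec[f"{g}_sd"] = s
            else:
                rec[f"{g}_pct"] = row.group_summary[g]
            rec[f"{g}_n"] = row.group_n[g]
        rec["p_unadjusted"] = row.overall_p_unadjusted
        rec["p_adjusted"] = row.overall_p_adjusted
        for pair, p in row.pairwise_p.items():
            rec[f"p_{pair[0]}_vs_{pair[1]}"] = p
        for pair, p in row.pairwise_p_adjusted.items():
            rec[f"p_adj_{pair[0]}_vs_{pair[1]}"] = p
        if row.flagged:
            rec["flagged"] = row.flagged
        recs.append(rec)
    return pd.DataFrame(recs)


def _grouped(df: pd.DataFrame, col: str, order=GROUP_ORDER) -> dict[str, np.ndarray]:
    return {
        g: df.loc[df["group"] == g, col].to_numpy()
        for g in order
        if (df["group"] == g).any()
    }


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in dependency order and write the run directory."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    warnings_seen: list[str] = []
    t0 = time.perf_counter()

    # ---- stage 1: cohort (simulate or ingest) ----
    if config.simulate:
        calib = (
            simulate.load_calibration(config.calibration_file)
            if config.calibration_file
            else simulate.DEFAULT_CALIBRATION
        )
        if config.size_factor != 1.0:
            calib = simulate.scaled_calibration(calib, config.size_factor)
        seed = _stage_seed(config.seed, "simulate")
        subjects, visits, airway_df = simulate.generate_cohort(
            calib, seed=np.random.default_rng(seed).integers(2**31)
        )
    else:
        subjects = pd.read_csv(out / "subjects.csv")
        visits = pd.read_csv(out / "visits.csv")
        airway_df = pd.read_csv(out / "airways.csv")
    _write_csv(subjects, out / "subjects.csv")
    _write_csv(visits, out / "visits.csv")
    _write_csv(airway_df, out / "airways.csv")
    timings["simulate"] = time.perf_counter() - t0

    # ---- stage 2: spirometry derivation and grouping ----
    t1 = time.perf_counter()
    derived = spirometry.derive_spirometry(subjects)
    derived["group"] = spirometry.assign_groups(
        derived,
        normal_fev1_rule=config.normal_fev1_rule,
        group4_mode=config.group4_mode,
    )
    mismatch = derived["group"] != derived["group_true"]
    if mismatch.any():
        msg = f"{int(mismatch.sum())} subjects classified outside their generated group"
        warnings_seen.append(msg)
        log.warning(msg)
    slopes = spirometry.cohort_slopes(visits)
    derived = derived.merge(
        slopes.rename("fev1_slope_ml_per_year"),
        left_on="subject_id",
        right_index=True,
        how="left",
    )
    derived["dyspnea_mod_severe"] = derived["mmrc"] >= 2
    timings["spiro_derive"] = time.perf_counter() - t1

    # ---- stage 3: CT quantification (PRM + Pi10) ----
    t2 = time.perf_counter()
    ct_available = config.ct_mode != "none"
    if ct_available:
        if config.ct_mode == "realize":
            base = np.random.default_rng(_stage_seed(config.seed, "volumes")).integers(
                2**31, size=len(derived)
            )
            pcts_e = np.empty(len(derived))
            pcts_f = np.empty(len(derived))
            voldir = out / "volumes"
            if config.save_volumes:
                voldir.mkdir(exist_ok=True)
            for i, row in enumerate(derived.itertuples(index=False)):
                insp, exp, mask = simulate.realize_paired_volume(
                    row.true_pct_emphysema / 100.0,
                    row.true_pct_fsad / 100.0,
                    shape=config.volume_shape,
                    seed=int(base[i]),
                )
                labels = prm.classify_prm_voxels(insp, exp, mask)
                summ = prm.summarize_prm(labels)
                pcts_e[i] = summ.pct_emphysema
                pcts_f[i] = summ.pct_fsad
                if config.save_volumes:
                    prm.save_volume(voldir / f"{row.subject_id}_prm.nii.gz", labels)
            derived["pct_emphysema"] = pcts_e
            derived["pct_fsad"] = pcts_f
        else:
            derived["pct_emphysema"] = derived["true_pct_emphysema"]
            derived["pct_fsad"] = derived["true_pct_fsad"]
        pi10_by_subject = {
            sid: prm.compute_pi10(
                grp["internal_perimeter_mm"].to_numpy(),
                grp["wall_area_mm2"].to_numpy(),
            )
            for sid, grp in airway_df.groupby("subject_id", sort=False)
        }
        derived["pi10"] = derived["subject_id"].map(pi10_by_subject)
    timings["prm"] = time.perf_counter() - t2

    # ---- stage 4: normative ULN fit and presence classification ----
    t3 = time.perf_counter()
    models = {}
    if ct_available:
        if config.normative_training == "reference_bed":
            bed_seed = np.random.default_rng(_stage_seed(config.seed, "normative"))
            train = simulate.generate_normative_truth(
                config.normative_training_n, seed=bed_seed.integers(2**31)
            )
        else:
            train = derived[derived["group"] == "neversmoker_normal"]
        for metric in ("pct_emphysema", "pct_fsad"):
            model = normative.fit_normative(train, metric, tau=config.tau)
            model.to_json(out / f"normative_{metric}.json")
            models[metric] = model
            derived[f"uln_{metric}"] = normative.predict_uln(model, derived)
        derived["emph_present"] = normative.classify_presence(
            derived["pct_emphysema"], derived["uln_pct_emphysema"]
        )
        derived["fsad_present"] = normative.classify_presence(
            derived["pct_fsad"], derived["uln_pct_fsad"]
        )
        either, both = normative.disease_flags(
            derived["emph_present"], derived["fsad_present"]
        )
        derived["either_present"] = either
        derived["both_present"] = both
    _write_csv(derived, out / "derived.csv")
    timings["normative"] = time.perf_counter() - t3

    # ---- stage 5: comparison tables ----
    t4 = time.perf_counter()
    core = derived[derived["group"].isin(GROUP_ORDER)]
    tables: dict[str, pd.DataFrame] = {}

    t1_rows = [
        stats.compare_categorical(
            {g: core.loc[core["group"] == g, "sex"].eq("male").to_numpy() for g in GROUP_ORDER},
            "Sex (% male)",
        ),
        stats.compare_categorical(
            {g: core.loc[core["group"] == g, "race"].eq("caucasian").to_numpy() for g in GROUP_ORDER},
            "Race (% white)",
        ),
        stats.compare_categorical(
            _grouped(core.assign(cs=core["current_smoker"].astype(bool)), "cs"),
            "Current smoker (%)",
        ),
        stats.compare_continuous(_grouped(core, "age"), "Age (years)"),
        stats.compare_continuous(
            {
                g: core.loc[core["group"] == g, "pack_years"].to_numpy()
                for g in ("discordant", "smoker_normal")
            },
            "Smoking history (pack-years)",
        ),
    ]
    tables["table1"] = _comparison_frame(t1_rows)

    def _adjusted(outcome: str, family: str) -> tuple[float, dict]:
        res = stats.adjusted_group_test(
            core, outcome, "group", ADJUST_COVARIATES, family=family
        )
        return res["p_lrt"], res["pairwise_p"]

    def _rows_for(spec_cont, spec_bin) -> list[stats.ComparisonRow]:
        rows = []
        for col, label in spec_cont:
            if col not in core.columns:
                continue
            row = stats.compare_continuous(_grouped(core, col), label)
            try:
                row.overall_p_adjusted, row.pairwise_p_adjusted = _adjusted(col, "linear")
            except RuntimeError as exc:
                warnings_seen.append(str(exc))
            rows.append(row)
        for col, label in spec_bin:
            if col not in core.columns:
                continue
            row = stats.compare_categorical(
                {g: core.loc[core["group"] == g, col].astype(bool).to_numpy() for g in GROUP_ORDER},
                label,
            )
            try:
                row.overall_p_adjusted, row.pairwise_p_adjusted = _adjusted(col, "logistic")
            except RuntimeError as exc:
                warnings_seen.append(str(exc))
            rows.append(row)
        return rows

    tables["table2"] = _comparison_frame(_rows_for(TABLE2_CONTINUOUS, TABLE2_BINARY))
    if ct_available:
        tables["table3"] = _comparison_frame(_rows_for(TABLE3_CONTINUOUS, TABLE3_BINARY))

        # within-discordant comparison by CT disease status
        disc = core[core["group"] == "discordant"]
        t4_rows = []
        split = {
            "with_disease": disc[disc["either_present"]],
            "without_disease": disc[~disc["either_present"]],
        }
        if all(len(v) >= 2 for v in split.values()):
            for col, label in (
                ("fev1_slope_ml_per_year", "Annual change in FEV1 (ml/year)"),
                ("exacerbations_year1", "Exacerbations (#/year)"),
                ("cat_score", "CAT score"),
                ("fef2575_pct_pred", "FEF25-75 % predicted"),
            ):
                t4_rows.append(
                    stats.compare_continuous(
                        {k: v[col].to_numpy() for k, v in split.items()}, label
                    )
                )
            t4_rows.append(
                stats.compare_categorical(
                    {k: v["chronic_bronchitis"].astype(bool).to_numpy() for k, v in split.items()},
                    "Chronic bronchitis (%)",
                )
            )
        tables["table4"] = _comparison_frame(t4_rows)
    timings["tables"] = time.perf_counter() - t4

    # ---- stage 6: diagnostic accuracy of the threshold rules ----
    t5 = time.perf_counter()
    accuracy: dict = {}
    if ct_available:
        truth = derived["either_present"].to_numpy()
        acc_rows = []
        for rule in config.threshold_rules:
            pred = stats.threshold_positive(
                derived["ratio"].to_numpy(), derived["lln_ratio"].to_numpy(), rule
            )
            acc = stats.diagnostic_accuracy(pred, truth, rule_name=rule)
            accuracy[rule] = {
                "sensitivity": acc.sensitivity,
                "specificity": acc.specificity,
                "tp": acc.table.tp,
                "fp": acc.table.fp,
                "fn": acc.table.fn,
                "tn": acc.table.tn,
            }
            acc_rows.append(
                {
                    "rule": rule,
                    "sensitivity": acc.sensitivity,
                    "specificity": acc.specificity,
                    "n": acc.table.total,
                }
            )
        tables["table5"] = pd.DataFrame(acc_rows)
        with open(out / "accuracy.json", "w") as fh:
            json.dump(accuracy, fh, indent=2)
    timings["accuracy"] = time.perf_counter() - t5

    for name, tbl in tables.items():
        _write_csv(tbl, out / f"{name}.csv")

    # ---- manifest ----
    hasher = hashlib.sha256()
    for name in sorted(tables):
        hasher.update((out / f"{name}.csv").read_bytes())
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "tables_sha256": hasher.hexdigest(),
        "n_subjects": int(len(derived)),
        "warnings": warnings_seen,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunReport(
        tables=tables,
        accuracy=accuracy,
        manifest=manifest,
        outdir=out,
        stage_seconds=timings,
        warnings=warnings_seen,
    )
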