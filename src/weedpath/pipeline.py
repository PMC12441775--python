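"""End-to-end orchestration: generate/load -> diversity -> TFI -> rank
tests -> path models, with CSV inputs and outputs and a reproducibility
manifest.

The pipeline mirrors the standard reporting layout of a herbicide
field-trial series: a treatment summary (mean TFI and weed biomass with rank-test
letters), an alpha/gamma diversity table, Hill profiles per field and
treatment, and the multi-group path-model coefficient, effect and R²
tables with the stepwise constraint trail.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import (HILL_ORDERS, alpha_gamma, communities_from_long,
                        profile_table, proportions, shannon_index)
from .pathmodel import (PathModelSpec, coefficient_table, effects,
                        r_squared, stepwise_constrain)
from .ranktests import all_pairs_test
from .synthetic import (TREATED_GROUPS, UNTREATED, GeneratorConfig, TrialData,
                        generate_mechanistic, generate_structural)
from .tfi import relative_biomass, tfi_table

logger = logging.getLogger("weedpath")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str = "weedpath_out"
    seed: int = 0
    mode: str = "mechanistic"            # generator mode when no inputs given
    metric: str = "richness"             # "richness" | "shannon" for the path model
    orders: tuple[float, ...] = HILL_ORDERS
    alpha: float = 0.05                  # rank-test significance level
    alpha_keep: float = 0.05             # stepwise LRT acceptance threshold
    log_base: float = math.e             # base of the density log-transform
    generator: GeneratorConfig | None = None
    surveys_path: str | None = None      # optional pre-existing inputs
    applications_path: str | None = None
    biomass_path: str | None = None


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_tables(surveys: pd.DataFrame, applications: pd.DataFrame,
                    biomass: pd.DataFrame) -> ValidationReport:
    """Schema and sanity checks on the three trial tables."""
    rep = ValidationReport()

    def need(df, name, cols):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            rep.errors.append(f"{name}: missing columns {missing}")
            return False
        return True

    if need(surveys, "surveys", ("field", "block", "species", "count")):
        if surveys.empty:
            rep.errors.append("surveys: table is empty")
        bad = surveys.index[surveys["count"] < 0].tolist()
        if bad:
            rep.errors.append(f"surveys: negative counts at rows {bad[:10]}")
    if need(applications, "applications",
            ("field", "treatment", "product", "applied_dose", "registered_dose")):
        for col in ("applied_dose", "registered_dose"):
            bad = applications.index[applications[col] <= 0].tolist()
            if bad:
                rep.errors.append(f"applications: nonpositive {col} at rows {bad[:10]}")
        over = applications.index[
            applications["applied_dose"] > applications["registered_dose"]].tolist()
        if over:
            rep.warnings.append(
                f"applications: applied dose exceeds registered dose at rows {over[:10]}")
        if applications["treatment"].astype(str).str.strip().eq("").any():
            rep.errors.append("applications: empty treatment labels")
    if need(biomass, "biomass", ("field", "treatment", "species", "biomass_g_m2")):
        bad = biomass.index[biomass["biomass_g_m2"] < 0].tolist()
        if bad:
            rep.errors.append(f"biomass: negative biomass at rows {bad[:10]}")
        # completeness of the field x treatment response matrix
        if not biomass.empty:
            fields = sorted(biomass["field"].unique())
            treats = sorted(biomass["treatment"].unique())
            seen = set(zip(biomass["field"], biomass["treatment"]))
            holes = [(f, t) for f in fields for t in treats if (f, t) not in seen]
            if holes:
                rep.warnings.append(
                    f"biomass: {len(holes)} field x treatment cells without any "
                    f"species entry (treated as zero), e.g. {holes[:5]}")
    return rep


# ---------------------------------------------------------------------------
# derived observations

def _diversity_value(quantities, metric: str) -> float:
    """Richness or Shannon index of a community; 0 for an empty one."""
    q = np.asarray(list(quantities), dtype=float)
    q = q[q > 0]
    if q.size == 0:
        return 0.0
    if metric == "richness":
        return float(q.size)
    if metric == "shannon":
        return shannon_index(proportions(q))
    raise ValueError(f"unknown diversity metric {metric!r}")


def observations_from_trial(trial: TrialData, metric: str = "richness",
                            log_base: float = math.e,
                            groups: tuple[str, ...] = TREATED_GROUPS) -> pd.DataFrame:
    """Field x treated-group path-model observations from raw trial tables.

    Autumn diversity and density come from the pooled per-field survey
    counts (identical for every group within a field, as the survey
    precedes treatment), TFI from the application records, and summer
    diversity from the per-plot biomass.
    """
    area = trial.config.n_blocks * trial.config.quadrat_area
    pooled = trial.surveys.groupby(["field", "species"])["count"].sum()
    tfis = tfi_table(trial.applications,
                     fields=sorted(trial.surveys["field"].unique()), treatments=groups)
    tfis = tfis.set_index(["field", "treatment"])["tfi"]
    bio = trial.biomass.groupby(["field", "treatment", "species"])["biomass_g_m2"].sum()

    rows = []
    for fid in sorted(trial.surveys["field"].unique()):
        counts = pooled.loc[fid]
        total_density = counts.sum() / area
        if total_density <= 0:
            raise ValueError(f"field {fid!r} has no weeds in the autumn survey")
        d_aut = _diversity_value(counts.values, metric)
        logn = math.log(total_density) / math.log(log_base)
        for g in groups:
            try:
                summer = bio.loc[(fid, g)]
                d_sum = _diversity_value(summer.values, metric)
            except KeyError:
                d_sum = 0.0
            rows.append({"field": fid, "group": g, "d_aut": d_aut,
                         "logn_aut": logn, "tfi": float(tfis.get((fid, g), 0.0)),
                         "d_sum": d_sum})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report tables

def treatment_summary(trial: TrialData, alpha: float = 0.05,
                      seed: int = 0) -> pd.DataFrame:
    """Mean TFI and weed biomass per treatment with rank-test letters.

    TFI is compared over the treated groups; biomass over all groups
    including the untreated control, with percentages relative to it.
    """
    fields = sorted(trial.surveys["field"].unique())
    groups = list(trial.config.groups)
    tfis = tfi_table(trial.applications, fields=fields, treatments=groups)
    tfi_wide = tfis.pivot(index="field", columns="treatment", values="tfi")[groups]
    _, tfi_letters = all_pairs_test(tfi_wide, alpha=alpha, seed=seed)

    all_groups = groups + [UNTREATED]
    totals = (trial.biomass.groupby(["field", "treatment"])["biomass_g_m2"].sum()
              .unstack(fill_value=0.0).reindex(index=fields, columns=all_groups,
                                               fill_value=0.0))
    _, bio_letters = all_pairs_test(totals, alpha=alpha, seed=seed + 1)
    untreated_mean = totals[UNTREATED].mean()

    rows = []
    for g in all_groups:
        row = {"treatment": g,
               "tfi": tfi_wide[g].mean() if g in tfi_wide else float("nan"),
               "tfi_letters": tfi_letters.get(g, ""),
               "biomass_g_m2": totals[g].mean(),
               "biomass_pct_untreated": relative_biomass(
                   totals[g].mean(), untreated_mean, report=True),
               "biomass_letters": bio_letters.get(g, "")}
        rows.append(row)
    return pd.DataFrame(rows)


def alpha_gamma_table(trial: TrialData) -> pd.DataFrame:
    """Gamma and alpha diversity (richness and equivalent richness) of
    the summer biomass data, per treatment."""
    comms = communities_from_long(trial.biomass, ["treatment", "field"],
                                  quantity_col="biomass_g_m2", basis="biomass")
    rows = []
    for t in list(trial.config.groups) + [UNTREATED]:
        per_field = [c for (tt, _), c in comms.items() if tt == t]
        if not per_field:
            continue
        g0, a0 = alpha_gamma(per_field, 0.0)
        g1, a1 = alpha_gamma(per_field, 1.0)
        rows.append({"treatment": t, "richness_gamma": g0, "richness_alpha": a0,
                     "eq_richness_gamma": g1, "eq_richness_alpha": a1})
    return pd.DataFrame(rows)


def hill_profile_report(trial: TrialData, orders=HILL_ORDERS, alpha: float = 0.05,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per field x treatment Hill profiles of summer biomass plus, for
    each order, rank-test letters across treatments."""
    comms = communities_from_long(trial.biomass, ["field", "treatment"],
                                  quantity_col="biomass_g_m2", basis="biomass")
    profiles = profile_table(comms, ["field", "treatment"], orders)
    letter_rows = []
    for a in orders:
        sub = profiles[profiles["order_a"] == a]
        wide = sub.pivot(index="field", columns="treatment", values="diversity")
        wide = wide.dropna()
        if wide.shape[0] >= 2 and wide.shape[1] >= 2:
            _, letters = all_pairs_test(wide, alpha=alpha, seed=seed)
            for t, ls in letters.items():
                letter_rows.append({"order_a": a, "treatment": t, "letters": ls})
    return profiles, pd.DataFrame(letter_rows)


# ---------------------------------------------------------------------------
# the run

def _config_manifest(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return str(obj)

    blob = json.dumps(config, default=enc, sort_keys=True)
    return {"package": "weedpath", "version": __version__, "seed": config.seed,
            "config": json.loads(blob), "config_sha256": hashlib.sha256(blob.encode()).hexdigest()}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain; returns the result tables and
    writes them, plus a manifest, under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    gen = config.generator or GeneratorConfig(seed=config.seed, mode=config.mode)
    if config.surveys_path:
        trial = TrialData(
            surveys=pd.read_csv(config.surveys_path),
            applications=pd.read_csv(config.applications_path),
            biomass=pd.read_csv(config.biomass_path),
            config=gen)
        logger.info("loaded trial tables from CSV inputs")
    elif gen.mode == "mechanistic":
        trial = generate_mechanistic(gen)
        logger.info("generated mechanistic trial (seed=%d)", gen.seed)
    else:
        obs = generate_structural(gen)
        trial = None
        logger.info("generated structural observations (seed=%d)", gen.seed)

    if trial is not None:
        report = validate_tables(trial.surveys, trial.applications, trial.biomass)
        for w in report.warnings:
            logger.warning(w)
        if not report.ok:
            raise ValueError("input validation failed: " + "; ".join(report.errors))
        trial.surveys.to_csv(outdir / "surveys.csv", index=False)
        trial.applications.to_csv(outdir / "applications.csv", index=False)
        trial.biomass.to_csv(outdir / "biomass.csv", index=False)

        results["treatment_summary"] = treatment_summary(trial, config.alpha, config.seed)
        results["alpha_gamma"] = alpha_gamma_table(trial)
        profiles, letters = hill_profile_report(trial, config.orders,
                                                config.alpha, config.seed)
        results["hill_profiles"] = profiles
        results["hill_letters"] = letters
        obs = observations_from_trial(trial, config.metric, config.log_base)

    results["observations"] = obs

    spec = PathModelSpec(groups=tuple(gen.groups))
    final_spec, fit, trail = stepwise_constrain(obs, spec, config.alpha_keep)
    logger.info("stepwise selection: shared=%s, loglik=%.3f",
                sorted(final_spec.shared), fit.loglik)
    results["path_coefficients"] = coefficient_table(fit, obs)
    results["path_r2"] = r_squared(fit, obs).reset_index(names="response")
    results["path_effects"] = pd.DataFrame(
        [effects(fit, g).__dict__ for g in final_spec.groups])
    results["path_trail"] = pd.DataFrame([t.__dict__ for t in trail])

    for name, df in results.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    manifest = _config_manifest(config)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
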