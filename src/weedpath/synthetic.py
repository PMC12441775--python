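"""Synthetic winter-wheat herbicide field trials.

The trials this package analyses consist of 15 fields, each carrying
four treated plot-groups (two decision-support-system variants and
two advisor variants) plus an untreated control, with autumn weed
counts, herbicide application records and early-summer dry biomass.
Because no raw data of that kind are distributable, this module
generates them, in two modes:

* **structural** — draws observations directly from the path-model
  equations (bivariate-normal exogenous block, two linear equations
  with Gaussian noise).  This is the mode for parameter-recovery and
  selection tests: the generating coefficients are known exactly.

* **mechanistic** — a simplified but explicit causal chain: species
  densities per field, Poisson quadrat counts per block, a
  dose-optimising decision rule per treatment (emulating a
  herbicide decision support system built on log-logistic
  dose-response curves and density-dependent target efficacies),
  survival, and biomass at harvest.  This mode exists for end-to-end
  demonstrations and for the qualitative density-to-intensity
  coupling patterns; its dose-response parameters are invented.

Default magnitudes target the trial conditions the package is built
for: total autumn
densities of roughly 17-662 plants m⁻² and 6-14 species per field, an
autumn density-richness correlation near 0.54, a shared density
effect on summer richness of 1.21, and mediated (through TFI) density
effects near -0.78/-0.41/-0.35/0 for the four treated groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tfi import ApplicationRecord

TREATED_GROUPS = ("DSSstd", "DSSred", "AdvLoc", "AdvSer")
UNTREATED = "Untreated"

# ---------------------------------------------------------------------------
# species pool (invented magnitudes; EPPO codes of common winter-wheat weeds)

_GRASSY = {"APESV", "POAAN", "AGGRE", "HORVX", "TTLWI", "IUNSS"}

#: code -> (mean autumn density plants m⁻², unit dry mass g/plant,
#:          baseline target efficacy)
SPECIES_POOL: dict[str, tuple[float, float, float]] = {
    "VIOAR": (28.0, 0.8, 0.62),   # Viola arvensis
    "MATSS": (22.0, 1.8, 0.72),   # Matricaria spec.
    "PAPRH": (12.0, 1.4, 0.72),   # Papaver rhoeas
    "BRSNN": (8.0, 2.0, 0.80),    # volunteer oilseed rape
    "STEME": (6.0, 2.5, 0.72),    # Stellaria media
    "APESV": (5.0, 0.8, 0.80),    # Apera spica-venti
    "CAPBP": (3.0, 2.4, 0.62),    # Capsella bursa-pastoris
    "GALAP": (0.15, 5.0, 0.80),   # Galium aparine
    "CHEAL": (0.12, 2.0, 0.72),   # Chenopodium album
    "HORVX": (0.10, 10.0, 0.80),  # volunteer barley
    "POLAV": (0.08, 2.0, 0.72),   # Polygonum aviculare
    "MYOAR": (0.07, 1.0, 0.62),   # Myosotis arvensis
    "VERHE": (0.06, 1.0, 0.62),   # Veronica hederifolia
    "CENCY": (0.05, 2.0, 0.62),   # Centaurea cyanus
    "AGGRE": (0.05, 3.0, 0.80),   # Elymus repens
    "POAAN": (0.05, 1.5, 0.62),   # Poa annua
    "TTLWI": (0.04, 8.0, 0.80),   # volunteer triticale
    "CIRAR": (0.03, 4.0, 0.72),   # Cirsium arvense
    "EQUAR": (0.03, 2.0, 0.62),   # Equisetum arvense
    "IUNSS": (0.02, 1.0, 0.62),   # Juncus spec.
    "LAMPU": (0.02, 1.0, 0.62),   # Lamium purpureum
}

#: product -> registered dose (L ha⁻¹); names are generic inventions
PRODUCTS: dict[str, float] = {
    "DicoStar": 1.5,
    "BroadSweep": 2.0,
    "GramiQuit": 1.0,
    "ResiduaL": 2.5,
    "UniMax": 2.0,
    "SpotFix": 1.25,
}


@dataclass(frozen=True)
class DoseResponseCurve:
    """Log-logistic efficacy of one herbicide on one species.

    ``efficacy(d) = max_efficacy * d^slope / (d^slope + ed50^slope)``
    with the dose ``d`` expressed as a fraction of the registered
    dose.  Strictly increasing with efficacy(0) = 0.
    """

    species: str
    herbicide: str
    ed50: float
    slope: float
    max_efficacy: float
    cost: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.max_efficacy <= 1.0):
            raise ValueError("max efficacy must be in (0, 1]")
        if self.ed50 <= 0 or self.slope <= 0:
            raise ValueError("ed50 and slope must be positive")

    def efficacy(self, dose: float) -> float:
        if dose <= 0:
            return 0.0
        dh = dose**self.slope
        return self.max_efficacy * dh / (dh + self.ed50**self.slope)

    def inverse(self, target: float) -> float:
        """Dose fraction achieving ``target`` efficacy (inf if unreachable)."""
        if target <= 0:
            return 0.0
        if target >= self.max_efficacy:
            return math.inf
        return self.ed50 * (target / (self.max_efficacy - target)) ** (1.0 / self.slope)


def default_curves(seed: int = 711) -> dict[tuple[str, str], DoseResponseCurve]:
    """Invented dose-response library: one curve per species x product.

    Grass specialists barely touch dicots and vice versa; the two
    broad-spectrum products control everything but need higher doses.
    Every species is guaranteed one product with max efficacy >= 0.985
    so that standard targets (<= 0.97) stay reachable.
    """
    rng = np.random.default_rng(seed)
    curves: dict[tuple[str, str], DoseResponseCurve] = {}
    for sp in SPECIES_POOL:
        grassy = sp in _GRASSY
        for prod in PRODUCTS:
            if prod == "GramiQuit":
                emax = rng.uniform(0.97, 0.995) if grassy else rng.uniform(0.10, 0.30)
            elif prod == "DicoStar":
                emax = rng.uniform(0.15, 0.30) if grassy else rng.uniform(0.90, 0.99)
            elif prod == "BroadSweep":
                emax = rng.uniform(0.50, 0.80) if grassy else rng.uniform(0.93, 0.995)
            elif prod == "ResiduaL":
                emax = rng.uniform(0.85, 0.98)
            elif prod == "UniMax":
                emax = rng.uniform(0.80, 0.97)
            else:  # SpotFix: strong on a random half of the pool
                emax = rng.uniform(0.90, 0.99) if rng.random() < 0.5 else rng.uniform(0.30, 0.60)
            # effective products reach ED50 around a quarter of the registered dose
            ed50 = rng.uniform(0.15, 0.30) if emax >= 0.9 else rng.uniform(0.2, 0.4)
            curves[(sp, prod)] = DoseResponseCurve(
                sp, prod, ed50=float(ed50),
                slope=float(rng.uniform(2.2, 3.2)), max_efficacy=float(emax))
    # guarantee: every species is controllable to 0.97 within the registered dose
    for sp in SPECIES_POOL:
        if not any(curves[(sp, p)].inverse(0.97) <= 0.9 for p in PRODUCTS):
            curves[(sp, "ResiduaL")] = DoseResponseCurve(
                sp, "ResiduaL", ed50=0.15, slope=3.0, max_efficacy=0.992)
    return curves


# ---------------------------------------------------------------------------
# configuration

def _structural_defaults() -> dict:
    """Per-group structural coefficients for the richness-metric model.

    Only the density-to-TFI coupling b differs between groups (strong
    for the DSS variants, absent for the blanket advisory service);
    the ecological paths d, e, f and the diversity effect a are
    common, matching the pattern the analysis is designed to detect.
    """
    groups = TREATED_GROUPS
    tfi_mean = {"DSSstd": 1.37, "DSSred": 1.07, "AdvLoc": 1.40, "AdvSer": 1.53}
    b = {"DSSstd": 0.433, "DSSred": 0.228, "AdvLoc": 0.194, "AdvSer": 0.0}
    coef = {}
    mu_d, mu_l = 10.0, 4.6
    a, c, d, e = -0.04, -1.8, 0.40, 1.21
    dsum_mean = 9.0
    for g in groups:
        alpha1 = tfi_mean[g] - a * mu_d - b[g] * mu_l
        alpha2 = dsum_mean - c * tfi_mean[g] - d * mu_d - e * mu_l
        coef[g] = {"a": a, "b": b[g], "c": c, "d": d, "e": e,
                   "alpha1": alpha1, "alpha2": alpha2}
    return coef


@dataclass
class GeneratorConfig:
    """Everything the trial generator needs; the seed fixes all draws."""

    n_fields: int = 15
    groups: tuple[str, ...] = TREATED_GROUPS
    seed: int = 0
    mode: str = "structural"  # "structural" | "mechanistic"

    # --- structural mode ---------------------------------------------------
    #: group -> {a, b, c, d, e, alpha1, alpha2}
    coefficients: dict = field(default_factory=_structural_defaults)
    #: exogenous block: means and ML covariance of (D_aut, logN_aut)
    exog_mean: tuple[float, float] = (10.0, 4.6)
    exog_sd: tuple[float, float] = (2.0, 0.9)
    exog_cov: float = 0.972  # path f; correlation 0.54
    resid_sd: tuple[float, float] = (0.35, 2.0)  # (sigma1: TFI, sigma2: D_sum)

    # --- mechanistic mode --------------------------------------------------
    species: dict = field(default_factory=lambda: dict(SPECIES_POOL))
    products: dict = field(default_factory=lambda: dict(PRODUCTS))
    curve_seed: int = 711
    n_blocks: int = 4
    quadrat_area: float = 1.0       # m² counted per block (10 x 0.1 m²)
    biomass_area: float = 1.0       # m² cut per plot at harvest
    field_sdlog: float = 0.55       # between-field spread of total density
    species_sdlog: float = 0.6      # within-field per-species spread
    target_gain: float = 0.05       # target-efficacy rise per ln(density+1)
    target_cap: float = 0.96
    reduced_by: dict = field(default_factory=lambda: {0.62: 0.15, 0.72: 0.09, 0.80: 0.03})
    decision_threshold: float = 0.5  # plants m⁻² below which a species is ignored
    escape_frac: float = 0.04       # plants escaping any treatment (spray shadows,
                                    # late emergence); field-to-field lognormal noise
    advloc_target: float = 0.95     # local advisor's flat target efficacy
    advloc_threshold: float = 1.0   # plants m⁻²: species the advisor acts on
    advisor_safety: float = 1.6     # advisors overdose relative to the optimum
    advser_plan: dict = field(default_factory=lambda: {"BroadSweep": 0.9, "GramiQuit": 0.65})

    def __post_init__(self) -> None:
        if self.mode not in ("structural", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        s1, s2 = self.exog_sd
        if self.exog_cov**2 >= (s1 * s2) ** 2:
            raise ValueError("exogenous covariance is not positive definite")


# ---------------------------------------------------------------------------
# structural mode

def generate_structural(config: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Observations drawn directly from the path equations.

    Returns a tidy table (field, group, d_aut, logn_aut, tfi, d_sum).
    (D_aut, logN_aut) are shared within a field across groups, as in a
    real trial where the autumn survey precedes treatment allocation.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    s1, s2 = config.exog_sd
    cov = np.array([[s1 * s1, config.exog_cov], [config.exog_cov, s2 * s2]])
    if np.linalg.det(cov) <= 0:
        raise ValueError("exogenous covariance is not positive definite")
    exog = rng.multivariate_normal(config.exog_mean, cov, size=config.n_fields)
    sd_t, sd_s = config.resid_sd
    rows = []
    for i in range(config.n_fields):
        d_aut, logn = exog[i]
        for g in config.groups:
            co = config.coefficients[g]
            tfi_val = (co["alpha1"] + co["a"] * d_aut + co["b"] * logn
                       + rng.normal(0.0, sd_t))
            d_sum = (co["alpha2"] + co["c"] * tfi_val + co["d"] * d_aut
                     + co["e"] * logn + rng.normal(0.0, sd_s))
            rows.append({"field": f"F{i + 1:02d}", "group": g, "d_aut": d_aut,
                         "logn_aut": logn, "tfi": tfi_val, "d_sum": d_sum})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mechanistic mode: DSS decision rule

class UnreachableTargetError(ValueError):
    """No herbicide in the portfolio can reach the target efficacy."""


def dss_decide(densities: Mapping[str, float],
               curves: Mapping[tuple[str, str], DoseResponseCurve],
               targets: Mapping[str, float],
               max_products: int = 3) -> tuple[dict[str, float], float]:
    """Minimal-cost dose plan meeting every species' target efficacy.

    For every combination of up to ``max_products`` herbicides the
    cheapest dose vector covering all target species is found exactly
    (candidate doses are the per-species required doses); the overall
    cheapest feasible plan is returned together with its TFI (the sum
    of dose fractions).  Lowering any target can therefore never
    increase the cost of the optimum; with equal product costs the
    same holds for the TFI.
    """
    species = [s for s, t in targets.items() if densities.get(s, 0.0) > 0.0 and t > 0.0]
    if not species:
        return {}, 0.0
    herbicides = sorted({h for (s, h) in curves if s in species})
    need = {}  # (s, h) -> dose fraction required, inf if unreachable
    for s in species:
        for h in herbicides:
            curve = curves.get((s, h))
            d = math.inf if curve is None else curve.inverse(targets[s])
            need[(s, h)] = d if d <= 1.0 else math.inf  # authorized use caps at full dose
    unreachable = [s for s in species
                   if all(math.isinf(need[(s, h)]) for h in herbicides)]
    if unreachable:
        raise UnreachableTargetError(
            f"no product reaches the target efficacy for species {unreachable}")

    cost_of = {h: (next(curves[(s, h)].cost for s in species if (s, h) in curves))
               for h in herbicides}

    best: tuple[float, int, tuple[str, ...], dict[str, float]] | None = None

    def consider(plan: dict[str, float]) -> None:
        nonlocal best
        cost = sum(cost_of[h] * d for h, d in plan.items())
        key = (cost, len(plan), tuple(sorted(plan)))
        if best is None or key < best[:3]:
            best = (*key, dict(plan))

    max_products = min(max_products, len(herbicides))
    for m in range(1, max_products + 1):
        for combo in itertools.combinations(herbicides, m):
            # enumerate candidate dose levels for all but the last product;
            # the last one must cover whatever remains
            level_sets = []
            for h in combo[:-1]:
                levels = sorted({0.0} | {need[(s, h)] for s in species
                                         if not math.isinf(need[(s, h)])})
                level_sets.append(levels)
            for doses in itertools.product(*level_sets):
                rest = [s for s in species
                        if not any(need[(s, h)] <= d + 1e-12
                                   for h, d in zip(combo[:-1], doses))]
                last = combo[-1]
                if rest:
                    if any(math.isinf(need[(s, last)]) for s in rest):
                        continue
                    d_last = max(need[(s, last)] for s in rest)
                else:
                    d_last = 0.0
                plan = {h: d for h, d in zip(combo[:-1], doses) if d > 0}
                if d_last > 0:
                    plan[last] = d_last
                if not plan:
                    continue
                # feasibility is guaranteed by construction
                consider(plan)
    if best is None:
        raise UnreachableTargetError(
            f"no feasible plan of <= {max_products} products for species {species}")
    plan = best[3]
    return plan, float(sum(plan.values()))


def standard_targets(densities: Mapping[str, float], config: GeneratorConfig,
                     reduced: bool = False) -> dict[str, float]:
    """Density-dependent target efficacies of the DSS decision rule.

    target = base(species) + gain * ln(1 + density), capped; the
    reduced variant lowers each target by a species-dependent 3-15
    percentage points.
    """
    out = {}
    for s, dens in densities.items():
        if dens < config.decision_threshold or s not in config.species:
            continue
        base = config.species[s][2]
        t = min(config.target_cap, base + config.target_gain * math.log1p(dens))
        if reduced:
            t -= config.reduced_by.get(base, 0.09)
        out[s] = max(t, 0.0)
    return out


# ---------------------------------------------------------------------------
# mechanistic mode: full trial

@dataclass
class TrialData:
    """One synthetic trial: the three tables the analysis consumes."""

    surveys: pd.DataFrame       # field, block, species, count, area_m2
    applications: pd.DataFrame  # field, treatment, product, applied_dose, registered_dose, season
    biomass: pd.DataFrame       # field, treatment, species, biomass_g_m2
    config: GeneratorConfig


def _advisor_local_plan(densities: Mapping[str, float], curves, config,
                        rng: np.random.Generator) -> dict[str, float]:
    """Local advisor: inspects the field and doses against the species
    judged relevant (above a density threshold, at most six), at one
    flat target efficacy, with dosing noise.  Unlike the DSS rule the
    target does not scale with density, so the density-to-intensity
    coupling is much weaker."""
    acting = sorted((s for s in densities
                     if densities[s] >= config.advloc_threshold),
                    key=densities.get, reverse=True)[:6]
    target = config.advloc_target
    while acting:
        try:
            plan, _ = dss_decide(densities, curves, {s: target for s in acting})
            break
        except UnreachableTargetError:
            target -= 0.05  # a pragmatic advisor settles for less
            if target < 0.7:
                acting = acting[:-1]
                target = config.advloc_target
    else:
        return {}
    noisy = {}
    for h, d in plan.items():
        d = d * config.advisor_safety * rng.lognormal(0.0, 0.15)
        noisy[h] = float(np.clip(d, 0.05, 1.0))
    return noisy


def generate_mechanistic(config: GeneratorConfig) -> TrialData:
    """Simulate the full trial chain for all groups plus the untreated control."""
    rng = np.random.default_rng(config.seed)
    curves = default_curves(config.curve_seed)
    sp_codes = list(config.species)
    means = np.array([config.species[s][0] for s in sp_codes])
    masses = np.array([config.species[s][1] for s in sp_codes])

    survey_rows, app_rows, bio_rows = [], [], []
    all_groups = list(config.groups) + [UNTREATED]

    for i in range(config.n_fields):
        fid = f"F{i + 1:02d}"
        # true species densities: common field fertility factor x species noise
        ffac = rng.lognormal(0.0, config.field_sdlog)
        dens = means * ffac * rng.lognormal(0.0, config.species_sdlog, size=len(sp_codes))

        # autumn survey: Poisson counts per block over the quadrat area
        counts = rng.poisson(dens * config.quadrat_area,
                             size=(config.n_blocks, len(sp_codes)))
        for b in range(config.n_blocks):
            for j, sp in enumerate(sp_codes):
                if counts[b, j] > 0:
                    survey_rows.append({"field": fid, "block": b + 1, "species": sp,
                                        "count": int(counts[b, j]),
                                        "area_m2": config.quadrat_area})
        # the decision uses the pooled observed density, as in the trial protocol
        obs_dens = {sp: counts[:, j].sum() / (config.n_blocks * config.quadrat_area)
                    for j, sp in enumerate(sp_codes)}

        for group in all_groups:
            if group == "DSSstd":
                plan, _ = dss_decide(obs_dens, curves,
                                     standard_targets(obs_dens, config))
            elif group == "DSSred":
                plan, _ = dss_decide(obs_dens, curves,
                                     standard_targets(obs_dens, config, reduced=True))
            elif group == "AdvLoc":
                plan = _advisor_local_plan(obs_dens, curves, config, rng)
            elif group == "AdvSer":
                plan = {h: float(np.clip(d * rng.lognormal(0.0, 0.08), 0.05, 1.0))
                        for h, d in config.advser_plan.items()}
            else:
                plan = {}
            for h, frac in plan.items():
                app_rows.append({"field": fid, "treatment": group, "product": h,
                                 "applied_dose": frac * config.products[h],
                                 "registered_dose": config.products[h],
                                 "season": "autumn"})
            # survival under independent action of the applied products,
            # plus a floor of plants no spraying reaches (shadows, late
            # emergence) that keeps treated plots from being weed-free
            escape = (config.escape_frac * rng.lognormal(0.0, 0.5)
                      if plan else 0.0)
            for j, sp in enumerate(sp_codes):
                if dens[j] <= 0:
                    continue
                surv = 1.0
                for h, frac in plan.items():
                    curve = curves.get((sp, h))
                    if curve is not None:
                        surv *= 1.0 - curve.efficacy(frac)
                surv = surv + escape * (1.0 - surv)
                n_surv = rng.poisson(dens[j] * surv * config.biomass_area
                                     * config.n_blocks)
                if n_surv > 0:
                    bm = (n_surv / (config.biomass_area * config.n_blocks)
                          * masses[j] * rng.lognormal(0.0, 0.4))
                    bio_rows.append({"field": fid, "treatment": group, "species": sp,
                                     "biomass_g_m2": float(bm)})

    return TrialData(
        surveys=pd.DataFrame(survey_rows),
        applications=pd.DataFrame(app_rows),
        biomass=pd.DataFrame(bio_rows),
        config=config,
    )


def generate(config: GeneratorConfig):
    """Dispatch on ``config.mode``."""
    if config.mode == "structural":
        return generate_structural(config)
    return generate_mechanistic(config)
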