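"""Synthetic cohort generation calibrated to published SPIROMICS summaries.

The generator emulates the statistical structure the borderline-airflow
analysis assumes: three analysis groups (discordant ever-smokers,
unobstructed ever-smokers, unobstructed never-smokers) with
group-conditional demographics and smoking exposure, spirometry that
satisfies each group's defining constraints exactly, skewed true
emphysema / fSAD lung fractions with calibrated presence prevalences
relative to a known normative upper-limit-of-normal (ULN) surface,
airway measurements realizing a target Pi10, symptom scores,
longitudinal FEV1 visits and first-year exacerbation counts.

Calibration defaults are transcribed from the published group summaries
(sizes 161 / 940 / 190, age, sex, race, pack-years, percent-predicted
spirometry, symptom scores, CT metrics and presence prevalences).  Two
modelling choices the publication does not constrain are documented in
docs/methods.md: a Gaussian-copula parameter couples a lower FEV1/FVC
ratio to a higher chance of CT abnormality, and presence-prevalence
calibration overrides moment matching of the fraction distributions
(each subject's fraction is drawn from the group's moment-matched
log-normal truncated above or below that subject's true ULN).
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import integrate
from scipy.special import ndtr, ndtri

from .nhanes3 import predicted_and_lln
from .prm import ellipsoid_mask

__all__ = [
    "GroupCalibration",
    "CohortCalibration",
    "OutcomeTruth",
    "NormativeTruth",
    "DEFAULT_CALIBRATION",
    "DEFAULT_TRUTH",
    "generate_cohort",
    "generate_normative_truth",
    "realize_paired_volume",
    "load_calibration",
    "save_calibration",
]

log = logging.getLogger(__name__)

DEFAULT_SCANNERS = ("scanner_A", "scanner_B", "scanner_C", "scanner_D")


# --------------------------------------------------------------------------
# calibration containers

@dataclass
class GroupCalibration:
    """Per-group generator targets (means/SDs on the published scales)."""

    n: int
    ever_smoker: bool
    pct_male: float
    pct_white: float
    pct_current_smoker: float
    age_mean: float
    age_sd: float
    pack_years_mean: float
    pack_years_sd: float
    fev1pp_mean: float
    fev1pp_sd: float
    fef2575pp_mean: float
    fef2575pp_sd: float
    sixmwd_mean: float
    sixmwd_sd: float
    sgrq_mean: float
    sgrq_sd: float
    cat_mean: float
    cat_sd: float
    p_medication: float
    p_chronic_bronchitis: float
    p_mmrc_ge2: float
    slope_mean_ml_yr: float
    slope_sd_ml_yr: float
    exacerbation_rate: float
    emph_mean: float
    emph_sd: float
    fsad_mean: float
    fsad_sd: float
    pi10_mean: float
    pi10_sd: float
    p_emph_present: float
    p_fsad_present: float
    p_both_present: float


@dataclass
class CohortCalibration:
    groups: dict[str, GroupCalibration]
    scanners: tuple[str, ...] = DEFAULT_SCANNERS
    #: Gaussian-copula correlation between (low) ratio and CT abnormality
    ratio_fraction_rho: float = 0.3
    #: weight of the shared disease factor in the two presence latents
    disease_factor_weight: float = 0.5
    #: non-white subjects split African-American vs Mexican-American
    p_nonwhite_african_american: float = 0.67


DEFAULT_CALIBRATION = CohortCalibration(
    groups={
        # ever-smokers, normal FEV1, LLN < FEV1/FVC < 0.70 ("discordant")
        "discordant": GroupCalibration(
            n=161, ever_smoker=True,
            pct_male=0.708, pct_white=0.894, pct_current_smoker=0.325,
            age_mean=69.3, age_sd=6.4,
            pack_years_mean=48.3, pack_years_sd=22.2,
            fev1pp_mean=92.1, fev1pp_sd=12.0,
            fef2575pp_mean=61.2, fef2575pp_sd=11.0,
            sixmwd_mean=437.5, sixmwd_sd=109.6,
            sgrq_mean=22.5, sgrq_sd=17.4,
            cat_mean=10.7, cat_sd=7.4,
            p_medication=0.344, p_chronic_bronchitis=0.173, p_mmrc_ge2=0.138,
            slope_mean_ml_yr=-60.5, slope_sd_ml_yr=120.5,
            exacerbation_rate=0.1,
            emph_mean=2.1, emph_sd=2.9,
            fsad_mean=18.0, fsad_sd=10.6,
            pi10_mean=3.70, pi10_sd=0.01,
            p_emph_present=0.387, p_fsad_present=0.153, p_both_present=0.10,
        ),
        # ever-smokers, normal FEV1, FEV1/FVC > 0.70
        "smoker_normal": GroupCalibration(
            n=940, ever_smoker=True,
            pct_male=0.490, pct_white=0.682, pct_current_smoker=0.500,
            age_mean=60.4, age_sd=9.7,
            pack_years_mean=43.1, pack_years_sd=27.3,
            fev1pp_mean=97.5, fev1pp_sd=12.8,
            fef2575pp_mean=102.3, fef2575pp_sd=33.4,
            sixmwd_mean=437.2, sixmwd_sd=97.7,
            sgrq_mean=24.2, sgrq_sd=19.1,
            cat_mean=11.3, cat_sd=8.1,
            p_medication=0.251, p_chronic_bronchitis=0.178, p_mmrc_ge2=0.136,
            slope_mean_ml_yr=-55.2, slope_sd_ml_yr=127.5,
            exacerbation_rate=0.1,
            emph_mean=0.7, emph_sd=2.6,
            fsad_mean=9.1, fsad_sd=10.0,
            # published SD rounds to 0.00; a sub-precision positive value is used
            pi10_mean=3.71, pi10_sd=0.004,
            p_emph_present=0.174, p_fsad_present=0.078, p_both_present=0.045,
        ),
        # never-smokers, normal FEV1, FEV1/FVC > 0.70
        "neversmoker_normal": GroupCalibration(
            n=190, ever_smoker=False,
            pct_male=0.379, pct_white=0.707, pct_current_smoker=0.0,
            age_mean=56.6, age_sd=10.2,
            pack_years_mean=0.0, pack_years_sd=0.0,
            fev1pp_mean=102.0, fev1pp_sd=11.5,
            fef2575pp_mean=121.3, fef2575pp_sd=32.5,
            sixmwd_mean=479.3, sixmwd_sd=103.4,
            sgrq_mean=8.8, sgrq_sd=10.0,
            cat_mean=4.7, cat_sd=6.0,
            p_medication=0.039, p_chronic_bronchitis=0.021, p_mmrc_ge2=0.027,
            slope_mean_ml_yr=-41.2, slope_sd_ml_yr=99.7,
            exacerbation_rate=0.02,
            emph_mean=0.3, emph_sd=0.9,
            fsad_mean=7.1, fsad_sd=8.3,
            pi10_mean=3.69, pi10_sd=0.01,
            p_emph_present=0.082, p_fsad_present=0.029, p_both_present=0.018,
        ),
    }
)


# --------------------------------------------------------------------------
# normative truth surface (known conditional 95th percentiles)

@dataclass(frozen=True)
class OutcomeTruth:
    """A linear conditional tau-quantile surface with known noise law.

    ``uln`` is the conditional quantile at ``tau`` (percent of lung).
    Training outcomes are generated as uln - q_offset + noise so that
    their conditional tau-quantile equals ``uln`` exactly; clipping to
    [0, 100] leaves the tau-quantile unchanged whenever it is interior.
    """

    name: str
    intercept: float           # ULN at age 60, female, BMI 27, reference scanner
    age_coef: float            # per year, centred at 60
    male_coef: float
    bmi_coef: float            # per kg/m^2, centred at 27
    scanner_offsets: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    noise: str = "exponential"  # "exponential" or "gaussian"
    noise_scale: float = 1.0
    tau: float = 0.95

    def quantile_offset(self) -> float:
        """Distance from the noise-free linear predictor to the tau-quantile."""
        if self.noise == "exponential":
            return self.noise_scale * math.log(1.0 / (1.0 - self.tau))
        if self.noise == "gaussian":
            return self.noise_scale * float(ndtri(self.tau))
        raise ValueError(f"unknown noise model {self.noise!r}")

    def uln(self, age, male, bmi, scanner_index) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        male = np.asarray(male, dtype=float)
        bmi = np.asarray(bmi, dtype=float)
        offs = np.asarray(self.scanner_offsets, dtype=float)[
            np.asarray(scanner_index, dtype=int)
        ]
        val = (
            self.intercept
            + self.age_coef * (age - 60.0)
            + self.male_coef * male
            + self.bmi_coef * (bmi - 27.0)
            + offs
        )
        return np.maximum(val, 0.05)

    def sample(self, uln: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        base = np.asarray(uln, dtype=float) - self.quantile_offset()
        if self.noise == "exponential":
            y = base + rng.exponential(self.noise_scale, size=base.shape)
        else:
            y = base + rng.normal(0.0, self.noise_scale, size=base.shape)
        return np.clip(y, 0.0, 100.0)


@dataclass(frozen=True)
class NormativeTruth:
    emph: OutcomeTruth
    fsad: OutcomeTruth
    scanners: tuple[str, ...] = DEFAULT_SCANNERS


DEFAULT_TRUTH = NormativeTruth(
    emph=OutcomeTruth(
        name="pct_emphysema",
        intercept=0.90, age_coef=0.040, male_coef=0.25, bmi_coef=0.010,
        scanner_offsets=(0.0, 0.10, -0.10, 0.05),
        noise="exponential", noise_scale=0.5,
    ),
    fsad=OutcomeTruth(
        name="pct_fsad",
        intercept=20.0, age_coef=0.35, male_coef=1.5, bmi_coef=0.08,
        scanner_offsets=(0.0, 0.8, -0.8, 0.4),
        noise="exponential", noise_scale=5.5,
    ),
)


# --------------------------------------------------------------------------
# numeric helpers

def _tn_mean(loc: float, sd: float, lo: float, hi: float) -> float:
    a = (lo - loc) / sd
    b = (hi - loc) / sd
    za = ndtr(a)
    zb = ndtr(b)
    denom = max(zb - za, 1e-300)
    phi = lambda t: math.exp(-0.5 * t * t) / math.sqrt(2 * math.pi)
    return loc + sd * (phi(a) - phi(b)) / denom


@functools.lru_cache(maxsize=4096)
def _tn_matched_loc(target: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose (lo, hi)-truncated normal mean equals target."""
    eps = 1e-6 * max(1.0, hi - lo if np.isfinite(hi) else sd)
    t = min(max(target, lo + eps), (hi - eps) if np.isfinite(hi) else target)
    a, b = t - 10 * sd, t + 10 * sd
    for _ in range(80):
        m = 0.5 * (a + b)
        if _tn_mean(m, sd, lo, hi) < t:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def _tn_sample(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float = np.inf,
    match_mean: bool = True,
    size: int | None = None,
) -> float | np.ndarray:
    """Truncated-normal draw whose *truncated* mean matches ``mean``."""
    if sd <= 0:
        v = np.clip(mean, lo, hi)
        return v if size is None else np.full(size, v)
    loc = _tn_matched_loc(round(mean, 6), round(sd, 6), round(lo, 3),
                          round(hi, 3) if np.isfinite(hi) else np.inf) \
        if match_mean else mean
    za, zb = ndtr((lo - loc) / sd), ndtr((hi - loc) / sd) if np.isfinite(hi) else 1.0
    u = rng.uniform(za, zb, size=size)
    return loc + sd * ndtri(np.clip(u, 1e-12, 1 - 1e-12))


def _bvn_upper(a: float, b: float, r: float) -> float:
    """P(Z1 > a, Z2 > b) for standard bivariate normal with correlation r."""
    if r >= 1 - 1e-9:
        return float(1.0 - ndtr(max(a, b)))
    s = math.sqrt(1.0 - r * r)

    def f(z):
        return math.exp(-0.5 * z * z) / math.sqrt(2 * math.pi) * ndtr((r * z - b) / s)

    val, _ = integrate.quad(f, a, a + 12.0, limit=100)
    return float(val)


@functools.lru_cache(maxsize=256)
def _solve_presence_corr(p_e: float, p_f: float, p_both: float) -> float:
    """Latent-normal correlation hitting the joint presence probability."""
    if p_e <= 0 or p_f <= 0:
        return 0.0
    c_e, c_f = float(ndtri(1 - p_e)), float(ndtri(1 - p_f))
    lo_feasible = max(0.0, p_e + p_f - 1.0)
    hi_feasible = min(p_e, p_f)
    target = min(max(p_both, lo_feasible + 1e-9), hi_feasible - 1e-9)
    if target != p_both:
        log.warning(
            "joint presence probability %.3f clipped to feasible %.4f", p_both, target
        )
    lo, hi = -0.995, 0.995
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _bvn_upper(c_e, c_f, mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _lognorm_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the requested mean and SD."""
    if mean <= 0:
        raise ValueError("log-normal moment matching needs a positive mean")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _lognorm_two_sided(
    rng: np.random.Generator,
    mu: float,
    sigma: float,
    threshold: float,
    above: bool,
) -> float:
    """Draw from the moment-matched log-normal, conditioned on one side of
    the threshold (this is how presence prevalences are made exact)."""
    z_thr = (math.log(max(threshold, 1e-6)) - mu) / sigma
    F = float(ndtr(z_thr))
    v = rng.uniform()
    u = F + (1.0 - F) * v if above else F * v
    u = min(max(u, 1e-12), 1 - 1e-12)
    val = math.exp(mu + sigma * float(ndtri(u)))
    return float(min(val, 99.0))


# --------------------------------------------------------------------------
# normative training bed

def generate_normative_truth(
    n: int,
    truth: NormativeTruth = DEFAULT_TRUTH,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Healthy-reference training table with known conditional quantiles.

    Covariates are sampled over the study's ranges (age 40-80, BMI around
    27, both sexes, four scanners); for each CT metric the outcome is
    drawn so that its conditional tau-quantile equals the truth surface
    exactly.  Columns ``uln_*_true`` carry that surface for recovery
    checks.
    """
    n_coef = 4 + len(truth.scanners) - 1
    if n < 10 * n_coef:
        raise ValueError(f"need n >= {10 * n_coef} for a stable quantile fit")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    age = rng.uniform(40.0, 80.0, n)
    male = rng.random(n) < 0.45
    bmi = np.clip(rng.normal(27.0, 4.5, n), 17.0, 45.0)
    scanner_idx = rng.integers(0, len(truth.scanners), n)
    df = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(male, "male", "female"),
            "bmi": bmi,
            "scanner": np.asarray(truth.scanners)[scanner_idx],
        }
    )
    for t in (truth.emph, truth.fsad):
        uln = t.uln(age, male, bmi, scanner_idx)
        df[t.name] = t.sample(uln, rng)
        df[f"uln_{t.name}_true"] = uln
    return df


# --------------------------------------------------------------------------
# paired CT volume realization

def realize_paired_volume(
    target_emph_frac: float,
    target_fsad_frac: float,
    shape: tuple[int, int, int] = (64, 64, 64),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired inspiratory/expiratory HU volumes realizing target PRM fractions.

    Voxel counts are round(fraction * n_masked) for emphysema and fSAD
    within a solid-ellipsoid lung mask; HU values are sampled strictly
    inside each class region so the joint thresholds recover the classes
    exactly.  Returns (insp_hu, exp_hu, mask) as float32 / bool arrays.
    """
    fe, ff = float(target_emph_frac), float(target_fsad_frac)
    if fe < 0 or ff < 0:
        raise ValueError("target fractions must be non-negative")
    if fe + ff > 1.0:
        raise ValueError(f"target fractions sum to {fe + ff:.3f} > 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mask = ellipsoid_mask(shape)
    idx = np.flatnonzero(mask.ravel())
    n = idx.size
    n_e = int(round(fe * n))
    n_f = int(round(ff * n))
    order = rng.permutation(n)
    e_idx = idx[order[:n_e]]
    f_idx = idx[order[n_e:n_e + n_f]]
    n_idx = idx[order[n_e + n_f:]]

    insp = rng.uniform(-150.0, 50.0, size=mask.size).astype(np.float32)
    exp = rng.uniform(-150.0, 50.0, size=mask.size).astype(np.float32)
    insp[e_idx] = rng.uniform(-1024.0, -960.0, n_e)
    exp[e_idx] = rng.uniform(-1000.0, -870.0, n_e)
    insp[f_idx] = rng.uniform(-940.0, -800.0, n_f)
    exp[f_idx] = rng.uniform(-1000.0, -870.0, n_f)
    insp[n_idx] = rng.uniform(-940.0, -800.0, n_idx.size)
    exp[n_idx] = rng.uniform(-840.0, -600.0, n_idx.size)
    return insp.reshape(shape), exp.reshape(shape), mask


# --------------------------------------------------------------------------
# cohort generation

_GROUP_RATIO_CEILING = 0.6999  # strict < 0.70 with a numeric guard


def _age_lower_bound(group: str, sex: str, race: str) -> float:
    """Youngest age at which the group's ratio window is non-empty."""
    if group != "discordant":
        return 40.0
    # find age where LLN(ratio) drops below 0.70
    lo, hi = 40.0, 80.0
    _, lln80 = predicted_and_lln(80.0, sex, race, 170.0, "FEV1/FVC")
    if lln80 >= _GROUP_RATIO_CEILING:
        raise ValueError(f"discordant group infeasible for {sex}/{race}")
    _, lln40 = predicted_and_lln(40.0, sex, race, 170.0, "FEV1/FVC")
    if lln40 < _GROUP_RATIO_CEILING:
        return 40.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        _, lln = predicted_and_lln(mid, sex, race, 170.0, "FEV1/FVC")
        if lln < _GROUP_RATIO_CEILING:
            hi = mid
        else:
            lo = mid
    return hi + 0.25


def _draw_mmrc(rng: np.random.Generator, p_ge2: float) -> int:
    if rng.random() < p_ge2:
        return int(rng.choice([2, 3, 4], p=[0.70, 0.25, 0.05]))
    return int(rng.choice([0, 1], p=[0.65, 0.35]))


def generate_cohort(
    calib: CohortCalibration = DEFAULT_CALIBRATION,
    seed: int = 0,
    truth: NormativeTruth = DEFAULT_TRUTH,
    n_airways: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table, a longitudinal visit table and airway measures.

    Returns ``(subjects, visits, airways)``.  Deterministic under a fixed
    seed.  Every generated subject satisfies its own group's spirometric
    constraints (verified downstream by the classification stage).
    """
    rng = np.random.default_rng(seed)
    rho = calib.ratio_fraction_rho
    w = calib.disease_factor_weight
    subjects: list[dict] = []
    visits: list[dict] = []
    airways: list[dict] = []
    sid = 0
    for gname, g in calib.groups.items():
        r_ef = _solve_presence_corr(
            round(g.p_emph_present, 6),
            round(g.p_fsad_present, 6),
            round(g.p_both_present, 6),
        )
        s_extra = (r_ef - w * w) / (1.0 - w * w)
        s_extra = min(max(s_extra, -1.0), 1.0)
        c_e = ndtri(1 - g.p_emph_present) if g.p_emph_present > 0 else np.inf
        c_f = ndtri(1 - g.p_fsad_present) if g.p_fsad_present > 0 else np.inf
        mu_e, sg_e = _lognorm_params(g.emph_mean, g.emph_sd)
        mu_f, sg_f = _lognorm_params(g.fsad_mean, g.fsad_sd)
        for _ in range(g.n):
            sid += 1
            subject_id = f"S{sid:05d}"
            sex = "male" if rng.random() < g.pct_male else "female"
            if rng.random() < g.pct_white:
                race = "caucasian"
            elif rng.random() < calib.p_nonwhite_african_american:
                race = "african_american"
            else:
                race = "mexican_american"
            age_lo = _age_lower_bound(gname, sex, race)
            age = float(_tn_sample(rng, g.age_mean, g.age_sd, max(40.0, age_lo), 80.0))
            height = float(np.clip(
                rng.normal(175.5 if sex == "male" else 162.0, 6.8), 145.0, 200.0
            ))
            bmi = float(_tn_sample(rng, 28.0, 5.0, 17.0, 45.0))
            current = bool(g.ever_smoker and rng.random() < g.pct_current_smoker)
            pack_years = (
                float(_tn_sample(rng, g.pack_years_mean, g.pack_years_sd, 20.5))
                if g.ever_smoker
                else 0.0
            )
            pred_fev1, lln_fev1 = predicted_and_lln(age, sex, race, height, "FEV1")
            _, lln_ratio = predicted_and_lln(age, sex, race, height, "FEV1/FVC")
            pred_fef, _ = predicted_and_lln(age, sex, race, height, "FEF25-75")

            # ratio window per group; lower ratio couples to disease via z_ratio
            z_ratio = rng.standard_normal()
            if gname == "discordant":
                lo_r, hi_r = lln_ratio + 1e-4, _GROUP_RATIO_CEILING
            elif gname.startswith("below_lln"):
                lo_r, hi_r = max(0.40, lln_ratio - 0.12), lln_ratio - 1e-4
            else:
                lo_r, hi_r = max(0.7001, lln_ratio + 1e-4), 0.92
            if lo_r >= hi_r:
                raise RuntimeError(
                    f"empty ratio window for {gname} subject (LLN {lln_ratio:.3f})"
                )
            ratio = lo_r + float(ndtr(z_ratio)) * (hi_r - lo_r)

            # normal FEV1: percent predicted above the subject's LLN cut
            # (not imposed on the obstructed below-LLN stratum)
            pp_floor = (
                30.0
                if gname.startswith("below_lln")
                else 100.0 * lln_fev1 / pred_fev1
            )
            fev1pp = float(_tn_sample(rng, g.fev1pp_mean, g.fev1pp_sd, pp_floor, 150.0))
            fev1 = fev1pp / 100.0 * pred_fev1
            fvc = fev1 / ratio
            fefpp = float(_tn_sample(rng, g.fef2575pp_mean, g.fef2575pp_sd, 10.0, 250.0))
            fef = fefpp / 100.0 * pred_fef

            scanner_idx = int(rng.integers(0, len(calib.scanners)))
            scanner = calib.scanners[scanner_idx]

            # joint presence flags (Gaussian copula with the ratio)
            z_dis = -rho * z_ratio + math.sqrt(1 - rho * rho) * rng.standard_normal()
            e1 = rng.standard_normal()
            e2 = rng.standard_normal()
            eps_f = s_extra * e1 + math.sqrt(max(0.0, 1 - s_extra**2)) * e2
            z_e = w * z_dis + math.sqrt(1 - w * w) * e1
            z_f = w * z_dis + math.sqrt(1 - w * w) * eps_f
            emph_present = bool(z_e > c_e)
            fsad_present = bool(z_f > c_f)

            male = 1.0 if sex == "male" else 0.0
            uln_e = float(truth.emph.uln(age, male, bmi, scanner_idx))
            uln_f = float(truth.fsad.uln(age, male, bmi, scanner_idx))
            true_emph = _lognorm_two_sided(rng, mu_e, sg_e, uln_e, emph_present)
            true_fsad = _lognorm_two_sided(rng, mu_f, sg_f, uln_f, fsad_present)
            if true_emph + true_fsad > 95.0:
                true_fsad = max(95.0 - true_emph, 0.0)

            pi10 = float(rng.normal(g.pi10_mean, g.pi10_sd))
            # airway measures on the line sqrt(WA) = a + 0.27 * perimeter
            slope_aw = 0.27
            intercept_aw = pi10 - 10.0 * slope_aw
            per = rng.uniform(6.0, 20.0, n_airways)
            sqrt_wa = intercept_aw + slope_aw * per + rng.normal(0.0, 0.01, n_airways)
            for p_mm, s_wa in zip(per, sqrt_wa):
                airways.append(
                    {
                        "subject_id": subject_id,
                        "internal_perimeter_mm": float(p_mm),
                        "wall_area_mm2": float(s_wa**2),
                    }
                )

            mmrc = _draw_mmrc(rng, g.p_mmrc_ge2)
            cb = bool(rng.random() < g.p_chronic_bronchitis)
            cough_months = int(rng.integers(3, 10)) if cb else int(rng.integers(0, 3))
            cough_years = int(rng.integers(2, 11)) if cb else int(rng.integers(0, 15))
            cat = float(_tn_sample(rng, g.cat_mean, g.cat_sd, 0.0, 40.0))
            sgrq = float(_tn_sample(rng, g.sgrq_mean, g.sgrq_sd, 0.0, 100.0))
            sixmwd = float(_tn_sample(rng, g.sixmwd_mean, g.sixmwd_sd, 50.0, 850.0))
            medication = bool(rng.random() < g.p_medication)
            exac = int(rng.poisson(g.exacerbation_rate))
            slope_true = float(rng.normal(g.slope_mean_ml_yr, g.slope_sd_ml_yr))

            # visits: baseline plus 1-3 follow-ups, maximum span 266-1749 days
            n_extra = int(rng.integers(1, 4))
            span = float(rng.uniform(266.0, 1749.0))
            days = [0.0]
            if n_extra > 1:
                days += sorted(rng.uniform(210.0, span * 0.9, n_extra - 1).tolist())
            days.append(span)
            for k, day in enumerate(days):
                noise = 0.0 if k == 0 else float(rng.normal(0.0, 0.015))
                f_t = max(fev1 + slope_true / 1000.0 * day / 365.25 + noise, 0.2)
                visits.append(
                    {
                        "subject_id": subject_id,
                        "visit_day": float(day),
                        "fev1_l": f_t,
                        "fvc_l": f_t / ratio,
                        "post_bronchodilator": True,
                    }
                )

            subjects.append(
                {
                    "subject_id": subject_id,
                    "group_true": gname,
                    "age": age,
                    "sex": sex,
                    "race": race,
                    "height_cm": height,
                    "bmi": bmi,
                    "ever_smoker": g.ever_smoker,
                    "current_smoker": current,
                    "pack_years": pack_years,
                    "scanner": scanner,
                    "fev1_l": fev1,
                    "fvc_l": fvc,
                    "fef2575_ls": fef,
                    "true_pct_emphysema": true_emph,
                    "true_pct_fsad": true_fsad,
                    "emph_present_true": emph_present,
                    "fsad_present_true": fsad_present,
                    "pi10_true": pi10,
                    "mmrc": mmrc,
                    "cat_score": cat,
                    "sgrq_total": sgrq,
                    "sixmwd_m": sixmwd,
                    "medication_use": medication,
                    "chronic_bronchitis": cb,
                    "cough_months": cough_months,
                    "cough_years": cough_years,
                    "exacerbations_year1": exac,
                    "observed_years": 1.0,
                    "fev1_slope_true_ml_per_year": slope_true,
                }
            )
    return pd.DataFrame(subjects), pd.DataFrame(visits), pd.DataFrame(airways)


# --------------------------------------------------------------------------
# calibration file round-trip

def save_calibration(calib: CohortCalibration, path) -> None:
    payload = {
        "groups": {k: asdict(v) for k, v in calib.groups.items()},
        "scanners": list(calib.scanners),
        "ratio_fraction_rho": calib.ratio_fraction_rho,
        "disease_factor_weight": calib.disease_factor_weight,
        "p_nonwhite_african_american": calib.p_nonwhite_african_american,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_calibration(path) -> CohortCalibration:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    groups = {k: GroupCalibration(**v) for k, v in payload.pop("groups").items()}
    payload["scanners"] = tuple(payload.get("scanners", DEFAULT_SCANNERS))
    return CohortCalibration(groups=groups, **payload)


def scaled_calibration(calib: CohortCalibration, factor: float) -> CohortCalibration:
    """Calibration with group sizes scaled by ``factor`` (minimum 10)."""
    groups = {
        k: replace(g, n=max(int(round(g.n * factor)), 10))
        for k, g in calib.groups.items()
    }
    return replace(calib, groups=groups)
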