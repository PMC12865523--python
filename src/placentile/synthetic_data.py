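"""Synthetic cohort generator with the statistical structure the charts assume.

Emulates a first-trimester screening cohort: ~2500 pregnancies scanned at
79-99 days' gestation (sparse at the extremes, peaked near day 89), five
positively skewed perfusion-fraction series whose four-parameter truth
distributions vary smoothly with gestational age, log-normal placental
volumes with injected fence-busting outliers, paired-segmentation Dice
values with injected triage failures, and rare clinical outcome flags at
realistic prevalences.

The truth curves are embedded in the output so chart-fitting code can be
scored on parameter recovery; regenerating with the same spec and seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import distributions as dist

GA_MIN, GA_MAX = 79, 99  # days; 11+2 to 14+1 weeks

SERIES = ("svfmbv1", "svfmbv2", "svfmbv3", "svfmbv4", "svfmbv5")


@dataclass(frozen=True)
class SeriesTruth:
    """Linear-in-age truth curves (start at day 79, end at day 99) for one series."""

    family: str = "BCPEo"
    mu: tuple = (0.16, 0.22)
    sigma: tuple = (0.40, 0.45)
    nu: tuple = (0.45, 0.45)
    tau: tuple = (2.0, 2.0)

    def at(self, t):
        """(mu, sigma, nu, tau) arrays at gestational ages ``t`` (days)."""
        t = np.asarray(t, float)
        frac = (t - GA_MIN) / (GA_MAX - GA_MIN)

        def interp(pair):
            return pair[0] + (pair[1] - pair[0]) * frac

        return interp(self.mu), interp(self.sigma), interp(self.nu), interp(self.tau)

    def params_at(self, t: float) -> dist.DistributionParams:
        mu, sigma, nu, tau = (float(v) for v in self.at(t))
        return dist.DistributionParams(self.family, mu, sigma, nu, tau)

    def median_curve(self, t):
        mu, sigma, nu, tau = self.at(t)
        return dist.quantile_arrays(0.5, mu, sigma, nu, tau, self.family)


def _default_series() -> dict:
    # positive skew throughout (Box-Cox power < 1), strongest in series 4
    return {
        "svfmbv1": SeriesTruth(mu=(0.16, 0.22), sigma=(0.40, 0.45), nu=(0.45, 0.45)),
        "svfmbv2": SeriesTruth(mu=(0.10, 0.14), sigma=(0.45, 0.50), nu=(0.35, 0.35)),
        "svfmbv3": SeriesTruth(mu=(0.20, 0.26), sigma=(0.35, 0.40), nu=(0.50, 0.50)),
        "svfmbv4": SeriesTruth(mu=(0.06, 0.09), sigma=(0.55, 0.60), nu=(0.05, 0.05)),
        "svfmbv5": SeriesTruth(mu=(0.18, 0.24), sigma=(0.38, 0.42), nu=(0.45, 0.45)),
    }


def _default_prevalences() -> dict:
    return {
        "miscarriage": 0.008,
        "stillbirth": 0.003,
        "termination": 0.007,
        "neonatal_death": 0.002,
        "preterm": 0.060,
        "anomaly": 0.010,
        "nnu_admission": 0.050,
        "diabetes": 0.040,
        "hypertensive_disease": 0.050,
        "aps_sle": 0.003,
        "incomplete_outcome": 0.020,
        "smoker": 0.0181,
        "previous_pe": 0.0157,
        "female_sex": 0.4963,
    }


@dataclass(frozen=True)
class TruthSpec:
    """Everything the generator needs: truth curves, GA weights, prevalences, rates."""

    series: dict = field(default_factory=_default_series)
    ga_peak: float = 89.0  # truncated-normal GA sampling: few cases at the extremes
    ga_sd: float = 4.5
    prevalences: dict = field(default_factory=_default_prevalences)
    volume_log_intercept: float = np.log(60.0)  # ~60 ml at day 79
    volume_log_slope: float = 0.025  # per day; ~99 ml by day 99
    volume_log_sd: float = 0.35
    volume_outlier_rate: float = 0.006
    dice_fail_rates: dict = field(
        default_factory=lambda: {"round1": 0.010, "round2": 0.005, "round3": 0.010}
    )

    def ga_weights(self) -> np.ndarray:
        days = np.arange(GA_MIN, GA_MAX + 1)
        w = stats.norm.pdf(days, self.ga_peak, self.ga_sd)
        return w / w.sum()

    def expected_exclusion_fraction(self) -> float:
        """Closed-form healthy-filter exclusion probability under flag independence."""
        p = self.prevalences
        doppler_abn = 0.05 + 0.05 - 0.05 * 0.05  # UA-PI > 95th or CPR < 5th
        p_fgr = 0.03 + 0.07 * doppler_abn  # bw < 3rd, or 3rd..10th with abnormality
        keys = (
            "miscarriage",
            "stillbirth",
            "termination",
            "neonatal_death",
            "preterm",
            "anomaly",
            "nnu_admission",
            "diabetes",
            "hypertensive_disease",
            "aps_sle",
            "incomplete_outcome",
        )
        keep = np.prod([1.0 - p[k] for k in keys]) * (1.0 - p_fgr)
        return float(1.0 - keep)

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["series"] = {k: asdict(v) for k, v in self.series.items()}
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "TruthSpec":
        doc = dict(doc)
        if "series" in doc:
            doc["series"] = {
                k: SeriesTruth(**{kk: tuple(vv) if isinstance(vv, list) else vv for kk, vv in v.items()})
                for k, v in doc["series"].items()
            }
        return cls(**doc)


@dataclass
class SyntheticCohort:
    """A generated cohort table plus its generating truth and seed."""

    frame: pd.DataFrame
    truth: TruthSpec
    seed: int

    def __len__(self):
        return len(self.frame)


def _draw_series(rng, truth: SeriesTruth, t) -> np.ndarray:
    """Sample one series at each case's GA; values above 1 are resampled
    (rejection) to keep perfusion fractions in their physical range."""
    mu, sigma, nu, tau = truth.at(t)
    u = rng.uniform(size=t.size)
    y = dist.quantile_arrays(u, mu, sigma, nu, tau, truth.family)
    for _ in range(100):
        bad = ~((y > 0) & (y < 1))
        if not bad.any():
            break
        u = rng.uniform(size=int(bad.sum()))
        y[bad] = dist.quantile_arrays(u, mu[bad], sigma[bad], nu[bad], tau[bad], truth.family)
    return y


def generate_cohort(spec: TruthSpec | None = None, n: int = 2500, seed: int = 0) -> SyntheticCohort:
    """Generate a synthetic screening cohort of ``n`` pregnancies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or TruthSpec()
    rng = np.random.default_rng(seed)
    days = np.arange(GA_MIN, GA_MAX + 1)
    ga = rng.choice(days, size=n, p=spec.ga_weights())
    df = pd.DataFrame({"case_id": np.arange(n), "ga_days": ga.astype(int)})

    for name in SERIES:
        df[name] = _draw_series(rng, spec.series[name], ga.astype(float))

    # placental volume: log-normal about a GA-increasing mean, plus injected
    # fence-busting outliers (x5 or /5)
    log_mean = spec.volume_log_intercept + spec.volume_log_slope * (ga - GA_MIN)
    vol = np.exp(log_mean + spec.volume_log_sd * rng.standard_normal(n))
    # injected outliers sit at ~8x the day's geometric mean, far beyond the
    # ~2x upper Tukey fence implied by the log-normal spread; high side only,
    # because the lower fence of right-skewed volumes is near (often below)
    # zero and cannot be reliably busted by any positive value
    is_out = rng.uniform(size=n) < spec.volume_outlier_rate
    vol_out = np.exp(log_mean + np.log(8.0) + 0.1 * rng.standard_normal(n))
    vol = np.where(is_out, vol_out, vol)
    df["placental_volume"] = vol
    df["volume_outlier_injected"] = is_out

    # paired-segmentation Dice values: high agreement baseline with rare
    # injected failures per triage round
    dice_p = 1.0 - 0.18 * rng.beta(2.0, 8.0, size=n)  # ~0.82-1.0, mass near 0.96
    dice_f = 1.0 - 0.30 * rng.beta(2.0, 8.0, size=n)
    u = rng.uniform(size=n)
    r = spec.dice_fail_rates
    r1 = u < r["round1"]
    r2 = (~r1) & (u < r["round1"] + r["round2"])
    r3 = (~r1) & (~r2) & (u < r["round1"] + r["round2"] + r["round3"])
    dice_p[r1] = rng.uniform(0.30, 0.58, size=int(r1.sum()))
    dice_p[r2] = rng.uniform(0.62, 0.74, size=int(r2.sum()))
    dice_f[r2] = rng.uniform(0.20, 0.38, size=int(r2.sum()))
    dice_p[r3] = rng.uniform(0.80, 0.98, size=int(r3.sum()))
    dice_f[r3] = rng.uniform(0.20, 0.38, size=int(r3.sum()))
    df["dice_placenta"] = dice_p
    df["dice_fluid"] = dice_f

    p = spec.prevalences
    for flag in (
        "termination",
        "neonatal_death",
        "anomaly",
        "nnu_admission",
        "diabetes",
        "hypertensive_disease",
        "aps_sle",
        "smoker",
        "previous_pe",
        "female_sex",
    ):
        df[flag] = rng.uniform(size=n) < p[flag]

    # delivery timing and viability: miscarriage / stillbirth are births
    # without signs of life on either side of the 24+0-week boundary
    u = rng.uniform(size=n)
    misc = u < p["miscarriage"]
    still = (~misc) & (u < p["miscarriage"] + p["stillbirth"])
    alive = ~(misc | still)
    preterm = alive & (rng.uniform(size=n) < p["preterm"] / (1 - p["miscarriage"] - p["stillbirth"]))
    delivery = np.empty(n)
    delivery[misc] = rng.integers(77, 168, size=int(misc.sum()))  # <= 23+6 weeks
    delivery[still] = rng.integers(168, 280, size=int(still.sum()))  # >= 24+0 weeks
    delivery[preterm] = rng.integers(196, 259, size=int(preterm.sum()))  # < 37+0
    at_term = alive & ~preterm
    delivery[at_term] = rng.integers(259, 295, size=int(at_term.sum()))
    df["delivery_ga_days"] = delivery.astype(int)
    df["signs_of_life"] = alive

    # growth/Doppler centiles; population centiles are uniform by construction
    df["bw_centile"] = rng.uniform(0.0, 100.0, size=n)
    df["ua_pi_centile"] = rng.uniform(0.0, 100.0, size=n)
    df["cpr_centile"] = rng.uniform(0.0, 100.0, size=n)
    incomplete = rng.uniform(size=n) < p["incomplete_outcome"]
    df.loc[incomplete, "bw_centile"] = np.nan

    return SyntheticCohort(frame=df, truth=spec, seed=seed)


def generate_mask_pair(shape, overlap_target: float, seed: int = 0):
    """Two binary 3-D masks of the given shape with Dice ~= overlap_target.

    Constructed by controlled voxel-set overlap: both masks get V voxels of
    which round(target * V) are shared, so the achieved Dice is within 1/V
    of the target (raises for shapes too small to guarantee 0.02 accuracy).
    """
    if not 0.0 <= overlap_target <= 1.0:
        raise ValueError("overlap_target must lie in [0, 1]")
    shape = tuple(shape)
    total = int(np.prod(shape))
    v = total // 3
    if v < 50:
        raise ValueError(f"shape {shape} too small: need >= 150 voxels for a 0.02-accurate pair")
    inter = int(round(overlap_target * v))
    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    a = np.zeros(total, bool)
    b = np.zeros(total, bool)
    a[order[:v]] = True
    b[order[v - inter : 2 * v - inter]] = True
    return a.reshape(shape), b.reshape(shape)
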