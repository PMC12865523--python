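"""End-to-end orchestration: cohort filters, summaries and the full chart run.

Flow: read (or simulate) a cohort table -> apply outcome definitions and
healthy-cohort exclusions -> segmentation/volumetry QC -> fit LMS and
quantile-regression candidates per measurement series -> AIC selection ->
emit centile tables, model JSON, calibration tables, Z-scores, cohort
summary and the excluded-case comparison.

The healthy-cohort filter builds a *proscriptive* reference population:
any pregnancy with a flagged adverse outcome or relevant maternal condition
is excluded, so the charts describe apparently healthy pregnancies only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import centile_tools, chart_models, qc, synthetic_data
from .chart_models import QR_BASES, QR_SOLVERS

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage named in the message."""


# ---------------------------------------------------------------------------
# outcome definitions
# ---------------------------------------------------------------------------

#: delivery before 37+0 weeks is preterm; birth without signs of life at
#: >= 24+0 weeks is stillbirth, at <= 23+6 weeks miscarriage
PRETERM_CUTOFF_DAYS = 37 * 7
STILLBIRTH_CUTOFF_DAYS = 24 * 7

EXCLUSION_CRITERIA = (
    "miscarriage",
    "stillbirth",
    "termination",
    "neonatal_death",
    "preterm",
    "anomaly",
    "fgr",
    "nnu_admission",
    "diabetes",
    "hypertensive_disease",
    "aps_sle",
    "incomplete_outcome",
)


def parse_ga(value) -> int:
    """Gestational age in days from integer days or a "weeks+days" string."""
    if isinstance(value, str):
        parts = value.strip().split("+")
        if len(parts) != 2:
            raise ValueError(f"malformed gestational age {value!r}; expected 'weeks+days'")
        weeks, days = int(parts[0]), int(parts[1])
        if not 0 <= days <= 6:
            raise ValueError(f"day part must be 0-6 in {value!r}")
        return weeks * 7 + days
    v = int(value)
    if v != value or v < 0:
        raise ValueError(f"gestational age must be a nonnegative whole number of days, got {value}")
    return v


def classify_fgr(bw_centile, ua_pi_centile=None, cpr_centile=None) -> bool:
    """Fetal growth restriction: birth weight < 3rd centile, or < 10th centile
    with a Doppler abnormality (UA-PI > 95th centile or CPR < 5th centile)."""
    if bw_centile is None or (isinstance(bw_centile, float) and np.isnan(bw_centile)):
        raise ValueError("missing birth-weight centile: FGR status unresolvable")
    if bw_centile < 3.0:
        return True
    if bw_centile < 10.0:
        ua_high = ua_pi_centile is not None and not _isnan(ua_pi_centile) and ua_pi_centile > 95.0
        cpr_low = cpr_centile is not None and not _isnan(cpr_centile) and cpr_centile < 5.0
        return ua_high or cpr_low
    return False


def _isnan(x):
    return isinstance(x, float) and np.isnan(x)


def classify_timing(delivery_ga, signs_of_life: bool) -> str:
    """Classify delivery as term / preterm / stillbirth / miscarriage.

    ``delivery_ga`` is integer days or a "weeks+days" string.  Boundaries:
    live birth before 37+0 weeks is preterm; birth without signs of life at
    >= 24+0 weeks is stillbirth and at <= 23+6 weeks miscarriage.
    """
    days = parse_ga(delivery_ga)
    if not signs_of_life:
        return "stillbirth" if days >= STILLBIRTH_CUTOFF_DAYS else "miscarriage"
    return "preterm" if days < PRETERM_CUTOFF_DAYS else "term"


def _record_exclusions(row) -> list:
    """All exclusion criteria a cohort record meets, in the canonical order."""
    hits = []
    timing = classify_timing(int(row["delivery_ga_days"]), bool(row["signs_of_life"]))
    if timing in ("miscarriage", "stillbirth", "preterm"):
        hits.append(timing)
    for flag in ("termination", "neonatal_death", "anomaly"):
        if bool(row.get(flag, False)):
            hits.append(flag)
    try:
        if classify_fgr(row.get("bw_centile"), row.get("ua_pi_centile"), row.get("cpr_centile")):
            hits.append("fgr")
    except ValueError:
        hits.append("incomplete_outcome")
    for flag in ("nnu_admission", "diabetes", "hypertensive_disease", "aps_sle"):
        if bool(row.get(flag, False)):
            hits.append(flag)
    if bool(row.get("incomplete_outcome", False)) and "incomplete_outcome" not in hits:
        hits.append("incomplete_outcome")
    return sorted(hits, key=EXCLUSION_CRITERIA.index)


def healthy_cohort_filter(records: pd.DataFrame):
    """Split a cohort into the healthy reference population and exclusions.

    A record is excluded if it meets *any* listed criterion.  The ledger
    reports both any-match counts (every criterion a case meets) and
    first-match counts (cases attributed to the first criterion they meet,
    flowchart-style), plus the overall totals.
    Returns ``(included, excluded, ledger)``.
    """
    any_match = {c: 0 for c in EXCLUSION_CRITERIA}
    first_match = {c: 0 for c in EXCLUSION_CRITERIA}
    excluded_mask = np.zeros(len(records), bool)
    reasons = []
    for i, (_, row) in enumerate(records.iterrows()):
        hits = _record_exclusions(row)
        reasons.append(";".join(hits))
        if hits:
            excluded_mask[i] = True
            first_match[hits[0]] += 1
            for h in hits:
                any_match[h] += 1
    included = records.loc[~excluded_mask].copy()
    excluded = records.loc[excluded_mask].copy()
    excluded["exclusion_reasons"] = [r for r, m in zip(reasons, excluded_mask) if m]
    ledger = {
        "n_input": int(len(records)),
        "n_included": int(len(included)),
        "n_excluded": int(len(excluded)),
        "any_match": any_match,
        "first_match": first_match,
    }
    return included, excluded, ledger


# ---------------------------------------------------------------------------
# summaries and group comparison
# ---------------------------------------------------------------------------


def percent(count: int, n: int, decimals: int = 2) -> float:
    """Percentage of ``count`` out of ``n``, rounded to ``decimals``."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / n, decimals)


def cohort_summary(records: pd.DataFrame, continuous=None, categorical=None) -> pd.DataFrame:
    """Characteristics table: median (IQR) for continuous, n (%) for categorical."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    n = len(records)
    if continuous is None:
        continuous = [
            c
            for c in records.columns
            if records[c].dtype.kind == "f" and not c.startswith("dice")
        ]
    if categorical is None:
        categorical = [c for c in records.columns if records[c].dtype.kind == "b"]
    rows = []
    for c in continuous:
        vals = records[c].dropna().to_numpy()
        if vals.size == 0:
            continue
        med, q1, q3 = np.quantile(vals, [0.5, 0.25, 0.75])
        rows.append(
            {
                "variable": c,
                "type": "continuous",
                "summary": f"{med:.1f} ({q1:.1f}-{q3:.1f})",
                "median": med,
                "q1": q1,
                "q3": q3,
            }
        )
    for c in categorical:
        count = int(records[c].sum())
        rows.append(
            {
                "variable": c,
                "type": "categorical",
                "summary": f"{count} ({percent(count, n):.2f})",
                "count": count,
                "pct": percent(count, n),
            }
        )
    return pd.DataFrame(rows)


def compare_excluded(included: pd.DataFrame, excluded: pd.DataFrame, continuous=None, categorical=None) -> pd.DataFrame:
    """Per-variable comparison of the study cohort against excluded cases.

    Continuous variables use the Wilcoxon rank-sum test, categorical ones
    Fisher's exact test (both delegated to scipy).  All-constant variables
    are skipped with a note.  Proportions are reported as count/n (pct to
    one decimal).
    """
    if len(included) == 0 or len(excluded) == 0:
        raise ValueError("both groups must be nonempty")
    n_in, n_ex = len(included), len(excluded)
    if continuous is None:
        continuous = [
            c
            for c in included.columns
            if included[c].dtype.kind == "f" and c in excluded.columns and not c.startswith("dice")
        ]
    if categorical is None:
        categorical = [c for c in included.columns if included[c].dtype.kind == "b" and c in excluded.columns]
    rows = []
    for c in continuous:
        x = included[c].dropna().to_numpy()
        y = excluded[c].dropna().to_numpy()
        if x.size == 0 or y.size == 0 or (np.ptp(np.concatenate([x, y])) == 0):
            rows.append({"variable": c, "test": "rank-sum", "note": "degenerate, skipped"})
            continue
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append(
            {
                "variable": c,
                "test": "rank-sum",
                "included": f"{np.median(x):.2f}",
                "excluded": f"{np.median(y):.2f}",
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    for c in categorical:
        a, b = int(included[c].sum()), int(excluded[c].sum())
        if (a == 0 and b == 0) or (a == n_in and b == n_ex):
            rows.append({"variable": c, "test": "fisher-exact", "note": "degenerate, skipped"})
            continue
        table = [[b, n_ex - b], [a, n_in - a]]
        odds, p = stats.fisher_exact(table)
        rows.append(
            {
                "variable": c,
                "test": "fisher-exact",
                "included": f"{a}/{n_in} ({percent(a, n_in, 1):.1f}%)",
                "excluded": f"{b}/{n_ex} ({percent(b, n_ex, 1):.1f}%)",
                "statistic": float(odds),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full chart-construction run needs."""

    cohort_path: str | None = None  # None -> simulate a cohort
    n: int = 2500
    seed: int = 0
    out_dir: str = "placentile_out"
    series: tuple = synthetic_data.SERIES
    families: tuple = ("BCCGo", "BCPEo", "SEP1", "SEP3")
    edf_grid: dict | None = None
    k: float = 2.0
    max_cycles: int = 1000
    target_centiles: tuple = centile_tools.TARGET_CENTILES
    enable_qr: bool = True
    qr_bases: tuple = QR_BASES
    qr_solvers: tuple = QR_SOLVERS
    qr_quantiles: tuple = chart_models.DEFAULT_QUANTILES
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("series", "families", "qr_bases", "qr_solvers", "qr_quantiles", "target_centiles"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def read_cohort(path) -> pd.DataFrame:
    """Read a delimited-text cohort table (tab-separated, header row,
    empty fields as missing)."""
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if df[col].dtype == object and set(df[col].dropna().unique()) <= {"True", "False"}:
            df[col] = df[col] == "True"
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}': {exc}") from exc

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chart-construction pipeline; returns the artifact bundle.

    The bundle maps series name -> dict with the selected model, comparison
    table, centile table and calibration report, plus cohort-level entries
    (ledger, QC report, summary).  All outputs are also written under
    ``config.out_dir``; reruns with the same config and seed are
    byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load ---
    if config.cohort_path is not None:
        cohort = _stage("load")(read_cohort, config.cohort_path)
    else:
        cohort = _stage("load")(
            lambda: synthetic_data.generate_cohort(n=config.n, seed=config.seed).frame
        )
    log.info("loaded cohort: %d records", len(cohort))

    # --- healthy-cohort filter ---
    included, excluded, ledger = _stage("filter")(healthy_cohort_filter, cohort)
    if len(included) == 0:
        raise PipelineError("stage 'filter': no records remain after exclusions")

    # --- QC stages 2-3 ---
    report = _stage("qc")(qc.qc_report, included)
    qc_excluded_ids = report.excluded_ids()
    analysis = included[~included["case_id"].isin(qc_excluded_ids)].copy()
    qc_outlier_cases = included[
        included["case_id"].isin(set(report.outliers.loc[report.outliers["outlier"], "case_id"]))
    ]
    if len(analysis) == 0:
        raise PipelineError("stage 'qc': no records remain after quality control")
    log.info("QC excluded %d cases; %d remain", len(qc_excluded_ids), len(analysis))

    # --- per-series model fitting and selection ---
    t = analysis["ga_days"].to_numpy(float)
    bundle = {
        "ledger": ledger,
        "qc": report,
        "summary": cohort_summary(analysis),
        "n_analysis": int(len(analysis)),
        "series": {},
    }
    if len(qc_outlier_cases):
        bundle["excluded_comparison"] = _stage("compare_excluded")(
            compare_excluded, analysis, qc_outlier_cases
        )
    for name in config.series:
        y = analysis[name].to_numpy(float)
        candidates = []
        for fam in config.families:
            candidates.append(
                _stage(f"fit:{name}:{fam}")(
                    chart_models.fit_lms,
                    t,
                    y,
                    fam,
                    edf_grid=config.edf_grid,
                    k=config.k,
                    max_cycles=config.max_cycles,
                )
            )
        if config.enable_qr:
            for basis in config.qr_bases:
                for solver in config.qr_solvers:
                    candidates.append(
                        _stage(f"fit_qr:{name}:{basis}:{solver}")(
                            chart_models.fit_quantile_curves,
                            t,
                            y,
                            basis=basis,
                            solver=solver,
                            quantile_levels=config.qr_quantiles,
                        )
                    )
        best, table = _stage(f"select:{name}")(chart_models.select_best_model, candidates)
        entry = {"model": best, "comparison": table}
        if isinstance(best, chart_models.FittedChartModel):
            entry["centiles"] = centile_tools.centile_table(best, centiles=config.target_centiles)
            entry["calibration"] = centile_tools.calibration_table(
                best, t, y, target_centiles=config.target_centiles
            )
            entry["z_scores"] = centile_tools.z_score(best, t, y)
            entry["tail_mass_above_1"] = _tail_mass_above_one(best)
        bundle["series"][name] = entry

    _stage("write")(_write_bundle, bundle, analysis, config, out)
    return bundle


def _tail_mass_above_one(model: chart_models.FittedChartModel) -> float:
    """Diagnostic: largest fitted-distribution mass above the physical bound 1.

    The response families have support beyond 1 while the measurement is a
    fraction in (0, 1); this surfaces how much probability the fitted
    model places out of range rather than resolving the mismatch.
    """
    from . import distributions as dist

    pc = model.param_curves
    grid = np.linspace(pc.t_min, pc.t_max, 9)
    mu, sigma, nu, tau = pc.values(grid)
    mass = 1.0 - dist.cdf_arrays(np.ones_like(grid), mu, sigma, nu, tau, model.family)
    return float(np.max(mass))


def _write_bundle(bundle, analysis, config, out: Path):
    ledger_doc = dict(bundle["ledger"])
    (out / "exclusion_ledger.json").write_text(json.dumps(ledger_doc, indent=1, sort_keys=True))
    bundle["summary"].to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    bundle["qc"].triage.to_csv(out / "qc_triage.tsv", sep="\t", index=False)
    bundle["qc"].outliers.to_csv(out / "qc_outliers.tsv", sep="\t", index=False)
    if "excluded_comparison" in bundle:
        bundle["excluded_comparison"].to_csv(out / "excluded_comparison.tsv", sep="\t", index=False)
    zs = {}
    for name, entry in bundle["series"].items():
        model = entry["model"]
        if isinstance(model, chart_models.FittedChartModel):
            (out / f"model_{name}.json").write_text(model.to_json())
            entry["centiles"].to_frame().to_csv(out / f"centiles_{name}.tsv", sep="\t", index=False)
            entry["calibration"].table.to_csv(out / f"calibration_{name}.tsv", sep="\t", index=False)
            zs[name] = entry["z_scores"]
        entry["comparison"].to_csv(out / f"model_comparison_{name}.tsv", sep="\t", index=False)
        if config.make_plots and isinstance(model, chart_models.FittedChartModel):
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            ax = centile_tools.plot_chart(
                model, analysis["ga_days"].to_numpy(float), analysis[name].to_numpy(float)
            )
            ax.set_title(name)
            ax.figure.savefig(out / f"chart_{name}.png", dpi=150)
            plt.close(ax.figure)
    if zs:
        zdf = pd.DataFrame({"case_id": analysis["case_id"].to_numpy(), **zs})
        zdf.to_csv(out / "z_scores.tsv", sep="\t", index=False)
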