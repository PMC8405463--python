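"""End-to-end study orchestration: QC -> kinetic fits -> BCF table ->
metabolite ratios -> cross-compound regression.

:func:`run_study` assembles a deterministic :class:`StudyReport` from the
water and body series, the compound table and a :class:`StudyConfig`.
Per-analyte failures (too few usable points, missing water series) annotate
the report instead of aborting it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .exceptions import InsufficientDataError, LinkageError
from .metabolism import RatioSeries, TrendResult, ratio_series, ratio_trend
from .physchem import CompoundProperties, classify_reach, load_compounds, log_d
from .qc import QCReport, control_check, water_variation_check
from .series import ConcentrationSeries, read_series_table
from .toxicokinetics import (
    KineticFit,
    bootstrap_uncertainty,
    detect_steady_state,
    fit_first_order,
)

__all__ = ["StudyConfig", "load_config", "RegressionResult",
           "regress_logbcf_logd", "StudyReport", "run_study"]


@dataclass
class StudyConfig:
    """Analysis options for one study run."""

    ph: float = 7.8
    water_variation_limit: float = 0.20
    water_variation_mode: str = "sd_over_mean"
    steady_state_tolerance: float = 0.20
    bootstrap_b: int = 200
    seed: int = 0
    cw_mode: str = "mean"
    weighting: str = "none"
    outlier_threshold: float = 2.0
    trend_alpha: float = 0.05
    body_lod: float = 6.0


def load_config(path: str | Path) -> StudyConfig:
    """Read a YAML config; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise LinkageError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**raw)


# ---------------------------------------------------------------------------
# cross-compound regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """OLS of log10(BCF_k) on log D, with studentized-residual outliers."""

    slope: float
    intercept: float
    r: float
    n: int
    outliers: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)


def regress_logbcf_logd(records, outlier_threshold: float = 2.0) -> RegressionResult:
    """Fit ``log10(BCF_k) = intercept + slope * log D`` across analytes.

    ``records`` is a DataFrame (or list of dicts) with columns ``analyte``,
    ``bcf_k``, ``log_d``.  Records with non-positive BCF are skipped with a
    note; fewer than three usable records raise an error.  Outliers are
    analytes with absolute studentized residual above ``outlier_threshold``
    (externally studentized when residual degrees of freedom allow, else
    internally).
    """
    df = pd.DataFrame(records)
    skipped = df.loc[df["bcf_k"] <= 0, "analyte"].tolist()
    df = df[df["bcf_k"] > 0].reset_index(drop=True)
    if len(df) < 3:
        raise InsufficientDataError(
            f"regression needs >= 3 records with BCF_k > 0, have {len(df)}"
        )
    y = np.log10(df["bcf_k"].to_numpy())
    x = df["log_d"].to_numpy()
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    r = float(np.corrcoef(x, y)[0, 1])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if model.ssr <= 1e-12 * max(ss_tot, 1e-30):
        # numerically perfect fit: studentized residuals are 0/0 noise
        outliers: list[str] = []
    else:
        infl = OLSInfluence(model)
        with np.errstate(divide="ignore", invalid="ignore"):
            if len(df) > 3:
                stud = infl.resid_studentized_external
            else:
                stud = infl.resid_studentized_internal
        # nan (0/0): leave-one-out fit perfect AND residual zero -> not an
        # outlier; +/-inf (zero LOO variance, nonzero residual) is kept
        stud = np.asarray(stud, dtype=float)
        stud[np.isnan(stud)] = 0.0
        outliers = df.loc[np.abs(stud) > outlier_threshold, "analyte"].tolist()
    return RegressionResult(slope=float(slope), intercept=float(intercept), r=r,
                            n=len(df), outliers=outliers, skipped=skipped)


# ---------------------------------------------------------------------------
# study report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Deterministic, text-serializable outcome of a full study run."""

    fits: dict[str, KineticFit]
    qc: QCReport
    ratios: dict[str, RatioSeries]
    trends: dict[str, TrendResult]
    regression: RegressionResult | None
    provenance: dict
    notes: list[str] = field(default_factory=list)

    def summary_table(self) -> pd.DataFrame:
        """One row per analyte: Cw mean +/- sd, BCF_k, BCF_48h, flags."""
        rows = []
        for name in sorted(self.fits):
            fit = self.fits[name]
            wv = self.qc.water_variation.get(name)
            ss = self.qc.steady_state.get(name)
            boot = fit.intervals or {}
            bcf_ci = boot.get("bcf_k")
            rows.append({
                "analyte": name,
                "cw_mean": fit.cw_mean,
                "cw_sd": wv.sd if wv else np.nan,
                "bcf_k": fit.bcf_k,
                "bcf_k_ci_lo": bcf_ci[0] if bcf_ci else np.nan,
                "bcf_k_ci_hi": bcf_ci[1] if bcf_ci else np.nan,
                "bcf_48h": np.nan if fit.bcf_48h is None else fit.bcf_48h,
                "steady_state": bool(ss.steady) if ss else False,
                "reach_class": classify_reach(max(fit.bcf_k, 0.0)),
                "converged": fit.converged,
            })
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Byte-stable report body (no timestamps)."""
        out = ["# bioconcentration study report", ""]
        out.append("## provenance")
        for k in sorted(self.provenance):
            out.append(f"{k}: {self.provenance[k]}")
        out.append("")
        out.append("## kinetic fits and BCFs")
        table = self.summary_table()
        out.append(table.to_csv(sep="\t", index=False, float_format="%.6g").rstrip())
        out.append("")
        out.append("## water variation QC")
        for name in sorted(self.qc.water_variation):
            r = self.qc.water_variation[name]
            out.append(f"{name}\tmean={r.mean:.6g}\tsd={r.sd:.6g}\t"
                       f"rel={r.relative_variation:.6g}\t"
                       f"{'pass' if r.passed else 'FAIL'} (limit {r.limit:g}, {r.mode})")
        if self.qc.control_check is not None:
            c = self.qc.control_check
            out.append(f"controls\tn={c.n_controls}\tdetects={c.n_detects}\t"
                       f"{'pass' if c.passed else 'FAIL'}")
        out.append("")
        if self.ratios:
            out.append("## metabolite/parent ratios")
            for key in sorted(self.ratios):
                rs = self.ratios[key]
                out.append(f"### {rs.metabolite} / {rs.parent}")
                out.append(rs.data.to_csv(sep="\t", index=False,
                                          float_format="%.6g").rstrip())
                trend = self.trends.get(key)
                if trend is not None:
                    out.append(f"trend: {trend.direction}\tS={trend.s}\t"
                               f"tau={trend.tau:.6g}\tp_one={trend.p_one_sided:.6g}\t"
                               f"p_two={trend.p_two_sided:.6g}\t({trend.method})")
                out.append("")
        if self.regression is not None:
            reg = self.regression
            out.append("## log BCF_k vs log D regression")
            out.append(f"slope={reg.slope:.6g}\tintercept={reg.intercept:.6g}\t"
                       f"r={reg.r:.6g}\tn={reg.n}")
            out.append(f"outliers: {', '.join(reg.outliers) if reg.outliers else '(none)'}")
            if reg.skipped:
                out.append(f"skipped (BCF_k <= 0): {', '.join(reg.skipped)}")
            out.append("")
        if self.notes:
            out.append("## notes")
            out.extend(f"- {n}" for n in self.notes)
            out.append("")
        return "\n".join(out) + "\n"

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.txt").write_text(self.to_text())
        self.summary_table().to_csv(directory / "bcf_table.tsv", sep="\t",
                                    index=False, float_format="%.6g")


def _as_series_list(obj) -> list[ConcentrationSeries]:
    if isinstance(obj, (str, Path)):
        return read_series_table(obj)
    return list(obj)


def _as_compounds(obj) -> dict[str, CompoundProperties]:
    if isinstance(obj, (str, Path)):
        return load_compounds(obj)
    return dict(obj)


def run_study(water, body, compounds, config: StudyConfig | None = None,
              controls: ConcentrationSeries | None = None) -> StudyReport:
    """Run the full analysis and assemble a :class:`StudyReport`.

    Parameters
    ----------
    water, body : path or iterable of ConcentrationSeries
        Exposure-medium and organism series (long-format delimited files or
        in-memory series).
    compounds : path or mapping
        Compound-properties table; every series analyte must resolve here.
    config : StudyConfig, optional
    controls : ConcentrationSeries, optional
        Unexposed-control body burdens for the contamination check.

    The report is deterministic given inputs and ``config.seed``; per-analyte
    analysis failures become notes, never exceptions.
    """
    config = config or StudyConfig()
    water_list = _as_series_list(water)
    body_list = _as_series_list(body)
    comp = _as_compounds(compounds)

    water_by = {s.analyte: s for s in water_list if s.medium == "water"}
    body_by = {s.analyte: s for s in body_list if s.medium == "organism"}
    for name in sorted(set(water_by) | set(body_by)):
        if name not in comp:
            raise LinkageError(f"series analyte {name!r} missing from compound table")

    qc = QCReport()
    notes: list[str] = []
    fits: dict[str, KineticFit] = {}

    for name in sorted(body_by):
        body_s = body_by[name]
        water_s = water_by.get(name)
        if water_s is not None:
            try:
                qc.water_variation[name] = water_variation_check(
                    water_s, limit=config.water_variation_limit,
                    mode=config.water_variation_mode)
            except InsufficientDataError as exc:
                notes.append(str(exc))
        try:
            qc.steady_state[name] = detect_steady_state(
                body_s, tolerance=config.steady_state_tolerance)
        except InsufficientDataError as exc:
            notes.append(str(exc))
        if water_s is None:
            notes.append(f"{name}: no water series; kinetic fit skipped")
            continue
        try:
            fit = fit_first_order(body_s, water_s, cw_mode=config.cw_mode,
                                  weighting=config.weighting)
        except InsufficientDataError as exc:
            notes.append(f"{name}: {exc}")
            continue
        if config.bootstrap_b > 0:
            try:
                boot = bootstrap_uncertainty(
                    body_s, water_s, b=config.bootstrap_b, seed=config.seed,
                    cw_mode=config.cw_mode, weighting=config.weighting)
                fit.intervals = boot.intervals
            except InsufficientDataError as exc:
                notes.append(f"{name}: bootstrap failed: {exc}")
        notes.extend(f"{name}: {n}" for n in fit.notes)
        fits[name] = fit

    if controls is not None:
        try:
            qc.control_check = control_check(controls, lod=config.body_lod)
        except InsufficientDataError as exc:
            notes.append(str(exc))

    ratios: dict[str, RatioSeries] = {}
    trends: dict[str, TrendResult] = {}
    for name in sorted(body_by):
        c = comp[name]
        if c.role == "metabolite" and c.parent in body_by:
            key = f"{name}/{c.parent}"
            rs = ratio_series(body_by[c.parent], body_by[name])
            ratios[key] = rs
            try:
                trends[key] = ratio_trend(rs, alpha=config.trend_alpha)
            except InsufficientDataError as exc:
                notes.append(f"{key}: {exc}")

    regression = None
    records = [{"analyte": n, "bcf_k": f.bcf_k, "log_d": log_d(
        comp[n].log_kow, comp[n].pka, config.ph)} for n, f in sorted(fits.items())]
    if records:
        try:
            regression = regress_logbcf_logd(
                records, outlier_threshold=config.outlier_threshold)
        except InsufficientDataError as exc:
            notes.append(f"regression skipped: {exc}")

    from . import __version__

    cfg_json = json.dumps(asdict(config), sort_keys=True)
    provenance = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.seed,
        "version": __version__,
    }
    return StudyReport(fits=fits, qc=qc, ratios=ratios, trends=trends,
                       regression=regression, provenance=provenance, notes=notes)
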