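"""Frozen-vs-FFPE concordance benchmark.

Frozen-derived expression is treated as the gold standard; each processing
pipeline (normalization engine x chip description) is rated by how well
the FFPE arm of matched pairs reproduces it:

* *sample correlation* — per matched pair, Pearson r between frozen and
  FFPE expression over all probesets (median reported);
* *probeset correlation* — per probeset, Pearson r across matched pairs,
  computed on the most variant half of probesets (by frozen-arm IQR);
* *fold-change agreement* — Pearson r (Fisher-z CI) and OLS slope
  (t-based CI) between the frozen and FFPE subgroup log2 fold changes;
* *sensitivity / PPV* — the fraction of frozen-DE probesets recovered in
  FFPE and the fraction of FFPE-DE probesets confirmed in frozen;
* *leave-one-out robustness* — spread of sensitivity/PPV when one sample
  is removed at a time, to show metric differences between pipelines are
  not driven by single arrays.

Differential expression uses an equal-variance two-sample t test per
probeset with Benjamini-Hochberg adjustment; the default call rule is raw
p < 1e-4, with an FDR < 0.01 alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class BenchmarkConfig:
    """Thresholds and levels of the concordance benchmark."""

    de_p_threshold: float = 1e-4
    fdr_threshold: float = 0.01
    de_rule: str = "p"  # 'p' (raw p) or 'fdr' (BH-adjusted)
    iqr_fraction: float = 0.5
    ci_level: float = 0.95

    def __post_init__(self):
        for name in ("de_p_threshold", "fdr_threshold", "iqr_fraction", "ci_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.de_rule not in {"p", "fdr"}:
            raise ConfigurationError("de_rule must be 'p' or 'fdr'")


@dataclass
class DEResult:
    """Per-probeset differential-expression statistics.

    ``table`` columns: ``log2_fc`` (mean of first subgroup minus mean of
    second, subgroups in sorted label order), ``t``, ``p``, ``p_adj``
    (Benjamini-Hochberg) and boolean ``de``.
    """

    table: pd.DataFrame
    groups: tuple[str, str]
    rule: str

    @property
    def de_ids(self) -> set[str]:
        return set(self.table.index[self.table["de"]])


def _pairs_table(pairs) -> list[tuple[str, str]]:
    """Normalize a pair spec (annotation frame or explicit tuples)."""
    if isinstance(pairs, pd.DataFrame):
        out = []
        for pid, grp in pairs.groupby("pair_id", sort=True):
            fr = grp.loc[grp["preservation"] == "frozen", "sample_id"]
            fp = grp.loc[grp["preservation"] == "ffpe", "sample_id"]
            if len(fr) != 1 or len(fp) != 1:
                raise ValidationError(f"pair {pid!r} is not a frozen/ffpe pair")
            out.append((fr.iloc[0], fp.iloc[0]))
        return out
    return [(f, p) for f, p in pairs]


def sample_correlation(
    frozen_expr: pd.DataFrame, ffpe_expr: pd.DataFrame, pairs
) -> tuple[pd.Series, float]:
    """Pearson r per matched pair over all common probesets, plus median."""
    common = frozen_expr.index.intersection(ffpe_expr.index)
    if len(common) < 2:
        raise ValidationError("need at least 2 common probesets")
    plist = _pairs_table(pairs)
    F = frozen_expr.loc[common]
    P = ffpe_expr.loc[common]
    r = {}
    for fcol, pcol in plist:
        r[fcol] = float(stats.pearsonr(F[fcol], P[pcol]).statistic)
    series = pd.Series(r, name="sample_correlation")
    return series, float(series.median())


def probeset_correlation(
    frozen_expr: pd.DataFrame,
    ffpe_expr: pd.DataFrame,
    pairs,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> tuple[pd.Series, float]:
    """Per-probeset r across pairs, on the most variant probesets.

    Probesets are ranked by the IQR of their frozen expression and the top
    ``iqr_fraction`` retained before correlating.  Retained probesets with
    zero variance in either arm are excluded (with a warning) rather than
    reported as NaN.
    """
    plist = _pairs_table(pairs)
    if len(plist) < 3:
        raise ValidationError("need at least 3 matched pairs")
    common = frozen_expr.index.intersection(ffpe_expr.index)
    F = frozen_expr.loc[common, [f for f, _ in plist]]
    P = ffpe_expr.loc[common, [p for _, p in plist]]
    k = int(np.floor(config.iqr_fraction * len(common)))
    if k < 1:
        raise ValidationError("iqr_fraction leaves no probeset")
    iqr = F.quantile(0.75, axis=1) - F.quantile(0.25, axis=1)
    ranked = sorted(common, key=lambda ps: (-iqr[ps], ps))
    keep = ranked[:k]

    Fa = F.loc[keep].to_numpy()
    Pa = P.loc[keep].to_numpy()
    fc = Fa - Fa.mean(axis=1, keepdims=True)
    pc = Pa - Pa.mean(axis=1, keepdims=True)
    denom = np.sqrt((fc**2).sum(axis=1) * (pc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (fc * pc).sum(axis=1) / denom
    series = pd.Series(r, index=keep, name="probeset_correlation")
    bad = series.isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} retained probesets had zero variance; excluded")
        series = series[~bad]
    return series, float(series.median())


def differential_expression(
    expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> DEResult:
    """Equal-variance two-sample t test per probeset with BH adjustment.

    ``labels`` maps sample id to subgroup; exactly two subgroups with at
    least two samples each are required.  The log2 fold change is the mean
    of the first subgroup (sorted label order) minus the second.
    """
    labels = pd.Series(labels)
    labels = labels.loc[[s for s in expr.columns if s in labels.index]]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 subgroups, found {groups}")
    ga = [s for s in expr.columns if labels.get(s) == groups[0]]
    gb = [s for s in expr.columns if labels.get(s) == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValidationError("each subgroup needs at least 2 samples")
    A = expr[ga].to_numpy(dtype=float)
    B = expr[gb].to_numpy(dtype=float)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    fc = A.mean(axis=1) - B.mean(axis=1)
    if config.de_rule == "p":
        de = p < config.de_p_threshold
    else:
        de = p_adj < config.fdr_threshold
    table = pd.DataFrame(
        {"log2_fc": fc, "t": np.nan_to_num(t, nan=0.0), "p": p, "p_adj": p_adj, "de": de},
        index=expr.index,
    )
    return DEResult(table=table, groups=(groups[0], groups[1]), rule=config.de_rule)


@dataclass
class EstimateWithCI:
    value: float
    ci_low: float
    ci_high: float
    level: float


@dataclass
class FoldChangeAgreement:
    correlation: EstimateWithCI
    slope: EstimateWithCI
    n: int


def fold_change_agreement(
    de_frozen: DEResult | pd.Series,
    de_ffpe: DEResult | pd.Series,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> FoldChangeAgreement:
    """Correlation and regression slope of FFPE on frozen fold changes.

    Computed over all common probesets (not only DE ones).  The
    correlation CI uses the Fisher z transform; the slope and its CI come
    from ordinary least squares of the FFPE fold change on the frozen one.
    A slope below 1 means FFPE fold changes are attenuated.
    """
    fx = de_frozen.table["log2_fc"] if isinstance(de_frozen, DEResult) else de_frozen
    fy = de_ffpe.table["log2_fc"] if isinstance(de_ffpe, DEResult) else de_ffpe
    common = fx.index.intersection(fy.index)
    n = len(common)
    if n < 3:
        raise ValidationError("need at least 3 common probesets")
    x = fx.loc[common].to_numpy(dtype=float)
    y = fy.loc[common].to_numpy(dtype=float)

    r = float(stats.pearsonr(x, y).statistic)
    zcrit = stats.norm.ppf(0.5 + config.ci_level / 2)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se_z = 1.0 / np.sqrt(n - 3)
    # clamp so a degenerate |r| = 1 still yields an interval containing r
    r_ci = (
        min(float(np.tanh(z - zcrit * se_z)), r),
        max(float(np.tanh(z + zcrit * se_z)), r),
    )

    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + config.ci_level / 2, df=n - 2)
    slope_ci = (
        float(res.slope - tcrit * res.stderr),
        float(res.slope + tcrit * res.stderr),
    )
    return FoldChangeAgreement(
        correlation=EstimateWithCI(r, r_ci[0], r_ci[1], config.ci_level),
        slope=EstimateWithCI(float(res.slope), slope_ci[0], slope_ci[1], config.ci_level),
        n=n,
    )


def sensitivity_ppv(
    de_frozen: DEResult | Iterable[str], de_ffpe: DEResult | Iterable[str]
) -> tuple[float | None, float | None]:
    """FFPE sensitivity and positive predictive value against frozen calls.

    sensitivity = |frozen-DE recovered in FFPE| / |frozen-DE|;
    ppv = |FFPE-DE confirmed in frozen| / |FFPE-DE|.
    An empty denominator yields ``None`` for that metric.
    """
    sf = de_frozen.de_ids if isinstance(de_frozen, DEResult) else set(de_frozen)
    sp = de_ffpe.de_ids if isinstance(de_ffpe, DEResult) else set(de_ffpe)
    inter = len(sf & sp)
    sens = inter / len(sf) if sf else None
    ppv = inter / len(sp) if sp else None
    return sens, ppv


@dataclass
class LeaveOneOutResult:
    sensitivity: pd.Series
    ppv: pd.Series
    sensitivity_mean: float
    sensitivity_sd: float
    ppv_mean: float
    ppv_sd: float
    n_skipped: int


def leave_one_out_robustness(
    frozen_expr: pd.DataFrame,
    ffpe_expr: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    pairs,
    config: BenchmarkConfig = BenchmarkConfig(),
) -> LeaveOneOutResult:
    """Recompute sensitivity/PPV with each matched pair removed in turn.

    ``labels`` is keyed by frozen sample id (each matched pair shares one
    subgroup).  Removals that would leave a subgroup with fewer than two
    samples are skipped with a warning.
    """
    plist = _pairs_table(pairs)
    labels = pd.Series(labels)
    sens, ppv = {}, {}
    skipped = 0
    for fcol, pcol in plist:
        keep_f = [f for f, _ in plist if f != fcol]
        keep_p = [p for _, p in plist if p != pcol]
        sub_f = pd.Series({f: labels[f] for f, _ in plist if f != fcol})
        if sub_f.value_counts().min() < 2 or len(sub_f.unique()) < 2:
            warnings.warn(f"removing {fcol!r} empties a subgroup; skipped")
            skipped += 1
            continue
        lab_f = {f: labels[f] for f, _ in plist if f != fcol}
        lab_p = {p: labels[[f for f, pp in plist if pp == p][0]] for p in keep_p}
        de_f = differential_expression(frozen_expr[keep_f], lab_f, config)
        de_p = differential_expression(ffpe_expr[keep_p], lab_p, config)
        s, v = sensitivity_ppv(de_f, de_p)
        sens[fcol] = np.nan if s is None else s
        ppv[fcol] = np.nan if v is None else v
    s = pd.Series(sens, name="sensitivity")
    v = pd.Series(ppv, name="ppv")
    return LeaveOneOutResult(
        sensitivity=s,
        ppv=v,
        sensitivity_mean=float(s.mean()),
        sensitivity_sd=float(s.std(ddof=1)),
        ppv_mean=float(v.mean()),
        ppv_sd=float(v.std(ddof=1)),
        n_skipped=skipped,
    )


@dataclass
class ConcordanceReport:
    """All benchmark metrics for one named pipeline."""

    pipeline: str
    sample_correlations: pd.Series
    median_sample_correlation: float
    probeset_correlations: pd.Series
    median_probeset_correlation: float
    fold_change: FoldChangeAgreement
    sensitivity: float | None
    ppv: float | None
    n_probesets: int
    n_de_frozen: int
    n_de_ffpe: int
    leave_one_out: LeaveOneOutResult | None = None

    def summary(self) -> dict:
        out = {
            "pipeline": self.pipeline,
            "n_probesets": self.n_probesets,
            "median_sample_correlation": self.median_sample_correlation,
            "median_probeset_correlation": self.median_probeset_correlation,
            "fc_correlation": self.fold_change.correlation.value,
            "fc_correlation_ci": [
                self.fold_change.correlation.ci_low,
                self.fold_change.correlation.ci_high,
            ],
            "fc_slope": self.fold_change.slope.value,
            "fc_slope_ci": [
                self.fold_change.slope.ci_low,
                self.fold_change.slope.ci_high,
            ],
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "n_de_frozen": self.n_de_frozen,
            "n_de_ffpe": self.n_de_ffpe,
        }
        if self.leave_one_out is not None:
            out["loo_sensitivity_mean"] = self.leave_one_out.sensitivity_mean
            out["loo_sensitivity_sd"] = self.leave_one_out.sensitivity_sd
            out["loo_ppv_mean"] = self.leave_one_out.ppv_mean
            out["loo_ppv_sd"] = self.leave_one_out.ppv_sd
        return out


def concordance_report(
    pipeline: str,
    frozen_expr: pd.DataFrame,
    ffpe_expr: pd.DataFrame,
    annotation: pd.DataFrame,
    config: BenchmarkConfig = BenchmarkConfig(),
    leave_one_out: bool = False,
) -> ConcordanceReport:
    """Compute every benchmark metric for one pipeline's expression pair."""
    pairs = _pairs_table(annotation)
    lab = annotation.set_index("sample_id")["subgroup"]
    lab_f = {f: lab[f] for f, _ in pairs}
    lab_p = {p: lab[p] for _, p in pairs}

    sc, sc_med = sample_correlation(frozen_expr, ffpe_expr, pairs)
    pc, pc_med = probeset_correlation(frozen_expr, ffpe_expr, pairs, config)
    de_f = differential_expression(frozen_expr[[f for f, _ in pairs]], lab_f, config)
    de_p = differential_expression(ffpe_expr[[p for _, p in pairs]], lab_p, config)
    fc = fold_change_agreement(de_f, de_p, config)
    sens, ppv = sensitivity_ppv(de_f, de_p)
    loo = None
    if leave_one_out:
        loo = leave_one_out_robustness(
            frozen_expr[[f for f, _ in pairs]],
            ffpe_expr[[p for _, p in pairs]],
            lab_f,
            pairs,
            config,
        )
    return ConcordanceReport(
        pipeline=pipeline,
        sample_correlations=sc,
        median_sample_correlation=sc_med,
        probeset_correlations=pc,
        median_probeset_correlation=pc_med,
        fold_change=fc,
        sensitivity=sens,
        ppv=ppv,
        n_probesets=len(frozen_expr.index.intersection(ffpe_expr.index)),
        n_de_frozen=len(de_f.de_ids),
        n_de_ffpe=len(de_p.de_ids),
        leave_one_out=loo,
    )


def compare_pipelines(reports: Sequence[ConcordanceReport]) -> pd.DataFrame:
    """Pairwise significance tests between pipelines.

    Sample correlations are matched by pair, so differences use the
    Wilcoxon signed-rank test; probeset correlations live on different
    probeset universes, so the Wilcoxon-Mann-Whitney test is used.
    Comparing a pipeline with itself (all-zero differences) reports p = 1
    by convention.
    """
    if len(reports) < 2:
        raise ValidationError("need at least 2 reports")
    idx0 = reports[0].sample_correlations.index
    for rep in reports[1:]:
        if not rep.sample_correlations.index.equals(idx0):
            raise ValidationError("reports cover different sample-pair sets")
    rows = []
    for i, ra in enumerate(reports):
        for rb in reports[i + 1 :]:
            diff = (ra.sample_correlations - rb.sample_correlations).to_numpy()
            nz = diff[diff != 0.0]
            if np.allclose(diff, 0.0) or nz.size == 0:
                w_p = 1.0
            else:
                method = "exact" if nz.size <= 25 else "auto"
                w_p = float(
                    stats.wilcoxon(nz, zero_method="wilcox", method=method).pvalue
                )
            a = ra.probeset_correlations.to_numpy()
            b = rb.probeset_correlations.to_numpy()
            if np.array_equal(a, b):
                u_p = 1.0
            else:
                u_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            rows.append(
                {
                    "pipeline_a": ra.pipeline,
                    "pipeline_b": rb.pipeline,
                    "sample_corr_wilcoxon_p": w_p,
                    "probeset_corr_mannwhitney_p": u_p,
                }
            )
    return pd.DataFrame(rows)
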