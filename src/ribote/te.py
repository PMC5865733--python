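"""Translational efficiency, negative-binomial count testing, and filtering.

TE for a transcript at a stage is the replicate-averaged footprint RPKM
divided by the replicate-averaged control RPKM (both post-floor).  Evidence
that footprint and control counts differ beyond sampling noise comes from a
negative-binomial exact test in the classic count-based differential
expression formulation: median-of-ratios size factors, per-transcript
method-of-moments dispersion shrunk toward a mean-dispersion trend, and a
two-sided conditional tail probability over CT/FP splits of the observed
total.  High-TE and low-TE transcript sets are then the exact conjunction of
the printed thresholds, with splice variants collapsed to unique genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix, LibraryKey, gene_id_of
from .quantify import ExpressionTable
from .utils import round_half_away

DISPERSION_FLOOR = 1e-8
TREND_MIN_TRANSCRIPTS = 100


def compute_te(ct_rpkm: float, fp_rpkm: float) -> float:
    """fp/ct at full precision; use :func:`te_report` for the printed value."""
    if ct_rpkm <= 0:
        raise ValueError("control RPKM must be positive (apply the floor first)")
    return fp_rpkm / ct_rpkm


def te_report(ct_rpkm: float, fp_rpkm: float) -> float:
    """TE as printed: two decimals, ties away from zero."""
    return round_half_away(compute_te(ct_rpkm, fp_rpkm), 2)


# ---------------------------------------------------------------------------
# NB exact test


def prepare_test_counts(counts: CountMatrix, stage: str) -> pd.DataFrame:
    """Per-transcript CT/FP replicate counts at one stage, zeros -> 1.

    Zero conversion applies only to the test's count inputs (RPKMs use the
    0.1 floor instead).
    """
    keys = [k for k in counts.libraries if k.stage == stage]
    ct = sorted(k for k in keys if k.lib_type == "CT")
    fp = sorted(k for k in keys if k.lib_type == "FP")
    if not ct or not fp:
        raise ValueError(f"stage {stage!r} needs at least one CT and one FP library")
    df = counts.counts[[k.label for k in ct + fp]].copy()
    return df.clip(lower=1)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth estimator.

    factor_j = median over all-positive transcripts of
    count[t, j] / geometric mean over libraries of count[t, .].
    """
    arr = counts.to_numpy(float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no transcript with all-positive counts; "
                         "convert zeros (prepare_test_counts) first")
    logs = np.log(arr[positive])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.median(np.exp(logs - log_geo), axis=0)
    return pd.Series(factors, index=counts.columns)


def _dispersion_estimates(norm: np.ndarray, cond: np.ndarray,
                          sf: np.ndarray) -> np.ndarray:
    """Method-of-moments dispersion pooled across both conditions.

    For each transcript: w = mean over conditions of the sample variance of
    normalized counts within the condition; the shot-noise part q0 * mean(1/s)
    is subtracted and the remainder divided by q0^2.
    """
    q0 = norm.mean(axis=1)
    variances = []
    for c in (0, 1):
        cols = cond == c
        if cols.sum() >= 2:
            variances.append(norm[:, cols].var(axis=1, ddof=1))
    if variances:
        w = np.mean(variances, axis=0)
    else:  # single replicate per condition: no within-condition variance
        w = np.zeros(norm.shape[0])
    xim = np.mean(1.0 / sf)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (w - q0 * xim) / np.square(q0)
    disp[~np.isfinite(disp)] = 0.0
    return disp  # unfloored: the trend fit needs the negative excursions


def _trend_dispersions(raw_w: np.ndarray, q0: np.ndarray) -> np.ndarray:
    """Mean-dispersion trend disp(q) = a0 + a1/q fitted to the raw
    method-of-moments estimates in linear space.

    Raw two-replicate estimates are far too unstable to use directly, and
    averaging their logs biases the dispersion downward (the estimates are
    chi-square-like); a linear-space fit of the classic parametric
    mean-dispersion relation is unbiased for the trend and keeps the test
    calibrated.  Transcripts then share the fitted trend value.
    """
    ok = q0 > 0
    if ok.sum() < TREND_MIN_TRANSCRIPTS:
        return np.maximum(raw_w, DISPERSION_FLOOR)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / q0[ok]])
    coef, *_ = np.linalg.lstsq(X, raw_w[ok], rcond=None)
    fitted = coef[0] + coef[1] / np.maximum(q0, 1e-12)
    return np.maximum(fitted, DISPERSION_FLOOR)


def _nb_logpmf_grid(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    if var > mu * (1 + 1e-9):
        r = mu * mu / (var - mu)
        p = r / (r + mu)
        return stats.nbinom.logpmf(k, r, p)
    return stats.poisson.logpmf(k, mu)


def _exact_pvalue(ka: int, kb: int, mu_a: float, var_a: float,
                  mu_b: float, var_b: float) -> float:
    """Two-sided conditional tail: P(splits at least as extreme | total)."""
    ks = ka + kb
    a = np.arange(ks + 1)
    logp = (_nb_logpmf_grid(a, mu_a, var_a)
            + _nb_logpmf_grid(ks - a, mu_b, var_b))
    logp_obs = logp[ka]
    m = logp.max()
    probs = np.exp(logp - m)
    denom = probs.sum()
    num = probs[logp <= logp_obs + 1e-12].sum()
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(num / denom, 1e-300)))  # p stays in (0, 1]


def nb_test(counts: pd.DataFrame, condition: Sequence[str] | None = None,
            factors: pd.Series | None = None,
            use_trend: bool = True) -> pd.Series:
    """Per-transcript two-sided p-values, CT vs FP.

    ``counts``: integer counts, columns = libraries (all CT columns then all
    FP columns unless ``condition`` labels them explicitly).  Counts must be
    >= 1 (run :func:`prepare_test_counts` first).
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    ncol = arr.shape[1]
    if condition is None:
        labels = [LibraryKey.from_label(c).lib_type for c in counts.columns]
    else:
        labels = list(condition)
    cond = np.array([0 if l == "CT" else 1 for l in labels])
    if set(cond) != {0, 1}:
        raise ValueError("need both CT and FP columns")
    if factors is None:
        factors = size_factors(counts)
    sf = factors.to_numpy(float)

    norm = arr / sf
    q0 = norm.mean(axis=1)
    raw = _dispersion_estimates(norm, cond, sf)
    if use_trend and arr.shape[0] >= TREND_MIN_TRANSCRIPTS:
        disp = _trend_dispersions(raw, q0)
    else:
        disp = np.maximum(raw, DISPERSION_FLOOR)

    s_a, s_b = sf[cond == 0].sum(), sf[cond == 1].sum()
    ss_a = np.square(sf[cond == 0]).sum()
    ss_b = np.square(sf[cond == 1]).sum()
    k_a = arr[:, cond == 0].sum(axis=1)
    k_b = arr[:, cond == 1].sum(axis=1)

    pvals = np.empty(arr.shape[0])
    for i in range(arr.shape[0]):
        mu_a = q0[i] * s_a
        mu_b = q0[i] * s_b
        var_a = mu_a + disp[i] * q0[i] ** 2 * ss_a
        var_b = mu_b + disp[i] * q0[i] ** 2 * ss_b
        pvals[i] = _exact_pvalue(int(k_a[i]), int(k_b[i]),
                                 mu_a, var_a, mu_b, var_b)
    return pd.Series(pvals, index=counts.index, name="pvalue")


# ---------------------------------------------------------------------------
# TE result assembly and filtering


def te_table(expression: ExpressionTable, counts: CountMatrix,
             stages: Iterable[str] | None = None,
             use_trend: bool = True) -> pd.DataFrame:
    """Master per-(transcript, stage) table: ct_rpkm, fp_rpkm, te, pvalue, padj.

    RPKMs are replicate-averaged post-floor; te is their full-precision
    ratio with a rounded companion column; the Benjamini-Hochberg column is
    informational only (filters use raw p-values).
    """
    if expression.rep_avg is None:
        raise ValueError("expression table lacks replicate averages")
    avg = expression.rep_avg
    if stages is None:
        stages = list(dict.fromkeys(avg.columns.get_level_values("stage")))
    frames = []
    for stage in stages:
        ct = avg[(stage, "CT")]
        fp = avg[(stage, "FP")]
        pvals = nb_test(prepare_test_counts(counts, stage), use_trend=use_trend)
        te = fp / ct
        df = pd.DataFrame({
            "transcript_id": avg.index, "stage": stage,
            "ct_rpkm": ct.to_numpy(), "fp_rpkm": fp.to_numpy(),
            "te": te.to_numpy(),
            "te_rounded": [round_half_away(x, 2) for x in te],
            "pvalue": pvals.reindex(avg.index).to_numpy(),
        })
        df["padj"] = _benjamini_hochberg(df["pvalue"].to_numpy())
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass(frozen=True)
class FilterCriteria:
    """Threshold conjunction for retaining transcripts at one stage."""

    pval_max: float            # strictly below
    te_bound: float
    te_direction: str          # "above" (strict >) or "at_most" (inclusive <=)
    abundance_field: str       # "fp_rpkm" or "ct_rpkm"
    abundance_min: float       # inclusive >=

    @classmethod
    def high_te(cls) -> "FilterCriteria":
        """Pval < 0.05, TE > 1, FP RPKM >= 1."""
        return cls(0.05, 1.0, "above", "fp_rpkm", 1.0)

    @classmethod
    def low_te(cls) -> "FilterCriteria":
        """Pval < 0.05, TE <= 0.1, CT RPKM >= 10."""
        return cls(0.05, 0.1, "at_most", "ct_rpkm", 10.0)


def filter_transcripts(results: pd.DataFrame, criteria: FilterCriteria,
                       stage: str) -> set[str]:
    """Transcripts passing the exact conjunction of the criteria at a stage."""
    df = results[results["stage"] == stage]
    missing = df["pvalue"].isna()
    df = df[~missing]
    if criteria.te_direction == "above":
        te_ok = df["te"] > criteria.te_bound
    elif criteria.te_direction == "at_most":
        te_ok = df["te"] <= criteria.te_bound
    else:
        raise ValueError(f"unknown te_direction {criteria.te_direction!r}")
    keep = ((df["pvalue"] < criteria.pval_max) & te_ok
            & (df[criteria.abundance_field] >= criteria.abundance_min))
    return set(df.loc[keep, "transcript_id"])


@dataclass
class GeneSet:
    """Per-stage passing transcripts with unique-gene collapsing."""

    per_stage: dict[str, set[str]]

    @property
    def per_stage_genes(self) -> dict[str, set[str]]:
        return {s: {gene_id_of(t) for t in tids}
                for s, tids in self.per_stage.items()}

    @property
    def union_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.per_stage_genes.values():
            out |= genes
        return out


def collapse_unique_genes(per_stage: Mapping[str, Iterable[str]]) -> GeneSet:
    return GeneSet({s: set(tids) for s, tids in per_stage.items()})


def expressed_counts(results: pd.DataFrame, threshold: float = 1.0,
                     ) -> pd.DataFrame:
    """Per stage: transcripts and unique genes with CT RPKM >= threshold."""
    rows = []
    for stage, df in results.groupby("stage", sort=False):
        expressed = df[df["ct_rpkm"] >= threshold]
        rows.append({"stage": stage,
                     "transcripts": len(expressed),
                     "unique_genes": len({gene_id_of(t)
                                          for t in expressed["transcript_id"]})})
    return pd.DataFrame(rows).set_index("stage")


def percentage(numerator: int, denominator: int) -> float:
    """Share of a gene set relative to the expressed denominator, in percent
    rounded to 2 decimals (e.g. 136 of 14888 -> 0.91)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_away(100.0 * numerator / denominator, 2)
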