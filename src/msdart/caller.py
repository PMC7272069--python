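"""Methylation calling from MspI vs HpaII MSD-tag counts.

A site is called MSD-methylated in a tissue when the PstI-MspI library shows
significantly more reads than the PstI-HpaII library for one of its tags,
under *two* negative-binomial tests of different construction that must both
agree (FDR <= 0.05 per test) together with a fold-change gate (FC >= 2 by
default).  Test A is an exact conditional NB test with qCML-style dispersion
shrinkage toward a common value; test B is a per-tag NB log-linear model
with trend-shrunk dispersions and a Wald test on the library coefficient.
Requiring agreement of both constructions is the method's guard against the
idiosyncrasies of either.

Counts are normalized by median-of-ratios size factors shared by both tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma
from scipy.stats import norm

from .stats_base import bh_adjust
from .tagbuilder import CountMatrix, MSDTag

DIRECTIONS = ("MspI_over_HpaII", "HpaII_over_MspI")
SCOPES = ("tissue_total", "tissue_mean", "per_replicate")

_PHI_GRID = np.logspace(-6, 1, 57)


@dataclass
class CallerParams:
    fdr_max: float = 0.05
    min_log2_fold_change: float = 1.0  # FC >= 2
    min_count: int = 3
    min_count_scope: str = "tissue_total"
    direction: str = "MspI_over_HpaII"
    require_no_missing_across_tissues: bool = True

    def validate(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if self.min_count_scope not in SCOPES:
            raise ValueError(f"min_count_scope must be one of {SCOPES}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass
class MethylationCall:
    tag_id: str
    site_id: str
    tissue: str
    mean_norm_mspi: float
    mean_norm_hpaii: float
    log2_fold_change: float
    p_exact: float
    p_glm: float
    fdr_exact: float
    fdr_glm: float
    status: str  # methylated | not_methylated | reverse_significant | filtered_*


@dataclass
class GridEvalRow:
    fdr_threshold: float
    fc_threshold: float
    min_count: int
    n_called: int
    n_covered_by_wgbs: int
    n_confirmed: int

    @property
    def validation_rate(self) -> Optional[float]:
        if self.n_covered_by_wgbs == 0:
            return None
        return self.n_confirmed / self.n_covered_by_wgbs


def _frame(counts) -> pd.DataFrame:
    return counts.data if isinstance(counts, CountMatrix) else counts


def _library_cols(df: pd.DataFrame, tissue: str, library: str) -> list:
    return [c for c in df.columns if c[0] == tissue and c[2] == library]


# ---------------------------------------------------------------------------
# filtering


def filter_tags(counts, params: CallerParams):
    """Apply the no-missing-across-tissues and minimum-count filters.

    Returns (filtered counts, status map tag_id -> status) where status is
    'pass', 'filtered_missing' or 'filtered_min_count'.
    """
    params.validate()
    df = _frame(counts)
    tissues = list(dict.fromkeys(df.columns.get_level_values(0)))
    status = pd.Series("pass", index=df.index, dtype=object)
    for tissue in tissues:
        mspi = df[_library_cols(df, tissue, "MspI")]
        if params.require_no_missing_across_tissues:
            status[(mspi.sum(axis=1) == 0) & (status == "pass")] = "filtered_missing"
        if params.min_count_scope == "tissue_total":
            evidence = mspi.sum(axis=1)
        elif params.min_count_scope == "tissue_mean":
            evidence = mspi.mean(axis=1)
        else:
            evidence = mspi.min(axis=1)
        status[(evidence < params.min_count) & (status == "pass")] = "filtered_min_count"
    keep = status[status == "pass"].index
    out = df.loc[keep]
    if isinstance(counts, CountMatrix):
        out = CountMatrix(out, overlap_corrected=counts.overlap_corrected,
                          spill=counts.spill)
    return out, dict(status)


# ---------------------------------------------------------------------------
# normalization


def estimate_normalization(counts, method: str = "median_of_ratios") -> pd.Series:
    """Per-column normalization factors, scaled to geometric mean 1.

    Default is median-of-ratios to the per-tag geometric mean over columns,
    computed on tags with no zero anywhere.  ``method="tmm"`` gives a trimmed
    mean of log-ratios against the first column.  When no zero-free tag
    exists, falls back to total-count scaling with a warning.
    """
    df = _frame(counts)
    y = df.values.astype(float)
    if method == "median_of_ratios":
        zero_free = (y > 0).all(axis=1)
        if not zero_free.any():
            warnings.warn("no zero-free tag; falling back to total-count scaling")
            totals = y.sum(axis=0)
            ok = totals > 0
            factors = np.ones_like(totals, dtype=float)
            if ok.any():
                factors[ok] = totals[ok] / np.exp(np.mean(np.log(totals[ok])))
            return pd.Series(factors, index=df.columns)
        sub = y[zero_free]
        log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(sub) - log_geomean, axis=0))
    elif method == "tmm":
        ref = y[:, 0]
        factors = np.empty(y.shape[1])
        for j in range(y.shape[1]):
            col = y[:, j]
            ok = (col > 0) & (ref > 0)
            m = np.log2(col[ok] / col[ok].sum()) - np.log2(ref[ok] / ref[ok].sum())
            a = 0.5 * (np.log2(col[ok] / col[ok].sum()) + np.log2(ref[ok] / ref[ok].sum()))
            lo_m, hi_m = np.quantile(m, [0.30, 0.70])
            lo_a, hi_a = np.quantile(a, [0.05, 0.95])
            keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
            tmm = m[keep].mean() if keep.any() else 0.0
            factors[j] = 2.0 ** tmm * col.sum() / ref.sum()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=df.columns)


# ---------------------------------------------------------------------------
# test A: exact conditional NB test with qCML-style shrinkage


def _group_cl(y: np.ndarray, phi: float) -> np.ndarray:
    """Conditional log-likelihood of dispersion for one group (tags x reps)."""
    n = y.shape[1]
    r = 1.0 / phi
    z = y.sum(axis=1)
    return (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )


def exact_nb_pvalue(z_a: int, z_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Exact conditional NB p-value (two-sided, doubled smaller tail).

    Group sums are NB with sizes n_a/phi and n_b/phi; conditioning on the
    total makes the mean cancel, leaving a negative-hypergeometric-type
    distribution over the split.  As phi -> 0 this converges to the binomial
    split Bin(z, n_a/(n_a+n_b)).
    """
    z = z_a + z_b
    if z == 0:
        return 1.0
    r_a, r_b = n_a / phi, n_b / phi
    k = np.arange(z + 1)
    lp = (
        gammaln(k + r_a) - gammaln(k + 1)
        + gammaln(z - k + r_b) - gammaln(z - k + 1)
    )
    lp -= lp.max()
    pk = np.exp(lp)
    pk /= pk.sum()
    p_low = pk[: z_a + 1].sum()
    p_high = pk[z_a:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def test_exact(
    counts,
    factors: pd.Series,
    tissue: str,
    prior_df: float = 10.0,
    phi_grid: np.ndarray = _PHI_GRID,
) -> pd.DataFrame:
    """Exact conditional NB test of MspI vs HpaII counts for one tissue.

    Dispersion is estimated per tag by conditional maximum likelihood on
    size-factor-equalized pseudo-counts, shrunk toward the common dispersion
    with weight prior_df / residual df.  Returns a DataFrame with columns
    ``p`` and ``dispersion`` indexed by tag.
    """
    df = _frame(counts)
    cols_a = _library_cols(df, tissue, "MspI")
    cols_b = _library_cols(df, tissue, "HpaII")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"need >= 2 replicates per library in tissue {tissue!r}")
    ya = df[cols_a].values / factors[cols_a].values
    yb = df[cols_b].values / factors[cols_b].values
    ya_r = np.round(ya)
    yb_r = np.round(yb)
    n_a, n_b = ya.shape[1], yb.shape[1]
    # dispersion profile over the grid, vectorised across tags
    cl = np.empty((df.shape[0], phi_grid.size))
    for j, phi in enumerate(phi_grid):
        cl[:, j] = _group_cl(ya_r, phi) + _group_cl(yb_r, phi)
    common_idx = int(np.argmax(cl.sum(axis=0)))
    df_tag = (n_a - 1) + (n_b - 1)
    weight = prior_df / max(df_tag, 1)
    shared = cl.mean(axis=0)
    obj = cl + weight * shared[None, :]
    phi_tag = phi_grid[np.argmax(obj, axis=1)]
    z_a = ya_r.sum(axis=1).astype(np.int64)
    z_b = yb_r.sum(axis=1).astype(np.int64)
    pvals = np.ones(df.shape[0])
    for i in range(df.shape[0]):
        pvals[i] = exact_nb_pvalue(int(z_a[i]), int(z_b[i]), n_a, n_b, float(phi_tag[i]))
    return pd.DataFrame(
        {"p": pvals, "dispersion": phi_tag},
        index=df.index,
    ).assign(common_dispersion=phi_grid[common_idx])


# ---------------------------------------------------------------------------
# test B: NB log-linear model, trend-shrunk dispersion, Wald test


def _fit_group_means(y: np.ndarray, s: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """MLE of the per-tag group mean under NB(mu = s_j * m, phi); Newton on log m.

    ``y``: (tags x reps); ``s``: size factors (reps,); ``phi``: (tags,).
    Group sums of zero are floored at half a read of total evidence so the
    log fold change stays finite.
    """
    s = s[None, :]
    floor = np.log(0.5 / s.sum())
    m = np.maximum(np.mean(y / s, axis=1), 0.5 / s.sum())
    beta = np.log(m)
    phi = phi[:, None]
    for _ in range(30):
        mu = s * np.exp(beta)[:, None]
        w = 1.0 + phi * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-10)
        step = np.clip(step, -3, 3)
        beta = np.maximum(beta + step, floor)
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(beta)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    phi = phi[:, None]
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + y * np.log(phi * mu / (1 + phi * mu))
        - r * np.log1p(phi * mu)
    ).sum(axis=1)


def _profile_loglik(ya, sa, yb, sb, phi_vec_per_tag):
    ma = _fit_group_means(ya, sa, phi_vec_per_tag)
    mb = _fit_group_means(yb, sb, phi_vec_per_tag)
    mua = sa[None, :] * ma[:, None]
    mub = sb[None, :] * mb[:, None]
    ll = _nb_loglik(ya, mua, phi_vec_per_tag) + _nb_loglik(yb, mub, phi_vec_per_tag)
    return ll, ma, mb


def test_glm(
    counts,
    factors: pd.Series,
    tissue: str,
    phi_grid: np.ndarray = _PHI_GRID,
    min_trend_tags: int = 50,
) -> pd.DataFrame:
    """NB log-linear Wald test of the library effect for one tissue.

    Per-tag dispersion is the profile MLE, shrunk log-normally toward a
    parametric mean-dispersion trend alpha(mu) = a0 + a1/mu fitted across
    tags; the Wald statistic uses the observed-information standard error of
    the fitted log fold change.  Returns columns ``p``, ``log2fc``,
    ``dispersion``, ``mean_mspi``, ``mean_hpaii``.
    """
    df = _frame(counts)
    cols_a = _library_cols(df, tissue, "MspI")
    cols_b = _library_cols(df, tissue, "HpaII")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"need >= 2 replicates per library in tissue {tissue!r}")
    ya = df[cols_a].values.astype(float)
    yb = df[cols_b].values.astype(float)
    sa = factors[cols_a].values
    sb = factors[cols_b].values
    g = df.shape[0]
    # profile dispersion MLE over the grid
    ll = np.empty((g, phi_grid.size))
    for j, phi in enumerate(phi_grid):
        phi_vec = np.full(g, phi)
        ll[:, j], _, _ = _profile_loglik(ya, sa, yb, sb, phi_vec)
    phi_mle = phi_grid[np.argmax(ll, axis=1)]
    base_mean = 0.5 * (np.mean(ya / sa[None, :], axis=1)
                       + np.mean(yb / sb[None, :], axis=1))
    # parametric trend alpha(mu) = a0 + a1/mu, least squares on informative tags
    ok = (base_mean > 0.5) & (phi_mle > phi_grid[0])
    if ok.sum() >= min_trend_tags:
        x = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(x, phi_mle[ok], rcond=None)
        a0 = max(coef[0], 1e-6)
        a1 = max(coef[1], 0.0)
        phi_trend = a0 + a1 / np.maximum(base_mean, 1e-6)
    else:
        if g >= min_trend_tags:
            warnings.warn("mean-dispersion trend fit failed; using tag-wise MLE")
        phi_trend = np.maximum(phi_mle, 1e-4)
    # log-normal shrinkage toward the trend
    n_res = (ya.shape[1] - 1) + (yb.shape[1] - 1)
    log_res = np.log(np.maximum(phi_mle, phi_grid[0])) - np.log(np.maximum(phi_trend, 1e-8))
    sampling_var = float(polygamma(1, max(n_res, 1) / 2.0))
    prior_var = max(np.var(log_res) - sampling_var, 0.25)
    log_grid = np.log(phi_grid)
    penalty = (log_grid[None, :] - np.log(np.maximum(phi_trend, 1e-8))[:, None]) ** 2 / (
        2.0 * prior_var
    )
    phi_map = phi_grid[np.argmax(ll - penalty, axis=1)]
    # final fit and Wald test at the MAP dispersion
    _, ma, mb = _profile_loglik(ya, sa, yb, sb, phi_map)
    mua = sa[None, :] * ma[:, None]
    mub = sb[None, :] * mb[:, None]
    info_a = (mua / (1 + phi_map[:, None] * mua)).sum(axis=1)
    info_b = (mub / (1 + phi_map[:, None] * mub)).sum(axis=1)
    se = np.sqrt(1.0 / np.maximum(info_a, 1e-10) + 1.0 / np.maximum(info_b, 1e-10))
    log2fc = np.log2(ma / mb)
    zstat = (np.log(ma) - np.log(mb)) / se
    p = 2.0 * norm.sf(np.abs(zstat))
    return pd.DataFrame(
        {
            "p": np.minimum(p, 1.0),
            "log2fc": log2fc,
            "dispersion": phi_map,
            "mean_mspi": ma,
            "mean_hpaii": mb,
        },
        index=df.index,
    )


# ---------------------------------------------------------------------------
# calling


def call_methylation(
    counts,
    params: CallerParams,
    tissue: str,
    factors: Optional[pd.Series] = None,
    tag_site: Optional[dict[str, str]] = None,
) -> list[MethylationCall]:
    """Run both NB tests on a filtered matrix and call per-tag status.

    BH correction is applied separately per test over the tested tags within
    the tissue.  A tag is ``methylated`` iff both FDRs are <= fdr_max and
    the log2 fold change meets the threshold in the configured direction;
    under ``direction="HpaII_over_MspI"`` passing tags are labelled
    ``reverse_significant``.
    """
    params.validate()
    df = _frame(counts)
    if factors is None:
        factors = estimate_normalization(df)
    res_exact = test_exact(df, factors, tissue)
    res_glm = test_glm(df, factors, tissue)
    fdr_exact = bh_adjust(res_exact["p"].values)
    fdr_glm = bh_adjust(res_glm["p"].values)
    sign = 1.0 if params.direction == "MspI_over_HpaII" else -1.0
    pass_label = "methylated" if sign > 0 else "reverse_significant"
    calls = []
    for i, tag_id in enumerate(df.index):
        lfc = res_glm["log2fc"].iloc[i]
        passed = (
            fdr_exact[i] <= params.fdr_max
            and fdr_glm[i] <= params.fdr_max
            and sign * lfc >= params.min_log2_fold_change
        )
        calls.append(
            MethylationCall(
                tag_id=tag_id,
                site_id=tag_site.get(tag_id, "") if tag_site else "",
                tissue=tissue,
                mean_norm_mspi=float(res_glm["mean_mspi"].iloc[i]),
                mean_norm_hpaii=float(res_glm["mean_hpaii"].iloc[i]),
                log2_fold_change=float(lfc),
                p_exact=float(res_exact["p"].iloc[i]),
                p_glm=float(res_glm["p"].iloc[i]),
                fdr_exact=float(fdr_exact[i]),
                fdr_glm=float(fdr_glm[i]),
                status=pass_label if passed else "not_methylated",
            )
        )
    return calls


def calls_to_frame(calls: list[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


def methylated_sites(calls: list[MethylationCall], rule: str = "any") -> set[str]:
    """Aggregate tag-level calls to site-level status.

    ``any``: a site is methylated if any associated tag is called; ``all``:
    every tested tag of the site must be called.
    """
    by_site: dict[str, list[bool]] = {}
    for c in calls:
        if not c.site_id:
            continue
        by_site.setdefault(c.site_id, []).append(
            c.status in ("methylated", "reverse_significant")
        )
    if rule == "any":
        return {s for s, flags in by_site.items() if any(flags)}
    if rule == "all":
        return {s for s, flags in by_site.items() if all(flags)}
    raise ValueError("rule must be 'any' or 'all'")


def evaluate_parameter_grid(
    counts,
    tags: list[MSDTag],
    wgbs_states: dict[str, str],
    tissue: str,
    fdr_values=(0.05, 0.01, 0.001),
    fc_values=(1.0, 2.0),
    min_count_values=(3, 5, 10),
    tolerance: float = 0.01,
):
    """Evaluate every (FDR, FC, min-count) combination against WGBS states.

    ``wgbs_states`` maps site_id -> state (fully_methylated / hemi_plus /
    hemi_minus / unmethylated / not_assessable).  Selection: among rows whose
    validation rate is within ``tolerance`` of the best, pick the largest
    number of called sites; ties broken by stricter FDR.  Returns
    (rows, selected CallerParams or None).
    """
    tag_site = {t.tag_id: t.msd_site_id for t in tags}
    confirmed_states = {"fully_methylated", "hemi_plus", "hemi_minus"}
    rows: list[GridEvalRow] = []
    for mc in min_count_values:
        base = CallerParams(min_count=mc)
        filtered, _ = filter_tags(counts, base)
        fdf = _frame(filtered)
        if fdf.shape[0] == 0:
            for fdr in fdr_values:
                for fc in fc_values:
                    rows.append(GridEvalRow(fdr, fc, mc, 0, 0, 0))
            continue
        factors = estimate_normalization(fdf)
        res_exact = test_exact(fdf, factors, tissue)
        res_glm = test_glm(fdf, factors, tissue)
        q_exact = bh_adjust(res_exact["p"].values)
        q_glm = bh_adjust(res_glm["p"].values)
        lfc = res_glm["log2fc"].values
        for fdr in fdr_values:
            for fc in fc_values:
                hit = (q_exact <= fdr) & (q_glm <= fdr) & (lfc >= np.log2(fc))
                sites_called = {
                    tag_site[t] for t in fdf.index[hit] if t in tag_site
                }
                covered = {
                    s for s in sites_called
                    if wgbs_states.get(s, "not_assessable") != "not_assessable"
                }
                confirmed = {
                    s for s in covered if wgbs_states.get(s) in confirmed_states
                }
                rows.append(
                    GridEvalRow(fdr, fc, mc, len(sites_called),
                                len(covered), len(confirmed))
                )
    rates = [r.validation_rate for r in rows if r.validation_rate is not None]
    if not rates:
        return rows, None
    best = max(rates)
    candidates = [
        r for r in rows
        if r.validation_rate is not None and r.validation_rate >= best - tolerance
    ]
    selected = sorted(
        candidates, key=lambda r: (-r.n_called, r.fdr_threshold)
    )[0]
    params = CallerParams(
        fdr_max=selected.fdr_threshold,
        min_log2_fold_change=float(np.log2(selected.fc_threshold)),
        min_count=selected.min_count,
    )
    return rows, params
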