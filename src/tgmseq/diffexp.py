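"""Two-condition differential expression with a negative-binomial exact test.

The statistics follow the original DESeq formulation: median-of-ratios
size factors; method-of-moments per-region dispersions with a fitted
mean-dispersion function alpha(mu) = a0 + a1/mu, taking the conservative
maximum of empirical and fitted values; and the conditional NB exact
test, which conditions on the total count K = kA + kB of a region and
sums the probabilities of all splits (a, K-a) no more likely than the
observed one.  Benjamini-Hochberg adjustment and the padj < 0.05 call
are applied within each analysis scope (gene regions and intergenic
windows separately).

The NB parameterization throughout is variance = mu + alpha * mu^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotate import ROLE_WINDOW, RegionCatalog

logger = logging.getLogger(__name__)

#: relative tolerance when comparing split probabilities to the observed one
_TIE_REL_TOL = 1e-7
#: total K above which the split enumeration is pruned outward from the mode
_PRUNE_K = 10_000
_PRUNE_TAIL = 1e-12


@dataclass
class NormalizationResult:
    size_factors: pd.Series          # per sample, positive
    geometric_means: pd.Series       # the reference pseudo-sample

    def normalized(self, counts: pd.DataFrame) -> pd.DataFrame:
        return counts / self.size_factors


@dataclass
class DispersionModel:
    empirical: pd.Series             # per-region method-of-moments alpha
    fit_coefficients: tuple[float, float]   # (a0, a1) in alpha(mu) = a0 + a1/mu
    fitted: pd.Series
    final: pd.Series                 # fitted (default) or max(empirical, fitted), >= floor
    floor: float
    sharing: str = "fit-only"

    def alpha_at(self, mu: np.ndarray | float) -> np.ndarray | float:
        a0, a1 = self.fit_coefficients
        return np.maximum(a0 + a1 / np.maximum(mu, 1e-300), self.floor)


@dataclass
class DEConfig:
    padj_cutoff: float = 0.05
    pseudocount: float = 1.0
    dispersion_floor: float = 1e-8
    dispersion_sharing: str = "fit-only"     # fit-only | maximum
    fit_mean_floor: float = 5.0              # min normalized mean entering the dispersion fit
    independent_filter: bool = True
    scope: str = "both-separately"   # genes | intergenic | both-separately
    reference_condition: str | None = None   # default: first in sample-sheet order

    def __post_init__(self) -> None:
        if not (0 < self.padj_cutoff < 1):
            raise ValueError("padj_cutoff must lie in (0, 1)")
        if self.scope not in ("genes", "intergenic", "both-separately"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.dispersion_sharing not in ("fit-only", "maximum"):
            raise ValueError(f"unknown dispersion_sharing {self.dispersion_sharing!r}")


def size_factors(count_matrix: pd.DataFrame) -> NormalizationResult:
    """Median-of-ratios normalization.

    s_j = median over regions i (with all-positive counts) of
    k_ij / geometric-mean_v(k_iv).  If no region is positive in every
    sample, the median for each sample falls back to the regions
    positive in that sample, with a warning.
    """
    k = count_matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    log_geo = logk.mean(axis=1)              # -inf for any row with a zero
    usable = np.isfinite(log_geo)
    geo = pd.Series(np.exp(log_geo), index=count_matrix.index)
    if usable.any():
        ratios = np.exp(logk[usable] - log_geo[usable, None])
        s = np.median(ratios, axis=0)
    else:
        logger.warning("no region with all-positive counts; per-sample fallback median-of-ratios")
        s = np.empty(k.shape[1])
        for j in range(k.shape[1]):
            pos = k[:, j] > 0
            if not pos.any():
                raise ValueError(f"sample {count_matrix.columns[j]} has no positive counts")
            # reference: geometric mean over samples positive in that row
            ref = np.exp(np.where(np.isfinite(logk[pos]), logk[pos], np.nan).mean(axis=1))
            s[j] = np.median(k[pos, j] / ref)
    sf = pd.Series(s, index=count_matrix.columns, name="size_factor")
    if (sf <= 0).any():
        raise ValueError("non-positive size factor estimated")
    return NormalizationResult(size_factors=sf, geometric_means=geo)


def estimate_dispersions(
    count_matrix: pd.DataFrame,
    normalization: NormalizationResult,
    sample_sheet,
    floor: float = 1e-8,
    fit_mean_floor: float = 5.0,
    sharing: str = "fit-only",
) -> DispersionModel:
    """Method-of-moments dispersions with a parametric a0 + a1/mu fit.

    Per region: alpha_i = max(0, (v_i - mu_i * xi) / mu_i^2), where v_i
    is the within-condition sample variance of normalized counts pooled
    across conditions, mu_i the overall normalized mean, and
    xi = mean_j(1/s_j) accounts for the shot-noise contribution of
    count sampling.  The curve alpha(mu) = a0 + a1/mu is fit by least
    squares over regions with mu >= ``fit_mean_floor``: below a few
    normalized counts the moment estimator is clipped noise, and its
    extreme 1/mu leverage would otherwise dominate the fit.

    ``sharing`` selects the final per-region value: ``fit-only`` (the
    fitted curve, as in the method's original formulation) or
    ``maximum`` (max of empirical and fitted, the conservative variant).
    With two replicates per condition the per-region estimate has a
    single degree of freedom per condition, so ``maximum`` trades a
    large loss of power for robustness to dispersion outliers.
    """
    if sharing not in ("fit-only", "maximum"):
        raise ValueError(f"unknown sharing mode {sharing!r}")
    s = normalization.size_factors
    q = count_matrix / s                      # normalized counts
    mu = q.mean(axis=1)
    xi = float((1.0 / s).mean())

    # pooled within-condition variance: average per-condition sample variances
    per_cond_var = []
    weights = []
    for cond in sample_sheet.conditions:
        cols = sample_sheet.samples_of(cond)
        if len(cols) >= 2:
            per_cond_var.append(q[cols].var(axis=1, ddof=1))
            weights.append(len(cols) - 1)
    if not per_cond_var:
        raise ValueError("dispersion estimation needs >=2 replicates in at least one condition")
    v = sum(w * pv for w, pv in zip(weights, per_cond_var)) / sum(weights)

    with np.errstate(divide="ignore", invalid="ignore"):
        emp = ((v - mu * xi) / mu**2).clip(lower=0.0)
    emp = emp.fillna(0.0)
    emp[mu == 0] = 0.0

    ok = mu >= fit_mean_floor
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(int(ok.sum())), 1.0 / mu[ok].to_numpy()])
        coef, *_ = np.linalg.lstsq(X, emp[ok].to_numpy(), rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        logger.warning("too few regions above fit_mean_floor=%g; dispersion fit degenerate", fit_mean_floor)
        a0, a1 = float(emp[mu > 0].mean()) if (mu > 0).any() else 0.0, 0.0
    with np.errstate(divide="ignore"):
        fitted = pd.Series(a0 + a1 / mu.to_numpy(), index=mu.index).clip(lower=floor)
    fitted[mu == 0] = floor

    if sharing == "maximum":
        final = pd.concat([emp, fitted], axis=1).max(axis=1).clip(lower=floor)
    else:
        final = fitted.copy()
    return DispersionModel(
        empirical=emp, fit_coefficients=(a0, a1), fitted=fitted, final=final,
        floor=floor, sharing=sharing,
    )


def _sum_logpmf(counts: np.ndarray, mu: float, var: float) -> np.ndarray:
    """log pmf of a condition-sum with given mean and variance (NB, Poisson limit)."""
    if var <= mu * (1 + 1e-12):
        return stats.poisson.logpmf(counts, mu)
    r = mu * mu / (var - mu)
    p = mu / var
    return stats.nbinom.logpmf(counts, r, p)


def _enumerate_pvalue(kA: int, K: int, muA: float, varA: float, muB: float, varB: float) -> tuple[float, float]:
    """(p-value of the observed split, smallest achievable p-value at this K)."""
    a = np.arange(K + 1)
    logp = _sum_logpmf(a, muA, varA) + _sum_logpmf(K - a, muB, varB)
    w = np.exp(logp - logp.max())
    total = w.sum()
    obs = w[kA]
    p = float(min(1.0, w[w <= obs * (1 + _TIE_REL_TOL)].sum() / total))
    wmin = w.min()
    p_min = float(min(1.0, w[w <= wmin * (1 + _TIE_REL_TOL)].sum() / total))
    return p, p_min


def min_achievable_pvalue(kA, kB, size_factors_a, size_factors_b, dispersion: float) -> float:
    """Smallest conditional p-value any split of this region's total could attain.

    The exact test conditions on the total K, so K (and with it this
    bound) is independent of the p-value under the null — making it a
    valid independent-filtering statistic: regions whose most extreme
    split cannot reach significance carry no information and only
    inflate the multiple-testing burden.
    """
    sa = np.asarray(size_factors_a, dtype=float)
    sb = np.asarray(size_factors_b, dtype=float)
    K = int(kA) + int(kB)
    if K == 0:
        return 1.0
    SA, SB = sa.sum(), sb.sum()
    q = K / (SA + SB)
    muA, muB = SA * q, SB * q
    varA = muA + dispersion * q * q * float((sa * sa).sum())
    varB = muB + dispersion * q * q * float((sb * sb).sum())
    if K > _PRUNE_K:
        return 0.0   # huge totals can always reach significance
    return _enumerate_pvalue(int(kA), K, muA, varA, muB, varB)[1]


def nb_exact_test(
    kA: int,
    kB: int,
    size_factors_a,
    size_factors_b,
    dispersion: float,
) -> float:
    """Conditional NB exact test for one region.

    With K = kA + kB and the pooled normalized mean under the null
    q = K / (S_A + S_B) (S_c the summed size factors of condition c),
    each condition-sum is NB with mean S_c * q and variance
    S_c * q + dispersion * q^2 * sum_j(s_j^2).  The p-value is the
    conditional probability mass of all splits (a, K - a) whose
    probability does not exceed that of the observed split.  Dispersion
    zero is the Poisson limit; K = 0 yields p = 1 by convention.
    """
    sa = np.asarray(size_factors_a, dtype=float)
    sb = np.asarray(size_factors_b, dtype=float)
    K = int(kA) + int(kB)
    if K == 0:
        return 1.0
    SA, SB = sa.sum(), sb.sum()
    q = K / (SA + SB)
    muA, muB = SA * q, SB * q
    varA = muA + dispersion * q * q * float((sa * sa).sum())
    varB = muB + dispersion * q * q * float((sb * sb).sum())

    if K <= _PRUNE_K:
        return _enumerate_pvalue(int(kA), K, muA, varA, muB, varB)[0]

    # large K: expand outward from the mode until the remaining tails are negligible
    mode = int(round(K * SA / (SA + SB)))
    chunk = 1024
    pieces: list[tuple[np.ndarray, np.ndarray]] = []
    lo, hi = mode, mode
    ref = _sum_logpmf(np.array([mode]), muA, varA)[0] + _sum_logpmf(np.array([K - mode]), muB, varB)[0]

    def block(a_lo: int, a_hi: int) -> tuple[np.ndarray, np.ndarray]:
        a = np.arange(a_lo, a_hi + 1)
        lp = _sum_logpmf(a, muA, varA) + _sum_logpmf(K - a, muB, varB)
        return a, np.exp(lp - ref)

    a0, w0 = block(max(0, mode - chunk), min(K, mode + chunk))
    pieces.append((a0, w0))
    lo, hi = int(a0[0]), int(a0[-1])
    total = float(w0.sum())
    while lo > 0:
        nlo = max(0, lo - chunk)
        a_, w_ = block(nlo, lo - 1)
        pieces.append((a_, w_))
        total += float(w_.sum())
        lo = nlo
        if w_.sum() < _PRUNE_TAIL * total and w_[0] < w_[-1]:
            break
    while hi < K:
        nhi = min(K, hi + chunk)
        a_, w_ = block(hi + 1, nhi)
        pieces.append((a_, w_))
        total += float(w_.sum())
        hi = nhi
        if w_.sum() < _PRUNE_TAIL * total and w_[-1] < w_[0]:
            break
    kA = int(kA)
    if lo <= kA <= hi:
        obs = float(np.exp(
            _sum_logpmf(np.array([kA]), muA, varA)[0]
            + _sum_logpmf(np.array([K - kA]), muB, varB)[0]
            - ref
        ))
    else:
        obs = 0.0  # observed split beyond the pruned range: deeper than any kept tail
    acc = 0.0
    for a_, w_ in pieces:
        acc += float(w_[w_ <= obs * (1 + _TIE_REL_TOL)].sum())
    if obs == 0.0:
        acc += 0.0  # pruned tails are below the observed probability by construction
    return float(min(1.0, acc / total)) if obs > 0 else float(min(1.0, _PRUNE_TAIL))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, NaN-tolerant, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def run_de(
    count_matrix: pd.DataFrame,
    sample_sheet,
    catalog: RegionCatalog,
    config: DEConfig | None = None,
) -> pd.DataFrame:
    """Full differential expression table, one row per catalog region.

    Size factors and dispersions are estimated once on the full matrix;
    the exact test runs per region, and BH adjustment plus the
    significance call are applied within each scope (gene regions and
    intergenic windows) separately.  Fold changes are
    (mean_mutant + c) / (mean_reference + c) of normalized condition
    means with pseudocount c, so de-repression from zero stays finite;
    regions with zero counts everywhere are reported with p = 1 and an
    undefined (NaN) fold change.
    """
    cfg = config or DEConfig()
    conds = sample_sheet.conditions
    if len(conds) != 2:
        raise ValueError(f"differential expression needs exactly two conditions, got {conds}")
    ref = cfg.reference_condition or conds[0]
    if ref not in conds:
        raise ValueError(f"reference condition {ref!r} not in sample sheet")
    alt = conds[0] if conds[1] == ref else conds[1]

    cat = catalog.to_frame()
    counts = count_matrix.loc[cat.index]

    norm = size_factors(counts)
    disp = estimate_dispersions(
        counts, norm, sample_sheet,
        floor=cfg.dispersion_floor,
        fit_mean_floor=cfg.fit_mean_floor,
        sharing=cfg.dispersion_sharing,
    )
    q = norm.normalized(counts)

    cols_a = sample_sheet.samples_of(ref)
    cols_b = sample_sheet.samples_of(alt)
    sf_a = norm.size_factors[cols_a].to_numpy()
    sf_b = norm.size_factors[cols_b].to_numpy()
    kA = counts[cols_a].sum(axis=1).to_numpy()
    kB = counts[cols_b].sum(axis=1).to_numpy()

    mean_a = q[cols_a].mean(axis=1)
    mean_b = q[cols_b].mean(axis=1)
    c = cfg.pseudocount
    fold = (mean_b + c) / (mean_a + c)
    all_zero = (kA + kB) == 0
    fold[all_zero] = np.nan

    pvals = np.empty(len(kA))
    pmins = np.empty(len(kA))
    for i, (a, b, d) in enumerate(zip(kA, kB, disp.final.to_numpy())):
        pvals[i] = nb_exact_test(a, b, sf_a, sf_b, d)
        pmins[i] = min_achievable_pvalue(a, b, sf_a, sf_b, d)

    res = pd.DataFrame(
        {
            "region_id": cat["id"],
            "role": cat["role"],
            "baseMean": q.mean(axis=1),
            "meanA": mean_a,
            "meanB": mean_b,
            "foldChange": fold,
            "log2FC": np.log2(fold),
            "pval": pvals,
            "pmin": pmins,
            "dispersion": disp.final,
        },
        index=cat.index,
    )

    is_window = res["role"] == ROLE_WINDOW
    if cfg.scope == "genes":
        scopes = [~is_window]
    elif cfg.scope == "intergenic":
        scopes = [is_window]
    else:
        scopes = [~is_window, is_window]

    res["padj"] = np.nan
    res["tested"] = False
    for mask in scopes:
        tested = _apply_scope_adjustment(res, mask, kA + kB, cfg)
        res.loc[tested.index, "padj"] = tested["padj"]
        res.loc[tested.index, "tested"] = True
    res["significant"] = res["padj"] < cfg.padj_cutoff
    res["direction"] = np.where(res["foldChange"] > 1, "up", "down")
    res.loc[res["foldChange"].isna(), "direction"] = "na"
    res.attrs["reference_condition"] = ref
    res.attrs["test_condition"] = alt
    res.attrs["size_factors"] = norm.size_factors.to_dict()
    return res


def _apply_scope_adjustment(res: pd.DataFrame, mask, totals: np.ndarray, cfg: DEConfig) -> pd.DataFrame:
    """BH within one scope, after independent filtering on the region total.

    Regions whose smallest achievable p-value is above the cutoff are
    never testable and are removed first.  When ``independent_filter``
    is set, a grid of thresholds on the total count K (the statistic
    the exact test conditions on, hence independent of p under the
    null) is scanned and the threshold maximizing the number of
    discoveries at the padj cutoff is kept — the standard
    independent-filtering procedure.  Filtered regions keep their raw
    p-value but receive no padj.
    """
    scope = res.loc[np.asarray(mask)].copy()
    scope["total"] = totals[np.asarray(mask)]
    scope = scope[scope["pmin"] < cfg.padj_cutoff]
    if scope.empty:
        return scope.assign(padj=np.nan)
    if not cfg.independent_filter:
        scope["padj"] = bh_adjust(scope["pval"])
        return scope
    quantiles = np.unique(np.quantile(scope["total"], np.linspace(0.0, 0.9, 10)))
    best_thr, best_rej = None, -1
    for thr in quantiles:
        kept = scope[scope["total"] >= thr]
        rej = int((bh_adjust(kept["pval"]) < cfg.padj_cutoff).sum())
        if rej > best_rej:
            best_thr, best_rej = thr, rej
    kept = scope[scope["total"] >= best_thr].copy()
    kept["padj"] = bh_adjust(kept["pval"])
    return kept


def write_de_table(res: pd.DataFrame, path) -> None:
    res.to_csv(path, sep="\t", index=False, float_format="%.6g")
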