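"""Monte-Carlo model comparison for single-cell allelic imbalance.

Three generative models are fit and tested against per-cell allelic count
tables:

* **coin-flip (binomial)** — every detected RNA's allelic origin is an
  independent Bernoulli draw at the pooled population ratio p_BL6; per
  cell, ``n_bl6 ~ Binomial(total, p_BL6)`` conditional on the observed
  total.
* **all-or-none (random monoallelic)** — every RNA in a cell shares one
  allelic identity, observed through per-allele false-detection noise at
  the rates measured in homozygous control tissue.
* **independent negative-binomial bursting** — each allele's count is an
  independent NB(r, p) draw; r and p come from the method of moments
  (p = mean/variance, r = mean^2/(variance - mean)), equivalently burst
  size (1-p)/p and burst frequency r.

Each test simulates the fitted model many times, computes the same
statistic (negative log-likelihood or Pearson correlation of the two
alleles) on every simulated dataset, and locates the observed statistic in
that Monte-Carlo null as an empirical percentile and an add-one-smoothed
two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .counts import validate_counts
from .synthetic import NegBinParams

__all__ = [
    "PopulationAllelicStats",
    "ModelTestResult",
    "population_stats",
    "binomial_nll",
    "coin_flip_test",
    "all_or_none_assign",
    "all_or_none_test",
    "fit_negbin_moments",
    "estimate_false_detection_rate",
    "bursting_fit_test",
    "paired_correlation_test",
    "burst_size_scan",
    "downsampling_robustness",
]


# --------------------------------------------------------------------------
# summary statistics
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationAllelicStats:
    """Pooled allelic ratio, per-allele moments and the allele correlation."""

    p_bl6_hat: float
    mean_bl6: float
    mean_jf1: float
    var_bl6: float
    var_jf1: float
    correlation: float
    n_cells: int


@dataclass
class ModelTestResult:
    """Observed statistic located in its Monte-Carlo null distribution."""

    model: str
    statistic: str  # "nll" or "correlation"
    observed: float
    null: np.ndarray
    percentile: float
    p_value: float
    n_sims: int
    rng_seed: int
    extra: dict = field(default_factory=dict)

    def rejects(self, central: float = 95.0) -> bool:
        """True when the observed statistic lies outside the central band."""
        half = (100.0 - central) / 2.0
        return self.percentile < half or self.percentile > 100.0 - half


def _locate(observed: float, null: np.ndarray) -> tuple[float, float]:
    """Empirical percentile and add-one two-sided p-value of obs in null."""
    n = len(null)
    below = float(np.sum(null <= observed))
    above = float(np.sum(null >= observed))
    percentile = 100.0 * below / n
    p = 2.0 * min((below + 1.0) / (n + 1.0), (above + 1.0) / (n + 1.0))
    return percentile, min(p, 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def population_stats(counts: pd.DataFrame, method: str = "pearson") -> PopulationAllelicStats:
    """Pooled BL6 fraction, per-allele moments and allele correlation.

    The pooled fraction p_bl6_hat = sum(n_bl6) / sum(n_bl6 + n_jf1) is the
    population allelic ratio every model conditions on.  Cells with zero
    assigned RNAs are kept in the moments but excluded from the
    correlation.
    """
    validate_counts(counts)
    if len(counts) < 2:
        raise ValueError("need at least 2 cells")
    b = counts["n_bl6"].to_numpy(dtype=float)
    j = counts["n_jf1"].to_numpy(dtype=float)
    pooled = b.sum() + j.sum()
    if pooled == 0:
        raise ValueError("pooled assigned count is zero")
    nz = (b + j) > 0
    if method == "pearson":
        corr = _pearson(b[nz], j[nz])
    elif method == "spearman":
        corr = float(stats.spearmanr(b[nz], j[nz]).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return PopulationAllelicStats(
        p_bl6_hat=float(b.sum() / pooled),
        mean_bl6=float(b.mean()),
        mean_jf1=float(j.mean()),
        var_bl6=float(b.var(ddof=1)),
        var_jf1=float(j.var(ddof=1)),
        correlation=corr,
        n_cells=len(counts),
    )


# --------------------------------------------------------------------------
# coin-flip (binomial) model
# --------------------------------------------------------------------------


def binomial_nll(counts: pd.DataFrame, p_bl6: float) -> float:
    """Negative log-likelihood of the counts under the shared-ratio binomial.

    NLL = -sum_j log Binom(n_bl6_j; n_bl6_j + n_jf1_j, p_bl6).  Cells with
    zero assigned RNAs contribute nothing.  At p in {0, 1}, incompatible
    counts give an infinite NLL.
    """
    b = counts["n_bl6"].to_numpy(dtype=np.int64)
    t = b + counts["n_jf1"].to_numpy(dtype=np.int64)
    return _binom_nll_arrays(b, t, p_bl6)


def _binom_nll_arrays(b, t, p) -> float:
    nz = t > 0
    if not np.any(nz):
        return 0.0
    with np.errstate(divide="ignore"):
        ll = stats.binom.logpmf(b[nz], t[nz], p)
    return float(-ll.sum())


def coin_flip_test(
    counts: pd.DataFrame,
    n_sims: int = 10_000,
    rng_seed: int = 0,
    p_bl6: float | None = None,
) -> ModelTestResult:
    """Monte-Carlo goodness of fit of the coin-flip binomial model.

    The pooled ratio p̂ is estimated from the data (or supplied); each
    simulation redraws every cell's BL6 count from Binomial(total_j, p̂)
    conditional on the observed per-cell totals, and the NLL at p̂ is
    recomputed.  Returns the observed NLL's percentile in that null.
    """
    st = population_stats(counts)
    p = st.p_bl6_hat if p_bl6 is None else p_bl6
    b = counts["n_bl6"].to_numpy(dtype=np.int64)
    t = b + counts["n_jf1"].to_numpy(dtype=np.int64)
    observed = _binom_nll_arrays(b, t, p)

    rng = stream(rng_seed, "coin_flip_test")
    nz = t > 0
    tt = t[nz]
    # one (n_sims, n_cells) block of conditional redraws; logpmf vectorizes
    sims = rng.binomial(tt, p, size=(n_sims, len(tt)))
    with np.errstate(divide="ignore"):
        null = -stats.binom.logpmf(sims, tt, p).sum(axis=1)
    percentile, pval = _locate(observed, null)
    return ModelTestResult(
        model="coin_flip",
        statistic="nll",
        observed=observed,
        null=null,
        percentile=percentile,
        p_value=pval,
        n_sims=n_sims,
        rng_seed=rng_seed,
        extra={"p_bl6_hat": p},
    )


# --------------------------------------------------------------------------
# all-or-none (random monoallelic) model
# --------------------------------------------------------------------------


def all_or_none_assign(counts: pd.DataFrame, rng_seed: int = 0) -> pd.DataFrame:
    """Idealize each cell to a single allelic identity by majority vote.

    All RNAs in a cell are reassigned to the cell's majority allele (a cell
    with 4 BL6 and 2 JF1 RNAs becomes 6 BL6, 0 JF1); exact ties are broken
    by a fair coin.  Per-cell totals are preserved.
    """
    validate_counts(counts)
    rng = stream(rng_seed, "all_or_none_assign")
    b = counts["n_bl6"].to_numpy(dtype=np.int64)
    j = counts["n_jf1"].to_numpy(dtype=np.int64)
    tot = b + j
    bl6_wins = np.where(b == j, rng.random(len(b)) < 0.5, b > j)
    out = counts.copy()
    out["n_bl6"] = np.where(bl6_wins, tot, 0)
    out["n_jf1"] = np.where(bl6_wins, 0, tot)
    return out


def _balanced_flip_quota(
    ideal_bl6: int, ideal_jf1: int, obs_bl6: int, fdr_bl6: float, fdr_jf1: float
) -> tuple[int, int]:
    """Flip counts (BL6->JF1, JF1->BL6) matching fdrs and the total constraint.

    The net flip balance is fixed by requiring the simulated population
    total of BL6 RNAs to equal the observed one; within that constraint the
    two directed flip counts stay as close as feasible to the expected
    counts implied by the homozygous false-detection rates.
    """
    net = ideal_bl6 - obs_bl6  # required net BL6 -> JF1 flips
    base_bj = fdr_bl6 * ideal_bl6
    base_jb = fdr_jf1 * ideal_jf1
    # shift both directed counts equally to meet the net constraint
    adjust = (net - (base_bj - base_jb)) / 2.0
    f_bj = int(round(base_bj + adjust))
    f_jb = f_bj - net
    if f_bj < 0:
        f_bj, f_jb = 0, -net
    if f_jb < 0:
        f_bj, f_jb = net, 0
    if f_bj < 0 or f_jb < 0 or f_bj > ideal_bl6 or f_jb > ideal_jf1:
        raise ValueError(
            "population-total constraint incompatible with the supplied "
            "false-detection rates and idealized totals"
        )
    return f_bj, f_jb


def _two_pop_nll(
    b: np.ndarray,
    j: np.ndarray,
    bl6_cell: np.ndarray,
    fdr_bl6: float,
    fdr_jf1: float,
) -> float:
    """Two-subpopulation binomial NLL of the all-or-none model.

    Cells grouped by (idealized) allelic identity; within each group the
    minority-allele count is modeled Binomial(cell total, homozygous
    false-detection rate of that group).
    """
    tot = b + j
    nz = tot > 0
    mask_b = bl6_cell & nz
    mask_j = (~bl6_cell) & nz
    nll = 0.0
    with np.errstate(divide="ignore"):
        if mask_b.any():
            nll -= stats.binom.logpmf(j[mask_b], tot[mask_b], fdr_bl6).sum()
        if mask_j.any():
            nll -= stats.binom.logpmf(b[mask_j], tot[mask_j], fdr_jf1).sum()
    return float(nll)


def all_or_none_test(
    counts: pd.DataFrame,
    fdr_bl6: float,
    fdr_jf1: float,
    n_sims: int = 10_000,
    rng_seed: int = 0,
) -> ModelTestResult:
    """Monte-Carlo test of the all-or-none model with technical noise.

    Starting from the majority-idealized population, each simulation flips
    RNA identities — a fixed number per direction, drawn uniformly without
    replacement from the RNAs of that identity — such that (i) expected flip
    counts follow the per-identity false-detection rates where feasible and
    (ii) the simulated population totals of BL6 and JF1 RNAs exactly equal
    the observed ones.  The statistic is the two-subpopulation NLL: cells
    grouped by idealized identity, with the minority count per cell modeled
    Binomial(total, fdr of that group).  The Pearson correlation null of
    the simulated populations is returned alongside (``extra``).
    """
    for name, v in (("fdr_bl6", fdr_bl6), ("fdr_jf1", fdr_jf1)):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    validate_counts(counts)
    rng = stream(rng_seed, "all_or_none_test")

    obs_b = counts["n_bl6"].to_numpy(dtype=np.int64)
    obs_j = counts["n_jf1"].to_numpy(dtype=np.int64)
    ideal = all_or_none_assign(counts, rng_seed=rng_seed)
    ib = ideal["n_bl6"].to_numpy(dtype=np.int64)
    ij = ideal["n_jf1"].to_numpy(dtype=np.int64)
    tot = ib + ij
    is_bl6_cell = ib > 0  # idealized identity (all RNAs on one side)
    # zero-total cells have no identity; they contribute nothing anywhere
    nz = tot > 0

    tot_ib, tot_ij, tot_ob = int(ib.sum()), int(ij.sum()), int(obs_b.sum())
    # feasibility check up front; also the expected flip quota for reporting
    exp_bj, exp_jb = _balanced_flip_quota(tot_ib, tot_ij, tot_ob, fdr_bl6, fdr_jf1)
    net = tot_ib - tot_ob  # required net BL6 -> JF1 flips, fixed by the data

    observed = _two_pop_nll(obs_b, obs_j, is_bl6_cell, fdr_bl6, fdr_jf1)
    obs_corr = _pearson(obs_b[nz].astype(float), obs_j[nz].astype(float))

    null = np.empty(n_sims)
    corr_null = np.empty(n_sims)
    for s in range(n_sims):
        # directed flip counts are binomial draws at the homozygous rates,
        # then repaired symmetrically so the simulated population totals
        # exactly equal the observed ones (the repair preserves the total
        # number of flips to within one RNA, keeping the noise variability)
        f_bj = int(rng.binomial(tot_ib, fdr_bl6))
        f_jb = int(rng.binomial(tot_ij, fdr_jf1))
        delta = (f_bj - f_jb) - net
        half = delta // 2
        f_bj -= delta - half
        f_jb += half
        if f_jb < 0:
            f_jb, f_bj = 0, net
        if f_bj < 0:
            f_bj, f_jb = 0, -net
        if f_bj > tot_ib or f_jb > tot_ij:
            raise ValueError(
                "population-total constraint incompatible with the supplied "
                "false-detection rates"
            )
        # uniform without-replacement draws of which RNAs flip, spread over
        # cells by a multivariate hypergeometric on per-cell counts
        flips_b = rng.multivariate_hypergeometric(ib, f_bj) if f_bj else np.zeros_like(ib)
        flips_j = rng.multivariate_hypergeometric(ij, f_jb) if f_jb else np.zeros_like(ij)
        sim_b = ib - flips_b + flips_j
        sim_j = ij - flips_j + flips_b
        # simulated populations are processed exactly like the data: cells
        # re-grouped by their own majority identity (ties by fair coin), so
        # flips that overturn a small cell's majority are absorbed the same
        # way they are in the observed table
        sim_bl6_cell = np.where(
            sim_b == sim_j, rng.random(len(sim_b)) < 0.5, sim_b > sim_j
        )
        null[s] = _two_pop_nll(sim_b, sim_j, sim_bl6_cell, fdr_bl6, fdr_jf1)
        corr_null[s] = _pearson(sim_b[nz].astype(float), sim_j[nz].astype(float))

    percentile, pval = _locate(observed, null)
    corr_pct, corr_p = _locate(obs_corr, corr_null[~np.isnan(corr_null)])
    return ModelTestResult(
        model="all_or_none",
        statistic="nll",
        observed=observed,
        null=null,
        percentile=percentile,
        p_value=pval,
        n_sims=n_sims,
        rng_seed=rng_seed,
        extra={
            "observed_correlation": obs_corr,
            "correlation_null": corr_null,
            "correlation_percentile": corr_pct,
            "correlation_p_value": corr_p,
            "expected_flips_bl6_to_jf1": exp_bj,
            "expected_flips_jf1_to_bl6": exp_jb,
        },
    )


def estimate_false_detection_rate(hom_counts: pd.DataFrame, true_allele: str) -> float:
    """False-detection rate from a homozygous control population.

    The fraction of uniquely assigned RNAs carrying the wrong strain
    identity in tissue homozygous for ``true_allele`` ("BL6" or "JF1").
    """
    validate_counts(hom_counts)
    b = int(hom_counts["n_bl6"].sum())
    j = int(hom_counts["n_jf1"].sum())
    if b + j == 0:
        raise ValueError("homozygous control has no uniquely assigned RNAs")
    if true_allele == "BL6":
        return j / (b + j)
    if true_allele == "JF1":
        return b / (b + j)
    raise ValueError("true_allele must be 'BL6' or 'JF1'")


# --------------------------------------------------------------------------
# negative-binomial bursting model
# --------------------------------------------------------------------------


def fit_negbin_moments(x) -> NegBinParams:
    """Method-of-moments negative-binomial fit of one allele's counts.

    p = mean/variance and r = mean^2/(variance - mean), using the sample
    variance (ddof=1); burst size (1-p)/p and burst frequency r follow.
    Underdispersed samples (variance <= mean) have no NB moments solution.
    """
    x = np.asarray(x, dtype=float)
    m = x.mean()
    v = x.var(ddof=1)
    if m <= 0:
        raise ValueError("sample mean must be > 0")
    if v <= m:
        raise ValueError("underdispersed; negative binomial moments undefined")
    return NegBinParams(p=m / v, r=m**2 / (v - m))


def _negbin_nll(x: np.ndarray, params: NegBinParams) -> float:
    with np.errstate(divide="ignore"):
        return float(-stats.nbinom.logpmf(x, params.r, params.p).sum())


def bursting_fit_test(
    counts: pd.DataFrame | np.ndarray,
    allele: str | None = None,
    n_sims: int = 10_000,
    rng_seed: int = 0,
    params: NegBinParams | None = None,
) -> ModelTestResult:
    """Monte-Carlo goodness of fit of the NB bursting model for one allele.

    Fits NB(r, p) by moments (unless ``params`` is supplied), simulates
    ``n_sims`` datasets of the same size from it, and compares the observed
    NLL under NB(r, p) with the simulated NLL distribution.
    """
    x = _allele_vector(counts, allele)
    fitted = fit_negbin_moments(x) if params is None else params
    observed = _negbin_nll(x, fitted)
    rng = stream(rng_seed, "bursting_fit_test")
    sims = rng.negative_binomial(fitted.r, fitted.p, size=(n_sims, len(x)))
    with np.errstate(divide="ignore"):
        null = -stats.nbinom.logpmf(sims, fitted.r, fitted.p).sum(axis=1)
    percentile, pval = _locate(observed, null)
    return ModelTestResult(
        model="bursting",
        statistic="nll",
        observed=observed,
        null=null,
        percentile=percentile,
        p_value=pval,
        n_sims=n_sims,
        rng_seed=rng_seed,
        extra={"params": fitted, "allele": allele},
    )


def _allele_vector(counts, allele):
    if isinstance(counts, pd.DataFrame):
        if allele not in ("BL6", "JF1"):
            raise ValueError("allele must be 'BL6' or 'JF1'")
        return counts["n_bl6" if allele == "BL6" else "n_jf1"].to_numpy(np.int64)
    return np.asarray(counts, dtype=np.int64)


def paired_correlation_test(
    counts: pd.DataFrame,
    params_bl6: NegBinParams,
    params_jf1: NegBinParams,
    n_sims: int = 10_000,
    fdr_bl6: float = 0.0,
    fdr_jf1: float = 0.0,
    rng_seed: int = 0,
) -> ModelTestResult:
    """Correlation test against independently bursting alleles.

    Each simulation draws the two alleles' counts independently from their
    fitted NBs and pairs them into cells at random, optionally applies one
    round of false-detection flips at the homozygous rates, and computes
    the Pearson correlation.  The observed correlation of the data is
    located in this null: coupled alleles (e.g. shared cell-to-cell
    scaling) fall above it, mutually exclusive expression below it.

    Observed and simulated correlations are both computed over every cell,
    zero-count cells included, so the two sides of the comparison share one
    convention (restricting to detected cells would bias the observed value
    relative to the unconditional simulations).
    """
    validate_counts(counts)
    n = len(counts)
    obs_b = counts["n_bl6"].to_numpy(dtype=float)
    obs_j = counts["n_jf1"].to_numpy(dtype=float)
    rng = stream(rng_seed, "paired_correlation_test")
    b = rng.negative_binomial(params_bl6.r, params_bl6.p, size=(n_sims, n))
    j = rng.negative_binomial(params_jf1.r, params_jf1.p, size=(n_sims, n))
    if fdr_bl6 > 0 or fdr_jf1 > 0:
        flips_b = rng.binomial(b, fdr_bl6)
        flips_j = rng.binomial(j, fdr_jf1)
        b, j = b - flips_b + flips_j, j - flips_j + flips_b
    bc = b - b.mean(axis=1, keepdims=True)
    jc = j - j.mean(axis=1, keepdims=True)
    denom = np.sqrt((bc**2).sum(axis=1) * (jc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        null = (bc * jc).sum(axis=1) / denom
    null = null[np.isfinite(null)]
    observed = _pearson(obs_b, obs_j)
    percentile, pval = _locate(observed, null)
    return ModelTestResult(
        model="bursting_paired",
        statistic="correlation",
        observed=observed,
        null=null,
        percentile=percentile,
        p_value=pval,
        n_sims=n_sims,
        rng_seed=rng_seed,
        extra={"fdr_bl6": fdr_bl6, "fdr_jf1": fdr_jf1},
    )


def burst_size_scan(
    counts: pd.DataFrame | np.ndarray,
    allele: str | None = None,
    burst_sizes=None,
    n_sims: int = 1000,
    rng_seed: int = 0,
    central: float = 95.0,
) -> pd.DataFrame:
    """Goodness of fit across a grid of imposed burst sizes.

    For each target burst size b, the NB is reparameterized to hold the
    sample mean fixed: p = 1/(1+b) and r = mean/b; the fit test then runs
    at those parameters.  A configuration is a "good fit" when the observed
    NLL lies inside the central band of its simulated null.
    """
    if burst_sizes is None:
        burst_sizes = np.round(np.arange(0.5, 5.01, 0.5), 10)
    x = _allele_vector(counts, allele)
    m = x.mean()
    if m <= 0:
        raise ValueError("sample mean must be > 0")
    half = (100.0 - central) / 2.0
    rows = []
    for i, b in enumerate(burst_sizes):
        params = NegBinParams(p=1.0 / (1.0 + b), r=m / b)
        res = bursting_fit_test(
            x, n_sims=n_sims, rng_seed=rng_seed + i, params=params
        )
        rows.append(
            {
                "burst_size": float(b),
                "burst_frequency": params.r,
                "observed_nll": res.observed,
                "percentile": res.percentile,
                "p_value": res.p_value,
                "good_fit": half <= res.percentile <= 100.0 - half,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# detection-efficiency robustness
# --------------------------------------------------------------------------


def downsampling_robustness(
    counts: pd.DataFrame,
    model: str = "coin_flip",
    n_sims: int = 5000,
    rng_seed: int = 0,
    fdr_bl6: float = 0.0,
    fdr_jf1: float = 0.0,
) -> dict:
    """Test whether partial detection distorts the model comparison.

    Requires a ``total`` column (pre-downsampling RNA count per cell).  The
    chosen model is simulated twice: directly on the assigned counts, and
    at the full totals followed by a hypergeometric thinning of each
    simulated cell down to its observed assigned count (which RNAs survive
    detection is a uniform draw without replacement).  The two NLL null
    distributions are compared by a two-sample KS test; for detection
    unbiased with respect to allele they should be indistinguishable.
    """
    validate_counts(counts)
    if "total" not in counts.columns:
        raise ValueError("downsampling robustness needs a 'total' column")
    b = counts["n_bl6"].to_numpy(np.int64)
    j = counts["n_jf1"].to_numpy(np.int64)
    assigned = b + j
    totals = counts["total"].to_numpy(np.int64)
    rng = stream(rng_seed, "downsampling_robustness")

    if model == "coin_flip":
        p = float(b.sum() / max(assigned.sum(), 1))
        nz = assigned > 0
        # twin generators with identical state: at detection rate 1 the
        # full-total draws then coincide with the direct draws exactly
        g_direct = stream(rng_seed, "downsampling_robustness", "draws")
        g_full = stream(rng_seed, "downsampling_robustness", "draws")
        direct = g_direct.binomial(assigned[nz], p, size=(n_sims, int(nz.sum())))
        full = g_full.binomial(totals[nz], p, size=(n_sims, int(nz.sum())))
        # thin each simulated cell back to its observed assigned count
        thinned = rng.hypergeometric(full, totals[nz] - full, assigned[nz])
        with np.errstate(divide="ignore"):
            nll_direct = -stats.binom.logpmf(direct, assigned[nz], p).sum(axis=1)
            nll_down = -stats.binom.logpmf(thinned, assigned[nz], p).sum(axis=1)
    elif model == "all_or_none":
        res_direct = all_or_none_test(
            counts, fdr_bl6, fdr_jf1, n_sims=n_sims, rng_seed=rng_seed
        )
        nll_direct = res_direct.null
        # idealize at full totals: identity by majority of assigned RNAs,
        # then flip at the fdrs and thin each cell back to its assigned count
        ideal = all_or_none_assign(counts, rng_seed=rng_seed)
        bl6_cell = ideal["n_bl6"].to_numpy(np.int64) > 0
        ib = np.where(bl6_cell, totals, 0)
        ij = totals - ib
        nll_down = np.empty(n_sims)
        nz = assigned > 0
        for s in range(n_sims):
            fb = rng.binomial(ib, fdr_bl6)
            fj = rng.binomial(ij, fdr_jf1)
            sb, sj = ib - fb + fj, ij - fj + fb
            keep_b = rng.hypergeometric(
                np.maximum(sb, 0), np.maximum(sj, 0) + (sb + sj == 0), assigned
            )
            keep_j = assigned - keep_b
            sim_bl6_cell = np.where(
                keep_b == keep_j, rng.random(len(keep_b)) < 0.5, keep_b > keep_j
            )
            nll_down[s] = _two_pop_nll(keep_b, keep_j, sim_bl6_cell, fdr_bl6, fdr_jf1)
    else:
        raise ValueError("model must be 'coin_flip' or 'all_or_none'")

    ks = stats.ks_2samp(nll_direct, nll_down)
    return {
        "model": model,
        "nll_direct": nll_direct,
        "nll_downsampled": nll_down,
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
    }
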