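"""Differentially methylated position (DMP) calling between two tissues.

The two-step procedure: (1) per-site linear models on M-values with tissue
(group-mean parametrization, contrast bone - blood) and age as a continuous
adjustment covariate, moderated t-statistics with empirical-Bayes variance
shrinkage across sites, Benjamini-Hochberg FDR; (2) retain only sites whose
mean paired beta-value difference exceeds a biological threshold
(|mean Delta-beta| > 0.2 by default).  A classical paired t-test on the
per-subject M differences is provided as a cross-check route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .io import SampleSheet
from .preprocess import MethylationMatrix, _trigamma_inverse

logger = logging.getLogger("methcord")

D0_CAP = 1e7  # prior df above this are reported as infinite


@dataclass(frozen=True)
class SitewiseFit:
    """Per-site OLS results for the tissue contrast."""

    effect: np.ndarray        # bone - blood M difference estimate
    s2: np.ndarray            # residual variance
    df_residual: float
    se_unscaled: float        # SE of the contrast per unit residual SD
    probe_ids: pd.Index


@dataclass(frozen=True)
class ModeratedStats:
    """Empirical-Bayes moderated t-statistics and their hyperparameters."""

    t: np.ndarray
    p: np.ndarray
    s2_post: np.ndarray
    d0: float                 # prior df (np.inf when the cap is hit)
    s02: float                # prior variance


def build_design(sheet: SampleSheet, sample_order: pd.Index,
                 include_age: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Group-mean design matrix (bone, blood indicators [+ centered age])
    and the bone-blood contrast vector, rows ordered as ``sample_order``."""
    table = sheet.table.set_index("sample_id").loc[sample_order]
    bone = (table["tissue"] == "bone").to_numpy(float)
    cols = [bone, 1.0 - bone]
    contrast = [1.0, -1.0]
    if include_age:
        age = table["age"].to_numpy(float)
        if np.ptp(age) == 0:
            logger.warning("age is constant; dropping it from the design")
        else:
            cols.append(age - age.mean())
            contrast.append(0.0)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConfigError("design matrix is rank deficient")
    return design, np.array(contrast)


def fit_sitewise_model(m: MethylationMatrix, sheet: SampleSheet,
                       include_age: bool = True) -> SitewiseFit:
    """Ordinary least squares per site; the effect is the tissue contrast.

    The estimate is parametrization-invariant: the group-mean form used
    here gives the same contrast as a treatment coding.
    """
    if m.domain != "mvalue":
        raise ConfigError("fit_sitewise_model operates on M-values")
    design, contrast = build_design(sheet, m.values.columns, include_age)
    y = m.values.values  # sites x samples
    n, p = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = y @ design @ xtx_inv  # sites x p
    resid = y - coef @ design.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    effect = coef @ contrast
    se_unscaled = float(np.sqrt(contrast @ xtx_inv @ contrast))
    return SitewiseFit(effect, s2, float(df), se_unscaled, m.values.index)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the distribution of log s^2 against a scaled F to get the
    prior df d0 and prior variance s0^2 (the empirical-Bayes hyperparameters).

    Uses the digamma/trigamma inversion on z = log s^2: with
    s^2 ~ s0^2 * F(df, d0), E[z] and Var[z] have closed forms in digamma/
    trigamma, so matching the sample moments yields (d0, s0^2) without
    iteration over sites.
    """
    s2 = np.asarray(s2, float)
    if len(s2) < 10:
        raise ConfigError("hyperparameter estimation needs >= 10 sites")
    z = np.log(np.maximum(s2, 1e-300))
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * float(_trigamma_inverse(e_var))
        if d0 > D0_CAP:
            d0 = np.inf
            s02 = float(np.exp(e_mean))
        else:
            s02 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        logger.info("no excess spread in log s^2: prior df is infinite")
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    return d0, s02


def moderate_statistics(fit: SitewiseFit,
                        d0: float | None = None,
                        s02: float | None = None) -> ModeratedStats:
    """Moderated t: posterior variance s~^2 = (d0*s0^2 + d*s^2)/(d0 + d),
    t = effect / (SE_unscaled * s~), two-sided p on d + d0 df.

    d0 = 0 reduces to the ordinary t; d0 = inf pools all sites to s0^2.
    Hyperparameters default to the moment-matched estimates.
    """
    if d0 is None or s02 is None:
        if np.allclose(fit.s2, fit.s2[0]):
            logger.info("all residual variances equal: using infinite prior df")
            est_d0, est_s02 = np.inf, float(fit.s2[0])
        else:
            est_d0, est_s02 = estimate_variance_prior(fit.s2, fit.df_residual)
        d0 = est_d0 if d0 is None else d0
        s02 = est_s02 if s02 is None else s02
    d = fit.df_residual
    if np.isinf(d0):
        s2_post = np.full_like(fit.s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * fit.s2) / (d0 + d)
        df_total = d + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.effect / (fit.se_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), np.nan, p)
    # zero-variance exact fits: infinite t means p = 0
    p = np.where(np.isinf(t), 0.0, p)
    return ModeratedStats(t, p, s2_post, float(d0), float(s02))


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min over j with p_(j) >= p_(i) of m * p_(j) / rank(j), capped at 1;
    NaN inputs propagate to NaN outputs with a warning.
    """
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if (~ok).any():
        logger.warning("bh_fdr: %d NaN p-value(s) propagated", int((~ok).sum()))
    if ok.any():
        pv = p[ok]
        if (pv < 0).any() or (pv > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        _, q_ok, _, _ = multipletests(pv, method="fdr_bh")
        q[ok] = q_ok
    return q


def mean_paired_delta_beta(beta: MethylationMatrix, sheet: SampleSheet) -> pd.Series:
    """|mean over subjects of (beta_bone - beta_blood)| per site.

    The signed mean is taken first, so opposite-direction pair differences
    cancel; only consistent-direction shifts survive the threshold.
    """
    if beta.domain != "beta":
        raise ConfigError("mean_paired_delta_beta operates on beta values")
    bone_ids, blood_ids = sheet.paired_samples()
    diff = beta.values[bone_ids].to_numpy() - beta.values[blood_ids].to_numpy()
    return pd.Series(np.abs(diff.mean(axis=1)), index=beta.values.index,
                     name="delta_beta")


def call_dmps(m: MethylationMatrix, beta: MethylationMatrix, sheet: SampleSheet,
              q_threshold: float = 0.05, dbeta_threshold: float = 0.2,
              include_age: bool = True) -> pd.DataFrame:
    """Run the two-step DMP procedure and return the per-site call table.

    Columns: effect (bone - blood mean M difference), delta_beta, t_mod, p,
    q, direction (hypo/hyper in bone relative to blood, from the sign of the
    M difference), is_dmp.
    """
    if not (0 < q_threshold < 1) or not (0 < dbeta_threshold < 1):
        raise ConfigError("thresholds must lie in (0, 1)")
    fit = fit_sitewise_model(m, sheet, include_age=include_age)
    mod = moderate_statistics(fit)
    q = bh_fdr(mod.p)
    dbeta = mean_paired_delta_beta(beta, sheet)
    table = pd.DataFrame({
        "effect": fit.effect,
        "delta_beta": dbeta.loc[fit.probe_ids].to_numpy(),
        "t_mod": mod.t,
        "p": mod.p,
        "q": q,
    }, index=fit.probe_ids)
    table.index.name = "probe_id"
    table["direction"] = np.where(table["effect"] < 0, "hypo", "hyper")
    table["is_dmp"] = (table["q"] < q_threshold) & (table["delta_beta"] > dbeta_threshold)
    return table


def paired_test_crosscheck(m: MethylationMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Classical paired t-test on per-subject M differences (df = n - 1).

    Zero-variance difference vectors get t = +/-inf and p = 0 by convention.
    """
    if m.domain != "mvalue":
        raise ConfigError("paired_test_crosscheck operates on M-values")
    bone_ids, blood_ids = sheet.paired_samples()
    diff = m.values[bone_ids].to_numpy() - m.values[blood_ids].to_numpy()
    n = diff.shape[1]
    if n < 2:
        raise ConfigError("paired t-test needs >= 2 subjects")
    mean = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    if zero_var.any():
        logger.info("paired t: %d zero-variance site(s) set to t=+/-inf, p=0",
                    int(zero_var.sum()))
        t = np.where(zero_var, np.sign(mean) * np.inf, t)
        # all-zero differences: t = 0/0 -> define as 0 (no effect, p = 1)
        t = np.where(zero_var & (mean == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(np.isinf(t), 0.0, p)
    out = pd.DataFrame({"t_paired": t, "p": p}, index=m.values.index)
    out.index.name = "probe_id"
    return out


def call_dmps_paired(m: MethylationMatrix, beta: MethylationMatrix,
                     sheet: SampleSheet, q_threshold: float = 0.05,
                     dbeta_threshold: float = 0.2) -> pd.DataFrame:
    """DMP calls via the paired-t route (cross-check for :func:`call_dmps`)."""
    paired = paired_test_crosscheck(m, sheet)
    q = bh_fdr(paired["p"].to_numpy())
    dbeta = mean_paired_delta_beta(beta, sheet)
    table = paired.assign(q=q, delta_beta=dbeta.loc[paired.index].to_numpy())
    table["is_dmp"] = (table["q"] < q_threshold) & (table["delta_beta"] > dbeta_threshold)
    return table
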