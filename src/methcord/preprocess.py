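"""Intensity-to-methylation conversion, probe QC filters and batch correction.

The QC chain mirrors standard array practice: detection-p filtering, removal
of SNP-overlapping probes, conversion of methylated/unmethylated intensities
(m, u) into beta-values beta = m/(m+u+alpha) and M-values
M = log2((m+alpha)/(u+alpha)) with an intensity offset alpha (default 100),
and an empirical-Bayes location/scale batch adjustment on the M scale that
protects the tissue effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .errors import ConfigError, DomainError
from .io import SampleSheet

logger = logging.getLogger("methcord")

BETA_EPS = 1e-6


@dataclass(frozen=True)
class IntensityDataset:
    """Methylated/unmethylated signal intensities, site x sample."""

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    alpha: float = 100.0

    def __post_init__(self) -> None:
        if self.methylated.shape != self.unmethylated.shape:
            raise DomainError("methylated and unmethylated matrices differ in shape")
        if self.alpha <= 0:
            raise DomainError(f"offset alpha must be > 0, got {self.alpha}")
        if (self.methylated.values < 0).any() or (self.unmethylated.values < 0).any():
            raise DomainError("negative signal intensity")


@dataclass(frozen=True)
class MethylationMatrix:
    """Site x sample methylation values with their value-domain tag."""

    values: pd.DataFrame
    domain: str  # "beta" or "mvalue"

    def __post_init__(self) -> None:
        if self.domain not in ("beta", "mvalue"):
            raise ConfigError(f"unknown value domain {self.domain!r}")
        if self.domain == "beta":
            v = self.values.values
            if (v < 0).any() or (v >= 1).any():
                raise DomainError("beta values must lie in [0, 1)")


def compute_beta(data: IntensityDataset) -> MethylationMatrix:
    """beta = m / (m + u + alpha); the alpha offset keeps the denominator positive."""
    beta = data.methylated / (data.methylated + data.unmethylated + data.alpha)
    return MethylationMatrix(beta, "beta")


def compute_m(data: IntensityDataset) -> MethylationMatrix:
    """M = log2((m + alpha) / (u + alpha)); finite for all non-negative intensities."""
    m = np.log2((data.methylated + data.alpha) / (data.unmethylated + data.alpha))
    return MethylationMatrix(m, "mvalue")


def beta_to_m(beta: MethylationMatrix) -> MethylationMatrix:
    """logit2 bridge M = log2(beta/(1-beta)); exact inverse of the beta/M pair
    only at alpha = 0.  beta values at 0 or 1 are clamped to [eps, 1-eps]."""
    if beta.domain != "beta":
        raise ConfigError("beta_to_m expects a beta-domain matrix")
    v = beta.values
    if ((v <= 0) | (v >= 1)).values.any():
        logger.warning("beta values at the domain boundary clamped to [%g, %g]",
                       BETA_EPS, 1 - BETA_EPS)
        v = v.clip(BETA_EPS, 1 - BETA_EPS)
    return MethylationMatrix(np.log2(v / (1 - v)), "mvalue")


def m_to_beta(m: MethylationMatrix) -> MethylationMatrix:
    """Inverse logit2: beta = 1 / (1 + 2**(-M))."""
    if m.domain != "mvalue":
        raise ConfigError("m_to_beta expects an mvalue-domain matrix")
    return MethylationMatrix(1.0 / (1.0 + 2.0 ** (-m.values)), "beta")


def detection_filter(detp: pd.DataFrame, threshold: float = 0.01) -> list[str]:
    """Probes kept iff detection p <= threshold in EVERY sample.

    The any-sample-fails rule is the conservative reading of excluding
    "failed probes": one bad measurement disqualifies the site for the
    paired analyses downstream.
    """
    v = detp.values
    if (v < 0).any() or (v > 1).any():
        raise DomainError("detection p-values must lie in [0, 1]")
    keep = (v <= threshold).all(axis=1)
    return detp.index[keep].tolist()


def snp_filter(annotation: pd.DataFrame, probes: list[str] | None = None) -> list[str]:
    """Probes whose ``snp_overlap`` flag is False; SNP-overlapping probes
    confound methylation with genotype and are removed."""
    if probes is None:
        probes = annotation.index.tolist()
    missing = [p for p in probes if p not in annotation.index]
    if missing:
        raise KeyError(f"probe(s) missing from annotation: {missing[:5]}")
    flags = annotation.loc[probes, "snp_overlap"].astype(bool)
    kept = [p for p, f in zip(probes, flags) if not f]
    if not kept:
        logger.warning("snp_filter removed every probe")
    return kept


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # asymptotic start: trigamma(y) ~ 1/y + 1/(2y^2)
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def batch_correct(m: MethylationMatrix, sheet: SampleSheet) -> MethylationMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment per site.

    Per site, a mean + tissue-effect model is fit (tissue is protected so
    biological signal is not removed); residuals are standardized, per-batch
    location (gamma) and scale (delta^2) estimates are shrunk toward
    batch-level priors (normal for gamma, inverse-gamma for delta^2,
    moments-matched), the adjustment is applied in residual space, and the
    site mean + tissue effect are restored.  A final re-centering keeps each
    site's overall mean exactly unchanged.  Single-batch input is returned
    unchanged.
    """
    if m.domain != "mvalue":
        raise ConfigError("batch_correct operates on M-values")
    table = sheet.table.set_index("sample_id").loc[m.values.columns]
    batches = table["batch"].astype(str)
    batch_levels = sorted(batches.unique())
    if len(batch_levels) == 1:
        logger.info("single batch: batch correction is the identity")
        return m
    counts = batches.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ConfigError(f"batch(es) with <2 samples: {small.index.tolist()}")

    y = m.values.values  # sites x samples
    n_sites, n_samples = y.shape
    # design: batch indicators (no intercept) + protected tissue covariate
    batch_dummies = pd.get_dummies(batches)[batch_levels].to_numpy(float)
    tissue = (table["tissue"] == "bone").to_numpy(float)
    tissue_c = tissue - tissue.mean()
    design = np.column_stack([batch_dummies, tissue_c])
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # p x sites
    n_batch = len(batch_levels)
    batch_effects = coef[:n_batch]  # per-batch means, sites along axis 1
    weights = counts.loc[batch_levels].to_numpy(float) / n_samples
    grand_mean = weights @ batch_effects  # per site
    stand_mean = grand_mean[None, :] + np.outer(tissue_c, coef[n_batch])  # samples x sites
    resid = y.T - design @ coef
    pooled_var = (resid**2).mean(axis=0)
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-16))
    z = (y.T - stand_mean) / pooled_sd[None, :]  # samples x sites

    adjusted = np.empty_like(z)
    for b, level in enumerate(batch_levels):
        idx = (batches == level).to_numpy()
        nb = idx.sum()
        zb = z[idx]
        gamma_hat = zb.mean(axis=0)
        delta2_hat = zb.var(axis=0, ddof=1)
        # normal prior on gamma: moments across sites
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        # inverse-gamma prior on delta^2: moments across sites
        v_bar = delta2_hat.mean()
        s2 = delta2_hat.var(ddof=1)
        if s2 > 0 and v_bar > 0:
            a_prior = (2 * s2 + v_bar**2) / s2
            b_prior = (v_bar * s2 + v_bar**3) / s2
            # posterior mode of the inverse-gamma given the gamma_hat residuals
            delta2_star = (b_prior + 0.5 * ((zb - gamma_hat) ** 2).sum(axis=0)) / (
                a_prior + nb / 2 - 1.0
            )
        else:  # degenerate (e.g. noiseless) scale distribution: no shrinkage
            delta2_star = np.where(delta2_hat > 0, delta2_hat, 1.0)
        if tau2 > 0:
            gamma_star = (nb * tau2 * gamma_hat + delta2_star * gamma_bar) / (
                nb * tau2 + delta2_star
            )
        else:
            gamma_star = np.full_like(gamma_hat, gamma_bar)
        adjusted[idx] = (zb - gamma_star[None, :]) / np.sqrt(delta2_star)[None, :]

    out = adjusted * pooled_sd[None, :] + stand_mean
    out = out.T  # sites x samples
    out += (y.mean(axis=1) - out.mean(axis=1))[:, None]  # exact mean preservation
    frame = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return MethylationMatrix(frame, "mvalue")


def sample_medians(data: IntensityDataset) -> pd.DataFrame:
    """Per-sample medians of the two channels, for the QC report (no
    automatic sample exclusion is applied)."""
    return pd.DataFrame({
        "median_methylated": data.methylated.median(axis=0),
        "median_unmethylated": data.unmethylated.median(axis=0),
    })
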