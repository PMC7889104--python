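"""Similarly methylated position (SMP) calling and the permutation null.

An SMP is a CpG site whose M-values in the two tissues track each other
within subjects: Pearson correlation across subjects between the paired
bone and blood vectors, t-tested on n-2 df, BH-FDR corrected, with a
methylation-similarity filter (per-pair |Delta-beta| below a threshold) and
a positive-correlation requirement.  Candidates are restricted to sites NOT
significant in the differential (DMP) stage, so SMP and DMP calls are
mutually exclusive by construction.

The permutation null breaks the matched pairing by shuffling subject labels
of the blood samples and re-running the full selection (correlation, BH
within the iteration, similarity filter), giving the chance distribution of
the SMP count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .differential import bh_fdr
from .io import SampleSheet
from .preprocess import MethylationMatrix

logger = logging.getLogger("methcord")


@dataclass(frozen=True)
class PermutationResult:
    """Null distribution of the SMP-passing count under label shuffling."""

    n_iterations: int
    observed_count: int
    null_counts: np.ndarray = field(repr=False)
    empirical_p: float
    seed: int

    def to_dict(self) -> dict:
        counts = np.asarray(self.null_counts)
        hist, edges = np.histogram(counts, bins=min(50, max(10, self.n_iterations // 20)))
        return {
            "n_iterations": self.n_iterations,
            "observed_count": self.observed_count,
            "empirical_p": self.empirical_p,
            "seed": self.seed,
            "null_count_mean": float(counts.mean()),
            "null_count_max": int(counts.max()),
            "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        }


def candidate_sites(dmp_q: pd.Series, q_threshold: float = 0.05) -> pd.Index:
    """Probes NOT differentially methylated at the DMP stage (q >= threshold);
    the pool from which SMPs may be drawn."""
    if dmp_q.isna().any():
        raise ValueError("missing DMP q-value(s); cannot form the candidate set")
    return dmp_q.index[dmp_q >= q_threshold]


def _paired_matrices(values: pd.DataFrame, sheet: SampleSheet
                     ) -> tuple[np.ndarray, np.ndarray]:
    bone_ids, blood_ids = sheet.paired_samples()
    return values[bone_ids].to_numpy(), values[blood_ids].to_numpy()


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of x and y; NaN where either row has
    zero variance."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / (sx * sy)
    r[(sx == 0) | (sy == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def sitewise_pair_correlation(m: MethylationMatrix, sheet: SampleSheet) -> pd.Series:
    """Per-site Pearson r between the subject-aligned bone and blood M-value
    vectors.  Zero-variance sites yield NaN (excluded from testing)."""
    if m.domain != "mvalue":
        raise ConfigError("sitewise_pair_correlation operates on M-values")
    bone, blood = _paired_matrices(m.values, sheet)
    r = _rowwise_pearson(bone, blood)
    n_nan = int(np.isnan(r).sum())
    if n_nan:
        logger.info("%d site(s) with zero variance: correlation undefined", n_nan)
    return pd.Series(r, index=m.values.index, name="r")


def correlation_test(r: pd.Series | np.ndarray, n: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df, two-sided.

    r = +/-1 maps to t = +/-inf, p = 0 by convention; NaN r propagates.
    """
    if n < 3:
        raise ConfigError(f"correlation test needs >= 3 subjects, got {n}")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    exact = np.abs(r) == 1.0
    if exact.any():
        logger.info("%d site(s) with |r| = 1: p = 0 by convention", int(exact.sum()))
        p = np.where(exact, 0.0, p)
    return t, p


def max_pair_delta_beta(beta: MethylationMatrix, sheet: SampleSheet) -> pd.Series:
    """Per site, max over subjects of |beta_bone - beta_blood| — the
    strictest reading of a per-pair similarity requirement."""
    if beta.domain != "beta":
        raise ConfigError("max_pair_delta_beta operates on beta values")
    bone, blood = _paired_matrices(beta.values, sheet)
    return pd.Series(np.abs(bone - blood).max(axis=1), index=beta.values.index,
                     name="max_pair_dbeta")


def call_smps(m: MethylationMatrix, beta: MethylationMatrix, sheet: SampleSheet,
              candidates: pd.Index | None = None,
              q_threshold: float = 0.05, dbeta_threshold: float = 0.2,
              dbeta_rule: str = "max") -> pd.DataFrame:
    """Full SMP chain on the candidate probes.

    Columns: r, t_r, p, q, max_pair_dbeta (or mean, per ``dbeta_rule``),
    mean_beta, beta_class (hypo: mean beta < 0.2; hyper: > 0.8; else mid),
    is_smp.  is_smp requires q < q_threshold, the Delta-beta similarity
    filter, and r > 0 (anti-correlated sites are not "similar").
    """
    if not (0 < q_threshold < 1) or not (0 < dbeta_threshold < 1):
        raise ConfigError("thresholds must lie in (0, 1)")
    if dbeta_rule not in ("max", "mean"):
        raise ConfigError(f"dbeta_rule must be 'max' or 'mean', got {dbeta_rule!r}")
    logger.info("SMP Delta-beta filter uses the per-pair %s", dbeta_rule)
    if candidates is None:
        candidates = m.values.index
    m_c = MethylationMatrix(m.values.loc[candidates], "mvalue")
    beta_c = MethylationMatrix(beta.values.loc[candidates], "beta")
    r = sitewise_pair_correlation(m_c, sheet)
    n = sheet.n_subjects
    t, p = correlation_test(r, n)
    q = bh_fdr(p)
    if dbeta_rule == "max":
        dbeta = max_pair_delta_beta(beta_c, sheet)
    else:
        bone, blood = _paired_matrices(beta_c.values, sheet)
        dbeta = pd.Series(np.abs((bone - blood).mean(axis=1)),
                          index=candidates, name="max_pair_dbeta")
    mean_beta = beta_c.values.mean(axis=1)
    table = pd.DataFrame({
        "r": r,
        "t_r": t,
        "p": p,
        "q": q,
        "max_pair_dbeta": dbeta,
        "mean_beta": mean_beta,
    }, index=candidates)
    table.index.name = "probe_id"
    table["beta_class"] = np.select(
        [mean_beta < 0.2, mean_beta > 0.8], ["hypo", "hyper"], default="mid")
    table["is_smp"] = (
        (table["q"] < q_threshold)
        & (table["max_pair_dbeta"] < dbeta_threshold)
        & (table["r"] > 0)
    )
    return table


def _smp_pass_count(bone_m: np.ndarray, blood_m: np.ndarray,
                    bone_b: np.ndarray, blood_b: np.ndarray, n: int,
                    q_threshold: float, dbeta_threshold: float) -> int:
    """SMP-passing count for one (possibly permuted) pairing; BH is
    recomputed inside so the null mimics the full selection procedure."""
    r = _rowwise_pearson(bone_m, blood_m)
    _, p = correlation_test(r, n)
    q = bh_fdr(p)
    dbeta = np.abs(bone_b - blood_b).max(axis=1)
    with np.errstate(invalid="ignore"):
        passed = (q < q_threshold) & (dbeta < dbeta_threshold) & (r > 0)
    return int(np.nansum(passed))


def permutation_null(m: MethylationMatrix, beta: MethylationMatrix,
                     sheet: SampleSheet, n_iterations: int = 10_000,
                     seed: int = 0, q_threshold: float = 0.05,
                     dbeta_threshold: float = 0.2,
                     candidates: pd.Index | None = None,
                     permutations: np.ndarray | None = None) -> PermutationResult:
    """Null distribution of the SMP count under subject-label shuffling.

    Each iteration draws a uniform random permutation of the blood samples'
    subject labels (bone fixed; the identity is an allowed draw), re-runs
    correlation + BH + the similarity filter against the permuted pairing,
    and records the passing count.  empirical p =
    (1 + #{null counts >= observed}) / (n_iterations + 1).

    ``permutations`` (n_iterations x n_subjects integer array) overrides the
    random draws — useful for deterministic checks.
    """
    if n_iterations < 100:
        logger.warning("n_iterations=%d < 100: empirical p will be unstable",
                       n_iterations)
    if candidates is not None:
        m = MethylationMatrix(m.values.loc[candidates], "mvalue")
        beta = MethylationMatrix(beta.values.loc[candidates], "beta")
    bone_m, blood_m = _paired_matrices(m.values, sheet)
    bone_b, blood_b = _paired_matrices(beta.values, sheet)
    n = sheet.n_subjects
    observed = _smp_pass_count(bone_m, blood_m, bone_b, blood_b, n,
                               q_threshold, dbeta_threshold)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_iterations, dtype=int)
    for i in range(n_iterations):
        perm = permutations[i] if permutations is not None else rng.permutation(n)
        null_counts[i] = _smp_pass_count(
            bone_m, blood_m[:, perm], bone_b, blood_b[:, perm], n,
            q_threshold, dbeta_threshold)
    emp_p = (1 + int((null_counts >= observed).sum())) / (n_iterations + 1)
    return PermutationResult(n_iterations, observed, null_counts, emp_p, seed)
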