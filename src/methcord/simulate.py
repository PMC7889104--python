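"""Synthetic matched two-tissue methylation datasets with planted truth.

The generator emulates the design of a matched bone-blood array study:
n subjects each contributing one bone and one blood sample, run in batches
(both samples of a subject share a batch), ages drawn per subject, with a
site x sample methylation matrix carrying three planted site classes:

* ``smp``  — similarly methylated: a per-subject random effect
  u_j ~ N(0, smp_subject_sd^2) is added to BOTH tissues of subject j, so
  the within-subject cross-tissue correlation is approximately the
  intraclass correlation smp_subject_sd^2 / (smp_subject_sd^2 + noise_sd^2).
* ``dmp``  — differentially methylated: a constant tissue offset is applied
  to the bone samples, sized on the beta scale at each site's baseline so
  the planted paired beta difference equals ``dmp_delta_beta``.
* ``null`` — independent noise per sample; no shared subject effect, no
  tissue offset.

Simulation operates on the M scale (unbounded, additive effects) and maps
to beta via the inverse logit2; intensity matrices are derived as
m = T*beta, u = T*(1-beta) with total signal T ~ LogNormal, so the
intensity-to-beta conversion recovers the planted beta up to the alpha
offset.  Detection failures and SNP-overlap flags are planted independently
of site class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import SampleSheet
from .preprocess import IntensityDataset, MethylationMatrix

# baseline M-value mixture: (weight, mean, sd) for hypo / mid / hyper levels,
# mimicking the bimodal methylation landscape of array data
BASELINE_MIXTURE = ((0.32, -3.5, 0.8), (0.22, 0.0, 1.2), (0.46, 3.5, 0.8))

ISLAND_PROBS = {"island": 0.21, "n_shore": 0.10, "s_shore": 0.10,
                "n_shelf": 0.05, "s_shelf": 0.05, "open_sea": 0.49}
GENIC_FEATURE_PROBS = {"TSS200": 0.12, "TSS1500": 0.16, "5UTR": 0.12,
                       "1stExon": 0.06, "Body": 0.45, "3UTR": 0.09}
P_INTERGENIC = 0.25
P_SECOND_FEATURE = 0.15   # gene-isoform multi-annotation
P_SECOND_GENE = 0.10
BETA_MARGIN = 1e-3        # planted beta targets stay inside (margin, 1-margin)


def logistic2(m: np.ndarray) -> np.ndarray:
    """Inverse of logit2: beta = 1 / (1 + 2**(-M))."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, float)))


def logit2(beta: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, float)
    return np.log2(beta / (1.0 - beta))


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters; the defaults reproduce a 12-subject,
    two-batch matched design with moderate planted effects."""

    n_subjects: int = 12
    n_sites: int = 5000
    frac_smp: float = 0.1
    frac_dmp: float = 0.1
    smp_subject_sd: float = 1.0    # between-subject SD at SMP sites (M units)
    noise_sd: float = 0.25         # within-tissue residual SD (M units)
    dmp_delta_beta: float = 0.4    # planted tissue offset on the beta scale
    batch_shift: float = 0.5       # M-value shift of batches 2+
    n_batches: int = 2
    frac_detection_fail: float = 2e-4   # per (site, sample) cell
    frac_snp_overlap: float = 0.034
    age_range: tuple[float, float] = (66.0, 85.0)
    age_slope_sd: float = 0.0      # per-site age slope SD (M units / year)
    seed: int = 0
    make_intensities: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3")
        for name in ("frac_smp", "frac_dmp", "frac_detection_fail",
                     "frac_snp_overlap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_smp + self.frac_dmp > 1:
            raise ConfigError("frac_smp + frac_dmp must be <= 1")
        if not 0.2 < self.dmp_delta_beta < 1:
            raise ConfigError("dmp_delta_beta must lie in (0.2, 1)")
        if self.n_batches < 1 or self.n_batches > self.n_subjects:
            raise ConfigError("n_batches must lie in [1, n_subjects]")
        if self.noise_sd <= 0 or self.smp_subject_sd < 0:
            raise ConfigError("noise_sd must be > 0 and smp_subject_sd >= 0")


@dataclass(frozen=True)
class SimulatedDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    beta: MethylationMatrix
    mvalues: MethylationMatrix
    detection_p: pd.DataFrame
    sheet: SampleSheet
    annotation: pd.DataFrame
    truth: pd.DataFrame            # per-site class + generating parameters
    config: SimulationConfig
    intensities: IntensityDataset | None = None


def _site_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n_smp = round(cfg.frac_smp * cfg.n_sites)
    n_dmp = round(cfg.frac_dmp * cfg.n_sites)
    classes = np.array(["smp"] * n_smp + ["dmp"] * n_dmp
                       + ["null"] * (cfg.n_sites - n_smp - n_dmp))
    return rng.permutation(classes)


def _baseline_m(n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for w, _, _ in BASELINE_MIXTURE])
    comp = rng.choice(len(BASELINE_MIXTURE), size=n, p=weights / weights.sum())
    means = np.array([m for _, m, _ in BASELINE_MIXTURE])[comp]
    sds = np.array([s for _, _, s in BASELINE_MIXTURE])[comp]
    return rng.normal(means, sds)


def _dmp_offsets(baseline_m: np.ndarray, delta_beta: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-site bone-tissue M offsets sized so the planted beta difference
    is +/- delta_beta at the site's baseline."""
    beta0 = logistic2(baseline_m)
    up_ok = beta0 + delta_beta < 1 - BETA_MARGIN
    down_ok = beta0 - delta_beta > BETA_MARGIN
    infeasible = ~(up_ok | down_ok)
    if infeasible.any():
        raise ConfigError(
            f"dmp_delta_beta={delta_beta} unreachable at {int(infeasible.sum())} "
            f"dmp site(s) with extreme baselines")
    sign = np.where(up_ok & down_ok, rng.choice([-1.0, 1.0], size=len(beta0)),
                    np.where(up_ok, 1.0, -1.0))
    target = beta0 + sign * delta_beta
    return logit2(target) - baseline_m


def _make_annotation(probe_ids: pd.Index, snp_flags: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = len(probe_ids)
    chroms = rng.choice([f"chr{i}" for i in list(range(1, 23)) + ["X"]], size=n)
    pos = rng.integers(10_000, 200_000_000, size=n)
    island = rng.choice(list(ISLAND_PROBS), size=n, p=list(ISLAND_PROBS.values()))
    genic = rng.random(n) >= P_INTERGENIC
    feat_names = list(GENIC_FEATURE_PROBS)
    feat_p = np.array(list(GENIC_FEATURE_PROBS.values()))
    primary = rng.choice(feat_names, size=n, p=feat_p / feat_p.sum())
    secondary = rng.choice(feat_names, size=n, p=feat_p / feat_p.sum())
    add_second = rng.random(n) < P_SECOND_FEATURE
    n_genes = max(50, n // 10)
    pool = np.array([f"GENE{i:05d}" for i in range(1, n_genes + 1)])
    gene1 = rng.choice(pool, size=n)
    gene2 = rng.choice(pool, size=n)
    add_gene2 = rng.random(n) < P_SECOND_GENE
    feature_class, genes = [], []
    for i in range(n):
        if genic[i]:
            fc = {primary[i]}
            if add_second[i]:
                fc.add(secondary[i])
            gs = {gene1[i]}
            if add_gene2[i]:
                gs.add(gene2[i])
        else:
            fc, gs = {"intergenic"}, set()
        feature_class.append(frozenset(fc))
        genes.append(frozenset(gs))
    ann = pd.DataFrame({
        "chrom": chroms,
        "pos": pos,
        "feature_class": feature_class,
        "island_class": island,
        "genes": genes,
        "snp_overlap": snp_flags.astype(bool),
    }, index=probe_ids)
    ann.index.name = "probe_id"
    return ann


def generate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic dataset; bit-identical for equal configs."""
    rng = np.random.default_rng(cfg.seed)
    n, s = cfg.n_subjects, cfg.n_sites
    probe_ids = pd.Index([f"cg{i:07d}" for i in range(1, s + 1)], name="probe_id")
    subjects = [f"S{j:03d}" for j in range(1, n + 1)]
    ages = rng.uniform(*cfg.age_range, size=n)
    # subjects split across batches as evenly as possible, pairs never split
    batch_of_subject = np.array([j % cfg.n_batches for j in range(n)])
    sample_rows = []
    for j, subj in enumerate(subjects):
        for tissue in ("bone", "blood"):
            sample_rows.append({
                "sample_id": f"{subj}_{tissue}",
                "subject_id": subj,
                "tissue": tissue,
                "batch": f"B{batch_of_subject[j] + 1}",
                "age": round(float(ages[j]), 1),
            })
    sheet = SampleSheet(pd.DataFrame(sample_rows))
    sample_ids = [row["sample_id"] for row in sample_rows]
    bone_cols = np.arange(0, 2 * n, 2)   # sample order: bone, blood per subject
    blood_cols = np.arange(1, 2 * n, 2)

    classes = _site_classes(cfg, rng)
    baseline = _baseline_m(s, rng)
    is_smp = classes == "smp"
    is_dmp = classes == "dmp"

    tissue_offset = np.zeros(s)
    if is_dmp.any():
        tissue_offset[is_dmp] = _dmp_offsets(baseline[is_dmp],
                                             cfg.dmp_delta_beta, rng)
    subject_sd = np.where(is_smp, cfg.smp_subject_sd, 0.0)
    age_slope = (rng.normal(0.0, cfg.age_slope_sd, size=s)
                 if cfg.age_slope_sd > 0 else np.zeros(s))

    m = np.tile(baseline[:, None], (1, 2 * n))
    subj_effect = rng.normal(size=(s, n)) * subject_sd[:, None]
    m[:, bone_cols] += subj_effect
    m[:, blood_cols] += subj_effect
    m[:, bone_cols] += tissue_offset[:, None]
    m += rng.normal(0.0, cfg.noise_sd, size=(s, 2 * n))
    if cfg.age_slope_sd > 0:
        age_c = ages - ages.mean()
        per_subject = np.outer(age_slope, age_c)
        m[:, bone_cols] += per_subject
        m[:, blood_cols] += per_subject
    # batch shift applied to every sample outside the first batch
    shifted = np.repeat(batch_of_subject > 0, 2)
    m[:, shifted] += cfg.batch_shift

    beta = logistic2(m)
    m_frame = pd.DataFrame(m, index=probe_ids, columns=sample_ids)
    beta_frame = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)

    fail = rng.random((s, 2 * n)) < cfg.frac_detection_fail
    detp = np.where(fail, rng.uniform(0.011, 1.0, size=(s, 2 * n)),
                    rng.uniform(0.0, 0.009, size=(s, 2 * n)))
    detp_frame = pd.DataFrame(detp, index=probe_ids, columns=sample_ids)

    snp_flags = rng.random(s) < cfg.frac_snp_overlap
    annotation = _make_annotation(probe_ids, snp_flags, rng)

    intensities = None
    if cfg.make_intensities:
        total = rng.lognormal(mean=math.log(5000.0), sigma=0.3, size=(s, 2 * n))
        meth = pd.DataFrame(total * beta, index=probe_ids, columns=sample_ids)
        unmeth = pd.DataFrame(total * (1.0 - beta), index=probe_ids,
                              columns=sample_ids)
        intensities = IntensityDataset(meth, unmeth)

    truth = pd.DataFrame({
        "class": classes,
        "baseline_m": baseline,
        "subject_sd": subject_sd,
        "tissue_offset_m": tissue_offset,
        "age_slope": age_slope,
    }, index=probe_ids)

    return SimulatedDataset(
        beta=MethylationMatrix(beta_frame, "beta"),
        mvalues=MethylationMatrix(m_frame, "mvalue"),
        detection_p=detp_frame,
        sheet=sheet,
        annotation=annotation,
        truth=truth,
        config=cfg,
        intensities=intensities,
    )


def truth_confusion(called: pd.Series, truth: pd.DataFrame,
                    target_class: str) -> dict[str, float]:
    """Exact confusion counts of a boolean call vector against the planted
    class, plus sensitivity, specificity and the empirical FDR
    (FP / max(TP + FP, 1))."""
    if target_class not in ("smp", "dmp"):
        raise ConfigError(f"target_class must be 'smp' or 'dmp', got {target_class!r}")
    if not called.index.equals(truth.index):
        if set(called.index) != set(truth.index):
            raise ValueError("call table and truth cover different probe sets")
        called = called.loc[truth.index]
    is_true = (truth["class"] == target_class).to_numpy()
    is_called = called.astype(bool).to_numpy()
    tp = int((is_called & is_true).sum())
    fp = int((is_called & ~is_true).sum())
    fn = int((~is_called & is_true).sum())
    tn = int((~is_called & ~is_true).sum())
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
        "fdr": fp / max(tp + fp, 1),
    }


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["age_range"] = list(d["age_range"])
    return d
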