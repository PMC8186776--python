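"""Synthetic miRNA-seq cohorts and qPCR panels with known ground truth.

The generator emulates the structure of a paired tumor/normal bulk
miRNA-seq cohort with unbalanced tumor subgroups: negative-binomial read
counts over log-normal library sizes, matched pairs coupled by a shared
patient effect, ordinal clinical covariates, and planted gene classes --

* ``stable``: near-zero fold change everywhere and low dispersion (the
  genes a reference-gene screen should recover),
* ``unstable``: tumor/normal and/or subgroup log2 fold changes of 0.5-2
  plus a fraction of outlier samples,
* ``clinical``: expression monotone in the pathologic-stage code,
* ``background``: modest random group effects and typical dispersion.

Per-sample expression is specified on a log2-CPM scale and renormalized so
that configured CPMs sum to one million per sample, which makes realized
CPM converge to the configured values.  A companion generator produces
qPCR Ct tables with configurable internal-control drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CountMatrix, validate_meta

CLASS_STABLE = "stable"
CLASS_UNSTABLE = "unstable"
CLASS_CLINICAL = "clinical"
CLASS_BACKGROUND = "background"


@dataclass(frozen=True)
class SimConfig:
    """Study design and effect sizes of the synthetic cohort."""

    n_genes: int = 200
    n_stable: int = 5
    n_unstable: int = 45
    n_clinical: int = 0
    n_patients_paired: int = 40
    n_tumor_only: int = 160
    subgroup_names: tuple[str, ...] = ("ERpos", "Her2over", "TNBC")
    # mimics the 795:39:125 ER+/Her2/TNBC imbalance of the cohort structure
    subgroup_props: tuple[float, ...] = (795 / 959, 39 / 959, 125 / 959)
    # library sizes: log-normal around ~5 million reads
    lib_size_meanlog: float = math.log(5e6)
    lib_size_sdlog: float = 0.35
    # per-gene baseline mean CPM: log10-uniform over ~1..20000
    cpm_log10_range: tuple[float, float] = (0.0, 4.3)
    # planted stable genes are well expressed (~50..5000 CPM)
    stable_cpm_log10_range: tuple[float, float] = (1.7, 3.7)
    dispersion: float = 0.2
    stable_dispersion: float = 0.05
    stable_max_lfc: float = 0.05
    unstable_lfc_range: tuple[float, float] = (0.5, 2.0)
    background_tn_sd: float = 0.2
    background_subtype_sd: float = 0.15
    clinical_slope: float = 0.3  # log2-CPM per stage code unit
    outlier_fraction: float = 0.03
    outlier_shift: float = 2.0  # |log2| shift applied to outlier samples
    pair_effect_sd: float = 0.4  # shared patient effect, log2-CPM
    # planted stable genes are stable *between patients* too: their total
    # biological dispersion (patient effect + NB) is low by definition
    stable_pair_effect_sd: float = 0.15
    missing_clinical_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_patients_paired + self.n_tumor_only <= 0:
            raise ValueError("degenerate design: need genes and samples")
        if self.n_stable + self.n_unstable + self.n_clinical > self.n_genes:
            raise ValueError("planted gene classes exceed n_genes")
        if abs(sum(self.subgroup_props) - 1.0) > 1e-9:
            raise ValueError("subgroup proportions must sum to 1")
        if len(self.subgroup_props) != len(self.subgroup_names):
            raise ValueError("subgroup names/proportions length mismatch")


def _gene_classes(cfg: SimConfig) -> list[str]:
    return (
        [CLASS_STABLE] * cfg.n_stable
        + [CLASS_UNSTABLE] * cfg.n_unstable
        + [CLASS_CLINICAL] * cfg.n_clinical
        + [CLASS_BACKGROUND] * (cfg.n_genes - cfg.n_stable - cfg.n_unstable - cfg.n_clinical)
    )


def _balance_signs(
    weights: np.ndarray, magnitudes: np.ndarray, signs: np.ndarray
) -> np.ndarray:
    """Flip effect signs so abundance-weighted totals stay balanced.

    CPM normalization divides by each sample's total; if planted fold
    changes shifted the configured total of one condition, every gene --
    including the planted stable ones -- would acquire a spurious relative
    fold change.  Effect magnitudes stay as drawn; only signs are chosen,
    greedily from the largest contribution down, to keep
    sum_g w_g * (2**(s_g * l_g) - 1) near zero.
    """
    plus = weights * (np.exp2(magnitudes) - 1.0)
    minus = weights * (np.exp2(-magnitudes) - 1.0)
    order = np.argsort(-np.maximum(plus, -minus))
    out = signs.copy()
    total = 0.0
    for i in order:
        if magnitudes[i] == 0.0:
            continue
        if abs(total + plus[i]) <= abs(total + minus[i]):
            out[i] = 1.0
            total += plus[i]
        else:
            out[i] = -1.0
            total += minus[i]
    return out


def _sample_clinical(rng: np.random.Generator, n: int, missing_frac: float) -> pd.DataFrame:
    """Ordinal clinical codes with cohort-like frequencies and missingness."""
    T = rng.choice([1, 2, 3, 4], size=n, p=[0.38, 0.35, 0.18, 0.09])
    N = rng.choice([0, 1, 2, 3], size=n, p=[0.50, 0.20, 0.20, 0.10])
    M = rng.choice([0, 1], size=n, p=[0.97, 0.03])
    stage = np.clip(T + N, 1, 7)
    neoplasm = rng.choice([0, 1], size=n, p=[0.85, 0.15])
    df = pd.DataFrame(
        {"T": T, "N": N, "M": M, "stage": stage, "neoplasm_status": neoplasm},
        dtype=float,
    )
    for col in ("T", "N", "stage"):
        df.loc[rng.random(n) < missing_frac, col] = np.nan
    df.loc[rng.random(n) < missing_frac / 2, "neoplasm_status"] = np.nan
    return df


def generate_dataset(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, sample metadata, per-gene ground truth).

    Deterministic given ``cfg.seed``.  The ground-truth table carries each
    gene's class, planted tumor/normal and per-subgroup log2 fold changes,
    clinical slope, dispersion and the configured mean CPM actually used
    after per-sample renormalization.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    n_pat = cfg.n_patients_paired + cfg.n_tumor_only
    patients = [f"P{i+1:04d}" for i in range(n_pat)]

    records = []
    for i, pat in enumerate(patients):
        records.append((f"{pat}-T", pat, "tumor"))
        if i < cfg.n_patients_paired:
            records.append((f"{pat}-N", pat, "normal"))
    meta = pd.DataFrame(records, columns=["sample_id", "patient_id", "tissue"])

    # fixed largest-remainder allocation: the subgroup imbalance is part of
    # the study design, only the patient assignment is random
    quota = np.array(cfg.subgroup_props) * n_pat
    sizes = np.floor(quota).astype(int)
    remainder = np.argsort(-(quota - sizes))
    sizes[remainder[: n_pat - sizes.sum()]] += 1
    subtypes = np.repeat(np.array(cfg.subgroup_names), sizes)
    rng.shuffle(subtypes)
    subtype_of = dict(zip(patients, subtypes))
    meta["subtype"] = [
        subtype_of[p] if t == "tumor" else "" for p, t in zip(meta["patient_id"], meta["tissue"])
    ]

    clin = _sample_clinical(rng, n_pat, cfg.missing_clinical_fraction)
    clin.index = patients
    for col in clin.columns:
        meta[col] = clin.loc[meta["patient_id"], col].to_numpy()

    gene_ids = [f"mir-{i+1:04d}" for i in range(G)]
    classes = np.array(_gene_classes(cfg))

    lo, hi = cfg.cpm_log10_range
    base_log2 = rng.uniform(lo, hi, size=G) * math.log2(10.0)
    slo, shi = cfg.stable_cpm_log10_range
    stable_mask = classes == CLASS_STABLE
    base_log2[stable_mask] = rng.uniform(slo, shi, size=stable_mask.sum()) * math.log2(10.0)

    # planted group effects (log2-CPM)
    k = len(cfg.subgroup_names)
    tn_lfc = np.zeros(G)
    sub_lfc = np.zeros((G, k))
    clin_slope = np.zeros(G)
    flo, fhi = cfg.unstable_lfc_range
    for g in range(G):
        cls = classes[g]
        if cls == CLASS_STABLE:
            tn_lfc[g] = rng.uniform(-cfg.stable_max_lfc, cfg.stable_max_lfc)
            sub_lfc[g] = rng.uniform(-cfg.stable_max_lfc, cfg.stable_max_lfc, size=k)
        elif cls == CLASS_UNSTABLE:
            which = rng.integers(0, 3)  # 0: T/N, 1: subgroup, 2: both
            if which in (0, 2):
                tn_lfc[g] = rng.choice([-1, 1]) * rng.uniform(flo, fhi)
            if which in (1, 2):
                sub_lfc[g] = rng.choice([-1, 1], size=k) * rng.uniform(flo, fhi, size=k)
        elif cls == CLASS_CLINICAL:
            clin_slope[g] = cfg.clinical_slope * rng.choice([-1, 1])
        else:
            tn_lfc[g] = rng.normal(0.0, cfg.background_tn_sd)
            sub_lfc[g] = rng.normal(0.0, cfg.background_subtype_sd, size=k)

    # keep configured totals comparable across conditions (see _balance_signs)
    w_base = np.exp2(base_log2)
    tn_signs = _balance_signs(w_base, np.abs(tn_lfc), np.sign(tn_lfc))
    tn_lfc = tn_signs * np.abs(tn_lfc)
    for j in range(k):
        w_tumor = w_base * np.exp2(tn_lfc)
        s = _balance_signs(w_tumor, np.abs(sub_lfc[:, j]), np.sign(sub_lfc[:, j]))
        sub_lfc[:, j] = s * np.abs(sub_lfc[:, j])

    dispersion = np.where(stable_mask, cfg.stable_dispersion, cfg.dispersion)

    samples = list(meta["sample_id"])
    S = len(samples)
    is_tumor = (meta["tissue"] == "tumor").to_numpy()
    sub_index = np.array(
        [
            cfg.subgroup_names.index(subtype_of[p]) for p in meta["patient_id"]
        ]
    )
    pat_index = np.array([patients.index(p) for p in meta["patient_id"]])
    stage_codes = clin["stage"].to_numpy()
    stage_centered = np.nan_to_num(stage_codes - np.nanmean(stage_codes))

    pair_sd = np.where(stable_mask, cfg.stable_pair_effect_sd, cfg.pair_effect_sd)
    pair_eff = rng.normal(0.0, 1.0, size=(G, n_pat)) * pair_sd[:, None]

    log2cpm = np.tile(base_log2[:, None], (1, S))
    log2cpm += pair_eff[:, pat_index]
    log2cpm[:, is_tumor] += tn_lfc[:, None]
    log2cpm[:, is_tumor] += sub_lfc[:, sub_index[is_tumor]]
    log2cpm[:, is_tumor] += np.outer(clin_slope, stage_centered[pat_index[is_tumor]])

    unstable_rows = np.where(classes == CLASS_UNSTABLE)[0]
    if cfg.outlier_fraction > 0 and unstable_rows.size:
        out_mask = rng.random((unstable_rows.size, S)) < cfg.outlier_fraction
        shifts = rng.choice([-1.0, 1.0], size=out_mask.shape) * cfg.outlier_shift
        log2cpm[unstable_rows] += out_mask * shifts

    cpm = np.exp2(log2cpm)
    cpm *= 1e6 / cpm.sum(axis=0, keepdims=True)

    lib = rng.lognormal(cfg.lib_size_meanlog, cfg.lib_size_sdlog, size=S)
    mu = cpm * lib[None, :] / 1e6
    n_param = 1.0 / dispersion
    p_param = n_param[:, None] / (n_param[:, None] + mu)
    counts = rng.negative_binomial(n_param[:, None], p_param)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    counts_df.index.name = "gene_id"

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "tn_log2fc": tn_lfc,
            **{
                f"subtype_log2fc_{name}": sub_lfc[:, j]
                for j, name in enumerate(cfg.subgroup_names)
            },
            "clinical_slope": clin_slope,
            "dispersion": dispersion,
            "mean_cpm": cpm.mean(axis=1),
        }
    ).set_index("gene_id")

    meta = meta.fillna({"subtype": ""})
    return CountMatrix(counts_df), validate_meta(meta), truth


@dataclass(frozen=True)
class QpcrAssay:
    """One qPCR assay: baseline Ct, planted tumor shift, technical noise."""

    baseline_ct: float
    tumor_log2fc: float = 0.0  # up-regulation lowers tumor Ct by this much
    noise_sd: float = 0.4


@dataclass(frozen=True)
class QpcrConfig:
    """A paired-design qPCR panel.

    Defaults mirror a 34-pair validation panel: an abundant but drifting
    small-RNA control, a moderately expressed tumor-shifted miRNA control,
    a stable candidate internal control, and a strongly up-regulated
    oncomiR target.
    """

    n_pairs: int = 34
    assays: dict[str, QpcrAssay] = field(
        default_factory=lambda: {
            "target": QpcrAssay(baseline_ct=28.0, tumor_log2fc=2.0),
            "ic-stable": QpcrAssay(baseline_ct=29.0, tumor_log2fc=0.0),
            "ic-drift": QpcrAssay(baseline_ct=26.6, tumor_log2fc=2.0),
            "ic-shifted": QpcrAssay(baseline_ct=31.0, tumor_log2fc=0.6),
        }
    )
    sample_offset_sd: float = 0.5  # per-sample input variation, hits all assays
    detection_limit: float = 37.0  # Ct above this is reported undetected
    seed: int = 0


def generate_qpcr(cfg: QpcrConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (Ct table samples x assays, metadata) for a paired design.

    Ct = baseline + sample offset - tumor_log2fc * [tumor] + noise; Cts
    beyond the detection limit are reported undetected (NaN).
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    for i in range(cfg.n_pairs):
        pat = f"Q{i+1:03d}"
        records.append((f"{pat}-T", pat, "tumor"))
        records.append((f"{pat}-N", pat, "normal"))
    meta = pd.DataFrame(records, columns=["sample_id", "patient_id", "tissue"])
    meta["subtype"] = ""
    for col in ("T", "N", "M", "stage", "neoplasm_status"):
        meta[col] = np.nan

    offset = rng.normal(0.0, cfg.sample_offset_sd, size=len(meta))
    is_tumor = (meta["tissue"] == "tumor").to_numpy()
    ct = {}
    for name, assay in cfg.assays.items():
        vals = (
            assay.baseline_ct
            + offset
            - assay.tumor_log2fc * is_tumor
            + rng.normal(0.0, assay.noise_sd, size=len(meta))
        )
        vals = np.where(vals > cfg.detection_limit, np.nan, vals)
        ct[name] = vals
    table = pd.DataFrame(ct, index=pd.Index(meta["sample_id"], name="sample_id"))
    return table, validate_meta(meta)
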