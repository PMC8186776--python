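"""Spearman association of expression with ordinal clinical features.

Clinical features (tumor size T, nodal status N, metastasis M, pathologic
stage, neoplasm status at follow-up) are encoded as ordinal integers and
correlated with expression-derived vectors.  Each defined association
feeds two scoring components: S_Cp on x = -log2(p) and S_Cr on x = |r_s|.
Trimming a correlation slice removes the *samples* whose expression falls
outside the percentile window, and their clinical codes with them, so the
expression and clinical vectors stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (
    CLINICAL_FEATURES,
    CpmMatrix,
    W_MID,
    complete_pairs,
    tissue_samples,
)

# ordinal encodings; codes strictly increase with severity
STAGE_CODES = {"I": 1, "IIA": 2, "IIB": 3, "IIIA": 4, "IIIB": 5, "IIIC": 6, "IV": 7}
NEOPLASM_CODES = {"tumor-free": 0, "with-tumor": 1, "tumor free": 0, "with tumor": 1}
_FEATURE_RANGE = {"T": (1, 4), "N": (0, 3), "M": (0, 1)}
_MISSING_TOKENS = {"", "na", "nan", "none", "unknown", "undefined"}


class EncodingError(ValueError):
    """A clinical value that is neither a known label nor a valid code."""


def _encode_one(feature: str, value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s.lower() in _MISSING_TOKENS or s.lower().startswith("undefined"):
        return np.nan
    if feature == "stage":
        if s.upper() in STAGE_CODES:
            return float(STAGE_CODES[s.upper()])
    if feature == "neoplasm_status":
        if s.lower() in NEOPLASM_CODES:
            return float(NEOPLASM_CODES[s.lower()])
    # bare integer codes (incl. "T2"-style prefixed labels)
    if feature in _FEATURE_RANGE and s[:1].upper() == feature[:1].upper():
        s = s[1:]
    try:
        code = float(s)
    except ValueError:
        raise EncodingError(f"unknown {feature} category {value!r}") from None
    if code != int(code) or code < 0:
        raise EncodingError(f"{feature} code must be a non-negative integer, got {value!r}")
    lo, hi = _FEATURE_RANGE.get(feature, (0, np.inf))
    if feature in _FEATURE_RANGE and not lo <= code <= hi:
        raise EncodingError(f"{feature} code {value!r} outside {lo}..{hi}")
    return code


def encode_clinical(meta: pd.DataFrame, feature: str) -> pd.Series:
    """Per-sample ordinal codes (float, NaN = missing), indexed by sample id."""
    if feature not in CLINICAL_FEATURES:
        raise ValueError(f"unsupported clinical feature {feature!r}")
    codes = meta[feature].map(lambda v: _encode_one(feature, v))
    return pd.Series(codes.to_numpy(dtype=float), index=meta["sample_id"], name=feature)


@dataclass(frozen=True)
class AssociationResult:
    r_s: float
    p: float
    n_used: int


def _rank_average_ties(a: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values receiving their average rank."""
    order = np.argsort(a, kind="mergesort")
    sa = a[order]
    n = a.size
    boundary = np.empty(n, dtype=bool)
    boundary[0] = True
    boundary[1:] = sa[1:] != sa[:-1]
    gid = np.cumsum(boundary) - 1
    counts = np.bincount(gid)
    ends = np.cumsum(counts)
    avg = (ends - counts + ends + 1) / 2.0
    ranks = np.empty(n, dtype=float)
    ranks[order] = avg[gid]
    return ranks


def spearman_assoc(x, y) -> AssociationResult | None:
    """Spearman correlation with average-rank ties and t-approximation p.

    Pairs with a missing entry are dropped.  Returns None ("undefined
    association") when fewer than 3 pairs remain or either vector is
    constant; the caller skips the corresponding component instances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return None
    rx = _rank_average_ties(x)
    ry = _rank_average_ties(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return AssociationResult(r_s=r, p=min(p, 1.0), n_used=n)


@dataclass(frozen=True)
class SliceAssociation:
    vector: str  # expression-vector label, e.g. "cpm:tumor"
    feature: str
    result: AssociationResult | None


def _trimmed_slice(values: np.ndarray, sample_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Keep samples whose value lies inside the (10,90) window of *values*."""
    plo, phi = np.percentile(values, [W_MID.lo, W_MID.hi])
    keep = (values >= plo) & (values <= phi)
    if not keep.any():
        keep[:] = True
    return values[keep], [s for s, k in zip(sample_ids, keep) if k]


def _assoc_over_features(
    vector_label: str,
    values: np.ndarray,
    clinical_samples: list[str],
    codes: dict[str, pd.Series],
) -> list[SliceAssociation]:
    out = []
    for feature in CLINICAL_FEATURES:
        y = codes[feature].reindex(clinical_samples).to_numpy(dtype=float)
        out.append(SliceAssociation(vector_label, feature, spearman_assoc(values, y)))
    return out


def clinical_codes(meta: pd.DataFrame) -> dict[str, pd.Series]:
    return {f: encode_clinical(meta, f) for f in CLINICAL_FEATURES}


def correlation_slices_two_group(
    cpm: CpmMatrix,
    gene: str,
    meta: pd.DataFrame,
    codes: dict[str, pd.Series] | None = None,
    paired_lfc: np.ndarray | None = None,
) -> list[SliceAssociation]:
    """The 15 (3 vectors x 5 features) correlation slices of two-group mode.

    Vectors: (10,90)-trimmed tumor CPM, (10,90)-trimmed normal CPM, and the
    (10,90)-trimmed per-pair log2 fold change.  Normal samples and pairs
    carry the clinical annotation of the patient's tumor.  Undefined
    associations are reported with ``result=None``.
    """
    if codes is None:
        codes = clinical_codes(meta)
    out: list[SliceAssociation] = []

    tumor_of_patient = meta[meta["tissue"] == "tumor"].set_index("patient_id")["sample_id"]
    patient_of_sample = meta.set_index("sample_id")["patient_id"]

    for tissue in ("tumor", "normal"):
        samples = tissue_samples(meta, tissue)
        if not samples:
            for feature in CLINICAL_FEATURES:
                out.append(SliceAssociation(f"cpm:{tissue}", feature, None))
            continue
        values = cpm.gene(gene, samples)
        vals, kept = _trimmed_slice(values, samples)
        # clinical codes come from the patient's tumor sample
        clin_samples = [tumor_of_patient.get(patient_of_sample[s], s) for s in kept]
        out.extend(_assoc_over_features(f"cpm:{tissue}", vals, clin_samples, codes))

    pairs = complete_pairs(meta)
    if pairs:
        if paired_lfc is None:
            from .scoring import paired_log_fc

            paired_lfc = paired_log_fc(cpm, gene, pairs)
        tum_samples = [t for t, _ in pairs]
        vals, kept = _trimmed_slice(np.asarray(paired_lfc, dtype=float), tum_samples)
        out.extend(_assoc_over_features("paired_lfc", vals, kept, codes))
    else:
        for feature in CLINICAL_FEATURES:
            out.append(SliceAssociation("paired_lfc", feature, None))
    return out


def correlation_slices_subgroup(
    cpm: CpmMatrix,
    gene: str,
    samples: list[str],
    label: str,
    codes: dict[str, pd.Series],
) -> list[SliceAssociation]:
    """The 5 correlation slices of one subgroup: trimmed CPM vs each feature."""
    values = cpm.gene(gene, samples)
    vals, kept = _trimmed_slice(values, samples)
    return _assoc_over_features(f"cpm:{label}", vals, kept, codes)
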