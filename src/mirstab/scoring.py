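"""Multi-component expression-stability scoring.

Every gene receives a set of component instances.  Each instance has a raw
value x (a fold change, a coefficient of variation, an outlier ratio, an
abundance transform or a clinical-correlation statistic), mapped to a score
in (0, 100] by a falling sigmoid

    S = 100 / (1 + Sq * (max(x - IV, 0) / (IP - IV))**CS)

so that any x at or below the ideal value IV scores 100 and x at the
inflection point IP scores 100/(1+Sq).  The overall stability score is the
weighted geometric mean of the instance factors min(S_i + CA_i, 100): the
constant add CA_i floors a collapsing component so it cannot annihilate
the product, and the cap keeps the overall score on the 0-100 scale (an
ideal gene with every component at 100 scores exactly 100).

Two grouping modes are provided.  Two-group (tumor vs normal) instantiates
the full published component table, including the matched-pair fold-change
families.  Multigroup (tumor subtypes) drops the paired families, computes
the pooled fold change between every subgroup pair (weight split across
pairs), applies the per-group families to each subgroup (weight split
across subgroups) and keeps a single pooled average-expression component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical import (
    SliceAssociation,
    clinical_codes,
    spearman_assoc,
)
from .data_io import (
    CLINICAL_FEATURES,
    CpmMatrix,
    DataError,
    PercentileWindow,
    W_HIGH,
    W_LOW,
    W_MID,
    complete_pairs,
    tissue_samples,
    validate_meta,
)
from .params import (
    DEFAULT_COMPONENT_PARAMS,
    ComponentParams,
)

logger = logging.getLogger(__name__)

#: CPM floor used inside log2 ratios so that zero expression stays defined
PSEUDO_CPM = 0.5

#: floor for p-values before -log2 (S_Cp) to avoid -log2(0)
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ComponentInstance:
    family: str
    slice: str
    params: ComponentParams
    x: float
    score: float
    weight: float

    @property
    def label(self) -> str:
        return f"{self.family}@{self.slice}"


def sigmoid_score(x: float, p: ComponentParams) -> float:
    """Falling sigmoid mapping a raw component value to (0, 100]."""
    if x <= p.iv:
        return 100.0
    if math.isinf(x):
        return 0.0
    return 100.0 / (1.0 + p.sq * ((x - p.iv) / (p.ip - p.iv)) ** p.cs)


def overall_score(instances: Sequence[ComponentInstance]) -> float:
    """Weighted geometric mean of min(score + CA, 100) over all instances."""
    if not instances:
        raise ValueError("no component instances")
    factors = []
    log_sum = 0.0
    w_sum = 0.0
    for inst in instances:
        factor = min(inst.score + inst.params.ca, 100.0)
        if factor <= 0.0:
            raise ValueError(f"non-positive factor for {inst.label} (score+CA={factor})")
        if inst.weight <= 0:
            raise ValueError(f"non-positive weight for {inst.label}")
        factors.append(factor)
        log_sum += inst.weight * math.log(factor)
        w_sum += inst.weight
    if all(f == factors[0] for f in factors):  # exact geometric-mean identity
        return factors[0]
    return math.exp(log_sum / w_sum)


def _window_values(arr: np.ndarray, w: PercentileWindow) -> np.ndarray:
    """Window trim; falls back to the full vector when the interpolated
    percentile bounds exclude every value (possible only for tiny n)."""
    plo, phi = np.percentile(arr, [w.lo, w.hi])
    out = arr[(arr >= plo) & (arr <= phi)]
    return out if out.size else arr


def _floored_ratio_log2(num: float, den: float, pseudo: float = PSEUDO_CPM) -> float:
    return math.log2(max(num, pseudo) / max(den, pseudo))


def pooled_log_fc(
    cpm: CpmMatrix,
    gene: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    w: PercentileWindow = W_MID,
) -> float:
    """log2 ratio of window-trimmed mean CPM of group A over group B.

    Means below 0.5 CPM are floored at 0.5 before the ratio, so zero
    expression on either side stays defined and two silent groups give 0.
    """
    if not len(group_a) or not len(group_b):
        raise DataError("pooled fold change needs two non-empty groups")
    ma = float(np.mean(_window_values(cpm.gene(gene, group_a), w)))
    mb = float(np.mean(_window_values(cpm.gene(gene, group_b), w)))
    return _floored_ratio_log2(ma, mb)


def paired_log_fc(
    cpm: CpmMatrix, gene: str, pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Per matched pair log2(CPM tumor / CPM normal), pair order preserved."""
    if not len(pairs):
        raise DataError("paired fold change needs at least one pair")
    t = cpm.gene(gene, [p[0] for p in pairs])
    n = cpm.gene(gene, [p[1] for p in pairs])
    return np.log2(np.maximum(t, PSEUDO_CPM) / np.maximum(n, PSEUDO_CPM))


class ScoringContext:
    """Precomputed sample bookkeeping shared by every gene's scoring.

    Holds the CPM matrix as a dense array, positional indices for tissues,
    matched pairs and subgroups, and per-slice clinical code vectors (the
    codes of the patient's *tumor* sample, which normal samples and pairs
    inherit).
    """

    def __init__(
        self,
        cpm: CpmMatrix,
        meta: pd.DataFrame,
        mode: str,
        subgroups: Mapping[str, Sequence[str]] | None = None,
    ) -> None:
        self.mode = mode
        self.X = cpm.cpm.to_numpy(dtype=float)
        self.gene_pos = {g: i for i, g in enumerate(cpm.gene_ids)}
        spos = {s: i for i, s in enumerate(cpm.sample_ids)}

        codes = clinical_codes(meta)
        tumor_of_patient = (
            meta[meta["tissue"] == "tumor"].set_index("patient_id")["sample_id"]
        )
        patient_of = meta.set_index("sample_id")["patient_id"]

        def code_vec(samples: list[str]) -> dict[str, np.ndarray]:
            # clinical values of the patient's tumor sample (fallback: own)
            clin_samples = [tumor_of_patient.get(patient_of[s], s) for s in samples]
            return {
                f: codes[f].reindex(clin_samples).to_numpy(dtype=float)
                for f in CLINICAL_FEATURES
            }

        self.tumor = tissue_samples(meta, "tumor")
        self.normal = tissue_samples(meta, "normal")
        self.tumor_pos = np.array([spos[s] for s in self.tumor], dtype=int)
        self.normal_pos = np.array([spos[s] for s in self.normal], dtype=int)

        self.pairs = complete_pairs(meta)
        self.pair_t_pos = np.array([spos[t] for t, _ in self.pairs], dtype=int)
        self.pair_n_pos = np.array([spos[n] for _, n in self.pairs], dtype=int)

        self.codes_tumor = code_vec(self.tumor)
        self.codes_normal = code_vec(self.normal)
        self.codes_pairs = code_vec([t for t, _ in self.pairs])

        self.subgroup_pos: dict[str, np.ndarray] = {}
        self.codes_subgroup: dict[str, dict[str, np.ndarray]] = {}
        if subgroups is not None:
            for name in sorted(subgroups):
                members = list(subgroups[name])
                self.subgroup_pos[name] = np.array([spos[s] for s in members], dtype=int)
                self.codes_subgroup[name] = code_vec(members)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.X[self.gene_pos[gene]]
        except KeyError:
            raise DataError(f"gene {gene!r} not in CPM matrix") from None


def _make_instance(
    family: str,
    slc: str,
    x: float | None,
    params: Mapping[str, ComponentParams],
    weight: float | None = None,
) -> ComponentInstance | None:
    """Build an instance, or None (skip, weight removed) for undefined x."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        logger.debug("skipping undefined component %s@%s", family, slc)
        return None
    p = params[family]
    return ComponentInstance(
        family=family,
        slice=slc,
        params=p,
        x=float(x),
        score=sigmoid_score(float(x), p),
        weight=p.w if weight is None else weight,
    )


def _dispersion_values(values: np.ndarray) -> dict[str, float | None]:
    """Raw x of the per-group families S_EStD, S_EoH, S_EoL on a CPM vector."""
    mid = _window_values(values, W_MID)
    high = _window_values(values, W_HIGH)
    low = _window_values(values, W_LOW)
    out: dict[str, float | None] = {}
    if mid.size >= 3 and mid.mean() > 0:
        out["S_EStD"] = float(np.std(mid, ddof=1) / mid.mean())
    else:
        out["S_EStD"] = None
    out["S_EoH"] = _floored_ratio_log2(float(high.mean()), float(mid.mean()))
    out["S_EoL"] = _floored_ratio_log2(float(mid.mean()), float(low.mean()))
    return out


def _ea_value(values: np.ndarray) -> float:
    """S_EA raw value 1/log2(trimmed mean CPM); infinite at <= 1 CPM."""
    m = float(np.mean(_window_values(values, W_MID)))
    if m <= 1.0:
        return math.inf
    return 1.0 / math.log2(m)


def _pooled_x(row: np.ndarray, pos_a: np.ndarray, pos_b: np.ndarray) -> float:
    ma = float(np.mean(_window_values(row[pos_a], W_MID)))
    mb = float(np.mean(_window_values(row[pos_b], W_MID)))
    return abs(_floored_ratio_log2(ma, mb))


def _trim_mask(values: np.ndarray) -> np.ndarray:
    plo, phi = np.percentile(values, [W_MID.lo, W_MID.hi])
    keep = (values >= plo) & (values <= phi)
    return keep if keep.any() else np.ones_like(keep)


def _assoc_slices(
    label: str, values: np.ndarray, codes: dict[str, np.ndarray]
) -> list[SliceAssociation]:
    """Trim values to their (10,90) window, correlate with each feature."""
    keep = _trim_mask(values)
    vals = values[keep]
    out = []
    for feature in CLINICAL_FEATURES:
        out.append(SliceAssociation(label, feature, spearman_assoc(vals, codes[feature][keep])))
    return out


def _clinical_instances(
    slices: Sequence[SliceAssociation],
    params: Mapping[str, ComponentParams],
    weight_cp: float | None = None,
    weight_cr: float | None = None,
) -> list[ComponentInstance]:
    out = []
    for sa in slices:
        slc = f"{sa.vector}|{sa.feature}"
        if sa.result is None:
            continue
        x_p = -math.log2(max(sa.result.p, P_FLOOR))
        inst = _make_instance("S_Cp", slc, x_p, params, weight_cp)
        if inst:
            out.append(inst)
        inst = _make_instance("S_Cr", slc, abs(sa.result.r_s), params, weight_cr)
        if inst:
            out.append(inst)
    return out


def _two_group_instances(
    ctx: ScoringContext, row: np.ndarray, params: Mapping[str, ComponentParams]
) -> list[ComponentInstance]:
    instances: list[ComponentInstance | None] = []

    instances.append(
        _make_instance(
            "S_DP", "tumor|normal", _pooled_x(row, ctx.tumor_pos, ctx.normal_pos), params
        )
    )

    slices: list[SliceAssociation] = []
    if len(ctx.pairs):
        lfc = np.log2(
            np.maximum(row[ctx.pair_t_pos], PSEUDO_CPM)
            / np.maximum(row[ctx.pair_n_pos], PSEUDO_CPM)
        )
        mid = _window_values(lfc, W_MID)
        high = _window_values(lfc, W_HIGH)
        low = _window_values(lfc, W_LOW)
        for fam, val in (
            ("S_DL", abs(float(mid.mean()))),
            ("S_DoO", abs(float(high.mean()))),
            ("S_DoU", abs(float(low.mean()))),
            ("S_DLc", float(np.abs(mid).mean())),
        ):
            instances.append(_make_instance(fam, "paired", val, params))
        slices.extend(_assoc_slices("paired_lfc", lfc, ctx.codes_pairs))

    for tissue, pos, codes in (
        ("normal", ctx.normal_pos, ctx.codes_normal),
        ("tumor", ctx.tumor_pos, ctx.codes_tumor),
    ):
        disp = _dispersion_values(row[pos])
        for fam in ("S_EStD", "S_EoH", "S_EoL"):
            instances.append(_make_instance(fam, tissue, disp[fam], params))
        slices.extend(_assoc_slices(f"cpm:{tissue}", row[pos], codes))

    instances.append(_make_instance("S_EA", "tumor", _ea_value(row[ctx.tumor_pos]), params))
    instances.extend(_clinical_instances(slices, params))
    return [i for i in instances if i is not None]


def _multigroup_instances(
    ctx: ScoringContext, row: np.ndarray, params: Mapping[str, ComponentParams]
) -> list[ComponentInstance]:
    names = sorted(ctx.subgroup_pos)
    k = len(names)
    instances: list[ComponentInstance | None] = []

    n_pairs = math.comb(k, 2)
    for a, b in combinations(names, 2):
        x = _pooled_x(row, ctx.subgroup_pos[a], ctx.subgroup_pos[b])
        instances.append(
            _make_instance("S_DP", f"{a}|{b}", x, params, params["S_DP"].w / n_pairs)
        )

    for name in names:
        pos = ctx.subgroup_pos[name]
        if pos.size >= 2:
            disp = _dispersion_values(row[pos])
        else:
            disp = {"S_EStD": None, "S_EoH": None, "S_EoL": None}
        for fam in ("S_EStD", "S_EoH", "S_EoL"):
            instances.append(_make_instance(fam, name, disp[fam], params, params[fam].w / k))
        if pos.size >= 3:
            slices = _assoc_slices(f"cpm:{name}", row[pos], ctx.codes_subgroup[name])
            instances.extend(
                _clinical_instances(slices, params, params["S_Cp"].w / k, params["S_Cr"].w / k)
            )

    pooled = np.concatenate([ctx.subgroup_pos[n] for n in names])
    instances.append(_make_instance("S_EA", "pooled", _ea_value(row[pooled]), params))
    return [i for i in instances if i is not None]


def component_values_two_group(
    cpm: CpmMatrix,
    gene: str,
    meta: pd.DataFrame,
    params: Mapping[str, ComponentParams] | None = None,
    ctx: ScoringContext | None = None,
) -> list[ComponentInstance]:
    """All component instances of the two-group (tumor vs normal) mode."""
    params = params or DEFAULT_COMPONENT_PARAMS
    if ctx is None:
        if not tissue_samples(meta, "tumor") or not tissue_samples(meta, "normal"):
            raise DataError("two-group mode needs both tumor and normal samples")
        ctx = ScoringContext(cpm, meta, "two_group")
    if not len(ctx.pairs):
        logger.debug("no complete pairs: paired families skipped for %s", gene)
    return _two_group_instances(ctx, ctx.row(gene), params)


def component_values_multigroup(
    cpm: CpmMatrix,
    gene: str,
    subgroups: Mapping[str, Sequence[str]],
    meta: pd.DataFrame,
    params: Mapping[str, ComponentParams] | None = None,
    ctx: ScoringContext | None = None,
) -> list[ComponentInstance]:
    """Component instances of the multi-subgroup mode.

    Paired families are removed; pooled fold change is computed between
    every unordered subgroup pair at weight W_DP / C(k,2); the per-group
    families run once per subgroup at weight W / k; a single pooled
    average-expression component remains.
    """
    params = params or DEFAULT_COMPONENT_PARAMS
    if len(subgroups) < 2:
        raise DataError("multigroup mode needs at least 2 subgroups")
    for name, members in subgroups.items():
        if len(members) < 3:
            logger.warning("subgroup %r has fewer than 3 samples", name)
    if ctx is None:
        ctx = ScoringContext(cpm, meta, "multigroup", subgroups)
    return _multigroup_instances(ctx, ctx.row(gene), params)


@dataclass(frozen=True)
class ScoreTable:
    """Per-gene component scores, overall score and rank for one criterion."""

    table: pd.DataFrame  # index gene_id; component columns, "S_exp", "rank"
    criterion: str
    instances: dict[str, list[ComponentInstance]] = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def score_genes(
    cpm: CpmMatrix,
    meta: pd.DataFrame,
    mode: str = "two_group",
    params: Mapping[str, ComponentParams] | None = None,
    subgroups: Mapping[str, Sequence[str]] | None = None,
    genes: Sequence[str] | None = None,
    criterion: str | None = None,
) -> ScoreTable:
    """Score every gene under one grouping criterion.

    Ranks are 1-based by descending overall score; ties break
    lexicographically on gene id, so the ranking is a deterministic
    permutation of the gene set.
    """
    meta = validate_meta(meta)
    params = params or DEFAULT_COMPONENT_PARAMS
    gene_list = list(genes) if genes is not None else cpm.gene_ids
    if not gene_list:
        raise DataError("no genes to score")

    if mode == "two_group":
        if not tissue_samples(meta, "tumor") or not tissue_samples(meta, "normal"):
            raise DataError("two-group mode needs both tumor and normal samples")
        ctx = ScoringContext(cpm, meta, mode)
        compute = _two_group_instances
    elif mode == "multigroup":
        if subgroups is None:
            from .data_io import subtype_groups

            subgroups = subtype_groups(meta)
        for name, members in subgroups.items():
            if len(members) < 3:
                logger.warning("subgroup %r has fewer than 3 samples", name)
        ctx = ScoringContext(cpm, meta, mode, subgroups)
        compute = _multigroup_instances
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = {}
    all_instances = {}
    for gene in gene_list:
        try:
            inst = compute(ctx, ctx.row(gene), params)
            s_exp = overall_score(inst)
        except (DataError, ValueError) as e:
            raise DataError(f"scoring failed for gene {gene!r}: {e}") from e
        row = {i.label: i.score for i in inst}
        row["S_exp"] = s_exp
        rows[gene] = row
        all_instances[gene] = inst

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    order = sorted(gene_list, key=lambda g: (-table.loc[g, "S_exp"], g))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(order) + 1)
    label = criterion or mode
    return ScoreTable(table=table, criterion=label, instances=all_instances)
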