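"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive: percentiles by explicit
interpolation on a sorted copy, trimmed statistics by scanning lists,
Spearman by the textbook rank formula.  No code is shared with the
package's scoring path.
"""

import math


def naive_percentile(values, q):
    s = sorted(values)
    n = len(s)
    if n == 1:
        return s[0]
    h = (n - 1) * q / 100.0
    lo = int(math.floor(h))
    hi = int(math.ceil(h))
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def naive_window(values, lo, hi):
    plo = naive_percentile(values, lo)
    phi = naive_percentile(values, hi)
    out = [v for v in values if plo <= v <= phi]
    return out if out else list(values)


def naive_mean(values):
    return sum(values) / len(values)


def naive_sd(values):
    m = naive_mean(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def floored_log2_ratio(a, b, pseudo=0.5):
    return math.log2(max(a, pseudo) / max(b, pseudo))


def naive_pooled_x(vals_a, vals_b):
    ma = naive_mean(naive_window(vals_a, 10, 90))
    mb = naive_mean(naive_window(vals_b, 10, 90))
    return abs(floored_log2_ratio(ma, mb))


def naive_paired_lfc(tumor_vals, normal_vals, pseudo=0.5):
    return [
        math.log2(max(t, pseudo) / max(n, pseudo))
        for t, n in zip(tumor_vals, normal_vals)
    ]


def naive_paired_family_x(lfc):
    mid = naive_window(lfc, 10, 90)
    return {
        "S_DL": abs(naive_mean(mid)),
        "S_DoO": abs(naive_mean(naive_window(lfc, 90, 100))),
        "S_DoU": abs(naive_mean(naive_window(lfc, 0, 10))),
        "S_DLc": naive_mean([abs(v) for v in mid]),
    }


def naive_dispersion_x(vals):
    mid = naive_window(vals, 10, 90)
    out = {}
    out["S_EStD"] = naive_sd(mid) / naive_mean(mid) if len(mid) >= 3 else None
    out["S_EoH"] = floored_log2_ratio(
        naive_mean(naive_window(vals, 90, 100)), naive_mean(mid)
    )
    out["S_EoL"] = floored_log2_ratio(
        naive_mean(mid), naive_mean(naive_window(vals, 0, 10))
    )
    return out


def naive_ea_x(vals):
    m = naive_mean(naive_window(vals, 10, 90))
    return 1.0 / math.log2(m) if m > 1.0 else math.inf


def naive_ranks(values):
    """Average-tie ranks, quadratic-time textbook definition."""
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def naive_spearman(x, y):
    """(r_s, p) by the rank-Pearson formula and t approximation."""
    from scipy import stats

    rx = naive_ranks(x)
    ry = naive_ranks(y)
    n = len(x)
    mx = naive_mean(rx)
    my = naive_mean(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    r = num / den
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * stats.t.sf(abs(t), n - 2)


def naive_sigmoid(x, iv, ip, cs, sq):
    if x <= iv:
        return 100.0
    return 100.0 / (1.0 + sq * ((x - iv) / (ip - iv)) ** cs)


def naive_weighted_geomean(factors_weights):
    num = sum(w * math.log(f) for f, w in factors_weights)
    den = sum(w for _, w in factors_weights)
    return math.exp(num / den)


def naive_beta_cdf_binomial(x, k, L):
    """P(Beta(k, L-k+1) <= x) via the binomial-sum identity."""
    return sum(
        math.comb(L, j) * x**j * (1 - x) ** (L - j) for j in range(k, L + 1)
    )


def naive_rra_rho(rvec):
    r = sorted(rvec)
    L = len(r)
    return min(naive_beta_cdf_binomial(r[k - 1], k, L) for k in range(1, L + 1))


def _oracle_trim_indices(vals):
    plo = naive_percentile(vals, 10)
    phi = naive_percentile(vals, 90)
    idx = [i for i, v in enumerate(vals) if plo <= v <= phi]
    return idx if idx else list(range(len(vals)))


def _oracle_clinical_x(label, vals, codes_by_feature, out):
    import math as _math

    idx = _oracle_trim_indices(vals)
    for feature, codes in codes_by_feature.items():
        pairs = [
            (vals[i], codes[i])
            for i in idx
            if codes[i] is not None and not _math.isnan(codes[i])
        ]
        if len(pairs) < 3:
            continue
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        if len(set(xs)) == 1 or len(set(ys)) == 1:
            continue
        r, p = naive_spearman(xs, ys)
        out[f"S_Cp@{label}|{feature}"] = -_math.log2(max(p, 1e-300))
        out[f"S_Cr@{label}|{feature}"] = abs(r)


def _clinical_code_lookup(meta):
    """feature -> {sample_id: code of the patient's tumor sample}."""
    import math as _math

    features = ("T", "N", "M", "stage", "neoplasm_status")
    tumor_of = {
        row["patient_id"]: row["sample_id"]
        for _, row in meta.iterrows()
        if row["tissue"] == "tumor"
    }
    by_sample = {f: {} for f in features}
    raw = {row["sample_id"]: row for _, row in meta.iterrows()}
    for _, row in meta.iterrows():
        src = raw.get(tumor_of.get(row["patient_id"], row["sample_id"]))
        for f in features:
            v = src[f]
            try:
                by_sample[f][row["sample_id"]] = float(v)
            except (TypeError, ValueError):
                by_sample[f][row["sample_id"]] = float("nan")
    return by_sample


def oracle_two_group_x(cpm_df, meta):
    """Every raw component value of two-group mode, computed naively."""
    lookup = _clinical_code_lookup(meta)
    tumor = [r["sample_id"] for _, r in meta.iterrows() if r["tissue"] == "tumor"]
    normal = [r["sample_id"] for _, r in meta.iterrows() if r["tissue"] == "normal"]
    t_of, n_of = {}, {}
    for _, r in meta.iterrows():
        (t_of if r["tissue"] == "tumor" else n_of)[r["patient_id"]] = r["sample_id"]
    pairs = [(t_of[p], n_of[p]) for p in sorted(set(t_of) & set(n_of))]

    out_all = {}
    for gene in cpm_df.index:
        row = cpm_df.loc[gene]
        out = {}
        tv = [row[s] for s in tumor]
        nv = [row[s] for s in normal]
        out["S_DP@tumor|normal"] = naive_pooled_x(tv, nv)
        if pairs:
            lfc = naive_paired_lfc([row[t] for t, _ in pairs], [row[n] for _, n in pairs])
            for fam, x in naive_paired_family_x(lfc).items():
                out[f"{fam}@paired"] = x
            _oracle_clinical_x(
                "paired_lfc",
                lfc,
                {f: [lookup[f][t] for t, _ in pairs] for f in lookup},
                out,
            )
        for tissue, vals, samples in (("normal", nv, normal), ("tumor", tv, tumor)):
            disp = naive_dispersion_x(vals)
            for fam, x in disp.items():
                if x is not None:
                    out[f"{fam}@{tissue}"] = x
            _oracle_clinical_x(
                f"cpm:{tissue}",
                vals,
                {f: [lookup[f][s] for s in samples] for f in lookup},
                out,
            )
        out["S_EA@tumor"] = naive_ea_x(tv)
        out_all[gene] = out
    return out_all


def oracle_multigroup_x(cpm_df, meta, subgroups):
    """Every raw component value of multigroup mode, computed naively."""
    from itertools import combinations

    lookup = _clinical_code_lookup(meta)
    names = sorted(subgroups)
    out_all = {}
    for gene in cpm_df.index:
        row = cpm_df.loc[gene]
        out = {}
        for a, b in combinations(names, 2):
            out[f"S_DP@{a}|{b}"] = naive_pooled_x(
                [row[s] for s in subgroups[a]], [row[s] for s in subgroups[b]]
            )
        pooled = []
        for name in names:
            samples = list(subgroups[name])
            vals = [row[s] for s in samples]
            pooled.extend(vals)
            if len(samples) >= 2:
                for fam, x in naive_dispersion_x(vals).items():
                    if x is not None:
                        out[f"{fam}@{name}"] = x
            if len(samples) >= 3:
                _oracle_clinical_x(
                    f"cpm:{name}",
                    vals,
                    {f: [lookup[f][s] for s in samples] for f in lookup},
                    out,
                )
        out["S_EA@pooled"] = naive_ea_x(pooled)
        out_all[gene] = out
    return out_all
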