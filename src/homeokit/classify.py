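"""Negative-binomial Wald testing and additivity / homoeolog-bias
classification of expression groups.

The test is deliberately explicit and simple: median-of-ratios size factors,
per-gene method-of-moments dispersion pooled across the two groups, a
delta-method standard error on the log ratio of normalized group means with a
0.5 pseudo-count, and a two-sided normal p-value. It trades the shrinkage
machinery of dedicated DE packages for a construction whose calibration can
be verified by simulation.

Relations are always reported first-named-group versus second: GT means the
first group is significantly higher.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    AdditivityCategory,
    BiasCategory,
    PatternClass,
    Relation,
)
from .quant import CountSet, compute_rpm, flag_expressed, sum_replicate_groups

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8
DEFAULT_ALPHA = 0.001


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ---------------------------------------------------------------------------
# NB Wald test

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over a geometric-mean reference.

    Only genes with all-positive counts contribute. Falls back to
    total-count ratios when no such gene exists.
    """
    mat = counts.values.astype(float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logs = np.log(mat[positive])
        ref = logs.mean(axis=1, keepdims=True)  # log geometric mean
        sf = np.exp(np.median(logs - ref, axis=0))
    else:
        totals = mat.sum(axis=0)
        if totals.sum() == 0:
            raise ValueError("all counts are zero; cannot compute size factors")
        sf = totals / np.exp(np.mean(np.log(np.where(totals > 0, totals, np.nan))))
        sf = np.where(np.isfinite(sf), sf, 1.0)
    return pd.Series(sf, index=counts.columns)


def _pooled_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion, df-weighted across both groups.

    Each per-gene estimate is floored at the across-gene median dispersion of
    well-covered genes: with 2-3 replicates per group the raw moment estimate
    collapses to zero for about half the genes, which makes the plug-in Wald
    statistic anticonservative; the global floor restores calibration without
    any distributional shrinkage machinery.
    """
    phis = []
    weights = []
    for norm in (norm_a, norm_b):
        n = norm.shape[1]
        if n < 2:
            continue
        mean = norm.mean(axis=1)
        var = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mean) / np.square(mean)
        phi = np.where(np.isfinite(phi), phi, 0.0)
        phis.append(phi * (n - 1))
        weights.append(n - 1)
    total = sum(weights)
    pooled = sum(phis) / total
    covered = (norm_a.mean(axis=1) > 5) & (norm_b.mean(axis=1) > 5)
    reference = pooled[covered] if covered.any() else pooled
    common = max(float(np.median(reference)), 0.0) if reference.size else 0.0
    return np.maximum(np.maximum(pooled, common), DISPERSION_FLOOR)


def nb_wald_test(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Test each gene for a difference in NB means between two groups.

    Returns a frame indexed by gene with columns mu_a, mu_b, log2fc (B over
    A), se (of the ln ratio), p, fdr, relation (A-vs-B). Genes with zero
    counts in every sample of both groups are skipped (absent from the
    output).
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("gene indexes differ between groups")
    pooled = pd.concat([counts_a, counts_b], axis=1)
    sf = size_factors(pooled)
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    norm_a = counts_a.values / sf.values[:n_a]
    norm_b = counts_b.values / sf.values[n_a:]

    keep = (counts_a.values.sum(axis=1) + counts_b.values.sum(axis=1)) > 0
    norm_a, norm_b = norm_a[keep], norm_b[keep]
    genes = counts_a.index[keep]

    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)
    phi = _pooled_dispersion(norm_a, norm_b)
    c = PSEUDOCOUNT
    lnfc = np.log(mu_b + c) - np.log(mu_a + c)
    se2 = (1.0 / n_a) * (1.0 / (mu_a + c) + phi) + (1.0 / n_b) * (1.0 / (mu_b + c) + phi)
    se = np.sqrt(se2)
    z = lnfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = bh_adjust(p)

    df = pd.DataFrame(
        {
            "mu_a": mu_a,
            "mu_b": mu_b,
            "log2fc": lnfc / np.log(2.0),
            "se": se,
            "p": p,
            "fdr": fdr,
        },
        index=genes,
    )
    df["relation"] = [
        relation_of(row.fdr, row.log2fc, alpha).value for row in df.itertuples()
    ]
    return df


def relation_of(fdr: float, log2fc: float, alpha: float = DEFAULT_ALPHA) -> Relation:
    """EQ unless fdr <= alpha; then GT if the first group is higher (log2fc,
    oriented B over A, negative), LT otherwise."""
    if fdr > alpha:
        return Relation.EQ
    return Relation.GT if log2fc < 0 else Relation.LT


# ---------------------------------------------------------------------------
# Category mappings

def classify_additivity(
    rel_bh_vs_mav: Relation, rel_bh_vs_bd: Relation, rel_bh_vs_bs: Relation
) -> AdditivityCategory:
    """Map the three hybrid-total relations to an additivity category."""
    if rel_bh_vs_mav is Relation.EQ:
        return AdditivityCategory.ADDITIVE
    if rel_bh_vs_bd is Relation.EQ and rel_bh_vs_bs is not Relation.EQ:
        return AdditivityCategory.ELD_BD
    if rel_bh_vs_bs is Relation.EQ and rel_bh_vs_bd is not Relation.EQ:
        return AdditivityCategory.ELD_BS
    if rel_bh_vs_bd is Relation.GT and rel_bh_vs_bs is Relation.GT:
        return AdditivityCategory.TRANSGRESSIVE_UP
    if rel_bh_vs_bd is Relation.LT and rel_bh_vs_bs is Relation.LT:
        return AdditivityCategory.TRANSGRESSIVE_DOWN
    return AdditivityCategory.OTHER_NONADDITIVE


_BIAS_TABLE = {
    (Relation.EQ, Relation.EQ): BiasCategory.NO_BIAS,
    (Relation.GT, Relation.GT): BiasCategory.BIAS_RETAINED,
    (Relation.LT, Relation.LT): BiasCategory.BIAS_RETAINED,
    (Relation.GT, Relation.EQ): BiasCategory.BIAS_LOST,
    (Relation.LT, Relation.EQ): BiasCategory.BIAS_LOST,
    (Relation.EQ, Relation.GT): BiasCategory.BIAS_GAINED,
    (Relation.EQ, Relation.LT): BiasCategory.BIAS_GAINED,
    (Relation.GT, Relation.LT): BiasCategory.BIAS_REVERSED,
    (Relation.LT, Relation.GT): BiasCategory.BIAS_REVERSED,
}


def classify_bias(
    rel_bd_vs_bs: Relation, rel_bhbd_vs_bhbs: Relation
) -> tuple[BiasCategory, PatternClass]:
    """Map (ancestral relation, homoeolog relation) to a bias category."""
    category = _BIAS_TABLE[(rel_bd_vs_bs, rel_bhbd_vs_bhbs)]
    pattern = (
        PatternClass.ANCESTRAL
        if category in (BiasCategory.NO_BIAS, BiasCategory.BIAS_RETAINED)
        else PatternClass.NONANCESTRAL
    )
    return category, pattern


# ---------------------------------------------------------------------------
# Whole-transcriptome classification

@dataclass
class ClassifyOptions:
    alpha: float = DEFAULT_ALPHA
    rpm_threshold: float = 1.0
    condition: Optional[str] = None


def classify_transcriptome(
    count_set: CountSet, options: ClassifyOptions = ClassifyOptions()
) -> pd.DataFrame:
    """Run the five group comparisons and emit per-gene category calls.

    Requires the four observed groups (BD, BS, BH_BD, BH_BS); derives the
    mid-ancestral and hybrid-total pseudo-samples by replicate-paired count
    summation. The expressed filter keeps genes whose mid-ancestral and
    hybrid-total RPM reach the threshold in every replicate. One row per
    expressed gene: all five relations, fdrs, log2fcs, the additivity
    category, the bias category, and the pattern class.
    """
    conditions = (
        [options.condition]
        if options.condition is not None
        else sorted(count_set.samples["condition"].unique())
    )
    frames = []
    for condition in conditions:
        frames.append(_classify_one_condition(count_set, condition, options))
    return pd.concat(frames, axis=0)


def _group_columns(cs: CountSet, group: str, condition: str) -> pd.DataFrame:
    mask = (cs.samples["group"] == group) & (cs.samples["condition"] == condition)
    ids = cs.samples.index[mask]
    if len(ids) == 0:
        raise ValueError(f"missing group {group!r} for condition {condition!r}")
    order = cs.samples.loc[ids, "replicate"].sort_values().index
    return cs.counts[order]


def _classify_one_condition(
    cs: CountSet, condition: str, options: ClassifyOptions
) -> pd.DataFrame:
    counts = {g: _group_columns(cs, g, condition) for g in ("BD", "BS", "BH_BD", "BH_BS")}
    libs = {g: cs.library_sizes[c.columns] for g, c in counts.items()}

    mav, mav_lib = sum_replicate_groups(
        counts["BD"], counts["BS"], libs["BD"], libs["BS"], "MAV"
    )
    bht, bht_lib = sum_replicate_groups(
        counts["BH_BD"], counts["BH_BS"], libs["BH_BD"], libs["BH_BS"], "BHT"
    )

    rpm_mav = compute_rpm(mav, mav_lib)
    rpm_bht = compute_rpm(bht, bht_lib)
    expressed = [
        g
        for g in cs.counts.index
        if flag_expressed(rpm_mav.loc[g], options.rpm_threshold)
        and flag_expressed(rpm_bht.loc[g], options.rpm_threshold)
    ]

    if not expressed:
        return pd.DataFrame()

    def sub(df: pd.DataFrame) -> pd.DataFrame:
        return df.loc[expressed]

    comparisons = {
        "bh_vs_mav": (sub(bht), sub(mav)),
        "bh_vs_bd": (sub(bht), sub(counts["BD"])),
        "bh_vs_bs": (sub(bht), sub(counts["BS"])),
        "bd_vs_bs": (sub(counts["BD"]), sub(counts["BS"])),
        "bhbd_vs_bhbs": (sub(counts["BH_BD"]), sub(counts["BH_BS"])),
    }
    results = {
        name: nb_wald_test(a, b, options.alpha) for name, (a, b) in comparisons.items()
    }

    rows = []
    for gene in expressed:
        rels = {}
        ok = True
        for name, res in results.items():
            if gene not in res.index:
                ok = False  # skipped (all-zero in that pair)
                break
            rels[name] = Relation(res.loc[gene, "relation"])
        if not ok:
            continue
        add_cat = classify_additivity(
            rels["bh_vs_mav"], rels["bh_vs_bd"], rels["bh_vs_bs"]
        )
        bias_cat, pattern = classify_bias(rels["bd_vs_bs"], rels["bhbd_vs_bhbs"])
        row = {"gene": gene, "condition": condition}
        for name in comparisons:
            row[f"rel_{name}"] = rels[name].value
            row[f"fdr_{name}"] = results[name].loc[gene, "fdr"]
            row[f"log2fc_{name}"] = results[name].loc[gene, "log2fc"]
        row["additivity"] = add_cat.value
        row["bias"] = bias_cat.value
        row["pattern_class"] = pattern.value
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame()
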