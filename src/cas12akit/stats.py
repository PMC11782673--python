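"""Differential abundance statistics for pooled pre-crRNA screens.

Per-construct two-group linear models on log-CPM with mean-variance trend
(observation) weights, empirical-Bayes variance moderation, moderated t/F
p-values, gene-level aggregation of each gene's constructs into a single
directional statistic, Benjamini-Hochberg FDR, over-representation tests,
essential-gene depletion QC and top-abundance hit reporting.

The gene aggregation is a mean-moderated-t statistic referenced against
either an empirical null built from non-targeting controls or a normal
approximation; it rewards genes whose constructs shift consistently in the
same direction, the defining behaviour of rotation gene-set tests used on
such screens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .counting import CountMatrix, LogCpmMatrix


@dataclass
class ModerationPrior:
    d0: float  # prior degrees of freedom (may be +inf)
    s0_2: float  # prior variance

    def __post_init__(self):
        if not (self.d0 > 0 and self.s0_2 > 0):
            raise ValueError("ModerationPrior requires d0 > 0 and s0_2 > 0")


# ---------------------------------------------------------------------------
# Per-construct linear models
# ---------------------------------------------------------------------------

def fit_construct_models(logcpm: LogCpmMatrix, groups, contrast,
                         weights: bool = True,
                         trend_frac: float = 0.5) -> pd.DataFrame:
    """Two-group model per construct; logFC = mean(A) - mean(B) in log2.

    *groups* assigns a label to each sample (in ``logcpm.sample_ids`` order);
    *contrast* is ``(label_A, label_B)``.  With ``weights=True``, residual
    square-root standard deviations are regressed on average log-count by
    lowess, per-observation standard deviations are predicted from fitted
    values, and inverse predicted variances serve as observation weights
    (weighted least squares); ``weights=False`` gives unweighted OLS.
    """
    groups = list(groups)
    if len(groups) != len(logcpm.sample_ids):
        raise ValueError("groups length != number of samples")
    label_a, label_b = contrast
    sel_a = np.array([g == label_a for g in groups])
    sel_b = np.array([g == label_b for g in groups])
    if sel_a.sum() < 2 or sel_b.sum() < 2:
        raise ValueError(
            f"comparison {label_a} vs {label_b}: each group needs >= 2 samples"
        )
    sel = sel_a | sel_b
    y = logcpm.values[:, sel]
    in_a = sel_a[sel]
    n = y.shape[1]
    df_resid = n - 2

    # unweighted pass: group means and residual variances
    mean_a = y[:, in_a].mean(axis=1)
    mean_b = y[:, ~in_a].mean(axis=1)
    fitted = np.where(in_a, mean_a[:, None], mean_b[:, None])
    resid = y - fitted
    s2_unw = (resid ** 2).sum(axis=1) / df_resid

    lib = logcpm.library_sizes[sel]
    if weights:
        w = _voom_weights(y, fitted, s2_unw, lib, trend_frac)
    else:
        w = np.ones_like(y)

    wa = w[:, in_a]
    wb = w[:, ~in_a]
    swa = wa.sum(axis=1)
    swb = wb.sum(axis=1)
    wmean_a = (wa * y[:, in_a]).sum(axis=1) / swa
    wmean_b = (wb * y[:, ~in_a]).sum(axis=1) / swb
    fitted_w = np.where(in_a, wmean_a[:, None], wmean_b[:, None])
    rw = y - fitted_w
    s2 = (w * rw ** 2).sum(axis=1) / df_resid
    se_unit = np.sqrt(1.0 / swa + 1.0 / swb)
    logfc = wmean_a - wmean_b

    if logcpm.counts is not None:
        degenerate = logcpm.counts[:, sel].sum(axis=1) == 0
    else:
        degenerate = np.zeros(len(logfc), dtype=bool)
    degenerate = degenerate | (s2 <= 0)

    return pd.DataFrame(
        {
            "construct_id": logcpm.construct_ids,
            "logFC": logfc,
            "s2": s2,
            "df": float(df_resid),
            "se_unit": se_unit,
            "amean": y.mean(axis=1),
            "degenerate": degenerate,
        }
    ).set_index("construct_id", drop=False)


def _voom_weights(y, fitted, s2_unw, lib, frac):
    """Observation weights from the lowess mean-variance trend."""
    offset = np.log2(lib + 1.0).mean() - np.log2(1e6)
    sx = y.mean(axis=1) + offset  # average log2 count per construct
    sy = np.sqrt(np.sqrt(np.maximum(s2_unw, 0.0)))  # sqrt of residual SD
    ok = s2_unw > 0
    if ok.sum() < 10:
        return np.ones_like(y)
    trend = lowess(sy[ok], sx[ok], frac=frac, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    tx, uniq = np.unique(tx, return_index=True)
    ty = ty[uniq]
    fitted_counts = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_counts, tx, ty)
    pred = np.maximum(pred, 1e-4)
    return 1.0 / pred ** 4


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def moderate_variances(fit: pd.DataFrame,
                       min_constructs: int = 10) -> tuple:
    """Shrink residual variances towards an empirical-Bayes prior.

    Fits a scaled-F model to the residual variances by the method of moments
    on ``e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2)``; the posterior
    variance is the df-weighted blend ``(d0*s0^2 + d_g*s2_g) / (d0 + d_g)``.
    Moderated t uses d0 + d_g degrees of freedom; the moderated F is t^2 for
    these single-contrast comparisons.  When the observed variances carry no
    excess spread the prior df is +inf and every posterior equals s0^2.

    Returns ``(stats_frame, ModerationPrior)``.
    """
    out = fit.copy()
    valid = (~out["degenerate"]) & (out["df"] > 0) & (out["s2"] > 0)
    if valid.sum() < min_constructs:
        raise ValueError(
            f"need >= {min_constructs} non-degenerate constructs for "
            f"moderation, have {int(valid.sum())}"
        )
    s2 = out.loc[valid, "s2"].to_numpy()
    dg = out.loc[valid, "df"].to_numpy()

    if np.allclose(s2, s2[0], rtol=1e-12, atol=0.0):
        # point-mass limit: no spread to attribute to sampling, shrink all
        # the way to the common observed value
        d0, s0 = np.inf, float(s2[0])
    else:
        e = np.log(s2) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
        emean = e.mean()
        evar = e.var(ddof=1) - special.polygamma(1, dg / 2.0).mean()
        if evar > 0:
            d0 = 2.0 * trigamma_inverse(evar)
            s0 = float(np.exp(
                emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0, s0 = np.inf, float(np.exp(emean))

    prior = ModerationPrior(d0=d0, s0_2=s0)
    s2_all = out["s2"].to_numpy()
    dg_all = out["df"].to_numpy()
    if np.isinf(d0):
        s2_post = np.full_like(s2_all, s0)
    else:
        s2_post = (d0 * s0 + dg_all * s2_all) / (d0 + dg_all)
    df_total = dg_all + d0

    t = out["logFC"].to_numpy() / (np.sqrt(s2_post) * out["se_unit"].to_numpy())
    if np.isinf(d0):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)

    deg = out["degenerate"].to_numpy()
    t = np.where(deg, 0.0, t)
    p = np.where(deg, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out["s2_post"] = s2_post
    out["moderated_t"] = t
    out["moderated_F"] = t ** 2
    out["df_total"] = df_total
    out["p_value"] = p
    return out, prior


# ---------------------------------------------------------------------------
# Gene aggregation
# ---------------------------------------------------------------------------

def aggregate_genes(stats_frame: pd.DataFrame, gene_map: dict,
                    null_mode: str = "normal", ntc_label: str = "NTC",
                    n_null: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Aggregate construct statistics to one directional result per gene.

    Gene statistic: mean moderated t over the gene's constructs, so
    same-direction constructs reinforce and opposed ones cancel.  Two-sided
    p-values come either from pseudo-genes resampled from the NTC constructs
    (``null_mode="ntc"``) or from a normal null with variance 1/n
    (``null_mode="normal"``).  BH q-values are appended.
    """
    df = stats_frame.copy()
    missing = [c for c in df["construct_id"] if c not in gene_map]
    if missing:
        raise ValueError(f"constructs missing from gene map: {missing[:3]}")
    df["gene_id"] = [gene_map[c] for c in df["construct_id"]]

    ntc = df[df["gene_id"] == ntc_label]
    targets = df[df["gene_id"] != ntc_label]
    if targets.empty:
        return pd.DataFrame(columns=["gene_id", "n_constructs", "mean_logFC",
                                     "stat", "p_value", "q_value", "direction"])

    mode = null_mode.lower()
    if mode == "ntc" and len(ntc) < 10:
        warnings.warn(
            f"only {len(ntc)} NTC constructs; falling back to normal null",
            stacklevel=2,
        )
        mode = "normal"
    if mode not in ("ntc", "normal"):
        raise ValueError(f"unknown null_mode {null_mode!r}")

    grouped = targets.groupby("gene_id", sort=True)
    gene_ids, stats_, nfcs, ns = [], [], [], []
    for gid, sub in grouped:
        gene_ids.append(gid)
        stats_.append(sub["moderated_t"].mean())
        nfcs.append(sub["logFC"].mean())
        ns.append(len(sub))
    stat = np.array(stats_)
    ncon = np.array(ns)

    if mode == "normal":
        p = 2.0 * sps.norm.sf(np.abs(stat) * np.sqrt(ncon))
    else:
        rng = np.random.default_rng(seed)
        ntc_t = ntc["moderated_t"].to_numpy()
        p = np.empty_like(stat)
        for size in np.unique(ncon):
            null = np.abs(
                rng.choice(ntc_t, size=(n_null, int(size))).mean(axis=1))
            null.sort()
            mask = ncon == size
            ge = len(null) - np.searchsorted(null, np.abs(stat[mask]),
                                             side="left")
            p[mask] = (1.0 + ge) / (n_null + 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    res = pd.DataFrame({
        "gene_id": gene_ids,
        "n_constructs": ncon,
        "mean_logFC": nfcs,
        "stat": stat,
        "p_value": p,
        "q_value": bh_fdr(p),
        "direction": np.where(stat >= 0, "up", "down"),
    })
    return res


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-equivariant."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Enrichment / reporting
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(hit_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_genes)
    if not hits <= universe:
        raise ValueError("hit genes must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(hits & members)
        p = sps.hypergeom.sf(k - 1, len(universe), len(members), len(hits))
        rows.append({"gene_set": name, "set_size": len(members),
                     "n_hits": len(hits), "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


def select_hits(gene_results: pd.DataFrame, fdr: float = 0.2,
                logfc_threshold: float = 0.0, direction: str = "up") -> list:
    """Hit genes at an FDR threshold with a logFC cut.

    direction "up": mean_logFC > threshold (enrichment); "down":
    mean_logFC < threshold (depletion).
    """
    sig = gene_results[gene_results["q_value"] <= fdr]
    if direction == "up":
        sig = sig[sig["mean_logFC"] > logfc_threshold]
    elif direction == "down":
        sig = sig[sig["mean_logFC"] < logfc_threshold]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return sorted(sig["gene_id"])


def depletion_qc(gene_results: pd.DataFrame, essential_ids, nonessential_ids,
                 logfc_col: str = "mean_logFC") -> dict:
    """Essential vs non-essential separation on a depletion comparison.

    Reports per-class median logFC and the Mann-Whitney probability that a
    random essential gene falls below a random non-essential gene.
    """
    idx = gene_results.set_index("gene_id")[logfc_col]
    ess = idx[idx.index.isin(set(essential_ids))].to_numpy()
    non = idx[idx.index.isin(set(nonessential_ids))].to_numpy()
    if len(ess) == 0 or len(non) == 0:
        raise ValueError("essential/non-essential class empty after "
                         "intersecting with results")
    u1 = sps.mannwhitneyu(ess, non, alternative="two-sided").statistic
    separation = 1.0 - u1 / (len(ess) * len(non))
    return {
        "median_logfc_essential": float(np.median(ess)),
        "median_logfc_nonessential": float(np.median(non)),
        "separation": float(separation),
        "n_essential": int(len(ess)),
        "n_nonessential": int(len(non)),
    }


def top_abundant_genes(counts: CountMatrix, gene_map: dict, k: int = 4) -> dict:
    """Per sample, the genes of the k highest-count constructs.

    Ties at the count boundary resolve to the lexicographically smaller
    construct id; NTC constructs report as "NTC".
    """
    out = {}
    for si, sid in enumerate(counts.sample_ids):
        ranked = sorted(
            zip(counts.counts[:, si], counts.construct_ids),
            key=lambda t: (-t[0], t[1]),
        )
        out[sid] = [gene_map.get(cid, "NTC") for _, cid in ranked[:k]]
    return out


def export_four_way(results_x: pd.DataFrame, results_y: pd.DataFrame,
                    hits=(), essential_ids=(), nonessential_ids=()) -> pd.DataFrame:
    """Per-gene (logFC_x, logFC_y, class) table for a 4-way comparison plot.

    Class priority: hit > essential > non-essential > other.  Genes present
    in only one comparison are dropped with a warning.
    """
    x = results_x.set_index("gene_id")["mean_logFC"]
    y = results_y.set_index("gene_id")["mean_logFC"]
    common = x.index.intersection(y.index)
    dropped = set(x.index).symmetric_difference(y.index)
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene(s) missing from one comparison, dropped",
            stacklevel=2,
        )
    hits, ess, non = set(hits), set(essential_ids), set(nonessential_ids)

    def classify(g):
        if g in hits:
            return "hit"
        if g in ess:
            return "essential"
        if g in non:
            return "non-essential"
        return "other"

    return pd.DataFrame({
        "gene_id": list(common),
        "logFC_x": x.loc[common].to_numpy(),
        "logFC_y": y.loc[common].to_numpy(),
        "class": [classify(g) for g in common],
    })
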