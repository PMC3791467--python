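"""Broad-sense heritability partitioned between nuclear and cytoplasmic genomes.

The line-heritability model for a replicated reciprocal RIL design is

    y = mu + C + G(C) + E + B(E) + CxE + eps

with C the cytoplasm (Kas/Tsu subpopulation), G(C) the RIL line nested in
its cytoplasm class, E the experiment, B(E) the block nested in
experiment, and CxE the cytoplasm-by-experiment interaction.  Experiment
and block are treated as random.  Variance components are estimated by
equating observed to expected mean squares (method of moments) on the
balanced complete-block design; negative solutions are truncated at
zero.  Heritabilities are H_cyto = s2_C / s2_p and H_nuclear =
s2_G(C) / s2_p with s2_p the sum of all components (per-observation
phenotypic variance).

Because the reciprocal subpopulations have unequal line counts the C
stratum is unbalanced; its mean-square coefficient uses the standard
effective class size n0 = (L - sum(n_c^2)/L) / (a - 1).  Under this
convention the cytoplasm component for a two-class factor with effects
+a/-a estimates 2 a^2 (the ddof=1 variance of the two class effects).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, KAS

log = logging.getLogger(__name__)

COMPONENTS = ["sigma2_C", "sigma2_G", "sigma2_E", "sigma2_B", "sigma2_CE", "sigma2_res"]


def fit_heritability(
    pheno: pd.DataFrame,
    genotypes: GenotypeMatrix,
    cyto_denominator: str = "cxe",
    log_scale: bool = True,
) -> pd.DataFrame:
    """Fit the line-heritability model to every metabolite.

    Parameters
    ----------
    pheno
        Long-format replicated phenotype table (normalized).
    genotypes
        Supplies the cytoplasm label per line.
    cyto_denominator
        Mean square used as the F-test denominator for the cytoplasm
        term: ``"cxe"`` (default, respects the random experiment
        structure) or ``"residual"``.

    Returns one row per metabolite with variance components, H values and
    p-values for the cytoplasm (C) and line (G(C)) terms.
    """
    if cyto_denominator not in ("cxe", "residual"):
        raise ValueError(f"unknown cyto_denominator {cyto_denominator!r}")
    wide = pheno.pivot_table(
        index=["line", "experiment", "block"],
        columns="metabolite",
        values="value",
        aggfunc="mean",
    )
    y = wide.to_numpy()
    if log_scale:
        y = np.log(y)
    mets = wide.columns.to_numpy()
    idx = wide.index
    lines = idx.get_level_values("line")
    exps = idx.get_level_values("experiment").to_numpy()
    blocks = idx.get_level_values("block").to_numpy()
    cyto = genotypes.cytoplasm.reindex(lines).to_numpy()

    line_codes, uniq_lines = pd.factorize(lines)
    exp_codes, uniq_exps = pd.factorize(exps)
    _, eb_codes = np.unique(
        np.stack([exps, blocks]), axis=1, return_inverse=True
    )
    cyto_codes = (cyto == KAS).astype(int)  # 1 = Kas, 0 = Tsu
    ce_codes = cyto_codes * len(uniq_exps) + exp_codes

    L = len(uniq_lines)
    n_e = len(uniq_exps)
    n_b = len(np.unique(blocks))
    r = n_e * n_b
    N = y.shape[0]
    if N != L * r or np.isnan(y).any():
        log.warning(
            "design is unbalanced (%d observations for %d lines x %d reps); "
            "variance components are approximate", N, L, r
        )

    line_cyto = np.zeros(L, dtype=int)
    line_cyto[line_codes] = cyto_codes
    n_kas = int(line_cyto.sum())
    n_tsu = L - n_kas
    if min(n_kas, n_tsu) < 2:
        raise ValueError("need at least 2 lines per cytoplasm class")
    n0 = (L - (n_kas**2 + n_tsu**2) / L) / (2 - 1)

    grand = np.nanmean(y, axis=0)
    dev = y - grand

    def group_ss(codes, weights_per_group=None):
        """SS of group-mean deviations, weighted by group size (obs units)."""
        k = codes.max() + 1
        sums = np.zeros((k, y.shape[1]))
        counts = np.zeros(k)
        np.add.at(sums, codes, np.nan_to_num(dev))
        np.add.at(counts, codes, 1.0)
        means = sums / counts[:, None]
        return means, counts

    line_means, line_counts = group_ss(line_codes)
    cyto_means, cyto_counts_obs = group_ss(cyto_codes)
    exp_means, exp_counts = group_ss(exp_codes)
    eb_means, eb_counts = group_ss(eb_codes)
    ce_means, ce_counts = group_ss(ce_codes)

    ss_c = (cyto_counts_obs[:, None] * cyto_means**2).sum(axis=0)
    # line deviations from own cytoplasm-class mean
    ss_g = (
        line_counts[:, None] * (line_means - cyto_means[line_cyto]) ** 2
    ).sum(axis=0)
    ss_e = (exp_counts[:, None] * exp_means**2).sum(axis=0)
    # block deviations from own experiment mean
    eb_to_exp = np.zeros(eb_means.shape[0], dtype=int)
    eb_to_exp[eb_codes] = exp_codes
    ss_b = (eb_counts[:, None] * (eb_means - exp_means[eb_to_exp]) ** 2).sum(axis=0)
    ce_to_cyto = np.zeros(ce_means.shape[0], dtype=int)
    ce_to_exp = np.zeros(ce_means.shape[0], dtype=int)
    ce_to_cyto[ce_codes] = cyto_codes
    ce_to_exp[ce_codes] = exp_codes
    ss_ce = (
        ce_counts[:, None]
        * (ce_means - cyto_means[ce_to_cyto] - exp_means[ce_to_exp]) ** 2
    ).sum(axis=0)
    ss_tot = np.nansum(dev**2, axis=0)
    ss_res = np.clip(ss_tot - ss_c - ss_g - ss_e - ss_b - ss_ce, 0.0, None)

    df_c = 1
    df_g = L - 2
    df_e = n_e - 1
    df_b = n_e * (n_b - 1)
    df_ce = (2 - 1) * (n_e - 1)
    df_res = N - 1 - df_c - df_g - df_e - df_b - df_ce

    ms_c = ss_c / df_c
    ms_g = ss_g / df_g
    ms_e = ss_e / max(df_e, 1)
    ms_b = ss_b / max(df_b, 1)
    ms_ce = ss_ce / max(df_ce, 1)
    ms_res = ss_res / df_res

    # method-of-moments solutions (before truncation the components sum to
    # the phenotypic variance implied by the mean squares)
    s2_res = ms_res
    s2_g = (ms_g - ms_res) / r
    s2_b = (ms_b - ms_res) / L
    s2_ce = (ms_ce - ms_res) / (n_b * n0)
    s2_c = (ms_c - ms_g - ms_ce + ms_res) / (r * n0)
    s2_e = (ms_e - ms_b - ms_ce + ms_res) / (L * n_b)

    comp = np.stack([s2_c, s2_g, s2_e, s2_b, s2_ce, s2_res])
    comp = np.clip(comp, 0.0, None)
    s2_p = comp.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_cyto = np.where(s2_p > 0, comp[0] / s2_p, 0.0)
        h_nuc = np.where(s2_p > 0, comp[1] / s2_p, 0.0)

    denom_c = ms_ce if cyto_denominator == "cxe" else ms_res
    df_denom_c = df_ce if cyto_denominator == "cxe" else df_res
    with np.errstate(invalid="ignore", divide="ignore"):
        f_c = np.where(denom_c > 0, ms_c / denom_c, np.nan)
        f_g = np.where(ms_res > 0, ms_g / ms_res, np.nan)
    p_c = stats.f.sf(f_c, df_c, df_denom_c)
    p_g = stats.f.sf(f_g, df_g, df_res)

    out = pd.DataFrame(
        {
            "metabolite": mets,
            "sigma2_C": comp[0],
            "sigma2_G": comp[1],
            "sigma2_E": comp[2],
            "sigma2_B": comp[3],
            "sigma2_CE": comp[4],
            "sigma2_res": comp[5],
            "sigma2_p": s2_p,
            "H_cyto": h_cyto,
            "H_nuclear": h_nuc,
            "p_cyto": p_c,
            "p_line": p_g,
        }
    )
    return out


def fit_line_heritability(
    pheno_one_metabolite: pd.DataFrame, genotypes: GenotypeMatrix, **kwargs
) -> pd.Series:
    """Fit the line-heritability model to a single metabolite's table."""
    res = fit_heritability(pheno_one_metabolite, genotypes, **kwargs)
    if len(res) != 1:
        raise ValueError("expected a table for exactly one metabolite")
    return res.iloc[0]


def summarize_heritability(
    results: pd.DataFrame, p_threshold: float = 0.01
) -> dict:
    """Counts of significant metabolites and H summaries per genome class."""
    if results.empty:
        raise ValueError("no heritability results to summarize")
    sig_line = results["p_line"] < p_threshold
    sig_cyto = results["p_cyto"] < p_threshold

    def _summary(h: pd.Series) -> dict:
        if h.empty:
            return {"mean": np.nan, "se": np.nan, "min": np.nan, "max": np.nan}
        return {
            "mean": float(h.mean()),
            "se": float(h.std(ddof=1) / np.sqrt(len(h))) if len(h) > 1 else np.nan,
            "min": float(h.min()),
            "max": float(h.max()),
        }

    return {
        "n_metabolites": int(len(results)),
        "n_significant_line": int(sig_line.sum()),
        "n_significant_cyto": int(sig_cyto.sum()),
        "H_nuclear": _summary(results.loc[sig_line, "H_nuclear"]),
        "H_cyto": _summary(results.loc[sig_cyto, "H_cyto"]),
        "p_threshold": p_threshold,
    }
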