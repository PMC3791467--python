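"""Additive, pairwise-epistasis and three-way ANOVA models at hotspot markers.

The additive model regresses each metabolite's line means on the ±1
allele codes of the hotspot markers, with the cytoplasm included as one
more biallelic locus.  The pairwise model adds all products of the main
effect codes; the three-way model adds selected cytoplasm x nuclear x
nuclear products.  Every term is a single degree of freedom, so the
Type III sum of squares of term j is beta_j^2 / [(X'X)^-1]_jj — exactly
the full-versus-reduced RSS difference — and its F test uses the
residual mean square.  Variance fractions divide the Type III SS by the
total (model + residual) sum of squares.

Multiple testing is controlled with Benjamini-Hochberg FDR pooled over
all terms and metabolites of one model family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CYTOPLASM, GenotypeMatrix, LineMeans

log = logging.getLogger(__name__)

_TINY = 1e-12


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class ModelSpec:
    """Main-effect loci plus interaction terms, each worth one df."""

    main: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...] = ()
    triples: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self):
        declared = set(self.main)
        if len(declared) != len(self.main):
            raise ValueError("duplicate main-effect locus in model spec")
        for term in list(self.pairs) + list(self.triples):
            if len(set(term)) != len(term):
                raise ValueError(f"repeated locus within interaction {term}")
            undeclared = set(term) - declared
            if undeclared:
                raise ValueError(
                    f"interaction {term} references undeclared loci {sorted(undeclared)}"
                )
        if len(set(self.pairs)) != len(self.pairs) or len(set(self.triples)) != len(
            self.triples
        ):
            raise ValueError("duplicate interaction term in model spec")

    @property
    def terms(self) -> list[str]:
        return (
            list(self.main)
            + [":".join(p) for p in self.pairs]
            + [":".join(t) for t in self.triples]
        )

    def without_cytoplasm(self) -> "ModelSpec":
        """Drop every term that involves the cytoplasm."""
        return ModelSpec(
            main=tuple(m for m in self.main if m != CYTOPLASM),
            pairs=tuple(p for p in self.pairs if CYTOPLASM not in p),
            triples=tuple(t for t in self.triples if CYTOPLASM not in t),
        )


def additive_spec(loci: list[str]) -> ModelSpec:
    return ModelSpec(main=tuple(loci))


def pairwise_spec(loci: list[str]) -> ModelSpec:
    """All loci as mains plus every pairwise interaction."""
    return ModelSpec(
        main=tuple(loci), pairs=tuple(itertools.combinations(loci, 2))
    )


def threeway_spec(
    base: ModelSpec, triples: list[tuple[str, str, str]]
) -> ModelSpec:
    return ModelSpec(main=base.main, pairs=base.pairs, triples=tuple(triples))


def model_df(spec: ModelSpec, n_lines: int = 316) -> dict:
    """Model degrees of freedom consumed (intercept excluded).

    Each biallelic main effect, pair and triple costs one df.  The
    available df follow the n_lines - 2 accounting used when comparing
    model size against the residual budget of a RIL panel.
    """
    consumed = len(spec.main) + len(spec.pairs) + len(spec.triples)
    available = n_lines - 2
    return {
        "consumed": consumed,
        "available": available,
        "fraction": consumed / available if available > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# fitting

def design_matrix(
    genotypes: GenotypeMatrix, spec: ModelSpec, lines: pd.Index | None = None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + one ±1-coded (or product) column per term."""
    lines = genotypes.lines if lines is None else lines
    cols = [np.ones(len(lines))]
    for locus in spec.main:
        cols.append(genotypes.locus_values(locus).reindex(lines).to_numpy(float))
    for pair in spec.pairs:
        a = genotypes.locus_values(pair[0]).reindex(lines).to_numpy(float)
        b = genotypes.locus_values(pair[1]).reindex(lines).to_numpy(float)
        cols.append(a * b)
    for t in spec.triples:
        prod = np.ones(len(lines))
        for locus in t:
            prod = prod * genotypes.locus_values(locus).reindex(lines).to_numpy(float)
        cols.append(prod)
    return np.column_stack(cols), ["intercept"] + spec.terms


def _aliased_columns(x: np.ndarray) -> np.ndarray:
    """Boolean mask of columns linearly dependent on earlier ones."""
    n, p = x.shape
    aliased = np.zeros(p, dtype=bool)
    basis = np.zeros((n, 0))
    for j in range(p):
        v = x[:, j].astype(float)
        if basis.shape[1]:
            v = v - basis @ (basis.T @ x[:, j])
        norm = np.linalg.norm(v)
        if norm < 1e-8 * max(np.linalg.norm(x[:, j]), 1.0):
            aliased[j] = True
        else:
            basis = np.column_stack([basis, v / norm])
    return aliased


def fit_marker_model(
    line_means: LineMeans,
    genotypes: GenotypeMatrix,
    spec: ModelSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit one model family to every metabolite.

    Returns ``(term_table, model_summary)``.  The term table is long:
    one row per metabolite x term with df, Type III SS, F, p, variance
    fraction and the allele-substitution effect (2 x coefficient).
    Terms perfectly confounded with earlier columns are flagged aliased
    and carry SS = 0.  Metabolites with missing line means drop the
    affected lines listwise.
    """
    x_full, names = design_matrix(genotypes, spec)
    values = line_means.values.reindex(genotypes.lines)
    term_rows = []
    sum_rows = []

    aliased = _aliased_columns(x_full)
    if aliased.any():
        log.warning(
            "aliased model terms reported with SS=0: %s",
            [names[j] for j in np.nonzero(aliased)[0]],
        )
    keep = ~aliased

    complete = values.notna().all(axis=0)
    y_all = values.to_numpy(float)

    def _fit_block(x: np.ndarray, y: np.ndarray, mets: list[str]):
        xk = x[:, keep]
        n, rank = xk.shape
        xtx = xk.T @ xk
        g = np.linalg.inv(xtx)
        b = g @ (xk.T @ y)  # rank x M
        resid = y - xk @ b
        rss = np.einsum("ij,ij->j", resid, resid)
        tss = np.einsum("ij,ij->j", y - y.mean(axis=0), y - y.mean(axis=0))
        df_res = n - rank
        ms_res = np.where(df_res > 0, rss / max(df_res, 1), np.nan)
        diag = np.diag(g)
        full_b = np.full((x.shape[1], y.shape[1]), np.nan)
        full_b[keep] = b
        full_ss = np.zeros((x.shape[1], y.shape[1]))
        full_ss[keep] = b**2 / diag[:, None]
        for mi, met in enumerate(mets):
            noiseless = rss[mi] < _TINY * max(tss[mi], 1.0)
            for j, name in enumerate(names):
                if name == "intercept":
                    continue
                ss3 = float(full_ss[j, mi])
                if aliased[j]:
                    f = p = np.nan
                else:
                    if noiseless or df_res == 0:
                        f = np.inf if ss3 > _TINY * max(tss[mi], 1.0) else 0.0
                        p = 0.0 if f == np.inf else 1.0
                    else:
                        f = ss3 / ms_res[mi]
                        p = float(stats.f.sf(f, 1, df_res))
                term_rows.append(
                    {
                        "metabolite": met,
                        "term": name,
                        "df": 1,
                        "ss3": 0.0 if aliased[j] else ss3,
                        "F": f,
                        "p": p,
                        "varfrac": (0.0 if aliased[j] else ss3 / tss[mi])
                        if tss[mi] > 0
                        else 0.0,
                        "effect": np.nan if aliased[j] else 2.0 * float(full_b[j, mi]),
                        "aliased": bool(aliased[j]),
                    }
                )
            sum_rows.append(
                {
                    "metabolite": met,
                    "n": n,
                    "df_model": rank - 1,
                    "df_resid": df_res,
                    "rss": float(rss[mi]),
                    "tss": float(tss[mi]),
                    "r2": 1.0 - rss[mi] / tss[mi] if tss[mi] > 0 else 0.0,
                }
            )

    mets_complete = [m for m in values.columns if complete[m]]
    if mets_complete:
        _fit_block(x_full, y_all[:, [values.columns.get_loc(m) for m in mets_complete]],
                   mets_complete)
    for met in values.columns:
        if complete[met]:
            continue
        mask = values[met].notna().to_numpy()
        log.info("metabolite %s: %d lines dropped for missing means", met,
                 (~mask).sum())
        _fit_block(x_full[mask], values.loc[mask, [met]].to_numpy(float), [met])

    term_table = pd.DataFrame(term_rows)
    summary = pd.DataFrame(sum_rows)
    return term_table, summary


# ---------------------------------------------------------------------------
# multiple testing and variance explained

def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    NaN p-values propagate as non-significant (q = NaN).
    """
    p = np.asarray(p_values, dtype=float)
    qvals = np.full_like(p, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if (~ok).any():
        log.warning("%d NaN p-values treated as non-significant", int((~ok).sum()))
    if ok.any():
        rej, qv, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        qvals[ok] = qv
        flags[ok] = qv < q
    return qvals, flags


def apply_fdr(term_table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Add pooled-family q-values and flags to a term table."""
    out = term_table.copy()
    out["q"], out["significant"] = fdr_adjust(out["p"].to_numpy(), q)
    return out


def variance_explained(
    term_table: pd.DataFrame,
    significant_only: bool = True,
    q: float = 0.05,
) -> pd.Series:
    """Per-metabolite r^2 = sum of variance fractions over (significant) terms."""
    tt = term_table
    if significant_only:
        if "significant" not in tt.columns:
            tt = apply_fdr(tt, q)
        tt = tt[tt["significant"].fillna(False)]
    r2 = tt.groupby("metabolite", sort=False)["varfrac"].sum()
    return r2.reindex(term_table["metabolite"].unique(), fill_value=0.0)


def r2_histogram(r2_values: pd.Series | np.ndarray, bin_width: float = 0.025) -> pd.DataFrame:
    """Binned counts of per-metabolite variance explained."""
    v = np.asarray(r2_values, dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(v, 0, 1), bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "count": counts})


FAMILIES = ("additive", "pairwise", "threeway")


def family_spec(base_spec: ModelSpec, family: str) -> ModelSpec:
    if family == "additive":
        return ModelSpec(main=base_spec.main)
    if family == "pairwise":
        return ModelSpec(main=base_spec.main, pairs=base_spec.pairs)
    if family == "threeway":
        return base_spec
    raise ValueError(f"unknown model family {family!r}")


def compare_with_without_cytoplasm(
    line_means: LineMeans,
    genotypes: GenotypeMatrix,
    base_spec: ModelSpec,
    q: float = 0.05,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Per-metabolite variance explained with and without cytoplasm terms.

    Each family (additive, pairwise and — if the base spec has triples —
    three-way) is fitted twice: once as specified and once with every
    cytoplasm-containing term removed.  With ``significant_only`` the
    r^2 sums FDR-significant Type III fractions; otherwise it is the
    full-model r^2 (so nested models give non-negative differences).
    """
    if CYTOPLASM not in base_spec.main:
        raise ValueError("base spec must include the cytoplasm as a main effect")
    families = ["additive", "pairwise"] + (
        ["threeway"] if base_spec.triples else []
    )
    frames = []
    for family in families:
        spec_with = family_spec(base_spec, family)
        spec_wo = spec_with.without_cytoplasm()
        r2 = {}
        for tag, spec in (("with", spec_with), ("without", spec_wo)):
            tt, summary = fit_marker_model(line_means, genotypes, spec)
            if significant_only:
                r2[tag] = variance_explained(apply_fdr(tt, q), True, q)
            else:
                r2[tag] = summary.set_index("metabolite")["r2"]
        df = pd.DataFrame(
            {
                "family": family,
                "metabolite": r2["with"].index,
                "r2_with": r2["with"].to_numpy(),
                "r2_without": r2["without"].reindex(r2["with"].index).to_numpy(),
            }
        )
        df["delta_r2"] = df["r2_with"] - df["r2_without"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
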