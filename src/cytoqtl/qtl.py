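"""Composite interval mapping (CIM) for RIL line means.

The scan regresses each metabolite's line means on the expected Kas
allele dosage at a grid of genome positions (Haley-Knott regression),
with forward-selected background marker cofactors; cofactors within a
window of the test position (same chromosome) are excluded from both the
null and the full model at that position.  LOD = (n/2) log10(RSS0/RSS1).

Genotype probabilities at pseudomarkers condition on the nearest flanking
observed markers through the RIL Markov chain with RIL-adjusted Haldane
recombination fractions, which is exact for the chain used by the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneticMap, GenotypeMatrix, KAS, TSU
from .simulate import ril_recomb

_TINY = 1e-12


@dataclass
class GenotypeProbs:
    """P(Kas) at every evaluation position, per line."""

    positions: pd.DataFrame  # columns: chrom, cm, marker (name or None)
    p_kas: np.ndarray  # (n_lines, n_positions)
    lines: pd.Index

    @property
    def dosage(self) -> np.ndarray:
        """Expected ±1 allele value (2 P(Kas) - 1) per line and position."""
        return 2.0 * self.p_kas - 1.0


def genotype_probs(
    gmap: GeneticMap, genotypes: GenotypeMatrix, step_cm: float = 1.0
) -> GenotypeProbs:
    """Conditional P(Kas) on a grid of markers plus ``step_cm`` pseudomarkers."""
    if step_cm <= 0:
        raise ValueError("step_cm must be positive")
    pos_rows = []
    cols = []
    for chrom in gmap.chromosomes:
        grp = gmap.chrom_table(chrom)
        mpos = grp["cm"].to_numpy()
        mnames = grp["marker"].to_list()
        obs = genotypes.alleles[mnames].to_numpy().astype(float)  # n x m, ±1
        grid = np.union1d(mpos, np.arange(mpos[0], mpos[-1] + _TINY, step_cm))
        # flanking marker indices for every grid point
        right = np.searchsorted(mpos, grid, side="left")
        right = np.clip(right, 0, len(mpos) - 1)
        left = np.clip(right - 1, 0, None)
        at_marker = np.isclose(grid, mpos[np.clip(right, 0, len(mpos) - 1)])
        for j, t in enumerate(grid):
            i_r = right[j]
            if at_marker[j]:
                p = (obs[:, i_r] == KAS).astype(float)
                name = mnames[i_r]
            else:
                i_l = left[j]
                rl = ril_recomb(t - mpos[i_l])
                rr = ril_recomb(mpos[i_r] - t)
                s_l, s_r = obs[:, i_l], obs[:, i_r]
                tlk = np.where(s_l == KAS, 1.0 - rl, rl)
                trk = np.where(s_r == KAS, 1.0 - rr, rr)
                num = tlk * trk
                den = num + (1.0 - tlk) * (1.0 - trk)
                p = num / den
                name = None
            pos_rows.append((chrom, float(t), name))
            cols.append(p)
    positions = pd.DataFrame(pos_rows, columns=["chrom", "cm", "marker"])
    return GenotypeProbs(positions, np.column_stack(cols), genotypes.lines)


# ---------------------------------------------------------------------------
# regression primitives

def _rss(design: np.ndarray, y: np.ndarray) -> float:
    resid = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(resid @ resid)


def hk_lod(
    y: np.ndarray, x: np.ndarray, cofactors: np.ndarray | None = None
) -> float:
    """LOD of adding regressor ``x`` to an intercept + cofactor model.

    Rank-deficient cofactor sets (e.g. duplicated columns) are handled by
    the least-squares fit; they cannot change the fitted subspace.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    ones = np.ones((n, 1))
    base = ones if cofactors is None or cofactors.size == 0 else np.column_stack(
        [ones, cofactors]
    )
    rss0 = _rss(base, y)
    if rss0 < _TINY:  # constant (or perfectly explained) phenotype
        return 0.0
    rss1 = _rss(np.column_stack([base, x]), y)
    rss1 = max(rss1, _TINY * rss0)
    return float(n / 2.0 * np.log10(rss0 / rss1))


def select_cofactors(
    y: np.ndarray, genotypes: GenotypeMatrix, gmap: GeneticMap, k: int = 3
) -> list[str]:
    """Greedy forward selection of ``k`` background markers.

    At each step the marker giving the largest RSS reduction is added;
    ties break to the lowest (chromosome, cM), which is the map order.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    markers = gmap.markers.to_list()
    if k > len(markers):
        raise ValueError(f"cannot select {k} cofactors from {len(markers)} markers")
    if k == 0:
        return []
    y = np.asarray(y, dtype=float)
    n = len(y)
    m_mat = genotypes.alleles[markers].to_numpy().astype(float).copy()
    # orthogonalize against the intercept
    y_r = y - y.mean()
    m_r = m_mat - m_mat.mean(axis=0)
    chosen: list[str] = []
    for _ in range(k):
        den = np.einsum("ij,ij->j", m_r, m_r)
        num = m_r.T @ y_r
        with np.errstate(invalid="ignore", divide="ignore"):
            red = np.where(den > _TINY * n, num**2 / den, 0.0)
        for name in chosen:  # already in the model
            red[markers.index(name)] = -np.inf
        j = int(np.argmax(red))
        chosen.append(markers[j])
        q = m_r[:, j]
        qn = q @ q
        if qn > _TINY:
            q = q / np.sqrt(qn)
            y_r = y_r - q * (q @ y_r)
            m_r = m_r - np.outer(q, q @ m_r)
    return chosen


def cim_scan(
    y: np.ndarray | pd.Series,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    window_cm: float = 10.0,
    k: int = 3,
    step_cm: float = 1.0,
    probs: GenotypeProbs | None = None,
    cofactors: list[str] | None = None,
    return_details: bool = False,
):
    """Composite interval mapping scan for one metabolite.

    Returns a DataFrame (chrom, cm, lod, effect) where ``effect`` is the
    Haley-Knott coefficient on the ±1 expected dosage (half the Kas-Tsu
    class difference).  With ``return_details`` also returns, per
    position, the tuple of cofactors actually used there.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(genotypes.lines).to_numpy()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if probs is None:
        probs = genotype_probs(gmap, genotypes, step_cm)
    if cofactors is None:
        cofactors = select_cofactors(y, genotypes, gmap, k)
    cof_pos = [gmap.position_of(m) for m in cofactors]
    cof_mat = (
        genotypes.alleles[cofactors].to_numpy().astype(float)
        if cofactors
        else np.zeros((n, 0))
    )

    pos = probs.positions
    x_all = probs.dosage
    lod = np.zeros(len(pos))
    eff = np.zeros(len(pos))
    used: list[tuple[str, ...]] = [()] * len(pos)

    # positions sharing the same active-cofactor subset are scanned together
    active_masks = np.ones((len(pos), len(cofactors)), dtype=bool)
    for ci, (cchrom, ccm) in enumerate(cof_pos):
        same = pos["chrom"].to_numpy() == cchrom
        near = np.abs(pos["cm"].to_numpy() - ccm) < window_cm
        active_masks[same & near, ci] = False

    keys = [tuple(np.nonzero(row)[0]) for row in active_masks]
    ones = np.ones((n, 1))
    for key in set(keys):
        sel = np.array([kk == key for kk in keys])
        z = np.column_stack([ones] + [cof_mat[:, [i]] for i in key])
        q, _ = np.linalg.qr(z)
        y_r = y - q @ (q.T @ y)
        rss0 = float(y_r @ y_r)
        xg = x_all[:, sel]
        x_r = xg - q @ (q.T @ xg)
        den = np.einsum("ij,ij->j", x_r, x_r)
        num = x_r.T @ y_r
        ok = den > _TINY * n
        beta = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        rss1 = rss0 - np.where(ok, num**2 / np.where(ok, den, 1.0), 0.0)
        rss1 = np.maximum(rss1, _TINY * max(rss0, _TINY))
        if rss0 < _TINY:
            lod[sel] = 0.0
        else:
            lod[sel] = n / 2.0 * np.log10(rss0 / rss1)
        eff[sel] = beta
        names = tuple(cofactors[i] for i in key)
        for idx in np.nonzero(sel)[0]:
            used[idx] = names

    scan = pos[["chrom", "cm", "marker"]].copy()
    scan["lod"] = np.maximum(lod, 0.0)
    scan["effect"] = eff
    if return_details:
        return scan, used
    return scan


def scan_permutation_threshold(
    y: np.ndarray | pd.Series,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    window_cm: float = 10.0,
    k: int = 3,
    step_cm: float = 1.0,
    probs: GenotypeProbs | None = None,
) -> float:
    """Genome-wide (1-alpha) quantile of max LOD under phenotype permutation.

    Phenotype values are shuffled across lines with the genotype rows
    (including the cytoplasm label) held fixed; cofactors are re-selected
    for every permuted phenotype so the permuted scans see exactly the
    procedure applied to the observed data.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if isinstance(y, pd.Series):
        y = y.reindex(genotypes.lines).to_numpy()
    y = np.asarray(y, dtype=float)
    if probs is None:
        probs = genotype_probs(gmap, genotypes, step_cm)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        scan = cim_scan(
            yp, gmap, genotypes, window_cm=window_cm, k=k, step_cm=step_cm,
            probs=probs,
        )
        maxima[i] = scan["lod"].max()
    return float(np.quantile(maxima, 1.0 - alpha))


def call_qtls(
    scan: pd.DataFrame,
    lod_threshold: float = 2.0,
    gmap: GeneticMap | None = None,
    line_means_col: pd.Series | None = None,
    genotypes: GenotypeMatrix | None = None,
    metabolite: str | None = None,
) -> pd.DataFrame:
    """Call QTL peaks with one-LOD support intervals from a scan.

    Local maxima above the threshold become QTLs; the one-LOD interval is
    the contiguous run around the peak with LOD >= peak - 1; lower peaks
    whose intervals overlap an accepted peak's interval merge into it.
    If line means and genotypes are supplied, the additive and percent
    effects are computed at the observed marker nearest the peak:
    percent = (mean_Tsu - mean_Kas) / mean_all (positive = Tsu allele
    increases the metabolite).
    """
    qtls = []
    for chrom, grp in scan.groupby("chrom", sort=False):
        grp = grp.sort_values("cm").reset_index(drop=True)
        lod = grp["lod"].to_numpy()
        cm = grp["cm"].to_numpy()
        above = lod > lod_threshold
        cand = [
            i
            for i in np.nonzero(above)[0]
            if (i == 0 or lod[i] >= lod[i - 1])
            and (i == len(lod) - 1 or lod[i] >= lod[i + 1])
        ]
        cand.sort(key=lambda i: -lod[i])
        accepted: list[tuple[float, float]] = []
        for i in cand:
            lo = hi = i
            cut = lod[i] - 1.0
            while lo > 0 and lod[lo - 1] >= cut:
                lo -= 1
            while hi < len(lod) - 1 and lod[hi + 1] >= cut:
                hi += 1
            lo_cm, hi_cm = cm[lo], cm[hi]
            if any(lo_cm <= b and a <= hi_cm for a, b in accepted):
                continue  # merged into a higher accepted peak
            accepted.append((lo_cm, hi_cm))
            row = {
                "metabolite": metabolite,
                "chrom": chrom,
                "peak_cm": float(cm[i]),
                "lod": float(lod[i]),
                "interval_lo": float(lo_cm),
                "interval_hi": float(hi_cm),
                "effect": float(grp["effect"].iloc[i]),
                "percent_effect": np.nan,
                "marker": None,
            }
            if gmap is not None:
                marker = gmap.nearest_marker(int(chrom), float(cm[i]))
                row["marker"] = marker
                if line_means_col is not None and genotypes is not None:
                    ym = line_means_col.reindex(genotypes.lines)
                    g = genotypes.alleles[marker]
                    mk = float(ym[g == KAS].mean())
                    mt = float(ym[g == TSU].mean())
                    row["effect"] = (mk - mt) / 2.0
                    row["percent_effect"] = (mt - mk) / float(ym.mean())
            qtls.append(row)
    cols = [
        "metabolite", "chrom", "peak_cm", "lod", "interval_lo", "interval_hi",
        "effect", "percent_effect", "marker",
    ]
    out = pd.DataFrame(qtls, columns=cols)
    return out.sort_values(["chrom", "peak_cm"]).reset_index(drop=True)


def scan_metabolites(
    lm_values: pd.DataFrame,
    gmap: GeneticMap,
    genotypes: GenotypeMatrix,
    lod_threshold: float = 2.0,
    window_cm: float = 10.0,
    k: int = 3,
    step_cm: float = 1.0,
) -> pd.DataFrame:
    """CIM scan + QTL calling for every metabolite column; one QTL table."""
    probs = genotype_probs(gmap, genotypes, step_cm)
    tables = []
    for met in lm_values.columns:
        y = lm_values[met]
        scan = cim_scan(
            y, gmap, genotypes, window_cm=window_cm, k=k, step_cm=step_cm,
            probs=probs,
        )
        called = call_qtls(
            scan, lod_threshold, gmap=gmap, line_means_col=y,
            genotypes=genotypes, metabolite=met,
        )
        if not called.empty:
            tables.append(called)
    if not tables:
        return call_qtls(pd.DataFrame(columns=["chrom", "cm", "lod", "effect"]))
    return pd.concat(tables, ignore_index=True)
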