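"""QTL-summation hotspot detection with a sliding window.

Each metabolite contributes a 1 at each of its QTL peak positions; a
centered, closed sliding window (default 5 cM, i.e. ±2.5 cM) counts, at
every grid position, the number of distinct metabolites with at least
one peak inside the window.  Significance is judged against a
permutation null that redraws every QTL's peak position uniformly on the
genetic map (per-metabolite QTL counts preserved).  Hotspots are named
``M.<roman chromosome>.<cM>`` after the convention for metabolomic QTL
hotspots (e.g. ``M.I.83`` = chromosome I at 83 cM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import GeneticMap

_ROMAN = [
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    if n <= 0:
        raise ValueError("roman numerals start at 1")
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def _grid(gmap: GeneticMap, step_cm: float) -> pd.DataFrame:
    rows = []
    for chrom in gmap.chromosomes:
        grp = gmap.chrom_table(chrom)
        start, end = float(grp["cm"].min()), float(grp["cm"].max())
        for p in np.arange(start, end + 1e-9, step_cm):
            rows.append((chrom, float(p)))
    return pd.DataFrame(rows, columns=["chrom", "cm"])


def qtl_count_profile(
    qtls: pd.DataFrame,
    gmap: GeneticMap,
    window_cm: float = 5.0,
    step_cm: float = 1.0,
) -> pd.DataFrame:
    """Distinct-metabolite QTL count in a centered window at each position."""
    grid = _grid(gmap, step_cm)
    counts = np.zeros(len(grid), dtype=int)
    half = window_cm / 2.0
    gchrom = grid["chrom"].to_numpy()
    gcm = grid["cm"].to_numpy()
    if not qtls.empty:
        for (met, chrom), grp in qtls.groupby(["metabolite", "chrom"], sort=False):
            sel = gchrom == chrom
            covered = np.zeros(sel.sum(), dtype=bool)
            pos = gcm[sel]
            for p in grp["peak_cm"].to_numpy():
                covered |= np.abs(pos - p) <= half + 1e-9
            counts[np.nonzero(sel)[0][covered]] += 1
    out = grid.copy()
    out["count"] = counts
    return out


def hotspot_permutation_threshold(
    qtls: pd.DataFrame,
    gmap: GeneticMap,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    window_cm: float = 5.0,
    step_cm: float = 1.0,
) -> float:
    """(1-alpha) quantile of the max window count under uniform peak placement.

    Each permutation redraws every QTL's peak uniformly on the genome
    (chromosome chosen proportional to map length), keeping the number
    of QTLs per metabolite fixed, then records the genome-wide maximum
    of the window-count profile.
    """
    if qtls.empty:
        raise ValueError("no QTLs to permute")
    chroms = gmap.chromosomes
    lengths = np.array([gmap.chrom_length(c) for c in chroms])
    offsets = np.concatenate([[0.0], np.cumsum(lengths)])
    total = offsets[-1]
    rng = np.random.default_rng(seed)
    n_qtl = len(qtls)
    mets = qtls["metabolite"].to_numpy()
    maxima = np.empty(n_perm)
    perm = qtls[["metabolite"]].copy()
    for i in range(n_perm):
        u = rng.uniform(0.0, total, n_qtl)
        ci = np.clip(np.searchsorted(offsets, u, side="right") - 1, 0, len(chroms) - 1)
        perm["chrom"] = np.asarray(chroms)[ci]
        perm["peak_cm"] = u - offsets[ci]
        prof = qtl_count_profile(perm, gmap, window_cm, step_cm)
        maxima[i] = prof["count"].max()
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def call_hotspots(
    profile: pd.DataFrame, threshold: float, gmap: GeneticMap
) -> pd.DataFrame:
    """Collapse contiguous above-threshold runs to named hotspots.

    Each run becomes one hotspot at its maximum-count position (a
    plateau of tied maxima resolves to its middle position); the
    representative marker is the observed marker nearest the center.
    """
    rows = []
    for chrom, grp in profile.groupby("chrom", sort=False):
        grp = grp.sort_values("cm").reset_index(drop=True)
        above = grp["count"].to_numpy() > threshold
        i = 0
        while i < len(grp):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(grp) and above[j + 1]:
                j += 1
            run = grp.iloc[i : j + 1]
            counts = run["count"].to_numpy()
            top = np.nonzero(counts == counts.max())[0]
            peak = run.iloc[int(top[len(top) // 2])]
            cm = float(peak["cm"])
            rows.append(
                {
                    "name": f"M.{roman(int(chrom))}.{round(cm)}",
                    "chrom": int(chrom),
                    "center_cm": cm,
                    "count": int(peak["count"]),
                    "marker": gmap.nearest_marker(int(chrom), cm),
                }
            )
            i = j + 1
    return pd.DataFrame(rows, columns=["name", "chrom", "center_cm", "count", "marker"])
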