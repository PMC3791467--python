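"""Center-of-phenotype cartography for epistatic locus pairs.

The four homozygous genotype classes of a locus pair are placed at the
corners (±1, ±1) of a genotype plane (Kas = +1, Tsu = -1 on each axis).
Treating each class's mean un-scaled abundance p_i as a mass gives a
center of mass

    x = sum(p_i * x_i) / sum(p_i),   y = sum(p_i * y_i) / sum(p_i),

which summarizes the allelic-effect structure of an epistatically
affected metabolite as a single point in [-1, 1]^2: marginal
displacement along an axis reflects that locus's effect, and the spread
of centers over metabolites compares the phenotypic reach of the two
loci.  Stratifying the calculation by cytoplasm class exposes nuclear
epistasis that pooling across cytoplasms hides.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, KAS, LineMeans, TSU

log = logging.getLogger(__name__)

CLASSES = ((1, 1), (1, -1), (-1, 1), (-1, -1))


class EmptyClassError(ValueError):
    """A homozygous genotype class has no lines (or an invalid mean)."""


def class_means_2x2(
    values: pd.Series,
    gx: pd.Series,
    gy: pd.Series,
    mask: pd.Series | None = None,
) -> dict[tuple[int, int], float]:
    """Mean abundance per homozygous class of (locusX, locusY)."""
    df = pd.DataFrame({"v": values, "x": gx, "y": gy}).dropna()
    if mask is not None:
        df = df[mask.reindex(df.index).fillna(False)]
    out = {}
    for cx, cy in CLASSES:
        sel = df[(df["x"] == cx) & (df["y"] == cy)]["v"]
        if sel.empty:
            raise EmptyClassError(f"genotype class (x={cx}, y={cy}) has no lines")
        m = float(sel.mean())
        if not (m > 0):
            raise EmptyClassError(f"non-positive mean in class (x={cx}, y={cy})")
        out[(cx, cy)] = m
    return out


def phenotype_center(class_means: dict[tuple[int, int], float]) -> tuple[float, float]:
    """Center of mass of the four class means on the genotype plane."""
    missing = set(CLASSES) - set(class_means)
    if missing:
        raise EmptyClassError(f"missing genotype classes {sorted(missing)}")
    if any(not (p > 0) for p in class_means.values()):
        raise EmptyClassError("class means must be positive")
    total = sum(class_means.values())
    x = sum(p * cx for (cx, _), p in class_means.items()) / total
    y = sum(p * cy for (_, cy), p in class_means.items()) / total
    return float(x), float(y)


def _locus_series(genotypes: GenotypeMatrix, locus: str) -> pd.Series:
    return genotypes.locus_values(locus)


def centers_for_interaction(
    line_means: LineMeans,
    genotypes: GenotypeMatrix,
    locus_pair: tuple[str, str],
    metabolite_set,
    gridsize: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-metabolite centers for one locus pair, plus hexbin counts.

    Class means are raw line means pooled over all other loci.
    Metabolites lacking a populated class are skipped with a log entry.
    Hexagonal bin counts over [-1, 1]^2 are exported for plotting.
    """
    gx = _locus_series(genotypes, locus_pair[0])
    gy = _locus_series(genotypes, locus_pair[1])
    rows = []
    for met in metabolite_set:
        try:
            cm = class_means_2x2(line_means.values[met], gx, gy)
        except EmptyClassError as exc:
            log.info("metabolite %s skipped for pair %s: %s", met, locus_pair, exc)
            continue
        x, y = phenotype_center(cm)
        rows.append({"metabolite": met, "x": x, "y": y})
    centers = pd.DataFrame(rows, columns=["metabolite", "x", "y"])
    hexes = hexbin_counts(centers["x"].to_numpy(), centers["y"].to_numpy(), gridsize)
    return centers, hexes


def hexbin_counts(
    x: np.ndarray, y: np.ndarray, gridsize: int = 30
) -> pd.DataFrame:
    """Hexagonal-grid bin counts over [-1, 1]^2 (matplotlib binning)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    try:
        coll = ax.hexbin(
            np.asarray(x, float),
            np.asarray(y, float),
            gridsize=gridsize,
            extent=(-1, 1, -1, 1),
        )
        counts = coll.get_array()
        offsets = coll.get_offsets()
    finally:
        plt.close(fig)
    out = pd.DataFrame(
        {"hex_x": offsets[:, 0], "hex_y": offsets[:, 1], "count": np.asarray(counts)}
    )
    return out[out["count"] > 0].reset_index(drop=True)


def distance_from_corner(
    x: float, y: float, corner: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Euclidean distance of a center from a genotype-plane corner."""
    return math.hypot(x - corner[0], y - corner[1])


def threeway_center_shift(
    line_means: LineMeans,
    genotypes: GenotypeMatrix,
    nuclear_pair: tuple[str, str],
    metabolite_set,
) -> pd.DataFrame:
    """Pooled versus cytoplasm-stratified centers for a nuclear locus pair.

    For each metabolite: the pairwise center pools both cytoplasm
    classes; stratified centers are computed within the Kas and the Tsu
    subpopulations; the three-way center is the mean of the two
    stratified centers.  The displacement between pooled and three-way
    centers, and the change in distance from the (1, 1) corner, quantify
    how much the cytoplasmic background reshapes the nuclear epistasis.
    """
    gx = _locus_series(genotypes, nuclear_pair[0])
    gy = _locus_series(genotypes, nuclear_pair[1])
    cyto = genotypes.cytoplasm
    rows = []
    for met in metabolite_set:
        vals = line_means.values[met]
        try:
            pooled = phenotype_center(class_means_2x2(vals, gx, gy))
            kas = phenotype_center(class_means_2x2(vals, gx, gy, mask=cyto == KAS))
            tsu = phenotype_center(class_means_2x2(vals, gx, gy, mask=cyto == TSU))
        except EmptyClassError as exc:
            log.info("metabolite %s skipped for pair %s: %s", met, nuclear_pair, exc)
            continue
        three = ((kas[0] + tsu[0]) / 2.0, (kas[1] + tsu[1]) / 2.0)
        d_pair = distance_from_corner(*pooled)
        d_three = distance_from_corner(*three)
        rows.append(
            {
                "metabolite": met,
                "x_pooled": pooled[0],
                "y_pooled": pooled[1],
                "x_kas": kas[0],
                "y_kas": kas[1],
                "x_tsu": tsu[0],
                "y_tsu": tsu[1],
                "x_threeway": three[0],
                "y_threeway": three[1],
                "dx": three[0] - pooled[0],
                "dy": three[1] - pooled[1],
                "dist_pairwise": d_pair,
                "dist_threeway": d_three,
                "delta_dist": d_three - d_pair,
                "direction": "increase" if d_three > d_pair else "decrease",
            }
        )
    return pd.DataFrame(rows)


def shift_summary(shifts: pd.DataFrame) -> dict:
    """Frequencies and central tendencies of distance-from-(1,1) changes."""
    if shifts.empty:
        return {"n": 0, "n_increase": 0, "n_decrease": 0}
    inc = shifts[shifts["delta_dist"] > 0]["delta_dist"]
    dec = shifts[shifts["delta_dist"] <= 0]["delta_dist"]
    return {
        "n": int(len(shifts)),
        "n_increase": int(len(inc)),
        "n_decrease": int(len(dec)),
        "mean_increase": float(inc.mean()) if len(inc) else np.nan,
        "mean_decrease": float(dec.mean()) if len(dec) else np.nan,
        "median_increase": float(inc.median()) if len(inc) else np.nan,
        "median_decrease": float(dec.median()) if len(dec) else np.nan,
    }
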