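"""Synthetic reciprocal-RIL populations with known genetic architecture.

Generates a genetic map, fully inbred RIL genotypes from a reciprocal
cross (two cytoplasm subpopulations), and replicated, positive,
ion-count-like metabolite phenotypes whose architecture (additive,
cytoplasmic, pairwise-epistatic and cytoplasm x nuclear x nuclear
three-way effects, plus experiment/block structure) is fully known, so
every downstream stage of the pipeline can be exercised against ground
truth.

Phenotypes are generated multiplicatively: effects act on the log scale
and are exponentiated, which keeps values strictly positive and makes
median normalization meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CYTOPLASM, KAS, TSU, GeneticMap, GenotypeMatrix, PHENO_COLUMNS


# ---------------------------------------------------------------------------
# recombination model (shared with the QTL scan)

def haldane_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Haldane map function: recombination fraction for a distance in cM."""
    d = np.asarray(d_cm, dtype=float) / 100.0  # Morgans
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def ril_recomb(d_cm: np.ndarray | float) -> np.ndarray | float:
    """RIL-adjusted recombination fraction R = 2r/(1+2r) between fixed lines.

    Repeated selfing to homozygosity inflates the observed recombinant
    fraction between adjacent markers relative to the single-meiosis
    fraction r (Haldane here).
    """
    r = haldane_r(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimulationConfig:
    """Scenario for one simulated population.

    Defaults are a desk-scale emulation of a reciprocal RIL metabolomics
    study: 5 chromosomes x 100 cM, 200 markers, 240 lines split 100 Kas /
    140 Tsu cytoplasm, 100 metabolites measured in 2 experiments x 2
    blocks (4 replicates).  The full-size study (316 lines split 136/180,
    1069 markers) is reachable by configuration.
    """

    seed: int
    n_lines: int = 240
    cyto_counts: tuple[int, int] = (100, 140)  # (Kas, Tsu)
    n_chromosomes: int = 5
    chrom_lengths: tuple[float, ...] = (100.0, 100.0, 100.0, 100.0, 100.0)
    n_markers: int = 200
    n_metabolites: int = 100
    n_experiments: int = 2
    n_blocks_per_experiment: int = 2
    marker_spacing: str = "equal"  # "equal" | "uniform"

    def __post_init__(self):
        if sum(self.cyto_counts) != self.n_lines:
            raise ValueError(
                f"cyto_counts {self.cyto_counts} do not sum to n_lines {self.n_lines}"
            )
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must have one entry per chromosome")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be strictly positive")
        if self.marker_spacing not in ("equal", "uniform"):
            raise ValueError(f"unknown marker_spacing {self.marker_spacing!r}")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage)))


def paper_scale_config(seed: int) -> SimulationConfig:
    """Configuration emulating the published Kas x Tsu population size."""
    # 1069 markers at a median spacing near 0.35 cM over five chromosomes.
    total = 0.35 * (1069 - 5)
    per = total / 5
    return SimulationConfig(
        seed=seed,
        n_lines=316,
        cyto_counts=(136, 180),
        n_chromosomes=5,
        chrom_lengths=(per,) * 5,
        n_markers=1069,
        n_metabolites=100,
    )


# ---------------------------------------------------------------------------
# map and genotypes

def simulate_map(config: SimulationConfig) -> GeneticMap:
    """Place markers along each chromosome (equal spacing or uniform draws)."""
    counts = _split_markers(config.n_markers, config.n_chromosomes)
    rng = config.rng(0)
    rows = []
    for chrom, (n, length) in enumerate(zip(counts, config.chrom_lengths), start=1):
        if n < 2:
            raise ValueError(f"chromosome {chrom} needs at least 2 markers, got {n}")
        if config.marker_spacing == "equal":
            pos = np.linspace(0.0, length, n)
        else:
            pos = np.sort(rng.uniform(0.0, length, n))
            pos[0], pos[-1] = 0.0, length
        for i, p in enumerate(pos, start=1):
            rows.append((f"c{chrom}m{i:04d}", chrom, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cm"]))


def _split_markers(n_markers: int, n_chrom: int) -> list[int]:
    base, extra = divmod(n_markers, n_chrom)
    return [base + (1 if i < extra else 0) for i in range(n_chrom)]


def simulate_ril_genotypes(gmap: GeneticMap, config: SimulationConfig) -> GenotypeMatrix:
    """Draw inbred RIL genotypes as a Markov chain along each chromosome.

    The chain starts from a fair allele draw at the first marker of each
    chromosome and switches parental allele between adjacent markers with
    the RIL-adjusted Haldane recombination fraction.  The first
    ``cyto_counts[0]`` lines carry the Kas cytoplasm, the rest Tsu.
    """
    rng = config.rng(1)
    n = config.n_lines
    cols: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        grp = gmap.chrom_table(chrom)
        markers = grp["marker"].to_list()
        pos = grp["cm"].to_numpy()
        cur = rng.choice(np.array([KAS, TSU], dtype=np.int8), size=n)
        cols[markers[0]] = cur
        big_r = ril_recomb(np.diff(pos))
        for m, r in zip(markers[1:], big_r):
            flip = rng.random(n) < r
            cur = np.where(flip, -cur, cur).astype(np.int8)
            cols[m] = cur
    lines = pd.Index([f"RIL{i:04d}" for i in range(1, n + 1)], name="line")
    alleles = pd.DataFrame(cols, index=lines)[gmap.markers.to_list()]
    cyto = np.full(n, TSU, dtype=np.int8)
    cyto[: config.cyto_counts[0]] = KAS
    return GenotypeMatrix(alleles, pd.Series(cyto, index=lines, name=CYTOPLASM))


# ---------------------------------------------------------------------------
# architecture

@dataclass
class MetaboliteArchitecture:
    """True generative effects (log scale) for one metabolite.

    ``additive`` maps locus name (marker or ``"cytoplasm"``) to its
    half-difference effect; ``pairwise`` maps (locusA, locusB) to an
    interaction coefficient on the product of the ±1 codes; ``threeway``
    maps a nuclear pair (A, B) to the coefficient on allele_A * allele_B *
    cytoplasm.  ``experiment``/``block``/``cyto_by_experiment`` carry the
    replicate-structure effects of the line-heritability model.
    """

    mu: float = 0.0
    additive: dict[str, float] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    threeway: dict[tuple[str, str], float] = field(default_factory=dict)
    experiment: dict[int, float] = field(default_factory=dict)
    block: dict[tuple[int, int], float] = field(default_factory=dict)
    cyto_by_experiment: dict[int, float] = field(default_factory=dict)
    resid_sd: float = 0.0

    def loci(self) -> set[str]:
        out = set(self.additive)
        for a, b in self.pairwise:
            out |= {a, b}
        for a, b in self.threeway:
            out |= {a, b, CYTOPLASM}
        return out

    def validate(self, gmap: GeneticMap) -> None:
        known = set(gmap.markers) | {CYTOPLASM}
        unknown = self.loci() - known
        if unknown:
            raise ValueError(f"architecture references unknown loci {sorted(unknown)}")
        if self.resid_sd < 0:
            raise ValueError("residual SD must be >= 0")
        for d in (self.additive, self.pairwise, self.threeway):
            if any(not math.isfinite(v) for v in d.values()):
                raise ValueError("architecture effect is not finite")


TrueArchitecture = dict[str, MetaboliteArchitecture]


def genetic_values(genotypes: GenotypeMatrix, arch: MetaboliteArchitecture) -> pd.Series:
    """Per-line genetic value (log scale) implied by one architecture."""
    g = pd.Series(arch.mu, index=genotypes.lines, dtype=float)
    for locus, eff in arch.additive.items():
        g += eff * genotypes.locus_values(locus)
    for (a, b), eff in arch.pairwise.items():
        g += eff * genotypes.locus_values(a) * genotypes.locus_values(b)
    for (a, b), eff in arch.threeway.items():
        g += (
            eff
            * genotypes.locus_values(a)
            * genotypes.locus_values(b)
            * genotypes.cytoplasm
        )
    return g


def simulate_metabolome(
    genotypes: GenotypeMatrix,
    architecture: TrueArchitecture,
    config: SimulationConfig,
    gmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """Replicated positive phenotypes from a known architecture.

    On the log scale each observation is the line's genetic value plus
    experiment, block-within-experiment and cytoplasm-by-experiment
    effects plus Gaussian noise; the result is exponentiated so all
    values are strictly positive ion-count-like abundances.
    """
    rng = config.rng(2)
    if gmap is not None:
        for arch in architecture.values():
            arch.validate(gmap)
    lines = genotypes.lines
    n = len(lines)
    cyto = genotypes.cytoplasm.to_numpy()
    frames = []
    for met, arch in architecture.items():
        g = genetic_values(genotypes, arch).to_numpy()
        for e in range(1, config.n_experiments + 1):
            for b in range(1, config.n_blocks_per_experiment + 1):
                y = g.copy()
                y += arch.experiment.get(e, 0.0)
                y += arch.block.get((e, b), 0.0)
                y += arch.cyto_by_experiment.get(e, 0.0) * cyto
                if arch.resid_sd > 0:
                    y += rng.normal(0.0, arch.resid_sd, n)
                frames.append(
                    pd.DataFrame(
                        {
                            "line": lines,
                            "experiment": e,
                            "block": b,
                            "metabolite": met,
                            "value": np.exp(y),
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=list(PHENO_COLUMNS))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# stock architectures

def null_architecture(
    n_metabolites: int, mu: float = 5.0, resid_sd: float = 0.3
) -> TrueArchitecture:
    """Pure-noise metabolites: no genetic signal at all."""
    return {
        f"met{i:04d}": MetaboliteArchitecture(mu=mu, resid_sd=resid_sd)
        for i in range(1, n_metabolites + 1)
    }


def additive_architecture(
    gmap: GeneticMap,
    rng: np.random.Generator,
    n_metabolites: int,
    h2: float = 0.2,
    n_loci: int = 1,
    mu: float = 5.0,
    resid_sd: float = 0.3,
) -> TrueArchitecture:
    """Random additive architectures targeting a per-observation h2.

    Effects are sized so that, with ±1 alleles of unit variance, the
    genetic variance is ``h2/(1-h2)`` times the residual variance.
    """
    sigma_g2 = h2 / (1.0 - h2) * resid_sd**2
    arch: TrueArchitecture = {}
    markers = gmap.markers.to_numpy()
    for i in range(1, n_metabolites + 1):
        loci = rng.choice(markers, size=n_loci, replace=False)
        a = math.sqrt(sigma_g2 / n_loci)
        arch[f"met{i:04d}"] = MetaboliteArchitecture(
            mu=mu,
            additive={str(l): a * rng.choice([-1.0, 1.0]) for l in loci},
            resid_sd=resid_sd,
        )
    return arch


def cytonuclear_scenario(
    gmap: GeneticMap,
    rng: np.random.Generator,
    n_metabolites: int = 100,
    cyto_fraction: float = 0.8,
    cyto_effect: float = 0.15,
    n_cytonuclear_pairs: int = 6,
    pair_fraction: float = 0.25,
    interaction_effect: float = 0.15,
    mu: float = 5.0,
    resid_sd: float = 0.3,
) -> tuple[TrueArchitecture, list[tuple[str, str]]]:
    """Scenario with widespread cytoplasm main effects and planted
    cytonuclear interactions.

    ``cyto_fraction`` of metabolites receive a cytoplasm main effect;
    ``n_cytonuclear_pairs`` (cytoplasm, nuclear marker) interactions are
    planted, each affecting ``pair_fraction`` of metabolites.  The
    nuclear partners are evenly spread across the map — they stand in
    for QTL hotspot markers, which are well-separated loci, so their
    interaction regressors segregate near-independently.  Returns the
    architecture and the planted pairs.
    """
    markers = gmap.markers.to_numpy()
    idx = np.linspace(0, len(markers) - 1, n_cytonuclear_pairs + 2)[1:-1]
    nuclear = markers[np.round(idx).astype(int)]
    pairs = [(CYTOPLASM, str(m)) for m in nuclear]
    arch: TrueArchitecture = {}
    for i in range(1, n_metabolites + 1):
        m = MetaboliteArchitecture(mu=mu, resid_sd=resid_sd)
        if rng.random() < cyto_fraction:
            m.additive[CYTOPLASM] = cyto_effect * rng.choice([-1.0, 1.0])
        for pair in pairs:
            if rng.random() < pair_fraction:
                m.pairwise[pair] = interaction_effect * rng.choice([-1.0, 1.0])
        arch[f"met{i:04d}"] = m
    return arch, pairs


def pipeline_scenario(
    gmap: GeneticMap,
    rng: np.random.Generator,
    n_metabolites: int = 100,
    n_hotspot_loci: int = 3,
    hotspot_fraction: float = 0.3,
    additive_effect: float = 0.25,
    cyto_fraction: float = 0.8,
    cyto_effect: float = 0.15,
    interaction_effect: float = 0.15,
    mu: float = 5.0,
    resid_sd: float = 0.3,
) -> tuple[TrueArchitecture, dict]:
    """End-to-end demo scenario: planted QTL hotspots plus cytonuclear terms.

    ``n_hotspot_loci`` markers (one per chromosome where possible) each
    carry an additive effect for ``hotspot_fraction`` of metabolites, so
    the scan-and-summation stages find real hotspots; most metabolites
    also get a cytoplasm main effect, and cytonuclear interactions are
    planted between the cytoplasm and the hotspot loci.
    """
    chroms = gmap.chromosomes
    hotspot_loci = []
    for i in range(n_hotspot_loci):
        grp = gmap.chrom_table(chroms[i % len(chroms)])
        hotspot_loci.append(str(grp["marker"].iloc[len(grp) // 2]))
    pairs = [(CYTOPLASM, m) for m in hotspot_loci[: min(2, n_hotspot_loci)]]
    arch: TrueArchitecture = {}
    for i in range(1, n_metabolites + 1):
        m = MetaboliteArchitecture(mu=mu, resid_sd=resid_sd)
        for locus in hotspot_loci:
            if rng.random() < hotspot_fraction:
                m.additive[locus] = additive_effect * rng.choice([-1.0, 1.0])
        if rng.random() < cyto_fraction:
            m.additive[CYTOPLASM] = cyto_effect * rng.choice([-1.0, 1.0])
        for pair in pairs:
            if rng.random() < 0.25:
                m.pairwise[pair] = interaction_effect * rng.choice([-1.0, 1.0])
        arch[f"met{i:04d}"] = m
    return arch, {"hotspot_loci": hotspot_loci, "cytonuclear_pairs": pairs}


def masked_epistasis_architecture(
    locus_a: str, locus_b: str, effect: float = 0.4, mu: float = 5.0
) -> MetaboliteArchitecture:
    """Nuclear epistasis visible in only one cytoplasmic background.

    In the Kas cytoplasm the phenotype is raised only in the double-Kas
    nuclear class; in the Tsu cytoplasm it is raised in every other
    class.  Pooled over cytoplasms the nuclear-pair interaction cancels
    exactly, so only the three-way term (and the cytonuclear terms that
    accompany it) carries signal.  Noiseless by default.
    """
    e = effect
    return MetaboliteArchitecture(
        mu=mu + e / 2.0,
        additive={CYTOPLASM: -e / 4.0},
        pairwise={(CYTOPLASM, locus_a): e / 4.0, (CYTOPLASM, locus_b): e / 4.0},
        threeway={(locus_a, locus_b): e / 4.0},
        resid_sd=0.0,
    )


# ---------------------------------------------------------------------------
# truth export

_TERM_SEP = "|"


def export_truth(architecture: TrueArchitecture, path) -> None:
    """Write all nonzero true effects to CSV, one row per term."""
    rows = []
    for met, arch in architecture.items():
        rows.append((met, "mu", arch.mu))
        rows.append((met, "resid_sd", arch.resid_sd))
        for locus, v in arch.additive.items():
            if v != 0:
                rows.append((met, f"additive:{locus}", v))
        for (a, b), v in arch.pairwise.items():
            if v != 0:
                rows.append((met, f"pairwise:{a}{_TERM_SEP}{b}", v))
        for (a, b), v in arch.threeway.items():
            if v != 0:
                rows.append((met, f"threeway:{a}{_TERM_SEP}{b}", v))
        for e, v in arch.experiment.items():
            if v != 0:
                rows.append((met, f"experiment:{e}", v))
        for (e, b), v in arch.block.items():
            if v != 0:
                rows.append((met, f"block:{e}{_TERM_SEP}{b}", v))
        for e, v in arch.cyto_by_experiment.items():
            if v != 0:
                rows.append((met, f"cyto_x_experiment:{e}", v))
    pd.DataFrame(rows, columns=["metabolite", "term", "value"]).to_csv(
        path, index=False
    )


def load_truth(path) -> TrueArchitecture:
    """Inverse of :func:`export_truth`."""
    df = pd.read_csv(path)
    arch: TrueArchitecture = {}
    for met, grp in df.groupby("metabolite", sort=False):
        m = MetaboliteArchitecture()
        for _, row in grp.iterrows():
            term, v = str(row["term"]), float(row["value"])
            if term == "mu":
                m.mu = v
            elif term == "resid_sd":
                m.resid_sd = v
            elif term.startswith("additive:"):
                m.additive[term.split(":", 1)[1]] = v
            elif term.startswith("pairwise:"):
                a, b = term.split(":", 1)[1].split(_TERM_SEP)
                m.pairwise[(a, b)] = v
            elif term.startswith("threeway:"):
                a, b = term.split(":", 1)[1].split(_TERM_SEP)
                m.threeway[(a, b)] = v
            elif term.startswith("experiment:"):
                m.experiment[int(term.split(":", 1)[1])] = v
            elif term.startswith("block:"):
                e, b = term.split(":", 1)[1].split(_TERM_SEP)
                m.block[(int(e), int(b))] = v
            elif term.startswith("cyto_x_experiment:"):
                m.cyto_by_experiment[int(term.split(":", 1)[1])] = v
            else:
                raise ValueError(f"unknown truth term {term!r}")
        arch[str(met)] = m
    return arch
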