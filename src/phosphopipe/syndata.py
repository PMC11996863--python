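"""Synthetic phosphoproteomics experiments with planted ground truth.

The generator emulates the statistical structure of a paired
insulin-stimulation study on iPS-derived hepatocytes: 8 control and 8 T2D
donors with equal sexes, two of the T2D donors excluded (final 8 CTL / 6
T2D), one basal and one insulin sample per retained donor, log2-scale
intensities with intensity-dependent (MNAR) missingness, and planted
insulin-responsive, impaired, emergent, sex-dimorphic and basal-shifted
sites.  Sequence windows of driver-kinase sites are sampled from that
kinase's position-specific scoring matrix so the kinome stage can be
verified end to end.

Every planted effect, the per-sample batch (surrogate-variable) score and
the pre-missingness intensities are returned as :class:`GroundTruth` for
use as test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    GeneSetCollection,
    PhosphoSiteTable,
    validate_design,
)
from .kinome import KinaseAtlas

#: planted classes in generation order; remaining sites are "null"
PLANTED_CLASSES = ("1A", "1B", "1C", "2A", "2B", "2C", "sexF", "sexM", "basal_shift")

#: default driver-kinase assignment per signaling class (atlas entry names).
#: Only the classes the emulated study maps to kinases carry a driver: the
#: emergent classes (an up- and a down-acting kinase gaining activity in
#: T2D) and the impaired insulin-stimulated class (a kinase losing
#: activity).  This keeps exactly one planted driver per enrichment side of
#: the insulin-state phenotype comparison, so driver inference has an
#: unambiguous ground truth.
DEFAULT_DRIVERS = {
    "1B": "KIN002",
    "1C": "KIN001",
    "2C": "KIN003",
}


def _default_per_class() -> dict[str, int]:
    return {
        "1A": 100, "1B": 100, "1C": 100,
        "2A": 100, "2B": 100, "2C": 100,
        "sexF": 100, "sexM": 100, "basal_shift": 100,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated experiment.

    The defaults reproduce the emulated design: 8 + 8 donors with two T2D
    donors (one of each sex) excluded, ~2,000 quantified sites at a mean
    log2 intensity of 23, donor offsets of 0.3 log2 units shared by both
    treatments (the pairing), residual noise of 0.5 log2 units, insulin
    responses of 0.6-2.0 log2 units, impaired sites losing 75-100% of the
    control response, a 1.5 log2-unit sex offset, and a logistic MNAR
    dropout centered 3 log2 units below the mean intensity.
    """

    n_ctl_donors: int = 8
    n_t2d_donors: int = 8
    n_t2d_excluded: int = 2
    sex_balance: bool = True
    n_sites: int = 2000
    baseline_mean: float = 23.0
    baseline_sd: float = 2.0
    donor_sd: float = 0.3
    noise_sd: float = 0.5
    sv_loading_sd: float = 0.5
    insulin_effect_range: tuple[float, float] = (0.6, 2.0)
    attenuation_range: tuple[float, float] = (0.75, 1.0)
    sex_effect: float = 1.5
    n_per_class: dict[str, int] = field(default_factory=_default_per_class)
    mnar_center: float = 20.0
    mnar_width: float = 0.7
    mnar_enabled: bool = True
    loc_prob_low_fraction: float = 0.1
    n_kinases: int = 50
    n_sharp_positions: tuple[int, int] = (2, 4)
    n_background: int = 5000
    flank_range: tuple[int, int] = (-5, 4)
    sites_per_gene: int = 2
    n_gene_sets: int = 20
    gene_set_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_ctl_donors, self.n_t2d_donors, self.n_t2d_excluded,
            self.n_sites, self.n_kinases,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if any(v < 0 for v in self.n_per_class.values()):
            raise ValueError("n_per_class counts must be >= 0")
        if sum(self.n_per_class.values()) > self.n_sites:
            raise ValueError("sum of n_per_class exceeds n_sites")
        unknown = set(self.n_per_class) - set(PLANTED_CLASSES)
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        for name in ("insulin_effect_range", "attenuation_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not well ordered")
        lo, hi = self.attenuation_range
        if not (0 <= lo and hi <= 1):
            raise ValueError("attenuation must lie in [0, 1]")
        if self.flank_range[0] > self.flank_range[1]:
            raise ValueError("flank_range is not well ordered")
        if self.flank_range[0] > 0 or self.flank_range[1] < 0:
            raise ValueError("flank_range must span position 0 (the phosphoresidue)")

    @property
    def flank_positions(self) -> list[int]:
        lo, hi = self.flank_range
        return [p for p in range(lo, hi + 1) if p != 0]

    @property
    def window_length(self) -> int:
        return len(self.flank_positions) + 1


@dataclass
class GroundTruth:
    """Planted truth for one simulated experiment.

    ``sites`` holds per-site class label, true insulin log2FC per
    phenotype, sex offset (F minus M), basal phenotype shift and driver
    kinase (empty string for none).  ``sv_scores`` is the standardized
    per-sample batch vector, ``sv_loadings`` its per-site loading, and
    ``true_matrix`` the pre-missingness log2 intensities.
    """

    sites: pd.DataFrame
    sv_scores: pd.Series
    sv_loadings: pd.Series
    true_matrix: pd.DataFrame

    def planted(self, label: str) -> pd.Index:
        return self.sites.index[self.sites["class_label"] == label]


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample design table: one basal + one insulin sample per retained donor.

    Donor cell lines are named ``{phenotype}_{sex}_C{number}``; sample ids
    append the treatment.  With ``sex_balance`` each phenotype splits
    equally between sexes (odd donor counts are an error).  Excluded T2D
    donors (alternating sex, starting with male) are absent entirely.
    """
    rows = []
    for pheno, n_donors in (("CTL", config.n_ctl_donors), ("T2D", config.n_t2d_donors)):
        if config.sex_balance:
            if n_donors % 2:
                raise ValueError(
                    f"sex_balance requires an even donor count, got {n_donors} {pheno}"
                )
            sexes = ["M"] * (n_donors // 2) + ["F"] * (n_donors // 2)
        else:
            sexes = ["M"] * n_donors
        for i, sex in enumerate(sexes, start=1):
            rows.append({"phenotype": pheno, "sex": sex, "donor": i})
    donors = pd.DataFrame(rows)

    # exclude the last T2D donors, alternating sex starting with male
    if config.n_t2d_excluded:
        t2d = donors[donors["phenotype"] == "T2D"]
        drop = []
        want = ["M", "F"] * (config.n_t2d_excluded // 2 + 1)
        for sex in want[: config.n_t2d_excluded]:
            pool = t2d[(t2d["sex"] == sex) & (~t2d.index.isin(drop))]
            if pool.empty:
                pool = t2d[~t2d.index.isin(drop)]
            drop.append(pool.index[-1])
        donors = donors.drop(index=drop)

    out = []
    for _, d in donors.iterrows():
        cell_line = f"{d.phenotype}_{d.sex}_C{d.donor:03d}"
        for treatment in ("basal", "insulin"):
            out.append(
                {
                    "sample_id": f"{cell_line}_{treatment}",
                    "cell_line": cell_line,
                    "phenotype": d.phenotype,
                    "sex": d.sex,
                    "treatment": treatment,
                }
            )
    return validate_design(pd.DataFrame(out))


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------


def _assign_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Site metadata skeleton: gene, position, class label, planted effects."""
    n = config.n_sites
    n_genes = max(1, n // config.sites_per_gene)
    genes = rng.integers(0, n_genes, size=n)
    labels = np.array(["null"] * n, dtype=object)
    start = 0
    for cls in PLANTED_CLASSES:
        cnt = config.n_per_class.get(cls, 0)
        labels[start : start + cnt] = cls
        start += cnt
    # shuffle so planted classes are not contiguous in site order
    perm = rng.permutation(n)
    labels = labels[perm]

    lo, hi = config.insulin_effect_range
    delta = rng.uniform(lo, hi, size=n)
    sign = np.ones(n)
    attenuation = rng.uniform(*config.attenuation_range, size=n)

    ctl_lfc = np.zeros(n)
    t2d_lfc = np.zeros(n)
    sex_offset = np.zeros(n)
    basal_shift = np.zeros(n)
    drivers = np.array([""] * n, dtype=object)
    for i, cls in enumerate(labels):
        if cls in ("2A", "2B", "2C"):
            sign[i] = -1.0
        if cls in ("1A", "2A"):
            ctl_lfc[i] = t2d_lfc[i] = sign[i] * delta[i]
        elif cls in ("1B", "2B"):
            ctl_lfc[i] = sign[i] * delta[i]
            t2d_lfc[i] = sign[i] * delta[i] * (1 - attenuation[i])
        elif cls in ("1C", "2C"):
            t2d_lfc[i] = sign[i] * delta[i]
        elif cls == "sexF":
            sex_offset[i] = config.sex_effect
        elif cls == "sexM":
            sex_offset[i] = -config.sex_effect
        elif cls == "basal_shift":
            basal_shift[i] = delta[i] * (1 if rng.random() < 0.5 else -1)
        drivers[i] = DEFAULT_DRIVERS.get(cls, "")

    sites = pd.DataFrame(
        {
            "gene": [f"GENE{g:05d}" for g in genes],
            "class_label": labels,
            "ctl_insulin_lfc": ctl_lfc,
            "t2d_insulin_lfc": t2d_lfc,
            "sex_offset": sex_offset,
            "basal_shift": basal_shift,
            "driver_kinase": drivers,
        }
    )
    # unique 1-based positions per gene, increasing in site order
    residues = rng.choice(["S", "T"], size=n, p=[0.75, 0.25])
    counter: dict[int, int] = {}
    positions = np.empty(n, dtype=int)
    for i, g in enumerate(genes):
        counter[g] = counter.get(g, 0) + 1
        positions[i] = counter[g] * 10 + int(rng.integers(1, 10))
    sites["residue"] = residues
    sites["position"] = positions
    sites.index = pd.Index(
        [f"{r.gene}_{r.residue}{r.position}" for r in sites.itertuples()],
        name="site_id",
    )
    return sites


def generate_intensities(
    config: SimulationConfig, design: pd.DataFrame
) -> tuple[PhosphoSiteTable, GroundTruth]:
    """Simulate the intensity matrix and its ground truth.

    A cell value is baseline(site) + donor offset (shared by both
    treatments of a cell line) + planted insulin / sex / basal-shift
    effects + SV loading x per-sample batch score + Gaussian noise.
    Cells are then masked missing with probability
    ``logistic((mnar_center - value) / mnar_width)``.

    Localization probabilities: planted effect sites draw Uniform(0.75, 1);
    a ``loc_prob_low_fraction`` share of null sites draws Uniform(0, 0.75)
    so the class-I filter is exercised without censoring the planted truth.
    """
    rng = np.random.default_rng(config.seed)
    sites = _assign_sites(config, rng)
    n = config.n_sites
    samples = design["sample_id"].tolist()
    m = len(samples)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    cell_lines = design["cell_line"].unique()
    donor_eff = {
        line: rng.normal(0.0, config.donor_sd, size=n) for line in cell_lines
    }
    sv_scores = rng.normal(size=m)
    sv_scores = (sv_scores - sv_scores.mean()) / sv_scores.std()
    sv_loadings = rng.normal(0.0, config.sv_loading_sd, size=n)

    is_insulin = (design["treatment"] == "insulin").to_numpy()
    is_t2d = (design["phenotype"] == "T2D").to_numpy()
    is_female = (design["sex"] == "F").to_numpy()

    M = np.tile(baseline[:, None], (1, m))
    for j, (_, row) in enumerate(design.iterrows()):
        M[:, j] += donor_eff[row.cell_line]
    insulin_lfc = np.where(
        is_t2d[None, :],
        sites["t2d_insulin_lfc"].to_numpy()[:, None],
        sites["ctl_insulin_lfc"].to_numpy()[:, None],
    )
    M += insulin_lfc * is_insulin[None, :]
    # sex_offset is the F-minus-M difference; apply it to female samples
    M += sites["sex_offset"].to_numpy()[:, None] * is_female[None, :]
    M += sites["basal_shift"].to_numpy()[:, None] * is_t2d[None, :]
    M += np.outer(sv_loadings, sv_scores)
    M += rng.normal(0.0, config.noise_sd, size=(n, m))

    if config.mnar_enabled:
        p_missing = 1.0 / (1.0 + np.exp(-(config.mnar_center - M) / config.mnar_width))
        mask = rng.random(size=(n, m)) < p_missing
    else:
        mask = np.zeros((n, m), dtype=bool)
    observed = np.where(mask, np.nan, M)

    loc_prob = rng.uniform(0.75, 1.0, size=n)
    null_idx = np.flatnonzero((sites["class_label"] == "null").to_numpy())
    n_low = int(round(config.loc_prob_low_fraction * n))
    low_idx = rng.choice(null_idx, size=min(n_low, len(null_idx)), replace=False)
    loc_prob[low_idx] = rng.uniform(0.0, 0.75, size=len(low_idx))

    # provisional background windows; simulate_experiment replaces them with
    # driver-motif windows once the atlas exists
    windows = _background_windows(
        config, sites["residue"].to_numpy(), rng=np.random.default_rng(config.seed + 1)
    )
    meta = pd.DataFrame(
        {
            "gene": sites["gene"],
            "residue": sites["residue"],
            "position": sites["position"],
            "window": windows,
            "localization_probability": loc_prob,
        },
        index=sites.index,
    )
    intensities = pd.DataFrame(
        np.power(2.0, observed), index=sites.index, columns=samples
    )
    table = PhosphoSiteTable(meta=meta, intensities=intensities)
    truth = GroundTruth(
        sites=sites,
        sv_scores=pd.Series(sv_scores, index=samples, name="sv_score"),
        sv_loadings=pd.Series(sv_loadings, index=sites.index, name="sv_loading"),
        true_matrix=pd.DataFrame(M, index=sites.index, columns=samples),
    )
    return table, truth


# ---------------------------------------------------------------------------
# kinase atlas and windows
# ---------------------------------------------------------------------------


def generate_kinase_atlas(config: SimulationConfig) -> KinaseAtlas:
    """Dirichlet-sampled PSSMs with 2-4 sharply preferred positions each,
    plus per-kinase background score distributions.

    Sharp positions concentrate ~80-95% of probability on one residue;
    the remaining positions are near-uniform.  Backgrounds are the scores
    of ``n_background`` windows drawn from uniform residue frequencies.
    """
    if config.n_kinases < 1:
        raise ValueError("n_kinases must be >= 1")
    rng = np.random.default_rng(config.seed + 1000)
    positions = config.flank_positions
    n_aa = len(AMINO_ACIDS)
    # deal sharp (position, residue) pairs without replacement across
    # kinases so no two specificities coincide exactly and the planted
    # driver of a site set stays identifiable; overflow (more kinases than
    # combinations) falls back to sampling with replacement
    pool = [(pi, ai) for pi in range(len(positions)) for ai in range(n_aa)]
    pool = [pool[i] for i in rng.permutation(len(pool))]
    matrices: dict[str, pd.DataFrame] = {}
    for i in range(config.n_kinases):
        name = f"KIN{i:03d}"
        lo, hi = config.n_sharp_positions
        n_sharp = min(int(rng.integers(lo, hi + 1)), len(positions))
        sharp: dict[int, int] = {}
        while len(sharp) < n_sharp:
            if pool:
                pi, ai = pool.pop()
            else:  # pragma: no cover - only for very large n_kinases
                pi, ai = int(rng.integers(len(positions))), int(rng.integers(n_aa))
            if pi not in sharp:
                sharp[pi] = ai
        mat = np.empty((len(positions), n_aa))
        for pi in range(len(positions)):
            if pi in sharp:
                alpha = np.full(n_aa, 0.25)
                alpha[sharp[pi]] = 15.0
            else:
                alpha = np.full(n_aa, 5.0)
            mat[pi] = rng.dirichlet(alpha)
        matrices[name] = pd.DataFrame(mat, index=positions, columns=list(AMINO_ACIDS))

    bg_rng = np.random.default_rng(config.seed + 2000)
    centers = bg_rng.choice(["S", "T"], size=config.n_background)
    bg_windows = _background_windows(config, centers, rng=bg_rng)
    from .kinome import raw_scores

    bg_scores = raw_scores(bg_windows, matrices)
    backgrounds = {
        name: np.sort(bg_scores[name].to_numpy()) for name in matrices
    }
    return KinaseAtlas(matrices=matrices, backgrounds=backgrounds)


def _background_windows(
    config: SimulationConfig, centers: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Windows with uniform background residue frequencies at the flanks."""
    positions = config.flank_positions
    lo, _ = config.flank_range
    out = []
    flanks = rng.integers(0, len(AMINO_ACIDS), size=(len(centers), len(positions)))
    for i, center in enumerate(centers):
        chars = [AMINO_ACIDS[j] for j in flanks[i]]
        chars.insert(-lo, str(center))  # center index = -lo
        out.append("".join(chars))
    return out


def generate_windows(
    truth: GroundTruth, atlas: KinaseAtlas, config: SimulationConfig
) -> pd.Series:
    """Sequence windows per site: driver sites sample their flanks from the
    driver kinase's PSSM, the rest from background frequencies; the center
    residue is the site's S/T."""
    rng = np.random.default_rng(config.seed + 3000)
    positions = config.flank_positions
    lo, _ = config.flank_range
    n = len(truth.sites)
    aa = np.array(AMINO_ACIDS)
    flanks = rng.integers(0, len(aa), size=(n, len(positions)))
    drivers = truth.sites["driver_kinase"].to_numpy()
    for kinase in sorted(set(drivers) - {""}):
        rows = np.flatnonzero(drivers == kinase)
        mat = atlas.matrices[kinase]
        for pi, pos in enumerate(positions):
            cdf = np.cumsum(mat.loc[pos].to_numpy())
            flanks[rows, pi] = np.minimum(
                np.searchsorted(cdf, rng.random(len(rows))), len(aa) - 1
            )
    residues = truth.sites["residue"].to_numpy()
    windows = []
    for i in range(n):
        chars = list(aa[flanks[i]])
        chars.insert(-lo, residues[i])
        windows.append("".join(chars))
    return pd.Series(windows, index=truth.sites.index, name="window")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def generate_gene_sets(
    truth: GroundTruth, config: SimulationConfig
) -> GeneSetCollection:
    """GMT-representable sets over the site table's gene universe.

    ``set_enriched`` draws most of its members from the parent genes of
    planted impaired/emergent (1B/1C/2B/2C) sites; the remaining sets are
    uniform draws from the universe.
    """
    rng = np.random.default_rng(config.seed + 4000)
    universe = pd.unique(truth.sites["gene"])
    regulated = pd.unique(
        truth.sites.loc[
            truth.sites["class_label"].isin(["1B", "1C", "2B", "2C"]), "gene"
        ]
    )
    size = min(config.gene_set_size, len(universe))
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    if len(regulated):
        n_reg = min(int(round(0.8 * size)), len(regulated))
        members = list(rng.choice(regulated, size=n_reg, replace=False))
        rest = np.setdiff1d(universe, members)
        members += list(rng.choice(rest, size=size - n_reg, replace=False))
        sets["set_enriched"] = tuple(members)
        descriptions["set_enriched"] = "planted regulated-site genes"
    for i in range(1, config.n_gene_sets):
        name = f"set_random_{i:02d}"
        sets[name] = tuple(rng.choice(universe, size=size, replace=False))
        descriptions[name] = "random background set"
    return GeneSetCollection(descriptions=descriptions, sets=sets)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    design: pd.DataFrame
    table: PhosphoSiteTable
    truth: GroundTruth
    atlas: KinaseAtlas
    gene_sets: GeneSetCollection


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a complete experiment: design, intensities, atlas,
    motif-consistent windows and gene sets, all from ``config.seed``."""
    design = generate_design(config)
    table, truth = generate_intensities(config, design)
    atlas = generate_kinase_atlas(config)
    windows = generate_windows(truth, atlas, config)
    meta = table.meta.copy()
    meta["window"] = windows
    table = PhosphoSiteTable(meta=meta, intensities=table.intensities)
    gene_sets = generate_gene_sets(truth, config)
    return SimulatedExperiment(
        config=config, design=design, table=table, truth=truth,
        atlas=atlas, gene_sets=gene_sets,
    )
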