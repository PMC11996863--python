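"""Readers, writers and core containers for the pipeline's file formats.

Canonical formats:

* **site table** — TSV; metadata columns ``site_id, gene, residue, position,
  window, localization_probability`` followed by one intensity column per
  sample.  Missing intensities are empty cells or ``NA``, never 0.
* **sample design** — CSV with ``sample_id, cell_line, phenotype, sex,
  treatment``.
* **gene sets** — standard GMT (name TAB description TAB member...).
* **kinase PSSMs** — long-format TSV (``kinase, position`` + 20 residue
  columns of probabilities) with a companion background-score table
  (``kinase, score``).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

META_COLUMNS = [
    "site_id",
    "gene",
    "residue",
    "position",
    "window",
    "localization_probability",
]

DESIGN_COLUMNS = ["sample_id", "cell_line", "phenotype", "sex", "treatment"]

PHENOTYPES = ("CTL", "T2D")
SEXES = ("M", "F")
TREATMENTS = ("basal", "insulin")


class FormatError(ValueError):
    """A file violated the pipeline's format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PhosphoSiteTable:
    """Sites x samples intensity matrix plus per-site metadata.

    Parameters
    ----------
    meta
        One row per site, indexed by ``site_id``, with columns
        ``gene, residue, position, window, localization_probability``.
    intensities
        Float frame indexed like ``meta`` with one column per sample;
        missing values are NaN.
    """

    meta: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        self.meta = self.meta.copy()
        self.intensities = self.intensities.astype(float).copy()
        validate_site_table(self)

    @property
    def site_ids(self) -> pd.Index:
        return self.meta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_sites(self) -> int:
        return len(self.meta)

    def subset_sites(self, site_ids: Sequence[str]) -> "PhosphoSiteTable":
        return PhosphoSiteTable(
            meta=self.meta.loc[site_ids],
            intensities=self.intensities.loc[site_ids],
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "PhosphoSiteTable":
        return PhosphoSiteTable(meta=self.meta, intensities=intensities)


def validate_site_table(table: PhosphoSiteTable) -> None:
    meta, inten = table.meta, table.intensities
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate site_id(s): {dups}")
    if not meta.index.equals(inten.index):
        raise FormatError("meta and intensity site_ids differ")
    missing = [c for c in META_COLUMNS[1:] if c not in meta.columns]
    if missing:
        raise FormatError(f"missing metadata columns: {missing}")
    lp = meta["localization_probability"].to_numpy(float)
    if np.any((lp < 0) | (lp > 1)):
        raise FormatError("localization_probability outside [0, 1]")
    for sid, res, win in zip(meta.index, meta["residue"], meta["window"]):
        if win[len(win) // 2] != res:
            raise FormatError(
                f"site {sid}: residue {res!r} is not the center of window {win!r}"
            )
    vals = inten.to_numpy(float)
    if np.any(vals[~np.isnan(vals)] < 0):
        raise FormatError("negative intensities present")


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    descriptions: dict[str, str]
    sets: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage.

    Defaults mirror the analysis the pipeline reproduces: class-I sites at
    localization probability >= 0.75; class membership at stimulation
    p < 0.05 and a +/-1.5-fold change; sex dimorphism at FDR < 0.1;
    clustering input at moderated-F FDR < 0.1; kinome regulated sets at
    FDR < 0.5 (basal CTL-vs-T2D) and FDR < 0.25 (insulin-state CTL-vs-T2D);
    kinome display significance at adjusted p <= 0.1 and top-15 predicted
    kinases per site.
    """

    loc_prob_min: float = 0.75
    stim_p: float = 0.05
    stim_fold: float = 1.5
    interaction_p: float = 0.05
    sex_fdr: float = 0.10
    cluster_fdr: float = 0.10
    kinome_regulated_fdr_basal: float = 0.5
    kinome_regulated_fdr_treated: float = 0.25
    kinome_display_adjp: float = 0.1
    top_k: int = 15
    # imputation
    knn_k: int = 10
    knn_min_shared: int = 4
    # clustering
    linkage: str = "complete"
    min_cluster_size: int = 20
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "loc_prob_min",
            "stim_p",
            "interaction_p",
            "sex_fdr",
            "cluster_fdr",
            "kinome_regulated_fdr_basal",
            "kinome_regulated_fdr_treated",
            "kinome_display_adjp",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.stim_fold < 1:
            raise ValueError("stim_fold must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file; keyword overrides win over file values."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# site table I/O
# ---------------------------------------------------------------------------


def read_site_table(path: str | Path) -> PhosphoSiteTable:
    """Read the canonical TSV site table.

    Missing intensities may be encoded as empty cells or ``NA``; any other
    non-numeric cell is an error naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df["site_id"].duplicated().any():
        dups = df.loc[df["site_id"].duplicated(), "site_id"].unique().tolist()
        raise FormatError(f"{path}: duplicate site_id(s): {dups}")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    meta = df[META_COLUMNS].set_index("site_id")
    meta["position"] = meta["position"].astype(int)
    meta["localization_probability"] = meta["localization_probability"].astype(float)

    inten = pd.DataFrame(index=meta.index, columns=sample_cols, dtype=float)
    for col in sample_cols:
        raw = df[col].str.strip()
        blank = (raw == "") | (raw == "NA")
        parsed = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            row = df.loc[bad.idxmax(), "site_id"]
            raise FormatError(
                f"{path}: non-numeric intensity {raw[bad.idxmax()]!r} "
                f"at site {row!r}, sample {col!r}"
            )
        inten[col] = parsed.to_numpy()
    inten.index = meta.index
    return PhosphoSiteTable(meta=meta, intensities=inten)


def write_site_table(table: PhosphoSiteTable, path: str | Path) -> None:
    """Write a site table TSV; round-trips through :func:`read_site_table`."""
    out = table.meta.reset_index()[META_COLUMNS].copy()
    for col in table.sample_ids:
        out[col] = table.intensities[col].to_numpy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


# ---------------------------------------------------------------------------
# design I/O
# ---------------------------------------------------------------------------


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design is missing columns {missing}")
    if design["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design")
    bad_ph = set(design["phenotype"]) - set(PHENOTYPES)
    bad_sex = set(design["sex"]) - set(SEXES)
    bad_tr = set(design["treatment"]) - set(TREATMENTS)
    if bad_ph or bad_sex or bad_tr:
        raise FormatError(
            f"invalid design levels: phenotype={bad_ph}, sex={bad_sex}, treatment={bad_tr}"
        )
    counts = design.groupby(["cell_line", "treatment"]).size()
    if (counts > 1).any():
        raise FormatError("a cell line has more than one sample for a treatment")
    return design


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, dtype=str)
    return validate_design(design)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name\\tdescription\\tmembers...``."""
    descriptions: dict[str, str] = {}
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            descriptions[name] = desc
            sets[name] = tuple(members)
    return GeneSetCollection(descriptions=descriptions, sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# PSSM atlas I/O
# ---------------------------------------------------------------------------


def read_pssm_matrices(path: str | Path, background_path: str | Path):
    """Read a kinase atlas from the long-format PSSM TSV plus backgrounds.

    Rows with probabilities not summing to 1 are renormalized with a logged
    warning when off by more than 1e-6; negative entries are an error; a
    kinase missing one of the positions present for it elsewhere is an error.
    """
    from .kinome import KinaseAtlas  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    expected = {"kinase", "position", *AMINO_ACIDS}
    missing = expected - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    aa_cols = list(AMINO_ACIDS)
    if (df[aa_cols].to_numpy(float) < 0).any():
        raise FormatError(f"{path}: negative PSSM probability")

    all_positions = np.sort(df["position"].unique())
    matrices: dict[str, pd.DataFrame] = {}
    for kinase, grp in df.groupby("kinase", sort=True):
        grp = grp.set_index("position")[aa_cols].astype(float)
        absent = set(all_positions) - set(grp.index)
        if absent:
            raise FormatError(
                f"{path}: kinase {kinase!r} missing position row(s) {sorted(absent)}"
            )
        rows = grp.to_numpy()
        sums = rows.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            logger.warning(
                "PSSM rows for %s renormalized (row sums off by up to %.3g)",
                kinase,
                float(np.max(np.abs(sums - 1))),
            )
        grp = grp.div(sums, axis=0)
        matrices[kinase] = grp.sort_index()

    bg = pd.read_csv(background_path, sep="\t")
    backgrounds = {
        str(k): np.sort(g["score"].to_numpy(float))
        for k, g in bg.groupby("kinase", sort=True)
    }
    return KinaseAtlas(matrices=matrices, backgrounds=backgrounds)


def write_pssm_matrices(atlas, path: str | Path, background_path: str | Path) -> None:
    rows = []
    for kinase in sorted(atlas.matrices):
        mat = atlas.matrices[kinase]
        for pos in mat.index:
            rows.append({"kinase": kinase, "position": int(pos), **mat.loc[pos].to_dict()})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
    bg_rows = []
    for kinase in sorted(atlas.backgrounds):
        for s in atlas.backgrounds[kinase]:
            bg_rows.append({"kinase": kinase, "score": s})
    pd.DataFrame(bg_rows).to_csv(
        background_path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# generic result-table writer
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV writer used for all stage outputs."""
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")
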