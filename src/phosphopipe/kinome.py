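"""Kinase-substrate motif inference and enrichment.

Each S/T phosphosite's sequence window is scored against every kinase's
position-specific scoring matrix (sum of log2 position-weights over the
flanks), calibrated to a percentile against that kinase's background score
distribution, and the top-15 kinases by percentile are the biochemically
predicted kinases for the site.  Per kinase, a 2x2 table of predicted vs
not among regulated vs unregulated sites yields a Haldane-corrected
frequency factor and a one-sided Fisher p-value; Benjamini-Hochberg
adjustment runs across kinases within each regulation side and the more
significant side is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_fdr
from .io import AMINO_ACIDS

logger = logging.getLogger(__name__)

#: probability floor applied before taking log2 of a PSSM weight
PSSM_FLOOR = 1e-4


@dataclass
class KinaseAtlas:
    """Named PSSMs over flank positions x residues plus background scores.

    ``matrices`` maps kinase name to a frame indexed by flank position
    (center position 0 excluded) with the 20 standard amino-acid columns;
    rows sum to 1.  ``backgrounds`` maps kinase name to a sorted array of
    raw scores of background phosphoproteome windows.
    """

    matrices: dict[str, pd.DataFrame]
    backgrounds: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, mat in self.matrices.items():
            if 0 in mat.index:
                raise ValueError(f"kinase {name!r}: PSSM contains center position 0")
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"kinase {name!r}: negative PSSM probability")
        for name in self.matrices:
            bg = self.backgrounds.get(name)
            if bg is None or len(bg) == 0:
                raise ValueError(f"kinase {name!r}: empty background distribution")

    @property
    def kinases(self) -> list[str]:
        return sorted(self.matrices)

    def __len__(self) -> int:
        return len(self.matrices)


@dataclass
class ContingencyTable:
    """Counts for one kinase and one regulation side.

    ``a`` regulated & predicted, ``b`` regulated & not, ``c`` unregulated &
    predicted, ``d`` unregulated & not.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")


def score_site(pssm: pd.DataFrame, window: str, positions=None) -> float:
    """Raw PSSM score of a sequence window: sum of log2 position weights.

    The window center (position 0) is the phosphoresidue and is not
    scored.  Flank positions outside the window and non-standard residues
    contribute 0.  Probabilities are floored at ``PSSM_FLOOR`` before the
    log.

    Raises
    ------
    ValueError
        If the window center is not S or T (tyrosine-centered sites are
        outside the S/T kinome).
    """
    center = len(window) // 2
    if window[center] not in ("S", "T"):
        raise ValueError(f"window center {window[center]!r} is not S/T")
    if positions is None:
        positions = pssm.index
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    mat = pssm.to_numpy()
    pos_row = {p: i for i, p in enumerate(pssm.index)}
    total = 0.0
    for pos in positions:
        idx = center + pos
        if idx < 0 or idx >= len(window):
            continue
        res = window[idx]
        col = aa_index.get(res)
        if col is None:
            continue
        total += float(np.log2(max(mat[pos_row[pos], col], PSSM_FLOOR)))
    return total


def percentile_score(raw: float, background: np.ndarray) -> float:
    """Percentile of a raw score in a sorted background distribution:
    ``100 * #(background <= raw) / len(background)``."""
    bg = np.asarray(background)
    if bg.size == 0:
        raise ValueError("empty background distribution")
    return 100.0 * float(np.searchsorted(bg, raw, side="right")) / bg.size


def raw_scores(
    windows: pd.Series | list, matrices: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Vectorized :func:`score_site` of many windows against many PSSMs."""
    if not isinstance(windows, pd.Series):
        windows = pd.Series(list(windows))
    kinases = sorted(matrices)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    # encode each window as residue indices per flank position (shared grid)
    positions = list(matrices[kinases[0]].index)
    codes = np.empty((len(windows), len(positions)), dtype=np.int64)
    win_list = list(windows)
    for pi, pos in enumerate(positions):
        codes[:, pi] = [
            aa_index.get(w[len(w) // 2 + pos], -1)
            if 0 <= len(w) // 2 + pos < len(w)
            else -1
            for w in win_list
        ]
    valid = codes >= 0
    safe = np.where(valid, codes, 0)
    raw = np.zeros((len(windows), len(kinases)))
    for ki, kinase in enumerate(kinases):
        mat = np.log2(np.maximum(matrices[kinase].to_numpy(), PSSM_FLOOR))
        if list(matrices[kinase].index) != positions:
            raise ValueError("all PSSMs must share the same flank positions")
        contrib = mat[np.arange(len(positions))[None, :], safe]
        raw[:, ki] = np.where(valid, contrib, 0.0).sum(axis=1)
    return pd.DataFrame(raw, index=windows.index, columns=kinases)


def score_all_sites(
    windows: pd.Series, atlas: KinaseAtlas, background: str = "dataset"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw and percentile scores for every S/T site against every kinase.

    Tyrosine-centered sites are skipped with a warning.  With
    ``background="dataset"`` (default) each kinase's percentile reference is
    the score distribution of all scored sites in the current dataset — the
    stand-in for a reference phosphoproteome; ``background="atlas"`` uses
    the atlas's stored background scores instead.  Returns
    (raw_scores, percentiles), sites x kinases.
    """
    keep = []
    for site_id, window in windows.items():
        if window[len(window) // 2] in ("S", "T"):
            keep.append(site_id)
        else:
            logger.warning("site %s is not S/T-centered; skipped from kinome", site_id)
    windows = windows.loc[keep]
    raw_df = raw_scores(windows, atlas.matrices)
    kinases = list(raw_df.columns)
    pct = np.empty(raw_df.shape)
    for ki, kinase in enumerate(kinases):
        vals = raw_df[kinase].to_numpy()
        bg = np.sort(vals) if background == "dataset" else atlas.backgrounds[kinase]
        pct[:, ki] = 100.0 * np.searchsorted(bg, vals, side="right") / len(bg)
    pct_df = pd.DataFrame(pct, index=windows.index, columns=kinases)
    return raw_df, pct_df


def predict_kinases(
    raw: pd.Series, percentiles: pd.Series, top_k: int = 15
) -> tuple[str, ...]:
    """Top-``top_k`` kinases for one site, ranked by percentile descending;
    boundary ties break by raw score, then kinase name."""
    df = pd.DataFrame({"pct": percentiles, "raw": raw})
    df = df.rename_axis("kinase").reset_index()
    df = df.sort_values(
        by=["pct", "raw", "kinase"], ascending=[False, False, True], kind="stable"
    )
    return tuple(df["kinase"].head(top_k))


def predict_all(
    raw_df: pd.DataFrame, pct_df: pd.DataFrame, top_k: int = 15
) -> pd.DataFrame:
    """Boolean sites x kinases membership matrix of top-``top_k`` predictions."""
    pred = pd.DataFrame(
        False, index=raw_df.index, columns=raw_df.columns, dtype=bool
    )
    for site_id in raw_df.index:
        chosen = predict_kinases(raw_df.loc[site_id], pct_df.loc[site_id], top_k)
        pred.loc[site_id, list(chosen)] = True
    return pred


def define_regulated_sets(
    diff: pd.DataFrame, fdr_cut: float
) -> tuple[pd.Index, pd.Index, pd.Index]:
    """Split one contrast's results into (up, down, unregulated) site sets.

    ``up`` = FDR < cut and log2FC > 0; ``down`` = FDR < cut and log2FC < 0;
    ``unregulated`` = FDR > cut.  Sites exactly at the cut fall in neither
    regulated set (strict inequalities).
    """
    fdr = diff["fdr"]
    lfc = diff["log2fc"]
    up = diff.index[(fdr < fdr_cut) & (lfc > 0)]
    down = diff.index[(fdr < fdr_cut) & (lfc < 0)]
    unreg = diff.index[fdr > fdr_cut]
    return up, down, unreg


def haldane_frequency_factor(table: ContingencyTable) -> float:
    """log2 ratio of predicted percentages after adding 0.5 to every cell."""
    a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d))
    return float(np.log2((a / (a + b)) / (c / (c + d))))


def fisher_one_sided(table: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p: ``P(A >= a)`` under the
    hypergeometric law with the table's margins, on raw integer counts."""
    a, b, c, d = table.a, table.b, table.c, table.d
    total = a + b + c + d
    if total == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, total, a + c, a + b))


def kinome_enrichment(
    predictions: pd.DataFrame,
    up: pd.Index,
    down: pd.Index,
    unregulated: pd.Index,
    display_adjp: float = 0.1,
) -> pd.DataFrame:
    """Per-kinase motif enrichment among regulated vs unregulated sites.

    For each kinase and each regulation side the 2x2 table (side vs
    unregulated, predicted vs not) gives a one-sided Fisher p on raw counts
    and a Haldane-corrected log2 frequency factor; BH adjustment runs
    across kinases within each side, and the side with the smaller
    adjusted p is reported (ties prefer ``up``).  ``significant`` marks
    adjusted p <= ``display_adjp``.
    """
    if len(unregulated) == 0:
        raise ValueError("unregulated set is empty")
    sides = {}
    for side_name, members in (("up", up), ("down", down)):
        if len(members) == 0:
            logger.warning("regulated side %r is empty; skipped", side_name)
            continue
        rows = []
        reg_pred = predictions.reindex(members).fillna(False)
        unreg_pred = predictions.reindex(unregulated).fillna(False)
        for kinase in predictions.columns:
            a = int(reg_pred[kinase].sum())
            b = len(members) - a
            c = int(unreg_pred[kinase].sum())
            d = len(unregulated) - c
            tab = ContingencyTable(a, b, c, d)
            rows.append(
                {
                    "kinase": kinase,
                    "side": side_name,
                    "a": a, "b": b, "c": c, "d": d,
                    "frequency_factor": haldane_frequency_factor(tab),
                    "p": fisher_one_sided(tab),
                    # log-scale p for deterministic ranking below underflow
                    "log_p": float(
                        stats.hypergeom.logsf(a - 1, a + b + c + d, a + c, a + b)
                    ),
                }
            )
        df = pd.DataFrame(rows)
        df["adj_p"] = bh_fdr(df["p"].to_numpy())
        sides[side_name] = df.set_index("kinase")
    if not sides:
        raise ValueError("both regulated sides are empty")

    chosen = []
    for kinase in predictions.columns:
        best = None
        for side_name in ("up", "down"):
            if side_name not in sides:
                continue
            row = sides[side_name].loc[kinase]
            if best is None or row["adj_p"] < best["adj_p"]:
                best = row
        chosen.append(best)
    out = pd.DataFrame(chosen)
    out.index = pd.Index(predictions.columns, name="kinase")
    out["significant"] = out["adj_p"] <= display_adjp
    int_cols = ["a", "b", "c", "d"]
    out[int_cols] = out[int_cols].astype(int)
    return out[
        ["side", "a", "b", "c", "d", "frequency_factor", "p", "log_p", "adj_p", "significant"]
    ]
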