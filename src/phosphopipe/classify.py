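"""Six-way signaling-class taxonomy and sex-dimorphism calls.

Class 1 sites increase phosphorylation on insulin stimulation (log2FC >=
log2(1.5) with p < 0.05 in control cells, T2D cells, or both); class 2
sites decrease.  Subclass A: the response does not differ between
phenotypes (interaction p >= threshold).  Subclass B ("impaired"): the
response difference is significant and the T2D response is the smaller in
magnitude.  Subclass C ("emergent"): the difference is significant and the
T2D response is the larger.  The strict emergent filter additionally
requires the T2D response itself to pass the fold/p thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffstats import contrast_frame

CLASS_LABELS = ("1A", "1B", "1C", "2A", "2B", "2C", "none")


def classify_sites(
    diff_results: pd.DataFrame,
    stim_p: float = 0.05,
    stim_fold: float = 1.5,
    interaction_p: float = 0.05,
) -> pd.DataFrame:
    """Assign each site a signaling class from the long differential table.

    ``diff_results`` must contain the ``ctl_ins_vs_bas``, ``t2d_ins_vs_bas``
    and ``stim_ratio_diff`` contrasts.  Returns a frame indexed by site with
    ``signaling_class``, ``strict_emergent``, ``sign_discordant`` and the
    supporting statistics.  A site qualifying for class 1 in one phenotype
    and class 2 in the other (both arms significant, opposite signs) is
    labeled by the control-cell direction and flagged ``sign_discordant``.
    """
    ctl = contrast_frame(diff_results, "ctl_ins_vs_bas")
    t2d = contrast_frame(diff_results, "t2d_ins_vs_bas")
    inter = contrast_frame(diff_results, "stim_ratio_diff")
    sites = ctl.index
    if not (sites.equals(t2d.index) and sites.equals(inter.index)):
        raise ValueError("contrasts cover different site sets")

    log_fold = np.log2(stim_fold)
    out = pd.DataFrame(
        {
            "ctl_log2fc": ctl["log2fc"],
            "ctl_p": ctl["p"],
            "t2d_log2fc": t2d["log2fc"],
            "t2d_p": t2d["p"],
            "interaction_log2fc": inter["log2fc"],
            "interaction_p": inter["p"],
        },
        index=sites,
    )

    ctl_up = (ctl["log2fc"] >= log_fold) & (ctl["p"] < stim_p)
    ctl_dn = (ctl["log2fc"] <= -log_fold) & (ctl["p"] < stim_p)
    t2d_up = (t2d["log2fc"] >= log_fold) & (t2d["p"] < stim_p)
    t2d_dn = (t2d["log2fc"] <= -log_fold) & (t2d["p"] < stim_p)

    is_class1 = ctl_up | t2d_up
    is_class2 = ctl_dn | t2d_dn
    discordant = is_class1 & is_class2
    # discordant sites take the control-cell direction
    class1 = is_class1 & (~discordant | ctl_up)
    class2 = is_class2 & ~class1

    sig_int = inter["p"] < interaction_p
    t2d_smaller = t2d["log2fc"].abs() < ctl["log2fc"].abs()
    subclass = np.where(~sig_int, "A", np.where(t2d_smaller, "B", "C"))

    labels = np.where(
        class1, np.char.add("1", subclass), np.where(class2, np.char.add("2", subclass), "none")
    )
    out["signaling_class"] = labels
    out["sign_discordant"] = discordant.to_numpy()
    out["strict_emergent"] = strict_emergent_filter(out, stim_p, stim_fold)
    return out


def strict_emergent_filter(
    classification: pd.DataFrame,
    stim_p: float = 0.05,
    stim_fold: float = 1.5,
) -> pd.Series:
    """Strict flag for emergent (1C/2C) sites: the T2D response itself shows
    a +/-``stim_fold`` change with p < ``stim_p``.  False for non-C sites."""
    log_fold = np.log2(stim_fold)
    is_c = classification["signaling_class"].isin(["1C", "2C"])
    passes = (classification["t2d_log2fc"].abs() >= log_fold) & (
        classification["t2d_p"] < stim_p
    )
    return (is_c & passes).rename("strict_emergent")


def call_sex_dimorphism(
    diff_results: pd.DataFrame, fdr_threshold: float = 0.1
) -> pd.Series:
    """Per-site sex dominance from the ``sex_F`` contrast.

    ``F`` when FDR < threshold and the female mean is higher, ``M`` when the
    male mean is higher, otherwise ``none``.
    """
    sex = contrast_frame(diff_results, "sex_F")
    sig = sex["fdr"] < fdr_threshold
    dominance = np.where(
        sig & (sex["log2fc"] > 0), "F", np.where(sig & (sex["log2fc"] < 0), "M", "none")
    )
    return pd.Series(dominance, index=sex.index, name="sex_dominance")
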