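"""Synthetic genetic array (SGA) screen analysis.

A query construct (e.g. an inducible toxic nucleoprotein) is crossed into
a genome-wide deletion collection; colony sizes on experimental vs control
plates give a relative-growth value per deletion strain. Strains above /
below growth thresholds are rescuers / sensitizers. Two chi-square null
hypotheses probe whether a designated gene set (deletions known to raise
or lower histone levels) behaves non-randomly, and a hypergeometric test
scores functional-category enrichment among rescuers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import warn

SGA_COLUMNS = ["gene", "plate", "position", "exp_size", "ctrl_size"]


def read_sga_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in SGA_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"SGA table missing columns {missing}")
    return tab


# --------------------------------------------------------- relative growth
def relative_growth(table: pd.DataFrame) -> pd.Series:
    """Per-strain relative growth with plate-median spatial normalization.

    Within each plate, experimental and control colony sizes are divided
    by their respective plate medians; relative_growth = median(normalized
    experimental) / median(normalized control) per strain. Strains whose
    control median is 0 are flagged missing (NaN) and should be excluded
    from downstream tests.
    """
    tab = table.copy()
    for col in ("exp_size", "ctrl_size"):
        med = tab.groupby("plate")[col].transform("median")
        if (med <= 0).any():
            bad = tab.loc[med <= 0, "plate"].iloc[0]
            raise ValueError(f"plate {bad!r} has non-positive median {col}")
        tab[f"norm_{col}"] = tab[col] / med
    per_strain = tab.groupby("gene", sort=False).agg(
        exp=("norm_exp_size", "median"), ctrl=("norm_ctrl_size", "median"))
    rg = per_strain["exp"] / per_strain["ctrl"]
    zero_ctrl = per_strain["ctrl"] == 0
    if zero_ctrl.any():
        warn(f"{int(zero_ctrl.sum())} strains with zero control growth "
             "flagged missing")
        rg[zero_ctrl] = np.nan
    rg.name = "relative_growth"
    return rg


def default_thresholds(rg: pd.Series, k: float = 2.0) -> tuple[float, float]:
    """1 +/- k robust SD (1.4826*MAD) of the screen's relative growth."""
    v = rg.dropna().to_numpy()
    robust_sd = 1.4826 * np.median(np.abs(v - np.median(v)))
    return 1.0 + k * robust_sd, 1.0 - k * robust_sd


def classify_hits(rg: pd.Series, pos_threshold: float,
                  neg_threshold: float) -> pd.Series:
    """rescuer if rg > pos_threshold, sensitizer if rg < neg_threshold,
    else neutral (NaN growth stays unclassified)."""
    if not neg_threshold < pos_threshold:
        raise ValueError("neg_threshold must be < pos_threshold")
    cls = pd.Series("neutral", index=rg.index, name="class")
    cls[rg > pos_threshold] = "rescuer"
    cls[rg < neg_threshold] = "sensitizer"
    cls[rg.isna()] = "missing"
    return cls


# -------------------------------------------------------- chi-square tests
@dataclass
class GeneSetTestResult:
    p_h01: float
    chi2_h01: float
    df_h01: int
    table_h01: pd.DataFrame
    p_h02: float
    chi2_h02: float
    df_h02: int
    table_h02: pd.DataFrame


def chi2_geneset_tests(classes: pd.Series, set_label: pd.Series) -> GeneSetTestResult:
    """The screen's two chi-square null hypotheses for a polarized gene set.

    H01 — the designated gene deletions (set_label != 'none') are randomly
    distributed across rescuer/neutral/sensitizer classes: chi-square on
    the 2x3 (in-set vs rest) x class table, df 2.

    H02 — deletions that raise vs lower the readout (histone_up vs
    histone_down) fall below vs above the growth thresholds by chance:
    chi-square on the 2x2 (set polarity) x (sensitizer vs rescuer) table,
    df 1, no continuity correction; Fisher's exact test is substituted
    with a warning when any expected cell is < 5.
    """
    df = pd.DataFrame({"cls": classes, "set": set_label}).dropna()
    df = df[df["cls"] != "missing"]
    in_set = df["set"] != "none"
    if not in_set.any():
        raise ValueError("gene set is empty")

    order = ["rescuer", "neutral", "sensitizer"]
    t1 = pd.DataFrame({
        "in_set": df.loc[in_set, "cls"].value_counts().reindex(order, fill_value=0),
        "rest": df.loc[~in_set, "cls"].value_counts().reindex(order, fill_value=0),
    }).T
    chi1, p1, dof1, exp1 = sps.chi2_contingency(t1.to_numpy(), correction=False)
    if (exp1 < 5).any():
        warn("H01 table has expected cells < 5; chi-square approximation "
             "may be poor")

    sub = df[in_set]
    up = sub["set"] == "histone_up"
    down = sub["set"] == "histone_down"
    if not (up.any() and down.any()):
        raise ValueError("H02 requires both histone_up and histone_down genes")
    t2 = pd.DataFrame({
        "sensitizer": [(sub.loc[up, "cls"] == "sensitizer").sum(),
                       (sub.loc[down, "cls"] == "sensitizer").sum()],
        "rescuer": [(sub.loc[up, "cls"] == "rescuer").sum(),
                    (sub.loc[down, "cls"] == "rescuer").sum()],
    }, index=["histone_up", "histone_down"])
    arr2 = t2.to_numpy()
    if arr2.sum() == 0 or (arr2.sum(0) == 0).any() or (arr2.sum(1) == 0).any():
        raise ValueError("H02 table degenerate: a margin is zero")
    chi2_, p2, dof2, exp2 = sps.chi2_contingency(arr2, correction=False)
    if (exp2 < 5).any():
        warn("H02 expected cells < 5; using Fisher's exact test")
        _, p2 = sps.fisher_exact(arr2)
    return GeneSetTestResult(
        p_h01=float(p1), chi2_h01=float(chi1), df_h01=int(dof1), table_h01=t1,
        p_h02=float(p2), chi2_h02=float(chi2_), df_h02=int(dof2), table_h02=t2,
    )


# ------------------------------------------------------ category enrichment
def category_enrichment(rescuers, categories: dict[str, set], universe) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each functional category
    among the rescuer genes, with Bonferroni-adjusted p alongside raw.

    Categories disjoint from the universe are skipped with a warning.
    """
    universe = set(universe)
    rescuers = set(rescuers) & universe
    N, n = len(universe), len(rescuers)
    rows = []
    for name, genes in categories.items():
        genes = set(genes) & universe
        if not genes:
            warn(f"category {name!r} disjoint from universe; skipped")
            continue
        K = len(genes)
        k = len(genes & rescuers)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": name, "hits": k, "category_size": K,
                     "n_rescuers": n, "universe": N, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
        out = out.sort_values("p").reset_index(drop=True)
    return out
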