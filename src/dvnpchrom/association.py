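"""Genome-wide association between protein enrichment and nucleosome loss.

The engine tiles the genome into overlapping windows, attaches per-window
enrichment (IP/input of mean-normalized tracks) and occupancy change
(control - treatment of mean-normalized MNase tracks; positive = loss),
bins windows into enrichment quintiles, and compares extreme bins with
Welch's t-test — optionally within input-signal strata to control for DNA
accessibility bias. The same machinery runs over fixed nucleosomal sites
(147 bp around each dyad) binned by sequence-predicted occupancy, for
which a GC-content proxy is provided (GC-rich DNA is predicted to form
more stable nucleosomes).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome import Genome
from .io import warn
from .stats import BoxplotSummary, WelchResult, boxplot_stats, welch_t

NUC_HALF_LO = 73   # nucleosomal site = [dyad-73, dyad+74), 147 bp
NUC_HALF_HI = 74


# ----------------------------------------------------------------- tiling
def tile_windows(genome: Genome, size: int = 500, step: int = 250) -> pd.DataFrame:
    """Tile each chromosome with fixed windows starting at 0, ``step`` bp
    apart; windows running past the end are dropped. Per-chromosome count
    is floor((L-size)/step)+1 for L >= size, else 0."""
    if step > size:
        raise ValueError("step must be <= size")
    frames = []
    for chrom, L in genome.chrom_lengths.items():
        if L < size:
            continue
        n = (L - size) // step + 1
        starts = np.arange(n) * step
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + size}
        ))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def window_signal(track: CoverageTrack, windows: pd.DataFrame) -> np.ndarray:
    """Arithmetic mean of per-base signal in each [start,end) window."""
    windows = windows.reset_index(drop=True)
    out = np.empty(len(windows))
    for chrom, grp in windows.groupby("chrom", sort=False):
        cs = np.concatenate([[0.0], np.cumsum(track.values[chrom])])
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        out[grp.index] = (cs[e] - cs[s]) / (e - s)
    return out


def occupancy_change(occ_control: np.ndarray, occ_treatment: np.ndarray) -> np.ndarray:
    """Nucleosome loss per unit: control - treatment (positive = loss).

    Both inputs must come from genome-mean-normalized tracks; the
    difference is then invariant to equal rescaling of both.
    """
    occ_control = np.asarray(occ_control, dtype=float)
    occ_treatment = np.asarray(occ_treatment, dtype=float)
    if occ_control.shape != occ_treatment.shape:
        raise ValueError("occupancy vectors have mismatched lengths")
    return occ_control - occ_treatment


def occupancy_log2_change(occ_control, occ_treatment, pseudocount: float = 0.05):
    """log2((control+pc)/(treatment+pc)) alternative loss statistic."""
    occ_control = np.asarray(occ_control, dtype=float)
    occ_treatment = np.asarray(occ_treatment, dtype=float)
    if occ_control.shape != occ_treatment.shape:
        raise ValueError("occupancy vectors have mismatched lengths")
    return np.log2((occ_control + pseudocount) / (occ_treatment + pseudocount))


# ---------------------------------------------------------------- binning
def quantile_bins(values, n_bins: int = 5) -> np.ndarray:
    """Equal-count rank bins (0 = lowest ... n_bins-1 = highest).

    Ranks are split at ceil(k*n/n_bins) boundaries; ties are broken by
    stable input order, so bin sizes differ by at most 1.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} values, got {n}")
    if len(np.unique(values)) == 1:
        warn("all values tied in quantile_bins; stable-order split applied")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    ranks = np.arange(n)
    labels[order] = (ranks * n_bins) // n
    return labels


def bin_labels(labels: np.ndarray, n_bins: int) -> list[str]:
    return [f"q{i + 1}" for i in range(n_bins)]


@dataclass
class TrendReport:
    """Per-bin medians plus the extreme-bin Welch comparison (q_top vs q1)."""

    bin_names: list[str]
    medians: list[float]
    summaries: list[BoxplotSummary]
    welch_top_vs_bottom: WelchResult
    n_per_bin: list[int]

    def monotone_increasing(self) -> bool:
        return all(b > a for a, b in zip(self.medians, self.medians[1:]))

    def monotone_decreasing(self) -> bool:
        return all(b < a for a, b in zip(self.medians, self.medians[1:]))


def bin_association(values, bins, notch_constant: float = 1.58) -> TrendReport:
    """Summarize a response (e.g., occupancy loss) across quantile bins.

    Returns per-bin box-plot summaries and the two-sided Welch test of the
    highest vs lowest bin.
    """
    values = np.asarray(values, dtype=float)
    bins = np.asarray(bins, dtype=int)
    uniq = np.sort(np.unique(bins))
    missing = set(range(int(bins.max()) + 1)) - set(int(b) for b in uniq)
    if missing:
        raise ValueError(f"empty bin(s) {sorted(missing)}")
    groups = [values[bins == b] for b in uniq]
    summaries = [boxplot_stats(g, notch_constant=notch_constant) for g in groups]
    return TrendReport(
        bin_names=[f"q{int(b) + 1}" for b in uniq],
        medians=[s.median for s in summaries],
        summaries=summaries,
        welch_top_vs_bottom=welch_t(groups[-1], groups[0]),
        n_per_bin=[len(g) for g in groups],
    )


def input_strata(input_signal, n_strata: int = 5) -> np.ndarray:
    """Quantile strata of the ChIP-input signal (accessibility control)."""
    return quantile_bins(input_signal, n_bins=n_strata)


def stratified_association(values, ranking_signal, input_signal,
                           n_bins: int = 5, n_strata: int = 5,
                           notch_constant: float = 1.58) -> dict[str, TrendReport]:
    """Re-run the quintile association within each input stratum.

    The ranking signal is re-binned inside every stratum so a DNA
    accessibility gradient cannot masquerade as enrichment-coupled loss.
    """
    values = np.asarray(values, dtype=float)
    ranking_signal = np.asarray(ranking_signal, dtype=float)
    strata = input_strata(input_signal, n_strata)
    out: dict[str, TrendReport] = {}
    for s in np.sort(np.unique(strata)):
        m = strata == s
        bins = quantile_bins(ranking_signal[m], n_bins)
        out[f"s{int(s) + 1}"] = bin_association(values[m], bins, notch_constant)
    return out


# ------------------------------------------------------------ window table
def build_window_table(genome: Genome,
                       dvnp_ip: CoverageTrack, dvnp_input: CoverageTrack,
                       mnase_control: CoverageTrack, mnase_treatment: CoverageTrack,
                       size: int = 500, step: int = 250, n_bins: int = 5,
                       enrichment_mode: str = "ip_over_input") -> pd.DataFrame:
    """Assemble the full per-window table behind the quintile analysis.

    All four tracks must be genome-mean normalized. Enrichment is the
    ratio of window means (IP/input) by default, or the IP window mean
    alone (enrichment_mode='ip_only'). Windows with zero input mean are
    dropped with a warning in ratio mode.
    """
    for name, tr in [("dvnp_ip", dvnp_ip), ("dvnp_input", dvnp_input),
                     ("mnase_control", mnase_control),
                     ("mnase_treatment", mnase_treatment)]:
        if tr.normalization == "raw":
            raise ValueError(f"track {name} must be normalized before windowing")
    tab = tile_windows(genome, size, step)
    tab["ip_signal"] = window_signal(dvnp_ip, tab)
    tab["input_signal"] = window_signal(dvnp_input, tab)
    tab["occ_control"] = window_signal(mnase_control, tab)
    tab["occ_treatment"] = window_signal(mnase_treatment, tab)
    if enrichment_mode == "ip_over_input":
        ok = tab["input_signal"] > 0
        if (~ok).any():
            warn(f"dropped {(~ok).sum()} windows with zero input signal")
            tab = tab[ok].reset_index(drop=True)
        tab["dvnp_enrichment"] = tab["ip_signal"] / tab["input_signal"]
    elif enrichment_mode == "ip_only":
        tab["dvnp_enrichment"] = tab["ip_signal"]
    else:
        raise ValueError(f"unknown enrichment_mode {enrichment_mode!r}")
    tab["occ_change"] = occupancy_change(tab["occ_control"].to_numpy(),
                                         tab["occ_treatment"].to_numpy())
    tab["dvnp_bin"] = quantile_bins(tab["dvnp_enrichment"].to_numpy(), n_bins)
    tab["input_stratum"] = input_strata(tab["input_signal"].to_numpy(), n_bins)
    return tab


# -------------------------------------------------------- nucleosomal sites
def nucleosome_site_table(dyads: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Validate a (chrom, dyad) table; sites whose 147 bp window leaves the
    chromosome are dropped with a warning."""
    tab = dyads[["chrom", "dyad"]].copy()
    keep = np.ones(len(tab), dtype=bool)
    for i, row in enumerate(tab.itertuples(index=False)):
        L = genome.chrom_lengths[row.chrom]
        if row.dyad - NUC_HALF_LO < 0 or row.dyad + NUC_HALF_HI > L:
            keep[i] = False
    if (~keep).any():
        warn(f"dropped {(~keep).sum()} nucleosomal sites off chromosome ends")
    return tab[keep].reset_index(drop=True)


def site_signal(track: CoverageTrack, sites: pd.DataFrame) -> np.ndarray:
    """Mean signal over the 147 bp nucleosomal window of each dyad."""
    win = sites.assign(start=sites["dyad"] - NUC_HALF_LO,
                       end=sites["dyad"] + NUC_HALF_HI)
    return window_signal(track, win[["chrom", "start", "end"]])


def predicted_occupancy_gc(genome: Genome, sites: pd.DataFrame,
                           window: int = 147) -> np.ndarray:
    """GC fraction of the ``window`` bp centred on each dyad — a sequence
    stability proxy (GC-rich sequences are predicted to form more stable,
    higher-occupancy nucleosomes). N bases are excluded from numerator and
    denominator; a window containing only Ns yields NaN."""
    if not genome.has_sequence():
        raise ValueError("genome sequence required for predicted occupancy")
    half_lo = window // 2
    half_hi = window - half_lo
    out = np.full(len(sites), np.nan)
    for i, row in enumerate(sites.itertuples(index=False)):
        seq = genome.sequence[row.chrom]
        lo, hi = row.dyad - half_lo, row.dyad + half_hi
        if lo < 0 or hi > len(seq):
            warn(f"site ({row.chrom},{row.dyad}) window off chromosome; dropped")
            continue
        w = seq[lo:hi]
        n_n = w.count("N")
        denom = len(w) - n_n
        if denom > 0:
            out[i] = (w.count("G") + w.count("C")) / denom
    return out


def build_nucsite_table(genome: Genome, dyads: pd.DataFrame,
                        mnase_control: CoverageTrack,
                        mnase_treatment: CoverageTrack,
                        n_bins: int = 5) -> pd.DataFrame:
    """Per-site table for the predicted-occupancy quintile analysis."""
    sites = nucleosome_site_table(dyads, genome)
    sites["predicted_occupancy"] = predicted_occupancy_gc(genome, sites)
    sites = sites.dropna(subset=["predicted_occupancy"]).reset_index(drop=True)
    sites["occ_control"] = site_signal(mnase_control, sites)
    sites["occ_treatment"] = site_signal(mnase_treatment, sites)
    sites["occ_change"] = occupancy_change(sites["occ_control"].to_numpy(),
                                           sites["occ_treatment"].to_numpy())
    sites["occupancy_bin"] = quantile_bins(
        sites["predicted_occupancy"].to_numpy(), n_bins)
    return sites
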