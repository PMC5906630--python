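"""Spike-in normalization and global RNAP II occupancy change.

Matched-depth sequencing libraries cannot reveal a uniform genome-wide
occupancy change: within-sample normalization rescales it away. Adding a
fixed mass of exogenous spike-in DNA per sample anchors the scale — if
cellular material drops, the spike-in claims a larger share of reads, and
dividing genomic coverage by the spike-in share restores absolute units.
This module computes per-sample spike-in scale factors, spike-scaled
per-gene occupancy over gene bodies (with a 3' buffer avoiding
polyadenylation-site peaks), and the global percent change.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .io import GeneAnnotation, warn
from .stats import WelchResult, welch_t


def spikein_factors(counts: pd.DataFrame, reference: str) -> pd.Series:
    """Per-sample scale factors from a spike-in count table.

    factor_s = (spike_reads_ref / spike_reads_s) * (mass_s / mass_ref)
    where mass is the effective added spike mass (spike_mass_added *
    dilution). The reference sample's factor is 1; genomic coverage of
    sample s is multiplied by factor_s before any cross-sample comparison.
    """
    tab = counts.set_index("sample")
    if reference not in tab.index:
        raise ValueError(f"reference sample {reference!r} not in table")
    if (tab["spike_reads"] <= 0).any():
        bad = tab.index[tab["spike_reads"] <= 0][0]
        raise ValueError(f"sample {bad!r} has zero spike-in reads")
    mass = tab["spike_mass_added"] * tab["dilution"]
    ref = tab.loc[reference]
    ref_mass = ref["spike_mass_added"] * ref["dilution"]
    factors = (ref["spike_reads"] / tab["spike_reads"]) * (mass / ref_mass)
    factors.name = "factor"
    return factors


def apply_spikein(track: CoverageTrack, factor: float) -> CoverageTrack:
    return track.scaled(factor, normalization="spikein")


def gene_body_occupancy(track: CoverageTrack, genes: GeneAnnotation,
                        end_buffer: int = 300) -> tuple[pd.Series, list[str]]:
    """Mean signal per gene over TSS..(polyA - end_buffer), strand-aware.

    Genes whose transcribed length is <= end_buffer are excluded and
    returned in the report list.
    """
    values: dict[str, float] = {}
    excluded: list[str] = []
    for row in genes.table.itertuples(index=False):
        glen = abs(row.tss - row.polya)
        span = glen - end_buffer
        if span < 1:
            excluded.append(row.id)
            continue
        v = track.values[row.chrom]
        if row.strand == "+":
            seg = v[row.tss:row.tss + span]
        else:
            seg = v[row.tss - span + 1:row.tss + 1]
        values[row.id] = float(seg.mean())
    if not values:
        raise ValueError("no genes remain after end-buffer exclusion")
    if excluded:
        warn(f"{len(excluded)} genes shorter than the {end_buffer} bp end "
             "buffer were excluded")
    return pd.Series(values, name="occupancy"), excluded


def gene_occupancy_table(track_control: CoverageTrack, track_treatment: CoverageTrack,
                         genes: GeneAnnotation, end_buffer: int = 300) -> pd.DataFrame:
    """Per-gene mean occupancy for both conditions on shared genes."""
    occ_c, _ = gene_body_occupancy(track_control, genes, end_buffer)
    occ_t, _ = gene_body_occupancy(track_treatment, genes, end_buffer)
    return pd.DataFrame({"occ_control": occ_c, "occ_treatment": occ_t}).dropna()


@dataclass
class GlobalChangeResult:
    """Global occupancy change summary.

    percent_reduction: 100*(1 - mean_t/mean_c) with condition means taken
    over per-gene mean occupancies (ratio of means — robust to
    low-coverage genes). percent_reduction_mean_of_ratios: the mean of
    per-gene ratios alternative. per_gene_change: control - treatment per
    gene. welch: two-sided Welch test between the per-gene occupancy
    vectors of the two conditions.
    """

    percent_reduction: float
    percent_reduction_mean_of_ratios: float
    mean_control: float
    mean_treatment: float
    per_gene_change: pd.Series
    welch: WelchResult
    n_genes: int


def global_change(tab: pd.DataFrame) -> GlobalChangeResult:
    """Estimate the global occupancy change from a gene occupancy table."""
    mean_c = float(tab["occ_control"].mean())
    mean_t = float(tab["occ_treatment"].mean())
    if mean_c <= 0:
        raise ValueError("control mean occupancy must be positive")
    ok = tab["occ_control"] > 0
    ratios = tab.loc[ok, "occ_treatment"] / tab.loc[ok, "occ_control"]
    return GlobalChangeResult(
        percent_reduction=100.0 * (1.0 - mean_t / mean_c),
        percent_reduction_mean_of_ratios=100.0 * (1.0 - float(ratios.mean())),
        mean_control=mean_c,
        mean_treatment=mean_t,
        per_gene_change=tab["occ_control"] - tab["occ_treatment"],
        welch=welch_t(tab["occ_treatment"], tab["occ_control"]),
        n_genes=len(tab),
    )


def rpb3_stage(ctrl_frags, treat_frags, genome, genes, spikein_counts: pd.DataFrame,
               control_sample: str, treatment_sample: str,
               size_range: tuple[int, int] = (50, 500),
               end_buffer: int = 300,
               use_spikein: bool = True) -> GlobalChangeResult:
    """End-to-end RNAP II occupancy-change stage.

    Fragment sets (already combined across replicates, or single samples)
    are size-filtered, midpoint-counted, depth-normalized to reads per
    base, spike-in scaled (unless use_spikein=False, the designed failure
    mode demonstrating the normalization is load-bearing), and reduced to
    the global percent change over gene bodies.
    """
    from .coverage import coverage_from_fragments, filter_fragments_by_size

    tracks = {}
    for name, frags in [(control_sample, ctrl_frags), (treatment_sample, treat_frags)]:
        f = filter_fragments_by_size(frags, *size_range)
        t = coverage_from_fragments(f, genome, mode="midpoint")
        # depth normalization: per-base rate, so libraries are comparable
        t = t.scaled(1.0 / len(f), normalization="raw")
        tracks[name] = t
    if use_spikein:
        factors = spikein_factors(spikein_counts, reference=control_sample)
        tracks = {s: apply_spikein(t, float(factors[s])) for s, t in tracks.items()}
    else:
        tracks = {s: t.scaled(1.0, normalization="spikein") for s, t in tracks.items()}
    tab = gene_occupancy_table(tracks[control_sample], tracks[treatment_sample],
                               genes, end_buffer)
    return global_change(tab)
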