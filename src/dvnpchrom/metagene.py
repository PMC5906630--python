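"""TSS-anchored average-gene (metagene) profiles.

Each gene contributes its per-base signal from ``upstream`` bp before the
TSS to ``downstream`` bp after it, read in transcription orientation, but
only until its polyadenylation site (optionally minus an ``end_buffer``).
The per-offset mean is taken over the genes still contributing at that
offset (ragged averaging), so short genes are never zero-filled.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .io import GeneAnnotation


@dataclass
class MetageneProfile:
    """Average-gene profile.

    positions: bp offsets relative to the TSS (offset 0 = the TSS base;
    negative = upstream). mean_signal: per-offset mean over contributing
    genes. n_genes: contributing-gene count per offset. excluded: gene ids
    whose truncated extent was < 1 bp downstream.
    """

    positions: np.ndarray
    mean_signal: np.ndarray
    n_genes: np.ndarray
    end_buffer: int = 0
    excluded: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.positions,
            "mean_signal": self.mean_signal,
            "n_genes": self.n_genes,
        })


def metagene_profile(track: CoverageTrack, genes: GeneAnnotation,
                     upstream: int = 500, downstream: int = 2500,
                     end_buffer: int = 0) -> MetageneProfile:
    """Average signal around TSSs in transcription orientation.

    Offsets run from -upstream to downstream-1. A gene contributes offset
    k only while k < transcribed_length - end_buffer (the polyA truncation
    rule); its upstream flank is never truncated by neighbours. Offsets
    falling off the chromosome are simply not contributed.
    """
    width = upstream + downstream
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    excluded: list[str] = []
    any_gene = False
    for row in genes.table.itertuples(index=False):
        v = track.values[row.chrom]
        L = len(v)
        glen = abs(row.tss - row.polya)
        max_off = min(downstream, glen - end_buffer)  # exclusive downstream bound
        if max_off < 1:
            excluded.append(row.id)
            continue
        any_gene = True
        if row.strand == "+":
            # offsets -upstream..max_off-1 -> positions tss-upstream..tss+max_off-1
            lo = row.tss - upstream
            hi = row.tss + max_off
            clip_lo, clip_hi = max(lo, 0), min(hi, L)
            if clip_hi <= clip_lo:
                continue
            seg = v[clip_lo:clip_hi]
            i0 = clip_lo - lo
        else:
            # offset k -> position tss - k; positions tss+upstream..tss-max_off+1
            lo = row.tss - max_off + 1
            hi = row.tss + upstream + 1
            clip_lo, clip_hi = max(lo, 0), min(hi, L)
            if clip_hi <= clip_lo:
                continue
            seg = v[clip_lo:clip_hi][::-1]
            i0 = hi - clip_hi
        total[i0:i0 + len(seg)] += seg
        count[i0:i0 + len(seg)] += 1
    if not any_gene:
        raise ValueError("no eligible genes for metagene profile")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetageneProfile(
        positions=np.arange(-upstream, downstream),
        mean_signal=mean,
        n_genes=count,
        end_buffer=end_buffer,
        excluded=excluded,
    )


def find_promoter_features(profile: MetageneProfile,
                           minus_one_window: tuple[int, int] = (-350, -80),
                           plus_one_window: tuple[int, int] = (-20, 200),
                           ) -> dict:
    """Locate the -1/+1 nucleosome peaks and the NDR trough in a profile.

    Peaks are the argmax of the mean signal within each search window; the
    trough is the argmin between the two peaks. Returns offsets and signal
    heights.
    """
    pos = profile.positions
    sig = profile.mean_signal

    def _argmax(window):
        m = (pos >= window[0]) & (pos < window[1])
        if not m.any():
            raise ValueError(f"empty search window {window}")
        idx = np.flatnonzero(m)
        return idx[np.nanargmax(sig[m])]

    i_minus = _argmax(minus_one_window)
    i_plus = _argmax(plus_one_window)
    between = slice(i_minus, i_plus + 1)
    i_trough = i_minus + int(np.nanargmin(sig[between]))
    return {
        "minus_one_offset": int(pos[i_minus]),
        "minus_one_height": float(sig[i_minus]),
        "plus_one_offset": int(pos[i_plus]),
        "plus_one_height": float(sig[i_plus]),
        "trough_offset": int(pos[i_trough]),
        "trough_depth": float(sig[i_trough]),
    }


def signal_at_offset(profile: MetageneProfile, offset: int) -> float:
    """Mean signal at one TSS-relative offset (for comparing conditions at
    fixed, e.g. control-detected, peak positions)."""
    idx = np.flatnonzero(profile.positions == offset)
    if len(idx) == 0:
        raise ValueError(f"offset {offset} outside profile range")
    return float(profile.mean_signal[idx[0]])


def genic_peak_spacing(profile: MetageneProfile, spacing_guess: int = 165,
                       search_to: int = 700) -> float:
    """Mean spacing between successive genic nucleosome peaks downstream of
    the TSS, estimated with a local-maximum scan at roughly nucleosomal
    periodicity."""
    from scipy.signal import find_peaks

    m = (profile.positions >= 0) & (profile.positions <= search_to)
    sig = profile.mean_signal[m]
    peaks, _ = find_peaks(sig, distance=spacing_guess // 2,
                          prominence=0.1 * np.nanmax(sig))
    if len(peaks) < 2:
        raise ValueError("fewer than two genic peaks detected")
    return float(np.mean(np.diff(peaks)))
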