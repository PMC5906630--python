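"""Per-base coverage tracks from fragment sets.

The MNase/ChIP signal model: fragments are reduced either to their full
span or to their midpoint, accumulated per base, optionally Gaussian
smoothed, and normalized to the genome-wide mean so that 1.0 means average
genomic coverage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import convolve1d

from .genome import Genome
from .io import FragmentSet, warn


@dataclass
class CoverageTrack:
    """Per-chromosome per-base signal with recorded normalization state.

    normalization: 'raw', 'genome_mean', or 'spikein'.
    source_mode: 'full_span' or 'midpoint' (how fragments were counted).
    sigma_applied: smoothing bandwidth already applied, or None.
    """

    values: dict[str, np.ndarray]
    normalization: str = "raw"
    source_mode: str | None = None
    sigma_applied: float | None = None

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for chrom, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite coverage values on {chrom!r}")

    @classmethod
    def zeros(cls, genome: Genome, **kw) -> "CoverageTrack":
        return cls({c: np.zeros(l) for c, l in genome.chrom_lengths.items()}, **kw)

    @property
    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    @property
    def genome_mean(self) -> float:
        n = sum(len(v) for v in self.values.values())
        return self.total / n

    def scaled(self, factor: float, normalization: str | None = None) -> "CoverageTrack":
        out = {c: v * factor for c, v in self.values.items()}
        return replace(self, values=out,
                       normalization=normalization or self.normalization)


def filter_fragments_by_size(frags: FragmentSet, min_bp: int, max_bp: int) -> FragmentSet:
    """Retain fragments whose length is within [min_bp, max_bp].

    The applied range is recorded on the returned set. An empty result is
    allowed (with a warning).
    """
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    lengths = frags.lengths
    keep = (lengths >= min_bp) & (lengths <= max_bp)
    out = FragmentSet(
        frags.records[keep],
        sample_label=frags.sample_label,
        size_filter_applied=(min_bp, max_bp),
    )
    if len(out) == 0:
        warn(f"size filter [{min_bp},{max_bp}] retained no fragments "
             f"for sample {frags.sample_label!r}")
    return out


def coverage_from_fragments(frags: FragmentSet, genome: Genome,
                            mode: str = "midpoint") -> CoverageTrack:
    """Accumulate fragments into a raw per-base track.

    mode='full_span' adds 1 to every base of [start,end); mode='midpoint'
    adds 1 at floor((start+end)/2). Total signal equals the summed fragment
    lengths (full_span) or the fragment count (midpoint).
    """
    if mode not in ("full_span", "midpoint"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    frags.validate(genome)
    values = {c: np.zeros(l) for c, l in genome.chrom_lengths.items()}
    for chrom, grp in frags.records.groupby("chrom", sort=False):
        start = grp["start"].to_numpy()
        end = grp["end"].to_numpy()
        L = genome.chrom_lengths[chrom]
        if mode == "midpoint":
            mids = (start + end) // 2
            values[chrom] += np.bincount(mids, minlength=L).astype(float)
        else:
            # difference-array trick: +1 at start, -1 at end, then cumsum
            delta = np.zeros(L + 1)
            np.add.at(delta, start, 1.0)
            np.add.at(delta, end, -1.0)
            values[chrom] += np.cumsum(delta[:-1])
    return CoverageTrack(values, normalization="raw", source_mode=mode)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Discrete Gaussian truncated at |d| <= 4*sigma, normalized to sum 1."""
    radius = int(np.ceil(4 * sigma))
    d = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def smooth_gaussian(track: CoverageTrack, sigma: float = 4.0,
                    circular: bool = False) -> CoverageTrack:
    """Gaussian-smooth a track (kernel truncated at 4*sigma).

    At linear chromosome ends the kernel is renormalized over the bases
    that exist (no signal is fabricated outside the genome), so total
    signal is conserved away from the ends and exactly on circular
    chromosomes. sigma=0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return replace(track, sigma_applied=0.0)
    k = gaussian_kernel(sigma)
    out: dict[str, np.ndarray] = {}
    for chrom, v in track.values.items():
        if circular:
            out[chrom] = convolve1d(v, k, mode="wrap")
        else:
            num = convolve1d(v, k, mode="constant", cval=0.0)
            den = convolve1d(np.ones_like(v), k, mode="constant", cval=0.0)
            out[chrom] = num / den
    return replace(track, values=out, sigma_applied=sigma)


def normalize_genome_mean(track: CoverageTrack) -> CoverageTrack:
    """Divide every base by the genome-wide mean; resulting mean is 1."""
    mean = track.genome_mean
    if mean <= 0:
        raise ValueError("cannot genome-mean normalize a zero-mean track")
    out = {c: v / mean for c, v in track.values.items()}
    return replace(track, values=out, normalization="genome_mean")


def mnase_occupancy_track(frags: FragmentSet, genome: Genome,
                          size_range: tuple[int, int] = (120, 200),
                          sigma: float = 4.0,
                          dedup: bool = False) -> CoverageTrack:
    """Standard MNase occupancy pipeline: size filter -> midpoint counting
    -> genome-mean normalization -> Gaussian smoothing."""
    frags = filter_fragments_by_size(frags, *size_range)
    if dedup:
        frags = frags.deduplicate()
    track = coverage_from_fragments(frags, genome, mode="midpoint")
    track = normalize_genome_mean(track)
    return smooth_gaussian(track, sigma)


def chip_enrichment_track(ip: FragmentSet, inp: FragmentSet, genome: Genome,
                          size_range: tuple[int, int] = (50, 500),
                          sigma: float = 4.0,
                          pseudocount: float = 0.0) -> CoverageTrack:
    """IP/input enrichment ratio of genome-mean-normalized midpoint tracks.

    A pseudocount (added to both normalized tracks before the ratio) guards
    against division by zero in sparse data; 0 disables it, in which case
    zero-input bases yield inf and should be window-averaged first.
    """
    t_ip = mnase_occupancy_track(ip, genome, size_range, sigma)
    t_in = mnase_occupancy_track(inp, genome, size_range, sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = {
            c: (t_ip.values[c] + pseudocount) / (t_in.values[c] + pseudocount)
            for c in genome.chrom_names
        }
    return CoverageTrack(
        {c: np.nan_to_num(v, nan=0.0, posinf=0.0) for c, v in vals.items()},
        normalization="genome_mean", source_mode="midpoint", sigma_applied=sigma,
    )
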