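"""Pipeline configuration: every analysis default in one declarative record.

Stored on disk as a flat ``key = value`` file so a run is reproducible from
the logged effective configuration alone.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, fields


@dataclass
class PipelineConfig:
    """Analysis parameters with their study defaults.

    smoothing_sigma : Gaussian smoothing bandwidth for midpoint tracks (bp).
    window_size / window_step : genome tiling (bp); overlapping tiles by
        default (500 bp windows every 250 bp).
    n_bins : quantile bins for enrichment association (5 = quintiles).
    upstream / downstream : metagene extent around the TSS (bp).
    rpb3_end_buffer : bp trimmed from the 3' end for RNAP II quantification,
        avoiding the large polyadenylation-site peaks.
    mnase_size_range / chip_size_range : retained fragment sizes (bp).
    notch_constant : box-plot notch half-width multiplier on IQR/sqrt(n).
    sga_pos_threshold / sga_neg_threshold : relative-growth cut-offs for
        rescuer / sensitizer calls; None = derive as 1 +/- 2 robust SD.
    dedup_fragments : drop duplicate (chrom,start,end) fragments before
        coverage. Off by default.
    """

    smoothing_sigma: float = 4.0
    window_size: int = 500
    window_step: int = 250
    n_bins: int = 5
    upstream: int = 500
    downstream: int = 2500
    rpb3_end_buffer: int = 300
    mnase_size_range: tuple[int, int] = (120, 200)
    chip_size_range: tuple[int, int] = (50, 500)
    notch_constant: float = 1.58
    sga_pos_threshold: float | None = None
    sga_neg_threshold: float | None = None
    dedup_fragments: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_step > self.window_size:
            raise ValueError("window_step must be <= window_size")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        for name in ("smoothing_sigma", "window_size", "window_step",
                     "upstream", "downstream", "rpb3_end_buffer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mnase_size_range", "chip_size_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 <= min <= max")

    # ------------------------------------------------------------ key=value
    def save(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, tuple):
                    value = f"{value[0]},{value[1]}"
                fh.write(f"{key} = {value}\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = value.strip()
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in fields(cls)}
        for key, value in raw.items():
            if key not in types:
                raise ValueError(f"unknown configuration key {key!r}")
            if isinstance(value, str):
                value = _parse(key, value)
            kwargs[key] = value
        return cls(**kwargs)


def _parse(key: str, text: str):
    if key in ("mnase_size_range", "chip_size_range"):
        lo, hi = text.split(",")
        return (int(lo), int(hi))
    if key == "dedup_fragments":
        return text.lower() in ("1", "true", "yes", "on")
    if key in ("sga_pos_threshold", "sga_neg_threshold"):
        return None if text.lower() in ("none", "") else float(text)
    if key in ("smoothing_sigma", "notch_constant"):
        return float(text)
    return int(text)
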