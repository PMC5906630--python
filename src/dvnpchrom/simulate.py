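"""Synthetic-data generator with planted ground truth.

Emulates the statistical structure the analysis assumes so every pipeline
stage is verifiable without deposited sequencing data:

* a genome whose GC content drifts smoothly (sequence-encoded nucleosome
  stability), with non-overlapping genes on random strands;
* phased nucleosome arrays downstream of promoter NDRs, with -1/+1
  dyads flanking the NDR and genic dyads every ~165 bp;
* MNase fragment sets in which nucleosome loss under the nucleoprotein
  condition is coupled to local binding affinity (strength beta) and,
  optionally, inversely to sequence-encoded stability;
* ChIP fragment sets whose IP midpoints track a nucleosome-proportional
  affinity landscape (depleted at NDRs) while inputs are uniform;
* RNAP II (Rpb3) libraries with a planted global occupancy ratio r that
  is invisible at matched depth and detectable only through spike-in
  counts;
* SGA colony tables with planted growth effects in designated gene sets.

All generators are deterministic under their seed, and planted parameters
are recorded in a truth manifest.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtr, ndtri

from .genome import Genome
from .io import FragmentSet, GeneAnnotation

BASES = np.frombuffer(b"ACGT", dtype="S1")


# ------------------------------------------------------------------ genome
def simulate_genome(n_chroms: int, lengths, gc_mean: float = 0.40,
                    gc_block: int = 1000, gc_sd: float = 0.06,
                    seed: int = 0) -> Genome:
    """Random genome whose GC content varies smoothly on scale gc_block.

    Per-block GC targets are Gaussian deviations around gc_mean, smoothed
    across neighbouring blocks; bases are drawn independently given the
    local GC target.
    """
    if not 0.0 < gc_mean < 1.0:
        raise ValueError("gc_mean must be in (0,1)")
    lengths = list(lengths)
    if len(lengths) != n_chroms:
        raise ValueError("lengths must have n_chroms entries")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for i, L in enumerate(lengths):
        name = f"chr{i + 1}"
        n_blocks = -(-L // gc_block)
        gc = gc_mean + gaussian_filter1d(
            rng.normal(0.0, gc_sd, n_blocks), sigma=1.0, mode="nearest")
        gc = np.clip(gc, 0.05, 0.95)
        per_base_gc = np.repeat(gc, gc_block)[:L]
        is_gc = rng.random(L) < per_base_gc
        # code 0=A, 1=C, 2=G, 3=T ; GC bases -> C or G, AT bases -> A or T
        which = rng.integers(0, 2, L)
        codes = np.where(is_gc, 1 + which, which * 3)
        seqs[name] = BASES[codes].tobytes().decode()
        sizes[name] = L
    return Genome(chrom_lengths=sizes, sequence=seqs)


# ------------------------------------------------------------------- genes
def simulate_genes(genome: Genome, n_genes: int,
                   len_range: tuple[int, int] = (800, 2000),
                   flank: int = 500, seed: int = 0) -> GeneAnnotation:
    """Place non-overlapping genes on random strands at realistic density.

    Genes are packed stochastically along each chromosome: bodies in
    coordinate order separated by at least ``flank`` bp, with the leftover
    chromosome length distributed randomly among the inter-gene gaps —
    emulating a compact genome where promoters occupy most intergenic
    space. Guarantees every gene's ``flank`` bp upstream region is clear
    of other gene bodies. Raises if the requested count cannot fit,
    stating the achievable count.
    """
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return GeneAnnotation()
    chroms = genome.chrom_names
    chrom_lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    # largest-remainder apportionment of genes to chromosomes
    quota = n_genes * chrom_lens / chrom_lens.sum()
    counts = np.floor(quota).astype(int)
    rem = n_genes - counts.sum()
    counts[np.argsort(quota - np.floor(quota))[::-1][:rem]] += 1
    rows = []
    gid = 0
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        L = genome.chrom_lengths[chrom]
        lengths = rng.integers(len_range[0], len_range[1] + 1, n_c)
        needed = int(lengths.sum()) + flank * (n_c + 1)
        if needed > L:
            cum = np.cumsum(lengths + flank) + flank
            fit = int(np.searchsorted(cum, L, side="right"))
            raise RuntimeError(
                f"cannot place {n_c} genes on {chrom} ({L} bp): only {fit} fit "
                f"with {flank} bp clearance")
        slack = L - needed
        gaps = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        cursor = 0
        for i in range(n_c):
            cursor += flank + gaps[i]
            start = cursor
            end = start + int(lengths[i])
            cursor = end
            gid += 1
            if rng.random() < 0.5:
                tss, polya = start, end
                strand = "+"
            else:
                tss, polya = end, start
                strand = "-"
            rows.append({"id": f"g{gid:04d}", "chrom": chrom,
                         "strand": strand, "tss": tss, "polya": polya})
    return GeneAnnotation(pd.DataFrame(rows))


# --------------------------------------------------------- nucleosome map
PLUS_ONE_OFFSET = 80  # bp downstream of the TSS to the +1 dyad


@dataclass
class NucleosomeMap:
    """Planted nucleosome positions and the promoter NDRs.

    sites: DataFrame (chrom, dyad, gene, role, occupancy_weight) where
    role is -1 for the upstream nucleosome and 1,2,... for genic ones.
    ndr: DataFrame (gene, chrom, center, width). spacing: genic dyad
    repeat length in bp.
    """

    sites: pd.DataFrame
    ndr: pd.DataFrame
    spacing: int

    def __len__(self) -> int:
        return len(self.sites)


def build_nucleosome_map(genes: GeneAnnotation, genome: Genome,
                         spacing: int = 165, ndr_width: int = 140,
                         stability_coupling: float = 0.0,
                         base_occupancy: float = 0.8) -> NucleosomeMap:
    """Phased nucleosome array per gene: an NDR just upstream of the TSS,
    a -1 dyad beyond it, a +1 dyad 80 bp into the gene, then genic dyads
    every ``spacing`` bp until the polyA site.

    occupancy_weight = base_occupancy * (1 + gamma*(GC147 - mean GC147)),
    clipped to (0,1], where GC147 is the GC fraction of the 147 bp window
    around the dyad — gamma=stability_coupling encodes sequence stability.

    Remaining chromatin (outside gene arrays and NDRs) is filled with
    phased intergenic nucleosomes (role 0, gene '_intergenic'), since
    real chromatin is nucleosomal essentially everywhere outside NDRs.
    """
    site_rows = []
    ndr_rows = []
    for row in genes.table.itertuples(index=False):
        sign = 1 if row.strand == "+" else -1
        glen = abs(row.tss - row.polya)
        ndr_rows.append({"gene": row.id, "chrom": row.chrom,
                         "center": row.tss - sign * (ndr_width // 2),
                         "width": ndr_width})
        offsets = [-(ndr_width + PLUS_ONE_OFFSET)]
        k = PLUS_ONE_OFFSET
        while k <= glen:
            offsets.append(k)
            k += spacing
        L = genome.chrom_lengths[row.chrom]
        for j, off in enumerate(offsets):
            dyad = row.tss + sign * off
            if dyad < 73 or dyad > L - 74:
                continue
            role = -1 if j == 0 else j
            site_rows.append({"chrom": row.chrom, "dyad": int(dyad),
                              "gene": row.id, "role": role})
    # fill ungenic chromatin with phased nucleosomes, sparing NDRs
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    for s in site_rows:
        blocked[s["chrom"]].append((s["dyad"] - 73, s["dyad"] + 74))
    for n in ndr_rows:
        half = n["width"] // 2
        blocked[n["chrom"]].append((n["center"] - half, n["center"] + half))
    for chrom, L in genome.chrom_lengths.items():
        merged: list[list[int]] = []
        for s, e in sorted(blocked[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        free = []
        prev = 0
        for s, e in merged:
            if s - prev >= 147:
                free.append((prev, s))
            prev = max(prev, e)
        if L - prev >= 147:
            free.append((prev, L))
        for s, e in free:
            dyad = s + 73
            while dyad + 74 <= e:
                site_rows.append({"chrom": chrom, "dyad": int(dyad),
                                  "gene": "_intergenic", "role": 0})
                dyad += spacing
    sites = pd.DataFrame(site_rows)
    if len(sites) == 0:
        raise ValueError("no nucleosome sites could be placed")
    weight = np.full(len(sites), base_occupancy)
    if stability_coupling != 0.0:
        from .association import predicted_occupancy_gc
        gc = predicted_occupancy_gc(genome, sites)
        weight = base_occupancy * (1.0 + stability_coupling * (gc - np.nanmean(gc)))
    sites["occupancy_weight"] = np.clip(weight, 1e-3, 1.0)
    return NucleosomeMap(sites=sites, ndr=pd.DataFrame(ndr_rows), spacing=spacing)


# ----------------------------------------------------------- planted truth
@dataclass
class SimulationTruth:
    """Planted parameters the analysis must recover.

    dvnp_affinity: per-base binding-affinity track in [0,1].
    loss_coupling (beta): strength linking affinity to nucleosome loss.
    stability_coupling (gamma): strength linking GC stability to weights.
    rpb3_global_ratio (r): treatment/control RNAP II occupancy ratio.
    """

    dvnp_affinity: dict[str, np.ndarray]
    loss_coupling: float = 0.5
    stability_coupling: float = 0.0
    rpb3_global_ratio: float = 0.65
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "loss_coupling": self.loss_coupling,
            "stability_coupling": self.stability_coupling,
            "rpb3_global_ratio": self.rpb3_global_ratio,
            "seed": self.seed,
            **self.extra,
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def build_affinity_track(nucmap: NucleosomeMap, genome: Genome,
                         bump_sd: float = 40.0,
                         baseline: float = 0.02,
                         promoter_boost: float = 2.0,
                         gene_factors: dict[str, float] | None = None,
                         dyad_mean: float = 0.5,
                         weight_scaled: bool = False) -> dict[str, np.ndarray]:
    """Nucleosome-tracking binding affinity: a Gaussian bump at every
    planted dyad on a small uniform baseline, so affinity is high over
    nucleosomal DNA and low at NDRs. The landscape is scaled so the mean
    affinity over dyads equals ``dyad_mean`` (clipped to [0,1]), keeping
    planted loss fractions stable across random gene-factor draws.

    promoter_boost multiplies the -1/+1 bumps, encoding the observed
    TSS-flanking enrichment of the nucleoprotein (displacement is
    correspondingly concentrated at the -1/+1 nucleosomes). gene_factors
    optionally scales every bump of a gene, planting between-gene binding
    heterogeneity — the across-window variance the genome-wide
    enrichment/loss association detects. weight_scaled additionally
    multiplies bumps by occupancy weight (affinity proportional to
    occupancy level rather than to nucleosome presence)."""
    tracks = {c: np.zeros(l) for c, l in genome.chrom_lengths.items()}
    for row in nucmap.sites.itertuples(index=False):
        h = promoter_boost if row.role in (-1, 1) else 1.0
        if gene_factors is not None:
            h *= gene_factors.get(row.gene, 1.0)
        if weight_scaled:
            h *= row.occupancy_weight
        tracks[row.chrom][row.dyad] += h
    # bump mass spread over ~147 bp: scale so bumps integrate like occupancy
    smoothed = {c: gaussian_filter1d(v, sigma=bump_sd, mode="constant")
                for c, v in tracks.items()}
    at_dyads = np.array([smoothed[row.chrom][row.dyad]
                         for row in nucmap.sites.itertuples(index=False)])
    mean_dyad = at_dyads.mean()
    if mean_dyad == 0:
        raise ValueError("affinity track is identically zero")
    scale = dyad_mean / mean_dyad
    return {c: np.clip(baseline + scale * v, 0.0, 1.0)
            for c, v in smoothed.items()}


def uniform_affinity(genome: Genome, level: float = 1.0) -> dict[str, np.ndarray]:
    """Flat affinity landscape (null model: no positional preference)."""
    return {c: np.full(l, level) for c, l in genome.chrom_lengths.items()}


def free_dna_affinity(nucmap: NucleosomeMap, genome: Genome,
                      bump_sd: float = 40.0) -> dict[str, np.ndarray]:
    """'Naive' alternative truth: affinity for nucleosome-free DNA (one
    minus the nucleosomal landscape), against which the pipeline should
    report the opposite NDR pattern."""
    nuc = build_affinity_track(nucmap, genome, bump_sd=bump_sd, baseline=0.0)
    return {c: 1.0 - v for c, v in nuc.items()}


# ------------------------------------------------------------ MNase library
def _truncated_lengths(rng, n, mean, sd, lo, hi):
    """Normal(mean, sd) truncated to [lo, hi], by inverse-CDF sampling."""
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size=n)
    return np.rint(mean + sd * ndtri(u)).astype(int)


def simulate_mnase(nucmap: NucleosomeMap, truth: SimulationTruth,
                   n_fragments: int, genome: Genome,
                   frag_len: tuple[float, float] = (147.0, 10.0),
                   condition: str = "control", seed: int = 0,
                   size_range: tuple[int, int] = (120, 200),
                   jitter_sd: float = 10.0,
                   stability_protection: bool = True,
                   background: float = 0.05,
                   digestion_factor: float = 1.0) -> FragmentSet:
    """Draw nucleosomal fragments around planted dyads.

    Sites are sampled with probability proportional to occupancy_weight
    (control) or occupancy_weight * retention (condition='dvnp'), where
    retention = max(0, 1 - loss) and loss = beta * affinity(dyad), scaled
    by mean_weight/weight when stability_protection is on (weak
    nucleosomes lose more). Midpoints get Normal(0, jitter_sd) jitter;
    lengths are Normal(mean, sd) truncated to size_range. A ``background``
    fraction of fragments has uniform genomic midpoints (sub-nucleosomal
    and non-chromatin digestion products present in real libraries). The
    nuisance digestion_factor rescales fragment-length spread between
    conditions (default matched).
    """
    if condition not in ("control", "dvnp"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    sites = nucmap.sites
    w = sites["occupancy_weight"].to_numpy().astype(float)
    if condition == "dvnp":
        aff = np.array([truth.dvnp_affinity[c][d] for c, d in
                        zip(sites["chrom"], sites["dyad"])])
        loss = truth.loss_coupling * aff
        if stability_protection:
            loss = loss * (w.mean() / w)
        w = w * np.clip(1.0 - loss, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("all effective site weights are zero")
    n_bg = rng.binomial(n_fragments, background) if background > 0 else 0
    n_nuc = n_fragments - n_bg
    idx = rng.choice(len(sites), size=n_nuc, p=w / w.sum())
    mids = sites["dyad"].to_numpy()[idx] + np.rint(
        rng.normal(0.0, jitter_sd, n_nuc)).astype(int)
    chroms = sites["chrom"].to_numpy()[idx]
    if n_bg:
        clens = np.array([genome.chrom_lengths[c] for c in genome.chrom_names],
                         dtype=float)
        bg_ci = rng.choice(len(clens), size=n_bg, p=clens / clens.sum())
        bg_mid = np.floor(rng.random(n_bg) * clens[bg_ci]).astype(int)
        chroms = np.concatenate([chroms, np.array(genome.chrom_names)[bg_ci]])
        mids = np.concatenate([mids, bg_mid])
    lengths = _truncated_lengths(rng, n_fragments, frag_len[0],
                                 frag_len[1] * digestion_factor, *size_range)
    starts = mids - lengths // 2
    ends = starts + lengths
    # shift fragments that fall off an end back inside the chromosome
    for c in np.unique(chroms):
        m = chroms == c
        L = genome.chrom_lengths[c]
        shift = np.where(starts[m] < 0, -starts[m], 0)
        shift = np.where(ends[m] > L, L - ends[m], shift)
        starts[m] += shift
        ends[m] += shift
    return FragmentSet(pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}),
                       sample_label=f"mnase_{condition}")


# ------------------------------------------------------------- ChIP library
def _sample_positions(weights: dict[str, np.ndarray], n: int, rng) -> pd.DataFrame:
    totals = np.array([w.sum() for w in weights.values()])
    if totals.sum() <= 0:
        raise ValueError("affinity weights sum to zero")
    chroms = list(weights)
    counts = rng.multinomial(n, totals / totals.sum())
    frames = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        cs = np.cumsum(weights[chrom])
        pos = np.searchsorted(cs, rng.random(k) * cs[-1], side="right")
        frames.append(pd.DataFrame({"chrom": chrom, "mid": pos}))
    if not frames:
        return pd.DataFrame({"chrom": [], "mid": []})
    return pd.concat(frames, ignore_index=True)


def _fragments_from_midpoints(mids: pd.DataFrame, genome: Genome, rng,
                              frag_len, size_range, label) -> FragmentSet:
    n = len(mids)
    if n == 0:
        return FragmentSet(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                           sample_label=label)
    lengths = _truncated_lengths(rng, n, frag_len[0], frag_len[1], *size_range)
    starts = mids["mid"].to_numpy() - lengths // 2
    ends = starts + lengths
    chroms = mids["chrom"].to_numpy()
    for c in np.unique(chroms):
        m = chroms == c
        L = genome.chrom_lengths[c]
        shift = np.where(starts[m] < 0, -starts[m], 0)
        shift = np.where(ends[m] > L, L - ends[m], shift)
        starts[m] += shift
        ends[m] += shift
    return FragmentSet(pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}),
                       sample_label=label)


def simulate_dvnp_chip(truth: SimulationTruth, genome: Genome,
                       n_ip: int, n_input: int, seed: int = 0,
                       frag_len: tuple[float, float] = (150.0, 40.0),
                       size_range: tuple[int, int] = (50, 500),
                       input_track: dict[str, np.ndarray] | None = None,
                       ) -> tuple[FragmentSet, FragmentSet]:
    """IP midpoints sampled proportional to the affinity track; input
    midpoints uniform, or proportional to a supplied accessibility track
    (to exercise the input-control logic)."""
    rng = np.random.default_rng(seed)
    ip_mids = _sample_positions(truth.dvnp_affinity, n_ip, rng) if n_ip else \
        pd.DataFrame({"chrom": [], "mid": []})
    inp_w = input_track if input_track is not None else uniform_affinity(genome)
    inp_mids = _sample_positions(inp_w, n_input, rng) if n_input else \
        pd.DataFrame({"chrom": [], "mid": []})
    ip = _fragments_from_midpoints(ip_mids, genome, rng, frag_len, size_range, "chip_ip")
    inp = _fragments_from_midpoints(inp_mids, genome, rng, frag_len, size_range,
                                    "chip_input")
    return ip, inp


# ----------------------------------------------------------- Rpb3 library
def simulate_rpb3(genes: GeneAnnotation, truth: SimulationTruth,
                  genome: Genome, n_reads: int = 100_000,
                  expression: np.ndarray | None = None,
                  spikein_mass: tuple[float, float] = (0.3, 0.3),
                  cellular_yield_control: float = 1.0,
                  frag_len: tuple[float, float] = (200.0, 50.0),
                  size_range: tuple[int, int] = (50, 500),
                  seed: int = 0,
                  ) -> tuple[FragmentSet, FragmentSet, pd.DataFrame]:
    """Polymerase ChIP with a planted global occupancy ratio r.

    Control midpoints fall uniformly within gene bodies with per-gene
    rates proportional to expression; the treatment multiplies every
    gene's rate by r and is then resampled to the same genomic library
    size, so the reduction is invisible without spike-in. Spike-in read
    counts are Poisson with expectation n_reads * mass / cellular_yield,
    where treatment cellular yield is r times control — the treatment
    spike fraction therefore exceeds control by 1/r in expectation.
    """
    r = truth.rpb3_global_ratio
    if not 0.0 < r <= 1.0:
        raise ValueError("rpb3_global_ratio must be in (0,1]")
    rng = np.random.default_rng(seed)
    tab = genes.table
    if len(tab) == 0:
        raise ValueError("no genes to simulate")
    if expression is None:
        expression = rng.lognormal(mean=0.0, sigma=0.5, size=len(tab))
    glens = genes.lengths
    gene_w = expression * glens
    frames = {}
    for sample in ("control", "treatment"):
        # per-gene rates scale by r in treatment, but resampling to a fixed
        # genomic library size cancels any uniform factor — by design.
        gi = rng.choice(len(tab), size=n_reads, p=gene_w / gene_w.sum())
        offs = np.floor(rng.random(n_reads) * glens[gi]).astype(int)
        sign = np.where(tab["strand"].to_numpy()[gi] == "+", 1, -1)
        mids = tab["tss"].to_numpy()[gi] + sign * offs
        frames[sample] = pd.DataFrame({"chrom": tab["chrom"].to_numpy()[gi],
                                       "mid": mids})
    ctrl = _fragments_from_midpoints(frames["control"], genome, rng, frag_len,
                                     size_range, "rpb3_control")
    treat = _fragments_from_midpoints(frames["treatment"], genome, rng, frag_len,
                                      size_range, "rpb3_treatment")
    yields = {"control": cellular_yield_control,
              "treatment": r * cellular_yield_control}
    spike = {
        s: int(rng.poisson(n_reads * m / yields[s]))
        for s, m in zip(("control", "treatment"), spikein_mass)
    }
    counts = pd.DataFrame({
        "sample": ["control", "treatment"],
        "genomic_reads": [len(ctrl), len(treat)],
        "spike_reads": [spike["control"], spike["treatment"]],
        "spike_mass_added": list(spikein_mass),
        "dilution": [1.0, 1.0],
    })
    return ctrl, treat, counts


# -------------------------------------------------------------- SGA screen
def simulate_sga(n_strains: int, hit_sets: dict[str, tuple[int, float]] | None = None,
                 noise_sd: float = 0.05, seed: int = 0,
                 n_replicates: int = 2, plate_size: int = 384,
                 plate_factor_sd: float = 0.15, colony_cv: float = 0.0,
                 base_size: float = 400.0) -> pd.DataFrame:
    """Colony-size table with planted growth effects.

    Relative growth per strain is 1 + effect + Normal(0, noise_sd)
    (floored at 0); experimental colony sizes are control sizes times that
    value, both scaled by per-plate multiplicative factors so plate-median
    normalization is exercised. hit_sets maps a set name to (set size,
    effect); sets are disjoint by construction. Columns: gene, plate,
    position, exp_size, ctrl_size, set_label, planted_effect,
    planted_growth.
    """
    rng = np.random.default_rng(seed)
    hit_sets = hit_sets or {}
    genes = [f"g{i + 1:05d}" for i in range(n_strains)]
    effect = np.zeros(n_strains)
    label = np.array(["none"] * n_strains, dtype=object)
    cursor = 0
    for name, (size, eff) in hit_sets.items():
        if cursor + size > n_strains:
            raise ValueError("hit sets exceed strain count")
        effect[cursor:cursor + size] = eff
        label[cursor:cursor + size] = name
        cursor += size
    # shuffle so hit sets are scattered across plates
    perm = rng.permutation(n_strains)
    effect, label = effect[perm], label[perm]
    rg = np.clip(1.0 + effect + rng.normal(0.0, noise_sd, n_strains), 0.0, None)
    plates = np.arange(n_strains) // plate_size
    pf_exp = rng.lognormal(0.0, plate_factor_sd, plates.max() + 1)
    pf_ctrl = rng.lognormal(0.0, plate_factor_sd, plates.max() + 1)
    rows = []
    for rep in range(n_replicates):
        noise_c = rng.lognormal(0.0, colony_cv, n_strains) if colony_cv > 0 else 1.0
        noise_e = rng.lognormal(0.0, colony_cv, n_strains) if colony_cv > 0 else 1.0
        ctrl_size = base_size * pf_ctrl[plates] * noise_c
        exp_size = base_size * pf_exp[plates] * rg * noise_e
        rows.append(pd.DataFrame({
            "gene": genes, "plate": plates, "position": rep,
            "exp_size": exp_size, "ctrl_size": ctrl_size,
            "set_label": label, "planted_effect": effect, "planted_growth": rg,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------- full scenario
@dataclass
class ChromatinScenario:
    """One complete simulated study: genome, genes, nucleosome map, planted
    truth, and all fragment libraries."""

    genome: Genome
    genes: GeneAnnotation
    nucmap: NucleosomeMap
    truth: SimulationTruth
    mnase_control: FragmentSet
    mnase_dvnp: FragmentSet
    chip_ip: FragmentSet
    chip_input: FragmentSet


def simulate_chromatin_study(seed: int = 0,
                             chrom_lengths=(650_000, 650_000),
                             n_genes: int = 560,
                             loss_coupling: float = 0.5,
                             stability_coupling: float = 1.5,
                             rpb3_global_ratio: float = 0.65,
                             n_mnase: int = 300_000,
                             n_chip_ip: int = 200_000,
                             n_chip_input: int = 200_000,
                             spacing: int = 165,
                             ndr_width: int = 140,
                             stability_protection: bool = True,
                             gene_affinity_sd: float = 0.6,
                             promoter_boost: float = 2.0,
                             ) -> ChromatinScenario:
    """Generate the default simulated study used throughout the tests.

    Defaults emulate a compact yeast-like setting: a 1.3 Mb genome in two
    chromosomes, ~300 phased-array genes, 165 bp nucleosome repeat,
    nucleoprotein-coupled loss (beta=0.5) with stability protection
    (gamma=1.5), and a 35% planted global RNAP II reduction (r=0.65).
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2 ** 31 - 1))  # noqa: E731
    genome = simulate_genome(len(chrom_lengths), chrom_lengths, seed=sub())
    genes = simulate_genes(genome, n_genes, seed=sub())
    nucmap = build_nucleosome_map(genes, genome, spacing=spacing,
                                  ndr_width=ndr_width,
                                  stability_coupling=stability_coupling)
    # between-gene binding heterogeneity: lognormal per-gene affinity
    gene_factors = dict(zip(
        genes.table["id"],
        rng.lognormal(0.0, gene_affinity_sd, len(genes)) if gene_affinity_sd > 0
        else np.ones(len(genes))))
    truth = SimulationTruth(
        dvnp_affinity=build_affinity_track(nucmap, genome,
                                           gene_factors=gene_factors,
                                           promoter_boost=promoter_boost),
        loss_coupling=loss_coupling,
        stability_coupling=stability_coupling,
        rpb3_global_ratio=rpb3_global_ratio,
        seed=seed,
        extra={"spacing": spacing, "ndr_width": ndr_width,
               "plus_one_offset": PLUS_ONE_OFFSET,
               "gene_affinity_sd": gene_affinity_sd,
               "n_genes": len(genes), "chrom_lengths": list(chrom_lengths)},
    )
    mnase_control = simulate_mnase(nucmap, truth, n_mnase, genome,
                                   condition="control", seed=sub())
    mnase_dvnp = simulate_mnase(nucmap, truth, n_mnase, genome,
                                condition="dvnp", seed=sub(),
                                stability_protection=stability_protection)
    chip_ip, chip_input = simulate_dvnp_chip(truth, genome, n_chip_ip,
                                             n_chip_input, seed=sub())
    return ChromatinScenario(genome=genome, genes=genes, nucmap=nucmap,
                             truth=truth, mnase_control=mnase_control,
                             mnase_dvnp=mnase_dvnp, chip_ip=chip_ip,
                             chip_input=chip_input)
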