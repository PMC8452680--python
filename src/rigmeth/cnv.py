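"""Copy-number profiles from combined methylation-array intensities.

The combined (methylated + unmethylated) signal of each probe is a
proxy for local DNA copy number.  Autosomal probes are tiled into
fixed-width bins (merged left-to-right until each bin holds a minimum
number of probes), each sample's per-bin mean total intensity is
compared against the median of a copy-number-neutral reference cohort
on the log2 scale, and the per-sample genome-wide median is centered at
zero.  Bin profiles are segmented per chromosome by least-squares
changepoint fitting with a per-changepoint penalty; focal gene calls,
arm-level calls and a breakpoint-burden count are derived from the
segments with explicit, configurable thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .synth import IntensityData

logger = logging.getLogger(__name__)

__all__ = [
    "total_intensity",
    "bin_genome",
    "log2_ratio",
    "segment_profile",
    "call_focal",
    "call_arm",
    "count_breakpoints",
    "Segment",
    "CNACall",
    "CNVProfile",
]


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2: float


@dataclass(frozen=True)
class CNACall:
    target: str
    status: str  # high_amplification | gain | neutral | loss |
    #              homozygous_deletion | not_assessable
    mean_log2: float
    span: int


@dataclass
class CNVProfile:
    sample_id: str
    bins: pd.DataFrame
    log2: pd.Series
    segments: list[Segment] = field(default_factory=list)
    calls: list[CNACall] = field(default_factory=list)
    breakpoint_count: int = 0


def total_intensity(data: IntensityData) -> pd.DataFrame:
    """Combined methylated + unmethylated signal per sample and probe."""
    return data.meth + data.unmeth


def bin_genome(manifest: pd.DataFrame, probe_ids, bin_width: int,
               min_probes: int, chrom_lengths: dict[str, int] | None = None,
               ) -> pd.DataFrame:
    """Tile autosomes into fixed-width bins holding >= min_probes probes.

    Bins are 0-based half-open, tiled per chromosome and merged
    left-to-right until each holds at least ``min_probes`` of the given
    (already filtered, autosomal) probes; a trailing deficient bin is
    merged into its predecessor.  Chromosomes with fewer than
    ``min_probes`` probes in total are dropped with a warning.

    Returns a DataFrame with columns chrom, start, end, n_probes,
    probes (list of probe ids), indexed by bin id.
    """
    probes = manifest.loc[probe_ids]
    probes = probes[~probes["chrom"].isin(["X", "Y"])]
    if probes.empty:
        raise ValueError("no autosomal probes to bin")
    rows = []
    chrom_order = sorted(probes["chrom"].unique(), key=_chrom_key)
    for chrom in chrom_order:
        sub = probes[probes["chrom"] == chrom].sort_values("pos")
        if len(sub) < min_probes:
            logger.warning("chromosome %s has %d probes (< %d); dropped",
                           chrom, len(sub), min_probes)
            continue
        length = (chrom_lengths[chrom] if chrom_lengths
                  else int(sub["pos"].max()))
        edges = list(range(0, length, bin_width)) + [length]
        pos0 = sub["pos"].to_numpy() - 1  # manifest is 1-based
        ids = sub.index.to_numpy()
        cur_start, cur_probes = 0, []
        for lo, hi in zip(edges[:-1], edges[1:]):
            cur_probes.extend(ids[(pos0 >= lo) & (pos0 < hi)])
            if len(cur_probes) >= min_probes:
                rows.append((chrom, cur_start, hi, cur_probes))
                cur_start, cur_probes = hi, []
        if cur_probes:
            if rows and rows[-1][0] == chrom:
                c, s, _, p = rows[-1]
                rows[-1] = (c, s, length, p + cur_probes)
            else:
                logger.warning("chromosome %s yields no full bin; dropped", chrom)
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "probes"])
    bins["n_probes"] = bins["probes"].map(len)
    bins.index = [f"{c}:{s}-{e}" for c, s, e in
                  zip(bins["chrom"], bins["start"], bins["end"])]
    return bins[["chrom", "start", "end", "n_probes", "probes"]]


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def _bin_means(totals: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean probe total per bin (samples x bins)."""
    cols = {}
    for bin_id, row in bins.iterrows():
        cols[bin_id] = totals.loc[:, row["probes"]].mean(axis=1)
    return pd.DataFrame(cols)


def log2_ratio(sample_totals: pd.DataFrame, reference_totals: pd.DataFrame,
               bins: pd.DataFrame, epsilon: float = 1.0) -> pd.DataFrame:
    """Median-centered per-bin log2 ratios against a diploid reference.

    Per bin: log2((sample bin mean + eps) / (median over reference
    samples of the bin mean + eps)); then each sample's genome-wide
    median log2 is centered at zero.  Bins whose reference median is
    zero even after the epsilon guard are masked (NaN).
    """
    if reference_totals.shape[0] < 3:
        raise ValueError("need >= 3 reference samples")
    B = _bin_means(sample_totals, bins)
    ref = _bin_means(reference_totals, bins).median(axis=0)
    denom = ref + epsilon
    with np.errstate(divide="ignore"):
        L = np.log2((B + epsilon).div(denom, axis=1))
    L = L.where(np.isfinite(L))
    masked = denom <= epsilon
    if masked.any():
        L.loc[:, masked[masked].index] = np.nan
    L = L.sub(L.median(axis=1, skipna=True), axis=0)
    return L


def _segment_chromosome(y: np.ndarray, penalty: float) -> list[tuple[int, int]]:
    """Optimal-partitioning changepoint fit: minimize within-segment SSE
    plus penalty per changepoint.  Returns [start, end) index pairs."""
    n = len(y)
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    F = np.empty(n + 1)
    F[0] = -penalty
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        i = np.arange(j)
        m = j - i
        tot = s1[j] - s1[i]
        cost = (s2[j] - s2[i]) - tot * tot / m  # SSE of y[i:j]
        v = F[:j] + cost + penalty
        arg = int(np.argmin(v))
        F[j] = v[arg]
        back[j] = arg
    cuts = []
    j = n
    while j > 0:
        cuts.append((back[j], j))
        j = back[j]
    return cuts[::-1]


def _robust_noise_var(log2: pd.Series, bins: pd.DataFrame) -> float:
    """Bin-level noise variance from within-chromosome successive
    differences (median absolute difference scaled to sigma; robust to
    true copy-number steps)."""
    diffs = []
    for chrom in bins["chrom"].unique():
        y = log2.loc[bins.index[bins["chrom"] == chrom]].to_numpy(dtype=float)
        y = y[np.isfinite(y)]
        if len(y) > 1:
            diffs.append(np.diff(y))
    if not diffs:
        return 0.0
    mad = np.median(np.abs(np.concatenate(diffs)))
    sigma = mad / (0.6745 * np.sqrt(2.0))
    return float(sigma * sigma)


def segment_profile(log2: pd.Series, bins: pd.DataFrame,
                    penalty: float | None = None) -> list[Segment]:
    """Segment one sample's bin profile per chromosome.

    Non-finite bins are masked before fitting; segments partition the
    remaining bins of each chromosome and carry their mean log2 ratio.
    With ``penalty=None`` a BIC-style penalty 3 * sigma^2 * ln(n) is used
    per chromosome, with sigma estimated robustly from successive bin
    differences; an explicit penalty is applied as given.
    """
    noise_var = _robust_noise_var(log2, bins) if penalty is None else None
    segments: list[Segment] = []
    for chrom in bins["chrom"].unique():
        cb = bins[bins["chrom"] == chrom]
        y = log2.loc[cb.index].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if not ok.any():
            continue
        idx = np.flatnonzero(ok)
        pen = (penalty if penalty is not None
               else max(3.0 * noise_var * np.log(max(int(ok.sum()), 2)), 1e-12))
        pieces = _segment_chromosome(y[ok], pen)
        for i, j in pieces:
            rows = cb.iloc[idx[i:j]]
            segments.append(Segment(
                chrom=chrom,
                start=int(rows["start"].iloc[0]),
                end=int(rows["end"].iloc[-1]),
                n_bins=j - i,
                mean_log2=float(y[ok][i:j].mean()),
            ))
    return segments


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def call_focal(segments: list[Segment], gene_regions: pd.DataFrame,
               chrom_lengths: dict[str, int],
               config: PipelineConfig | None = None) -> list[CNACall]:
    """Focal gene-level calls from the overlapping segment of largest
    absolute amplitude.

    ``gene_regions`` is a BED-like frame with chrom/start/end/name.
    High-level amplification requires mean log2 >= amp_threshold with a
    segment no longer than ``focal_span_fraction`` of the chromosome;
    homozygous deletion mirrors it at del_threshold; gains/losses use
    +/-0.4 by default.
    """
    config = config or PipelineConfig()
    calls = []
    for _, region in gene_regions.iterrows():
        over = [s for s in segments if s.chrom == str(region["chrom"])
                and _overlap(s.start, s.end, region["start"], region["end"]) > 0]
        if not over:
            calls.append(CNACall(region["name"], "not_assessable", np.nan, 0))
            continue
        seg = max(over, key=lambda s: abs(s.mean_log2))
        span = seg.end - seg.start
        focal_limit = config.focal_span_fraction * chrom_lengths[seg.chrom]
        m = seg.mean_log2
        if m >= config.amp_threshold and span <= focal_limit:
            status = "high_amplification"
        elif m <= config.del_threshold:
            status = "homozygous_deletion"
        elif m <= config.loss_threshold:
            status = "loss"
        elif m >= config.gain_threshold:
            status = "gain"
        else:
            status = "neutral"
        calls.append(CNACall(region["name"], status, m, span))
    return calls


def call_arm(segments: list[Segment], arms: dict[str, tuple[str, int, int]],
             config: PipelineConfig | None = None) -> list[CNACall]:
    """Arm-level gain/loss calls.

    An arm is called gained when its length-weighted mean log2 is at
    least +arm_threshold and at least ``arm_min_fraction`` of the
    covered arm territory lies in segments at or above that threshold;
    losses are symmetric.
    """
    config = config or PipelineConfig()
    calls = []
    for name, (chrom, a_start, a_end) in arms.items():
        weights, means = [], []
        for s in segments:
            if s.chrom != chrom:
                continue
            ov = _overlap(s.start, s.end, a_start, a_end)
            if ov > 0:
                weights.append(ov)
                means.append(s.mean_log2)
        if not weights:
            calls.append(CNACall(name, "not_assessable", np.nan, 0))
            continue
        weights = np.array(weights, dtype=float)
        means = np.array(means)
        covered = weights.sum()
        wmean = float((weights * means).sum() / covered)
        frac_up = weights[means >= config.arm_threshold].sum() / covered
        frac_down = weights[means <= -config.arm_threshold].sum() / covered
        if wmean >= config.arm_threshold and frac_up >= config.arm_min_fraction:
            status = "gain"
        elif wmean <= -config.arm_threshold and frac_down >= config.arm_min_fraction:
            status = "loss"
        else:
            status = "neutral"
        calls.append(CNACall(name, status, wmean, int(covered)))
    return calls


def count_breakpoints(segments: list[Segment], min_delta: float = 0.3) -> int:
    """Genome-wide count of amplitude-significant segment transitions.

    Counts, within each chromosome, adjacent-segment transitions whose
    mean log2 ratios differ by at least ``min_delta`` — a reproducible
    surrogate for visually counted chromosomal breakpoints.
    """
    count = 0
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom_segs in by_chrom.values():
        chrom_segs.sort(key=lambda s: s.start)
        for a, b in zip(chrom_segs, chrom_segs[1:]):
            if abs(b.mean_log2 - a.mean_log2) >= min_delta:
                count += 1
    return count


def profile_cohort(data_totals: pd.DataFrame, reference_totals: pd.DataFrame,
                   bins: pd.DataFrame, gene_regions: pd.DataFrame,
                   arms: dict[str, tuple[str, int, int]],
                   chrom_lengths: dict[str, int],
                   config: PipelineConfig | None = None,
                   ) -> dict[str, CNVProfile]:
    """Bin, segment and call every sample in ``data_totals``."""
    config = config or PipelineConfig()
    L = log2_ratio(data_totals, reference_totals, bins, config.cnv_epsilon)
    profiles = {}
    for sid in data_totals.index:
        segs = segment_profile(L.loc[sid], bins, config.segment_penalty)
        calls = (call_focal(segs, gene_regions, chrom_lengths, config)
                 + call_arm(segs, arms, config))
        profiles[sid] = CNVProfile(
            sample_id=sid, bins=bins, log2=L.loc[sid], segments=segs,
            calls=calls,
            breakpoint_count=count_breakpoints(segs, config.breakpoint_min_delta))
    return profiles
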