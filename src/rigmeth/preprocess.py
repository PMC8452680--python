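"""Normalization chain and probe filtering for combined 450k/EPIC data.

The pipeline order is fixed: platform intersection, per-sample
background correction (shift the 5th percentile of the negative control
probes of each color channel to zero), per-sample dye-bias correction
(scale the mean of the normalization controls of each channel to
10,000), log2 transform, per-probe linear batch adjustment for tissue
material (FFPE/frozen) and array type (450k/EPIC), back-transform, beta
values with an offset of 100, and the four probe filters (X/Y,
SNP-proximal, multi-mapping, not on both platforms).

The methylated signal is treated as the green channel and the
unmethylated signal as the red channel; background and dye-bias factors
are estimated per sample per channel from that channel's controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .synth import IntensityData

logger = logging.getLogger(__name__)

__all__ = [
    "combine_platforms",
    "background_correct",
    "dye_bias_correct",
    "batch_adjust",
    "beta_values",
    "filter_probes",
    "normalize",
    "NormalizedData",
]

_CHANNEL_OF = {"meth": "grn", "unmeth": "red"}

MIN_NEGATIVE_CONTROLS = 20

#: a SNP within this many bases of (and including) the targeted CpG site
#: makes a probe SNP-proximal; the boundary is inclusive
SNP_PROXIMITY_BP = 5


def combine_platforms(data: IntensityData, manifest: pd.DataFrame) -> IntensityData:
    """Restrict the probe universe to probes present on both arrays."""
    missing = data.meth.columns.difference(manifest.index)
    if len(missing):
        raise ValueError(f"probes absent from manifest: {list(missing)[:5]}")
    flags = manifest.loc[data.meth.columns]
    keep = data.meth.columns[(flags["on_450k"] & flags["on_epic"]).to_numpy()]
    if len(keep) == 0:
        raise ValueError("empty platform intersection")
    return data.subset_probes(keep)


def _quantile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile between order statistics (pinned for
    bit-reproducibility; identical to numpy's default 'linear' method)."""
    return float(np.quantile(values, q, method="linear"))


def background_correct(intensities: np.ndarray, negative_controls: np.ndarray,
                       percentile: float = 5.0, clamp: bool = True,
                       ) -> tuple[np.ndarray, float]:
    """Shift one sample/channel so the negative-control percentile is zero.

    Subtracts the (default 5th) percentile of the sample's negative
    controls from every intensity of that channel.  Query intensities
    are clamped at zero (signals are physical); the returned shift can
    be applied to the controls unclamped so the fixed point -- a
    recomputed control percentile of exactly zero -- is preserved.

    Returns (corrected, shift).
    """
    negative_controls = np.asarray(negative_controls, dtype=float)
    if negative_controls.size == 0:
        raise ValueError("no negative controls for channel")
    if negative_controls.size < MIN_NEGATIVE_CONTROLS:
        raise ValueError(
            f"need >= {MIN_NEGATIVE_CONTROLS} negative controls per channel, "
            f"got {negative_controls.size}")
    shift = _quantile(negative_controls, percentile / 100.0)
    corrected = np.asarray(intensities, dtype=float) - shift
    if clamp:
        corrected = np.maximum(corrected, 0.0)
    return corrected, shift


def dye_bias_correct(intensities: np.ndarray, normalization_controls: np.ndarray,
                     target: float = 10_000.0) -> tuple[np.ndarray, float]:
    """Scale one sample/channel so the normalization-control mean hits target.

    Returns (corrected, factor) with factor = target / mean(controls).
    """
    normalization_controls = np.asarray(normalization_controls, dtype=float)
    if normalization_controls.size == 0:
        raise ValueError("no normalization controls for channel")
    mean = float(normalization_controls.mean())
    if mean <= 0:
        raise ValueError(f"normalization-control mean must be > 0, got {mean}")
    factor = target / mean
    return np.asarray(intensities, dtype=float) * factor, factor


def _sample_controls(controls: pd.DataFrame, sample_id: str, ctype: str,
                     channel: str) -> np.ndarray:
    sel = controls[(controls["sample_id"] == sample_id)
                   & (controls["control_type"] == ctype)
                   & (controls["channel"] == channel)]
    return sel["intensity"].to_numpy(dtype=float)


def batch_adjust(log2_matrix: pd.DataFrame, covariates: pd.DataFrame,
                 factors: tuple[str, ...] = ("material", "array"),
                 ) -> pd.DataFrame:
    """Remove additive batch effects from a log2 intensity matrix.

    Fits, per probe, an ordinary-least-squares linear model with
    additive factor effects for each covariate (treatment coding, fitted
    jointly across factors) and subtracts the mean-centered fitted batch
    component, so per-probe batch-group means are equalized while the
    per-probe grand mean is preserved.  A factor confounded with another
    (identical sample partition) is skipped with a warning.
    """
    covariates = covariates.loc[log2_matrix.index]
    n = len(log2_matrix)
    cols: list[np.ndarray] = []
    for fac in factors:
        codes, levels = pd.factorize(covariates[fac], sort=True)
        if len(levels) < 2:
            logger.warning("batch factor %r has a single level; skipped", fac)
            continue
        counts = np.bincount(codes)
        if counts.min() < 2:
            raise ValueError(f"batch factor {fac!r} has a level with < 2 samples")
        # treatment coding, reference level dropped; skip a factor whose
        # columns do not extend the column space (confounded design)
        new = [(codes == lvl).astype(float) for lvl in range(1, len(levels))]
        base = np.column_stack([np.ones(n)] + cols)
        trial = np.column_stack([base] + new)
        if np.linalg.matrix_rank(trial) < base.shape[1] + len(new):
            logger.warning("batch factor %r is confounded with an earlier "
                           "factor; skipped", fac)
            continue
        cols.extend(new)
    if not cols:
        return log2_matrix.copy()

    X = np.column_stack([np.ones(len(log2_matrix))] + cols)
    Y = log2_matrix.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_component = X[:, 1:] @ coef[1:, :]
    batch_component -= batch_component.mean(axis=0, keepdims=True)
    adjusted = Y - batch_component
    return pd.DataFrame(adjusted, index=log2_matrix.index,
                        columns=log2_matrix.columns)


def beta_values(meth: pd.DataFrame, unmeth: pd.DataFrame,
                offset: float = 100.0) -> pd.DataFrame:
    """Beta = M / (M + U + offset), elementwise; always in [0, 1)."""
    m = meth.to_numpy(dtype=float)
    u = unmeth.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("negative intensities passed to beta_values")
    beta = m / (m + u + offset)
    return pd.DataFrame(beta, index=meth.index, columns=meth.columns)


def filter_probes(manifest: pd.DataFrame) -> tuple[pd.Index, dict[str, int]]:
    """Apply the four probe filters; return retained ids and removal counts.

    Removes, in order: X/Y probes, SNP-proximal probes (SNP within
    ``SNP_PROXIMITY_BP`` bases of and including the targeted CpG; the
    boundary is inclusive, so distance 5 is removed and 6 kept), probes
    without a unique genome mapping at one allowed mismatch, and probes
    not present on both platforms.  If the manifest carries a numeric
    ``snp_distance`` column it is thresholded here; otherwise the
    precomputed ``snp_proximal`` flag is used.  Control probes are not
    part of the query universe and are excluded up front.
    """
    q = manifest[manifest["control_type"] == "none"]
    report: dict[str, int] = {"input": len(q)}
    keep = q

    def snp_mask(m: pd.DataFrame) -> pd.Series:
        flag = m["snp_proximal"].astype(bool)
        if "snp_distance" in m.columns:
            flag = flag | (pd.to_numeric(m["snp_distance"], errors="coerce")
                           <= SNP_PROXIMITY_BP)
        return ~flag

    for rule, mask_fn in (
        ("xy", lambda m: ~m["chrom"].isin(["X", "Y"])),
        ("snp_proximal", snp_mask),
        ("multi_mapping", lambda m: ~m["multi_mapping"]),
        ("platform", lambda m: m["on_450k"] & m["on_epic"]),
    ):
        mask = mask_fn(keep)
        report[f"removed_{rule}"] = int((~mask).sum())
        keep = keep[mask]
    report["retained"] = len(keep)
    if len(keep) == 0:
        raise ValueError("all probes removed by filtering")
    return keep.index, report


@dataclass
class NormalizedData:
    """Output of the full normalization chain.

    ``beta`` is restricted to the filtered probe set; ``meth`` /
    ``unmeth`` are the fully corrected intensities on the same probes.
    ``cnv_totals`` holds the combined background- and dye-bias-corrected
    signal before the per-probe batch model: multiplicative batch
    factors cancel in the median-centered copy-number ratio, whereas the
    per-probe batch fit would let large copy-number segments bleed into
    the batch-group estimates, so copy-number analysis consumes this
    matrix.  ``report`` records the per-stage parameters applied.
    """

    beta: pd.DataFrame
    meth: pd.DataFrame
    unmeth: pd.DataFrame
    cnv_totals: pd.DataFrame
    meta: pd.DataFrame
    filter_report: dict[str, int]
    report: dict


def normalize(data: IntensityData, manifest: pd.DataFrame,
              config: PipelineConfig | None = None) -> NormalizedData:
    """Run the full chain on a cohort; see the module docstring for order."""
    config = config or PipelineConfig()
    data = combine_platforms(data, manifest)
    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    samples = data.sample_ids
    shifts: dict[str, dict[str, float]] = {}
    factors: dict[str, dict[str, float]] = {}

    for si, s in enumerate(samples):
        for name, mat in (("meth", meth), ("unmeth", unmeth)):
            channel = _CHANNEL_OF[name]
            if config.apply_background:
                neg = _sample_controls(data.controls, s, "negative", channel)
                if neg.size == 0:
                    raise ValueError(f"sample {s!r}: no negative controls "
                                     f"({channel} channel)")
                mat[si], shift = background_correct(
                    mat[si], neg, config.negative_control_percentile)
                shifts.setdefault(s, {})[channel] = shift
            if config.apply_dye_bias:
                norm = _sample_controls(data.controls, s, "normalization", channel)
                if config.apply_background and norm.size:
                    norm = norm - shifts[s][channel]
                mat[si], factor = dye_bias_correct(
                    mat[si], norm, config.normalization_control_target)
                factors.setdefault(s, {})[channel] = factor

    cnv_totals = pd.DataFrame(meth + unmeth, index=samples,
                              columns=data.meth.columns)

    # log2 (guarded against zeros), batch adjust each signal individually,
    # back-transform
    if config.apply_batch_adjust:
        out = []
        for mat in (meth, unmeth):
            log2m = pd.DataFrame(np.log2(mat + 1.0), index=samples,
                                 columns=data.meth.columns)
            adj = batch_adjust(log2m, data.meta)
            out.append(np.maximum(2.0 ** adj.to_numpy() - 1.0, 0.0))
        meth, unmeth = out

    meth_df = pd.DataFrame(meth, index=samples, columns=data.meth.columns)
    unmeth_df = pd.DataFrame(unmeth, index=samples, columns=data.meth.columns)
    beta = beta_values(meth_df, unmeth_df, config.beta_offset)
    retained, filter_report = filter_probes(manifest)
    retained = retained.intersection(beta.columns)
    report = {
        "negative_control_percentile": config.negative_control_percentile,
        "quantile_method": "linear interpolation between order statistics",
        "normalization_control_target": config.normalization_control_target,
        "beta_offset": config.beta_offset,
        "background_shifts": shifts,
        "dye_bias_factors": factors,
        "n_samples": len(samples),
    }
    return NormalizedData(
        beta=beta.loc[:, retained],
        meth=meth_df.loc[:, retained],
        unmeth=unmeth_df.loc[:, retained],
        cnv_totals=cnv_totals.loc[:, retained],
        meta=data.meta.loc[samples],
        filter_report=filter_report,
        report=report,
    )
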