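"""Configuration objects for the simulation and analysis pipeline.

All named constants of the analysis live here: normalization targets
(negative-control percentile, normalization-control mean, beta offset),
probe-selection size, t-SNE parameters, copy-number thresholds and the
statistics options.  Every run serializes its effective configuration so
that thresholds are auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "GenomeModel",
    "CNVPlant",
    "ClinicalConfig",
    "SynthConfig",
    "PipelineConfig",
    "default_genome",
    "REFERENCE_CLASSES",
]

#: Methylation reference classes emulated by the generator: the pediatric
#: high-grade-glioma subgroups used as the comparison cohort for
#: radiation-induced gliomas, plus pleomorphic xanthoastrocytoma.
REFERENCE_CLASSES = (
    "pedGBM_RTK1",
    "pedGBM_RTK2",
    "pedGBM_MYCN",
    "DMG_K27",
    "GBM_G34",
    "PXA",
)


@dataclass(frozen=True)
class GenomeModel:
    """Scaled synthetic genome.

    Chromosome lengths are desk-scale (tens of Mb rather than hundreds)
    so that full simulated cohorts run in minutes; every positional
    parameter is configurable.  Arm boundaries split each chromosome at
    ``centromere`` into p ([0, cen)) and q ([cen, length)), 0-based
    half-open.  ``genes`` holds focal-CNV target regions analogous to the
    recurrently altered glioma loci (PDGFRA, CDKN2A/B, MET, CDK4).
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {**{str(c): 10_000_000 for c in range(1, 23)},
                                 "X": 10_000_000, "Y": 5_000_000}
    )
    centromere_frac: float = 0.4
    genes: dict[str, tuple[str, int, int]] = field(
        default_factory=lambda: {
            "PDGFRA": ("4", 4_000_000, 4_200_000),
            "CDKN2A/B": ("9", 1_200_000, 1_400_000),
            "MET": ("7", 7_000_000, 7_200_000),
            "CDK4": ("12", 6_000_000, 6_200_000),
        }
    )

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_lengths if c not in ("X", "Y")]

    def centromere(self, chrom: str) -> int:
        return int(self.chrom_lengths[chrom] * self.centromere_frac)

    def arms(self) -> dict[str, tuple[str, int, int]]:
        """Arm regions (0-based half-open) for all autosomes, e.g. '13q'."""
        out: dict[str, tuple[str, int, int]] = {}
        for chrom in self.autosomes:
            cen = self.centromere(chrom)
            out[f"{chrom}p"] = (chrom, 0, cen)
            out[f"{chrom}q"] = (chrom, cen, self.chrom_lengths[chrom])
        return out


@dataclass(frozen=True)
class CNVPlant:
    """One ground-truth copy-number segment planted into one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid plant interval {self.start}-{self.end}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass
class ClinicalConfig:
    """Clinical-table generator settings.

    Group sizes, tumor locations, latency and survival reflect the
    radiation-induced glioma cohort structure: gliomas after
    medulloblastoma (MB) arise mostly in the cerebellum with short
    survival, gliomas after acute lymphoblastic leukemia (ALL) mostly in
    the cerebral hemispheres.  Survival times are exponential with a
    per-group hazard; censoring is independent exponential.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {"ALL": 9, "MB": 23})
    location_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "ALL": {"hemisphere": 7 / 9, "posterior_fossa": 2 / 9},
            "MB": {"cerebellum": 20 / 23, "hemisphere": 3 / 23},
        }
    )
    #: median overall survival in months per group; hazard = ln2 / median
    median_os_months: dict[str, float] = field(
        default_factory=lambda: {"ALL": 8.5, "MB": 6.0}
    )
    #: fraction of patients whose follow-up ends before the event
    censor_frac: float = 0.2
    latency_median_years: dict[str, float] = field(
        default_factory=lambda: {"ALL": 8.0, "MB": 5.0}
    )
    latency_sigma: float = 0.5
    age_range_years: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ALL": (9.0, 18.0), "MB": (7.0, 40.0)}
    )
    p_male: float = 1.28 / 2.28


@dataclass
class SynthConfig:
    """Synthetic cohort generator settings.

    The defaults encode the study conditions the generator emulates: a
    query cohort of 32 radiation-induced gliomas (29 with a pedGBM_RTK1
    methylation signature, 3 PXA-like) against reference cohorts of 20
    samples for each of six pediatric HGG methylation classes, with
    FFPE/frozen and 450k/EPIC batch structure and recurrent copy-number
    alterations planted at cohort frequencies.
    """

    seed: int = 0
    n_probes: int = 44_000
    n_negative_controls: int = 300   # per channel
    n_normalization_controls: int = 50  # per channel
    frac_xy: float = 0.05
    frac_snp_proximal: float = 0.02
    frac_multi_mapping: float = 0.01
    frac_450k_only: float = 0.04
    frac_epic_only: float = 0.08
    genome: GenomeModel = field(default_factory=GenomeModel)

    ref_class_counts: dict[str, int] = field(
        default_factory=lambda: {c: 20 for c in REFERENCE_CLASSES}
    )
    query_class_counts: dict[str, int] = field(
        default_factory=lambda: {"pedGBM_RTK1": 29, "PXA": 3}
    )
    #: number of signature CpGs per class and their beta shift
    signature_size: int = 300
    signature_delta_beta: float = 0.3
    #: sd of Gaussian noise added on the logit(beta) scale
    noise_sd: float = 0.25
    #: total-intensity model: T ~ 2**Normal(log2(scale), log2_sd)
    intensity_scale: float = 5000.0
    intensity_log2_sd: float = 0.5
    #: relative intensity retained for homozygous deletions (copy number 0)
    zero_cn_floor: float = 0.01
    #: multiplicative batch effects per (grn, red) channel
    material_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"FFPE": (0.80, 0.88), "frozen": (1.0, 1.0)}
    )
    array_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"450k": (1.0, 1.0), "EPIC": (1.20, 1.10)}
    )
    frac_ffpe: float = 0.5
    frac_epic: float = 0.3
    neg_control_scale: float = 30.0
    norm_control_mean: float = 10_000.0
    norm_control_sd: float = 300.0

    cnv_plants: list[CNVPlant] = field(default_factory=list)
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_probes", "n_negative_controls", "n_normalization_controls",
                     "signature_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.signature_delta_beta <= 0.5:
            raise ValueError("signature_delta_beta must keep beta within [0, 1]")

    @property
    def query_sample_ids(self) -> list[str]:
        n = sum(self.query_class_counts.values())
        return [f"RIG_{i + 1:02d}" for i in range(n)]

    @property
    def ref_sample_ids(self) -> list[str]:
        ids = []
        for cls, n in self.ref_class_counts.items():
            ids.extend(f"REF_{cls}_{i + 1:02d}" for i in range(n))
        return ids

    @classmethod
    def default_study(cls, seed: int = 0) -> "SynthConfig":
        """Configuration reproducing the emulated study conditions,
        including the recurrent copy-number alterations planted at their
        cohort frequencies."""
        cfg = cls(seed=seed)
        cfg.cnv_plants = default_cnv_plants(cfg, seed=seed)
        return cfg


# Cohort frequencies of the recurrent alterations: (per-group counts for
# ALL-RIG / MB-RIG where the split matters, otherwise pooled).  Focal
# amplification plants use copy number 8, focal homozygous deletions 0,
# arm-level gains 3 and losses 1.
_FOCAL_PLANT_MARGIN = 300_000  # plants extend this far beyond the gene region


def default_cnv_plants(cfg: SynthConfig, seed: int = 0) -> list[CNVPlant]:
    """Build the default plant list for the 32-sample query cohort.

    PDGFRA amplification in 6/9 ALL-RIG and 11/23 MB-RIG, CDKN2A/B loss
    in 4/9 and 17/23, MET amplification in 9/32, CDK4 amplification in
    5/32; arm-level events: 1q gain 16/32, 1p loss 19/32, 6q loss 18/32,
    13q loss 23/32, 14q loss 16/32.  Which specific samples carry each
    event is drawn (deterministically under the seed) without
    replacement, respecting the per-group counts where they are defined.
    """
    import numpy as np

    queries = cfg.query_sample_ids
    sizes = cfg.clinical.group_sizes
    n_all = sizes.get("ALL", 0)
    all_ids = queries[:n_all]
    mb_ids = queries[n_all:]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    genome = cfg.genome
    arms = genome.arms()

    def pick(pool: list[str], k: int) -> list[str]:
        k = min(k, len(pool))
        return list(rng.choice(pool, size=k, replace=False))

    plants: list[CNVPlant] = []

    def focal(gene: str, samples: list[str], cn: int) -> None:
        chrom, gs, ge = genome.genes[gene]
        start = max(0, gs - _FOCAL_PLANT_MARGIN)
        end = min(genome.chrom_lengths[chrom], ge + _FOCAL_PLANT_MARGIN)
        for s in samples:
            plants.append(CNVPlant(s, chrom, start, end, cn))

    def arm(name: str, samples: list[str], cn: int) -> None:
        chrom, start, end = arms[name]
        for s in samples:
            plants.append(CNVPlant(s, chrom, start, end, cn))

    focal("PDGFRA", pick(all_ids, 6) + pick(mb_ids, 11), 8)
    focal("CDKN2A/B", pick(all_ids, 4) + pick(mb_ids, 17), 0)
    focal("MET", pick(queries, 9), 8)
    focal("CDK4", pick(queries, 5), 8)
    arm("1q", pick(queries, 16), 3)
    arm("1p", pick(queries, 19), 1)
    arm("6q", pick(queries, 18), 1)
    arm("13q", pick(queries, 23), 1)
    arm("14q", pick(queries, 16), 1)
    return plants


@dataclass
class PipelineConfig:
    """End-to-end analysis settings; houses every named constant."""

    seed: int = 42
    # normalization
    negative_control_percentile: float = 5.0
    normalization_control_target: float = 10_000.0
    beta_offset: float = 100.0
    apply_background: bool = True
    apply_dye_bias: bool = True
    apply_batch_adjust: bool = True
    # probe selection / embedding
    n_select_probes: int = 10_000
    tsne_theta: float = 0.0
    tsne_pca: bool = False
    tsne_max_iter: int = 2500
    tsne_perplexity: float = 20.0
    distance_weights: str = "variance"  # variance | uniform
    k_neighbors: int = 5
    # CNV
    bin_width: int = 200_000
    min_probes_per_bin: int = 10
    cnv_epsilon: float = 1.0
    #: None selects a BIC-style adaptive penalty per chromosome
    segment_penalty: float | None = None
    gain_threshold: float = 0.4
    loss_threshold: float = -0.4
    amp_threshold: float = 1.0
    del_threshold: float = -1.0
    arm_threshold: float = 0.15
    arm_min_fraction: float = 0.5
    focal_span_fraction: float = 0.10
    breakpoint_min_delta: float = 0.3
    # statistics
    t_test_variant: str = "welch"  # welch | student
    alpha: float = 0.05
    n_top_genes: int = 100

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_genome() -> GenomeModel:
    return GenomeModel()
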