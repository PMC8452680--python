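"""Seeded generators for synthetic methylation-array cohorts.

The generator emulates the data structures of an Illumina 450k/EPIC
study: a probe manifest with platform membership and filter flags,
per-sample methylated/unmethylated intensities with negative and
normalization control probes, FFPE/frozen and 450k/EPIC batch effects,
planted copy-number segments, and a clinical table.  Every draw is
deterministic under the configured seed, and full ground truth (class
labels, signature probes, true copy-number segments, batch assignments,
pre-batch total intensities) is returned for downstream recovery tests.

Model sketch
------------
For probe p with baseline methylation fraction b_p (bimodal across
probes) and sample s of class c:

    beta*_sp   = b_p shifted by +/- delta at c's signature probes
    beta_sp    = expit(logit(beta*_sp) + eps),  eps ~ N(0, sigma^2)
    T_sp       = 2**N(log2(scale), tau) * max(cn_sp, floor) / 2
    M_sp, U_sp = beta_sp * T_sp, (1 - beta_sp) * T_sp

followed by multiplicative batch factors per color channel: the tissue
material (FFPE/frozen) factor applies to query probes only, the array
(450k/EPIC) factor also shifts the normalization-control channel means,
so dye-bias correction removes the array scale while the material effect
is left for the linear batch model.  Copy number cn_sp enters the total
intensity, never beta, keeping the methylation and copy-number channels
separable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ClinicalConfig, CNVPlant, SynthConfig

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityData",
    "SimulationTruth",
    "make_manifest",
    "simulate_cohort",
    "simulate_clinical",
]

MANIFEST_COLUMNS = [
    "chrom", "pos", "on_450k", "on_epic",
    "snp_proximal", "multi_mapping", "control_type", "channel",
]


@dataclass
class IntensityData:
    """Raw (or corrected) array intensities for a cohort.

    ``meth`` / ``unmeth`` are samples x probes DataFrames; ``controls``
    is a long table with one row per (sample, control probe) carrying
    ``control_type`` (negative | normalization), ``channel`` (grn | red)
    and ``intensity``; ``meta`` is indexed by sample id with ``material``
    and ``array`` columns.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    controls: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index):
            raise ValueError("meth/unmeth sample sets differ")
        if not self.meth.columns.equals(self.unmeth.columns):
            raise ValueError("meth/unmeth probe sets differ")
        missing = self.meth.index.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"metadata missing for samples: {list(missing)[:5]}")
        for name, m in (("meth", self.meth), ("unmeth", self.unmeth)):
            arr = m.to_numpy()
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{name} intensities must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.index)

    def copy(self) -> "IntensityData":
        return IntensityData(self.meth.copy(), self.unmeth.copy(),
                             self.controls.copy(), self.meta.copy())

    def subset_probes(self, probe_ids) -> "IntensityData":
        return IntensityData(self.meth.loc[:, probe_ids],
                             self.unmeth.loc[:, probe_ids],
                             self.controls, self.meta)


@dataclass
class SimulationTruth:
    """Ground-truth ledger for one simulated cohort."""

    labels: pd.Series                      # sample_id -> class label
    roles: pd.Series                       # sample_id -> reference | query
    segments: dict[str, list[CNVPlant]]    # sample_id -> planted segments
    batch: pd.DataFrame                    # sample_id -> material, array
    signatures: dict[str, pd.DataFrame]    # class -> probe_id, direction, target beta
    baseline_beta: pd.Series               # probe_id -> baseline fraction
    total_intensity: pd.DataFrame = field(default=None, repr=False)  # pre-batch T


def _place_uniform(rng: np.random.Generator, chroms: list[str],
                   lengths: dict[str, int], n: int) -> tuple[np.ndarray, np.ndarray]:
    """Place n probes uniformly along the given chromosomes (length-weighted)."""
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    idx = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    pos = (rng.random(n) * sizes[idx]).astype(np.int64) + 1  # 1-based
    return np.array(chroms, dtype=object)[idx], pos


def make_manifest(config: SynthConfig) -> pd.DataFrame:
    """Generate a probe manifest with platform membership and filter flags.

    Returns a DataFrame indexed by probe_id with columns chrom, pos
    (1-based), on_450k, on_epic, snp_proximal, multi_mapping,
    control_type, channel.  Query probes are placed uniformly along the
    declared chromosomes; flag fractions follow the configured
    proportions in expectation.
    """
    if config.n_probes <= 0:
        raise ValueError("n_probes must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    g = config.genome
    n = config.n_probes

    on_xy = rng.random(n) < config.frac_xy
    n_xy = int(on_xy.sum())
    chrom = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    xy = [c for c in ("X", "Y") if c in g.chrom_lengths]
    auto = g.autosomes
    if n_xy and xy:
        chrom[on_xy], pos[on_xy] = _place_uniform(rng, xy, g.chrom_lengths, n_xy)
    else:
        on_xy[:] = False
    chrom[~on_xy], pos[~on_xy] = _place_uniform(rng, auto, g.chrom_lengths,
                                                int((~on_xy).sum()))

    platform_draw = rng.random(n)
    on_450k = platform_draw >= config.frac_epic_only
    on_epic = ~((platform_draw >= config.frac_epic_only)
                & (platform_draw < config.frac_epic_only + config.frac_450k_only))
    snp = rng.random(n) < config.frac_snp_proximal
    multi = rng.random(n) < config.frac_multi_mapping

    probe_ids = [f"cg{i:08d}" for i in range(n)]
    manifest = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "on_450k": on_450k, "on_epic": on_epic,
        "snp_proximal": snp, "multi_mapping": multi,
        "control_type": "none", "channel": "",
    }, index=pd.Index(probe_ids, name="probe_id"))

    rows = []
    for ctype, count, prefix in (
        ("negative", config.n_negative_controls, "neg"),
        ("normalization", config.n_normalization_controls, "norm"),
    ):
        for channel in ("grn", "red"):
            for i in range(count):
                rows.append((f"ctl_{prefix}_{channel}_{i:04d}", ctype, channel))
    if rows:
        ctl = pd.DataFrame({
            "chrom": "1", "pos": 1, "on_450k": True, "on_epic": True,
            "snp_proximal": False, "multi_mapping": False,
            "control_type": [r[1] for r in rows],
            "channel": [r[2] for r in rows],
        }, index=pd.Index([r[0] for r in rows], name="probe_id"))
        manifest = pd.concat([manifest, ctl])
    return manifest[MANIFEST_COLUMNS]


def query_probes(manifest: pd.DataFrame) -> pd.DataFrame:
    """Non-control probes of a manifest (the query probe universe)."""
    return manifest[manifest["control_type"] == "none"]


def _signature_sets(rng: np.random.Generator, manifest: pd.DataFrame,
                    classes: list[str], m: int, delta: float,
                    ) -> dict[str, pd.DataFrame]:
    """Pick disjoint per-class signature probe sets among 'clean' probes
    (autosomal, both platforms, unflagged), so signatures survive probe
    filtering.  Half of each signature is hyper-, half hypomethylated."""
    q = query_probes(manifest)
    clean = q[q["on_450k"] & q["on_epic"] & ~q["snp_proximal"]
              & ~q["multi_mapping"] & ~q["chrom"].isin(["X", "Y"])]
    need = m * len(classes)
    if need > len(clean):
        raise ValueError(f"not enough clean probes for signatures "
                         f"({need} needed, {len(clean)} available)")
    chosen = rng.choice(clean.index.to_numpy(), size=need, replace=False)
    out = {}
    for i, cls in enumerate(classes):
        ids = chosen[i * m:(i + 1) * m]
        direction = np.where(np.arange(m) % 2 == 0, 1, -1)
        out[cls] = pd.DataFrame({
            "probe_id": ids,
            "direction": direction,
            "target_beta": 0.5 + direction * delta,
        })
    return out


def simulate_cohort(config: SynthConfig, manifest: pd.DataFrame,
                    ) -> tuple[IntensityData, SimulationTruth]:
    """Simulate reference and query intensity cohorts with ground truth.

    Reference samples (per ``ref_class_counts``) are copy-number neutral;
    query samples (per ``query_class_counts``) additionally carry the
    configured ``cnv_plants``.  See the module docstring for the
    generative model.
    """
    g = config.genome
    for plant in config.cnv_plants:
        if plant.chrom not in g.chrom_lengths:
            raise ValueError(f"CNV plant on unknown chromosome {plant.chrom!r}")
        if plant.end > g.chrom_lengths[plant.chrom]:
            raise ValueError(
                f"CNV plant {plant.chrom}:{plant.start}-{plant.end} outside "
                f"chromosome bounds (length {g.chrom_lengths[plant.chrom]})")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    q = query_probes(manifest)
    probe_ids = q.index
    n_probes = len(probe_ids)

    # sample roster: references then queries
    sample_ids, labels, roles = [], [], []
    for cls, count in config.ref_class_counts.items():
        for i in range(count):
            sample_ids.append(f"REF_{cls}_{i + 1:02d}")
            labels.append(cls)
            roles.append("reference")
    qids = config.query_sample_ids
    k = 0
    for cls, count in config.query_class_counts.items():
        for _ in range(count):
            sample_ids.append(qids[k])
            labels.append(cls)
            roles.append("query")
            k += 1
    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ValueError("no samples requested")
    labels = pd.Series(labels, index=sample_ids, name="class")
    roles = pd.Series(roles, index=sample_ids, name="role")

    # verify planted segments do not overlap within a sample
    seg_by_sample: dict[str, list[CNVPlant]] = {s: [] for s in sample_ids}
    for plant in config.cnv_plants:
        if plant.sample_id not in seg_by_sample:
            raise ValueError(f"CNV plant for unknown sample {plant.sample_id!r}")
        seg_by_sample[plant.sample_id].append(plant)
    for s, segs in seg_by_sample.items():
        segs.sort(key=lambda p: (p.chrom, p.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(f"overlapping CNV plants in sample {s}")

    # baseline betas: bimodal across probes
    comp = rng.random(n_probes) < 0.5
    baseline = np.where(comp, rng.beta(2.0, 12.0, n_probes),
                        rng.beta(12.0, 2.0, n_probes))
    baseline = np.clip(baseline, 1e-3, 1 - 1e-3)

    classes = sorted(set(config.ref_class_counts) | set(config.query_class_counts))
    signatures = _signature_sets(rng, manifest, classes, config.signature_size,
                                 config.signature_delta_beta)
    col_pos = pd.Series(np.arange(n_probes), index=probe_ids)

    # signature probes sit at a mid-range baseline (0.5) for every sample;
    # only members of the owning class are shifted by +/- delta, so a zero
    # shift makes all classes exchangeable
    for sig in signatures.values():
        baseline[col_pos[sig["probe_id"].to_numpy()].to_numpy()] = 0.5
    mean_beta = np.tile(baseline, (n_samples, 1))
    for cls, sig in signatures.items():
        rows = np.flatnonzero(labels.to_numpy() == cls)
        if len(rows) == 0:
            continue
        cols = col_pos[sig["probe_id"].to_numpy()].to_numpy()
        mean_beta[np.ix_(rows, cols)] = sig["target_beta"].to_numpy()

    noise = rng.normal(0.0, config.noise_sd, size=(n_samples, n_probes))
    beta = expit(logit(mean_beta) + noise)

    # copy-number factor on total intensity
    cn_factor = np.ones((n_samples, n_probes))
    pos = q["pos"].to_numpy()
    chrom_arr = q["chrom"].to_numpy()
    row_pos = {s: i for i, s in enumerate(sample_ids)}
    for s, segs in seg_by_sample.items():
        for plant in segs:
            mask = ((chrom_arr == plant.chrom) & (pos - 1 >= plant.start)
                    & (pos - 1 < plant.end))
            factor = max(plant.copy_number, 0) / 2.0
            if plant.copy_number == 0:
                factor = config.zero_cn_floor
            cn_factor[row_pos[s], mask] = factor

    total = (2.0 ** rng.normal(np.log2(config.intensity_scale),
                               config.intensity_log2_sd,
                               size=(n_samples, n_probes))) * cn_factor
    meth = beta * total
    unmeth = (1.0 - beta) * total

    # batch assignment and multiplicative effects per channel
    material = np.where(rng.random(n_samples) < config.frac_ffpe, "FFPE", "frozen")
    array = np.where(rng.random(n_samples) < config.frac_epic, "EPIC", "450k")
    meta = pd.DataFrame({"material": material, "array": array}, index=sample_ids)
    f_grn = np.array([config.material_effects[m][0] * config.array_effects[a][0]
                      for m, a in zip(material, array)])
    f_red = np.array([config.material_effects[m][1] * config.array_effects[a][1]
                      for m, a in zip(material, array)])
    meth_obs = meth * f_grn[:, None]
    unmeth_obs = unmeth * f_red[:, None]

    # control probes: negatives near zero, normalization controls with
    # array-dependent channel means (material degradation does not touch
    # the control oligos)
    ctl = manifest[manifest["control_type"] != "none"]
    rows = []
    for si, s in enumerate(sample_ids):
        a_grn, a_red = config.array_effects[array[si]]
        for (ctype, channel), grp in ctl.groupby(["control_type", "channel"],
                                                 sort=True):
            k_ctl = len(grp)
            if ctype == "negative":
                vals = np.abs(rng.normal(0.0, config.neg_control_scale, k_ctl))
            else:
                chan_f = a_grn if channel == "grn" else a_red
                vals = np.clip(rng.normal(config.norm_control_mean * chan_f,
                                          config.norm_control_sd, k_ctl), 1.0, None)
            rows.append(pd.DataFrame({
                "sample_id": s, "probe_id": grp.index, "control_type": ctype,
                "channel": channel, "intensity": vals,
            }))
    controls = (pd.concat(rows, ignore_index=True) if rows
                else pd.DataFrame(columns=["sample_id", "probe_id",
                                           "control_type", "channel", "intensity"]))

    data = IntensityData(
        meth=pd.DataFrame(meth_obs, index=sample_ids, columns=probe_ids),
        unmeth=pd.DataFrame(unmeth_obs, index=sample_ids, columns=probe_ids),
        controls=controls,
        meta=meta,
    )
    truth = SimulationTruth(
        labels=labels, roles=roles, segments=seg_by_sample, batch=meta.copy(),
        signatures=signatures,
        baseline_beta=pd.Series(baseline, index=probe_ids, name="baseline_beta"),
        total_intensity=pd.DataFrame(total, index=sample_ids, columns=probe_ids),
    )
    return data, truth


def simulate_clinical(config: SynthConfig) -> pd.DataFrame:
    """Simulate the per-patient clinical table for the query cohort.

    Columns: patient_id, primary_disease, location, sex, age_years,
    latency_years, os_months, event.  Survival is exponential with
    hazard ln2/median per group; censoring is an independent exponential
    clock calibrated so that a fraction ``censor_frac`` of patients are
    censored in expectation.
    """
    cc = config.clinical
    for grp, probs in cc.location_probs.items():
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"location probabilities for {grp!r} sum to {total}")
    for grp, med in cc.median_os_months.items():
        if med <= 0:
            raise ValueError(f"median OS for {grp!r} must be > 0")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    qids = config.query_sample_ids
    rows = []
    i = 0
    for grp, size in cc.group_sizes.items():
        hazard = np.log(2.0) / cc.median_os_months[grp]
        # P(censor before event) = ch / (ch + h)  for competing exponentials
        c = cc.censor_frac
        censor_hazard = hazard * c / (1.0 - c) if c > 0 else 0.0
        locs = list(cc.location_probs[grp])
        loc_p = np.array([cc.location_probs[grp][l] for l in locs])
        lo, hi = cc.age_range_years[grp]
        for _ in range(size):
            pid = qids[i] if i < len(qids) else f"RIG_{i + 1:02d}"
            i += 1
            event_t = rng.exponential(1.0 / hazard)
            censor_t = (rng.exponential(1.0 / censor_hazard)
                        if censor_hazard > 0 else np.inf)
            rows.append({
                "patient_id": pid,
                "primary_disease": grp,
                "location": locs[rng.choice(len(locs), p=loc_p)],
                "sex": "M" if rng.random() < cc.p_male else "F",
                "age_years": rng.uniform(lo, hi),
                "latency_years": float(np.exp(rng.normal(
                    np.log(cc.latency_median_years[grp]), cc.latency_sigma))),
                "os_months": float(min(event_t, censor_t)),
                "event": bool(event_t <= censor_t),
            })
    return pd.DataFrame(rows)
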