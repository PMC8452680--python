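"""One-call reproduction of the emulated cohort study.

Simulates the default study conditions (32-sample query cohort against
six 20-sample reference classes, with recurrent copy-number alterations
planted at their cohort frequencies), runs normalization, nearest-
reference classification and the copy-number pipeline, and returns the
per-sample results next to the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classify, cnv, preprocess, synth
from .config import PipelineConfig, SynthConfig


@dataclass
class StudyResult:
    config: SynthConfig
    truth: synth.SimulationTruth
    normalized: preprocess.NormalizedData
    assignments: list[classify.ClassAssignment]
    profiles: dict[str, cnv.CNVProfile]
    clinical: pd.DataFrame

    @property
    def assigned_labels(self) -> pd.Series:
        return pd.Series({a.sample_id: a.label for a in self.assignments})

    def call_matrix(self) -> pd.DataFrame:
        rows = {sid: {c.target: c.status for c in p.calls}
                for sid, p in self.profiles.items()}
        return pd.DataFrame(rows).T.sort_index()

    def breakpoint_counts(self) -> pd.Series:
        return pd.Series({sid: p.breakpoint_count
                          for sid, p in self.profiles.items()}).sort_index()


def run_study(seed: int = 0, synth_config: SynthConfig | None = None,
              pipeline_config: PipelineConfig | None = None) -> StudyResult:
    """Simulate the default study cohort and run the full analysis."""
    cfg = synth_config or SynthConfig.default_study(seed=seed)
    pc = pipeline_config or PipelineConfig(seed=seed)
    manifest = synth.make_manifest(cfg)
    data, truth = synth.simulate_cohort(cfg, manifest)
    norm = preprocess.normalize(data, manifest, pc)

    roles = truth.roles
    refs = roles[roles == "reference"].index
    queries = roles[roles == "query"].index
    probes = classify.select_probes(norm.beta, pc.n_select_probes)
    sub = norm.beta.loc[:, probes]
    assignments = classify.assign_class(sub.loc[queries], sub.loc[refs],
                                        truth.labels, k=pc.k_neighbors,
                                        weights=pc.distance_weights)

    g = cfg.genome
    bins = cnv.bin_genome(manifest, norm.beta.columns, pc.bin_width,
                          pc.min_probes_per_bin, g.chrom_lengths)
    genes = pd.DataFrame([{"chrom": c, "start": s, "end": e, "name": n}
                          for n, (c, s, e) in g.genes.items()])
    profiles = cnv.profile_cohort(norm.cnv_totals.loc[queries],
                                  norm.cnv_totals.loc[refs],
                                  bins, genes, g.arms(), g.chrom_lengths, pc)
    clinical = synth.simulate_clinical(cfg)
    return StudyResult(config=cfg, truth=truth, normalized=norm,
                       assignments=assignments, profiles=profiles,
                       clinical=clinical)
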