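"""End-to-end orchestration over cohorts of fields, plus cohort statistics.

A cohort is a set of animals, each with a genotype label and a number of
fields (images). Each field is simulated (or loaded), nuclei are
segmented, foci detected and compartmented, and sarcoplasmic 5'↔3'
nearest-neighbour pairing summarized; the per-field rows form a tidy
cohort table. Group comparisons use two-tailed Mann-Whitney U tests on
per-animal means (never per-image values, which would inflate n), and
correlations use Pearson r or Spearman's rho on per-image metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import FieldSummary, compartment_counts
from .coloc import nearest_neighbor_distances
from .detect import segment_nuclei
from .synthetic import SceneConfig, generate_field

SIGNIFICANCE = 0.05


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage is named in the message."""


@dataclass(frozen=True)
class AnimalConfig:
    animal_id: str
    genotype: str
    scene: SceneConfig
    n_fields: int = 3


@dataclass(frozen=True)
class CohortConfig:
    animals: tuple
    seed: int = 0
    nuclear_algorithm: str = "huang"
    threshold: object = "auto"
    pairing_radius_um: float = 1.0


@dataclass
class PipelineResult:
    table: pd.DataFrame
    summaries: dict = field(default_factory=dict)   # (animal_id, field) -> FieldSummary


def _field_seed(base: int, animal_index: int, field_index: int) -> int:
    return int((base * 100_003 + animal_index * 1_009 + field_index) % 2**31)


def _field_row(animal: AnimalConfig, summary: FieldSummary,
               pairing_radius_um: float) -> dict:
    c = summary.count
    row = dict(
        nuclei=summary.nuclei_count,
        fraction_expressing_nuclei=summary.fraction_expressing_nuclei,
    )
    for channel in ("5p", "3p"):
        for size_class in ("small", "large"):
            row[f"{size_class}_{channel}_total"] = c(channel, size_class, "total")
            row[f"{size_class}_{channel}_nuclear"] = c(channel, size_class, "nuclear")
            row[f"{size_class}_{channel}_sarcoplasmic"] = c(
                channel, size_class, "sarcoplasmic")
    # sarcoplasmic small-focus pairing, pooled over both directions
    src = [f.centroid_um for f in summary.foci[("5p", "sarcoplasmic")]
           if f.size_class == "small"]
    tgt = [f.centroid_um for f in summary.foci[("3p", "sarcoplasmic")]
           if f.size_class == "small"]
    if src and tgt:
        d53 = nearest_neighbor_distances(src, tgt, "5p_to_3p").distances_um
        d35 = nearest_neighbor_distances(tgt, src, "3p_to_5p").distances_um
        pooled = np.concatenate([d53, d35])
        row["frac_paired_within_r"] = float(np.mean(pooled <= pairing_radius_um))
        row["frac_beyond_30um"] = float(np.mean(pooled > 30.0))
    else:
        row["frac_paired_within_r"] = np.nan
        row["frac_beyond_30um"] = np.nan
    return row


def run_pipeline(config: CohortConfig) -> PipelineResult:
    """Simulate → segment → detect → compartment → pair, per field.

    Fully reproducible from the config: every field's scene seed is
    derived from the cohort seed, the animal index and the field index.
    """
    if not config.animals:
        raise ValueError("cohort is empty")
    rows = []
    summaries = {}
    for ai, animal in enumerate(config.animals):
        for fi in range(animal.n_fields):
            scene = replace(animal.scene,
                            seed=_field_seed(config.seed, ai, fi))
            try:
                sim = generate_field(scene)
            except Exception as exc:           # noqa: BLE001 - stage naming
                raise PipelineStageError(
                    f"simulate failed for {animal.animal_id} field {fi}: {exc}"
                ) from exc
            try:
                mask = segment_nuclei(sim.images["dapi"],
                                      config.nuclear_algorithm)
            except Exception as exc:           # noqa: BLE001
                raise PipelineStageError(
                    f"segment failed for {animal.animal_id} field {fi}: {exc}"
                ) from exc
            try:
                summary = compartment_counts(
                    {"5p": sim.images["5p"], "3p": sim.images["3p"]},
                    mask, scene.geometry, threshold=config.threshold)
            except Exception as exc:           # noqa: BLE001
                raise PipelineStageError(
                    f"detect/compartment failed for {animal.animal_id} "
                    f"field {fi}: {exc}") from exc
            row = dict(animal_id=animal.animal_id, genotype=animal.genotype,
                       field=fi)
            row.update(_field_row(animal, summary, config.pairing_radius_um))
            rows.append(row)
            summaries[(animal.animal_id, fi)] = summary
    return PipelineResult(table=pd.DataFrame(rows), summaries=summaries)


def per_animal_means(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mean of a per-image metric per animal, keeping the genotype label."""
    return (table.groupby(["genotype", "animal_id"], as_index=False)[metric]
            .mean())


def compare_cohorts(table: pd.DataFrame, metric: str,
                    groups: tuple[str, str] = ("wt", "mdx")) -> dict:
    """Two-tailed Mann-Whitney U on per-animal means of ``metric``."""
    means = per_animal_means(table, metric)
    a = means.loc[means.genotype == groups[0], metric].to_numpy()
    b = means.loc[means.genotype == groups[1], metric].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 per-animal means in each group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return dict(statistic=float(res.statistic), pvalue=float(res.pvalue),
                significant=bool(res.pvalue < SIGNIFICANCE),
                group_means={groups[0]: float(a.mean()),
                             groups[1]: float(b.mean())})


def correlate(table: pd.DataFrame, x_metric: str, y_metric: str,
              method: str = "pearson") -> tuple[float, float]:
    """Correlation of two per-image metrics (Pearson r or Spearman rho)."""
    sub = table[[x_metric, y_metric]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired observations")
    x = sub[x_metric].to_numpy(dtype=float)
    y = sub[y_metric].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no defined correlation")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)
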