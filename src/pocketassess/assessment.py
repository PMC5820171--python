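"""Ensemble assessment: site scores per model, z-scoring, ranking,
functional-vs-structural correlation, filtering, and exposure metrics.

Two evaluation modes mirror how prediction ensembles are assessed:
``all_models`` treats every submitted model of every source as an
independent prediction, ``model_1`` restricts to each source's
self-declared best model (model_index 1). PF z-scores are computed within
the selected set with the population standard deviation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .microenvironment import (BackgroundStats, Featurizer, FeatureVector,
                               build_background)
from .site_compare import (DEFAULT_CUTOFF, SiteDefinition, align_sites,
                           centers_from_residues)
from .structural_metrics import compute_scores
from .structure_io import StructureModel, resolve_selection

__all__ = [
    "AssessmentRecord",
    "CorrelationReport",
    "VariantMetrics",
    "AssessConfig",
    "featurize_site",
    "score_ensemble",
    "zscore_records",
    "rank_by",
    "spearman",
    "filter_models_by_rmsd",
    "top_k",
    "classify_exposure",
    "variant_site_metrics",
    "aggregate_patches",
]

logger = logging.getLogger(__name__)

BURIED_MAX = 0.09
EXPOSED_MIN = 0.36


@dataclass
class AssessmentRecord:
    target_id: str
    site_id: str
    source_id: str
    model_index: int
    pf_score: float
    gdt_ts: float
    tm: float
    rmsd_global: float
    rmsd_local: float
    n_matched: int = 0
    pf_zscore: float | None = None
    rank_functional: int | None = None
    rank_structural: int | None = None


@dataclass
class CorrelationReport:
    site_id: str
    mode: str
    coefficient: float
    n_models: int


@dataclass
class VariantMetrics:
    relacc_std: float
    acc_err: float
    frac_ss_correct: float
    frac_exposure_correct: float


@dataclass
class AssessConfig:
    cutoff: float = DEFAULT_CUTOFF
    max_missing_fraction: float = 0.5
    min_site_centers: int = 3


def featurize_site(structure: StructureModel, site: SiteDefinition,
                   featurizer: Featurizer) -> tuple[list[FeatureVector], list]:
    """Resolve, map to centers, and featurize a site on one structure.

    Returns the feature vectors (one per resolvable center) and the list
    of selectors/residues that could not be realized.
    """
    residues, missing_sel = resolve_selection(structure, site.selectors)
    centers, missing_res = centers_from_residues(structure, residues)
    annotated = featurizer.annotate(structure)
    vectors = [
        featurizer.featurize_center(annotated, c.center, label=c.label,
                                    chem_class=c.chem_class)
        for c in centers
    ]
    return vectors, list(missing_sel) + [r.key for r in missing_res]


def background_from_structures(structures: Sequence[StructureModel],
                               featurizer: Featurizer | None = None,
                               n_pairs: int = 200, seed: int = 0) -> BackgroundStats:
    """Calibrate a background from every residue center of the given pool.

    Pass the reference plus a handful of decoys so each chemistry class is
    represented by several distinct microenvironments.
    """
    featurizer = featurizer or Featurizer()
    vectors: list[FeatureVector] = []
    for structure in structures:
        centers, _ = centers_from_residues(structure, structure.residues)
        annotated = featurizer.annotate(structure)
        vectors.extend(
            featurizer.featurize_center(annotated, c.center, label=c.label,
                                        chem_class=c.chem_class)
            for c in centers)
    return build_background(vectors, n_pairs=n_pairs, seed=seed)


def score_ensemble(reference: StructureModel, site: SiteDefinition,
                   models: Sequence[StructureModel], bg: BackgroundStats,
                   config: AssessConfig | None = None,
                   featurizer: Featurizer | None = None,
                   ) -> tuple[list[AssessmentRecord], list[str]]:
    """Score every model of an ensemble against the reference site.

    pf_score is the total alignment score of the reference site vs the
    model site. Models missing more than ``max_missing_fraction`` of the
    site centers are excluded and reported (second return value).
    """
    config = config or AssessConfig()
    featurizer = featurizer or Featurizer()
    ref_vectors, ref_missing = featurize_site(reference, site, featurizer)
    if ref_missing:
        raise ValueError(f"site not fully resolvable in reference: {ref_missing}")
    n_site = len(ref_vectors)

    records: list[AssessmentRecord] = []
    excluded: list[str] = []
    for model in models:
        vectors, _ = featurize_site(model, site, featurizer)
        tag = f"{model.source_id}#{model.model_index}"
        if len(vectors) < max(config.min_site_centers,
                              int(np.ceil((1 - config.max_missing_fraction) * n_site))):
            excluded.append(tag)
            logger.warning("excluding %s: %d/%d site centers resolvable",
                           tag, len(vectors), n_site)
            continue
        aln = align_sites(ref_vectors, vectors, bg, cutoff=config.cutoff)
        scores = compute_scores(model, reference, site)
        records.append(AssessmentRecord(
            target_id=site.target_id, site_id=site.site_id,
            source_id=model.source_id, model_index=model.model_index,
            pf_score=aln.total_score, n_matched=aln.n_matched,
            gdt_ts=scores.gdt_ts, tm=scores.tm,
            rmsd_global=scores.rmsd_global, rmsd_local=scores.rmsd_local,
        ))
    if not records:
        raise ValueError("no model retains enough site centers to score")
    logger.info("scored %d models (%d excluded) for site %s",
                len(records), len(excluded), site.site_id)
    return records, excluded


def _population_zscores(values: np.ndarray) -> np.ndarray:
    mean = values.mean()
    std = values.std()  # population (ddof=0), matching scipy.stats.zscore
    if std == 0:
        raise ValueError("all scores identical: z-scores undefined")
    return (values - mean) / std


def zscore_records(records: Sequence[AssessmentRecord],
                   mode: str = "all_models") -> list[AssessmentRecord]:
    """Attach pf_zscore within the mode's selection; returns new records."""
    if mode == "all_models":
        selected = list(records)
    elif mode == "model_1":
        selected = [r for r in records if r.model_index == 1]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(selected) < 3:
        raise ValueError(f"mode {mode!r} selects {len(selected)} records; need >= 3")
    z = _population_zscores(np.array([r.pf_score for r in selected]))
    return [dataclasses.replace(r, pf_zscore=float(zi)) for r, zi in zip(selected, z)]


_RANK_FIELD = {
    "pf_score": "rank_functional",
    "pf_zscore": "rank_functional",
    "gdt_ts": "rank_structural",
    "tm": "rank_structural",
    "rmsd_global": "rank_structural",
    "rmsd_local": "rank_structural",
}
# default sort direction per key: 'asc' ranks the smallest value 1
_RANK_DIRECTION = {
    "pf_score": "asc", "pf_zscore": "asc",
    "gdt_ts": "desc", "tm": "desc",
    "rmsd_global": "asc", "rmsd_local": "asc",
}


def rank_by(records: Sequence[AssessmentRecord], key: str,
            direction: str | None = None) -> list[AssessmentRecord]:
    """Dense ranks 1..N by ``key``; ties broken by (source_id, model_index).

    Returns new records (inputs are not mutated) carrying the rank in
    ``rank_functional`` or ``rank_structural`` depending on the key.
    """
    direction = direction or _RANK_DIRECTION.get(key, "asc")
    sign = 1.0 if direction == "asc" else -1.0
    field = _RANK_FIELD.get(key, "rank_functional")
    order = sorted(
        range(len(records)),
        key=lambda i: (sign * getattr(records[i], key),
                       records[i].source_id, records[i].model_index),
    )
    out = [dataclasses.replace(r) for r in records]
    for rank, i in enumerate(order, start=1):
        setattr(out[i], field, rank)
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average-tie ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero rank variance")
    return float(np.corrcoef(rx, ry)[0, 1])


def filter_models_by_rmsd(records: Sequence[AssessmentRecord],
                          max_rmsd: float = 5.0, min_count: int = 10
                          ) -> tuple[list[AssessmentRecord], dict]:
    """Keep records with rmsd_global <= max_rmsd (boundary inclusive).

    The site is eligible only when strictly more than ``min_count`` models
    survive; otherwise the kept list is empty and the report says why.
    """
    kept = [r for r in records if r.rmsd_global <= max_rmsd]
    eligible = len(kept) > min_count
    report = {"n_input": len(records), "n_within": len(kept),
              "eligible": eligible, "max_rmsd": max_rmsd, "min_count": min_count}
    return (list(kept) if eligible else []), report


def top_k(records: Sequence[AssessmentRecord], k: int = 30,
          key: str = "pf_zscore") -> list[AssessmentRecord]:
    """First k records by key (most negative first); no padding."""
    order = sorted(records, key=lambda r: (getattr(r, key), r.source_id, r.model_index))
    return order[:k]


def classify_exposure(relacc: float) -> str:
    """buried (< 0.09) / intermediate (0.09 <= RelAcc < 0.36) / exposed (>= 0.36)."""
    if relacc < 0:
        raise ValueError("relative accessibility must be non-negative")
    if relacc < BURIED_MAX:
        return "buried"
    if relacc < EXPOSED_MIN:
        return "intermediate"
    return "exposed"


def variant_site_metrics(predicted_relacc: np.ndarray, predicted_ss: np.ndarray,
                         reference_relacc: np.ndarray, reference_ss: np.ndarray
                         ) -> VariantMetrics:
    """Accuracy of per-residue accessibility/secondary-structure predictions.

    ``predicted_*`` arrays are (n_models, n_residues); reference arrays are
    (n_residues,). relacc_std averages the across-model population std per
    residue; acc_err is the RMSD of predicted vs reference RelAcc pooled
    over all (residue, model) pairs.
    """
    pred = np.asarray(predicted_relacc, dtype=float)
    pss = np.asarray(predicted_ss)
    ref = np.asarray(reference_relacc, dtype=float)
    rss = np.asarray(reference_ss)
    if pred.ndim != 2 or pred.shape[1] != ref.size or pss.shape != pred.shape \
            or rss.size != ref.size:
        raise ValueError("array shapes do not line up")
    if pred.shape[0] < 2:
        raise ValueError("need at least 2 models for the std metric")
    relacc_std = float(pred.std(axis=0).mean())
    acc_err = float(np.sqrt(np.mean((pred - ref[None, :]) ** 2)))
    frac_ss = float(np.mean(pss == rss[None, :]))
    ref_cls = np.array([classify_exposure(v) for v in ref])
    pred_cls = np.array([[classify_exposure(v) for v in row] for row in pred])
    frac_exp = float(np.mean(pred_cls == ref_cls[None, :]))
    return VariantMetrics(relacc_std=relacc_std, acc_err=acc_err,
                          frac_ss_correct=frac_ss, frac_exposure_correct=frac_exp)


def aggregate_patches(records: Sequence[AssessmentRecord]
                      ) -> dict[tuple[str, str, int], float]:
    """Mean pf_zscore over a target's patches, per (target, source, model)."""
    groups: dict[tuple[str, str, int], list[float]] = {}
    for r in records:
        if r.pf_zscore is None:
            raise ValueError("records must carry pf_zscore before aggregation")
        groups.setdefault((r.target_id, r.source_id, r.model_index), []).append(r.pf_zscore)
    return {k: float(np.mean(v)) for k, v in groups.items()}
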