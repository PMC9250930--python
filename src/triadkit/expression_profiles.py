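"""Triad expression-bias analysis and tissue-specificity calling.

A triad's expression in a tissue is summarised by the normalized homoeolog
fractions (f_A, f_B, f_D) on the 2-simplex.  Each retained (triad, tissue)
pair is assigned the nearest of seven category centroids by Euclidean
distance:

========================  =====================
Balanced                  (1/3, 1/3, 1/3)
A/B/D dominant            (1,0,0) / (0,1,0) / (0,0,1)
A/B/D suppressed          (0,1/2,1/2) / (1/2,0,1/2) / (1/2,1/2,0)
========================  =====================

The centroid coordinates follow the standard polyploid expression-bias
methodology for wheat triads (the suppressed centroids put the suppressed
subgenome at zero and split the remainder equally); this is the one imported
assumption of the module and the classification is otherwise pure geometry.

Triads whose summed expression in a tissue falls below 1 TPM are excluded
before normalization (optionally the filter can be applied per homoeolog
instead of to the sum).  Stages and cultivars are aggregated by maximum TPM
before any per-tissue computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import ExpressionRecord, TISSUES
from .homoeolog_map import HomoeologGroup
from .synthetic_data import CENTROIDS, BIAS_CATEGORIES

logger = logging.getLogger("triadkit")

#: Tissue classes used for specificity calling: roots, leaves/shoots, and
#: the reproductive spike+grain pool.
TISSUE_CLASSES: dict[str, tuple[str, ...]] = {
    "root": ("root",),
    "leaf_shoot": ("leaf_shoot",),
    "spike_grain": ("spike", "grain"),
}

SPECIFICITY_CALLS = ("root_specific", "leaf_shoot_specific",
                     "spike_grain_specific", "ubiquitous", "not_expressed")

_CENTROID_MATRIX = np.array([CENTROIDS[c] for c in BIAS_CATEGORIES])


@dataclass(frozen=True)
class TriadExpressionProfile:
    """A classified (triad, tissue) expression point."""

    group: HomoeologGroup
    tissue: str
    tpm: tuple[float, float, float]
    fractions: tuple[float, float, float]
    category: str
    distances: tuple[float, ...]


@dataclass(frozen=True)
class TissueSpecificityCall:
    gene_id: str
    call: str
    max_tpm: tuple[float, ...]  # per tissue class, in TISSUE_CLASSES order


def aggregate_tpm(
        records: Iterable[ExpressionRecord]) -> dict[tuple[str, str], float]:
    """Per (gene, tissue) TPM, maximised over stages and cultivars."""
    out: dict[tuple[str, str], float] = {}
    for r in records:
        key = (r.gene_id, r.tissue)
        out[key] = max(out.get(key, 0.0), r.tpm)
    return out


def _triad_tpms(group: HomoeologGroup, tissue: str,
                tpm: Mapping[tuple[str, str], float]) -> tuple[float, ...]:
    vals = []
    for sg in ("A", "B", "D"):
        gid = group.members_of(sg)[0]
        if (gid, tissue) not in tpm:
            logger.warning("no expression record for %s in %s; treated as 0",
                           gid, tissue)
        vals.append(tpm.get((gid, tissue), 0.0))
    return tuple(vals)


def filter_triads(
    records: Iterable[ExpressionRecord],
    triads: Iterable[HomoeologGroup],
    threshold_tpm: float = 1.0,
    per_homoeolog: bool = False,
) -> list[tuple[HomoeologGroup, str, tuple[float, float, float]]]:
    """Retain (triad, tissue) pairs expressed at or above the TPM threshold.

    By default the filter applies to the triad sum (sum >= threshold); with
    ``per_homoeolog=True`` every homoeolog must individually reach the
    threshold.  A member without an expression record counts as 0 TPM (and
    is logged).
    """
    tpm = aggregate_tpm(records)
    retained = []
    for group in triads:
        if group.category != "triad":
            raise ValueError(f"not a triad: {group}")
        for tissue in TISSUES:
            vals = _triad_tpms(group, tissue, tpm)
            ok = (all(v >= threshold_tpm for v in vals) if per_homoeolog
                  else sum(vals) >= threshold_tpm)
            if ok:
                retained.append((group, tissue, vals))
    return retained


def normalize_triad(tpm_a: float, tpm_b: float,
                    tpm_d: float) -> tuple[float, float, float]:
    """Homoeolog fractions f_X = tpm_X / (tpm_A + tpm_B + tpm_D)."""
    total = tpm_a + tpm_b + tpm_d
    if total <= 0:
        raise ValueError("cannot normalize an all-zero triad; "
                         "filter sub-threshold triads first")
    return (tpm_a / total, tpm_b / total, tpm_d / total)


def classify_triad(
        f_a: float, f_b: float,
        f_d: float) -> tuple[str, tuple[float, ...]]:
    """Nearest centroid by Euclidean distance on the simplex.

    Returns the winning category and the distances to all seven centroids in
    category order; ties resolve to the earlier category (Balanced first,
    then dominants A/B/D, then suppressed A/B/D).  Distances are quantized
    to 12 decimals before the argmin so that a point on a decision boundary
    (e.g. (2/3, 1/6, 1/6), equidistant from Balanced and A-dominant) is
    classified identically regardless of how its fractions were computed.
    """
    if not math.isclose(f_a + f_b + f_d, 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1; normalize first")
    point = np.array([f_a, f_b, f_d])
    dists = np.sqrt(((point - _CENTROID_MATRIX) ** 2).sum(axis=1))
    winner = int(np.argmin(np.round(dists, 12)))
    return BIAS_CATEGORIES[winner], tuple(float(d) for d in dists)


def triad_profiles(
    records: Iterable[ExpressionRecord],
    triads: Iterable[HomoeologGroup],
    threshold_tpm: float = 1.0,
    per_homoeolog: bool = False,
) -> list[TriadExpressionProfile]:
    """Filter, normalize and classify every (triad, tissue) pair."""
    out = []
    for group, tissue, vals in filter_triads(records, triads, threshold_tpm,
                                             per_homoeolog):
        fractions = normalize_triad(*vals)
        category, distances = classify_triad(*fractions)
        out.append(TriadExpressionProfile(group, tissue, vals, fractions,
                                          category, distances))
    return out


def summarize_by_tissue(
        profiles: Iterable[TriadExpressionProfile]) -> pd.DataFrame:
    """Per tissue: number of expressed triads and percentage per category.

    Percentages are rounded to one decimal, the reporting style of the
    study; the unrounded values sum to 100 exactly.
    """
    profiles = list(profiles)
    tissues = [t for t in TISSUES
               if any(p.tissue == t for p in profiles)]
    rows = []
    for tissue in tissues:
        cats = [p.category for p in profiles if p.tissue == tissue]
        n = len(cats)
        row = {"tissue": tissue, "n_triads": n}
        for cat in BIAS_CATEGORIES:
            row[f"pct_{cat}"] = round(100.0 * cats.count(cat) / n, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def call_tissue_specificity(
    records: Iterable[ExpressionRecord],
    expressed_threshold: float = 1.0,
    gene_ids: Sequence[str] | None = None,
) -> list[TissueSpecificityCall]:
    """Classify each gene as tissue-specific, ubiquitous or not expressed.

    A gene is *X-specific* when its maximum TPM (over stages and cultivars)
    reaches the threshold within tissue class X and stays below it in both
    other classes; *not expressed* when it never reaches the threshold;
    *ubiquitous* otherwise.  Genes listed in ``gene_ids`` but absent from
    the records are called not_expressed with a warning.
    """
    tpm = aggregate_tpm(records)
    seen = sorted({gid for gid, _ in tpm})
    targets = list(gene_ids) if gene_ids is not None else seen
    calls = []
    for gid in targets:
        if gid not in set(seen):
            logger.warning("gene %s has no expression records; "
                           "called not_expressed", gid)
        maxima = tuple(
            max((tpm.get((gid, t), 0.0) for t in members), default=0.0)
            for members in TISSUE_CLASSES.values())
        above = [m >= expressed_threshold for m in maxima]
        if not any(above):
            call = "not_expressed"
        elif sum(above) == 1:
            cls = list(TISSUE_CLASSES)[above.index(True)]
            call = f"{cls}_specific"
        else:
            call = "ubiquitous"
        calls.append(TissueSpecificityCall(gid, call, maxima))
    return calls


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def profiles_table(profiles: Iterable[TriadExpressionProfile],
                   group_labels: Mapping[HomoeologGroup, str] | None = None
                   ) -> pd.DataFrame:
    """Ternary coordinates and categories as a flat table (for external
    ternary plotting)."""
    rows = []
    for p in profiles:
        label = (group_labels or {}).get(p.group,
                                         min(p.group.all_members()))
        rows.append((label, p.tissue, *p.tpm, *p.fractions, p.category))
    return pd.DataFrame(rows, columns=[
        "group", "tissue", "tpm_A", "tpm_B", "tpm_D",
        "f_A", "f_B", "f_D", "category"])


def log2_matrix(records: Iterable[ExpressionRecord]) -> pd.DataFrame:
    """A gene x tissue matrix of log2(tpm + 1), for heatmap export."""
    tpm = aggregate_tpm(records)
    genes = sorted({gid for gid, _ in tpm})
    data = {t: [np.log2(tpm.get((g, t), 0.0) + 1.0) for g in genes]
            for t in TISSUES}
    return pd.DataFrame(data, index=genes)
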