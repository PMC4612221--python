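"""Functional-purity and prediction-quality assessments.

Three assessments validate a family classification:

* **EC purity** — families whose EC-annotated members all share one
  four-field EC number are functionally pure; the report histograms unique
  EC counts per family.
* **Precision-recall / F_max** — CAFA-style protein-centric evaluation of
  GO predictions against propagated truth sets: at each confidence
  threshold, precision is averaged over proteins with at least one
  prediction, recall over all assessment proteins; F_max is the best
  harmonic mean over thresholds, with prediction coverage reported
  separately.
* **Conserved-residue enrichment** — per family, the proportion of
  conserved positions that are catalytic minus the proportion of all
  positions that are catalytic, tested against a zero median with a
  one-sided Wilcoxon signed-rank test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UsageError

logger = logging.getLogger(__name__)


@dataclass
class PurityReport:
    ec_sets: dict[str, set[str]]       # family id -> unique EC numbers
    histogram: dict[int, int]          # #unique ECs -> family count
    fraction_single_ec: float


@dataclass
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_max: float
    coverage: float


@dataclass
class EnrichmentReport:
    per_family: dict[str, float]
    per_superfamily: dict[str, float] = field(default_factory=dict)
    p_value: float | None = None


# ---------------------------------------------------------------------------
# EC purity
# ---------------------------------------------------------------------------

def ec_purity(
    families: dict[str, list[str]], ec_annotations
) -> PurityReport:
    """Unique-EC counts per family over EC-annotated members.

    ``families`` maps family id -> member accessions. Families without any
    EC-annotated member are excluded from the histogram and the fraction.
    """
    ec_sets: dict[str, set[str]] = {}
    for fam_id, members in families.items():
        ecs: set[str] = set()
        for member in members:
            ecs |= ec_annotations.terms_for(member)
        if ecs:
            ec_sets[fam_id] = ecs
    histogram: dict[int, int] = {}
    for ecs in ec_sets.values():
        histogram[len(ecs)] = histogram.get(len(ecs), 0) + 1
    n = len(ec_sets)
    fraction = histogram.get(1, 0) / n if n else 0.0
    return PurityReport(ec_sets=ec_sets, histogram=histogram,
                        fraction_single_ec=fraction)


# ---------------------------------------------------------------------------
# Precision-recall / F_max
# ---------------------------------------------------------------------------

def pr_curve(
    predictions: dict[str, dict[str, float]],
    truth: dict[str, set[str]],
    thresholds: np.ndarray | None = None,
) -> PRCurve:
    """CAFA protein-centric precision-recall over confidence thresholds.

    ``predictions``: protein -> {term: confidence}; ``truth``: protein ->
    propagated experimental term set. Proteins with an empty truth set are
    excluded with a warning. Precision at a threshold averages over
    proteins with >= 1 prediction at that threshold; recall averages over
    all assessment proteins.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.01, 0.01), 2)
    proteins = []
    for pid, terms in truth.items():
        if not terms:
            logger.warning("protein %s has an empty truth set; excluded", pid)
            continue
        proteins.append(pid)
    if not proteins:
        raise UsageError("no assessment proteins with non-empty truth")
    precision = np.zeros(len(thresholds))
    recall = np.zeros(len(thresholds))
    for k, tau in enumerate(thresholds):
        precisions = []
        recalls = []
        for pid in proteins:
            pred_terms = {
                t for t, c in predictions.get(pid, {}).items() if c >= tau
            }
            true_terms = truth[pid]
            tp = len(pred_terms & true_terms)
            if pred_terms:
                precisions.append(tp / len(pred_terms))
            recalls.append(tp / len(true_terms))
        precision[k] = float(np.mean(precisions)) if precisions else 0.0
        recall[k] = float(np.mean(recalls))
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 2 * precision * recall / (precision + recall)
    f = np.nan_to_num(f, nan=0.0)
    covered = sum(
        1 for pid in proteins
        if any(c > 0 for c in predictions.get(pid, {}).values())
    )
    return PRCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        f_max=float(f.max()),
        coverage=covered / len(proteins),
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def enrichment(
    n_columns: int,
    conserved_cols: set[int] | list[int],
    catalytic_cols: set[int] | list[int],
) -> float:
    """(catalytic fraction among conserved) - (catalytic fraction overall).

    Columns are 0-based alignment columns. Undefined (raises) when there are
    no conserved columns; callers skip and log such families.
    """
    conserved = set(conserved_cols)
    catalytic = set(catalytic_cols)
    if n_columns <= 0:
        raise UsageError("alignment must have columns")
    if not conserved:
        raise UsageError("enrichment undefined without conserved columns")
    return len(conserved & catalytic) / len(conserved) - len(catalytic) / n_columns


def wilcoxon_one_sided(values, null_median: float = 0.0) -> float:
    """One-sided Wilcoxon signed-rank p-value for median > ``null_median``.

    Exact distribution for n <= 25 (no ties among nonzero values), normal
    approximation with continuity correction above; zero differences are
    dropped, ties get mid-ranks. All-zero input returns p = 1.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        raise UsageError("need at least 5 values for the signed-rank test")
    diffs = values - null_median
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        diffs, alternative="greater", zero_method="wilcox",
        correction=True, method=method,
    )
    return float(res.pvalue)


def enrichment_report(
    family_enrichments: dict[str, float],
    superfamily_of: dict[str, str] | None = None,
) -> EnrichmentReport:
    """Average per-family enrichments per superfamily and test median > 0."""
    report = EnrichmentReport(per_family=dict(family_enrichments))
    if superfamily_of is None:
        superfamily_of = {fam: "SF" for fam in family_enrichments}
    groups: dict[str, list[float]] = {}
    for fam, value in family_enrichments.items():
        groups.setdefault(superfamily_of[fam], []).append(value)
    report.per_superfamily = {
        sf: float(np.mean(vals)) for sf, vals in groups.items()
    }
    vals = list(report.per_superfamily.values())
    if len(vals) >= 5:
        report.p_value = wilcoxon_one_sided(vals)
    return report
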