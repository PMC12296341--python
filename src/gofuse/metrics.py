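"""CAFA-style evaluation: protein-centric Fmax, example-based F1,
micro-AUPR and MCC, plus the frequency sweep, the protein-pair matching
statistic and benchmark-table improvement summaries.

Fmax follows the CAFA convention: over a threshold grid τ ∈ {0.01, …,
1.00}, precision is averaged over proteins that predict at least one term
at τ, recall over all proteins that carry at least one true term, and
Fmax is the maximum harmonic mean (ties resolved toward the smaller τ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, matthews_corrcoef

TAU_GRID = np.round(np.arange(0.01, 1.005, 0.01), 2)


# --------------------------------------------------------------------------
# core metrics
# --------------------------------------------------------------------------

def _check_shapes(scores: np.ndarray, labels: np.ndarray) -> None:
    scores, labels = np.asarray(scores), np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 2:
        raise ValueError(f"shape mismatch: scores {scores.shape}, labels {labels.shape}")


def precision_recall_at(
    scores: np.ndarray, labels: np.ndarray, tau: float
) -> tuple[float, float]:
    """CAFA precision/recall at one threshold (predictions are score ≥ τ)."""
    pred = scores >= tau
    tp = (pred & (labels > 0)).sum(axis=1)
    n_pred = pred.sum(axis=1)
    n_true = (labels > 0).sum(axis=1)
    predicting = n_pred > 0
    has_truth = n_true > 0
    precision = float((tp[predicting] / n_pred[predicting]).mean()) if predicting.any() else 0.0
    recall = float((tp[has_truth] / n_true[has_truth]).mean()) if has_truth.any() else 0.0
    return precision, recall


def fmax(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Protein-centric Fmax and its arg-max threshold τ*."""
    _check_shapes(scores, labels)
    labels = np.asarray(labels)
    if not (labels > 0).any(axis=1).any():
        raise ValueError("no protein has any true label: recall undefined")
    best_f, best_tau = 0.0, float(TAU_GRID[0])
    for tau in TAU_GRID:
        pr, rc = precision_recall_at(scores, labels, float(tau))
        f = 2 * pr * rc / (pr + rc) if (pr + rc) > 0 else 0.0
        if f > best_f:
            best_f, best_tau = f, float(tau)
    return best_f, best_tau


def example_f1(scores: np.ndarray, labels: np.ndarray, tau: float = 0.5) -> float:
    """Mean per-protein F1 at a fixed threshold.  A protein with neither
    predictions nor true terms contributes F1 = 1 by convention."""
    _check_shapes(scores, labels)
    pred = np.asarray(scores) >= tau
    truth = np.asarray(labels) > 0
    tp = (pred & truth).sum(axis=1)
    denom = pred.sum(axis=1) + truth.sum(axis=1)
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 1.0)
    return float(f1.mean())


def micro_aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the micro precision-recall curve over all n·γ pairs
    (step integration, no trapezoid interpolation)."""
    _check_shapes(scores, labels)
    y = np.asarray(labels).ravel()
    if y.sum() == 0:
        raise ValueError("micro-AUPR undefined without any positive pair")
    return float(average_precision_score(y, np.asarray(scores).ravel()))


def micro_mcc(scores: np.ndarray, labels: np.ndarray, tau: float = 0.5) -> float:
    """Matthews coefficient of the flattened confusion at τ (0 when a
    marginal is zero)."""
    _check_shapes(scores, labels)
    return float(
        matthews_corrcoef(
            np.asarray(labels).ravel() > 0, np.asarray(scores).ravel() >= tau
        )
    )


@dataclass
class EvalReport:
    """Threshold sweep plus the four headline metrics."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fmax: float
    tau_star: float
    example_f1: float
    aupr: float
    mcc: float
    n: int
    gamma: int
    notes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fmax": self.fmax,
            "tau_star": self.tau_star,
            "example_f1": self.example_f1,
            "aupr": self.aupr,
            "mcc": self.mcc,
            "n": self.n,
            "gamma": self.gamma,
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "tau": self.thresholds,
                "precision": self.precision,
                "recall": self.recall,
            }
        ).to_csv(path, sep="\t", index=False)


def evaluate(scores: np.ndarray, labels: np.ndarray) -> EvalReport:
    """Full CAFA-style report: threshold sweep, Fmax, F1@0.5, AUPR, MCC."""
    _check_shapes(scores, labels)
    pr = np.empty(TAU_GRID.size)
    rc = np.empty(TAU_GRID.size)
    for i, tau in enumerate(TAU_GRID):
        pr[i], rc[i] = precision_recall_at(scores, labels, float(tau))
    f, tau_star = fmax(scores, labels)
    return EvalReport(
        thresholds=TAU_GRID.copy(),
        precision=pr,
        recall=rc,
        fmax=f,
        tau_star=tau_star,
        example_f1=example_f1(scores, labels),
        aupr=micro_aupr(scores, labels),
        mcc=micro_mcc(scores, labels),
        n=scores.shape[0],
        gamma=scores.shape[1],
        notes={"f1_tau": 0.5, "mcc_tau": 0.5, "empty_vs_empty_f1": 1.0},
    )


# --------------------------------------------------------------------------
# protein-pair matching against an interaction-confidence table
# --------------------------------------------------------------------------

@dataclass
class PairSelection:
    """Protein pairs with highly similar predicted annotation sets."""

    pairs: list[tuple[str, str, float]]
    precision_floor: float = 0.75
    similarity_floor: float = 0.70


@dataclass
class PairMatchResult:
    n_selected: int
    n_matched: int
    rate: float | None          # None when no pair was selected
    selection: PairSelection | None = None


def pair_matching_rate(
    scores: np.ndarray,
    labels: np.ndarray,
    confidence_table: dict[tuple[str, str], float],
    protein_ids: list[str],
    precision_floor: float = 0.75,
    similarity_floor: float = 0.70,
    match_cutoff: float = 70.0,
    tau: float = 0.5,
) -> PairMatchResult:
    """Select proteins whose per-protein precision at τ is at least the
    floor, pair those whose positive predicted term sets have Jaccard
    similarity at least the similarity floor, and count pairs whose
    interaction-confidence score (0–99.9) reaches the cutoff.

    The confidence table is keyed by unordered protein-id pairs; missing
    pairs count as unmatched.
    """
    _check_shapes(scores, labels)
    pred = np.asarray(scores) >= tau
    truth = np.asarray(labels) > 0
    keep: list[int] = []
    for i in range(pred.shape[0]):
        n_pred = pred[i].sum()
        if n_pred == 0:
            continue
        precision = (pred[i] & truth[i]).sum() / n_pred
        if precision >= precision_floor:
            keep.append(i)
    pairs: list[tuple[str, str, float]] = []
    for i, j in combinations(keep, 2):
        inter = (pred[i] & pred[j]).sum()
        union = (pred[i] | pred[j]).sum()
        if union == 0:
            continue
        jac = inter / union
        if jac >= similarity_floor:
            a, b = sorted((protein_ids[i], protein_ids[j]))
            pairs.append((a, b, float(jac)))
    matched = 0
    for a, b, _ in pairs:
        score = confidence_table.get((a, b), confidence_table.get((b, a)))
        if score is not None and score >= match_cutoff:
            matched += 1
    rate = matched / len(pairs) if pairs else None
    return PairMatchResult(
        n_selected=len(pairs),
        n_matched=matched,
        rate=rate,
        selection=PairSelection(pairs, precision_floor, similarity_floor),
    )


def matching_rate_from_counts(counts: pd.DataFrame) -> PairMatchResult:
    """Aggregate per-aspect (selected, matched) pair counts into the
    overall matching rate (percentage handled by the caller)."""
    selected = int(counts["selected"].sum())
    matched = int(counts["matched"].sum())
    return PairMatchResult(
        n_selected=selected,
        n_matched=matched,
        rate=matched / selected if selected else None,
    )


# --------------------------------------------------------------------------
# frequency sweep
# --------------------------------------------------------------------------

def frequency_sweep(
    cohort,
    graph,
    thresholds: list[int],
    train_config=None,
    test_fraction: float = 0.1,
    seed: int = 0,
    switches=None,
    n_species: int | None = None,
) -> pd.DataFrame:
    """Rebuild the label space at each threshold, retrain the predictor on
    the train split and report held-out Fmax.

    Returns a table with columns threshold, gamma_retained, fmax, valid;
    a threshold that empties the label space yields an invalid row and the
    sweep continues.
    """
    from .data_io import split_cohort
    from .model import GoFuseModel, ModuleSwitches, TrainConfig, train as train_model
    from .ontology import build_label_matrix, prune_by_frequency

    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    train_config = train_config or TrainConfig()
    switches = switches or ModuleSwitches()
    if n_species is None:
        n_species = max(cohort.taxonomy.values(), default=0)
    rows = []
    for threshold in thresholds:
        try:
            space = prune_by_frequency(graph, cohort.annotations, threshold)
        except ValueError:
            rows.append(
                {"threshold": threshold, "gamma_retained": 0, "fmax": np.nan,
                 "valid": False}
            )
            continue
        y = build_label_matrix(space, cohort.annotations, cohort.protein_ids)
        work = _with_aspect_labels(cohort, space, y)
        train_part, test_part = split_cohort(work, test_fraction, seed)
        model = GoFuseModel(
            space,
            d=cohort.seq_archive.dim,
            d_prime=cohort.text_archive.dim,
            n_species=n_species,
            switches=switches,
            seed=seed,
        )
        train_model(
            model, train_part, train_part.labels[space.graph.aspect], train_config
        )
        scores = model.predict(test_part)
        f, _ = fmax(scores, test_part.labels[space.graph.aspect])
        rows.append(
            {"threshold": threshold, "gamma_retained": space.gamma, "fmax": f,
             "valid": True}
        )
    return pd.DataFrame(rows)


def _with_aspect_labels(cohort, space, y):
    from dataclasses import replace

    aspect = space.graph.aspect
    return replace(
        cohort,
        labels={**cohort.labels, aspect: y},
        label_term_ids={**cohort.label_term_ids, aspect: space.term_ids},
    )


# --------------------------------------------------------------------------
# benchmark-table summaries
# --------------------------------------------------------------------------

def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference CSVs (published CAFA5 benchmark
    summaries used as fixed inputs): ``plm_benchmark_fmax``,
    ``plm_benchmark_f1``, ``ppi_pair_counts`` or ``go_term_counts``."""
    ref = resources.files("gofuse.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")


def improvement_summary(table: pd.DataFrame) -> float:
    """Mean paired difference enhanced − base over all table cells."""
    for col in ("base", "enhanced"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    bad = table[table[["base", "enhanced"]].isna().any(axis=1)]
    if not bad.empty:
        first = bad.iloc[0]
        raise ValueError(
            f"unpaired cell for model {first.get('model')!r} "
            f"aspect {first.get('aspect')!r}"
        )
    return float((table["enhanced"] - table["base"]).mean())


def method_row_means(table: pd.DataFrame, model: str) -> float:
    """Mean enhanced value over the aspects of one base model."""
    rows = table[table["model"] == model]
    if rows.empty:
        raise ValueError(f"model {model!r} not in table")
    return float(rows["enhanced"].mean())


def retained_fraction(counts: pd.DataFrame) -> float:
    """Fraction (%) of GO terms surviving pruning, from per-aspect total
    and pruned counts."""
    total = counts["total"].sum()
    retained = (counts["total"] - counts["pruned"]).sum()
    return 100.0 * retained / total
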