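"""End-to-end orchestration: ontology → pruning → fusion → taxonomy →
head training → evaluation, with reproducible manifests.

Two entry styles are supported: on-disk cohort directories (what the CLI
drives) and in-memory cohorts (what scripts, notebooks and tests use via
:func:`train_on_cohort` / :func:`evaluate_model`).  Every artifact written
carries a digest of the run configuration so runs are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import Cohort, split_cohort
from .metrics import EvalReport, evaluate
from .model import GoFuseModel, ModuleSwitches, TrainConfig, train
from .ontology import (
    GoGraph,
    LabelSpace,
    auto_threshold,
    build_label_matrix,
    prune_by_frequency,
)
from .simulate import SimConfig, generate_cohort, load_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    cohort_dir: str
    output_dir: str
    aspect: str = "BP"
    switches: ModuleSwitches = field(default_factory=ModuleSwitches)
    threshold: int = 21
    auto_threshold: bool = False
    propagate: bool = False
    test_fraction: float = 0.1
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def digest(self) -> str:
        payload = {
            **{k: v for k, v in asdict(self).items()},
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def build_label_space(
    cohort: Cohort,
    graph: GoGraph,
    threshold: int = 21,
    use_auto_threshold: bool = False,
) -> LabelSpace:
    if use_auto_threshold:
        threshold = auto_threshold(cohort.n)
    return prune_by_frequency(graph, cohort.annotations, threshold)


def train_on_cohort(
    cohort: Cohort,
    graph: GoGraph,
    threshold: int = 0,
    switches: ModuleSwitches | None = None,
    train_config: TrainConfig | None = None,
    test_fraction: float = 0.1,
    propagate: bool = False,
    seed: int = 0,
) -> tuple[GoFuseModel, list[float], Cohort, Cohort]:
    """Prune, split, train.  Returns (model, loss trace, train, test)
    with label matrices re-aligned to the pruned label space."""
    space = prune_by_frequency(graph, cohort.annotations, threshold)
    aspect = graph.aspect
    y = build_label_matrix(space, cohort.annotations, cohort.protein_ids, propagate)
    from dataclasses import replace

    work = replace(
        cohort,
        labels={**cohort.labels, aspect: y},
        label_term_ids={**cohort.label_term_ids, aspect: space.term_ids},
    )
    train_part, test_part = split_cohort(work, test_fraction, seed)
    model = GoFuseModel(
        space,
        d=cohort.seq_archive.dim,
        d_prime=cohort.text_archive.dim,
        n_species=max(cohort.taxonomy.values(), default=0),
        switches=switches or ModuleSwitches(),
        seed=seed,
    )
    trace = train(model, train_part, train_part.labels[aspect], train_config)
    return model, trace, train_part, test_part


def evaluate_model(model: GoFuseModel, cohort: Cohort) -> EvalReport:
    scores = model.predict(cohort)
    return evaluate(scores, cohort.labels[model.label_space.graph.aspect])


# --------------------------------------------------------------------------
# directory-based runs (CLI surface)
# --------------------------------------------------------------------------

def run_simulate(config: SimConfig, out_dir: str | Path) -> None:
    cohort, graphs = generate_cohort(config)
    write_cohort(cohort, graphs, out_dir)
    Path(out_dir, "sim_config.json").write_text(json.dumps(asdict(config), indent=1))


def run_train(config: RunConfig) -> Path:
    """Full training run from a cohort directory; writes checkpoint,
    label-space manifest and loss trace, and returns the output prefix."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, graphs = load_cohort(config.cohort_dir)
    if config.switches.taxonomy and not cohort.taxonomy:
        raise ValueError("taxonomy switch is on but the cohort has no taxonomy table")
    if config.aspect not in graphs:
        raise ValueError(f"aspect {config.aspect} not present in the ontology")
    try:
        model, trace, train_part, test_part = train_on_cohort(
            cohort,
            graphs[config.aspect],
            threshold=(0 if config.auto_threshold else config.threshold),
            switches=config.switches,
            train_config=config.train,
            test_fraction=config.test_fraction,
            propagate=config.propagate,
            seed=config.seed,
        )
    except Exception as err:
        raise RuntimeError(
            f"training stage failed (config {config.digest()}): {err}"
        ) from err
    prefix = out / f"model_{config.aspect}"
    model.save(prefix)
    model.label_space.save(out / f"labels_{config.aspect}")
    (out / "loss_trace.json").write_text(
        json.dumps({"config_digest": config.digest(), "loss": trace}, indent=1)
    )
    np.save(out / "test_rows.npy", np.array(
        [cohort.protein_ids.index(p) for p in test_part.protein_ids]
    ))
    logger.info("run %s finished: final loss %.5f", config.digest(), trace[-1])
    return prefix


def run_evaluate(config: RunConfig, checkpoint_prefix: str | Path) -> EvalReport:
    """Evaluate a saved checkpoint on the held-out split recorded at
    training time; refuses on a term-order digest mismatch."""
    cohort, graphs = load_cohort(config.cohort_dir)
    space = build_label_space(
        cohort, graphs[config.aspect], config.threshold, config.auto_threshold
    )
    model = GoFuseModel(
        space,
        d=cohort.seq_archive.dim,
        d_prime=cohort.text_archive.dim,
        n_species=max(cohort.taxonomy.values(), default=0),
        switches=config.switches,
        seed=config.seed,
    )
    model.load(checkpoint_prefix)
    y = build_label_matrix(
        space, cohort.annotations, cohort.protein_ids, config.propagate
    )
    from dataclasses import replace

    work = replace(
        cohort,
        labels={**cohort.labels, config.aspect: y},
        label_term_ids={**cohort.label_term_ids, config.aspect: space.term_ids},
    )
    rows_path = Path(config.output_dir) / "test_rows.npy"
    if rows_path.exists():
        work = work.take(np.load(rows_path))
    report = evaluate_model(model, work)
    report.notes["config_digest"] = config.digest()
    report.to_json(Path(config.output_dir) / f"eval_{config.aspect}.json")
    report.to_tsv(Path(config.output_dir) / f"eval_{config.aspect}.tsv")
    return report


def run_ablations(
    cohort: Cohort,
    graph: GoGraph,
    threshold: int = 0,
    train_config: TrainConfig | None = None,
    variants: dict[str, ModuleSwitches] | None = None,
    seed: int = 0,
) -> dict[str, EvalReport]:
    """Train and evaluate a set of module-switch variants on a shared
    split.  Defaults to the five canonical variants: full, each single
    module alone, and the bare linear probe."""
    if variants is None:
        variants = {
            "full": ModuleSwitches(),
            "relation_only": ModuleSwitches(text=False, taxonomy=False),
            "text_only": ModuleSwitches(taxonomy=False, relation=False),
            "taxonomy_only": ModuleSwitches(text=False, relation=False),
            "none": ModuleSwitches(text=False, taxonomy=False, relation=False),
        }
    reports = {}
    for name, switches in variants.items():
        model, _, _, test_part = train_on_cohort(
            cohort,
            graph,
            threshold=threshold,
            switches=switches,
            train_config=train_config,
            seed=seed,
        )
        reports[name] = evaluate_model(model, test_part)
    return reports


def all_switch_variants() -> dict[str, ModuleSwitches]:
    """The 2³ ablation grid."""
    out = {}
    for text in (True, False):
        for taxonomy in (True, False):
            for relation in (True, False):
                name = "+".join(
                    n
                    for n, on in (
                        ("text", text),
                        ("taxonomy", taxonomy),
                        ("relation", relation),
                    )
                    if on
                ) or "none"
                out[name] = ModuleSwitches(text, taxonomy, relation)
    return out
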