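"""Backward elimination over omics types and the architecture ablations."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .training import DataBundle, TrainConfig, run_single, summarize

__all__ = [
    "EliminationTrace",
    "backward_eliminate",
    "reduced_architecture",
    "attention_ablation",
]


@dataclass
class EliminationTrace:
    """Every subset evaluated during backward elimination, in order.

    ``evaluations`` holds (round, subset, score, accepted) tuples; the
    accepted path is the sequence of best models; ``final_subset`` is the
    selected combination.  Termination is either ``"no_improvement"`` or
    ``"exhausted"`` (no omics left).
    """

    evaluations: list = field(default_factory=list)
    accepted_path: list = field(default_factory=list)
    final_subset: tuple = ()
    termination: str = ""


def backward_eliminate(omics_names, score_fn) -> EliminationTrace:
    """Greedy backward elimination at the level of omics data type.

    Starting from the full set, every leave-one-out subset is scored; if the
    best child strictly improves on the current best model it becomes the new
    best and the process recurses, otherwise it stops.  Ties among equally
    scoring children are broken by the lexicographic order of the removed
    name, for determinism.  A score_fn failure scores that subset -inf and is
    recorded in the trace.
    """
    current = tuple(omics_names)
    if not current:
        raise ValueError("need at least one omics type")

    def safe_score(subset):
        try:
            return float(score_fn(subset)), None
        except Exception as exc:
            return float("-inf"), f"{type(exc).__name__}: {exc}"

    trace = EliminationTrace()
    score, err = safe_score(current)
    trace.evaluations.append((0, current, score, True, err))
    trace.accepted_path.append((current, score))
    best_subset, best_score = current, score

    round_no = 0
    while len(best_subset) > 1:
        round_no += 1
        children = []
        for removed in sorted(best_subset):
            child = tuple(n for n in best_subset if n != removed)
            child_score, err = safe_score(child)
            children.append((child_score, removed, child, err))
        # tie-break among equal scores: lexicographically smallest removed name
        top = max(c[0] for c in children)
        winners = [c for c in children if c[0] == top]
        best_child = min(winners, key=lambda c: c[1])
        for child_score, removed, child, err in children:
            accepted = (child == best_child[2]) and child_score > best_score
            trace.evaluations.append((round_no, child, child_score, accepted, err))
        if best_child[0] > best_score:
            best_subset, best_score = best_child[2], best_child[0]
            trace.accepted_path.append((best_subset, best_score))
        else:
            trace.termination = "no_improvement"
            break
    else:
        trace.termination = "exhausted"
    trace.final_subset = best_subset
    return trace


def reduced_architecture(
    bundle: DataBundle,
    config: TrainConfig,
    omics_names=(),
    modalities=None,
    seeds=None,
) -> dict:
    """Train/evaluate the bypass architectures (0 or 1 omics network).

    With no omics the encoder output feeds a single linear head; with one,
    the single omics chain runs without the attention layer.  Same protocol,
    same hyperparameters.
    """
    omics_names = tuple(omics_names)
    if len(omics_names) > 1:
        raise ValueError("reduced architecture covers 0 or 1 omics types")
    if seeds is None:
        seeds = list(range(config.n_seeds))
    records = []
    for seed in seeds:
        out = run_single(bundle, config, seed, modalities, omics_names)
        records.append(out["metrics"])
    return {"omics": omics_names, "seeds": list(seeds), **summarize(records)}


def attention_ablation(
    bundle: DataBundle,
    config: TrainConfig,
    omics_names,
    modalities=None,
    seeds=None,
    variants=("joingcla", "self_attention"),
) -> list:
    """Identical pipeline with the fusion operator swapped, paired by seed."""
    omics_names = tuple(omics_names)
    if len(omics_names) < 2:
        raise ValueError("attention ablation needs >= 2 omics types")
    if seeds is None:
        seeds = list(range(config.n_seeds))
    rows = []
    for variant in variants:
        cfg = replace(config, variant=variant)
        records = []
        for seed in seeds:
            out = run_single(bundle, cfg, seed, modalities, omics_names)
            records.append(out["metrics"])
        rows.append({"variant": variant, "omics": omics_names,
                     "seeds": list(seeds), **summarize(records)})
    return rows
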