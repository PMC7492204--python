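"""Dual-gated survival classification and regression tree (CART).

Greedy recursive partitioning of a censored cDAF outcome: at each node the
best dichotomization of every candidate variable is found by the Cox
partial-likelihood score test, the strongest variable is selected, and the
split is accepted only if *both* the score test and the log-rank test on the
induced two groups are significant at ``alpha`` and both children contain at
least ``min_node_size`` subjects.  A branch ends when no acceptable split
remains.  Every node carries Kaplan-Meier probabilities of remaining disease
activity-free at the landmark months 6, 12, 18 and 24.

Because the two age-derived variables "disease duration" and "age at first
symptom" differ from "age at baseline" by a linear identity, they are never
offered to the tree together: model variant A uses disease duration, variant
B uses age at first symptom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cutpoints import BinarySplit, best_binary_split
from .survival import SurvivalDataset, km_estimate

LANDMARK_MONTHS = (6.0, 12.0, 18.0, 24.0)

#: Measurement scale of each candidate variable in the study's models.
DEFAULT_VARIABLE_KINDS: dict[str, str] = {
    "female": "binary",
    "poly_index": "binary",
    "relapse_count_2y": "ordinal",
    "dominant_symptom": "categorical",
    "baseline_edss": "ordinal",
    "most_affected_kfs": "categorical",
    "prior_dmt": "categorical",
    "age_at_baseline": "continuous",
    "disease_duration": "continuous",
    "age_at_first_symptom": "continuous",
}

#: Candidate variable lists for the two model variants.
VARIANT_VARIABLES: dict[str, tuple[str, ...]] = {
    "A": (
        "female",
        "poly_index",
        "relapse_count_2y",
        "dominant_symptom",
        "baseline_edss",
        "most_affected_kfs",
        "prior_dmt",
        "age_at_baseline",
        "disease_duration",
    ),
    "B": (
        "female",
        "poly_index",
        "relapse_count_2y",
        "dominant_symptom",
        "baseline_edss",
        "most_affected_kfs",
        "prior_dmt",
        "age_at_baseline",
        "age_at_first_symptom",
    ),
}


@dataclass(frozen=True)
class CartConfig:
    """Tuning parameters for the dual-gated survival tree."""

    alpha: float = 0.05
    min_node_size: int = 5
    model_variant: str = "A"
    candidate_variables: Optional[tuple[str, ...]] = None
    variable_kinds: Optional[dict[str, str]] = None
    max_depth: Optional[int] = None
    horizon: float = 24.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.model_variant not in ("A", "B"):
            raise ValueError("model_variant must be 'A' or 'B'")
        variables = self.variables
        if "disease_duration" in variables and "age_at_first_symptom" in variables:
            raise ValueError(
                "disease_duration and age_at_first_symptom are collinear with "
                "age_at_baseline and may not enter the same model"
            )
        if self.model_variant == "A" and "age_at_first_symptom" in variables:
            raise ValueError("variant A excludes age_at_first_symptom")
        if self.model_variant == "B" and "disease_duration" in variables:
            raise ValueError("variant B excludes disease_duration")

    @property
    def variables(self) -> tuple[str, ...]:
        if self.candidate_variables is not None:
            return tuple(self.candidate_variables)
        return VARIANT_VARIABLES[self.model_variant]

    @property
    def kinds(self) -> dict[str, str]:
        kinds = dict(DEFAULT_VARIABLE_KINDS)
        if self.variable_kinds:
            kinds.update(self.variable_kinds)
        missing = [v for v in self.variables if v not in kinds]
        if missing:
            raise ValueError(f"no measurement kind declared for variables: {missing}")
        return kinds


@dataclass
class CartNode:
    """One node: subject counts, split evidence, and landmark cDAF probabilities."""

    n: int
    n_events: int
    depth: int
    km_cdaf: dict[float, float]
    split: Optional[BinarySplit] = None
    children: Optional[tuple["CartNode", "CartNode"]] = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def score_p(self) -> Optional[float]:
        return self.split.score_p if self.split else None

    @property
    def logrank_p(self) -> Optional[float]:
        return self.split.logrank_p if self.split else None


def node_summary(d: SurvivalDataset, landmarks: tuple[float, ...] = LANDMARK_MONTHS) -> dict[float, float]:
    """KM probabilities of remaining event-free at the landmark months."""
    if len(d) < 1:
        raise ValueError("node must contain at least one subject")
    curve = km_estimate(d)
    return {t: curve.prob_at(t) for t in landmarks}


@dataclass
class CartTree:
    """A fitted dual-gated survival tree."""

    root: CartNode
    config: CartConfig
    variable_kinds: dict[str, str] = field(default_factory=dict)

    def leaves(self) -> list[CartNode]:
        out: list[CartNode] = []

        def walk(node: CartNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def depth(self) -> int:
        def walk(node: CartNode) -> int:
            if node.is_leaf:
                return node.depth
            return max(walk(node.children[0]), walk(node.children[1]))

        return walk(self.root)

    def nodes(self) -> list[CartNode]:
        out: list[CartNode] = []

        def walk(node: CartNode) -> None:
            out.append(node)
            if not node.is_leaf:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return out

    def summary(self, landmark: float = 24.0) -> str:
        """Indented text rendering with the month-``landmark`` cDAF probability."""
        lines: list[str] = []

        def walk(node: CartNode, label: str) -> None:
            prob = node.km_cdaf.get(landmark)
            head = (
                f"{'  ' * node.depth}{label}n={node.n}, events={node.n_events}, "
                f"cDAF@{landmark:g}m={prob:.3f}" if prob is not None else
                f"{'  ' * node.depth}{label}n={node.n}, events={node.n_events}"
            )
            lines.append(head)
            if not node.is_leaf:
                s = node.split
                lines.append(
                    f"{'  ' * node.depth}  split: {s.description} "
                    f"(score p={s.score_p:.4g}, log-rank p={s.logrank_p:.4g})"
                )
                walk(node.children[0], "[left ] ")
                walk(node.children[1], "[right] ")

        walk(self.root, "")
        return "\n".join(lines)


class SurvivalCART:
    """Model object: dual-gated survival CART over a cDAF survival dataset."""

    def __init__(self, data: SurvivalDataset, config: CartConfig | None = None) -> None:
        if len(data) == 0:
            raise ValueError("empty dataset")
        self.data = data
        self.config = config or CartConfig()
        for v in self.config.variables:
            if v not in data.covariates.columns:
                raise KeyError(f"candidate variable {v!r} not in dataset")

    def _grow(self, d: SurvivalDataset, depth: int) -> CartNode:
        cfg = self.config
        node = CartNode(
            n=len(d), n_events=d.n_events, depth=depth, km_cdaf=node_summary(d)
        )
        if cfg.max_depth is not None and depth >= cfg.max_depth:
            return node
        if len(d) < 2 * cfg.min_node_size or d.n_events == 0:
            return node

        kinds = cfg.kinds
        best: Optional[BinarySplit] = None
        for variable in cfg.variables:  # fixed order: deterministic tie-break
            cand = best_binary_split(d, variable, kinds[variable], cfg.min_node_size)
            if cand is None:
                continue
            if best is None or cand.score_p < best.score_p:
                best = cand

        if best is None or not (best.score_p < cfg.alpha and best.logrank_p < cfg.alpha):
            return node

        mask = best.mask(d.covariates)
        node.split = best
        node.children = (
            self._grow(d.subset(mask), depth + 1),
            self._grow(d.subset(~mask), depth + 1),
        )
        return node

    def fit(self) -> CartTree:
        root = self._grow(self.data, 0)
        return CartTree(root=root, config=self.config, variable_kinds=dict(self.config.kinds))


def build_tree(d: SurvivalDataset, cfg: CartConfig | None = None) -> CartTree:
    """Fit the dual-gated survival tree; wrapper over :class:`SurvivalCART`."""
    return SurvivalCART(d, cfg).fit()


# ---------------------------------------------------------------------------
# Serialization: lossless nested JSON round-trip.

def _node_to_dict(node: CartNode) -> dict:
    doc = {
        "n": node.n,
        "n_events": node.n_events,
        "depth": node.depth,
        "km_cdaf": {f"{m:g}": p for m, p in node.km_cdaf.items()},
        "split": node.split.to_dict() if node.split else None,
    }
    if node.children:
        doc["children"] = [_node_to_dict(c) for c in node.children]
    return doc


def _node_from_dict(doc: dict) -> CartNode:
    node = CartNode(
        n=doc["n"],
        n_events=doc["n_events"],
        depth=doc["depth"],
        km_cdaf={float(m): p for m, p in doc["km_cdaf"].items()},
        split=BinarySplit.from_dict(doc["split"]) if doc["split"] else None,
    )
    if "children" in doc:
        left, right = (_node_from_dict(c) for c in doc["children"])
        node.children = (left, right)
    return node


def render_tree(tree: CartTree) -> str:
    """Serialize a fitted tree to a nested JSON document."""
    doc = {
        "config": {
            "alpha": tree.config.alpha,
            "min_node_size": tree.config.min_node_size,
            "model_variant": tree.config.model_variant,
            "candidate_variables": list(tree.config.variables),
            "max_depth": tree.config.max_depth,
            "horizon": tree.config.horizon,
        },
        "variable_kinds": tree.variable_kinds,
        "root": _node_to_dict(tree.root),
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def parse_tree(text: str) -> CartTree:
    """Inverse of :func:`render_tree`."""
    doc = json.loads(text)
    cfg = doc["config"]
    config = CartConfig(
        alpha=cfg["alpha"],
        min_node_size=cfg["min_node_size"],
        model_variant=cfg["model_variant"],
        candidate_variables=tuple(cfg["candidate_variables"]),
        variable_kinds=doc["variable_kinds"],
        max_depth=cfg["max_depth"],
        horizon=cfg["horizon"],
    )
    return CartTree(
        root=_node_from_dict(doc["root"]),
        config=config,
        variable_kinds=doc["variable_kinds"],
    )
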