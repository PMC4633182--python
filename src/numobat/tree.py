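"""Cross-validated decision-tree key induction.

A CART classifier (Gini impurity, binary splits on continuous ratios,
split thresholds at midpoints of adjacent sorted values) is fitted to
labeled nest-sample mean ratios, validated by leave-one-nest-out
cross-validation overall and per node, checked per node by Welch
t-tests on the split feature, and rendered as a numbered dichotomous
key in the traditional couplet format.  The induced tree serializes to
the same JSON schema the identification engine reads, so a rendered
key classifies exactly like the tree it came from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .key_engine import Key

__all__ = [
    "TreeConfig",
    "InducedTree",
    "NodeTTest",
    "TreeValidation",
    "build_tree",
    "loocv_tree",
    "node_ttest",
    "node_ttests",
    "render_key",
    "substitute_region_node",
]


@dataclass(frozen=True)
class TreeConfig:
    """rpart-style control parameters."""

    min_leaf: int = 3          # minimum nests per leaf
    max_depth: int | None = None
    ccp_alpha: float = 0.0     # cost-complexity penalty

    def estimator(self) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=self.min_leaf,
            max_depth=self.max_depth,
            ccp_alpha=self.ccp_alpha,
            random_state=0,
        )


@dataclass
class NodeTTest:
    node_id: int
    feature: str
    t: float
    df: float
    p_value: float
    p_holm: float | None = None


@dataclass
class TreeValidation:
    overall_rate: float
    per_node_rate: dict[int, float]
    n_validated: int
    skipped: list[str] = field(default_factory=list)


class InducedTree:
    """A fitted CART key over nest-mean ratios."""

    def __init__(
        self,
        estimator: DecisionTreeClassifier,
        X: pd.DataFrame,
        y: pd.Series,
        config: TreeConfig,
    ):
        self.estimator = estimator
        self.features = list(X.columns)
        self.classes = [str(c) for c in estimator.classes_]
        self.X = X
        self.y = y
        self.config = config
        self._build_nodes()

    # -- structure ----------------------------------------------------
    def _build_nodes(self) -> None:
        t = self.estimator.tree_
        # which training rows reach each node
        paths = self.estimator.decision_path(self.X.values).toarray().astype(bool)
        self.nodes: dict[int, dict] = {}
        for nid in range(t.node_count):
            rows = paths[:, nid]
            counts = pd.Series(self.y[rows]).value_counts()
            majority = str(counts.idxmax())
            node = {
                "id": nid,
                "n": int(rows.sum()),
                "class_counts": counts.to_dict(),
                "majority": majority,
                "success": float(counts.max() / rows.sum()),
                "is_leaf": t.children_left[nid] == -1,
            }
            if not node["is_leaf"]:
                feat = self.features[t.feature[nid]]
                thr = float(t.threshold[nid])
                left_rows = rows & (self.X[feat].values <= thr)
                right_rows = rows & (self.X[feat].values > thr)
                for side, rr in (("low", left_rows), ("high", right_rows)):
                    v = self.X.loc[rr, feat]
                    node[f"{side}_stats"] = {
                        "mean": float(v.mean()), "min": float(v.min()),
                        "max": float(v.max()), "n": int(rr.sum()),
                    }
                node.update(
                    feature=feat,
                    threshold=thr,
                    low=int(t.children_left[nid]),
                    high=int(t.children_right[nid]),
                )
            else:
                node["taxon"] = majority
            self.nodes[nid] = node

    @property
    def internal_nodes(self) -> list[int]:
        return [n for n, d in self.nodes.items() if not d["is_leaf"]]

    @property
    def leaves(self) -> list[int]:
        return [n for n, d in self.nodes.items() if d["is_leaf"]]

    def gini_decreases(self) -> dict[int, float]:
        """Total (weighted) Gini impurity decrease achieved by each split."""
        t = self.estimator.tree_
        out = {}
        for nid in self.internal_nodes:
            l, r = t.children_left[nid], t.children_right[nid]
            n, nl, nr = (
                t.weighted_n_node_samples[nid],
                t.weighted_n_node_samples[l],
                t.weighted_n_node_samples[r],
            )
            out[nid] = float(
                n * t.impurity[nid] - nl * t.impurity[l] - nr * t.impurity[r]
            )
        return out

    # -- prediction ---------------------------------------------------
    def predict(self, ratios: pd.DataFrame) -> pd.Series:
        pred = self.estimator.predict(ratios[self.features].values)
        return pd.Series([str(p) for p in pred], index=ratios.index)

    def subtree_classes(self) -> dict[int, set[str]]:
        """Classes of training nests below each node."""
        out: dict[int, set[str]] = {}

        def walk(nid: int) -> set[str]:
            node = self.nodes[nid]
            if node["is_leaf"]:
                out[nid] = set(map(str, node["class_counts"]))
            else:
                out[nid] = walk(node["low"]) | walk(node["high"])
            return out[nid]

        walk(0)
        return out

    # -- export -------------------------------------------------------
    def couplet_numbers(self) -> dict[int, int]:
        """Pre-order couplet numbering of internal nodes (root = 1)."""
        numbers: dict[int, int] = {}

        def walk(nid: int) -> None:
            node = self.nodes[nid]
            if node["is_leaf"]:
                return
            numbers[nid] = len(numbers) + 1
            walk(node["low"])
            walk(node["high"])

        walk(0)
        return numbers

    def to_key(self) -> Key:
        """Serialize to the identification-engine key schema."""
        numbers = self.couplet_numbers()
        if not numbers:  # single leaf
            only = self.nodes[0]["taxon"]
            return Key(
                {"taxa": [only], "root": "1",
                 "nodes": {"1": {
                     "type": "threshold", "feature": "CS", "threshold": 0.0,
                     "low": {"taxon": only}, "high": {"taxon": only},
                 }}}
            )

        nodes: dict[str, dict] = {}
        for nid, num in numbers.items():
            node = self.nodes[nid]

            def target(child: int) -> dict:
                c = self.nodes[child]
                if c["is_leaf"]:
                    return {"taxon": c["taxon"]}
                return {"node": str(numbers[child])}

            nodes[str(num)] = {
                "type": "threshold",
                "feature": node["feature"],
                "threshold": node["threshold"],
                "low": target(node["low"]),
                "high": target(node["high"]),
                "low_range": [node["low_stats"]["min"], node["low_stats"]["max"]],
                "high_range": [node["high_stats"]["min"], node["high_stats"]["max"]],
            }
        return Key({"taxa": sorted(set(self.classes)), "root": "1", "nodes": nodes})


def build_tree(
    nest_ratios: pd.DataFrame,
    labels: pd.Series | list[str],
    config: TreeConfig = TreeConfig(),
) -> InducedTree:
    """Induce the CART key from labeled nest-mean ratios.

    ``nest_ratios`` has one row per nest (index: nest id) and one
    column per ratio; columns are sorted for a deterministic feature
    order.  Classes with fewer nests than the minimum leaf size may end
    up unrepresented and trigger a warning.
    """
    X = nest_ratios[sorted(nest_ratios.columns)].astype(float)
    y = pd.Series([str(l) for l in labels], index=X.index)
    if y.nunique() < 2:
        est = config.estimator().fit(X.values, y.values)
        return InducedTree(est, X, y, config)
    small = y.value_counts()
    small = small[small < config.min_leaf]
    if not small.empty:
        warnings.warn(
            f"class(es) with fewer nests than min_leaf={config.min_leaf}: "
            f"{sorted(small.index)}; they may be unrepresented in the key",
            stacklevel=2,
        )
    est = config.estimator().fit(X.values, y.values)
    return InducedTree(est, X, y, config)


def loocv_tree(
    nest_ratios: pd.DataFrame,
    labels: pd.Series | list[str],
    config: TreeConfig = TreeConfig(),
) -> TreeValidation:
    """Leave-one-nest-out validation of the induced key.

    The overall rate counts nests correctly classified by a tree refit
    without them.  The per-node rates are branch-decision accuracies on
    the full tree: for each held-out nest routed through the full tree,
    a node's decision is correct when the nest descends toward the
    branch whose subtree contains its class (nests whose class occurs
    on both or neither side of a node do not score that node).
    """
    y = pd.Series([str(l) for l in labels], index=nest_ratios.index)
    counts = y.value_counts()
    full = build_tree(nest_ratios, y, config)
    side_classes = full.subtree_classes()

    hits = 0
    n_validated = 0
    skipped: list[str] = []
    node_hits: dict[int, list[int]] = {n: [0, 0] for n in full.internal_nodes}
    for nest in nest_ratios.index:
        if counts[y[nest]] - 1 < 1:
            skipped.append(str(nest))
            continue
        mask = nest_ratios.index != nest
        refit = build_tree(nest_ratios[mask], y[mask], config)
        pred = refit.predict(nest_ratios.loc[[nest]]).iloc[0]
        hits += int(pred == y[nest])
        n_validated += 1
        # per-node branch decisions on the full tree
        nid = 0
        while not full.nodes[nid]["is_leaf"]:
            node = full.nodes[nid]
            lo, hi = node["low"], node["high"]
            value = float(nest_ratios.loc[nest, node["feature"]])
            went = lo if value <= node["threshold"] else hi
            in_lo = y[nest] in side_classes[lo]
            in_hi = y[nest] in side_classes[hi]
            if in_lo != in_hi:
                correct_side = lo if in_lo else hi
                node_hits[nid][1] += 1
                node_hits[nid][0] += int(went == correct_side)
            nid = went
    per_node = {
        n: (h / t if t else float("nan")) for n, (h, t) in node_hits.items()
    }
    return TreeValidation(
        overall_rate=hits / n_validated if n_validated else float("nan"),
        per_node_rate=per_node,
        n_validated=n_validated,
        skipped=skipped,
    )


def node_ttest(tree: InducedTree, node_id: int) -> NodeTTest:
    """Welch two-sample t-test on a node's split feature between its
    two branch groups of training nests."""
    node = tree.nodes[node_id]
    if node["is_leaf"]:
        raise ValueError(f"node {node_id} is a leaf")
    feat, thr = node["feature"], node["threshold"]
    reached = tree.estimator.decision_path(tree.X.values).toarray()[:, node_id] > 0
    v = tree.X[feat].values
    a, b = v[reached & (v <= thr)], v[reached & (v > thr)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"node {node_id}: each branch group needs >= 2 nests")
    res = stats.ttest_ind(a, b, equal_var=False)
    return NodeTTest(
        node_id=node_id, feature=feat, t=float(res.statistic),
        df=float(res.df), p_value=float(res.pvalue),
    )


def node_ttests(tree: InducedTree) -> list[NodeTTest]:
    """All node t-tests with Holm-adjusted p-values alongside the raw ones."""
    tests = [node_ttest(tree, n) for n in tree.internal_nodes]
    order = np.argsort([t.p_value for t in tests])
    m = len(tests)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = (m - rank) * tests[idx].p_value
        running = max(running, min(1.0, adj))
        tests[idx].p_holm = running
    return tests


def render_key(tree: InducedTree, latin_prefix: str = "") -> str:
    """Render the induced tree as numbered dichotomous couplets.

    Each lobe states the split ratio, its threshold, the branch's
    [min, max] over the training nests, and either the next couplet
    number or the leaf taxon.
    """
    numbers = tree.couplet_numbers()
    if not numbers:
        return f"Only one taxon present: {latin_prefix}{tree.nodes[0]['taxon']}"
    lines: list[str] = []

    def describe(nid: int, side: str) -> str:
        node = tree.nodes[nid]
        s = node[f"{side}_stats"]
        op = "<" if side == "low" else ">"
        child = tree.nodes[node[side]]
        dest = (
            f"{latin_prefix}{child['taxon']}"
            if child["is_leaf"]
            else str(numbers[node[side]])
        )
        return (
            f"{node['feature']} {op} {node['threshold']:.4g} "
            f"[{s['min']:.4g}, {s['max']:.4g}] … {dest}"
        )

    for nid in sorted(numbers, key=numbers.get):
        num = numbers[nid]
        success = tree.nodes[nid]["success"]
        lines.append(f"{num}. {describe(nid, 'low')}  ({success:.0%})")
        lines.append(f"-  {describe(nid, 'high')}")
    return "\n".join(lines)


def substitute_region_node(
    key: Key,
    node_id: str,
    match_regions: list[str],
    if_match: dict,
    else_target: dict,
    note: str = "threshold replaced by geographic distribution",
) -> Key:
    """Replace one couplet of a serialized key by a region test.

    Mirrors the published key's manual substitution of two continuous
    thresholds with "more reliable data about geographic distribution".
    """
    data = {**key.data, "nodes": {k: dict(v) for k, v in key.nodes.items()}}
    data["nodes"][node_id] = {
        "type": "region",
        "feature": "region",
        "match": list(match_regions),
        "if_match": dict(if_match),
        "else": dict(else_target),
        "note": note,
    }
    return Key(data)
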