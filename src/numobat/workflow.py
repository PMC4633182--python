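"""High-level orchestration of the delimitation workflow.

Step 1: nest-centroid clustering (UPGMA and Ward in parallel);
Step 2: cross-linkage congruence → classification hypothesis with
wild-cards → iterative confirmatory LDA on individual workers with
nest-mean posteriors; validation by LOOCV.  These helpers glue the
stage modules together for the CLI, scripts and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cluster import (
    ClusterHypothesis,
    Dendrogram,
    agglomerate,
    centroid_matrix,
    congruence_hypothesis,
)
from .core import NestSample, SpecimenRecord, aggregate_nests
from .lda import LDAModel, WildcardResult, fit_lda, wildcard_iterate

__all__ = ["nest_ratio_frame", "DelimitationResult", "delimit_species"]


def nest_ratio_frame(
    nests: list[NestSample], ratio_names: list[str] | None = None
) -> pd.DataFrame:
    """Nest-mean ratio table (rows: nests, columns: named ratios)."""
    rows = {n.nest_id: dict(n.ratios(ratio_names).ratios) for n in nests}
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


@dataclass
class DelimitationResult:
    nests: list[NestSample]
    upgma: Dendrogram
    ward: Dendrogram
    hypothesis: ClusterHypothesis
    wildcard: WildcardResult
    model: LDAModel

    @property
    def final_labels(self) -> dict[str, str]:
        """nest_id → confirmed cluster label."""
        return self.wildcard.labels


def delimit_species(
    records: list[SpecimenRecord],
    k: int,
    *,
    traits: list[str] | None = None,
    max_iter: int = 25,
) -> DelimitationResult:
    """Run the exploratory + confirmatory pipeline at ``k`` clusters."""
    nests = aggregate_nests(records)
    cm = centroid_matrix(nests, traits)
    upgma = agglomerate(cm, "UPGMA")
    ward = agglomerate(cm, "WARD")
    hypothesis = congruence_hypothesis(upgma, ward, k)
    wc = wildcard_iterate(records, hypothesis, max_iter=max_iter)
    model = fit_lda(
        records, [wc.labels[r.nest_id] for r in records], traits=traits
    )
    return DelimitationResult(
        nests=nests, upgma=upgma, ward=ward, hypothesis=hypothesis,
        wildcard=wc, model=model,
    )
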