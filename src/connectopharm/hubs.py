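"""Split-half hub definition and hub-averaged metric extraction.

Hubs are defined on one randomly selected half of the control group only:
node degree (at the primary edge density) is averaged over those definition
subjects, and nodes whose mean degree exceeds the across-node mean by more
than ``k`` standard deviations (default 1.5) are designated hubs.  The held
out half of the controls is reserved for evaluation, so group comparisons of
hub metrics never reuse the subjects that chose the hubs.  An odd control
count puts the extra subject in the evaluation half (75 controls -> 37
definition, 38 evaluation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import BinaryGraph
from .metrics import HUB_METRICS, NODE_METRICS, MetricsRecord

__all__ = ["HubSet", "split_half", "identify_hubs", "hub_summary"]


@dataclass
class HubSet:
    """Hub node ids plus the provenance of the decision."""

    hub_nodes: np.ndarray
    definition_cohort: list[str]
    evaluation_cohort: list[str]
    threshold: float
    mean_degree: np.ndarray  # per node, across definition subjects
    k: float = 1.5

    def __post_init__(self) -> None:
        self.hub_nodes = np.asarray(self.hub_nodes, dtype=int)
        self.mean_degree = np.asarray(self.mean_degree, dtype=float)
        if set(self.definition_cohort) & set(self.evaluation_cohort):
            raise ValueError("definition and evaluation cohorts must be disjoint")
        if self.hub_nodes.size and (
            self.hub_nodes.min() < 0 or self.hub_nodes.max() >= self.mean_degree.size
        ):
            raise ValueError("hub node index outside the node set")

    @property
    def n_hubs(self) -> int:
        return self.hub_nodes.size


def split_half(control_ids: list[str], seed: int = 0) -> tuple[list[str], list[str]]:
    """Random disjoint split of controls into definition and evaluation halves.

    With an odd count the extra subject goes to the evaluation half.
    """
    ids = list(control_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 controls to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_def = len(ids) // 2
    definition = [ids[i] for i in sorted(perm[:n_def])]
    evaluation = [ids[i] for i in sorted(perm[n_def:])]
    return definition, evaluation


def identify_hubs(
    definition_graphs: dict[str, BinaryGraph],
    k: float = 1.5,
    evaluation_cohort: list[str] | None = None,
) -> HubSet:
    """Hub set from the definition cohort's graphs at one density.

    Per-node degree is averaged across the definition subjects; hubs are the
    nodes whose mean degree exceeds ``mean + k * SD``, with mean and SD
    taken across *nodes* of that cohort-mean degree vector (the rule selects
    nodes, so the spread that matters is the spread over nodes).
    """
    if not definition_graphs:
        raise ValueError("no definition graphs supplied")
    graphs = list(definition_graphs.values())
    n = graphs[0].n_nodes
    if any(g.n_nodes != n for g in graphs):
        raise ValueError("definition graphs have inconsistent node sets")
    labels = graphs[0].node_labels
    if any(g.node_labels != labels for g in graphs):
        raise ValueError("definition graphs have inconsistent node labels")

    mean_deg = np.mean([g.degree() for g in graphs], axis=0)
    mu, sigma = mean_deg.mean(), mean_deg.std(ddof=0)
    threshold = mu + k * sigma
    hubs = np.flatnonzero(mean_deg > threshold) if sigma > 0 else np.array([], dtype=int)
    return HubSet(
        hub_nodes=hubs,
        definition_cohort=sorted(definition_graphs),
        evaluation_cohort=sorted(evaluation_cohort or []),
        threshold=float(threshold),
        mean_degree=mean_deg,
        k=k,
    )


def hub_summary(record: MetricsRecord, hubs: HubSet) -> MetricsRecord:
    """Fill the hub-averaged centrality fields of a MetricsRecord in place.

    With an empty hub set the hub fields stay missing (NaN) and a warning is
    emitted.
    """
    if hubs.n_hubs == 0:
        warnings.warn(
            f"empty hub set: hub metrics left missing for {record.subject_id}",
            stacklevel=2,
        )
        for name in HUB_METRICS:
            setattr(record, name, np.nan)
        return record
    if hubs.hub_nodes.max() >= record.n_nodes:
        raise ValueError("hub ids outside the record's node set")
    for metric, field_name in zip(NODE_METRICS, HUB_METRICS):
        setattr(record, field_name, float(record.node_metric(metric)[hubs.hub_nodes].mean()))
    return record
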