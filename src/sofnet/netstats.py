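"""Graph-level summaries of the selected connectivity model.

The selected edges form a small weighted graph over the 17 networks.  A
network's *importance* is the L1 norm of the selected weights on its incident
edges; summing importances over all networks double-counts every edge, so the
grand total is twice the model's L1 norm.  The storage-vs-retrieval contrast
is a one-sample t test of the storage-group importances (zeros included for
networks never selected) against zero.  For interpretation, each β weight can
be sign-adjusted by the direction of its group-mean connectivity, so that a
positive adjusted weight always means "more connectivity, faster forgetting".
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import ConnectivityMatrix, Parcellation, YEO17

__all__ = [
    "ImportanceTable",
    "node_importance",
    "storage_retrieval_test",
    "selection_enrichment",
    "sign_adjusted_weights",
]


@dataclass(frozen=True)
class ImportanceTable:
    """Per-network L1 importance with group labels."""

    table: pd.DataFrame  # index: network; columns: importance, group

    def importance(self, network: str) -> float:
        return float(self.table.loc[network, "importance"])

    def by_group(self, group: str) -> pd.Series:
        return self.table.loc[self.table["group"] == group, "importance"]


def _edge_endpoints(edge: str) -> tuple[str, str]:
    a, _, b = edge.partition("~")
    if not b:
        raise ValueError(f"edge {edge!r} is not of the form 'A~B'")
    return a, b


def node_importance(
    betas: Mapping[str, float],
    parcellation: Parcellation = YEO17,
) -> ImportanceTable:
    """L1 norm of selected edge weights incident to each network.

    ``betas`` maps edge names (``"Default A~Visual A"``) to weights; networks
    with no selected edge get importance 0.
    """
    imp = {n: 0.0 for n in parcellation.networks}
    for edge, b in betas.items():
        a, c = _edge_endpoints(edge)
        for endpoint in (a, c):
            if endpoint not in imp:
                raise KeyError(f"unknown network {endpoint!r} in edge {edge!r}")
        imp[a] += abs(b)
        imp[c] += abs(b)
    df = pd.DataFrame(
        {
            "importance": [imp[n] for n in parcellation.networks],
            "group": [parcellation.groups[n] for n in parcellation.networks],
        },
        index=list(parcellation.networks),
    )
    return ImportanceTable(df)


def storage_retrieval_test(
    importances: ImportanceTable,
) -> tuple[float, float, float | None, int, float | None]:
    """One-sample t test of the storage-network importances against zero.

    Unselected storage networks contribute zeros.  Returns
    (mean, sd, t, dof, p) with the n−1 sample SD; a zero-variance sample
    yields ``t = p = None`` (undefined-statistic flag).
    """
    vals = importances.by_group("Storage").to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 storage networks")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    dof = len(vals) - 1
    if sd == 0:
        return mean, sd, None, dof, None
    t = mean / (sd / np.sqrt(len(vals)))
    p = float(2 * stats.t.sf(abs(t), dof))
    return mean, sd, float(t), dof, p


def selection_enrichment(
    selected_edges: Sequence[str],
    parcellation: Parcellation = YEO17,
    within_dmn: Literal["exclude", "storage", "neither"] = "exclude",
) -> float:
    """Probability that a uniform draw of as many edges from the DMN-anchored
    pool is at least as storage-pure as the observed selection.

    Each edge's non-DMN endpoint determines its group.  Within-DMN edges are
    handled per ``within_dmn``: excluded from pool and draw (default), or
    counted with the storage group, or kept in the pool but in neither group
    (in which case an all-storage draw must avoid them too).  With k observed
    storage edges out of k drawn, the probability is the hypergeometric
    point mass C(S, k)/C(N, k) of drawing only storage edges.
    """
    dmn = set(parcellation.dmn)
    others = [n for n in parcellation.networks if n not in dmn]
    n_within = len(parcellation.dmn) * (len(parcellation.dmn) - 1) // 2
    n_cross = len(parcellation.dmn) * len(others)
    n_storage_cross = len(parcellation.dmn) * len(parcellation.storage)

    def classify(edge: str) -> str:
        a, b = _edge_endpoints(edge)
        if a in dmn and b in dmn:
            return "within"
        out = b if a in dmn else a
        if out not in parcellation.groups:
            raise KeyError(f"unknown network {out!r}")
        return parcellation.groups[out].lower()

    kinds = [classify(e) for e in selected_edges]
    if within_dmn == "exclude":
        pool, storage_pool = n_cross, n_storage_cross
        kinds = [k for k in kinds if k != "within"]
    elif within_dmn == "storage":
        pool = n_cross + n_within
        storage_pool = n_storage_cross + n_within
        kinds = ["storage" if k == "within" else k for k in kinds]
    elif within_dmn == "neither":
        pool, storage_pool = n_cross + n_within, n_storage_cross
    else:
        raise ValueError(f"unknown within_dmn convention {within_dmn!r}")
    k = len(kinds)
    if k > pool:
        raise ValueError(f"cannot draw {k} edges from a pool of {pool}")
    if k == 0:
        return 1.0
    if any(kind not in ("storage", "retrieval", "within") for kind in kinds):
        raise ValueError(f"unclassifiable edges among {kinds}")
    if any(kind != "storage" for kind in kinds):
        return 1.0  # observed selection is not storage-pure; event is certain
    return comb(storage_pool, k) / comb(pool, k)


def sign_adjusted_weights(
    betas: Mapping[str, float],
    group_mean: ConnectivityMatrix,
) -> dict[str, float]:
    """β weights multiplied by the sign of the group-mean connectivity.

    A positive adjusted weight means an *increase* in (signed) connectivity
    predicts faster forgetting even when the underlying edge is
    anti-correlated at the group level.  An exactly-zero group mean yields a
    zero weight with a warning.
    """
    import warnings

    out: dict[str, float] = {}
    for edge, b in betas.items():
        a, c = _edge_endpoints(edge)
        m = group_mean[a, c]
        if m == 0.0:
            warnings.warn(
                f"group-mean connectivity of {edge!r} is exactly 0; "
                "sign-adjusted weight set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            out[edge] = 0.0
        else:
            out[edge] = b * float(np.sign(m))
    return out
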