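"""Network-level functional connectomes and DMN edge features.

Time series from the 17 networks of the Yeo parcellation are reduced to
17×17 Pearson or partial-correlation matrices.  Partial correlations between
two networks condition on the remaining 15 and are computed from the inverse
covariance (precision) matrix.  Group averages use Fisher's r-to-z
transformation.  The predictive analysis consumes the 45 edges that involve
at least one Default Mode subnetwork: the 3 within-DMN pairs plus each DMN
subnetwork's 14 connections to the other networks (3×14 + 3 = 45).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "ConnectivityMatrix",
    "YEO17",
    "pearson_connectome",
    "partial_connectome",
    "fisher_group_average",
    "extract_features",
    "feature_names",
]

Group = Literal["DMN", "Storage", "Retrieval"]


@dataclass(frozen=True)
class Parcellation:
    """Ordered network names and their DMN/Storage/Retrieval assignment."""

    networks: tuple[str, ...]
    groups: dict[str, Group]

    def __post_init__(self) -> None:
        if set(self.networks) != set(self.groups):
            raise ValueError("groups must cover exactly the listed networks")
        bad = {g for g in self.groups.values()} - {"DMN", "Storage", "Retrieval"}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def dmn(self) -> list[str]:
        return [n for n in self.networks if self.groups[n] == "DMN"]

    @property
    def storage(self) -> list[str]:
        return [n for n in self.networks if self.groups[n] == "Storage"]

    @property
    def retrieval(self) -> list[str]:
        return [n for n in self.networks if self.groups[n] == "Retrieval"]

    def index(self, name: str) -> int:
        try:
            return self.networks.index(name)
        except ValueError:
            raise KeyError(f"unknown network {name!r}") from None


#: The 17-network Yeo resting-state parcellation, in its canonical order,
#: with each non-DMN network assigned to the storage group (sensory,
#: somatomotor and salience regions supporting encoding and consolidation)
#: or the retrieval group (frontoparietal control regions supporting
#: voluntary memory access).
YEO17 = Parcellation(
    networks=(
        "Visual A",
        "Visual B",
        "Somatomotor A",
        "Somatomotor B",
        "Dorsal Attention A",
        "Dorsal Attention B",
        "Salience A",
        "Salience B",
        "Limbic A",
        "Limbic B",
        "Control A",
        "Control B",
        "Control C",
        "Default A",
        "Default B",
        "Default C",
        "Temporal Parietal",
    ),
    groups={
        "Visual A": "Storage",
        "Visual B": "Storage",
        "Somatomotor A": "Storage",
        "Somatomotor B": "Storage",
        "Dorsal Attention A": "Retrieval",
        "Dorsal Attention B": "Storage",
        "Salience A": "Storage",
        "Salience B": "Retrieval",
        "Limbic A": "Storage",
        "Limbic B": "Retrieval",
        "Control A": "Retrieval",
        "Control B": "Retrieval",
        "Control C": "Storage",
        "Default A": "DMN",
        "Default B": "DMN",
        "Default C": "DMN",
        "Temporal Parietal": "Retrieval",
    },
)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric network×network correlation matrix with unit diagonal."""

    values: np.ndarray
    networks: tuple[str, ...]
    kind: Literal["pearson", "partial"]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.networks)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        off = v[~np.eye(n, dtype=bool)]
        if np.any(np.abs(off) > 1 + 1e-9):
            raise ValueError("off-diagonal entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        i = self.networks.index(a)
        j = self.networks.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.networks), columns=list(self.networks)
        )


def _as_array(ts: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(ts, pd.DataFrame):
        return ts.to_numpy(dtype=float), tuple(map(str, ts.columns))
    arr = np.asarray(ts, dtype=float)
    return arr, tuple(f"roi{i:02d}" for i in range(arr.shape[1]))


def pearson_connectome(
    ts: np.ndarray | pd.DataFrame,
    networks: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Product-moment correlation matrix of ROI time series (volumes × networks)."""
    arr, names = _as_array(ts)
    if networks is not None:
        names = tuple(networks)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 volumes")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        dead = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance time series for network(s): {dead}")
    r = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2
    return ConnectivityMatrix(values=r, networks=names, kind="pearson")


def partial_connectome(
    ts: np.ndarray | pd.DataFrame,
    networks: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Partial correlations of each network pair given the remaining networks.

    Computed from the precision matrix Ω = Σ⁻¹ as ρ_ij = −Ω_ij/√(Ω_ii·Ω_jj);
    algebraically identical to correlating the residuals of each pair after
    regressing out the other 15 series.  A singular covariance triggers a
    ridge-regularized inverse (λ = 1e−6 × mean diagonal) with a warning.
    The diagonal is reported as 1 by convention.
    """
    arr, names = _as_array(ts)
    if networks is not None:
        names = tuple(networks)
    n_vol, n_net = arr.shape
    if n_vol <= n_net + 1:
        raise ValueError(
            f"need more than {n_net + 1} volumes for {n_net} networks, got {n_vol}"
        )
    cov = np.cov(arr, rowvar=False)
    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        lam = 1e-6 * float(np.mean(np.diag(cov)))
        warnings.warn(
            f"singular covariance; using ridge-regularized inverse (λ={lam:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
        omega = np.linalg.inv(cov + lam * np.eye(n_net))
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2
    rho = np.clip(rho, -1.0, 1.0)
    return ConnectivityMatrix(values=rho, networks=names, kind="partial")


def fisher_group_average(
    matrices: Iterable[ConnectivityMatrix],
) -> ConnectivityMatrix:
    """Group-average connectivity via Fisher r-to-z: tanh(mean(atanh r))."""
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices to average")
    kinds = {m.kind for m in mats}
    nets = {m.networks for m in mats}
    if len(kinds) > 1 or len(nets) > 1:
        raise ValueError("matrices must share kind and parcellation")
    stack = np.stack([m.values for m in mats])
    if np.any(np.abs(stack) >= 1 - 1e-12):
        off = ~np.eye(stack.shape[1], dtype=bool)
        if np.any(np.abs(stack[:, off]) >= 1 - 1e-12):
            warnings.warn(
                "|r| = 1 encountered; clipping before z-transform",
                RuntimeWarning,
                stacklevel=2,
            )
    clipped = np.clip(stack, -(1 - 1e-7), 1 - 1e-7)
    avg = np.tanh(np.mean(np.arctanh(clipped), axis=0))
    np.fill_diagonal(avg, 1.0)
    return ConnectivityMatrix(values=avg, networks=mats[0].networks, kind=mats[0].kind)


def feature_names(parcellation: Parcellation = YEO17) -> list[str]:
    """Canonical order of the 45 DMN-anchored edge features.

    The 3 within-DMN pairs first (A–B, A–C, B–C), then each DMN subnetwork's
    edges to the 14 non-DMN networks, partners in parcellation order.  The
    LASSO β weights are reported in — and only meaningful under — this order.
    """
    dmn = parcellation.dmn
    others = [n for n in parcellation.networks if n not in dmn]
    names = [f"{a}~{b}" for i, a in enumerate(dmn) for b in dmn[i + 1:]]
    for a in dmn:
        names.extend(f"{a}~{b}" for b in others)
    return names


def extract_features(
    matrix: ConnectivityMatrix,
    parcellation: Parcellation = YEO17,
) -> pd.Series:
    """The 45 DMN-anchored edge values of a connectivity matrix, in canonical
    order, as a named Series."""
    missing = set(parcellation.networks) - set(matrix.networks)
    if missing:
        raise KeyError(f"matrix lacks networks: {sorted(missing)}")
    vals = []
    for name in feature_names(parcellation):
        a, b = name.split("~")
        vals.append(matrix[a, b])
    return pd.Series(vals, index=feature_names(parcellation), dtype=float)
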