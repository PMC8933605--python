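"""Per-channel network features of a directed adjacency matrix.

For an adjacency matrix whose entry (l, s) is the flow from channel s to
channel l:

* inflow(g)  = sum over s of entry (g, s)   -- the g-th row sum,
* outflow(g) = sum over l of entry (l, g)   -- the g-th column sum,
* information flow IF(g) = outflow(g) / inflow(g),

and the classification feature vector is the serial fusion
``[IF_1..IF_N, OUT_1..OUT_N]`` of length 2N.

Under the default full row normalization with self-terms included, every
inflow is identically 1 and IF therefore equals OUT elementwise; this
degeneracy is deliberate (the definitions are implemented exactly as
stated) and is discussed in the methods notes.  With ``exclude_self``
adjacency matrices the three vectors are genuinely distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DegenerateInputError
from .connectivity import AdjacencyMatrix

__all__ = [
    "NetworkFeatures",
    "inflow",
    "outflow",
    "information_flow",
    "feature_vector",
    "network_features",
    "features_to_csv",
]


@dataclass
class NetworkFeatures:
    """Inflow/outflow/information-flow vectors of one adjacency matrix."""

    inflow: np.ndarray
    outflow: np.ndarray
    info_flow: np.ndarray
    fused: np.ndarray
    band: str
    m: int
    channels: list[str]


def inflow(am: AdjacencyMatrix) -> np.ndarray:
    """Row sums: total information received by each channel."""
    return am.values.sum(axis=1)


def outflow(am: AdjacencyMatrix) -> np.ndarray:
    """Column sums: total information emitted by each channel."""
    return am.values.sum(axis=0)


def information_flow(am: AdjacencyMatrix) -> np.ndarray:
    """Outflow-to-inflow ratio per channel."""
    in_ = inflow(am)
    if (in_ <= 0).any():
        raise DegenerateInputError(
            "information flow undefined: some channel has zero inflow"
        )
    return outflow(am) / in_


def feature_vector(am: AdjacencyMatrix) -> np.ndarray:
    """Length-2N fused vector ``[IF_1..IF_N, OUT_1..OUT_N]``."""
    return np.concatenate([information_flow(am), outflow(am)])


def network_features(am: AdjacencyMatrix) -> NetworkFeatures:
    """All feature vectors of one adjacency matrix, bundled."""
    return NetworkFeatures(
        inflow=inflow(am),
        outflow=outflow(am),
        info_flow=information_flow(am),
        fused=feature_vector(am),
        band=am.band.name,
        m=am.m,
        channels=list(am.channels),
    )


def features_to_csv(
    features: np.ndarray,
    labels: np.ndarray,
    channels: list[str],
    band: str,
    m: int,
    path: str | Path,
) -> Path:
    """Write a trials x 2N feature matrix as CSV.

    Columns: ``trial``, ``label``, ``band``, ``m``, then ``IF_<ch>`` and
    ``OUT_<ch>`` per channel in order.
    """
    features = np.asarray(features)
    n = len(channels)
    if features.shape[1] != 2 * n:
        raise ValueError(
            f"feature matrix has {features.shape[1]} columns, expected {2 * n}"
        )
    cols = [f"IF_{c}" for c in channels] + [f"OUT_{c}" for c in channels]
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "m", int(m))
    df.insert(0, "band", band)
    df.insert(0, "label", np.asarray(labels))
    df.insert(0, "trial", np.arange(len(df)))
    path = Path(path)
    df.to_csv(path, index=False)
    return path
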