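"""Signed bipartite TF-target network construction by correlation thresholding.

Edges connect a regulator layer (TFs) to a disjoint target layer: a TF-target
pair is linked when the absolute Pearson correlation of their expression (or
fold-change) profiles reaches a threshold (0.8 by default), with the sign of
the correlation read as activation (+) or repression (-).  The edge set
doubles as the connectivity pattern constraining the NCA decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nca import ConnectivityPattern

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignedEdge:
    tf_id: str
    target_id: str
    weight: float   # Pearson r
    sign: int       # +1 activation, -1 repression

    def __post_init__(self) -> None:
        if not -1.0 <= self.weight <= 1.0:
            raise ValueError(f"correlation weight {self.weight} outside [-1, 1]")
        if self.sign != (1 if self.weight > 0 else -1):
            raise ValueError("edge sign must equal sign(weight)")


@dataclass
class RegulatoryNetwork:
    """Signed bipartite TF -> target edge set."""

    tfs: list[str]
    targets: list[str]
    edges: list[SignedEdge]

    def __post_init__(self) -> None:
        overlap = set(self.tfs) & set(self.targets)
        if overlap:
            raise ValueError(f"TF and target layers overlap: {sorted(overlap)[:5]}")
        pairs = [(e.tf_id, e.target_id) for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (tf, target) edges")
        tfset, tgset = set(self.tfs), set(self.targets)
        for e in self.edges:
            if e.tf_id not in tfset or e.target_id not in tgset:
                raise ValueError(f"edge {e.tf_id}->{e.target_id} references unknown node")
        connected = {e.tf_id for e in self.edges}
        dangling = tfset - connected
        if dangling:
            raise ValueError(f"TFs without edges: {sorted(dangling)[:5]}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_pattern(self) -> ConnectivityPattern:
        """Targets x TFs signed connectivity pattern for the NCA stage."""
        t_index = {t: i for i, t in enumerate(self.targets)}
        f_index = {f: i for i, f in enumerate(self.tfs)}
        entries = tuple((t_index[e.target_id], f_index[e.tf_id]) for e in self.edges)
        signs = tuple(e.sign for e in self.edges)
        return ConnectivityPattern(len(self.targets), len(self.tfs), entries, signs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.tf_id, e.target_id, e.weight, e.sign) for e in self.edges],
            columns=["tf_id", "target_id", "r", "sign"])


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def correlation_profiles(tf_profiles: np.ndarray,
                         tg_profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation between every TF profile and every target profile.

    Inputs are TFs x conditions and targets x conditions over the same
    condition axis (>= 3 points).  Constant rows have undefined correlation;
    they yield NaN in the result and a warning, and are therefore never
    thresholded into the network.
    """
    tf = np.asarray(tf_profiles, dtype=float)
    tg = np.asarray(tg_profiles, dtype=float)
    if tf.ndim != 2 or tg.ndim != 2:
        raise ValueError("profiles must be 2-D")
    if tf.shape[1] != tg.shape[1]:
        raise ValueError(
            f"condition axes differ: {tf.shape[1]} vs {tg.shape[1]}")
    if tf.shape[1] < 3:
        raise ValueError("need >= 3 conditions for a meaningful correlation")

    def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = x - x.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(c, axis=1)
        flat = norm == 0
        safe = np.where(flat, 1.0, norm)
        return c / safe[:, None], flat

    ztf, flat_tf = _standardize(tf)
    ztg, flat_tg = _standardize(tg)
    if flat_tf.any() or flat_tg.any():
        warnings.warn(
            f"{int(flat_tf.sum())} TF and {int(flat_tg.sum())} target profiles "
            "are constant; their correlations are undefined (NaN)",
            stacklevel=2)
    corr = np.clip(ztf @ ztg.T, -1.0, 1.0)
    corr[flat_tf, :] = np.nan
    corr[:, flat_tg] = np.nan
    return corr


def build_signed_network(corr: np.ndarray, threshold: float,
                         tf_ids: list[str], target_ids: list[str]) -> RegulatoryNetwork:
    """Threshold a TF x target correlation matrix into a signed network.

    An edge exists iff |r| >= threshold (NaN never qualifies); its sign is
    sign(r).  Targets that also appear in the TF list are removed from the
    target layer first, and TFs left with no surviving edge are dropped with
    a log record, so the result is a clean bipartite network in which every
    listed TF is connected.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(tf_ids), len(target_ids)):
        raise ValueError("corr shape does not match id lists")

    tfset = set(tf_ids)
    keep_tg = [j for j, t in enumerate(target_ids) if t not in tfset]
    dropped_overlap = len(target_ids) - len(keep_tg)
    if dropped_overlap:
        logger.info("removed %d targets also present in the TF layer",
                    dropped_overlap)

    edges_by_tf: dict[str, list[SignedEdge]] = {}
    for i, tf in enumerate(tf_ids):
        for j in keep_tg:
            r = corr[i, j]
            if np.isnan(r) or abs(r) < threshold:
                continue
            edges_by_tf.setdefault(tf, []).append(
                SignedEdge(tf, target_ids[j], float(r), 1 if r > 0 else -1))

    kept_tfs = [tf for tf in tf_ids if tf in edges_by_tf]
    dropped_tfs = [tf for tf in tf_ids if tf not in edges_by_tf]
    if dropped_tfs:
        logger.info("dropped %d TFs with no edge at |r| >= %g: %s",
                    len(dropped_tfs), threshold, dropped_tfs)
    edges = [e for tf in kept_tfs for e in edges_by_tf[tf]]
    connected_targets = {e.target_id for e in edges}
    targets = [target_ids[j] for j in keep_tg
               if target_ids[j] in connected_targets]
    return RegulatoryNetwork(tfs=kept_tfs, targets=targets, edges=edges)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def degree_table(net: RegulatoryNetwork) -> pd.DataFrame:
    """Per-TF connection counts split into activations and repressions.

    Sorted by total connections descending (ties by TF id) — the ordering of
    the study's printed degree table.
    """
    rows = []
    for tf in net.tfs:
        tf_edges = [e for e in net.edges if e.tf_id == tf]
        act = sum(1 for e in tf_edges if e.sign > 0)
        rep = sum(1 for e in tf_edges if e.sign < 0)
        rows.append({"tf_id": tf, "connections": act + rep,
                     "activations": act, "repressions": rep})
    table = pd.DataFrame(rows, columns=["tf_id", "connections",
                                        "activations", "repressions"])
    if table.empty:
        return table
    return (table.sort_values(["connections", "tf_id"],
                              ascending=[False, True])
            .reset_index(drop=True))


def hub_summary(net: RegulatoryNetwork, k: int = 5) -> dict:
    """Degree distribution and the top-k hub TFs (no distribution fit)."""
    table = degree_table(net)
    degrees = table["connections"].to_numpy()
    dist = (pd.Series(degrees).value_counts().sort_index()
            .rename_axis("degree").rename("n_tfs").reset_index())
    return {
        "degree_sequence": sorted(degrees.tolist(), reverse=True),
        "top": table.head(k)[["tf_id", "connections"]].to_records(index=False).tolist(),
        "distribution": dist,
    }


def intersect_curated(de_tfs: set[str], curated: set[str]) -> list[str]:
    """Differentially expressed TFs that are also in the curated heat list,
    in deterministic lexicographic order."""
    return sorted(set(de_tfs) & set(curated))
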