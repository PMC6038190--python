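"""Downstream piRNA signature statistics.

Given deregulation calls, this module computes the analyses that characterize
a disease- or differentiation-associated piRNA signature: element-of-origin
enrichment of a called set against the genome-wide null proportions (per-class
one-vs-rest chi-square goodness of fit, 1 df), positional cytosine-composition
comparison between called sets and the full reference, the "memory" fraction
of deregulated piRNAs already deregulated in parental fibroblasts,
direction-stratified overlaps between two cohorts, and hierarchical
clustering of samples on a selected feature panel with group-separation
scoring (adjusted Rand index).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .de import DECall
from .quantify import positional_base_content
from .reference import ORIGIN_CLASSES, ReferenceSet


def chi2_gof_1df(k: float, n: float, p0: float) -> float:
    """One-vs-rest goodness-of-fit statistic, 1 df, no continuity correction.

    chi2 = (k - n p0)^2 / (n p0) + ((n-k) - n(1-p0))^2 / (n(1-p0)).
    """
    e1 = n * p0
    e0 = n * (1.0 - p0)
    return (k - e1) ** 2 / e1 + ((n - k) - e0) ** 2 / e0


def origin_enrichment(
    query_ids: Iterable[str],
    ref: ReferenceSet,
    null_props: pd.Series,
) -> pd.DataFrame:
    """Test each origin class for over/under-representation in a query set.

    The null proportions are treated as fixed (the genome-wide abundance of
    each class among all reference piRNAs), so each class gets a one-vs-rest
    chi-square goodness-of-fit test with 1 df; the reported p is the upper
    tail, the conventional reading of a "two-sided chi-square test". Classes
    with p0 of exactly 0 or 1 are marked untestable.
    """
    ids = list(query_ids)
    if not ids:
        raise ValueError("origin_enrichment: empty query set")
    missing = [i for i in ids if i not in ref]
    if missing:
        raise KeyError(f"query ids not in reference: {missing[:5]}")
    n = len(ids)
    obs = {c: 0 for c in ORIGIN_CLASSES}
    for i in ids:
        obs[ref[i].origin_class] += 1

    rows = []
    for cls in ORIGIN_CLASSES:
        p0 = float(null_props.get(cls, 0.0))
        k = obs[cls]
        expected = n * p0
        testable = 0.0 < p0 < 1.0
        if testable:
            chi2 = chi2_gof_1df(k, n, p0)
            p = float(stats.chi2.sf(chi2, df=1))
            if k > expected:
                direction = "enriched"
            elif k < expected:
                direction = "depleted"
            else:
                direction = "none"
        else:
            chi2, p, direction = np.nan, np.nan, "untestable"
        rows.append(
            {
                "origin_class": cls,
                "k": k,
                "n": n,
                "p0": p0,
                "expected": expected,
                "chi2": chi2,
                "p": p,
                "direction": direction,
                "testable": testable,
            }
        )
    return pd.DataFrame(rows).set_index("origin_class")


@dataclass(frozen=True)
class CompositionBias:
    """Positional base-composition profiles for up/down/universe sets."""

    base: str
    up: pd.DataFrame
    down: pd.DataFrame
    universe: pd.DataFrame
    diff_up: pd.Series  # up fraction - universe fraction, per position
    diff_down: pd.Series
    threshold: float

    @property
    def flagged_up(self) -> list[int]:
        d = self.diff_up.dropna()
        return list(d.index[d.abs() > self.threshold])

    @property
    def flagged_down(self) -> list[int]:
        d = self.diff_down.dropna()
        return list(d.index[d.abs() > self.threshold])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frac_up": self.up["fraction"],
                "frac_down": self.down["fraction"],
                "frac_all": self.universe["fraction"],
                "denom_up": self.up["denominator"],
                "denom_down": self.down["denominator"],
                "denom_all": self.universe["denominator"],
                "diff_up": self.diff_up,
                "diff_down": self.diff_down,
            }
        )


def composition_bias(
    up_ids: Iterable[str],
    down_ids: Iterable[str],
    universe_ids: Iterable[str],
    ref: ReferenceSet,
    base: str = "C",
    max_pos: int = 29,
    threshold: float = 0.1,
) -> CompositionBias:
    """Compare positional base content of the up/down sets against the universe.

    In the disease signature, cytosine is over-represented at positions 2-9 of
    the upregulated piRNAs relative to all piRNAs analysed; this reports the
    per-position profiles and the up-all / down-all differences, flagging
    positions where |difference| exceeds ``threshold``.
    """
    up, down, uni = list(up_ids), list(down_ids), list(universe_ids)
    if not uni:
        raise ValueError("composition_bias: empty universe")
    if set(up) & set(down):
        raise ValueError("composition_bias: up and down sets overlap")
    prof_uni = positional_base_content(ref.sequences(uni), base, max_pos)
    empty = pd.DataFrame(
        {"fraction": np.nan, "denominator": 0},
        index=pd.RangeIndex(1, max_pos + 1, name="position"),
    )
    prof_up = positional_base_content(ref.sequences(up), base, max_pos) if up else empty
    prof_down = positional_base_content(ref.sequences(down), base, max_pos) if down else empty.copy()
    return CompositionBias(
        base=base,
        up=prof_up,
        down=prof_down,
        universe=prof_uni,
        diff_up=prof_up["fraction"] - prof_uni["fraction"],
        diff_down=prof_down["fraction"] - prof_uni["fraction"],
        threshold=threshold,
    )


@dataclass(frozen=True)
class MemoryReport:
    """Fraction of stage-deregulated piRNAs already deregulated in fibroblasts."""

    stage: str
    n_memory: int
    n_total_deregulated: int
    memory_ids: tuple[str, ...]

    @property
    def fraction(self) -> float:
        return self.n_memory / self.n_total_deregulated


def memory_fraction(
    stage_call: DECall,
    fibro_call: DECall,
    direction_matched: bool = False,
    stage: str = "",
) -> MemoryReport:
    """Memory piRNAs: stage-deregulated features already called in fibroblasts.

    Default is direction-agnostic membership; ``direction_matched=True``
    additionally requires the same direction in both stages.
    """
    stage_all = stage_call.all_ids
    if not stage_all:
        raise ValueError("memory_fraction: empty stage call")
    if direction_matched:
        mem = (stage_call.up & fibro_call.up) | (stage_call.down & fibro_call.down)
    else:
        mem = stage_all & fibro_call.all_ids
    return MemoryReport(
        stage=stage,
        n_memory=len(mem),
        n_total_deregulated=len(stage_all),
        memory_ids=tuple(sorted(mem)),
    )


@dataclass(frozen=True)
class OverlapReport:
    """Direction-stratified overlap of two deregulation calls."""

    up_shared: tuple[str, ...]
    down_shared: tuple[str, ...]
    n_up_a: int
    n_up_b: int
    n_down_a: int
    n_down_b: int

    @property
    def n_up_shared(self) -> int:
        return len(self.up_shared)

    @property
    def n_down_shared(self) -> int:
        return len(self.down_shared)

    @property
    def n_shared_deregulated(self) -> int:
        return len(set(self.up_shared) | set(self.down_shared))


def direction_overlap(call_a: DECall, call_b: DECall) -> OverlapReport:
    """Up-with-up and down-with-down overlaps between two cohorts' calls."""
    return OverlapReport(
        up_shared=tuple(sorted(call_a.up & call_b.up)),
        down_shared=tuple(sorted(call_a.down & call_b.down)),
        n_up_a=len(call_a.up),
        n_up_b=len(call_b.up),
        n_down_a=len(call_a.down),
        n_down_b=len(call_b.down),
    )


@dataclass(frozen=True)
class ClusterReport:
    """Two-cluster cut of a sample dendrogram and its agreement with groups."""

    linkage_matrix: np.ndarray
    labels: pd.Series
    ari: float


def hcluster(
    log_matrix: pd.DataFrame,
    feature_ids: Sequence[str],
    sheet: pd.DataFrame,
    group_col: str = "group",
) -> ClusterReport:
    """Hierarchically cluster samples on a feature panel; score group separation.

    Distance is 1 - Pearson correlation between sample columns over the
    selected features, with average linkage and a two-cluster cut; the
    adjusted Rand index compares the cut to the sample-sheet groups.
    """
    missing = [f for f in feature_ids if f not in log_matrix.index]
    if missing:
        raise KeyError(f"features absent from matrix: {missing[:5]}")
    sub = log_matrix.loc[list(feature_ids)]
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    sds = sub.std(axis=0, ddof=0)
    flat = list(sds.index[sds == 0])
    if flat:
        raise ValueError(
            f"zero-variance sample column(s) {flat}: correlation distance undefined"
        )
    corr = np.corrcoef(sub.to_numpy().T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(Z, t=2, criterion="maxclust")
    groups = sheet.loc[sub.columns, group_col].astype(str)
    ari = float(adjusted_rand_score(groups.to_numpy(), labels))
    return ClusterReport(
        linkage_matrix=Z,
        labels=pd.Series(labels, index=sub.columns, name="cluster"),
        ari=ari,
    )
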