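"""TF subclass assignment from motif similarity.

TFs within a family are grouped into subclasses by hierarchical clustering of
their pairwise motif similarity: clustering runs on the distance 1 - r, the
number of subclasses k is chosen by the elbow rule (smallest k whose
within-cluster sum of squares drops below 10% of the unpartitioned WSS), and
subclasses with fewer than five members are flagged as excluded from
downstream subclass-determining-site analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .motifs import MotifSimilarityMatrix

DEFAULT_MIN_SUBCLASS = 5
WSS_ELBOW_FRACTION = 0.10


@dataclass
class SubclassPartition:
    subclass_of: dict[str, int]
    k: int
    wss_curve: dict[int, float]
    retained: set[int] = field(default_factory=set)

    def members(self, label: int) -> list[str]:
        return [t for t, s in self.subclass_of.items() if s == label]

    def labels(self) -> list[int]:
        return sorted(set(self.subclass_of.values()))

    def retained_subclass_of(self) -> dict[str, int]:
        return {t: s for t, s in self.subclass_of.items() if s in self.retained}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tf_id": list(self.subclass_of),
                "subclass": list(self.subclass_of.values()),
                "retained": [
                    s in self.retained for s in self.subclass_of.values()
                ],
            }
        )


def _wss(features: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squares of feature rows about cluster centroids."""
    total = 0.0
    for lab in np.unique(labels):
        rows = features[labels == lab]
        total += ((rows - rows.mean(axis=0)) ** 2).sum()
    return float(total)


def cluster_subclasses(
    sim: MotifSimilarityMatrix,
    min_size: int = DEFAULT_MIN_SUBCLASS,
    linkage_method: str = "average",
    elbow_fraction: float = WSS_ELBOW_FRACTION,
) -> SubclassPartition:
    """Partition TFs into subclasses via the elbow/WSS rule.

    Rows of the similarity matrix serve as Euclidean feature vectors for the
    WSS computation.  The chosen k is the smallest number of clusters whose
    WSS falls below ``elbow_fraction`` of the WSS of the single unpartitioned
    cluster; k = n always qualifies (WSS 0), so a choice always exists.
    """
    ids = sim.tf_ids
    n = len(ids)
    features = sim.values
    if n < min_size:
        warnings.warn(
            f"only {n} TFs (< {min_size}); single subclass, excluded downstream"
        )
        labels = {t: 1 for t in ids}
        return SubclassPartition(labels, 1, {1: _wss(features, np.ones(n))}, set())

    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=linkage_method)

    wss_curve: dict[int, float] = {}
    wss1 = _wss(features, np.ones(n, dtype=int))
    wss_curve[1] = wss1
    chosen_k, chosen_labels = 1, np.ones(n, dtype=int)
    if wss1 > 0:
        for k in range(2, n + 1):
            labels = fcluster(Z, t=k, criterion="maxclust")
            wss_curve[k] = _wss(features, labels)
            if wss_curve[k] < elbow_fraction * wss1:
                chosen_k, chosen_labels = k, labels
                break
        else:  # pragma: no cover - k = n has WSS 0 when wss1 > 0
            chosen_k, chosen_labels = n, np.arange(1, n + 1)

    subclass_of = {t: int(lab) for t, lab in zip(ids, chosen_labels)}
    counts = pd.Series(chosen_labels).value_counts()
    retained = {int(lab) for lab, c in counts.items() if c >= min_size}
    return SubclassPartition(subclass_of, int(chosen_k), wss_curve, retained)


def iqr(values) -> float:
    """Interquartile range with linear-interpolation (type-7) quartiles."""
    q25, q75 = np.percentile(np.asarray(values, dtype=float), [25, 75])
    return float(q75 - q25)


def diversity_stats(
    sim_by_group: dict[str, MotifSimilarityMatrix],
    counts: dict[str, int],
) -> dict:
    """Per-group IQR of between-motif similarity vs group size.

    Reports each group's interquartile range of off-diagonal similarities
    (linear-interpolation quartiles) and, with at least three groups, the
    Spearman correlation between IQR and motif count.
    """
    groups = sorted(sim_by_group)
    iqrs = {g: iqr(sim_by_group[g].off_diagonal()) for g in groups}
    report: dict = {"iqr": iqrs, "counts": {g: counts[g] for g in groups}}
    if len(groups) >= 3:
        x = [iqrs[g] for g in groups]
        y = [counts[g] for g in groups]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearmanr(x, y)
        report["spearman_rho"] = None if np.isnan(rho) else float(rho)
        report["spearman_p"] = None if np.isnan(p) else float(p)
    else:
        report["spearman_rho"] = None
        report["spearman_p"] = None
    return report
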