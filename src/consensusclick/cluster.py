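"""Consensus-click aggregation: constrained Ward clustering of volunteer clicks.

Clicks made on one image by many volunteers are grouped by spatial
position with agglomerative hierarchical clustering (Ward linkage on
Euclidean distance).  The dendrogram is then cut per branch: descending
from the root, a node becomes a final cluster as soon as no volunteer
contributes more than one click beneath it.  The rationale is behavioural
— a volunteer clicks each penguin once, so two nearby clicks by the same
person are two penguins — and along every root-to-leaf path the rule picks
the highest admissible node, maximising clicks per cluster.

Each cluster yields one consensus click: the coordinate-wise median of its
member clicks (robust to outliers), per-type probabilities equal to the
label fractions among members, and a true-positive probability equal to
the cluster size divided by the number of volunteers who answered that
animals were present in the image.

The estimator :class:`ConstrainedWard` exposes the clustering step in
scikit-learn form; :func:`aggregate_subject` and :func:`aggregate_table`
wire it into the full table-to-table pipeline.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import LABELS, ConsensusClick, RawClassificationData
from .filtering import FilterReport, apply_filters

__all__ = [
    "ConstrainedWard",
    "build_merge_tree",
    "constrained_cut",
    "consensus_from_cluster",
    "aggregate_subject",
    "aggregate_table",
    "merge_tree_to_dict",
]


def build_merge_tree(coords: np.ndarray) -> np.ndarray | None:
    """Ward agglomeration over 2-D click coordinates.

    Returns a SciPy linkage matrix (one row per merge: left child, right
    child, merge height, subtree size), or ``None`` for the degenerate
    single-click tree, which has no merges.  Coordinates are used raw, with
    no standardisation: both axes are pixels in the same resized space.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"expected (n, 2) coordinates, got shape {coords.shape}")
    if len(coords) == 0:
        raise ValueError("cannot build a merge tree from zero clicks")
    if len(coords) == 1:
        return None
    return linkage(coords, method="ward")


def constrained_cut(
    tree: np.ndarray | None,
    volunteers: Sequence,
) -> np.ndarray:
    """Cut the dendrogram into the largest clusters with distinct volunteers.

    Top-down recursion from the root: a node is accepted as a final
    cluster iff no volunteer contributes more than one leaf beneath it;
    otherwise both children are visited.  Because admissibility is
    inherited by descendants, the result is the unique coarsest
    tree-respecting partition satisfying the constraint.

    Parameters
    ----------
    tree : linkage matrix or None
        Output of :func:`build_merge_tree` (``None`` means one click).
    volunteers : sequence
        Volunteer id per leaf, in the leaf order the tree was built from.

    Returns
    -------
    labels : ndarray of int
        Cluster label per click, numbered 0..k-1 in order of each
        cluster's first leaf.
    """
    volunteers = list(volunteers)
    n = len(volunteers)
    if n == 0:
        return np.empty(0, dtype=int)
    if tree is None or n == 1:
        if n != 1:
            raise ValueError("tree/volunteer length mismatch")
        return np.zeros(1, dtype=int)
    if tree.shape[0] != n - 1:
        raise ValueError(
            f"linkage has {tree.shape[0]} merges but {n} volunteers given"
        )

    # leaves[i] for node i (leaves 0..n-1, merges n..2n-2)
    leaves: list[list[int]] = [[i] for i in range(n)]
    for j in range(n - 1):
        left, right = int(tree[j, 0]), int(tree[j, 1])
        leaves.append(leaves[left] + leaves[right])

    labels = np.full(n, -1, dtype=int)
    accepted: list[list[int]] = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        members = leaves[node]
        vols = [volunteers[i] for i in members]
        if len(set(vols)) == len(vols):
            accepted.append(members)
        else:
            j = node - n
            stack.append(int(tree[j, 1]))
            stack.append(int(tree[j, 0]))

    accepted.sort(key=min)
    for cluster_id, members in enumerate(accepted):
        labels[members] = cluster_id
    assert (labels >= 0).all(), "constrained cut did not partition the leaves"
    return labels


def merge_tree_to_dict(tree: np.ndarray | None) -> dict:
    """Merge tree as a JSON-serialisable dict, for debugging dumps."""
    if tree is None:
        return {"n_leaves": 1, "merges": []}
    n = tree.shape[0] + 1
    return {
        "n_leaves": n,
        "merges": [
            {
                "left": int(row[0]),
                "right": int(row[1]),
                "height": float(row[2]),
                "size": int(row[3]),
            }
            for row in tree
        ],
    }


class ConstrainedWard(ClusterMixin, BaseEstimator):
    """Ward agglomerative clustering with a one-click-per-volunteer constraint.

    Unlike plain agglomerative clustering, the number of clusters is not a
    parameter: the dendrogram is cut per branch at the highest node under
    which every volunteer appears at most once.

    Parameters
    ----------
    None.  The linkage method (Ward on Euclidean distance) and the cut rule
    are the algorithm; there is nothing to tune.

    Attributes
    ----------
    labels_ : ndarray of shape (n_clicks,)
        Cluster label of each click.
    n_clusters_ : int
        Number of clusters found.
    linkage_ : ndarray or None
        SciPy linkage matrix (``None`` when fitted on a single click).
    n_features_in_ : int
        Always 2 (x and y pixel coordinates).

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[10.0, 10.0], [11.0, 10.0], [400.0, 300.0]])
    >>> ConstrainedWard().fit_predict(X, volunteers=["a", "b", "a"])
    array([0, 0, 1])
    """

    def fit(self, X, y=None, volunteers: Sequence | None = None):
        """Cluster click coordinates.

        Parameters
        ----------
        X : array-like of shape (n_clicks, 2)
            Click coordinates in resized-image pixels.
        y : ignored
            Present for scikit-learn API compatibility.
        volunteers : sequence of length n_clicks, optional
            Volunteer id per click.  If omitted every click is treated as
            coming from a distinct volunteer, so the constraint is vacuous
            and all clicks merge into one cluster.
        """
        X = check_array(X, ensure_min_samples=1)
        if X.shape[1] != 2:
            raise ValueError(f"expected 2 coordinate columns, got {X.shape[1]}")
        if volunteers is None:
            volunteers = np.arange(len(X))
        elif len(volunteers) != len(X):
            raise ValueError(
                f"{len(volunteers)} volunteer ids for {len(X)} clicks"
            )
        self.linkage_ = build_merge_tree(X)
        self.labels_ = constrained_cut(self.linkage_, volunteers)
        self.n_clusters_ = int(self.labels_.max()) + 1 if len(self.labels_) else 0
        self.n_features_in_ = 2
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_

    def cluster_centers(self, X) -> np.ndarray:
        """Coordinate-wise medians of the fitted clusters, shape (k, 2)."""
        check_is_fitted(self, "labels_")
        X = np.asarray(X, dtype=float)
        return np.array(
            [
                np.median(X[self.labels_ == k], axis=0)
                for k in range(self.n_clusters_)
            ]
        )


def consensus_from_cluster(
    cluster: pd.DataFrame,
    n_yes_volunteers: int,
    image_name: str = "",
) -> ConsensusClick:
    """Summarise one click cluster as a consensus click.

    Centre coordinates are coordinate-wise medians (for an even-sized
    cluster, the mean of the two central values).  The probability of each
    type is the fraction of member clicks carrying that label; the
    probability of a true positive is the cluster size over the number of
    distinct volunteers who answered yes for the image.
    """
    if cluster.empty:
        raise ValueError("cannot summarise an empty cluster")
    if n_yes_volunteers <= 0:
        raise ValueError(
            "true-positive probability undefined with zero yes-voters"
        )
    num_markings = len(cluster)
    if n_yes_volunteers < num_markings:
        raise ValueError(
            f"{num_markings} markings but only {n_yes_volunteers} yes-voters"
        )
    label_counts = cluster["label"].value_counts()
    rec = ConsensusClick(
        image_name=image_name,
        x_centre=float(np.median(cluster["x"])),
        y_centre=float(np.median(cluster["y"])),
        probability_of_adult=float(label_counts.get("adult", 0)) / num_markings,
        probability_of_chick=float(label_counts.get("chick", 0)) / num_markings,
        probability_of_egg=float(label_counts.get("egg", 0)) / num_markings,
        probability_of_true_positive=num_markings / n_yes_volunteers,
        num_markings=num_markings,
    )
    rec.validate()
    return rec


def aggregate_subject(
    clicks: pd.DataFrame,
    n_yes_volunteers: int,
    image_name: str = "",
) -> list[ConsensusClick]:
    """Run the full clustering on the (already filtered) clicks of one subject.

    Every click ends up in exactly one consensus click.  Clusters are
    emitted in order of their first click in the input, so the output is
    deterministic given the input ordering.
    """
    if clicks.empty:
        return []
    bad = set(clicks["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown label(s) {sorted(bad)} in clicks")
    est = ConstrainedWard().fit(
        clicks[["x", "y"]].to_numpy(dtype=float),
        volunteers=clicks["volunteer_id"].tolist(),
    )
    out = []
    for k in range(est.n_clusters_):
        members = clicks.iloc[np.flatnonzero(est.labels_ == k)]
        out.append(consensus_from_cluster(members, n_yes_volunteers, image_name))
    return out


def _consensus_frame(records: Iterable[ConsensusClick]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": r.image_name,
                "x_centre": r.x_centre,
                "y_centre": r.y_centre,
                "probability_of_adult": r.probability_of_adult,
                "probability_of_chick": r.probability_of_chick,
                "probability_of_egg": r.probability_of_egg,
                "probability_of_true_positive": r.probability_of_true_positive,
                "num_markings": r.num_markings,
            }
            for r in records
        ],
        columns=[
            "name",
            "x_centre",
            "y_centre",
            "probability_of_adult",
            "probability_of_chick",
            "probability_of_egg",
            "probability_of_true_positive",
            "num_markings",
        ],
    )


def aggregate_table(
    data: RawClassificationData,
    *,
    filter_duplicates: bool = True,
    filter_bounds: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter and aggregate a whole raw-classification table.

    Applies the hygiene filters, then clusters each subject's clicks and
    emits one consensus-click row per detection, named after the subject's
    image.  Subjects with yes-voters but no retained clicks contribute no
    rows.

    Returns the consensus DataFrame (consensus-CSV columns) and the merged
    :class:`~consensusclick.filtering.FilterReport`.
    """
    clicks, report = apply_filters(
        data.clicks,
        data.images,
        duplicates=filter_duplicates,
        bounds=filter_bounds,
    )
    denominators = data.yes_denominators()
    names = data.images.set_index("subject_id")["path"].str.rsplit("/", n=1).str[-1]

    records: list[ConsensusClick] = []
    for subject in data.images["subject_id"]:
        subject_clicks = clicks[clicks["subject_id"] == subject]
        if subject_clicks.empty:
            continue
        n_yes = int(denominators.get(subject, 0))
        records.extend(
            aggregate_subject(subject_clicks, n_yes, image_name=names[subject])
        )
    return _consensus_frame(records), report
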