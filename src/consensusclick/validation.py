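"""Count validation against gold-standard annotations.

Consensus clicks are turned into per-image counts by thresholding: a
detection is counted when strictly more than ``k`` volunteers marked it
(``num_markings > k``) and its type probability strictly exceeds 0.5.
Counts are compared with expert gold-standard (GS) counts image by image,
summarising the absolute differences and the direction of disagreement
(overestimate GS < CS, underestimate GS > CS, match GS = CS).

Raising the markings threshold trades overestimates for underestimates:
more volunteers must agree before a detection is counted, which removes
spurious single-click detections but also drops genuinely-present animals
that few volunteers marked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("adult_only", "chick_only", "adult_plus_chick")

_GS_COLUMNS = {
    "adult_only": ("n_adults",),
    "chick_only": ("n_chicks",),
    "adult_plus_chick": ("n_adults", "n_chicks"),
}


@dataclass(frozen=True)
class ThresholdSpec:
    """One counting rule: markings threshold, probability threshold, category.

    ``min_markings_exclusive = k`` keeps detections with strictly more
    than ``k`` markings, so ``k = 2`` requires three or more volunteers.
    The probability threshold is likewise strict (a 0.5 type probability
    is excluded).
    """

    min_markings_exclusive: int = 1
    type_probability_threshold: float = 0.5
    category: str = "adult_only"

    def __post_init__(self) -> None:
        if self.min_markings_exclusive < 0:
            raise ValueError("markings threshold must be >= 0")
        if not 0 <= self.type_probability_threshold < 1:
            raise ValueError("probability threshold must be in [0, 1)")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )


def _type_probability(consensus: pd.DataFrame, category: str) -> pd.Series:
    if category == "adult_only":
        return consensus["probability_of_adult"]
    if category == "chick_only":
        return consensus["probability_of_chick"]
    return consensus["probability_of_adult"] + consensus["probability_of_chick"]


def count_at_threshold(consensus: pd.DataFrame, spec: ThresholdSpec) -> int:
    """Count the detections of one image passing a threshold rule.

    For the combined category the summed adult+chick probability is
    thresholded, so an individual split 0.5/0.5 between adult and chick
    still counts as a penguin.
    """
    if consensus.empty:
        return 0
    passing = (consensus["num_markings"] > spec.min_markings_exclusive) & (
        _type_probability(consensus, spec.category)
        > spec.type_probability_threshold
    )
    return int(passing.sum())


def counts_per_image(
    consensus: pd.DataFrame,
    spec: ThresholdSpec,
    image_names: Iterable[str] | None = None,
) -> pd.Series:
    """Thresholded counts for every image in a consensus table.

    ``image_names`` fixes the image universe: images there with no passing
    detection get a count of 0 (an image with no consensus rows at the
    threshold was still processed).  By default the universe is every
    image appearing in the consensus table.
    """
    if image_names is None:
        image_names = consensus["name"].unique()
    if consensus.empty:
        counts = pd.Series(0, index=pd.Index(image_names, name="image_name"))
        return counts
    passing = consensus[
        (consensus["num_markings"] > spec.min_markings_exclusive)
        & (
            _type_probability(consensus, spec.category)
            > spec.type_probability_threshold
        )
    ]
    counts = passing.groupby("name").size()
    return counts.reindex(pd.Index(image_names, name="image_name"), fill_value=0)


@dataclass
class ComparisonSummary:
    """Agreement statistics between gold-standard and consensus counts.

    ``average_difference`` is the mean of absolute per-image differences
    |GS - CS| and ``sigma`` their sample standard deviation; the direction
    of disagreement is carried by the three percentages, which partition
    100%.
    """

    n_images: int
    average_difference: float
    sigma: float
    prop_diff_0_or_1: float
    pct_overestimate: float  # GS < CS
    pct_underestimate: float  # GS > CS
    pct_match: float  # GS = CS
    unmatched: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "average_difference": self.average_difference,
            "sigma": self.sigma,
            "prop_diff_0_or_1": self.prop_diff_0_or_1,
            "pct_overestimate": self.pct_overestimate,
            "pct_underestimate": self.pct_underestimate,
            "pct_match": self.pct_match,
        }


def _gs_counts(gold: pd.DataFrame, category: str) -> pd.Series:
    cols = _GS_COLUMNS[category]
    counts = gold[list(cols)].sum(axis=1)
    counts.index = gold["image_name"]
    return counts


def compare_images(
    gold: pd.DataFrame,
    cs_counts: Mapping[str, int] | pd.Series,
    category: str = "adult_only",
    *,
    filter_gold: bool = True,
) -> ComparisonSummary:
    """Compare per-image consensus counts against the gold standard.

    The gold standard is first restricted to images that contain animals
    and were marked complete (the two published selection criteria);
    ``filter_gold=False`` skips that restriction.  Images present in only
    one of the two tables are excluded, logged, and listed in
    ``unmatched``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if filter_gold:
        gold = gold[gold["contains_animals"] & gold["marked_complete"]]
    gs = _gs_counts(gold, category)
    cs = pd.Series(dict(cs_counts)) if not isinstance(cs_counts, pd.Series) else cs_counts

    shared = gs.index.intersection(cs.index)
    unmatched = sorted(set(gs.index).symmetric_difference(set(cs.index)))
    if unmatched:
        logger.warning(
            "%d image(s) present in only one table were excluded: %s",
            len(unmatched),
            ", ".join(unmatched[:10]) + ("..." if len(unmatched) > 10 else ""),
        )

    diff = gs.loc[shared].astype(float) - pd.Series(cs).loc[shared].astype(float)
    n = len(diff)
    if n == 0:
        return ComparisonSummary(0, float("nan"), float("nan"), float("nan"),
                                 float("nan"), float("nan"), float("nan"),
                                 unmatched=unmatched)
    abs_diff = diff.abs()
    return ComparisonSummary(
        n_images=n,
        average_difference=float(abs_diff.mean()),
        sigma=float(abs_diff.std(ddof=1)) if n > 1 else float("nan"),
        prop_diff_0_or_1=float((abs_diff <= 1).mean()),
        pct_overestimate=float((diff < 0).mean() * 100),
        pct_underestimate=float((diff > 0).mean() * 100),
        pct_match=float((diff == 0).mean() * 100),
        unmatched=unmatched,
    )


def chick_subset(
    gold: pd.DataFrame,
    cs_chick_counts: Mapping[str, int] | pd.Series,
) -> pd.Index:
    """Images where chicks are present according to GS and/or CS data.

    Used for the chick-only comparison: keeping the many chick-free images
    would make chick accuracy look spuriously high.
    """
    cs = pd.Series(dict(cs_chick_counts)) if not isinstance(cs_chick_counts, pd.Series) else cs_chick_counts
    gs_has = set(gold.loc[gold["n_chicks"] > 0, "image_name"])
    cs_has = set(cs.index[cs > 0])
    keep = gs_has | cs_has
    return pd.Index(
        [name for name in gold["image_name"] if name in keep], name="image_name"
    )


def threshold_sweep(
    gold: pd.DataFrame,
    consensus: pd.DataFrame,
    k_levels: Sequence[int] = (1, 2, 3, 4),
    categories: Sequence[str] = CATEGORIES,
    *,
    probability_threshold: float = 0.5,
    image_names: Iterable[str] | None = None,
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Comparison summaries over a grid of thresholds and categories.

    One row per (markings threshold k, category), with the agreement
    statistics of :func:`compare_images`.  ``image_names`` fixes the
    consensus image universe (default: images appearing in the consensus
    table); ``restrict_to`` limits the comparison to a subset of images
    (e.g. the chick-present subset).
    """
    if image_names is None:
        image_names = list(consensus["name"].unique()) if not consensus.empty else []
    else:
        image_names = list(image_names)
    if gold.empty and len(image_names) == 0:
        return pd.DataFrame(
            columns=["threshold", "category", "n_images", "average_difference",
                     "sigma", "prop_diff_0_or_1", "pct_overestimate",
                     "pct_underestimate", "pct_match"]
        )
    rows = []
    for category in categories:
        for k in k_levels:
            spec = ThresholdSpec(
                min_markings_exclusive=k,
                type_probability_threshold=probability_threshold,
                category=category,
            )
            cs = counts_per_image(consensus, spec, image_names)
            gold_k = gold
            if restrict_to is not None:
                keep = set(restrict_to)
                gold_k = gold[gold["image_name"].isin(keep)]
                cs = cs[cs.index.isin(keep)]
            summary = compare_images(gold_k, cs, category)
            rows.append(
                {"threshold": k, "category": category, **summary.to_dict()}
            )
    return pd.DataFrame(rows)
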