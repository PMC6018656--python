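"""Pre-clustering click hygiene.

Two failure modes of the live annotation platform are repaired before
clustering:

* a volunteer is occasionally shown the same subject twice — because the
  clustering constraint places clicks by the same volunteer in separate
  clusters, duplicate classifications would inflate the detection count,
  so only the earliest session per (volunteer, subject) is kept;
* on touch devices the marker can be dragged beyond the image boundary —
  such clicks have coordinates outside the resized frame and are dropped.

Both filters are idempotent and commute; every removal is accounted for in
a :class:`FilterReport` whose counts always reconcile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Union

import pandas as pd

from .io import ImageRecord


@dataclass
class FilterReport:
    """Accounting of clicks removed by the hygiene filters.

    Invariant: ``n_input_clicks == n_removed_duplicates +
    n_removed_out_of_bounds + n_retained``.
    """

    n_input_clicks: int = 0
    n_removed_duplicates: int = 0
    n_removed_out_of_bounds: int = 0
    n_retained: int = 0
    per_subject: dict[str, dict[str, int]] = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.n_removed_duplicates + self.n_removed_out_of_bounds + self.n_retained
        )
        if total != self.n_input_clicks:
            raise AssertionError(
                f"filter counts do not reconcile: {self.n_input_clicks} input vs "
                f"{total} accounted"
            )

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Combine with a report for a later filtering stage.

        The later stage's input is this stage's retained set, so retained
        counts come from ``other`` while removals accumulate.
        """
        merged = FilterReport(
            n_input_clicks=self.n_input_clicks,
            n_removed_duplicates=self.n_removed_duplicates
            + other.n_removed_duplicates,
            n_removed_out_of_bounds=self.n_removed_out_of_bounds
            + other.n_removed_out_of_bounds,
            n_retained=other.n_retained,
        )
        for subject in set(self.per_subject) | set(other.per_subject):
            a = self.per_subject.get(subject, {})
            b = other.per_subject.get(subject, {})
            merged.per_subject[subject] = {
                "n_input_clicks": a.get("n_input_clicks", b.get("n_input_clicks", 0)),
                "n_removed_duplicates": a.get("n_removed_duplicates", 0)
                + b.get("n_removed_duplicates", 0),
                "n_removed_out_of_bounds": a.get("n_removed_out_of_bounds", 0)
                + b.get("n_removed_out_of_bounds", 0),
                "n_retained": b.get("n_retained", a.get("n_retained", 0)),
            }
        merged.check()
        return merged

    def to_dict(self) -> dict:
        return {
            "n_input_clicks": self.n_input_clicks,
            "n_removed_duplicates": self.n_removed_duplicates,
            "n_removed_out_of_bounds": self.n_removed_out_of_bounds,
            "n_retained": self.n_retained,
            "per_subject": self.per_subject,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _make_report(clicks: pd.DataFrame, removed_mask: pd.Series, kind: str) -> FilterReport:
    report = FilterReport(
        n_input_clicks=int(len(clicks)),
        n_retained=int((~removed_mask).sum()),
    )
    setattr(report, kind, int(removed_mask.sum()))
    if clicks.empty:
        report.check()
        return report
    for subject, grp in clicks.groupby("subject_id", sort=False):
        sub_removed = int(removed_mask.loc[grp.index].sum())
        report.per_subject[str(subject)] = {
            "n_input_clicks": int(len(grp)),
            "n_removed_duplicates": sub_removed if kind == "n_removed_duplicates" else 0,
            "n_removed_out_of_bounds": (
                sub_removed if kind == "n_removed_out_of_bounds" else 0
            ),
            "n_retained": int(len(grp)) - sub_removed,
        }
    report.check()
    return report


def _session_order_key(session: str) -> tuple[int, str]:
    # numeric-aware ordering: "2" sorts before "10"
    s = str(session)
    return (len(s), s) if s.isdigit() else (1_000_000, s)


def first_sessions(table: pd.DataFrame) -> pd.Series:
    """Earliest session id per (volunteer_id, subject_id) pair.

    "Earliest" is the smallest session id under numeric-aware ordering,
    which for session ids synthesised from file order is the first
    classification.  Any table with volunteer_id / subject_id /
    session_id columns works, so the registry can be built from the full
    classification list rather than from the clicks alone.
    """
    if table.empty:
        return pd.Series(dtype=object)
    return (
        table.groupby(["volunteer_id", "subject_id"])["session_id"]
        .agg(lambda s: min(s, key=_session_order_key))
    )


def remove_duplicate_sessions(
    clicks: pd.DataFrame,
    session_registry: pd.Series | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep only the earliest session's clicks per (volunteer, subject).

    A repeated classification of the same subject by the same volunteer is
    removed in full.  ``session_registry`` (the output of
    :func:`first_sessions`, possibly computed on the unfiltered table)
    fixes which session counts as earliest; by default it is derived from
    ``clicks`` itself.  With a fixed registry the duplicate test is a
    per-click predicate, so this filter commutes with the bounds filter.
    """
    if clicks.empty:
        return clicks.copy(), _make_report(clicks, pd.Series(dtype=bool), "n_removed_duplicates")
    if session_registry is None:
        session_registry = first_sessions(clicks)
    keys = pd.MultiIndex.from_frame(clicks[["volunteer_id", "subject_id"]])
    first = session_registry.reindex(keys)
    # pairs absent from the registry have nothing to be a duplicate of
    removed = (clicks["session_id"].values != first.values) & first.notna().values
    removed = pd.Series(removed, index=clicks.index)
    report = _make_report(clicks, removed, "n_removed_duplicates")
    return clicks[~removed].copy(), report


def _bounds_frame(
    images: Union[ImageRecord, pd.DataFrame],
) -> pd.DataFrame:
    if isinstance(images, ImageRecord):
        return pd.DataFrame(
            {
                "subject_id": [images.subject_id],
                "resized_size_x": [images.resized_size_x],
                "resized_size_y": [images.resized_size_y],
            }
        )
    return images


def remove_out_of_bounds(
    clicks: pd.DataFrame,
    images: Union[ImageRecord, pd.DataFrame],
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop clicks dragged beyond the image boundary.

    A click is removed iff ``x < 0``, ``x > resized width``, ``y < 0`` or
    ``y > resized height``, using each image's own resized dimensions
    (1000x562.5 or 1000x750 for the published cameras).  Inequalities are
    strict: clicks exactly on the boundary are kept.
    """
    if clicks.empty:
        return clicks.copy(), _make_report(clicks, pd.Series(dtype=bool), "n_removed_out_of_bounds")
    bounds = _bounds_frame(images).set_index("subject_id")
    width = clicks["subject_id"].map(bounds["resized_size_x"])
    height = clicks["subject_id"].map(bounds["resized_size_y"])
    if width.isna().any():
        unknown = sorted(clicks.loc[width.isna(), "subject_id"].unique())
        raise KeyError(f"no image dimensions for subject(s): {unknown}")
    removed = (
        (clicks["x"] < 0)
        | (clicks["x"] > width)
        | (clicks["y"] < 0)
        | (clicks["y"] > height)
    )
    report = _make_report(clicks, removed, "n_removed_out_of_bounds")
    return clicks[~removed].copy(), report


def remove_out_of_bounds_consensus(
    consensus: pd.DataFrame,
    images: pd.DataFrame,
) -> pd.DataFrame:
    """Post-hoc variant: drop consensus clicks whose centre is out of bounds.

    Mirrors removing accidental markings during subsequent analysis rather
    than before clustering.  ``images`` must map ``image_name`` or
    ``subject_id`` rows to resized dimensions.
    """
    bounds = images.copy()
    if "image_name" not in bounds.columns:
        bounds["image_name"] = bounds["path"].str.rsplit("/", n=1).str[-1]
    bounds = bounds.set_index("image_name")
    width = consensus["name"].map(bounds["resized_size_x"])
    height = consensus["name"].map(bounds["resized_size_y"])
    keep = (
        (consensus["x_centre"] >= 0)
        & (consensus["x_centre"] <= width)
        & (consensus["y_centre"] >= 0)
        & (consensus["y_centre"] <= height)
    )
    return consensus[keep].copy()


def apply_filters(
    clicks: pd.DataFrame,
    images: Union[ImageRecord, pd.DataFrame, None] = None,
    *,
    duplicates: bool = True,
    bounds: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run both hygiene filters (each optional) and merge the reports."""
    retained = clicks
    report = _make_report(clicks, pd.Series(False, index=clicks.index), "n_removed_duplicates")
    if duplicates:
        retained, report = remove_duplicate_sessions(
            retained, session_registry=first_sessions(clicks)
        )
    if bounds:
        if images is None:
            raise ValueError("bounds filtering requires image dimensions")
        retained, bounds_report = remove_out_of_bounds(retained, images)
        report = report.merge(bounds_report)
    report.check()
    return retained, report
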