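"""Reading and writing the two annotation CSV dialects, and coordinate conventions.

Two tables flow through the pipeline:

* **raw classifications** — one row per volunteer click (or per blank
  classification), with anonymised volunteer id, subject id, click x/y in
  resized-image pixels, the type label, per-classification flags and image
  metadata;
* **consensus clicks** — the aggregated detections produced by the
  clustering algorithm, one row per detected individual.

Coordinates use the resized image space: every image is scaled to a width
of 1000 px with aspect ratio preserved, so the published camera resolutions
1920x1080 and 2048x1536 become 1000x562.5 and 1000x750.  The origin (0, 0)
is the top-left corner with y increasing downward.  Fractional heights such
as 562.5 are kept exact; the out-of-bounds filter depends on them.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

LABELS = ("adult", "chick", "egg", "other")
ANIMALS_PRESENT = ("yes", "no", "cant_tell")
ALL_MARKED = ("complete", "incomplete")
LUNAR_PHASES = (
    "full",
    "new",
    "newcres",
    "firstq",
    "waxinggib",
    "waninggib",
    "lastq",
    "oldcres",
)

RESIZED_WIDTH = 1000.0
TIMESTAMP_FORMAT = "%Y:%m:%d %H:%M:%S"

#: Mandatory columns of the raw-classification dialect, in documented order.
RAW_COLUMNS = (
    "user_name",
    "subject_zooniverse_id",
    "lunar_phase",
    "original_size_x",
    "original_size_y",
    "path",
    "temperature_f",
    "timestamp",
    "animals_present",
    "all_marked",
    "value",
    "x",
    "y",
)

#: Columns of the consensus-click dialect, in documented order.
CONSENSUS_COLUMNS = (
    "name",
    "x_centre",
    "y_centre",
    "probability_of_adult",
    "probability_of_chick",
    "probability_of_egg",
    "probability_of_true_positive",
    "num_markings",
)

GOLD_COLUMNS = (
    "image_name",
    "n_adults",
    "n_chicks",
    "contains_animals",
    "marked_complete",
)


class SchemaError(ValueError):
    """A table is missing mandatory columns or is otherwise unusable."""


class VocabularyError(ValueError):
    """A cell holds a value outside its closed vocabulary."""


class InvariantError(ValueError):
    """A record violates a structural invariant and cannot be written."""


def rescale_point(
    x: float,
    y: float,
    original_size: tuple[float, float],
    target_width: float = RESIZED_WIDTH,
) -> tuple[float, float]:
    """Map a point from original-image pixels into resized-image pixels.

    Both axes are scaled by the same factor ``target_width / original_x``,
    so aspect ratio is preserved exactly: a 1920x1080 frame maps onto
    1000x562.5 and a 2048x1536 frame onto 1000x750.

    Parameters
    ----------
    x, y : float
        Point in original-image pixels, origin top-left.
    original_size : (width, height)
        Original image dimensions in pixels; both must be positive.
    target_width : float
        Width of the resized space (default 1000).

    Returns
    -------
    (x', y') : tuple of float
    """
    ox, oy = original_size
    if ox <= 0 or oy <= 0:
        raise ValueError(f"original size must be positive, got {original_size!r}")
    if target_width <= 0:
        raise ValueError(f"target width must be positive, got {target_width!r}")
    # multiply before dividing: the full-frame corner must land exactly on
    # (target_width, target_width * oy / ox), e.g. (1000, 562.5)
    return (x * target_width / ox, y * target_width / ox)


def resized_dimensions(
    original_size: tuple[float, float], target_width: float = RESIZED_WIDTH
) -> tuple[float, float]:
    """Resized (width, height) of an image, aspect ratio preserved."""
    return rescale_point(*original_size, original_size, target_width)


@dataclass(frozen=True)
class ImageRecord:
    """Metadata for one photographed subject (one time-lapse frame)."""

    subject_id: str
    path: str
    original_size_x: float
    original_size_y: float
    timestamp: datetime | None = None
    temperature_f: float | None = None
    lunar_phase: str | None = None

    @property
    def resized_size_x(self) -> float:
        return RESIZED_WIDTH

    @property
    def resized_size_y(self) -> float:
        return resized_dimensions((self.original_size_x, self.original_size_y))[1]

    @property
    def image_name(self) -> str:
        # "DAMOa/DAMOa2014a_000025" -> "DAMOa2014a_000025"
        return self.path.rsplit("/", 1)[-1]


@dataclass(frozen=True)
class RawClick:
    """One volunteer's marking of one individual in one image."""

    subject_id: str
    volunteer_id: str
    session_id: str
    x: float
    y: float
    label: str
    animals_present: str = "yes"
    all_marked: str = "complete"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise VocabularyError(
                f"unknown label {self.label!r}; expected one of {LABELS}"
            )


@dataclass(frozen=True)
class ConsensusClick:
    """One aggregated detection: median coordinates plus type probabilities.

    ``probability_of_true_positive`` is the fraction of yes-answering
    volunteers who marked this location, so ``num_markings`` divided by it
    recovers the number of yes-voters and must be integral.
    """

    image_name: str
    x_centre: float
    y_centre: float
    probability_of_adult: float
    probability_of_chick: float
    probability_of_egg: float
    probability_of_true_positive: float
    num_markings: int

    def validate(self) -> None:
        probs = (
            self.probability_of_adult,
            self.probability_of_chick,
            self.probability_of_egg,
        )
        if any(p < 0 or p > 1 for p in probs):
            raise InvariantError(f"type probability outside [0,1] in {self!r}")
        if sum(probs) > 1 + 1e-9:
            raise InvariantError(
                f"type probabilities sum to {sum(probs)} > 1 in {self!r}"
            )
        if not (0 < self.probability_of_true_positive <= 1):
            raise InvariantError(
                f"probability_of_true_positive outside (0,1] in {self!r}"
            )
        if self.num_markings < 1:
            raise InvariantError(f"num_markings < 1 in {self!r}")
        n_yes = self.num_markings / self.probability_of_true_positive
        if abs(n_yes - round(n_yes)) > 1e-9:
            raise InvariantError(
                f"num_markings / probability_of_true_positive = {n_yes} "
                f"is not integral in {self!r}"
            )


@dataclass
class RawClassificationData:
    """Parsed raw-classification table.

    Attributes
    ----------
    clicks : DataFrame
        One row per click: subject_id, volunteer_id, session_id, x, y,
        label, animals_present, all_marked.
    classifications : DataFrame
        One row per (subject_id, volunteer_id, session_id) classification
        with its animals_present / all_marked answers; this includes blank
        ("no" / "can't tell") classifications and yes-answers with zero
        clicks, and is the source of the yes-voter denominators.
    images : DataFrame
        One row per subject with path, original and resized dimensions,
        timestamp, temperature_f, lunar_phase.
    malformed : list of (row, message)
        1-based data-row numbers of rows that could not be parsed, with the
        reason; these rows contribute no clicks.
    """

    clicks: pd.DataFrame
    classifications: pd.DataFrame
    images: pd.DataFrame
    malformed: list[tuple[int, str]] = field(default_factory=list)

    def yes_denominators(self) -> pd.Series:
        """Distinct volunteers answering yes, per subject.

        A volunteer who answered yes but placed no clicks still counts.
        """
        yes = self.classifications[self.classifications["animals_present"] == "yes"]
        return yes.groupby("subject_id")["volunteer_id"].nunique()

    def image_records(self) -> list[ImageRecord]:
        return [
            ImageRecord(
                subject_id=row.subject_id,
                path=row.path,
                original_size_x=row.original_size_x,
                original_size_y=row.original_size_y,
                timestamp=row.timestamp,
                temperature_f=row.temperature_f,
                lunar_phase=row.lunar_phase,
            )
            for row in self.images.itertuples(index=False)
        ]


def _normalise_animals_present(value: str) -> str:
    v = value.strip().lower().replace("'", "").replace("’", "")
    v = v.replace(" ", "_")
    if v in ("cant_tell", "canttell", "cant tell"):
        return "cant_tell"
    return v


def read_raw_classifications(
    source: Union[str, Path, _stdio.TextIOBase],
) -> RawClassificationData:
    """Parse a raw-classification CSV into clicks, denominators and metadata.

    Rows whose ``animals_present`` answer is "no" or "can't tell" carry no
    click but are retained as classification records (they enter retirement
    logic, not the yes denominator).  Rows that cannot be parsed are
    skipped and reported in ``malformed`` with their 1-based data-row
    number.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    VocabularyError
        If a row's type label is outside {adult, chick, egg, other}.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    has_session = "session_id" in df.columns
    session_counter: dict[tuple[str, str], int] = {}
    previous_key: tuple[str, str] | None = None

    clicks_rows: list[dict] = []
    classification_rows: dict[tuple[str, str, str], dict] = {}
    image_rows: dict[str, dict] = {}
    malformed: list[tuple[int, str]] = []

    for i, row in enumerate(df.itertuples(index=False), start=1):
        volunteer = str(row.user_name).strip()
        subject = str(row.subject_zooniverse_id).strip()
        if not volunteer or not subject:
            malformed.append((i, "missing user_name or subject_zooniverse_id"))
            continue

        answer = _normalise_animals_present(str(row.animals_present))
        if answer not in ANIMALS_PRESENT:
            malformed.append((i, f"unknown animals_present value {row.animals_present!r}"))
            continue

        key = (volunteer, subject)
        if has_session:
            session = str(row.session_id).strip() or "1"
        else:
            # Synthesised: a contiguous run of rows for one (volunteer,
            # subject) pair is one classification session; a later,
            # non-contiguous run is a repeat viewing of the same subject.
            if key != previous_key:
                session_counter[key] = session_counter.get(key, 0) + 1
            session = str(session_counter[key])
        previous_key = key

        all_marked = str(row.all_marked).strip().lower() or "complete"
        if all_marked not in ALL_MARKED:
            malformed.append((i, f"unknown all_marked value {row.all_marked!r}"))
            continue

        if subject not in image_rows:
            img, problem = _parse_image_metadata(row, subject)
            if problem is not None:
                malformed.append((i, problem))
                continue
            image_rows[subject] = img

        classification_rows.setdefault(
            (subject, volunteer, session),
            {
                "subject_id": subject,
                "volunteer_id": volunteer,
                "session_id": session,
                "animals_present": answer,
                "all_marked": all_marked,
            },
        )

        label = str(row.value).strip().lower()
        x_raw, y_raw = str(row.x).strip(), str(row.y).strip()
        if answer in ("no", "cant_tell"):
            continue  # blank classification: denominator only, no click
        if not label and not x_raw and not y_raw:
            continue  # yes-answer without a marking: denominator only
        if label not in LABELS:
            raise VocabularyError(
                f"row {i}: unknown label {row.value!r}; expected one of {LABELS}"
            )
        try:
            x, y = float(x_raw), float(y_raw)
        except ValueError:
            malformed.append((i, f"non-numeric coordinates ({row.x!r}, {row.y!r})"))
            continue
        clicks_rows.append(
            {
                "subject_id": subject,
                "volunteer_id": volunteer,
                "session_id": session,
                "x": x,
                "y": y,
                "label": label,
                "animals_present": answer,
                "all_marked": all_marked,
            }
        )

    clicks = pd.DataFrame(
        clicks_rows,
        columns=[
            "subject_id",
            "volunteer_id",
            "session_id",
            "x",
            "y",
            "label",
            "animals_present",
            "all_marked",
        ],
    )
    classifications = pd.DataFrame(
        list(classification_rows.values()),
        columns=["subject_id", "volunteer_id", "session_id", "animals_present", "all_marked"],
    )
    images = pd.DataFrame(
        list(image_rows.values()),
        columns=[
            "subject_id",
            "path",
            "original_size_x",
            "original_size_y",
            "resized_size_x",
            "resized_size_y",
            "timestamp",
            "temperature_f",
            "lunar_phase",
        ],
    )
    return RawClassificationData(
        clicks=clicks,
        classifications=classifications,
        images=images,
        malformed=malformed,
    )


def _parse_image_metadata(row, subject: str) -> tuple[dict | None, str | None]:
    try:
        osx = float(str(row.original_size_x).strip())
        osy = float(str(row.original_size_y).strip())
    except ValueError:
        return None, (
            f"non-numeric original size "
            f"({row.original_size_x!r}, {row.original_size_y!r})"
        )
    if osx <= 0 or osy <= 0:
        return None, f"non-positive original size ({osx}, {osy})"

    lunar = str(row.lunar_phase).strip().lower() or None
    if lunar is not None and lunar not in LUNAR_PHASES:
        return None, f"unknown lunar_phase value {row.lunar_phase!r}"

    ts_raw = str(row.timestamp).strip()
    timestamp = None
    if ts_raw:
        try:
            timestamp = datetime.strptime(ts_raw, TIMESTAMP_FORMAT)
        except ValueError:
            return None, f"timestamp {row.timestamp!r} not in YYYY:MM:DD HH:MM:SS"

    temp_raw = str(row.temperature_f).strip()
    temperature = None
    if temp_raw:
        try:
            temperature = float(temp_raw)
        except ValueError:
            return None, f"non-numeric temperature_f {row.temperature_f!r}"

    _, resized_y = resized_dimensions((osx, osy))
    return (
        {
            "subject_id": subject,
            "path": str(row.path).strip(),
            "original_size_x": osx,
            "original_size_y": osy,
            "resized_size_x": RESIZED_WIDTH,
            "resized_size_y": resized_y,
            "timestamp": timestamp,
            "temperature_f": temperature,
            "lunar_phase": lunar,
        },
        None,
    )


def _as_consensus_records(
    records: Union[pd.DataFrame, Iterable[ConsensusClick]],
) -> list[ConsensusClick]:
    if isinstance(records, pd.DataFrame):
        return [
            ConsensusClick(
                image_name=str(r.name),
                x_centre=float(r.x_centre),
                y_centre=float(r.y_centre),
                probability_of_adult=float(r.probability_of_adult),
                probability_of_chick=float(r.probability_of_chick),
                probability_of_egg=float(r.probability_of_egg),
                probability_of_true_positive=float(r.probability_of_true_positive),
                num_markings=int(r.num_markings),
            )
            for r in records.itertuples(index=False)
        ]
    return list(records)


def write_consensus(
    records: Union[pd.DataFrame, Sequence[ConsensusClick]],
    sink: Union[str, Path, _stdio.TextIOBase],
) -> None:
    """Write consensus clicks as CSV in the documented column order.

    Every record is validated first; an invariant violation refuses the
    whole write and names the offending record.
    """
    recs = _as_consensus_records(records)
    for rec in recs:
        rec.validate()
    rows = [
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
        for r in recs
    ]
    _write_csv(sink, CONSENSUS_COLUMNS, rows)


def _write_csv(sink, columns, rows) -> None:
    def _dump(fh) -> None:
        writer = csv.DictWriter(fh, fieldnames=list(columns), lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)

    if isinstance(sink, (str, Path)):
        with open(sink, "w", newline="", encoding="utf-8") as fh:
            _dump(fh)
    else:
        _dump(sink)


def read_consensus(source: Union[str, Path, _stdio.TextIOBase]) -> pd.DataFrame:
    """Read a consensus-click CSV into a DataFrame (documented columns)."""
    df = pd.read_csv(source)
    missing = [c for c in CONSENSUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df["num_markings"] = df["num_markings"].astype(int)
    return df[list(CONSENSUS_COLUMNS)]


def read_gold_standard(source: Union[str, Path, _stdio.TextIOBase]) -> pd.DataFrame:
    """Read gold-standard per-image counts.

    Columns: image_name, n_adults, n_chicks, contains_animals,
    marked_complete; the two flags are parsed as booleans.
    """
    df = pd.read_csv(source)
    missing = [c for c in GOLD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("contains_animals", "marked_complete"):
        df[col] = (
            df[col]
            .astype(str)
            .str.strip()
            .str.lower()
            .map({"true": True, "false": False, "1": True, "0": False,
                  "yes": True, "no": False})
        )
        if df[col].isna().any():
            raise VocabularyError(f"non-boolean value in column {col}")
    df["n_adults"] = df["n_adults"].astype(int)
    df["n_chicks"] = df["n_chicks"].astype(int)
    return df[list(GOLD_COLUMNS)]


def write_gold_standard(
    df: pd.DataFrame, sink: Union[str, Path, _stdio.TextIOBase]
) -> None:
    """Write a gold-standard counts table (column order fixed)."""
    rows = [
        {
            "image_name": r.image_name,
            "n_adults": int(r.n_adults),
            "n_chicks": int(r.n_chicks),
            "contains_animals": bool(r.contains_animals),
            "marked_complete": bool(r.marked_complete),
        }
        for r in df.itertuples(index=False)
    ]
    _write_csv(sink, GOLD_COLUMNS, rows)
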