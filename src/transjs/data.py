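"""Capture-history data model and file dialects.

Individual encounter histories are binary detection vectors over ``T``
survey occasions.  Occasion 1 is the translocation release, which counts as
a survey at which every released animal is recorded, so translocated
individuals always have a 1 in the first position.  Wild-born recruits can
first appear no earlier than occasion ``tau``.

Two on-disk dialects are supported:

* ``csv`` — header ``id,origin,group,occ1..occT``, one row per individual.
* ``inp`` — program-MARK style: ``<binary history> <freq_translocated>
  <freq_wild>;`` per line, ``/* ... */`` comments ignored.

Study-level metadata (occasion times, ``tau``, occasion covariates) lives in
a separate key-value design file (YAML), not in the history files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

ORIGIN_TRANSLOCATED = "translocated"
ORIGIN_WILD = "wild"
_ORIGINS = (ORIGIN_TRANSLOCATED, ORIGIN_WILD)


class ValidationError(ValueError):
    """A capture history or study design violates a structural invariant."""


class ParseError(ValueError):
    """A data file could not be parsed; the message names the line."""


@dataclass
class CaptureHistory:
    """One individual's binary detection record.

    Parameters
    ----------
    individual_id : str
        Unique label for the animal.
    origin : str
        ``"translocated"`` (released at occasion 1) or ``"wild"``
        (recruited into the population after release).
    detections : array-like of {0, 1}
        Detection indicator per survey occasion, length ``T``.
    group : str, optional
        Group label (e.g. sex) used for group-structured models.
    """

    individual_id: str
    origin: str
    detections: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        det = np.asarray(self.detections, dtype=np.int8)
        if det.ndim != 1 or not np.isin(det, (0, 1)).all():
            raise ValidationError(
                f"{self.individual_id}: detections must be a 1-D 0/1 vector"
            )
        object.__setattr__(self, "detections", det)
        if self.origin not in _ORIGINS:
            raise ValidationError(
                f"{self.individual_id}: origin must be one of {_ORIGINS}, "
                f"got {self.origin!r}"
            )

    @property
    def first_capture(self) -> int:
        """1-based occasion of first detection (``f_i``)."""
        return int(np.argmax(self.detections)) + 1

    @property
    def last_capture(self) -> int:
        """1-based occasion of last detection (``delta_i``)."""
        return int(len(self.detections) - np.argmax(self.detections[::-1]))

    @property
    def n_detections(self) -> int:
        return int(self.detections.sum())


@dataclass
class StudyDesign:
    """Survey layout: occasions, timing, entry window and covariates.

    ``occasion_times`` are elapsed months since the release (occasion 1 at
    0), strictly increasing; ``tau`` is the first occasion at which wild
    recruits can appear (``2 <= tau <= T``).  ``covariates`` is an optional
    per-occasion table (rows indexed 1..T) of survey-level covariates such
    as effort, air temperature or moon phase.
    """

    n_occasions: int
    occasion_times: np.ndarray
    tau: int
    groups: tuple[str, ...] = ()
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.occasion_times, dtype=float)
        T = int(self.n_occasions)
        if T < 2:
            raise ValidationError("need at least two survey occasions")
        if times.shape != (T,):
            raise ValidationError(
                f"occasion_times has length {times.size}, expected T={T}"
            )
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValidationError(
                "occasion_times must start at 0 and be strictly increasing"
            )
        if not 2 <= self.tau <= T:
            raise ValidationError(f"tau must satisfy 2 <= tau <= T, got {self.tau}")
        object.__setattr__(self, "occasion_times", times)
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.covariates is not None and len(self.covariates) != T:
            raise ValidationError("covariate table must have one row per occasion")

    @property
    def interval_months(self) -> np.ndarray:
        """Length of each of the T-1 inter-survey intervals, in months."""
        return np.diff(self.occasion_times)

    def covariate(self, name: str) -> np.ndarray:
        if self.covariates is None or name not in self.covariates.columns:
            raise KeyError(f"design has no occasion covariate {name!r}")
        return self.covariates[name].to_numpy(dtype=float)


@dataclass
class CaptureData:
    """A validated study design plus its attached capture histories."""

    design: StudyDesign
    histories: list[CaptureHistory]

    def __post_init__(self) -> None:
        validate_histories(self.design, self.histories)

    @property
    def n_observed(self) -> int:
        """D — number of observed individuals, translocated included."""
        return len(self.histories)

    @property
    def n_translocated(self) -> int:
        """n0 — number of translocated (released) individuals."""
        return sum(h.origin == ORIGIN_TRANSLOCATED for h in self.histories)

    def subset(self, group: str) -> "CaptureData":
        sub = [h for h in self.histories if h.group == group]
        return CaptureData(replace(self.design, groups=(group,)), sub)

    def detection_matrix(self) -> np.ndarray:
        return np.array([h.detections for h in self.histories], dtype=np.int8)


def validate_histories(
    design: StudyDesign, histories: Sequence[CaptureHistory]
) -> None:
    """Check every history against the design's structural invariants.

    Raises :class:`ValidationError` on the first violation: length
    mismatch, a translocated animal not recorded at release, a wild
    animal detected before ``tau``, an all-zero history, or an unknown
    group label.
    """
    T, tau = design.n_occasions, design.tau
    for h in histories:
        if len(h.detections) != T:
            raise ValidationError(
                f"{h.individual_id}: history length {len(h.detections)} != T={T}"
            )
        if h.n_detections == 0:
            raise ValidationError(
                f"{h.individual_id}: all-zero history; never-seen individuals "
                "are represented through the never-seen probability, not rows"
            )
        if h.origin == ORIGIN_TRANSLOCATED and h.detections[0] != 1:
            raise ValidationError(
                f"{h.individual_id}: translocated individual not recorded at "
                "the release occasion"
            )
        if h.origin == ORIGIN_WILD and h.first_capture < tau:
            raise ValidationError(
                f"{h.individual_id}: wild individual detected at occasion "
                f"{h.first_capture} before first entry occasion tau={tau}"
            )
        if design.groups and h.group is not None and h.group not in design.groups:
            raise ValidationError(
                f"{h.individual_id}: unknown group label {h.group!r}"
            )


# ---------------------------------------------------------------------------
# file dialects


def _default_design(T: int, histories: Sequence[CaptureHistory]) -> StudyDesign:
    # tau inferred as the earliest wild first-capture (or 2 when no wild
    # individuals are present); unit monthly spacing by default.
    wild_f = [h.first_capture for h in histories if h.origin == ORIGIN_WILD]
    tau = min(wild_f) if wild_f else 2
    groups = tuple(sorted({h.group for h in histories if h.group is not None}))
    return StudyDesign(
        n_occasions=T,
        occasion_times=np.arange(T, dtype=float),
        tau=max(2, tau),
        groups=groups,
    )


def read_histories(
    path: str | Path,
    dialect: str = "csv",
    design: StudyDesign | None = None,
) -> CaptureData:
    """Read capture histories from ``path`` in the given dialect.

    When ``design`` is None a minimal design is inferred from the file
    (T from history length, ``tau`` from the earliest wild first capture,
    unit monthly spacing); pass an explicit design — e.g. from
    :func:`read_design` — whenever real occasion timing matters.
    """
    path = Path(path)
    if dialect == "csv":
        histories, T = _read_csv(path)
    elif dialect == "inp":
        histories, T = _read_inp(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if design is None:
        design = _default_design(T, histories)
    return CaptureData(design, histories)


def _read_csv(path: Path) -> tuple[list[CaptureHistory], int]:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    occ_cols = [c for c in df.columns if re.fullmatch(r"occ\d+", c)]
    expected = {"id", "origin", "group"}
    if not expected.issubset(df.columns) or not occ_cols:
        raise ParseError(
            f"{path}: CSV dialect requires header id,origin,group,occ1..occT"
        )
    occ_cols = sorted(occ_cols, key=lambda c: int(c[3:]))
    histories = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        values = [getattr(row, c) for c in occ_cols]
        if any(v not in ("0", "1") for v in values):
            raise ParseError(
                f"{path}, line {row_no}: occasion values must be '0' or '1'"
            )
        group = getattr(row, "group")
        group = None if pd.isna(group) or group == "" else str(group)
        try:
            histories.append(
                CaptureHistory(
                    individual_id=str(row.id),
                    origin=str(row.origin),
                    detections=np.array(values, dtype=np.int8),
                    group=group,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {row_no}: {exc}") from exc
    return histories, len(occ_cols)


_INP_LINE = re.compile(r"^([01]+)\s+(\d+)(?:\s+(\d+))?\s*;$")


def _read_inp(path: Path) -> tuple[list[CaptureHistory], int]:
    text = re.sub(r"/\*.*?\*/", "", path.read_text(), flags=re.S)
    histories: list[CaptureHistory] = []
    T: int | None = None
    counter = 0
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _INP_LINE.match(line)
        if m is None:
            raise ParseError(
                f"{path}, line {line_no}: expected '<history> <freq_trans> "
                f"<freq_wild>;', got {raw!r}"
            )
        hist = m.group(1)
        if m.group(3) is None:
            # plain single-frequency MARK line: a release-occasion detection
            # identifies a translocated animal, so origin follows x_1
            if hist[0] == "1":
                n_trans, n_wild = int(m.group(2)), 0
            else:
                n_trans, n_wild = 0, int(m.group(2))
        else:
            n_trans, n_wild = int(m.group(2)), int(m.group(3))
        if T is None:
            T = len(hist)
        elif len(hist) != T:
            raise ParseError(
                f"{path}, line {line_no}: history length {len(hist)} != {T}"
            )
        det = np.frombuffer(hist.encode(), dtype=np.uint8) - ord("0")
        for origin, count in (
            (ORIGIN_TRANSLOCATED, n_trans),
            (ORIGIN_WILD, n_wild),
        ):
            for _ in range(count):
                counter += 1
                try:
                    histories.append(
                        CaptureHistory(f"ind{counter:05d}", origin, det.copy())
                    )
                except ValidationError as exc:
                    raise ValidationError(
                        f"{path}, line {line_no}: {exc}"
                    ) from exc
    if T is None:
        raise ParseError(f"{path}: no records found")
    return histories, T


def write_histories(data: CaptureData, path: str | Path, dialect: str = "csv") -> None:
    """Write histories to ``path``; round-trips with :func:`read_histories`.

    The ``inp`` dialect aggregates identical (history, origin) rows into
    frequency counts and does not preserve individual ids or group labels.
    """
    path = Path(path)
    if dialect == "csv":
        T = data.design.n_occasions
        rows = {
            "id": [h.individual_id for h in data.histories],
            "origin": [h.origin for h in data.histories],
            "group": [h.group if h.group is not None else "" for h in data.histories],
        }
        det = data.detection_matrix()
        for j in range(T):
            rows[f"occ{j + 1}"] = det[:, j] if data.histories else []
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "inp":
        counts: dict[str, list[int]] = {}
        for h in data.histories:
            key = "".join(map(str, h.detections))
            freq = counts.setdefault(key, [0, 0])
            freq[0 if h.origin == ORIGIN_TRANSLOCATED else 1] += 1
        with open(path, "w") as fh:
            for key in sorted(counts):
                n_trans, n_wild = counts[key]
                fh.write(f"{key} {n_trans} {n_wild};\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design from a YAML key-value file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cov = doc.get("covariates")
    times = doc["occasion_times_months"]
    if isinstance(times, str):
        times = [float(v) for v in times.split(",")]
    T = int(doc["T"])
    covariates = None
    if cov:
        covariates = pd.DataFrame(cov, index=pd.RangeIndex(1, T + 1))
    return StudyDesign(
        n_occasions=T,
        occasion_times=np.asarray(times, dtype=float),
        tau=int(doc["tau"]),
        groups=tuple(doc.get("groups", ())),
        covariates=covariates,
    )


def write_design(design: StudyDesign, path: str | Path) -> None:
    doc: dict = {
        "T": int(design.n_occasions),
        "occasion_times_months": [float(t) for t in design.occasion_times],
        "tau": int(design.tau),
    }
    if design.groups:
        doc["groups"] = list(design.groups)
    if design.covariates is not None:
        doc["covariates"] = {
            c: [float(v) for v in design.covariates[c]]
            for c in design.covariates.columns
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def summarize(data: CaptureData) -> pd.DataFrame:
    """Per-occasion capture and first-capture counts.

    Returns a table indexed by occasion with columns ``captures``,
    ``first_captures`` and ``months_since_release``; first-capture counts
    sum to D over occasions.
    """
    T = data.design.n_occasions
    det = data.detection_matrix()
    captures = det.sum(axis=0) if len(det) else np.zeros(T, int)
    first = np.zeros(T, dtype=int)
    for h in data.histories:
        first[h.first_capture - 1] += 1
    return pd.DataFrame(
        {
            "captures": captures,
            "first_captures": first,
            "months_since_release": data.design.occasion_times,
        },
        index=pd.RangeIndex(1, T + 1, name="occasion"),
    )
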