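"""Packaged study data and the through-line selection procedure.

The study asked six individual creators and one musical group to produce
a creative work (music, prose, poetry, visual art) inspired by a
Paleolithic zoomorphic figurine, and to describe their creative process.
Three process descriptions were returned (the group SLT, writer SW and
musician WC).  Thematic coding of those descriptions — a human
procedure, outside this package — yields a boolean creators × themes
presence matrix over four candidate through-lines:

- ``LH`` lion-human hybrid,
- ``S``  subtractive sculpting / negative space,
- ``D``  deterioration / erosion by natural forces,
- ``W``  waiting to be found (with a story to tell).

A *through-line* is a thread of continuity between inspirational source
and creative output.  The selection rule keeps themes appearing in at
least ``min_count`` descriptions, plus an explicit ``retained`` set for
themes kept on qualitative grounds (here S: present only in the music,
but not straightforwardly implementable in any other domain and central
to the group's output).  The selected through-lines drive
:func:`build_lineage_fixture`, which emits the six-step lineage from
carver to creator to audience consumed by :mod:`rafnet.lineage`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from rafnet.lineage import LineageEvent

__all__ = [
    "ParticipantRecord",
    "ThemeMatrix",
    "load_participants",
    "load_theme_matrix",
    "count_participant_entities",
    "count_descriptions_with_theme",
    "select_through_lines",
    "build_lineage_fixture",
]


@dataclass(frozen=True)
class ParticipantRecord:
    """One roster entry: an individual artist or a named group.

    Demographics (age, nationality, experience lower bound) are carried
    for fidelity but not used by any computation.
    """

    code: str
    medium: str
    age: int | None = None
    nationality: str | None = None
    experience_years: int | None = None
    group_members: tuple[str, ...] = ()
    provided_description: bool = False

    @property
    def is_group(self) -> bool:
        return bool(self.group_members)


@dataclass(frozen=True)
class ThemeMatrix:
    """Creators × themes boolean presence matrix."""

    creators: tuple[str, ...]
    themes: tuple[str, ...]
    present: tuple[tuple[bool, ...], ...]  # one row per theme
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.present) != len(self.themes):
            raise ValueError("one presence row per theme required")
        for row in self.present:
            if len(row) != len(self.creators):
                raise ValueError("presence row width must match creators")

    def as_array(self) -> np.ndarray:
        return np.array(self.present, dtype=bool)


def _read_rows(path: Path | None, default: str) -> list[dict[str, str]]:
    if path is None:
        text = (resources.files("rafnet.data") / default).read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def _opt(cell: str) -> str | None:
    cell = cell.strip()
    return None if cell in ("", "-") else cell


def load_participants(path: Path | None = None) -> list[ParticipantRecord]:
    """Load the participant roster (packaged fixture by default).

    Rows whose ``group`` column names another code are that group's
    members; the group's own row carries no demographics and its
    ``group_members`` are assembled from the member rows.
    """
    rows = _read_rows(path, "participants.tsv")
    members: dict[str, list[str]] = {}
    for row in rows:
        g = _opt(row.get("group", "-") or "-")
        if g:
            members.setdefault(g, []).append(row["code"].strip())
    records = []
    for row in rows:
        code = row["code"].strip()
        age = _opt(row.get("age", "-") or "-")
        exp = _opt(row.get("experience_years", "-") or "-")
        records.append(ParticipantRecord(
            code=code,
            medium=row["medium"].strip(),
            age=int(age) if age else None,
            nationality=_opt(row.get("nationality", "-") or "-"),
            experience_years=int(exp) if exp else None,
            group_members=tuple(members.get(code, ())),
            provided_description=(row.get("provided_description", "-") or
                                  "-").strip() == "yes"))
    codes = [r.code for r in records]
    if len(codes) != len(set(codes)):
        raise ValueError("duplicate participant codes in roster")
    return records


def load_theme_matrix(path: Path | None = None) -> ThemeMatrix:
    """Load the through-line presence matrix (packaged fixture by default)."""
    rows = _read_rows(path, "themes.tsv")
    if not rows:
        raise ValueError("empty theme matrix")
    creators = tuple(k for k in rows[0] if k not in ("theme", "label"))
    themes, present, labels = [], [], {}
    for row in rows:
        themes.append(row["theme"].strip())
        labels[row["theme"].strip()] = (row.get("label") or "").strip()
        marks = []
        for c in creators:
            mark = row[c].strip()
            if mark not in ("+", "-"):
                raise ValueError(f"theme {row['theme']!r}, creator {c!r}: "
                                 f"entry must be + or -, got {mark!r}")
            marks.append(mark == "+")
        present.append(tuple(marks))
    return ThemeMatrix(creators, tuple(themes), tuple(present), labels)


def count_participant_entities(records: Iterable[ParticipantRecord]) -> int:
    """Number of participant entities: each individual counts 1, a group
    with listed members counts 1 and its members are excluded."""
    records = list(records)
    member_codes = {m for r in records for m in r.group_members}
    count = 0
    for r in records:
        if r.is_group:
            count += 1
        elif r.code in member_codes:
            continue  # counted through the group
        else:
            count += 1
    overlap = member_codes & {r.code for r in records if r.is_group}
    if overlap:
        raise ValueError(f"codes are both group and member: {sorted(overlap)}")
    return count


def count_descriptions_with_theme(matrix: ThemeMatrix, theme: str) -> int:
    """How many creators' process descriptions contain the theme."""
    if theme not in matrix.themes:
        raise ValueError(f"unknown theme {theme!r}")
    row = matrix.present[matrix.themes.index(theme)]
    return sum(row)


def select_through_lines(matrix: ThemeMatrix,
                         min_count: int = 2,
                         retained: Iterable[str] = ()) -> list[str]:
    """Themes present in at least ``min_count`` descriptions, plus the
    explicitly retained ones, in matrix row order.

    ``retained`` expresses the qualitative exception under which a theme
    below threshold is still kept as a through-line; passing the empty
    set gives the plain multiplicity rule.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    retained = frozenset(retained)
    missing = retained - set(matrix.themes)
    if missing:
        raise ValueError(f"retained themes not in matrix: {sorted(missing)}")
    return [t for t in matrix.themes
            if count_descriptions_with_theme(matrix, t) >= min_count
            or t in retained]


# ---------------------------------------------------------------------------
# the six-step lineage

TEACHER = "g"   # the creator's (music) teacher
CARVER = "h"    # the individual who carved the figurine, long ago


def build_lineage_fixture(through_lines: Sequence[str],
                          creator: str = "i",
                          audience: Sequence[str] = ("j",),
                          ) -> list[LineageEvent]:
    """Emit the six-step cross-domain-transfer lineage for one creator.

    1. *Social background knowledge*: domain knowledge M flows from a
       teacher g to the creator (the teacher's own acquisition is an
       individual-learning event in the same step — every social
       transmission is preceded somewhere in the lineage by individual
       learning or creative thought of the transmitted content).
    2. *Building on social learning*: practice and experimentation add
       individually learned knowledge Mp, and the catalyst n — domain
       knowledge together with the desire to express the figurine in the
       creator's medium — enters the creator's foodset.
    3. *Through-line transmission*: each through-line T reaches the
       creator socially from the carver h (via the study pamphlet),
       F ↦ F ∪ {T_creator}.
    4. *Cross-domain transfer*: one catalyzed creative reaction per
       through-line, T →_n musT, each product entering ¬F.
    5. *Synthesis*: the musical forms combine in a single catalyzed
       reaction musT1 + ... + musTk →_n musL, the finished piece.
    6. *Cultural incorporation*: the piece is transmitted socially to
       each audience member j, entering F_j (the re-tag rule).

    With an empty audience step 6 is omitted and the lineage has five
    steps.  MR ids are suffixed with the owning individual's code.
    """
    through_lines = list(through_lines)
    if not through_lines:
        raise ValueError("at least one through-line required")
    c = creator
    n_i = f"n_{c}"
    events = [
        # step one: socially learned background knowledge
        LineageEvent(1, "individual", TEACHER, outputs=(f"M_{TEACHER}",)),
        LineageEvent(1, "social", c, outputs=(f"M_{c}",),
                     inputs=(f"M_{TEACHER}",), source=TEACHER),
        # step two: building on social learning
        LineageEvent(2, "individual", c, outputs=(f"Mp_{c}",)),
        LineageEvent(2, "individual", c, outputs=(n_i,)),
    ]
    for t in through_lines:
        events.append(LineageEvent(3, "individual", CARVER,
                                   outputs=(f"{t}_{CARVER}",)))
        events.append(LineageEvent(3, "social", c, outputs=(f"{t}_{c}",),
                                   inputs=(f"{t}_{CARVER}",), source=CARVER))
    for t in through_lines:
        events.append(LineageEvent(4, "creative", c,
                                   outputs=(f"mus{t}_{c}",),
                                   inputs=(f"{t}_{c}",), catalysts=(n_i,)))
    events.append(LineageEvent(
        5, "creative", c, outputs=(f"musL_{c}",),
        inputs=tuple(f"mus{t}_{c}" for t in through_lines),
        catalysts=(n_i,)))
    for member in audience:
        events.append(LineageEvent(6, "social", member,
                                   outputs=(f"musF_{member}",),
                                   inputs=(f"musL_{c}",), source=c))
    return events
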