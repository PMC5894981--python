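"""Stage alphabets, scoring-standard harmonisation, and clock conventions.

Hypnograms arrive coded under either the Rechtschaffen & Kales (R&K) or the
AASM standard.  Both are harmonised to a single five-letter canonical
alphabet: WASO (wake after sleep onset), S1, S2, SWS (slow-wave sleep,
merging R&K stages 3 and 4 / AASM N3) and REM.

Clock times are stored as minutes since 12:00 noon.  Typical lights-off
times (early evening through a little past midnight) are then monotone
increasing, so the bedtime exclusion window, which spans midnight, needs no
wrap-around logic.
"""

from __future__ import annotations

import numpy as np

#: Canonical stage order.  Integer codes used throughout the package are the
#: positions in this tuple (WASO=0 ... REM=4), matching the row/column order
#: of first-order transition matrices.
CANONICAL_STAGES: tuple[str, ...] = ("WASO", "S1", "S2", "SWS", "REM")

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(CANONICAL_STAGES)}

#: Sleep stages (canonical alphabet minus wake).
SLEEP_STAGES: tuple[str, ...] = ("S1", "S2", "SWS", "REM")

#: Raw alphabet accepted in hypnogram files.  MOV (movement time) and UNS
#: (unscored) have no stage of their own and are recoded contextually by
#: :func:`map_raw_stages`.
RAW_ALPHABET: tuple[str, ...] = ("W", "N1", "N2", "N3", "S3", "S4", "R", "MOV", "UNS")

#: Total mapping raw -> canonical for scoreable epochs.  R&K stages 3 and 4
#: and AASM N3 all collapse to SWS.
RAW_TO_CANONICAL: dict[str, str] = {
    "W": "WASO",
    "N1": "S1",
    "N2": "S2",
    "N3": "SWS",
    "S3": "SWS",
    "S4": "SWS",
    "R": "REM",
}

_CONTEXTUAL = frozenset({"MOV", "UNS"})


def map_raw_stages(raw: list[str]) -> tuple[list[str], int]:
    """Map a raw stage sequence to the canonical 5-letter alphabet.

    MOV/UNS epochs carry no stage information; each takes the preceding
    epoch's canonical stage (a leading run of them takes the first scoreable
    epoch's stage), which preserves bout continuity.  Canonical input passes
    through unchanged (the map is idempotent).

    Returns the canonical sequence and the number of recoded MOV/UNS epochs.
    """
    out: list[str] = []
    n_recode = 0
    pending = 0  # leading MOV/UNS epochs awaiting a stage
    for i, tok in enumerate(raw):
        if tok in _CONTEXTUAL:
            n_recode += 1
            if out:
                out.append(out[-1])
            else:
                pending += 1
            continue
        if tok in STAGE_INDEX:
            canon = tok
        else:
            try:
                canon = RAW_TO_CANONICAL[tok]
            except KeyError:
                raise ValueError(f"unknown stage code {tok!r} at epoch {i}") from None
        if pending:
            out.extend([canon] * pending)
            pending = 0
        out.append(canon)
    if pending:
        raise ValueError("hypnogram contains only MOV/UNS epochs")
    return out, n_recode


def encode_stages(stages: list[str]) -> np.ndarray:
    """Canonical labels -> int8 codes (WASO=0 ... REM=4)."""
    try:
        return np.array([STAGE_INDEX[s] for s in stages], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-canonical stage label {e.args[0]!r}") from None


def decode_stages(codes: np.ndarray) -> list[str]:
    return [CANONICAL_STAGES[int(c)] for c in codes]


def parse_clock(text: str) -> float:
    """Parse 'HH:MM' (24 h) into minutes since 12:00 noon, in [0, 1440)."""
    try:
        hh, mm = text.strip().split(":")
        h, m = int(hh), int(mm)
    except (ValueError, AttributeError):
        raise ValueError(f"invalid clock time {text!r}") from None
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"invalid clock time {text!r}")
    return float((h * 60 + m - 720) % 1440)


def format_clock(minutes_since_noon: float) -> str:
    """Inverse of :func:`parse_clock` (minutes rounded)."""
    total = (int(round(minutes_since_noon)) + 720) % 1440
    return f"{total // 60:02d}:{total % 60:02d}"
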