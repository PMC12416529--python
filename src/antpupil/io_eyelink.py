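"""Minimal EyeLink ASC dialect: parsing, writing, and trial-window extraction.

The dialect covers the lines the pupillometry pipeline actually consumes:

* ``SAMPLE`` lines — ``<time>\t<gx>\t<gy>\t<pupil>`` with ``.`` as the
  missing-pupil token (blinks leave gaps in the pupil column);
* ``SBLINK``/``EBLINK`` and ``SSACC``/``ESACC`` event pairs (one eye);
* ``MSG`` lines carrying trial markers.

Times are milliseconds on a 2 ms sampling grid (500 Hz). Missing pupil
samples are represented internally as NaN — explicitly marked, never
dropped, because the blink-interpolation stage needs the gaps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING_TOKEN = "."

CUE_TYPES = ("none", "center", "spatial")
TARGET_TYPES = ("congruent", "incongruent")

#: fixed trial duration (ms) and cue→target gap (100 ms cue + 400 ms fixation)
TRIAL_DURATION_MS = 4000.0
CUE_TO_TARGET_MS = 500.0
MAX_RT_MS = 1700.0
SAMPLE_STEP_MS = 2.0


class AscFormatError(ValueError):
    """Raised when a stream has no parsable samples."""


class AscIntegrityError(ValueError):
    """Raised when parsed sample timestamps are not strictly increasing."""


@dataclass
class EyeSession:
    """One continuous eye-tracking recording (single eye, 500 Hz)."""

    sample_times: np.ndarray          # ms, strictly increasing
    pupil: np.ndarray                 # AU; NaN marks missing samples
    gaze: np.ndarray                  # (n, 2) screen pixels
    blinks: list[tuple[float, float]] = field(default_factory=list)
    saccades: list[tuple[float, float]] = field(default_factory=list)
    messages: list[tuple[float, str]] = field(default_factory=list)
    n_unparsed: int = 0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze = np.asarray(self.gaze, dtype=float).reshape(-1, 2)
        if self.sample_times.size == 0:
            raise AscFormatError("session has no samples")
        if np.any(np.diff(self.sample_times) <= 0):
            raise AscIntegrityError("sample timestamps not strictly increasing")
        span = (self.sample_times[0], self.sample_times[-1] + SAMPLE_STEP_MS)
        for name in ("blinks", "saccades"):
            for s, e in getattr(self, name):
                if e < s or s < span[0] or e > span[1]:
                    raise AscIntegrityError(
                        f"{name} event ({s}, {e}) outside recording span {span}"
                    )

    @property
    def n_samples(self) -> int:
        return int(self.sample_times.size)


@dataclass
class TrialRecord:
    """One ANT trial: condition labels, event times (ms, absolute), response.

    ``cue_onset`` is virtual for no-cue trials (``target_onset - 500``) so the
    cue-aligned timeline is defined for every trial. ``response_time`` is the
    absolute time of the button press; ``rt`` is relative to target onset.
    """

    index: int
    cue_type: str
    target_type: str
    fixation_duration: float
    cue_onset: float
    target_onset: float
    rt: float | None = None
    response_time: float | None = None
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.cue_type not in CUE_TYPES:
            raise ValueError(f"unknown cue type {self.cue_type!r}")
        if self.target_type not in TARGET_TYPES:
            raise ValueError(f"unknown target type {self.target_type!r}")
        if abs((self.target_onset - self.cue_onset) - CUE_TO_TARGET_MS) > 1e-9:
            raise ValueError("target_onset - cue_onset must be exactly 500 ms")
        if self.rt is not None and not (0 < self.rt <= MAX_RT_MS):
            raise ValueError(f"rt {self.rt} outside (0, {MAX_RT_MS}] ms")

    @property
    def start(self) -> float:
        """Trial window start: cue onset minus the initial fixation."""
        return self.cue_onset - self.fixation_duration

    @property
    def end(self) -> float:
        return self.start + TRIAL_DURATION_MS

    @property
    def condition(self) -> tuple[str, str]:
        return (self.cue_type, self.target_type)


@dataclass
class TrialTrace:
    """A single trial's raw pupil trace cut from the continuous recording."""

    trial: TrialRecord
    times: np.ndarray                 # absolute ms
    pupil: np.ndarray                 # AU, NaN = missing
    blinks: list[tuple[float, float]]
    missing_data: bool                # trial window not fully covered


# ---------------------------------------------------------------------------
# parsing / writing


def _fmt(x: float) -> str:
    xf = float(x)
    return str(int(xf)) if xf.is_integer() else repr(xf)


def parse_asc(stream: str | io.TextIOBase) -> EyeSession:
    """Parse the ASC dialect into an :class:`EyeSession`.

    Unparseable lines are counted in ``n_unparsed`` and otherwise ignored;
    a stream with no SAMPLE lines raises :class:`AscFormatError`.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    times: list[float] = []
    pupil: list[float] = []
    gaze: list[tuple[float, float]] = []
    blinks: list[tuple[float, float]] = []
    saccades: list[tuple[float, float]] = []
    messages: list[tuple[float, str]] = []
    n_unparsed = 0

    for line in lines:
        line = line.strip()
        if not line or line.startswith(("**", "#")):
            continue
        tok = line.split()
        try:
            if tok[0] == "MSG":
                messages.append((float(tok[1]), " ".join(tok[2:])))
            elif tok[0] == "EBLINK":
                blinks.append((float(tok[2]), float(tok[3])))
            elif tok[0] == "ESACC":
                saccades.append((float(tok[2]), float(tok[3])))
            elif tok[0] in ("SBLINK", "SSACC"):
                continue  # interval recorded at the matching E* line
            else:
                t = float(tok[0])
                gx, gy = float(tok[1]), float(tok[2])
                p = np.nan if tok[3] == MISSING_TOKEN else float(tok[3])
                times.append(t)
                gaze.append((gx, gy))
                pupil.append(p)
        except (IndexError, ValueError):
            n_unparsed += 1

    if not times:
        raise AscFormatError("no SAMPLE lines found")
    return EyeSession(
        sample_times=np.array(times),
        pupil=np.array(pupil),
        gaze=np.array(gaze),
        blinks=blinks,
        saccades=saccades,
        messages=messages,
        n_unparsed=n_unparsed,
    )


def write_asc(session: EyeSession) -> str:
    """Emit a stream that :func:`parse_asc` reparses to an identical session.

    Events are emitted as S*/E* pairs interleaved before the first sample at
    or after the event start, mimicking the EyeLink file layout.
    """
    out: list[str] = ["** ANT pupil session export"]
    events: list[tuple[float, str]] = []
    for t, text in session.messages:
        events.append((t, f"MSG\t{_fmt(t)}\t{text}"))
    for s, e in session.blinks:
        events.append((s, f"SBLINK R {_fmt(s)}"))
        events.append((e, f"EBLINK R {_fmt(s)} {_fmt(e)}"))
    for s, e in session.saccades:
        events.append((s, f"SSACC R {_fmt(s)}"))
        events.append((e, f"ESACC R {_fmt(s)} {_fmt(e)}"))
    events.sort(key=lambda x: x[0])

    ev_i = 0
    for i in range(session.n_samples):
        t = session.sample_times[i]
        while ev_i < len(events) and events[ev_i][0] <= t:
            out.append(events[ev_i][1])
            ev_i += 1
        p = session.pupil[i]
        ptok = MISSING_TOKEN if np.isnan(p) else repr(float(p))
        out.append(
            f"{_fmt(t)}\t{repr(float(session.gaze[i, 0]))}\t"
            f"{repr(float(session.gaze[i, 1]))}\t{ptok}"
        )
    for _, line in events[ev_i:]:
        out.append(line)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# trial tables (TSV)

_TRIAL_COLUMNS = [
    "index", "cue_type", "target_type", "fixation_duration",
    "cue_onset", "target_onset", "rt", "response_time", "correct",
]


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "index": t.index,
            "cue_type": t.cue_type,
            "target_type": t.target_type,
            "fixation_duration": t.fixation_duration,
            "cue_onset": t.cue_onset,
            "target_onset": t.target_onset,
            "rt": np.nan if t.rt is None else t.rt,
            "response_time": np.nan if t.response_time is None else t.response_time,
            "correct": t.correct,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    trials = []
    for _, r in df.iterrows():
        trials.append(
            TrialRecord(
                index=int(r["index"]),
                cue_type=str(r["cue_type"]),
                target_type=str(r["target_type"]),
                fixation_duration=float(r["fixation_duration"]),
                cue_onset=float(r["cue_onset"]),
                target_onset=float(r["target_onset"]),
                rt=None if pd.isna(r["rt"]) else float(r["rt"]),
                response_time=None if pd.isna(r["response_time"]) else float(r["response_time"]),
                correct=None if pd.isna(r["correct"]) else bool(r["correct"]),
            )
        )
    return trials


def read_trials_tsv(path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path, sep="\t"))


def write_trials_tsv(trials: list[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trial-window extraction


def clip_intervals(
    intervals: list[tuple[float, float]], lo: float, hi: float
) -> list[tuple[float, float]]:
    """Intersect each (start, end) interval with [lo, hi); drop empties."""
    out = []
    for s, e in intervals:
        cs, ce = max(s, lo), min(e, hi)
        if ce > cs:
            out.append((cs, ce))
    return out


def extract_trial_traces(
    session: EyeSession, trials: list[TrialRecord]
) -> list[TrialTrace]:
    """Cut the continuous recording into per-trial 4000 ms pupil traces.

    Each trial's half-open window ``[start, start + 4000)`` should yield
    2000 samples at 500 Hz; a window not fully covered by the recording is
    returned truncated with ``missing_data=True`` (it then fails pupil QC
    rather than aborting the run).
    """
    traces = []
    expected = int(round(TRIAL_DURATION_MS / SAMPLE_STEP_MS))
    for tr in trials:
        i0 = int(np.searchsorted(session.sample_times, tr.start, side="left"))
        i1 = int(np.searchsorted(session.sample_times, tr.end, side="left"))
        times = session.sample_times[i0:i1]
        missing = times.size != expected
        traces.append(
            TrialTrace(
                trial=tr,
                times=times,
                pupil=session.pupil[i0:i1].copy(),
                blinks=clip_intervals(session.blinks, tr.start, tr.end),
                missing_data=missing,
            )
        )
    return traces
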