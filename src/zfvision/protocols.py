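"""Illumination schedules for larval zebrafish behavioral assays.

An :class:`AssayProtocol` is an ordered, contiguous list of
:class:`LightEpoch` objects that together partition the recording
``[0, total_duration_s]``.  Light transitions (abrupt intensity changes at
epoch boundaries) anchor the analysis windows of the visual motor response
(VMR) and flash-stimulus threshold response (FSTR) assays.

Time origin: ``t = 0`` is the start of the recording.  Any out-of-tank
dark/light adaptation preceding the recording is carried as metadata
(``adaptation_s``) and contributes no epochs; only in-recording
pre-illumination periods (e.g. the 30 min of darkness before the first VMR
light-ON step) are epochs.

Intensities are percent of the enclosure maximum (100% is nominally
8,000 lux); only relative percent matters downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "LightEpoch",
    "Transition",
    "AssayProtocol",
    "ScheduleAlignmentError",
    "make_vmr_protocol",
    "make_fstr_protocol",
    "make_freeswim_protocol",
    "transitions",
]

#: Absolute time tolerance for epoch-contiguity checks (one millisecond).
TIME_TOL_S = 1e-3


class ScheduleAlignmentError(ValueError):
    """Raised when epoch boundaries do not land on acquisition-bin edges."""


@dataclass(frozen=True)
class LightEpoch:
    """A constant-intensity stretch of the illumination schedule."""

    start_s: float
    duration_s: float
    intensity_pct: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError(f"epoch duration must be > 0, got {self.duration_s}")
        if not 0.0 <= self.intensity_pct <= 100.0:
            raise ValueError(
                f"intensity_pct must lie in [0, 100], got {self.intensity_pct}"
            )

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class Transition:
    """An abrupt intensity change at an epoch boundary.

    ``direction`` is ``"ON"`` iff ``to_pct > from_pct``.
    """

    time_s: float
    direction: str
    from_pct: float
    to_pct: float

    def __post_init__(self) -> None:
        expected = "ON" if self.to_pct > self.from_pct else "OFF"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with intensity change "
                f"{self.from_pct} -> {self.to_pct}"
            )


_KNOWN_NAMES = {
    "freeswim_light",
    "freeswim_dark",
    "vmr",
    "vmr_mesopic",
    "fstr",
    "color_maze",
}


@dataclass(frozen=True)
class AssayProtocol:
    """An assay's full illumination schedule plus acquisition metadata.

    Parameters
    ----------
    name
        Assay label; conventionally one of ``freeswim_light``,
        ``freeswim_dark``, ``vmr``, ``vmr_mesopic``, ``fstr``, ``color_maze``.
    epochs
        Ordered, contiguous, non-overlapping epochs starting at ``t = 0``.
    bin_s
        Acquisition bin length in seconds (1, 10, 60 or 300 in practice).
    adaptation_s
        Pre-recording adaptation time; metadata only.
    adaptation_intensity_pct
        Illumination during the pre-recording adaptation (default 0,
        i.e. dark adaptation).  If the first epoch's intensity differs,
        ``t = 0`` itself counts as a transition.
    """

    name: str
    epochs: tuple[LightEpoch, ...]
    bin_s: float = 1.0
    adaptation_s: float = 0.0
    adaptation_intensity_pct: float = 0.0

    def __post_init__(self) -> None:
        epochs = tuple(self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValueError("protocol needs at least one epoch")
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if abs(epochs[0].start_s) > TIME_TOL_S:
            raise ValueError("first epoch must start at t = 0")
        for prev, cur in zip(epochs, epochs[1:]):
            if abs(cur.start_s - prev.end_s) > TIME_TOL_S:
                raise ValueError(
                    f"epochs not contiguous at t = {prev.end_s:g} s "
                    f"(next starts at {cur.start_s:g} s)"
                )

    @property
    def total_duration_s(self) -> float:
        return self.epochs[-1].end_s

    def intensity_at(self, t_s: float) -> float:
        """Illumination percent at time ``t_s`` (right-open epochs)."""
        if not 0.0 <= t_s <= self.total_duration_s:
            raise ValueError(f"t = {t_s} s outside the recording")
        for ep in self.epochs:
            if ep.start_s <= t_s < ep.end_s:
                return ep.intensity_pct
        return self.epochs[-1].intensity_pct

    def validate_bin_alignment(self) -> None:
        """Require every epoch boundary to land on an acquisition-bin edge."""
        for ep in self.epochs:
            for t in (ep.start_s, ep.end_s):
                if abs(t / self.bin_s - round(t / self.bin_s)) * self.bin_s > TIME_TOL_S:
                    raise ScheduleAlignmentError(
                        f"epoch boundary at t = {t:g} s does not land on the "
                        f"{self.bin_s:g} s bin grid"
                    )

    def transitions(self) -> list[Transition]:
        """All abrupt intensity changes, sorted by time.

        One :class:`Transition` per adjacent epoch pair with unequal
        intensity, plus one at ``t = 0`` when the first epoch's intensity
        differs from the adaptation intensity (e.g. a flash presented to a
        dark-adapted larva at recording start).
        """
        out: list[Transition] = []
        first = self.epochs[0]
        if first.intensity_pct != self.adaptation_intensity_pct:
            direction = (
                "ON" if first.intensity_pct > self.adaptation_intensity_pct else "OFF"
            )
            out.append(
                Transition(
                    time_s=0.0,
                    direction=direction,
                    from_pct=self.adaptation_intensity_pct,
                    to_pct=first.intensity_pct,
                )
            )
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if cur.intensity_pct != prev.intensity_pct:
                direction = "ON" if cur.intensity_pct > prev.intensity_pct else "OFF"
                out.append(
                    Transition(
                        time_s=cur.start_s,
                        direction=direction,
                        from_pct=prev.intensity_pct,
                        to_pct=cur.intensity_pct,
                    )
                )
        return out

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, stream=None) -> str | None:
        doc = {
            "name": self.name,
            "adaptation_s": float(self.adaptation_s),
            "adaptation_intensity_pct": float(self.adaptation_intensity_pct),
            "bin_s": float(self.bin_s),
            "epochs": [
                [float(e.start_s), float(e.duration_s), float(e.intensity_pct)]
                for e in self.epochs
            ],
        }
        return yaml.safe_dump(doc, stream, sort_keys=False)

    @classmethod
    def from_yaml(cls, source) -> "AssayProtocol":
        if isinstance(source, (str, bytes)) and "\n" not in str(source) and ":" not in str(source):
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        elif isinstance(source, io.IOBase):
            doc = yaml.safe_load(source)
        else:
            doc = yaml.safe_load(source)
        epochs = tuple(LightEpoch(s, d, i) for s, d, i in doc["epochs"])
        return cls(
            name=doc["name"],
            epochs=epochs,
            bin_s=float(doc.get("bin_s", 1.0)),
            adaptation_s=float(doc.get("adaptation_s", 0.0)),
            adaptation_intensity_pct=float(doc.get("adaptation_intensity_pct", 0.0)),
        )


def transitions(protocol: AssayProtocol) -> list[Transition]:
    """Functional alias for :meth:`AssayProtocol.transitions`."""
    return protocol.transitions()


def make_vmr_protocol(
    n_trials: int = 3,
    on_intensity_pct: float = 30.0,
    pre_dark_min: float = 30.0,
    bin_s: float = 1.0,
    *,
    adaptation_s: float = 2 * 3600.0,
    name: str | None = None,
) -> AssayProtocol:
    """Standard visual motor response schedule.

    ``pre_dark_min`` minutes of darkness, then ``n_trials`` repeats of
    30 min light-ON (at ``on_intensity_pct``) followed by 30 min light-OFF.
    The default 3-trial, 30-min pre-dark schedule is 3.5 h of tracking; the
    mesopic variant (2 trials at 5%) is 2.5 h.
    """
    if n_trials not in (2, 3):
        raise ValueError("n_trials must be 2 or 3")
    if pre_dark_min < 0:
        raise ValueError("pre_dark_min must be >= 0")
    half_s = 30 * 60.0
    epochs: list[LightEpoch] = []
    t = 0.0
    if pre_dark_min > 0:
        epochs.append(LightEpoch(t, pre_dark_min * 60.0, 0.0))
        t += pre_dark_min * 60.0
    for _ in range(n_trials):
        epochs.append(LightEpoch(t, half_s, on_intensity_pct))
        t += half_s
        epochs.append(LightEpoch(t, half_s, 0.0))
        t += half_s
    if name is None:
        name = "vmr_mesopic" if on_intensity_pct <= 5 else "vmr"
    proto = AssayProtocol(
        name=name, epochs=tuple(epochs), bin_s=bin_s, adaptation_s=adaptation_s
    )
    proto.validate_bin_alignment()
    return proto


def make_fstr_protocol(
    cue_lengths_ms=(10, 20, 50, 100, 250, 500, 1000),
    rest_min: float = 20.0,
    order: str = "forward",
    *,
    pre_dark_min: float = 0.0,
    flash_intensity_pct: float = 30.0,
    bin_s: float = 1.0,
    adaptation_s: float = 2 * 3600.0,
) -> AssayProtocol:
    """Flash-stimulus threshold response schedule.

    Alternates a brief light cue (default 30%) with ``rest_min`` minutes of
    darkness.  ``order="reverse"`` presents the cue lengths in reverse so
    forward/reverse runs can be averaged to cancel habituation.
    ``pre_dark_min`` adds an in-recording dark period before the first cue
    (needed when pre-flash analysis windows must be recorded).

    Flash boundaries are generally not aligned to the acquisition bin grid
    (a 10 ms cue cannot be); downstream window extraction snaps to bin
    edges, and the final rest epoch is padded so the total recording is a
    whole number of bins.
    """
    cues = list(cue_lengths_ms)
    if not cues:
        raise ValueError("need at least one cue length")
    if any(c <= 0 for c in cues):
        raise ValueError("cue lengths must be positive")
    if rest_min <= 0:
        raise ValueError("rest_min must be > 0")
    if pre_dark_min < 0:
        raise ValueError("pre_dark_min must be >= 0")
    if order == "reverse":
        cues = cues[::-1]
    elif order != "forward":
        raise ValueError("order must be 'forward' or 'reverse'")
    epochs: list[LightEpoch] = []
    t = 0.0
    if pre_dark_min > 0:
        epochs.append(LightEpoch(t, pre_dark_min * 60.0, 0.0))
        t += pre_dark_min * 60.0
    for cue_ms in cues:
        cue_s = cue_ms / 1000.0
        epochs.append(LightEpoch(t, cue_s, flash_intensity_pct))
        t += cue_s
        epochs.append(LightEpoch(t, rest_min * 60.0, 0.0))
        t += rest_min * 60.0
    # pad the trailing rest so total duration lands on the bin grid
    pad = (-t) % bin_s
    if pad > TIME_TOL_S:
        last = epochs[-1]
        epochs[-1] = LightEpoch(last.start_s, last.duration_s + pad, last.intensity_pct)
    return AssayProtocol(
        name="fstr", epochs=tuple(epochs), bin_s=bin_s, adaptation_s=adaptation_s
    )


def make_freeswim_protocol(
    condition: str = "light",
    duration_min: float = 5.0,
    intensity_pct: float = 30.0,
    bin_s: float = 10.0,
    *,
    adaptation_s: float = 2 * 3600.0,
) -> AssayProtocol:
    """Constant-illumination spontaneous-swim schedule (light at 30% or dark)."""
    if condition not in ("light", "dark"):
        raise ValueError("condition must be 'light' or 'dark'")
    pct = intensity_pct if condition == "light" else 0.0
    proto = AssayProtocol(
        name=f"freeswim_{condition}",
        epochs=(LightEpoch(0.0, duration_min * 60.0, pct),),
        bin_s=bin_s,
        adaptation_s=adaptation_s,
        adaptation_intensity_pct=pct,
    )
    proto.validate_bin_alignment()
    return proto
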