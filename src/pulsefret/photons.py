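"""Photon-stream data model for pulsed-interleaved-excitation confocal data.

A measurement is a time-ordered list of detected photons.  Each photon
carries

* a *macrotime* (``timestamps``): integer clock ticks since the start of the
  experiment, at ``timestamp_resolution`` seconds per tick;
* a *microtime* (``nanotimes``): integer TCSPC channels since the last laser
  sync pulse, at ``nanotime_resolution`` seconds per channel.  With pulsed
  interleaved excitation (PIE) at 20 MHz the sync period is 50 ns, and the
  microtime encodes both the fluorescence decay and which laser (donor or
  acceptor) fired;
* a *detector* id.  Four single-photon detectors split the emission by
  polarization (parallel / perpendicular) and by color (donor / acceptor
  wavelength band).

The :class:`ChannelMap` records which detector plays which role and where the
two PIE excitation gates sit inside the sync period.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ChannelMap", "PhotonStream", "PHOTON_CLASSES"]

#: integer codes for (excitation gate -> detection color) photon classes
PHOTON_CLASSES = {"DD": 0, "DA": 1, "AA": 2, "AD": 3, "other": 4}


@dataclass(frozen=True)
class ChannelMap:
    """Detector roles and PIE excitation gates.

    Gates are half-open microtime windows in nanoseconds; together they must
    fit inside one PIE period without overlapping.
    """

    donor_parallel: int = 0
    donor_perpendicular: int = 1
    acceptor_parallel: int = 2
    acceptor_perpendicular: int = 3
    donor_gate_ns: tuple[float, float] = (0.0, 25.0)
    acceptor_gate_ns: tuple[float, float] = (25.0, 50.0)
    pie_period_ns: float = 50.0

    def __post_init__(self) -> None:
        d0, d1 = self.donor_gate_ns
        a0, a1 = self.acceptor_gate_ns
        if not (0 <= d0 < d1 <= self.pie_period_ns):
            raise ValueError(f"donor gate {self.donor_gate_ns} outside PIE period")
        if not (0 <= a0 < a1 <= self.pie_period_ns):
            raise ValueError(f"acceptor gate {self.acceptor_gate_ns} outside PIE period")
        if max(d0, a0) < min(d1, a1):
            raise ValueError("donor and acceptor PIE gates overlap")
        ids = {self.donor_parallel, self.donor_perpendicular,
               self.acceptor_parallel, self.acceptor_perpendicular}
        if len(ids) != 4:
            raise ValueError("detector ids must be distinct")

    @property
    def donor_channels(self) -> tuple[int, int]:
        return (self.donor_parallel, self.donor_perpendicular)

    @property
    def acceptor_channels(self) -> tuple[int, int]:
        return (self.acceptor_parallel, self.acceptor_perpendicular)

    @property
    def all_channels(self) -> tuple[int, ...]:
        return self.donor_channels + self.acceptor_channels

    def to_dict(self) -> dict:
        return {
            "donor_parallel": self.donor_parallel,
            "donor_perpendicular": self.donor_perpendicular,
            "acceptor_parallel": self.acceptor_parallel,
            "acceptor_perpendicular": self.acceptor_perpendicular,
            "donor_gate_ns": list(self.donor_gate_ns),
            "acceptor_gate_ns": list(self.acceptor_gate_ns),
            "pie_period_ns": self.pie_period_ns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMap":
        d = dict(d)
        for key in ("donor_gate_ns", "acceptor_gate_ns"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)


@dataclass
class PhotonStream:
    """Time-ordered photon events with macrotime, microtime and detector id."""

    timestamps: np.ndarray            # int64 ticks, nondecreasing
    nanotimes: np.ndarray             # int32 TCSPC channels
    detectors: np.ndarray             # uint8 detector ids
    timestamp_resolution: float = 12.5e-9   # s per tick (80 MHz clock)
    nanotime_resolution: float = 16e-12     # s per TCSPC channel
    channel_map: ChannelMap = field(default_factory=ChannelMap)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.nanotimes = np.asarray(self.nanotimes, dtype=np.int32)
        self.detectors = np.asarray(self.detectors, dtype=np.uint8)

    # -- basic queries ----------------------------------------------------
    @property
    def n_photons(self) -> int:
        return int(self.timestamps.size)

    @property
    def times_s(self) -> np.ndarray:
        """Macrotimes in seconds (float64)."""
        return self.timestamps * self.timestamp_resolution

    @property
    def nanotimes_ns(self) -> np.ndarray:
        """Microtimes in nanoseconds (float64)."""
        return self.nanotimes * (self.nanotime_resolution * 1e9)

    @property
    def duration_s(self) -> float:
        if self.n_photons == 0:
            return 0.0
        return float(self.timestamps[-1] * self.timestamp_resolution)

    def validate(self) -> None:
        """Raise ``ValueError`` on malformed streams.

        The error message names the first offending photon index.
        """
        n = self.n_photons
        if not (self.nanotimes.size == n and self.detectors.size == n):
            raise ValueError(
                f"array length mismatch: timestamps={n}, "
                f"nanotimes={self.nanotimes.size}, detectors={self.detectors.size}"
            )
        if n == 0:
            return
        bad = np.nonzero(np.diff(self.timestamps) < 0)[0]
        if bad.size:
            raise ValueError(
                f"timestamps not nondecreasing: first offending index {bad[0] + 1}"
            )
        period_ch = self.channel_map.pie_period_ns * 1e-9 / self.nanotime_resolution
        bad = np.nonzero((self.nanotimes < 0) | (self.nanotimes >= period_ch))[0]
        if bad.size:
            raise ValueError(
                f"nanotime outside PIE period: first offending index {bad[0]}"
            )
        known = set(self.channel_map.all_channels)
        bad = np.nonzero(~np.isin(self.detectors, sorted(known)))[0]
        if bad.size:
            raise ValueError(
                f"unmapped detector id {self.detectors[bad[0]]} at index {bad[0]}"
            )

    # -- PIE / channel classification -------------------------------------
    def excitation_gate_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean masks for donor-excitation and acceptor-excitation photons.

        Gates are resolved to integer TCSPC channels (truncation), so a
        boundary channel straddling a gate edge belongs to the later gate —
        consistent with how microtimes are quantized on acquisition.
        """
        res_ns = self.nanotime_resolution * 1e9
        d0, d1 = (int(x / res_ns) for x in self.channel_map.donor_gate_ns)
        a0, a1 = (int(x / res_ns) for x in self.channel_map.acceptor_gate_ns)
        nt = self.nanotimes
        return (nt >= d0) & (nt < d1), (nt >= a0) & (nt < a1)

    def photon_classes(self) -> np.ndarray:
        """Classify each photon as DD, DA, AA or AD (excitation -> detection).

        DD: donor excitation, donor emission; DA: donor excitation, acceptor
        emission; AA: acceptor excitation, acceptor emission; AD: acceptor
        excitation, donor emission (normally background only).
        """
        dex, aex = self.excitation_gate_masks()
        in_donor_ch = np.isin(self.detectors, self.channel_map.donor_channels)
        in_acc_ch = np.isin(self.detectors, self.channel_map.acceptor_channels)
        cls = np.full(self.n_photons, PHOTON_CLASSES["other"], dtype=np.int8)
        cls[dex & in_donor_ch] = PHOTON_CLASSES["DD"]
        cls[dex & in_acc_ch] = PHOTON_CLASSES["DA"]
        cls[aex & in_acc_ch] = PHOTON_CLASSES["AA"]
        cls[aex & in_donor_ch] = PHOTON_CLASSES["AD"]
        return cls

    def select(self, mask: np.ndarray) -> "PhotonStream":
        """Return a new stream containing the photons where ``mask`` is True."""
        return replace(
            self,
            timestamps=self.timestamps[mask],
            nanotimes=self.nanotimes[mask],
            detectors=self.detectors[mask],
            metadata=dict(self.metadata),
        )

    @classmethod
    def empty(cls, **kwargs) -> "PhotonStream":
        return cls(
            timestamps=np.empty(0, dtype=np.int64),
            nanotimes=np.empty(0, dtype=np.int32),
            detectors=np.empty(0, dtype=np.uint8),
            **kwargs,
        )
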